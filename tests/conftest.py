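import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from signrepo.network import DirectedSignedNetwork, EdgeType


def make_net(edges, extra_genes=()):
    """Build a network from (source, destination, type-label) triples."""
    net = DirectedSignedNetwork()
    for g in extra_genes:
        net.add_gene(g)
    for u, v, lab in edges:
        net.add_edge(u, v, EdgeType(lab))
    return net


@pytest.fixture
def branching_net():
    """T has two choices (out-degree 2): a direct neutral hop to G and a
    signed detour via A; A's only edge continues to G."""
    return make_net([
        ("T", "G", "neutral"),
        ("T", "A", "positive"),
        ("A", "G", "neutral"),
    ])


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A desk-scale planted-signal fixture, generated once and written to
    disk for pipeline tests: 1 disease, 40 drugs, 12 known."""
    from signrepo.simulate import FixtureSpec, generate_fixture, write_fixture

    spec = FixtureSpec(
        n_genes=240, n_drugs=40, n_diseases=1, n_known=12,
        genes_per_disease=(6, 10), seed=11,
    )
    fixture = generate_fixture(spec)
    directory = tmp_path_factory.mktemp("fixture")
    write_fixture(fixture, directory)
    return spec, fixture, directory
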