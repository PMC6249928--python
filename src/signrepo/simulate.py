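"""Seed-reproducible synthetic fixtures with a planted treatment signal.

The generator emulates the data model the pipeline consumes — a directed
gene network with three edge types, drugs with 1–5 typed targets, diseases
with gene sets, and known drug–disease associations — and plants the
opposite-regulation signal the method is built on: drugs known to treat a
disease are wired so that short net-negative paths run from their targets to
the disease genes, while all other drugs attach to the network uniformly.

Reproducibility: every entity draws from its own substream derived from the
global seed, so e.g. adding a drug does not perturb the network topology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .network import DirectedSignedNetwork, EdgeType
from .validate import ModuleCatalog
from .vectors import DrugTargetInteraction

__all__ = ["FixtureSpec", "Fixture", "generate_fixture", "write_fixture",
           "read_fixture", "planted_matrix"]

_TYPES = (EdgeType.POSITIVE, EdgeType.NEGATIVE, EdgeType.NEUTRAL)

# substream ids (second word of the seed sequence)
_S_NETWORK, _S_DISEASE, _S_DRUG, _S_PLANT, _S_MODULE, _S_NOISE = range(6)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study.

    Defaults describe a desk-scale study: a 600-gene network with mean
    out-degree 3 and a 1:1:2 positive:negative:neutral edge mix, 100 drugs
    with 1–5 targets each, 3 diseases with 8–15 genes, and 15 known
    (planted treating) drugs per disease.  ``signal_strength`` sets the
    planting rate (probability 1 − exp(−s) per target × disease-gene pair);
    ``noise_sd`` is the expected number of spurious random signed edges per
    drug target.
    """

    n_genes: int = 600
    mean_out_degree: float = 3.0
    edge_type_proportions: tuple[float, float, float] = (0.25, 0.25, 0.5)
    n_drugs: int = 100
    targets_per_drug: tuple[int, int] = (1, 5)
    n_diseases: int = 3
    genes_per_disease: tuple[int, int] = (8, 15)
    n_known: int = 15
    signal_strength: float = 1.0
    noise_sd: float = 0.1
    n_random_modules: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not math.isclose(sum(self.edge_type_proportions), 1.0, abs_tol=1e-9):
            raise ValueError("edge type proportions must sum to 1")
        for name in ("n_genes", "n_drugs", "n_diseases", "n_known"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_known > self.n_drugs:
            raise ValueError("more known drugs than drugs")
        lo, hi = self.targets_per_drug
        if not (1 <= lo <= hi):
            raise ValueError("invalid targets_per_drug range")
        # drugs take disjoint target blocks; diseases use the residual genes
        if self.n_genes < hi * self.n_drugs + self.genes_per_disease[1]:
            raise ValueError(
                "n_genes too small for disjoint drug-target blocks plus "
                "disease genes"
            )


@dataclass
class Fixture:
    spec: FixtureSpec
    network: DirectedSignedNetwork
    drug_targets: list[DrugTargetInteraction]
    disease_genes: dict[str, set[str]]
    known_associations: dict[str, set[str]]
    modules: ModuleCatalog


def _rng(spec: FixtureSpec, *stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, *stream])


def _sample_type(rng: np.random.Generator, props) -> EdgeType:
    return _TYPES[rng.choice(3, p=list(props))]


def generate_fixture(spec: FixtureSpec) -> Fixture:
    genes = [f"G{i:04d}" for i in range(spec.n_genes)]

    # -- network: directed preferential attachment on out-edges ------
    net = DirectedSignedNetwork()
    for g in genes:
        net.add_gene(g)
    rng = _rng(spec, _S_NETWORK)
    attach_weight = np.ones(spec.n_genes)  # degree + 1
    for i in range(1, spec.n_genes):
        m = max(1, rng.poisson(spec.mean_out_degree))
        w = attach_weight[:i] / attach_weight[:i].sum()
        targets = rng.choice(i, size=min(m, i), replace=False, p=w)
        for j in targets:
            # attachment is preferential; orientation is random so directed
            # paths exist both toward and away from early genes
            u, v = (genes[i], genes[j]) if rng.random() < 0.5 \
                else (genes[j], genes[i])
            net.add_edge(u, v, _sample_type(rng, spec.edge_type_proportions))
            attach_weight[j] += 1

    # -- drugs: disjoint target blocks, typed uniformly ---------------
    lo, hi = spec.targets_per_drug
    drugs = [f"DR{i:03d}" for i in range(spec.n_drugs)]
    drug_targets: list[DrugTargetInteraction] = []
    targets_of: dict[str, list[DrugTargetInteraction]] = {}
    for i, drug in enumerate(drugs):
        drng = _rng(spec, _S_DRUG, i)
        k = int(drng.integers(lo, hi + 1))
        block = genes[i * hi:(i + 1) * hi]
        chosen = drng.choice(hi, size=k, replace=False)
        mine = [
            DrugTargetInteraction(drug, block[c], _TYPES[drng.integers(3)])
            for c in sorted(chosen)
        ]
        drug_targets.extend(mine)
        targets_of[drug] = mine

    # -- diseases: gene sets from the residual (non-target) genes -----
    residual = genes[hi * spec.n_drugs:]
    diseases = [f"DIS{i:02d}" for i in range(spec.n_diseases)]
    disease_genes: dict[str, set[str]] = {}
    lo_d, hi_d = spec.genes_per_disease
    for i, disease in enumerate(diseases):
        drng = _rng(spec, _S_DISEASE, i)
        size = int(drng.integers(lo_d, hi_d + 1))
        idx = drng.choice(len(residual), size=size, replace=False)
        disease_genes[disease] = {residual[j] for j in sorted(idx)}

    # -- plant the treatment signal -----------------------------------
    p_plant = 1.0 - math.exp(-spec.signal_strength)
    known: dict[str, set[str]] = {}
    for i, disease in enumerate(diseases):
        prng = _rng(spec, _S_PLANT, i)
        treating = prng.choice(spec.n_drugs, size=spec.n_known, replace=False)
        known[disease] = {drugs[j] for j in sorted(treating)}
        for j in sorted(treating):
            for t in targets_of[drugs[j]]:
                # edge sign opposes the drug-target sign: net effect on the
                # disease gene is negative ("drug opposes disease genes")
                etype = (EdgeType.POSITIVE if t.type is EdgeType.NEGATIVE
                         else EdgeType.NEGATIVE)
                for g in sorted(disease_genes[disease]):
                    if p_plant > 0 and prng.random() < p_plant:
                        net.add_edge(t.target, g, etype)

    # -- structural noise: spurious signed edges from drug targets ----
    if spec.noise_sd > 0:
        nrng = _rng(spec, _S_NOISE)
        signed = (EdgeType.POSITIVE, EdgeType.NEGATIVE)
        for t in drug_targets:
            for _ in range(nrng.poisson(spec.noise_sd)):
                g = genes[nrng.integers(spec.n_genes)]
                if g != t.target:
                    net.add_edge(t.target, g, signed[nrng.integers(2)])

    # -- module catalog: random modules + one planted per disease -----
    mrng = _rng(spec, _S_MODULE)
    modules: dict[str, frozenset[str]] = {}
    for i in range(spec.n_random_modules):
        size = int(mrng.integers(10, 21))
        idx = mrng.choice(spec.n_genes, size=size, replace=False)
        modules[f"M{i:03d}"] = frozenset(genes[j] for j in idx)
    for disease in diseases:
        path_genes = set(disease_genes[disease])
        for drug in known[disease]:
            path_genes |= {t.target for t in targets_of[drug]}
        modules[f"M_{disease}"] = frozenset(path_genes)
    catalog = ModuleCatalog(modules=modules, background=frozenset(genes))

    return Fixture(
        spec=spec, network=net, drug_targets=drug_targets,
        disease_genes=disease_genes, known_associations=known,
        modules=catalog,
    )


def write_fixture(fixture: Fixture, directory: str | Path) -> list[Path]:
    """Write all fixture tables as TSV; returns the written paths."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    paths = []

    p = d / "genes.tsv"
    p.write_text("".join(f"{g}\n" for g in sorted(fixture.network.genes)))
    paths.append(p)

    p = d / "edges.tsv"
    with open(p, "w") as fh:
        for u, v, t in sorted(fixture.network.edges(),
                              key=lambda e: (e[0], e[1], e[2].value)):
            fh.write(f"{u}\t{v}\t{t.value}\tdirected\n")
    paths.append(p)

    p = d / "drug_targets.tsv"
    with open(p, "w") as fh:
        for t in sorted(fixture.drug_targets,
                        key=lambda t: (t.drug, t.target, t.type.value)):
            fh.write(f"{t.drug}\t{t.target}\t{t.type.value}\n")
    paths.append(p)

    p = d / "disease_genes.tsv"
    with open(p, "w") as fh:
        for disease in sorted(fixture.disease_genes):
            for g in sorted(fixture.disease_genes[disease]):
                fh.write(f"{disease}\t{g}\n")
    paths.append(p)

    p = d / "known_associations.tsv"
    with open(p, "w") as fh:
        for disease in sorted(fixture.known_associations):
            for drug in sorted(fixture.known_associations[disease]):
                fh.write(f"{drug}\t{disease}\n")
    paths.append(p)

    p = d / "modules.tsv"
    with open(p, "w") as fh:
        for mid in sorted(fixture.modules.modules):
            for g in sorted(fixture.modules.modules[mid]):
                fh.write(f"{mid}\t{g}\n")
    paths.append(p)
    return paths


def read_fixture(directory: str | Path, spec: FixtureSpec | None = None) -> Fixture:
    """Read a fixture directory written by :func:`write_fixture`."""
    from .network import read_network
    from .vectors import read_disease_genes, read_drug_targets
    from .classify import read_known_associations
    from .validate import read_module_catalog

    d = Path(directory)
    net = read_network(d / "edges.tsv")
    for line in (d / "genes.tsv").read_text().splitlines():
        if line:
            net.add_gene(line)
    background = set(net.genes)
    return Fixture(
        spec=spec if spec is not None else FixtureSpec(),
        network=net,
        drug_targets=read_drug_targets(d / "drug_targets.tsv"),
        disease_genes=read_disease_genes(d / "disease_genes.tsv"),
        known_associations=read_known_associations(d / "known_associations.tsv"),
        modules=read_module_catalog(d / "modules.tsv", background=background),
    )


def planted_matrix(
    n_true: int = 15,
    n_false: int = 45,
    n_signal_genes: int = 5,
    n_genes: int = 10,
    signal: float = 1.0,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Directly synthesise a DV matrix with labels for classifier tests.

    TRUE rows have DV ≈ −signal on the first ``n_signal_genes`` columns,
    FALSE rows ≈ 0; Gaussian noise of sd ``noise_sd`` everywhere.
    """
    rng = np.random.default_rng(seed)
    n = n_true + n_false
    X = rng.normal(0.0, noise_sd, size=(n, n_genes))
    X[:n_true, :n_signal_genes] -= signal
    labels = np.array([True] * n_true + [False] * n_false)
    drugs = [f"DR{i:03d}" for i in range(n)]
    genes = [f"G{i:03d}" for i in range(n_genes)]
    df = pd.DataFrame(X, index=pd.Index(drugs, name="drug_id"), columns=genes)
    return df, labels
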