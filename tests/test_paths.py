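from fractions import Fraction

import numpy as np
import pytest

from signrepo.network import EdgeType
from signrepo.paths import (
    PathExplosionError,
    ScoredPath,
    find_shortest_paths,
    gene_pair_score,
    path_type,
    path_weight,
)

from conftest import make_net
from oracles import brute_force_paths, random_typed_network

P, N, U = EdgeType.POSITIVE, EdgeType.NEGATIVE, EdgeType.NEUTRAL


class TestPathType:
    @pytest.mark.parametrize("types,expected", [
        ([P, N], -1),
        ([U, P, U], 1),      # neutral edges are excluded from the product
        ([N, N], 1),
        ([U, U], 1),         # empty signed set: empty product
        ([N], -1),
    ])
    def test_product_of_signed_edges(self, types, expected):
        assert path_type(types) == expected


class TestPathWeight:
    def test_departure_node_product(self):
        # out_degree(T)=2, out_degree(A)=1; destination G excluded
        net = make_net([("T", "A", "positive"), ("T", "X", "neutral"),
                        ("A", "G", "neutral")])
        assert path_weight(net, ("T", "A", "G")) == pytest.approx(0.5)

    def test_all_out_degree_one_gives_unit_weight(self):
        net = make_net([("T", "A", "neutral"), ("A", "G", "negative")])
        assert path_weight(net, ("T", "A", "G")) == 1.0

    def test_single_hop(self):
        net = make_net([("T", "G", "positive"), ("T", "a", "neutral"),
                        ("T", "b", "neutral"), ("T", "c", "neutral")])
        assert path_weight(net, ("T", "G")) == pytest.approx(0.25)

    def test_include_destination_switch(self):
        net = make_net([("T", "G", "positive"), ("G", "X", "neutral"),
                        ("G", "Y", "neutral")])
        assert path_weight(net, ("T", "G")) == 1.0
        assert path_weight(net, ("T", "G"), include_destination=True) == 0.5

    def test_include_destination_sink_raises(self):
        net = make_net([("T", "G", "positive")])
        with pytest.raises(ZeroDivisionError):
            path_weight(net, ("T", "G"), include_destination=True)


class TestFindShortestPaths:
    def test_signed_constraint_rejects_neutral_shortcut(self, branching_net):
        paths = find_shortest_paths(branching_net, "T", "G", require_signed=True)
        assert len(paths) == 1
        assert paths[0].nodes == ("T", "A", "G")
        assert len(paths[0].edge_types) == 2

    def test_unconstrained_takes_the_short_neutral_hop(self, branching_net):
        paths = find_shortest_paths(branching_net, "T", "G", require_signed=False)
        assert len(paths) == 1
        assert paths[0].nodes == ("T", "G")

    def test_parallel_typed_edges_are_distinct_paths(self):
        net = make_net([("T", "A", "neutral"), ("A", "G", "neutral"),
                        ("A", "G", "negative")])
        signed = find_shortest_paths(net, "T", "G", require_signed=True)
        assert len(signed) == 1
        assert signed[0].edge_types == (U, N)
        both = find_shortest_paths(net, "T", "G", require_signed=False)
        assert len(both) == 2

    def test_unreachable_gives_empty_list(self):
        net = make_net([("T", "A", "positive")], extra_genes=["G"])
        assert find_shortest_paths(net, "T", "G") == []

    def test_max_length_caps_search(self):
        net = make_net([("a", "b", "positive"), ("b", "c", "positive"),
                        ("c", "d", "positive")])
        assert find_shortest_paths(net, "a", "d", max_length=2) == []
        assert len(find_shortest_paths(net, "a", "d", max_length=3)) == 1

    def test_errors(self, branching_net):
        with pytest.raises(KeyError):
            find_shortest_paths(branching_net, "nope", "G")
        with pytest.raises(KeyError):
            find_shortest_paths(branching_net, "T", "nope")
        with pytest.raises(ValueError):
            find_shortest_paths(branching_net, "T", "T")
        with pytest.raises(ValueError):
            find_shortest_paths(branching_net, "T", "G", max_length=0)

    def test_path_explosion_raises(self):
        # two parallel signed edges per hop over 3 hops: 8 tied paths
        net = make_net([(u, v, t) for u, v in
                        [("a", "b"), ("b", "c"), ("c", "d")]
                        for t in ("positive", "negative")])
        with pytest.raises(PathExplosionError):
            find_shortest_paths(net, "a", "d", max_paths=7)

    def test_scored_path_validation(self):
        with pytest.raises(ValueError):
            ScoredPath(nodes=("a",), edge_types=(), path_type=1, weight=1.0)


class TestGenePairScore:
    def test_signed_sum_of_two_paths(self):
        # two length-2 routes: positive-neutral (T=+1) and negative-neutral
        # (T=−1) with weights 1/2 × 1 each → V = 0
        net = make_net([("T", "A", "positive"), ("T", "B", "negative"),
                        ("A", "G", "neutral"), ("B", "G", "neutral")])
        score = gene_pair_score(net, "T", "G")
        assert len(score.paths) == 2
        assert score.value == pytest.approx(0.5 - 0.5)

    def test_unreachable_pair_scores_zero(self):
        net = make_net([("T", "A", "positive")], extra_genes=["G"])
        score = gene_pair_score(net, "T", "G")
        assert score.value == 0 and score.paths == []

    def test_single_negative_path(self):
        net = make_net([("T", "G", "negative")] +
                       [("T", f"x{i}", "neutral") for i in range(5)])
        score = gene_pair_score(net, "T", "G")
        assert score.value == pytest.approx(-1 / 6)


def _check_against_oracle(edges, source, destination, require_signed,
                          max_length=6, genes=()):
    net = make_net(edges, extra_genes=genes)
    got = find_shortest_paths(net, source, destination,
                              require_signed=require_signed,
                              max_length=max_length)
    exp_paths, exp_t, exp_w, exp_v = brute_force_paths(
        [tuple(e) for e in edges], source, destination, require_signed,
        max_length)
    got_keyed = sorted(
        (p.nodes, tuple(e.value for e in p.edge_types)) for p in got
    )
    assert got_keyed == exp_paths
    by_key = {(p.nodes, tuple(e.value for e in p.edge_types)): p for p in got}
    for key, t, w in zip(exp_paths, exp_t, exp_w):
        assert by_key[key].path_type == t
        assert by_key[key].weight == pytest.approx(float(w))
    v = sum(p.path_type * p.weight for p in got)
    assert v == pytest.approx(float(exp_v))


def test_oracle_equivalence_on_random_networks():
    """Constrained shortest paths, T, W, V match brute-force enumeration."""
    rng = np.random.default_rng(2024)
    for _ in range(60):
        genes, edges = random_typed_network(rng)
        s, t = (genes[i] for i in rng.choice(len(genes), 2, replace=False))
        for require_signed in (False, True):
            _check_against_oracle(edges, s, t, require_signed, genes=genes)


def test_sign_flip_symmetry():
    """Swapping positive and negative edges maps T to T·(−1)^|signed|."""
    rng = np.random.default_rng(7)
    flip = {"positive": "negative", "negative": "positive",
            "neutral": "neutral"}
    for _ in range(20):
        genes, edges = random_typed_network(rng)
        s, t = (genes[i] for i in rng.choice(len(genes), 2, replace=False))
        net = make_net(edges, extra_genes=genes)
        flipped = make_net([(u, v, flip[lab]) for u, v, lab in edges],
                           extra_genes=genes)
        a = find_shortest_paths(net, s, t, require_signed=True)
        b = find_shortest_paths(flipped, s, t, require_signed=True)
        key = lambda p: p.nodes
        assert sorted(p.nodes for p in a) == sorted(p.nodes for p in b)
        bmap = {}
        for p in b:
            bmap.setdefault(p.nodes, []).append(p)
        for p in sorted(a, key=key):
            n_signed = sum(1 for e in p.edge_types if e.sign)
            twin = [q for q in bmap[p.nodes]
                    if [flip[e.value] for e in p.edge_types]
                    == [e.value for e in q.edge_types]]
            assert len(twin) == 1
            assert twin[0].path_type == p.path_type * (-1) ** n_signed
            assert twin[0].weight == pytest.approx(p.weight)


def test_adding_edge_never_lengthens_shortest_path():
    rng = np.random.default_rng(99)
    for _ in range(20):
        genes, edges = random_typed_network(rng)
        s, t = (genes[i] for i in rng.choice(len(genes), 2, replace=False))
        net = make_net(edges, extra_genes=genes)
        base = find_shortest_paths(net, s, t, require_signed=True)
        base_len = len(base[0].edge_types) if base else None
        u, v = (genes[i] for i in rng.choice(len(genes), 2, replace=False))
        net.add_edge(u, v, EdgeType.POSITIVE)
        after = find_shortest_paths(net, s, t, require_signed=True)
        after_len = len(after[0].edge_types) if after else None
        if base_len is not None:
            assert after_len is not None and after_len <= base_len


def test_weights_bounded():
    rng = np.random.default_rng(5)
    for _ in range(20):
        genes, edges = random_typed_network(rng)
        s, t = (genes[i] for i in rng.choice(len(genes), 2, replace=False))
        net = make_net(edges, extra_genes=genes)
        paths = find_shortest_paths(net, s, t)
        for p in paths:
            assert 0 < p.weight <= 1
        v = sum(p.path_type * p.weight for p in paths)
        assert abs(v) <= sum(p.weight for p in paths) + 1e-12
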