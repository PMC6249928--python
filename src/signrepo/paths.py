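"""Constrained shortest-path enumeration and the T / W / V path scores.

Influence of a drug-target gene on a disease gene is quantified over the
*shortest* directed paths between them:

* the path type ``T`` is the product of the signs of the path's non-neutral
  edges (+1 activating, −1 inhibiting); a path with no signed edge has
  ``T = +1`` (empty product), so it transmits the drug–target sign unchanged;
* the path weight ``W`` is the product of reciprocal out-degrees of the
  departure nodes, modelling dilution of influence at each branching gene;
* the gene-pair score ``V = Σ T_i · W_i`` sums over all tied shortest paths.

When the drug binds its target without a direction of regulation (a neutral
drug–target interaction), a path made only of neutral edges would carry no
regulatory information at all, so at least one signed edge is required on
the path; the shortest *satisfying* length may then exceed the unconstrained
shortest length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .network import DirectedSignedNetwork, EdgeType

__all__ = [
    "ScoredPath",
    "GenePairScore",
    "PathExplosionError",
    "path_type",
    "path_weight",
    "find_shortest_paths",
    "gene_pair_score",
    "write_scores",
]

DEFAULT_MAX_LENGTH = 6
DEFAULT_MAX_PATHS = 10_000


class PathExplosionError(RuntimeError):
    """Raised when a gene pair has more tied shortest paths than the safety cap."""


@dataclass(frozen=True)
class ScoredPath:
    """One shortest path with its sign type T and weight W."""

    nodes: tuple[str, ...]
    edge_types: tuple[EdgeType, ...]
    path_type: int
    weight: float

    def __post_init__(self) -> None:
        if len(self.nodes) < 2 or len(self.edge_types) != len(self.nodes) - 1:
            raise ValueError("path must have n >= 2 nodes and n-1 edges")


@dataclass
class GenePairScore:
    """Aggregate of all shortest paths from one target gene to one disease gene."""

    source: str
    destination: str
    paths: list[ScoredPath] = field(default_factory=list)

    @property
    def value(self) -> float:
        """V = Σ T_i · W_i over the stored shortest paths (0 if unreachable)."""
        return sum(p.path_type * p.weight for p in self.paths)

    @property
    def path_length(self) -> int | None:
        return len(self.paths[0].edge_types) if self.paths else None


def path_type(edge_types: list[EdgeType] | tuple[EdgeType, ...]) -> int:
    """Product of ±1 over the signed edges of a path; +1 when none exist."""
    t = 1
    for e in edge_types:
        if e.sign:
            t *= e.sign
    return t


def path_weight(
    net: DirectedSignedNetwork,
    nodes: list[str] | tuple[str, ...],
    *,
    include_destination: bool = False,
    distinct_neighbors: bool = False,
) -> float:
    """Product of reciprocal out-degrees along a path.

    By default the product runs over the departure nodes only (the terminal
    gene's fan-out cannot dilute signal already delivered, and a sink
    destination would otherwise divide by zero).  ``include_destination``
    restores the all-nodes reading and raises on a zero-out-degree terminal.
    """
    span = nodes if include_destination else nodes[:-1]
    w = 1.0
    for g in span:
        d = net.out_degree(g, distinct_neighbors=distinct_neighbors)
        if d == 0:
            raise ZeroDivisionError(
                f"gene {g!r} has out-degree 0; cannot weight a path through it"
            )
        w /= d
    return w


def find_shortest_paths(
    net: DirectedSignedNetwork,
    source: str,
    destination: str,
    *,
    require_signed: bool = False,
    max_length: int = DEFAULT_MAX_LENGTH,
    max_paths: int = DEFAULT_MAX_PATHS,
    include_destination_degree: bool = False,
    distinct_neighbors: bool = False,
) -> list[ScoredPath]:
    """Enumerate ALL minimal-length simple paths from source to destination.

    Paths are node-simple; parallel typed edges yield distinct paths.  With
    ``require_signed`` a path must contain at least one positive or negative
    edge, and minimality is taken among satisfying paths, so the returned
    length may exceed the unconstrained shortest length.  Returns an empty
    list when no satisfying path of at most ``max_length`` edges exists.
    """
    if source not in net:
        raise KeyError(f"unknown gene: {source!r}")
    if destination not in net:
        raise KeyError(f"unknown gene: {destination!r}")
    if source == destination:
        raise ValueError("source and destination must differ")
    if max_length < 1:
        raise ValueError("max_length must be >= 1")

    dist = net.hop_distances_to(destination)
    if dist.get(source, max_length + 1) > max_length:
        return []

    results: list[tuple[tuple[str, ...], tuple[EdgeType, ...]]] = []

    def dfs(node: str, visited: set[str], trail: list[str],
            etypes: list[EdgeType], remaining: int, signed_seen: bool) -> None:
        if node == destination:
            if signed_seen or not require_signed:
                results.append((tuple(trail), tuple(etypes)))
                if len(results) > max_paths:
                    raise PathExplosionError(
                        f"more than {max_paths} tied shortest paths between "
                        f"{source!r} and {destination!r}"
                    )
            return
        if remaining == 0:
            return
        for nxt, etype in net.successors(node):
            if nxt in visited:
                continue
            if dist.get(nxt, remaining + 1) > remaining - 1:
                continue
            visited.add(nxt)
            trail.append(nxt)
            etypes.append(etype)
            dfs(nxt, visited, trail, etypes,
                remaining - 1, signed_seen or etype.sign != 0)
            etypes.pop()
            trail.pop()
            visited.remove(nxt)

    # iterative deepening: the first depth with a satisfying path is minimal
    for length in range(dist.get(source, 1), max_length + 1):
        dfs(source, {source}, [source], [], length, False)
        if results:
            break

    scored = [
        ScoredPath(
            nodes=nodes,
            edge_types=etypes,
            path_type=path_type(etypes),
            weight=path_weight(
                net, nodes,
                include_destination=include_destination_degree,
                distinct_neighbors=distinct_neighbors,
            ),
        )
        for nodes, etypes in results
    ]
    scored.sort(key=lambda p: (p.nodes, tuple(e.value for e in p.edge_types)))
    return scored


def gene_pair_score(
    net: DirectedSignedNetwork,
    source: str,
    destination: str,
    *,
    require_signed: bool = False,
    max_length: int = DEFAULT_MAX_LENGTH,
    **kwargs,
) -> GenePairScore:
    """Score one target-gene → disease-gene pair (V of the stored paths)."""
    paths = find_shortest_paths(
        net, source, destination,
        require_signed=require_signed, max_length=max_length, **kwargs,
    )
    return GenePairScore(source=source, destination=destination, paths=paths)


def write_scores(scores: list[GenePairScore], path) -> None:
    """Export pair scores as TSV ``source destination n_paths path_length V``."""
    with open(path, "w") as fh:
        fh.write("source\tdestination\tn_paths\tpath_length\tV\n")
        for s in scores:
            length = s.path_length if s.path_length is not None else "NA"
            fh.write(
                f"{s.source}\t{s.destination}\t{len(s.paths)}\t{length}\t{s.value:.10g}\n"
            )
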