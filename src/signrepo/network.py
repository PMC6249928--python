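"""Directed gene network with typed (signed) edges.

The network substrate for path scoring: a directed multigraph over genes
whose edges carry one of three interaction types — *positive* (activation or
expression), *negative* (inhibition or repression) or *neutral* (binding).
Positive and negative edges carry a sign (+1/−1) that propagates along
paths; neutral edges carry no sign and merely provide connectivity.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeType",
    "InteractionRecord",
    "DirectedSignedNetwork",
    "convert_interaction_name",
    "build_network",
    "read_interaction_table",
    "read_network",
    "write_edge_list",
    "write_sif",
]


class EdgeType(enum.Enum):
    """Interaction type of a directed gene–gene edge.

    The ``sign`` is +1 for positive, −1 for negative and 0 for neutral;
    0 means "carries no sign" — neutral edges are excluded from the path-type
    product, never multiplied into it.
    """

    POSITIVE = "positive"
    NEGATIVE = "negative"
    NEUTRAL = "neutral"

    @property
    def sign(self) -> int:
        return _SIGNS[self]

    @classmethod
    def from_label(cls, label: str) -> "EdgeType":
        return cls(label.strip().lower())


_SIGNS = {EdgeType.POSITIVE: 1, EdgeType.NEGATIVE: -1, EdgeType.NEUTRAL: 0}

#: Interaction-name → edge-type conversion table.  Names absent from the
#: table (phosphorylation, indirect effect, dissociation, dephosphorylation,
#: ubiquitination, missing interaction, methylation, glycosylation, state
#: change, and anything unknown) are unassigned and the record is dropped.
_NAME_TABLE = {
    "activation": EdgeType.POSITIVE,
    "expression": EdgeType.POSITIVE,
    "repression": EdgeType.NEGATIVE,
    "inhibition": EdgeType.NEGATIVE,
    "binding": EdgeType.NEUTRAL,
    # type labels pass through unchanged so edge tables may mix both forms
    "positive": EdgeType.POSITIVE,
    "negative": EdgeType.NEGATIVE,
    "neutral": EdgeType.NEUTRAL,
}


def convert_interaction_name(name: str) -> EdgeType | None:
    """Map an interaction name to an :class:`EdgeType`.

    Matching is case-insensitive after trimming whitespace.  Returns ``None``
    (the discard marker) for unassigned names; callers drop such records.
    """
    if not name or not name.strip():
        raise ValueError("interaction name must be a non-empty string")
    key = name.strip().lower()
    etype = _NAME_TABLE.get(key)
    if etype is None:
        logger.warning("unassigned interaction name %r: record discarded", name)
    return etype


@dataclass(frozen=True)
class InteractionRecord:
    """One row of a gene–gene interaction table."""

    source: str
    destination: str
    name: str
    direction: str = "directed"  # "directed" or "undirected"


class DirectedSignedNetwork:
    """Directed multigraph of genes with typed edges.

    Backed by a :class:`networkx.MultiDiGraph` whose edge keys are the type
    labels, so duplicate ``(source, destination, type)`` triples collapse to
    a single edge while parallel edges of *different* types between the same
    ordered gene pair coexist.
    """

    def __init__(self) -> None:
        self._g = nx.MultiDiGraph()
        self._version = 0  # bumped on mutation; invalidates BFS caches
        self._dist_cache: dict = {}

    # -- construction -------------------------------------------------

    def add_gene(self, gene: str) -> None:
        self._g.add_node(gene)

    def add_edge(self, source: str, destination: str, etype: EdgeType) -> None:
        """Add one typed edge.  Self-loops are discarded with a warning."""
        if source == destination:
            logger.warning("self-loop %s->%s discarded", source, destination)
            return
        self._g.add_edge(source, destination, key=etype.value, etype=etype)
        self._version += 1
        self._dist_cache.clear()

    # -- queries -------------------------------------------------------

    @property
    def genes(self) -> set[str]:
        return set(self._g.nodes)

    def __contains__(self, gene: str) -> bool:
        return gene in self._g

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    def edges(self) -> Iterator[tuple[str, str, EdgeType]]:
        for u, v, k in self._g.edges(keys=True):
            yield u, v, EdgeType(k)

    def out_degree(self, gene: str, *, distinct_neighbors: bool = False) -> int:
        """Number of outgoing interactions of ``gene``.

        By default parallel typed edges count separately ("the number of
        interaction from the node to adjacent nodes"); with
        ``distinct_neighbors`` each successor counts once regardless of how
        many typed edges reach it.
        """
        if gene not in self._g:
            raise KeyError(f"unknown gene: {gene!r}")
        if distinct_neighbors:
            return sum(1 for _ in self._g.successors(gene))
        return self._g.out_degree(gene)

    def successors(self, gene: str) -> Iterator[tuple[str, EdgeType]]:
        """Yield (neighbor, edge type) for every outgoing typed edge."""
        if gene not in self._g:
            raise KeyError(f"unknown gene: {gene!r}")
        for _, v, k in self._g.out_edges(gene, keys=True):
            yield v, EdgeType(k)

    def hop_distances_to(self, destination: str) -> dict[str, int]:
        """Hop count from every gene to ``destination``, ignoring edge types.

        Cached per destination until the network is mutated; used to prune
        path enumeration.
        """
        key = (self._version, destination)
        if key not in self._dist_cache:
            self._dist_cache.clear()  # keep only the current version
            self._dist_cache[key] = nx.single_source_shortest_path_length(
                self._g.reverse(copy=False), destination
            )
        return self._dist_cache[key]


class InputFormatError(ValueError):
    """A malformed row in an input table."""


def build_network(records: Iterable[InteractionRecord]) -> DirectedSignedNetwork:
    """Assemble a network from interaction records.

    Directed records yield one edge, undirected records yield both
    orientations with the same type; records whose name is unassigned
    contribute nothing.  The gene set is the union of endpoints of retained
    edges (genes appearing only in discarded records are absent).
    """
    net = DirectedSignedNetwork()
    for rec in records:
        etype = convert_interaction_name(rec.name)
        if etype is None:
            continue
        net.add_edge(rec.source, rec.destination, etype)
        if rec.direction.strip().lower() == "undirected":
            net.add_edge(rec.destination, rec.source, etype)
    return net


def read_interaction_table(path: str | Path) -> list[InteractionRecord]:
    """Parse a tab-separated edge table.

    Columns: ``source  destination  type_or_name  [direction]``; the fourth
    column defaults to ``directed``.  Lines starting with ``#`` are skipped.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (3, 4):
                raise InputFormatError(
                    f"{path}:{lineno}: expected 3 or 4 tab-separated columns, "
                    f"got {len(fields)}"
                )
            direction = fields[3] if len(fields) == 4 else "directed"
            records.append(
                InteractionRecord(fields[0], fields[1], fields[2], direction)
            )
    return records


def read_network(path: str | Path) -> DirectedSignedNetwork:
    return build_network(read_interaction_table(path))


def write_edge_list(net: DirectedSignedNetwork, path: str | Path) -> None:
    """Write the network as a 4-column directed edge table (round-trippable)."""
    with open(path, "w") as fh:
        for u, v, etype in sorted(net.edges(), key=lambda e: (e[0], e[1], e[2].value)):
            fh.write(f"{u}\t{v}\t{etype.value}\tdirected\n")


def write_sif(net: DirectedSignedNetwork, path: str | Path) -> None:
    """Write the network in SIF dialect ``source  type  destination``."""
    with open(path, "w") as fh:
        for u, v, etype in sorted(net.edges(), key=lambda e: (e[0], e[1], e[2].value)):
            fh.write(f"{u}\t{etype.value}\t{v}\n")
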