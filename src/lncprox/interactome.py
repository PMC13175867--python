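"""Interactome and gene-set I/O, connected components, and degree bins.

The interactome is an undirected graph of physical protein--protein
interactions over gene symbols.  Symbols are compared case-sensitively and
exactly; no alias mapping is attempted, because silent identifier aliasing
corrupts set statistics.  Query symbols absent from the graph are dropped
and reported by the callers that map gene sets onto the graph.

Degree bins are the substrate of the degree-preserving randomization null:
nodes are partitioned by degree into contiguous ranges, each holding at
least ``min_bin_size`` nodes, and null sets are drawn uniformly from the
bin of each query gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Interactome",
    "GeneSet",
    "DegreeBins",
    "read_edge_list",
    "write_edge_list",
    "read_gene_set",
    "largest_connected_component",
    "build_degree_bins",
]


class Interactome:
    """Undirected, simple (no self-loop, no multi-edge) gene-symbol graph."""

    def __init__(self, edges: Iterable[tuple[str, str]] = (), name: str = "",
                 nodes: Iterable[str] = ()):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for a, b in edges:
            if not a or not b:
                raise ValueError("empty gene symbol in edge list")
            if a == b:
                continue
            g.add_edge(a, b)
        self.graph = g
        self.name = name

    @classmethod
    def from_nx(cls, g: nx.Graph, name: str = "") -> "Interactome":
        out = cls(name=name)
        h = nx.Graph()
        h.add_nodes_from(g.nodes)
        h.add_edges_from((a, b) for a, b in g.edges if a != b)
        out.graph = h
        return out

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset((a, b)) for a, b in self.graph.edges}

    def degree(self, node: str) -> int:
        return self.graph.degree[node]

    def neighbors(self, node: str) -> set[str]:
        return set(self.graph.neighbors(node))

    def __len__(self) -> int:
        return self.graph.number_of_nodes()

    def __contains__(self, node: str) -> bool:
        return node in self.graph

    def __eq__(self, other) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return (f"Interactome(name={self.name!r}, n_nodes={len(self)}, "
                f"n_edges={self.graph.number_of_edges()})")


@dataclass(frozen=True)
class GeneSet:
    """Named set of gene symbols (duplicates collapsed on construction)."""

    name: str
    members: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class DegreeBins:
    """Partition of graph nodes into contiguous ascending degree ranges.

    Every bin except possibly one (when the trailing remainder is merged)
    holds at least ``min_bin_size`` nodes.
    """

    min_bin_size: int
    bins: list[tuple[int, int]]  # inclusive (lo_degree, hi_degree) ranges
    assignment: dict[str, int] = field(repr=False)
    bin_members: dict[int, set[str]] = field(repr=False)

    def bin_of(self, node: str) -> int:
        return self.assignment[node]


def read_edge_list(path, format: str = "tsv", header: bool = False) -> Interactome:
    """Read an undirected edge list (2-column TSV or SIF triples).

    Self-loops are dropped (with a logged count) and duplicate edges are
    collapsed regardless of orientation.
    """
    path = Path(path)
    if format not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format {format!r}")
    edges = []
    n_self = 0
    with open(path) as fh:
        lines = fh.read().splitlines()
    if header and lines:
        lines = lines[1:]
    seen_any = False
    for i, line in enumerate(lines, start=2 if header else 1):
        if not line.strip():
            continue
        fields = line.split("\t") if format == "tsv" else line.split()
        if format == "tsv" and len(fields) < 2:
            fields = line.split()
        if format == "sif":
            if len(fields) == 2:
                raise ValueError(f"{path}:{i}: SIF line needs node relation node")
            a, b = fields[0], fields[2] if len(fields) >= 3 else None
            if b is None:
                raise ValueError(f"{path}:{i}: malformed SIF line: {line!r}")
        else:
            if len(fields) < 2:
                raise ValueError(f"{path}:{i}: expected 2 columns, got {len(fields)}")
            a, b = fields[0].strip(), fields[1].strip()
        if not a or not b:
            raise ValueError(f"{path}:{i}: empty symbol")
        seen_any = True
        if a == b:
            n_self += 1
            continue
        edges.append((a, b))
    if not seen_any:
        raise ValueError(f"{path}: empty edge list")
    if n_self:
        logger.info("dropped %d self-loop(s) reading %s", n_self, path)
    return Interactome(edges, name=path.stem)


def write_edge_list(g: Interactome, path) -> None:
    """Write the graph as a 2-column TSV, one edge per line, sorted."""
    rows = sorted(tuple(sorted(e)) for e in g.edges)
    with open(path, "w") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def read_gene_set(path, format: str = "list") -> list[GeneSet]:
    """Read gene sets from GMT (one set per line) or a one-symbol-per-line list."""
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if format == "gmt":
        for i, line in enumerate(lines, start=1):
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{i}: GMT line needs name, description, members")
            name, members = fields[0], [m for m in fields[2:] if m]
            if not members:
                raise ValueError(f"{path}:{i}: gene set {name!r} has no members")
            sets.append(GeneSet(name, frozenset(members)))
    elif format == "list":
        members = frozenset(ln.strip() for ln in lines if ln.strip())
        if not members:
            raise ValueError(f"{path}: no gene symbols found")
        sets.append(GeneSet(path.stem, members))
    else:
        raise ValueError(f"unknown gene-set format {format!r}")
    return sets


def largest_connected_component(g: Interactome) -> Interactome:
    """Induced subgraph on the largest component.

    Ties between equally sized components are broken in favour of the one
    containing the lexicographically smallest symbol, so output is
    deterministic.  Shortest-path statistics are only defined within one
    component, so all proximity computation runs on this subgraph.
    """
    if len(g) == 0:
        raise ValueError("empty graph has no connected component")
    comps = sorted(nx.connected_components(g.graph),
                   key=lambda c: (-len(c), min(c)))
    best = comps[0]
    dropped = len(g) - len(best)
    if dropped:
        logger.info("largest_connected_component: dropped %d node(s)", dropped)
    return Interactome.from_nx(g.graph.subgraph(best).copy(), name=g.name)


def build_degree_bins(g: Interactome, min_bin_size: int) -> DegreeBins:
    """Greedy low-to-high merge of degree values into bins of >= min_bin_size.

    Unique degree values are walked in ascending order, accumulating genes
    until the current bin reaches ``min_bin_size``; an undersized trailing
    remainder is merged into the previous bin.
    """
    if len(g) == 0:
        raise ValueError("cannot bin an empty graph")
    if min_bin_size < 1:
        raise ValueError("min_bin_size must be >= 1")
    if min_bin_size > len(g):
        raise ValueError(
            f"min_bin_size={min_bin_size} exceeds node count {len(g)}; "
            "use a smaller value")
    by_degree: dict[int, set[str]] = {}
    for node in g.graph.nodes:
        by_degree.setdefault(g.graph.degree[node], set()).add(node)
    degrees = sorted(by_degree)

    bins: list[tuple[int, int]] = []
    bin_members: dict[int, set[str]] = {}
    cur: set[str] = set()
    lo = degrees[0]
    for d in degrees:
        cur |= by_degree[d]
        if len(cur) >= min_bin_size:
            bid = len(bins)
            bins.append((lo, d))
            bin_members[bid] = cur
            cur = set()
            lo = d + 1
    if cur:  # undersized remainder -> merge into previous bin
        if bins:
            bid = len(bins) - 1
            bins[bid] = (bins[bid][0], degrees[-1])
            bin_members[bid] |= cur
        else:
            bins.append((degrees[0], degrees[-1]))
            bin_members[0] = cur
    assignment = {node: bid for bid, members in bin_members.items()
                  for node in members}
    return DegreeBins(min_bin_size=min_bin_size, bins=bins,
                      assignment=assignment, bin_members=bin_members)
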