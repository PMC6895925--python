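"""Gene-level interactome: graph container, edge-list readers/writers, merging.

The interactome is an undirected graph whose nodes are gene symbols and whose
edges are binary physical protein-protein interactions.  Each edge carries the
set of source databases it was observed in (e.g., a literature-curated
repository and a systematic screening project), so that multi-source merges
remain auditable.

Gene identity is exact, case-preserved string match on symbols; alias or
isoform resolution is deliberately out of scope and inputs are assumed to be
harmonized upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "Interactome",
    "EdgeListParseError",
    "MergeReport",
    "read_edge_list",
    "write_edge_list",
    "merge_interactomes",
]


class EdgeListParseError(ValueError):
    """Raised when an edge-list row cannot be parsed (names the line number)."""


def _canonical(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered representation of an edge."""
    return (a, b) if a <= b else (b, a)


class Interactome:
    """Undirected gene-interaction graph with per-edge source tags.

    Invariants: no self-loops; edges are unordered; every edge endpoint is a
    node; every edge has a non-empty source set.
    """

    def __init__(self) -> None:
        self._g = nx.Graph()

    # -- construction -----------------------------------------------------

    def add_node(self, gene: str) -> None:
        self._g.add_node(gene)

    def add_edge(self, a: str, b: str, sources: Iterable[str] = ()) -> None:
        """Add an undirected edge, unioning source tags on duplicates.

        Self-loops are silently ignored (the propagation and extraction
        formulas assume i != j); callers that need to report them should
        check ``a == b`` themselves.
        """
        if a == b:
            return
        tags = set(sources)
        if self._g.has_edge(a, b):
            self._g.edges[a, b]["sources"].update(tags)
        else:
            self._g.add_edge(a, b, sources=tags)

    # -- queries ----------------------------------------------------------

    @property
    def graph(self) -> nx.Graph:
        """The underlying :class:`networkx.Graph` (shared, not a copy)."""
        return self._g

    @property
    def nodes(self) -> set[str]:
        return set(self._g.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {_canonical(a, b) for a, b in self._g.edges}

    @property
    def num_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def num_edges(self) -> int:
        return self._g.number_of_edges()

    def has_node(self, gene: str) -> bool:
        return self._g.has_node(gene)

    def has_edge(self, a: str, b: str) -> bool:
        return self._g.has_edge(a, b)

    def edge_sources(self, a: str, b: str) -> set[str]:
        return set(self._g.edges[a, b]["sources"])

    def neighbors(self, gene: str) -> Iterator[str]:
        return self._g.neighbors(gene)

    def degree(self, gene: str) -> int:
        return self._g.degree(gene)

    def sorted_nodes(self) -> list[str]:
        """Deterministic node ordering used to index vectors and matrices."""
        return sorted(self._g.nodes)

    def copy(self) -> "Interactome":
        out = Interactome()
        out._g = self._g.copy()
        for a, b in out._g.edges:
            out._g.edges[a, b]["sources"] = set(out._g.edges[a, b]["sources"])
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Interactome):
            return NotImplemented
        return self.nodes == other.nodes and self.edges == other.edges

    def __repr__(self) -> str:
        return f"Interactome({self.num_nodes} nodes, {self.num_edges} edges)"


def read_edge_list(path: str | Path, source_tag: str, fmt: str | None = None) -> Interactome:
    """Read a TSV or SIF edge list into an :class:`Interactome`.

    TSV rows carry two gene-symbol columns (extra columns ignored); SIF rows
    carry ``nodeA <tab> interaction-type <tab> nodeB`` and the middle column
    is ignored.  Lines starting with ``#`` are headers/comments.  Duplicate
    rows and reversed duplicates collapse to a single edge; self-loops are
    dropped with a logged warning.

    Parameters
    ----------
    path:
        File to read.
    source_tag:
        Tag recorded in every edge's source set (e.g., ``"HINT"``).
    fmt:
        ``"tsv"`` or ``"sif"``; inferred from the file suffix when ``None``.
    """
    path = Path(path)
    if fmt is None:
        fmt = "sif" if path.suffix.lower() == ".sif" else "tsv"
    if fmt not in ("tsv", "sif"):
        raise ValueError(f"unknown edge-list format: {fmt!r}")

    net = Interactome()
    n_self_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = [f for f in line.split("\t") if f.strip() != ""]
            if len(fields) == 1:  # tolerate space-separated rows
                fields = line.split()
            if len(fields) < 2:
                raise EdgeListParseError(
                    f"{path}:{lineno}: expected at least 2 gene columns, got {len(fields)}"
                )
            if fmt == "sif" and len(fields) >= 3:
                a, b = fields[0].strip(), fields[2].strip()
            else:
                a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                n_self_loops += 1
                continue
            net.add_edge(a, b, sources=(source_tag,))
    if n_self_loops:
        logger.warning("%s: dropped %d self-loop row(s)", path, n_self_loops)
    return net


def write_edge_list(net: Interactome, path: str | Path) -> None:
    """Write a sorted, deduplicated TSV edge list: gene_a, gene_b, sources."""
    with open(path, "w") as fh:
        fh.write("#gene_a\tgene_b\tsources\n")
        for a, b in sorted(net.edges):
            tags = ",".join(sorted(net.edge_sources(a, b)))
            fh.write(f"{a}\t{b}\t{tags}\n")


@dataclass(frozen=True)
class MergeReport:
    """Edge-overlap bookkeeping for a two-source merge."""

    edges_a_only: int
    edges_b_only: int
    edges_shared: int

    @property
    def edges_total(self) -> int:
        return self.edges_a_only + self.edges_b_only + self.edges_shared


def merge_interactomes(a: Interactome, b: Interactome) -> Interactome:
    """Union of two interactomes; per-edge source sets are unioned.

    Merge is commutative and idempotent on edge sets.  Overlap counts are
    logged; use :func:`merge_report` for programmatic access.
    """
    rep = merge_report(a, b)
    logger.info(
        "merge: %d edges only in first, %d only in second, %d shared",
        rep.edges_a_only, rep.edges_b_only, rep.edges_shared,
    )
    out = a.copy()
    for node in b.nodes:
        out.add_node(node)
    for x, y in b.edges:
        out.add_edge(x, y, sources=b.edge_sources(x, y))
    return out


def merge_report(a: Interactome, b: Interactome) -> MergeReport:
    ea, eb = a.edges, b.edges
    shared = ea & eb
    return MergeReport(len(ea - eb), len(eb - ea), len(shared))
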