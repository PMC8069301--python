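"""Undirected gene–gene interaction networks.

The interactome is treated purely topologically: an unweighted, undirected
graph over case-normalized gene identifiers. Edge weights, interaction types
and extra columns in source files are ignored. The reference instance for the
OSA–dementia analysis is PCNet v1.3 exported to a two-column edge list, with
the ubiquitously connected UBC hub removed before any neighbourhood query.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = ["GeneSet", "GeneNetwork", "load_edge_list", "exclude_genes"]


def _norm(gene: str) -> str:
    """Case-normalize a gene identifier (identifiers are opaque strings)."""
    return str(gene).strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of case-normalized gene identifiers."""

    label: str
    genes: frozenset[str]

    def __init__(self, label: str, genes: Iterable[str]):
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "genes", frozenset(_norm(g) for g in genes))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return _norm(gene) in self.genes

    def __iter__(self) -> Iterator[str]:
        return iter(sorted(self.genes))

    def __or__(self, other: "GeneSet") -> "GeneSet":
        return GeneSet(f"{self.label}|{other.label}", self.genes | other.genes)


class GeneNetwork:
    """Undirected, unweighted gene–gene interaction graph.

    Invariants: no self-loops, unordered edges are unique, adjacency is
    symmetric, every edge endpoint is a node. Backed by a ``networkx.Graph``.
    """

    def __init__(self, provenance: str = ""):
        self.graph = nx.Graph()
        self.provenance = provenance

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str]],
        nodes: Iterable[str] = (),
        provenance: str = "",
    ) -> "GeneNetwork":
        net = cls(provenance=provenance)
        for g in nodes:
            net.graph.add_node(_norm(g))
        dropped = 0
        for a, b in edges:
            a, b = _norm(a), _norm(b)
            if a == b:
                net.graph.add_node(a)
                dropped += 1
                continue
            net.graph.add_edge(a, b)
        if dropped:
            logger.warning("dropped %d self-loop edge(s)", dropped)
        return net

    # -- basic queries ----------------------------------------------------

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.graph.edges}

    def __contains__(self, gene: str) -> bool:
        return _norm(gene) in self.graph

    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def adjacency(self) -> dict[str, set[str]]:
        """Node → neighbour-set mapping (a materialized copy)."""
        return {g: set(nbrs) for g, nbrs in self.graph.adjacency()}

    def neighbors(self, gene: str) -> GeneSet:
        """All genes sharing an edge with ``gene``; never contains ``gene``."""
        g = _norm(gene)
        if g not in self.graph:
            raise KeyError(f"gene {g!r} is not a node of the network")
        return GeneSet(f"neighbors({g})", self.graph.neighbors(g))

    def neighborhood_of_set(self, seeds: GeneSet | Iterable[str]) -> GeneSet:
        """Union of neighbour sets over all seed genes present in the network.

        Seed genes absent from the network are skipped (count logged). The
        result may overlap the seeds; candidate filtering is done elsewhere.
        """
        genes = seeds.genes if isinstance(seeds, GeneSet) else {_norm(g) for g in seeds}
        label = seeds.label if isinstance(seeds, GeneSet) else "seeds"
        missing = sum(1 for g in genes if g not in self.graph)
        if missing:
            logger.info("neighborhood_of_set: %d seed gene(s) not in network, skipped", missing)
        out: set[str] = set()
        for g in genes:
            if g in self.graph:
                out.update(self.graph.neighbors(g))
        return GeneSet(f"neighborhood({label})", out)

    # -- I/O ---------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        """Write the canonical edge list: endpoints sorted within each edge,
        edges sorted lexicographically, one edge per line.

        Isolated nodes are written as self-pair lines (``g<TAB>g``) so the
        node set round-trips; the loader keeps the node and drops the loop.
        """
        lines = sorted(tuple(sorted(e)) for e in self.graph.edges)
        isolated = sorted(g for g in self.graph.nodes if self.graph.degree(g) == 0)
        with open(path, "w") as fh:
            for a, b in sorted(lines + [(g, g) for g in isolated]):
                fh.write(f"{a}\t{b}\n")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def load_edge_list(
    path: str | Path,
    format: str = "tsv-2col",
    mapping: dict[str, str] | None = None,
    provenance: str | None = None,
) -> GeneNetwork:
    """Load an undirected network from a TSV edge list or SIF file.

    Parameters
    ----------
    path:
        Two-or-more-column TSV (``gene_a<TAB>gene_b[<TAB>ignored...]``) or SIF
        (``node1 relation node2``). ``.gz`` is handled transparently.
    format:
        ``"tsv-2col"`` or ``"sif"``.
    mapping:
        Optional identifier translation applied to every token at load time
        (e.g. Entrez → symbol). Unmapped tokens pass through unchanged.

    Duplicate lines and reversed duplicates collapse to a single edge;
    self-loops are dropped with a warning (the node is retained).
    """
    path = Path(path)
    if format not in ("tsv-2col", "sif"):
        raise ValueError(f"unknown edge-list format {format!r}")
    if not path.exists():
        raise FileNotFoundError(f"edge list not found: {path}")
    mapping = {_norm(k): _norm(v) for k, v in (mapping or {}).items()}

    net = GeneNetwork(provenance=provenance or str(path))
    self_loops = 0
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            tokens = line.split("\t") if format == "tsv-2col" else line.split()
            if format == "sif":
                if len(tokens) == 1:
                    # SIF allows orphan nodes on single-token lines
                    g = mapping.get(_norm(tokens[0]), _norm(tokens[0]))
                    net.graph.add_node(g)
                    continue
                if len(tokens) < 3:
                    raise ValueError(
                        f"{path}:{lineno}: SIF line needs node, relation, node "
                        f"(got {len(tokens)} token(s))"
                    )
                pair = (tokens[0], tokens[2])
            else:
                if len(tokens) < 2:
                    raise ValueError(
                        f"{path}:{lineno}: expected >=2 tab-separated gene tokens, "
                        f"got {len(tokens)}"
                    )
                pair = (tokens[0], tokens[1])
            a, b = (_norm(t) for t in pair)
            a, b = mapping.get(a, a), mapping.get(b, b)
            if a == b:
                net.graph.add_node(a)
                self_loops += 1
                continue
            net.graph.add_edge(a, b)
    if self_loops:
        logger.warning("%s: dropped %d self-loop line(s)", path.name, self_loops)
    logger.info("loaded %s: %d nodes, %d edges", path.name, net.n_nodes(), net.n_edges())
    return net


def exclude_genes(net: GeneNetwork, excluded: GeneSet | Iterable[str]) -> GeneNetwork:
    """Remove genes and all their incident edges from the network.

    The canonical use is dropping the UBC hub, which links to nearly every
    gene and would otherwise make almost everything a candidate. Excluding an
    absent gene is a logged no-op; the operation is idempotent.
    """
    genes = excluded.genes if isinstance(excluded, GeneSet) else {_norm(g) for g in excluded}
    present = genes & net.nodes
    absent = genes - present
    if absent:
        logger.info("exclude_genes: %d gene(s) not in network (no-op): %s",
                    len(absent), ", ".join(sorted(absent)))
    out = GeneNetwork(provenance=net.provenance)
    out.graph = net.graph.copy()
    out.graph.remove_nodes_from(present)
    if present:
        logger.info("excluded %d gene(s); network now %d nodes, %d edges",
                    len(present), out.n_nodes(), out.n_edges())
    return out
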