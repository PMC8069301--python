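"""Primary-candidate identification.

A gene is a primary candidate for a disease pair when it has at least one
direct network neighbour in each disease's gene set. Candidacy is binary and
distance-1 only — no diffusion, no 2-hop extension, no degree weighting.
By default genes that are themselves disease genes are excluded from
candidacy (``exclude_seeds=True``), so reported drivers are genes *between*
the two disease modules rather than members of either.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .network import GeneNetwork, GeneSet

logger = logging.getLogger(__name__)

__all__ = ["CandidateRecord", "CandidateSet", "find_primary_candidates", "candidate_gene_ids"]


@dataclass(frozen=True)
class CandidateRecord:
    """One candidate with its supporting disease genes on each side.

    ``support_a`` / ``support_b`` are exactly the candidate's neighbours that
    lie in disease set A / B; both are nonempty by construction and never
    contain the candidate itself.
    """

    gene: str
    support_a: GeneSet
    support_b: GeneSet

    def __post_init__(self):
        if not self.support_a.genes or not self.support_b.genes:
            raise ValueError(f"candidate {self.gene}: empty support set")
        if self.gene in self.support_a or self.gene in self.support_b:
            raise ValueError(f"candidate {self.gene} occurs in its own support")


@dataclass
class CandidateSet:
    """Sorted, unique candidate records plus the run configuration snapshot."""

    records: list[CandidateRecord]
    label_a: str = "A"
    label_b: str = "B"
    exclude_seeds: bool = True
    config: dict = field(default_factory=dict)

    def __post_init__(self):
        genes = [r.gene for r in self.records]
        if len(genes) != len(set(genes)):
            raise ValueError("duplicate candidate gene identifiers")
        self.records = sorted(self.records, key=lambda r: r.gene)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def genes(self) -> list[str]:
        return [r.gene for r in self.records]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("gene\tsupport_a\tsupport_b\n")
            for r in self.records:
                fh.write(
                    f"{r.gene}\t{','.join(sorted(r.support_a.genes))}"
                    f"\t{','.join(sorted(r.support_b.genes))}\n"
                )


def candidate_gene_ids(
    adjacency: dict[str, set[str]],
    set_a: set[str],
    set_b: set[str],
    exclude_seeds: bool = True,
) -> set[str]:
    """Candidate gene identifiers only, without support sets.

    Because the graph is undirected, a gene has a neighbour in S exactly when
    it is adjacent to some member of S, so the candidate set is the
    intersection of the two seed-set neighbourhoods. This is the hot path the
    permutation null calls once per replicate.
    """
    na: set[str] = set()
    for s in set_a:
        nbrs = adjacency.get(s)
        if nbrs:
            na |= nbrs
    hits: set[str] = set()
    for s in set_b:
        nbrs = adjacency.get(s)
        if nbrs:
            hits |= na & nbrs
    if exclude_seeds:
        hits -= set_a
        hits -= set_b
    return hits


def find_primary_candidates(
    net: GeneNetwork,
    set_a: GeneSet,
    set_b: GeneSet,
    exclude_seeds: bool = True,
) -> CandidateSet:
    """Identify every gene linked to both disease gene sets.

    A gene g is a record iff neighbors(g) ∩ set_a ≠ ∅ and
    neighbors(g) ∩ set_b ≠ ∅ (and, when ``exclude_seeds``, g is in neither
    seed set). Seed genes absent from the network are skipped with a logged
    count; records are sorted by gene identifier.
    """
    nodes = net.nodes
    a_in = set_a.genes & nodes
    b_in = set_b.genes & nodes
    skipped = (len(set_a.genes) - len(a_in)) + (len(set_b.genes) - len(b_in))
    if skipped:
        logger.info("find_primary_candidates: %d seed gene(s) not in network, skipped", skipped)
    if not a_in and not b_in:
        raise ValueError(
            "both disease gene sets are empty after restriction to the network"
        )

    adj = net.adjacency()
    records = []
    for g in candidate_gene_ids(adj, a_in, b_in, exclude_seeds):
        nbrs = adj[g]
        records.append(
            CandidateRecord(
                gene=g,
                support_a=GeneSet(set_a.label, nbrs & a_in),
                support_b=GeneSet(set_b.label, nbrs & b_in),
            )
        )
    out = CandidateSet(
        records=records,
        label_a=set_a.label,
        label_b=set_b.label,
        exclude_seeds=exclude_seeds,
        config={
            "exclude_seeds": exclude_seeds,
            "n_seeds_a_in_network": len(a_in),
            "n_seeds_b_in_network": len(b_in),
        },
    )
    logger.info("primary candidates: %d (|A∩net|=%d, |B∩net|=%d)",
                len(out), len(a_in), len(b_in))
    return out
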