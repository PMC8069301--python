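"""Permutation null for primary candidates.

Each replicate redraws the two disease inputs at their observed sizes,
reruns the candidate identification, and counts, per observed candidate g,
the replicates whose null candidate set contains g (x). The empirical
p-value is x divided by the number of iterations — by default 100·n with n
the number of observed primary candidates — and Benjamini–Hochberg step-up
adjustment across candidates controls the FDR.

Two null universes are supported:

``gene``
    replicates sample gene sets of sizes |A|, |B| uniformly without
    replacement from the network's node set;
``disease_id``
    replicates sample CUI lists of the observed lengths from the
    disease–variant table's CUI universe and expand them to gene sets
    through the variant→gene mapping, mimicking how the observed sets were
    themselves assembled.

In both modes the two samples are drawn independently and may overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .candidates import CandidateSet, candidate_gene_ids
from .disgenet import DiseaseGeneMapping
from .network import GeneNetwork, GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "empirical_pvalue",
    "bh_adjust",
    "sample_null_replicate",
    "run_permutation",
    "significant_drivers",
]


@dataclass(frozen=True)
class PermutationConfig:
    """Configuration of one permutation run.

    ``iterations=None`` means the default 100·n, resolved against the
    candidate set when the run starts. ``plus_one`` switches the p-value to
    the conservative (x+1)/(iterations+1) estimator.
    """

    mode: str = "disease_id"  # or "gene"
    iterations: Optional[int] = None
    seed: int = 0
    alpha: float = 0.05
    plus_one: bool = False
    log_every: int = 0  # replicates between progress messages; 0 = silent
    record_replicates: bool = False  # keep per-replicate overlap counts

    def __post_init__(self):
        if self.mode not in ("gene", "disease_id"):
            raise ValueError(f"unknown permutation mode {self.mode!r}")
        if self.iterations is not None and self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")


@dataclass
class PermutationResult:
    """Per-candidate occurrence counts and (adjusted) empirical p-values."""

    genes: list[str]
    x: dict[str, int]
    p: dict[str, float]
    q: dict[str, float]
    iterations: int
    seed: int
    mode: str
    replicate_hits: Optional[list[int]] = field(default=None, repr=False)

    def to_tsv(self, path: str | Path, candidates: CandidateSet, alpha: float) -> None:
        by_gene = {r.gene: r for r in candidates}
        with open(path, "w") as fh:
            fh.write("gene\tsupport_a\tsupport_b\tx\tp\tq\tsignificant\n")
            for g in sorted(self.genes, key=lambda g: (self.p[g], g)):
                r = by_gene[g]
                fh.write(
                    f"{g}\t{','.join(sorted(r.support_a.genes))}"
                    f"\t{','.join(sorted(r.support_b.genes))}"
                    f"\t{self.x[g]}\t{self.p[g]:.6g}\t{self.q[g]:.6g}"
                    f"\t{int(self.q[g] <= alpha)}\n"
                )


def empirical_pvalue(x: int, iterations: int, plus_one: bool = False) -> float:
    """Empirical p-value x/iterations (or (x+1)/(iterations+1))."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    if not (0 <= x <= iterations):
        raise ValueError(f"count x={x} outside [0, {iterations}]")
    if plus_one:
        return (x + 1) / (iterations + 1)
    return x / iterations


def bh_adjust(pvalues) -> list[float]:
    """Benjamini–Hochberg step-up adjusted values, in input order.

    q_(i) = min_{j>=i} p_(j)·m/j, clipped to 1, with m the list length.
    Guarantees q >= p and monotonicity of q along sorted p.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    # q >= p holds mathematically; guard against one-ulp rounding of p·m/j
    q_sorted = np.maximum(q_sorted, p[order])
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q.tolist()


def sample_null_replicate(
    rng: np.random.Generator,
    mode: str,
    *,
    universe: tuple[str, ...],
    size_a: int,
    size_b: int,
    mapping: Optional[DiseaseGeneMapping] = None,
) -> tuple[set[str], set[str]]:
    """Draw one null replicate: two sets, independently, without replacement.

    In ``gene`` mode the universe is the network node set and the returned
    sets are gene sets. In ``disease_id`` mode the universe is the CUI
    universe of the disease–variant table; the sampled CUI lists are expanded
    to gene sets via the variant→gene mapping.
    """
    n = len(universe)
    if size_a > n or size_b > n:
        raise ValueError(
            f"sample size ({max(size_a, size_b)}) exceeds universe size ({n})"
        )
    arr = np.asarray(universe, dtype=object)
    draw_a = set(rng.choice(arr, size=size_a, replace=False)) if size_a else set()
    draw_b = set(rng.choice(arr, size=size_b, replace=False)) if size_b else set()
    if mode == "gene":
        return draw_a, draw_b
    if mapping is None:
        raise ValueError("disease_id mode requires a DiseaseGeneMapping")
    return mapping.genes_of_cuis(draw_a), mapping.genes_of_cuis(draw_b)


def run_permutation(
    net: GeneNetwork,
    set_a: GeneSet,
    set_b: GeneSet,
    candidates: CandidateSet,
    cfg: PermutationConfig,
    mapping: Optional[DiseaseGeneMapping] = None,
) -> PermutationResult:
    """Estimate per-candidate null occurrence probabilities.

    Every replicate applies the same candidate rule (including the observed
    run's ``exclude_seeds`` flag) to freshly sampled inputs; x(g) counts the
    replicates whose null candidate set contains the observed candidate g.
    Deterministic given ``cfg.seed``.
    """
    if len(candidates) == 0:
        raise ValueError("candidate set is empty; nothing to test")
    iterations = cfg.iterations if cfg.iterations is not None else 100 * len(candidates)
    if iterations < 1:
        raise ValueError("iterations must be >= 1")

    if cfg.mode == "gene":
        universe = tuple(sorted(net.nodes))
        size_a = len(set_a.genes & net.nodes)
        size_b = len(set_b.genes & net.nodes)
    else:
        if mapping is None:
            raise ValueError("disease_id mode requires DisGeNET tables (mapping)")
        universe = mapping.cui_universe()
        size_a = len(mapping.query_a.cuis)
        size_b = len(mapping.query_b.cuis)

    adj = net.adjacency()
    observed = set(candidates.genes())
    exclude_seeds = candidates.exclude_seeds
    rng = np.random.default_rng(cfg.seed)

    counts = dict.fromkeys(observed, 0)
    replicate_hits: Optional[list[int]] = [] if cfg.record_replicates else None
    for it in range(iterations):
        sa, sb = sample_null_replicate(
            rng, cfg.mode, universe=universe, size_a=size_a, size_b=size_b,
            mapping=mapping,
        )
        null_cands = candidate_gene_ids(adj, sa, sb, exclude_seeds=exclude_seeds)
        hit = null_cands & observed
        for g in hit:
            counts[g] += 1
        if replicate_hits is not None:
            replicate_hits.append(len(hit))
        if cfg.log_every and (it + 1) % cfg.log_every == 0:
            logger.info("permutation: %d/%d replicates", it + 1, iterations)

    genes = candidates.genes()
    p = {g: empirical_pvalue(counts[g], iterations, cfg.plus_one) for g in genes}
    qvals = bh_adjust([p[g] for g in genes])
    q = dict(zip(genes, qvals))
    logger.info("permutation done: %d replicates, %d candidates, min p=%.3g",
                iterations, len(genes), min(p.values()))
    return PermutationResult(
        genes=genes, x={g: counts[g] for g in genes}, p=p, q=q,
        iterations=iterations, seed=cfg.seed, mode=cfg.mode,
        replicate_hits=replicate_hits,
    )


def significant_drivers(
    res: PermutationResult, candidates: CandidateSet, alpha: float = 0.05
) -> CandidateSet:
    """Candidates surviving the FDR filter (q <= alpha), ordered by p then gene."""
    missing = set(candidates.genes()) - set(res.genes)
    if missing:
        raise ValueError(f"result does not cover candidates: {sorted(missing)[:5]}")
    keep = [r for r in candidates if res.q[r.gene] <= alpha]
    keep.sort(key=lambda r: (res.p[r.gene], r.gene))
    out = CandidateSet(
        records=keep,
        label_a=candidates.label_a,
        label_b=candidates.label_b,
        exclude_seeds=candidates.exclude_seeds,
        config={**candidates.config, "alpha": alpha, "iterations": res.iterations,
                "seed": res.seed, "mode": res.mode},
    )
    # CandidateSet sorts by gene; keep the p-ordering available to callers
    out.records = keep
    return out
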