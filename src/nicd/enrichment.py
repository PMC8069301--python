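"""Fisher-exact gene-set enrichment against GMT pathway libraries.

A local reimplementation of the over-representation test behind Enrichr-style
services: for each library term, a one-sided upper-tail hypergeometric test
on the 2×2 table (k, n−k, K−k, N−K−n+k) with k the query∩term overlap, K the
term size, n the query size and N the background. The background defaults to
the union of genes across the library's terms (overridable, e.g. to the
network node count). Only the Fisher p (and its BH-adjusted q across the
library's terms) is computed — no z-score/combined-score ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from scipy.stats import hypergeom

from .network import GeneSet, _norm
from .permutation import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["GmtLibrary", "EnrichmentResult", "read_gmt", "fisher_enrichment",
           "hypergeom_upper_tail", "write_enrichment_tsv"]


@dataclass
class GmtLibrary:
    """Named gene sets: term name → member genes, plus a background size."""

    name: str
    terms: dict[str, frozenset[str]]
    background_size: Optional[int] = None  # default: |union of term genes|

    def __post_init__(self):
        for term, genes in self.terms.items():
            if not genes:
                raise ValueError(f"term {term!r} has no genes")
        universe_n = len(self.universe())
        if self.background_size is None:
            self.background_size = universe_n
        largest = max((len(g) for g in self.terms.values()), default=0)
        if self.background_size < largest:
            raise ValueError(
                f"background_size {self.background_size} smaller than the "
                f"largest term ({largest} genes)"
            )

    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.terms)


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's overlap statistics: p is the one-sided Fisher-exact value."""

    term: str
    overlap: frozenset[str]
    k: int  # overlap size
    K: int  # term size
    n: int  # query size (restricted to background)
    N: int  # background size
    p: float
    q: float = float("nan")


def read_gmt(path: str | Path, name: str | None = None) -> GmtLibrary:
    """Parse a GMT file: ``term<TAB>description<TAB>gene...`` per line.

    Duplicate genes within a term collapse; an empty file yields an empty
    library with a warning.
    """
    path = Path(path)
    terms: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs term, description and at "
                    f"least one gene (got {len(fields)} field(s))"
                )
            term = fields[0].strip()
            genes = frozenset(_norm(g) for g in fields[2:] if g.strip())
            if not genes:
                raise ValueError(f"{path}:{lineno}: term {term!r} has no gene tokens")
            terms[term] = genes
    lib = GmtLibrary(name=name or path.stem, terms=terms) if terms else GmtLibrary(
        name=name or path.stem, terms={}, background_size=0
    )
    if not terms:
        logger.warning("%s: empty GMT library", path.name)
    logger.info("%s: %d terms, %d distinct genes", path.name, len(lib), len(lib.universe()))
    return lib


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeom(N, K, n): the one-sided Fisher-exact p."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(f"invalid 2x2 table: k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_enrichment(
    query: GeneSet | Iterable[str],
    lib: GmtLibrary,
    background: Optional[Iterable[str]] = None,
) -> list[EnrichmentResult]:
    """Test the query against every library term; BH-adjust across terms.

    Query genes outside the background are dropped with a logged count.
    Results are sorted by ascending p, ties by term name.
    """
    qgenes = query.genes if isinstance(query, GeneSet) else frozenset(_norm(g) for g in query)
    if not qgenes:
        raise ValueError("query gene set is empty")
    if background is not None:
        bg = frozenset(_norm(g) for g in background)
        N = len(bg)
        restricted = qgenes & bg
    else:
        bg = lib.universe()
        N = lib.background_size if lib.background_size else len(bg)
        restricted = qgenes & bg if N == len(bg) else qgenes
    dropped = len(qgenes) - len(restricted)
    if dropped:
        logger.info("fisher_enrichment: %d query gene(s) outside background dropped", dropped)
    n = len(restricted)
    if n == 0 or N < n:
        raise ValueError(
            f"background (N={N}) cannot hold the restricted query (n={n})"
        )

    results = []
    for term, genes in lib.terms.items():
        term_genes = genes if background is None else genes & bg
        K = len(term_genes)
        if K == 0 or K > N:
            continue
        overlap = restricted & term_genes
        results.append(
            EnrichmentResult(
                term=term, overlap=frozenset(overlap), k=len(overlap),
                K=K, n=n, N=N,
                p=hypergeom_upper_tail(len(overlap), K, n, N),
            )
        )
    qvals = bh_adjust([r.p for r in results])
    results = [
        EnrichmentResult(term=r.term, overlap=r.overlap, k=r.k, K=r.K,
                         n=r.n, N=r.N, p=r.p, q=qv)
        for r, qv in zip(results, qvals)
    ]
    results.sort(key=lambda r: (r.p, r.term))
    return results


def write_enrichment_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("term\tk\tK\tn\tN\tp\tq\toverlap\n")
        for r in results:
            fh.write(
                f"{r.term}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p:.6g}\t{r.q:.6g}"
                f"\t{','.join(sorted(r.overlap))}\n"
            )
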