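"""Disease–variant and variant–gene association tables.

Assembles disease gene sets the way DisGeNET dump files are organised: a
disease (a UMLS CUI) maps to variants, and variants map to genes. A gene
belongs to a disease's set iff any of the disease's variants has a
variant→gene mapping record — membership is unfiltered by association score
or evidence class. Column names are configurable because dump schemas drift
between releases; the defaults match `all_variant_disease_associations.tsv`
and `variant_to_gene_mappings.tsv` (``diseaseId``, ``snpId``, ``geneSymbol``).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .network import GeneSet, _norm

logger = logging.getLogger(__name__)

__all__ = [
    "DiseaseVariantTable",
    "VariantGeneTable",
    "DiseaseQuery",
    "DiseaseGeneMapping",
    "read_disease_variant_table",
    "read_variant_gene_table",
    "variants_for_diseases",
    "genes_for_diseases",
    "intersect_variant_sets",
]

_CUI_RE = re.compile(r"^C\d+$")

#: default column names in DisGeNET dump files
DISEASE_VARIANT_COLUMNS = ("diseaseId", "snpId")
VARIANT_GENE_COLUMNS = ("snpId", "geneSymbol")


@dataclass
class DiseaseVariantTable:
    """Deduplicated (disease CUI, variant id) association pairs."""

    df: pd.DataFrame  # columns: cui, variant

    def __post_init__(self):
        self.df = self.df[["cui", "variant"]].astype(str).drop_duplicates(ignore_index=True)

    def __len__(self) -> int:
        return len(self.df)

    def cuis(self) -> set[str]:
        return set(self.df["cui"])

    def variants_of(self, cui: str) -> set[str]:
        return set(self.df.loc[self.df["cui"] == cui, "variant"])


@dataclass
class VariantGeneTable:
    """Deduplicated (variant id, gene) mapping pairs.

    A variant may map to several genes (e.g. overlapping/antisense loci).
    """

    df: pd.DataFrame  # columns: variant, gene

    def __post_init__(self):
        df = self.df[["variant", "gene"]].astype(str)
        df["gene"] = df["gene"].map(_norm)
        self.df = df.drop_duplicates(ignore_index=True)

    def __len__(self) -> int:
        return len(self.df)

    def genes_of(self, variants: Iterable[str]) -> set[str]:
        vs = set(variants)
        return set(self.df.loc[self.df["variant"].isin(vs), "gene"])


@dataclass(frozen=True)
class DiseaseQuery:
    """A disease/phenotype defined as a list of UMLS CUIs."""

    label: str
    cuis: tuple[str, ...]

    def __init__(self, label: str, cuis: Sequence[str]):
        cuis = tuple(dict.fromkeys(str(c).strip() for c in cuis if str(c).strip()))
        if not cuis:
            raise ValueError(f"disease query {label!r} has no CUIs")
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "cuis", cuis)

    @classmethod
    def from_file(cls, path: str | Path, label: str | None = None) -> "DiseaseQuery":
        """Read one CUI per line (blank lines and ``#`` comments skipped)."""
        path = Path(path)
        cuis = [
            ln.strip()
            for ln in path.read_text().splitlines()
            if ln.strip() and not ln.lstrip().startswith("#")
        ]
        return cls(label or path.stem, cuis)


def _read_two_columns(
    path: str | Path,
    columns: Sequence[str],
    out_names: tuple[str, str],
    what: str,
) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path.name}: missing required column(s) {missing} for {what}; "
            f"found headers {list(df.columns)}"
        )
    out = df[list(columns)].dropna()
    out.columns = list(out_names)
    if out.empty:
        logger.warning("%s: no data rows (%s)", path.name, what)
    return out.reset_index(drop=True)


def read_disease_variant_table(
    path: str | Path,
    columns: Sequence[str] = DISEASE_VARIANT_COLUMNS,
) -> DiseaseVariantTable:
    """Read a disease→variant association dump (TSV, optionally gzipped)."""
    df = _read_two_columns(path, columns, ("cui", "variant"), "disease-variant table")
    tab = DiseaseVariantTable(df)
    bad = [c for c in tab.cuis() if not _CUI_RE.match(c)]
    if bad:
        logger.warning("%d CUI value(s) do not match C<digits>, e.g. %s",
                       len(bad), bad[:3])
    logger.info("%s: %d unique (cui, variant) pairs over %d CUIs",
                Path(path).name, len(tab), len(tab.cuis()))
    return tab


def read_variant_gene_table(
    path: str | Path,
    columns: Sequence[str] = VARIANT_GENE_COLUMNS,
) -> VariantGeneTable:
    """Read a variant→gene mapping dump (TSV, optionally gzipped)."""
    df = _read_two_columns(path, columns, ("variant", "gene"), "variant-gene table")
    tab = VariantGeneTable(df)
    logger.info("%s: %d unique (variant, gene) pairs", Path(path).name, len(tab))
    return tab


def variants_for_diseases(dvt: DiseaseVariantTable, q: DiseaseQuery) -> set[str]:
    """Union of variants over every CUI in the query."""
    out: set[str] = set()
    for cui in q.cuis:
        vs = dvt.variants_of(cui)
        if not vs:
            logger.warning("query %s: CUI %s has no variant associations", q.label, cui)
        out |= vs
    return out


def genes_for_diseases(
    dvt: DiseaseVariantTable, vgt: VariantGeneTable, q: DiseaseQuery
) -> GeneSet:
    """Disease gene set: every gene with a mapping record from any query variant."""
    genes = vgt.genes_of(variants_for_diseases(dvt, q))
    logger.info("query %s (%d CUIs): %d genes", q.label, len(q.cuis), len(genes))
    return GeneSet(q.label, genes)


def intersect_variant_sets(a: set[str], b: set[str]) -> set[str]:
    """Shared variants between two diseases (the SNP cross-check)."""
    common = set(a) & set(b)
    logger.info("variant intersection: |a|=%d, |b|=%d, |a∩b|=%d",
                len(a), len(b), len(common))
    return common


@dataclass
class DiseaseGeneMapping:
    """The full disease→gene mapping context for one disease pair.

    Bundles the two tables with the pair of CUI queries; used by the
    permutation null in ``disease_id`` mode, where replicates resample CUIs
    from the table's CUI universe and re-expand them to gene sets.
    """

    dvt: DiseaseVariantTable
    vgt: VariantGeneTable
    query_a: DiseaseQuery
    query_b: DiseaseQuery
    _cui_to_genes: dict[str, frozenset[str]] = field(default=None, repr=False)  # type: ignore[assignment]

    def gene_set(self, q: DiseaseQuery) -> GeneSet:
        return genes_for_diseases(self.dvt, self.vgt, q)

    def cui_universe(self) -> tuple[str, ...]:
        return tuple(sorted(self.dvt.cuis()))

    def genes_of_cuis(self, cuis: Iterable[str]) -> set[str]:
        """Fast union of per-CUI gene sets (precomputed on first use)."""
        if self._cui_to_genes is None:
            merged = self.dvt.df.merge(self.vgt.df, on="variant")
            self._cui_to_genes = {
                cui: frozenset(sub["gene"])
                for cui, sub in merged.groupby("cui", sort=False)
            }
        out: set[str] = set()
        for cui in cuis:
            out |= self._cui_to_genes.get(cui, frozenset())
        return out
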