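"""End-to-end pipeline: tables → gene sets → candidates → permutation → report.

A single declarative config drives a run; every under-specified choice
(hub exclusion, alpha, iterations, sampling mode, seed) is materialized into
a provenance sidecar so the run is reproducible byte for byte.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from . import __version__
from .candidates import CandidateSet, find_primary_candidates
from .disgenet import (
    DISEASE_VARIANT_COLUMNS,
    VARIANT_GENE_COLUMNS,
    DiseaseGeneMapping,
    DiseaseQuery,
    genes_for_diseases,
    intersect_variant_sets,
    read_disease_variant_table,
    read_variant_gene_table,
    variants_for_diseases,
)
from .enrichment import fisher_enrichment, read_gmt, write_enrichment_tsv
from .network import GeneSet, exclude_genes, load_edge_list
from .permutation import PermutationConfig, run_permutation, significant_drivers

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "chromosome_summary"]


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    network: str
    disease_variants: str
    variant_genes: str
    cuis_a: str
    cuis_b: str
    output_dir: str
    label_a: str = "disease_a"
    label_b: str = "disease_b"
    gmt_libraries: list[str] = field(default_factory=list)
    excluded_genes: list[str] = field(default_factory=lambda: ["UBC"])
    network_format: str = "tsv-2col"
    disease_variant_columns: tuple[str, str] = DISEASE_VARIANT_COLUMNS
    variant_gene_columns: tuple[str, str] = VARIANT_GENE_COLUMNS
    exclude_seeds: bool = True
    permutation: PermutationConfig = field(default_factory=PermutationConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        perm = PermutationConfig(**raw.pop("permutation", {}))
        return cls(permutation=perm, **raw)

    def validate_paths(self) -> None:
        paths = [self.network, self.disease_variants, self.variant_genes,
                 self.cuis_a, self.cuis_b, *self.gmt_libraries]
        missing = [p for p in paths if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input file(s): {missing}")


@dataclass
class PipelineResult:
    candidates: CandidateSet
    drivers: CandidateSet
    permutation: "object"
    enrichment: dict[str, list]
    counts: dict[str, int]
    output_dir: Path


def _stage(name: str):
    logger.info("stage: %s", name)


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full analysis and write the report files.

    Outputs in ``cfg.output_dir``: ``candidates.tsv``, ``permutation.tsv``
    (all candidates with x, p, q), ``drivers.tsv`` (significant drivers with
    per-library pathway flags), one ``enrichment_<library>.tsv`` per GMT
    library, ``variant_intersection.tsv`` and ``provenance.json``.
    """
    cfg.validate_paths()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    _stage("disgenet_io")
    dvt = read_disease_variant_table(cfg.disease_variants, cfg.disease_variant_columns)
    vgt = read_variant_gene_table(cfg.variant_genes, cfg.variant_gene_columns)
    q_a = DiseaseQuery.from_file(cfg.cuis_a, label=cfg.label_a)
    q_b = DiseaseQuery.from_file(cfg.cuis_b, label=cfg.label_b)
    mapping = DiseaseGeneMapping(dvt, vgt, q_a, q_b)
    set_a = genes_for_diseases(dvt, vgt, q_a)
    set_b = genes_for_diseases(dvt, vgt, q_b)

    variants_a = variants_for_diseases(dvt, q_a)
    variants_b = variants_for_diseases(dvt, q_b)
    shared_variants = intersect_variant_sets(variants_a, variants_b)
    with open(outdir / "variant_intersection.tsv", "w") as fh:
        fh.write("metric\tvalue\n")
        fh.write(f"n_variants_{cfg.label_a}\t{len(variants_a)}\n")
        fh.write(f"n_variants_{cfg.label_b}\t{len(variants_b)}\n")
        fh.write(f"n_shared_variants\t{len(shared_variants)}\n")
        fh.write(f"shared_variants\t{','.join(sorted(shared_variants))}\n")

    _stage("network_core")
    net = load_edge_list(cfg.network, format=cfg.network_format)
    net = exclude_genes(net, GeneSet("excluded", cfg.excluded_genes))

    _stage("candidate_finder")
    candidates = find_primary_candidates(net, set_a, set_b, cfg.exclude_seeds)
    candidates.to_tsv(outdir / "candidates.tsv")

    _stage("permutation_test")
    if len(candidates) == 0:
        logger.warning("no primary candidates; writing header-only reports")
        res = None
        drivers = CandidateSet(records=[], label_a=cfg.label_a, label_b=cfg.label_b,
                               exclude_seeds=cfg.exclude_seeds)
        (outdir / "permutation.tsv").write_text(
            "gene\tsupport_a\tsupport_b\tx\tp\tq\tsignificant\n")
    else:
        res = run_permutation(net, set_a, set_b, candidates, cfg.permutation,
                              mapping=mapping)
        res.to_tsv(outdir / "permutation.tsv", candidates, cfg.permutation.alpha)
        drivers = significant_drivers(res, candidates, cfg.permutation.alpha)

    _stage("enrichment")
    enrichment: dict[str, list] = {}
    flagged: dict[str, set[str]] = {}
    for gmt_path in cfg.gmt_libraries:
        lib = read_gmt(gmt_path)
        if len(drivers) == 0 or len(lib) == 0:
            enrichment[lib.name] = []
            flagged[lib.name] = set()
            write_enrichment_tsv([], outdir / f"enrichment_{lib.name}.tsv")
            continue
        driver_set = GeneSet("drivers", drivers.genes())
        try:
            results = fisher_enrichment(driver_set, lib)
        except ValueError as err:
            logger.warning("enrichment against %s skipped: %s", lib.name, err)
            results = []
        enrichment[lib.name] = results
        # pathway flag: membership in any term enriched at q <= alpha
        flagged[lib.name] = {
            g for r in results if r.q <= cfg.permutation.alpha for g in r.overlap
        }
        write_enrichment_tsv(results, outdir / f"enrichment_{lib.name}.tsv")

    _stage("report")
    lib_names = list(enrichment)
    with open(outdir / "drivers.tsv", "w") as fh:
        header = ["gene", f"support_{cfg.label_a}", f"support_{cfg.label_b}",
                  *lib_names, "x", "p", "q"]
        fh.write("\t".join(header) + "\n")
        if len(drivers) == 0:
            logger.warning("empty driver set: header-only driver report")
        for r in drivers:
            flags = ["1" if r.gene in flagged.get(nm, set()) else "0" for nm in lib_names]
            fh.write("\t".join([
                r.gene,
                ",".join(sorted(r.support_a.genes)),
                ",".join(sorted(r.support_b.genes)),
                *flags,
                str(res.x[r.gene]), f"{res.p[r.gene]:.6g}", f"{res.q[r.gene]:.6g}",
            ]) + "\n")

    counts = {
        "n_network_nodes": net.n_nodes(),
        "n_network_edges": net.n_edges(),
        f"n_genes_{cfg.label_a}": len(set_a),
        f"n_genes_{cfg.label_b}": len(set_b),
        f"n_variants_{cfg.label_a}": len(variants_a),
        f"n_variants_{cfg.label_b}": len(variants_b),
        "n_shared_variants": len(shared_variants),
        "n_candidates": len(candidates),
        "n_drivers": len(drivers),
    }
    provenance = {
        "nicd_version": __version__,
        "config": {
            **{k: v for k, v in asdict(cfg).items() if k != "permutation"},
            "permutation": asdict(cfg.permutation),
        },
        "iterations_run": res.iterations if res is not None else 0,
        "counts": counts,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %s", json.dumps(counts))
    return PipelineResult(candidates=candidates, drivers=drivers, permutation=res,
                          enrichment=enrichment, counts=counts, output_dir=outdir)


def chromosome_summary(
    drivers: CandidateSet, gene_locations: str | Path
) -> Counter:
    """Tabulate drivers per chromosome from a two-column gene→chromosome TSV.

    Genes absent from the mapping are counted under ``"unmapped"``.
    """
    mapping: dict[str, str] = {}
    with open(gene_locations) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 2 and parts[0].strip():
                mapping[parts[0].strip().upper()] = parts[1].strip()
    counts: Counter = Counter()
    for r in drivers:
        counts[mapping.get(r.gene, "unmapped")] += 1
    return counts
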