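"""Self-contained synthetic scenarios with planted ground truth.

Generates everything the pipeline consumes — a random interactome, two
synthetic "diseases" in DisGeNET dump format (CUI→variant and variant→gene
tables), CUI query files — plus a truth manifest. The construction plants:

* **drivers**: genes outside both disease sets with at least one edge to a
  disease-A gene and at least one to a disease-B gene (always primary
  candidates);
* **one-sided decoys**: genes with at least one edge to one disease's genes
  and, enforced by edge removal, zero edges to the other's (never primary
  candidates).

The background is an independent-edge (Erdős–Rényi) random graph, chosen for
tractable null probabilities; variants are synthesized rs-numbered tokens so
the parsers see realistic variant→gene multiplicity. Deterministic and
byte-identical given a seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np

from .candidates import find_primary_candidates
from .disgenet import (
    DiseaseQuery,
    genes_for_diseases,
    read_disease_variant_table,
    read_variant_gene_table,
)
from .network import GeneNetwork, GeneSet, load_edge_list

logger = logging.getLogger(__name__)

__all__ = ["ScenarioConfig", "ScenarioTruth", "generate_scenario", "verify_truth"]


@dataclass(frozen=True)
class ScenarioConfig:
    n_genes: int = 2000
    background_edge_prob: float = 0.002
    n_cuis_a: int = 14
    n_cuis_b: int = 3
    genes_per_cui: int = 5
    n_planted_drivers: int = 5
    n_decoys_a: int = 5
    n_decoys_b: int = 5
    variants_per_gene: int = 2
    n_background_cuis: int = 0  # extra CUIs over background genes (disease_id nulls)
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_genes, self.n_cuis_a, self.n_cuis_b, self.genes_per_cui,
                  self.n_planted_drivers, self.n_decoys_a, self.n_decoys_b,
                  self.variants_per_gene, self.n_background_cuis)
        if any(c < 0 for c in counts):
            raise ValueError("all scenario counts must be >= 0")
        if not (0.0 <= self.background_edge_prob <= 1.0):
            raise ValueError("background_edge_prob must lie in [0, 1]")
        n_seed_genes = (self.n_cuis_a + self.n_cuis_b) * self.genes_per_cui
        reserved = n_seed_genes + self.n_planted_drivers + self.n_decoys_a + self.n_decoys_b
        if reserved > self.n_genes:
            raise ValueError(
                f"n_genes={self.n_genes} cannot hold {n_seed_genes} disease genes "
                f"+ {self.n_planted_drivers} drivers + "
                f"{self.n_decoys_a + self.n_decoys_b} decoys"
            )
        if self.n_genes == 0:
            raise ValueError("n_genes must be positive")


@dataclass
class ScenarioTruth:
    """Ground truth and file manifest of one generated scenario."""

    planted_drivers: list[str]
    decoys_a: list[str]
    decoys_b: list[str]
    genes_per_cui_map: dict[str, list[str]]
    cuis_a: list[str]
    cuis_b: list[str]
    files: dict[str, str]
    seed: int
    config: dict = field(default_factory=dict)

    def genes_a(self) -> set[str]:
        return {g for c in self.cuis_a for g in self.genes_per_cui_map[c]}

    def genes_b(self) -> set[str]:
        return {g for c in self.cuis_b for g in self.genes_per_cui_map[c]}

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ScenarioTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gene_name(i: int) -> str:
    return f"SYG{i:05d}"


def generate_scenario(cfg: ScenarioConfig, outdir: str | Path) -> ScenarioTruth:
    """Write a full synthetic scenario into ``outdir`` and return its truth.

    Files written: ``network.tsv`` (edge list), ``disease_variants.tsv`` and
    ``variant_genes.tsv`` (DisGeNET dump format), ``cuis_a.txt``/``cuis_b.txt``
    (one CUI per line) and ``truth.json`` (the manifest).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    genes = [_gene_name(i) for i in range(cfg.n_genes)]
    order = rng.permutation(cfg.n_genes)
    cursor = 0

    def take(k: int) -> list[str]:
        nonlocal cursor
        out = [genes[i] for i in order[cursor:cursor + k]]
        cursor += k
        return out

    cuis_a = [f"C9{i:06d}" for i in range(cfg.n_cuis_a)]
    cuis_b = [f"C8{i:06d}" for i in range(cfg.n_cuis_b)]
    gene_map = {c: sorted(take(cfg.genes_per_cui)) for c in cuis_a + cuis_b}
    genes_a = {g for c in cuis_a for g in gene_map[c]}
    genes_b = {g for c in cuis_b for g in gene_map[c]}
    drivers = sorted(take(cfg.n_planted_drivers))
    decoys_a = sorted(take(cfg.n_decoys_a))
    decoys_b = sorted(take(cfg.n_decoys_b))
    background = [genes[i] for i in order[cursor:]]

    bg_cuis = [f"C7{i:06d}" for i in range(cfg.n_background_cuis)]
    for i, c in enumerate(bg_cuis):
        if not background:
            raise ValueError("n_background_cuis set but no background genes remain")
        picked = rng.choice(np.asarray(background, dtype=object),
                            size=min(cfg.genes_per_cui, len(background)),
                            replace=False)
        gene_map[c] = sorted(str(g) for g in picked)

    # background graph, then enforce planted adjacency / decoy one-sidedness
    g = nx.fast_gnp_random_graph(
        cfg.n_genes, cfg.background_edge_prob,
        seed=int(rng.integers(2**31 - 1)),
    )
    graph = nx.relabel_nodes(g, {i: genes[i] for i in range(cfg.n_genes)})

    def force_edge(node: str, pool: set[str]) -> None:
        if not (set(graph[node]) & pool):
            target = str(rng.choice(np.asarray(sorted(pool), dtype=object)))
            graph.add_edge(node, target)

    def forbid_edges(node: str, pool: set[str]) -> None:
        for other in set(graph[node]) & pool:
            graph.remove_edge(node, other)

    if cfg.n_planted_drivers and (not genes_a or not genes_b):
        raise ValueError("cannot plant drivers without genes on both diseases")
    for d in drivers:
        force_edge(d, genes_a)
        force_edge(d, genes_b)
        forbid_edges(d, genes_a & genes_b)  # defensive; pools are disjoint
    if cfg.n_decoys_a and not genes_a:
        raise ValueError("cannot plant A-decoys without disease-A genes")
    for d in decoys_a:
        force_edge(d, genes_a)
        forbid_edges(d, genes_b)
    if cfg.n_decoys_b and not genes_b:
        raise ValueError("cannot plant B-decoys without disease-B genes")
    for d in decoys_b:
        force_edge(d, genes_b)
        forbid_edges(d, genes_a)

    net = GeneNetwork.from_edges(graph.edges, nodes=genes, provenance="synthetic")
    net.to_tsv(outdir / "network.tsv")

    # DisGeNET-format tables: variants_per_gene synthetic rs tokens per disease gene
    dv_rows: list[tuple[str, str]] = []
    vg_rows: list[tuple[str, str]] = []
    variant_no = 1
    for cui in sorted(gene_map):
        for gene in gene_map[cui]:
            for _ in range(cfg.variants_per_gene):
                rs = f"rs{variant_no:07d}"
                variant_no += 1
                dv_rows.append((cui, rs))
                vg_rows.append((rs, gene))
    with open(outdir / "disease_variants.tsv", "w") as fh:
        fh.write("diseaseId\tsnpId\n")
        for cui, rs in dv_rows:
            fh.write(f"{cui}\t{rs}\n")
    with open(outdir / "variant_genes.tsv", "w") as fh:
        fh.write("snpId\tgeneSymbol\n")
        for rs, gene in vg_rows:
            fh.write(f"{rs}\t{gene}\n")
    (outdir / "cuis_a.txt").write_text("".join(f"{c}\n" for c in cuis_a))
    (outdir / "cuis_b.txt").write_text("".join(f"{c}\n" for c in cuis_b))

    truth = ScenarioTruth(
        planted_drivers=drivers,
        decoys_a=decoys_a,
        decoys_b=decoys_b,
        genes_per_cui_map=gene_map,
        cuis_a=cuis_a,
        cuis_b=cuis_b,
        files={
            "network": "network.tsv",
            "disease_variants": "disease_variants.tsv",
            "variant_genes": "variant_genes.tsv",
            "cuis_a": "cuis_a.txt",
            "cuis_b": "cuis_b.txt",
        },
        seed=cfg.seed,
        config=asdict(cfg),
    )
    truth.to_json(outdir / "truth.json")
    logger.info("scenario written to %s: %d nodes, %d edges, %d drivers",
                outdir, net.n_nodes(), net.n_edges(), len(drivers))
    return truth


def verify_truth(truth: ScenarioTruth, directory: str | Path) -> dict[str, bool]:
    """Reload the scenario files and check every ground-truth invariant.

    Returns a check-name → pass mapping. Checks: the disease gene sets
    reassemble from the tables exactly as the manifest records; every planted
    driver has edges to both disease sets and sits outside them; every decoy
    touches exactly one side; drivers are recovered (and decoys absent) when
    the candidate identification runs on the reloaded files.
    """
    directory = Path(directory)
    for fname in truth.files.values():
        if not (directory / fname).exists():
            raise FileNotFoundError(directory / fname)

    net = load_edge_list(directory / truth.files["network"])
    dvt = read_disease_variant_table(directory / truth.files["disease_variants"])
    vgt = read_variant_gene_table(directory / truth.files["variant_genes"])
    q_a = DiseaseQuery.from_file(directory / truth.files["cuis_a"], label="disease_a")
    q_b = DiseaseQuery.from_file(directory / truth.files["cuis_b"], label="disease_b")
    set_a = genes_for_diseases(dvt, vgt, q_a)
    set_b = genes_for_diseases(dvt, vgt, q_b)

    checks: dict[str, bool] = {}
    checks["gene_set_a_matches_manifest"] = set_a.genes == frozenset(truth.genes_a())
    checks["gene_set_b_matches_manifest"] = set_b.genes == frozenset(truth.genes_b())

    adj = net.adjacency()
    drivers = set(truth.planted_drivers)
    checks["drivers_outside_seed_sets"] = not (drivers & (set_a.genes | set_b.genes))
    checks["driver_bi_linkage"] = all(
        adj.get(d, set()) & set_a.genes and adj.get(d, set()) & set_b.genes
        for d in drivers
    )
    checks["decoys_a_one_sided"] = all(
        adj.get(d, set()) & set_a.genes and not adj.get(d, set()) & set_b.genes
        for d in truth.decoys_a
    )
    checks["decoys_b_one_sided"] = all(
        adj.get(d, set()) & set_b.genes and not adj.get(d, set()) & set_a.genes
        for d in truth.decoys_b
    )

    if set_a.genes or set_b.genes:
        cands = set(find_primary_candidates(net, set_a, set_b).genes())
        checks["drivers_are_candidates"] = drivers <= cands
        checks["decoys_not_candidates"] = not (
            cands & (set(truth.decoys_a) | set(truth.decoys_b))
        )
    for name, ok in checks.items():
        if not ok:
            logger.warning("verify_truth: check %r FAILED", name)
    return checks
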