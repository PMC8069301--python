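# Methods

## The model

`nicd` identifies **common driver genes** for a pair of comorbid diseases
from purely topological evidence on a gene–gene interaction network. The
procedure has four stages.

**1. Disease gene sets.** Each disease is defined as a list of UMLS CUIs.
From a disease→variant association table and a variant→gene mapping table
(DisGeNET dump format), the disease gene set is

    G(D) = { g : ∃ v, (c, v) in disease–variant table for some c in D,
                      (v, g) in variant–gene table }.

Membership is deliberately unfiltered — any variant–gene mapping record
suffices; association scores and evidence classes are ignored. The variant
sets of the two diseases are also intersected and reported, as a check on
whether the diseases share anything at the SNP level (for the OSA–dementia
pair they do not).

**2. Primary candidates.** On an undirected, unweighted interactome, a gene
g is a *primary candidate* iff it has at least one direct neighbour in each
disease gene set:

    N(g) ∩ G(A) ≠ ∅  and  N(g) ∩ G(B) ≠ ∅.

Candidacy is binary and distance-1 only: no diffusion, no multi-hop paths,
no weighting by the number of supporting neighbours. By default genes
belonging to either disease set are excluded from candidacy
(`exclude_seeds=True`), so candidates are bridges *between* the two disease
modules; the flag is configurable for sensitivity analysis. The
near-universally connected UBC hub is removed from the network before any
query (default exclusion list `{UBC}`), since a gene adjacent to almost
everything would make almost everything a candidate.

**3. Permutation null.** To measure how easily a candidate arises by
chance, the identification is re-run on randomly drawn inputs. With n the
number of observed primary candidates, the default is 100·n replicates. In
each replicate two input sets are drawn independently, uniformly without
replacement, at the observed sizes; the candidate rule (including the
`exclude_seeds` flag) is applied; and every observed candidate found in the
replicate's candidate set has its count x incremented. Then

    p(g) = x(g) / iterations          (exactly; p = 0 is possible),

with an opt-in conservative estimator (x+1)/(iterations+1). Benjamini–
Hochberg step-up adjustment across the observed candidates gives q-values,
and drivers are the candidates with q ≤ α (default α = 0.05).

Two null universes are provided, because the resampling unit is genuinely
ambiguous in this design:

* `disease_id` (default): replicates draw CUI lists of the observed lengths
  from the association table's CUI universe and expand them to gene sets
  exactly as the observed queries were — the null preserves the
  CUI-to-gene-set expansion machinery;
* `gene`: replicates draw gene sets of the observed sizes directly from the
  network's node set.

Both are first-class and tested. The two drawn sets may overlap each other
(independence is the simplest defensible choice and is what the exact
enumeration oracles assume). Degree-preserving rewiring nulls and analytic
hypergeometric shortcuts are intentionally out of scope — they would change
the method, not re-implement it.

The reference OSA–dementia report is arithmetically consistent with this
design read as n = number of primary candidates (3610, hence 361000
replicates): every one of its 42 printed p-values times 361000 lands within
0.5 of a positive integer (e.g. 8.31×10⁻⁶ ↔ 3 counts, 1.36×10⁻⁴ ↔ 49),
which would not hold for n = number of final drivers. The acceptance suite
checks this property.

**4. Enrichment.** Surviving drivers are annotated against GMT pathway
libraries with the one-sided Fisher exact test: for a term of size K, query
of size n and background N, p = P(X ≥ k) with X ~ Hypergeometric(N, K, n).
BH adjustment is applied per library. The background defaults to the union
of the library's genes and is overridable (e.g. to the network node count);
web-service score corrections (z-score/combined score) are not reproduced
since their constants are not published. The driver report marks each
driver that belongs to any term enriched at q ≤ α, per library.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `excluded_genes` | `[UBC]` | hub genes removed from the network before queries |
| `exclude_seeds` | `True` | disease genes cannot themselves be candidates |
| `mode` | `disease_id` | null universe: CUIs re-expanded, or network genes |
| `iterations` | `100·n` | permutation replicates (n = primary candidates) |
| `alpha` | `0.05` | BH FDR threshold for driver selection (and enrichment flags) |
| `plus_one` | `False` | conservative (x+1)/(it+1) empirical p |
| `seed` | required | single RNG seed; runs are byte-reproducible |

α is a required, logged configuration value: the driver-selection cutoff is
the one under-specified choice that most affects the output, so it is
materialized into every provenance sidecar rather than hidden.

## Synthetic scenarios

The generator builds a fully self-contained study: an Erdős–Rényi
background graph over `n_genes` genes, two synthetic diseases
(`n_cuis_a`/`n_cuis_b` CUIs, `genes_per_cui` genes each, disjoint pools,
`variants_per_gene` synthetic rs-tokens per gene), plus three planted
structures with enforced adjacency:

* **planted drivers** — outside both disease sets, ≥1 edge to each side
  (always primary candidates);
* **one-sided decoys** — ≥1 edge to one side, edges to the other side
  removed (never primary candidates);
* background genes, which may become candidates by chance — that is the
  realistic part of the null.

Defaults mirror the desk-scale study conditions: 2000 genes, edge
probability 0.002 (mean degree ≈ 4, the sparse-interactome regime), 14+3
CUIs with 5 genes per CUI (70 vs 15 disease genes, preserving the strong
A/B asymmetry of the dementia-vs-OSA sets), 5 drivers, 5+5 decoys, 2
variants per gene. `verify_truth` reloads every emitted file through the
production parsers and re-checks all invariants.

An Erdős–Rényi background was chosen over a configuration-model graph
because it makes the null candidacy probability of any planted driver
analytically tractable; the cost is an unrealistically thin degree tail, so
synthetic results say nothing about hub-driven artifacts beyond the UBC
rule. Likewise, synthetic scenarios contain no linkage structure between
variants and no evidence scores — passing the recovery test shows the
statistical chain is correct, not that real DisGeNET evidence is clean.

On synthetic data the permutation tests run in `gene` mode: a miniature
scenario has only 17 disease CUIs, so a `disease_id` null drawn from so
small a universe would largely resample the observed queries themselves — a
property of the fixture's size, not of the method. The optional
`n_background_cuis` knob pads the CUI universe with decoy phenotypes so
`disease_id` mode can be exercised synthetically as well.

## Numerical choices

* Empirical p is the exact ratio x/iterations, allowing p = 0, matching the
  published report's arithmetic; the plus-one estimator is opt-in.
* BH is implemented directly (q_(i) = min_{j≥i} p_(j)·m/j, clipped to 1),
  with q clamped to ≥ p to absorb one-ulp float rounding; it is tested
  against an independent step-up oracle and statsmodels.
* The Fisher tail uses `scipy.stats.hypergeom.sf(k−1, N, K, n)`; it is
  verified against full combinatorial enumeration for all tables with
  N ≤ 20 at 10⁻⁹.
* Gene identifiers are opaque, uppercased strings; no symbol↔Entrez
  translation is attempted (an optional mapping file can be applied at
  network load). Mixing identifier spaces silently would corrupt every set
  intersection the method relies on.
* Canonical network TSV output sorts edges lexicographically with endpoints
  sorted per edge; isolated nodes round-trip as self-pair lines, which the
  loader folds back into bare nodes.
* Ties in driver ordering break by gene identifier; reports are therefore
  byte-stable under a fixed seed.

## Problem sizes used by the test suite

The desk-scale suite verifies the statistics where exact answers exist:
exhaustive oracles up to 300-node graphs for candidacy, a 5-gene universe
whose null is enumerable (P = 4/25) for the permutation, all N ≤ 20 tables
for the Fisher tail, and ten 2000-gene scenarios for end-to-end planted-
driver recovery. The full-scale analysis (a ~19k-node interactome, ~3600
candidates, 361000 replicates) needs the external PCNet and DisGeNET
downloads; `profiles/osa_dementia.yaml` documents that run.

## Known limitations

* Candidacy ignores how *many* neighbours support a gene; a single shared
  edge on each side suffices. This is faithful to the method but makes
  results sensitive to single false-positive interactions.
* The `disease_id` null inherits the size distribution of whatever CUIs it
  samples, so diseases with atypically large gene sets make the null
  conservative for small-set pairs.
* No network-propagation or expression data enters the analysis; "common
  driver" here is a purely topological statement.
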