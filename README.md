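# nicd — network-based identification of common driver genes

`nicd` finds genes that plausibly drive **two** comorbid diseases at once.
Given an undirected gene–gene interaction network and two disease gene sets
assembled from DisGeNET-style dump tables (disease CUI → variant → gene),
it reports every gene with direct network links into *both* disease sets,
filters those candidates through a permutation null with Benjamini–Hochberg
FDR control, and annotates the survivors by Fisher-exact pathway enrichment
against GMT libraries. The reference application is the obstructive sleep
apnea (OSA) / dementia pair on PCNet v1.3, where the procedure yields 42
common drivers dominated by olfactory-receptor and GPCR signalling genes.

It is aimed at systems-biology practitioners who want a transparent,
fully reproducible implementation of the neighbour-intersection +
permutation recipe — every run is driven by one declarative config, seeded,
and emits a provenance sidecar.

## The statistic

A gene g is a **primary candidate** iff

&nbsp;&nbsp;&nbsp;&nbsp;N(g) ∩ G(A) ≠ ∅ and N(g) ∩ G(B) ≠ ∅,

with N(g) the network neighbours of g and G(A), G(B) the disease gene sets
(by default g itself may not belong to either set, and the promiscuous UBC
hub is removed first). For n observed candidates, 100·n permutation
replicates redraw the inputs at their observed sizes — either as random CUI
lists re-expanded through the variant tables (`disease_id` mode, default)
or as random gene sets from the network (`gene` mode) — and

&nbsp;&nbsp;&nbsp;&nbsp;p(g) = x(g) / iterations,

where x(g) counts replicates whose null candidate set contains g. BH-
adjusted q ≤ α (default 0.05) selects the **common drivers**. Enrichment of
the drivers against a GMT library term of size K uses the one-sided
hypergeometric tail P(X ≥ k), X ~ HG(N, K, n). Details, design choices and
limitations: [docs/methods.md](docs/methods.md).

## Worked example

Generate a synthetic study — 2000 genes, two diseases of 70 and 15 genes,
5 planted bridge drivers, 10 one-sided decoys — then run the pipeline:

```bash
nicd simulate --out scn --seed 1
cat > run.yaml <<EOF
network: scn/network.tsv
disease_variants: scn/disease_variants.tsv
variant_genes: scn/variant_genes.tsv
cuis_a: scn/cuis_a.txt
cuis_b: scn/cuis_b.txt
output_dir: out
permutation: {mode: gene, seed: 1}
EOF
nicd run --config run.yaml
```

which prints

```
wrote reports to out
n_network_nodes	2000
n_network_edges	3987
n_genes_disease_a	70
n_genes_disease_b	15
n_variants_disease_a	140
n_variants_disease_b	30
n_shared_variants	0
n_candidates	15
n_drivers	15
```

Reading the counts: the two synthetic diseases share no variants
(`n_shared_variants 0`, mirroring the SNP cross-check of the OSA–dementia
study); 15 genes touch both disease modules (`n_candidates`), the 5 planted
drivers plus 10 that arise from random background edges; and at 100·15 =
1500 replicates all 15 survive the FDR filter — background candidates are
*genuine* bridges in this graph, the permutation test only removes genes
that recur by chance under resampling. The driver report shows each
driver's supporting genes on both sides with its occurrence count and
(adjusted) empirical p-value:

```
gene     support_disease_a  support_disease_b  x  p            q
SYG00939 SYG00700           SYG00352           1  0.000666667  0.005
SYG01053 SYG01246           SYG01269           1  0.000666667  0.005
SYG01953 SYG01879           SYG00073           4  0.00266667   0.01
```

`out/` also contains the full per-candidate permutation table, one
enrichment TSV per GMT library (when configured), the variant-intersection
report and `provenance.json` with every materialized default.

For a real disease pair, point the same config at a PCNet edge-list export,
the two DisGeNET dump files and your CUI lists —
[profiles/osa_dementia.yaml](profiles/osa_dementia.yaml) is a filled-in
template for the OSA–dementia analysis (the 14+3 CUI query lists ship in
`nicd.data`, as does the published 42-driver report for comparison).

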