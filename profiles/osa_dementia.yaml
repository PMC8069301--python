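# Reproduction profile: common driver genes between obstructive sleep apnea
# and the dementia umbrella.
#
# Fill in the three external inputs (none are redistributable here):
#   network          — PCNet v1.3 exported from NDEx
#                      (UUID f93f402c-86d4-11e7-a10d-0ac135e8bacf) as a
#                      two-column TSV edge list
#   disease_variants — DisGeNET all_variant_disease_associations.tsv.gz
#   variant_genes    — DisGeNET variant_to_gene_mappings.tsv.gz
#   gmt_libraries    — "KEGG 2019 Human" and "BioPlanet 2019" GMT files
#
# The CUI query lists (14 dementia CUIs, 3 OSA CUIs) ship with the package:
#   python -c "from nicd.data import data_path; print(data_path('cuis_dementia.txt'))"
#
# With the dumps as they stood in late May 2020 this run yields 1108 dementia
# genes, 23 OSA genes, 3610 primary candidates, 42 significant drivers and an
# empty variant intersection. DisGeNET releases drift; record the dump date
# alongside any rerun.

network: /path/to/pcnet_v1.3_edges.tsv
disease_variants: /path/to/all_variant_disease_associations.tsv.gz
variant_genes: /path/to/variant_to_gene_mappings.tsv.gz
cuis_a: /path/to/cuis_dementia.txt   # copy from nicd.data
cuis_b: /path/to/cuis_osa.txt
label_a: dementia
label_b: osa
gmt_libraries:
  - /path/to/KEGG_2019_Human.gmt
  - /path/to/BioPlanet_2019.gmt
excluded_genes: [UBC]
output_dir: results/osa_dementia
permutation:
  mode: disease_id
  iterations: null   # 100 x number of primary candidates
  seed: 0
  alpha: 0.05
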