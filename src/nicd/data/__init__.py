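"""Packaged reference data for the OSA–dementia disease pair.

* ``osa_dementia_drivers.tsv`` — the published report of 42 common driver
  genes for obstructive sleep apnea vs. the dementia umbrella, with each
  driver's supporting disease genes, olfactory/GPCR pathway flags and
  permutation p-value. Shipped so the report format and its arithmetic can
  be checked without the external interactome and association dumps.
* ``cuis_dementia.txt`` / ``cuis_osa.txt`` — the UMLS CUI query lists
  (14 dementia-umbrella CUIs, 3 OSA CUIs) used to assemble the disease gene
  sets from DisGeNET-format dumps in the reproduction profile.
"""

from importlib import resources
from pathlib import Path

import pandas as pd

from ..disgenet import DiseaseQuery

__all__ = ["load_reference_drivers", "reference_query", "data_path"]

#: iterations behind the reference report's empirical p-values: 100 × 3610
#: primary candidates.
REFERENCE_ITERATIONS = 361_000


def data_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files(__package__) / name)


def load_reference_drivers() -> pd.DataFrame:
    """The 42-row OSA–dementia driver reference table.

    Columns: common_gene, dementia_genes, osa_genes (comma-joined supports),
    olfactory / gpcr (0/1 pathway flags), p_value (empirical permutation p).
    """
    df = pd.read_csv(data_path("osa_dementia_drivers.tsv"), sep="\t")
    df["olfactory"] = df["olfactory"].astype(bool)
    df["gpcr"] = df["gpcr"].astype(bool)
    return df


def reference_query(disease: str) -> DiseaseQuery:
    """CUI query list for ``"dementia"`` or ``"osa"``."""
    fname = {"dementia": "cuis_dementia.txt", "osa": "cuis_osa.txt"}
    if disease not in fname:
        raise KeyError(f"unknown reference disease {disease!r}")
    return DiseaseQuery.from_file(data_path(fname[disease]), label=disease)
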