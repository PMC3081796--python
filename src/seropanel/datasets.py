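"""Packaged reference tables from the source study.

Two small tab-separated fixtures ship with the package:

* ``table1_candidates.tsv`` — the published candidate biomarker panel
  (per time point: accession, human homolog gene id, description, detection
  counts out of six animals per group, normalized scan-count ratio with "-"
  for treated-only proteins, and Holm-Sidak adjusted p-value);
* ``table2_go_annotations.tsv`` — the published one-term-per-category GO
  classification of those proteins.

``PUBLISHED_ID_TOTALS`` records the reported number of proteins identified
(by two or more peptides) per time point, the input to the identification
summary statistic.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .go import read_go_map

#: Proteins identified per time point in the source study.
PUBLISHED_ID_TOTALS = {"4h": 818, "1d": 928, "3d": 978}

#: Treated group size in the source study.
N_TREATED = 6

CANDIDATE_COLUMNS = [
    "timepoint",
    "protein_accession",
    "gene_id",
    "description",
    "detect_c",
    "detect_t",
    "ratio",
    "p_adjusted",
]


def _data_path(name: str):
    return resources.files("seropanel.data").joinpath(name)


def load_candidate_table() -> pd.DataFrame:
    """The published candidate panel; "-" ratios parsed as NaN (undefined)."""
    with resources.as_file(_data_path("table1_candidates.tsv")) as path:
        df = pd.read_csv(
            path,
            sep="\t",
            dtype={"gene_id": str},
            na_values={"ratio": ["-"]},
            keep_default_na=False,
        )
    df["ratio"] = pd.to_numeric(df["ratio"], errors="coerce")
    df["p_adjusted"] = df["p_adjusted"].astype(float)
    for col in ("detect_c", "detect_t"):
        df[col] = df[col].astype(np.int64)
    return df[CANDIDATE_COLUMNS]


def load_go_annotations() -> pd.DataFrame:
    """The published protein -> GO component/process mapping."""
    with resources.as_file(_data_path("table2_go_annotations.tsv")) as path:
        return read_go_map(path)


def candidate_tables_by_timepoint() -> dict[str, pd.DataFrame]:
    """The published panel split per time point, preserving row order."""
    table = load_candidate_table()
    return {
        tp: sub.reset_index(drop=True)
        for tp, sub in table.groupby("timepoint", sort=False)
    }
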