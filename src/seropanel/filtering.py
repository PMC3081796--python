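"""Identification filtering and IEF fraction merging.

PSMs are kept when both identification probabilities clear their thresholds
(spectrum 0.85, protein 0.60 by default; comparisons are inclusive so the
printed thresholds are attainable values). The ten IEF fractions of each
sample are then pooled, and within each sample a protein must be supported
by at least two distinct peptide sequences (the two-peptide rule) to count
as detected. The result is a per-sample protein spectral-count matrix.

The two-peptide rule is applied per sample after fraction merging: a peptide
seen once in fraction 3 and a different peptide seen once in fraction 7 of
the same sample together satisfy the rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import PSM_COLUMNS

_PROB_COLUMNS = ("spectrum_probability", "protein_probability")


@dataclass(frozen=True)
class FilterThresholds:
    spectrum_probability_min: float = 0.85
    protein_probability_min: float = 0.60
    min_unique_peptides: int = 2

    def __post_init__(self) -> None:
        for name in ("spectrum_probability_min", "protein_probability_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_unique_peptides < 1:
            raise ValueError("min_unique_peptides must be >= 1")


def filter_psms(psms: pd.DataFrame, thresholds: FilterThresholds) -> pd.DataFrame:
    """Retain PSMs with both probabilities at or above their thresholds.

    Row order is preserved. A record with a missing probability is an error
    (the record's positional index is named).
    """
    for col in _PROB_COLUMNS:
        if col not in psms.columns:
            raise ValueError(f"PSM table lacks column {col!r}")
        na = psms[col].isna()
        if na.any():
            first = int(np.flatnonzero(na.to_numpy())[0])
            raise ValueError(f"record {first} has missing {col}")
    mask = (psms["spectrum_probability"] >= thresholds.spectrum_probability_min) & (
        psms["protein_probability"] >= thresholds.protein_probability_min
    )
    return psms.loc[mask].copy()


def assemble_protein_hits(
    psms: pd.DataFrame, thresholds: FilterThresholds
) -> pd.DataFrame:
    """Merge fractions per sample and apply the two-peptide rule.

    Input is assumed probability-filtered. Returns one row per retained
    (sample, protein) with its pooled spectral count and the number of
    distinct peptide sequences supporting it.
    """
    if psms.empty:
        return pd.DataFrame(
            columns=[
                "sample_id",
                "protein_accession",
                "unique_peptide_count",
                "spectral_count",
            ]
        )
    hits = (
        psms.groupby(["sample_id", "protein_accession"], sort=True)
        .agg(
            unique_peptide_count=("peptide_sequence", "nunique"),
            spectral_count=("peptide_sequence", "size"),
        )
        .reset_index()
    )
    keep = hits["unique_peptide_count"] >= thresholds.min_unique_peptides
    return hits.loc[keep].reset_index(drop=True)


@dataclass
class CountMatrix:
    """Per-sample protein spectral counts plus the study design.

    ``counts``: proteins (rows) x samples (columns), non-negative integers,
    zero where a protein was not detected in a sample. ``design``: indexed by
    sample_id with columns animal_id, group, timepoint.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if set(self.counts.columns) != set(self.design.index):
            raise ValueError("count matrix columns must match design sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("spectral counts must be non-negative")

    @property
    def totals(self) -> pd.Series:
        """Per-sample grand total spectral counts (column sums)."""
        return self.counts.sum(axis=0)

    def samples(self, timepoint: str, group: str) -> pd.Index:
        d = self.design
        return d.index[(d["timepoint"] == timepoint) & (d["group"] == group)]


def design_from_psms(psms: pd.DataFrame) -> pd.DataFrame:
    """Sample metadata (animal, group, timepoint) recovered from a PSM table."""
    design = (
        psms[["sample_id", "animal_id", "group", "timepoint"]]
        .drop_duplicates()
        .set_index("sample_id")
        .sort_index()
    )
    if design.index.has_duplicates:
        dup = design.index[design.index.duplicated()][0]
        raise ValueError(f"sample {dup!r} has inconsistent design metadata")
    return design


def build_count_matrix(hits: pd.DataFrame, design: pd.DataFrame) -> CountMatrix:
    """Pivot protein hits into a CountMatrix over the full design.

    Samples without any retained hit appear as all-zero columns. Duplicate
    (sample, protein) rows are an upstream merging failure and rejected.
    """
    if "sample_id" in design.columns:
        design = design.set_index("sample_id")
    unknown = set(hits["sample_id"]) - set(design.index)
    if unknown:
        raise ValueError(f"unknown sample_id {sorted(unknown)[0]!r} in protein hits")
    dup = hits.duplicated(subset=["sample_id", "protein_accession"])
    if dup.any():
        row = hits.loc[dup].iloc[0]
        raise ValueError(
            "duplicate (sample, protein) rows for "
            f"({row['sample_id']}, {row['protein_accession']}); "
            "fractions must be merged upstream"
        )
    if hits.empty:
        counts = pd.DataFrame(
            np.zeros((0, len(design)), dtype=np.int64), columns=design.index
        )
    else:
        counts = (
            hits.pivot(
                index="protein_accession", columns="sample_id", values="spectral_count"
            )
            .reindex(columns=design.index)
            .fillna(0)
            .astype(np.int64)
        )
        counts = counts.sort_index()
    counts.columns.name = None
    counts.index.name = "protein_accession"
    return CountMatrix(counts=counts, design=design)


def write_count_matrix(matrix: CountMatrix, counts_path: str | Path, design_path: str | Path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t")
    matrix.design.to_csv(design_path, sep="\t")


def read_count_matrix(counts_path: str | Path, design_path: str | Path) -> CountMatrix:
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts = counts.astype(np.int64)
    design = pd.read_csv(design_path, sep="\t", index_col=0)
    return CountMatrix(counts=counts, design=design)
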