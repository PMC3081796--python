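"""Tab-separated readers/writers for the pipeline's tables.

Conventions: ratios printed to 4 decimals or "-" when undefined; G to 4
decimals; p-values in scientific notation. Parsing reverses the "-" marker
to NaN.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

COMPARISON_COLUMNS = [
    "protein_accession",
    "timepoint",
    "x_c",
    "x_t",
    "T_c",
    "T_t",
    "ratio",
    "G",
    "p_raw",
    "detect_c",
    "detect_t",
]


def _format_ratio(r: float) -> str:
    return "-" if pd.isna(r) else f"{r:.4f}"


def write_comparisons(comparisons: pd.DataFrame, path: str | Path) -> None:
    out = comparisons[COMPARISON_COLUMNS].copy()
    out["ratio"] = out["ratio"].map(_format_ratio)
    out["G"] = out["G"].map(lambda g: f"{g:.4f}")
    out["p_raw"] = out["p_raw"].map(lambda p: f"{p:.6E}")
    out.to_csv(path, sep="\t", index=False)


def read_comparisons(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values={"ratio": ["-"]}, keep_default_na=False)
    df["ratio"] = pd.to_numeric(df["ratio"], errors="coerce")
    for col in ("G", "p_raw"):
        df[col] = df[col].astype(float)
    for col in ("x_c", "x_t", "T_c", "T_t", "detect_c", "detect_t"):
        df[col] = df[col].astype(np.int64)
    return df[COMPARISON_COLUMNS]


def write_candidates(candidates: pd.DataFrame, path: str | Path) -> None:
    out = candidates.copy()
    out["ratio"] = out["ratio"].map(_format_ratio)
    out["p_adjusted"] = out["p_adjusted"].map(lambda p: f"{p:.6E}")
    out.to_csv(path, sep="\t", index=False)


def read_candidates(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values={"ratio": ["-"]}, keep_default_na=False)
    df["ratio"] = pd.to_numeric(df["ratio"], errors="coerce")
    df["p_adjusted"] = df["p_adjusted"].astype(float)
    return df
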