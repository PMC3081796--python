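"""Post-statistics biomarker filter cascade and cross-time-point overlap.

The cascade reproduces a stringent candidate-selection procedure:

1. pre-filter: raw G-test p < 0.05 AND elevated in the treated group
   (ratio > 1 or treated-only);
2. Holm-Sidak step-down adjustment over the pre-filtered family (family size
   m is the elevated subset per time point, not the full protein list);
3. keep adjusted p < 0.05;
4. keep at least a twofold normalized scan-count ratio — treated-only
   proteins (undefined ratio) bypass this rule;
5. keep proteins detected in at least 50% of the treated samples (the
   boundary is inclusive: 3 of 6 passes).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CascadeConfig:
    alpha_prefilter: float = 0.05
    alpha_adjusted: float = 0.05
    min_fold: float = 2.0
    min_detection_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("alpha_prefilter", "alpha_adjusted", "min_detection_fraction"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.min_fold < 1.0:
            raise ValueError("min_fold must be >= 1")


def prefilter_elevated(
    comparisons: pd.DataFrame, config: CascadeConfig
) -> pd.DataFrame:
    """Elevated-in-treated subset with raw p below the pre-filter alpha.

    The number of retained rows is the Holm-Sidak family size m for this
    time point. Mixing time points in one call is an error.
    """
    if comparisons["timepoint"].nunique() > 1:
        raise ValueError("prefilter_elevated expects a single time point")
    ratio = comparisons["ratio"]
    elevated = (ratio > 1.0) | (ratio.isna() & (comparisons["x_t"] > 0))
    keep = (comparisons["p_raw"] < config.alpha_prefilter) & elevated
    return comparisons.loc[keep].copy()


def holm_sidak(p_values) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values, in input order.

    Sort ascending; the rank-i candidate (1-based, family size m) is
    1 - (1 - p_(i))^(m - i + 1); running maxima enforce monotonicity and
    values are capped at 1. Computed via expm1/log1p so very small inputs
    do not underflow to zero prematurely.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("holm_sidak requires at least one p-value")
    if np.isnan(p).any() or ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    k = m - np.arange(m)  # m, m-1, ..., 1
    with np.errstate(divide="ignore"):
        candidate = -np.expm1(k * np.log1p(-sorted_p))
    candidate = np.where(sorted_p >= 1.0, 1.0, candidate)
    adjusted_sorted = np.minimum(np.maximum.accumulate(candidate), 1.0)
    adjusted = np.empty(m, dtype=float)
    adjusted[order] = adjusted_sorted
    return adjusted


def min_detection_count(config: CascadeConfig, n_treated: int) -> int:
    """Smallest treated-detection count satisfying the frequency rule."""
    return math.ceil(config.min_detection_fraction * n_treated)


def filter_candidates(
    rows: pd.DataFrame, config: CascadeConfig, n_treated: int
) -> pd.DataFrame:
    """Final three filters on rows that already carry adjusted p-values.

    Keeps adjusted p < alpha, ratio >= min_fold (undefined ratios bypass),
    and treated detection at or above the frequency threshold. Output is
    sorted by descending ratio (undefined-ratio rows last), ties broken by
    ascending adjusted p.
    """
    if n_treated < 1:
        raise ValueError("n_treated must be >= 1")
    ratio = rows["ratio"]
    keep = (
        (rows["p_adjusted"] < config.alpha_adjusted)
        & (ratio.isna() | (ratio >= config.min_fold))
        & (rows["detect_t"] >= min_detection_count(config, n_treated))
    )
    out = rows.loc[keep].copy()
    return out.sort_values(
        ["ratio", "p_adjusted"],
        ascending=[False, True],
        na_position="last",
        kind="stable",
    ).reset_index(drop=True)


def apply_cascade(
    comparisons: pd.DataFrame, config: CascadeConfig, n_treated: int
) -> pd.DataFrame:
    """Full cascade on one time point's comparison table.

    Returns the candidate panel with columns timepoint, protein_accession,
    detect_c, detect_t, ratio, p_adjusted (descriptive columns, if present
    in the input, are carried through).
    """
    elevated = prefilter_elevated(comparisons, config)
    if elevated.empty:
        out = elevated.assign(p_adjusted=pd.Series(dtype=float))
    else:
        out = elevated.assign(p_adjusted=holm_sidak(elevated["p_raw"]))
    candidates = filter_candidates(out, config, n_treated)
    lead = ["timepoint", "protein_accession"]
    extra = [
        c
        for c in ("gene_id", "description")
        if c in candidates.columns
    ]
    tail = ["detect_c", "detect_t", "ratio", "p_adjusted"]
    return candidates[lead + extra + tail]


@dataclass
class OverlapReport:
    """Candidate-set overlaps between time points."""

    per_timepoint: dict[str, frozenset[str]]
    pairwise: dict[tuple[str, str], frozenset[str]]

    @property
    def union(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for s in self.per_timepoint.values():
            out |= s
        return out

    @property
    def n_distinct(self) -> int:
        return len(self.union)

    def pair_size(self, tp_a: str, tp_b: str) -> int:
        key = (tp_a, tp_b) if (tp_a, tp_b) in self.pairwise else (tp_b, tp_a)
        return len(self.pairwise[key])

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "timepoint_a": a,
                "timepoint_b": b,
                "n_shared": len(shared),
                "shared_proteins": ",".join(sorted(shared)),
            }
            for (a, b), shared in self.pairwise.items()
        ]
        return pd.DataFrame(
            rows, columns=["timepoint_a", "timepoint_b", "n_shared", "shared_proteins"]
        )

    def summary(self) -> str:
        lines = [
            f"distinct candidate proteins across time points: {self.n_distinct}"
        ]
        for (a, b), shared in self.pairwise.items():
            names = ", ".join(sorted(shared)) if shared else "(none)"
            lines.append(f"{a} & {b}: {len(shared)} shared — {names}")
        return "\n".join(lines)


def cross_timepoint_overlap(
    candidates: Mapping[str, pd.DataFrame]
) -> OverlapReport:
    """Pairwise intersections and overall union of candidate panels."""
    sets = {
        tp: frozenset(df["protein_accession"]) for tp, df in candidates.items()
    }
    pairwise = {
        (a, b): sets[a] & sets[b] for a, b in combinations(sets, 2)
    }
    return OverlapReport(per_timepoint=sets, pairwise=pairwise)
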