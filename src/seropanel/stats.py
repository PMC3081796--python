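"""Pooled two-group spectral-count statistics.

For each protein at one time point, counts are pooled (summed) over the six
control and six treated samples. Two quantities are computed from the pooled
counts x_c, x_t and the group grand totals T_c, T_t:

* the normalized scan count ratio R = (x_t / T_t) / (x_c / T_c), undefined
  (reported "-") when the protein was never seen in controls;
* the G statistic, the likelihood-ratio goodness-of-fit test of a common
  detection rate across groups,

      G = 2 * [ x_c * ln(x_c / e_c) + x_t * ln(x_t / e_t) ],
      e_g = T_g * (x_c + x_t) / (T_c + T_t),

  referred to the chi-square distribution with 1 degree of freedom.

When one pooled count is zero the log term is infinite; 0.5 is added to both
counts (and to both totals) for the G computation only — the ratio column
still reports the undefined marker. Reported p-values are floored at 1e-300
so underflow never renders an exact zero for finite G.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.stats import chi2

P_FLOOR = 1e-300


def _validate_counts(x_c: float, x_t: float, T_c: float, T_t: float) -> None:
    if min(x_c, x_t) < 0:
        raise ValueError("spectral counts must be non-negative")
    if T_c <= 0 or T_t <= 0:
        raise ValueError("group totals must be positive")
    if x_c > T_c or x_t > T_t:
        raise ValueError("pooled count exceeds its group total")


def normalized_ratio(x_c: float, x_t: float, T_c: float, T_t: float) -> float:
    """Treated/control rate ratio after total-scan normalization.

    Returns NaN (the undefined marker, rendered "-") when x_c == 0.
    """
    _validate_counts(x_c, x_t, T_c, T_t)
    if x_c == 0:
        return math.nan
    return (x_t / T_t) / (x_c / T_c)


def _g_arrays(
    x_c: np.ndarray, x_t: np.ndarray, T_c: np.ndarray, T_t: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    xc = np.asarray(x_c, dtype=float).copy()
    xt = np.asarray(x_t, dtype=float).copy()
    tc = np.asarray(T_c, dtype=float) * np.ones_like(xc)
    tt = np.asarray(T_t, dtype=float) * np.ones_like(xt)
    zero = (xc == 0) | (xt == 0)
    xc[zero] += 0.5
    xt[zero] += 0.5
    tc = tc + 0.5 * zero
    tt = tt + 0.5 * zero
    both = xc + xt
    e_c = tc * both / (tc + tt)
    e_t = tt * both / (tc + tt)
    g = 2.0 * (xc * np.log(xc / e_c) + xt * np.log(xt / e_t))
    g = np.maximum(g, 0.0)  # guard tiny negative round-off at the null
    p = np.clip(chi2.sf(g, df=1), P_FLOOR, 1.0)
    return g, p


def g_test(x_c: float, x_t: float, T_c: float, T_t: float) -> tuple[float, float]:
    """G statistic and its chi-square (df=1) upper-tail p-value.

    A protein absent from both groups has no test and is an error.
    """
    _validate_counts(x_c, x_t, T_c, T_t)
    if x_c + x_t == 0:
        raise ValueError("protein absent from both groups: G-test undefined")
    g, p = _g_arrays(
        np.array([x_c]), np.array([x_t]), np.array([T_c]), np.array([T_t])
    )
    return float(g[0]), float(p[0])


def pooled_group_counts(matrix, timepoint: str) -> pd.DataFrame:
    """Pooled counts, group grand totals and detection counts at a time point.

    Returns one row per protein in the matrix with columns x_c, x_t, T_c,
    T_t, detect_c, detect_t. Totals are grand totals over all proteins in
    the group's samples at that time point.
    """
    design = matrix.design
    if timepoint not in set(design["timepoint"]):
        raise ValueError(f"time point {timepoint!r} absent from design")
    control = matrix.samples(timepoint, "control")
    treated = matrix.samples(timepoint, "treated")
    if len(control) == 0 or len(treated) == 0:
        raise ValueError(
            f"time point {timepoint!r} needs at least one control and one "
            "treated sample"
        )
    sub_c = matrix.counts[control]
    sub_t = matrix.counts[treated]
    out = pd.DataFrame(
        {
            "x_c": sub_c.sum(axis=1),
            "x_t": sub_t.sum(axis=1),
            "detect_c": (sub_c > 0).sum(axis=1),
            "detect_t": (sub_t > 0).sum(axis=1),
        }
    )
    out["T_c"] = int(out["x_c"].sum())
    out["T_t"] = int(out["x_t"].sum())
    return out[["x_c", "x_t", "T_c", "T_t", "detect_c", "detect_t"]]


def compare_groups(matrix, timepoint: str) -> pd.DataFrame:
    """Per-protein group comparison table at one time point.

    One row per protein detected in at least one sample at the time point,
    with pooled counts, normalized ratio (NaN when undefined), G, raw
    p-value and per-group detection counts.
    """
    pooled = pooled_group_counts(matrix, timepoint)
    present = pooled[(pooled["x_c"] + pooled["x_t"]) > 0]
    if present.empty:
        raise ValueError(f"no proteins detected at time point {timepoint!r}")
    x_c = present["x_c"].to_numpy(dtype=float)
    x_t = present["x_t"].to_numpy(dtype=float)
    T_c = present["T_c"].to_numpy(dtype=float)
    T_t = present["T_t"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(x_c > 0, (x_t / T_t) / np.where(x_c > 0, x_c / T_c, 1.0), np.nan)
    g, p = _g_arrays(x_c, x_t, T_c, T_t)
    return pd.DataFrame(
        {
            "protein_accession": present.index,
            "timepoint": timepoint,
            "x_c": present["x_c"].to_numpy(),
            "x_t": present["x_t"].to_numpy(),
            "T_c": present["T_c"].to_numpy(),
            "T_t": present["T_t"].to_numpy(),
            "ratio": ratio,
            "G": g,
            "p_raw": p,
            "detect_c": present["detect_c"].to_numpy(),
            "detect_t": present["detect_t"].to_numpy(),
        }
    ).reset_index(drop=True)
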