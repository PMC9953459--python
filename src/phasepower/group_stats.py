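"""Per-dataset aggregation and across-dataset hypothesis tests.

The unit of analysis is the dataset: per-trial features are reduced to
per-dataset condition means (per phase bin, per power half), and the group
tests are classical paired / one-sample t-tests across datasets with
Bonferroni-adjusted significance levels.  The central statistic is

    corrected_effect = (AUC_high^TMS - AUC_low^TMS)
                     - (AUC_high^Control - AUC_low^Control)

which removes the contribution of ongoing-oscillation continuation (high
pre-stimulus power predicting high post-window amplitude even without a
stimulus) from the power dependence of the stimulus response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .trial_metrics import PHASE_BINS

__all__ = ["GroupResult", "summarize_dataset", "normalized_auc", "corrected_effect",
           "paired_t", "one_sample_t", "adjust_alpha"]


@dataclass
class GroupResult:
    """Outcome of one across-dataset contrast."""

    contrast: str
    values: np.ndarray = field(repr=False)  # per-dataset values entering the test
    t: float = np.nan
    df: int = 0
    p: float = np.nan
    alpha: float = 0.05
    significant: bool = False
    degenerate: bool = False
    n: int = 0


def _finite(values: np.ndarray) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    return v[np.isfinite(v)]


def one_sample_t(values: np.ndarray, mu0: float = 0.0, contrast: str = "",
                 alpha: float = 0.05) -> GroupResult:
    """Two-sided one-sample t-test of ``mean(values) == mu0``.

    Datasets with missing (NaN) values are dropped pairwise.  Zero
    variance is flagged as degenerate (``t`` infinite and ``p = 0`` when
    the mean differs from ``mu0``; ``t = 0``, ``p = 1`` otherwise).
    """
    v = _finite(values)
    n = len(v)
    if n < 2:
        raise ValueError("need at least two finite values")
    sd = v.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if np.isclose(v.mean(), mu0):
            t, p = 0.0, 1.0
        else:
            t, p = math_copysign_inf(v.mean() - mu0), 0.0
        return GroupResult(contrast, v, t, df, p, alpha, p < alpha, True, n)
    t = (v.mean() - mu0) / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return GroupResult(contrast, v, float(t), df, float(p), alpha, p < alpha, False, n)


def math_copysign_inf(x: float) -> float:
    return np.inf if x > 0 else -np.inf


def paired_t(values_a: np.ndarray, values_b: np.ndarray, contrast: str = "",
             alpha: float = 0.05) -> GroupResult:
    """Two-sided paired t-test of ``mean(a - b) == 0`` across datasets."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    return one_sample_t(a[ok] - b[ok], 0.0, contrast, alpha)


def adjust_alpha(family_alpha: float, m: int) -> float:
    """Bonferroni-adjusted per-test significance level ``family_alpha / m``."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    if not 0 < family_alpha <= 1:
        raise ValueError("family_alpha must be in (0, 1]")
    return family_alpha / m


# ---------------------------------------------------------------------------
# Per-dataset summaries


def summarize_dataset(features: pd.DataFrame) -> pd.DataFrame:
    """Reduce one dataset's per-trial feature table to per-band cell means.

    ``features`` needs columns ``band``, ``auc_tms``, ``auc_control``,
    ``bin_tms``, ``bin_control``, ``power_label_tms``,
    ``power_label_control``, ``pass_threshold_tms``,
    ``pass_threshold_control`` (one row per trial per band).  Returns one
    row per band with mean AUC per phase bin (both conditions, before and
    after the mean-power threshold), the all-trials ("random") means, the
    low/high-power means, and cell counts.  Empty cells yield NaN.
    """
    rows = []
    for band, g in features.groupby("band", sort=True):
        row: dict[str, float] = {"band": band, "n_trials": len(g)}
        for cond in ("tms", "control"):
            auc = g[f"auc_{cond}"].to_numpy()
            bins = g[f"bin_{cond}"].to_numpy()
            labels = g[f"power_label_{cond}"].to_numpy()
            passed = g[f"pass_threshold_{cond}"].to_numpy(dtype=bool)
            row[f"auc_random_{cond}"] = auc.mean() if len(auc) else np.nan
            row[f"auc_random_{cond}_thr"] = auc[passed].mean() if passed.any() else np.nan
            row[f"n_random_{cond}_thr"] = int(passed.sum())
            for bin_label in PHASE_BINS:
                m = bins == bin_label
                row[f"auc_{bin_label}_{cond}"] = auc[m].mean() if m.any() else np.nan
                row[f"n_{bin_label}_{cond}"] = int(m.sum())
                mt = m & passed
                row[f"auc_{bin_label}_{cond}_thr"] = auc[mt].mean() if mt.any() else np.nan
                row[f"n_{bin_label}_{cond}_thr"] = int(mt.sum())
            for half in ("low", "high"):
                m = labels == half
                row[f"auc_{half}_{cond}"] = auc[m].mean() if m.any() else np.nan
                row[f"n_{half}_{cond}"] = int(m.sum())
        rows.append(row)
    return pd.DataFrame(rows)


def normalized_auc(summary_row: pd.Series | dict, condition: str = "tms",
                   thresholded: bool = False) -> dict[str, float]:
    """Per-bin normalized AUC: bin mean minus the all-trials mean.

    Empty bins propagate as NaN (the dataset is then dropped from the
    group test for that bin).
    """
    suffix = "_thr" if thresholded else ""
    random_mean = summary_row[f"auc_random_{condition}{suffix}"]
    if not np.isfinite(random_mean):
        raise ValueError("random-category mean undefined for this dataset")
    return {b: summary_row[f"auc_{b}_{condition}{suffix}"] - random_mean for b in PHASE_BINS}


def corrected_effect(summary_row: pd.Series | dict) -> float:
    """Stimulus-specific power effect for one dataset and band, in uV*ms.

    ``(high - low | TMS) - (high - low | Control)``; NaN if any of the
    four cell means is undefined.
    """
    cells = [summary_row[f"auc_{half}_{cond}"]
             for cond in ("tms", "control") for half in ("high", "low")]
    if not np.all(np.isfinite(cells)):
        return np.nan
    return (cells[0] - cells[1]) - (cells[2] - cells[3])
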