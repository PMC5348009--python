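"""Pointwise group comparisons of time courses with FDR control.

Per time point, an unpaired two-tailed t test (classic pooled-variance, not
Welch, configurable) compares the subject-mean curves of two groups; for
on/off within-subject designs the paired variant is used.  The family of p
values — all time points of one comparison (one figure panel) — is corrected
with the Benjamini–Hochberg step-up procedure at q = 0.05, yielding the
"significance band" of time points.

ANOVA-style omnibus comparisons of latency summaries are deliberately not
reimplemented; :func:`latency_table` exports the per-subject latencies in a
tidy table for any off-the-shelf ANOVA routine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FDR_Q",
    "PointwiseTestResult",
    "pointwise_ttest",
    "fdr_bh",
    "pointwise_comparison",
    "latency_table",
]

FDR_Q = 0.05


@dataclass
class PointwiseTestResult:
    time_s: float
    t_stat: float
    p_value: float
    significant: bool = False


def pointwise_ttest(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    time_s: np.ndarray,
    paired: bool = False,
    equal_var: bool = True,
) -> list[PointwiseTestResult]:
    """Two-tailed t test at each time point (subjects x time inputs).

    Zero-variance degeneracies (e.g. paired differences all equal) yield
    NaN p values and are flagged by ``significant = False`` downstream.
    """
    a = np.asarray(curves_a, dtype=float)
    b = np.asarray(curves_b, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("curves must be (n_subjects, n_times) with equal n_times")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    if paired:
        if a.shape[0] != b.shape[0]:
            raise ValueError("paired test requires matched subject order")
        import warnings

        with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_rel(a, b, axis=0)
        # zero-variance differences: the statistic is undefined, not extreme
        degenerate = np.isclose(np.std(a - b, axis=0, ddof=1), 0.0)
        t = np.where(degenerate, np.nan, t)
        p = np.where(degenerate, np.nan, p)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(a, b, axis=0, equal_var=equal_var)
    return [
        PointwiseTestResult(float(ts), float(tv), float(pv))
        for ts, tv, pv in zip(time_s, t, p)
    ]


def fdr_bh(p_values: np.ndarray, q: float = FDR_Q) -> np.ndarray:
    """Benjamini–Hochberg step-up significance mask at level ``q``.

    NaN p values are treated as non-significant and do not enter the family.
    """
    p = np.asarray(p_values, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        mask[ok] = multipletests(p[ok], alpha=q, method="fdr_bh")[0]
    return mask


def pointwise_comparison(
    curves_a: np.ndarray,
    curves_b: np.ndarray,
    time_s: np.ndarray,
    paired: bool = False,
    q: float = FDR_Q,
    equal_var: bool = True,
) -> list[PointwiseTestResult]:
    """t test at every time point + BH correction across those time points."""
    results = pointwise_ttest(curves_a, curves_b, time_s, paired, equal_var)
    sig = fdr_bh(np.array([r.p_value for r in results]), q)
    for r, s in zip(results, sig):
        r.significant = bool(s)
    return results


def latency_table(rows: list[dict]) -> pd.DataFrame:
    """Tidy per-subject latency table (subject, group, signal, condition,
    latency_s, ...) for export to external ANOVA tooling."""
    return pd.DataFrame(rows)
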