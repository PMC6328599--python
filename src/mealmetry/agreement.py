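"""Bland-Altman agreement statistics for intake estimates.

Bias (mean estimation error) is the mean of differences d = estimated -
actual over all meals pooled across subjects; the limits of agreement (LOA)
are bias +/- 1.96 * SD(d), with 1.96 taken literally.  Confidence intervals
use the t distribution with n - 1 degrees of freedom:

    bias CI : bias +/- t_{n-1} * sqrt(SD^2 / n)
    LOA CI  : LOA  +/- t_{n-1} * sqrt(3 * SD^2 / n)

All SDs are sample SDs (n - 1), consistent with the t-based intervals.
Meals from the same subject are pooled as independent points; this follows
the common single-measurement convention and slightly understates the
uncertainty under repeated measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .modeling import mean_ape

__all__ = [
    "EvaluationReport",
    "bias_stats",
    "limits_of_agreement",
    "bias_confidence_interval",
    "loa_confidence_interval",
    "significance_of_bias",
    "bland_altman_data",
    "evaluate",
]

LOA_Z = 1.96


@dataclass
class EvaluationReport:
    """Per-meal errors plus pooled MAPE, bias, LOA and their 95% CIs."""

    n_meals: int
    per_meal: list[dict] = field(repr=False)
    mape_mean: float = 0.0
    mape_sd: float = 0.0
    bias: float = 0.0
    bias_sd: float = 0.0
    loa_lower: float = 0.0
    loa_upper: float = 0.0
    bias_ci: tuple[float, float] = (0.0, 0.0)
    loa_lower_ci: tuple[float, float] = (0.0, 0.0)
    loa_upper_ci: tuple[float, float] = (0.0, 0.0)


def bias_stats(estimates, actuals) -> tuple[float, float, int]:
    """Mean and sample SD of the differences (estimated - actual)."""
    est = np.asarray(estimates, dtype=float)
    act = np.asarray(actuals, dtype=float)
    if est.shape != act.shape:
        raise ValueError("estimates and actuals must have the same length")
    if est.size < 2:
        raise ValueError("need at least 2 pairs (sample SD undefined)")
    d = est - act
    return float(d.mean()), float(d.std(ddof=1)), int(d.size)


def limits_of_agreement(bias: float, bias_sd: float) -> tuple[float, float]:
    """(bias - 1.96 SD, bias + 1.96 SD)."""
    if bias_sd < 0:
        raise ValueError("bias_sd must be >= 0")
    return bias - LOA_Z * bias_sd, bias + LOA_Z * bias_sd


def _t_quantile(n: int, level: float) -> float:
    if n < 2:
        raise ValueError("need n >= 2 for a t-based interval")
    return float(stats.t.ppf(0.5 + level / 2, df=n - 1))


def bias_confidence_interval(
    bias: float, bias_sd: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """bias +/- t_{n-1} * sqrt(SD^2 / n)."""
    hw = _t_quantile(n, level) * np.sqrt(bias_sd**2 / n)
    return bias - hw, bias + hw


def loa_confidence_interval(
    loa_value: float, bias_sd: float, n: int, level: float = 0.95
) -> tuple[float, float]:
    """LOA +/- t_{n-1} * sqrt(3 * SD^2 / n)."""
    hw = _t_quantile(n, level) * np.sqrt(3 * bias_sd**2 / n)
    return loa_value - hw, loa_value + hw


def significance_of_bias(report: EvaluationReport) -> bool:
    """True iff the 95% CI for bias excludes 0."""
    lo, hi = report.bias_ci
    return not (lo <= 0.0 <= hi)


def evaluate(subject_ids, meal_ids, estimates, actuals) -> EvaluationReport:
    """Assemble the full agreement report for one model's estimates."""
    est = np.asarray(estimates, dtype=float)
    act = np.asarray(actuals, dtype=float)
    ape, mape, mape_sd = mean_ape(est, act)
    bias, sd, n = bias_stats(est, act)
    lo, hi = limits_of_agreement(bias, sd)
    per_meal = [
        {
            "subject_id": s,
            "meal_id": m,
            "estimated": float(e),
            "actual": float(a),
            "difference": float(e - a),
            "APE": float(p),
        }
        for s, m, e, a, p in zip(subject_ids, meal_ids, est, act, ape)
    ]
    return EvaluationReport(
        n_meals=n,
        per_meal=per_meal,
        mape_mean=mape,
        mape_sd=mape_sd,
        bias=bias,
        bias_sd=sd,
        loa_lower=lo,
        loa_upper=hi,
        bias_ci=bias_confidence_interval(bias, sd, n),
        loa_lower_ci=loa_confidence_interval(lo, sd, n),
        loa_upper_ci=loa_confidence_interval(hi, sd, n),
    )


def bland_altman_data(estimates, actuals) -> tuple[pd.DataFrame, dict[str, float]]:
    """Points and reference lines for a Bland-Altman plot.

    Returns a DataFrame with one (mean, difference) row per pair and the
    bias / LOA reference values; suitable for CSV export.
    """
    est = np.asarray(estimates, dtype=float)
    act = np.asarray(actuals, dtype=float)
    if est.shape != act.shape:
        raise ValueError("estimates and actuals must have the same length")
    df = pd.DataFrame({"mean": (est + act) / 2.0, "difference": est - act})
    if est.size >= 2:
        bias, sd, _ = bias_stats(est, act)
        lo, hi = limits_of_agreement(bias, sd)
    else:
        bias = float(df["difference"].iloc[0]) if est.size else 0.0
        lo = hi = bias
    refs = {"bias": bias, "loa_lower": lo, "loa_upper": hi}
    return df, refs
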