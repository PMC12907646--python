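"""Cohort-level summaries of critical times.

Aggregates the per-subject critical-time tables into: median/IQR summaries
per testing condition, cumulative detection curves (proportion of subjects
with a detected critical time as a function of follow-up time), group
comparisons across conditions (Kruskal-Wallis), difference-from-ground-truth
analyses, and univariable regressions of critical time on the baseline
ground-truth parameters.

Conventions: censored subjects (NaN critical time) are excluded from medians
and quartiles but count in the denominator of detection proportions.
Quantiles use linear interpolation between order statistics; printed critical
times are quantized to the visit grid, so the interpolation rule rarely
matters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

from .simulate import PermutationSpec

__all__ = [
    "OUTCOMES",
    "PREDICTORS",
    "PermutationSummary",
    "summarize_critical_times",
    "detection_curve",
    "compare_groups",
    "difference_from_truth",
    "regress_predictors",
    "summary_table",
]

OUTCOMES = ("tcv", "tgv", "tcr", "tgr")
#: baseline ground-truth parameters used as univariable predictors
PREDICTORS = ("md0_db", "slope_db_per_year", "sigma_db", "reliability")


@dataclass(frozen=True)
class PermutationSummary:
    """Detected-subject quantiles and the cumulative detection curve of one
    outcome under one testing condition."""

    spec: PermutationSpec
    outcome: str
    n_total: int
    n_detected: int
    median: float
    q25: float
    q75: float
    detection_proportion_by_time: pd.DataFrame  # columns: time, proportion


def summarize_critical_times(
    critical_times: pd.DataFrame,
    outcome: str,
    spec: PermutationSpec,
    time_grid: np.ndarray,
) -> PermutationSummary:
    """Median/IQR over detected subjects plus the cumulative detection curve.

    ``time_grid`` is the permutation's visit-time grid over which the step
    curve is evaluated.  With zero detected subjects the quantiles are NaN
    and the curve is identically zero.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    values = critical_times[outcome].to_numpy(dtype=float)
    detected = values[~np.isnan(values)]
    n_total = len(values)
    curve = detection_curve(values, np.asarray(time_grid, dtype=float))
    if len(detected) == 0:
        med = q25 = q75 = float("nan")
    else:
        med, q25, q75 = (
            float(np.median(detected)),
            float(np.quantile(detected, 0.25)),
            float(np.quantile(detected, 0.75)),
        )
    return PermutationSummary(
        spec=spec,
        outcome=outcome,
        n_total=n_total,
        n_detected=int(len(detected)),
        median=med,
        q25=q25,
        q75=q75,
        detection_proportion_by_time=curve,
    )


def detection_curve(values: np.ndarray, time_grid: np.ndarray) -> pd.DataFrame:
    """Proportion of all subjects (censored included in the denominator) with
    a detected critical time <= t, for each t on the grid."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    detected = values[~np.isnan(values)]
    if n == 0:
        prop = np.zeros_like(time_grid, dtype=float)
    else:
        prop = np.searchsorted(np.sort(detected), time_grid, side="right") / n
    return pd.DataFrame({"time": time_grid, "proportion": prop})


def compare_groups(groups: dict[str, np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis rank test across groups of detected critical times.

    Returns ``(H, p)``.  Raises if fewer than two groups or any group is
    empty after dropping censored values.
    """
    cleaned = []
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        v = v[~np.isnan(v)]
        if len(v) == 0:
            raise ValueError(f"group {name!r} has no detected values")
        cleaned.append(v)
    if len(cleaned) < 2:
        raise ValueError("need at least two groups")
    h, p = stats.kruskal(*cleaned)
    return float(h), float(p)


def difference_from_truth(
    critical_times: pd.DataFrame,
    quantity: str,
) -> dict:
    """Distribution of estimate-minus-truth differences at the critical time.

    ``quantity`` is ``"variability"`` (uses subjects with both TcV and TgV
    detected, differences in dB) or ``"reliability"`` (both TcR and TgR
    detected).  Returns summary statistics and a one-sample t-test against
    zero; an empty filtered set yields ``n == 0`` with NaN statistics.
    """
    if quantity == "variability":
        both = critical_times[["tcv", "tgv"]].notna().all(axis=1)
        diffs = critical_times.loc[both, "diff_var_db"].to_numpy(dtype=float)
    elif quantity == "reliability":
        both = critical_times[["tcr", "tgr"]].notna().all(axis=1)
        diffs = critical_times.loc[both, "diff_rel"].to_numpy(dtype=float)
    else:
        raise ValueError("quantity must be 'variability' or 'reliability'")
    diffs = diffs[~np.isnan(diffs)]
    out = {
        "n": int(len(diffs)),
        "median": float("nan"),
        "q25": float("nan"),
        "q75": float("nan"),
        "min": float("nan"),
        "max": float("nan"),
        "t_stat": float("nan"),
        "p_value": float("nan"),
    }
    if len(diffs) == 0:
        return out
    out.update(
        median=float(np.median(diffs)),
        q25=float(np.quantile(diffs, 0.25)),
        q75=float(np.quantile(diffs, 0.75)),
        min=float(diffs.min()),
        max=float(diffs.max()),
    )
    if len(diffs) > 1 and np.ptp(diffs) > 0:
        t, p = stats.ttest_1samp(diffs, 0.0)
        out.update(t_stat=float(t), p_value=float(p))
    return out


def regress_predictors(
    critical_times: pd.DataFrame,
    population: pd.DataFrame,
    outcome: str,
) -> pd.DataFrame:
    """Univariable OLS of the critical time on each baseline parameter.

    Pools whatever rows are passed in (typically all 12 permutations of a
    schedule family stacked); censored subjects are dropped per regression.
    One simple regression is fitted per predictor -- per-predictor R^2 values
    are then summable across rows.  Degenerate (zero-variance) predictors are
    flagged with NaN results.
    """
    if outcome not in OUTCOMES:
        raise ValueError(f"unknown outcome {outcome!r}")
    merged = critical_times.merge(population, on="subject_id", how="left")
    detected = merged[~merged[outcome].isna()]
    rows = []
    y = detected[outcome].to_numpy(dtype=float)
    for pred in PREDICTORS:
        x = detected[pred].to_numpy(dtype=float)
        if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            if len(x) >= 3 and np.ptp(y) == 0 and np.ptp(x) > 0:
                # constant outcome: slope 0, no explained variance
                rows.append((outcome, pred, 0.0, float("nan"), float("nan"), 0.0))
            else:
                rows.append(
                    (outcome, pred, float("nan"), float("nan"), float("nan"), float("nan"))
                )
            continue
        model = sm.OLS(y, sm.add_constant(x)).fit()
        rows.append(
            (
                outcome,
                pred,
                float(model.params[1]),
                float(model.bse[1]),
                float(model.pvalues[1]),
                float(model.rsquared),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["outcome", "predictor", "coefficient", "standard_error", "p_value", "r_squared"],
    )


def summary_table(
    results_by_spec: dict[PermutationSpec, pd.DataFrame],
    outcome: str,
) -> pd.DataFrame:
    """Median (q25, q75) cells arranged as review interval x tests per visit."""
    multipliers = sorted({s.interval_multiplier for s in results_by_spec})
    ks = sorted({s.tests_per_visit for s in results_by_spec})
    table = pd.DataFrame(index=multipliers, columns=ks, dtype=object)
    table.index.name = "interval_multiplier"
    for spec, df in results_by_spec.items():
        vals = df[outcome].dropna()
        if len(vals) == 0:
            cell = "censored"
        else:
            cell = (
                f"{np.median(vals):g} "
                f"({np.quantile(vals, 0.25):g}, {np.quantile(vals, 0.75):g})"
            )
        table.loc[spec.interval_multiplier, spec.tests_per_visit] = cell
    table.columns = [f"{k}_tests_per_visit" for k in ks]
    return table
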