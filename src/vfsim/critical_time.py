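"""Critical times for estimating intrinsic variability and reliability.

At every follow-up visit the clinician-observable estimates are updated
cumulatively:

* **variability** -- the sample SD (n-1 denominator) of all valid MD results
  up to that visit.  Under the long-term plan the results are first
  "normalized": an ordinary-least-squares slope is fitted to all valid
  (time, MD) points observed so far and subtracted (``md - slope*t``), since
  the true progression rate is not clinically knowable.  The short-term plan
  skips normalization (progression over days is negligible on the analysis
  side), using raw MD values.
* **reliability** -- the cumulative proportion of reliable results among all
  administered tests up to that visit (discarded tests count in the
  denominator).

Two rolling-window stopping rules are then scanned over the per-visit
estimate series:

* consecutive criterion (clinically observable): the first 3 consecutive
  defined estimates whose spread is within the tolerance (default 5%) of the
  triplet mean; the time of the third visit is the critical time (TcV for
  variability, TcR for reliability).
* ground-truth criterion (validation only): the first 3 consecutive defined
  estimates each within the tolerance of the subject's true parameter (TgV,
  TgR).

Visits at which no valid result was obtained are skipped when counting
consecutive estimates; they do not reset the window.  Subjects whose rule
never fires within the schedule horizon are censored (NaN).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import CohortSeries, CoreSeries, PermutationSpec, derive_permutation
from .population import SubjectParams

__all__ = [
    "RunningEstimates",
    "CriticalTimes",
    "running_slope_and_adjust",
    "estimate_variability",
    "estimate_reliability",
    "running_estimates",
    "find_critical_time_consecutive",
    "find_critical_time_ground_truth",
    "compute_critical_times",
    "compute_critical_times_cohort",
    "CRITICAL_TIME_COLUMNS",
]

DEFAULT_TOLERANCE = 0.05
_WINDOW = 3  # consecutive estimates required by both stopping rules

CRITICAL_TIME_COLUMNS = [
    "subject_id",
    "tests_per_visit",
    "interval_multiplier",
    "tcv",
    "tgv",
    "tcr",
    "tgr",
    "var_at_tcv_db",
    "rel_at_tcr",
    "diff_var_db",
    "diff_rel",
]


@dataclass(frozen=True)
class RunningEstimates:
    """Per-visit cumulative estimates for one subject under one condition.

    Undefined entries are NaN.  ``window_eligible`` marks visits that count
    towards the consecutive window for variability (estimate defined and at
    least one valid result at that visit).
    """

    times: np.ndarray
    variability: np.ndarray  # sigma-hat, dB
    reliability: np.ndarray  # p-hat
    slope: np.ndarray  # r-hat, dB/yr (NaN under the short-term plan)
    n_valid_tests: np.ndarray  # cumulative valid results
    window_eligible: np.ndarray  # bool, for the variability window


@dataclass(frozen=True)
class CriticalTimes:
    """Per-subject critical times under one testing condition.

    NaN encodes "censored": the rule never fired within the schedule horizon.
    ``diff_var`` and ``diff_rel`` are estimate-at-critical-time minus ground
    truth, defined whenever TcV / TcR was detected.
    """

    subject_id: int
    spec: PermutationSpec
    tcv: float
    tgv: float
    tcr: float
    tgr: float
    var_at_tcv: float
    rel_at_tcr: float
    diff_var: float
    diff_rel: float


def running_slope_and_adjust(
    times: np.ndarray,
    values: np.ndarray,
    valid: np.ndarray | None = None,
) -> tuple[np.ndarray, list[np.ndarray | None]]:
    """Per-visit OLS slope and progression-adjusted values (long-term plan).

    ``values``/``valid`` are (n_visits, tests) arrays.  At each visit ``v``
    with valid data on >= 2 distinct visit times, the OLS slope over all
    valid (t, md) points up to ``v`` is computed and *all* those points are
    adjusted as ``md - slope*t``.  Earlier visits yield ``(nan, None)``.

    Returns ``(slopes, adjusted)`` where ``slopes`` is (n_visits,) and
    ``adjusted[v]`` is the 1-d array of adjusted valid values up to ``v`` (or
    ``None`` while undefined).
    """
    times = np.asarray(times, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if valid is None:
        valid = np.ones_like(values, dtype=bool)
    valid = np.atleast_2d(np.asarray(valid, dtype=bool))
    n_visits = values.shape[0]
    slopes = np.full(n_visits, np.nan)
    adjusted: list[np.ndarray | None] = [None] * n_visits
    for v in range(n_visits):
        m = valid[: v + 1]
        y = values[: v + 1][m]
        t = np.broadcast_to(times[: v + 1, None], m.shape)[m]
        if len(y) < 2 or np.ptp(t) == 0:
            continue
        # normal equations on the valid points seen so far
        tbar, ybar = t.mean(), y.mean()
        denom = np.sum((t - tbar) ** 2)
        slope = np.sum((t - tbar) * (y - ybar)) / denom
        slopes[v] = slope
        adjusted[v] = y - slope * t
    return slopes, adjusted


def estimate_variability(adjusted_values: np.ndarray) -> float:
    """Sample SD (n-1 denominator) of the valid adjusted values; NaN if < 2."""
    x = np.asarray(adjusted_values, dtype=float)
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1))


def estimate_reliability(reliable_mask: np.ndarray) -> float:
    """Cumulative reliable-test proportion; administered tests (including
    discarded ones) form the denominator.  NaN when no test was administered."""
    m = np.asarray(reliable_mask, dtype=bool)
    if m.size == 0:
        return float("nan")
    return float(m.sum() / m.size)


def running_estimates(
    core: CoreSeries,
    detrend: bool,
) -> RunningEstimates:
    """Cumulative per-visit variability and reliability estimates for one
    subject.  ``detrend=True`` applies the long-term normalization step."""
    times = core.visit_times
    values = core.md_values
    mask = core.reliable_mask
    n_visits = len(times)
    var = np.full(n_visits, np.nan)
    rel = np.full(n_visits, np.nan)
    slopes = np.full(n_visits, np.nan)
    n_valid = np.zeros(n_visits, dtype=np.int64)
    if detrend:
        slopes, adjusted = running_slope_and_adjust(times, values, mask)
    for v in range(n_visits):
        m = mask[: v + 1]
        n_valid[v] = m.sum()
        rel[v] = estimate_reliability(m)
        if detrend:
            if adjusted[v] is not None:
                var[v] = estimate_variability(adjusted[v])
        else:
            var[v] = estimate_variability(values[: v + 1][m])
    has_new_valid = mask.any(axis=1)
    eligible = has_new_valid & ~np.isnan(var)
    return RunningEstimates(
        times=times,
        variability=var,
        reliability=rel,
        slope=slopes,
        n_valid_tests=n_valid,
        window_eligible=eligible,
    )


def _scan(
    times: np.ndarray,
    estimates: np.ndarray,
    qualifies,
) -> tuple[float, float]:
    """Scan defined estimates in visit order; return (time, estimate) of the
    third member of the first qualifying triplet, or (nan, nan)."""
    defined = np.flatnonzero(~np.isnan(np.asarray(estimates, dtype=float)))
    est = np.asarray(estimates, dtype=float)
    for j in range(len(defined) - _WINDOW + 1):
        idx = defined[j : j + _WINDOW]
        triplet = est[idx]
        if qualifies(triplet):
            return float(times[idx[-1]]), float(triplet[-1])
    return float("nan"), float("nan")


def find_critical_time_consecutive(
    times: np.ndarray,
    estimates: np.ndarray,
    tolerance: float = DEFAULT_TOLERANCE,
) -> float:
    """Time of the third of the first 3 consecutive defined estimates whose
    range is within ``tolerance`` of the triplet mean; NaN if never.

    NaN estimates are skipped without resetting the window.  A triplet of
    identical values (including zeros) always qualifies.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    def ok(triplet: np.ndarray) -> bool:
        return float(np.ptp(triplet)) <= tolerance * float(np.mean(triplet))

    return _scan(times, estimates, ok)[0]


def find_critical_time_ground_truth(
    times: np.ndarray,
    estimates: np.ndarray,
    truth: float,
    tolerance: float = DEFAULT_TOLERANCE,
) -> float:
    """Time of the third of the first 3 consecutive defined estimates each
    within ``tolerance`` of the ground truth; NaN if never."""
    if truth <= 0:
        raise ValueError("truth must be positive")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")

    def ok(triplet: np.ndarray) -> bool:
        return bool(np.all(np.abs(triplet - truth) <= tolerance * truth))

    return _scan(times, estimates, ok)[0]


def compute_critical_times(
    core: CoreSeries,
    spec: PermutationSpec,
    params: SubjectParams,
    mode: str,
    tolerance: float = DEFAULT_TOLERANCE,
) -> CriticalTimes:
    """All four critical times for one subject under one testing condition.

    ``mode`` is ``"long_term"`` (normalize for progression before estimating
    variability) or ``"short_term"`` (raw values).  The consecutive-criterion
    rows also record the estimate at the critical time and its difference
    from the subject's ground truth.
    """
    if mode not in ("long_term", "short_term"):
        raise ValueError("mode must be 'long_term' or 'short_term'")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    sub = derive_permutation(core, spec)
    est = running_estimates(sub, detrend=(mode == "long_term"))
    var_for_window = np.where(est.window_eligible, est.variability, np.nan)
    tcv, var_at_tcv = _scan(
        est.times,
        var_for_window,
        lambda tr: float(np.ptp(tr)) <= tolerance * float(np.mean(tr)),
    )
    # ground-truth comparison needs a positive truth (relative band)
    tgv = (
        find_critical_time_ground_truth(est.times, var_for_window, params.sigma, tolerance)
        if params.sigma > 0
        else float("nan")
    )
    tcr, rel_at_tcr = _scan(
        est.times,
        est.reliability,
        lambda tr: float(np.ptp(tr)) <= tolerance * float(np.mean(tr)),
    )
    tgr = (
        find_critical_time_ground_truth(est.times, est.reliability, params.reliability, tolerance)
        if params.reliability > 0
        else float("nan")
    )
    return CriticalTimes(
        subject_id=params.subject_id,
        spec=spec,
        tcv=tcv,
        tgv=tgv,
        tcr=tcr,
        tgr=tgr,
        var_at_tcv=var_at_tcv,
        rel_at_tcr=rel_at_tcr,
        diff_var=var_at_tcv - params.sigma,
        diff_rel=rel_at_tcr - params.reliability,
    )


# ---------------------------------------------------------------------------
# vectorised cohort path
# ---------------------------------------------------------------------------


def _cohort_running_stats(
    cohort: CohortSeries,
    detrend: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Cumulative variability/reliability estimate matrices for a cohort.

    Returns ``(variability, var_eligible, reliability)`` of shape
    (n_subjects, n_visits); undefined variability entries are NaN and
    ``var_eligible`` additionally excludes visits with no valid result.
    """
    times = cohort.visit_times
    md = cohort.md_values
    mask = cohort.reliable_mask
    n, v, k = md.shape

    mvalid = mask.astype(np.float64)
    y = np.where(mask, md, 0.0)

    per_visit_n = mvalid.sum(axis=2)  # (n, v)
    cn = np.cumsum(per_visit_n, axis=1)
    sy = np.cumsum(y.sum(axis=2), axis=1)
    sy2 = np.cumsum((y * y).sum(axis=2), axis=1)

    total_tests = k * np.arange(1, v + 1, dtype=np.float64)
    reliability = cn / total_tests[None, :]

    with np.errstate(invalid="ignore", divide="ignore"):
        if detrend:
            st = np.cumsum(times[None, :] * per_visit_n, axis=1)
            st2 = np.cumsum((times**2)[None, :] * per_visit_n, axis=1)
            sty = np.cumsum(times[None, :] * y.sum(axis=2), axis=1)
            # OLS slope over all valid points so far
            d = cn * st2 - st * st
            slope_def = (cn >= 2) & (d > 1e-9)
            slope = np.where(slope_def, (cn * sty - st * sy) / np.where(d > 0, d, 1.0), np.nan)
            # adjusted values a = y - slope*t; sums via expansion
            sa = sy - slope * st
            sa2 = sy2 - 2.0 * slope * sty + slope * slope * st2
            ss = sa2 - sa * sa / np.where(cn > 0, cn, 1.0)
            var_def = slope_def & (cn >= 2)
        else:
            ss = sy2 - sy * sy / np.where(cn > 0, cn, 1.0)
            var_def = cn >= 2
        variance = np.where(var_def, ss / np.where(cn > 1, cn - 1.0, 1.0), np.nan)
    variability = np.sqrt(np.clip(variance, 0.0, None), where=~np.isnan(variance),
                          out=np.full_like(variance, np.nan))

    has_new_valid = per_visit_n > 0
    var_eligible = has_new_valid & var_def
    return variability, var_eligible, reliability


def _first_triplet(
    times: np.ndarray,
    estimates: np.ndarray,
    eligible: np.ndarray,
    condition: str,
    tolerance: float,
    truth: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised rolling-window scan over (n_subjects, n_visits) estimates.

    ``condition`` is ``"consecutive"`` (triplet range within tolerance of the
    triplet mean) or ``"truth"`` (each member within tolerance of ``truth``).
    Returns per-subject (critical_time, estimate_at_critical_time), NaN where
    censored.
    """
    n, v = estimates.shape
    if v < _WINDOW:
        return np.full(n, np.nan), np.full(n, np.nan)
    # stable-compact eligible visits to the front, preserving visit order
    order = np.argsort(~eligible, axis=1, kind="stable")
    count = eligible.sum(axis=1)
    ce = np.take_along_axis(np.where(eligible, estimates, np.nan), order, axis=1)

    a, b, c = ce[:, :-2], ce[:, 1:-1], ce[:, 2:]
    if condition == "consecutive":
        hi = np.maximum(np.maximum(a, b), c)
        lo = np.minimum(np.minimum(a, b), c)
        mean = (a + b + c) / 3.0
        with np.errstate(invalid="ignore"):
            q = (hi - lo) <= tolerance * mean
    elif condition == "truth":
        tr = truth[:, None]
        with np.errstate(invalid="ignore"):
            band = tolerance * tr
            q = (
                (np.abs(a - tr) <= band)
                & (np.abs(b - tr) <= band)
                & (np.abs(c - tr) <= band)
            )
    else:  # pragma: no cover
        raise ValueError(condition)
    slots = np.arange(v - 2)
    q &= (slots[None, :] + _WINDOW) <= count[:, None]

    found = q.any(axis=1)
    first = np.argmax(q, axis=1)
    third = np.clip(first + 2, 0, v - 1)
    visit_idx = np.take_along_axis(order, third[:, None], axis=1)[:, 0]
    ct = np.where(found, times[visit_idx], np.nan)
    est_at = np.where(found, np.take_along_axis(ce, third[:, None], axis=1)[:, 0], np.nan)
    return ct, est_at


def compute_critical_times_cohort(
    core: CohortSeries,
    spec: PermutationSpec,
    population: pd.DataFrame,
    mode: str,
    tolerance: float = DEFAULT_TOLERANCE,
) -> pd.DataFrame:
    """Vectorised equivalent of :func:`compute_critical_times` for a cohort.

    Returns one row per subject with columns ``CRITICAL_TIME_COLUMNS``;
    censored critical times are NaN.  Agrees exactly with the per-subject
    path.
    """
    if mode not in ("long_term", "short_term"):
        raise ValueError("mode must be 'long_term' or 'short_term'")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    sub = derive_permutation(core, spec)
    variability, var_eligible, reliability = _cohort_running_stats(
        sub, detrend=(mode == "long_term")
    )
    times = sub.visit_times
    sigma = population["sigma_db"].to_numpy()
    rel_truth = population["reliability"].to_numpy()
    all_eligible = np.ones_like(reliability, dtype=bool)

    tcv, var_at_tcv = _first_triplet(
        times, variability, var_eligible, "consecutive", tolerance
    )
    tgv, _ = _first_triplet(
        times, variability, var_eligible, "truth", tolerance, truth=sigma
    )
    tgv = np.where(sigma > 0, tgv, np.nan)
    tcr, rel_at_tcr = _first_triplet(
        times, reliability, all_eligible, "consecutive", tolerance
    )
    tgr, _ = _first_triplet(
        times, reliability, all_eligible, "truth", tolerance, truth=rel_truth
    )
    tgr = np.where(rel_truth > 0, tgr, np.nan)
    return pd.DataFrame(
        {
            "subject_id": population["subject_id"].to_numpy(),
            "tests_per_visit": spec.tests_per_visit,
            "interval_multiplier": spec.interval_multiplier,
            "tcv": tcv,
            "tgv": tgv,
            "tcr": tcr,
            "tgr": tgr,
            "var_at_tcv_db": var_at_tcv,
            "rel_at_tcr": rel_at_tcr,
            "diff_var_db": var_at_tcv - sigma,
            "diff_rel": rel_at_tcr - rel_truth,
        }
    )
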