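"""Generation of the core longitudinal visual-field series.

The core dataset holds, for every subject, 4 mean-deviation (MD) results per
visit on the finest schedule (3-monthly visits over 20 years for the
long-term plan; daily visits over 28 days for the short-term plan).  Each MD
result is the subject's true trajectory ``md0 + slope * t`` plus i.i.d.
Gaussian test-retest noise, and each result independently passes or fails the
subject's intrinsic reliability check.  Unreliable results are generated and
then masked, representing data loss.

Sparser testing conditions (fewer tests per visit, longer review intervals)
are obtained by *subsetting* the core series, never by re-simulation, so that
the data under a 6-monthly review is exactly a subset of the data under a
3-monthly review for the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .population import SubjectParams

__all__ = [
    "Schedule",
    "LONG_TERM",
    "SHORT_TERM",
    "CoreSeries",
    "CohortSeries",
    "PermutationSpec",
    "all_permutations",
    "simulate_core",
    "simulate_cohort",
    "derive_permutation",
]

_VALID_TESTS = (1, 2, 3, 4)
_VALID_MULTIPLIERS = (1, 2, 4)


@dataclass(frozen=True)
class Schedule:
    """Visit grid of a follow-up plan.

    ``visit_times`` are in years for the long-term plan and in days for the
    short-term plan; ``slope_time_factor`` converts a visit time into years so
    that the dB/year progression rate applies on either grid (1/365 for the
    daily grid).
    """

    name: str
    visit_times: np.ndarray
    slope_time_factor: float
    tests_per_visit_core: int = 4

    def __post_init__(self) -> None:
        t = np.asarray(self.visit_times, dtype=float)
        if t.ndim != 1 or len(t) == 0 or t[0] != 0:
            raise ValueError("visit_times must be a 1-d grid starting at 0")
        if np.any(np.diff(t) <= 0):
            raise ValueError("visit_times must be strictly increasing")
        object.__setattr__(self, "visit_times", t)

    @property
    def n_visits(self) -> int:
        return len(self.visit_times)


#: 81 visits at 0, 0.25, ..., 20.0 years
LONG_TERM = Schedule("long_term", np.arange(81) * 0.25, slope_time_factor=1.0)
#: 28 visits at days 0, 1, ..., 27
SHORT_TERM = Schedule("short_term", np.arange(28.0), slope_time_factor=1.0 / 365.0)


def schedule_by_name(name: str) -> Schedule:
    try:
        return {"long_term": LONG_TERM, "short_term": SHORT_TERM}[name]
    except KeyError:
        raise ValueError(f"unknown schedule {name!r}") from None


@dataclass(frozen=True)
class PermutationSpec:
    """A testing condition: ``tests_per_visit`` in {1..4} and a review-interval
    multiplier in {1, 2, 4} applied to the core visit grid (3/6/12-monthly for
    the long-term plan; 1/2/4-daily for the short-term plan)."""

    tests_per_visit: int
    interval_multiplier: int

    def __post_init__(self) -> None:
        if self.tests_per_visit not in _VALID_TESTS:
            raise ValueError("tests_per_visit must be in {1, 2, 3, 4}")
        if self.interval_multiplier not in _VALID_MULTIPLIERS:
            raise ValueError("interval_multiplier must be in {1, 2, 4}")

    @property
    def label(self) -> str:
        return f"k{self.tests_per_visit}_m{self.interval_multiplier}"


def all_permutations() -> list[PermutationSpec]:
    """The 12 tests-per-visit x review-interval conditions."""
    return [PermutationSpec(k, m) for m, k in product(_VALID_MULTIPLIERS, _VALID_TESTS)]


@dataclass(frozen=True)
class CoreSeries:
    """One subject's simulated series: ``md_values`` and ``reliable_mask`` are
    (n_visits, tests_per_visit) arrays on ``visit_times``."""

    subject_id: int
    schedule: Schedule
    visit_times: np.ndarray
    md_values: np.ndarray
    reliable_mask: np.ndarray

    def __post_init__(self) -> None:
        if self.md_values.shape != self.reliable_mask.shape:
            raise ValueError("md_values and reliable_mask must share a shape")
        if self.md_values.shape[0] != len(self.visit_times):
            raise ValueError("row count must equal number of visits")


@dataclass(frozen=True)
class CohortSeries:
    """Vectorised core data for a whole cohort.

    ``md_values`` and ``reliable_mask`` have shape
    (n_subjects, n_visits, tests_per_visit); row ``i`` belongs to
    ``subject_ids[i]``.
    """

    schedule: Schedule
    visit_times: np.ndarray
    subject_ids: np.ndarray
    md_values: np.ndarray
    reliable_mask: np.ndarray

    @property
    def n_subjects(self) -> int:
        return self.md_values.shape[0]

    def subject(self, index: int) -> CoreSeries:
        """Extract the :class:`CoreSeries` of one subject by positional index."""
        return CoreSeries(
            subject_id=int(self.subject_ids[index]),
            schedule=self.schedule,
            visit_times=self.visit_times,
            md_values=self.md_values[index],
            reliable_mask=self.reliable_mask[index],
        )

    def to_frame(self) -> pd.DataFrame:
        """Long-format dump: subject_id, visit_index, time, test_index, md_db,
        reliable (0/1)."""
        n, v, k = self.md_values.shape
        return pd.DataFrame(
            {
                "subject_id": np.repeat(self.subject_ids, v * k),
                "visit_index": np.tile(np.repeat(np.arange(v), k), n),
                "time": np.tile(np.repeat(self.visit_times, k), n),
                "test_index": np.tile(np.arange(k), n * v),
                "md_db": self.md_values.ravel(),
                "reliable": self.reliable_mask.ravel().astype(np.int8),
            }
        )


def _simulate_arrays(
    md0: np.ndarray,
    slope: np.ndarray,
    sigma: np.ndarray,
    reliability: np.ndarray,
    schedule: Schedule,
    rng_noise: np.random.Generator,
    rng_rel: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    t_years = schedule.visit_times * schedule.slope_time_factor
    n = len(md0)
    v = schedule.n_visits
    k = schedule.tests_per_visit_core
    truth = md0[:, None] + slope[:, None] * t_years[None, :]  # (n, v)
    eps = rng_noise.standard_normal((n, v, k)) * sigma[:, None, None]
    md = truth[:, :, None] + eps
    mask = rng_rel.random((n, v, k)) < reliability[:, None, None]
    return md, mask


def simulate_core(
    params: SubjectParams,
    schedule: Schedule,
    rng: np.random.Generator,
) -> CoreSeries:
    """Simulate one subject's core series (4 tests at every scheduled visit).

    Every test result is drawn as ``md0 + slope*t + Normal(0, sigma^2)`` and
    independently flagged reliable with probability ``reliability``;
    unreliable results stay in ``md_values`` but are masked out.
    """
    if params.sigma < 0:
        raise ValueError("sigma must be non-negative")
    if not 0 <= params.reliability <= 1:
        raise ValueError("reliability must lie in [0, 1]")
    md, mask = _simulate_arrays(
        np.array([params.md0]),
        np.array([params.slope]),
        np.array([params.sigma]),
        np.array([params.reliability]),
        schedule,
        rng,
        rng,
    )
    return CoreSeries(
        subject_id=params.subject_id,
        schedule=schedule,
        visit_times=schedule.visit_times,
        md_values=md[0],
        reliable_mask=mask[0],
    )


def simulate_cohort(
    population: pd.DataFrame,
    schedule: Schedule,
    seed_seq: np.random.SeedSequence,
) -> CohortSeries:
    """Simulate the core series of every subject in the population table.

    Noise and reliability draws come from two independent child streams of
    ``seed_seq``, so the result is reproducible from the master seed alone.
    """
    child_noise, child_rel = seed_seq.spawn(2)
    rng_noise = np.random.default_rng(child_noise)
    rng_rel = np.random.default_rng(child_rel)
    md, mask = _simulate_arrays(
        population["md0_db"].to_numpy(),
        population["slope_db_per_year"].to_numpy(),
        population["sigma_db"].to_numpy(),
        population["reliability"].to_numpy(),
        schedule,
        rng_noise,
        rng_rel,
    )
    return CohortSeries(
        schedule=schedule,
        visit_times=schedule.visit_times,
        subject_ids=population["subject_id"].to_numpy(),
        md_values=md,
        reliable_mask=mask,
    )


def derive_permutation(core, spec: PermutationSpec):
    """Restrict a core series to a testing condition.

    Retains visits 0, m, 2m, ... (visit times preserved, not re-indexed) and
    the first ``tests_per_visit`` test columns of each retained visit.  Works
    on a single-subject :class:`CoreSeries` or a :class:`CohortSeries`.
    """
    m, k = spec.interval_multiplier, spec.tests_per_visit
    times = core.visit_times[::m]
    if isinstance(core, CohortSeries):
        return CohortSeries(
            schedule=core.schedule,
            visit_times=times,
            subject_ids=core.subject_ids,
            md_values=core.md_values[:, ::m, :k],
            reliable_mask=core.reliable_mask[:, ::m, :k],
        )
    return CoreSeries(
        subject_id=core.subject_id,
        schedule=core.schedule,
        visit_times=times,
        md_values=core.md_values[::m, :k],
        reliable_mask=core.reliable_mask[::m, :k],
    )
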