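"""Ground-truth subject parameters for the simulated cohort.

Each simulated patient is characterised by four immutable quantities:

* baseline mean deviation ``md0`` (dB), drawn from a normal distribution;
* progression rate ``slope`` (dB/year), drawn from an Azzalini skew-normal
  distribution whose negative shape parameter yields a long tail of fast
  progressors;
* intrinsic inter-visit variability ``sigma`` (dB), the test-retest noise SD,
  drawn from a lognormal distribution so that it is strictly positive;
* intrinsic reliability ``reliability``, the probability that a single test
  returns usable data, drawn from a beta distribution linearly rescaled onto
  a clinically plausible interval.

The four parameters are sampled mutually independently.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

__all__ = [
    "DistributionConfig",
    "SubjectParams",
    "sample_skew_normal",
    "sample_population",
    "summarize_population",
    "POPULATION_COLUMNS",
]

#: canonical column order of the population table
POPULATION_COLUMNS = [
    "subject_id",
    "md0_db",
    "slope_db_per_year",
    "sigma_db",
    "reliability",
]


@dataclass(frozen=True)
class DistributionConfig:
    """Hyperparameters of the four ground-truth parameter distributions.

    Defaults reproduce the reference cohort: mostly early-stage glaucoma
    (median MD around -4 dB), a skewed progression-rate distribution with a
    fast-progressing tail, lognormal variability with median
    ``exp(0.5) ~ 1.65`` dB, and a reliability distribution biased towards
    highly reliable subjects with a long left tail.
    """

    md_mean: float = -4.0  # dB
    md_sd: float = 2.0  # dB
    slope_location: float = -0.05  # dB/yr
    slope_scale: float = 0.8  # dB/yr
    slope_skew: float = -2.0
    var_log_mean: float = 0.5  # log-dB
    var_log_sigma: float = 0.4  # log-dB
    rel_low: float = 0.5
    rel_high: float = 0.99
    rel_alpha: float = 9.0
    rel_beta: float = 1.5

    def __post_init__(self) -> None:
        if self.md_sd <= 0:
            raise ValueError("md_sd must be positive")
        if self.slope_scale <= 0:
            raise ValueError("slope_scale must be positive")
        if self.var_log_sigma <= 0:
            raise ValueError("var_log_sigma must be positive")
        if not (0 <= self.rel_low < self.rel_high <= 1):
            raise ValueError("require 0 <= rel_low < rel_high <= 1")
        if self.rel_alpha <= 0 or self.rel_beta <= 0:
            raise ValueError("beta shape parameters must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "DistributionConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown distribution keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class SubjectParams:
    """Ground-truth quadruple of one simulated subject."""

    subject_id: int
    md0: float  # dB
    slope: float  # dB/yr
    sigma: float  # dB, > 0
    reliability: float  # in [rel_low, rel_high]


def sample_skew_normal(
    location: float,
    scale: float,
    skew: float,
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw ``n`` values from the Azzalini skew-normal SN(location, scale, skew).

    Uses the two-normal delta representation
    ``X = loc + scale * (delta*|Z0| + sqrt(1-delta^2)*Z1)`` with
    ``delta = skew / sqrt(1 + skew^2)``, which reduces to a plain normal draw
    when ``skew == 0``.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if n < 0:
        raise ValueError("n must be non-negative")
    delta = skew / np.sqrt(1.0 + skew * skew)
    z0 = rng.standard_normal(n)
    z1 = rng.standard_normal(n)
    return location + scale * (delta * np.abs(z0) + np.sqrt(1.0 - delta * delta) * z1)


def sample_population(
    config: DistributionConfig,
    n: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample ``n`` subjects; returns a table with columns ``POPULATION_COLUMNS``.

    ``md0 ~ Normal(md_mean, md_sd)``; ``slope`` skew-normal;
    ``sigma = exp(Normal(var_log_mean, var_log_sigma))``;
    ``reliability = rel_low + (rel_high - rel_low) * Beta(rel_alpha, rel_beta)``.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    md0 = rng.normal(config.md_mean, config.md_sd, size=n)
    slope = sample_skew_normal(
        config.slope_location, config.slope_scale, config.slope_skew, n, rng
    )
    sigma = np.exp(rng.normal(config.var_log_mean, config.var_log_sigma, size=n))
    rel = config.rel_low + (config.rel_high - config.rel_low) * rng.beta(
        config.rel_alpha, config.rel_beta, size=n
    )
    return pd.DataFrame(
        {
            "subject_id": np.arange(n, dtype=np.int64),
            "md0_db": md0,
            "slope_db_per_year": slope,
            "sigma_db": sigma,
            "reliability": rel,
        }
    )


def subject_params(row: pd.Series) -> SubjectParams:
    """Convert one population-table row into a :class:`SubjectParams`."""
    return SubjectParams(
        subject_id=int(row["subject_id"]),
        md0=float(row["md0_db"]),
        slope=float(row["slope_db_per_year"]),
        sigma=float(row["sigma_db"]),
        reliability=float(row["reliability"]),
    )


def summarize_population(population: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of each ground-truth parameter.

    Returns a table indexed by parameter with columns ``median``, ``q25``,
    ``q75``. Raises on an empty cohort.
    """
    if len(population) == 0:
        raise ValueError("population is empty")
    cols = [c for c in POPULATION_COLUMNS if c != "subject_id"]
    out = {
        "median": population[cols].median(),
        "q25": population[cols].quantile(0.25),
        "q75": population[cols].quantile(0.75),
    }
    return pd.DataFrame(out)
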