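"""Signal-to-noise detection-probability calculator.

Given a fixed MD difference of interest ("signal" ``d``, e.g. 0.8 dB of
progression) and a subject's intrinsic variability ("noise" ``sigma``), the
probability that a single test detects the difference is modelled as the
standard normal CDF of the signal-to-noise ratio, ``Phi(d / sigma)`` --
one-sided detection of a positive shift.  With ``n`` independent tests per
visit, the probability of detection on at least one test follows the
binomial complement ``1 - (1 - p)^n``.  The grid over variability levels and
tests per visit supports tailoring test intensity to a patient's measured
variability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "DetectionGrid",
    "single_test_detection",
    "at_least_one_detection",
    "build_detection_grid",
]

DEFAULT_SIGNAL = 0.8  # dB
DEFAULT_VARIABILITY_LEVELS = (0.5, 1.0, 1.5, 2.0, 2.5)  # dB


def single_test_detection(signal: float, variability: float) -> float:
    """Probability that one test detects a ``signal`` dB difference:
    ``Phi(signal / variability)``.  Requires positive variability."""
    if variability <= 0:
        raise ValueError("variability must be positive")
    return float(norm.cdf(signal / variability))


def at_least_one_detection(p_single: float, n: int) -> float:
    """Probability of detection on >= 1 of ``n`` independent tests:
    ``1 - (1 - p)^n``."""
    if not 0 <= p_single <= 1:
        raise ValueError("p_single must lie in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    return float(1.0 - (1.0 - p_single) ** n)


@dataclass(frozen=True)
class DetectionGrid:
    """Detection probabilities over variability levels x tests per visit."""

    signal: float
    variability_levels: np.ndarray
    tests_per_visit: np.ndarray
    snr: np.ndarray  # signal / sigma, per variability level
    p_single: np.ndarray  # (levels,)
    p_at_least_one: np.ndarray  # (levels, tests)

    def to_frame(self) -> pd.DataFrame:
        """Rows: variability level; columns: SNR, p per tests-per-visit."""
        df = pd.DataFrame(
            self.p_at_least_one,
            index=self.variability_levels,
            columns=[f"{n}_tests_per_visit" for n in self.tests_per_visit],
        )
        df.insert(0, "snr", self.snr)
        df.index.name = "variability_db"
        return df


def build_detection_grid(
    signal: float = DEFAULT_SIGNAL,
    variability_levels=DEFAULT_VARIABILITY_LEVELS,
    max_tests: int = 4,
) -> DetectionGrid:
    """Full grid of single-test and at-least-one detection probabilities.

    Probabilities are non-increasing as variability grows and non-decreasing
    in the number of tests per visit.
    """
    levels = np.asarray(variability_levels, dtype=float)
    if np.any(levels <= 0):
        raise ValueError("all variability levels must be positive")
    if max_tests < 1:
        raise ValueError("max_tests must be >= 1")
    tests = np.arange(1, max_tests + 1)
    p1 = np.array([single_test_detection(signal, s) for s in levels])
    grid = 1.0 - (1.0 - p1[:, None]) ** tests[None, :]
    return DetectionGrid(
        signal=float(signal),
        variability_levels=levels,
        tests_per_visit=tests,
        snr=signal / levels,
        p_single=p1,
        p_at_least_one=grid,
    )
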