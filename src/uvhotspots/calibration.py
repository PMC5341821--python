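"""Poisson-binomial calibration of the cluster-count threshold.

Each sample contributes at most one "hit" to a fixed window of width ``w``
with probability ``p_i = n_i * w / G`` (``n_i`` the sample's genome-wide SNV
count, ``G`` the genome length).  The cross-sample hit count is then
Poisson-binomial, and the detection threshold ``k`` is the smallest count
whose exact upper tail falls below a chosen significance level.  The tail is
computed by the exact O(n*k) convolution recurrence — cohort sizes are tens
of samples, so no approximation is needed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Cohort


@dataclass
class RateVector:
    """Per-sample probabilities of >= 1 SNV in one window."""

    p: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.ndim != 1:
            raise ValueError("rates must be a 1-D vector")
        if np.any((self.p < 0) | (self.p > 1)):
            raise ValueError("all rates must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.p)


@dataclass
class CalibrationResult:
    k: int
    tail: float
    tail_adjusted: float | None = None


def pois_binom_tail(rates: RateVector | np.ndarray, k: int) -> float:
    """Exact ``P(X >= k)`` for ``X = sum_i Bernoulli(p_i)``.

    Dynamic programme over ``P(X = j)`` for ``j < k`` with an absorbing
    bucket for mass reaching ``k``; the absorbed mass is accumulated
    additively, which keeps tiny tails accurate (no ``1 - sum`` cancellation).
    """
    p = rates.p if isinstance(rates, RateVector) else np.asarray(rates, dtype=float)
    if k < 0:
        raise ValueError("k must be >= 0")
    n = len(p)
    if k == 0:
        return 1.0
    if k > n:
        return 0.0
    dp = np.zeros(k)
    dp[0] = 1.0
    tail = 0.0
    for pi in p:
        tail += dp[k - 1] * pi
        dp[1:] = dp[1:] * (1.0 - pi) + dp[:-1] * pi
        dp[0] *= 1.0 - pi
    return float(min(1.0, tail))


def estimate_rates(cohort: Cohort, w: int) -> RateVector:
    """Per-sample window hit rates ``p_i = n_i * w / G`` (clipped to [0, 1])."""
    if cohort.n_samples == 0:
        raise ValueError("cohort has no samples")
    counts = cohort.per_sample_counts().to_numpy(dtype=float)
    p = counts * w / cohort.genome_length
    if np.any(p > 1):
        warnings.warn("per-sample window rates exceed 1; clipping", stacklevel=2)
        p = np.clip(p, 0.0, 1.0)
    return RateVector(p)


def calibrate_threshold(
    rates: RateVector, alpha: float, n_tests: int | None = None
) -> CalibrationResult:
    """Smallest ``k`` with ``P(X >= k) < alpha``.

    ``n_tests``, when given, additionally reports the Bonferroni-adjusted
    tail ``min(1, tail * n_tests)``; it is deliberately a caller-supplied
    multiplier (the number of windows tested is a property of the scan, not
    of the rate model).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    n = len(rates)
    for k in range(n + 1):
        tail = pois_binom_tail(rates, k)
        if tail < alpha:
            adjusted = min(1.0, tail * n_tests) if n_tests else None
            return CalibrationResult(k=k, tail=tail, tail_adjusted=adjusted)
    raise ValueError(f"no threshold k <= {n} achieves tail < {alpha}")
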