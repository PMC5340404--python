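"""Two-community diversity comparison via difference confidence envelopes.

With independent samples from two communities, the difference of the
unbiased estimates, Z_r(1) - Z_r(2), is asymptotically normal with variance
sigma_1^2/n_1 + sigma_2^2/n_2, giving a Wald interval per order.  Assembling
the intervals over r = 1..v gives a pointwise envelope; identical diversity
is rejected when zero stays outside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateVarianceWarning, InvalidCommunityError, InvalidOrderError
from .estimation import (
    ConfidenceInterval,
    SampleCounts,
    sigma_estimate,
    z_estimate,
    _check_estimation_order,
)


@dataclass(frozen=True)
class DifferenceProfile:
    orders: np.ndarray
    differences: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    n1: int
    n2: int

    def __len__(self) -> int:
        return int(self.orders.size)


@dataclass(frozen=True)
class SignificanceSummary:
    """Zero-in-envelope report for a difference profile (pointwise, no
    multiplicity correction)."""

    orders: np.ndarray
    zero_inside: np.ndarray  # bool per order
    verdict: str  # "significant" | "not_significant" | "inconclusive"
    level: float

    def describe(self) -> str:
        if self.verdict == "significant":
            head = "significant difference at every order (pointwise envelope)"
        elif self.verdict == "not_significant":
            head = "no significant difference at any order (pointwise envelope)"
        else:
            head = "inconclusive: zero is inside the envelope at some orders only"
        rows = [
            f"  r={int(r)}: zero {'inside' if z else 'outside'} the interval"
            for r, z in zip(self.orders, self.zero_inside)
        ]
        return "\n".join([head] + rows)


def _sigma_or_zero(sample: SampleCounts, r: int) -> float:
    """σ̂_r, treating the single-species degenerate case as exactly 0.

    A one-species sample has Z_r = 0 with no sampling variability in the
    estimator's normal limit; it participates in a difference interval with
    zero variance contribution, flagged by a warning.
    """
    if sample.k < 2:
        warnings.warn(
            "single observed species: variance contribution taken as 0",
            DegenerateVarianceWarning,
            stacklevel=3,
        )
        return 0.0
    return sigma_estimate(sample, r)


def difference_interval(
    sample1: SampleCounts,
    sample2: SampleCounts,
    r: int,
    alpha: float = 0.05,
) -> ConfidenceInterval:
    """Asymptotic CI for zeta_r(1) - zeta_r(2); not clamped (lives in [-1, 1])."""
    if not (0.0 < alpha < 1.0):
        raise InvalidCommunityError(f"alpha must be in (0,1), got {alpha}")
    n_min = min(sample1.n, sample2.n)
    r = _check_estimation_order(r, n_min)
    d = z_estimate(sample1, r) - z_estimate(sample2, r)
    s1 = _sigma_or_zero(sample1, r)
    s2 = _sigma_or_zero(sample2, r)
    se = np.sqrt(s1**2 / sample1.n + s2**2 / sample2.n)
    margin = stats.norm.ppf(1.0 - alpha / 2.0) * se
    return ConfidenceInterval(lower=d - margin, upper=d + margin, level=1.0 - alpha)


def difference_profile(
    sample1: SampleCounts,
    sample2: SampleCounts,
    v: int,
    alpha: float = 0.05,
    richness: float | None = None,
) -> DifferenceProfile:
    """Per-order difference CIs for r = 1..v, v <= min(n1, n2) - 1."""
    n_min = min(sample1.n, sample2.n)
    if v > n_min - 1:
        raise InvalidOrderError(
            f"profile bound v={v} exceeds min(n1, n2) - 1 = {n_min - 1}"
        )
    v = _check_estimation_order(v, n_min)
    if richness is not None and v > richness - 1:
        warnings.warn(
            f"orders beyond {int(np.floor(richness)) - 1} exceed the advisory "
            "richness bound v <= S_hat - 1",
            stacklevel=2,
        )
    orders = np.arange(1, v + 1)
    diff = np.empty(v)
    lo = np.empty(v)
    hi = np.empty(v)
    with warnings.catch_warnings():
        warnings.simplefilter("once", DegenerateVarianceWarning)
        for i, r in enumerate(orders):
            ci = difference_interval(sample1, sample2, int(r), alpha)
            diff[i] = (ci.lower + ci.upper) / 2.0
            lo[i], hi[i] = ci.lower, ci.upper
    return DifferenceProfile(
        orders=orders,
        differences=diff,
        lower=lo,
        upper=hi,
        level=1.0 - alpha,
        n1=sample1.n,
        n2=sample2.n,
    )


def significance_summary(profile: DifferenceProfile) -> SignificanceSummary:
    """Classify the envelope: zero outside at all orders -> "significant";
    inside at all orders -> "not_significant"; otherwise "inconclusive"."""
    if len(profile) == 0:
        raise InvalidCommunityError("cannot summarize an empty profile")
    inside = (profile.lower <= 0.0) & (0.0 <= profile.upper)
    if not inside.any():
        verdict = "significant"
    elif inside.all():
        verdict = "not_significant"
    else:
        verdict = "inconclusive"
    return SignificanceSummary(
        orders=profile.orders,
        zero_inside=inside,
        verdict=verdict,
        level=profile.level,
    )
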