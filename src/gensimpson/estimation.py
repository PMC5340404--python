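"""Unbiased estimation of generalized Simpson's entropy from sample counts.

For a multinomial sample of n individuals with observed species counts
``n'_1, ..., n'_K`` the estimator

    Z_r = sum_s p̂'_s * prod_{j=1..r} (1 - (n'_s - 1) / (n - j))

is the uniformly minimum variance unbiased estimator of zeta_r for every
order 1 <= r <= n - 1.  Z_r is consistent and asymptotically normal; the
delta method yields an asymptotic standard deviation sigma_r and Wald-type
confidence intervals, which transform monotonically to the effective-number
(diversity) scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .community import _check_order, effective_number
from .errors import (
    DegenerateVarianceWarning,
    InvalidCommunityError,
    InvalidOrderError,
    OrderValidityWarning,
    UndefinedVarianceError,
)


@dataclass(frozen=True)
class SampleCounts:
    """Observed species abundances from one community sample.

    counts are the abundances of the K *observed* species (all >= 1);
    unobserved species carry no information for Z_r and are not stored.
    """

    counts: np.ndarray
    labels: tuple | None = None

    def __post_init__(self):
        c = np.asarray(self.counts)
        if c.ndim != 1 or c.size < 1:
            raise InvalidCommunityError("counts must be a non-empty 1-D vector")
        if not np.issubdtype(c.dtype, np.integer):
            if not np.all(c == np.floor(c)):
                raise InvalidCommunityError("counts must be integers")
            c = c.astype(np.int64)
        else:
            c = c.astype(np.int64)
        if np.any(c < 1):
            raise InvalidCommunityError("every observed count must be >= 1")
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != c.size:
                raise InvalidCommunityError("labels and counts lengths differ")
            if len(set(labels)) != len(labels):
                raise InvalidCommunityError("species labels must be unique")
            object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        """Total sample size."""
        return int(self.counts.sum())

    @property
    def k(self) -> int:
        """Observed richness K."""
        return int(self.counts.size)

    @property
    def proportions(self) -> np.ndarray:
        """Empirical proportions p̂'_s = n'_s / n."""
        return self.counts / self.n


@dataclass(frozen=True)
class EntropyEstimate:
    r: int
    value: float
    sigma: float
    n: int


@dataclass(frozen=True)
class ConfidenceInterval:
    lower: float
    upper: float
    level: float

    def __post_init__(self):
        if not (0.0 < self.level < 1.0):
            raise InvalidCommunityError(f"level must be in (0,1), got {self.level}")
        if self.lower > self.upper:
            raise InvalidCommunityError("lower bound exceeds upper bound")

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


@dataclass(frozen=True)
class Profile:
    """Per-order estimates with a pointwise confidence envelope."""

    orders: np.ndarray
    estimates: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    scale: str  # "entropy" | "diversity"
    level: float
    n: int
    warnings: tuple = ()

    def __len__(self) -> int:
        return int(self.orders.size)


def _check_estimation_order(r: int, n: int) -> int:
    r = _check_order(r)
    if r > n - 1:
        raise InvalidOrderError(
            f"no unbiased estimator of zeta_r exists for r={r} with n={n}: need r <= n-1"
        )
    return r


def z_many(counts: np.ndarray, r: int) -> np.ndarray:
    """Vectorized Z_r over rows of a (reps, S) count matrix (zeros allowed).

    Zero-count species contribute nothing (their p̂ factor is 0), so rows
    may contain structural zeros from multinomial draws.
    """
    c = np.asarray(counts, dtype=float)
    if c.ndim == 1:
        c = c[None, :]
    n = c.sum(axis=1, keepdims=True)
    prod = np.ones_like(c)
    for j in range(1, r + 1):
        prod *= 1.0 - (c - 1.0) / (n - j)
    return np.sum((c / n) * prod, axis=1)


def z_estimate(sample: SampleCounts, r: int) -> float:
    """Unbiased estimate Z_r of generalized Simpson's entropy.

    Computed by direct product accumulation: every factor
    ``1 - (n'_s - 1)/(n - j)`` lies in [0, 1] for j <= r <= n-1 (a zero
    factor occurs before any factor could turn negative), so the result is
    always in [0, 1] and no log-space care is needed.
    """
    r = _check_estimation_order(r, sample.n)
    return float(z_many(sample.counts, r)[0])


def plugin_z_estimate(sample: SampleCounts, r: int) -> float:
    """Naive plug-in estimator ``sum_s p̂_s (1 - p̂_s)**r`` (biased low)."""
    r = _check_order(r)
    p = sample.proportions
    return float(np.sum(p * (1.0 - p) ** r))


def _gradient(p: np.ndarray, r: int) -> np.ndarray:
    """d zeta_r / d p_s = (1-p)^r - r p (1-p)^(r-1), elementwise."""
    return (1.0 - p) ** r - r * p * (1.0 - p) ** (r - 1)


def asymptotic_sd(probs: np.ndarray, r: int) -> float:
    """Delta-method sd of sqrt(n) (Z_r - zeta_r) at proportion vector ``probs``.

    Equals sqrt(h' Σ h) where Σ is the multinomial covariance of the first
    K-1 proportions and h_j = g(p_j) - g(p_K) with g the zeta_r gradient;
    that quadratic form reduces to the variance of g under p, which is what
    is computed here (invariant to which species is singled out as the K-th).
    """
    p = np.asarray(probs, dtype=float)
    g = _gradient(p, r)
    m = float(np.sum(p * g))
    var = float(np.sum(p * g * g) - m * m)
    return float(np.sqrt(max(var, 0.0)))


def sigma_estimate(sample: SampleCounts, r: int) -> float:
    """Estimated asymptotic sd σ̂_r of sqrt(n)(Z_r − zeta_r).

    Undefined for a single observed species.  When p̂ is exactly uniform the
    gradient is constant and σ̂ = 0; a warning is raised because the normal
    approximation degenerates there.
    """
    r = _check_estimation_order(r, sample.n)
    if sample.k < 2:
        raise UndefinedVarianceError(
            "asymptotic variance is undefined with a single observed species"
        )
    sigma = asymptotic_sd(sample.proportions, r)
    if np.all(sample.counts == sample.counts[0]):
        warnings.warn(
            "empirical distribution is exactly uniform: sigma_hat = 0 and the "
            "asymptotic confidence interval degenerates",
            DegenerateVarianceWarning,
            stacklevel=2,
        )
        return 0.0
    return sigma


def confidence_interval(
    sample: SampleCounts, r: int, alpha: float = 0.05
) -> ConfidenceInterval:
    """Asymptotic (1-alpha) CI ``Z_r ± z_{alpha/2} σ̂_r / sqrt(n)``, clamped to [0, 1]."""
    if not (0.0 < alpha < 1.0):
        raise InvalidCommunityError(f"alpha must be in (0,1), got {alpha}")
    z = z_estimate(sample, r)
    sigma = sigma_estimate(sample, r)
    margin = stats.norm.ppf(1.0 - alpha / 2.0) * sigma / np.sqrt(sample.n)
    return ConfidenceInterval(
        lower=max(0.0, z - margin), upper=min(1.0, z + margin), level=1.0 - alpha
    )


def entropy_profile(
    sample: SampleCounts,
    v: int,
    alpha: float = 0.05,
    richness: float | None = None,
) -> Profile:
    """Estimates and pointwise CIs for zeta_r, r = 1..v.

    If a richness estimate Ŝ is supplied, orders beyond Ŝ - 1 (where zeta_r
    is no longer guaranteed to be maximized by the uniform distribution)
    trigger an ``OrderValidityWarning`` recorded on the profile.
    """
    v = _check_estimation_order(v, sample.n)
    orders = np.arange(1, v + 1)
    est = np.empty(v)
    lo = np.empty(v)
    hi = np.empty(v)
    notes = []
    with warnings.catch_warnings():
        # a uniform-p̂ sample would warn once per order; once is enough
        warnings.simplefilter("once", DegenerateVarianceWarning)
        for i, r in enumerate(orders):
            est[i] = z_estimate(sample, int(r))
            ci = confidence_interval(sample, int(r), alpha)
            lo[i], hi[i] = ci.lower, ci.upper
    if richness is not None and v > richness - 1:
        msg = (
            f"orders r > {int(np.floor(richness)) - 1} exceed the estimated-richness "
            f"bound r <= S_hat - 1 (S_hat = {richness:g}); zeta_r may not be a valid "
            "diversity measure there"
        )
        warnings.warn(msg, OrderValidityWarning, stacklevel=2)
        notes.append(msg)
    return Profile(
        orders=orders,
        estimates=est,
        lower=lo,
        upper=hi,
        scale="entropy",
        level=1.0 - alpha,
        n=sample.n,
        warnings=tuple(notes),
    )


def diversity_profile(
    sample: SampleCounts,
    v: int,
    alpha: float = 0.05,
    richness: float | None = None,
) -> Profile:
    """Effective-number profile: entropy_profile mapped through D = 1/(1 - t^(1/r)).

    The transform is monotone increasing, so the per-order envelope carries
    over and inference on either scale is equivalent.
    """
    prof = entropy_profile(sample, v, alpha, richness)
    est = np.array(
        [effective_number(t, int(r)) for t, r in zip(prof.estimates, prof.orders)]
    )
    lo = np.array([effective_number(t, int(r)) for t, r in zip(prof.lower, prof.orders)])
    hi = np.array([effective_number(t, int(r)) for t, r in zip(prof.upper, prof.orders)])
    return Profile(
        orders=prof.orders,
        estimates=est,
        lower=lo,
        upper=hi,
        scale="diversity",
        level=prof.level,
        n=prof.n,
        warnings=prof.warnings,
    )
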