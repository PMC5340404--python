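"""Jackknife species-richness estimation (Burnham–Overton family).

Profiles of generalized Simpson's entropy are only valid diversity measures
up to order r = S - 1, but S is unknown when sampling is incomplete.  The
k-th order jackknife corrects observed richness K using the counts f_i of
species seen exactly i times; a sequential significance test picks the
smallest adequate order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidCommunityError, InvalidOrderError
from .estimation import SampleCounts

MAX_JACKKNIFE_ORDER = 5


@dataclass(frozen=True)
class RichnessEstimate:
    estimate: float
    order: int
    k_observed: int
    n: int
    frequency_counts: tuple  # f_1 .. f_{order+1}


def frequency_counts(sample: SampleCounts, max_i: int) -> np.ndarray:
    """f_i = number of species observed exactly i times, for i = 1..max_i."""
    if max_i < 1:
        raise InvalidOrderError(f"max_i must be >= 1, got {max_i}")
    c = sample.counts
    return np.array([int(np.sum(c == i)) for i in range(1, max_i + 1)])


def _jackknife_coefficients(n: int, order: int) -> np.ndarray:
    """Coefficient a_i on f_i in Ŝ_k = K + sum_i a_i f_i.

    Derived from the generalized (delete-j) jackknife: with
    c_j = (-1)^j C(k,j) (n-j)^k / k! and the exact mean subsample richness
    S̄_{n-j} = K - sum_i f_i C(n-i, j-i)/C(n, j), expanding gives
    a_i = -sum_{j>=i} c_j C(n-i, j-i)/C(n, j).  Reproduces the classical
    printed formulas, e.g. order 1: f_1 (n-1)/n; order 2:
    f_1 (2n-3)/n - f_2 (n-2)^2 / (n(n-1)).
    """
    k = order
    a = np.zeros(k)
    kfact = math.factorial(k)
    for i in range(1, k + 1):
        acc = 0.0
        for j in range(i, k + 1):
            c_j = (-1) ** j * math.comb(k, j) * (n - j) ** k / kfact
            acc += c_j * math.comb(n - i, j - i) / math.comb(n, j)
        a[i - 1] = -acc
    return a


def jackknife(sample: SampleCounts, order: int) -> RichnessEstimate:
    """Order-k jackknife richness estimate (k = 1..5)."""
    if not (1 <= order <= MAX_JACKKNIFE_ORDER):
        raise InvalidOrderError(
            f"jackknife order must be in 1..{MAX_JACKKNIFE_ORDER}, got {order}"
        )
    n = sample.n
    if n <= order:
        raise InvalidOrderError(f"need n > order, got n={n}, order={order}")
    f = frequency_counts(sample, order + 1)
    a = _jackknife_coefficients(n, order)
    estimate = sample.k + float(a @ f[:order])
    return RichnessEstimate(
        estimate=estimate,
        order=order,
        k_observed=sample.k,
        n=n,
        frequency_counts=tuple(int(x) for x in f),
    )


def _sequential_test_pvalue(sample: SampleCounts, k: int) -> float:
    """P-value of the Burnham–Overton test of Ŝ_{k+1} against Ŝ_k.

    Under the hypothesis that order k already removes the bias, the
    difference d = Ŝ_{k+1} - Ŝ_k is asymptotically normal with variance
    estimated by (K/(K-1)) (sum_i b_i^2 f_i - d^2/K), where b_i is the
    difference of the f_i coefficients of the two estimators.
    """
    n = sample.n
    kk = sample.k
    f = frequency_counts(sample, k + 1).astype(float)
    a_lo = np.zeros(k + 1)
    a_lo[:k] = _jackknife_coefficients(n, k)
    a_hi = _jackknife_coefficients(n, k + 1)
    b = a_hi - a_lo
    d = float(b @ f)
    var = (kk / (kk - 1)) * (float(b**2 @ f) - d**2 / kk)
    if var <= 0:
        return 1.0
    t = d / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(t)))


def select_jackknife_order(sample: SampleCounts, alpha: float = 0.05) -> int:
    """Smallest order k whose sequential test against order k+1 is
    non-significant, capped at 5.

    With no singletons (f_1 = 0) the sample carries no evidence of unseen
    species and order 1 is returned immediately.
    """
    if sample.k < 2:
        warnings.warn(
            "fewer than two observed species: defaulting to jackknife order 1",
            stacklevel=2,
        )
        return 1
    if int(np.sum(sample.counts == 1)) == 0:
        return 1
    for k in range(1, MAX_JACKKNIFE_ORDER):
        if sample.n <= k + 1:
            return k
        if _sequential_test_pvalue(sample, k) >= alpha:
            return k
    return MAX_JACKKNIFE_ORDER


def max_valid_order(richness: RichnessEstimate | float) -> int:
    """Largest entropy order with guaranteed evenness: floor(Ŝ) - 1."""
    est = richness.estimate if isinstance(richness, RichnessEstimate) else richness
    if est < 2:
        raise InvalidCommunityError(f"richness estimate must be >= 2, got {est}")
    return int(math.floor(est)) - 1
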