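"""Comparator diversity indices: HCDT (Tsallis) entropy, Hill numbers, and
Hurlbert's expected-species index.

HCDT entropy ^qT = (sum_s p_s^q - 1)/(1 - q) generalizes richness (q=0),
Shannon (q=1, by limit) and Simpson (q=2, where ^2T = zeta_1).  Its
effective number is the Hill number ^qD = (sum_s p_s^q)^(1/(1-q)).
Hurlbert's index ^kH = sum_s [1 - (1-p_s)^k] is the expected number of
species in a sample of k individuals; ^2H = 1 + zeta_1.  Only plug-in Hill
numbers are provided (profiles computed on p̂ are biased); Hurlbert's index
has an unbiased rarefaction estimator implemented here.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln

from .community import Community
from .errors import DegenerateCommunityError, InvalidCommunityError, InvalidOrderError
from .estimation import ConfidenceInterval, SampleCounts
from .community import _check_order, effective_number, zeta

_Q1_TOL = 1e-9  # |q - 1| below this uses the Shannon limit


def hcdt_entropy(community: Community, q: float) -> float:
    """HCDT (Tsallis) entropy of order q >= 0; Shannon entropy at q = 1."""
    if q < 0:
        raise InvalidOrderError(f"HCDT order q must be >= 0, got {q}")
    p = community.probs
    if abs(q - 1.0) < _Q1_TOL:
        return float(-np.sum(p * np.log(p)))
    return float((np.sum(p**q) - 1.0) / (1.0 - q))


def hill_diversity(community: Community, q: float) -> float:
    """Hill number ^qD = (sum p^q)^(1/(1-q)); exp(Shannon) at q = 1."""
    if q < 0:
        raise InvalidOrderError(f"Hill order q must be >= 0, got {q}")
    p = community.probs
    if abs(q - 1.0) < _Q1_TOL:
        return float(np.exp(-np.sum(p * np.log(p))))
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def match_q(community: Community, r: int, tol: float = 1e-8) -> float:
    """HCDT order q whose Hill diversity equals the order-r generalized
    Simpson diversity of the same community.

    For r = 1 the answer is exactly q = 2 (since ^2T = zeta_1 implies
    ^2D = 1/(1 - zeta_1) = ^1D^zeta).  The Hill profile of a non-uniform
    community is strictly decreasing in q, so the match is found by
    bracketing and Brent root-finding; the initial bracket [0, 2] expands
    upward if needed.  Uniform communities are degenerate (every q matches).
    """
    r = _check_order(r)
    if community.is_uniform(tol=1e-15):
        raise DegenerateCommunityError(
            "uniform community: Hill diversity is constant in q, no unique match"
        )
    target = effective_number(zeta(community, r), r)

    def fn(q):
        return hill_diversity(community, q) - target

    lo, hi = 0.0, 2.0
    while fn(hi) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise DegenerateCommunityError("failed to bracket a matching q")
    if fn(lo) < 0:
        raise DegenerateCommunityError(
            f"target diversity {target:g} exceeds richness {community.richness}"
        )
    return float(brentq(fn, lo, hi, xtol=tol, rtol=4 * np.finfo(float).eps))


def hurlbert_index(community: Community, k: int) -> float:
    """Hurlbert's ^kH = sum_s [1 - (1 - p_s)^k]: expected species in k draws."""
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise InvalidOrderError(f"k must be an integer >= 1, got {k!r}")
    p = community.probs
    return float(np.sum(1.0 - (1.0 - p) ** k))


def _log_comb(n: float, k: float) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hurlbert_unbiased(sample: SampleCounts, k: int) -> float:
    """Unbiased (rarefaction) estimate of ^kH:
    sum_s [1 - C(n - n'_s, k) / C(n, k)].

    The s-th term is the probability that species s appears in a size-k
    subsample drawn without replacement; binomials are evaluated through
    log-gamma so n may be large.  k = n returns the observed richness K.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise InvalidOrderError(f"k must be an integer >= 1, got {k!r}")
    n = sample.n
    if k > n:
        raise InvalidOrderError(f"k={k} exceeds the sample size n={n}")
    c = sample.counts
    log_cnk = _log_comb(n, k)
    out = 0.0
    for ns in c:
        if n - ns < k:
            out += 1.0
        else:
            out += 1.0 - math.exp(_log_comb(n - ns, k) - log_cnk)
    return float(out)


def hurlbert_effective_number(value: float, k: int, tol: float = 1e-9) -> float:
    """Effective number of species for Hurlbert's index.

    Solves D (1 - (1 - 1/D)^k) = value for D >= 1.  The left side increases
    from 1 (D = 1) towards k (D -> inf), so value must lie in [1, k];
    value = k returns infinity.
    """
    if not isinstance(k, (int, np.integer)) or k < 1:
        raise InvalidOrderError(f"k must be an integer >= 1, got {k!r}")
    if not (1.0 <= value <= k):
        raise InvalidCommunityError(f"Hurlbert value must be in [1, {k}], got {value}")
    if value == 1.0:
        return 1.0
    if k == 1:
        # ^1H = 1 for every community; only value == 1 is admissible above
        return 1.0

    def fn(d):
        return d * (1.0 - (1.0 - 1.0 / d) ** k) - value

    hi = 2.0
    while fn(hi) < 0:
        hi *= 2.0
        if hi > 1e12:
            return math.inf
    return float(brentq(fn, 1.0, hi, xtol=tol, rtol=4 * np.finfo(float).eps))


def bootstrap_envelope(
    sample: SampleCounts,
    statistic,
    b: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ConfidenceInterval:
    """Percentile bootstrap interval of ``statistic`` (a SampleCounts -> float
    callable) over ``b`` multinomial resamples of size n from p̂."""
    if b < 100:
        raise InvalidOrderError(f"need at least 100 bootstrap replicates, got {b}")
    rng = np.random.default_rng(seed)
    n = sample.n
    p = sample.proportions
    draws = rng.multinomial(n, p, size=b)
    vals = np.empty(b)
    for i in range(b):
        counts = draws[i]
        nz = counts > 0
        vals[i] = statistic(SampleCounts(counts[nz]))
    lo, hi = np.quantile(vals, [alpha / 2.0, 1.0 - alpha / 2.0])
    return ConfidenceInterval(lower=float(lo), upper=float(hi), level=1.0 - alpha)
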