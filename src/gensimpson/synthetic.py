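"""Synthetic communities, seeded multinomial sampling, and exact oracles.

The abundance models (uniform, geometric, log-series, Zipf) span the range
from perfectly even to strongly skewed communities typical of ecological
surveys.  ``enumerate_expectation`` computes the exact expectation of any
sample statistic by summing over every multinomial outcome — the oracle used
to certify unbiasedness of the estimators at small n — and
``coverage_experiment`` measures empirical confidence-interval coverage.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .community import Community, _check_order, zeta
from .errors import (
    DegenerateCommunityError,
    EnumerationBoundError,
    InvalidCommunityError,
)
from .estimation import SampleCounts, asymptotic_sd, z_many

_FAMILIES = ("uniform", "geometric", "log-series", "zipf")

# enumeration refuses beyond this: C(n+S-1, S-1) outcome compositions
_ENUM_MAX_S = 4
_ENUM_MAX_N = 8


@dataclass(frozen=True)
class AbundanceModel:
    """Parametric species-abundance distribution.

    family:
      - "uniform":    p_s = 1/S (no shape parameter)
      - "geometric":  p_s ∝ ratio**(s-1), 0 < ratio < 1 (niche-preemption)
      - "log-series": p_s ∝ theta**s / s, 0 < theta < 1 (Fisher)
      - "zipf":       p_s ∝ s**(-exponent), exponent > 0 (rank-abundance)
    """

    family: str
    s: int
    shape: float | None = None

    def __post_init__(self):
        if self.family not in _FAMILIES:
            raise InvalidCommunityError(
                f"unknown family {self.family!r}; choose from {_FAMILIES}"
            )
        if self.s < 1:
            raise InvalidCommunityError(f"need S >= 1 species, got {self.s}")
        if self.family == "uniform":
            return
        if self.shape is None:
            raise InvalidCommunityError(f"family {self.family!r} needs a shape parameter")
        if self.family in ("geometric", "log-series") and not (0 < self.shape < 1):
            raise InvalidCommunityError(
                f"{self.family} shape must be in (0, 1), got {self.shape}"
            )
        if self.family == "zipf" and self.shape <= 0:
            raise InvalidCommunityError(f"zipf exponent must be > 0, got {self.shape}")


def make_community(model: AbundanceModel) -> Community:
    """Deterministic probability vector for an abundance model."""
    s = model.s
    ranks = np.arange(1, s + 1, dtype=float)
    if model.family == "uniform":
        w = np.ones(s)
    elif model.family == "geometric":
        w = model.shape ** (ranks - 1)
    elif model.family == "log-series":
        w = model.shape**ranks / ranks
    else:  # zipf
        w = ranks ** (-model.shape)
    return Community(w / w.sum())


def sample_counts(
    community: Community, n: int, seed: int | np.random.Generator | None = None
) -> SampleCounts:
    """Multinomial sample of n individuals; zero-count species are omitted,
    matching the observed-species convention of the estimators."""
    if n < 1:
        raise InvalidCommunityError(f"sample size must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draw = rng.multinomial(n, community.probs)
    nz = draw > 0
    labels = None
    if community.labels is not None:
        labels = tuple(l for l, keep in zip(community.labels, nz) if keep)
    return SampleCounts(draw[nz], labels=labels)


def _compositions(n: int, parts: int):
    """All ways to write n as an ordered sum of `parts` non-negative ints."""
    for cuts in itertools.combinations(range(n + parts - 1), parts - 1):
        prev = -1
        out = []
        for c in cuts:
            out.append(c - prev - 1)
            prev = c
        out.append(n + parts - 2 - prev)
        yield tuple(out)


def enumerate_expectation(community: Community, n: int, statistic) -> float:
    """Exact E[statistic(sample)] under multinomial(n, p) by full enumeration.

    ``statistic`` receives a SampleCounts built from the non-zero part of
    each outcome.  Refuses when S > 4 or n > 8 (combinatorial blow-up).
    """
    s = community.richness
    if s > _ENUM_MAX_S or n > _ENUM_MAX_N:
        raise EnumerationBoundError(
            f"enumeration limited to S <= {_ENUM_MAX_S}, n <= {_ENUM_MAX_N} "
            f"(got S={s}, n={n})"
        )
    if n < 1:
        raise InvalidCommunityError(f"sample size must be >= 1, got {n}")
    logp = np.log(community.probs)
    log_nfact = gammaln(n + 1)
    total = 0.0
    for counts in _compositions(n, s):
        c = np.array(counts)
        logprob = log_nfact - gammaln(c + 1).sum() + float(c @ logp)
        nz = c > 0
        total += math.exp(logprob) * statistic(SampleCounts(c[nz]))
    return total


def coverage_experiment(
    community: Community,
    n: int,
    r: int,
    reps: int,
    alpha: float = 0.05,
    seed: int | None = None,
) -> float:
    """Fraction of seeded replicate samples whose (1-alpha) CI covers the
    true zeta_r.  Vectorized over replicates; uniform communities are
    rejected because the asymptotic variance vanishes there."""
    if community.is_uniform(tol=1e-15) and community.richness > 1:
        raise DegenerateCommunityError(
            "coverage is undefined for a uniform community (sigma_r = 0)"
        )
    if reps < 100:
        raise InvalidCommunityError(f"need >= 100 replicates, got {reps}")
    r = _check_order(r)
    rng = np.random.default_rng(seed)
    true = zeta(community, r)
    draws = rng.multinomial(n, community.probs, size=reps)
    z = z_many(draws, r)
    # delta-method sd per replicate from p̂ (zero counts contribute nothing)
    p_hat = draws / n
    g = (1.0 - p_hat) ** r - r * p_hat * (1.0 - p_hat) ** (r - 1)
    m = np.sum(p_hat * g, axis=1)
    var = np.maximum(np.sum(p_hat * g * g, axis=1) - m * m, 0.0)
    margin = stats.norm.ppf(1.0 - alpha / 2.0) * np.sqrt(var / n)
    lo = np.clip(z - margin, 0.0, 1.0)
    hi = np.clip(z + margin, 0.0, 1.0)
    return float(np.mean((lo <= true) & (true <= hi)))


def mc_sd_experiment(
    community: Community, n: int, r: int, reps: int, seed: int | None = None
) -> tuple[float, float]:
    """Monte-Carlo sd of sqrt(n)(Z_r - zeta_r) and the analytic sigma_r.

    Used to validate the delta-method variance (the sign convention of the
    gradient vector) against straight simulation.
    """
    r = _check_order(r)
    rng = np.random.default_rng(seed)
    draws = rng.multinomial(n, community.probs, size=reps)
    z = z_many(draws, r)
    mc = float(np.std(np.sqrt(n) * (z - zeta(community, r)), ddof=1))
    return mc, asymptotic_sd(community.probs, r)
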