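"""Ground-truth diversity quantities for a community with known proportions.

A community is described by its species proportions ``p_1, ..., p_S``.
Generalized Simpson's entropy of order ``r`` is

    zeta_r = sum_s p_s * (1 - p_s)**r

which equals the probability that the (r+1)-st individual drawn from the
community belongs to a species not seen in the first r draws.  ``1 - zeta_1``
is Simpson's classical concentration index.  Larger ``r`` weights rare
species more heavily; zeta_r behaves as a diversity measure (maximized by
the uniform distribution) for ``r <= S - 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidCommunityError, InvalidOrderError, InvalidTransferError

#: absolute tolerance on sum(p) == 1; vectors outside are rejected, never renormalized
PROB_SUM_TOL = 1e-12


def _check_order(r: int) -> int:
    if not isinstance(r, (int, np.integer)) or isinstance(r, bool):
        raise InvalidOrderError(f"order r must be an integer, got {r!r}")
    if r < 1:
        raise InvalidOrderError(f"order r must be >= 1, got {r}")
    return int(r)


@dataclass(frozen=True)
class Community:
    """Species proportions of a (fully known) community.

    Parameters
    ----------
    probs : array-like of float
        Proportions ``p_s``; every entry must lie in (0, 1] and the vector
        must sum to 1 within ``PROB_SUM_TOL``.  Zero entries are rejected:
        zeta is continuous in p -> 0 (adding a vanishing species does not
        change it), so callers drop unobserved species up front rather than
        have them silently ignored.
    labels : tuple of str, optional
        Species identifiers, same length as ``probs``.
    """

    probs: np.ndarray
    labels: tuple | None = None

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size < 1:
            raise InvalidCommunityError("probs must be a non-empty 1-D vector")
        if np.any(p <= 0) or np.any(p > 1):
            raise InvalidCommunityError("every proportion must be in (0, 1]")
        total = float(p.sum())
        if abs(total - 1.0) > PROB_SUM_TOL:
            raise InvalidCommunityError(
                f"proportions sum to {total!r}, not 1 (tolerance {PROB_SUM_TOL}); "
                "renormalization is refused — fix the input"
            )
        p = p.copy()
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)
        if self.labels is not None:
            labels = tuple(self.labels)
            if len(labels) != p.size:
                raise InvalidCommunityError("labels and probs lengths differ")
            object.__setattr__(self, "labels", labels)

    @property
    def richness(self) -> int:
        """Number of species S."""
        return int(self.probs.size)

    @classmethod
    def uniform(cls, s: int) -> "Community":
        """Community of ``s`` equiprobable species."""
        if s < 1:
            raise InvalidCommunityError("need at least one species")
        return cls(np.full(s, 1.0 / s))

    def is_uniform(self, tol: float = 0.0) -> bool:
        p = self.probs
        return bool(np.all(np.abs(p - p[0]) <= tol))


def zeta(community: Community, r: int) -> float:
    """Generalized Simpson's entropy ``zeta_r = sum_s p_s (1 - p_s)**r``."""
    r = _check_order(r)
    p = community.probs
    return float(np.sum(p * (1.0 - p) ** r))


def information(p: float, r: int) -> float:
    """Information (rarity) function ``I(p) = (1 - p)**r``.

    The probability of not seeing a species of proportion ``p`` in a sample
    of size ``r``; strictly decreasing in p with I(1) = 0.
    """
    r = _check_order(r)
    if not (0.0 < p <= 1.0):
        raise InvalidCommunityError(f"p must be in (0, 1], got {p}")
    return float((1.0 - p) ** r)


def effective_number(zeta_value: float, r: int) -> float:
    """Effective number of species ``D = 1 / (1 - zeta_r**(1/r))``.

    Inverts ``zeta_r = (1 - 1/D)**r``, i.e. the number of equiprobable
    species with the same entropy.  A value >= 1 signals infinite diversity
    (returned as ``math.inf`` rather than raising, because clamped CI upper
    bounds can legitimately hit 1).
    """
    r = _check_order(r)
    if zeta_value < 0:
        raise InvalidCommunityError(f"zeta must be >= 0, got {zeta_value}")
    if zeta_value >= 1.0:
        return math.inf
    if zeta_value == 0.0:
        return 1.0
    return 1.0 / (1.0 - zeta_value ** (1.0 / r))


def apply_transfer(community: Community, s: int, t: int, h: float) -> Community:
    """Transfer probability ``h`` from species ``t`` to species ``s``.

    Requires ``p_s < p_t`` and ``p_s + h <= p_t - h`` so the abundance
    order of the two species is preserved.  Indices are 0-based.
    """
    p = community.probs
    if s == t:
        raise InvalidTransferError("transfer requires two distinct species")
    if not (p[s] < p[t]):
        raise InvalidTransferError(f"need p[s] < p[t], got {p[s]} >= {p[t]}")
    if h <= 0:
        raise InvalidTransferError(f"transfer amount must be > 0, got {h}")
    if p[s] + h > p[t] - h + PROB_SUM_TOL:
        raise InvalidTransferError(
            f"transfer of {h} reverses the order: {p[s] + h} > {p[t] - h}"
        )
    q = p.copy()
    q[s] += h
    q[t] -= h
    return Community(q, labels=community.labels)


def transfer_threshold(r: int) -> float:
    """Weak-transfer threshold ``T = 2 / (r + 1)``.

    Any order-preserving transfer between two species whose proportions sum
    to at most T strictly increases zeta_r.  For r = 1 this is T = 1, the
    full principle of transfers (the Simpson case).
    """
    r = _check_order(r)
    return 2.0 / (r + 1)
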