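"""Unbiased estimator Z_r, delta-method sd, confidence intervals, profiles."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gensimpson import (
    Community,
    DegenerateVarianceWarning,
    InvalidCommunityError,
    InvalidOrderError,
    OrderValidityWarning,
    SampleCounts,
    UndefinedVarianceError,
    asymptotic_sd,
    confidence_interval,
    diversity_profile,
    entropy_profile,
    enumerate_expectation,
    plugin_z_estimate,
    sigma_estimate,
    z_estimate,
    zeta,
)
from gensimpson.estimation import z_many
from conftest import random_simplex


def random_counts(rng, max_k=8, max_total=60):
    k = rng.integers(1, max_k + 1)
    c = rng.integers(1, max(2, max_total // k), size=k)
    return SampleCounts(c)


class TestSampleCounts:
    def test_invariants(self):
        s = SampleCounts(np.array([3, 2, 1]), labels=("a", "b", "c"))
        assert s.n == 6 and s.k == 3
        assert np.allclose(s.proportions.sum(), 1.0)

    @pytest.mark.parametrize("counts", [[0, 2], [-1], [], [1.5]])
    def test_invalid_counts(self, counts):
        with pytest.raises(InvalidCommunityError):
            SampleCounts(np.array(counts))

    def test_duplicate_labels(self):
        with pytest.raises(InvalidCommunityError):
            SampleCounts(np.array([1, 2]), labels=("a", "a"))


class TestZEstimate:
    @pytest.mark.parametrize("r", [1, 2, 3, 4])
    def test_single_species_is_zero(self, r):
        assert z_estimate(SampleCounts(np.array([5])), r) == 0.0

    @pytest.mark.parametrize("r", [1, 2, 3])
    def test_all_singletons_is_one(self, r):
        assert z_estimate(SampleCounts(np.array([1, 1, 1, 1])), r) == 1.0

    def test_hand_worked_values(self):
        assert z_estimate(SampleCounts(np.array([2, 1])), 1) == pytest.approx(2 / 3)
        assert z_estimate(SampleCounts(np.array([2, 2])), 2) == pytest.approx(1 / 3)

    def test_order_bound(self):
        s = SampleCounts(np.array([2, 1]))
        with pytest.raises(InvalidOrderError):
            z_estimate(s, 3)  # r must be <= n-1

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000), st.integers(1, 6))
    def test_always_in_unit_interval(self, seed, r):
        s = random_counts(np.random.default_rng(seed))
        if r > s.n - 1:
            return
        assert 0.0 <= z_estimate(s, r) <= 1.0

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_z1_closed_form(self, seed):
        """Z_1 = sum n_s (n - n_s) / (n (n-1)), an algebraic identity."""
        s = random_counts(np.random.default_rng(seed))
        if s.n < 2:
            return
        c, n = s.counts, s.n
        expected = float(np.sum(c * (n - c)) / (n * (n - 1)))
        assert z_estimate(s, 1) == pytest.approx(expected, abs=1e-12)

    def test_vectorized_matches_scalar(self, rng):
        draws = rng.multinomial(40, [0.5, 0.3, 0.2], size=25)
        for r in (1, 3, 5):
            vec = z_many(draws, r)
            for row, v in zip(draws, vec):
                s = SampleCounts(row[row > 0])
                assert z_estimate(s, r) == pytest.approx(float(v), abs=1e-12)

    @pytest.mark.parametrize("s_size", [2, 3])
    def test_exact_unbiasedness_by_enumeration(self, s_size, enum_communities):
        """E[Z_r] over all multinomial outcomes equals zeta_r exactly."""
        for comm in enum_communities[s_size]:
            for n in range(2, 7):
                for r in range(1, n):
                    e = enumerate_expectation(
                        comm, n, lambda x, r=r: z_estimate(x, r)
                    )
                    assert e == pytest.approx(zeta(comm, r), abs=1e-10)

    def test_plugin_is_biased_low(self, enum_communities):
        """The naive plug-in estimator underestimates zeta_r throughout the
        valid diversity range r <= S-1 (beyond it the sign can flip)."""
        for s_size, comms in enum_communities.items():
            for comm in comms:
                for n in (3, 5):
                    for r in range(1, min(n, s_size)):
                        e = enumerate_expectation(
                            comm, n, lambda x, r=r: plugin_z_estimate(x, r)
                        )
                        assert e < zeta(comm, r)


class TestSigma:
    def test_uniform_counts_warn_and_zero(self):
        with pytest.warns(DegenerateVarianceWarning):
            assert sigma_estimate(SampleCounts(np.array([3, 3, 3])), 1) == 0.0

    def test_single_species_undefined(self):
        with pytest.raises(UndefinedVarianceError):
            sigma_estimate(SampleCounts(np.array([7])), 1)

    def test_hand_delta_method(self):
        s = SampleCounts(np.array([60, 40]))
        assert sigma_estimate(s, 1) == pytest.approx(math.sqrt(0.4**2 * 0.24), rel=1e-12)

    def test_quadratic_form_and_permutation_invariance(self, rng):
        """The O(K) variance identity equals the explicit h' Sigma h quadratic
        form, whichever species is eliminated as the K-th."""
        for _ in range(20):
            p = random_simplex(rng, int(rng.integers(2, 9)))
            r = int(rng.integers(1, 5))
            ours = asymptotic_sd(p, r)
            perm = rng.permutation(p.size)
            q = p[perm]
            g = (1 - q) ** r - r * q * (1 - q) ** (r - 1)
            h = g[:-1] - g[-1]
            sigma = np.diag(q[:-1]) - np.outer(q[:-1], q[:-1])
            explicit = math.sqrt(max(h @ sigma @ h, 0.0))
            assert ours == pytest.approx(explicit, abs=1e-12)

    @pytest.mark.parametrize("r", [1, 2, 3])
    def test_monte_carlo_variance_consistency(self, r):
        """MC sd of sqrt(n)(Z_r - zeta_r) matches the analytic sigma_r
        within 5% for p=(0.6, 0.3, 0.1) at n=2000."""
        from gensimpson import mc_sd_experiment

        c = Community(np.array([0.6, 0.3, 0.1]))
        mc, analytic = mc_sd_experiment(c, 2000, r, 20_000, seed=42)
        assert mc == pytest.approx(analytic, rel=0.05)


class TestConfidenceInterval:
    def test_arithmetic(self):
        s = SampleCounts(np.array([60, 40]))
        ci = confidence_interval(s, 1, alpha=0.05)
        z = z_estimate(s, 1)
        margin = 1.959963984540054 * sigma_estimate(s, 1) / 10.0
        assert ci.lower == pytest.approx(z - margin, abs=1e-9)
        assert ci.upper == pytest.approx(z + margin, abs=1e-9)
        assert ci.level == 0.95

    def test_degenerate_interval(self):
        with pytest.warns(DegenerateVarianceWarning):
            ci = confidence_interval(SampleCounts(np.array([5, 5])), 1)
        assert ci.lower == ci.upper == z_estimate(SampleCounts(np.array([5, 5])), 1)

    def test_clamped_to_unit_interval(self):
        # near-all-singleton sample: Z close to 1, upper bound clamps at 1
        s = SampleCounts(np.array([2] + [1] * 30))
        ci = confidence_interval(s, 1)
        assert ci.upper == 1.0
        assert 0.0 <= ci.lower <= 1.0


class TestProfiles:
    def test_all_singletons_entropy_profile(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateVarianceWarning)
            prof = entropy_profile(SampleCounts(np.array([1, 1, 1, 1])), 3)
        assert np.allclose(prof.estimates, 1.0)
        assert prof.scale == "entropy"

    def test_order_bound_error(self):
        s = SampleCounts(np.array([2, 2]))
        with pytest.raises(InvalidOrderError):
            entropy_profile(s, 4)  # v = n

    def test_profile_tracks_closed_form(self, rng):
        """Samples from uniform S=20: every estimate sits within 3 standard
        errors of (1 - 1/20)^r."""
        c = Community.uniform(20)
        draws = rng.multinomial(200, c.probs)
        s = SampleCounts(draws[draws > 0])
        prof = entropy_profile(s, 19)
        for r, est in zip(prof.orders, prof.estimates):
            true = (1 - 1 / 20) ** r
            se = asymptotic_sd(s.proportions, int(r)) / math.sqrt(200)
            assert abs(est - true) <= max(3 * se, 0.02)

    def test_diversity_profile_transform(self):
        s = SampleCounts(np.array([8, 5, 3, 2, 1, 1]))
        ent = entropy_profile(s, 4)
        div = diversity_profile(s, 4)
        assert div.scale == "diversity"
        for i, r in enumerate(ent.orders):
            f = lambda t: 1.0 / (1.0 - t ** (1.0 / r)) if 0 < t < 1 else math.inf
            assert div.estimates[i] == pytest.approx(f(ent.estimates[i]))
            assert div.lower[i] <= div.estimates[i] <= div.upper[i]

    def test_all_singletons_diversity_infinite(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", DegenerateVarianceWarning)
            prof = diversity_profile(SampleCounts(np.array([1, 1, 1])), 2)
        assert np.all(np.isinf(prof.estimates))

    def test_richness_bound_warning(self):
        s = SampleCounts(np.array([8, 5, 3, 2, 1, 1]))
        with pytest.warns(OrderValidityWarning):
            prof = entropy_profile(s, 10, richness=6.0)
        assert prof.warnings
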