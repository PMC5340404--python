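# Methods

## Model and assumptions

A community is a taxocene with species proportions p₁, …, p_S (all strictly
positive; the constructor rejects zeros and refuses to renormalize vectors
whose sum deviates from 1 by more than 1e−12 — silent renormalization hides
data errors). Sampling is assumed i.i.d. multinomial: either the population
is effectively infinite or sampling is with replacement; finite-population
corrections are out of scope.

Generalized Simpson's entropy ζ_r = Σ p_s(1−p_s)^r is a trace-form index
with information function I(p) = (1−p)^r, the probability of missing a
species of proportion p in r draws. Its axiomatic standing:

- symmetry, continuity, decreasing information: always;
- weak principle of transfers: any order-preserving transfer between species
  with p_s + p_t ≤ 2/(r+1) strictly increases ζ_r;
- evenness (uniform maximizes): guaranteed for r ≤ S − 1. Beyond that range
  it *may* fail, but not immediately — for S = 2 the first failing order is
  r = 4 (ζ₄ = u(1−3u) in u = p(1−p) peaks at u = 1/6, not at the uniform's
  u = 1/4), which is the failure exhibit used in the tests. Orders r = 2, 3
  at S = 2 still favor the uniform.

## Estimation

Z_r (the product form above) is exactly unbiased for 1 ≤ r ≤ n−1 and is
computed by direct product accumulation: every factor 1 − (n'_s−1)/(n−j)
lies in [0, 1] (a zero factor occurs before any could go negative), so the
estimate is always in [0, 1] and needs no log-space arithmetic. Requests
with r ≥ n raise an error — no unbiased estimator exists there.

The asymptotic variance comes from the delta method in the (K−1)-free-
parameter multinomial parameterization: Σ̂ = diag(p̂) − p̂p̂ᵀ over the first
K−1 species and gradient components ĥ_j = g(p̂_j) − g(p̂_K) with
g(p) = (1−p)^r − r·p·(1−p)^{r−1}. The sign convention (a minus between the
two terms of g) is fixed as the analytic gradient ∂ζ_r/∂p_j; it is validated
empirically by agreement (within Monte-Carlo error) between the analytic
σ_r and the simulated sd of √n(Z_r − ζ_r). The quadratic form ĥᵀΣ̂ĥ is
evaluated through the equivalent O(K) identity Var_p̂[g] = Σ p̂g² − (Σ p̂g)²,
which also makes the choice of "last" species manifestly irrelevant (a unit
test checks this against the explicit matrix form under permutations).

Degenerate cases: a single observed species has no defined variance
(error); an exactly uniform p̂ gives σ̂ = 0 with a warning rather than an
error so that profiles do not abort mid-range. Confidence intervals
Z_r ± z_{α/2}σ̂_r/√n are clamped to [0, 1] since ζ_r is a probability
(default α = 0.05). The effective-number transform D = 1/(1 − t^{1/r}) is
monotone increasing, so entropy-scale intervals map endpoint-wise onto the
diversity scale with identical inferential content; t ≥ 1 (possible after
clamping) maps to a distinguished infinite diversity instead of raising.

Two-community differences use Z_r(1) − Z_r(2) ± z_{α/2}√(σ̂₁²/n₁ + σ̂₂²/n₂),
unclamped (differences live in [−1, 1]). Samples with a single observed
species participate with zero variance contribution plus a warning. The
profile envelope is pointwise, with no multiplicity correction; the summary
verdict operationalizes "zero generally in/out of the envelope" as
all-orders-in → not significant, all-orders-out → significant, otherwise
inconclusive. This all/none/mixed rule is a stated convention of this
package, not a quantified test.

## Richness and the valid order range

Jackknife richness estimators (orders 1–5) are generated from the
generalized delete-j jackknife closed form

  Ŝ_k = Σ_{j=0}^{k} (−1)^j C(k,j) (n−j)^k / k! · S̄_{n−j},
  S̄_{n−j} = K − Σ_i f_i C(n−i, j−i) / C(n, j),

where f_i counts species seen exactly i times. This reproduces the classical
printed polynomials (order 1: K + f₁(n−1)/n; order 2:
K + f₁(2n−3)/n − f₂(n−2)²/(n(n−1)); …), verified by unit test. Order
selection follows the sequential-test idea: for k = 1, 2, …, test
d = Ŝ_{k+1} − Ŝ_k against zero with variance (K/(K−1))(Σ b_i²f_i − d²/K)
(b_i the f_i-coefficient differences) and pick the smallest k whose test is
non-significant at α = 0.05, capped at 5. With no singletons the sample
shows no evidence of unseen species and order 1 is returned directly; only
the integer order is returned (no estimate interpolation between orders).
Note that orders ≥ 2 can drop below the observed K when doubletons dominate
singletons; order 1 never does. The maximal valid entropy order is
floor(Ŝ) − 1 (conservative for fractional Ŝ).

## Comparator indices

HCDT (Tsallis) entropy (Σp^q − 1)/(1−q) and its Hill diversity
(Σp^q)^{1/(1−q)} use the Shannon limits −Σp log p and exp(·) within
|q−1| < 1e−9. Only plug-in versions on p̂ are offered, and the CLI labels
them biased: bias-corrected HCDT estimation is a substantial separate method
and out of scope. The q↔r matching solves ^qD = ^rD^ζ by Brent root-finding
on q (Hill diversity is strictly decreasing in q for non-uniform p); the
bracket [0, 2] auto-expands upward; r = 1 lands exactly on q = 2 because
²T = ζ₁. Uniform communities are degenerate (every q matches) and raise.

Hurlbert's index ^kH = Σ[1 − (1−p_s)^k] (expected species among k
individuals; ²H = 1 + ζ₁) is estimated without bias by the rarefaction form
Σ[1 − C(n−n'_s, k)/C(n, k)], binomials via log-gamma so n can be large.
Its effective number solves D(1 − (1−1/D)^k) = value monotonically
(tolerance 1e−9); value = k maps to infinity. Bootstrap envelopes are
percentile intervals over B seeded multinomial resamples from p̂ (default
B = 1000, minimum 100).

## Synthetic data

The generator covers the spectrum a field ecologist meets: `uniform`
(perfect evenness), `geometric` (niche preemption, ratio in (0,1); ratio 0.7
at S = 10 is the moderately uneven benchmark community used for the coverage
study), `log-series` (Fisher; the classic model for species-rich assemblages
with long singleton tails, used for the richness-bias studies), and `zipf`
rank-abundance. Sampling is multinomial with a seeded generator; zero-count
species are omitted, matching the observed-species convention of the
estimators. The generator emulates abundance structure only: it does not
model spatial aggregation, detection bias, or sampling without replacement,
so passing tests certify the estimators under ideal random sampling, not
robustness to those field realities.

The enumeration oracle sums statistic × probability over all C(n+S−1, S−1)
multinomial outcomes (log-space probabilities) and refuses beyond S ≤ 4,
n ≤ 8. It underwrites the unbiasedness certificates for Z_r and the
Hurlbert estimator, the negative-bias demonstration for the plug-in
estimator (strict for r ≤ S−1; beyond the valid range the bias can change
sign), and the accumulation-curve identity E[#singletons in r+1 draws]/(r+1)
= ζ_r.

## Problem sizes and numerical choices

The simulation studies use sizes at which the asymptotics are visibly
settled while the full suite stays desk-scale: variance consistency at
n = 2000 with 20 000 replicates (MC/analytic sd ratio within 5%), CI
coverage at n = 1000 with 2000 replicates (within ±0.02 of 0.95), axiom
checks with hundreds of randomized trials, bootstrap coverage with 60 outer
replicates. All randomized tests are seeded; hypothesis property tests run
derandomized. Root-finding tolerances: 1e−8 (q-matching), 1e−9 (Hurlbert
effective number).

## Known limitations

- Asymptotic (Wald) intervals only; no small-sample or Bayesian intervals.
- Two independent samples only; no paired designs, no >2-community or
  FWER-adjusted envelopes.
- Plug-in Hill/HCDT values are biased under incomplete sampling; they are
  provided for profile comparison, not as estimators of the true values.
- The uniform-p̂ degenerate case (σ̂ = 0) yields zero-width intervals whose
  nominal coverage claim does not apply.
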