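# Methods

## Model and data

Study i contributes independent binomial counts X_iT ~ Bin(n_iT, p_iT) and
X_iC ~ Bin(n_iC, p_iC). The effect measure is the log-odds-ratio
θi = logit(p_iT) − logit(p_iC); the random-effects model (REM) fixes the
control-arm probability and takes logit(p_iT) = logit(p_iC) + θi with
θi ~ N(θ, τ²). The target of inference throughout is the heterogeneity
variance τ².

Arm probabilities are estimated either by maximum likelihood p̃ = x/n or by
the bias-reducing adjusted rule p̂ = (x+½)/(n+1) (equivalent to adding ½ to
every cell), which keeps estimates strictly inside (0,1) and removes the
O(1/n) bias of the log-odds. Two policies decide when the adjusted rule
applies: `only` (a study is adjusted iff any of its four cells is zero; the
adjustment then applies to all four cells of that study) and `always`.
Whenever the adjusted proportion is used, n+1 replaces n in the variance
denominators, so the conditional variance equals the Woolf form on the
½-augmented cells. Double-zero and double-n studies carry no information
about the odds ratio and are excluded, both when reading user data and in
the simulations (with K reduced accordingly).

## Variances of the study-level estimate

Conditional on the study's probabilities, the delta method gives
v² = [N_T p_T(1−p_T)]⁻¹ + [N_C p_C(1−p_C)]⁻¹. Under the REM the
unconditional variance of θ̂ decomposes as

    Var(θ̂) = E v² + τ² · C,    C = 1 + [(p_T(1−p_T))⁻¹ − 2] / (2 N_T).

The inflation factor C arises from a second-order expansion of the
conditional variance in the random effect: writing u(θi) = [N_T p_T(θi)(1−p_T(θi))]⁻¹
with p_T = expit(α + θi), one finds u'' = [(p_T(1−p_T))⁻¹ − 2]/N_T, and
averaging over θi ~ N(θ, τ²) contributes τ²·u''/2 beyond the τ² carried by
the effect itself. Since p(1−p) ≤ ¼, C ≥ 1 + 1/N_T > 1, and C → 1 as the
treatment arm grows; both properties are tested.

The unconditional variance always uses adjusted proportions (and N = n+1);
its treatment-arm probability is either the study's own p̂_iT (**naive**) or
the model-based prediction p̄_iT = expit(logit(p̂_iC) + θ̂) (**model**). The
pooled θ̂ inside p̄_iT is the fixed effective-sample-size-weighted mean
Σñᵢθ̂ᵢ/Σñᵢ; this keeps the unconditional machinery free of estimated
variances, consistent with the fixed-weights design. (An inverse-variance
pooled effect is available separately for reporting.)

## Q statistics and the moment estimators

With weights wᵢ, W = Σwᵢ, qᵢ = wᵢ/W, the generalized Cochran statistic is
Q = Σwᵢ(θ̂ᵢ − θ̄_w)². Q_IV uses wᵢ = 1/v̂ᵢ²; Q_F uses the effective sample
sizes wᵢ = ñᵢ = n_iC n_iT/nᵢ, which do not depend on any estimated variance
(changing the ½-adding policy changes the θ̂ᵢ but never the weights of Q_F —
this invariance is tested). Under the REM,

    E Q_F = W Σ qᵢ(1−qᵢ) M₂ᵢ,

with M₂ᵢ = v̂ᵢ² + τ² (conditional) or Êvᵢ² + τ²Cᵢ (unconditional). Setting
E Q_F equal to the observed Q_F and solving for τ² gives the moment
estimators SSC (conditional) and SSU model / SSU naive (unconditional),
truncated at zero with the raw value retained for diagnostics. When the raw
value is positive the inversion identity E Q_F(τ̂²) = Q_F(obs) holds to
1e−8 and is asserted in tests.

## Distribution of Q_F and the median-unbiased estimators

Conditional on the weights and second moments, Q_F is a quadratic form
W·Θ'(diag(q) − qq')Θ in independent normals Θᵢ ~ N(0, M₂ᵢ), hence
distributed as Σ λ_k z_k² with λ the eigenvalues of S^{1/2}BS^{1/2},
B = W(diag(q) − qq'), S = diag(M₂). B annihilates the constant vector, so
exactly one structural zero eigenvalue is dropped (cutoff 1e−10 relative to
the largest; more than one dropped eigenvalue triggers a warning). The trace
identity Σλ = E Q_F is asserted to 1e−10.

The CDF F(x | τ²) is evaluated by Ruben's mixture-of-central-chi-squares
series with centering constant β = 2λ_min λ_max/(λ_min+λ_max), a running
chi-square-CDF recursion, truncation tolerance 1e−9 (far below any
statistical resolution used downstream), a 10,000-term cap, and a
Monte-Carlo fallback (100,000 draws, logged warning) that in practice never
fires on meta-analytic spectra. Two independent oracles check it: an
Imhof-type numerical inversion of the characteristic function (vectorized
Gauss–Legendre panels sized to the oscillation period, tail chosen for a
~1e−9 bound) and direct simulation; agreement is ≤1e−6 and within 3 Monte
Carlo SEs respectively. The approximation is known to degrade for very small
arm sizes; the package reports, and does not attempt to repair, this.

F(x | τ²) is strictly decreasing in τ² (tested on a grid), so

- **SMC / SMU**: τ̂² = max(0, root of F(Q_F | τ²) = ½), by bisection with
  absolute tolerance 1e−8, initial bracket [0, 5] doubled up to 1e4 (beyond
  which the estimate is flagged non-converged);
- **FPC / FPU**: the 100(1−α)% interval {τ² ≥ 0 : α/2 ≤ F(Q_F | τ²) ≤ 1−α/2},
  with miscoverage split equally between tails. If F(Q_F | 0) < α/2 the set
  is empty below zero and [0, 0] is returned (`degenerate_zero`); if only
  the lower constraint binds at 0 the interval is [0, U], the common case in
  practice. The upper search doubles its bracket to a cap of 1e4
  (`upper_unbounded` beyond). Interior endpoints satisfy |F − target| ≤ 1e−6.

## Comparator estimators

DL (moment estimator from E Q_IV), REML (fixed-point iteration, relative
tolerance 1e−8, max 1000 iterations, started at DL), Mandel–Paule (bisection
for Q_gen(τ²) = K−1 with weights 1/(v̂²+τ²)), the Q-profile interval
(chi-square(K−1) band for Q_gen) and the profile-likelihood interval
(likelihood-ratio inversion with θ profiled out; the ML point is located by
bounded scalar minimization). In the balanced equal-variance case REML and
MP collapse to max(0, SS/(K−1) − v), used as a closed-form oracle. DL, REML,
MP, SSC (as a generalized-Q moment estimator with user weights) and the
Q-profile interval are additionally cross-checked against R's metafor on
fixed synthetic fixtures under both ½-adding policies.

Following the policy/estimator pairing of the study design, the
unconditional estimators (SSU, SMU, FPU) are reported by default only under
the `always` policy — they are defined through the adjusted proportions —
while DL/REML/MP/SSC/SMC/QP/PL/FPC come in both policies.

## Simulation harness

The scenario grid crosses θ ∈ {0, 0.1, 0.5, 1, 1.5, 2}, τ² ∈ {0, 0.1, …, 1},
K ∈ {5, 10, 30}, piC ∈ {0.1, 0.2, 0.5}, and eight size patterns: equal
n ∈ {20, 40, 100, 250} and four unequal five-study sets with means
{30, 60, 100, 160} and skewness 1.464 (repeated 2× and 6× for K = 10, 30);
the control fraction is f = ½ throughout (all sizes are even, so
n_C = n_T = n/2 exactly) — 4752 scenarios in all. Each repetition draws
θi ~ N(θ, τ²), simulates the binomial counts, discards double-zero/double-n
studies, and drops the repetition if fewer than 3 studies survive;
per-estimator failures are counted and excluded per-estimator, so the
observed number of repetitions is used. The unequal size sets are assigned
to studies in fixed order.

Randomness uses one independent `SeedSequence(entropy=seed, spawn_key=(rep,))`
stream per repetition, so results are identical regardless of execution
order and fully determined by (scenario, seed).

Reported metrics: mean bias; **median bias** P(τ̂² ≥ τ²) − P(τ̂² ≤ τ²), with
ties counted in both tails (so a point mass at a true τ² = 0 contributes
zero); and for intervals the coverage with its left/right decomposition
(miss-left: τ² below the lower limit; miss-right: above the upper limit),
which diagnoses tail imbalance that overall coverage hides.

What the generator emulates — and does not: it reproduces the binomial REM
with fixed control-arm probabilities and a fixed control fraction. It does
not model random intercepts, correlated (p_iC, p_iT), non-normal random
effects, selective reporting, or measurement differences between studies,
so passing simulation benchmarks demonstrates correctness under the stated
model, not robustness to those violations. The `stead_like` fixture profile
mimics only the *shape* of a large sparse-event review (17 mostly balanced
trials, totals 182–3128, event rates ≈ 4–6%); it is synthetic and matches
no published dataset.

## Problem sizes and numerical choices

Benchmark recomputations in `scripts/acceptance.py` use the full 10,000
repetitions (about a minute in total on one CPU: the median-type estimators
need ~30 CDF evaluations per repetition). The test suite runs its stochastic
checks at 2,000 repetitions with tolerances widened to the corresponding
Monte-Carlo standard errors, and the coverage check for FPC at 2,000
repetitions, keeping the whole suite under a minute. Estimator tolerances
(bisection 1e−8 on τ², interval endpoints 1e−6 on the probability scale,
eigenvalue cutoff 1e−10) are fixed and not exposed as tuning knobs.

## Known limitations

- I² is reported from the textbook (Q_IV − (K−1))/Q_IV formula alongside the
  chi-square p-value; published analyses occasionally print values computed
  under other conventions, which this package does not attempt to match.
- The KD (gamma-approximation) point and interval estimators and one-stage
  GLMM methods are out of scope, as are relative-risk and risk-difference
  effect measures and arm-based exact models.
- The Farebrother approximation, and hence SMC/SMU/FPC/FPU, inherits reduced
  accuracy for very small arm sizes (n ≲ 40 with rare events); the
  simulation harness quantifies the resulting bias and coverage error rather
  than correcting it.
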