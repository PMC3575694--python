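# Methods

## Model

Two nonnegative component failure times (T₁, T₂) are linked, conditionally
on a binary treatment indicator Z with P(Z=1) = `p_treat` (default 0.5), by
an Archimedean copula applied to marginal survivor probabilities:
S(t₁, t₂ | z) = C(S₁(t₁|z), S₂(t₂|z); θ).  The margins are exponential with
proportional hazards, λₖ(t|z) = λₖ₀ e^{βₖ z}; the type structure would admit
other parametric baselines but none are implemented, because exponential
margins are what the design calculus and the simulator target.  The
composite endpoint is T = min(T₁, T₂); its survivor is the copula diagonal
and its density follows analytically from the copula partial derivatives,
f(t|z) = ∂₁C·h₁S₁ + ∂₂C·h₂S₂.  All four families (Clayton, Frank,
Gumbel–Hougaard, independence) use closed-form partials; the Clayton
diagonal additionally has the closed form
(e^{θΛ₁} + e^{θΛ₂} − 1)^{−1/θ}, kept as an internal cross-check (agreement
to 1e−12 is asserted in the tests).

Dependence is parameterized by θ or Kendall's τ.  Clayton and Gumbel use
the closed-form maps τ = θ/(θ+2) and τ = (θ−1)/θ; Frank evaluates the
generator integral τ = 1 + 4∫₀¹ φ(t)/φ′(t) dt by adaptive quadrature in a
cancellation-safe form, and inverts it by bracketed root-finding (supported
range |τ| ≤ 0.98, which keeps e^θ representable).  |θ| < 1e−8 in the
Clayton/Frank families is evaluated as the independence limit.

## Sampling

Pairs (U₁, U₂) are drawn by conditional-distribution inversion: U₁ uniform,
then U₂ from the conditional quantile of ∂C/∂u₁.  Clayton and Frank have
closed-form conditional quantiles; Gumbel inverts the conditional CDF by
64 steps of vectorized bisection on [1e−12, 1−1e−12] (monotone, so the
error is below 2⁻⁶⁴).  Component times follow by exponential inversion
Tₖ = −log Uₖ / (λₖ e^{βₖ z}).  Negative-dependence Clayton (θ < 0) is
supported for evaluation but not for sampling; the trial simulator is
restricted to τ ≥ 0, the regime the design machinery studies.  All
randomness flows through explicit `numpy.random.Generator` objects; a
master seed spawns independent per-replicate `SeedSequence` streams, so any
single replicate is reproducible in isolation.

## Design calculus

A design fixes the horizon C† (default 1, defining the time unit), the
control-arm ordering probability p₁ = P(T₁ < T₂ | Z=0), the administrative
censoring rate π_A = P(C† < T) averaged over arms, and the net censoring
rate π = P(C < T) ≥ π_A once exponential withdrawal W ~ Exp(ρ) is added
(C = min(W, C†)).  The rates (λ₁, λ₂) solve the two constraints by hybrid
root-finding on log-rates (for positivity), started from the independence
closed form λ₁ = p₁s, λ₂ = (1−p₁)s; p₁ is evaluated as
∫₀¹ ∂₁C(u, u^{λ₂/λ₁}) du after substituting u = S₁(t|0), which removes the
semi-infinite integration range.  ρ then solves
E_Z[P(W<T<C†|Z)] + π_A = π by bracketed Brent iteration; ρ = 0 exactly when
π = π_A.  Solved constraints are required to round-trip to 1e−8.

Sample size uses the Schoenfeld event count
D = (z_{1−γ₁} + z_{1−γ₂})² / (p(1−p)α*²) with the *limiting* value α* of the
analysis as the planning effect, and m = ⌈D / P(T<C)⌉ with P(T<C) = 1 − π.
γ₁ = 0.05 is used one-sided (z₀.₉₅ = 1.6449): this convention exactly
reproduces the reference subject counts the package's tests pin (621 at
α* = log 0.8, π = 0.2), and the replicate Wald test uses the same
z_{1−γ₁} threshold so that empirical power lands on the planned 1 − γ₂.

## Limiting values

The misspecified composite-endpoint Cox estimator converges to the root α*
of the population score u(α) given in the README.  u is evaluated by
Gauss–Kronrod quadrature on (0, C†] at absolute tolerance 1e−10 (the only
non-smooth point of the censoring survivor G is the horizon itself, which
is the integration endpoint), and the root is found by Brent's method on
[−3, 3], widened once to [−6, 6] if the bracket fails.  Under independence
with a common β the score vanishes at β analytically, and the implementation
reproduces this to 1e−8.  The limiting Breslow baseline
Ψ*(t) = ∫₀ᵗ Σ_z P(z)G f(·|z) / s⁽⁰⁾(α*, ·) collapses, for equal censoring
across arms, to a censoring-free expression; it is validated against
averaged Breslow estimates from replicate fits.

The WLW component estimators are consistent for (β₁, β₂), so the limiting
global value is c′β with c = Σ⁻¹J[J′Σ⁻¹J]⁻¹ built from the limiting robust
covariance Σ(β).  Σ is approximated by the Monte-Carlo backend: the average
over R seeded trials of m subjects of the per-trial subject-level sandwich
covariance scaled by m (defaults R = 50, m = 200 000; a convergence check
at m = 50k/200k/400k moves the limit by < 2e−4).  The reported Monte-Carlo
SE is the dispersion of per-trial weighted combinations across the R
trials.  An analytic-integral backend could be slotted behind the same
contract; it is not implemented because the empirical backend already
resolves the limit well below the precision at which it is compared.

## Estimation

The Cox fitter is specialized to one binary covariate, which makes every
risk-set sum a pair of at-risk counts (n₀(t), n₁(t)): the partial
likelihood, score, observed information, Breslow baseline and per-subject
score residuals are computed exactly in O(m log m).  Newton iteration
starts at 0 with step-halving on any likelihood decrease and stops when the
step is below 1e−10; |α̂| > 30 or an all-events-in-one-arm configuration
raises a divergence error naming the offending arm.  The model-based SE is
the inverse root information; the robust SE is the unscaled score-residual
sandwich (no m/(m−1) small-sample factor, matching the large-sample
theory the package targets).  Tied event times use the Breslow convention —
the simulator produces continuous times, but imported CSV data may not.

The WLW analysis fits each component by the same fitter under working
independence, with follow-up for *each* component censored only at
C = min(W, C†) — never at the other component's event or at the composite
event — so all observed events contribute.  The joint 2×2 covariance of
(β̂₁, β̂₂) stacks the two per-subject score residuals (subjects are the
independence units) into a sandwich; the global estimate uses
minimum-variance weights, and its model-based SE (computed from the
inverse informations alone) is reported alongside the robust one because
working independence makes the two differ under positive dependence.

## Replicate studies

`run_study` aggregates, over seeded replicates, the mean estimate (AVE),
empirical SE (ESE), average model-based and robust SEs (ASE₁, ASE₂),
empirical coverage of nominal robust CIs for the limiting value (ECP*) and
for β₁ (ECP), and empirical power (EP) of the robust Wald test at the
one-sided design level.  Replicates whose fit diverges are excluded and
counted; more than 1% divergent replicates aborts the study rather than
silently biasing the estimator distribution.  `reproduce_table` runs the
full censoring grid {(π_A, π)} × {common effects, β₂ = 0} for the composite
(Clayton and independence) and WLW analyses, deriving each row's m from its
own limiting value.  The default replicate count is 2000; the test suite
and the acceptance script use 40–500 replicates with Monte-Carlo-width
tolerances, which resolves the quantities being checked while keeping runs
at the scale of seconds to minutes.

## What the simulator does and does not emulate

The generator reproduces exactly the structural assumptions above:
exchangeable Archimedean dependence, exponential margins, proportional
hazards for a single binary covariate, completely independent censoring,
and component follow-up to the end of study.  Real trials violate most of
these in some measure — non-exponential baselines, covariate-dependent or
response-dependent censoring (a subject withdrawn *because* of a first
event), treatment effects that vary over time, more than two components.
Passing tests therefore certify the internal consistency of the asymptotic
theory and its finite-sample agreement under the stated model, not
robustness of the conclusions to those violations.  Within the model,
however, the qualitative findings the tests pin down — attenuation of the
composite-endpoint effect that grows with dependence, peaks at p₁ = 0.5 and
shrinks with censoring; censoring-invariance under independence; the WLW
global limit dominating the composite limit in magnitude — are exact
statements about the limits, not simulation artifacts.

## Known limitations

* Two components only; exchangeable K > 2 copulas are out of scope.
* Margins are exponential; the hazard-ratio and limit machinery would
  extend to other parametric baselines but is untested there.
* Frank dependence is supported on |τ| ≤ 0.98; Clayton sampling on τ ≥ 0.
* The WLW limiting covariance backend is Monte Carlo; its seed-to-seed
  variation (reported as `mc_se`, ~3e−5 at default settings) is negligible
  for design work but means the last printed decimal of a WLW limit can
  move with the seed.
* Published three-decimal reference values for dependent-component limits
  are matched to about one unit in the last printed digit; the package's
  own quadrature/root-finding values are the ones validated against its
  large-sample simulation oracle.
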