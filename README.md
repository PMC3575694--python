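# cecox — composite endpoints and Cox misspecification in randomized trials

Randomized trials in cardiology, oncology and other fields routinely analyze
a *composite endpoint* — the time T = min(T₁, T₂) to the first of several
component events — with a Cox proportional-hazards model.  `cecox` is a tool
for biostatisticians who want to understand, quantify and simulate what that
analysis actually estimates when the component times are dependent.

## The model

Component times (T₁, T₂) are given exponential margins with proportional
hazards for a binary treatment Z,

    λₖ(t | z) = λₖ₀ exp(βₖ z),   k = 1, 2,

and are coupled through an Archimedean copula on the survivor scale,

    S(t₁, t₂ | z) = C(S₁(t₁|z), S₂(t₂|z); θ),

with Clayton, Frank, Gumbel–Hougaard and independence families supported and
dependence parameterized by Kendall's τ.  Even when both margins obey
proportional hazards, the composite endpoint's hazard ratio
h(t|1)/h(t|0) is generally *time-varying* — the exceptions being the
Gumbel–Hougaard family with a common β, and independent components with
either a common β or equal baselines (where the constant effect is
(e^{β₁}+e^{β₂})/2).

The Cox model fitted to T is therefore misspecified, and its maximum
partial-likelihood estimator converges not to β but to α*, the root of the
population score

    u(α) = ∫₀^{C†} [ P(Z=1) G(s) f(s|1) − e(α, s) Σ_z P(Z=z) G(s) f(s|z) ] ds,

where f and S are the composite density/survivor, G(s) = e^{−ρs} is the
withdrawal survivor on the study interval (0, C†], and
e(α, s) = s⁽¹⁾/s⁽⁰⁾ with s⁽ʳ⁾(α, s) = Σ_z P(Z=z) zʳ e^{αz} G(s) S(s|z).
`cecox` computes α* by adaptive quadrature plus root-finding, the limiting
Breslow baseline Ψ*(t), and the limiting value of the Wei–Lin–Weissfeld
(WLW) global estimator c(β)′β, whose minimum-variance weights
c = Σ⁻¹J[J′Σ⁻¹J]⁻¹ come from the limiting robust covariance Σ(β).

It also provides the surrounding trial machinery: solving baseline rates
(λ₁, λ₂) from design constraints (the probability p₁ = P(T₁<T₂|Z=0) and the
administrative censoring rate π_A = P(C†<T)), solving an exponential
withdrawal rate ρ for a net censoring rate π, Schoenfeld event counts
D = (z_{1−γ₁}+z_{1−γ₂})²/(p(1−p)α*²) and subject counts m = ⌈D/P(T<C)⌉, a
seeded trial simulator, a hand-written (lifelines-cross-checked) Cox fitter
with model-based and robust sandwich standard errors, and the WLW
component/global analysis.

## Worked example

```python
import numpy as np
from cecox import (CopulaSpec, solve_design, limiting_alpha,
                   relative_bias_percent, required_events, required_subjects,
                   SimConfig, run_study)

copula = CopulaSpec.from_tau("clayton", 0.4)
beta = np.log(0.8)                     # 20% hazard reduction on both components
model, design = solve_design(copula, beta, beta, p1=0.25,
                             pi_admin=0.2, pi_net=0.2)
print(f"lambda1 = {model.margin1.rate:.4f}, lambda2 = {model.margin2.rate:.4f}")

alpha_star = limiting_alpha(model, design)
print(f"alpha* = {alpha_star:.4f}  (true common beta = {beta:.4f})")
print(f"relative bias = {relative_bias_percent(alpha_star, beta):.1f}%")

m = required_subjects(required_events(alpha_star), design.p_event)
print(f"required subjects m = {m}")

summary = run_study(SimConfig(model=model, design=design, m=m, reps=500,
                              seed=1, alpha_star_ref=alpha_star,
                              beta1_ref=beta))
print(f"AVE = {summary.ave:.3f}, ESE = {summary.ese:.3f}, "
      f"ECP* = {summary.ecp_star:.1f}%, EP = {summary.ep:.1f}%")
```

prints

```
lambda1 = 0.8542, lambda2 = 1.6108
alpha* = -0.1942  (true common beta = -0.2231)
relative bias = -13.0%
required subjects m = 820
AVE = -0.198, ESE = 0.078, ECP* = 94.8%, EP = 80.0%
```

Reading: under moderate Clayton dependence (τ = 0.4), a treatment that cuts
both component hazards by 20% looks like only a 17.7% reduction
(e^{−0.194}) in the composite-endpoint Cox analysis — a 13% attenuation of
the log hazard ratio.  Replicate trials at the planned sample size center
on α* (AVE ≈ α*, coverage of α* near the nominal 95%), not on β, and the
Wald test still attains its planned 80% power *for α**.  The WLW global
analysis, by contrast, stays centered on β (`run_study(...,
analysis="wlw")`).

A command-line interface mirrors the library: `cecox design`, `cecox
limits`, `cecox hrcurve`, `cecox table`, `cecox simulate`, `cecox fit` (see
`cecox --help`).

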