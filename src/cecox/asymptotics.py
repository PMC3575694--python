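"""Limiting values of misspecified composite-endpoint and WLW estimators.

When the fitted Cox model h(t|z) = psi0(t) exp(alpha z) for the composite
endpoint is misspecified (the usual case once the components are dependent),
the maximum partial-likelihood estimator converges to alpha_star, the root
of the population-level score

    u(alpha) = int_0^{C} [ P(Z=1) G(s) f(s|1)
                 - e(alpha, s) * sum_z P(Z=z) G(s) f(s|z) ] ds,

where f and S are the composite density/survivor, G(s) = exp(-rho s) is the
withdrawal survivor on (0, C-dagger], e = s1/s0 and

    s_r(alpha, s) = sum_z P(Z=z) z^r exp(alpha z) G(s) S(s|z).

The Breslow baseline estimator converges to

    Psi_star(t) = int_0^t [sum_z P(Z=z) G(s) f(s|z)] / s0(alpha_star, s) ds.

The WLW component estimators remain consistent for (beta1, beta2); the
global estimate converges to c' beta with minimum-variance weights built
from the limiting robust covariance Sigma(beta), which this module
approximates by averaging subject-level sandwich covariance estimates
(scaled by m) over R large simulated trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize

from .composite_model import JointModel, composite_density, composite_survivor
from .design import TrialDesign

__all__ = [
    "LimitSet",
    "WLWLimit",
    "expected_score",
    "limiting_alpha",
    "relative_bias_percent",
    "limiting_baseline",
    "wlw_limiting_value",
]

_QUAD_KW = dict(epsabs=1e-10, epsrel=1e-10, limit=200)


@dataclass(frozen=True)
class WLWLimit:
    """Limiting WLW global value with its Monte-Carlo provenance."""

    value: float
    weights: np.ndarray
    sigma: np.ndarray
    mc_se: float
    n_trials: int
    m_per_trial: int


@dataclass(frozen=True)
class LimitSet:
    """Bundle of limiting quantities for a solved model/design."""

    alpha_star: float
    wlw: WLWLimit | None = None


def _score_integrand(model: JointModel, design: TrialDesign, alpha: float):
    p = model.p_treat
    rho = design.rho
    ea = np.exp(alpha)

    def integrand(s: float) -> float:
        g = np.exp(-rho * s)
        f0 = composite_density(model, s, 0)
        f1 = composite_density(model, s, 1)
        s0_ = composite_survivor(model, s, 0)
        s1_ = composite_survivor(model, s, 1)
        num = p * ea * s1_
        den = (1 - p) * s0_ + p * ea * s1_
        e = num / den
        return float(g * (p * f1 - e * ((1 - p) * f0 + p * f1)))

    return integrand


def expected_score(model: JointModel, design: TrialDesign, alpha: float) -> float:
    """Population score u(alpha) for the composite-endpoint Cox fit."""
    val, _ = integrate.quad(
        _score_integrand(model, design, alpha), 0.0, design.c_admin, **_QUAD_KW
    )
    return val


def limiting_alpha(model: JointModel, design: TrialDesign) -> float:
    """Root alpha_star of the expected score on [-3, 3] (widened once)."""
    lo, hi = -3.0, 3.0
    f = lambda a: expected_score(model, design, a)
    if f(lo) * f(hi) > 0:
        lo, hi = -6.0, 6.0
        if f(lo) * f(hi) > 0:
            raise RuntimeError(
                "expected score has no sign change on [-6, 6]; "
                "cannot bracket alpha_star"
            )
    return float(optimize.brentq(f, lo, hi, xtol=1e-10, rtol=1e-12))


def relative_bias_percent(alpha_star: float, beta: float) -> float:
    """Asymptotic percent relative bias 100 * (alpha_star - beta) / beta."""
    if beta == 0:
        raise ValueError("relative bias undefined at beta = 0")
    return 100.0 * (alpha_star - beta) / beta


def limiting_baseline(
    model: JointModel, design: TrialDesign, alpha_star: float, t: float
) -> float:
    """Limit Psi_star(t) of the Breslow baseline cumulative hazard."""
    if not 0 < t <= design.c_admin:
        raise ValueError("t must lie in (0, C-dagger]")
    p = model.p_treat
    rho = design.rho
    ea = np.exp(alpha_star)

    def integrand(s: float) -> float:
        g = np.exp(-rho * s)
        f_mix = ((1 - p) * composite_density(model, s, 0)
                 + p * composite_density(model, s, 1))
        s0 = g * ((1 - p) * composite_survivor(model, s, 0)
                  + p * ea * composite_survivor(model, s, 1))
        return float(g * f_mix / s0)

    val, _ = integrate.quad(integrand, 0.0, t, **_QUAD_KW)
    return val


def wlw_limiting_value(
    model: JointModel,
    design: TrialDesign,
    n_trials: int = 50,
    m_per_trial: int = 200_000,
    seed: int = 0,
) -> WLWLimit:
    """Limiting WLW global value c(beta)' beta.

    The component limits are the true (beta1, beta2).  The limiting robust
    covariance Sigma(beta) is approximated by the average, over ``n_trials``
    seeded trials of ``m_per_trial`` subjects, of the per-trial sandwich
    estimate scaled by m.  The Monte-Carlo SE reported is the dispersion of
    the per-trial weighted combinations.
    """
    from .estimation import fit_wlw
    from .simulation_engine import sample_trial

    betas = model.betas
    j = np.ones(2)
    ss = np.random.SeedSequence(seed)
    sigmas = []
    per_trial_value = []
    for child in ss.spawn(n_trials):
        data = sample_trial(model, design, m_per_trial,
                            np.random.default_rng(child))
        fit = fit_wlw(data)
        sigmas.append(m_per_trial * fit.sigma_hat)
        sig_inv = np.linalg.inv(sigmas[-1])
        w_r = sig_inv @ j / (j @ sig_inv @ j)
        per_trial_value.append(float(w_r @ betas))
    sigma = np.mean(sigmas, axis=0)
    eig = np.linalg.eigvalsh(sigma)
    if eig.min() <= 0:
        raise np.linalg.LinAlgError(
            f"limiting covariance estimate not positive definite ({eig})"
        )
    sig_inv = np.linalg.inv(sigma)
    weights = sig_inv @ j / (j @ sig_inv @ j)
    value = float(weights @ betas)
    mc_se = float(np.std(per_trial_value, ddof=1) / np.sqrt(n_trials))
    return WLWLimit(value=value, weights=weights, sigma=sigma, mc_se=mc_se,
                    n_trials=n_trials, m_per_trial=m_per_trial)
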