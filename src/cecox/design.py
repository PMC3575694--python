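"""Trial-design calculus: rate solving, censoring, events and sample size.

A design is specified by the study horizon C-dagger (administrative
censoring time, default 1), the probability p1 = P(T1 < T2 | Z=0) that the
type-1 event occurs first among controls, the administrative censoring rate
pi_A = P(C-dagger < T) for the composite endpoint across arms, and the net
censoring rate pi = P(C < T) once exponential withdrawal (rate rho) is
added, subject to pi_A <= pi.  Given a copula and treatment effects, the
baseline rates (lambda1, lambda2) are solved from (p1, pi_A) and rho from
pi.  Sample size uses the Schoenfeld event count

    D = (z_{1-gamma1} + z_{1-gamma2})^2 / (p(1-p) * alpha_star^2)

with p the randomization probability and alpha_star the planning log hazard
ratio, and m = ceil(D / P(T < C)) subjects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats

from .composite_model import (
    JointModel,
    MarginSpec,
    composite_density,
    composite_survivor,
)
from .copulas import CopulaSpec, copula_partial_u1

__all__ = [
    "TrialDesign",
    "SampleSizeSpec",
    "DesignError",
    "prob_first_event_is_component1",
    "admin_censoring_prob",
    "net_censoring_prob",
    "solve_margin_rates",
    "solve_withdrawal_rate",
    "solve_design",
    "required_events",
    "required_subjects",
]

_QUAD_KW = dict(epsabs=1e-12, epsrel=1e-10, limit=200)


class DesignError(RuntimeError):
    """Raised when a design constraint system cannot be solved."""


@dataclass(frozen=True)
class TrialDesign:
    """A solved trial design (rates live on the accompanying JointModel)."""

    c_admin: float = 1.0
    p1: float = 0.25
    pi_admin: float = 0.2
    pi_net: float = 0.2
    rho: float = 0.0
    p_treat: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.p1 < 1.0:
            raise ValueError("p1 must be in (0, 1)")
        if self.pi_net < self.pi_admin - 1e-12:
            raise ValueError(
                "net censoring must dominate administrative censoring "
                "(pi_A <= pi)"
            )
        if self.rho < 0:
            raise ValueError("withdrawal rate rho must be >= 0")

    @property
    def p_event(self) -> float:
        """P(T < C), the probability a subject's composite event is observed."""
        return 1.0 - self.pi_net


@dataclass(frozen=True)
class SampleSizeSpec:
    """Error rates and planning effect for the event/subject calculation.

    ``gamma1`` is the one-sided type-I error, ``gamma2`` is one minus the
    power, ``alpha_star`` the planning log hazard ratio.
    """

    alpha_star: float
    gamma1: float = 0.05
    gamma2: float = 0.20

    def __post_init__(self) -> None:
        if not (0 < self.gamma1 < 0.5 and 0 < self.gamma2 < 0.5):
            raise ValueError("gamma1 and gamma2 must lie in (0, 0.5)")
        if self.alpha_star == 0:
            raise ValueError("planning effect alpha_star must be nonzero")


# ---------------------------------------------------------------------------
# model functionals
# ---------------------------------------------------------------------------


def prob_first_event_is_component1(model: JointModel, z: int = 0) -> float:
    """P(T1 < T2 | z), the mass of a type-1 first event.

    The sub-density integral over t of dC/du1(S1, S2) * h1 * S1 is mapped to
    the finite interval u = S1(t|z) in (0, 1), where the type-2 survivor is
    u ** (h2/h1) under exponential margins:

        P(T1 < T2 | z) = int_0^1 dC/du1(u, u**r) du,   r = h2(z)/h1(z).
    """
    r = float(model.margin2.hazard(z) / model.margin1.hazard(z))

    def integrand(u: float) -> float:
        return float(copula_partial_u1(model.copula, u, u ** r))

    val, _ = integrate.quad(integrand, 0.0, 1.0, **_QUAD_KW)
    return val


def admin_censoring_prob(model: JointModel, c_admin: float = 1.0) -> float:
    """pi_A = P(C-dagger < T) = E_Z[S(C-dagger | Z)]."""
    p = model.p_treat
    return float((1 - p) * composite_survivor(model, c_admin, 0)
                 + p * composite_survivor(model, c_admin, 1))


def net_censoring_prob(model: JointModel, rho: float, c_admin: float = 1.0) -> float:
    """pi = P(C < T) with C = min(W, C-dagger), W ~ Exponential(rho):
    E_Z[P(W < T < C-dagger | Z) + P(C-dagger < T | Z)]."""
    if rho == 0.0:
        return admin_censoring_prob(model, c_admin)

    def part(z: int) -> float:
        def integrand(t: float) -> float:
            return float(-np.expm1(-rho * t) * composite_density(model, t, z))

        val, _ = integrate.quad(integrand, 0.0, c_admin, **_QUAD_KW)
        return val + float(composite_survivor(model, c_admin, z))

    p = model.p_treat
    return (1 - p) * part(0) + p * part(1)


# ---------------------------------------------------------------------------
# constraint solving
# ---------------------------------------------------------------------------


def _independence_start(
    beta1: float, beta2: float, p1: float, pi_admin: float,
    p_treat: float, c_admin: float,
) -> tuple[float, float]:
    """Closed-form rates under independence, used to start the 2-D solve.

    With independent exponential components, P(T1 < T2 | Z=0) =
    lambda1/(lambda1+lambda2), so lambda1 = p1*s, lambda2 = (1-p1)*s and the
    total control rate s is set by the censoring constraint."""

    def resid(s: float) -> float:
        lam0 = s * (p1 * np.exp(beta1 * 0) + (1 - p1) * np.exp(beta2 * 0))
        lam1 = s * (p1 * np.exp(beta1) + (1 - p1) * np.exp(beta2))
        return ((1 - p_treat) * np.exp(-lam0 * c_admin)
                + p_treat * np.exp(-lam1 * c_admin) - pi_admin)

    s = optimize.brentq(resid, 1e-10, 1e4, xtol=1e-14, rtol=1e-14)
    return p1 * s, (1 - p1) * s


def solve_margin_rates(
    copula: CopulaSpec,
    beta1: float,
    beta2: float,
    p1: float,
    pi_admin: float,
    p_treat: float = 0.5,
    c_admin: float = 1.0,
) -> tuple[float, float]:
    """Solve (lambda1, lambda2) so that P(T1 < T2 | Z=0) = p1 and
    P(C-dagger < T) = pi_admin.  Root-finding is on log-rates, started from
    the independence closed form."""
    if not 0 < p1 < 1:
        raise ValueError("p1 must be in (0, 1)")
    if not 0 < pi_admin < 1:
        raise ValueError("pi_admin must be in (0, 1)")

    start = _independence_start(beta1, beta2, p1, pi_admin, p_treat, c_admin)

    def build(loglams: np.ndarray) -> JointModel:
        l1, l2 = np.exp(loglams)
        return JointModel(copula, MarginSpec(l1, beta1), MarginSpec(l2, beta2),
                          p_treat)

    def resid(loglams: np.ndarray) -> np.ndarray:
        model = build(loglams)
        return np.array([
            prob_first_event_is_component1(model, 0) - p1,
            admin_censoring_prob(model, c_admin) - pi_admin,
        ])

    sol = optimize.root(resid, np.log(start), method="hybr", tol=1e-12)
    final = resid(sol.x)
    if not np.all(np.abs(final) < 1e-8):
        raise DesignError(
            "margin-rate solve did not meet constraints: "
            f"residuals={final}, rates={np.exp(sol.x)}, message={sol.message}"
        )
    l1, l2 = np.exp(sol.x)
    return float(l1), float(l2)


def solve_withdrawal_rate(
    model: JointModel, pi_net: float, c_admin: float = 1.0
) -> float:
    """Solve the exponential withdrawal rate rho so that P(C < T) = pi_net."""
    pi_admin = admin_censoring_prob(model, c_admin)
    if pi_net < pi_admin - 1e-10:
        raise ValueError(
            f"pi_net={pi_net} below administrative censoring pi_A={pi_admin:.6f} "
            "(requires pi_A <= pi)"
        )
    if abs(pi_net - pi_admin) <= 1e-10:
        return 0.0

    def resid(rho: float) -> float:
        return net_censoring_prob(model, rho, c_admin) - pi_net

    hi = 1.0
    while resid(hi) < 0:
        hi *= 2.0
        if hi > 1e6:
            raise DesignError("withdrawal-rate solve failed to bracket")
    rho = optimize.brentq(resid, 0.0, hi, xtol=1e-12, rtol=1e-12)
    if abs(resid(rho)) > 1e-8:
        raise DesignError(f"withdrawal-rate solve residual too large at rho={rho}")
    return float(rho)


def solve_design(
    copula: CopulaSpec,
    beta1: float,
    beta2: float,
    p1: float,
    pi_admin: float,
    pi_net: float | None = None,
    p_treat: float = 0.5,
    c_admin: float = 1.0,
) -> tuple[JointModel, TrialDesign]:
    """Solve the full design: rates from (p1, pi_A), then rho from pi."""
    pi_net = pi_admin if pi_net is None else pi_net
    l1, l2 = solve_margin_rates(copula, beta1, beta2, p1, pi_admin, p_treat,
                                c_admin)
    model = JointModel(copula, MarginSpec(l1, beta1), MarginSpec(l2, beta2),
                       p_treat)
    rho = solve_withdrawal_rate(model, pi_net, c_admin)
    design = TrialDesign(c_admin=c_admin, p1=p1, pi_admin=pi_admin,
                         pi_net=pi_net, rho=rho, p_treat=p_treat)
    return model, design


# ---------------------------------------------------------------------------
# sample size
# ---------------------------------------------------------------------------


def required_events(
    alpha_star: float,
    gamma1: float = 0.05,
    gamma2: float = 0.20,
    p_treat: float = 0.5,
) -> float:
    """Schoenfeld event count D (kept fractional; see required_subjects)."""
    spec = SampleSizeSpec(alpha_star, gamma1, gamma2)  # validates
    zq = stats.norm.ppf(1 - spec.gamma1) + stats.norm.ppf(1 - spec.gamma2)
    return float(zq ** 2 / (p_treat * (1 - p_treat) * alpha_star ** 2))


def required_subjects(n_events: float, p_event: float) -> int:
    """m = ceil(D / P(T < C))."""
    if not 0 < p_event <= 1:
        raise ValueError("p_event must be in (0, 1]")
    return math.ceil(n_events / p_event)
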