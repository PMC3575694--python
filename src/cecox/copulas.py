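"""Archimedean copulas for bivariate failure-time dependence.

Implements the Clayton, Frank and Gumbel-Hougaard families together with the
independence copula.  A copula ``C(u1, u2; theta)`` couples two uniform
margins; in this package it is applied to marginal *survivor* probabilities,
so ``C(S1(t1), S2(t2))`` is the joint probability that both failure times
exceed their arguments.  Dependence strength may be given either as the
natural parameter ``theta`` or as Kendall's tau, which for these families is
in one-to-one correspondence with theta:

* Clayton:          tau = theta / (theta + 2),      theta >= -1
* Gumbel-Hougaard:  tau = (theta - 1) / theta,      theta >= 1
* Frank:            tau = 1 + 4 * int_0^1 phi(t)/phi'(t) dt (generator
  integral, evaluated by adaptive quadrature),      theta != 0

All sampling goes through an explicit :class:`numpy.random.Generator`; there
is no global random state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, optimize, stats

__all__ = [
    "CopulaSpec",
    "CopulaDomainError",
    "copula_value",
    "copula_partial_u1",
    "copula_partial_u2",
    "tau_from_theta",
    "theta_from_tau",
    "sample_uniform_pairs",
]

FAMILIES = ("clayton", "frank", "gumbel", "independence")

#: |theta| below this is evaluated in the independence limit (Clayton, Frank)
#: to avoid catastrophic cancellation near theta = 0.
_THETA_EPS = 1e-8

#: Frank tau is supported on |tau| <= _FRANK_TAU_MAX; the corresponding theta
#: stays within a range where exp(theta) is representable.
_FRANK_TAU_MAX = 0.98
_FRANK_THETA_MAX = 300.0

_CONSISTENCY_TOL = 1e-10

#: bracket shrinkage for numeric conditional inversion (Gumbel sampler).
_INV_EPS = 1e-12


class CopulaDomainError(ValueError):
    """Raised when theta (or tau) lies outside a family's admissible range."""


def _check_family(family: str) -> None:
    if family not in FAMILIES:
        raise CopulaDomainError(
            f"unknown copula family {family!r}; expected one of {FAMILIES}"
        )


def _check_theta(family: str, theta: float | None) -> None:
    _check_family(family)
    if family == "independence":
        if theta is not None:
            raise CopulaDomainError("independence copula takes no theta")
        return
    if theta is None or not np.isfinite(theta):
        raise CopulaDomainError(f"{family} copula requires a finite theta")
    if family == "clayton" and theta < -1:
        raise CopulaDomainError(
            f"clayton theta must satisfy theta >= -1, got {theta}"
        )
    if family == "gumbel" and theta < 1:
        raise CopulaDomainError(
            f"gumbel theta must satisfy theta >= 1, got {theta}"
        )
    # frank: any finite theta; theta ~ 0 handled as the independence limit.


@dataclass(frozen=True)
class CopulaSpec:
    """An Archimedean copula family with its dependence parameter.

    Parameters
    ----------
    family
        One of ``clayton``, ``frank``, ``gumbel`` or ``independence``.
    theta
        Natural dependence parameter (``None`` for independence).
    tau
        Kendall's tau implied by ``theta``; filled in automatically by the
        constructors and checked for consistency to 1e-10.
    """

    family: str
    theta: float | None
    tau: float

    def __post_init__(self) -> None:
        _check_theta(self.family, self.theta)
        implied = tau_from_theta(self.family, self.theta)
        if abs(implied - self.tau) > _CONSISTENCY_TOL:
            raise CopulaDomainError(
                f"tau={self.tau} inconsistent with theta={self.theta} "
                f"for family {self.family!r} (implied tau={implied})"
            )

    @classmethod
    def from_theta(cls, family: str, theta: float | None = None) -> "CopulaSpec":
        _check_theta(family, theta)
        return cls(family, theta, tau_from_theta(family, theta))

    @classmethod
    def from_tau(cls, family: str, tau: float) -> "CopulaSpec":
        theta = theta_from_tau(family, tau)
        if family != "independence" and theta is not None:
            tau = tau_from_theta(family, theta)  # snap to the exact map
        return cls(family, theta, tau)

    @property
    def is_independence(self) -> bool:
        """True when the spec evaluates as the independence copula."""
        if self.family == "independence":
            return True
        if self.family in ("clayton", "frank") and abs(self.theta) < _THETA_EPS:
            return True
        return False


# ---------------------------------------------------------------------------
# Kendall's tau <-> theta
# ---------------------------------------------------------------------------


def _frank_tau(theta: float) -> float:
    """Kendall's tau for the Frank family via the Archimedean generator
    integral tau = 1 + 4 * int_0^1 phi(t)/phi'(t) dt."""
    if abs(theta) < _THETA_EPS:
        return 0.0
    if theta < 0:
        return -_frank_tau(-theta)  # radial symmetry of the Frank family

    def phi_over_dphi(t: float) -> float:
        # phi(t) = -log(expm1(-theta t)/expm1(-theta));
        # phi'(t) = theta e^{-theta t} / expm1(-theta t).
        # Stable form: phi/phi' = num * (1 - e^{-theta t}) * e^{theta t}/theta
        # with num = log1p(-e^{-theta}) - log1p(-e^{-theta t}) (negative).
        et = np.exp(-theta * t)
        num = np.log1p(-np.exp(-theta)) - np.log1p(-et)
        return num * -(1.0 - et) / (theta * et)

    # phi/phi' has a mild t*log(t) endpoint behaviour at 0; QUADPACK meets
    # ~1e-12 absolute accuracy here but flags roundoff, so silence that.
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        val, _ = integrate.quad(phi_over_dphi, 0.0, 1.0, epsabs=1e-12,
                                epsrel=1e-11, limit=200)
    return 1.0 + 4.0 * val


def tau_from_theta(family: str, theta: float | None = None) -> float:
    """Kendall's tau implied by the family's dependence parameter."""
    _check_theta(family, theta)
    if family == "independence":
        return 0.0
    if family == "clayton":
        return theta / (theta + 2.0)
    if family == "gumbel":
        return (theta - 1.0) / theta
    return _frank_tau(theta)


def theta_from_tau(family: str, tau: float) -> float | None:
    """Invert the tau(theta) map; raises if tau is unattainable."""
    _check_family(family)
    if not -1.0 <= tau <= 1.0:
        raise CopulaDomainError(f"Kendall's tau must lie in [-1, 1], got {tau}")
    if family == "independence":
        if tau != 0.0:
            raise CopulaDomainError("independence copula implies tau = 0")
        return None
    if family == "clayton":
        if tau >= 1.0:
            raise CopulaDomainError("clayton requires tau < 1")
        return 2.0 * tau / (1.0 - tau)
    if family == "gumbel":
        if not 0.0 <= tau < 1.0:
            raise CopulaDomainError(
                f"gumbel attains only tau in [0, 1), got {tau}"
            )
        return 1.0 / (1.0 - tau)
    # frank
    if tau == 0.0:
        return 0.0
    if abs(tau) > _FRANK_TAU_MAX:
        raise CopulaDomainError(
            f"frank tau supported on |tau| <= {_FRANK_TAU_MAX}, got {tau}"
        )
    sign = 1.0 if tau > 0 else -1.0
    theta = optimize.brentq(
        lambda th: _frank_tau(sign * th) - sign * abs(tau),
        _THETA_EPS, _FRANK_THETA_MAX, xtol=1e-13, rtol=1e-14,
    )
    return sign * theta


# ---------------------------------------------------------------------------
# Copula function and partial derivatives
# ---------------------------------------------------------------------------


def _as_unit(u, name: str):
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return u


def copula_value(spec: CopulaSpec, u1, u2):
    """Evaluate C(u1, u2; theta).  Accepts scalars or arrays (broadcast).

    Results are clipped to [0, 1]: the closed forms can overshoot by a few
    ulp at the corners (e.g. Frank at u1 = u2 = 1)."""
    return np.clip(_copula_value_raw(spec, u1, u2), 0.0, 1.0)


def _copula_value_raw(spec: CopulaSpec, u1, u2):
    u1 = _as_unit(u1, "u1")
    u2 = _as_unit(u2, "u2")
    if spec.is_independence:
        return u1 * u2
    th = spec.theta
    if spec.family == "clayton":
        with np.errstate(divide="ignore", over="ignore"):
            a = u1 ** (-th) + u2 ** (-th) - 1.0
        if th > 0:
            # a >= 1 always; u=0 gives a=inf -> C=0
            with np.errstate(over="ignore"):
                out = a ** (-1.0 / th)
            return np.where((u1 == 0) | (u2 == 0), 0.0, out)
        out = np.maximum(a, 0.0) ** (-1.0 / th)
        return out
    if spec.family == "frank":
        em = np.expm1(-th)
        val = -np.log1p(np.expm1(-th * u1) * np.expm1(-th * u2) / em) / th
        return np.where((u1 == 0) | (u2 == 0), 0.0, val)
    # gumbel
    with np.errstate(divide="ignore"):
        a1 = (-np.log(u1)) ** th
        a2 = (-np.log(u2)) ** th
    out = np.exp(-((a1 + a2) ** (1.0 / th)))
    return np.where((u1 == 0) | (u2 == 0), 0.0, out)


def copula_partial_u1(spec: CopulaSpec, u1, u2):
    """dC/du1, the conditional distribution P(U2 <= u2 | U1 = u1).

    Inputs with u1 = 0 are undefined and should be avoided by callers; the
    marginal survivor probabilities this package feeds in are strictly
    positive on the study interval.
    """
    u1 = _as_unit(u1, "u1")
    u2 = _as_unit(u2, "u2")
    if spec.is_independence:
        return np.ones_like(u1, dtype=float) * u2
    th = spec.theta
    if spec.family == "clayton":
        with np.errstate(divide="ignore", over="ignore"):
            if th > 0:
                # dC/du1 = (C/u1)^(1+theta) = b^(-(1+theta)/theta) with
                # b = 1 + (u1/u2)^theta - u1^theta  (stable as u1,u2 -> 0)
                b = 1.0 + (u1 / np.where(u2 == 0, np.nan, u2)) ** th - u1 ** th
                out = b ** (-(1.0 + th) / th)
                return np.where(u2 == 0, 0.0, out)
            a = u1 ** (-th) + u2 ** (-th) - 1.0
            out = np.where(a > 0, np.maximum(a, 1e-300) ** (-(1.0 + th) / th)
                           * u1 ** (-th - 1.0), 0.0)
            return out
    if spec.family == "frank":
        e1 = np.expm1(-th * u1)
        e2 = np.expm1(-th * u2)
        em = np.expm1(-th)
        return (e1 + 1.0) * e2 / (em + e1 * e2)
    # gumbel
    with np.errstate(divide="ignore"):
        l1 = -np.log(u1)
        l2 = -np.log(np.clip(u2, 1e-300, 1.0))
        a = l1 ** th + l2 ** th
        out = np.exp(-(a ** (1.0 / th))) * a ** (1.0 / th - 1.0) \
            * l1 ** (th - 1.0) / u1
    return np.where(u2 == 0, 0.0, out)


def copula_partial_u2(spec: CopulaSpec, u1, u2):
    """dC/du2; all supported families are exchangeable."""
    return copula_partial_u1(spec, u2, u1)


# ---------------------------------------------------------------------------
# Sampling by conditional-distribution inversion
# ---------------------------------------------------------------------------


def _conditional_quantile(spec: CopulaSpec, u1, v):
    """Solve dC/du1 (u1, u2) = v for u2 (vectorized)."""
    if spec.is_independence:
        return v
    th = spec.theta
    if spec.family == "clayton":
        if th < 0:
            raise CopulaDomainError(
                "sampling is supported for tau >= 0 only (clayton theta >= 0)"
            )
        return (1.0 + u1 ** (-th) * (v ** (-th / (1.0 + th)) - 1.0)) ** (-1.0 / th)
    if spec.family == "frank":
        e1 = np.expm1(-th * u1)
        em = np.expm1(-th)
        y = v * em / ((e1 + 1.0) - v * e1)
        return -np.log1p(y) / th
    # gumbel: monotone bisection on u2 in [eps, 1-eps]
    lo = np.full_like(u1, _INV_EPS)
    hi = np.full_like(u1, 1.0 - _INV_EPS)
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        too_low = copula_partial_u1(spec, u1, mid) < v
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    return 0.5 * (lo + hi)


def sample_uniform_pairs(
    spec: CopulaSpec, n: int, rng: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` i.i.d. pairs (U1, U2) with joint law C.

    ``rng`` is either a seed (int) or a :class:`numpy.random.Generator`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(
        rng, np.random.Generator) else rng
    u1 = rng.uniform(size=n)
    v = rng.uniform(size=n)
    u2 = _conditional_quantile(spec, u1, v)
    return u1, np.clip(u2, 0.0, 1.0)


def empirical_kendall_tau(u1: np.ndarray, u2: np.ndarray) -> float:
    """Sample Kendall's tau (thin wrapper kept here for oracle use)."""
    return float(stats.kendalltau(u1, u2).statistic)
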