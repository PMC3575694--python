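"""Cox partial-likelihood estimation for a binary treatment, and the
Wei-Lin-Weissfeld (WLW) marginal analysis.

The composite-endpoint analysis fits a single Cox model to the time to the
first event.  The WLW analysis fits one Cox model per component under a
working independence assumption, estimates the joint covariance of the two
coefficients with a subject-level sandwich estimator, and combines the
component estimates with minimum-variance weights:

    w = Sigma^{-1} J [J' Sigma^{-1} J]^{-1},   J = (1, 1)',
    beta_global = w' beta_hat,   se = [J' Sigma^{-1} J]^{-1/2}.

Because every subject is followed for each component until their common
censoring time C_i = min(W_i, C-dagger), the WLW fits use all observed
component events, not only the first.

The fitter is specialized to a single binary covariate: risk-set sums
collapse to at-risk counts per arm, so the partial likelihood, score,
information, Breslow baseline and per-subject score residuals are all exact
and O(m log m).  Ties are handled with the Breslow convention (the package's
simulator produces continuous times, but imported data may contain ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TrialData",
    "CoxFit",
    "WLWFit",
    "ConvergenceError",
    "fit_cox_binary",
    "fit_wlw",
]

TRIAL_COLUMNS = ["id", "z", "x1", "d1", "x2", "d2", "x", "d"]


class ConvergenceError(RuntimeError):
    """Partial-likelihood maximization diverged (e.g. monotone likelihood)."""


@dataclass(frozen=True)
class TrialData:
    """Subject-level observed data for a two-component trial.

    ``x_k`` = min(T_k, C) and ``d_k`` = 1{T_k <= C} for component k;
    ``x``/``d`` are the same for the composite endpoint T = min(T1, T2).
    """

    id: np.ndarray
    z: np.ndarray
    x1: np.ndarray
    d1: np.ndarray
    x2: np.ndarray
    d2: np.ndarray
    x: np.ndarray
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.id)
        for c in TRIAL_COLUMNS[1:]:
            if len(getattr(self, c)) != n:
                raise ValueError("all columns must have equal length")
        for c in ("z", "d1", "d2", "d"):
            v = getattr(self, c)
            if not np.isin(v, (0, 1)).all():
                raise ValueError(f"column {c} must be 0/1")
        evt = self.d == 1
        if not np.allclose(self.x[evt],
                           np.minimum(self.x1, self.x2)[evt]):
            raise ValueError("composite time must equal min(x1, x2) at events")

    def __len__(self) -> int:
        return len(self.id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({c: getattr(self, c) for c in TRIAL_COLUMNS})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TrialData":
        missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"TrialData frame missing columns: {missing}")
        kw = {c: df[c].to_numpy() for c in TRIAL_COLUMNS}
        kw["id"] = kw["id"].astype(int)
        for c in ("z", "d1", "d2", "d"):
            kw[c] = kw[c].astype(int)
        for c in ("x1", "x2", "x"):
            kw[c] = kw[c].astype(float)
        return cls(**kw)


@dataclass(frozen=True)
class CoxFit:
    """A fitted Cox model with one binary covariate."""

    alpha_hat: float
    se_model: float
    se_robust: float
    loglik: float
    n_events: int
    information: float
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    score_residuals: np.ndarray = field(repr=False)

    def breslow(self, t) -> np.ndarray:
        """Breslow baseline cumulative hazard evaluated at times ``t``."""
        idx = np.searchsorted(self.baseline_times, np.asarray(t, float),
                              side="right")
        padded = np.concatenate([[0.0], self.baseline_cumhaz])
        return padded[idx]


@dataclass(frozen=True)
class WLWFit:
    """WLW component fits, joint robust covariance and global estimate."""

    beta_hat: np.ndarray
    sigma_hat: np.ndarray
    weights: np.ndarray
    global_estimate: float
    se_global: float
    se_model_global: float
    fits: tuple[CoxFit, CoxFit]


def _risk_table(time, event, z):
    """Per distinct event time: event counts and at-risk counts by arm."""
    time = np.asarray(time, float)
    event = np.asarray(event)
    z = np.asarray(z)
    order = np.argsort(time, kind="stable")
    t_s, e_s, z_s = time[order], event[order], z[order]
    m = len(t_s)
    n1_total = int(z_s.sum())
    cum_z = np.concatenate([[0], np.cumsum(z_s)])

    emask = e_s == 1
    ut, inv = np.unique(t_s[emask], return_inverse=True)
    d = np.bincount(inv).astype(float)
    dz = np.bincount(inv, weights=z_s[emask].astype(float))
    first = np.searchsorted(t_s, ut, side="left")
    n_risk = m - first
    n1 = n1_total - cum_z[first]
    n0 = n_risk - n1
    return ut, d, dz, n0.astype(float), n1.astype(float)


def _loglik(alpha, d, dz, n0, n1):
    s0 = n0 + np.exp(alpha) * n1
    return alpha * dz.sum() - np.sum(d * np.log(s0))


def fit_cox_binary(time, event, z, max_iter: int = 50) -> CoxFit:
    """Maximum partial-likelihood fit of h(t|z) = psi0(t) exp(alpha z).

    Newton iterations from alpha = 0 with step halving; convergence when the
    step falls below 1e-10.  Model-based SE from the observed information,
    robust SE from the score-residual sandwich.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    z = np.asarray(z, int)
    n_events = int(event.sum())
    if n_events == 0:
        raise ValueError("no events observed; cannot fit")
    ut, d, dz, n0, n1 = _risk_table(time, event, z)
    d_tot, dz_tot = d.sum(), dz.sum()
    if dz_tot == 0:
        raise ConvergenceError(
            "monotone partial likelihood: all events in the control arm (z=0)"
        )
    if dz_tot == d_tot:
        raise ConvergenceError(
            "monotone partial likelihood: all events in the treated arm (z=1)"
        )

    alpha = 0.0
    ll = _loglik(alpha, d, dz, n0, n1)
    for _ in range(max_iter):
        ea = np.exp(alpha)
        p = ea * n1 / (n0 + ea * n1)
        score = dz_tot - np.sum(d * p)
        info = np.sum(d * p * (1.0 - p))
        if info <= 0:
            raise ConvergenceError("vanishing information in Newton step")
        step = score / info
        new = alpha + step
        ll_new = _loglik(new, d, dz, n0, n1)
        halvings = 0
        while ll_new < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new = alpha + step
            ll_new = _loglik(new, d, dz, n0, n1)
            halvings += 1
        alpha, ll = new, ll_new
        if abs(alpha) > 30:
            raise ConvergenceError("estimate diverged (|alpha| > 30)")
        if abs(step) < 1e-10:
            break
    else:
        raise ConvergenceError("Newton iterations failed to converge")

    ea = np.exp(alpha)
    s0 = n0 + ea * n1
    p = ea * n1 / s0
    info = float(np.sum(d * p * (1.0 - p)))
    dl = d / s0                      # Breslow increments
    cumhaz = np.cumsum(dl)

    # per-subject score residuals U_i (input order)
    cum_dl = np.concatenate([[0.0], cumhaz])
    cum_pdl = np.concatenate([[0.0], np.cumsum(p * dl)])
    idx = np.searchsorted(ut, time, side="right")
    l_at = cum_dl[idx]
    q_at = cum_pdl[idx]
    # p at each subject's own event time (0 where no event)
    pos = np.searchsorted(ut, time)
    p_at_event = np.where(event == 1, p[np.clip(pos, 0, len(ut) - 1)], 0.0)
    resid = (event * (z - p_at_event)
             - np.exp(alpha * z) * (z * l_at - q_at))

    se_model = 1.0 / np.sqrt(info)
    se_robust = float(np.sqrt(np.sum(resid ** 2)) / info)
    return CoxFit(
        alpha_hat=float(alpha),
        se_model=float(se_model),
        se_robust=se_robust,
        loglik=float(ll),
        n_events=n_events,
        information=info,
        baseline_times=ut,
        baseline_cumhaz=cumhaz,
        score_residuals=resid,
    )


def fit_wlw(data: TrialData) -> WLWFit:
    """WLW analysis: component Cox fits, joint sandwich covariance of
    (beta1_hat, beta2_hat), minimum-variance weights and global estimate."""
    fit1 = fit_cox_binary(data.x1, data.d1, data.z)
    fit2 = fit_cox_binary(data.x2, data.d2, data.z)
    beta_hat = np.array([fit1.alpha_hat, fit2.alpha_hat])
    infos = np.array([fit1.information, fit2.information])

    resid = np.column_stack([fit1.score_residuals, fit2.score_residuals])
    bread = resid.T @ resid
    sigma = bread / np.outer(infos, infos)   # Cov(beta_hat), 2x2 sandwich

    eig = np.linalg.eigvalsh(sigma)
    if eig.min() <= 0:
        raise np.linalg.LinAlgError(
            f"sandwich covariance not positive definite (eigenvalues {eig})"
        )
    sig_inv = np.linalg.inv(sigma)
    j = np.ones(2)
    denom = float(j @ sig_inv @ j)
    weights = sig_inv @ j / denom
    global_estimate = float(weights @ beta_hat)
    se_global = float(1.0 / np.sqrt(denom))
    v_model = np.diag(1.0 / infos)
    se_model_global = float(np.sqrt(weights @ v_model @ weights))
    return WLWFit(
        beta_hat=beta_hat,
        sigma_hat=sigma,
        weights=weights,
        global_estimate=global_estimate,
        se_global=se_global,
        se_model_global=se_model_global,
        fits=(fit1, fit2),
    )
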