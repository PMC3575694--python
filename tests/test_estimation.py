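import numpy as np
import pandas as pd
import pytest

from cecox.estimation import (
    ConvergenceError,
    TrialData,
    fit_cox_binary,
    fit_wlw,
)
from cecox.io import make_fixture
from cecox.simulation_engine import sample_trial

LOG08 = np.log(0.8)


def grid_search_loglik(time, event, z, alpha):
    """Independent brute-force Breslow log partial likelihood."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    z = np.asarray(z, int)
    ll = 0.0
    for t in np.unique(time[event == 1]):
        at_event = (time == t) & (event == 1)
        risk = time >= t
        for zi in z[at_event]:
            ll += alpha * zi
        ll -= at_event.sum() * np.log(np.sum(np.exp(alpha * z[risk])))
    return ll


def test_symmetric_fixture_has_zero_effect():
    data = make_fixture("symmetric6")
    fit = fit_cox_binary(data.x, data.d, data.z)
    assert fit.alpha_hat == pytest.approx(0.0, abs=1e-12)


def test_fit_matches_grid_search_oracle():
    """The Newton fit agrees with an exhaustive grid maximization of an
    independently coded log partial likelihood."""
    data = make_fixture("wlw-toy")
    fit = fit_cox_binary(data.x, data.d, data.z)
    grid = np.arange(-2.0, 2.0, 1e-4)
    lls = [grid_search_loglik(data.x, data.d, data.z, a) for a in grid]
    assert fit.alpha_hat == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)
    # interior local maximum of the fitter's own log likelihood
    for eps in (-0.01, 0.01):
        shifted = fit_cox_binary(data.x, data.d, data.z)
        assert grid_search_loglik(data.x, data.d, data.z, fit.alpha_hat) >= \
            grid_search_loglik(data.x, data.d, data.z, fit.alpha_hat + eps)


def test_fit_matches_lifelines(clayton_common):
    """Cross-check coefficient, model-based SE and robust SE against an
    established Cox implementation on a simulated trial."""
    lifelines = pytest.importorskip("lifelines")
    model, design = clayton_common
    data = sample_trial(model, design, 600, 90210)
    mine = fit_cox_binary(data.x, data.d, data.z)
    df = pd.DataFrame({"t": data.x, "e": data.d, "z": data.z})
    cph = lifelines.CoxPHFitter().fit(df, "t", "e")
    assert mine.alpha_hat == pytest.approx(float(cph.params_.iloc[0]), abs=1e-6)
    assert mine.se_model == pytest.approx(
        float(cph.summary["se(coef)"].iloc[0]), abs=1e-6)
    rob = lifelines.CoxPHFitter().fit(df, "t", "e", robust=True)
    assert mine.se_robust == pytest.approx(
        float(rob.summary["se(coef)"].iloc[0]), abs=1e-6)


def test_score_is_zero_at_estimate():
    data = make_fixture("wlw-toy")
    fit = fit_cox_binary(data.x, data.d, data.z)
    # sum of score residuals equals the score at alpha_hat
    assert fit.score_residuals.sum() == pytest.approx(0.0, abs=1e-8)


def test_parameter_recovery_under_correct_specification(indep_common):
    model, design = indep_common
    data = sample_trial(model, design, 5000, 1)
    fit = fit_cox_binary(data.x, data.d, data.z)
    assert abs(fit.alpha_hat - LOG08) < 3 * fit.se_robust


def test_model_and_robust_se_agree_when_correct(indep_common):
    """Correct specification: sandwich and information SEs coincide on
    average (Monte Carlo)."""
    model, design = indep_common
    ratios = []
    ss = np.random.SeedSequence(55)
    for child in ss.spawn(30):
        data = sample_trial(model, design, 1000, np.random.default_rng(child))
        fit = fit_cox_binary(data.x, data.d, data.z)
        ratios.append(fit.se_robust / fit.se_model)
    assert np.mean(ratios) == pytest.approx(1.0, abs=0.02)


def test_separated_fixture_diverges():
    data = make_fixture("separated")
    with pytest.raises(ConvergenceError, match="z=0"):
        fit_cox_binary(data.x, data.d, data.z)


def test_no_events_rejected():
    with pytest.raises(ValueError):
        fit_cox_binary([1.0, 1.0], [0, 0], [0, 1])


def test_breslow_ties_handled():
    """Tied event times use the Breslow convention without error."""
    t = np.array([0.5, 0.5, 0.5, 0.8, 1.0, 1.0])
    e = np.array([1, 1, 0, 1, 0, 1])
    z = np.array([0, 1, 1, 0, 0, 1])
    fit = fit_cox_binary(t, e, z)
    assert np.isfinite(fit.alpha_hat)
    assert len(fit.baseline_times) == len(np.unique(t[e == 1]))


# ---------------------------------------------------------------------------
# WLW
# ---------------------------------------------------------------------------


def test_wlw_toy_weights_sum_to_one():
    fit = fit_wlw(make_fixture("wlw-toy"))
    assert fit.weights.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.all(np.linalg.eigvalsh(fit.sigma_hat) > 0)


def test_wlw_global_is_average_for_equal_variances():
    """If the covariance were exchangeable the weights are 1/2 each; check
    the algebra on a constructed covariance."""
    sigma = np.array([[0.04, 0.01], [0.01, 0.04]])
    j = np.ones(2)
    w = np.linalg.inv(sigma) @ j / (j @ np.linalg.inv(sigma) @ j)
    np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-14)


def test_wlw_recovery_and_minimum_variance(clayton_common):
    """Global estimate recovers the common beta and its SE undercuts both
    component robust SEs."""
    model, design = clayton_common
    data = sample_trial(model, design, 2000, 99)
    fit = fit_wlw(data)
    assert abs(fit.global_estimate - LOG08) < 3 * fit.se_global
    assert fit.se_global <= fit.fits[0].se_robust * (1 + 1e-9)
    assert fit.se_global <= fit.fits[1].se_robust * (1 + 1e-9)


def test_wlw_component_consistency(clayton_diff):
    """Component fits recover (beta1, beta2) = (log 0.8, 0) at large m."""
    model, design = clayton_diff
    data = sample_trial(model, design, 20_000, 123)
    fit = fit_wlw(data)
    se = np.sqrt(np.diag(fit.sigma_hat))
    assert abs(fit.beta_hat[0] - LOG08) < 3 * se[0]
    assert abs(fit.beta_hat[1] - 0.0) < 3 * se[1]


def test_wlw_uses_all_component_events(clayton_common):
    """Censoring component-2 follow-up at the composite event changes the
    component-2 estimate: the WLW fit must use post-first-event records."""
    model, design = clayton_common
    data = sample_trial(model, design, 2000, 7)
    full = fit_wlw(data)
    trunc = TrialData(
        id=data.id, z=data.z,
        x1=data.x1, d1=data.d1,
        x2=np.minimum(data.x2, data.x),
        d2=np.where(data.x2 <= data.x, data.d2, 0),
        x=data.x, d=data.d,
    )
    other = fit_wlw(trunc)
    assert other.beta_hat[1] != pytest.approx(full.beta_hat[1], abs=1e-6)


def test_trial_data_frame_round_trip():
    data = make_fixture("wlw-toy")
    again = TrialData.from_frame(data.to_frame())
    for col in ("id", "z", "x1", "d1", "x2", "d2", "x", "d"):
        np.testing.assert_array_equal(getattr(data, col), getattr(again, col))


def test_trial_data_validation():
    with pytest.raises(ValueError):
        TrialData(
            id=np.array([1]), z=np.array([2]),  # bad arm code
            x1=np.array([0.5]), d1=np.array([1]),
            x2=np.array([0.6]), d2=np.array([0]),
            x=np.array([0.5]), d=np.array([1]),
        )
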