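import numpy as np
import pytest
from scipy import stats

from cecox.asymptotics import limiting_alpha
from cecox.composite_model import composite_survivor
from cecox.simulation_engine import (
    SimConfig,
    TABLE_CENSORING_ROWS,
    reproduce_table,
    run_study,
    sample_trial,
)

LOG08 = np.log(0.8)


def test_sample_trial_deterministic(clayton_common):
    model, design = clayton_common
    a = sample_trial(model, design, 500, 13)
    b = sample_trial(model, design, 500, 13)
    for col in ("z", "x1", "d1", "x2", "d2", "x", "d"):
        np.testing.assert_array_equal(getattr(a, col), getattr(b, col))


def test_sample_trial_respects_design_rates(clayton_common):
    """Empirical censoring fraction and latent P(T1 < T2 | Z=0) round-trip
    the design constraints.  Latent component times are reconstructed by
    replaying the generator's draw sequence."""
    from cecox.copulas import sample_uniform_pairs
    model, design = clayton_common
    m = 100_000
    data = sample_trial(model, design, m, 5150)
    emp_cens = 1.0 - data.d.mean()
    assert abs(emp_cens - 0.2) < 3 * np.sqrt(0.2 * 0.8 / m)
    # replay the stream: Bernoulli arms, then the copula pair
    rng = np.random.default_rng(5150)
    z = rng.binomial(1, model.p_treat, size=m)
    u1, u2 = sample_uniform_pairs(model.copula, m, rng)
    np.testing.assert_array_equal(z, data.z)
    t1 = -np.log(u1) / model.margin1.hazard(z)
    t2 = -np.log(u2) / model.margin2.hazard(z)
    emp_p1 = np.mean(t1[z == 0] < t2[z == 0])
    assert abs(emp_p1 - 0.25) < 3 * np.sqrt(0.25 * 0.75 / (z == 0).sum())
    np.testing.assert_allclose(np.minimum(np.minimum(t1, t2), design.c_admin),
                               data.x, rtol=1e-12)


def test_composite_times_match_survivor_by_ks(clayton_common):
    """Kolmogorov-Smirnov test of simulated composite times against the
    model survivor, per arm (uncensored design, rho=0 horizon ignored)."""
    model, design = clayton_common
    rng = np.random.default_rng(314159)
    data = sample_trial(model, design, 100_000, rng)
    for z in (0, 1):
        # use latent composite times: censoring here is only at C-dagger, so
        # condition on events before the horizon
        mask = (data.z == z) & (data.d == 1)
        t = data.x[mask]
        s_h = float(composite_survivor(model, design.c_admin, z))

        def cdf(x):
            s = composite_survivor(model, np.asarray(x), z)
            return (1.0 - s) / (1.0 - s_h)  # truncated at the horizon

        p = stats.kstest(t, cdf).pvalue
        assert p > 0.01


def test_run_study_centers_on_limiting_value(clayton_common):
    model, design = clayton_common
    a_star = limiting_alpha(model, design)
    s = run_study(SimConfig(model=model, design=design, m=816, reps=300,
                            seed=2, alpha_star_ref=a_star, beta1_ref=LOG08))
    assert abs(s.ave - a_star) < 4 * s.ese / np.sqrt(s.reps_used)
    assert 0.9 * s.ase2 < s.ese < 1.15 * s.ase2
    assert s.n_divergent == 0


def test_run_study_ecp_equals_ecp_star_under_independence(indep_common):
    """Independent components with common effects: alpha* = beta1, so the
    two coverage columns must agree replicate for replicate."""
    model, design = indep_common
    a_star = limiting_alpha(model, design)
    assert a_star == pytest.approx(LOG08, abs=1e-8)
    s = run_study(SimConfig(model=model, design=design, m=644, reps=200,
                            seed=3, alpha_star_ref=a_star, beta1_ref=a_star))
    assert s.ecp == s.ecp_star


def test_run_study_wlw_recovers_common_effect(clayton_common):
    model, design = clayton_common
    s = run_study(SimConfig(model=model, design=design, m=621, reps=200,
                            seed=4, analysis="wlw", alpha_star_ref=LOG08,
                            beta1_ref=LOG08))
    assert abs(s.ave - LOG08) < 4 * s.ese / np.sqrt(s.reps_used)
    # robust SE tracks the empirical SE; the working-independence
    # model-based SE is systematically smaller under positive dependence
    assert 0.85 * s.ase2 < s.ese < 1.15 * s.ase2
    assert s.ase1 < s.ase2


def test_coverage_for_beta1_collapses_under_unequal_effects(clayton_diff):
    """When beta2 = 0 the composite limit sits far from beta1, so nominal
    CIs for beta1 almost never cover it at the planned sample size."""
    model, design = clayton_diff
    a_star = limiting_alpha(model, design)
    s = run_study(SimConfig(model=model, design=design, m=21_743, reps=60,
                            seed=5, alpha_star_ref=a_star, beta1_ref=LOG08))
    assert s.ecp < 5.0
    assert 93.0 - 10 < s.ecp_star  # centred on alpha*, loose at 60 reps


def test_empirical_power_near_nominal(clayton_common):
    """m derived from alpha* at 80% power gives EP near 80%."""
    model, design = clayton_common
    a_star = limiting_alpha(model, design)
    s = run_study(SimConfig(model=model, design=design, m=816, reps=300,
                            seed=6, alpha_star_ref=a_star, beta1_ref=LOG08))
    assert abs(s.ep - 80.0) < 3 * 100 * np.sqrt(0.8 * 0.2 / 300) + 2.0


def test_reproduce_table_schema_and_consistency():
    """One row from each table: identical schema; AVE within Monte-Carlo
    error of the limiting-value column."""
    frames = {}
    for which in (1, 2, 3):
        frames[which] = reproduce_table(
            which, reps=40, seed=11, row_subset=[0], scenarios=("common",),
            wlw_sigma_trials=4, wlw_sigma_m=5000,
        )
    cols = list(frames[1].columns)
    assert list(frames[2].columns) == cols
    assert list(frames[3].columns) == cols
    for which, df in frames.items():
        row = df.iloc[0]
        assert abs(row["ave"] - row["limit"]) < 4 * row["ese"] / np.sqrt(40)
    # common-effect independence rows keep alpha* = log 0.8
    assert frames[2].iloc[0]["limit"] == pytest.approx(LOG08, abs=1e-8)
    # sample sizes derived from the limit (table 2 row 1: 621 under the
    # one-sided convention; table 1 row 1 within a few of the printed 816)
    assert frames[2].iloc[0]["m"] == 621
    assert abs(frames[1].iloc[0]["m"] - 816) <= 15


def test_censoring_grid_is_the_standard_ten():
    assert len(TABLE_CENSORING_ROWS) == 10
    assert all(pa <= pi for pa, pi in TABLE_CENSORING_ROWS)


def test_run_study_rejects_bad_config(clayton_common):
    model, design = clayton_common
    with pytest.raises(ValueError):
        SimConfig(model=model, design=design, m=1, reps=10, seed=0)
    with pytest.raises(ValueError):
        SimConfig(model=model, design=design, m=10, reps=0, seed=0)
    with pytest.raises(ValueError):
        SimConfig(model=model, design=design, m=10, reps=5, seed=0,
                  analysis="nope")
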