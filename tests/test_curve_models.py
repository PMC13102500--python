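"""Nonlinear gamma-likelihood time-course models."""

import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm
from helpers import toy_dataset
from scipy.stats import gamma as gamma_dist

from cortstress import (LogisticParams, QuadraticParams, SimConfig,
                        fit_curve, fit_sex_logistic, gamma_negloglik,
                        logistic_mean, parametric_bootstrap_band,
                        predict_with_ci, quadratic_mean, simulate_dataset)


# ---------------------------------------------------------------------- means

def test_logistic_mean_closed_form_points():
    p = LogisticParams(45.0, 0.12, 25.0)
    assert logistic_mean(25.0, p) == pytest.approx(22.5)      # a/2 at x0
    assert logistic_mean(1e6, p) == pytest.approx(45.0)       # asymptote
    assert logistic_mean(10.0, p) < logistic_mean(50.0, p)    # increasing, b>0


def test_logistic_mean_overflow_safe():
    p = LogisticParams(45.0, 8.0, 0.0)
    vals = logistic_mean(np.array([-100.0, 100.0]), p)        # |b(t-x0)| = 800
    assert np.all(np.isfinite(vals))
    assert vals[0] == pytest.approx(0.0, abs=1e-300)
    assert vals[1] == pytest.approx(45.0)


def test_quadratic_mean_closed_form_points():
    assert quadratic_mean(0.0, QuadraticParams(3.0, 2.0, -0.01)) == 3.0
    p = QuadraticParams(0.0, 2.0, -0.01)
    assert -p.b / (2 * p.c) == pytest.approx(100.0)           # vertex
    grid = quadratic_mean(np.linspace(0, 300, 7), QuadraticParams(1.0, 0.0, 0.0))
    assert np.all(grid == 1.0)


# ----------------------------------------------------------------- likelihood

def test_negloglik_of_unit_exponential():
    ds = toy_dataset([1.0], times=[10.0])
    assert gamma_negloglik(ds, "null", 1.0, 1.0) == pytest.approx(1.0)


def test_negloglik_agrees_with_scipy_summation():
    """Direct-summation oracle on a frozen 20-point dataset."""
    rng = np.random.default_rng(42)
    t = np.linspace(1, 200, 20)
    p = LogisticParams(45.0, 0.12, 25.0)
    mu = logistic_mean(t, p)
    y = rng.gamma(5.0, mu / 5.0)
    ds = toy_dataset(y, times=t)
    oracle = -gamma_dist.logpdf(y, a=5.0, scale=mu / 5.0).sum()
    assert gamma_negloglik(ds, "logistic", p, 5.0) == pytest.approx(oracle, abs=1e-10)
    assert oracle == pytest.approx(76.57024210305086, abs=1e-8)  # frozen value


def test_saturated_means_minimize_negloglik():
    rng = np.random.default_rng(3)
    y = rng.gamma(4.0, 2.0, size=12)
    ds = toy_dataset(y, times=np.arange(12.0))
    base = gamma_negloglik(ds, "null", float(np.mean(y)), 2.0)
    # saturated bound: per-observation means equal to the data beat any
    # constant mean at the same shape
    sat = -gamma_dist.logpdf(y, a=2.0, scale=y / 2.0).sum()
    assert sat <= base


def test_infeasible_mean_is_infinite():
    ds = toy_dataset([1.0, 2.0], times=[0.0, 100.0])
    assert gamma_negloglik(ds, "quadratic", QuadraticParams(1.0, -1.0, 0.0), 2.0) == np.inf


# ----------------------------------------------------------------------- fits

def test_null_fit_is_sample_mean():
    fit = fit_curve(toy_dataset([1.0, 2.0, 3.0]), "null")
    assert float(fit.params) == pytest.approx(2.0, abs=1e-10)
    assert fit.k == 2 and fit.resid_df == 2


def test_near_noiseless_logistic_recovery():
    """At shape 1e4 the data sit on the curve; parameters return within 1%."""
    cfg = SimConfig(
        n_shot=0, n_baseline=0, n_trapped=200, n_female=100, n_male=100,
        trapped_time_window=(0.5, 210.0),
        curve=LogisticParams(45.0, 0.12, 25.0), trapped_shape=1e4, seed=5,
    )
    fit = fit_curve(simulate_dataset(cfg), "logistic")
    assert fit.converged
    assert fit.params.a == pytest.approx(45.0, rel=0.01)
    assert fit.params.b == pytest.approx(0.12, rel=0.01)
    assert fit.params.x0 == pytest.approx(25.0, rel=0.01)


def test_fit_bookkeeping_on_study_sized_data(default_ds):
    fit = fit_curve(default_ds, "logistic")
    assert fit.k == 4                       # a, b, x0 + gamma shape
    assert fit.resid_df == len(default_ds) - 3


def test_optimum_matches_independent_negloglik(default_ds):
    """Optimizer-reported log-likelihood equals the density summation at
    its own parameters (oracle equivalence)."""
    for model in ("null", "logistic", "quadratic"):
        fit = fit_curve(default_ds, model)
        assert -fit.log_lik == pytest.approx(
            gamma_negloglik(default_ds, model, fit.params, fit.shape), abs=1e-6)


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_logistic_never_beaten_by_null(seed):
    cfg = dataclasses.replace(SimConfig(), seed=seed)
    ds = simulate_dataset(cfg)
    assert fit_curve(ds, "logistic").log_lik >= fit_curve(ds, "null").log_lik - 1e-6


def test_quadratic_fit_matches_identity_link_glm(default_ds):
    """Independent route: the gamma quadratic ML fit coincides with an
    identity-link gamma GLM on (1, t, t^2)."""
    fit = fit_curve(default_ds, "quadratic")
    t = default_ds.time_array()
    X = np.column_stack([np.ones_like(t), t, t * t])
    res = sm.GLM(default_ds.cort_array(), X,
                 family=sm.families.Gamma(sm.families.links.Identity())).fit()
    assert fit.params.as_array() == pytest.approx(np.asarray(res.params), rel=1e-4)


def test_degenerate_inputs_raise():
    from cortstress import CurveFitError
    flat_times = toy_dataset([1.0, 2.0, 3.0, 4.0, 5.0], times=[7.0] * 5)
    with pytest.raises(CurveFitError, match="variation"):
        fit_curve(flat_times, "logistic")


# ---------------------------------------------------------------- predictions

def test_zero_covariance_collapses_band(default_ds):
    fit = fit_curve(default_ds, "logistic")
    fit.cov = np.zeros_like(fit.cov)
    (band,) = predict_with_ci(fit, [30.0])
    assert band.lo95 == band.mean == band.hi95


def test_band_is_finite_and_mean_monotone(default_ds):
    fit = fit_curve(default_ds, "logistic")
    bands = predict_with_ci(fit, [fit.params.x0, fit.params.x0 + 500.0])
    for b in bands:
        assert np.isfinite(b.mean) and np.isfinite(b.lo95) and np.isfinite(b.hi95)
        assert 0.0 <= b.lo95 <= b.mean <= b.hi95
    assert bands[0].mean <= bands[1].mean


def test_singular_covariance_marks_band_unavailable(default_ds):
    fit = fit_curve(default_ds, "logistic")
    fit.cov = None
    (band,) = predict_with_ci(fit, [30.0])
    assert band.lo95 is None and band.hi95 is None
    assert np.isfinite(band.mean)


def test_delta_band_tracks_parametric_bootstrap():
    """Delta-method widths within 25% of bootstrap widths at interior times."""
    cfg = SimConfig(
        n_shot=0, n_baseline=0, n_trapped=63, n_female=30, n_male=33,
        trapped_time_window=(0.5, 210.0),
        curve=LogisticParams(45.0, 0.12, 25.0), trapped_shape=6.0, seed=5,
    )
    fit = fit_curve(simulate_dataset(cfg), "logistic")
    times = [25.0, 50.0, 100.0]
    boot = parametric_bootstrap_band(fit, times, n_boot=400, seed=1)
    delta = predict_with_ci(fit, times)
    for row, d in zip(boot, delta):
        boot_w = row[2] - row[1]
        delta_w = d.hi95 - d.lo95
        assert delta_w == pytest.approx(boot_w, rel=0.25)


# ------------------------------------------------------------ sex-specific

def test_sex_fits_never_fall_below_shared_fit(default_ds):
    pooled = fit_sex_logistic(default_ds, frozenset())
    for varying in ({"a"}, {"b"}, {"x0"}, {"a", "b"}, {"a", "x0"},
                    {"b", "x0"}, {"a", "b", "x0"}):
        fit = fit_sex_logistic(default_ds, varying, pooled=pooled)
        assert fit.log_lik >= pooled.log_lik - 1e-6
        assert fit.k == 4 + len(varying)
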