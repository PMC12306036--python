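"""RW2 structure matrices, PC priors, the sampler, and forecasting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import apcsmooth as m
from apcsmooth.grid import APCDataset, ModelFamily, build_design
from apcsmooth.rw2 import (
    BETA_PREC,
    PCPrior,
    RW2Component,
    SamplerConfig,
    conditional_posterior,
    default_priors,
    fit_bayes,
    forecast_rw2,
    log_pc_prior_tau,
    log_prior_rw2,
    pc_prior_rate,
    rw2_conditional_forecast,
    rw2_structure,
    second_difference_matrix,
    summarize_posterior,
)

FAST = SamplerConfig(iterations=1_500, burn_in=400, thin=2, seed=11)


# ----------------------------------------------------------------- structure

def test_structure_matrix_stencils():
    R = rw2_structure(5).toarray()
    np.testing.assert_allclose(R[2], [1, -4, 6, -4, 1])
    np.testing.assert_allclose(R[0], [1, -2, 1, 0, 0])
    np.testing.assert_allclose(R[1], [-2, 5, -4, 1, 0])
    np.testing.assert_allclose(rw2_structure(3).toarray(),
                               [[1, -2, 1], [-2, 4, -2], [1, -2, 1]])


@pytest.mark.parametrize("n", [3, 5, 12, 30])
def test_structure_matrix_identities(n):
    R = rw2_structure(n).toarray()
    D = second_difference_matrix(n).toarray()
    np.testing.assert_allclose(R, D.T @ D)
    t = np.arange(1, n + 1, dtype=float)
    np.testing.assert_allclose(R @ np.ones(n), 0, atol=1e-12)
    np.testing.assert_allclose(R @ t, 0, atol=1e-12)
    assert np.linalg.matrix_rank(R) == n - 2


def test_structure_matrix_rejects_tiny_fields():
    with pytest.raises(ValueError):
        rw2_structure(2)


def test_rw1_structure_for_completeness():
    R = rw2_structure(4, order=1).toarray()
    np.testing.assert_allclose(R @ np.ones(4), 0, atol=1e-12)
    assert np.linalg.matrix_rank(R) == 3


# ------------------------------------------------------------------ PC prior

def test_pc_prior_rate_examples():
    assert pc_prior_rate(1.0, 0.01) == pytest.approx(-np.log(0.01), rel=1e-12)
    assert pc_prior_rate(-np.log(0.3), 0.3) == pytest.approx(1.0, rel=1e-12)
    with pytest.raises(ValueError):
        pc_prior_rate(-1.0, 0.01)
    with pytest.raises(ValueError):
        pc_prior_rate(1.0, 1.5)


def test_pc_prior_tail_calibration():
    """sigma ~ Exp(kappa) gives empirical P(sigma > U) = alpha within MC
    error (1e6 draws)."""
    U, alpha = 3.0, 0.01
    kappa = pc_prior_rate(U, alpha)
    rng = np.random.default_rng(0)
    sigma = rng.exponential(1.0 / kappa, size=1_000_000)
    phat = np.mean(sigma > U)
    se = np.sqrt(alpha * (1 - alpha) / 1e6)
    assert abs(phat - alpha) < 3 * se


def test_pc_prior_density_integrates_to_exponential():
    """The tau-scale density transforms back to Exp(kappa) on sigma."""
    kappa = pc_prior_rate(1.0, 0.05)
    taus = np.logspace(-3, 5, 7)
    for tau in taus:
        sigma = tau ** -0.5
        # change of variables: pi_tau(tau) = pi_sigma(sigma) * |dsigma/dtau|
        expected = (kappa * np.exp(-kappa * sigma)) * 0.5 * tau ** -1.5
        assert log_pc_prior_tau(tau, kappa) == pytest.approx(
            np.log(expected), rel=1e-10)


# ----------------------------------------------------------------- log prior

def test_log_prior_linear_field():
    f = 2.0 + 3.0 * np.arange(6)
    for tau in (0.5, 1.0, 4.0):
        assert log_prior_rw2(f, tau) == pytest.approx(2.0 * np.log(tau))


def test_log_prior_hand_value():
    # f = (0, 0, 1), tau = 2: -(2/2)*1^2 + (1/2)*ln 2
    assert log_prior_rw2(np.array([0.0, 0.0, 1.0]), 2.0) == pytest.approx(
        -1.0 + 0.5 * np.log(2.0))


@settings(deadline=None, max_examples=50)
@given(st.integers(3, 25), st.integers(0, 1000))
def test_quadratic_form_identity(n, seed):
    """sum (second differences)^2 equals f'Rf."""
    rng = np.random.default_rng(seed)
    f = rng.standard_normal(n)
    lhs = np.sum((f[:-2] - 2 * f[1:-1] + f[2:]) ** 2)
    rhs = f @ rw2_structure(n).toarray() @ f
    assert lhs == pytest.approx(rhs, rel=1e-9, abs=1e-12)


# ------------------------------------------------------------------- sampler

def test_gaussian_posterior_matches_dense_kriging_oracle(gaussian_dataset):
    """Constrained posterior at fixed tau vs full-dimension ridge +
    conditioning-by-kriging linear algebra."""
    from scipy.linalg import solve

    ds = gaussian_dataset
    d = build_design(ds)
    taus = {"age": 3.0, "period": 8.0, "cohort": 5.0}
    fam = ModelFamily("gaussian", theta=0.04)
    eta_mean, eta_sd, fields, _, _ = conditional_posterior(ds, d, taus, fam)

    g = ds.grid
    I, J, K = g.I, g.J, g.K
    dim = 3 + I + J + K
    a, p, c = g.cell_indices()
    X = np.zeros((I * J, dim))
    X[:, :3] = d.fixed_columns(a, p, c)
    for r in range(I * J):
        X[r, 3 + a[r] - 1] = 1
        X[r, 3 + I + p[r] - 1] = 1
        X[r, 3 + I + J + c[r] - 1] = 1
    Qp = np.zeros((dim, dim))
    Qp[:3, :3] = BETA_PREC * np.eye(3)
    for tau_s, n0, nn in ((taus["age"], 3, I), (taus["period"], 3 + I, J),
                          (taus["cohort"], 3 + I + J, K)):
        Qp[n0:n0 + nn, n0:n0 + nn] = tau_s * rw2_structure(nn).toarray()
    W = 1.0 / 0.04
    H = X.T @ X * W + Qp + 1e-10 * np.eye(dim)
    mu = solve(H, X.T @ ds.counts.ravel() * W)
    A = np.zeros((6, dim))
    for i, (n0, nn) in enumerate(((3, I), (3 + I, J), (3 + I + J, K))):
        A[2 * i, n0:n0 + nn] = 1
        A[2 * i + 1, n0:n0 + nn] = np.arange(1, nn + 1)
    SA = solve(H, A.T)
    mu_c = mu - SA @ solve(A @ SA, A @ mu)
    np.testing.assert_allclose(eta_mean, X @ mu_c, atol=1e-6)
    np.testing.assert_allclose(fields["age"], mu_c[3:3 + I], atol=1e-6)


def test_sampler_respects_constraints(fixture_dataset, small_design,
                                       poisson_family):
    fit = fit_bayes(fixture_dataset, small_design, family=poisson_family,
                    config=FAST)
    for s in ("age", "period", "cohort"):
        f = fit.f_samples(s)
        t = np.arange(1, f.shape[1] + 1)
        norms = np.maximum(np.linalg.norm(f, axis=1), 1e-8)
        assert np.max(np.abs(f.sum(axis=1)) / norms) < 1e-8
        assert np.max(np.abs((f * t).sum(axis=1)) / norms) < 1e-8


def test_sampler_reproducible(fixture_dataset, small_design, poisson_family):
    cfg = SamplerConfig(iterations=600, burn_in=200, thin=1, seed=42)
    f1 = fit_bayes(fixture_dataset, small_design, family=poisson_family,
                   config=cfg)
    f2 = fit_bayes(fixture_dataset, small_design, family=poisson_family,
                   config=cfg)
    np.testing.assert_array_equal(f1.z_samples, f2.z_samples)
    np.testing.assert_array_equal(f1.tau_samples, f2.tau_samples)


def test_posterior_covers_truth_with_large_counts():
    """Simulation-based check at reduced scale: with informative Poisson
    data the posterior concentrates near the generating surface."""
    cfg = m.SimulationConfig(age_start=10, age_end=34, period_start=2000,
                             period_end=2007, fit_end=2007,
                             population=7_500_000.0)
    ds = m.aggregate_ages(m.simulate_counts(cfg, 21), 5)
    truth = m.true_aggregated_log_rate(cfg).ravel()
    d = build_design(ds)
    fit = fit_bayes(ds, d, default_priors(d), ModelFamily("poisson"), FAST)
    eta = fit.eta_samples()
    med = np.median(eta, axis=0)
    sd = np.std(eta, axis=0)
    frac = np.mean(np.abs(med - truth) <= 3 * sd)
    assert frac >= 0.95


def test_degenerate_dataset_rejected(small_design, fixture_dataset):
    empty = APCDataset(fixture_dataset.grid,
                       np.full_like(fixture_dataset.counts, np.nan),
                       fixture_dataset.exposure)
    with pytest.raises(ValueError):
        fit_bayes(empty, small_design, family=ModelFamily("poisson"),
                  config=FAST)


# ---------------------------------------------------------------- forecasting

def test_forecast_conditional_law():
    """Forecast mean continues the line through the last two nodes; the
    variance grows as tau^-1 * t(t+1)(2t+1)/6."""
    rng = np.random.default_rng(0)
    f = np.cumsum(np.cumsum(rng.standard_normal(8)))
    tau = 2.5
    mean, cov = rw2_conditional_forecast(f, tau, 4)
    for t in range(1, 5):
        assert mean[t - 1] == pytest.approx((1 + t) * f[-1] - t * f[-2])
        assert cov[t - 1, t - 1] == pytest.approx(
            t * (t + 1) * (2 * t + 1) / 6.0 / tau)


def test_forecast_zero_horizon(fixture_dataset, poisson_family):
    fit0 = forecast_rw2(fixture_dataset, 0, family=poisson_family,
                        config=FAST)
    assert fit0.dataset.grid.J == fixture_dataset.grid.J
    preds = summarize_posterior(fit0)
    assert preds.is_forecast.sum() == 0
    mean, cov = rw2_conditional_forecast(np.arange(5.0), 1.0, 0)
    assert mean.size == 0 and cov.size == 0


def test_forecast_widths_nondecreasing(fixture_dataset, poisson_family):
    fit = forecast_rw2(fixture_dataset, 3, family=poisson_family,
                       config=FAST)
    preds = summarize_posterior(fit)
    J = fixture_dataset.grid.J
    widths = [np.mean((preds.upper - preds.lower)[preds.period_idx == J + t])
              for t in (1, 2, 3)]
    assert widths[0] <= widths[1] <= widths[2]


# ----------------------------------------------------------------- summaries

def test_summarize_requires_enough_samples(fixture_dataset, small_design,
                                            poisson_family):
    cfg = SamplerConfig(iterations=260, burn_in=200, thin=2, seed=1)
    fit = fit_bayes(fixture_dataset, small_design, family=poisson_family,
                    config=cfg)
    with pytest.raises(ValueError):
        summarize_posterior(fit)


def test_quantiles_match_sort_oracle(fixture_dataset, small_design,
                                      poisson_family):
    fit = fit_bayes(fixture_dataset, small_design, family=poisson_family,
                    config=FAST)
    preds = summarize_posterior(fit)
    eta = fit.eta_samples()
    for j in (0, 7, 20):
        col = np.sort(eta[:, j])
        assert preds.lower[j] <= preds.eta[j] <= preds.upper[j]
        assert preds.eta[j] == pytest.approx(np.quantile(col, 0.5))
        assert preds.lower[j] == pytest.approx(np.quantile(col, 0.025))
        assert preds.upper[j] == pytest.approx(np.quantile(col, 0.975))


def test_component_length_validation(fixture_dataset, small_design):
    bad = default_priors(small_design)
    bad["age"] = RW2Component(n=4, prior=PCPrior())
    with pytest.raises(ValueError):
        fit_bayes(fixture_dataset, small_design, priors=bad,
                  family=ModelFamily("poisson"), config=FAST)
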