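"""Trajectory-mixture estimation: closed forms, EM behavior, selection."""

import numpy as np
import pytest

from trajmap.longdata import LongitudinalData
from trajmap.trajectory import (
    GroupTrajectoryModel,
    TrajectoryModelSpec,
    count_params,
    fit_mixture,
    prune_orders,
    prune_rule,
    select_model,
)

from conftest import make_mixture_data


@pytest.mark.parametrize(
    "k, orders, use_cov, ncov, expected",
    [
        (1, [3], False, 0, 5),       # 4 coefficients + sigma
        (3, [2, 2, 2], False, 0, 12),  # 9 + 2 + 1
        (2, [1, 1], True, 4, 10),    # 4 + 1 + 1 + 4 shared covariates
    ],
)
def test_count_params(k, orders, use_cov, ncov, expected):
    spec = TrajectoryModelSpec(
        k=k, orders=orders, use_covariates=use_cov, covariate_sharing="shared"
    )
    assert count_params(spec, ncov) == expected


def test_spec_validation():
    with pytest.raises(ValueError):
        TrajectoryModelSpec(k=2, orders=[1])
    with pytest.raises(ValueError):
        TrajectoryModelSpec(k=1, orders=[4])
    with pytest.raises(ValueError):
        TrajectoryModelSpec(k=0)


def test_k1_equals_ols_closed_form():
    """A single-component mixture collapses to pooled OLS: the maximized
    log-likelihood must equal the Gaussian OLS closed form."""
    for seed in range(5):
        rng = np.random.default_rng(seed)
        n, T = 60, 5
        t = np.tile(np.arange(T, dtype=float), (n, 1))
        y = 100 + 2 * t - 0.3 * t**2 + rng.normal(0, 3, (n, T))
        data = LongitudinalData(
            np.arange(n).astype(str), np.zeros(n).astype(str), t, y,
            np.ones((n, T), bool),
        )
        fit = fit_mixture(data, TrajectoryModelSpec(k=1, orders=[3]),
                          n_restarts=1, seed=0)
        X = np.vstack([t.ravel() ** d for d in range(4)]).T
        b = np.linalg.lstsq(X, y.ravel(), rcond=None)[0]
        ssr = float(((y.ravel() - X @ b) ** 2).sum())
        nobs = y.size
        s2 = ssr / nobs
        ll_ols = -nobs / 2 * np.log(2 * np.pi * s2) - nobs / 2
        assert fit.loglik == pytest.approx(ll_ols, abs=1e-6)
        assert np.all(fit.bpp == 1.0)


def test_k_exceeds_n_errors():
    data, _ = make_mixture_data([100.0], [1.0], n=3, seed=0)
    with pytest.raises(ValueError, match="exceeds"):
        GroupTrajectoryModel(data, TrajectoryModelSpec(k=4))


def test_em_loglik_monotone(two_group_data):
    """EM never decreases the observed-data log-likelihood."""
    data, _ = two_group_data
    fit = fit_mixture(data, TrajectoryModelSpec(k=2, orders=[0, 0]),
                      n_restarts=1, seed=0)
    diffs = np.diff(fit.em_trace)
    assert np.all(diffs >= -1e-7)


def test_bpp_rows_and_bic_identity(two_group_data):
    data, _ = two_group_data
    fit = fit_mixture(data, TrajectoryModelSpec(k=2, orders=[1, 1]),
                      n_restarts=2, seed=0)
    assert np.max(np.abs(fit.bpp.sum(axis=1) - 1)) < 1e-10
    assert abs(fit.pi.sum() - 1) < 1e-12
    n = data.n_individuals
    assert fit.bic == pytest.approx(fit.loglik - fit.n_params / 2 * np.log(n),
                                    abs=1e-9)
    assert np.all(fit.bpp >= 0)
    assert float(np.min(np.atleast_1d(fit.sigma))) > 0


def test_two_group_parameter_recovery(two_group_data):
    """Intercept-only truth at 100/150, sigma 5, pi (0.6, 0.4), N=400:
    pi within 0.05, intercepts within 1.5, almost all BPPs decisive."""
    data, _ = two_group_data
    fit = fit_mixture(data, TrajectoryModelSpec(k=2, orders=[0, 0]),
                      n_restarts=3, seed=1)
    assert fit.converged
    order = np.argsort([b[0] for b in fit.beta])
    intercepts = np.array([fit.beta[j][0] for j in order])
    pis = fit.pi[order]
    assert np.abs(pis - np.array([0.6, 0.4])).max() < 0.05
    assert np.abs(intercepts - np.array([100.0, 150.0])).max() < 1.5
    assert np.mean(fit.bpp.max(axis=1) > 0.99) > 0.95


def test_recovery_improves_with_n():
    """Estimates approach truth as N grows (200 vs 800)."""
    errs = {}
    for n in (200, 800):
        data, _ = make_mixture_data([100.0, 130.0], [0.5, 0.5], sigma=5.0,
                                    n=n, seed=5)
        fit = fit_mixture(data, TrajectoryModelSpec(k=2, orders=[0, 0]),
                          n_restarts=2, seed=2)
        ints = np.sort([b[0] for b in fit.beta])
        errs[n] = np.abs(ints - np.array([100.0, 130.0])).max()
    assert errs[800] <= errs[200] + 0.25  # allow tiny Monte-Carlo slack


def test_label_permutation_equivalence(two_group_data):
    """Relabeling subgroups leaves loglik/BIC unchanged and permutes BPP
    columns: different restarts that find the same optimum with swapped
    labels must agree up to column order."""
    data, _ = two_group_data
    spec = TrajectoryModelSpec(k=2, orders=[0, 0])
    a = fit_mixture(data, spec, n_restarts=1, seed=0)
    b = fit_mixture(data, spec, n_restarts=4, seed=123)
    assert a.loglik == pytest.approx(b.loglik, abs=1e-5)
    assert a.bic == pytest.approx(b.bic, abs=1e-5)
    oa = np.argsort([c[0] for c in a.beta])
    ob = np.argsort([c[0] for c in b.beta])
    assert np.allclose(a.bpp[:, oa], b.bpp[:, ob], atol=1e-5)


@pytest.mark.parametrize(
    "pvals, expected",
    [
        ((np.nan, 0.001, 0.20, 0.60), 1),
        ((np.nan, 0.30, 0.70, 0.90), 0),
        ((np.nan, 0.2, 0.01, 0.04), 3),
        ((np.nan, 0.06, 0.06, 0.06), 0),
    ],
)
def test_prune_rule(pvals, expected):
    assert prune_rule(np.array(pvals), 0.05) == expected


def test_prune_orders_recovers_quadratic():
    """Strong pure-quadratic curvature prunes to order 2 in most runs."""
    hits = 0
    runs = 10
    for seed in range(runs):
        rng = np.random.default_rng(100 + seed)
        n, T = 300, 6  # enough visits to separate the raw-power terms
        t = np.tile(np.arange(T, dtype=float), (n, 1))
        y = 100 + 1.0 * t + 2.0 * t**2 + rng.normal(0, 5, (n, T))
        data = LongitudinalData(
            np.arange(n).astype(str), np.zeros(n).astype(str), t, y,
            np.ones((n, T), bool),
        )
        spec = prune_orders(data, k=1, alpha=0.05, seed=seed, n_restarts=1)
        hits += spec.orders[0] == 2
    assert hits >= 0.9 * runs


def test_select_model_single_group():
    """No mixture structure: BIC penalty should favor k=1."""
    data, _ = make_mixture_data([120.0], [1.0], sigma=6.0, n=300, seed=8)
    fit = select_model(data, k_max=3, n_restarts=2, seed=0)
    assert fit.spec.k == 1


def test_select_model_three_groups():
    """Three well-separated intercept groups, N=600: k=3 recovered in most
    simulated datasets."""
    hits = 0
    runs = 8
    for seed in range(runs):
        data, _ = make_mixture_data(
            [100.0, 125.0, 150.0], [0.4, 0.35, 0.25], sigma=5.0, n=600,
            seed=200 + seed,
        )
        fit = select_model(data, k_max=4, n_restarts=2, seed=seed)
        hits += fit.spec.k == 3
    assert hits >= 0.8 * runs


def test_covariate_fit_recovers_effects():
    """Group-specific covariate coefficients approach the simulated truth."""
    data, _ = make_mixture_data([100.0, 140.0], [0.5, 0.5], sigma=5.0, n=500,
                                seed=3, covariates=True)
    spec = TrajectoryModelSpec(k=2, orders=[0, 0], use_covariates=True)
    fit = fit_mixture(data, spec, n_restarts=2, seed=0)
    assert fit.converged
    # truth: AGE slope 0.2, SEX shift 4.0 in every subgroup
    g = np.atleast_2d(fit.gamma)
    assert np.abs(g[:, 0] - 0.2).max() < 0.1
    assert np.abs(g[:, 1] - 4.0).max() < 2.0


def test_missing_visits_supported():
    data, _ = make_mixture_data([100.0, 150.0], [0.5, 0.5], n=200, seed=4)
    mask = data.mask.copy()
    mask[::7, 1] = False  # drop some middle visits
    data2 = LongitudinalData(
        data.individual_ids, data.family_ids, data.times, data.values, mask
    )
    fit = fit_mixture(data2, TrajectoryModelSpec(k=2, orders=[0, 0]),
                      n_restarts=2, seed=0)
    assert fit.converged
    assert np.max(np.abs(fit.bpp.sum(axis=1) - 1)) < 1e-10
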