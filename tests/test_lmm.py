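"""Trajectory mixed model: likelihood oracles, fitting, RMSE, comparison."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal, norm

from csfrisk.cohort import CohortConfig, LmmTruth, generate_trajectories
from csfrisk.lmm import LmmParams, LmmSpec, compare_models, fit_lmm, lmm_loglik, rmse


def _visits(records):
    return pd.DataFrame(records, columns=["subject_id", "time", "zmmse"])


def _two_group_spec(subjects_a, subjects_b):
    groups = {s: 0 for s in subjects_a} | {s: 1 for s in subjects_b}
    return LmmSpec(groups=groups)


def test_single_visit_standard_normal_density():
    """One subject, one visit, unit residual variance, zero residual:
    the log-likelihood is the standard normal log-density at the mean."""
    vis = _visits([("a", 0.0, -1.3), ("b", 0.0, -1.7)])
    spec = _two_group_spec(["a"], ["b"])
    params = LmmParams(
        beta=np.array([-1.3, 0.0, -0.4, 0.0]),
        var_u0=0.0, var_u1=0.0, cov_u01=0.0, rho=0.0, var_e=1.0,
    )
    # subject b: residual -1.7 - (-1.3 - 0.4) = 0 as well
    assert lmm_loglik(params, vis, spec) == pytest.approx(2 * (-0.5 * np.log(2 * np.pi)))


def test_independent_residual_closed_form(rng):
    """With no random effects and rho = 0 the likelihood is a sum of
    independent Gaussian log-densities."""
    subjects = [f"s{i}" for i in range(6)]
    spec = _two_group_spec(subjects[:3], subjects[3:])
    rows = []
    for s in subjects:
        for t in range(4):
            rows.append((s, float(t), float(rng.normal(-1.0, 0.6))))
    vis = _visits(rows)
    beta = np.array([-1.1, -0.05, -0.3, -0.2])
    params = LmmParams(beta=beta, var_u0=0.0, var_u1=0.0, cov_u01=0.0, rho=0.0, var_e=0.36)
    groups = dict(spec.groups)
    expected = 0.0
    for s, t, z in rows:
        mu = beta[0] + beta[1] * t + beta[2] * groups[s] + beta[3] * t * groups[s]
        expected += norm.logpdf(z, loc=mu, scale=0.6)
    assert lmm_loglik(params, vis, spec) == pytest.approx(expected, rel=1e-9)


@pytest.mark.parametrize("residual_correlation", ["order", "continuous"])
def test_loglik_matches_dense_mvn_oracle(rng, residual_correlation):
    """Structured-covariance likelihood equals a naive dense
    multivariate-normal evaluation on irregular small data."""
    subjects = [f"s{i}" for i in range(8)]
    groups = {s: int(i >= 4) for i, s in enumerate(subjects)}
    spec = LmmSpec(groups=groups, residual_correlation=residual_correlation)
    rows, times_by_subject = [], {}
    for i, s in enumerate(subjects):
        extra = np.sort(rng.uniform(0.5, 6.0, size=rng.integers(0, 4)))
        times = np.concatenate([[0.0], np.round(extra, 2)])
        times_by_subject[s] = times
        for t in times:
            rows.append((s, float(t), float(rng.normal(-1.0, 1.0))))
    vis = _visits(rows)
    params = LmmParams(
        beta=np.array([-1.2, -0.08, -0.35, -0.3]),
        var_u0=0.8, var_u1=0.04, cov_u01=-0.05, rho=0.35, var_e=0.3,
    )
    g = np.array([[0.8, -0.05], [-0.05, 0.04]])
    expected = 0.0
    df = vis.set_index("subject_id")
    for s in subjects:
        t = times_by_subject[s]
        y = df.loc[[s], "zmmse"].to_numpy()
        gi = groups[s]
        x = np.column_stack([np.ones_like(t), t, np.full_like(t, gi), t * gi])
        z = np.column_stack([np.ones_like(t), t])
        if residual_correlation == "order":
            lag = np.abs(np.subtract.outer(np.arange(t.size), np.arange(t.size)))
        else:
            lag = np.abs(np.subtract.outer(t, t))
        v = z @ g @ z.T + 0.3 * 0.35**lag
        expected += multivariate_normal.logpdf(y, mean=x @ params.beta, cov=v)
    assert lmm_loglik(params, vis, spec) == pytest.approx(expected, rel=1e-9)


def test_invalid_covariance_parameters_rejected():
    vis = _visits([("a", 0.0, 0.0), ("b", 0.0, 0.0)])
    spec = _two_group_spec(["a"], ["b"])
    bad_rho = LmmParams(np.zeros(4), 1.0, 1.0, 0.0, 1.0, 1.0)
    with pytest.raises(ValueError, match="rho|correlation"):
        lmm_loglik(bad_rho, vis, spec)
    bad_g = LmmParams(np.zeros(4), 1.0, 1.0, 2.0, 0.0, 1.0)
    with pytest.raises(ValueError, match="semi-definite"):
        lmm_loglik(bad_g, vis, spec)


def test_baseline_and_ordering_validation():
    spec = _two_group_spec(["a"], ["b"])
    no_baseline = _visits([("a", 1.0, 0.0), ("b", 0.0, 0.0)])
    with pytest.raises(ValueError, match="baseline"):
        lmm_loglik(LmmParams(np.zeros(4), 0, 0, 0, 0, 1), no_baseline, spec)


def test_fit_matches_gls_and_ols_when_variance_components_vanish(rng):
    """Data with iid residuals only: the ML fixed effects equal the
    closed-form GLS solution at the fitted covariance (dense per-subject
    oracle, 1e-4), and approach OLS since the estimated variance
    components are near zero."""
    groups = pd.Series(
        [0] * 40 + [1] * 40, index=[f"s{i}" for i in range(80)]
    )
    cfg = CohortConfig(
        lmm_truth=LmmTruth(var_u0=0.0, var_u1=0.0, rho=0.0, var_e=0.04)
    )
    vis = generate_trajectories(groups, cfg, rng)
    fit = fit_lmm(vis, LmmSpec(groups=groups.to_dict()))
    # dense GLS oracle at the fitted covariance parameters
    g = np.array(
        [
            [fit.params.var_u0, fit.params.cov_u01],
            [fit.params.cov_u01, fit.params.var_u1],
        ]
    )
    xtvix = np.zeros((4, 4))
    xtviy = np.zeros(4)
    for sid, grp in vis.groupby("subject_id"):
        t = grp["time"].to_numpy()
        y = grp["zmmse"].to_numpy()
        gi = groups[sid]
        x = np.column_stack([np.ones_like(t), t, np.full_like(t, float(gi)), t * gi])
        z = np.column_stack([np.ones_like(t), t])
        lag = np.abs(np.subtract.outer(np.arange(t.size), np.arange(t.size)))
        v = z @ g @ z.T + fit.params.var_e * fit.params.rho**lag
        vinv = np.linalg.inv(v)
        xtvix += x.T @ vinv @ x
        xtviy += x.T @ vinv @ y
    beta_gls = np.linalg.solve(xtvix, xtviy)
    assert fit.params.beta == pytest.approx(beta_gls, abs=1e-4)
    x_all = np.column_stack(
        [
            np.ones(len(vis)),
            vis["time"],
            vis["subject_id"].map(groups),
            vis["time"] * vis["subject_id"].map(groups),
        ]
    )
    beta_ols, *_ = np.linalg.lstsq(x_all, vis["zmmse"].to_numpy(), rcond=None)
    assert fit.params.beta == pytest.approx(beta_ols, abs=5e-3)


def test_time_unit_consistency(small_visits, binary_groups):
    """Fitting with time in months and rescaling the time slopes by 12
    reproduces the fit in years (within optimizer tolerance)."""
    spec = LmmSpec(groups=binary_groups.to_dict())
    fit_y = fit_lmm(small_visits, spec)
    months = small_visits.assign(time=small_visits["time"] * 12.0)
    fit_m = fit_lmm(months, LmmSpec(groups=binary_groups.to_dict()))
    beta_m = fit_m.params.beta
    assert beta_m[0] == pytest.approx(fit_y.params.beta[0], abs=2e-3)
    assert beta_m[1] * 12 == pytest.approx(fit_y.params.beta[1], abs=2e-3)
    assert beta_m[2] == pytest.approx(fit_y.params.beta[2], abs=5e-3)
    assert beta_m[3] * 12 == pytest.approx(fit_y.params.beta[3], abs=2e-3)


def test_information_criteria_identities(small_visits, binary_groups):
    fit = fit_lmm(small_visits, LmmSpec(groups=binary_groups.to_dict()))
    assert fit.converged
    assert fit.n_params == 4 + 4  # 4 fixed effects + 4 covariance parameters
    assert fit.aic == pytest.approx(-2 * fit.loglik + 2 * fit.n_params)
    assert fit.bic == pytest.approx(-2 * fit.loglik + fit.n_params * np.log(fit.n_obs))


def test_rmse_trivial_cases():
    vis = _visits([("a", 0.0, -1.3), ("b", 0.0, -1.7)])
    spec = _two_group_spec(["a"], ["b"])
    params = LmmParams(np.array([-1.3, 0.0, -0.4, 0.0]), 0.0, 0.0, 0.0, 0.0, 1.0)
    fit = fit_lmm(
        _visits([("a", 0.0, -1.3), ("a", 1.0, -1.4), ("b", 0.0, -1.7), ("b", 1.0, -1.9)]),
        spec,
    )
    # perfect predictions -> 0
    fit_perfect = fit
    fit_perfect.params = params
    assert rmse(fit_perfect, vis, mode="marginal") == pytest.approx(0.0)
    # single observation with residual r -> |r|
    off = _visits([("a", 0.0, -1.3 + 0.25), ("b", 0.0, -1.7)])
    assert rmse(fit_perfect, off, mode="marginal") == pytest.approx(0.25 / np.sqrt(2))


def test_conditional_rmse_beats_marginal_with_random_intercepts(rng):
    """When most variance sits in random intercepts, subject-level BLUPs
    must shrink the prediction error."""
    wins = 0
    groups = pd.Series([0] * 30 + [1] * 30, index=[f"s{i}" for i in range(60)])
    cfg = CohortConfig(lmm_truth=LmmTruth(var_u0=1.5, var_u1=0.0, rho=0.0, var_e=0.1))
    for _ in range(20):
        vis = generate_trajectories(groups, cfg, rng)
        fit = fit_lmm(vis, LmmSpec(groups=groups.to_dict()))
        wins += fit.rmse_conditional < fit.rmse_marginal
    assert wins == 20


def test_compare_models_identity_and_data_guard(small_visits, binary_groups):
    spec = LmmSpec(groups=binary_groups.to_dict())
    fit1 = fit_lmm(small_visits, spec)
    fit2 = fit_lmm(small_visits, LmmSpec(groups=binary_groups.to_dict()))
    table = compare_models({"a": fit1, "b": fit2})
    assert table.loc[0, "aic"] == pytest.approx(table.loc[1, "aic"])
    other = small_visits.assign(zmmse=small_visits["zmmse"] + 0.1)
    fit3 = fit_lmm(other, spec)
    with pytest.raises(ValueError, match="different"):
        compare_models({"a": fit1, "c": fit3})


def test_binary_model_preferred_for_binary_effect(rng):
    """Data generated with a purely binary group effect: the binary
    grouping should beat a finer 4-level grouping on AIC in most
    replicates (the finer model spends parameters on null contrasts)."""
    subjects = [f"s{i}" for i in range(120)]
    binary = pd.Series([0] * 60 + [1] * 60, index=subjects)
    fine = pd.Series([0] * 30 + [1] * 30 + [2] * 30 + [3] * 30, index=subjects)
    # fine levels {0,1} are truly reference, {2,3} truly pathological
    cfg = CohortConfig()
    wins = 0
    n_rep = 10
    for _ in range(n_rep):
        vis = generate_trajectories(binary, cfg, rng)
        fb = fit_lmm(vis, LmmSpec(groups=binary.to_dict()))
        ff = fit_lmm(vis, LmmSpec(groups=fine.to_dict()))
        table = compare_models({"binary": fb, "fine": ff})
        wins += table.loc[0, "model"] == "binary"
    assert wins >= 8
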