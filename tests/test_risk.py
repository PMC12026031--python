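"""Cox calibration, ROC/AUC, DeLong comparison, diagnostic tables."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from csfrisk.risk import (
    delong_compare,
    diagnostic_table,
    fit_cox,
    predict_event_probability,
    roc_auc,
    CoxFit,
)

SIX_SUBJECTS = pd.DataFrame(
    {
        "subject_id": [f"x{i}" for i in range(6)],
        "event": [1, 0, 1, 1, 0, 1],
        "time": [2.0, 3.0, 1.0, 4.0, 2.5, 5.0],
    }
)
SIX_COVARIATE = pd.Series(
    [0.0, 1.0, 2.0, 0.5, 1.5, 2.5], index=SIX_SUBJECTS["subject_id"]
)


def _partial_loglik(beta, x, time, event):
    """Breslow partial log-likelihood by direct enumeration."""
    ll = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        for i in np.where((time == t) & (event == 1))[0]:
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[at_risk])))
    return ll


def test_cox_beta_matches_grid_search_oracle():
    fit = fit_cox(SIX_SUBJECTS, SIX_COVARIATE)
    x = SIX_COVARIATE.to_numpy()
    t = SIX_SUBJECTS["time"].to_numpy()
    e = SIX_SUBJECTS["event"].to_numpy()
    grid = np.linspace(-3, 3, 60001)
    best = grid[np.argmax([_partial_loglik(b, x, t, e) for b in grid])]
    assert fit.beta == pytest.approx(best, abs=1e-4)


def test_cox_scale_equivariance():
    fit1 = fit_cox(SIX_SUBJECTS, SIX_COVARIATE)
    fit2 = fit_cox(SIX_SUBJECTS, 2.0 * SIX_COVARIATE)
    assert fit2.beta == pytest.approx(fit1.beta / 2.0, rel=1e-5)


def test_cox_null_recovery(rng):
    """Covariate independent of event times: beta within 2 SE of zero in
    at least 44/50 seeded replicates (~nominal 95% coverage)."""
    hits = 0
    for _ in range(50):
        n = 150
        time = rng.exponential(5.0, n)
        cens = rng.uniform(1, 10, n)
        event = (time <= cens).astype(int)
        obs = np.minimum(time, cens)
        out = pd.DataFrame(
            {"subject_id": [f"s{i}" for i in range(n)], "event": event, "time": obs}
        )
        cov = pd.Series(rng.normal(size=n), index=out["subject_id"])
        fit = fit_cox(out, cov)
        hits += abs(fit.beta) < 2 * fit.se
    assert hits >= 44


def test_cox_preconditions():
    no_events = SIX_SUBJECTS.assign(event=0)
    with pytest.raises(ValueError, match="event"):
        fit_cox(no_events, SIX_COVARIATE)
    const = pd.Series(1.0, index=SIX_SUBJECTS["subject_id"])
    with pytest.raises(ValueError, match="constant"):
        fit_cox(SIX_SUBJECTS, const)


def test_cox_separation_flagged():
    """All events in the high-score half: the partial likelihood is
    maximized at infinity and must be flagged, not silently returned."""
    out = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(8)],
            "event": [1, 1, 1, 1, 0, 0, 0, 0],
            "time": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0],
        }
    )
    cov = pd.Series([5.0] * 4 + [0.0] * 4, index=out["subject_id"])
    fit = fit_cox(out, cov)
    assert fit.diagnostic is not None


def test_event_probability_closed_form():
    fit = CoxFit(
        beta=np.log(2.0), se=0.1,
        baseline_times=np.array([1.0, 5.0]),
        baseline_cumhaz=np.array([0.2, 0.5]),
        horizon=10.0,
    )
    with pytest.warns(UserWarning, match="horizon"):
        p = predict_event_probability(fit, 1.0)
    assert p == pytest.approx(1 - np.exp(-0.5 * 2.0))  # ~0.6321
    fit0 = CoxFit(
        beta=0.0, se=0.1,
        baseline_times=np.array([1.0]), baseline_cumhaz=np.array([0.3]), horizon=1.0,
    )
    assert predict_event_probability(fit0, -3.0) == predict_event_probability(fit0, 7.0)
    empty = CoxFit(
        beta=1.0, se=0.1, baseline_times=np.array([]), baseline_cumhaz=np.array([]),
        horizon=1.0,
    )
    assert predict_event_probability(empty, 2.0) == 0.0


def test_monotone_transform_invariance_of_cox_roc(rng):
    """With beta > 0 the Cox probability transform is strictly monotone,
    so the AUC of the predicted probabilities equals the AUC of the raw
    score exactly: the Cox step calibrates, it does not re-rank."""
    n = 120
    score = rng.integers(0, 5, n).astype(float)
    rate = 0.05 * np.exp(0.8 * score)
    time = rng.exponential(1.0 / rate)
    cens = rng.uniform(1, 12, n)
    event = (time <= cens).astype(int)
    out = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "event": event,
            "time": np.minimum(time, cens),
        }
    )
    cov = pd.Series(score, index=out["subject_id"])
    fit = fit_cox(out, cov)
    assert fit.beta > 0
    probs = np.array([predict_event_probability(fit, s) for s in score])
    assert roc_auc(probs, event) == roc_auc(score, event)


def test_auc_matches_all_pairs_oracle(rng):
    for _ in range(50):
        n = int(rng.integers(10, 40))
        scores = np.round(rng.normal(size=n), 1)  # ties likely
        labels = (rng.random(n) < 0.4).astype(int)
        if labels.min() == labels.max():
            continue
        x = scores[labels == 1]
        y = scores[labels == 0]
        oracle = np.mean(
            (x[:, None] > y[None, :]) + 0.5 * (x[:, None] == y[None, :])
        )
        assert roc_auc(scores, labels) == pytest.approx(oracle)
    assert roc_auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
    assert roc_auc([1, 1, 1, 1], [0, 0, 1, 1]) == 0.5


def test_auc_single_class_rejected():
    with pytest.raises(ValueError):
        roc_auc([1, 2, 3], [1, 1, 1])


def test_delong_identical_scores_degenerate(rng):
    s = rng.normal(size=50)
    labels = (rng.random(50) < 0.5).astype(int)
    cmp = delong_compare(s, s, labels)
    assert cmp.degenerate
    assert cmp.auc_a == cmp.auc_b


def test_delong_components_match_direct_enumeration():
    """Variance/covariance equal the structural components computed by
    explicit double loops on a small fixed dataset."""
    a = np.array([0.1, 0.4, 0.35, 0.8, 0.7, 0.2, 0.55])
    b = np.array([0.3, 0.2, 0.5, 0.9, 0.4, 0.1, 0.6])
    labels = np.array([0, 0, 1, 1, 1, 0, 1])
    cmp = delong_compare(a, b, labels)

    def components(scores):
        x = scores[labels == 1]
        y = scores[labels == 0]
        m, n = len(x), len(y)
        v10 = np.array(
            [np.mean([(xi > yj) + 0.5 * (xi == yj) for yj in y]) for xi in x]
        )
        v01 = np.array(
            [np.mean([(xi > yj) + 0.5 * (xi == yj) for xi in x]) for yj in y]
        )
        return v10, v01

    v10a, v01a = components(a)
    v10b, v01b = components(b)
    m, n = len(v10a), len(v01a)
    var_a = np.var(v10a, ddof=1) / m + np.var(v01a, ddof=1) / n
    cov = np.cov(v10a, v10b, ddof=1)[0, 1] / m + np.cov(v01a, v01b, ddof=1)[0, 1] / n
    assert cmp.var_a == pytest.approx(var_a)
    assert cmp.cov_ab == pytest.approx(cov)
    expected_z = (cmp.auc_a - cmp.auc_b) / np.sqrt(cmp.var_a + cmp.var_b - 2 * cov)
    assert cmp.z == pytest.approx(expected_z)
    assert cmp.p == pytest.approx(2 * norm.sf(abs(expected_z)))


def test_diagnostic_table_arithmetic():
    dt = diagnostic_table(
        np.repeat([1, 1, 0, 0], [40, 20, 10, 80]),
        np.repeat([1, 0, 1, 0], [40, 20, 10, 80]),
    )
    assert (dt.tp, dt.fp, dt.fn, dt.tn) == (40, 20, 10, 80)
    assert dt.odds_ratio == pytest.approx(16.0)
    assert dt.sensitivity == pytest.approx(0.8)
    assert dt.specificity == pytest.approx(0.8)
    assert dt.lr_pos == pytest.approx(4.0)
    assert dt.lr_neg == pytest.approx(0.25)
    se = np.sqrt(1 / 40 + 1 / 20 + 1 / 10 + 1 / 80)
    assert dt.or_ci_low == pytest.approx(16.0 * np.exp(-1.96 * se))
    assert dt.or_ci_high == pytest.approx(16.0 * np.exp(1.96 * se))
    assert not dt.corrected


def test_diagnostic_table_zero_cell_corrected():
    dt = diagnostic_table(
        np.repeat([1, 0], [30, 70]), np.repeat([1, 0], [30, 70])
    )  # perfect classifier: fp = fn = 0
    assert dt.corrected
    assert np.isfinite(dt.odds_ratio)
    assert dt.odds_ratio == pytest.approx((30.5 * 70.5) / (0.5 * 0.5))


def test_diagnostic_table_random_matches_formula_oracle(rng):
    for _ in range(50):
        cells = rng.integers(1, 60, size=4)
        tp, fp, fn, tn = (int(c) for c in cells)
        pred = np.repeat([1, 1, 0, 0], [tp, fp, fn, tn])
        ev = np.repeat([1, 0, 1, 0], [tp, fp, fn, tn])
        dt = diagnostic_table(pred, ev)
        assert dt.odds_ratio == pytest.approx((tp * tn) / (fp * fn))
        width = 1.96 * np.sqrt(1 / tp + 1 / fp + 1 / fn + 1 / tn)
        assert np.log(dt.or_ci_high) - np.log(dt.odds_ratio) == pytest.approx(width)


def test_diagnostic_table_empty_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        diagnostic_table(np.array([1, 1, 0]), np.array([0, 0, 0]))
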