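"""Dementia-risk discrimination: Cox calibration, ROC/AUC, paired DeLong
comparison, and Youden-style diagnostic 2x2 summaries.

Because follow-up lengths vary, raw scores are first converted into
time-dependent conversion probabilities through a Cox proportional
hazards model (Breslow ties and baseline), evaluated at a fixed horizon
(default 10 years).  Those probabilities are the ROC test variables.
Since the Cox transform is strictly monotone in the score whenever
beta > 0, this step calibrates rather than re-ranks: the AUC equals the
AUC of the raw score.  Correlated AUCs from the same subjects are
compared with the structural-components estimator of DeLong et al.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sksurv.linear_model import CoxPHSurvivalAnalysis
from sksurv.util import Surv

__all__ = [
    "OutcomeRecord",
    "CoxFit",
    "RiskComparison",
    "DiagnosticTable",
    "fit_cox",
    "predict_event_probability",
    "roc_auc",
    "delong_compare",
    "diagnostic_table",
]


@dataclass(frozen=True)
class OutcomeRecord:
    """Time-to-dementia outcome: event=True is conversion, otherwise the
    subject is censored at ``time`` (years from baseline)."""

    subject_id: str
    event: bool
    time: float

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(
                f"subject {self.subject_id!r}: follow-up time must be positive"
            )


@dataclass
class CoxFit:
    """Cox proportional-hazards fit with a Breslow baseline.

    ``beta`` is the log hazard ratio per unit of the score;
    ``baseline_times``/``baseline_cumhaz`` tabulate the step-function
    baseline cumulative hazard; ``diagnostic`` flags degenerate fits
    (e.g. monotone separation driving |beta| to infinity).
    """

    beta: float
    se: float
    baseline_times: np.ndarray
    baseline_cumhaz: np.ndarray
    horizon: float = 10.0
    diagnostic: str | None = None

    def cumulative_hazard_at(self, t: float) -> float:
        if self.baseline_times.size == 0:
            return 0.0
        if t > self.baseline_times[-1]:
            warnings.warn(
                f"horizon {t} y exceeds the last observed time "
                f"{self.baseline_times[-1]:.3g} y; using the last "
                "cumulative-hazard step",
                stacklevel=2,
            )
            return float(self.baseline_cumhaz[-1])
        idx = np.searchsorted(self.baseline_times, t, side="right") - 1
        return float(self.baseline_cumhaz[idx]) if idx >= 0 else 0.0


@dataclass(frozen=True)
class RiskComparison:
    """Paired DeLong comparison of two correlated AUCs."""

    auc_a: float
    auc_b: float
    var_a: float
    var_b: float
    cov_ab: float
    z: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class DiagnosticTable:
    """2x2 classification summary with likelihood ratios and the
    diagnostic odds ratio (Woolf logit CI; Haldane-Anscombe 0.5
    correction when a cell is empty, flagged via ``corrected``)."""

    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: float
    specificity: float
    lr_pos: float
    lr_neg: float
    odds_ratio: float
    or_ci_low: float
    or_ci_high: float
    corrected: bool


_SEPARATION_BETA = 20.0


def fit_cox(outcomes: pd.DataFrame, covariate: pd.Series, horizon: float = 10.0) -> CoxFit:
    """Fit a one-covariate Cox model (Breslow tie handling and baseline).

    ``outcomes`` needs columns subject_id, event (0/1), time (years);
    ``covariate`` is indexed by subject_id.
    """
    df = outcomes.set_index("subject_id") if "subject_id" in outcomes.columns else outcomes
    x = covariate.reindex(df.index)
    if x.isna().any():
        raise ValueError(
            f"missing covariate for subjects: {list(x.index[x.isna()])[:5]}"
        )
    event = df["event"].astype(bool).to_numpy()
    time = df["time"].to_numpy(float)
    if not (time > 0).all():
        raise ValueError("all follow-up times must be positive")
    if event.sum() < 1:
        raise ValueError("at least one conversion event is required")
    xv = x.to_numpy(float)
    if np.ptp(xv) == 0:
        raise ValueError("covariate is constant; hazard ratio is unidentifiable")

    est = CoxPHSurvivalAnalysis(ties="breslow")
    y = Surv.from_arrays(event=event, time=time)
    diagnostic = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            est.fit(xv[:, None], y)
            beta = float(est.coef_[0])
            se = float(np.sqrt(np.diag(np.linalg.inv(-_cox_hessian(beta, xv, event, time)))[0]))
            bt = np.asarray(est.cum_baseline_hazard_.x, float)
            bh = np.asarray(est.cum_baseline_hazard_.y, float)
        except Exception as exc:  # optimizer blow-up under separation
            beta, se = np.sign(np.corrcoef(xv, event)[0, 1]) * np.inf, np.inf
            bt, bh = _breslow_baseline(0.0, xv, event, time)
            diagnostic = f"cox fit failed ({exc}); monotone separation suspected"
    if diagnostic is None and (
        not np.isfinite(se) or se > 50.0 * (1.0 + abs(beta))
    ):
        diagnostic = (
            f"standard error {se:.3g} is far larger than the estimate: "
            "flat partial likelihood, monotone separation suspected"
        )
    if diagnostic is None and abs(beta) > _SEPARATION_BETA:
        diagnostic = (
            f"|beta| = {abs(beta):.3g} exceeds {_SEPARATION_BETA}: "
            "monotone separation (all events on one side of the score)"
        )
    return CoxFit(
        beta=beta,
        se=se,
        baseline_times=bt,
        baseline_cumhaz=bh,
        horizon=horizon,
        diagnostic=diagnostic,
    )


def _cox_hessian(beta: float, x: np.ndarray, event: np.ndarray, time: np.ndarray) -> np.ndarray:
    """Second derivative of the Breslow partial log-likelihood (1 covariate)."""
    h = 0.0
    eta = np.exp(beta * x)
    for t in np.unique(time[event]):
        at_risk = time >= t
        d = int(np.sum(event & (time == t)))
        w = eta[at_risk]
        xr = x[at_risk]
        s0 = w.sum()
        s1 = float(w @ xr)
        s2 = float(w @ xr**2)
        h -= d * (s2 / s0 - (s1 / s0) ** 2)
    return np.array([[h]])


def _breslow_baseline(beta: float, x: np.ndarray, event: np.ndarray, time: np.ndarray):
    eta = np.exp(beta * x)
    times = np.unique(time[event])
    cumhaz = np.cumsum(
        [np.sum(event & (time == t)) / eta[time >= t].sum() for t in times]
    )
    return times, np.asarray(cumhaz, float)


def predict_event_probability(fit: CoxFit, covariate_value: float) -> float:
    """P(conversion by the horizon | score) = 1 - exp(-L0(h) * exp(beta*x))."""
    lam0 = fit.cumulative_hazard_at(fit.horizon)
    return float(1.0 - np.exp(-lam0 * np.exp(fit.beta * covariate_value)))


def roc_auc(scores, labels) -> float:
    """Empirical AUC (Mann-Whitney with half-credit for ties)."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present for ROC analysis")
    return float(roc_auc_score(labels, np.asarray(scores, float)))


def _delong_components(scores: np.ndarray, labels: np.ndarray):
    x = scores[labels == 1]
    y = scores[labels == 0]
    psi = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    return float(psi.mean()), psi.mean(axis=1), psi.mean(axis=0)


def delong_compare(scores_a, scores_b, labels) -> RiskComparison:
    """Paired DeLong test for the difference of two correlated AUCs.

    Both score vectors must cover the same subjects in the same order.
    A (near-)zero variance of the difference yields a degenerate
    comparison flag with NaN z and p.
    """
    a = np.asarray(scores_a, float)
    b = np.asarray(scores_b, float)
    labels = np.asarray(labels).astype(int)
    if a.shape != b.shape or a.shape != labels.shape:
        raise ValueError("scores_a, scores_b and labels must be aligned 1-d arrays")
    if len(np.unique(labels)) < 2:
        raise ValueError("both outcome classes must be present")

    auc_a, v10a, v01a = _delong_components(a, labels)
    auc_b, v10b, v01b = _delong_components(b, labels)
    m, n = v10a.size, v01a.size

    def _var(u, w):
        return float(np.var(u, ddof=1)) / u.size + float(np.var(w, ddof=1)) / w.size

    def _cov(u1, u2, w1, w2):
        c10 = float(np.cov(u1, u2, ddof=1)[0, 1]) if m > 1 else 0.0
        c01 = float(np.cov(w1, w2, ddof=1)[0, 1]) if n > 1 else 0.0
        return c10 / m + c01 / n

    var_a = _var(v10a, v01a)
    var_b = _var(v10b, v01b)
    cov_ab = _cov(v10a, v10b, v01a, v01b)
    denom = var_a + var_b - 2.0 * cov_ab
    if denom <= 1e-15:
        return RiskComparison(
            auc_a=auc_a, auc_b=auc_b, var_a=var_a, var_b=var_b, cov_ab=cov_ab,
            z=float("nan"), p=float("nan"), degenerate=True,
        )
    z = (auc_a - auc_b) / np.sqrt(denom)
    p = 2.0 * stats.norm.sf(abs(z))
    return RiskComparison(
        auc_a=auc_a, auc_b=auc_b, var_a=var_a, var_b=var_b, cov_ab=cov_ab,
        z=float(z), p=float(p), degenerate=False,
    )


def diagnostic_table(predicted_high, outcomes) -> DiagnosticTable:
    """Counts and derived diagnostics for a binary risk call vs conversion.

    Requires all four margins non-zero; an empty *cell* triggers the
    Haldane-Anscombe 0.5 correction for the OR and its CI (flagged).
    """
    pred = np.asarray(predicted_high).astype(bool)
    ev = np.asarray(outcomes).astype(bool)
    if pred.shape != ev.shape:
        raise ValueError("predicted_high and outcomes must be aligned")
    tp = int(np.sum(pred & ev))
    fp = int(np.sum(pred & ~ev))
    fn = int(np.sum(~pred & ev))
    tn = int(np.sum(~pred & ~ev))
    if tp + fn == 0 or fp + tn == 0 or tp + fp == 0 or fn + tn == 0:
        raise ValueError("degenerate 2x2 table: an entire margin is empty")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    lr_pos = sens / (1.0 - spec) if spec < 1.0 else float("inf")
    lr_neg = (1.0 - sens) / spec if spec > 0.0 else float("inf")
    corrected = 0 in (tp, fp, fn, tn)
    cells = np.array([tp, fp, fn, tn], float) + (0.5 if corrected else 0.0)
    odds_ratio = (cells[0] * cells[3]) / (cells[1] * cells[2])
    se_log = float(np.sqrt(np.sum(1.0 / cells)))
    log_or = np.log(odds_ratio)
    return DiagnosticTable(
        tp=tp, fp=fp, fn=fn, tn=tn,
        sensitivity=sens, specificity=spec,
        lr_pos=lr_pos, lr_neg=lr_neg,
        odds_ratio=float(odds_ratio),
        or_ci_low=float(np.exp(log_or - 1.96 * se_log)),
        or_ci_high=float(np.exp(log_or + 1.96 * se_log)),
        corrected=corrected,
    )
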