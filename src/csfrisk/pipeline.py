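"""End-to-end orchestration: score -> calibrate -> cross-tab -> trajectory
models -> conversion-risk comparison, with a structured report.

Mirrors the reference analysis flow on any conforming dataset: every
subject is scored with the Erlangen Score (with and without the amyloid
ratio), pTau/Abeta1-42 cut-offs are calibrated per assay panel by the
Youden index on neurochemically definite cases vs biomarker-negative
controls, trajectory mixed models are fitted for each grouping scheme
(plus SCI/MCI strata when available), and Cox-calibrated conversion
probabilities feed ROC/AUC with paired DeLong tests and diagnostic
2x2 tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .ers import ers_total, ers_without_ratio
from .io import CohortBundle, PanelConfig
from .lmm import LmmFit, LmmSpec, compare_models, fit_lmm
from .panels import AssayPanel, CsfProfile, Direction, classify_marker_zone, constellation_of
from .ptau_ratio import (
    YoudenCalibration,
    calibrate_youden_cutoff,
    classify_ratio,
    ptau_ab42_ratio,
)
from .risk import (
    delong_compare,
    diagnostic_table,
    fit_cox,
    predict_event_probability,
    roc_auc,
)

__all__ = [
    "score_profiles",
    "calibrate_panels",
    "crosstab_ers",
    "crosstab_ratio",
    "AnalysisReport",
    "run_full_comparison",
]

log = logging.getLogger("csfrisk")


def score_profiles(
    profiles: list[CsfProfile],
    panels: dict[str, AssayPanel],
    calibrations: dict[str, YoudenCalibration] | None = None,
) -> pd.DataFrame:
    """Per-subject scoring table.

    Columns: sub-scores and totals of the Erlangen Score with and
    without the ratio adjustment, the binary risk classes, the ATN(R)
    constellation label, and the pTau/Abeta1-42 ratio (classified when a
    calibration is supplied for the subject's panel)."""
    rows = []
    for p in profiles:
        panel = panels[p.panel_id]
        full = ers_total(p, panel)
        bare = ers_without_ratio(p, panel)
        row = {
            "subject_id": p.subject_id,
            "panel_id": p.panel_id,
            "constellation": constellation_of(p, panel).label,
            "amyloid_subscore": full.amyloid_subscore,
            "tau_subscore": full.tau_subscore,
            "sum_score": full.sum_score,
            "ratio_adjustment": full.ratio_adjustment,
            "ers_total": full.total,
            "ers_risk": full.risk_class,
            "ers_high": int(full.total > 1),
            "ers_noratio_total": bare.total,
            "ers_noratio_risk": bare.risk_class,
            "ptau_ab42": ptau_ab42_ratio(p),
        }
        if calibrations and p.panel_id in calibrations:
            res = classify_ratio(p, calibrations[p.panel_id])
            row["ratio_risk"] = res.risk_class
            row["ratio_high"] = int(res.risk_class == "high")
        rows.append(row)
    return pd.DataFrame(rows)


def _clearly(profile: CsfProfile, panel: AssayPanel, pathological: bool) -> bool:
    """All four markers clearly (>band) on the requested side."""
    f = panel.borderline_fraction
    a = classify_marker_zone(profile.ab42, panel.ab42_cutoff, Direction.LOW_IS_PATHOLOGICAL, f)
    t = classify_marker_zone(profile.ptau, panel.ptau_cutoff, Direction.HIGH_IS_PATHOLOGICAL, f)
    n = classify_marker_zone(profile.ttau, panel.ttau_cutoff, Direction.HIGH_IS_PATHOLOGICAL, f)
    if profile.ab40 is None:
        return False
    ratio = profile.amyloid_ratio
    want = 2 if pathological else 0
    r_ok = (
        ratio < (1 - f) * panel.amyloid_ratio_cutoff
        if pathological
        else ratio > (1 + f) * panel.amyloid_ratio_cutoff
    )
    return a.score == want and t.score == want and n.score == want and r_ok


def calibrate_panels(
    profiles: list[CsfProfile], panels: dict[str, AssayPanel]
) -> dict[str, YoudenCalibration]:
    """Youden-index pTau/Abeta1-42 cut-off per panel.

    Cases are neurochemically definite AD profiles (all four markers
    clearly pathological), controls are biomarker-negative (all clearly
    normal).  Panels without at least one of each are skipped with a
    log message."""
    out: dict[str, YoudenCalibration] = {}
    for pid, panel in panels.items():
        members = [p for p in profiles if p.panel_id == pid]
        cases = [ptau_ab42_ratio(p) for p in members if _clearly(p, panel, True)]
        controls = [ptau_ab42_ratio(p) for p in members if _clearly(p, panel, False)]
        if not cases or not controls:
            log.info(
                "panel %s: no definite cases or controls (%d/%d); skipping calibration",
                pid, len(cases), len(controls),
            )
            continue
        out[pid] = calibrate_youden_cutoff(cases, controls)
    return out


def crosstab_ers(scored: pd.DataFrame) -> pd.DataFrame:
    """Constellation x Erlangen-Score-level count table (reference
    cross-tab layout)."""
    tab = pd.crosstab(scored["ers_total"], scored["constellation"])
    tab["Total"] = tab.sum(axis=1)
    return tab


def crosstab_ratio(scored: pd.DataFrame) -> pd.DataFrame:
    if "ratio_risk" not in scored.columns:
        raise ValueError("scored table carries no ratio classification")
    tab = pd.crosstab(scored["ratio_risk"], scored["constellation"])
    tab["Total"] = tab.sum(axis=1)
    return tab


@dataclass
class AnalysisReport:
    """Structured output of the full comparison."""

    scored: pd.DataFrame
    calibrations: dict[str, YoudenCalibration]
    crosstab: pd.DataFrame
    crosstab_ratio: pd.DataFrame | None
    model_table: pd.DataFrame | None
    risk_table: pd.DataFrame | None
    delong: dict[str, dict[str, float]]
    diagnostics: dict[str, dict[str, Any]]
    flags: list[str]
    provenance: dict[str, Any]

    def to_json_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {
            "provenance": self.provenance,
            "flags": self.flags,
            "calibrations": {
                k: dataclasses.asdict(v) for k, v in self.calibrations.items()
            },
            "crosstab_ers": self.crosstab.to_dict(),
            "crosstab_ratio": (
                self.crosstab_ratio.to_dict() if self.crosstab_ratio is not None else None
            ),
            "models": (
                self.model_table.to_dict(orient="records")
                if self.model_table is not None
                else None
            ),
            "risk": (
                self.risk_table.to_dict(orient="records")
                if self.risk_table is not None
                else None
            ),
            "delong": self.delong,
            "diagnostics": self.diagnostics,
        }
        return d

    def json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2, sort_keys=True, default=str)

    @property
    def content_hash(self) -> str:
        return hashlib.sha256(self.json().encode()).hexdigest()

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.json(), encoding="utf-8")
        self.scored.to_csv(out / "scored.csv", index=False)
        self.crosstab.to_csv(out / "crosstab_ers.csv")
        if self.crosstab_ratio is not None:
            self.crosstab_ratio.to_csv(out / "crosstab_ratio.csv")
        if self.model_table is not None:
            self.model_table.to_csv(out / "model_comparison.csv", index=False)
        if self.risk_table is not None:
            self.risk_table.to_csv(out / "risk_comparison.csv", index=False)


def _config_hash(bundle: CohortBundle, horizon: float) -> str:
    h = hashlib.sha256()
    h.update(f"horizon={horizon}".encode())
    for pid in sorted(bundle.panel_config.panels):
        h.update(repr(bundle.panel_config.panels[pid]).encode())
    for df in (bundle.biomarkers, bundle.visits, bundle.outcomes):
        h.update(df.to_csv(index=False).encode())
    return h.hexdigest()


def _fit_models(
    visits: pd.DataFrame, scored: pd.DataFrame, strata: pd.Series | None
) -> tuple[pd.DataFrame | None, list[str]]:
    flags: list[str] = []
    if visits.empty:
        return None, ["trajectory stage skipped: no visit data"]
    idx = scored.set_index("subject_id")
    groupings: dict[str, tuple[pd.Series, pd.DataFrame]] = {}

    def add(label: str, series: pd.Series, vis: pd.DataFrame) -> None:
        vis = vis[vis["subject_id"].isin(series.index)]
        if series.nunique() < 2 or vis.empty:
            flags.append(f"model {label!r} skipped: fewer than two groups")
            return
        groupings[label] = (series, vis)

    add("ers_ordinal", idx["ers_total"], visits)
    add("ers_binary", idx["ers_high"], visits)
    if "ratio_high" in idx.columns:
        add("ratio_binary", idx["ratio_high"], visits)
    add("ers_noratio_ordinal", idx["ers_noratio_total"], visits)
    if strata is not None:
        for stratum in sorted(strata.dropna().unique()):
            members = strata.index[strata == stratum]
            vis = visits[visits["subject_id"].isin(members)]
            add(f"ers_binary[{stratum}]", idx.loc[idx.index.isin(members), "ers_high"], vis)
            if "ratio_high" in idx.columns:
                add(
                    f"ratio_binary[{stratum}]",
                    idx.loc[idx.index.isin(members), "ratio_high"],
                    vis,
                )

    fits: dict[str, LmmFit] = {}
    rows = []
    for label, (series, vis) in groupings.items():
        log.info("fitting trajectory model %s", label)
        fit = fit_lmm(vis, LmmSpec(groups=series.to_dict()))
        if not fit.converged:
            flags.append(f"model {label!r} did not converge: {fit.message}")
        fits[label] = fit
        rows.append(
            {
                "model": label,
                "n_obs": fit.n_obs,
                "n_subjects": fit.n_subjects,
                "n_params": fit.n_params,
                "loglik": fit.loglik,
                "aic": fit.aic,
                "bic": fit.bic,
                "rmse_marginal": fit.rmse_marginal,
                "rmse_conditional": fit.rmse_conditional,
                "converged": fit.converged,
            }
        )
    if not rows:
        return None, flags
    table = pd.DataFrame(rows).sort_values("aic", kind="stable").reset_index(drop=True)
    # sanity: models on the full visit table are mutually comparable
    full = {k: v for k, v in fits.items() if "[" not in k}
    if len(full) > 1:
        compare_models(full)
    return table, flags


def _risk_stage(
    scored: pd.DataFrame, outcomes: pd.DataFrame, horizon: float
) -> tuple[pd.DataFrame | None, dict, dict, list[str]]:
    flags: list[str] = []
    if outcomes.empty:
        return None, {}, {}, ["risk stage skipped: no outcome data"]
    idx = scored.set_index("subject_id")
    out = outcomes[outcomes["subject_id"].isin(idx.index)].copy()
    labels = out["event"].to_numpy(int)
    if len(np.unique(labels)) < 2:
        return None, {}, {}, ["risk stage skipped: single outcome class"]

    score_cols = {"ers": "ers_total", "ptau_ab42": "ptau_ab42", "ers_noratio": "ers_noratio_total"}
    rows, probs = [], {}
    for name, col in score_cols.items():
        cov = idx[col].astype(float)
        try:
            cox = fit_cox(out, cov, horizon=horizon)
        except ValueError as exc:
            flags.append(f"cox fit for {name!r} skipped: {exc}")
            continue
        if cox.diagnostic:
            flags.append(f"cox fit for {name!r}: {cox.diagnostic}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p = np.array(
                [predict_event_probability(cox, x) for x in cov.reindex(out["subject_id"])]
            )
        probs[name] = p
        rows.append(
            {
                "score": name,
                "cox_beta": cox.beta,
                "cox_se": cox.se,
                "auc": roc_auc(p, labels),
                "horizon_years": horizon,
            }
        )
    risk_table = pd.DataFrame(rows) if rows else None

    delong: dict[str, dict[str, float]] = {}
    for a, b in (("ers", "ptau_ab42"), ("ers_noratio", "ptau_ab42")):
        if a in probs and b in probs:
            cmp = delong_compare(probs[a], probs[b], labels)
            delong[f"{a}_vs_{b}"] = {
                "auc_a": cmp.auc_a, "auc_b": cmp.auc_b, "z": cmp.z, "p": cmp.p,
                "degenerate": cmp.degenerate,
            }

    diagnostics: dict[str, dict[str, Any]] = {}
    for name, col in (("ers", "ers_high"), ("ratio", "ratio_high")):
        if col not in idx.columns:
            continue
        pred = idx[col].reindex(out["subject_id"]).to_numpy(int)
        try:
            diagnostics[name] = dataclasses.asdict(diagnostic_table(pred, labels))
        except ValueError as exc:
            flags.append(f"diagnostic table for {name!r} skipped: {exc}")
    return risk_table, delong, diagnostics, flags


def run_full_comparison(
    bundle: CohortBundle, horizon: float = 10.0, out_dir: str | Path | None = None
) -> AnalysisReport:
    """Execute the whole analysis flow on a validated cohort bundle.

    Stages that are impossible on the supplied data (no visits, single
    outcome class, one-group covariates) are flagged and skipped; the
    remaining stages still run.  The report is deterministic for fixed
    inputs (``content_hash``)."""
    cfg_hash = _config_hash(bundle, horizon)
    log.info("run_full_comparison start (config %s)", cfg_hash[:12])
    panels = bundle.panel_config.panels
    calibrations = calibrate_panels(bundle.profiles, panels)
    scored = score_profiles(bundle.profiles, panels, calibrations)
    crosstab = crosstab_ers(scored)
    ct_ratio = crosstab_ratio(scored) if "ratio_risk" in scored.columns else None

    model_table, model_flags = _fit_models(bundle.visits, scored, bundle.strata)
    risk_table, delong, diagnostics, risk_flags = _risk_stage(
        scored, bundle.outcomes, horizon
    )
    report = AnalysisReport(
        scored=scored,
        calibrations=calibrations,
        crosstab=crosstab,
        crosstab_ratio=ct_ratio,
        model_table=model_table,
        risk_table=risk_table,
        delong=delong,
        diagnostics=diagnostics,
        flags=model_flags + risk_flags,
        provenance={
            "config_hash": cfg_hash,
            "package": "csfrisk",
            "version": __version__,
            "n_subjects": int(len(bundle.profiles)),
            "horizon_years": horizon,
        },
    )
    if out_dir is not None:
        report.save(out_dir)
    log.info("run_full_comparison done (%d flags)", len(report.flags))
    return report
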