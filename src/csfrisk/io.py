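"""Delimited-text readers/writers and panel configuration.

Dialect: UTF-8, comma-separated, header row required, "." decimal.
Decimal-comma cells (common in German-locale exports) are rejected with
line-numbered diagnostics rather than guessed at.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import DEFAULT_PANEL, SyntheticCohort
from .panels import AssayPanel, CsfProfile

__all__ = [
    "ValidationError",
    "PanelConfig",
    "read_panel_config",
    "read_biomarker_csv",
    "read_visits_csv",
    "read_outcomes_csv",
    "CohortBundle",
    "read_tables",
    "write_cohort",
]


class ValidationError(ValueError):
    """Input-table or configuration violation (distinct from computation
    failures for CLI exit-code purposes)."""


@dataclass(frozen=True)
class PanelConfig:
    panels: dict[str, AssayPanel]
    priority: list[str]

    def rank(self, panel_id: str) -> int:
        try:
            return self.priority.index(panel_id)
        except ValueError:
            return len(self.priority)


DEFAULT_PANEL_CONFIG = PanelConfig(
    panels={DEFAULT_PANEL.panel_id: DEFAULT_PANEL},
    priority=[DEFAULT_PANEL.panel_id],
)


def read_panel_config(path: str | Path) -> PanelConfig:
    """YAML/JSON panel file: a ``panels`` list of AssayPanel records and
    an optional ``priority`` list of panel ids."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "panels" not in raw:
        raise ValidationError(f"{path}: expected a mapping with a 'panels' list")
    panels = {}
    for i, rec in enumerate(raw["panels"]):
        try:
            panel = AssayPanel(**rec)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: panel entry {i}: {exc}") from exc
        panels[panel.panel_id] = panel
    priority = raw.get("priority", list(panels))
    unknown = [p for p in priority if p not in panels]
    if unknown:
        raise ValidationError(f"{path}: priority lists unknown panels {unknown}")
    return PanelConfig(panels=panels, priority=list(priority))


def _read_csv(path: str | Path, required: list[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except Exception as exc:
        raise ValidationError(f"{path}: unreadable CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def _numeric(df: pd.DataFrame, col: str, path, allow_missing: bool = False) -> pd.Series:
    raw = df[col]
    vals = pd.to_numeric(raw, errors="coerce")
    bad = vals.isna() & raw.notna()
    if bad.any():
        lines = [i + 2 for i in df.index[bad][:5]]  # +2: header + 1-based
        example = raw[bad].iloc[0]
        hint = " (decimal commas are not parsed; use '.')" if "," in str(example) else ""
        raise ValidationError(
            f"{path}: column {col!r} has non-numeric values at lines {lines}, "
            f"e.g. {example!r}{hint}"
        )
    if not allow_missing and vals.isna().any():
        lines = [i + 2 for i in df.index[vals.isna()][:5]]
        raise ValidationError(f"{path}: column {col!r} empty at lines {lines}")
    return vals


def read_biomarker_csv(
    path: str | Path, panel_config: PanelConfig = DEFAULT_PANEL_CONFIG
) -> tuple[list[CsfProfile], pd.DataFrame]:
    """One row per subject (and assay panel): subject_id, ab42, ab40,
    ptau, ttau, panel_id; optional stratum.  Empty ab40 = not measured.
    When a subject has rows on several panels, the highest-priority
    panel is kept."""
    df = _read_csv(path, ["subject_id", "ab42", "ptau", "ttau", "panel_id"])
    if "ab40" not in df.columns:
        df["ab40"] = np.nan
    for col in ("ab42", "ptau", "ttau"):
        df[col] = _numeric(df, col, path)
    df["ab40"] = _numeric(df, "ab40", path, allow_missing=True)

    unknown = sorted(set(df["panel_id"]) - set(panel_config.panels))
    if unknown:
        raise ValidationError(f"{path}: unknown panel ids {unknown}")

    df["_rank"] = df["panel_id"].map(panel_config.rank)
    dup = df.duplicated(subset=["subject_id", "panel_id"], keep=False)
    if dup.any():
        sids = sorted(set(df.loc[dup, "subject_id"]))[:5]
        raise ValidationError(
            f"{path}: conflicting duplicate rows for subject/panel pairs, "
            f"subjects {sids}"
        )
    df = (
        df.sort_values(["subject_id", "_rank"], kind="stable")
        .drop_duplicates("subject_id", keep="first")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    profiles = []
    for rec in df.itertuples():
        try:
            profiles.append(
                CsfProfile(
                    subject_id=str(rec.subject_id),
                    ab42=float(rec.ab42),
                    ptau=float(rec.ptau),
                    ttau=float(rec.ttau),
                    ab40=None if pd.isna(rec.ab40) else float(rec.ab40),
                    panel_id=str(rec.panel_id),
                )
            )
        except ValueError as exc:
            raise ValidationError(f"{path}: line {rec.Index + 2}: {exc}") from exc
    return profiles, df


def read_visits_csv(path: str | Path) -> pd.DataFrame:
    """Longitudinal visits: subject_id, time_years (or time), zmmse."""
    df = pd.read_csv(path, encoding="utf-8")
    if "time_years" in df.columns and "time" not in df.columns:
        df = df.rename(columns={"time_years": "time"})
    missing = [c for c in ("subject_id", "time", "zmmse") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    df["time"] = _numeric(df, "time", path)
    df["zmmse"] = _numeric(df, "zmmse", path)
    df["subject_id"] = df["subject_id"].astype(str)
    return df[["subject_id", "time", "zmmse"]]


def read_outcomes_csv(path: str | Path) -> pd.DataFrame:
    """Time-to-dementia outcomes: subject_id, event (0/1), time_years."""
    df = pd.read_csv(path, encoding="utf-8")
    if "time_years" in df.columns and "time" not in df.columns:
        df = df.rename(columns={"time_years": "time"})
    missing = [c for c in ("subject_id", "event", "time") if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    df["time"] = _numeric(df, "time", path)
    ev = _numeric(df, "event", path)
    if not ev.isin([0, 1]).all():
        raise ValidationError(f"{path}: event flags must be 0 or 1")
    df["event"] = ev.astype(int)
    df["subject_id"] = df["subject_id"].astype(str)
    if (df["time"] <= 0).any():
        lines = [i + 2 for i in df.index[df["time"] <= 0][:5]]
        raise ValidationError(f"{path}: non-positive follow-up times at lines {lines}")
    return df[["subject_id", "event", "time"]]


@dataclass
class CohortBundle:
    """Validated, referentially consistent cohort tables."""

    profiles: list[CsfProfile]
    biomarkers: pd.DataFrame
    visits: pd.DataFrame
    outcomes: pd.DataFrame
    panel_config: PanelConfig

    @property
    def strata(self) -> pd.Series | None:
        if "stratum" in self.biomarkers.columns and self.biomarkers["stratum"].notna().all():
            return self.biomarkers.set_index("subject_id")["stratum"]
        return None


def read_tables(
    biomarkers_path: str | Path,
    visits_path: str | Path | None = None,
    outcomes_path: str | Path | None = None,
    panel_config: PanelConfig = DEFAULT_PANEL_CONFIG,
) -> CohortBundle:
    """Load and cross-validate the cohort tables.

    Visit or outcome rows naming subjects absent from the biomarker
    table are rejected (with the offending subject ids)."""
    profiles, bio = read_biomarker_csv(biomarkers_path, panel_config)
    known = set(bio["subject_id"].astype(str))
    visits = pd.DataFrame(columns=["subject_id", "time", "zmmse"])
    outcomes = pd.DataFrame(columns=["subject_id", "event", "time"])
    if visits_path is not None:
        visits = read_visits_csv(visits_path)
        orphans = sorted(set(visits["subject_id"]) - known)
        if orphans:
            raise ValidationError(
                f"{visits_path}: visits reference unknown subjects {orphans[:5]}"
            )
    if outcomes_path is not None:
        outcomes = read_outcomes_csv(outcomes_path)
        orphans = sorted(set(outcomes["subject_id"]) - known)
        if orphans:
            raise ValidationError(
                f"{outcomes_path}: outcomes reference unknown subjects {orphans[:5]}"
            )
    return CohortBundle(
        profiles=profiles,
        biomarkers=bio,
        visits=visits,
        outcomes=outcomes,
        panel_config=panel_config,
    )


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Export a synthetic cohort as the three CSV tables plus the truth
    parameters as JSON."""
    import dataclasses
    import json

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "biomarkers": out / "biomarkers.csv",
        "visits": out / "visits.csv",
        "outcomes": out / "outcomes.csv",
        "truth": out / "truth.json",
    }
    cohort.biomarker_frame().to_csv(paths["biomarkers"], index=False)
    cohort.visits.rename(columns={"time": "time_years"}).to_csv(
        paths["visits"], index=False
    )
    cohort.outcomes.rename(columns={"time": "time_years"}).to_csv(
        paths["outcomes"], index=False
    )
    cfg = dataclasses.asdict(cohort.config)
    cfg["panel"] = dataclasses.asdict(cohort.config.panel)
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True, default=float)
    return paths
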