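"""Synthetic memory-clinic cohorts for exercising the full pipeline.

The generator emulates the statistical structure the analysis assumes
for a 259-subject non-demented (SCI/MCI) memory-clinic cohort:

* 13 ATN(R) biomarker constellations with the reference cross-tab
  frequencies, analyte values drawn log-uniformly inside the requested
  zone (clearly normal / clearly pathological, optionally borderline);
* MMSE z-score trajectories from the random-intercept/random-slope
  mixed model with AR(1) residual correlation at the reference fixed
  effects (pathological-group deficit and faster annual decline);
* exponential conversion-to-dementia times with a group-dependent
  hazard, censored at a variable follow-up end whose distribution is a
  two-component uniform mixture solved to have median 3.25 years and
  interquartile range 4.9 years;
* annual visits from baseline to the follow-up end.

Everything is deterministic given the config seed.  A deterministic
259-subject fixture with the exact reference constellation counts is
also provided for table-level checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ers import ers_total
from .panels import AssayPanel, CsfProfile

__all__ = [
    "CONSTELLATION_ORDER",
    "TABLE1_COUNTS",
    "DEFAULT_PANEL",
    "LmmTruth",
    "HazardTruth",
    "FollowupMixture",
    "CohortConfig",
    "SyntheticCohort",
    "generate_biomarkers",
    "table1_fixture",
    "generate_trajectories",
    "generate_outcomes",
    "generate_cohort",
]

# (R, A, T, N) flags in the reference cross-tab column order, with the
# published column totals (sum 259).
CONSTELLATION_ORDER: tuple[tuple[bool, bool, bool, bool], ...] = (
    (False, False, False, False),
    (True, False, False, False),
    (False, True, False, False),
    (True, True, False, False),
    (True, False, False, True),
    (True, True, False, True),
    (True, False, True, False),
    (True, True, True, False),
    (True, False, True, True),
    (True, True, True, True),
    (False, False, False, True),
    (False, False, True, False),
    (False, False, True, True),
)
TABLE1_COUNTS: tuple[int, ...] = (87, 1, 5, 5, 3, 2, 2, 3, 58, 30, 9, 18, 36)

DEFAULT_PANEL = AssayPanel(
    panel_id="synthetic",
    ab42_cutoff=600.0,
    ptau_cutoff=60.0,
    ttau_cutoff=400.0,
    amyloid_ratio_cutoff=0.05,
)


@dataclass(frozen=True)
class LmmTruth:
    """Data-generating trajectory model (time in years, binary group).

    Defaults are the reference binary-score fit: baseline deficit of the
    pathological group (beta2) and its extra annual decline (beta3).
    """

    beta0: float = -1.30
    beta1: float = -0.07
    beta2: float = -0.40
    beta3: float = -0.40
    var_u0: float = 1.0
    var_u1: float = 0.02
    cov_u01: float = 0.0
    rho: float = 0.3
    var_e: float = 0.25


@dataclass(frozen=True)
class HazardTruth:
    """Exponential conversion hazard: rate = baseline_rate * exp(log_hr * g).

    Defaults solved so that with the 156/103 low/high split and the
    default follow-up mixture about 31% of subjects convert.
    """

    baseline_rate: float = 0.0535
    log_hr: float = 1.1


@dataclass(frozen=True)
class FollowupMixture:
    """Follow-up end (years): w * U(short) + (1 - w) * U(long).

    Defaults solved in closed form for median 3.25 y and IQR 4.9 y on a
    1-13 y support (eligibility required 12-156 months of follow-up).
    """

    weight_short: float = 0.498
    short: tuple[float, float] = (1.0, 3.761)
    long: tuple[float, float] = (1.0, 13.0)

    def draw(self, n: int, rng: np.random.Generator) -> np.ndarray:
        pick = rng.random(n) < self.weight_short
        short = rng.uniform(self.short[0], self.short[1], n)
        long = rng.uniform(self.long[0], self.long[1], n)
        return np.where(pick, short, long)


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 259
    constellation_weights: tuple[float, ...] = tuple(
        c / sum(TABLE1_COUNTS) for c in TABLE1_COUNTS
    )
    borderline_probability: float = 0.0
    lmm_truth: LmmTruth = field(default_factory=LmmTruth)
    hazard_truth: HazardTruth = field(default_factory=HazardTruth)
    followup: FollowupMixture = field(default_factory=FollowupMixture)
    panel: AssayPanel = field(default_factory=lambda: DEFAULT_PANEL)
    mci_fraction: float = 208.0 / 259.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.constellation_weights) != len(CONSTELLATION_ORDER):
            raise ValueError(
                f"need {len(CONSTELLATION_ORDER)} constellation weights"
            )
        if abs(sum(self.constellation_weights) - 1.0) > 1e-9:
            raise ValueError("constellation weights must sum to 1")
        if not 0.0 <= self.borderline_probability <= 1.0:
            raise ValueError("borderline_probability must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    profiles: list[CsfProfile]
    visits: pd.DataFrame
    outcomes: pd.DataFrame
    strata: pd.Series  # subject_id -> "SCI"/"MCI"
    config: CohortConfig

    def biomarker_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": p.subject_id,
                "ab42": p.ab42,
                "ab40": p.ab40,
                "ptau": p.ptau,
                "ttau": p.ttau,
                "panel_id": p.panel_id,
                "stratum": self.strata.get(p.subject_id),
            }
            for p in self.profiles
        ]
        return pd.DataFrame(rows)


def _log_uniform(rng: np.random.Generator, low: float, high: float) -> float:
    return float(np.exp(rng.uniform(np.log(low), np.log(high))))


def _draw_marker(
    rng: np.random.Generator,
    cutoff: float,
    low_is_pathological: bool,
    pathological: bool,
    borderline: bool,
    band: float,
) -> float:
    """Draw a value in the requested zone, never crossing the binary
    cut-off (so the requested constellation is reproduced by
    construction)."""
    if borderline:
        # stay strictly inside the requested half of the +/-band
        u = 0.02 + 0.96 * rng.random()
        if pathological == low_is_pathological:
            return cutoff * (1.0 - band * u)
        return cutoff * (1.0 + band * u)
    if pathological == low_is_pathological:
        return _log_uniform(rng, 0.45 * cutoff, (1.0 - band) * cutoff * 0.97)
    return _log_uniform(rng, (1.0 + band) * cutoff * 1.03, 2.2 * cutoff)


def generate_biomarkers(
    config: CohortConfig, rng: np.random.Generator | None = None
) -> list[CsfProfile]:
    """Draw one CSF profile per subject.

    A constellation is sampled by weight; each analyte is then placed in
    its clearly-normal or clearly-pathological zone (log-uniform), or in
    the borderline band with probability ``borderline_probability``, and
    Abeta1-40 is set so the amyloid ratio falls on the requested R side.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    panel = config.panel
    band = panel.borderline_fraction
    idx = rng.choice(
        len(CONSTELLATION_ORDER), size=config.n_subjects,
        p=np.asarray(config.constellation_weights),
    )
    profiles = []
    for i, ci in enumerate(idx):
        r, a, t, n = CONSTELLATION_ORDER[ci]
        bl = rng.random(4) < config.borderline_probability
        ab42 = _draw_marker(rng, panel.ab42_cutoff, True, a, bl[0], band)
        ptau = _draw_marker(rng, panel.ptau_cutoff, False, t, bl[1], band)
        ttau = _draw_marker(rng, panel.ttau_cutoff, False, n, bl[2], band)
        ratio = _draw_marker(rng, panel.amyloid_ratio_cutoff, True, r, bl[3], band)
        profiles.append(
            CsfProfile(
                subject_id=f"S{i:04d}",
                ab42=ab42,
                ptau=ptau,
                ttau=ttau,
                ab40=ab42 / ratio,
                panel_id=panel.panel_id,
            )
        )
    return profiles


# fixed clear-zone values for the deterministic fixture (>10% past the
# synthetic-panel cut-offs on the requested side)
_FIXTURE_VALUES = {
    "ab42": {True: 450.0, False: 800.0},
    "ptau": {True: 80.0, False: 40.0},
    "ttau": {True: 550.0, False: 250.0},
    "ratio": {True: 0.038, False: 0.07},
}


def table1_fixture(
    borderline_variant: bool = False, panel: AssayPanel = DEFAULT_PANEL
) -> list[CsfProfile]:
    """Deterministic 259-subject cohort with the exact reference
    constellation counts and all values clearly (>10%) beyond the
    cut-offs.

    With ``borderline_variant=True`` one R+A-T+N+ subject's Abeta1-42 is
    moved into the borderline-normal band (5% above the cut-off), which
    lifts that subject's total from 3 to 4 — the one off-diagonal cell
    of the reference cross-tab that requires a borderline value.
    """
    profiles = []
    k = 0
    for (r, a, t, n), count in zip(CONSTELLATION_ORDER, TABLE1_COUNTS):
        for j in range(count):
            ab42 = _FIXTURE_VALUES["ab42"][a]
            if borderline_variant and (r, a, t, n) == (True, False, True, True) and j == 0:
                ab42 = 1.05 * panel.ab42_cutoff  # borderline, binary-normal
            ratio = _FIXTURE_VALUES["ratio"][r]
            profiles.append(
                CsfProfile(
                    subject_id=f"S{k:04d}",
                    ab42=ab42,
                    ptau=_FIXTURE_VALUES["ptau"][t],
                    ttau=_FIXTURE_VALUES["ttau"][n],
                    ab40=ab42 / ratio,
                    panel_id=panel.panel_id,
                )
            )
            k += 1
    return profiles


def generate_trajectories(
    groups: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    followups: pd.Series | None = None,
) -> pd.DataFrame:
    """Simulate annual zMMSE visits from the trajectory model truth.

    ``groups`` maps subject_id to the numeric group covariate (0 =
    reference, 1 = pathological for the binary scores).  Visits run at
    0, 1, 2, ... years, truncated at the subject's follow-up end (drawn
    from the config mixture unless supplied).
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    truth = config.lmm_truth
    subjects = list(groups.index)
    if followups is None:
        followups = pd.Series(
            config.followup.draw(len(subjects), rng), index=subjects
        )
    g_cov = np.array(
        [[truth.var_u0, truth.cov_u01], [truth.cov_u01, truth.var_u1]]
    )
    chol = np.linalg.cholesky(g_cov + 1e-12 * np.eye(2))
    rows = []
    for sid in subjects:
        g = float(groups[sid])
        u0, u1 = chol @ rng.standard_normal(2)
        n_vis = int(np.floor(followups[sid])) + 1
        times = np.arange(n_vis, dtype=float)
        e = np.empty(n_vis)
        e[0] = np.sqrt(truth.var_e) * rng.standard_normal()
        innov_sd = np.sqrt(truth.var_e * (1.0 - truth.rho**2))
        for k in range(1, n_vis):
            e[k] = truth.rho * e[k - 1] + innov_sd * rng.standard_normal()
        z = (
            truth.beta0
            + truth.beta1 * times
            + truth.beta2 * g
            + truth.beta3 * g * times
            + u0
            + u1 * times
            + e
        )
        rows.extend(
            {"subject_id": sid, "time": float(tt), "zmmse": float(zz)}
            for tt, zz in zip(times, z)
        )
    return pd.DataFrame(rows)


def generate_outcomes(
    groups: pd.Series,
    config: CohortConfig,
    rng: np.random.Generator | None = None,
    followups: pd.Series | None = None,
) -> pd.DataFrame:
    """Simulate conversion-to-dementia outcomes.

    Event times are exponential with rate baseline * exp(log_hr * g);
    censoring occurs at the follow-up end.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    hz = config.hazard_truth
    subjects = list(groups.index)
    if followups is None:
        followups = pd.Series(
            config.followup.draw(len(subjects), rng), index=subjects
        )
    rows = []
    for sid in subjects:
        rate = hz.baseline_rate * np.exp(hz.log_hr * float(groups[sid]))
        t_event = rng.exponential(1.0 / rate) if rate > 0 else np.inf
        f = float(followups[sid])
        event = bool(t_event <= f)
        rows.append(
            {
                "subject_id": sid,
                "event": int(event),
                "time": float(t_event if event else f),
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig | None = None) -> SyntheticCohort:
    """Full reproducible cohort: biomarkers, visits, outcomes, strata.

    The trajectory/outcome group is the binary risk class of the
    full score (total > 1 = pathological), and one follow-up draw per
    subject censors both the visit schedule and the event time.
    """
    config = CohortConfig() if config is None else config
    rng = np.random.default_rng(config.seed)
    profiles = generate_biomarkers(config, rng)
    groups = pd.Series(
        {
            p.subject_id: int(ers_total(p, config.panel).total > 1)
            for p in profiles
        }
    )
    followups = pd.Series(
        config.followup.draw(len(profiles), rng),
        index=[p.subject_id for p in profiles],
    )
    visits = generate_trajectories(groups, config, rng, followups)
    outcomes = generate_outcomes(groups, config, rng, followups)
    strata = pd.Series(
        np.where(rng.random(len(profiles)) < config.mci_fraction, "MCI", "SCI"),
        index=[p.subject_id for p in profiles],
    )
    return SyntheticCohort(
        profiles=profiles,
        visits=visits,
        outcomes=outcomes,
        strata=strata,
        config=config,
    )
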