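"""pTau181/Abeta1-42 ratio: computation, Youden-index cut-off calibration,
and binary risk classification.

The ratio is a single-quotient alternative to multi-marker scoring: high
pTau in the numerator and low Abeta1-42 in the denominator both push the
ratio up, so values above an assay-specific threshold flag combined
amyloid and tau pathology.  Thresholds are calibrated empirically per
assay panel by maximizing Youden's J = sensitivity + specificity - 1 over
neurochemically definite AD cases versus biomarker-negative controls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .panels import CsfProfile

__all__ = [
    "RatioResult",
    "YoudenCalibration",
    "DegenerateSeparationWarning",
    "ptau_ab42_ratio",
    "calibrate_youden_cutoff",
    "classify_ratio",
]


class DegenerateSeparationWarning(UserWarning):
    """Cases and controls are not separable (best J = 0)."""


@dataclass(frozen=True)
class YoudenCalibration:
    """Result of empirical Youden-index threshold calibration.

    ``cutoff`` is a midpoint between adjacent distinct pooled values (or
    an infinite sentinel in degenerate cases); ``youden_j`` equals
    sensitivity + specificity - 1 at that cut-off.
    """

    cutoff: float
    youden_j: float
    sensitivity: float
    specificity: float
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if not -1.0 <= self.youden_j <= 1.0:
            raise ValueError(f"youden_j must lie in [-1, 1], got {self.youden_j}")
        if abs(self.youden_j - (self.sensitivity + self.specificity - 1.0)) > 1e-12:
            raise ValueError("youden_j must equal sensitivity + specificity - 1")


@dataclass(frozen=True)
class RatioResult:
    ratio: float
    cutoff: float
    risk_class: str  # "low" or "high"; high iff ratio strictly above cutoff


def ptau_ab42_ratio(profile: CsfProfile) -> float:
    """pTau181 / Abeta1-42 (dimensionless)."""
    return profile.ptau / profile.ab42


def calibrate_youden_cutoff(
    case_ratios, control_ratios
) -> YoudenCalibration:
    """Choose the threshold maximizing Youden's J over all candidates.

    Candidates are midpoints between consecutive distinct pooled values
    plus -inf/+inf sentinels.  Sensitivity is the fraction of cases
    strictly above the threshold, specificity the fraction of controls at
    or below it.  Ties in J are broken toward the candidate with higher
    specificity, then toward the smaller cut-off.  When the best J is 0
    a DegenerateSeparationWarning is issued.
    """
    cases = np.asarray(case_ratios, dtype=float)
    controls = np.asarray(control_ratios, dtype=float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("calibration requires at least one case and one control")

    pooled = np.unique(np.concatenate([cases, controls]))
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    candidates = np.concatenate([[-np.inf], mids, [np.inf]])

    sens = (cases[None, :] > candidates[:, None]).mean(axis=1)
    spec = (controls[None, :] <= candidates[:, None]).mean(axis=1)
    j = sens + spec - 1.0

    # lexicographic: max J, then max specificity, then min cutoff
    order = np.lexsort((candidates, -spec, -j))
    best = order[0]

    if j[best] <= 0:
        warnings.warn(
            "cases and controls are not separable (best Youden J = "
            f"{j[best]:.3g})", DegenerateSeparationWarning, stacklevel=2,
        )
    return YoudenCalibration(
        cutoff=float(candidates[best]),
        youden_j=float(j[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        n_cases=int(cases.size),
        n_controls=int(controls.size),
    )


def classify_ratio(profile: CsfProfile, calibration: YoudenCalibration) -> RatioResult:
    """High dementia risk iff the ratio lies strictly above the cut-off."""
    r = ptau_ab42_ratio(profile)
    return RatioResult(
        ratio=r,
        cutoff=calibration.cutoff,
        risk_class="high" if r > calibration.cutoff else "low",
    )
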