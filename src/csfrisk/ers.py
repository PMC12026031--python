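"""The Erlangen Score: an ordinal 0-4 CSF dementia-risk score.

Construction: an amyloid sub-score (Abeta1-42 zone, 0/1/2) plus a tau
sub-score (the higher of the pTau181 and tTau zones, 0/1/2) give a sum
score 0-4.  When the Abeta1-42/Abeta1-40 ratio is available it is added
as +1 (pathological) or -1 (normal) and the result is clamped back into
[0, 4].  Totals above one are considered pathological ("suspicious for
Alzheimer's disease").  Without the ratio, the unadjusted sum is read on
a three-level risk scale (low 0-1, medium 2, high 3-4).
"""

from __future__ import annotations

from dataclasses import dataclass

from .panels import (
    AssayPanel,
    CsfProfile,
    Direction,
    MarkerZone,
    RatioUnavailableError,
    amyloid_ratio_status,
    classify_marker_zone,
)

__all__ = ["ErsResult", "tau_subscore", "ers_total", "ers_without_ratio"]


@dataclass(frozen=True)
class ErsResult:
    """One subject's Erlangen Score decomposition.

    ``ratio_adjustment`` is +1/-1 when the amyloid ratio was applied and 0
    when it was unavailable (or deliberately ignored); ``total`` is the
    clamped final score.  ``risk_class`` is "low"/"high" on the
    ratio-adjusted scale and may be "medium" only on the no-ratio scale.
    """

    amyloid_subscore: int
    tau_subscore: int
    sum_score: int
    ratio_adjustment: int
    total: int
    risk_class: str
    suspicious_for_ad: bool

    def __post_init__(self) -> None:
        if not 0 <= self.total <= 4:
            raise ValueError(f"total must lie in [0, 4], got {self.total}")
        expected = min(4, max(0, self.sum_score + self.ratio_adjustment))
        if self.total != expected:
            raise ValueError("total must equal clamp(sum_score + ratio_adjustment, 0, 4)")
        if self.suspicious_for_ad != (self.total >= 2):
            raise ValueError("suspicious_for_ad must hold exactly when total >= 2")


def tau_subscore(ptau_zone: MarkerZone, ttau_zone: MarkerZone) -> int:
    """Tau sub-score: the higher of the pTau181 and tTau zone scores."""
    return max(ptau_zone.score, ttau_zone.score)


def _zones(profile: CsfProfile, panel: AssayPanel) -> tuple[int, int]:
    f = panel.borderline_fraction
    a = classify_marker_zone(profile.ab42, panel.ab42_cutoff,
                             Direction.LOW_IS_PATHOLOGICAL, f)
    t = classify_marker_zone(profile.ptau, panel.ptau_cutoff,
                             Direction.HIGH_IS_PATHOLOGICAL, f)
    n = classify_marker_zone(profile.ttau, panel.ttau_cutoff,
                             Direction.HIGH_IS_PATHOLOGICAL, f)
    return a.score, tau_subscore(t, n)


def _three_level_class(total: int) -> str:
    # no-ratio scale: low 0-1, medium 2, high 3-4
    if total <= 1:
        return "low"
    if total == 2:
        return "medium"
    return "high"


def ers_total(profile: CsfProfile, panel: AssayPanel) -> ErsResult:
    """Full Erlangen Score with the amyloid-ratio adjustment.

    Falls back to the three-level no-ratio scale (adjustment 0) when
    Abeta1-40 was not measured.
    """
    a, t = _zones(profile, panel)
    sum_score = a + t
    try:
        ratio_path = amyloid_ratio_status(profile, panel)
    except RatioUnavailableError:
        return ErsResult(
            amyloid_subscore=a,
            tau_subscore=t,
            sum_score=sum_score,
            ratio_adjustment=0,
            total=sum_score,
            risk_class=_three_level_class(sum_score),
            suspicious_for_ad=sum_score >= 2,
        )
    adjustment = 1 if ratio_path else -1
    total = min(4, max(0, sum_score + adjustment))
    return ErsResult(
        amyloid_subscore=a,
        tau_subscore=t,
        sum_score=sum_score,
        ratio_adjustment=adjustment,
        total=total,
        risk_class="high" if total >= 2 else "low",
        suspicious_for_ad=total >= 2,
    )


def ers_without_ratio(profile: CsfProfile, panel: AssayPanel) -> ErsResult:
    """Erlangen Score ignoring the amyloid ratio even when available."""
    a, t = _zones(profile, panel)
    sum_score = a + t
    return ErsResult(
        amyloid_subscore=a,
        tau_subscore=t,
        sum_score=sum_score,
        ratio_adjustment=0,
        total=sum_score,
        risk_class=_three_level_class(sum_score),
        suspicious_for_ad=sum_score >= 2,
    )
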