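"""CSF assay panels, subject profiles, and three-zone marker classification.

Each CSF analyte (Abeta1-42, pTau181, tTau) is judged against an
assay-specific decision limit with a known pathological direction:
Abeta1-42 is pathological when *low*, both tau species when *high*.
Because immunoassay values near the decision limit are analytically
uncertain, a borderline band of +/-10% (configurable) around the cut-off
is distinguished from the clearly normal and clearly pathological zones.
The ordinal zone score (0 normal / 1 borderline / 2 clearly pathological)
feeds the Erlangen Score; the plain binary status (strictly past the
cut-off in the pathological direction) defines the ATN(R) constellation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

__all__ = [
    "Direction",
    "AssayPanel",
    "CsfProfile",
    "MarkerZone",
    "Constellation",
    "RatioUnavailableError",
    "classify_marker_zone",
    "amyloid_ratio_status",
    "constellation_of",
]


class Direction(enum.Enum):
    """Which side of the cut-off is pathological for a marker."""

    LOW_IS_PATHOLOGICAL = "low"
    HIGH_IS_PATHOLOGICAL = "high"


class RatioUnavailableError(ValueError):
    """Raised when the Abeta1-42/Abeta1-40 ratio is requested but Abeta1-40
    was not measured.  Deliberately distinct from a default value: callers
    must decide how to proceed without the ratio."""


@dataclass(frozen=True)
class AssayPanel:
    """Decision limits for one immunoassay combination.

    Parameters
    ----------
    panel_id : str
        Identifier of the assay combination.
    ab42_cutoff : float
        Abeta1-42 decision limit in pg/mL; pathological below.
    ptau_cutoff : float
        pTau181 decision limit in pg/mL; pathological above.
    ttau_cutoff : float
        Total-tau decision limit in pg/mL; pathological above.
    amyloid_ratio_cutoff : float
        Abeta1-42/Abeta1-40 decision limit (dimensionless); pathological
        strictly below.  0.05 for manual immunoassays, 0.06 for the
        automated-platform dialect.
    ptau_ab42_cutoff : float or None
        pTau181/Abeta1-42 decision limit; pathological strictly above.
        None until produced by Youden calibration.
    borderline_fraction : float
        Half-width of the borderline band as a fraction of the cut-off.
    """

    panel_id: str
    ab42_cutoff: float
    ptau_cutoff: float
    ttau_cutoff: float
    amyloid_ratio_cutoff: float = 0.05
    ptau_ab42_cutoff: float | None = None
    borderline_fraction: float = 0.10

    def __post_init__(self) -> None:
        for name in ("ab42_cutoff", "ptau_cutoff", "ttau_cutoff", "amyloid_ratio_cutoff"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.ptau_ab42_cutoff is not None and not self.ptau_ab42_cutoff > 0:
            raise ValueError(
                f"ptau_ab42_cutoff must be strictly positive, got {self.ptau_ab42_cutoff!r}"
            )
        if not 0.0 < self.borderline_fraction < 1.0:
            raise ValueError(
                f"borderline_fraction must lie in (0, 1), got {self.borderline_fraction!r}"
            )


@dataclass(frozen=True)
class CsfProfile:
    """One subject's CSF analyte concentrations (pg/mL).

    ``ab40`` may be None when Abeta1-40 was not measured; the amyloid
    ratio is then unavailable and Erlangen scoring falls back to its
    three-level no-ratio scale.
    """

    subject_id: str
    ab42: float
    ptau: float
    ttau: float
    ab40: float | None = None
    panel_id: str = "default"

    def __post_init__(self) -> None:
        for name in ("ab42", "ptau", "ttau"):
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive for subject "
                                 f"{self.subject_id!r}, got {v!r}")
        if self.ab40 is not None and not self.ab40 > 0:
            raise ValueError(f"ab40 must be strictly positive for subject "
                             f"{self.subject_id!r}, got {self.ab40!r}")

    @property
    def amyloid_ratio(self) -> float:
        """Abeta1-42/Abeta1-40 ratio; raises if Abeta1-40 is missing."""
        if self.ab40 is None:
            raise RatioUnavailableError(
                f"subject {self.subject_id!r}: Abeta1-40 not measured, "
                "amyloid ratio unavailable"
            )
        return self.ab42 / self.ab40


@dataclass(frozen=True)
class MarkerZone:
    """Three-zone classification of one marker value.

    ``score`` is 0 (clearly normal), 1 (borderline) or 2 (clearly
    pathological); ``pathological`` is the plain binary status by the
    strict cut-off.  A borderline score can sit on either side of the
    cut-off, so score 1 carries either binary status.
    """

    score: int
    pathological: bool

    def __post_init__(self) -> None:
        if self.score == 2 and not self.pathological:
            raise ValueError("score 2 implies pathological binary status")
        if self.score == 0 and self.pathological:
            raise ValueError("score 0 implies normal binary status")


@dataclass(frozen=True)
class Constellation:
    """ATN(R) biomarker constellation: amyloid ratio (R), Abeta1-42 (A),
    pTau181 (T), total tau (N).  ``R`` is None when the ratio is
    unavailable."""

    R: bool | None
    A: bool
    T: bool
    N: bool

    @property
    def label(self) -> str:
        def sign(flag: bool | None) -> str:
            return "?" if flag is None else ("+" if flag else "-")

        return f"R{sign(self.R)}A{sign(self.A)}T{sign(self.T)}N{sign(self.N)}"

    @property
    def is_snap(self) -> bool:
        """Suspected non-Alzheimer pathology: normal amyloid markers with
        pathological tau and/or neurodegeneration markers."""
        return self.R is False and not self.A and (self.T or self.N)


def classify_marker_zone(
    value: float,
    cutoff: float,
    direction: Direction,
    borderline_fraction: float = 0.10,
) -> MarkerZone:
    """Place a marker value into the normal / borderline / pathological zone.

    The borderline band is symmetric: ``|value - cutoff| <= f * cutoff``
    scores 1.  Beyond the band the value is clearly normal (0) or clearly
    pathological (2, deviation > ``f`` past the cut-off).  Band-edge ties
    fall into the borderline zone; the binary status is strict
    (pathological only strictly past the plain cut-off).
    """
    if not value > 0:
        raise ValueError(f"marker value must be strictly positive, got {value!r}")
    if not cutoff > 0:
        raise ValueError(f"cutoff must be strictly positive, got {cutoff!r}")
    if not 0.0 < borderline_fraction < 1.0:
        raise ValueError(f"borderline_fraction must lie in (0, 1), got {borderline_fraction!r}")

    band = borderline_fraction * cutoff
    if direction is Direction.LOW_IS_PATHOLOGICAL:
        pathological = value < cutoff
        if value < cutoff - band:
            score = 2
        elif value > cutoff + band:
            score = 0
        else:
            score = 1
    else:
        pathological = value > cutoff
        if value > cutoff + band:
            score = 2
        elif value < cutoff - band:
            score = 0
        else:
            score = 1
    return MarkerZone(score=score, pathological=pathological)


def amyloid_ratio_status(profile: CsfProfile, panel: AssayPanel) -> bool:
    """True when the Abeta1-42/Abeta1-40 ratio is pathological, i.e.
    strictly below the panel cut-off.  Raises RatioUnavailableError when
    Abeta1-40 is missing."""
    return profile.amyloid_ratio < panel.amyloid_ratio_cutoff


def constellation_of(profile: CsfProfile, panel: AssayPanel) -> Constellation:
    """Binary ATN(R) flags from the plain cut-offs.  ``R`` is None when
    Abeta1-40 is missing."""
    f = panel.borderline_fraction
    a = classify_marker_zone(profile.ab42, panel.ab42_cutoff, Direction.LOW_IS_PATHOLOGICAL, f)
    t = classify_marker_zone(profile.ptau, panel.ptau_cutoff, Direction.HIGH_IS_PATHOLOGICAL, f)
    n = classify_marker_zone(profile.ttau, panel.ttau_cutoff, Direction.HIGH_IS_PATHOLOGICAL, f)
    r: bool | None
    try:
        r = amyloid_ratio_status(profile, panel)
    except RatioUnavailableError:
        r = None
    return Constellation(R=r, A=a.pathological, T=t.pathological, N=n.pathological)
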