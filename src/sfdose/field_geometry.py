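"""Equivalent-square field sizing from dosimetric field widths.

Small-field correction factors are indexed by the equivalent square field
size S_clin, the geometric mean of the cross-plane (A) and in-plane (B)
dosimetric field widths (FWHM) measured at the reference depth:

    S_clin = sqrt(A * B)

Widths are taken at the measurement plane (e.g. the 110 cm plane for a
100 cm SSD scan at 10 cm depth) and fed into the geometric mean at that
plane; no back-projection to the isocentre plane is applied before the
geometric mean.  S_clin is carried unrounded internally and reported at
0.01 cm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ConsistencyError, ValidationError
from .scan_processing import (
    LATERAL_AXES,
    ScanCurve,
    fwhm,
    normalize_to_cax,
    recenter,
)

__all__ = [
    "FieldGeometry",
    "project_length",
    "equivalent_square",
    "sclin_from_profiles",
]


@dataclass
class FieldGeometry:
    """Collimator setting plus (optionally) measured dosimetric widths.

    ``sclin_cm``, once computed, always lies between the two measured
    widths because it is their geometric mean.
    """

    collimator_x_cm: float
    collimator_y_cm: float
    defined_by: str = "jaw"  # "jaw" | "mlc"
    ssd_cm: float = 100.0
    measurement_depth_mm: float = 100.0
    fwhm_cross_cm: float | None = None
    fwhm_in_cm: float | None = None
    sclin_cm: float | None = None

    def __post_init__(self) -> None:
        if self.defined_by not in ("jaw", "mlc"):
            raise ValidationError(f"defined_by must be jaw or mlc, got {self.defined_by!r}")
        for name in ("collimator_x_cm", "collimator_y_cm", "ssd_cm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.measurement_depth_mm < 0:
            raise ValidationError("measurement_depth_mm must be non-negative")
        if self.sclin_cm is not None:
            if self.fwhm_cross_cm is None or self.fwhm_in_cm is None:
                raise ValidationError("sclin_cm present without measured widths")
            lo = min(self.fwhm_cross_cm, self.fwhm_in_cm)
            hi = max(self.fwhm_cross_cm, self.fwhm_in_cm)
            if not lo - 1e-12 <= self.sclin_cm <= hi + 1e-12:
                raise ValidationError("sclin_cm must lie between the measured widths")


def project_length(length_cm: float, ref_cm: float, target_cm: float) -> float:
    """Divergently project a length from one source distance to another.

    A collimator side defined at 100 cm projects to ``side * 110/100`` at
    the 110 cm plane (100 cm SSD, 10 cm depth).
    """
    if length_cm <= 0 or ref_cm <= 0 or target_cm <= 0:
        raise ValidationError("lengths and distances must be positive")
    return length_cm * target_cm / ref_cm


def equivalent_square(a_cm: float, b_cm: float) -> float:
    """Equivalent square field side: geometric mean of the two FWHMs."""
    if a_cm <= 0 or b_cm <= 0:
        raise ValidationError("field widths must be positive")
    return math.sqrt(a_cm * b_cm)


def sclin_from_profiles(cross: ScanCurve, inplane: ScanCurve) -> FieldGeometry:
    """Measure FWHMs of a cross-plane / in-plane profile pair and form S_clin.

    Each profile is CAX-normalized, recentred on the midpoint of its 50%
    crossings and renormalized before the width is read; widths are
    converted mm -> cm at the measurement plane.
    """
    if cross.axis not in LATERAL_AXES or inplane.axis not in LATERAL_AXES:
        raise ValidationError("both curves must be lateral profiles")
    same_field = (
        cross.field_x_cm == inplane.field_x_cm
        and cross.field_y_cm == inplane.field_y_cm
        and cross.ssd_cm == inplane.ssd_cm
        and cross.scan_depth_mm == inplane.scan_depth_mm
    )
    if not same_field:
        raise ConsistencyError(
            "cross-plane and in-plane profiles describe different fields"
        )

    def width_cm(profile: ScanCurve) -> float:
        p = normalize_to_cax(profile)
        p = normalize_to_cax(recenter(p))
        return fwhm(p) / 10.0

    a = width_cm(cross)
    b = width_cm(inplane)
    return FieldGeometry(
        collimator_x_cm=cross.field_x_cm,
        collimator_y_cm=cross.field_y_cm,
        ssd_cm=cross.ssd_cm,
        measurement_depth_mm=float(cross.scan_depth_mm),
        fwhm_cross_cm=a,
        fwhm_in_cm=b,
        sclin_cm=equivalent_square(a, b),
    )
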