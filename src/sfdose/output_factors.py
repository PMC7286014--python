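"""Field output factors (FOFs) and small-field output correction factors.

The field output factor of a clinical field f_clin relative to the
machine-specific reference field f_msr (here 10 x 10 cm2) is

    Omega = (M_clin / M_msr) * k(S_clin)

where M are detector readings and k is the detector-specific output
correction factor tabulated against the equivalent square field size
S_clin.  The uncorrected FOF is the bare reading ratio; k absorbs volume
averaging and fluence-perturbation effects that make small-field reading
ratios detector dependent.

The intermediate field method (IFM) daisy-chains a small-field detector
(reliable in small fields) to a reference ionization chamber (reliable in
large fields) through an intermediate field f_int:

    Omega = (M^det_clin / M^det_int) * k^det(clin<-int)
          * (M^ic_int / M^ic_msr) * k^ic(int<-msr)

With f_int = f_msr and k^ic = 1 this reduces exactly to the direct method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    ConsistencyError,
    RangeError,
    ValidationError,
)
from .field_geometry import FieldGeometry

__all__ = [
    "ReadingSet",
    "KFactorTable",
    "FOFTable",
    "IFMConfig",
    "uncorrected_fof",
    "derive_k",
    "interpolate_k",
    "corrected_fof",
    "ifm_fof",
    "build_fof_table",
    "small_field_flag",
]

#: coefficient of variation above which repeated readings are flagged
CV_WARNING_THRESHOLD = 0.01


@dataclass
class ReadingSet:
    """Repeated electrometer readings for one (detector, field) pair."""

    detector_id: str
    field: FieldGeometry
    readings: Sequence[float]
    environment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        readings = np.asarray(self.readings, dtype=float)
        if readings.ndim != 1 or len(readings) < 1:
            raise ValidationError("need at least one reading")
        if np.any(readings <= 0):
            raise ValidationError("readings must be positive")
        self.readings = readings
        if len(readings) >= 2:
            cv = readings.std(ddof=1) / readings.mean()
            if cv > CV_WARNING_THRESHOLD:
                warnings.warn(
                    f"{self.detector_id}: reading CV {cv:.2%} exceeds "
                    f"{CV_WARNING_THRESHOLD:.0%}",
                    stacklevel=2,
                )

    @property
    def mean(self) -> float:
        return float(np.mean(self.readings))


@dataclass
class KFactorTable:
    """Output correction factors k(S_clin) for one detector model.

    ``points`` is an ordered list of (sclin_cm, k) pairs with strictly
    increasing abscissae.  k tables are input data (protocol tables or
    generator-implied values), never embedded constants.
    """

    detector_model: str
    points: Sequence[tuple[float, float]]
    source: str = ""

    def __post_init__(self) -> None:
        pts = [(float(s), float(k)) for s, k in self.points]
        if not pts:
            raise ValidationError("k table must be non-empty")
        sclin = np.array([p[0] for p in pts])
        kvals = np.array([p[1] for p in pts])
        if not np.all(np.diff(sclin) > 0):
            raise ValidationError("k-table abscissae must be strictly increasing")
        if np.any(kvals <= 0):
            raise ValidationError("k values must be positive")
        self.points = pts
        self._sclin = sclin
        self._k = kvals

    @classmethod
    def from_csv(cls, path, detector_model: str) -> "KFactorTable":
        """Load one detector's rows from a ``detector_model,sclin_cm,k`` CSV."""
        # round_trip parsing: k-table knots must match the written values exactly
        frame = pd.read_csv(path, float_precision="round_trip")
        rows = frame[frame["detector_model"] == detector_model]
        if rows.empty:
            raise ConfigurationError(
                f"no k-table rows for detector model {detector_model!r}"
            )
        rows = rows.sort_values("sclin_cm")
        return cls(
            detector_model=detector_model,
            points=list(zip(rows["sclin_cm"], rows["k"])),
            source=str(path),
        )


def uncorrected_fof(clin: ReadingSet, msr: ReadingSet) -> float:
    """Ratio of mean clinical-field reading to mean reference-field reading.

    Readings are averaged before ratioing (ratio of means), matching
    charge-collection practice.
    """
    if clin.detector_id != msr.detector_id:
        raise ConsistencyError(
            f"detector mismatch: {clin.detector_id} vs {msr.detector_id}"
        )
    return clin.mean / msr.mean


def derive_k(dose_ratio: float, reading_ratio: float) -> float:
    """Empirical output correction factor: true dose ratio / reading ratio."""
    if dose_ratio <= 0 or reading_ratio <= 0:
        raise ValidationError("ratios must be positive")
    return dose_ratio / reading_ratio


def interpolate_k(table: KFactorTable, sclin_cm: float, clamp: bool = False) -> float:
    """Piecewise-linear interpolation of k at ``sclin_cm``; exact at knots.

    Out-of-range queries raise a :class:`RangeError` unless ``clamp`` is
    set, in which case the endpoint value is returned with a warning.
    Extrapolating k below the smallest tabulated field is exactly the
    failure mode the strict default protects against.
    """
    lo, hi = table._sclin[0], table._sclin[-1]
    if not lo <= sclin_cm <= hi:
        if not clamp:
            raise RangeError(
                f"S_clin {sclin_cm:.3f} cm outside k-table range "
                f"[{lo:.3f}, {hi:.3f}] cm for {table.detector_model}"
            )
        warnings.warn(
            f"S_clin {sclin_cm:.3f} cm clamped to k-table range "
            f"[{lo:.3f}, {hi:.3f}] cm",
            stacklevel=2,
        )
        sclin_cm = min(max(sclin_cm, lo), hi)
    return float(np.interp(sclin_cm, table._sclin, table._k))


def corrected_fof(uncorrected: float, k: float) -> float:
    """Apply the output correction factor to an uncorrected FOF."""
    if uncorrected <= 0 or k <= 0:
        raise ValidationError("uncorrected FOF and k must be positive")
    return uncorrected * k


def ifm_fof(
    m_clin_det: float,
    m_int_det: float,
    k_det_clin_int: float,
    m_int_ic: float,
    m_msr_ic: float,
    k_ic_int_msr: float,
) -> float:
    """Intermediate field method: daisy-chained corrected output factor."""
    args = (m_clin_det, m_int_det, k_det_clin_int, m_int_ic, m_msr_ic, k_ic_int_msr)
    if any(a <= 0 for a in args):
        raise ValidationError("all readings and factors must be positive")
    return (m_clin_det / m_int_det) * k_det_clin_int * (m_int_ic / m_msr_ic) * k_ic_int_msr


def small_field_flag(sclin_cm: float, threshold_cm: float) -> bool:
    """Advisory flag: field is 'small' when S_clin is strictly below threshold.

    The physical criterion is loss of lateral charged particle equilibrium;
    the threshold is configuration, not a protocol constant.
    """
    if sclin_cm <= 0 or threshold_cm <= 0:
        raise ValidationError("sizes must be positive")
    return sclin_cm < threshold_cm


@dataclass
class IFMConfig:
    """Configuration of the intermediate-field daisy chain.

    ``chamber_readings`` must contain the reference ionization chamber's
    reading sets at the intermediate and msr fields; ``chamber_k_table``
    is that chamber's k(S_clin) table (relative to msr).
    """

    intermediate_side_cm: float
    chamber_readings: Sequence[ReadingSet]
    chamber_k_table: KFactorTable
    chamber_id: str = "IC"


@dataclass
class FOFTable:
    """Per-detector table of uncorrected and corrected output factors."""

    detector_id: str
    frame: pd.DataFrame  # columns: collimator_side_cm, sclin_cm,
    #          fof_uncorrected, k_applied, fof_corrected, method, small_field

    def __post_init__(self) -> None:
        fof = self.frame["fof_corrected"].to_numpy()
        if np.any(fof <= 0) or np.any(fof > 1.2):
            raise ValidationError("corrected FOFs must lie in (0, 1.2]")
        ordered = self.frame.sort_values("collimator_side_cm")
        if np.any(np.diff(ordered["fof_corrected"].to_numpy()) < -1e-12):
            warnings.warn(
                f"{self.detector_id}: corrected FOF not monotone in field size",
                stacklevel=2,
            )

    def fof(self, side_cm: float, column: str = "fof_corrected") -> float:
        row = self.frame[self.frame["collimator_side_cm"] == side_cm]
        if len(row) != 1:
            raise ConsistencyError(f"no unique row for side {side_cm} cm")
        return float(row[column].iloc[0])


def _find_reading(
    readings: Iterable[ReadingSet], side_cm: float, what: str
) -> ReadingSet:
    matches = [
        r for r in readings if float(r.field.collimator_x_cm) == float(side_cm)
    ]
    if len(matches) != 1:
        raise ConfigurationError(
            f"expected exactly one {what} reading set at {side_cm} cm, "
            f"found {len(matches)}"
        )
    return matches[0]


def build_fof_table(
    readings: Sequence[ReadingSet],
    geometries: Mapping[float, FieldGeometry],
    k_table: KFactorTable,
    method: str = "direct",
    ifm_config: IFMConfig | None = None,
    msr_side_cm: float = 10.0,
    small_field_threshold_cm: float = 2.0,
) -> FOFTable:
    """Assemble a per-detector FOF table across clinical field sizes.

    ``geometries`` maps collimator side (cm) to a :class:`FieldGeometry`
    with ``sclin_cm`` filled in; the msr field must be present among
    ``readings``.  Under ``method="ifm"`` the detector's chain correction
    k(clin<-int) is derived from its msr-referenced table as
    k(S_clin)/k(S_int), and the reference chamber closes the chain from
    the intermediate field to msr.
    """
    if method not in ("direct", "ifm"):
        raise ConfigurationError(f"unknown method {method!r}")
    if not readings:
        raise ConfigurationError("no reading sets supplied")
    detector_id = readings[0].detector_id
    if any(r.detector_id != detector_id for r in readings):
        raise ConsistencyError("all reading sets must share one detector")
    try:
        msr = _find_reading(readings, msr_side_cm, "msr")
    except ConfigurationError:
        raise ConfigurationError(
            f"msr field ({msr_side_cm} cm) missing from readings"
        ) from None

    if method == "ifm":
        if ifm_config is None:
            raise ConfigurationError("method='ifm' requires an IFMConfig")
        s_int_side = ifm_config.intermediate_side_cm
        det_int = _find_reading(readings, s_int_side, "detector intermediate")
        ic_int = _find_reading(
            ifm_config.chamber_readings, s_int_side, "chamber intermediate"
        )
        ic_msr = _find_reading(
            ifm_config.chamber_readings, msr_side_cm, "chamber msr"
        )
        s_int = _sclin_of(geometries, s_int_side)
        k_det_int = interpolate_k(k_table, s_int)
        k_ic_int = interpolate_k(ifm_config.chamber_k_table, s_int)

    rows = []
    for reading in sorted(readings, key=lambda r: r.field.collimator_x_cm):
        side = float(reading.field.collimator_x_cm)
        sclin = _sclin_of(geometries, side)
        u = uncorrected_fof(reading, msr)
        if side == msr_side_cm:
            # FOF at the msr field is 1 by definition, before and after correction
            k_applied, corrected, row_method = 1.0, 1.0, method
        elif method == "direct":
            k_applied = interpolate_k(k_table, sclin)
            corrected = corrected_fof(u, k_applied)
            row_method = "direct"
        else:
            k_clin = interpolate_k(k_table, sclin)
            k_chain = k_clin / k_det_int
            corrected = ifm_fof(
                reading.mean,
                det_int.mean,
                k_chain,
                ic_int.mean,
                ic_msr.mean,
                k_ic_int,
            )
            k_applied = k_chain * k_ic_int
            row_method = "ifm"
        rows.append(
            {
                "collimator_side_cm": side,
                "sclin_cm": sclin,
                "fof_uncorrected": u,
                "k_applied": k_applied,
                "fof_corrected": corrected,
                "method": row_method,
                "small_field": small_field_flag(sclin, small_field_threshold_cm),
            }
        )
    frame = pd.DataFrame(rows).sort_values("collimator_side_cm", ignore_index=True)
    return FOFTable(detector_id=detector_id, frame=frame)


def _sclin_of(geometries: Mapping[float, FieldGeometry], side_cm: float) -> float:
    try:
        geometry = geometries[side_cm]
    except KeyError:
        raise ConfigurationError(
            f"no field geometry for collimator side {side_cm} cm"
        ) from None
    if geometry.sclin_cm is None:
        raise ConfigurationError(
            f"geometry for {side_cm} cm has no computed S_clin"
        )
    return float(geometry.sclin_cm)
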