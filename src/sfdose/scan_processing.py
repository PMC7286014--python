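"""Water-phantom scan curves: parsing, smoothing and metric extraction.

A :class:`ScanCurve` holds one depth-dose or lateral-profile scan together
with its acquisition geometry (detector, collimator setting, SSD, scan
depth).  The operations in this module implement the standard commissioning
metrics: percentage depth dose at a depth, depth of maximum dose (d_max),
full width at half maximum (FWHM) and the 20-80% penumbra widths.

Conventions
-----------
* depth in mm, positive downward from the water surface;
* lateral positions in mm, 0 on the beam central axis;
* field sizes in cm at the 100 cm isocentre plane unless stated;
* dose values are relative (arbitrary units until normalized).

Level crossings and point queries use linear interpolation between the
bracketing samples; d_max is refined by a parabolic fit through the maximum
sample and its neighbours.  Smoothing is local polynomial least squares
(Savitzky-Golay), which preserves peak position and any polynomial of the
fitted order exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from scipy.signal import savgol_filter

from .errors import (
    DegenerateInputError,
    RangeError,
    ScanParseError,
    ShapeError,
    ValidationError,
)

__all__ = [
    "ScanCurve",
    "ScanSet",
    "read_scan_table",
    "write_scan_table",
    "smooth",
    "normalize_to_max",
    "normalize_to_cax",
    "pdd_at_depth",
    "find_dmax",
    "level_crossings",
    "fwhm",
    "penumbra_widths",
    "recenter",
]

AXES = ("depth", "crossline", "inline")
LATERAL_AXES = ("crossline", "inline")
NORMALIZATIONS = ("raw", "max100", "cax100")


@dataclass(frozen=True)
class ScanCurve:
    """One measured or simulated scan curve with its geometry metadata.

    Parameters
    ----------
    axis
        ``"depth"`` for a percentage-depth-dose scan, ``"crossline"`` or
        ``"inline"`` for a lateral profile.
    positions
        Strictly increasing coordinates in mm (depth or off-axis distance).
    values
        Non-negative relative dose values, one per position.
    detector_id
        Detector label, e.g. ``"CC01"``.
    field_x_cm, field_y_cm
        Collimator setting at 100 cm.
    ssd_cm
        Source-surface distance.
    scan_depth_mm
        Depth of a lateral profile; must be absent for depth scans.
    normalized
        ``"raw"``, ``"max100"`` (maximum = 100) or ``"cax100"`` (central
        axis = 100).
    """

    axis: str
    positions: np.ndarray
    values: np.ndarray
    detector_id: str
    field_x_cm: float
    field_y_cm: float
    ssd_cm: float = 100.0
    scan_depth_mm: float | None = None
    normalized: str = "raw"

    def __post_init__(self) -> None:
        positions = np.asarray(self.positions, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "positions", positions)
        object.__setattr__(self, "values", values)
        if self.axis not in AXES:
            raise ValidationError(f"unknown axis {self.axis!r}")
        if self.normalized not in NORMALIZATIONS:
            raise ValidationError(f"unknown normalization {self.normalized!r}")
        if positions.ndim != 1 or values.ndim != 1:
            raise ValidationError("positions and values must be 1-D")
        if len(positions) != len(values):
            raise ValidationError("positions and values must have equal length")
        if len(positions) < 5:
            raise ValidationError("a scan curve needs at least 5 samples")
        if not np.all(np.diff(positions) > 0):
            raise ValidationError("positions must be strictly increasing")
        if np.any(values < 0):
            raise ValidationError("dose values must be non-negative")
        if self.axis == "depth" and self.scan_depth_mm is not None:
            raise ValidationError("depth scans must not carry scan_depth_mm")
        if self.axis in LATERAL_AXES and self.scan_depth_mm is None:
            raise ValidationError("lateral profiles require scan_depth_mm")

    @property
    def key(self) -> tuple:
        """Identity of the curve within a :class:`ScanSet`."""
        return (
            self.detector_id,
            self.axis,
            float(self.field_x_cm),
            float(self.field_y_cm),
            None if self.scan_depth_mm is None else float(self.scan_depth_mm),
        )

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class ScanSet:
    """A collection of scan curves with unique (detector, axis, field, depth) keys."""

    curves: list[ScanCurve] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for curve in self.curves:
            if curve.key in seen:
                raise ValidationError(f"duplicate curve key {curve.key}")
            seen.add(curve.key)

    def add(self, curve: ScanCurve) -> None:
        if any(curve.key == c.key for c in self.curves):
            raise ValidationError(f"duplicate curve key {curve.key}")
        self.curves.append(curve)

    def get(self, **criteria) -> ScanCurve:
        """Return the unique curve whose attributes match ``criteria``."""
        matches = [
            c
            for c in self.curves
            if all(getattr(c, k) == v for k, v in criteria.items())
        ]
        if len(matches) != 1:
            raise ValidationError(
                f"{len(matches)} curves match {criteria}; expected exactly 1"
            )
        return matches[0]

    def __iter__(self) -> Iterator[ScanCurve]:
        return iter(self.curves)

    def __len__(self) -> int:
        return len(self.curves)


# ---------------------------------------------------------------------------
# scan-file dialect


_HEADER_KEYS = {
    "detector",
    "field_x_cm",
    "field_y_cm",
    "ssd_cm",
    "axis",
    "depth_mm",
    "units",
    "normalized",
}


def read_scan_table(path: str | Path) -> ScanSet:
    """Read a scan file in the sfdose text dialect.

    The dialect is UTF-8 text: header lines ``#key=value`` (keys: detector,
    field_x_cm, field_y_cm, ssd_cm, axis, depth_mm [lateral only], units),
    then two comma-separated numeric columns ``position_mm,value``.  A
    repeated header block starts a new curve, so one file can carry several
    curves.
    """
    path = Path(path)
    scan_set = ScanSet()
    header: dict[str, str] = {}
    rows: list[tuple[float, float]] = []
    in_data = False
    header_line = 0

    def flush(line_number: int) -> None:
        nonlocal header, rows, in_data
        if not in_data:
            return
        if not rows:
            raise ScanParseError("header block with no data rows", header_line)
        scan_set.add(_curve_from_block(header, rows, line_number))
        header, rows, in_data = {}, [], False

    line_number = 0
    with path.open("r", encoding="utf-8") as handle:
        for line_number, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if in_data:
                    flush(line_number)
                if not header:
                    header_line = line_number
                body = line[1:].strip()
                if "=" not in body:
                    raise ScanParseError(
                        f"malformed header {line!r} (expected #key=value)",
                        line_number,
                    )
                key, _, value = body.partition("=")
                key = key.strip()
                if key not in _HEADER_KEYS:
                    raise ScanParseError(f"unknown header key {key!r}", line_number)
                header[key] = value.strip()
            else:
                parts = line.split(",")
                if len(parts) != 2:
                    raise ScanParseError(
                        f"expected 'position_mm,value', got {line!r}", line_number
                    )
                try:
                    rows.append((float(parts[0]), float(parts[1])))
                except ValueError:
                    raise ScanParseError(
                        f"non-numeric position/value {line!r}", line_number
                    ) from None
                in_data = True
        flush(line_number)
    if len(scan_set) == 0:
        raise ScanParseError(f"no curves found in {path}")
    return scan_set


def _curve_from_block(
    header: dict[str, str], rows: list[tuple[float, float]], line_number: int
) -> ScanCurve:
    required = {"detector", "field_x_cm", "field_y_cm", "axis"}
    missing = required - header.keys()
    if missing:
        raise ScanParseError(
            f"missing header keys {sorted(missing)}", line_number
        )
    axis = header["axis"]
    rows = sorted(rows)
    positions, values = zip(*rows)
    try:
        return ScanCurve(
            axis=axis,
            positions=np.array(positions),
            values=np.array(values),
            detector_id=header["detector"],
            field_x_cm=float(header["field_x_cm"]),
            field_y_cm=float(header["field_y_cm"]),
            ssd_cm=float(header.get("ssd_cm", 100.0)),
            scan_depth_mm=(
                float(header["depth_mm"]) if "depth_mm" in header else None
            ),
            normalized=header.get("normalized", "raw"),
        )
    except ValueError as exc:
        raise ScanParseError(str(exc), line_number) from exc


def write_scan_table(curves: Iterable[ScanCurve] | ScanSet, path: str | Path) -> Path:
    """Write curves to one file in the dialect read by :func:`read_scan_table`.

    Numbers are written with ``repr``-level precision so that a
    write-then-read round trip reproduces values to better than 1e-9
    relative.
    """
    path = Path(path)
    lines: list[str] = []
    for curve in curves:
        lines.append(f"#detector={curve.detector_id}")
        lines.append(f"#axis={curve.axis}")
        lines.append(f"#field_x_cm={curve.field_x_cm:.6g}")
        lines.append(f"#field_y_cm={curve.field_y_cm:.6g}")
        lines.append(f"#ssd_cm={curve.ssd_cm:.6g}")
        if curve.scan_depth_mm is not None:
            lines.append(f"#depth_mm={curve.scan_depth_mm:.6g}")
        lines.append(f"#normalized={curve.normalized}")
        for x, v in zip(curve.positions, curve.values):
            lines.append(f"{float(x)!r},{float(v)!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# smoothing and normalization


def smooth(curve: ScanCurve, window: int = 7, polyorder: int = 2) -> ScanCurve:
    """Savitzky-Golay smoothing of a scan curve.

    Fits a least-squares polynomial of order ``polyorder`` in a sliding
    window of ``window`` samples; polynomials up to that order pass through
    unchanged. Endpoints are completed by evaluating the polynomial fitted
    to the terminal window.
    """
    if window % 2 == 0:
        raise ValidationError("smoothing window must be odd")
    if not 3 <= window <= len(curve):
        raise ValidationError(
            f"window must be in [3, {len(curve)}], got {window}"
        )
    if polyorder >= window:
        raise ValidationError("polyorder must be smaller than window")
    spacing = np.diff(curve.positions)
    if np.allclose(spacing, spacing[0], rtol=1e-6, atol=0.0):
        smoothed = savgol_filter(curve.values, window, polyorder, mode="interp")
    else:
        smoothed = _savgol_nonuniform(curve.positions, curve.values, window, polyorder)
    return replace(curve, values=np.maximum(smoothed, 0.0))


def _savgol_nonuniform(
    x: np.ndarray, y: np.ndarray, window: int, polyorder: int
) -> np.ndarray:
    """Per-point windowed polynomial fit for non-uniform grids."""
    half = window // 2
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - half, n - window))
        sel = slice(lo, lo + window)
        # local coordinates keep the Vandermonde system well conditioned
        coeffs = np.polynomial.polynomial.polyfit(x[sel] - x[i], y[sel], polyorder)
        out[i] = coeffs[0]
    return out


def normalize_to_max(curve: ScanCurve) -> ScanCurve:
    """Scale a depth curve so its maximum equals 100."""
    if curve.axis != "depth":
        raise ValidationError("normalize_to_max applies to depth scans")
    peak = float(np.max(curve.values))
    if peak <= 0:
        raise DegenerateInputError("cannot normalize an all-zero curve")
    return replace(curve, values=curve.values * (100.0 / peak), normalized="max100")


def normalize_to_cax(profile: ScanCurve) -> ScanCurve:
    """Scale a lateral profile so its value on the central axis equals 100."""
    if profile.axis not in LATERAL_AXES:
        raise ValidationError("normalize_to_cax applies to lateral profiles")
    if not profile.positions[0] <= 0.0 <= profile.positions[-1]:
        raise RangeError("central axis (position 0) outside scan range")
    cax = float(np.interp(0.0, profile.positions, profile.values))
    if cax <= 0:
        raise DegenerateInputError("central-axis value is not positive")
    return replace(profile, values=profile.values * (100.0 / cax), normalized="cax100")


# ---------------------------------------------------------------------------
# depth-dose metrics


def pdd_at_depth(curve: ScanCurve, depth_mm: float) -> float:
    """Percentage depth dose at ``depth_mm`` by linear interpolation.

    The curve must be a depth scan normalized to 100 at its maximum
    (``normalized="max100"``).
    """
    if curve.axis != "depth":
        raise ValidationError("pdd_at_depth applies to depth scans")
    if curve.normalized != "max100":
        raise ValidationError("curve must be normalized to max100 first")
    if not curve.positions[0] <= depth_mm <= curve.positions[-1]:
        raise RangeError(
            f"depth {depth_mm} mm outside scan range "
            f"[{curve.positions[0]}, {curve.positions[-1]}] mm"
        )
    return float(np.interp(depth_mm, curve.positions, curve.values))


def find_dmax(curve: ScanCurve) -> float:
    """Depth of maximum dose, refined by a parabola through the peak sample.

    A flat plateau of tied maxima returns the plateau midpoint.  If the
    maximum sits on a scan boundary the boundary depth is returned with a
    warning (no interior refinement is possible there).
    """
    if curve.axis != "depth":
        raise ValidationError("find_dmax applies to depth scans")
    values = curve.values
    positions = curve.positions
    peak = np.max(values)
    tied = np.flatnonzero(values == peak)
    if len(tied) > 1:
        return float(0.5 * (positions[tied[0]] + positions[tied[-1]]))
    i = int(tied[0])
    if i == 0 or i == len(values) - 1:
        warnings.warn(
            "maximum at scan boundary; returning boundary depth unrefined",
            stacklevel=2,
        )
        return float(positions[i])
    # parabola through the three samples around the peak (grid may be nonuniform)
    a, b, c = np.polyfit(positions[i - 1 : i + 2], values[i - 1 : i + 2], 2)
    if a >= 0:  # numerically flat triple; fall back to the sample
        return float(positions[i])
    vertex = -b / (2.0 * a)
    lo, hi = positions[i - 1], positions[i + 1]
    return float(min(max(vertex, lo), hi))


# ---------------------------------------------------------------------------
# lateral-profile metrics


def level_crossings(profile: ScanCurve, level: float) -> tuple[float, float]:
    """Positions where a profile crosses ``level`` (percent of CAX dose).

    The profile must be normalized to ``cax100``.  Each crossing is located
    by linear interpolation between the bracketing samples; exactly one
    crossing per side of the peak is required, otherwise a
    :class:`ShapeError` naming the offending side is raised.
    """
    if profile.axis not in LATERAL_AXES:
        raise ValidationError("level_crossings applies to lateral profiles")
    if profile.normalized != "cax100":
        raise ValidationError("profile must be normalized to cax100 first")
    if not 0 < level < 100:
        raise ValidationError("level must be in (0, 100) percent")
    x = profile.positions
    v = profile.values - level
    crossings: list[float] = []
    for i in range(len(v) - 1):
        if v[i] == 0.0:
            crossings.append(float(x[i]))
        elif v[i] * v[i + 1] < 0:
            t = v[i] / (v[i] - v[i + 1])
            crossings.append(float(x[i] + t * (x[i + 1] - x[i])))
    if v[-1] == 0.0:
        crossings.append(float(x[-1]))
    peak_pos = float(x[int(np.argmax(profile.values))])
    left = [c for c in crossings if c < peak_pos]
    right = [c for c in crossings if c >= peak_pos]
    if len(left) != 1:
        raise ShapeError(
            f"{len(left)} crossings of {level}% on the left side; expected 1"
        )
    if len(right) != 1:
        raise ShapeError(
            f"{len(right)} crossings of {level}% on the right side; expected 1"
        )
    return left[0], right[0]


def fwhm(profile: ScanCurve) -> float:
    """Full width at half maximum (dosimetric field width), in mm."""
    left, right = level_crossings(profile, 50.0)
    return right - left


def penumbra_widths(profile: ScanCurve) -> tuple[float, float]:
    """20-80% penumbra widths (left, right) of a lateral profile, in mm."""
    left20, right20 = level_crossings(profile, 20.0)
    left80, right80 = level_crossings(profile, 80.0)
    return abs(left80 - left20), abs(right20 - right80)


def recenter(profile: ScanCurve) -> ScanCurve:
    """Shift positions so the midpoint of the 50% crossings is at 0."""
    if profile.axis not in LATERAL_AXES:
        raise ValidationError("recenter applies to lateral profiles")
    if profile.normalized == "cax100":
        work = profile
    else:
        # use half of the profile maximum for centering when CAX
        # normalization is not available yet
        peak = float(np.max(profile.values))
        if peak <= 0:
            raise DegenerateInputError("cannot recenter an all-zero profile")
        work = replace(
            profile, values=profile.values * (100.0 / peak), normalized="cax100"
        )
    left, right = level_crossings(work, 50.0)
    mid = 0.5 * (left + right)
    return replace(profile, positions=profile.positions - mid)
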