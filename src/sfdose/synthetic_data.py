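"""Synthetic golden-beam and detector-response generator.

Emulates a 6 MV flattened photon beam (TPR20,10 = 0.665) and the detector
effects that make small-field reading ratios detector dependent, so the
whole analysis chain can be exercised with known ground truth:

* depth dose: bi-exponential build-up/attenuation
  ``PDD(d) ~ (1 - exp(-a d)) * exp(-mu d)``, with maximum at
  ``d_max = ln(1 + a/mu) / a``;
* lateral profile: error-function edges from Gaussian source blur,
  ``P(x) = O(S) * 1/2 [erf((w/2 - x)/(sigma sqrt2)) + erf((w/2 + x)/(sigma sqrt2))]``
  with ``w`` the field width projected to the scan depth;
* field output factor: saturating growth with field size times a smooth
  source-occlusion drop below an onset width, normalized to exactly 1 at
  the 10 cm machine-specific reference field;
* detector response ``r(S)``: 1-D top-hat volume averaging over the
  detector's sensitive length, times a signed exponential
  over/under-response (shielded diodes over-respond in small fields from
  scatter off the dense encapsulation; unshielded diodes under-respond;
  chambers are near-neutral), normalized so ``r(10 cm) = 1``.

The implied output correction factor is then ``k(S) = 1 / r(S)`` — the
exact algebraic inverse of the response perturbation — so a noise-free
pipeline run must recover the true output factor to machine precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import erf

from .errors import ConfigurationError, ValidationError
from .field_geometry import FieldGeometry, sclin_from_profiles
from .output_factors import ReadingSet
from .scan_processing import ScanCurve, write_scan_table

__all__ = [
    "BeamModel",
    "DetectorResponseModel",
    "ScenarioConfig",
    "SyntheticScenario",
    "default_detectors",
    "true_profile",
    "true_pdd",
    "true_fof",
    "detector_response",
    "implied_k",
    "simulate_readings",
    "generate_scenario",
]


@dataclass(frozen=True)
class BeamModel:
    """Parameters of the synthetic flattened 6 MV beam.

    ``dmax_mm`` and ``mu_per_mm`` are the physical handles (depth of dose
    maximum and exponential attenuation); the build-up coefficient is
    solved from them.  ``sigma_mm`` is the Gaussian source-blur scale of
    the profile edges at the measurement depth.  The output-factor plateau
    is ``1 - c1 exp(-S/lambda)`` with a smooth occlusion drop below
    ``occlusion_onset_cm``.  Small per-axis width biases mimic the
    cross-plane / in-plane asymmetry of a real collimator.
    """

    energy_label: str = "6 MV"
    tpr2010: float = 0.665
    dmax_mm: float = 15.0
    mu_per_mm: float = 0.0050
    sigma_mm: float = 3.0
    occlusion_onset_cm: float = 1.2
    occlusion_scale_cm: float = 2.0
    fof_drop_c1: float = 0.45
    fof_scale_cm: float = 4.0
    ssd_cm: float = 100.0
    width_bias_cross_mm: float = -0.5
    width_bias_in_mm: float = +0.5

    def __post_init__(self) -> None:
        for name in (
            "tpr2010",
            "dmax_mm",
            "mu_per_mm",
            "sigma_mm",
            "occlusion_onset_cm",
            "occlusion_scale_cm",
            "fof_scale_cm",
            "ssd_cm",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.fof_drop_c1 < 1:
            raise ValidationError("fof_drop_c1 must be in (0, 1)")

    @property
    def buildup_per_mm(self) -> float:
        """Build-up coefficient a solving d_max = ln(1 + a/mu) / a."""
        mu, dmax = self.mu_per_mm, self.dmax_mm

        def fn(a: float) -> float:
            return np.log1p(a / mu) - a * dmax

        return float(brentq(fn, 1e-6, 10.0, xtol=1e-14))

    def projected_width_mm(self, field_cm: float, depth_mm: float, axis: str = "crossline") -> float:
        """Dosimetric aperture width at scan depth, with per-axis bias."""
        bias = self.width_bias_in_mm if axis == "inline" else self.width_bias_cross_mm
        ssd_mm = self.ssd_cm * 10.0
        return field_cm * 10.0 * (ssd_mm + depth_mm) / ssd_mm + bias

    def occlusion(self, field_cm: float) -> float:
        """Source-occlusion output drop: 1 above onset, smooth decay below."""
        if field_cm >= self.occlusion_onset_cm:
            return 1.0
        u = (self.occlusion_onset_cm - field_cm) / self.occlusion_scale_cm
        return float(np.exp(-(u * u)))


@dataclass(frozen=True)
class DetectorResponseModel:
    """Detector-specific perturbation of the reading ratio.

    ``aperture_mm`` is the 1-D sensitive length along the scan axis used
    for top-hat volume averaging (chamber cavity length or diode
    diameter).  ``beta`` and ``tau_cm`` parametrize the signed exponential
    over-response ``1 + beta exp(-S/tau)``: positive for shielded diodes,
    negative for unshielded diodes, ~0 for chambers.  ``pdd_tilt_per_mm``
    applies a small depth-linear tilt to emulate detector-dependent
    depth-dose differences.
    """

    detector_id: str
    kind: str  # microchamber | shielded_diode | unshielded_diode | reference_chamber
    aperture_mm: float = 0.0
    beta: float = 0.0
    tau_cm: float = 2.0
    pdd_tilt_per_mm: float = 0.0

    def __post_init__(self) -> None:
        kinds = ("microchamber", "shielded_diode", "unshielded_diode", "reference_chamber")
        if self.kind not in kinds:
            raise ValidationError(f"unknown detector kind {self.kind!r}")
        if self.aperture_mm < 0:
            raise ValidationError("aperture must be non-negative")
        if self.tau_cm <= 0:
            raise ValidationError("tau must be positive")
        if self.beta <= -1:
            raise ValidationError("beta must exceed -1 (response must stay positive)")


def default_detectors() -> dict[str, DetectorResponseModel]:
    """The study's detector set with nominal sensitive dimensions.

    Apertures are the 3.6 mm micro-chamber cavity length and 2.0 mm diode
    diameter; the scan detector EDGE has a 0.8 mm sensitive side.  The
    over/under-response amplitudes are fixture parameters tuned once so
    the uncorrected cross-detector spread at 1 cm sits in the few-percent
    regime typical of these detector classes.
    """
    return {
        "CC01": DetectorResponseModel(
            "CC01", "microchamber", aperture_mm=3.6, beta=0.0, pdd_tilt_per_mm=1.0e-4
        ),
        "PFD": DetectorResponseModel("PFD", "shielded_diode", aperture_mm=2.0, beta=0.10),
        "EFD": DetectorResponseModel(
            "EFD", "unshielded_diode", aperture_mm=2.0, beta=-0.06, pdd_tilt_per_mm=-8.0e-5
        ),
        "REF": DetectorResponseModel("REF", "reference_chamber", aperture_mm=0.0, beta=0.0),
    }


# ---------------------------------------------------------------------------
# golden-beam truth


def _profile_values(
    beam: BeamModel, field_cm: float, depth_mm: float, x_mm: np.ndarray, axis: str = "crossline"
) -> np.ndarray:
    w = beam.projected_width_mm(field_cm, depth_mm, axis)
    s = beam.sigma_mm * np.sqrt(2.0)
    edges = 0.5 * (erf((w / 2.0 - x_mm) / s) + erf((w / 2.0 + x_mm) / s))
    return beam.occlusion(field_cm) * edges


def true_profile(
    beam: BeamModel,
    field_cm: float,
    depth_mm: float,
    axis: str = "crossline",
    grid_mm: float = 0.2,
    detector_id: str = "TRUTH",
) -> ScanCurve:
    """Noise-free lateral profile with error-function edges.

    Sampled on a ``grid_mm`` grid spanning +-1.5 projected widths; the 50%
    level of an isolated erf edge sits exactly at the projected half-width,
    so the FWHM of a generated profile equals the projected width (up to
    edge overlap in the smallest fields).
    """
    if field_cm <= 0 or depth_mm < 0 or grid_mm <= 0:
        raise ValidationError("field, depth and grid must be positive")
    w = beam.projected_width_mm(field_cm, depth_mm, axis)
    half_span = 1.5 * w
    n = int(np.floor(half_span / grid_mm))
    x = np.arange(-n, n + 1) * grid_mm
    values = _profile_values(beam, field_cm, depth_mm, x, axis)
    return ScanCurve(
        axis=axis,
        positions=x,
        values=values,
        detector_id=detector_id,
        field_x_cm=field_cm,
        field_y_cm=field_cm,
        ssd_cm=beam.ssd_cm,
        scan_depth_mm=depth_mm,
        normalized="raw",
    )


def true_pdd(
    beam: BeamModel,
    field_cm: float,
    depths_mm: np.ndarray | None = None,
    detector_id: str = "TRUTH",
) -> ScanCurve:
    """Noise-free depth-dose curve, normalized to 100 at its analytic maximum."""
    if depths_mm is None:
        depths_mm = np.arange(0.0, 310.0 + 0.25, 0.5)
    depths_mm = np.asarray(depths_mm, dtype=float)
    if not np.all(np.diff(depths_mm) > 0):
        raise ValidationError("depths must be strictly increasing")
    a, mu = beam.buildup_per_mm, beam.mu_per_mm
    raw = -np.expm1(-a * depths_mm) * np.exp(-mu * depths_mm)
    peak = -np.expm1(-a * beam.dmax_mm) * np.exp(-mu * beam.dmax_mm)
    return ScanCurve(
        axis="depth",
        positions=depths_mm,
        values=100.0 * raw / peak,
        detector_id=detector_id,
        field_x_cm=field_cm,
        field_y_cm=field_cm,
        ssd_cm=beam.ssd_cm,
        normalized="max100",
    )


def true_fof(beam: BeamModel, sclin_cm: float, msr_cm: float = 10.0) -> float:
    """Ground-truth field output factor, exactly 1 at the msr field."""
    if sclin_cm <= 0:
        raise ValidationError("field size must be positive")

    def g(s: float) -> float:
        return (1.0 - beam.fof_drop_c1 * np.exp(-s / beam.fof_scale_cm)) * beam.occlusion(s)

    return g(sclin_cm) / g(msr_cm)


def _volume_average(beam: BeamModel, field_cm: float, aperture_mm: float, depth_mm: float) -> float:
    """Mean of the true profile over a centred top-hat aperture / CAX value."""
    if aperture_mm == 0.0:
        return 1.0
    half = aperture_mm / 2.0
    x = np.linspace(-half, half, 201)
    values = _profile_values(beam, field_cm, depth_mm, x)
    central = _profile_values(beam, field_cm, depth_mm, np.array([0.0]))[0]
    return float(np.trapezoid(values, x) / (aperture_mm * central))


def detector_response(
    det: DetectorResponseModel,
    beam: BeamModel,
    sclin_cm: float,
    depth_mm: float = 100.0,
    msr_cm: float = 10.0,
) -> float:
    """Relative detector response r(S), normalized so r(msr) = 1."""
    if sclin_cm <= 0:
        raise ValidationError("field size must be positive")

    def raw(s: float) -> float:
        va = _volume_average(beam, s, det.aperture_mm, depth_mm)
        return va * (1.0 + det.beta * np.exp(-s / det.tau_cm))

    return raw(sclin_cm) / raw(msr_cm)


def implied_k(
    det: DetectorResponseModel,
    beam: BeamModel,
    sclin_cm: float,
    depth_mm: float = 100.0,
    msr_cm: float = 10.0,
) -> float:
    """Output correction factor implied by the response model: 1 / r(S)."""
    return 1.0 / detector_response(det, beam, sclin_cm, depth_mm, msr_cm)


# ---------------------------------------------------------------------------
# scenario generation


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic commissioning scenario."""

    fields_cm: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 6.0, 10.0)
    detectors: Mapping[str, DetectorResponseModel] = field(default_factory=default_detectors)
    beam: BeamModel = field(default_factory=BeamModel)
    noise_sd: float = 0.003
    scan_noise_sd: float = 0.0
    n_repeats: int = 3
    profile_depth_mm: float = 100.0
    scan_detector: str = "EDGE"
    scan_detector_aperture_mm: float = 0.8
    msr_cm: float = 10.0

    def __post_init__(self) -> None:
        if not self.fields_cm:
            raise ConfigurationError("at least one field size required")
        if any(f <= 0 for f in self.fields_cm):
            raise ConfigurationError("field sizes must be positive")
        if self.msr_cm not in self.fields_cm:
            raise ConfigurationError("field list must include the msr field")
        if self.noise_sd < 0 or self.scan_noise_sd < 0:
            raise ConfigurationError("noise levels must be non-negative")
        if self.n_repeats < 1:
            raise ConfigurationError("need at least one repeat")

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigurationError("scenario config must be a YAML mapping")
        kwargs: dict = {}
        if "fields_cm" in raw:
            kwargs["fields_cm"] = tuple(float(f) for f in raw["fields_cm"])
        if "beam" in raw:
            kwargs["beam"] = BeamModel(**raw["beam"])
        if "detectors" in raw:
            kwargs["detectors"] = {
                name: DetectorResponseModel(detector_id=name, **params)
                for name, params in raw["detectors"].items()
            }
        for key in (
            "noise_sd",
            "scan_noise_sd",
            "n_repeats",
            "profile_depth_mm",
            "scan_detector",
            "scan_detector_aperture_mm",
            "msr_cm",
        ):
            if key in raw:
                kwargs[key] = raw[key]
        unknown = set(raw) - set(kwargs) - {"fields_cm", "beam", "detectors"}
        if unknown:
            raise ConfigurationError(f"unknown config keys {sorted(unknown)}")
        return cls(**kwargs)


@dataclass
class SyntheticScenario:
    """Manifest and ground truth of one generated scenario."""

    seed: int
    config: ScenarioConfig
    out_dir: Path
    files: list[Path]
    truth: dict  # per-field truth: Omega_true, dosimetric S_clin, widths, implied k


def _convolve_with_aperture(curve: ScanCurve, aperture_mm: float) -> ScanCurve:
    """Top-hat convolution emulating 1-D volume averaging during scanning."""
    if aperture_mm <= 0:
        return curve
    dx = float(curve.positions[1] - curve.positions[0])
    n = max(1, int(round(aperture_mm / dx)))
    if n % 2 == 0:  # keep the kernel symmetric about the sample
        n += 1
    kernel = np.ones(n) / n
    # edge padding keeps the flat tails flat
    padded = np.pad(curve.values, (n, n), mode="edge")
    smoothed = np.convolve(padded, kernel, mode="same")[n:-n]
    return replace(curve, values=smoothed)


def simulate_readings(
    config: ScenarioConfig,
    det: DetectorResponseModel,
    field_cm: float,
    rng: np.random.Generator,
) -> ReadingSet:
    """Repeated electrometer readings: Omega_true x r(S) x (1 + noise)."""
    omega = true_fof(config.beam, field_cm, config.msr_cm)
    r = detector_response(det, config.beam, field_cm, config.profile_depth_mm, config.msr_cm)
    noise = rng.normal(0.0, config.noise_sd, size=config.n_repeats) if config.noise_sd > 0 else np.zeros(config.n_repeats)
    readings = omega * r * (1.0 + noise)
    return ReadingSet(
        detector_id=det.detector_id,
        field=FieldGeometry(
            collimator_x_cm=field_cm,
            collimator_y_cm=field_cm,
            ssd_cm=config.beam.ssd_cm,
            measurement_depth_mm=config.profile_depth_mm,
        ),
        readings=readings,
    )


def generate_scenario(
    config: ScenarioConfig, seed: int, out_dir: str | Path
) -> SyntheticScenario:
    """Write a complete synthetic commissioning dataset to ``out_dir``.

    Emits, per field: scan-detector profiles (cross + inline) and a PDD
    per detector (scan files in the sfdose dialect); plus one readings CSV
    over all detectors and fields, a k-table CSV with the generator's
    implied correction factors, and ``truth.json``.  The k-table knots sit
    at the dosimetric S_clin extracted from the emitted scan-detector
    profiles — the same protocol-style index a user of a correction-factor
    table would look up — and the same seed always reproduces
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    beam = config.beam
    files: list[Path] = []
    truth: dict = {
        "seed": seed,
        "beam": {
            "tpr2010": beam.tpr2010,
            "dmax_mm": beam.dmax_mm,
            "mu_per_mm": beam.mu_per_mm,
            "sigma_mm": beam.sigma_mm,
        },
        "fields": {},
    }
    scan_det = DetectorResponseModel(
        config.scan_detector, "shielded_diode", aperture_mm=config.scan_detector_aperture_mm
    )

    # --- scan files: profiles from the scan detector, PDDs per detector
    for field_cm in sorted(config.fields_cm):
        profiles = []
        for axis in ("crossline", "inline"):
            p = true_profile(
                beam,
                field_cm,
                config.profile_depth_mm,
                axis=axis,
                detector_id=config.scan_detector,
            )
            p = _convolve_with_aperture(p, scan_det.aperture_mm)
            if config.scan_noise_sd > 0:
                noise = rng.normal(0.0, config.scan_noise_sd, size=len(p))
                p = replace(p, values=np.maximum(p.values * (1.0 + noise), 0.0))
            profiles.append(p)
        path = out_dir / f"profiles_{_fname(field_cm)}cm.scan"
        files.append(write_scan_table(profiles, path))

        geometry = sclin_from_profiles(*profiles)
        truth["fields"][_fkey(field_cm)] = {
            "collimator_side_cm": field_cm,
            "omega_true": true_fof(beam, field_cm, config.msr_cm),
            "projected_width_cross_mm": beam.projected_width_mm(
                field_cm, config.profile_depth_mm, "crossline"
            ),
            "projected_width_in_mm": beam.projected_width_mm(
                field_cm, config.profile_depth_mm, "inline"
            ),
            "fwhm_cross_cm": geometry.fwhm_cross_cm,
            "fwhm_in_cm": geometry.fwhm_in_cm,
            "sclin_dosimetric_cm": geometry.sclin_cm,
            "implied_k": {
                name: implied_k(det, beam, field_cm, config.profile_depth_mm, config.msr_cm)
                for name, det in config.detectors.items()
            },
        }

    pdd_curves = []
    for name, det in config.detectors.items():
        base = true_pdd(beam, config.msr_cm, detector_id=name)
        tilt = 1.0 + det.pdd_tilt_per_mm * (base.positions - beam.dmax_mm)
        values = np.maximum(base.values * tilt, 0.0)
        values = values * (100.0 / values.max())
        pdd_curves.append(replace(base, values=values))
    pdd_path = out_dir / "pdd.scan"
    files.append(write_scan_table(pdd_curves, pdd_path))

    # --- readings CSV
    reading_rows = ["detector,field_side_cm,defined_by,repeat,reading"]
    for name, det in sorted(config.detectors.items()):
        for field_cm in sorted(config.fields_cm):
            reading_set = simulate_readings(config, det, field_cm, rng)
            for repeat, value in enumerate(reading_set.readings, start=1):
                reading_rows.append(f"{name},{field_cm:g},jaw,{repeat},{float(value)!r}")
    readings_path = out_dir / "readings.csv"
    readings_path.write_text("\n".join(reading_rows) + "\n")
    files.append(readings_path)

    # --- implied k table, indexed by dosimetric S_clin
    k_rows = ["detector_model,sclin_cm,k"]
    for name, det in sorted(config.detectors.items()):
        for field_cm in sorted(config.fields_cm):
            entry = truth["fields"][_fkey(field_cm)]
            k = entry["implied_k"][name]
            k_rows.append(
                f"{name},{float(entry['sclin_dosimetric_cm'])!r},{float(k)!r}"
            )
    ktable_path = out_dir / "ktable.csv"
    ktable_path.write_text("\n".join(k_rows) + "\n")
    files.append(ktable_path)

    truth_path = out_dir / "truth.json"
    truth_path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    files.append(truth_path)

    return SyntheticScenario(
        seed=seed, config=config, out_dir=out_dir, files=files, truth=truth
    )


def _fname(field_cm: float) -> str:
    return f"{field_cm:g}".replace(".", "p")


def _fkey(field_cm: float) -> str:
    return f"{field_cm:g}"
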