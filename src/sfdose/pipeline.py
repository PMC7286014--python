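"""End-to-end analysis of a commissioning dataset on disk.

Glues the modules together in the order a physicist would run them: read
the scan files, extract dosimetric widths and S_clin per field, ratio the
readings, look up the correction factors, and summarize the cross-detector
spread.  The synthetic generator emits exactly this layout, so the same
entry point serves simulated and measured data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .dataset_comparison import ComparisonReport, summarize_fof
from .errors import ConfigurationError
from .field_geometry import FieldGeometry, sclin_from_profiles
from .output_factors import (
    FOFTable,
    IFMConfig,
    KFactorTable,
    ReadingSet,
    build_fof_table,
)
from .scan_processing import read_scan_table

__all__ = ["PipelineResult", "read_readings_csv", "run_fof_pipeline"]


@dataclass
class PipelineResult:
    """Everything the FOF pipeline computed for one dataset."""

    geometries: dict[float, FieldGeometry]
    fof_tables: dict[str, FOFTable]
    uncorrected_report: ComparisonReport | None
    corrected_report: ComparisonReport | None


def read_readings_csv(path: str | Path) -> dict[str, list[ReadingSet]]:
    """Read a ``detector,field_side_cm,defined_by,repeat,reading`` CSV.

    Returns reading sets grouped by detector, one set per field size.
    """
    frame = pd.read_csv(path, float_precision="round_trip")
    required = {"detector", "field_side_cm", "defined_by", "reading"}
    missing = required - set(frame.columns)
    if missing:
        raise ConfigurationError(f"readings CSV missing columns {sorted(missing)}")
    by_detector: dict[str, list[ReadingSet]] = {}
    group_keys = ["detector", "field_side_cm", "defined_by"]
    for (detector, side, defined_by), group in frame.groupby(group_keys, sort=True):
        by_detector.setdefault(str(detector), []).append(
            ReadingSet(
                detector_id=str(detector),
                field=FieldGeometry(
                    collimator_x_cm=float(side),
                    collimator_y_cm=float(side),
                    defined_by=str(defined_by),
                ),
                readings=group["reading"].to_numpy(),
            )
        )
    return by_detector


def measure_geometries(
    profile_files: Sequence[str | Path],
) -> dict[float, FieldGeometry]:
    """Extract S_clin per field from cross/in-plane profile scan files."""
    geometries: dict[float, FieldGeometry] = {}
    for path in profile_files:
        scan_set = read_scan_table(path)
        cross = scan_set.get(axis="crossline")
        inplane = scan_set.get(axis="inline")
        geometry = sclin_from_profiles(cross, inplane)
        geometries[float(geometry.collimator_x_cm)] = geometry
    return geometries


def run_fof_pipeline(
    scan_dir: str | Path,
    detectors_in_stats: Sequence[str] | None = None,
    method: str = "direct",
    intermediate_side_cm: float = 4.0,
    chamber_id: str = "REF",
    msr_side_cm: float = 10.0,
) -> PipelineResult:
    """Run the full FOF analysis on a dataset directory.

    Expects ``profiles_*.scan`` files (one per field, cross + inline),
    ``readings.csv`` and ``ktable.csv`` in ``scan_dir`` — the layout the
    synthetic generator emits.  Under ``method="ifm"`` the detector named
    ``chamber_id`` closes the daisy chain through the intermediate field.
    """
    scan_dir = Path(scan_dir)
    profile_files = sorted(scan_dir.glob("profiles_*.scan"))
    if not profile_files:
        raise ConfigurationError(f"no profiles_*.scan files in {scan_dir}")
    geometries = measure_geometries(profile_files)

    readings_by_detector = read_readings_csv(scan_dir / "readings.csv")
    ktable_path = scan_dir / "ktable.csv"

    fof_tables: dict[str, FOFTable] = {}
    for detector, reading_sets in readings_by_detector.items():
        k_table = KFactorTable.from_csv(ktable_path, detector)
        ifm_config = None
        if method == "ifm" and detector != chamber_id:
            if chamber_id not in readings_by_detector:
                raise ConfigurationError(
                    f"IFM chamber {chamber_id!r} has no readings"
                )
            ifm_config = IFMConfig(
                intermediate_side_cm=intermediate_side_cm,
                chamber_readings=readings_by_detector[chamber_id],
                chamber_k_table=KFactorTable.from_csv(ktable_path, chamber_id),
                chamber_id=chamber_id,
            )
        fof_tables[detector] = build_fof_table(
            reading_sets,
            geometries,
            k_table,
            method="direct" if detector == chamber_id else method,
            ifm_config=ifm_config,
            msr_side_cm=msr_side_cm,
        )

    uncorrected_report = corrected_report = None
    if detectors_in_stats is not None and len(detectors_in_stats) >= 2:
        tables = [fof_tables[d] for d in sorted(fof_tables)]
        uncorrected_report = summarize_fof(
            tables, detectors_in_stats, column="fof_uncorrected"
        )
        corrected_report = summarize_fof(
            tables, detectors_in_stats, column="fof_corrected"
        )
    return PipelineResult(
        geometries=geometries,
        fof_tables=fof_tables,
        uncorrected_report=uncorrected_report,
        corrected_report=corrected_report,
    )
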