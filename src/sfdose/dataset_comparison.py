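"""Cross-detector and cross-commissioning-dataset comparison statistics.

The comparison statistic throughout is the percent standard deviation,

    %SD = SD / mean * 100,

with the sample standard deviation (n-1 divisor).  Reports round with
round-half-even at the field's reporting precision: output factors to 3
decimals, SD to 2, %SD to 1 decimal, matching common commissioning-table
practice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConsistencyError, ValidationError
from .output_factors import FOFTable

__all__ = [
    "ComparisonReport",
    "MUDataset",
    "sample_sd",
    "percent_sd",
    "summary_percent_sd",
    "summarize_fof",
    "mlc_jaw_ratios",
    "mu_percent_sd",
    "render_report",
]


def sample_sd(values: Sequence[float]) -> float:
    """Sample standard deviation (n-1 divisor)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValidationError("sample SD requires at least two values")
    if np.all(values == values[0]):  # exact-zero guarantee for constant input
        return 0.0
    return float(values.std(ddof=1))


def percent_sd(values: Sequence[float]) -> float:
    """Percent standard deviation: sample SD over mean, times 100."""
    values = np.asarray(values, dtype=float)
    mean = values.mean() if values.size else 0.0
    if values.size < 2:
        raise ValidationError("percent SD requires at least two values")
    if mean <= 0:
        raise ValidationError("percent SD requires a positive mean")
    return float(sample_sd(values) / mean * 100.0)


def summary_percent_sd(mean: float, sd: float) -> float:
    """Percent SD from an already-summarized (mean, SD) pair."""
    if mean <= 0:
        raise ValidationError("mean must be positive")
    if sd < 0:
        raise ValidationError("SD must be non-negative")
    return sd / mean * 100.0


@dataclass
class MUDataset:
    """Calculated monitor units for one plan across commissioning datasets."""

    case: str
    technique: str  # "symmetric" | "imrt" | "vmat"
    mu_by_dataset: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.technique not in ("symmetric", "imrt", "vmat"):
            raise ValidationError(f"unknown technique {self.technique!r}")
        if len(self.mu_by_dataset) < 2:
            raise ValidationError("need MU from at least two datasets")
        if any(v <= 0 for v in self.mu_by_dataset.values()):
            raise ValidationError("MU values must be positive")


@dataclass
class ComparisonReport:
    """Per-index mean / SD / %SD across groups, plus the raw values.

    ``table`` has one row per index (field side in cm, or case label) with
    one raw column per group and the columns ``mean``, ``sd``,
    ``percent_sd`` computed over ``pooled_groups`` only; other groups are
    shown but excluded from the statistics.
    """

    index_name: str
    table: pd.DataFrame
    pooled_groups: tuple[str, ...]
    rounding: dict = field(
        default_factory=lambda: {"values": 3, "mean": 3, "sd": 2, "percent_sd": 1}
    )

    def __post_init__(self) -> None:
        if self.table.empty:
            raise ValidationError("comparison report must not be empty")
        if len(self.pooled_groups) < 2:
            raise ValidationError("need at least two groups in the statistics")
        if (self.table["percent_sd"] < 0).any():
            raise ValidationError("percent SD must be non-negative")

    def rounded(self) -> pd.DataFrame:
        """Report table with round-half-even at the reporting precision."""
        out = self.table.copy()
        for column in out.columns:
            if column == "mean":
                digits = self.rounding["mean"]
            elif column == "sd":
                digits = self.rounding["sd"]
            elif column == "percent_sd":
                digits = self.rounding["percent_sd"]
            elif pd.api.types.is_numeric_dtype(out[column]):
                digits = self.rounding["values"]
            else:
                continue
            out[column] = out[column].round(digits)
        return out


def summarize_fof(
    tables: Sequence[FOFTable],
    detectors_in_stats: Sequence[str] | None = None,
    column: str = "fof_corrected",
) -> ComparisonReport:
    """Cross-detector mean / SD / %SD per field size.

    All tables must share the same field-size index.  Detectors not listed
    in ``detectors_in_stats`` appear as raw columns but are excluded from
    the pooled statistics (the convention used when reference-class
    detectors are shown alongside the small-field set).
    """
    if not tables:
        raise ValidationError("no FOF tables supplied")
    index = tables[0].frame["collimator_side_cm"].to_numpy()
    for t in tables[1:]:
        other = t.frame["collimator_side_cm"].to_numpy()
        if len(other) != len(index) or not np.allclose(other, index):
            raise ConsistencyError(
                f"{t.detector_id}: field-size index does not match {tables[0].detector_id}"
            )
    labels = [t.detector_id for t in tables]
    if detectors_in_stats is None:
        pooled = tuple(labels)
    else:
        pooled = tuple(detectors_in_stats)
        missing = set(pooled) - set(labels)
        if missing:
            raise ConsistencyError(f"detectors {sorted(missing)} not among tables")
    if len(pooled) < 2:
        raise ValidationError("need at least two detectors in the statistics")
    data = {"collimator_side_cm": index}
    for t in tables:
        data[t.detector_id] = t.frame[column].to_numpy()
    frame = pd.DataFrame(data)
    pooled_values = frame[list(pooled)].to_numpy()
    frame["mean"] = pooled_values.mean(axis=1)
    frame["sd"] = pooled_values.std(axis=1, ddof=1)
    frame["percent_sd"] = frame["sd"] / frame["mean"] * 100.0
    return ComparisonReport(
        index_name="collimator_side_cm", table=frame, pooled_groups=pooled
    )


def mlc_jaw_ratios(
    fof_mlc: FOFTable, fof_jaw: FOFTable, column: str = "fof_uncorrected"
) -> pd.DataFrame:
    """Per-field-size ratio of MLC-defined to jaw-defined output factors."""
    mlc_index = fof_mlc.frame["collimator_side_cm"].to_numpy()
    jaw_index = fof_jaw.frame["collimator_side_cm"].to_numpy()
    if len(mlc_index) != len(jaw_index) or not np.allclose(mlc_index, jaw_index):
        raise ConsistencyError("MLC and jaw tables have different field-size indices")
    jaw = fof_jaw.frame[column].to_numpy()
    if np.any(jaw <= 0):
        raise ValidationError("jaw output factors must be positive")
    return pd.DataFrame(
        {
            "collimator_side_cm": mlc_index,
            "mlc": fof_mlc.frame[column].to_numpy(),
            "jaw": jaw,
            "ratio": fof_mlc.frame[column].to_numpy() / jaw,
        }
    )


def mu_percent_sd(cases: Sequence[MUDataset]) -> ComparisonReport:
    """Per-case mean MU, SD and %SD across commissioning datasets."""
    if not cases:
        raise ValidationError("no MU cases supplied")
    dataset_labels: list[str] = []
    for case in cases:
        for label in case.mu_by_dataset:
            if label not in dataset_labels:
                dataset_labels.append(label)
    rows = []
    for case in cases:
        values = [case.mu_by_dataset[d] for d in dataset_labels if d in case.mu_by_dataset]
        row = {"case": case.case, "technique": case.technique}
        for d in dataset_labels:
            row[d] = case.mu_by_dataset.get(d, np.nan)
        row["mean"] = float(np.mean(values))
        row["sd"] = sample_sd(values)
        row["percent_sd"] = percent_sd(values)
        rows.append(row)
    report = ComparisonReport(
        index_name="case",
        table=pd.DataFrame(rows),
        pooled_groups=tuple(dataset_labels),
        rounding={"values": 1, "mean": 1, "sd": 1, "percent_sd": 1},
    )
    return report


def read_mu_csv(path) -> list[MUDataset]:
    """Read a ``case,technique,dataset_label,mu`` CSV into MU datasets."""
    frame = pd.read_csv(path)
    cases = []
    for (case, technique), group in frame.groupby(["case", "technique"], sort=False):
        cases.append(
            MUDataset(
                case=str(case),
                technique=str(technique),
                mu_by_dataset=dict(zip(group["dataset_label"], group["mu"])),
            )
        )
    return cases


def render_report(report: ComparisonReport, path, format: str = "csv") -> Path:
    """Serialize a report deterministically in csv, json or markdown.

    Numbers are rounded per the report's reporting rules before writing,
    so re-reading a rendered file yields exactly the rounded values.
    """
    path = Path(path)
    rounded = report.rounded()
    if format == "csv":
        rounded.to_csv(path, index=False)
    elif format == "json":
        payload = {
            "index": report.index_name,
            "pooled_groups": list(report.pooled_groups),
            "rows": json.loads(rounded.to_json(orient="records")),
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "markdown":
        path.write_text(_markdown_table(rounded) + "\n")
    else:
        raise ValidationError(f"unknown report format {format!r}")
    return path


def _markdown_table(frame: pd.DataFrame) -> str:
    header = "| " + " | ".join(str(c) for c in frame.columns) + " |"
    rule = "| " + " | ".join("---" for _ in frame.columns) + " |"
    lines = [header, rule]
    for _, row in frame.iterrows():
        lines.append("| " + " | ".join(_fmt(v) for v in row) + " |")
    return "\n".join(lines)


def _fmt(value) -> str:
    if isinstance(value, float):
        if np.isnan(value):
            return ""
        return f"{value:g}"
    return str(value)
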