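"""Per-sample microarray quality control.

Implements the per-sample QC battery applied before scoring: mean probe
intensity, presence of negative or saturated (>16-bit) linear intensities,
housekeeping (GAPDH/ACTB) 3'/5' ratios, spike-in control ordering (poly-A
sample-prep and labelled-cRNA hybridization series), and an RNA degradation
slope over position-annotated probes.  Samples failing any enabled check
are removed prior to analysis.

Conventions
-----------
The matrix stores log2 intensities.  Negativity and saturation are
linear-scale concepts: a non-finite (NaN) entry encodes a non-positive
linear reading (which has no log2 representation) and is counted by the
negativity check; an entry above log2(saturation_level) is saturated.
Checks whose control probes are absent from the platform are recorded as
skipped, never as failed.  Spatial checks (center of intensity, border
controls) require raw array geometry and are reported as not evaluable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CONTROL_ROLES",
    "QCThresholds",
    "SampleQC",
    "QCReport",
    "read_control_annotation",
    "write_control_annotation",
    "qc_sample",
    "qc_matrix",
    "apply_qc",
]

logger = logging.getLogger(__name__)

CONTROL_ROLES = (
    "housekeeping_3prime",
    "housekeeping_5prime",
    "polyA_spike",
    "hyb_spike",
    "degradation",
    "border_positive",
    "border_negative",
)

_SPIKE_ROLES = ("polyA_spike", "hyb_spike")


@dataclass
class QCThresholds:
    """Pass/fail bounds for the per-sample checks.

    The underlying study names the QC parameters but no cutoffs; these
    defaults are community-conventional and all overridable.  A
    ``max_3p5p_ratio`` of 3.0 (GAPDH) and 10.0 (ACTB) reflects the usual
    tolerance for 3' bias of the two housekeeping transcripts;
    ``max_degradation_slope=None`` records the slope but treats it as
    warn-only.
    """

    max_fraction_negative: float = 0.0
    max_fraction_saturated: float = 0.01
    saturation_level: float = float(2 ** 16)
    max_3p5p_ratio: dict[str, float] = field(
        default_factory=lambda: {"GAPDH": 3.0, "ACTB": 10.0})
    default_max_3p5p_ratio: float = 3.0
    max_degradation_slope: float | None = None
    require_spike_order: bool = True

    def __post_init__(self) -> None:
        for name in ("max_fraction_negative", "max_fraction_saturated",
                     "saturation_level", "default_max_3p5p_ratio"):
            if float(getattr(self, name)) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.saturation_level <= 0:
            raise ValueError("saturation_level must be positive")
        for target, bound in self.max_3p5p_ratio.items():
            if bound <= 0:
                raise ValueError(f"max_3p5p_ratio[{target!r}] must be positive")

    def ratio_bound(self, target: str) -> float:
        return float(self.max_3p5p_ratio.get(target, self.default_max_3p5p_ratio))


@dataclass
class SampleQC:
    """QC metrics and verdict for one sample."""

    sample_id: str
    mean_intensity: float
    fraction_negative: float
    fraction_saturated: float
    ratios_3p5p: dict[str, float]
    degradation_slope: float | None
    spike_order_pass: bool | None
    failed_checks: list[str]
    skipped_checks: list[str]

    @property
    def passed(self) -> bool:
        return not self.failed_checks

    def to_row(self) -> dict:
        row: dict = {
            "sample_id": self.sample_id,
            "mean_intensity": self.mean_intensity,
            "fraction_negative": self.fraction_negative,
            "fraction_saturated": self.fraction_saturated,
        }
        for target in sorted(self.ratios_3p5p):
            row[f"ratio_3p5p_{target}"] = self.ratios_3p5p[target]
        row["degradation_slope"] = (
            np.nan if self.degradation_slope is None else self.degradation_slope)
        row["spike_order_pass"] = (
            "" if self.spike_order_pass is None else str(self.spike_order_pass))
        row["passed"] = self.passed
        row["failed_checks"] = ";".join(self.failed_checks)
        row["skipped_checks"] = ";".join(self.skipped_checks)
        return row


class QCReport:
    """Collection of per-sample QC results (one :class:`SampleQC` each)."""

    def __init__(self, samples: Sequence[SampleQC]):
        self.samples = list(samples)

    def __iter__(self):
        return iter(self.samples)

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, sample_id: str) -> SampleQC:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    @property
    def passing(self) -> list[str]:
        return [s.sample_id for s in self.samples if s.passed]

    @property
    def failing(self) -> list[str]:
        return [s.sample_id for s in self.samples if not s.passed]

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame([s.to_row() for s in self.samples])
        return frame.set_index("sample_id")

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample_id")


def read_control_annotation(path: str | Path) -> pd.DataFrame:
    """Read control-probe annotation TSV.

    Columns: ``probe_id``, ``role`` (one of :data:`CONTROL_ROLES`),
    ``target`` (e.g. GAPDH), ``rank`` (spike series order), ``position``
    (probe position index for degradation analysis); rank/position may be
    empty.
    """
    controls = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "role": str,
                                                  "target": str})
    required = {"probe_id", "role", "target", "rank", "position"}
    missing = required - set(controls.columns)
    if missing:
        raise ValueError(f"{path}: control annotation missing columns {sorted(missing)}")
    bad_roles = set(controls["role"]) - set(CONTROL_ROLES)
    if bad_roles:
        raise ValueError(f"{path}: unknown control roles {sorted(bad_roles)}")
    for role in _SPIKE_ROLES:
        ranks = controls.loc[controls["role"] == role, "rank"].dropna()
        if ranks.duplicated().any():
            raise ValueError(f"{path}: duplicate spike ranks in series {role!r}")
    return controls.set_index("probe_id")


def write_control_annotation(controls: pd.DataFrame, path: str | Path) -> None:
    controls.to_csv(path, sep="\t", index_label="probe_id", na_rep="")


def _linear(values: np.ndarray) -> np.ndarray:
    return np.exp2(values)


def qc_sample(expression: pd.DataFrame, sample_id: str,
              controls: pd.DataFrame | None = None,
              thresholds: QCThresholds | None = None) -> SampleQC:
    """Run the QC battery on one sample (column) of a probes x samples matrix."""
    thresholds = thresholds or QCThresholds()
    if sample_id not in expression.columns:
        raise KeyError(f"sample {sample_id!r} not in matrix")
    col = expression[sample_id].astype(float)
    values = col.to_numpy()
    finite = np.isfinite(values)
    failed: list[str] = []
    skipped: list[str] = []

    mean_intensity = float(values[finite].mean()) if finite.any() else math.nan
    fraction_negative = float((~finite).mean())
    log2_sat = math.log2(thresholds.saturation_level)
    fraction_saturated = float((values[finite] > log2_sat).mean()) if finite.any() else 0.0

    if fraction_negative > thresholds.max_fraction_negative:
        failed.append("negative_values")
    if fraction_saturated > thresholds.max_fraction_saturated:
        failed.append("saturation")

    ratios: dict[str, float] = {}
    slope: float | None = None
    spike_pass: bool | None = None

    if controls is None:
        skipped.extend(["3p5p_ratio", "degradation_slope", "spike_order"])
    else:
        present = controls[controls.index.isin(expression.index)]
        # 3'/5' housekeeping ratios (linear scale)
        hk3 = present[present["role"] == "housekeeping_3prime"]
        hk5 = present[present["role"] == "housekeeping_5prime"]
        targets = sorted(set(hk3["target"]) & set(hk5["target"]))
        if not targets:
            skipped.append("3p5p_ratio")
        for target in targets:
            lin3_all = _linear(col[hk3.index[hk3["target"] == target]].to_numpy())
            lin5_all = _linear(col[hk5.index[hk5["target"] == target]].to_numpy())
            lin3_all = lin3_all[np.isfinite(lin3_all)]
            lin5_all = lin5_all[np.isfinite(lin5_all)]
            lin3 = lin3_all.mean() if lin3_all.size else math.nan
            lin5 = lin5_all.mean() if lin5_all.size else math.nan
            if not np.isfinite(lin5) or lin5 <= 0 or not np.isfinite(lin3):
                ratios[target] = math.nan
                failed.append(f"3p5p_ratio_{target}_undefined")
                continue
            ratios[target] = float(lin3 / lin5)
            if ratios[target] > thresholds.ratio_bound(target):
                failed.append(f"3p5p_ratio_{target}")

        # RNA degradation slope over position-annotated probes
        pos_probes = present[present["position"].notna()]
        pos = pos_probes["position"].astype(float).to_numpy()
        if len(np.unique(pos)) >= 2:
            intens = col[pos_probes.index].to_numpy()
            ok = np.isfinite(intens)
            if ok.sum() >= 2 and len(np.unique(pos[ok])) >= 2:
                slope = float(np.polyfit(pos[ok], intens[ok], 1)[0])
        if slope is None:
            skipped.append("degradation_slope")
        elif thresholds.max_degradation_slope is None:
            skipped.append("degradation_slope_threshold")
        elif abs(slope) > thresholds.max_degradation_slope:
            failed.append("degradation_slope")

        # spike-in ordering (poly-A and hybridization series)
        spike_results: list[bool] = []
        for role in _SPIKE_ROLES:
            series = present[(present["role"] == role) & present["rank"].notna()]
            if len(series) < 2:
                continue
            ordered = series.sort_values("rank")
            intens = col[ordered.index].to_numpy()
            spike_results.append(bool(np.all(np.diff(intens) >= -1e-9))
                                 and bool(np.all(np.isfinite(intens))))
        if not spike_results:
            skipped.append("spike_order")
        else:
            spike_pass = all(spike_results)
            if thresholds.require_spike_order and not spike_pass:
                failed.append("spike_order")

    # spatial checks need raw array geometry: not evaluable from a matrix
    skipped.extend(["center_of_intensity", "border_controls"])

    return SampleQC(sample_id, mean_intensity, fraction_negative,
                    fraction_saturated, ratios, slope, spike_pass,
                    failed, skipped)


def qc_matrix(expression: pd.DataFrame,
              controls: pd.DataFrame | None = None,
              thresholds: QCThresholds | None = None) -> QCReport:
    """Run :func:`qc_sample` over every sample, preserving column order."""
    thresholds = thresholds or QCThresholds()
    return QCReport([qc_sample(expression, s, controls, thresholds)
                     for s in expression.columns])


def apply_qc(expression: pd.DataFrame, report: QCReport,
             annotations: pd.DataFrame | None = None):
    """Drop failing samples from the matrix (and annotations, if given).

    Returns ``(filtered_expression, removed_ids)`` — or a 3-tuple including
    filtered annotations when provided.  Sample order is preserved; the
    removal list is sorted by sample id.  Idempotent: re-running on the
    filtered output removes nothing further.
    """
    reported = {s.sample_id for s in report}
    missing = set(expression.columns) - reported
    if missing:
        raise ValueError(f"samples without QC report: {sorted(missing)}")
    passing = set(report.passing)
    keep = [s for s in expression.columns if s in passing]
    removed = sorted(s for s in expression.columns if s not in passing)
    for sample_id in removed:
        logger.warning("QC removed sample %s (failed: %s)", sample_id,
                       ";".join(report[sample_id].failed_checks))
    if not keep:
        logger.warning("QC removed every sample")
    filtered = expression[keep]
    if annotations is not None:
        ann = annotations.loc[[s for s in annotations.index if s in passing]]
        return filtered, removed, ann
    return filtered, removed
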