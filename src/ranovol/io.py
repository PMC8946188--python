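"""Reading, writing and validation of longitudinal volume data.

The unit of analysis is the *lesion*: one treated meningioma followed with a
sequence of MRI-derived volume measurements.  Times are expressed in months
relative to the start of radiotherapy (negative = pre-treatment baseline).
Patients with more than one treated lesion contribute one row per lesion and
lesions are treated as statistically independent.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

log = logging.getLogger(__name__)

#: days per month used when converting calendar dates to months from RT start
DAYS_PER_MONTH = 30.44

TRAJECTORY_COLUMNS = ("lesion_id", "patient_id", "time_months", "volume_cm3")
COVARIATE_COLUMNS = (
    "lesion_id",
    "fractionation_group",
    "who_group",
    "age_years",
    "sex",
    "baseline_volume_cm3",
    "recurrence",
    "preceding_surgery",
)

FRACTIONATION_GROUPS = ("conventional", "srs_or_hypofractionated")
WHO_GROUPS = ("low_grade", "who2")
SEXES = ("male", "female")


@dataclass(frozen=True)
class VolumeMeasurement:
    """A single volumetric measurement of one lesion.

    Parameters
    ----------
    time_months : float
        Months relative to the start of radiotherapy (may be negative).
    volume_cm3 : float
        Segmented tumor volume in cm³; must be strictly positive.
    """

    time_months: float
    volume_cm3: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.time_months):
            raise ValidationError(f"time_months must be finite, got {self.time_months!r}")
        if not (np.isfinite(self.volume_cm3) and self.volume_cm3 > 0):
            raise ValidationError(
                f"volume_cm3 must be a positive finite number, got {self.volume_cm3!r}"
            )


@dataclass(frozen=True)
class VolumeTrajectory:
    """Ordered volume measurements of one lesion, including a pre-RT baseline.

    Invariants enforced at construction: measurements strictly increasing in
    time, at least one measurement at time <= 0 (the baseline scan) and at
    least one follow-up at time > 0.

    The working baseline volume ``V0`` is the volume of the *latest*
    measurement with time <= 0; earlier pre-treatment scans are retained but
    ignored for response assessment (a warning is logged when several exist).
    """

    lesion_id: str
    patient_id: str
    measurements: tuple[VolumeMeasurement, ...]

    def __post_init__(self) -> None:
        ms = tuple(self.measurements)
        object.__setattr__(self, "measurements", ms)
        if len(ms) < 2:
            raise ValidationError(
                f"lesion {self.lesion_id!r}: need at least a baseline and one follow-up"
            )
        times = [m.time_months for m in ms]
        if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
            raise ValidationError(
                f"lesion {self.lesion_id!r}: measurement times must be strictly "
                f"increasing without duplicates, got {times}"
            )
        n_pre = sum(t <= 0 for t in times)
        if n_pre == 0:
            raise ValidationError(
                f"lesion {self.lesion_id!r}: no baseline measurement (time_months <= 0)"
            )
        if n_pre > 1:
            log.warning(
                "lesion %r: %d pre-RT scans; using the latest as baseline",
                self.lesion_id,
                n_pre,
            )
        if not any(t > 0 for t in times):
            raise ValidationError(
                f"lesion {self.lesion_id!r}: no follow-up measurement (time_months > 0)"
            )

    @property
    def baseline(self) -> VolumeMeasurement:
        """Latest measurement with time <= 0."""
        return [m for m in self.measurements if m.time_months <= 0][-1]

    @property
    def baseline_volume(self) -> float:
        return self.baseline.volume_cm3

    @property
    def followups(self) -> tuple[VolumeMeasurement, ...]:
        """All measurements with time > 0, in time order."""
        return tuple(m for m in self.measurements if m.time_months > 0)

    @property
    def last_followup_months(self) -> float:
        return self.followups[-1].time_months

    def scaled(self, factor: float) -> "VolumeTrajectory":
        """Return a copy with every volume multiplied by ``factor`` (> 0)."""
        if factor <= 0:
            raise ValidationError("scale factor must be positive")
        return VolumeTrajectory(
            self.lesion_id,
            self.patient_id,
            tuple(
                VolumeMeasurement(m.time_months, m.volume_cm3 * factor)
                for m in self.measurements
            ),
        )


@dataclass(frozen=True)
class LesionRecord:
    """Per-lesion covariates used in the cohort-level statistics."""

    lesion_id: str
    fractionation_group: str
    who_group: str
    age_years: float
    sex: str
    baseline_volume_cm3: float
    recurrence: bool
    preceding_surgery: bool

    def __post_init__(self) -> None:
        if self.fractionation_group not in FRACTIONATION_GROUPS:
            raise ValidationError(
                f"lesion {self.lesion_id!r}: fractionation_group must be one of "
                f"{FRACTIONATION_GROUPS}, got {self.fractionation_group!r}"
            )
        if self.who_group not in WHO_GROUPS:
            raise ValidationError(
                f"lesion {self.lesion_id!r}: who_group must be one of {WHO_GROUPS}"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"lesion {self.lesion_id!r}: sex must be one of {SEXES}")
        if not self.age_years > 0:
            raise ValidationError(f"lesion {self.lesion_id!r}: age_years must be positive")
        if not self.baseline_volume_cm3 > 0:
            raise ValidationError(
                f"lesion {self.lesion_id!r}: baseline_volume_cm3 must be positive"
            )


def check_baseline_consistency(
    trajectories: Sequence[VolumeTrajectory],
    records: Sequence[LesionRecord],
    rtol: float = 1e-6,
) -> None:
    """Verify covariate baseline volumes against trajectory baselines.

    Raises :class:`ValidationError` when both are supplied for a lesion and
    disagree beyond relative tolerance ``rtol``.
    """
    by_id = {t.lesion_id: t for t in trajectories}
    for rec in records:
        traj = by_id.get(rec.lesion_id)
        if traj is None:
            continue
        v0 = traj.baseline_volume
        if abs(rec.baseline_volume_cm3 - v0) > rtol * max(abs(v0), 1e-30):
            raise ValidationError(
                f"lesion {rec.lesion_id!r}: covariate baseline volume "
                f"{rec.baseline_volume_cm3} cm³ disagrees with trajectory baseline {v0} cm³"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _frame_to_trajectories(df: pd.DataFrame, source: str) -> list[VolumeTrajectory]:
    for col in TRAJECTORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{source}: missing required column {col!r}")
    trajectories: list[VolumeTrajectory] = []
    for lesion_id, group in df.groupby("lesion_id", sort=True):
        group = group.sort_values("time_months")
        measurements = []
        for row in group.itertuples():
            vol = float(row.volume_cm3)
            if not vol > 0:
                raise ValidationError(
                    f"{source}: lesion {lesion_id!r}, row {row.Index}: "
                    f"volume_cm3 must be positive, got {vol}"
                )
            measurements.append(VolumeMeasurement(float(row.time_months), vol))
        patient_id = str(group["patient_id"].iloc[0])
        trajectories.append(
            VolumeTrajectory(str(lesion_id), patient_id, tuple(measurements))
        )
    return trajectories


def read_trajectories(
    path: str | Path,
    fmt: str | None = None,
    rt_start_date: str | None = None,
) -> list[VolumeTrajectory]:
    """Read longitudinal volume tables from CSV or JSON.

    CSV columns: ``lesion_id, patient_id, time_months, volume_cm3``.  A table
    with a ``scan_date`` column instead of ``time_months`` is accepted when
    ``rt_start_date`` is given; dates are converted with 1 month = 30.44 days.
    JSON holds a list of row objects with the same keys.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    if fmt == "csv":
        df = pd.read_csv(path)
    elif fmt == "json":
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        raise FormatError(f"unknown trajectory format {fmt!r}")
    if "time_months" not in df.columns and "scan_date" in df.columns:
        if rt_start_date is None:
            raise FormatError(
                f"{path}: table has scan_date but no time_months; "
                "rt_start_date is required to convert dates"
            )
        start = pd.Timestamp(rt_start_date)
        days = (pd.to_datetime(df["scan_date"]) - start).dt.total_seconds() / 86400.0
        df = df.assign(time_months=days / DAYS_PER_MONTH)
    return _frame_to_trajectories(df, str(path))


def read_covariates(path: str | Path) -> list[LesionRecord]:
    """Read the per-lesion covariate CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    for col in COVARIATE_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    records = []
    for row in df.itertuples():
        records.append(
            LesionRecord(
                lesion_id=str(row.lesion_id),
                fractionation_group=str(row.fractionation_group),
                who_group=str(row.who_group),
                age_years=float(row.age_years),
                sex=str(row.sex),
                baseline_volume_cm3=float(row.baseline_volume_cm3),
                recurrence=bool(int(row.recurrence)),
                preceding_surgery=bool(int(row.preceding_surgery)),
            )
        )
    return records


def write_trajectories(trajectories: Sequence[VolumeTrajectory], path: str | Path) -> None:
    """Write trajectories to the canonical CSV layout."""
    rows = [
        {
            "lesion_id": t.lesion_id,
            "patient_id": t.patient_id,
            "time_months": m.time_months,
            "volume_cm3": m.volume_cm3,
        }
        for t in trajectories
        for m in t.measurements
    ]
    pd.DataFrame(rows, columns=list(TRAJECTORY_COLUMNS)).to_csv(path, index=False)


def write_covariates(records: Sequence[LesionRecord], path: str | Path) -> None:
    rows = [
        {
            "lesion_id": r.lesion_id,
            "fractionation_group": r.fractionation_group,
            "who_group": r.who_group,
            "age_years": r.age_years,
            "sex": r.sex,
            "baseline_volume_cm3": r.baseline_volume_cm3,
            "recurrence": int(r.recurrence),
            "preceding_surgery": int(r.preceding_surgery),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(COVARIATE_COLUMNS)).to_csv(path, index=False)


ASSESSMENT_COLUMNS = (
    "lesion_id",
    "best_relative_volume",
    "best_category",
    "te_detected",
    "te_peak_time_months",
    "te_peak_increase_fraction",
    "te_resolution_time_months",
    "te_unresolved_at_last_fu",
    "naive_event",
    "naive_event_time_months",
    "te_aware_event",
    "te_aware_event_time_months",
)


def write_assessments(assessments: Sequence, path: str | Path) -> None:
    """Write one summary row per assessed lesion (see :mod:`ranovol.response`).

    The table round-trips through :func:`read_assessment_table`.
    """
    if len(assessments) == 0:
        raise ValidationError("cannot write an empty assessment collection")
    rows = []
    for a in assessments:
        rows.append(
            {
                "lesion_id": a.lesion_id,
                "best_relative_volume": a.best_relative_volume,
                "best_category": a.best_category,
                "te_detected": int(a.te.detected),
                "te_peak_time_months": a.te.peak_time_months,
                "te_peak_increase_fraction": a.te.peak_increase_fraction,
                "te_resolution_time_months": a.te.resolution_time_months,
                "te_unresolved_at_last_fu": int(a.te.unresolved_at_last_fu),
                "naive_event": int(a.naive_event),
                "naive_event_time_months": a.naive_event_time_months,
                "te_aware_event": int(a.te_aware_event),
                "te_aware_event_time_months": a.te_aware_event_time_months,
            }
        )
    pd.DataFrame(rows, columns=list(ASSESSMENT_COLUMNS)).to_csv(path, index=False)


def read_assessment_table(path: str | Path) -> pd.DataFrame:
    """Read an assessment summary CSV back into a DataFrame."""
    df = pd.read_csv(path)
    for col in ASSESSMENT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for col in ("te_detected", "te_unresolved_at_last_fu", "naive_event", "te_aware_event"):
        df[col] = df[col].astype(bool)
    return df


# ---------------------------------------------------------------------------
# segmentation masks
# ---------------------------------------------------------------------------


def mask_volume(
    label_mask: np.ndarray,
    voxel_spacing_mm: Sequence[float],
    label: int = 1,
) -> float:
    """Volume in cm³ of all voxels equal to ``label`` in a 3D label mask.

    ``volume = count(mask == label) * prod(spacing_mm) / 1000``.
    """
    mask = np.asarray(label_mask)
    if mask.ndim != 3:
        raise ValidationError(f"label mask must be 3D, got ndim={mask.ndim}")
    spacing = tuple(float(s) for s in voxel_spacing_mm)
    if len(spacing) != 3 or any(not (np.isfinite(s) and s > 0) for s in spacing):
        raise ValidationError(
            f"voxel spacing must be three positive numbers, got {voxel_spacing_mm!r}"
        )
    count = int(np.count_nonzero(mask == label))
    return count * spacing[0] * spacing[1] * spacing[2] / 1000.0


def nifti_mask_volume(path: str | Path, label: int = 1) -> float:
    """Volume in cm³ of ``label`` in a NIfTI label image; spacing from the header."""
    import nibabel as nib

    img = nib.load(str(path))
    spacing = img.header.get_zooms()[:3]
    return mask_volume(np.asanyarray(img.dataobj), spacing, label)
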