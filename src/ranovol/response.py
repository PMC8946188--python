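"""Volumetric RANO response classification and pseudoprogression detection.

A lesion's follow-up volumes are expressed relative to the pre-treatment
baseline V0.  Per-timepoint categories follow the volumetric RANO meningioma
thresholds:

* progressive disease (PD): volume >= 140% of the smaller of baseline and the
  running nadir (minimum volume over baseline and all earlier follow-ups);
* partial response (PR): volume <= 35% of baseline;
* minor response (MR): volume <= 60% of baseline;
* stable disease (SD): everything else.

PD takes precedence over PR/MR when both fire (regrowth from a deep nadir
must never be masked by a still-low ratio to baseline).

Transient enlargement (pseudoprogression) is a volume increase >= 20% over
baseline followed by a spontaneous regression of >= 20% relative to the
maximum volume reached during the enlargement episode.  Two progression
rules are derived per lesion:

* *naive*: the first PD-classified follow-up is a progression event;
* *TE-aware*: a PD crossing whose enlargement episode later resolves
  (regression >= 20% from the episode maximum) is not counted; the lesion is
  censored at last follow-up unless a later, distinct PD occurs.  An
  enlargement that has not resolved by last follow-up cannot be confirmed as
  pseudoprogression and counts as an event under both rules.

All threshold comparisons are inclusive and use a relative tolerance of 1e-9
so that boundary cases (e.g. exactly 140%) are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ValidationError
from .io import VolumeTrajectory

#: relative tolerance for inclusive threshold comparisons
REL_TOL = 1e-9

CATEGORIES = ("PD", "SD", "MR", "PR")


def _ge(x: float, y: float) -> bool:
    """x >= y with relative tolerance (both operands positive in practice)."""
    return x >= y - REL_TOL * abs(y)


def _le(x: float, y: float) -> bool:
    return x <= y + REL_TOL * abs(y)


@dataclass(frozen=True)
class RanoThresholds:
    """Decision thresholds for classification and pseudoprogression.

    Attributes
    ----------
    pd_factor : float
        Progression when volume >= ``pd_factor`` x min(baseline, nadir);
        default 1.40 (a >= 40% increase).
    mr_ceiling : float
        Minor response when relative volume <= ``mr_ceiling`` (default 0.60).
    pr_ceiling : float
        Partial response when relative volume <= ``pr_ceiling`` (default 0.35).
    te_rise_factor : float
        Transient-enlargement rise threshold relative to the reference volume
        (default 1.20, i.e. a >= 20% increase).
    te_fall_fraction : float
        Required spontaneous regression relative to the episode maximum
        (default 0.20).
    te_reference : str
        Reference for the TE rise: ``"baseline"`` (default) or ``"nadir"``
        (the running minimum including baseline).
    """

    pd_factor: float = 1.40
    mr_ceiling: float = 0.60
    pr_ceiling: float = 0.35
    te_rise_factor: float = 1.20
    te_fall_fraction: float = 0.20
    te_reference: str = "baseline"

    def __post_init__(self) -> None:
        ok = (
            0 < self.pr_ceiling < self.mr_ceiling < 1
            < self.te_rise_factor <= self.pd_factor
        )
        if not ok:
            raise ValidationError(
                "thresholds must satisfy 0 < pr_ceiling < mr_ceiling < 1 "
                "< te_rise_factor <= pd_factor"
            )
        if not 0 < self.te_fall_fraction < 1:
            raise ValidationError("te_fall_fraction must be in (0, 1)")
        if self.te_reference not in ("baseline", "nadir"):
            raise ValidationError("te_reference must be 'baseline' or 'nadir'")


DEFAULT_THRESHOLDS = RanoThresholds()


@dataclass(frozen=True)
class TimepointAssessment:
    """Classification of one follow-up scan."""

    time_months: float
    relative_volume: float
    nadir_before: float  # min of baseline and earlier follow-ups, as fraction of V0
    category: str


@dataclass(frozen=True)
class TransientEnlargementRecord:
    """Outcome of pseudoprogression detection for one lesion.

    ``peak_*`` fields are populated whenever a qualifying rise occurred
    (detected episodes and unresolved enlargements alike) and are NaN
    otherwise.  ``unresolved_at_last_fu`` marks a rise without a subsequent
    qualifying regression.
    """

    detected: bool
    peak_time_months: float = math.nan
    peak_increase_fraction: float = math.nan
    resolution_time_months: float = math.nan
    unresolved_at_last_fu: bool = False


@dataclass(frozen=True)
class ResponseAssessment:
    """Full response assessment of one lesion trajectory."""

    lesion_id: str
    timepoints: tuple[TimepointAssessment, ...]
    best_relative_volume: float
    best_category: str
    te: TransientEnlargementRecord
    naive_event: bool
    naive_event_time_months: float
    te_aware_event: bool
    te_aware_event_time_months: float
    last_followup_months: float


def relative_volumes(traj: VolumeTrajectory) -> list[tuple[float, float]]:
    """(time, V(t)/V0) for every follow-up scan; the baseline maps to 1.0."""
    v0 = traj.baseline_volume
    return [(m.time_months, m.volume_cm3 / v0) for m in traj.followups]


def classify_timepoint(
    volume: float,
    baseline: float,
    nadir_before: float,
    thresholds: RanoThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """RANO category of a single volume given baseline and prior nadir.

    PD is tested against min(baseline, nadir_before) and takes precedence
    over the baseline-referenced PR/MR ceilings.
    """
    if not (volume > 0 and baseline > 0 and nadir_before > 0):
        raise ValidationError("volume, baseline and nadir must be positive")
    reference = min(baseline, nadir_before)
    if _ge(volume, thresholds.pd_factor * reference):
        return "PD"
    ratio = volume / baseline
    if _le(ratio, thresholds.pr_ceiling):
        return "PR"
    if _le(ratio, thresholds.mr_ceiling):
        return "MR"
    return "SD"


def _best_category(best_relative: float, thresholds: RanoThresholds) -> str:
    if _le(best_relative, thresholds.pr_ceiling):
        return "PR"
    if _le(best_relative, thresholds.mr_ceiling):
        return "MR"
    return "SD"


def detect_transient_enlargement(
    traj: VolumeTrajectory,
    thresholds: RanoThresholds = DEFAULT_THRESHOLDS,
) -> TransientEnlargementRecord:
    """Detect a transient-enlargement episode in one trajectory.

    The episode starts at the first follow-up whose volume is at least
    ``te_rise_factor`` times the reference (baseline V0 by default).  The
    episode maximum is tracked forward in time; the episode *resolves* at the
    first later scan whose volume is at most ``(1 - te_fall_fraction)`` times
    the episode maximum.  A rise that never resolves is reported with
    ``unresolved_at_last_fu=True`` and ``detected=False``.
    """
    v0 = traj.baseline_volume
    fups = traj.followups
    times = [m.time_months for m in fups]
    vols = [m.volume_cm3 for m in fups]

    rise_idx = None
    running_min = v0
    for i, v in enumerate(vols):
        ref = v0 if thresholds.te_reference == "baseline" else running_min
        if _ge(v, thresholds.te_rise_factor * ref):
            rise_idx = i
            break
        running_min = min(running_min, v)
    if rise_idx is None:
        return TransientEnlargementRecord(detected=False)

    peak_idx = rise_idx
    peak = vols[rise_idx]
    for k in range(rise_idx + 1, len(vols)):
        if _le(vols[k], (1.0 - thresholds.te_fall_fraction) * peak):
            return TransientEnlargementRecord(
                detected=True,
                peak_time_months=times[peak_idx],
                peak_increase_fraction=peak / v0 - 1.0,
                resolution_time_months=times[k],
                unresolved_at_last_fu=False,
            )
        if vols[k] > peak:
            peak = vols[k]
            peak_idx = k
    return TransientEnlargementRecord(
        detected=False,
        peak_time_months=times[peak_idx],
        peak_increase_fraction=peak / v0 - 1.0,
        unresolved_at_last_fu=True,
    )


def _te_aware_event_index(
    vols: Sequence[float], categories: Sequence[str], thresholds: RanoThresholds
) -> int | None:
    """First PD index whose enlargement episode does not resolve.

    Starting from a PD-classified scan, the episode maximum is tracked
    forward; if a later scan regresses by >= ``te_fall_fraction`` from the
    episode maximum the crossing is attributed to pseudoprogression and the
    search continues after the resolution scan.
    """
    i = 0
    n = len(vols)
    while i < n:
        if categories[i] != "PD":
            i += 1
            continue
        peak = vols[i]
        resolved_at = None
        for k in range(i + 1, n):
            if _le(vols[k], (1.0 - thresholds.te_fall_fraction) * peak):
                resolved_at = k
                break
            peak = max(peak, vols[k])
        if resolved_at is None:
            return i
        i = resolved_at + 1
    return None


def assess_trajectory(
    traj: VolumeTrajectory,
    thresholds: RanoThresholds = DEFAULT_THRESHOLDS,
) -> ResponseAssessment:
    """Classify every follow-up, derive best response, TE and both event rules."""
    v0 = traj.baseline_volume
    fups = traj.followups
    times = [m.time_months for m in fups]
    vols = [m.volume_cm3 for m in fups]

    timepoints: list[TimepointAssessment] = []
    nadir = v0
    for t, v in zip(times, vols):
        cat = classify_timepoint(v, v0, nadir, thresholds)
        timepoints.append(TimepointAssessment(t, v / v0, nadir / v0, cat))
        nadir = min(nadir, v)
    categories = [tp.category for tp in timepoints]

    best_rel = min(v / v0 for v in vols)
    best_cat = _best_category(best_rel, thresholds)

    te = detect_transient_enlargement(traj, thresholds)

    last_fu = times[-1]
    naive_idx = next((i for i, c in enumerate(categories) if c == "PD"), None)
    naive_event = naive_idx is not None
    naive_time = times[naive_idx] if naive_event else last_fu

    te_idx = _te_aware_event_index(vols, categories, thresholds)
    te_event = te_idx is not None
    te_time = times[te_idx] if te_event else last_fu

    return ResponseAssessment(
        lesion_id=traj.lesion_id,
        timepoints=tuple(timepoints),
        best_relative_volume=best_rel,
        best_category=best_cat,
        te=te,
        naive_event=naive_event,
        naive_event_time_months=naive_time,
        te_aware_event=te_event,
        te_aware_event_time_months=te_time,
        last_followup_months=last_fu,
    )


def assess_cohort(
    trajectories: Iterable[VolumeTrajectory],
    thresholds: RanoThresholds = DEFAULT_THRESHOLDS,
) -> list[ResponseAssessment]:
    """Assess every trajectory in a cohort."""
    return [assess_trajectory(t, thresholds) for t in trajectories]


def cohort_best_response_summary(assessments: Sequence[ResponseAssessment]) -> dict:
    """Best-response category counts and summary of best relative change.

    Returns a dict with per-category ``counts``, the cohort size ``n``, and
    ``mean_change`` / ``min_change`` / ``max_change`` of best relative volume
    minus one (i.e. -0.23 for a best response of -23% from baseline).
    """
    if len(assessments) == 0:
        raise ValidationError("cannot summarize an empty assessment collection")
    counts = {"SD": 0, "MR": 0, "PR": 0}
    for a in assessments:
        counts[a.best_category] += 1
    changes = np.array([a.best_relative_volume - 1.0 for a in assessments])
    return {
        "n": len(assessments),
        "counts": counts,
        "mean_change": float(changes.mean()),
        "min_change": float(changes.min()),
        "max_change": float(changes.max()),
    }
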