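from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from ranovol import VolumeMeasurement, VolumeTrajectory


def make_trajectory(
    rel_series: list[tuple[float, float]],
    v0: float = 10.0,
    lesion_id: str = "L1",
    patient_id: str = "P1",
    baseline_time: float = -0.33,
) -> VolumeTrajectory:
    """Trajectory from (time, relative volume) follow-up pairs plus a baseline."""
    measurements = [VolumeMeasurement(baseline_time, v0)] + [
        VolumeMeasurement(t, r * v0) for t, r in rel_series
    ]
    return VolumeTrajectory(lesion_id, patient_id, tuple(measurements))


@pytest.fixture
def traj_factory():
    return make_trajectory


def reference_cohort_69() -> list[VolumeTrajectory]:
    """A hand-built 69-lesion cohort with a known event structure.

    Five lesions cross the progression threshold (naive events at 6, 7.5, 9,
    18 and 30 months); three of those crossings resolve spontaneously by
    >= 20% from the episode peak (confirmed transient enlargement), leaving
    two TE-aware events.  Every other lesion is followed, stably, to 72
    months, so there is no censoring before the last event.
    """
    cohort = []
    te_like = [
        [(3, 1.0), (6, 1.6), (10, 1.1), (72, 0.9)],
        [(3, 1.0), (7.5, 1.7), (10.5, 1.2), (72, 0.95)],
        [(3, 1.0), (9, 1.5), (12, 1.05), (72, 0.9)],
    ]
    progression_like = [
        [(3, 1.0), (18, 1.5), (72, 2.5)],
        [(3, 0.95), (30, 1.6), (72, 2.2)],
    ]
    for i, series in enumerate(te_like + progression_like):
        cohort.append(make_trajectory(series, lesion_id=f"E{i:02d}", patient_id=f"PE{i:02d}"))
    for i in range(64):
        cohort.append(
            make_trajectory(
                [(3, 0.97), (24, 0.90), (72, 0.85)],
                lesion_id=f"C{i:02d}",
                patient_id=f"PC{i:02d}",
            )
        )
    return cohort


@pytest.fixture(scope="session")
def reference_cohort():
    return reference_cohort_69()
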