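"""Classify a single lesion trajectory and detect pseudoprogression.

A meningioma measured at 10 cm³ before radiotherapy balloons to 25 cm³ at
6 months and then shrinks back — the signature of transient enlargement
rather than true progression.
"""

from ranovol import VolumeMeasurement, VolumeTrajectory, assess_trajectory

traj = VolumeTrajectory(
    lesion_id="L1",
    patient_id="P1",
    measurements=(
        VolumeMeasurement(-0.3, 10.0),  # baseline, 10 days before RT
        VolumeMeasurement(3.0, 10.0),
        VolumeMeasurement(6.0, 25.0),   # +150%: crosses the 140% PD threshold
        VolumeMeasurement(9.0, 11.0),   # spontaneous regression (56% from peak)
        VolumeMeasurement(21.0, 9.0),
    ),
)

a = assess_trajectory(traj)
print("per-scan categories:", [(tp.time_months, tp.category) for tp in a.timepoints])
print(f"best response: {a.best_relative_volume:.0%} of baseline -> {a.best_category}")
print(f"transient enlargement detected: {a.te.detected} "
      f"(peak +{a.te.peak_increase_fraction:.0%} at {a.te.peak_time_months} months, "
      f"resolved at {a.te.resolution_time_months} months)")
print(f"naive rule:    event={a.naive_event} at {a.naive_event_time_months} months")
print(f"TE-aware rule: event={a.te_aware_event} "
      f"(censored at {a.te_aware_event_time_months} months)")

# The 6-month scan is classified PD, so the naive rule counts an event; the
# TE-aware rule recognises the >= 20% regression from the peak and censors
# the lesion at last follow-up instead.
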