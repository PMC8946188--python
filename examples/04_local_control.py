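"""Dual Kaplan-Meier local control: the cost of ignoring pseudoprogression.

A cohort is simulated with an elevated transient-enlargement rate so the
contrast between the two progression rules is visible at n = 69.
"""

from ranovol import SimulationConfig, assess_cohort, dual_local_control, simulate_cohort

cohort = simulate_cohort(
    SimulationConfig(te_prob_srs_hypo=0.5, te_prob_conventional=0.10, seed=5)
)
assessments = assess_cohort(cohort.trajectories)
dual = dual_local_control(assessments, horizon_months=60.0)

n_te = sum(a.te.detected for a in assessments)
print(f"transient enlargements detected: {n_te}")
print(f"naive events:    {sum(a.naive_event for a in assessments)}")
print(f"TE-aware events: {sum(a.te_aware_event for a in assessments)}")
print(f"5-year local control, naive:    {dual.naive_control:.1%}")
print(f"5-year local control, TE-aware: {dual.te_aware_control:.1%}")

# Every confirmed pseudoprogression counted as an event drags the naive
# curve down; the TE-aware curve dominates it pointwise because its event
# set is a subset of the naive one.
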