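"""Synthetic cohorts of post-radiotherapy meningioma volume trajectories.

The generator emulates the study conditions the pipeline is meant to
analyse: ~69 lesions, 12 of them treated with SRS or hypofractionation and
the rest conventionally fractionated; lognormal baseline volumes with median
4.7 cm³; slow ongoing volumetric regression after radiotherapy with a best
response mix of roughly SD 81% / MR 13% / PR 6%; rare transient-enlargement
(pseudoprogression) episodes confined to 4.1-10.3 months post-RT with peak
increases between +24% and +389%, much more frequent after SRS or
hypofractionation (25%) than after conventional fractionation (1/57); rare
true progression; an adaptive MRI schedule (first follow-up at 3 months,
then every 6-12 months, shortened to 3 months after any >= 20% enlargement)
and lognormal follow-up horizons with median 42.3 months; multiplicative
lognormal measurement noise.

Latent kinetics are deliberately simple and isolated behind
:func:`latent_volume` so alternative functional forms can be swapped:

* controlled lesions follow an exponential relaxation towards a plateau,
  ``V(t)/V0 = f_inf + (1 - f_inf) * exp(-t / tau)``;
* transient enlargement adds a Gaussian bump centred in the TE window (gated
  to zero at t = 0 so the baseline anchors exactly at V0);
* true progression multiplies the controlled curve by exponential growth
  after a latent onset time.

Each lesion draws a *response stratum* (SD / MR / PR) from the configured
mix and a target best relative volume ``b`` uniformly within the stratum's
band; the plateau ``f_inf`` is then solved so that the noise-free trajectory
attains exactly ``b`` at the lesion's last scheduled scan.  The recorded
ground-truth class is therefore exactly recoverable from the noise-free
measurements.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import ValidationError
from .io import LesionRecord, VolumeMeasurement, VolumeTrajectory

TRUE_CLASSES = (
    "controlled_sd",
    "controlled_mr",
    "controlled_pr",
    "transient_enlargement",
    "true_progression",
)

#: time over which the TE bump is ramped in from zero (months); keeps the
#: baseline anchored at V0 while leaving the bump exact at its centre
#: (the TE window starts well after this ramp).
_TE_GATE_MONTHS = 2.0


def quartile_ratio_sigma(q1: float, q3: float) -> float:
    """Lognormal sigma back-derived from a printed interquartile range.

    For a lognormal distribution Q3/Q1 = exp(2 * z_0.75 * sigma), hence
    sigma = ln(Q3/Q1) / (2 * z_0.75).  With the cohort's baseline-volume IQR
    1.3-9.0 cm³ this gives sigma ~= 1.43.
    """
    z = norm.ppf(0.75)
    return math.log(q3 / q1) / (2.0 * z)


@dataclass(frozen=True)
class SimulationConfig:
    """All generator parameters.  Defaults encode the emulated study conditions."""

    n_lesions: int = 69
    frac_srs_hypo: float = 12 / 69
    te_prob_srs_hypo: float = 0.25
    te_prob_conventional: float = 1 / 57
    progression_prob: float = 2 / 69
    baseline_volume_median_cm3: float = 4.7
    baseline_volume_log_sigma: float = quartile_ratio_sigma(1.3, 9.0)
    best_response_mix: tuple[float, float, float] = (0.81, 0.13, 0.06)
    # target best-relative-volume bands per stratum (SD / MR / PR); the SD
    # band extends above 1 because some controlled lesions never shrink
    # (best changes up to about +19%)
    sd_band: tuple[float, float] = (0.60, 1.19)
    mr_band: tuple[float, float] = (0.35, 0.60)
    pr_band: tuple[float, float] = (0.14, 0.35)
    regression_timescale_months: float = 24.0
    te_window_months: tuple[float, float] = (4.1, 10.3)
    te_peak_increase_range: tuple[float, float] = (0.24, 3.89)
    te_bump_width_months: float = 2.0
    progression_growth_rate: float = 0.15  # per month, after latent onset
    followup_median_months: float = 42.3
    followup_log_sigma: float = 0.45
    followup_bounds_months: tuple[float, float] = (6.0, 120.0)
    baseline_scan_months: float = -0.33
    first_followup_months: float = 3.0
    routine_interval_months: tuple[float, float] = (6.0, 12.0)
    shortened_interval_months: float = 3.0
    enlargement_trigger: float = 1.20  # shorten interval when latest / min >= this
    noise_cv: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.n_lesions < 1:
            problems.append("n_lesions must be >= 1")
        for name in ("frac_srs_hypo", "te_prob_srs_hypo", "te_prob_conventional", "progression_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                problems.append(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.best_response_mix) - 1.0) > 1e-9:
            problems.append("best_response_mix must sum to 1")
        for name in ("sd_band", "mr_band", "pr_band", "te_window_months",
                     "te_peak_increase_range", "routine_interval_months",
                     "followup_bounds_months"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                problems.append(f"{name} must be an ordered pair, got ({lo}, {hi})")
        if self.noise_cv < 0:
            problems.append("noise_cv must be >= 0")
        for name in ("regression_timescale_months", "te_bump_width_months",
                     "progression_growth_rate", "followup_median_months"):
            if not getattr(self, name) > 0:
                problems.append(f"{name} must be positive")
        if problems:
            raise ValidationError("invalid simulation config: " + "; ".join(problems))


@dataclass(frozen=True)
class GroundTruth:
    """Simulation labels for one lesion, used in parameter-recovery tests."""

    lesion_id: str
    true_class: str
    te_peak_time: float | None = None
    progression_time: float | None = None
    response_stratum: str = "SD"  # underlying controlled stratum (SD/MR/PR)

    def __post_init__(self) -> None:
        if self.true_class not in TRUE_CLASSES:
            raise ValidationError(f"unknown true_class {self.true_class!r}")
        if (self.te_peak_time is not None) != (self.true_class == "transient_enlargement"):
            raise ValidationError("te_peak_time set iff class is transient_enlargement")
        if (self.progression_time is not None) != (self.true_class == "true_progression"):
            raise ValidationError("progression_time set iff class is true_progression")


@dataclass(frozen=True)
class LesionKinetics:
    """Per-lesion latent-curve parameters."""

    true_class: str
    v0_cm3: float
    plateau_fraction: float  # f_inf
    timescale_months: float  # tau
    te_peak_time: float | None = None
    te_amplitude: float | None = None  # added relative volume at bump centre
    te_width_months: float | None = None
    onset_months: float | None = None
    growth_rate: float | None = None


def latent_volume(t: float, kinetics: LesionKinetics) -> float:
    """Noise-free volume (cm³) of a lesion at time ``t`` months from RT start.

    For t < 0 the volume is the baseline V0 exactly.
    """
    k = kinetics
    if k.true_class not in TRUE_CLASSES:
        raise ValidationError(f"unknown lesion class {k.true_class!r}")
    if t < 0:
        return k.v0_cm3
    f = k.plateau_fraction
    rel = f + (1.0 - f) * math.exp(-t / k.timescale_months)
    if k.true_class == "transient_enlargement":
        gate = min(1.0, t / _TE_GATE_MONTHS)
        z = (t - k.te_peak_time) / k.te_width_months
        rel += k.te_amplitude * math.exp(-0.5 * z * z) * gate
    elif k.true_class == "true_progression" and t > k.onset_months:
        rel *= math.exp(k.growth_rate * (t - k.onset_months))
    return k.v0_cm3 * rel


def next_scan_time(
    config: SimulationConfig,
    scan_times: Sequence[float],
    observed_volumes: Sequence[float],
    horizon_months: float,
    rng: np.random.Generator,
) -> float | None:
    """Adaptive imaging schedule: next scan time, or None when follow-up ends.

    The first follow-up is at 3 months post-RT; subsequent intervals are
    drawn uniformly from 6-12 months, shortened to 3 months whenever the
    latest observed volume exceeds the prior observed minimum by >= 20%.
    Follow-up stops at the lesion's horizon; the last scan is placed at the
    horizon itself (the lesion's final imaging date).
    """
    post = [t for t in scan_times if t > 0]
    if not post:
        return min(config.first_followup_months, horizon_months)
    current = post[-1]
    if current >= horizon_months - 1e-9:
        return None
    latest = observed_volumes[-1]
    prior_min = min(observed_volumes[:-1])
    if latest >= config.enlargement_trigger * prior_min * (1 - 1e-9):
        interval = config.shortened_interval_months
    else:
        interval = rng.uniform(*config.routine_interval_months)
    return min(current + interval, horizon_months)


@dataclass(frozen=True)
class SimulatedCohort:
    trajectories: tuple[VolumeTrajectory, ...]
    records: tuple[LesionRecord, ...]
    truths: tuple[GroundTruth, ...]
    kinetics: tuple[LesionKinetics, ...]
    horizons: tuple[float, ...]


_STRATUM_TO_CLASS = {"SD": "controlled_sd", "MR": "controlled_mr", "PR": "controlled_pr"}


def _draw_horizon(config: SimulationConfig, rng: np.random.Generator) -> float:
    lo, hi = config.followup_bounds_months
    mu = math.log(config.followup_median_months)
    for _ in range(1000):
        t = math.exp(rng.normal(mu, config.followup_log_sigma))
        if lo <= t <= hi:
            return t
    return float(np.clip(math.exp(mu), lo, hi))


def _category_of(b: float, config: SimulationConfig) -> str:
    if b <= config.mr_band[0]:
        return "PR"
    if b <= config.mr_band[1]:
        return "MR"
    return "SD"


def _simulate_lesion(
    config: SimulationConfig, index: int, srs: bool
) -> tuple[VolumeTrajectory, LesionRecord, GroundTruth, LesionKinetics, float]:
    rng = np.random.default_rng([config.seed, index])
    lesion_id = f"L{index:03d}"

    horizon = _draw_horizon(config, rng)
    tau = config.regression_timescale_months

    # response stratum and target best relative volume
    stratum = ["SD", "MR", "PR"][rng.choice(3, p=list(config.best_response_mix))]
    band = {"SD": config.sd_band, "MR": config.mr_band, "PR": config.pr_band}[stratum]
    b_target = rng.uniform(*band)

    # overlay class: transient enlargement / true progression / controlled
    p_te = config.te_prob_srs_hypo if srs else config.te_prob_conventional
    u = rng.uniform()
    if u < p_te:
        true_class = "transient_enlargement"
    elif u < p_te + config.progression_prob:
        true_class = "true_progression"
    else:
        true_class = _STRATUM_TO_CLASS[stratum]

    te_peak_time = None
    te_peak_increase = None
    if true_class == "transient_enlargement":
        te_peak_time = rng.uniform(*config.te_window_months)
        te_peak_increase = rng.uniform(*config.te_peak_increase_range)
        # a transiently enlarging lesion must eventually regress >= 20%
        # below its episode peak, so its underlying target best relative
        # volume is kept safely below 0.8 x (1 + peak increase)
        b_target = min(b_target, 0.75 * (1.0 + te_peak_increase))

    # plateau solved so the noise-free curve attains b_target at the horizon
    # (the last scheduled scan); a deep response within short follow-up is
    # modelled with a faster per-lesion regression timescale so the target
    # stays attainable
    decay = math.exp(-horizon / tau)
    f_inf = (b_target - decay) / (1.0 - decay)
    if f_inf < 0.01:
        f_inf = 0.01
        if true_class != "true_progression":
            tau = horizon / math.log((1.0 - f_inf) / (b_target - f_inf))
            decay = math.exp(-horizon / tau)

    v0 = math.exp(rng.normal(math.log(config.baseline_volume_median_cm3),
                             config.baseline_volume_log_sigma))

    kin_kwargs = dict(
        true_class=true_class,
        v0_cm3=v0,
        plateau_fraction=f_inf,
        timescale_months=tau,
    )
    progression_time = None
    if true_class == "transient_enlargement":
        tp = te_peak_time
        c_at_peak = f_inf + (1.0 - f_inf) * math.exp(-tp / tau)
        kin_kwargs.update(
            te_peak_time=tp,
            te_amplitude=(1.0 + te_peak_increase) - c_at_peak,
            te_width_months=config.te_bump_width_months,
        )
    elif true_class == "true_progression":
        onset = rng.uniform(0.15 * horizon, 0.35 * horizon)
        kin_kwargs.update(onset_months=onset, growth_rate=config.progression_growth_rate)
        progression_time = onset
    kinetics = LesionKinetics(**kin_kwargs)

    # measurement noise: multiplicative lognormal with unit mean
    sigma_ln = math.sqrt(math.log(1.0 + config.noise_cv**2))

    def observe(t: float) -> float:
        v = latent_volume(t, kinetics)
        if sigma_ln > 0:
            v *= math.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln))
        return v

    times = [config.baseline_scan_months]
    volumes = [observe(times[0])]
    while True:
        t_next = next_scan_time(config, times, volumes, horizon, rng)
        if t_next is None:
            break
        times.append(t_next)
        volumes.append(observe(t_next))

    trajectory = VolumeTrajectory(
        lesion_id,
        patient_id="",  # filled by the cohort assembler
        measurements=tuple(
            VolumeMeasurement(t, v) for t, v in zip(times, volumes)
        ),
    )

    record = LesionRecord(
        lesion_id=lesion_id,
        fractionation_group="srs_or_hypofractionated" if srs else "conventional",
        who_group="who2" if rng.uniform() < 0.10 else "low_grade",
        age_years=float(np.clip(round(rng.normal(63.0, 13.0)), 36, 86)),
        sex="female" if rng.uniform() < 0.75 else "male",
        baseline_volume_cm3=volumes[0],
        recurrence=bool(rng.uniform() < 0.17),
        preceding_surgery=bool(rng.uniform() < 0.07),
    )
    truth = GroundTruth(
        lesion_id=lesion_id,
        true_class=true_class,
        te_peak_time=te_peak_time,
        progression_time=progression_time,
        response_stratum=stratum,
    )
    return trajectory, record, truth, kinetics, horizon


def simulate_cohort(config: SimulationConfig | None = None, **overrides) -> SimulatedCohort:
    """Generate a reproducible synthetic cohort.

    Per-lesion random substreams are derived deterministically from
    ``(seed, lesion index)``, so the cohort is reproducible and stable under
    lesion reordering.  SRS/hypofractionated lesions are the first
    ``round(n_lesions * frac_srs_hypo)`` indices.
    """
    if config is None:
        config = SimulationConfig()
    if overrides:
        config = replace(config, **overrides)
    config.validate()

    n = config.n_lesions
    n_srs = round(n * config.frac_srs_hypo)
    # ~64 patients for 69 lesions: a few patients carry two lesions
    n_patients = max(1, round(n * 64 / 69))

    trajectories, records, truths, kinetics, horizons = [], [], [], [], []
    for i in range(n):
        traj, rec, truth, kin, horizon = _simulate_lesion(config, i, srs=i < n_srs)
        traj = VolumeTrajectory(
            traj.lesion_id, f"P{i % n_patients:03d}", traj.measurements
        )
        trajectories.append(traj)
        records.append(rec)
        truths.append(truth)
        kinetics.append(kin)
        horizons.append(horizon)
    return SimulatedCohort(
        trajectories=tuple(trajectories),
        records=tuple(records),
        truths=tuple(truths),
        kinetics=tuple(kinetics),
        horizons=tuple(horizons),
    )
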