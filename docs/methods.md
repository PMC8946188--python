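# Methods

## Units of analysis and data model

The lesion, not the patient, is the unit of analysis: patients with several
treated meningiomas contribute one independent row per lesion and no
within-patient correlation is modelled. Times are months from the start of
radiotherapy (1 month = 30.44 days when converting calendar dates); volumes
are cm³. The baseline volume `V0` is the latest scan at `t ≤ 0`; earlier
pre-treatment scans are kept but ignored (with a logged warning). Segmented
label masks contribute volumes as `count(label) × voxel volume / 1000`.

## Response classification

Per-timepoint categories use the volumetric thresholds 1.40 (progression,
against the smaller of baseline and the running nadir), 0.60 (minor
response) and 0.35 (partial response), all inclusive. PD takes precedence
over PR/MR at the same scan: regrowth of ≥ 40% from a deep nadir is
progression even when the volume is still far below baseline. Threshold
comparisons carry a relative tolerance of 1e-9 so boundary volumes (exactly
140%, 60%, 35%, 120%) classify deterministically. Best response considers
follow-up scans only and may be positive (a lesion that never shrinks is
SD as long as it stays below the progression trigger).

### Transient enlargement

An enlargement *episode* starts at the first follow-up with
`V ≥ 1.20 · V0` (the rise reference is baseline by default; the running
nadir is available as a configuration option). The episode maximum is
tracked forward in time; the episode *resolves* at the first later scan
with `V ≤ 0.80 ×` episode maximum. A resolved episode is transient
enlargement; a rise that never resolves is reported as
`unresolved_at_last_fu` and is **not** TE — it cannot be confirmed as
pseudoprogression and therefore counts as an event under both survival
rules once it crosses the PD threshold. Episode semantics (rather than a
single global maximum) were chosen so that a trajectory with an early
resolved enlargement followed by late regrowth is handled coherently: the
early crossing is pseudoprogression, the late regrowth a distinct
progression event. The tests compare the implementation against an
independent literal re-evaluation of these definitions on every trajectory
of length ≤ 5 over a 9-value volume grid (66,429 trajectories).

### Event rules

*Naive*: the first PD-classified scan is the event. *TE-aware*: starting
from a PD scan, if the episode resolves the crossing is discounted and the
search continues after the resolution scan; the lesion is censored at last
follow-up unless a later, distinct PD occurs. By construction TE-aware
events are a subset of naive events, so the TE-aware Kaplan–Meier curve
dominates the naive curve pointwise (property-tested).

## Survival analysis

The product-limit estimate is computed by `lifelines.KaplanMeierFitter`
(ties resolved events-first) and repackaged as a step function with at-risk
counts and censoring marks; an independent hand-rolled product-limit oracle
checks it to 1e-12 on random small cohorts. Fixed-horizon control uses the
right-continuous step value at the largest event time ≤ horizon; horizons
beyond the last observed time return the last value with an explicit
extrapolation warning. Confidence bands are the log-log (exponential
Greenwood) intervals lifelines produces; they are informational only.

## Cohort statistics

Fisher's exact two-sided p is the sum of hypergeometric probabilities of
all tables (margins fixed) no more likely than the observed one.
Probabilities are compared as exact integers (`C(r1,k)·C(r2,c1-k)`), so tie
decisions are deterministic and the result agrees with a rational-arithmetic
enumeration oracle to machine precision; scipy's implementation is
cross-checked in a test. The reported odds ratio is the sample
cross-product `ad/bc` (infinite when `bc = 0`).

Wilcoxon rank-sum uses the exact null distribution for combined n ≤ 30
without ties and the tie-corrected normal approximation otherwise (no
continuity correction, so identical samples give p = 1 exactly).

Logistic fits are unpenalized maximum likelihood (statsmodels GLM,
binomial family, iteration cap 100). Under complete separation the
degenerate fit is reported as such — odds ratio → 0 or ∞ with Wald p near
1 and `separation_flag` set — rather than switching to a penalized
estimator, matching how clinical software reports such rows. Continuous
covariates are dichotomized at the cohort median (≥ cutpoint → 1);
predictors with univariate Wald p < 0.300 enter the multivariate model.

## Synthetic cohort generator

The generator emulates the study conditions: 69 lesions (12
SRS/hypofractionated, 57 conventional, assigned deterministically),
lognormal baseline volumes with median 4.7 cm³ and log-sigma 1.434 —
back-derived from the interquartile range 1.3–9.0 cm³ via the quartile
ratio `σ = ln(Q3/Q1)/(2 z_0.75)`; a lognormal cannot also reproduce the
asymmetry of that IQR around the median, which is accepted — transient
enlargement with probability 0.25 (SRS/hypo) vs 1/57 (conventional), true
progression probability 2/69, follow-up horizons lognormal around 42.3
months truncated to [6, 120], and multiplicative lognormal measurement
noise with CV 0.05 (the within-lesion measurement error is not known
empirically; the CV is a free parameter reported with every simulated
result).

**Kinetics.** Controlled lesions relax exponentially towards a plateau:
`r(t) = f∞ + (1 − f∞) e^{−t/τ}`, τ = 24 months by default. Each lesion
draws a response stratum (SD/MR/PR with probabilities 0.81/0.13/0.06) and a
target best relative volume `b` uniformly within the stratum band — SD
(0.60, 1.19], MR (0.35, 0.60], PR (0.14, 0.35], the outer limits taken from
the observed best-change range of −86% to +19% — and `f∞` is solved so the
noise-free curve attains exactly `b` at the last scheduled scan. Deep
responses within short follow-up are modelled by shortening that lesion's τ
instead of truncating the target, which keeps the stratum mix an unbiased
multinomial draw. Transient enlargement adds a Gaussian bump (width 2
months) centred at `t_p ~ U(4.1, 10.3)` months with amplitude set so the
peak relative increase lies in (0.24, 3.89); the bump is ramped in over the
first 2 months so the baseline anchors exactly at `V0`, and the underlying
target `b` is capped at `0.75 (1 + peak)` so the ≥ 20% regression is
expressible within follow-up. True progression multiplies the controlled
curve by `e^{0.15 (t − t_0)}` after a latent onset `t_0 ~ U(0.15 T, 0.35 T)`
(T = horizon), which guarantees an observable PD crossing by the final scan
even for the shortest horizons. The functional forms are package
inventions — the emulated study reports only endpoints and ranges — and are
isolated behind `latent_volume` so alternatives can be swapped.

**Imaging schedule.** Baseline at −0.33 months, first follow-up at 3
months, then intervals drawn from U[6, 12] months, shortened to 3 months
whenever the latest observed volume exceeds the prior observed minimum by
≥ 20%; follow-up stops at the lesion's horizon with the final scan placed
at the horizon itself (the last imaging date). Covariates are drawn from
the emulated frequencies (75% female, 10% WHO II, 17% recurrence, 7%
preceding surgery, age ≈ N(63, 13) clipped to 36–86).

**Reproducibility.** A single global seed; per-lesion substreams derive
from `(seed, lesion index)`, so cohorts are bit-reproducible and stable
under reordering.

**What the generator does not emulate.** Monotone latent curves mean every
controlled lesion attains its best response at the last scan, whereas real
cohorts show it earlier in about half of cases; regression depth does not
differ by fractionation arm; scan timing irregularities beyond the
interval jitter, within-patient correlation, and measurement-error
structure beyond a constant CV are absent. Passing tests therefore
demonstrate correctness of the analysis chain under these idealized
kinetics, not the realism of any particular trajectory shape.

## Recovery and calibration checks

Ground-truth recovery maps an assessment to a class (TE detected →
transient enlargement; else TE-aware event → true progression; else the
best-response category). Without noise, recovery is exact for every lesion
whose *sampled* noise-free series expresses its enlargement (a scan during
the rise and one after the regression); enlargements that fall entirely
between scans are excluded from the noise-free check because no assessment
could see them — a scan merely lying within one bump-width of the peak does
not guarantee the 20% rise was sampled when the peak increase is small.
With 5% noise, ≥ 90% of 500 lesions are required to recover; the observed
misclassifications sit almost entirely at the SD/MR boundary, where noise
biases the observed minimum downward. Generator calibration (response-mix
frequencies, SRS-arm TE counts against Binomial(12, 0.25)) is checked on
the ground-truth labels across 200 default cohorts.

Problem sizes used by the test-suite and acceptance script: exhaustive
classifier grids of 66,429 trajectories, recovery cohorts of 500 lesions,
50 assessed and 200 generator-calibration cohorts of 69 lesions, and 500
random tables (n ≤ 200) for the Fisher enumeration equivalence. These sizes
give stable statistics at desk scale.

## Known limitations

* No confirmatory-scan requirement before calling progression: assessment
  is per scan.
* Distant lesions, corticosteroid use, clinical status, T2/edema changes
  and dose–response mechanisms are out of scope.
* The five-year control figures of a real cohort depend on its censoring
  pattern; the reference event structure used in the acceptance checks
  reproduces the event counts (5 naive / 2 TE-aware among 69) without
  early censoring, which brackets but does not equal a study-specific
  estimate.
* Under complete separation the logistic Wald p-value is uninformative by
  construction; the flag, not the p, is the signal.
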