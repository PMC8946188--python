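"""End-to-end workflow: read or simulate -> assess -> survival -> statistics.

Produces the tabular artifacts of a full cohort analysis: per-lesion
assessment CSV, Kaplan-Meier curve CSVs under both progression rules, a
logistic-regression table of candidate pseudoprogression predictors, the
fractionation x transient-enlargement 2x2 with Fisher's exact test, a
long-format spider table for plotting, and a JSON summary.  Optional
matplotlib figures (spider plot and dual KM plot) sit behind a flag; the
analysis surfaces are the tables, not the images.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .errors import ValidationError
from .response import (
    DEFAULT_THRESHOLDS,
    RanoThresholds,
    ResponseAssessment,
    assess_cohort,
    cohort_best_response_summary,
)
from .simulate import SimulationConfig, simulate_cohort
from .stats import (
    DEFAULT_SCREEN_P,
    TwoByTwo,
    dichotomize,
    fisher_exact,
    multivariate_screen_and_fit,
    wilcoxon_rank_sum,
)
from .survival import KMCurve, dual_local_control

log = logging.getLogger(__name__)

SPIDER_CLASSES = (
    "progression",
    "transient enlargement/pseudoprogression",
    "volumetric regression",
    "volumetric control",
)


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of (``trajectories_path``, ``simulation``) must be supplied.
    """

    trajectories_path: str | Path | None = None
    covariates_path: str | Path | None = None
    simulation: SimulationConfig | None = None
    thresholds: RanoThresholds = field(default_factory=RanoThresholds)
    horizon_months: float = 60.0
    out_dir: str | Path = "ranovol_out"
    seed: int | None = None
    make_plots: bool = False

    def validate(self) -> None:
        if (self.trajectories_path is None) == (self.simulation is None):
            raise ValidationError(
                "exactly one of trajectories_path or simulation must be supplied"
            )


def lesion_outcome_class(assessment: ResponseAssessment) -> str:
    """Map one lesion to the four spider-plot outcome classes.

    Priority: progression (a TE-aware event) > transient enlargement >
    volumetric regression (best response MR or PR) > volumetric control.
    """
    if assessment.te_aware_event:
        return "progression"
    if assessment.te.detected:
        return "transient enlargement/pseudoprogression"
    if assessment.best_category in ("MR", "PR"):
        return "volumetric regression"
    return "volumetric control"


def spider_table(assessments: Sequence[ResponseAssessment]) -> pd.DataFrame:
    """Long-format (lesion, time, relative volume, outcome class) table."""
    if len(assessments) == 0:
        raise ValidationError("cannot build a spider table from no assessments")
    rows = []
    for a in assessments:
        cls = lesion_outcome_class(a)
        for tp in a.timepoints:
            rows.append(
                {
                    "lesion_id": a.lesion_id,
                    "time_months": tp.time_months,
                    "relative_volume": tp.relative_volume,
                    "outcome_class": cls,
                }
            )
    return pd.DataFrame(rows)


def _km_frame(curve: KMCurve) -> pd.DataFrame:
    censored = np.asarray(curve.censor_times)
    return pd.DataFrame(
        {
            "time_months": curve.times,
            "survival": curve.survival,
            "at_risk": curve.at_risk,
            "n_censored_before": [int(np.sum(censored < t)) for t in curve.times],
        }
    )


def _predictor_frame(
    records: Sequence[tio.LesionRecord],
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Candidate pseudoprogression predictors, dichotomized as in the analysis plan.

    Continuous covariates (baseline volume, age) are split at the cohort
    median; all others are binary indicators.
    """
    volume = np.array([r.baseline_volume_cm3 for r in records])
    age = np.array([r.age_years for r in records])
    cuts = {"baseline_volume_cm3": float(np.median(volume)), "age_years": float(np.median(age))}
    frame = pd.DataFrame(
        {
            "srs_or_hypofractionated": [
                int(r.fractionation_group == "srs_or_hypofractionated") for r in records
            ],
            "baseline_volume_high": dichotomize(volume, cuts["baseline_volume_cm3"]),
            "who2": [int(r.who_group == "who2") for r in records],
            "age_high": dichotomize(age, cuts["age_years"]),
            "recurrence": [int(r.recurrence) for r in records],
            "male": [int(r.sex == "male") for r in records],
            "preceding_surgery": [int(r.preceding_surgery) for r in records],
        }
    )
    return frame, cuts


def cohort_statistics(
    assessments: Sequence[ResponseAssessment],
    records: Sequence[tio.LesionRecord],
    screen_p: float = DEFAULT_SCREEN_P,
) -> dict:
    """Fractionation/TE contrast and the screened logistic-regression table."""
    by_id = {a.lesion_id: a for a in assessments}
    records = [r for r in records if r.lesion_id in by_id]
    te = np.array([int(by_id[r.lesion_id].te.detected) for r in records])
    srs = np.array(
        [int(r.fractionation_group == "srs_or_hypofractionated") for r in records]
    )
    table = TwoByTwo.from_vectors(te, srs)
    fisher = fisher_exact(table)

    best_change = np.array(
        [by_id[r.lesion_id].best_relative_volume - 1.0 for r in records]
    )
    if srs.min() != srs.max():
        wilcoxon_p = wilcoxon_rank_sum(best_change[srs == 1], best_change[srs == 0])
    else:
        wilcoxon_p = float("nan")

    result = {
        "te_table": table,
        "fisher": fisher,
        "te_rate_srs_hypo": table.exposed_rate if (table.a + table.b) else float("nan"),
        "te_rate_conventional": table.unexposed_rate if (table.c + table.d) else float("nan"),
        "wilcoxon_best_change_p": wilcoxon_p,
        "logistic": None,
        "cutpoints": None,
    }
    predictors, cuts = _predictor_frame(records)
    result["cutpoints"] = cuts
    if te.min() != te.max():
        result["logistic"] = multivariate_screen_and_fit(te, predictors, screen_p)
    else:
        log.info("outcome has a single class; logistic regression skipped")
    return result


def logistic_table(model) -> pd.DataFrame:
    """Flatten a :class:`~ranovol.stats.ScreenedModel` into a report table."""
    multi = {r.predictor: r for r in model.multivariate}
    rows = []
    for r in model.univariate:
        m = multi.get(r.predictor)
        rows.append(
            {
                "predictor": r.predictor,
                "univariate_or": r.odds_ratio,
                "univariate_p": r.p_value,
                "included_in_multivariate": r.included_in_multivariate,
                "multivariate_or": m.odds_ratio if m else np.nan,
                "multivariate_p": m.p_value if m else np.nan,
                "separation_flag": r.separation_flag,
            }
        )
    return pd.DataFrame(rows)


def _plot_outputs(assessments, dual, out_dir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {
        "progression": "darkred",
        "transient enlargement/pseudoprogression": "orange",
        "volumetric regression": "green",
        "volumetric control": "c",
    }
    fig, ax = plt.subplots(figsize=(7, 5))
    for a in assessments:
        cls = lesion_outcome_class(a)
        times = [0.0] + [tp.time_months for tp in a.timepoints]
        rels = [1.0] + [tp.relative_volume for tp in a.timepoints]
        ax.plot(times, 100 * np.asarray(rels), color=colors[cls], lw=0.8, alpha=0.7)
    ax.axhline(140, ls="--", c="gray", lw=0.8)
    ax.set_xlabel("months from RT start")
    ax.set_ylabel("relative volume (%)")
    fig.savefig(out_dir / "spider.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(7, 5))
    for curve, label, color in (
        (dual.naive_curve, "pseudoprogression not accounted for", "red"),
        (dual.te_aware_curve, "pseudoprogression accounted for", "blue"),
    ):
        t = [0.0] + list(curve.times) + [curve.last_observed_time]
        s = [1.0] + list(curve.survival) + [curve.survival[-1] if curve.survival else 1.0]
        ax.step(t, s, where="post", label=label, color=color)
        ax.plot(curve.censor_times, [curve.survival_at(ct) for ct in curve.censor_times],
                "|", color=color, ms=8)
    ax.set_ylim(0, 1.05)
    ax.set_xlabel("months from RT start")
    ax.set_ylabel("local control")
    ax.legend(loc="lower left")
    fig.savefig(out_dir / "km.png", dpi=150)
    plt.close(fig)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow and write all artifacts to ``out_dir``.

    Returns the summary dictionary that is also written to ``summary.json``.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    records: list[tio.LesionRecord] | None = None
    if config.simulation is not None:
        sim = config.simulation
        if config.seed is not None:
            sim = dataclasses.replace(sim, seed=config.seed)
        cohort = simulate_cohort(sim)
        trajectories = list(cohort.trajectories)
        records = list(cohort.records)
        tio.write_trajectories(trajectories, out_dir / "trajectories.csv")
        tio.write_covariates(records, out_dir / "covariates.csv")
        truth_rows = [
            {
                "lesion_id": t.lesion_id,
                "true_class": t.true_class,
                "te_peak_time": t.te_peak_time,
                "progression_time": t.progression_time,
                "response_stratum": t.response_stratum,
            }
            for t in cohort.truths
        ]
        pd.DataFrame(truth_rows).to_csv(out_dir / "ground_truth.csv", index=False)
    else:
        trajectories = tio.read_trajectories(config.trajectories_path)
        if config.covariates_path is not None:
            records = tio.read_covariates(config.covariates_path)
            tio.check_baseline_consistency(trajectories, records)
    log.info("stage read/simulate: %d lesions", len(trajectories))

    assessments = assess_cohort(trajectories, config.thresholds)
    tio.write_assessments(assessments, out_dir / "assessments.csv")
    spider = spider_table(assessments)
    spider.to_csv(out_dir / "spider.csv", index=False)
    n_te = sum(a.te.detected for a in assessments)
    log.info(
        "stage assess: %d lesions, %d transient enlargements, %d naive / %d TE-aware events",
        len(assessments),
        n_te,
        sum(a.naive_event for a in assessments),
        sum(a.te_aware_event for a in assessments),
    )

    dual = dual_local_control(assessments, config.horizon_months)
    _km_frame(dual.naive_curve).to_csv(out_dir / "km_naive.csv", index=False)
    _km_frame(dual.te_aware_curve).to_csv(out_dir / "km_te_aware.csv", index=False)
    log.info(
        "stage survival: control at %.0f months %.3f (naive) vs %.3f (TE-aware)",
        config.horizon_months,
        dual.naive_control,
        dual.te_aware_control,
    )

    best = cohort_best_response_summary(assessments)
    summary: dict = {
        "n_lesions": len(assessments),
        "best_response_counts": best["counts"],
        "best_response_pct": {
            k: 100.0 * v / best["n"] for k, v in best["counts"].items()
        },
        "mean_best_change_pct": 100.0 * best["mean_change"],
        "te_count": int(n_te),
        "te_incidence_pct": 100.0 * n_te / len(assessments),
        "naive_events": int(sum(a.naive_event for a in assessments)),
        "te_aware_events": int(sum(a.te_aware_event for a in assessments)),
        "horizon_months": config.horizon_months,
        "control_naive_pct": 100.0 * dual.naive_control,
        "control_te_aware_pct": 100.0 * dual.te_aware_control,
    }

    if records is not None:
        stats = cohort_statistics(assessments, records)
        t = stats["te_table"]
        summary["te_table"] = {"a": t.a, "b": t.b, "c": t.c, "d": t.d}
        summary["te_odds_ratio"] = stats["fisher"].odds_ratio
        summary["te_fisher_p"] = stats["fisher"].p_value
        summary["te_rate_srs_hypo_pct"] = 100.0 * stats["te_rate_srs_hypo"]
        summary["te_rate_conventional_pct"] = 100.0 * stats["te_rate_conventional"]
        summary["wilcoxon_best_change_p"] = stats["wilcoxon_best_change_p"]
        if stats["logistic"] is not None:
            logistic_table(stats["logistic"]).to_csv(
                out_dir / "logistic_table.csv", index=False
            )
        log.info("stage stats: 2x2 = %s, Fisher p = %.4f", summary["te_table"],
                 stats["fisher"].p_value)

    if config.make_plots:
        _plot_outputs(assessments, dual, out_dir)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_default)
    return summary
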