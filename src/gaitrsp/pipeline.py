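"""End-to-end orchestration: raw cohort -> waveforms -> features -> report.

The per-subject path mirrors the processing chain of a wearable gait lab:

1. low-pass filter all eight trials (10 Hz zero-phase Butterworth);
2. estimate each sensor's attitude from its static trial and rotate the
   walking accelerations into the gravity-aligned frame;
3. detect IC/TO events from the foot gyroscope, segment every sensor's
   accelerations into time-normalized 60/40 stance/swing cycles, and
   ensemble-average into one 300-point waveform per sensor;
4. reduce each sensor's cohort waveform matrix to n−1 PC scores (PCA is
   fit once on the full cohort, matching the published procedure; see
   docs/methods.md for the leakage trade-off), append baseline KOOS;
5. label responders from KOOS effect sizes, then run LDA + sequential
   forward selection under repeated stratified 10-fold CV per sensor set
   and compare sets by ANOVA + Fisher's LSD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import (
    classification,
    features,
    gait_segmentation as seg,
    outcomes,
    preprocessing as prep,
    reporting,
)
from .preprocessing import PLACEMENTS
from .synthetic_data import koos_frames


def process_subject(record, cutoff_hz: float = 10.0, order: int = 4) -> dict:
    """Compute the four per-sensor 300-point gait waveforms of one subject."""
    foot = prep.lowpass_filter(record.trial("foot", "walking"), cutoff_hz, order)
    events = seg.detect_events(foot)
    waveforms = {}
    for p in PLACEMENTS:
        static = prep.lowpass_filter(record.trial(p, "static"), cutoff_hz, order)
        walking = prep.lowpass_filter(record.trial(p, "walking"), cutoff_hz, order)
        att = prep.estimate_attitude(static)
        corrected = prep.apply_attitude(walking, att)
        cycles, _ = seg.segment_and_normalize(corrected, events)
        waveforms[p] = seg.average_waveform(cycles, p)
    return waveforms


def cohort_waveforms(cohort, cutoff_hz: float = 10.0, order: int = 4) -> dict:
    """Per-placement n×300 waveform DataFrames (index subject_id)."""
    per_subject = {r.subject_id: process_subject(r, cutoff_hz, order) for r in cohort}
    return seg.frame_to_matrices(seg.waveforms_to_frame(per_subject))


@dataclass
class AnalysisResult:
    """Everything the full analysis produces for one cohort."""

    labels: pd.DataFrame  # mean_d + label per subject
    max_chance_pct: float
    results: list  # SelectionResult per sensor set
    comparison: classification.ComparisonReport | None
    importance: reporting.ImportanceReport | None  # best set's final model
    loading_profiles: dict | None
    tables: dict

    def result_for(self, sensor_set) -> classification.SelectionResult:
        key = tuple(sorted(sensor_set))
        for r in self.results:
            if tuple(sorted(r.sensor_set)) == key:
                return r
        raise KeyError(f"no result for sensor set {sensor_set}")


def run_analysis(
    cohort,
    sensors=PLACEMENTS,
    sensor_sets=None,
    n_iterations: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    mode: str = "selection",
    denominator: str = "baseline_sd",
    scale_pca: bool = True,
    waveforms: dict | None = None,
) -> AnalysisResult:
    """Run the full responder-prediction analysis on a cohort.

    ``sensor_sets`` defaults to all non-empty subsets of ``sensors`` (15
    for the four placements).  Precomputed ``waveforms`` may be passed to
    skip signal processing.
    """
    if waveforms is None:
        waveforms = cohort_waveforms(cohort)
    pre, post = koos_frames(cohort)
    d = outcomes.effect_sizes(pre, post, denominator=denominator)
    labels_df = outcomes.label_responders(d)
    labels = labels_df["label"]
    max_chance = outcomes.max_chance_criterion(labels)

    if sensor_sets is None:
        sensor_sets = classification.enumerate_sensor_sets(sensors)
    # one cohort-level PCA per sensor, shared by every subset containing it
    pca_models = {
        s: features.fit_pca(waveforms[s].loc[labels.index].to_numpy(), s, scale=scale_pca)
        for s in {p for ss in sensor_sets for p in ss}
    }

    results = []
    for ss in sensor_sets:
        table = features.build_feature_table(
            waveforms, pre, labels, sensors=ss, scale=scale_pca, pca_models=pca_models
        )
        res = classification.repeated_cv_evaluation(
            table,
            n_iterations=n_iterations,
            n_folds=n_folds,
            seed=seed,
            mode=mode,
            sensor_set=tuple(ss),
        )
        results.append(res)

    comparison = (
        classification.compare_sensor_sets(results)
        if len(results) >= 2 and n_iterations >= 2
        else None
    )

    importance = None
    profiles = None
    best = comparison.best_set if comparison else results[0].sensor_set
    best_res = next(r for r in results if r.sensor_set == tuple(best))
    if best_res.selected_feature_names:
        table = features.build_feature_table(
            waveforms, pre, labels, sensors=best, scale=scale_pca, pca_models=pca_models
        )
        sel = table.features[best_res.selected_feature_names]
        Z = (sel - sel.mean()) / sel.std(ddof=1).replace(0, 1.0)
        final = classification.fit_lda(Z.to_numpy(), labels.to_numpy())
        importance = reporting.relative_importance(final, best_res.selected_feature_names)
        gait_selected = [f for f in best_res.selected_feature_names if not f.startswith("koos_")]
        profiles = reporting.loading_map(
            {s: pca_models[s] for s in best}, gait_selected, importance.proportions
        )

    return AnalysisResult(
        labels=labels_df,
        max_chance_pct=max_chance,
        results=results,
        comparison=comparison,
        importance=importance,
        loading_profiles=profiles,
        tables=reporting.results_tables(results),
    )


def report_to_dict(result: AnalysisResult) -> dict:
    """JSON-serializable summary of an AnalysisResult."""
    out = {
        "max_chance_pct": result.max_chance_pct,
        "labels": {
            sid: {"mean_d": float(row.mean_d), "label": row.label}
            for sid, row in result.labels.iterrows()
        },
        "sensor_sets": [
            {
                "sensor_set": list(r.sensor_set),
                "mean_accuracy": r.mean_accuracy,
                "sd_accuracy": r.sd_accuracy,
                "formatted": r.formatted_accuracy(),
                "selected_features": list(r.selected_feature_names),
                "error_trajectory": [float(e) for e in r.cv_error_trajectory],
                "iteration_accuracies": [float(a) for a in r.iteration_accuracies],
                "mode": r.mode,
            }
            for r in result.results
        ],
    }
    if result.comparison is not None:
        out["comparison"] = {
            "anova_f": result.comparison.anova_f,
            "anova_p": result.comparison.anova_p,
            "best_set": list(result.comparison.best_set),
            "equivalent_sets": [list(s) for s in result.comparison.equivalent_sets],
            "pairwise": result.comparison.pairwise.to_dict(orient="records"),
        }
    if result.importance is not None:
        out["importance_pct"] = {
            str(k): float(v) for k, v in result.importance.proportions.items()
        }
        out["importance_gait_vs_pro"] = {
            "gait": result.importance.gait_pct,
            "pro": result.importance.pro_pct,
        }
    return out
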