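"""Derived analytics: feature importance, loading maps, summary tables.

Relative importance of a feature in a fitted discriminant model is its sum
of squared coefficients across the k−1 discriminant functions, normalized
so the selected features total 100%.  For this to compare gait PCs and
KOOS subscales on one axis the model must be fitted on standardized
features.  Loading maps project the selected gait PCs back onto the
300-point gait-cycle waveform: each sensor's signed profile is the
importance-weighted sum of its selected PC loading vectors, zero wherever
no selected PC loads.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classification import LdaModel, SelectionResult
from .features import PcaModel, SENSOR_PREFIX

PREFIX_TO_SENSOR = {v: k for k, v in SENSOR_PREFIX.items()}


@dataclass
class ImportanceReport:
    """Percent of discriminant loading per selected feature (sums to 100)."""

    proportions: pd.Series  # index feature name, values percent
    gait_pct: float  # total over gait-PC features
    pro_pct: float  # total over patient-reported-outcome features


def relative_importance(model: LdaModel, feature_names) -> ImportanceReport:
    """Sum of squared discriminant coefficients per feature, as percents."""
    if model is None or model.scalings is None:
        raise ValueError("model is not fitted")
    names = list(feature_names)
    if model.scalings.shape[0] != len(names):
        raise ValueError(
            f"model has {model.scalings.shape[0]} features but "
            f"{len(names)} names were given"
        )
    ssq = (model.scalings**2).sum(axis=1)
    total = ssq.sum()
    if total == 0:
        raise ValueError("all discriminant coefficients are zero")
    prop = pd.Series(100.0 * ssq / total, index=names)
    is_pro = prop.index.str.startswith("koos_")
    return ImportanceReport(
        proportions=prop,
        gait_pct=float(prop[~is_pro].sum()),
        pro_pct=float(prop[is_pro].sum()),
    )


def _parse_pc_name(name: str):
    sensor = PREFIX_TO_SENSOR.get(name[:1])
    if sensor is None or not name[1:].isdigit():
        raise KeyError(f"unknown gait PC name {name!r}")
    return sensor, int(name[1:])


def loading_map(pca_models: dict, selected_pc_names, weights) -> dict:
    """Signed 300-point loading profile per sensor.

    ``weights`` maps feature name -> importance weight; each sensor's
    profile is Σ weight · loading-vector over its selected PCs (linear in
    the weights).  Sensors with no selected PCs get an all-zero profile.
    """
    profiles = {p: np.zeros(300) for p in pca_models}
    for name in selected_pc_names:
        sensor, k = _parse_pc_name(name)
        if sensor not in pca_models:
            raise KeyError(f"no PCA model for sensor {sensor!r} (feature {name!r})")
        model: PcaModel = pca_models[sensor]
        if not 1 <= k <= model.n_components:
            raise KeyError(f"{name!r}: PC index out of range (1..{model.n_components})")
        profiles[sensor] = profiles[sensor] + float(weights[name]) * model.loadings[:, k - 1]
    return profiles


def results_tables(results: list) -> dict:
    """Summary tables from a list of SelectionResults.

    Returns ``{"models": ..., "accuracy": ...}``: a model table (selected
    gait PCs, selected KOOS subscales, formatted accuracy per sensor set)
    and accuracy-chart data (mean/sd per set, set size).
    """
    model_rows, acc_rows = [], []
    for r in results:
        gait = [f for f in r.selected_feature_names if not f.startswith("koos_")]
        pro = [f.removeprefix("koos_") for f in r.selected_feature_names if f.startswith("koos_")]
        name = "+".join(r.sensor_set)
        model_rows.append(
            {
                "sensor_set": name,
                "gait_pcs": ", ".join(gait),
                "koos_subscales": ", ".join(pro),
                "n_features": len(r.selected_feature_names),
                "accuracy": f"{100 * r.mean_accuracy:.1f}%",
            }
        )
        acc_rows.append(
            {
                "sensor_set": name,
                "n_sensors": len(r.sensor_set),
                "mean_accuracy_pct": 100 * r.mean_accuracy,
                "sd_accuracy": r.sd_accuracy,
                "formatted": r.formatted_accuracy(),
            }
        )
    return {"models": pd.DataFrame(model_rows), "accuracy": pd.DataFrame(acc_rows)}


def tables_to_json(tables: dict) -> str:
    """Serialize the summary tables to JSON (row-oriented, round-trips)."""
    return json.dumps(
        {name: df.to_dict(orient="records") for name, df in tables.items()}, indent=2
    )


def tables_from_json(text: str) -> dict:
    return {name: pd.DataFrame(rows) for name, rows in json.loads(text).items()}


# ---------------------------------------------------------------------------
# optional figures (headless; JSON/CSV outputs above never require these)
# ---------------------------------------------------------------------------


def plot_accuracy(accuracy_table: pd.DataFrame, path, max_chance_pct: float | None = None):
    """Accuracy-vs-sensor-set chart (single placements and best arrays)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = accuracy_table.sort_values(["n_sensors", "sensor_set"])
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.errorbar(
        range(len(df)),
        df.mean_accuracy_pct,
        yerr=100 * df.sd_accuracy,
        fmt="o",
        capsize=3,
    )
    if max_chance_pct is not None:
        ax.axhline(max_chance_pct, ls="--", color="gray", label="max chance")
        ax.legend()
    ax.set_xticks(range(len(df)))
    ax.set_xticklabels(df.sensor_set, rotation=45, ha="right")
    ax.set_ylabel("10×10-fold CV accuracy (%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_loading_map(profiles: dict, path, group_waveforms: dict | None = None):
    """Per-sensor signed PC-loading profiles over the 300-point waveform,
    optionally over sub-group mean waveforms."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sensors = list(profiles)
    fig, axes = plt.subplots(len(sensors), 1, figsize=(8, 2.2 * len(sensors)), squeeze=False)
    x = np.arange(300)
    for ax, sensor in zip(axes[:, 0], sensors):
        prof = profiles[sensor]
        ax.fill_between(x, 0, prof, where=prof >= 0, color="tab:blue", alpha=0.5)
        ax.fill_between(x, 0, prof, where=prof < 0, color="tab:orange", alpha=0.5)
        if group_waveforms:
            for label, wf in group_waveforms.items():
                ax.plot(x, wf[sensor], lw=0.8, label=label)
            ax.legend(fontsize=6)
        for edge in (100, 200):
            ax.axvline(edge, color="k", lw=0.5)
        ax.set_title(sensor, fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
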