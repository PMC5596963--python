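"""Per-participant KOOS effect sizes and responder labels.

Treatment response is quantified per subject and subscale as a Cohen's d:
the pre→post change divided by a standard deviation.  The default
denominator is the cohort baseline SD of that subscale (sample SD, ddof=1);
a pooled pre/post SD is available as an alternative since the literature is
not uniform on standardizing individual change scores.  The four subscale
effect sizes (pain, symptoms, ADL, QoL) are averaged and thresholded:

* Non-responder:  mean d < 0.2
* Low-responder:  0.2 ≤ mean d < 0.8
* High-responder: mean d ≥ 0.8

Boundary values go to the higher band (0.2 → Low, 0.8 → High); worsening
(negative d) falls under Non-responder.  The maximum chance criterion —
the accuracy of always predicting the largest sub-group — is the baseline
any classifier of these labels must beat.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synthetic_data import KOOS_SUBSCALES

LOW_THRESHOLD = 0.2
HIGH_THRESHOLD = 0.8


def _check_scores(df: pd.DataFrame, name: str) -> pd.DataFrame:
    df = df[list(KOOS_SUBSCALES)]
    if ((df < 0) | (df > 100)).any().any():
        raise ValueError(f"{name} KOOS scores must lie in [0, 100]")
    return df


def effect_sizes(
    pre: pd.DataFrame,
    post: pd.DataFrame,
    denominator: str = "baseline_sd",
) -> pd.DataFrame:
    """Per-subject, per-subscale Cohen's d of the pre→post change.

    ``pre``/``post`` are indexed by subject with the four subscale columns.
    ``denominator`` is ``"baseline_sd"`` (cohort SD of the pre scores) or
    ``"pooled_sd"`` (root-mean-square of pre and post SDs).
    """
    if not pre.index.equals(post.index):
        raise ValueError("pre and post KOOS records must cover the same subjects")
    if len(pre) < 2:
        raise ValueError("need at least 2 subjects for the SD denominator")
    pre = _check_scores(pre, "pre")
    post = _check_scores(post, "post")
    sd_pre = pre.std(axis=0, ddof=1)
    if denominator == "baseline_sd":
        sd = sd_pre
    elif denominator == "pooled_sd":
        sd = np.sqrt((sd_pre**2 + post.std(axis=0, ddof=1) ** 2) / 2.0)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    zero = sd[sd == 0].index.tolist()
    if zero:
        raise ValueError(f"zero baseline SD for subscale(s) {zero}: Cohen's d undefined")
    return (post - pre) / sd


def label_responders(d: pd.DataFrame) -> pd.DataFrame:
    """Mean the four subscale effect sizes and assign responder labels.

    Returns a DataFrame (index subject_id) with ``mean_d`` and ``label``.
    """
    missing = [s for s in KOOS_SUBSCALES if s not in d.columns]
    if missing:
        raise ValueError(f"effect-size table lacks subscale(s) {missing}")
    mean_d = d[list(KOOS_SUBSCALES)].mean(axis=1)
    label = pd.Series(
        np.where(mean_d < LOW_THRESHOLD, "Non", np.where(mean_d < HIGH_THRESHOLD, "Low", "High")),
        index=d.index,
        name="label",
    )
    return pd.DataFrame({"mean_d": mean_d, "label": label})


def max_chance_criterion(labels) -> float:
    """Percent accuracy of always predicting the largest class (raw, not
    rounded; e.g. sub-groups of 10/20/9 give 51.28...)."""
    labels = pd.Series(labels)
    if len(labels) == 0:
        raise ValueError("no labels given")
    return 100.0 * labels.value_counts().iloc[0] / len(labels)
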