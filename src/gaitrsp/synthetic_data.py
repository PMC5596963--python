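"""Synthetic knee-OA gait cohorts: IMU walking/static trials + KOOS scores.

The generator is a statistical emulator, not a biomechanical simulation.
Each placement (back, thigh, shank, foot) gets smooth per-axis acceleration
templates built from a handful of Gaussian bumps positioned in percent gait
cycle, with a stance impact transient near initial contact and a swing lobe;
the foot gyroscope's mediolateral axis carries the classic stride signature
(dominant positive mid-swing peak flanked by negative troughs at toe-off
and initial contact) used for event detection.  Stride durations jitter
multiplicatively around the subject's cadence, so gait cycles differ in
length before time-normalization.

Responder sub-structure is injected twice:

* group-dependent additive waveform perturbations, localized in stance and
  near toe-off, strongest on the thigh and weaker on the back (nothing on
  shank/foot) — so the thigh is the planted best single sensor;
* KOOS pre/post pairs whose per-subscale change is scaled by the cohort
  baseline SD so that each subject's mean Cohen's d lands inside the band
  of its intended label (Non < 0.2 ≤ Low < 0.8 ≤ High), with margins.

Gravity, projected through a random per-sensor mounting tilt (pitch/roll
only), is added to the accelerations; a matching 5 s static standing trial
is produced per sensor so downstream attitude correction can be exercised
against the stored ground-truth rotations.
"""

from __future__ import annotations

import json
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .preprocessing import PLACEMENTS, SensorTrial

KOOS_SUBSCALES = ("pain", "symptoms", "adl", "qol")
GROUPS = ("Non", "Low", "High")

# ---------------------------------------------------------------------------
# waveform templates: axis -> [(center %GC, width %GC, amplitude g), ...]
# Stance occupies [0, 100*stance_fraction) %GC; initial contact is at 0,
# toe-off at 100*stance_fraction.  Amplitudes are dynamic accelerations in g
# (gravity is added separately on the vertical axis).
# ---------------------------------------------------------------------------
ACCEL_TEMPLATES: Mapping[str, Mapping[str, list]] = {
    "back": {
        "vertical": [(3, 4, 0.45), (28, 6, 0.20), (53, 4, 0.40), (80, 10, -0.15)],
        "ap": [(8, 5, 0.25), (45, 8, -0.20), (70, 8, 0.15)],
        "ml": [(10, 6, 0.20), (60, 8, -0.20), (85, 6, 0.10)],
    },
    "thigh": {
        "vertical": [(4, 3, 0.70), (30, 10, 0.15), (55, 5, 0.50), (75, 8, -0.20)],
        "ap": [(5, 4, 0.40), (50, 6, -0.35), (80, 8, 0.30)],
        "ml": [(12, 6, 0.25), (58, 6, -0.25), (85, 5, 0.15)],
    },
    "shank": {
        "vertical": [(3, 2.5, 1.00), (58, 4, 0.60), (80, 8, -0.25)],
        "ap": [(4, 3, 0.60), (55, 5, -0.50), (78, 6, 0.35)],
        "ml": [(6, 4, 0.30), (60, 5, -0.30), (88, 5, 0.20)],
    },
    "foot": {
        "vertical": [(2, 2, 1.20), (60, 3, 0.80), (78, 6, -0.30)],
        "ap": [(3, 2.5, 0.80), (58, 4, -0.70), (82, 5, 0.50)],
        "ml": [(8, 5, 0.30), (62, 4, -0.35), (90, 4, 0.25)],
    },
}

# group-effect bumps added as (sensor-observed effect level) * effect_scale
# * bump.  Localized in stance / near toe-off; thigh strongest, back weaker
# — the shank and foot carry no group information.
EFFECT_TEMPLATES: Mapping[str, Mapping[str, list]] = {
    "thigh": {"vertical": [(40, 8, 1.0)], "ap": [(58, 5, 0.8)]},
    "back": {"vertical": [(55, 6, 0.6), (95, 4, 0.4)]},
}

# sd of the sensor-specific noise on the observed effect level: the thigh
# reads the responder trait crisply, the back only a degraded echo of it —
# so the thigh is structurally the best single sensor, not just the largest
# amplitude (a shared trait read noise-free from two places would make the
# two sensors statistically interchangeable)
EFFECT_LEVEL_NOISE_SD = {"thigh": 0.15, "back": 0.55}

# foot gyroscope mediolateral (sensor y) axis, °/s.  Sign convention:
# mid-swing peak positive; toe-off and initial-contact troughs negative.
FOOT_GYRO_ML = [(0, 3, -200.0), (60, 3, -150.0), (80, 4, 300.0)]

# mild sensor-frame gyro content for the remaining channels (°/s)
GENERIC_GYRO = [(10, 8, 40.0), (65, 8, -50.0), (85, 6, 30.0)]

# KOOS baseline means by group (High responders start with worse scores,
# leaving the baseline subscales weakly predictive, as in real cohorts)
KOOS_BASELINE_MEAN = {"Non": 62.0, "Low": 57.0, "High": 52.0}
KOOS_BASELINE_SD = 12.0
# target mean Cohen's d bands per label, with margin to the 0.2/0.8 cuts
EFFECT_SIZE_BANDS = {"Non": (-0.15, 0.10), "Low": (0.30, 0.70), "High": (0.90, 1.40)}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level simulation parameters.

    ``cadence_hz`` is the (mean, sd) of the subject-level gait-cycle rate in
    cycles/s; ``stride_jitter_sd`` is the multiplicative per-stride duration
    jitter.  ``effect_scale`` scales the group-dependent waveform bumps (g
    per unit effect level); ``group_level_sd`` is the between-subject spread
    of that level around the group codes 0/1/2.
    """

    n_subjects: int = 39
    group_fractions: tuple = (10 / 39, 20 / 39, 9 / 39)
    cadence_hz: tuple = (1.0, 0.05)
    stance_fraction: float = 0.60
    trial_duration_s: float = 60.0
    static_duration_s: float = 5.0
    sample_rate_hz: float = 100.0
    tilt_deg_sd: float = 5.0
    noise_g_sd: float = 0.05
    gyro_noise_dps_sd: float = 5.0
    effect_scale: float = 0.08
    group_level_sd: float = 0.35
    subject_amp_sd: float = 0.10
    stride_jitter_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if len(self.group_fractions) != 3:
            raise ValueError("group_fractions must have 3 entries (Non, Low, High)")
        if any(f < 0 for f in self.group_fractions):
            raise ValueError("group fractions must be non-negative")
        if not np.isclose(sum(self.group_fractions), 1.0):
            raise ValueError("group_fractions must sum to 1")
        if not 0.0 < self.stance_fraction < 1.0:
            raise ValueError("stance_fraction must lie in (0, 1)")
        for name in ("trial_duration_s", "static_duration_s", "sample_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cadence_hz[0] <= 0:
            raise ValueError("mean cadence must be positive")

    def group_counts(self) -> dict:
        """Largest-remainder apportionment of n_subjects to the 3 groups."""
        raw = np.array(self.group_fractions) * self.n_subjects
        counts = np.floor(raw).astype(int)
        rem = raw - counts
        for i in np.argsort(-rem)[: self.n_subjects - counts.sum()]:
            counts[i] += 1
        if (counts == 0).any():
            bad = [g for g, c in zip(GROUPS, counts) if c == 0]
            raise ValueError(
                f"group fractions give zero subjects for {bad} at n={self.n_subjects}"
            )
        return dict(zip(GROUPS, (int(c) for c in counts)))


@dataclass
class SubjectRecord:
    """One subject: 8 sensor trials, KOOS pre/post, and metadata."""

    subject_id: str
    group: str  # ground-truth label assigned at generation
    trials: dict  # (placement, trial_type) -> SensorTrial
    koos_pre: dict  # subscale -> score
    koos_post: dict

    def trial(self, placement: str, trial_type: str) -> SensorTrial:
        return self.trials[(placement, trial_type)]


@dataclass
class GroundTruth:
    """Generation-time oracle for recovery tests."""

    labels: dict  # subject_id -> group
    event_indices: dict  # subject_id -> (ic indices, to indices)
    rotations: dict  # subject_id -> {placement: 3x3 sensor->global rotation}
    effect_levels: dict  # subject_id -> continuous waveform-effect level
    koos_effect_sizes: dict  # subject_id -> {subscale: intended Cohen's d}


def _bumps(phase_pct: np.ndarray, bumps: list) -> np.ndarray:
    """Evaluate Gaussian bumps on per-stride phase (percent), with wrap.

    Bumps near 0 or 100 %GC spill across stride boundaries; evaluating each
    bump at phase, phase-100 and phase+100 keeps the signal continuous.
    """
    out = np.zeros_like(phase_pct)
    for c, w, a in bumps:
        for shift in (-100.0, 0.0, 100.0):
            d = phase_pct - (c + shift)
            out += a * np.exp(-0.5 * (d / w) ** 2)
    return out


def _stride_phase(spec: CohortSpec, rng: np.random.Generator):
    """Stride boundary times and per-sample phase for one walking trial.

    Returns (sample phase in %GC, IC times, TO times); the trial starts at
    an initial contact.
    """
    mean_dur = 1.0 / max(
        rng.normal(spec.cadence_hz[0], spec.cadence_hz[1]), 0.2 * spec.cadence_hz[0]
    )
    durs = []
    total = 0.0
    while total < spec.trial_duration_s + mean_dur:
        d = mean_dur * (1.0 + spec.stride_jitter_sd * rng.standard_normal())
        durs.append(d)
        total += d
    starts = np.concatenate([[0.0], np.cumsum(durs)])
    t = np.arange(int(round(spec.trial_duration_s * spec.sample_rate_hz))) / spec.sample_rate_hz
    k = np.searchsorted(starts, t, side="right") - 1
    phase = 100.0 * (t - starts[k]) / np.asarray(durs)[k]
    ic_times = starts[starts < t[-1] + 0.5 / spec.sample_rate_hz]
    to_times = ic_times[:-1] + spec.stance_fraction * np.asarray(durs)[: len(ic_times) - 1]
    return phase, ic_times, to_times[to_times < t[-1]]


def _mount_rotation(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Random pitch/roll mounting tilt (no yaw), as sensor->global rotation."""
    angle = np.deg2rad(rng.normal(0.0, spec.tilt_deg_sd))
    azim = rng.uniform(0.0, 2 * np.pi)
    axis = np.array([np.cos(azim), np.sin(azim), 0.0])
    return Rotation.from_rotvec(axis * angle).as_matrix()


def generate_cohort(spec: CohortSpec):
    """Generate a cohort of SubjectRecords plus its GroundTruth oracle."""
    rng = np.random.default_rng(spec.seed)
    counts = spec.group_counts()
    labels = np.repeat(GROUPS, [counts[g] for g in GROUPS])
    rng.shuffle(labels)

    n_static = int(round(spec.static_duration_s * spec.sample_rate_hz))
    subjects, gt_events, gt_rot, gt_levels = [], {}, {}, {}

    # KOOS baselines first (cohort SD is needed to scale the changes)
    pre = np.empty((spec.n_subjects, len(KOOS_SUBSCALES)))
    for i, g in enumerate(labels):
        pre[i] = np.clip(
            rng.normal(KOOS_BASELINE_MEAN[g], KOOS_BASELINE_SD, len(KOOS_SUBSCALES)),
            5.0,
            90.0,
        )
    sd_pre = pre.std(axis=0, ddof=1)
    target_d = np.empty_like(pre)
    for i, g in enumerate(labels):
        mean_d = rng.uniform(*EFFECT_SIZE_BANDS[g])
        target_d[i] = mean_d + rng.normal(0.0, 0.08, len(KOOS_SUBSCALES))
    post = np.clip(pre + target_d * sd_pre, 0.0, 100.0)

    for i, g in enumerate(labels):
        sid = f"sub{i + 1:03d}"
        level = {"Non": 0.0, "Low": 1.0, "High": 2.0}[g] + rng.normal(0.0, spec.group_level_sd)
        gt_levels[sid] = level
        phase, ic_times, to_times = _stride_phase(spec, rng)
        fs = spec.sample_rate_hz
        gt_events[sid] = (
            np.round(ic_times * fs).astype(int),
            np.round(to_times * fs).astype(int),
        )
        # per-subject amplitude individuality, shared across trials
        amps = {
            p: {ax: rng.normal(1.0, spec.subject_amp_sd) for ax in ("vertical", "ap", "ml")}
            for p in PLACEMENTS
        }
        trials, rots = {}, {}
        n_walk = phase.shape[0]
        for p in PLACEMENTS:
            R = _mount_rotation(spec, rng)
            rots[p] = R
            obs_level = level + rng.normal(0.0, EFFECT_LEVEL_NOISE_SD.get(p, 0.0))
            # global-frame specific force: x=AP, y=ML, z=vertical (+1 g)
            f = np.empty((n_walk, 3))
            for j, ax in enumerate(("ap", "ml", "vertical")):
                w = amps[p][ax] * _bumps(phase, ACCEL_TEMPLATES[p][ax])
                eff = EFFECT_TEMPLATES.get(p, {}).get(ax)
                if eff:
                    w = w + obs_level * spec.effect_scale * _bumps(phase, eff)
                f[:, j] = w
            f[:, 2] += 1.0
            accel = f @ R + rng.normal(0.0, spec.noise_g_sd, (n_walk, 3))
            gyro = rng.normal(0.0, spec.gyro_noise_dps_sd, (n_walk, 3))
            gyro[:, 0] += 0.5 * _bumps(phase, GENERIC_GYRO)
            gyro[:, 2] += 0.3 * _bumps(phase, GENERIC_GYRO)
            if p == "foot":
                gyro[:, 1] += _bumps(phase, FOOT_GYRO_ML)
            else:
                gyro[:, 1] += _bumps(phase, GENERIC_GYRO)
            trials[(p, "walking")] = SensorTrial(p, "walking", fs, accel, gyro)
            static_accel = np.array([0.0, 0.0, 1.0]) @ R + rng.normal(
                0.0, spec.noise_g_sd, (n_static, 3)
            )
            static_gyro = rng.normal(0.0, spec.gyro_noise_dps_sd, (n_static, 3))
            trials[(p, "static")] = SensorTrial(p, "static", fs, static_accel, static_gyro)
        # note: sensor reading s = R_m^T f_global, with R_m = sensor->global;
        # `f @ R` above computes rows R^T f because R rows are global axes.
        gt_rot[sid] = rots
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=g,
                trials=trials,
                koos_pre=dict(zip(KOOS_SUBSCALES, pre[i])),
                koos_post=dict(zip(KOOS_SUBSCALES, post[i])),
            )
        )

    truth = GroundTruth(
        labels={s.subject_id: s.group for s in subjects},
        event_indices=gt_events,
        rotations=gt_rot,
        effect_levels=gt_levels,
        koos_effect_sizes={
            s.subject_id: dict(zip(KOOS_SUBSCALES, target_d[i]))
            for i, s in enumerate(subjects)
        },
    )
    return subjects, truth


# ---------------------------------------------------------------------------
# cohort I/O: CSV time series per trial + KOOS table + JSON manifest
# ---------------------------------------------------------------------------

_TS_COLUMNS = ["t_s", "ax_g", "ay_g", "az_g", "gx_dps", "gy_dps", "gz_dps"]


def _trial_filename(subject_id: str, placement: str, trial_type: str) -> str:
    return f"{subject_id}_{placement}_{trial_type}.csv"


def write_cohort(cohort, directory, truth: GroundTruth | None = None) -> dict:
    """Write a cohort to ``directory``; returns the manifest dict.

    Layout: one CSV per (subject, placement, trial type) — 8 per subject —
    plus ``koos.csv`` (long format) and ``manifest.json``.  Floats are
    written with ``repr`` precision so a read-back round-trips exactly.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"subjects": []}
    koos_rows = []
    for rec in cohort:
        files = {}
        for (p, tt), trial in sorted(rec.trials.items()):
            fn = _trial_filename(rec.subject_id, p, tt)
            df = pd.DataFrame(
                np.column_stack([trial.times, trial.accel, trial.gyro]),
                columns=_TS_COLUMNS,
            )
            df.to_csv(directory / fn, index=False)
            files[f"{p}/{tt}"] = fn
        for phase_name, scores in (("pre", rec.koos_pre), ("post", rec.koos_post)):
            koos_rows.append({"subject_id": rec.subject_id, "phase": phase_name, **scores})
        entry = {
            "subject_id": rec.subject_id,
            "group": rec.group,
            "sample_rate_hz": rec.trials[("back", "walking")].sample_rate,
            "files": files,
        }
        manifest["subjects"].append(entry)
    pd.DataFrame(koos_rows).to_csv(directory / "koos.csv", index=False)
    if truth is not None:
        manifest["ground_truth_labels"] = truth.labels
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_cohort(directory):
    """Read a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    koos = pd.read_csv(directory / "koos.csv")
    cohort = []
    for entry in manifest["subjects"]:
        sid = entry["subject_id"]
        trials = {}
        for p in PLACEMENTS:
            for tt in ("static", "walking"):
                key = f"{p}/{tt}"
                fn = entry["files"].get(key)
                path = directory / fn if fn else None
                if path is None or not path.exists():
                    raise FileNotFoundError(f"subject {sid}: missing {p} {tt} trial")
                df = pd.read_csv(path, float_precision="round_trip")
                trials[(p, tt)] = SensorTrial(
                    p,
                    tt,
                    entry["sample_rate_hz"],
                    df[["ax_g", "ay_g", "az_g"]].to_numpy(),
                    df[["gx_dps", "gy_dps", "gz_dps"]].to_numpy(),
                )
        sub = koos[koos.subject_id == sid]
        pre = sub[sub.phase == "pre"].iloc[0]
        post = sub[sub.phase == "post"].iloc[0]
        cohort.append(
            SubjectRecord(
                subject_id=sid,
                group=entry["group"],
                trials=trials,
                koos_pre={s: float(pre[s]) for s in KOOS_SUBSCALES},
                koos_post={s: float(post[s]) for s in KOOS_SUBSCALES},
            )
        )
    return cohort


def koos_frames(cohort):
    """Pre/post KOOS DataFrames (index subject_id, columns subscales)."""
    idx = [r.subject_id for r in cohort]
    pre = pd.DataFrame([r.koos_pre for r in cohort], index=idx)[list(KOOS_SUBSCALES)]
    post = pd.DataFrame([r.koos_post for r in cohort], index=idx)[list(KOOS_SUBSCALES)]
    return pre, post
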