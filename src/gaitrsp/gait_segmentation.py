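"""Gait-event detection, cycle segmentation, and time-normalization.

Initial contact (IC) and toe-off (TO) are detected from the foot sensor's
mediolateral angular velocity, which shows one dominant positive peak per
stride at mid-swing flanked by negative troughs: the trough preceding the
peak is toe-off, the trough following it is initial contact.  Each IC→IC
cycle of the attitude-corrected accelerations is then linearly interpolated
onto a fixed grid — 60 points for stance (IC to TO) and 40 for swing (TO to
the next IC) — and the per-axis cycles are ensemble-averaged and
concatenated (vertical, anteroposterior, mediolateral) into one 300-point
waveform per sensor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .preprocessing import SensorTrial, GLOBAL_AXES

#: index of the mediolateral axis in the sensor-frame gyroscope
ML_GYRO_AXIS = 1

STANCE_FRACTION_BOUNDS = (0.4, 0.8)
MIN_CYCLES = 5


@dataclass
class GaitEvents:
    """Alternating gait events: IC, TO, IC, ... as sample indices.

    ``initial_contacts`` has one more use than ``toe_offs`` conceptually:
    cycle i runs from initial_contacts[i] to initial_contacts[i+1] with
    toe_offs[i] strictly inside it.
    """

    initial_contacts: np.ndarray
    toe_offs: np.ndarray

    def __post_init__(self):
        ic = np.asarray(self.initial_contacts, dtype=int)
        to = np.asarray(self.toe_offs, dtype=int)
        if len(ic) < 2 or len(to) != len(ic) - 1:
            raise ValueError("need ICs and one TO between each consecutive IC pair")
        if not (np.all(np.diff(ic) > 0) and np.all(np.diff(to) > 0)):
            raise ValueError("event indices must be strictly increasing")
        if not np.all((to > ic[:-1]) & (to < ic[1:])):
            raise ValueError("every toe-off must lie strictly between consecutive ICs")
        self.initial_contacts = ic
        self.toe_offs = to

    @property
    def n_cycles(self) -> int:
        return len(self.initial_contacts) - 1

    def cycles(self):
        """Iterate (ic, to, next_ic) triples."""
        for i in range(self.n_cycles):
            yield (
                int(self.initial_contacts[i]),
                int(self.toe_offs[i]),
                int(self.initial_contacts[i + 1]),
            )


@dataclass
class GaitWaveform:
    """300-point average gait waveform for one sensor.

    Concatenation order: vertical[0:100], anteroposterior[100:200],
    mediolateral[200:300]; each axis block is 60 stance + 40 swing points.
    """

    placement: str
    vector: np.ndarray
    n_cycles_averaged: int

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=float)
        if v.shape != (300,):
            raise ValueError("waveform vector must have exactly 300 points")
        if not np.all(np.isfinite(v)):
            raise ValueError("waveform contains non-finite values")
        if self.n_cycles_averaged < MIN_CYCLES:
            raise ValueError(f"waveform averaged from fewer than {MIN_CYCLES} cycles")
        self.vector = v


def detect_events(
    foot_trial: SensorTrial,
    prominence_dps: float = 50.0,
    window_frac: float = 0.4,
) -> GaitEvents:
    """Detect IC/TO events from the foot's mediolateral angular velocity.

    Mid-swing peaks are located first (prominence ≥ ``prominence_dps``,
    minimum separation half the median stride estimate); toe-off is the
    most negative sample in a window of ``window_frac`` × the inter-peak
    interval before each peak, initial contact the most negative sample in
    the matching window after it.  Incomplete first/last strides (windows
    extending past the trial) are discarded.
    """
    if foot_trial.trial_type != "walking":
        raise ValueError("event detection needs a walking trial")
    w = foot_trial.gyro[:, ML_GYRO_AXIS]

    def _dominant_peaks(distance=None):
        # the flat mid-stance region between the IC and TO troughs is also a
        # local maximum with substantial prominence; keep only peaks whose
        # prominence is at least half the largest (shift-invariant), which
        # isolates the dominant mid-swing peak of each stride
        kwargs = {"prominence": prominence_dps}
        if distance is not None:
            kwargs["distance"] = distance
        peaks, props = find_peaks(w, **kwargs)
        if len(peaks) == 0:
            return peaks
        prom = props["prominences"]
        return peaks[prom >= 0.5 * prom.max()]

    peaks = _dominant_peaks()
    if len(peaks) < 2:
        raise ValueError("insufficient gait cycles")
    stride = np.median(np.diff(peaks))
    peaks = _dominant_peaks(distance=max(int(0.5 * stride), 1))
    if len(peaks) < 2:
        raise ValueError("insufficient gait cycles")
    stride = np.median(np.diff(peaks))
    win = max(int(round(window_frac * stride)), 1)

    tos, ics = [], []
    for p in peaks:
        if p - win < 0 or p + win >= len(w):
            continue
        tos.append(p - win + int(np.argmin(w[p - win : p])))
        ics.append(p + 1 + int(np.argmin(w[p + 1 : p + win + 1])))
    # cycle i: ics[i] .. ics[i+1] with tos[i+1] inside it
    ic_arr = np.asarray(ics, dtype=int)
    to_arr = np.asarray(tos[1:], dtype=int)
    if len(ic_arr) - 1 < 6:
        raise ValueError("insufficient gait cycles")
    return GaitEvents(initial_contacts=ic_arr, toe_offs=to_arr)


def segment_and_normalize(
    trial: SensorTrial,
    events: GaitEvents,
    n_stance: int = 60,
    n_swing: int = 40,
):
    """Time-normalize each gait cycle onto a fixed stance/swing grid.

    Stance (IC..TO inclusive) is linearly interpolated onto ``n_stance``
    equally spaced points and swing (the samples after TO up to and
    including the next IC) onto ``n_swing`` points, so a cycle whose stance
    spans exactly ``n_stance`` samples and swing exactly ``n_swing`` samples
    is returned unchanged.  Cycles whose stance fraction falls outside
    (0.4, 0.8) are dropped as event mis-detections.

    Returns ``(cycles, n_dropped)`` where each cycle is a 100×3 array with
    axis columns ordered (vertical, anteroposterior, mediolateral).
    """
    if "vertical" not in trial.axes:
        raise ValueError("trial must be attitude-corrected before segmentation")
    T = trial.n_samples
    if events.initial_contacts[0] < 0 or events.initial_contacts[-1] >= T:
        raise ValueError("gait events out of trial range")
    # reorder columns (ap, ml, vertical) -> (vertical, ap, ml)
    order = [trial.axes.index("vertical"), trial.axes.index("ap"), trial.axes.index("ml")]
    acc = trial.accel[:, order]
    sample_idx = np.arange(T, dtype=float)

    cycles, n_dropped = [], 0
    lo, hi = STANCE_FRACTION_BOUNDS
    for ic, to, ic2 in events.cycles():
        frac = (to - ic) / (ic2 - ic)
        if not lo < frac < hi:
            n_dropped += 1
            continue
        pos_st = np.linspace(ic, to, n_stance)
        pos_sw = to + (ic2 - to) * np.arange(1, n_swing + 1) / n_swing
        pos = np.concatenate([pos_st, pos_sw])
        cyc = np.column_stack([np.interp(pos, sample_idx, acc[:, j]) for j in range(3)])
        cycles.append(cyc)
    return cycles, n_dropped


def average_waveform(cycles, placement: str) -> GaitWaveform:
    """Ensemble-average normalized cycles into one 300-point waveform."""
    if len(cycles) < MIN_CYCLES:
        raise ValueError(
            f"need at least {MIN_CYCLES} gait cycles to average, got {len(cycles)}"
        )
    mean = np.mean(np.stack(cycles), axis=0)  # 100 x 3, (vertical, ap, ml)
    vector = np.concatenate([mean[:, 0], mean[:, 1], mean[:, 2]])
    return GaitWaveform(placement=placement, vector=vector, n_cycles_averaged=len(cycles))


# ---------------------------------------------------------------------------
# cohort-level waveform table I/O
# ---------------------------------------------------------------------------

WAVEFORM_COLUMNS = [f"p{i + 1:03d}" for i in range(300)]


def waveforms_to_frame(per_subject: dict) -> pd.DataFrame:
    """Rows (subject_id, placement, p001..p300, n_cycles) from a nested dict
    ``{subject_id: {placement: GaitWaveform}}``."""
    rows = []
    for sid, by_placement in per_subject.items():
        for placement, wf in by_placement.items():
            rows.append(
                {
                    "subject_id": sid,
                    "placement": placement,
                    **dict(zip(WAVEFORM_COLUMNS, wf.vector)),
                    "n_cycles": wf.n_cycles_averaged,
                }
            )
    return pd.DataFrame(rows)


def frame_to_matrices(frame: pd.DataFrame) -> dict:
    """Per-placement n×300 waveform matrices (DataFrame indexed by subject)."""
    out = {}
    for placement, grp in frame.groupby("placement", sort=False):
        out[placement] = grp.set_index("subject_id")[WAVEFORM_COLUMNS].astype(float)
    return out
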