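import numpy as np
import pytest

from gaitrsp import preprocessing as prep
from gaitrsp.gait_segmentation import (
    GaitEvents,
    GaitWaveform,
    average_waveform,
    detect_events,
    segment_and_normalize,
)
from gaitrsp.preprocessing import GLOBAL_AXES, SensorTrial
from gaitrsp.synthetic_data import CohortSpec, generate_cohort


def corrected_trial(accel, fs=100.0):
    accel = np.asarray(accel, dtype=float)
    return SensorTrial("thigh", "walking", fs, accel, np.zeros_like(accel), axes=GLOBAL_AXES)


def filtered_foot(record):
    return prep.lowpass_filter(record.trial("foot", "walking"))


class TestGaitEvents:
    def test_alternation_invariant_enforced(self):
        GaitEvents(initial_contacts=[0, 100, 200], toe_offs=[60, 160])
        with pytest.raises(ValueError, match="between consecutive"):
            GaitEvents(initial_contacts=[0, 100, 200], toe_offs=[60, 90])
        with pytest.raises(ValueError, match="increasing"):
            GaitEvents(initial_contacts=[100, 100], toe_offs=[50])


class TestDetectEvents:
    def test_noiseless_events_recovered_exactly(self, noiseless_cohort):
        cohort, truth = noiseless_cohort
        for rec in cohort[:3]:
            ev = detect_events(filtered_foot(rec))
            true_ic, true_to = truth.event_indices[rec.subject_id]
            assert np.all(np.isin(ev.initial_contacts, true_ic))
            assert np.all(np.isin(ev.toe_offs, true_to))
            assert ev.n_cycles >= 25  # 30 s trial at 1 Hz, ends trimmed

    def test_noisy_events_within_two_samples_of_truth(self):
        """100 walking trials at 10 deg/s gyro noise: every detected event
        within +-2 samples (20 ms) of the generator's ground truth."""
        worst = 0
        for seed in range(5):
            spec = CohortSpec(n_subjects=20, gyro_noise_dps_sd=10.0, seed=100 + seed)
            cohort, truth = generate_cohort(spec)
            for rec in cohort:
                ev = detect_events(filtered_foot(rec))
                true_ic, true_to = truth.event_indices[rec.subject_id]
                for det, tru in ((ev.initial_contacts, true_ic), (ev.toe_offs, true_to)):
                    worst = max(worst, int(np.abs(tru[None, :] - det[:, None]).min(axis=1).max()))
        assert worst <= 2

    def test_constant_gyro_raises_insufficient_cycles(self):
        trial = SensorTrial("foot", "walking", 100.0, np.zeros((1000, 3)), np.zeros((1000, 3)))
        with pytest.raises(ValueError, match="insufficient gait cycles"):
            detect_events(trial)

    def test_offset_below_prominence_threshold_is_ignored(self, noiseless_cohort):
        cohort, _ = noiseless_cohort
        foot = filtered_foot(cohort[0])
        ev_a = detect_events(foot)
        shifted = SensorTrial(
            "foot", "walking", foot.sample_rate, foot.accel, foot.gyro + 30.0
        )
        ev_b = detect_events(shifted)
        assert np.array_equal(ev_a.initial_contacts, ev_b.initial_contacts)
        assert np.array_equal(ev_a.toe_offs, ev_b.toe_offs)


class TestSegmentAndNormalize:
    def test_coincident_grid_is_identity(self, rng):
        acc = rng.normal(0, 1, (100, 3))
        events = GaitEvents(initial_contacts=[0, 99], toe_offs=[59])
        cycles, dropped = segment_and_normalize(corrected_trial(acc), events)
        assert dropped == 0 and len(cycles) == 1
        # vertical is column 2 in the corrected frame, column 0 in cycles
        expected = acc[:, [2, 0, 1]]
        assert np.allclose(cycles[0], expected, atol=1e-12)

    def test_normalization_is_idempotent(self, rng):
        acc = rng.normal(0, 1, (100, 3))
        events = GaitEvents(initial_contacts=[0, 99], toe_offs=[59])
        once, _ = segment_and_normalize(corrected_trial(acc), events)
        again, _ = segment_and_normalize(
            corrected_trial(once[0][:, [1, 2, 0]]), events
        )
        assert np.allclose(once[0], again[0], atol=1e-12)

    def test_linear_ramp_normalizes_to_piecewise_linear_grid(self):
        t = np.arange(200, dtype=float) / 20.0  # keep within sensor range
        acc = np.column_stack([t, t, t])
        ic, to, ic2 = 10, 65, 107
        events = GaitEvents(initial_contacts=[ic, ic2], toe_offs=[to])
        cycles, _ = segment_and_normalize(corrected_trial(acc), events)
        expected = (
            np.concatenate([np.linspace(ic, to, 60), to + (ic2 - to) * np.arange(1, 41) / 40])
            / 20.0
        )
        assert np.allclose(cycles[0][:, 0], expected, atol=1e-10)

    def test_bad_stance_fraction_cycles_dropped(self, rng):
        acc = rng.normal(0, 1, (400, 3))
        events = GaitEvents(initial_contacts=[0, 99, 198], toe_offs=[59, 129])
        # second cycle stance fraction (129-99)/99 = 0.30 < 0.4 -> dropped
        cycles, dropped = segment_and_normalize(corrected_trial(acc), events)
        assert len(cycles) == 1 and dropped == 1

    def test_events_out_of_range_rejected(self, rng):
        acc = rng.normal(0, 1, (90, 3))
        events = GaitEvents(initial_contacts=[0, 99], toe_offs=[59])
        with pytest.raises(ValueError, match="out of trial range"):
            segment_and_normalize(corrected_trial(acc), events)

    def test_uncorrected_trial_rejected(self, rng):
        trial = SensorTrial("thigh", "walking", 100.0, rng.normal(0, 1, (100, 3)),
                            np.zeros((100, 3)))
        with pytest.raises(ValueError, match="attitude-corrected"):
            segment_and_normalize(trial, GaitEvents([0, 99], [59]))

    def test_sixty_second_walk_retains_58_or_59_cycles(self):
        spec = CohortSpec(
            n_subjects=3,
            group_fractions=(1 / 3, 1 / 3, 1 / 3),
            cadence_hz=(1.0, 0.0),
            stride_jitter_sd=0.0,
            noise_g_sd=0.0,
            gyro_noise_dps_sd=0.0,
            tilt_deg_sd=0.0,
            seed=11,
        )
        cohort, _ = generate_cohort(spec)
        rec = cohort[0]
        ev = detect_events(filtered_foot(rec))
        walking = prep.lowpass_filter(rec.trial("thigh", "walking"))
        att = prep.estimate_attitude(prep.lowpass_filter(rec.trial("thigh", "static")))
        cycles, _ = segment_and_normalize(prep.apply_attitude(walking, att), ev)
        assert 58 <= len(cycles) <= 59


class TestAverageWaveform:
    def test_identical_cycles_average_to_one_cycle(self, rng):
        cyc = rng.normal(0, 1, (100, 3))
        wf = average_waveform([cyc] * 6, "thigh")
        assert wf.vector == pytest.approx(
            np.concatenate([cyc[:, 0], cyc[:, 1], cyc[:, 2]])
        )
        assert wf.n_cycles_averaged == 6

    def test_opposite_cycles_cancel(self, rng):
        cyc = rng.normal(0, 1, (100, 3))
        wf = average_waveform([cyc, -cyc, cyc, -cyc, cyc, -cyc], "back")
        assert np.allclose(wf.vector, 0.0, atol=1e-12)

    def test_fewer_than_five_cycles_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 5"):
            average_waveform([rng.normal(0, 1, (100, 3))] * 4, "foot")

    def test_waveform_vector_has_300_points_per_placement(self, default_waveforms):
        for placement, frame in default_waveforms.items():
            assert frame.shape == (39, 300)

    def test_waveform_invariants(self):
        with pytest.raises(ValueError, match="300"):
            GaitWaveform("back", np.zeros(299), 10)
        with pytest.raises(ValueError, match="fewer than"):
            GaitWaveform("back", np.zeros(300), 3)
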