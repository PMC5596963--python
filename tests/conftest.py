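import numpy as np
import pytest
from hypothesis import settings

from gaitrsp import outcomes, pipeline
from gaitrsp.synthetic_data import CohortSpec, generate_cohort, koos_frames

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Small cohort with no noise, tilt, cadence variation or stride jitter:
    signals are exactly periodic and events land exactly on samples."""
    spec = CohortSpec(
        n_subjects=6,
        group_fractions=(1 / 3, 1 / 3, 1 / 3),
        cadence_hz=(1.0, 0.0),
        trial_duration_s=30.0,
        noise_g_sd=0.0,
        gyro_noise_dps_sd=0.0,
        tilt_deg_sd=0.0,
        stride_jitter_sd=0.0,
        seed=5,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def small_cohort():
    """12-subject cohort at default noise with shortened trials."""
    spec = CohortSpec(n_subjects=12, trial_duration_s=30.0, seed=2)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size cohort (n=39, groups 10/20/9) at default noise."""
    return generate_cohort(CohortSpec(seed=1))


@pytest.fixture(scope="session")
def default_waveforms(default_cohort):
    cohort, _ = default_cohort
    return pipeline.cohort_waveforms(cohort)


@pytest.fixture(scope="session")
def default_labels(default_cohort):
    cohort, _ = default_cohort
    pre, post = koos_frames(cohort)
    return outcomes.label_responders(outcomes.effect_sizes(pre, post))["label"]


@pytest.fixture(scope="session")
def recovery_cohorts():
    """Five seeded full-size cohorts with processed waveforms and labels,
    shared by the parameter-recovery acceptance checks."""
    out = []
    for seed in range(1, 6):
        cohort, truth = generate_cohort(CohortSpec(seed=seed))
        waveforms = pipeline.cohort_waveforms(cohort)
        pre, post = koos_frames(cohort)
        labels = outcomes.label_responders(outcomes.effect_sizes(pre, post))["label"]
        out.append({"cohort": cohort, "truth": truth, "waveforms": waveforms,
                    "pre": pre, "labels": labels, "seed": seed})
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
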