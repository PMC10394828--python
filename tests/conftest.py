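"""Shared fixtures: small seeded synthetic cohorts generated at test time."""

import dataclasses

import numpy as np
import pytest

from tiltpress import synthetic_data as sd


@pytest.fixture(scope="session")
def tf_cohort():
    """Six-subject cohort with known resonances for TF-recovery checks."""
    cfg = sd.tf_validation_config(seed=11)
    recordings, truth = sd.generate_cohort(cfg)
    return cfg, recordings, truth


@pytest.fixture(scope="session")
def stats_cohort():
    """Six-subject cohort with 1 mmHg sensor noise for statistics checks."""
    cfg = sd.stats_validation_config(seed=7)
    recordings, truth = sd.generate_cohort(cfg)
    return cfg, recordings, truth


@pytest.fixture(scope="session")
def quiet_cohort():
    """One noise-free subject (pulse and respiration on, noise/artifacts off)."""
    base = sd.default_cohort_config(seed=3, n_subjects=1)
    specs = tuple(
        dataclasses.replace(s, noise_sd=0.0, artifact_rate=0.0)
        for s in base.channel_specs
    )
    cfg = dataclasses.replace(base, channel_specs=specs, broadband_frac=0.0,
                              between_subject_sd=0.0)
    recordings, truth = sd.generate_cohort(cfg)
    return cfg, recordings, truth


def truth_peak_frequencies(truth, channel="ICP", band=(0.5, 30.0)):
    """Resonance locations of the generator's analytic response (dense grid)."""
    from scipy.signal import find_peaks

    f = np.linspace(band[0], band[1], 20000)
    mag = truth.tf_magnitude_db(0, channel, f)
    idx, _ = find_peaks(mag, prominence=3.0)
    return f[idx]
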