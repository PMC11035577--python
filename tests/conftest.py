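"""Shared fixtures: small synthetic participants generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from errpfusion import cardiac, eeg, pupil, synth


def clean_config(**overrides) -> synth.GeneratorConfig:
    """Noise-free, artifact-free generator configuration."""
    base = dict(seed=5, n_runs=1, eeg_noise_sd_uV=0.0,
                pupil_noise_sd_mm=0.0, pupil_drift_sd_mm=0.0,
                pupil_hippus_sd_mm=0.0, pupil_amp_jitter=0.0,
                blink_rate_hz=0.0, rsa_amp_s=0.0, rr_jitter_s=0.0,
                ocular_gain_h_uV_per_deg=0.0, ocular_gain_v_uV_per_deg=0.0,
                ocular_gain_blink_uV=0.0)
    base.update(overrides)
    return synth.GeneratorConfig(**base)


@pytest.fixture(scope="session")
def clean_participant() -> synth.Participant:
    """One noise-free participant (single run): exact-recovery oracle data."""
    return synth.simulate_participant(clean_config(), calibration_duration_s=42.0)


@pytest.fixture(scope="session")
def noisy_participant() -> synth.Participant:
    """One participant at generator defaults (two runs)."""
    cfg = synth.GeneratorConfig(seed=42, n_runs=2)
    return synth.simulate_participant(cfg, calibration_duration_s=60.0)


@pytest.fixture(scope="session")
def noisy_epochs(noisy_participant):
    """Preprocessed EEG + pupil epochs of the default participant."""
    es = eeg.preprocess_eeg(noisy_participant)
    ps = pupil.preprocess_pupil(noisy_participant)
    return es, ps


@pytest.fixture(scope="session")
def small_cohort():
    """Six default participants (two runs each) through both pipelines."""
    cfgs = synth.cohort_configs(6, base_seed=11, n_runs=2)
    eeg_sets, pupil_sets, hr_sets = [], [], []
    for cfg in cfgs:
        part = synth.simulate_participant(cfg, calibration_duration_s=60.0)
        eeg_sets.append(eeg.preprocess_eeg(part))
        pupil_sets.append(pupil.preprocess_pupil(part))
        t, hr = cardiac.rr_to_hr(part.flight.rr)
        hr_sets.append(cardiac.epoch_hr(t, hr, part.flight.events))
    return eeg_sets, pupil_sets, hr_sets
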