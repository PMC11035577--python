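"""EEG chain: filter responses, ocular subtraction, epoching, cleaning."""

import numpy as np
import pytest

from errpfusion import eeg as eegmod
from errpfusion import synth
from errpfusion.containers import ContinuousEEG
from errpfusion.montage import CHANNELS_58, CHANNELS_63
from errpfusion.synth import simulate_paradigm, synth_eye_calibration

from conftest import clean_config


def _sine_eeg(freq_hz, fs=512.0, dur_s=20.0, n_ch=2):
    t = np.arange(int(dur_s * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq_hz * t), (n_ch, 1))
    return ContinuousEEG([f"C{i}" for i in range(n_ch)], fs, data), t


def _gain(filtered, t, fs):
    """Steady-state amplitude in the middle half of the record."""
    mid = slice(len(t) // 4, 3 * len(t) // 4)
    return np.sqrt(2.0) * filtered[0, mid].std()


class TestFilterRaw:
    def test_dc_removed(self):
        raw = ContinuousEEG(["a"], 512.0, np.full((1, 10240), 7.0))
        out = eegmod.filter_raw(raw)
        assert np.abs(out.data).max() < 1e-6

    def test_line_noise_attenuated_40db(self):
        raw, t = _sine_eeg(50.0)
        out = eegmod.filter_raw(raw)
        assert _gain(out.data, t, raw.fs_hz) < 10 ** (-40 / 20)

    def test_passband_gain_near_unity(self):
        raw, t = _sine_eeg(10.0)
        out = eegmod.filter_raw(raw)
        assert abs(_gain(out.data, t, raw.fs_hz) - 1.0) < 0.01

    def test_low_rate_rejected(self):
        raw = ContinuousEEG(["a"], 128.0, np.zeros((1, 1000)))
        with pytest.raises(ValueError):
            eegmod.filter_raw(raw)

    def test_zero_phase_preserves_pulse_symmetry(self):
        fs = 512.0
        n = 8193  # odd length: the pulse center sits exactly on a sample
        t = (np.arange(n) - n // 2) / fs
        pulse = np.exp(-0.5 * (t / 0.05) ** 2)
        out = eegmod.filter_raw(ContinuousEEG(["a"], fs, pulse[None]))
        y = out.data[0]
        # forward-backward edge-state handling leaves ~1e-4 relative residue
        assert np.abs(y - y[::-1]).max() < 1e-3 * np.abs(y).max()


class TestOcularModel:
    def test_exact_weight_recovery_noise_free(self):
        cfg = clean_config(ocular_gain_h_uV_per_deg=0.6,
                           ocular_gain_v_uV_per_deg=1.0,
                           ocular_gain_blink_uV=60.0, blink_rate_hz=0.12)
        calib = synth_eye_calibration(cfg, duration_s=42.0)
        model = eegmod.fit_ocular_model(calib)
        assert np.allclose(model.weights, synth.ocular_gain_matrix(cfg),
                           atol=1e-7)

    def test_orthogonal_channel_gets_zero_weights(self):
        cfg = clean_config(ocular_gain_h_uV_per_deg=0.6,
                           ocular_gain_v_uV_per_deg=1.0,
                           ocular_gain_blink_uV=60.0, blink_rate_hz=0.12)
        calib = synth_eye_calibration(cfg, duration_s=42.0)
        oz = calib.eeg.channel_names.index("Oz")
        calib.eeg.data[oz] = 0.0  # a channel carrying no ocular signal
        model = eegmod.fit_ocular_model(calib)
        assert np.allclose(model.weights[oz], 0.0, atol=1e-9)

    def test_missing_segments_rejected(self):
        cfg = clean_config()
        calib = synth_eye_calibration(cfg, duration_s=42.0)
        calib.segments = []
        with pytest.raises(ValueError):
            eegmod.fit_ocular_model(calib)

    def test_model_averaging(self):
        w1 = eegmod.OcularModel(np.ones((3, 3)), ["a", "b", "c"])
        w2 = eegmod.OcularModel(3 * np.ones((3, 3)), ["a", "b", "c"])
        avg = eegmod.average_models([w1, w2])
        assert np.allclose(avg.weights, 2.0)

    def test_removal_cancels_contamination(self):
        """Filtered contamination is removed to < 1% residual power."""
        cfg = clean_config(ocular_gain_h_uV_per_deg=0.6,
                           ocular_gain_v_uV_per_deg=1.0,
                           ocular_gain_blink_uV=60.0, blink_rate_hz=0.2)
        calib = synth_eye_calibration(cfg, duration_s=42.0)
        model = eegmod.fit_ocular_model(calib)
        contaminated = eegmod.filter_raw(calib.eeg)
        cleaned = eegmod.remove_ocular(contaminated, model, calib.gaze)
        frontal = [calib.eeg.channel_names.index(c) for c in ("Fp1", "Fp2")]
        before = np.sum(contaminated.data[frontal] ** 2)
        after = np.sum(cleaned.data[frontal] ** 2)
        assert after < 0.01 * before

    def test_zero_model_is_identity(self):
        cfg = clean_config(blink_rate_hz=0.1)
        calib = synth_eye_calibration(cfg, duration_s=42.0)
        model = eegmod.OcularModel.zero(calib.eeg.channel_names)
        out = eegmod.remove_ocular(calib.eeg, model, calib.gaze)
        assert np.array_equal(out.data, calib.eeg.data)

    def test_zero_references_leave_signal_untouched(self):
        from errpfusion.containers import GazePupilStream
        n = 1200
        t = np.arange(n) / 120.0
        gaze = GazePupilStream(t, np.zeros(n), np.zeros(n), np.ones(n),
                               np.ones(n), np.ones(n, bool), np.ones(n, bool))
        rng = np.random.default_rng(0)
        raw = ContinuousEEG(["a", "b"], 512.0,
                            rng.standard_normal((2, 5120)))
        model = eegmod.OcularModel(np.ones((2, 3)), ["a", "b"])
        out = eegmod.remove_ocular(raw, model, gaze, prefilter_refs=False)
        assert np.allclose(out.data, raw.data)


class TestNarrowbandResample:
    def test_channel_count_and_rate(self, clean_participant):
        filt = eegmod.filter_raw(clean_participant.flight.eeg)
        out = eegmod.narrowband_resample_select(filt)
        assert len(out.channel_names) == 58
        assert out.fs_hz == 64.0
        assert set(out.channel_names) == set(CHANNELS_58)

    def test_sub_band_frequencies_attenuated(self):
        raw, t = _sine_eeg(0.5, dur_s=60.0)
        import warnings as w
        with w.catch_warnings():
            w.simplefilter("ignore")
            out = eegmod.narrowband_resample_select(
                ContinuousEEG(["FCz", "Cz"], raw.fs_hz, raw.data))
        mid = slice(out.n_samples // 4, 3 * out.n_samples // 4)
        amp = np.sqrt(2.0) * out.data[0, mid].std()
        assert amp < 0.35  # 4th-order edge at 1 Hz, zero-phase (squared)


class TestEpoching:
    @pytest.fixture(scope="class")
    def events9(self):
        return simulate_paradigm(9, seed=4)

    def test_epoch_counts_and_length(self, events9):
        dur = max(e.onset_s for e in events9) + 5
        fs = 64.0
        eeg = ContinuousEEG(["FCz", "Cz"], fs,
                            np.zeros((2, int(dur * fs))))
        ep = eegmod.epoch_trials(eeg, events9)
        assert ep.data.shape[2] == 96          # 1.5 s at 64 Hz
        assert int(np.sum(ep.labels != "correct")) == 9 * 21

    def test_out_of_bounds_trials_skipped_and_logged(self, events9):
        fs = 64.0
        short = ContinuousEEG(["FCz"], fs, np.zeros((1, int(100 * fs))))
        ep = eegmod.epoch_trials(short, events9)
        assert len(ep.rejection_log) > 0
        assert all(r[2] == "out_of_bounds" for r in ep.rejection_log)
        assert len(ep.labels) + len(ep.rejection_log) == len(events9)


class TestRejection:
    @pytest.fixture(scope="class")
    def clean_epochs(self):
        rng = np.random.default_rng(1)
        from errpfusion.containers import EpochSet
        n, c, s = 120, 4, 96
        return EpochSet(rng.standard_normal((n, c, s)) * 5.0,
                        np.array(["correct"] * n),
                        -0.5 + np.arange(s) / 64.0, 64.0,
                        ["FCz", "Cz", "Pz", "Oz"], np.arange(n))

    def test_amplitude_spike_rejected_with_reason(self, clean_epochs):
        ep = clean_epochs.select_trials(np.arange(clean_epochs.n_trials))
        ep.data = ep.data.copy()
        ep.data[3, 1, 10] = 50.0
        out = eegmod.reject_artifacts(ep)
        assert not out.kept_mask[3]
        reasons = {entry[0]: entry[2] for entry in out.rejection_log}
        assert "amplitude" in reasons[3]

    def test_clean_gaussian_rejection_below_5_percent(self, clean_epochs):
        out = eegmod.reject_artifacts(clean_epochs)
        assert 1.0 - out.kept_mask.mean() < 0.05

    def test_kept_trials_unaltered(self, clean_epochs):
        out = eegmod.reject_artifacts(clean_epochs)
        assert np.array_equal(out.data, clean_epochs.data)

    def test_too_few_trials_refused(self, clean_epochs):
        with pytest.raises(ValueError):
            eegmod.reject_artifacts(clean_epochs.select_trials(np.arange(5)))


class TestChannelInterpolation:
    @pytest.fixture(scope="class")
    def spatial_epochs(self):
        """Spatially smooth epochs built from a few scalp sources."""
        from errpfusion.containers import EpochSet
        from errpfusion.montage import scalp_topography

        rng = np.random.default_rng(2)
        names = list(CHANNELS_58)
        topos = np.stack([scalp_topography(c, 0.08, names)
                          for c in ("FCz", "Pz", "C3", "C4")])
        n, s = 40, 96
        sources = rng.standard_normal((n, 4, s))
        data = np.einsum("nks,kc->ncs", sources, topos)
        return EpochSet(data, np.array(["correct"] * n),
                        -0.5 + np.arange(s) / 64.0, 64.0, names,
                        np.arange(n))

    def test_noisy_channel_flagged_and_improved(self, spatial_epochs):
        rng = np.random.default_rng(3)
        ep = spatial_epochs.select_trials(np.arange(spatial_epochs.n_trials))
        ep.data = ep.data.copy()
        ch = ep.channel_names.index("Cz")
        truth = ep.data[:, ch, :].copy()
        noise = rng.standard_normal(truth.shape) * 3 * truth.std()
        ep.data[:, ch, :] = truth + noise
        out, bad = eegmod.interpolate_bad_channels(ep)
        assert "Cz" in bad
        corr_bad = np.corrcoef(ep.data[:, ch, :].ravel(), truth.ravel())[0, 1]
        corr_fix = np.corrcoef(out.data[:, ch, :].ravel(), truth.ravel())[0, 1]
        assert corr_fix > corr_bad
        # untouched channels are bit-identical
        other = [i for i in range(len(ep.channel_names)) if i != ch]
        assert np.array_equal(out.data[:, other, :], ep.data[:, other, :])

    def test_flagging_invariant_to_channel_order(self, spatial_epochs):
        flags = set(eegmod.flag_high_variance_channels(spatial_epochs))
        perm = np.random.default_rng(4).permutation(len(spatial_epochs.channel_names))
        from errpfusion.containers import EpochSet
        shuffled = EpochSet(spatial_epochs.data[:, perm, :],
                            spatial_epochs.labels, spatial_epochs.t_axis,
                            spatial_epochs.fs_hz,
                            [spatial_epochs.channel_names[i] for i in perm],
                            spatial_epochs.event_ids)
        assert set(eegmod.flag_high_variance_channels(shuffled)) == flags

    def test_constant_equal_variance_epochs_unflagged(self):
        from errpfusion.containers import EpochSet
        rng = np.random.default_rng(5)
        base = rng.standard_normal((20, 1, 96))
        data = np.repeat(base, 6, axis=1)  # identical variance everywhere
        ep = EpochSet(data, np.array(["correct"] * 20),
                      -0.5 + np.arange(96) / 64.0, 64.0,
                      ["FCz", "Cz", "Pz", "C3", "C4", "Oz"], np.arange(20))
        assert eegmod.flag_high_variance_channels(ep) == []


class TestGrandAverage:
    def test_single_trial_equals_rereferenced_trial(self):
        from errpfusion.containers import EpochSet
        rng = np.random.default_rng(6)
        data = rng.standard_normal((1, 3, 96))
        ep = EpochSet(data, np.array(["target"]),
                      -0.5 + np.arange(96) / 64.0, 64.0,
                      ["FCz", "Cz", "Pz"], np.array([0]))
        ga = eegmod.grand_average_erp([ep])
        car = data[0] - data[0].mean(axis=0, keepdims=True)
        assert np.allclose(ga.mean["target"], car)
        assert np.allclose(ga.sem["target"], 0.0)

    def test_sem_zero_for_identical_participants(self):
        from errpfusion.containers import EpochSet
        rng = np.random.default_rng(7)
        data = rng.standard_normal((4, 3, 96))
        mk = lambda: EpochSet(data.copy(), np.array(["target"] * 4),
                              -0.5 + np.arange(96) / 64.0, 64.0,
                              ["FCz", "Cz", "Pz"], np.arange(4))
        ga = eegmod.grand_average_erp([mk(), mk(), mk()])
        assert np.allclose(ga.sem["target"], 0.0)

    def test_mismatched_axes_rejected(self):
        from errpfusion.containers import EpochSet
        mk = lambda s: EpochSet(np.zeros((2, 2, s)), np.array(["target"] * 2),
                                np.arange(s) / 64.0, 64.0, ["FCz", "Cz"],
                                np.arange(2))
        with pytest.raises(ValueError):
            eegmod.grand_average_erp([mk(96), mk(48)])


def test_full_chain_preserves_injected_latencies(clean_participant):
    """Noise-free end-to-end: component latencies survive to ±1 sample at 64 Hz."""
    ep = eegmod.preprocess_eeg(clean_participant, reject=False,
                               interpolate=False)
    ga = eegmod.grand_average_erp([ep])
    sample = 1.0 / 64.0
    assert abs(eegmod.negative_peak_latency(ga, "FCz", "target") - 0.234) <= sample
    assert abs(eegmod.negative_peak_latency(ga, "FCz", "passive") - 0.250) <= sample
    assert abs(eegmod.negative_peak_latency(ga, "FCz", "active") - 0.266) <= sample
    assert abs(eegmod.positive_peak_latency(ga, "FCz", "target", (0.25, 0.45))
               - 0.313) <= sample
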