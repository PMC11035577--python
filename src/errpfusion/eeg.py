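"""EEG preprocessing: filtering, ocular-artifact removal, epoching, cleaning.

The chain follows a fixed order: broadband 0.4-30 Hz band-pass with 50/100 Hz
notches -> calibration-based ocular subtraction -> 1-10 Hz analysis band ->
resampling to 64 Hz -> frontal-channel drop -> epoching -> trial rejection
(amplitude / kurtosis / joint probability) -> bad-channel interpolation.
All filters are non-causal (zero-phase, forward-backward Butterworth).

Ocular correction is a multi-reference least-squares subtraction: channel
weights onto horizontal/vertical gaze and a smoothed blink waveform, fitted
on the labeled artifact segments of the eye-calibration runs and applied
block-wise (the first calibration's model to runs 1-4, the second's to the
remaining runs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import butter, iirnotch, filtfilt, resample_poly, sosfiltfilt
from scipy.stats import kurtosis as _kurtosis

from .containers import (ContinuousEEG, EpochSet, GazePupilStream,
                         MultimodalRecording, ParadigmEvent)
from .montage import CHANNELS_63, FRONTAL_DROP, position_array
from .synth import ocular_reference_signals

__all__ = [
    "OcularModel", "filter_raw", "fit_ocular_model", "remove_ocular",
    "apply_ocular_blockwise", "narrowband_resample_select", "epoch_trials",
    "reject_artifacts", "interpolate_bad_channels", "grand_average_erp",
    "GrandAverage", "negative_peak_latency", "preprocess_eeg",
]

BROADBAND_HZ = (0.4, 30.0)
NOTCH_HZ = (50.0, 100.0)
ANALYSIS_BAND_HZ = (1.0, 10.0)
TARGET_FS_HZ = 64.0
EPOCH_WINDOW_S = (-0.5, 1.0)
CORRECT_WINDOW_START_S = 1.5   # after passing the previous target
AMPLITUDE_LIMIT_UV = 35.0
STAT_REJECT_SD = 5.0
VARIANCE_IQR_FACTOR = 1.5


def _bandpass(data: np.ndarray, fs: float, lo: float, hi: float,
              order: int = 4) -> np.ndarray:
    sos = butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    return sosfiltfilt(sos, data, axis=-1)


def filter_raw(eeg: ContinuousEEG) -> ContinuousEEG:
    """Zero-phase 0.4-30 Hz band-pass (Butterworth order 4) + 50/100 Hz notches."""
    if eeg.fs_hz <= 200:
        raise ValueError("sampling rate must exceed 200 Hz for the 100 Hz notch")
    data = _bandpass(eeg.data, eeg.fs_hz, *BROADBAND_HZ)
    for f0 in NOTCH_HZ:
        b, a = iirnotch(f0, Q=30.0, fs=eeg.fs_hz)
        data = filtfilt(b, a, data, axis=-1)
    return ContinuousEEG(list(eeg.channel_names), eeg.fs_hz, data)


def _filter_references(refs: np.ndarray, fs: float) -> np.ndarray:
    """Pass the ocular references through the same broadband filter chain."""
    out = _bandpass(refs, fs, *BROADBAND_HZ)
    for f0 in NOTCH_HZ:
        b, a = iirnotch(f0, Q=30.0, fs=fs)
        out = filtfilt(b, a, out, axis=-1)
    return out


@dataclass
class OcularModel:
    """Per-channel least-squares weights onto K=3 ocular reference signals.

    References: horizontal gaze angle, vertical gaze angle, and the blink
    indicator convolved with a smooth pulse kernel (see
    :func:`errpfusion.synth.blink_waveform`), resampled to the EEG rate.
    """

    weights: np.ndarray            # (n_channels, 3)
    channel_names: list[str]
    intercept: np.ndarray = None   # (n_channels,)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.intercept is None:
            self.intercept = np.zeros(self.weights.shape[0])

    @classmethod
    def zero(cls, channel_names) -> "OcularModel":
        return cls(np.zeros((len(channel_names), 3)), list(channel_names))


def fit_ocular_model(calib: MultimodalRecording,
                     prefilter: bool = False) -> OcularModel:
    """Fit ocular-subtraction weights on a calibration recording.

    Least squares of each EEG channel on the three references, restricted to
    the labeled artifact segments (saccades and blinks).  With ``prefilter``
    the calibration EEG and references are passed through the broadband
    filter first, matching how the model is later applied.
    """
    if not calib.segments:
        raise ValueError("calibration recording has no labeled segments")
    eeg = filter_raw(calib.eeg) if prefilter else calib.eeg
    refs = ocular_reference_signals(calib.gaze, eeg.fs_hz, eeg.n_samples)
    if prefilter:
        refs = _filter_references(refs, eeg.fs_hz)

    mask = np.zeros(eeg.n_samples, dtype=bool)
    for seg in calib.segments:
        if seg.kind in ("horizontal", "vertical", "blink"):
            i0 = max(0, int(seg.start_s * eeg.fs_hz))
            i1 = min(eeg.n_samples, int(seg.end_s * eeg.fs_hz))
            mask[i0:i1] = True
    if not mask.any():
        raise ValueError("no artifact segments labeled in calibration")

    X = np.column_stack([refs[:, mask].T, np.ones(int(mask.sum()))])
    Y = eeg.data[:, mask].T
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    return OcularModel(coef[:3].T, list(eeg.channel_names), coef[3])


def average_models(models) -> OcularModel:
    """Average the weights of several fitted models (same channel order)."""
    w = np.mean([m.weights for m in models], axis=0)
    b = np.mean([m.intercept for m in models], axis=0)
    return OcularModel(w, list(models[0].channel_names), b)


def remove_ocular(eeg: ContinuousEEG, model: OcularModel,
                  gaze: GazePupilStream, prefilter_refs: bool = True) -> ContinuousEEG:
    """Subtract the modeled ocular contribution from continuous EEG.

    ``prefilter_refs`` passes the references through the same broadband
    filter applied to the EEG, so that subtraction cancels the (filtered)
    contamination exactly when the mixing is linear.
    """
    if model.weights.shape[0] != len(eeg.channel_names):
        raise ValueError("model/channel mismatch")
    refs = ocular_reference_signals(gaze, eeg.fs_hz, eeg.n_samples)
    if prefilter_refs:
        refs = _filter_references(refs, eeg.fs_hz)
    data = eeg.data - model.weights @ refs
    return ContinuousEEG(list(eeg.channel_names), eeg.fs_hz, data)


def apply_ocular_blockwise(eeg: ContinuousEEG, models,
                           gaze: GazePupilStream,
                           run_spans: dict[int, tuple[float, float]],
                           first_block_runs: int = 4,
                           prefilter_refs: bool = True) -> ContinuousEEG:
    """Apply per-block ocular models to one continuous session.

    The first calibration's model corrects runs 1..first_block_runs, the
    second corrects the remaining runs (mirroring the two recording blocks).
    With a single model, it is applied throughout.
    """
    if len(models) == 1 or not run_spans:
        return remove_ocular(eeg, models[0], gaze, prefilter_refs)
    runs = sorted(run_spans)
    block2 = [r for r in runs if r > first_block_runs]
    if not block2:
        return remove_ocular(eeg, models[0], gaze, prefilter_refs)
    boundary_s = run_spans[block2[0]][0]
    b = int(boundary_s * eeg.fs_hz)
    corrected1 = remove_ocular(eeg, models[0], gaze, prefilter_refs)
    corrected2 = remove_ocular(eeg, models[1], gaze, prefilter_refs)
    data = np.concatenate([corrected1.data[:, :b], corrected2.data[:, b:]],
                          axis=1)
    return ContinuousEEG(list(eeg.channel_names), eeg.fs_hz, data)


def narrowband_resample_select(eeg: ContinuousEEG) -> ContinuousEEG:
    """1-10 Hz band-pass, anti-aliased resampling to 64 Hz, frontal drop.

    Low frequencies carry the error-related information, hence the narrow
    analysis band; the frontopolar/anterior-frontal row is removed to limit
    residual ocular contamination, leaving 58 channels.
    """
    data = _bandpass(eeg.data, eeg.fs_hz, *ANALYSIS_BAND_HZ)
    ratio = TARGET_FS_HZ / eeg.fs_hz
    from fractions import Fraction
    frac = Fraction(ratio).limit_denominator(1000)
    data = resample_poly(data, frac.numerator, frac.denominator, axis=-1)
    names = list(eeg.channel_names)
    drop = [c for c in FRONTAL_DROP if c in names]
    if len(drop) < len(FRONTAL_DROP):
        import warnings
        warnings.warn("montage lacks some frontal labels; dropping those present")
    keep = [i for i, c in enumerate(names) if c not in FRONTAL_DROP]
    return ContinuousEEG([names[i] for i in keep], TARGET_FS_HZ, data[keep])


def epoch_trials(eeg: ContinuousEEG, events: list[ParadigmEvent],
                 window_s: tuple[float, float] = EPOCH_WINDOW_S) -> EpochSet:
    """Cut labeled trials out of the continuous signal.

    Error trials span [-0.5, 1] s around the error onset; correct trials are
    1.5-s windows starting 1.5 s after the previous target was passed.
    Trials exceeding the recording are skipped and logged.
    """
    fs = eeg.fs_hz
    n_samp = int(round((window_s[1] - window_s[0]) * fs))
    t_axis = window_s[0] + np.arange(n_samp) / fs
    data, labels, ids, log = [], [], [], []
    for i, ev in enumerate(events):
        if ev.is_error:
            start_t = ev.onset_s + window_s[0]
        else:
            start_t = ev.prev_target_pass_s + CORRECT_WINDOW_START_S
        i0 = int(round(start_t * fs))
        if i0 < 0 or i0 + n_samp > eeg.n_samples:
            log.append((i, ev.condition, "out_of_bounds"))
            continue
        data.append(eeg.data[:, i0:i0 + n_samp])
        labels.append(ev.condition)
        ids.append(i)
    if not data:
        raise ValueError("no trial fits inside the recording")
    return EpochSet(np.stack(data), np.array(labels), t_axis, fs,
                    list(eeg.channel_names), np.array(ids),
                    rejection_log=log)


def _joint_probability_stat(data: np.ndarray, n_grid: int = 512,
                            max_pool: int = 5000) -> np.ndarray:
    """Per-trial, per-channel mean negative log density of sample amplitudes.

    The per-channel amplitude density is a Gaussian kernel estimate over
    samples pooled across trials (subsampled for tractability), evaluated on
    a grid and interpolated.  Mirrors the joint-probability statistic used
    by standard EEG toolboxes for trial rejection.
    """
    from scipy.stats import gaussian_kde

    n_trials, n_ch, n_samp = data.shape
    out = np.empty((n_trials, n_ch))
    rng = np.random.default_rng(0)  # subsampling only; statistic is robust
    for c in range(n_ch):
        pooled = data[:, c, :].ravel()
        if len(pooled) > max_pool:
            pooled_fit = rng.choice(pooled, max_pool, replace=False)
        else:
            pooled_fit = pooled
        lo, hi = pooled.min(), pooled.max()
        pad = 0.05 * (hi - lo + 1e-12)
        grid = np.linspace(lo - pad, hi + pad, n_grid)
        if np.ptp(pooled_fit) < 1e-12:
            out[:, c] = 0.0
            continue
        dens = gaussian_kde(pooled_fit)(grid)
        dens = np.maximum(dens, 1e-12)
        logd = np.log(dens)
        vals = np.interp(data[:, c, :], grid, logd)
        out[:, c] = -vals.mean(axis=-1)
    return out


def _zscore_across_trials(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0] = 1.0
    return (x - mu) / sd


def reject_artifacts(epochs: EpochSet,
                     amplitude_limit_uv: float = AMPLITUDE_LIMIT_UV,
                     stat_sd: float = STAT_REJECT_SD) -> EpochSet:
    """Flag contaminated trials; never alters kept data.

    A trial is rejected when (i) any sample exceeds the ±35 µV amplitude
    limit, (ii) any channel's kurtosis z-score across trials exceeds 5 SD,
    or (iii) any channel's joint-probability z-score exceeds 5 SD.
    """
    data = epochs.data
    if data.shape[0] < 10:
        raise ValueError("need at least 10 trials for stable z-scoring")

    amp_bad = np.any(np.abs(data) > amplitude_limit_uv, axis=(1, 2))
    kurt = _kurtosis(data, axis=2, fisher=True, bias=True)   # (trials, ch)
    kurt_bad = np.any(_zscore_across_trials(kurt) > stat_sd, axis=1)
    jp = _joint_probability_stat(data)
    jp_bad = np.any(_zscore_across_trials(jp) > stat_sd, axis=1)

    kept = epochs.kept_mask & ~(amp_bad | kurt_bad | jp_bad)
    log = list(epochs.rejection_log)
    for i in range(data.shape[0]):
        reasons = [r for r, bad in (("amplitude", amp_bad[i]),
                                    ("kurtosis", kurt_bad[i]),
                                    ("joint_probability", jp_bad[i])) if bad]
        if reasons:
            log.append((int(epochs.event_ids[i]), epochs.labels[i],
                        "+".join(reasons)))
    return EpochSet(data, epochs.labels, epochs.t_axis, epochs.fs_hz,
                    list(epochs.channel_names), epochs.event_ids, kept, log)


def flag_high_variance_channels(epochs: EpochSet,
                                factor: float = VARIANCE_IQR_FACTOR) -> list[str]:
    """Channels whose variance (pooled over kept trials) exceeds Q3 + 1.5*IQR."""
    data = epochs.data[epochs.kept_mask]
    var = data.var(axis=2).mean(axis=0)      # (n_channels,)
    q1, q3 = np.percentile(var, [25, 75])
    iqr = q3 - q1
    thr = q3 + factor * iqr
    return [epochs.channel_names[i] for i in np.nonzero(var > thr)[0]]


def interpolate_bad_channels(epochs: EpochSet,
                             bad: list[str] | None = None,
                             max_fraction: float = 0.25) -> tuple[EpochSet, list[str]]:
    """Replace high-variance channels by spherical-spline interpolation.

    Channels are flagged by the variance criterion (or supplied explicitly)
    and rebuilt from the remaining channels using the spherical-spline
    interpolation operator on the template montage positions.
    """
    if bad is None:
        bad = flag_high_variance_channels(epochs)
    if not bad:
        return epochs, []
    if len(bad) > max_fraction * len(epochs.channel_names):
        raise RuntimeError(
            f"{len(bad)} channels flagged (> {max_fraction:.0%}); data unusable")
    from mne.channels.interpolation import _make_interpolation_matrix

    names = list(epochs.channel_names)
    bad_idx = [names.index(b) for b in bad]
    good_idx = [i for i in range(len(names)) if i not in bad_idx]
    pos_good = position_array([names[i] for i in good_idx])
    pos_bad = position_array(bad)
    interp = _make_interpolation_matrix(pos_good, pos_bad)   # (n_bad, n_good)

    data = epochs.data.copy()
    data[:, bad_idx, :] = np.einsum("bg,tgs->tbs", interp,
                                    data[:, good_idx, :])
    out = EpochSet(data, epochs.labels, epochs.t_axis, epochs.fs_hz,
                   names, epochs.event_ids, epochs.kept_mask,
                   list(epochs.rejection_log) + [("channels_interpolated", tuple(bad))])
    return out, bad


# ---------------------------------------------------------------------------
# grand averaging

@dataclass
class GrandAverage:
    """Across-participant mean ± SEM traces per condition."""

    t_axis: np.ndarray
    channel_names: list[str]
    mean: dict                    # condition -> (n_channels, n_samples)
    sem: dict
    n_participants: int = 0
    per_participant: dict = field(default_factory=dict)


def grand_average_erp(epoch_sets: list[EpochSet]) -> GrandAverage:
    """Common-average re-reference, participant condition means, group mean ± SEM."""
    ref = epoch_sets[0]
    for es in epoch_sets[1:]:
        if len(es.t_axis) != len(ref.t_axis) or abs(es.fs_hz - ref.fs_hz) > 1e-9:
            raise ValueError("epoch sets must share the time axis")
        if list(es.channel_names) != list(ref.channel_names):
            raise ValueError("epoch sets must share channels")

    conditions = sorted({str(l) for es in epoch_sets for l in es.labels})
    per_part: dict[str, list[np.ndarray]] = {c: [] for c in conditions}
    for es in epoch_sets:
        kept = es.kept()
        car = kept.data - kept.data.mean(axis=1, keepdims=True)
        for c in conditions:
            m = kept.labels == c
            if m.any():
                per_part[c].append(car[m].mean(axis=0))

    mean, sem = {}, {}
    for c in conditions:
        stack = np.stack(per_part[c])
        mean[c] = stack.mean(axis=0)
        sem[c] = (stack.std(axis=0, ddof=1) / np.sqrt(len(stack))
                  if len(stack) > 1 else np.zeros_like(stack[0]))
    return GrandAverage(ref.t_axis, list(ref.channel_names), mean, sem,
                        len(epoch_sets), per_part)


def negative_peak_latency(ga: GrandAverage, channel: str, condition: str,
                          window_s: tuple[float, float] = (0.18, 0.30)) -> float:
    """Latency (s) of the most negative point of a grand-average trace."""
    ch = ga.channel_names.index(channel)
    m = (ga.t_axis >= window_s[0]) & (ga.t_axis <= window_s[1])
    trace = ga.mean[condition][ch][m]
    return float(ga.t_axis[m][int(np.argmin(trace))])


def positive_peak_latency(ga: GrandAverage, channel: str, condition: str,
                          window_s: tuple[float, float]) -> float:
    ch = ga.channel_names.index(channel)
    m = (ga.t_axis >= window_s[0]) & (ga.t_axis <= window_s[1])
    trace = ga.mean[condition][ch][m]
    return float(ga.t_axis[m][int(np.argmax(trace))])


# ---------------------------------------------------------------------------
# orchestration

def preprocess_eeg(participant, reject: bool = True,
                   interpolate: bool = True) -> EpochSet:
    """Run the full EEG chain for one participant (synthetic or loaded).

    filter -> block-wise ocular removal -> 1-10 Hz / 64 Hz / channel drop ->
    epoching -> artifact rejection -> bad-channel interpolation.
    """
    flight = participant.flight
    eeg = filter_raw(flight.eeg)
    models = [fit_ocular_model(c) for c in participant.calibrations]
    if models:
        eeg = apply_ocular_blockwise(eeg, models, flight.gaze,
                                     flight.run_spans)
    eeg = narrowband_resample_select(eeg)
    epochs = epoch_trials(eeg, flight.events)
    if reject:
        epochs = reject_artifacts(epochs)
    if interpolate:
        epochs, _ = interpolate_bad_channels(epochs)
    return epochs
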