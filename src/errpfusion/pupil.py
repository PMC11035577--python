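"""Pupillometric preprocessing: blink interpolation, filtering, PFE correction.

Order of operations: linear blink interpolation (per eye) -> resampling to
128 Hz and zero-phase 0.1-10 Hz band-pass -> subtraction of the cubic
gaze-dependent pupil-size bias (pupil foreshortening error, fitted on the
horizontal-saccade segments of the eye-calibration runs) -> eye averaging ->
epoching with variance-based trial rejection (separately for error and
correct trials) -> baseline correction (pre-onset window for error trials,
whole-trial mean for correct trials).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.signal import butter, resample_poly, sosfiltfilt

from .containers import (GazePupilStream, MultimodalRecording, ParadigmEvent,
                         PFEModel, PupilEpochSet, Segment)

__all__ = [
    "interpolate_blinks", "resample_filter_pupil", "fit_pfe", "correct_pfe",
    "epoch_pupil", "preprocess_pupil", "pupil_peak_latency",
]

PUPIL_FS_HZ = 128.0
PUPIL_BAND_HZ = (0.1, 10.0)
EPOCH_WINDOW_S = (-0.5, 1.0)
CORRECT_WINDOW_START_S = 1.5
VARIANCE_IQR_FACTOR = 1.5


def _interp_invalid(t: np.ndarray, x: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Linear interpolation of invalid runs between flanking valid samples."""
    if valid.all():
        return x.copy()
    if not valid.any():
        raise ValueError("an eye is entirely invalid; cannot interpolate")
    out = x.copy()
    out[~valid] = np.interp(t[~valid], t[valid], x[valid])
    return out


def interpolate_blinks(stream: GazePupilStream) -> GazePupilStream:
    """Replace blink dropouts in the pupil traces by linear interpolation.

    Validity flags are preserved for audit; leading/trailing invalid runs
    take the nearest valid value (np.interp end behaviour).
    """
    out = stream.copy()
    out.pupil_left_mm = _interp_invalid(stream.t_s, stream.pupil_left_mm,
                                        stream.valid_left.astype(bool))
    out.pupil_right_mm = _interp_invalid(stream.t_s, stream.pupil_right_mm,
                                         stream.valid_right.astype(bool))
    return out


def resample_filter_pupil(stream: GazePupilStream,
                          fs_out: float = PUPIL_FS_HZ) -> GazePupilStream:
    """Uniform resampling to 128 Hz + zero-phase 0.1-10 Hz band-pass.

    The gaze channels are resampled alongside (linearly) so that the
    foreshortening correction can be evaluated sample-by-sample; the filter
    is applied to the pupil traces only.  The band-pass removes absolute
    level: downstream of this step the traces are pupil-size *changes*.
    """
    from fractions import Fraction

    fs_in = stream.fs_hz
    frac = Fraction(fs_out / fs_in).limit_denominator(1000)
    n_out = int(round(len(stream.t_s) * fs_out / fs_in))
    t_out = np.arange(n_out) / fs_out + stream.t_s[0]

    sos = butter(4, [PUPIL_BAND_HZ[0], PUPIL_BAND_HZ[1]], btype="bandpass",
                 fs=fs_out, output="sos")

    def do(x):
        y = resample_poly(x, frac.numerator, frac.denominator)[:n_out]
        return sosfiltfilt(sos, y)

    valid_l = np.interp(t_out, stream.t_s, stream.valid_left.astype(float)) > 0.5
    valid_r = np.interp(t_out, stream.t_s, stream.valid_right.astype(float)) > 0.5
    return GazePupilStream(
        t_out,
        np.interp(t_out, stream.t_s, stream.gaze_h_deg),
        np.interp(t_out, stream.t_s, stream.gaze_v_deg),
        do(stream.pupil_left_mm), do(stream.pupil_right_mm),
        valid_l, valid_r)


def fit_pfe(calib_stream: GazePupilStream,
            saccade_segments: list[Segment]) -> PFEModel:
    """Cubic regression of pupil size on horizontal gaze angle, per eye.

    Fitted over the horizontal-saccade segments of the calibration runs.
    The vertical gaze angle is not part of the model (the observed
    dependency is on horizontal angle).
    """
    mask = np.zeros(len(calib_stream.t_s), dtype=bool)
    for seg in saccade_segments:
        if seg.kind == "horizontal":
            mask |= (calib_stream.t_s >= seg.start_s) & (calib_stream.t_s < seg.end_s)
    if not mask.any():
        raise ValueError("no horizontal-saccade segments supplied")

    coeffs = {}
    for eye, pupil, valid in (("left", calib_stream.pupil_left_mm,
                               calib_stream.valid_left),
                              ("right", calib_stream.pupil_right_mm,
                               calib_stream.valid_right)):
        m = mask & valid.astype(bool)
        g = calib_stream.gaze_h_deg[m]
        if len(np.unique(np.round(g, 3))) < 4:
            raise ValueError("need >= 4 distinct horizontal angles to fit a cubic")
        V = np.vander(g, 4, increasing=True)
        c, *_ = np.linalg.lstsq(V, pupil[m], rcond=None)
        coeffs[eye] = c
    g_all = calib_stream.gaze_h_deg[mask]
    return PFEModel(coeffs["left"], coeffs["right"],
                    center_deg=float(g_all.mean()),
                    angle_range_deg=(float(g_all.min()), float(g_all.max())))


def correct_pfe(stream: GazePupilStream, model: PFEModel) -> GazePupilStream:
    """Subtract the gaze-dependent pupil-size bias per eye.

    Only the gaze-dependent part of the cubic (relative to its value at the
    calibration center angle) is removed; the absolute pupil level is
    preserved and later handled by trial baselines.
    """
    lo, hi = model.angle_range_deg
    span = hi - lo
    g = stream.gaze_h_deg
    if np.any((g < lo - 0.5 * span) | (g > hi + 0.5 * span)):
        warnings.warn("gaze angles far outside the calibration range; "
                      "extrapolating the cubic foreshortening model")
    out = stream.copy()
    out.pupil_left_mm = stream.pupil_left_mm - model.bias_mm(g, "left")
    out.pupil_right_mm = stream.pupil_right_mm - model.bias_mm(g, "right")
    return out


def _variance_reject(variances: np.ndarray,
                     factor: float = VARIANCE_IQR_FACTOR) -> np.ndarray:
    """True for trials whose variance exceeds Q3 + 1.5*IQR."""
    if len(variances) == 0:
        return np.zeros(0, dtype=bool)
    q1, q3 = np.percentile(variances, [25, 75])
    return variances > q3 + factor * (q3 - q1)


def epoch_pupil(stream: GazePupilStream, events: list[ParadigmEvent],
                window_s: tuple[float, float] = EPOCH_WINDOW_S) -> PupilEpochSet:
    """Eye-averaged, variance-cleaned, baseline-corrected pupil epochs.

    Error trials span [-0.5, 1] s around onset with the mean of [-0.5, 0] s
    subtracted; correct trials are 1.5-s windows starting 1.5 s after the
    previous target pass with their whole-trial mean subtracted.  The
    variance rejection (Q3 + 1.5*IQR) runs separately for the error and
    correct pools, so rejections in one pool never influence the other.
    """
    fs = stream.fs_hz
    avg = 0.5 * (stream.pupil_left_mm + stream.pupil_right_mm)
    n_samp = int(round((window_s[1] - window_s[0]) * fs))
    t_axis = window_s[0] + np.arange(n_samp) / fs

    data, labels, ids, log = [], [], [], []
    t0 = stream.t_s[0]
    for i, ev in enumerate(events):
        start_t = (ev.onset_s + window_s[0]) if ev.is_error else \
            (ev.prev_target_pass_s + CORRECT_WINDOW_START_S)
        i0 = int(round((start_t - t0) * fs))
        if i0 < 0 or i0 + n_samp > len(avg):
            log.append((i, ev.condition, "out_of_bounds"))
            continue
        data.append(avg[i0:i0 + n_samp])
        labels.append(ev.condition)
        ids.append(i)
    if not data:
        raise ValueError("no trial fits inside the stream")
    data = np.stack(data)
    labels = np.array(labels)
    ids = np.array(ids)

    kept = np.ones(len(labels), dtype=bool)
    for pool in (labels != "correct", labels == "correct"):
        var = data[pool].var(axis=1)
        bad = _variance_reject(var)
        idx = np.nonzero(pool)[0][bad]
        kept[idx] = False
        for j in idx:
            log.append((int(ids[j]), str(labels[j]), "variance"))

    base_mask = t_axis < 0
    corrected = data.copy()
    is_err = labels != "correct"
    corrected[is_err] -= data[is_err][:, base_mask].mean(axis=1, keepdims=True)
    corrected[~is_err] -= data[~is_err].mean(axis=1, keepdims=True)

    return PupilEpochSet(corrected, labels, t_axis, fs, ids, kept, log)


def grand_average_pupil(epoch_sets: list[PupilEpochSet]) -> dict:
    """Across-participant mean ± SEM pupil traces per condition."""
    conditions = sorted({str(l) for es in epoch_sets for l in es.labels})
    t_axis = epoch_sets[0].t_axis
    out = {"t_axis": t_axis, "mean": {}, "sem": {}}
    for c in conditions:
        parts = []
        for es in epoch_sets:
            kept = es.kept()
            m = kept.labels == c
            if m.any():
                parts.append(kept.data[m].mean(axis=0))
        stack = np.stack(parts)
        out["mean"][c] = stack.mean(axis=0)
        out["sem"][c] = (stack.std(axis=0, ddof=1) / np.sqrt(len(stack))
                         if len(stack) > 1 else np.zeros_like(stack[0]))
    return out


def pupil_peak_latency(ga: dict, condition: str,
                       window_s: tuple[float, float] = (0.4, 0.9)) -> float:
    """Latency (s) of the maximum grand-average dilation in a window."""
    t = ga["t_axis"]
    m = (t >= window_s[0]) & (t <= window_s[1])
    return float(t[m][int(np.argmax(ga["mean"][condition][m]))])


def preprocess_pupil(participant) -> PupilEpochSet:
    """Full pupil chain for one participant.

    Blink interpolation -> 128 Hz resampling + 0.1-10 Hz band-pass -> PFE
    fit on the first calibration's horizontal segments -> correction ->
    epoching with variance rejection and baselines.
    """
    calib = participant.calibrations[0]
    cal_stream = interpolate_blinks(calib.gaze)
    model = fit_pfe(cal_stream, calib.segments)
    stream = interpolate_blinks(participant.flight.gaze)
    stream = resample_filter_pupil(stream)
    stream = correct_pfe(stream, model)
    return epoch_pupil(stream, participant.flight.events)
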