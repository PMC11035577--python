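"""Cardiac processing: RR series -> epoch-averaged heart-rate change traces.

The chest strap reports beat-to-beat RR intervals; each beat's heart rate is
the inverse of its RR interval (in bpm).  Beat-wise HR is linearly
interpolated onto a uniform grid (4 Hz by default; HR variations of
interest are well below 1 Hz), epoched over [-0.5, 3] s around error
onsets, and baseline-corrected by the pre-onset window mean.
"""

from __future__ import annotations

import numpy as np

from .containers import HREpochSet, ParadigmEvent, RRSeries

__all__ = ["rr_to_hr", "epoch_hr", "peak_deceleration", "detect_r_peaks",
           "grand_average_hr"]

HR_FS_HZ = 4.0
HR_EPOCH_WINDOW_S = (-0.5, 3.0)
DECEL_WINDOW_S = (0.7, 1.7)
CORRECT_WINDOW_START_S = 1.5


def rr_to_hr(rr: RRSeries, fs_out: float = HR_FS_HZ) -> tuple[np.ndarray, np.ndarray]:
    """Uniform heart-rate stream (t_s, hr_bpm) from an RR series.

    HR at each R peak is 60/RR; values are linearly interpolated between
    peaks, held constant beyond the first/last peak.
    """
    if len(rr.r_peak_t_s) < 2:
        raise ValueError("need at least two R peaks")
    hr_at_peaks = 60.0 / rr.rr_s
    t = np.arange(0.0, rr.r_peak_t_s[-1], 1.0 / fs_out)
    return t, np.interp(t, rr.r_peak_t_s, hr_at_peaks)


def epoch_hr(hr_t: np.ndarray, hr_bpm: np.ndarray,
             events: list[ParadigmEvent],
             window_s: tuple[float, float] = HR_EPOCH_WINDOW_S) -> HREpochSet:
    """[-0.5, 3] s epochs of HR change, baseline = mean of [-0.5, 0] s.

    Correct trials are anchored 1.5 s after the previous target pass, as in
    the other modalities; epochs extending past the stream are skipped and
    logged.
    """
    fs = 1.0 / (hr_t[1] - hr_t[0])
    n_samp = int(round((window_s[1] - window_s[0]) * fs))
    t_axis = window_s[0] + np.arange(n_samp) / fs
    data, labels, ids, log = [], [], [], []
    for i, ev in enumerate(events):
        anchor = ev.onset_s if ev.is_error else \
            ev.prev_target_pass_s + CORRECT_WINDOW_START_S
        i0 = int(round((anchor + window_s[0] - hr_t[0]) * fs))
        if i0 < 0 or i0 + n_samp > len(hr_bpm):
            log.append((i, ev.condition, "out_of_bounds"))
            continue
        trial = hr_bpm[i0:i0 + n_samp]
        data.append(trial - trial[t_axis < 0].mean())
        labels.append(ev.condition)
        ids.append(i)
    if not data:
        raise ValueError("no trial fits inside the HR stream")
    return HREpochSet(np.stack(data), np.array(labels), t_axis, fs,
                      np.array(ids), log)


def peak_deceleration(epochs: HREpochSet,
                      window_s: tuple[float, float] = DECEL_WINDOW_S) -> dict:
    """Per-condition minimum of the trial-average HR change in [0.7, 1.7] s."""
    t = epochs.t_axis
    m = (t >= window_s[0] - 1e-9) & (t <= window_s[1] + 1e-9)
    if not m.any():
        raise ValueError("epoch axis does not cover the deceleration window")
    out = {}
    for c in np.unique(epochs.labels):
        trials = epochs.data[epochs.labels == c]
        out[str(c)] = float(trials.mean(axis=0)[m].min())
    return out


def grand_average_hr(epoch_sets: list[HREpochSet]) -> dict:
    """Across-participant mean ± SEM HR-change traces per condition."""
    conditions = sorted({str(l) for es in epoch_sets for l in es.labels})
    t_axis = epoch_sets[0].t_axis
    out = {"t_axis": t_axis, "mean": {}, "sem": {}}
    for c in conditions:
        parts = [es.data[es.labels == c].mean(axis=0) for es in epoch_sets
                 if (es.labels == c).any()]
        stack = np.stack(parts)
        out["mean"][c] = stack.mean(axis=0)
        out["sem"][c] = (stack.std(axis=0, ddof=1) / np.sqrt(len(stack))
                         if len(stack) > 1 else np.zeros_like(stack[0]))
    return out


def detect_r_peaks(ecg: np.ndarray, fs_hz: float,
                   min_distance_s: float = 0.3) -> RRSeries:
    """Threshold-based R-peak detector (optional utility; the core path
    consumes strap-reported RR intervals directly)."""
    from scipy.signal import find_peaks

    thr = np.percentile(ecg, 99) * 0.5
    peaks, _ = find_peaks(ecg, height=thr,
                          distance=max(1, int(min_distance_s * fs_hz)))
    if len(peaks) < 2:
        raise ValueError("fewer than two R peaks detected")
    t = peaks / fs_hz
    return RRSeries(t[1:], np.diff(t))
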