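"""Synthetic generator for the VR flight-simulation error paradigm.

Emulates the statistical structure the downstream analysis assumes: per-run
event schedules (70 targets, 21 errors of three types), continuous EEG with
condition-specific event-related components over 1/f background plus ocular
contamination, gaze/pupil streams with a cubic gaze-dependent pupil-size
distortion (pupil foreshortening) and blink dropouts, and an RR-interval
series with respiratory sinus arrhythmia and a post-error heart-rate
deceleration.  Eye-calibration recordings with labeled saccade/blink
segments make the ocular and foreshortening models identifiable.

Everything is deterministic given the configuration seed.  The EEG is built
additively (components + background + ocular mixing), so zeroing one term
removes exactly its contribution — which is what makes the preprocessing
chain verifiable against injected ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, sosfiltfilt
from scipy.signal.windows import hann

from .containers import (CLASS_ORDER, ERROR_CONDITIONS, ContinuousEEG,
                         GazePupilStream, MultimodalRecording, ParadigmEvent,
                         RRSeries, Segment)
from .montage import CHANNELS_63, scalp_topography

__all__ = [
    "ERPComponentSpec", "GeneratorConfig", "simulate_paradigm", "synth_eeg",
    "synth_pupil", "synth_rr", "synth_eye_calibration", "simulate_participant",
    "default_erp_components", "blink_waveform", "session_duration_s",
]


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class ERPComponentSpec:
    """One event-related component: a Gaussian bump with a scalp map."""

    name: str              # P1 | ERN | Pe | N400
    latency_s: float       # peak latency after event onset
    amplitude_uV: float    # signed peak amplitude at the topography maximum
    width_s: float         # Gaussian standard deviation of the bump
    topo_center: str = "FCz"

    def __post_init__(self):
        if not (0.0 <= self.latency_s <= 1.0):
            raise ValueError("latency_s must lie in [0, 1] s")
        if self.width_s <= 0:
            raise ValueError("width_s must be positive")


def default_erp_components() -> dict[str, tuple[ERPComponentSpec, ...]]:
    """Per-condition component defaults.

    Latencies and amplitudes encode the emulated grand-average waveform at
    FCz: an initial positivity (P1) at 188 ms in all error conditions, the
    error negativity (ERN) at 234/250/266 ms for target/passive/active, the
    error positivity (Pe) at 313/344/391 ms, and a late negativity (N400) at
    469/484/500 ms.  Active-condition components are delayed relative to
    passive ones component-by-component.  Correct trials carry no
    event-locked components.  Bump widths and the N400 amplitudes are
    generator choices (free parameters of the emulation) picked so that neighbouring
    components remain separable after the 1-10 Hz analysis band-pass.
    """
    def c(name, lat, amp, width, center="FCz"):
        return ERPComponentSpec(name, lat, amp, width, center)

    return {
        "target": (
            c("P1", 0.188, 1.33, 0.018),
            c("ERN", 0.234, -2.0, 0.016),
            c("Pe", 0.313, 4.16, 0.035, "Cz"),
            c("N400", 0.469, -1.5, 0.045, "Cz"),
        ),
        "passive": (
            c("P1", 0.188, 1.03, 0.018),
            c("ERN", 0.250, -1.6, 0.016),
            c("Pe", 0.344, 1.30, 0.035, "Cz"),
            c("N400", 0.484, -1.2, 0.045, "Cz"),
        ),
        "active": (
            c("P1", 0.188, 0.748, 0.018),
            c("ERN", 0.266, -1.7, 0.016),
            c("Pe", 0.391, 1.08, 0.035, "Cz"),
            c("N400", 0.500, -1.0, 0.045, "Cz"),
        ),
        "correct": (),
    }


@dataclass(frozen=True)
class PupilComponent:
    latency_s: float
    amplitude_mm: float
    width_s: float


@dataclass(frozen=True)
class HRDecelSpec:
    magnitude_bpm: float = 2.0   # peak heart-rate drop
    latency_s: float = 1.1      # time of the deceleration minimum
    width_s: float = 0.30       # Gaussian standard deviation


@dataclass(frozen=True)
class GeneratorConfig:
    """All tunable quantities of the generator; the seed fixes the output."""

    seed: int = 0
    n_runs: int = 9
    fs_eeg: float = 512.0
    fs_gaze: float = 120.0

    # EEG background and ocular mixing
    eeg_noise_sd_uV: float = 4.0
    one_over_f_exponent: float = 1.0
    ocular_gain_h_uV_per_deg: float = 0.6     # scaled lateral-frontal map
    ocular_gain_v_uV_per_deg: float = 1.0     # scaled frontal map
    ocular_gain_blink_uV: float = 60.0        # scaled frontal map
    erp_components: dict = field(default_factory=default_erp_components)
    erp_amplitude_scale: float = 1.0          # per-participant gain

    # gaze / pupil
    gaze_sd_h_deg: float = 8.0
    gaze_sd_v_deg: float = 4.0
    pupil_base_mm: float = 3.5
    pupil_noise_sd_mm: float = 0.01
    pupil_drift_sd_mm: float = 0.05
    pupil_hippus_sd_mm: float = 0.035   # slow in-band oscillation (~0.2-0.6 Hz)
    pupil_amp_jitter: float = 0.3       # lognormal sd of per-trial dilation gain
    pupil_components: dict = field(default_factory=lambda: {
        "target": PupilComponent(0.625, 0.12, 0.15),
        "passive": PupilComponent(0.656, 0.10, 0.15),
        "active": PupilComponent(0.734, 0.09, 0.15),
        "correct": None,
    })
    # ascending cubic coefficients (mm, mm/deg, mm/deg^2, mm/deg^3)
    pfe_coeffs_left: tuple = (0.0, 2.0e-3, -3.0e-4, -1.5e-6)
    pfe_coeffs_right: tuple = (0.0, -1.5e-3, -2.5e-4, 1.0e-6)
    blink_rate_hz: float = 0.12
    blink_duration_s: float = 0.20

    # cardiac
    rr_base_s: float = 0.80
    rsa_amp_s: float = 0.04
    # breathing free-runs: keep the period incommensurate with the ~4 s
    # inter-target interval so respiration is not phase-locked to trials
    rsa_freq_hz: float = 0.31
    rr_jitter_s: float = 0.005
    hr_decel: HRDecelSpec = field(default_factory=HRDecelSpec)

    # paradigm timing
    inter_target_s: float = 4.0
    inter_target_jitter_s: float = 0.2
    inter_run_gap_s: float = 5.0

    def __post_init__(self):
        for name in ("fs_eeg", "fs_gaze", "rr_base_s", "inter_target_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    def with_(self, **kw) -> "GeneratorConfig":
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# paradigm schedule

TARGET_JUMP_LEAD_S = 1.6          # target jumps 1.6 s before projected pass
ERROR_LEAD_RANGE_S = (1.1, 1.8)   # passive/active lead, uniform

_N_TARGETS = 70
_N_PER_ERROR = 7


def _run_schedule(rng: np.random.Generator, run_index: int, t0: float,
                  cfg: GeneratorConfig) -> tuple[list[ParadigmEvent], float]:
    intervals = cfg.inter_target_s + rng.uniform(
        -cfg.inter_target_jitter_s, cfg.inter_target_jitter_s, _N_TARGETS)
    passes = t0 + cfg.inter_target_s + np.concatenate(([0.0], np.cumsum(intervals[:-1])))
    conditions = (["target"] * _N_PER_ERROR + ["passive"] * _N_PER_ERROR
                  + ["active"] * _N_PER_ERROR
                  + ["correct"] * (_N_TARGETS - 3 * _N_PER_ERROR))
    rng.shuffle(conditions)
    events = []
    for k, (p, cond) in enumerate(zip(passes, conditions)):
        prev = passes[k - 1] if k > 0 else t0
        if cond == "target":
            onset = p - TARGET_JUMP_LEAD_S
            direction = "left" if rng.random() < 0.5 else "right"
        elif cond in ("passive", "active"):
            onset = p - rng.uniform(*ERROR_LEAD_RANGE_S)
            direction = "left" if rng.random() < 0.5 else "right"
        else:
            onset = p
            direction = "none"
        events.append(ParadigmEvent(run_index, float(onset), cond,
                                    float(prev), direction))
    run_end = float(passes[-1]) + cfg.inter_target_s
    return events, run_end


def simulate_paradigm(n_runs: int, seed: int,
                      cfg: GeneratorConfig | None = None) -> list[ParadigmEvent]:
    """Schedule ``n_runs`` flight-simulation runs on one session clock.

    Each run contains 70 targets roughly 4 s apart; 30% of them (randomized
    order) trigger an error, seven per error condition, so 21 error events
    and 49 correct targets per run.  Target jumps occur a fixed 1.6 s before
    the projected target pass; passive/active interaction errors are drawn
    uniformly 1.1-1.8 s before it.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    cfg = cfg or GeneratorConfig(seed=seed)
    rng = np.random.default_rng([int(seed) % (2**31), 0])
    events: list[ParadigmEvent] = []
    t0 = 0.0
    for r in range(1, n_runs + 1):
        run_events, run_end = _run_schedule(rng, r, t0, cfg)
        events.extend(run_events)
        t0 = run_end + cfg.inter_run_gap_s
    return events


def run_spans(events: list[ParadigmEvent], cfg: GeneratorConfig) -> dict[int, tuple[float, float]]:
    """Per-run (start, end) spans implied by a schedule."""
    spans: dict[int, tuple[float, float]] = {}
    for ev in events:
        lo, hi = spans.get(ev.run_index, (np.inf, -np.inf))
        spans[ev.run_index] = (min(lo, ev.prev_target_pass_s),
                               max(hi, ev.onset_s + cfg.inter_target_s))
    return spans


def session_duration_s(events: list[ParadigmEvent], cfg: GeneratorConfig) -> float:
    """Total stream duration needed to cover a schedule (with padding)."""
    last = max(max(ev.onset_s, ev.prev_target_pass_s) for ev in events)
    return float(last + cfg.inter_target_s + 2.0)


# ---------------------------------------------------------------------------
# shared stochastic sources (gaze, blinks) -- identical across modalities

def _lowpass_noise(rng, n, fs, cutoff_hz, sd):
    """Smooth Gaussian process: white noise low-passed at ``cutoff_hz``.

    Generated with generous padding (several filter time constants) that is
    trimmed afterwards, so zero-phase edge transients never reach the output.
    """
    pad = int(min(5 * n, 10.0 / cutoff_hz * fs))
    x = rng.standard_normal(n + 2 * pad)
    if n > 30:
        sos = butter(2, cutoff_hz / (fs / 2), btype="low", output="sos")
        x = sosfiltfilt(sos, x)
    x = x[pad:pad + n]
    s = x.std()
    return x * (sd / s) if s > 0 else x


def _gaze_process(duration_s: float, cfg: GeneratorConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic (per seed) smooth gaze wander at fs_gaze."""
    n = int(round(duration_s * cfg.fs_gaze))
    rng = np.random.default_rng([int(cfg.seed) % (2**31), 2])
    t = np.arange(n) / cfg.fs_gaze
    gh = _lowpass_noise(rng, n, cfg.fs_gaze, 0.4, cfg.gaze_sd_h_deg)
    gv = _lowpass_noise(rng, n, cfg.fs_gaze, 0.4, cfg.gaze_sd_v_deg)
    return t, gh, gv


def _blink_process(duration_s: float, cfg: GeneratorConfig) -> np.ndarray:
    """Boolean blink indicator at fs_gaze (Poisson blink onsets)."""
    n = int(round(duration_s * cfg.fs_gaze))
    ind = np.zeros(n, dtype=bool)
    if cfg.blink_rate_hz <= 0:
        return ind
    rng = np.random.default_rng([int(cfg.seed) % (2**31), 3])
    t = 0.0
    while True:
        t += rng.exponential(1.0 / cfg.blink_rate_hz)
        if t >= duration_s - cfg.blink_duration_s:
            break
        i0 = int(t * cfg.fs_gaze)
        i1 = min(n, i0 + max(1, int(cfg.blink_duration_s * cfg.fs_gaze)))
        ind[i0:i1] = True
    return ind


def blink_waveform(indicator: np.ndarray, fs_hz: float,
                   kernel_s: float = 0.15) -> np.ndarray:
    """Canonical smooth blink source: indicator convolved with a Hann kernel.

    Both the generator (to contaminate EEG) and the ocular-removal stage (to
    build its blink reference from validity flags) use this same waveform,
    so the contamination is exactly within the span of the references.
    """
    ind = np.asarray(indicator, dtype=float)
    m = max(3, int(round(kernel_s * fs_hz)))
    k = hann(m)
    k = k / k.sum()
    return np.convolve(ind, k, mode="same")


def _resample_to(t_src, x_src, fs_out, n_out):
    t_out = np.arange(n_out) / fs_out
    return np.interp(t_out, t_src, x_src)


def ocular_reference_signals(gaze: GazePupilStream, fs_out: float,
                             n_out: int) -> np.ndarray:
    """(3, n) ocular references at ``fs_out``: gaze_h, gaze_v, blink wave.

    The blink indicator is taken from the per-eye validity flags (a sample
    is a blink when both eyes are invalid).
    """
    ind = (~gaze.valid_left) & (~gaze.valid_right)
    fs_gaze = gaze.fs_hz
    bw = blink_waveform(ind, fs_gaze)
    refs = np.stack([
        _resample_to(gaze.t_s, gaze.gaze_h_deg, fs_out, n_out),
        _resample_to(gaze.t_s, gaze.gaze_v_deg, fs_out, n_out),
        _resample_to(gaze.t_s, bw, fs_out, n_out),
    ])
    return refs


def ocular_gain_matrix(cfg: GeneratorConfig) -> np.ndarray:
    """(n_channels, 3) mixing weights of the ocular sources into the EEG.

    Horizontal gaze projects with a left-right antisymmetric lateral-frontal
    pattern, vertical gaze and blinks with a symmetric frontal pattern that
    decays toward posterior sites.
    """
    topo_f7 = scalp_topography("F7", 0.06)
    topo_f8 = scalp_topography("F8", 0.06)
    frontal = 0.5 * (scalp_topography("Fp1", 0.07) + scalp_topography("Fp2", 0.07))
    g = np.stack([
        cfg.ocular_gain_h_uV_per_deg * (topo_f8 - topo_f7),
        cfg.ocular_gain_v_uV_per_deg * frontal,
        cfg.ocular_gain_blink_uV * frontal,
    ], axis=1)
    return g


# ---------------------------------------------------------------------------
# EEG synthesis

def _one_over_f_noise(rng, shape, fs, exponent, sd):
    """Per-channel 1/f^a background noise with the requested time-domain SD."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    spec = (rng.standard_normal((shape[0], len(freqs)))
            + 1j * rng.standard_normal((shape[0], len(freqs)))) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    s = x.std(axis=-1, keepdims=True)
    s[s == 0] = 1.0
    return x / s * sd


def _component_kernel(comp: ERPComponentSpec, fs: float) -> tuple[np.ndarray, int]:
    """Sampled Gaussian bump and the offset (samples) of its peak."""
    half = int(round(4 * comp.width_s * fs))
    i = np.arange(-half, half + 1)
    k = comp.amplitude_uV * np.exp(-0.5 * (i / (comp.width_s * fs)) ** 2)
    return k, half


def synth_eeg(events: list[ParadigmEvent], cfg: GeneratorConfig,
              duration_s: float | None = None) -> ContinuousEEG:
    """Continuous 63-channel EEG (µV) for a schedule.

    signal = event-locked component bumps (per condition, scaled by the
    channel topography) + 1/f background + linear ocular mixing of the
    shared gaze/blink sources.
    """
    if not events:
        raise ValueError("events must be non-empty")
    duration_s = duration_s or session_duration_s(events, cfg)
    fs = cfg.fs_eeg
    n = int(round(duration_s * fs))
    for ev in events:
        if ev.onset_s < 0 or ev.onset_s > duration_s:
            raise ValueError(f"event at {ev.onset_s:.2f}s beyond stream duration")

    data = np.zeros((len(CHANNELS_63), n))

    # event-locked components
    topo_cache: dict[str, np.ndarray] = {}
    for ev in events:
        for comp in cfg.erp_components.get(ev.condition, ()):
            if comp.topo_center not in topo_cache:
                topo_cache[comp.topo_center] = scalp_topography(comp.topo_center)
            topo = topo_cache[comp.topo_center]
            k, half = _component_kernel(comp, fs)
            center = int(round((ev.onset_s + comp.latency_s) * fs))
            lo, hi = center - half, center + half + 1
            klo, khi = max(0, -lo), len(k) - max(0, hi - n)
            lo, hi = max(0, lo), min(n, hi)
            if lo < hi:
                data[:, lo:hi] += (cfg.erp_amplitude_scale
                                   * np.outer(topo, k[klo:khi]))

    # background noise
    if cfg.eeg_noise_sd_uV > 0:
        rng = np.random.default_rng([int(cfg.seed) % (2**31), 1])
        data += _one_over_f_noise(rng, (len(CHANNELS_63), n), fs,
                                  cfg.one_over_f_exponent, cfg.eeg_noise_sd_uV)

    # ocular contamination, from the same gaze/blink processes as the pupil
    gains = ocular_gain_matrix(cfg)
    if np.any(gains != 0):
        gaze = synth_pupil(events, cfg, duration_s=duration_s)
        refs = ocular_reference_signals(gaze, fs, n)
        data += gains @ refs

    return ContinuousEEG(list(CHANNELS_63), fs, data)


# ---------------------------------------------------------------------------
# pupil synthesis

def _pupil_true(events, cfg, t, rng=None):
    """Gaze-independent pupil diameter common to both eyes (mm).

    Each dilation's amplitude is jittered per trial (lognormal gain), the
    dominant source of single-trial variability in evoked pupil responses.
    """
    p = np.full(len(t), cfg.pupil_base_mm)
    for ev in events:
        comp = cfg.pupil_components.get(ev.condition)
        gain = (float(np.exp(rng.normal(0.0, cfg.pupil_amp_jitter)))
                if rng is not None and cfg.pupil_amp_jitter > 0 else 1.0)
        if comp is None:
            continue
        center = ev.onset_s + comp.latency_s
        m = np.abs(t - center) < 5 * comp.width_s
        p[m] += gain * comp.amplitude_mm * np.exp(
            -0.5 * ((t[m] - center) / comp.width_s) ** 2)
    return p


def _hippus_noise(rng, n, fs, sd):
    """Band-limited (~0.2-0.6 Hz) slow pupil oscillation."""
    pad = int(min(5 * n, 50.0 * fs))
    x = rng.standard_normal(n + 2 * pad)
    sos = butter(2, [0.2 / (fs / 2), 0.6 / (fs / 2)], btype="bandpass",
                 output="sos")
    x = sosfiltfilt(sos, x)[pad:pad + n]
    s = x.std()
    return x * (sd / s) if s > 0 else x


def synth_pupil(events: list[ParadigmEvent], cfg: GeneratorConfig,
                duration_s: float | None = None) -> GazePupilStream:
    """Gaze + per-eye pupil streams at fs_gaze.

    observed pupil = baseline + condition dilation bump + slow drift +
    measurement noise + cubic gaze-dependent foreshortening bias, per eye;
    blinks appear as invalid samples (diameter set to 0).
    """
    if not events:
        raise ValueError("events must be non-empty")
    duration_s = duration_s or session_duration_s(events, cfg)
    t, gh, gv = _gaze_process(duration_s, cfg)
    n = len(t)
    rng = np.random.default_rng([int(cfg.seed) % (2**31), 4])

    p_true = _pupil_true(events, cfg, t, rng)
    if cfg.pupil_drift_sd_mm > 0:
        p_true = p_true + _lowpass_noise(rng, n, cfg.fs_gaze, 0.05,
                                         cfg.pupil_drift_sd_mm)
    if cfg.pupil_hippus_sd_mm > 0:
        p_true = p_true + _hippus_noise(rng, n, cfg.fs_gaze,
                                        cfg.pupil_hippus_sd_mm)

    eyes = {}
    for eye, coeffs in (("left", cfg.pfe_coeffs_left),
                        ("right", cfg.pfe_coeffs_right)):
        bias = np.polynomial.polynomial.polyval(gh, np.asarray(coeffs))
        noise = (rng.standard_normal(n) * cfg.pupil_noise_sd_mm
                 if cfg.pupil_noise_sd_mm > 0 else 0.0)
        eyes[eye] = p_true + bias + noise

    blink = _blink_process(duration_s, cfg)
    valid = ~blink
    for eye in eyes:
        eyes[eye] = np.where(valid, eyes[eye], 0.0)

    return GazePupilStream(t, gh, gv, eyes["left"], eyes["right"],
                           valid.copy(), valid.copy())


# ---------------------------------------------------------------------------
# RR synthesis

def synth_rr(events: list[ParadigmEvent], cfg: GeneratorConfig,
             duration_s: float | None = None) -> RRSeries:
    """RR-interval series with RSA and post-error RR lengthening.

    RR(t) = rr_base + rsa_amp * sin(2*pi*rsa_freq*t) + deceleration kernel
    summed over error events + Gaussian jitter.  The deceleration kernel is
    expressed in bpm and converted to seconds around the base rate.
    """
    if not events:
        raise ValueError("events must be non-empty")
    if cfg.rr_base_s <= 0:
        raise ValueError("rr_base_s must be positive")
    duration_s = duration_s or session_duration_s(events, cfg)
    rng = np.random.default_rng([int(cfg.seed) % (2**31), 5])

    d = cfg.hr_decel
    drr = cfg.rr_base_s**2 * d.magnitude_bpm / 60.0  # RR lengthening, s
    err_onsets = np.array([ev.onset_s for ev in events if ev.is_error])
    rsa_phase = rng.uniform(0.0, 2 * np.pi)  # free-running respiration

    peaks = [0.0]
    t = 0.0
    while True:
        rr = cfg.rr_base_s + cfg.rsa_amp_s * np.sin(
            2 * np.pi * cfg.rsa_freq_hz * t + rsa_phase)
        if drr != 0 and len(err_onsets):
            # the RR interval ending at the next beat reflects lengthening
            # over its span; evaluating the kernel at the projected end time
            # places the heart-rate dip at the kernel latency
            dt = (t + cfg.rr_base_s) - err_onsets
            m = (dt > -1.0) & (dt < d.latency_s + 5 * d.width_s)
            if m.any():
                rr += drr * np.sum(np.exp(
                    -0.5 * ((dt[m] - d.latency_s) / d.width_s) ** 2))
        if cfg.rr_jitter_s > 0:
            rr += rng.standard_normal() * cfg.rr_jitter_s
        rr = max(0.3, rr)
        t += rr
        if t > duration_s:
            break
        peaks.append(t)
    peaks = np.asarray(peaks)
    return RRSeries(peaks[1:], np.diff(peaks))


# ---------------------------------------------------------------------------
# eye-calibration runs

_CAL_ANGLES_DEG = (-30.0, -20.0, -10.0, 0.0, 10.0, 20.0, 30.0)


def synth_eye_calibration(cfg: GeneratorConfig,
                          duration_s: float = 300.0) -> MultimodalRecording:
    """~5-minute calibration recording with labeled artifact segments.

    Three labeled phases partition the recording: horizontal saccades
    stepping through seven angles (which is what makes the cubic
    foreshortening model identifiable), vertical saccades, and a paced-blink
    phase.  EEG is contaminated through the same ocular mixing as flight
    runs; the pupil carries the same cubic distortion.
    """
    fs_g = cfg.fs_gaze
    n = int(round(duration_s * fs_g))
    t = np.arange(n) / fs_g
    rng = np.random.default_rng([int(cfg.seed) % (2**31), 6])

    third = duration_s / 3.0
    segments = [Segment(0.0, third, "horizontal"),
                Segment(third, 2 * third, "vertical"),
                Segment(2 * third, duration_s, "blink")]

    gh = np.zeros(n)
    gv = np.zeros(n)
    # horizontal phase: hold each angle ~1.4 s, cycling
    hold = max(1, int(1.4 * fs_g))
    idx = np.arange(int(third * fs_g))
    gh[idx] = [_CAL_ANGLES_DEG[(i // hold) % len(_CAL_ANGLES_DEG)] for i in idx]
    # vertical phase
    vangles = (-15.0, -7.5, 0.0, 7.5, 15.0)
    idx = np.arange(int(third * fs_g), int(2 * third * fs_g))
    gv[idx] = [vangles[((i - idx[0]) // hold) % len(vangles)] for i in idx]

    # paced blinks every ~1.5 s in the blink phase
    blink = np.zeros(n, dtype=bool)
    bt = 2 * third + 1.0
    while bt < duration_s - cfg.blink_duration_s:
        i0 = int(bt * fs_g)
        blink[i0:i0 + max(1, int(cfg.blink_duration_s * fs_g))] = True
        bt += 1.5
    valid = ~blink

    # pupil with foreshortening bias (no event-locked dilations)
    p_true = np.full(n, cfg.pupil_base_mm)
    eyes = {}
    for eye, coeffs in (("left", cfg.pfe_coeffs_left),
                        ("right", cfg.pfe_coeffs_right)):
        bias = np.polynomial.polynomial.polyval(gh, np.asarray(coeffs))
        noise = (rng.standard_normal(n) * cfg.pupil_noise_sd_mm
                 if cfg.pupil_noise_sd_mm > 0 else 0.0)
        eyes[eye] = np.where(valid, p_true + bias + noise, 0.0)

    gaze = GazePupilStream(t, gh, gv, eyes["left"], eyes["right"],
                           valid.copy(), valid.copy())

    # EEG: background + ocular mixing of exactly these sources
    n_eeg = int(round(duration_s * cfg.fs_eeg))
    data = np.zeros((len(CHANNELS_63), n_eeg))
    if cfg.eeg_noise_sd_uV > 0:
        data += _one_over_f_noise(rng, (len(CHANNELS_63), n_eeg), cfg.fs_eeg,
                                  cfg.one_over_f_exponent, cfg.eeg_noise_sd_uV)
    data += ocular_gain_matrix(cfg) @ ocular_reference_signals(
        gaze, cfg.fs_eeg, n_eeg)
    eeg = ContinuousEEG(list(CHANNELS_63), cfg.fs_eeg, data)

    return MultimodalRecording(eeg=eeg, gaze=gaze, segments=segments)


# ---------------------------------------------------------------------------
# participant-level convenience

@dataclass
class Participant:
    """One synthetic participant: two calibration runs + a flight session."""

    cfg: GeneratorConfig
    calibrations: list[MultimodalRecording]
    flight: MultimodalRecording


def simulate_participant(cfg: GeneratorConfig,
                         calibration_duration_s: float = 120.0) -> Participant:
    """Generate one participant's session.

    Two eye-calibration recordings (one per experiment block) precede the
    flight session, mirroring the acquisition protocol; calibration length
    is shortened from the real ~5 minutes by default since the synthetic
    artifact segments are stationary.
    """
    events = simulate_paradigm(cfg.n_runs, cfg.seed, cfg)
    duration = session_duration_s(events, cfg)
    eeg = synth_eeg(events, cfg, duration)
    gaze = synth_pupil(events, cfg, duration)
    rr = synth_rr(events, cfg, duration)
    flight = MultimodalRecording(eeg=eeg, gaze=gaze, rr=rr, events=events,
                                 run_spans=run_spans(events, cfg))
    calibs = [synth_eye_calibration(cfg.with_(seed=(cfg.seed * 2 + k) % (2**31)),
                                    calibration_duration_s)
              for k in range(2)]
    return Participant(cfg, calibs, flight)


def cohort_configs(n_participants: int, base_seed: int,
                   amplitude_jitter: float = 0.15, **overrides) -> list[GeneratorConfig]:
    """Configs for a synthetic cohort.

    Participants share the condition structure (component latencies are the
    paradigm truth) and differ in their noise realizations and in an overall
    response-amplitude gain (lognormal, sd ``amplitude_jitter``), a mild
    stand-in for inter-subject amplitude variability.
    """
    rng = np.random.default_rng([int(base_seed) % (2**31), 7])
    cfgs = []
    for p in range(n_participants):
        gain = float(np.exp(rng.normal(0.0, amplitude_jitter)))
        cfgs.append(GeneratorConfig(
            seed=int((base_seed * 1000 + p) % (2**31)),
            erp_amplitude_scale=gain, **overrides))
    return cfgs
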