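"""In-memory containers shared across the preprocessing and decoding stages.

All modalities share one session clock: ``t = 0`` at recording start, event
onsets in seconds, and each consumer converts to its own sample indices.
Epoch containers carry an ``event_id`` per trial so that trials surviving
the per-modality artifact rejections can be re-aligned for fusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Class order used everywhere (row/column order of confusion matrices).
CLASS_ORDER: tuple[str, ...] = ("target", "passive", "active", "correct")
ERROR_CONDITIONS: tuple[str, ...] = ("target", "passive", "active")


@dataclass(frozen=True)
class ParadigmEvent:
    """One target of the flight paradigm (erroneous or correct)."""

    run_index: int                 # 1-based run number
    onset_s: float                 # error onset (or projected pass for correct)
    condition: str                 # target | passive | active | correct
    prev_target_pass_s: float      # when the previous target was passed
    direction: str = "none"        # left | right | none

    def __post_init__(self):
        if self.condition not in CLASS_ORDER:
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def is_error(self) -> bool:
        return self.condition != "correct"


@dataclass
class ContinuousEEG:
    """Continuous multichannel EEG in microvolts."""

    channel_names: list[str]
    fs_hz: float
    data: np.ndarray  # (n_channels, n_samples), µV

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_names):
            raise ValueError("data must be (n_channels, n_samples)")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def pick(self, names) -> "ContinuousEEG":
        idx = [self.channel_names.index(n) for n in names]
        return ContinuousEEG(list(names), self.fs_hz, self.data[idx].copy())

    def copy(self) -> "ContinuousEEG":
        return ContinuousEEG(list(self.channel_names), self.fs_hz, self.data.copy())


@dataclass
class GazePupilStream:
    """Gaze angles (degrees) and per-eye pupil diameter (mm) on one clock."""

    t_s: np.ndarray
    gaze_h_deg: np.ndarray
    gaze_v_deg: np.ndarray
    pupil_left_mm: np.ndarray
    pupil_right_mm: np.ndarray
    valid_left: np.ndarray
    valid_right: np.ndarray

    def __post_init__(self):
        n = len(self.t_s)
        for name in ("gaze_h_deg", "gaze_v_deg", "pupil_left_mm",
                     "pupil_right_mm", "valid_left", "valid_right"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (n,):
                raise ValueError(f"{name} length mismatch")
            setattr(self, name, arr)
        self.t_s = np.asarray(self.t_s, dtype=float)
        if n > 1 and not np.all(np.diff(self.t_s) > 0):
            raise ValueError("t_s must be strictly increasing")

    @property
    def fs_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t_s)))

    def copy(self) -> "GazePupilStream":
        return GazePupilStream(*(np.copy(getattr(self, f)) for f in (
            "t_s", "gaze_h_deg", "gaze_v_deg", "pupil_left_mm",
            "pupil_right_mm", "valid_left", "valid_right")))


@dataclass
class RRSeries:
    """R-peak times and RR intervals (seconds)."""

    r_peak_t_s: np.ndarray
    rr_s: np.ndarray

    def __post_init__(self):
        self.r_peak_t_s = np.asarray(self.r_peak_t_s, dtype=float)
        self.rr_s = np.asarray(self.rr_s, dtype=float)
        if self.r_peak_t_s.shape != self.rr_s.shape:
            raise ValueError("r_peak_t_s and rr_s must align")
        if np.any(self.rr_s <= 0):
            raise ValueError("rr_s must be positive")
        if len(self.r_peak_t_s) > 1 and not np.all(np.diff(self.r_peak_t_s) > 0):
            raise ValueError("peak times must be strictly increasing")


@dataclass
class Segment:
    """Labeled interval of a calibration recording."""

    start_s: float
    end_s: float
    kind: str  # horizontal | vertical | blink | rest


@dataclass
class MultimodalRecording:
    """Synchronized EEG + gaze/pupil + RR series + events, shared t=0."""

    eeg: ContinuousEEG
    gaze: GazePupilStream
    rr: RRSeries | None = None
    events: list[ParadigmEvent] = field(default_factory=list)
    segments: list[Segment] = field(default_factory=list)
    run_spans: dict[int, tuple[float, float]] = field(default_factory=dict)


@dataclass
class EpochSet:
    """Trials x channels x samples with labels on a common time axis."""

    data: np.ndarray          # (n_trials, n_channels, n_samples), µV
    labels: np.ndarray        # condition strings, one per trial
    t_axis: np.ndarray        # seconds relative to onset
    fs_hz: float
    channel_names: list[str]
    event_ids: np.ndarray     # stable trial identity across modalities
    kept_mask: np.ndarray = None
    rejection_log: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.event_ids = np.asarray(self.event_ids)
        if self.kept_mask is None:
            self.kept_mask = np.ones(len(self.labels), dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def kept(self) -> "EpochSet":
        """Return only the trials that survived rejection."""
        m = self.kept_mask
        return EpochSet(self.data[m], self.labels[m], self.t_axis, self.fs_hz,
                        list(self.channel_names), self.event_ids[m],
                        np.ones(int(m.sum()), dtype=bool), list(self.rejection_log))

    def select_trials(self, idx) -> "EpochSet":
        return EpochSet(self.data[idx], self.labels[idx], self.t_axis,
                        self.fs_hz, list(self.channel_names),
                        self.event_ids[idx], self.kept_mask[idx],
                        list(self.rejection_log))


@dataclass
class PupilEpochSet:
    """Baseline-corrected, eye-averaged pupil epochs (trials x samples, mm)."""

    data: np.ndarray
    labels: np.ndarray
    t_axis: np.ndarray
    fs_hz: float
    event_ids: np.ndarray
    kept_mask: np.ndarray = None
    rejection_log: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.event_ids = np.asarray(self.event_ids)
        if self.kept_mask is None:
            self.kept_mask = np.ones(len(self.labels), dtype=bool)
        self.kept_mask = np.asarray(self.kept_mask, dtype=bool)

    def kept(self) -> "PupilEpochSet":
        m = self.kept_mask
        return PupilEpochSet(self.data[m], self.labels[m], self.t_axis,
                             self.fs_hz, self.event_ids[m],
                             np.ones(int(m.sum()), dtype=bool),
                             list(self.rejection_log))

    def as_epochset(self, channel_name: str = "PUPIL") -> EpochSet:
        """View as a one-channel EpochSet (for the shared decoder path)."""
        return EpochSet(self.data[:, None, :], self.labels, self.t_axis,
                        self.fs_hz, [channel_name], self.event_ids,
                        self.kept_mask, list(self.rejection_log))


@dataclass
class HREpochSet:
    """Baseline-corrected heart-rate change epochs (trials x samples, bpm)."""

    data: np.ndarray
    labels: np.ndarray
    t_axis: np.ndarray
    fs_hz: float
    event_ids: np.ndarray
    rejection_log: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        self.event_ids = np.asarray(self.event_ids)


@dataclass
class ConfusionMatrix:
    """M x M counts; rows = true class, columns = predicted class."""

    counts: np.ndarray
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        m = len(self.class_order)
        if self.counts.shape != (m, m):
            raise ValueError("counts must be (M, M)")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_predictions(cls, y_true, y_pred,
                         class_order=CLASS_ORDER) -> "ConfusionMatrix":
        index = {c: i for i, c in enumerate(class_order)}
        m = len(class_order)
        counts = np.zeros((m, m), dtype=int)
        for t, p in zip(y_true, y_pred):
            counts[index[t], index[p]] += 1
        return cls(counts, tuple(class_order))

    def conditionals(self, smoothing: float = 1.0) -> np.ndarray:
        """P(true = i | predicted = j): column-normalized smoothed counts."""
        c = self.counts + smoothing
        return c / c.sum(axis=0, keepdims=True)


@dataclass
class DecodingResult:
    """Per-evaluation-time accuracies and confusions for one configuration."""

    times_s: np.ndarray          # evaluation times (window end), seconds
    accuracy: np.ndarray         # mean fraction correct per time
    confusion: np.ndarray        # (n_times, M, M) pooled test-fold counts
    class_order: tuple[str, ...] = CLASS_ORDER
    meta: dict = field(default_factory=dict)

    @property
    def peak_accuracy(self) -> float:
        return float(np.max(self.accuracy))

    @property
    def peak_time_s(self) -> float:
        return float(self.times_s[int(np.argmax(self.accuracy))])

    def mean_correct_post(self, t_start: float = 0.0, t_end: float = 1.0) -> float:
        """Mean fraction correct over evaluation times in [t_start, t_end]."""
        m = (self.times_s >= t_start - 1e-9) & (self.times_s <= t_end + 1e-9)
        if not m.any():
            raise ValueError("result does not cover the requested window")
        return float(np.mean(self.accuracy[m]))


@dataclass
class PFEModel:
    """Per-eye cubic pupil-foreshortening model (mm as a function of deg)."""

    coeffs_left: np.ndarray    # polynomial coefficients, ascending degree 0..3
    coeffs_right: np.ndarray
    center_deg: float = 0.0    # mean calibration gaze angle
    angle_range_deg: tuple[float, float] = (-30.0, 30.0)

    def __post_init__(self):
        self.coeffs_left = np.asarray(self.coeffs_left, dtype=float)
        self.coeffs_right = np.asarray(self.coeffs_right, dtype=float)
        for c in (self.coeffs_left, self.coeffs_right):
            if c.shape != (4,):
                raise ValueError("cubic model needs 4 coefficients per eye")

    def bias_mm(self, gaze_h_deg: np.ndarray, eye: str) -> np.ndarray:
        """Gaze-dependent pupil-size bias, zero at the calibration center.

        Only the gaze-dependent part of the cubic is returned; the constant
        term (true mean pupil size at the calibration center) is preserved in
        the data, since trial baselines remove absolute level later anyway.
        """
        c = self.coeffs_left if eye == "left" else self.coeffs_right
        g = np.asarray(gaze_h_deg, dtype=float)
        full = np.polynomial.polynomial.polyval(g, c)
        at_center = np.polynomial.polynomial.polyval(self.center_deg, c)
        return full - at_center
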