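"""Asynchronous sliding-window multiclass decoding of error processing.

Epochs are resampled to 32 Hz; a window of 1, 4, 8, or 16 samples slides
through each trial in steps of one sample (an output every 31.25 ms).  For
each window position a classifier is trained on the training folds of a
10x5 stratified cross-validation and evaluated on the test fold: features
are the raw amplitudes of the layout channels inside the window (C*W
values), z-scored per feature on the training folds, projected onto the
principal components explaining 99% of the training variance, and fed to a
four-class linear discriminant with analytic (Ledoit-Wolf) covariance
shrinkage — the standard "shrinkage LDA" of event-related potential
decoding.  An output at time t uses the window ending at t, so accuracy
rises only after the informative samples have entered the window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler

from .containers import CLASS_ORDER, DecodingResult, EpochSet

__all__ = [
    "DECODE_FS_HZ", "WINDOW_LENGTHS", "FoldPlan", "balance_classes",
    "make_folds", "resample_epochs", "TrainedWindowModel",
    "train_window_decoder", "sliding_predictions", "decode_sliding",
    "generic_decode", "peak_metrics",
]

DECODE_FS_HZ = 32.0
#: window lengths in samples at 32 Hz: 1 sample, 125 ms, 250 ms, 500 ms
WINDOW_LENGTHS: tuple[int, ...] = (1, 4, 8, 16)
PCA_VARIANCE = 0.99


def resample_epochs(epochs: EpochSet, fs_out: float = DECODE_FS_HZ) -> EpochSet:
    """Anti-aliased resampling of an epoch set to the decoding rate."""
    from fractions import Fraction
    from scipy.signal import resample_poly

    if abs(epochs.fs_hz - fs_out) < 1e-9:
        return epochs
    frac = Fraction(fs_out / epochs.fs_hz).limit_denominator(1000)
    data = resample_poly(epochs.data, frac.numerator, frac.denominator, axis=-1)
    n = data.shape[-1]
    t_axis = epochs.t_axis[0] + np.arange(n) / fs_out
    return EpochSet(data, epochs.labels, t_axis, fs_out,
                    list(epochs.channel_names), epochs.event_ids,
                    epochs.kept_mask, list(epochs.rejection_log))


def balance_classes(epochs: EpochSet, seed: int) -> EpochSet:
    """Subsample correct trials to the average error-class count.

    All error trials are kept; correct trials are drawn without replacement
    down to round(mean of the three error-class counts) (round half to
    even).  If fewer correct trials are available, all are kept and a
    warning is logged.
    """
    labels = epochs.labels
    err_counts = [int(np.sum(labels == c)) for c in CLASS_ORDER if c != "correct"]
    if min(err_counts) == 0 or not np.any(labels == "correct"):
        raise ValueError("all four classes must be present")
    target = int(np.round(np.mean(err_counts)))
    correct_idx = np.nonzero(labels == "correct")[0]
    rng = np.random.default_rng(seed)
    log = list(epochs.rejection_log)
    if len(correct_idx) < target:
        log.append(("balance", f"only {len(correct_idx)} correct trials "
                               f"available for target {target}"))
        chosen = correct_idx
    else:
        chosen = rng.choice(correct_idx, size=target, replace=False)
    keep = np.sort(np.concatenate([np.nonzero(labels != "correct")[0], chosen]))
    out = epochs.select_trials(keep)
    out.rejection_log = log
    return out


@dataclass(frozen=True)
class FoldPlan:
    """Stratified 10x5 cross-validation assignments: fold index per trial."""

    assignments: np.ndarray      # (repetitions, n_trials) of fold indices
    n_folds: int
    rng_seed: int

    @property
    def repetitions(self) -> int:
        return self.assignments.shape[0]

    def split(self):
        """Yield (rep, fold, train_idx, test_idx) over all 50 models."""
        for rep in range(self.repetitions):
            a = self.assignments[rep]
            for fold in range(self.n_folds):
                test = np.nonzero(a == fold)[0]
                train = np.nonzero(a != fold)[0]
                yield rep, fold, train, test


def make_folds(labels, seed: int, repetitions: int = 10,
               n_folds: int = 5) -> FoldPlan:
    """Build ``repetitions`` independent stratified n-fold partitions."""
    labels = np.asarray(labels)
    for c in np.unique(labels):
        if np.sum(labels == c) < n_folds:
            raise ValueError(f"class {c!r} has fewer than {n_folds} trials")
    assignments = np.empty((repetitions, len(labels)), dtype=int)
    for rep in range(repetitions):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=(seed * 101 + rep) % (2**31))
        for fold, (_, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            assignments[rep, test] = fold
    return FoldPlan(assignments, n_folds, seed)


# ---------------------------------------------------------------------------
# per-window model

def _encode(labels) -> np.ndarray:
    index = {c: i for i, c in enumerate(CLASS_ORDER)}
    return np.array([index[str(l)] for l in labels])


@dataclass
class TrainedWindowModel:
    """Standardization + 99%-variance projection + shrinkage discriminant."""

    scaler: StandardScaler
    pca: PCA
    lda: LinearDiscriminantAnalysis
    channels: list[str]
    window: int
    position: int                # index of the last window sample

    @property
    def n_components(self) -> int:
        return int(self.pca.n_components_)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return self.pca.transform(self.scaler.transform(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted class indices (ties broken toward the lowest index)."""
        scores = self.lda.decision_function(self.transform(X))
        if scores.ndim == 1:
            scores = np.column_stack([-scores, scores])
        classes = self.lda.classes_
        return classes[np.argmax(scores, axis=1)]


def _window_features(data: np.ndarray, ch_idx, position: int,
                     window: int) -> np.ndarray:
    """Flatten the (C, W) amplitude block ending at ``position``."""
    lo = position - window + 1
    return data[:, ch_idx, lo:position + 1].reshape(data.shape[0], -1)


def _fit_window(X: np.ndarray, y: np.ndarray, channels, window,
                position) -> TrainedWindowModel:
    if len(X) <= len(np.unique(y)):
        raise ValueError("fewer training trials than classes")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    n_comp = PCA_VARIANCE if min(Xs.shape) > 1 and Xs.shape[1] > 1 else None
    pca = PCA(n_components=n_comp, svd_solver="full").fit(Xs)
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    lda.fit(pca.transform(Xs), y)
    return TrainedWindowModel(scaler, pca, lda, list(channels), window, position)


def train_window_decoder(train_epochs: EpochSet, layout_channels,
                         window: int, position: int) -> TrainedWindowModel:
    """Fit one window model on (already resampled) training epochs."""
    n = train_epochs.data.shape[-1]
    if not (window - 1 <= position < n):
        raise ValueError("window does not fit at this position")
    ch_idx = [train_epochs.channel_names.index(c) for c in layout_channels]
    X = _window_features(train_epochs.data, ch_idx, position, window)
    return _fit_window(X, _encode(train_epochs.labels),
                       layout_channels, window, position)


# ---------------------------------------------------------------------------
# sliding evaluation

@dataclass
class SlidingPredictions:
    """Raw per-fold predictions at every window position.

    ``test_pred[(rep, fold)]`` and ``train_pred[(rep, fold)]`` are
    (n_positions, n_trials_in_set) arrays of class indices; the companion
    ``*_idx`` dicts give the trial indices.  This is the common substrate
    for accuracy traces, training-set confusion matrices, and fusion.
    """

    positions: np.ndarray
    times_s: np.ndarray
    y: np.ndarray
    test_idx: dict = field(default_factory=dict)
    test_pred: dict = field(default_factory=dict)
    train_idx: dict = field(default_factory=dict)
    train_pred: dict = field(default_factory=dict)


def sliding_predictions(epochs: EpochSet, layout_channels, window: int,
                        fold_plan: FoldPlan,
                        predict_train: bool = False) -> SlidingPredictions:
    """Train/test every fold at every window position."""
    data = epochs.data
    n = data.shape[-1]
    y = _encode(epochs.labels)
    ch_idx = [epochs.channel_names.index(c) for c in layout_channels]
    positions = np.arange(window - 1, n)
    out = SlidingPredictions(positions, epochs.t_axis[positions], y)

    feats = [_window_features(data, ch_idx, p, window) for p in positions]
    for rep, fold, train, test in fold_plan.split():
        te = np.empty((len(positions), len(test)), dtype=int)
        tr = (np.empty((len(positions), len(train)), dtype=int)
              if predict_train else None)
        for k in range(len(positions)):
            model = _fit_window(feats[k][train], y[train], layout_channels,
                                window, int(positions[k]))
            te[k] = model.predict(feats[k][test])
            if predict_train:
                tr[k] = model.predict(feats[k][train])
        out.test_idx[(rep, fold)] = test
        out.test_pred[(rep, fold)] = te
        if predict_train:
            out.train_idx[(rep, fold)] = train
            out.train_pred[(rep, fold)] = tr
    return out


def _result_from_predictions(sp: SlidingPredictions,
                             meta: dict) -> DecodingResult:
    n_pos = len(sp.positions)
    m = len(CLASS_ORDER)
    acc_folds = []
    confusion = np.zeros((n_pos, m, m), dtype=int)
    for key, test in sp.test_idx.items():
        pred = sp.test_pred[key]
        truth = sp.y[test]
        acc_folds.append((pred == truth[None, :]).mean(axis=1))
        for k in range(n_pos):
            np.add.at(confusion[k], (truth, pred[k]), 1)
    accuracy = np.mean(acc_folds, axis=0)
    return DecodingResult(sp.times_s, accuracy, confusion, CLASS_ORDER, meta)


def decode_sliding(epochs: EpochSet, layout_channels, window: int,
                   fold_plan: FoldPlan, meta: dict | None = None) -> DecodingResult:
    """Cross-validated accuracy trace for one layout/window configuration.

    Fold accuracies are averaged unweighted over the repetitions x folds
    models; the confusion tensor pools test-fold counts per evaluation time.
    """
    sp = sliding_predictions(epochs, layout_channels, window, fold_plan)
    return _result_from_predictions(sp, dict(meta or {},
                                             window=window,
                                             channels=tuple(layout_channels)))


def generic_decode(epoch_sets: list[EpochSet], window: int, seed: int,
                   channel: str = "PUPIL") -> list[DecodingResult]:
    """Leave-one-participant-out transfer decoding.

    For each held-out participant, the training pool is the concatenation
    of every other participant's class-balanced epochs; a window model is
    trained per position on the pool and evaluated on the held-out
    participant's balanced epochs.
    """
    if len(epoch_sets) < 3:
        raise ValueError("generic decoding needs at least 3 participants")
    balanced = [balance_classes(es.kept(), seed=(seed * 977 + i) % (2**31))
                for i, es in enumerate(epoch_sets)]
    n = balanced[0].data.shape[-1]
    positions = np.arange(window - 1, n)
    results = []
    for held in range(len(balanced)):
        train_sets = [b for i, b in enumerate(balanced) if i != held]
        Xtr_all = np.concatenate([b.data for b in train_sets])
        ytr = _encode(np.concatenate([b.labels for b in train_sets]))
        test = balanced[held]
        yte = _encode(test.labels)
        ch_idx = [test.channel_names.index(channel)]
        acc = np.empty(len(positions))
        m = len(CLASS_ORDER)
        confusion = np.zeros((len(positions), m, m), dtype=int)
        for k, p in enumerate(positions):
            Xtr = _window_features(Xtr_all, ch_idx, int(p), window)
            Xte = _window_features(test.data, ch_idx, int(p), window)
            model = _fit_window(Xtr, ytr, [channel], window, int(p))
            pred = model.predict(Xte)
            acc[k] = float(np.mean(pred == yte))
            np.add.at(confusion[k], (yte, pred), 1)
        results.append(DecodingResult(test.t_axis[positions], acc, confusion,
                                      CLASS_ORDER,
                                      {"held_out": held, "window": window,
                                       "mode": "generic"}))
    return results


def peak_metrics(result: DecodingResult) -> tuple[float, float, float]:
    """(peak accuracy, its time, mean fraction correct over [0, 1] s)."""
    return (result.peak_accuracy, result.peak_time_s,
            result.mean_correct_post(0.0, 1.0))
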