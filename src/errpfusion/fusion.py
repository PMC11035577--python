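"""Hybrid EEG + pupil decoding: simple fusion and Bayesian belief fusion.

Simple fusion (SF) treats the pupil trace as one extra data channel next to
the EEG layout channels; the shared decoder's per-feature standardization
gives both modalities zero mean and equal variance on the training folds
before projection.

Bayesian fusion (BF) combines the class predictions of the two unimodal
classifiers through their confusion matrices: with confusion counts
n_ij (true class i, predicted class j) estimated on the training folds,
the belief for class c_i given predictions e_1..e_K is

    O(c_i) ∝ P(c_i) * prod_k P(c_i | e_k = c_j),
    P(c_i | e_k = c_j) = n_ij / sum_i n_ij,

and the fused output is the class maximizing O.  Priors are uniform (the
classes are balanced by construction) and counts receive Laplace +1
smoothing before column normalization so that empty columns never produce
zero beliefs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .containers import CLASS_ORDER, ConfusionMatrix, DecodingResult, EpochSet
from .decoding import (DECODE_FS_HZ, FoldPlan, resample_epochs,
                       sliding_predictions)

__all__ = [
    "align_trials", "simple_fusion_features", "BayesianFusionModel",
    "estimate_confusions", "bayes_fuse", "bayes_fusion_decode",
]


def align_trials(eeg_epochs: EpochSet, pupil_epochs: EpochSet) -> tuple[EpochSet, EpochSet]:
    """Restrict both modalities to the events surviving both rejections."""
    e = eeg_epochs.kept()
    p = pupil_epochs.kept()
    common = np.intersect1d(e.event_ids, p.event_ids)
    if len(common) == 0:
        raise ValueError("no common trials between the modalities")
    ei = np.nonzero(np.isin(e.event_ids, common))[0]
    pi = np.nonzero(np.isin(p.event_ids, common))[0]
    ei = ei[np.argsort(e.event_ids[ei])]
    pi = pi[np.argsort(p.event_ids[pi])]
    return e.select_trials(ei), p.select_trials(pi)


def simple_fusion_features(eeg_epochs: EpochSet,
                           pupil_epochs: EpochSet) -> EpochSet:
    """Fused epoch set: EEG channels + the pupil trace as one more channel.

    Both inputs are aligned on their shared events and resampled to the
    32 Hz decoding rate; per-modality normalization happens later inside
    the decoder (per-feature z-scoring on the training folds).
    """
    e, p = align_trials(eeg_epochs, pupil_epochs)
    e = resample_epochs(e, DECODE_FS_HZ)
    p = resample_epochs(p, DECODE_FS_HZ)
    n = min(e.data.shape[-1], p.data.shape[-1])
    if not np.array_equal(e.labels, p.labels):
        raise ValueError("label mismatch after alignment")
    data = np.concatenate([e.data[:, :, :n], p.data[:, :, :n]], axis=1)
    return EpochSet(data, e.labels, e.t_axis[:n], DECODE_FS_HZ,
                    list(e.channel_names) + list(p.channel_names),
                    e.event_ids)


@dataclass
class BayesianFusionModel:
    """Per-classifier confusion matrices + priors + smoothing constant."""

    confusions: list                      # K ConfusionMatrix objects
    priors: np.ndarray = None             # (M,), defaults to uniform
    smoothing: float = 1.0
    class_order: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self):
        m = len(self.class_order)
        if self.priors is None:
            self.priors = np.full(m, 1.0 / m)
        self.priors = np.asarray(self.priors, dtype=float)
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")

    def conditionals(self) -> list[np.ndarray]:
        return [c.conditionals(self.smoothing) for c in self.confusions]


def estimate_confusions(sp, rep_fold: tuple[int, int],
                        position_index: int) -> ConfusionMatrix:
    """Confusion matrix of one fold's model at one evaluation position.

    Counts come from the model's predictions on its own training folds, as
    the cross-validation protocol prescribes; note this estimate is
    optimistically biased (the model has seen these trials).
    """
    train = sp.train_idx[rep_fold]
    pred = sp.train_pred[rep_fold][position_index]
    truth = sp.y[train]
    m = len(CLASS_ORDER)
    counts = np.zeros((m, m), dtype=int)
    np.add.at(counts, (truth, pred), 1)
    return ConfusionMatrix(counts, CLASS_ORDER)


def bayes_fuse(predictions, model: BayesianFusionModel) -> int:
    """Fused class index for one sample given K unimodal predictions."""
    conds = model.conditionals()
    o = model.priors.copy()
    for cond, e_k in zip(conds, predictions):
        o = o * cond[:, int(e_k)]
    return int(np.argmax(o))


def _fuse_batch(preds_per_clf, conds, priors) -> np.ndarray:
    """Vectorized fusion for arrays of predictions (one per classifier)."""
    o = np.tile(priors[:, None], (1, len(preds_per_clf[0])))
    for cond, pred in zip(conds, preds_per_clf):
        o *= cond[:, pred]
    return np.argmax(o, axis=0)


def bayes_fusion_decode(eeg_epochs: EpochSet, pupil_epochs: EpochSet,
                        layout_channels, window: int, fold_plan: FoldPlan,
                        smoothing: float = 1.0,
                        meta: dict | None = None) -> DecodingResult:
    """Cross-validated Bayesian fusion of the EEG and pupil classifiers.

    Both unimodal classifiers are trained on the same folds of the aligned
    trials; per fold and evaluation position, their training-fold confusion
    matrices define the conditionals through which the test-fold
    predictions are fused.
    """
    e, p = align_trials(eeg_epochs, pupil_epochs)
    e = resample_epochs(e, DECODE_FS_HZ)
    p = resample_epochs(p, DECODE_FS_HZ)
    n = min(e.data.shape[-1], p.data.shape[-1])

    sp_e = sliding_predictions(e, layout_channels, window, fold_plan,
                               predict_train=True)
    sp_p = sliding_predictions(p, [p.channel_names[0]], window, fold_plan,
                               predict_train=True)

    n_pos = min(len(sp_e.positions), len(sp_p.positions))
    m = len(CLASS_ORDER)
    priors = np.full(m, 1.0 / m)
    acc_folds = []
    confusion = np.zeros((n_pos, m, m), dtype=int)
    for key in sp_e.test_idx:
        test = sp_e.test_idx[key]
        truth = sp_e.y[test]
        acc = np.empty(n_pos)
        for k in range(n_pos):
            conds = [estimate_confusions(sp_e, key, k).conditionals(smoothing),
                     estimate_confusions(sp_p, key, k).conditionals(smoothing)]
            fused = _fuse_batch([sp_e.test_pred[key][k],
                                 sp_p.test_pred[key][k]], conds, priors)
            acc[k] = float(np.mean(fused == truth))
            np.add.at(confusion[k], (truth, fused), 1)
        acc_folds.append(acc)
    accuracy = np.mean(acc_folds, axis=0)
    return DecodingResult(sp_e.times_s[:n_pos], accuracy, confusion,
                          CLASS_ORDER, dict(meta or {}, window=window,
                                            mode="bf"))
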