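"""Significance thresholds and group statistics for the decoding analyses.

The chance-level threshold for an n-trial four-class problem is the
smallest achievable accuracy k/n whose upper-tail cumulative binomial
probability (success probability 1/c) does not exceed alpha.  Group
comparisons use paired Wilcoxon signed-rank tests with Benjamini-Hochberg
FDR correction, and Friedman omnibus tests across decoding methods with
Nemenyi post-hoc comparisons where the omnibus test is significant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .containers import HREpochSet, PupilEpochSet

__all__ = [
    "SignificanceSpec", "binomial_threshold", "average_threshold",
    "wilcoxon_paired", "fdr_adjust", "peak_response_tests",
    "samplewise_comparison", "compare_decoders", "friedman_nemenyi",
    "nemenyi_posthoc",
]

PUPIL_PEAK_WINDOW_S = (0.5, 0.8)
HR_DECEL_WINDOW_S = (0.7, 1.7)


@dataclass(frozen=True)
class SignificanceSpec:
    n_trials: int
    n_classes: int = 4
    alpha: float = 0.05

    def __post_init__(self):
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")


def binomial_threshold(spec: SignificanceSpec) -> float:
    """Smallest accuracy fraction significantly above chance.

    Returns k*/n where k* is the smallest correct-count with
    P(X >= k*) <= alpha under X ~ Binomial(n, 1/c).
    """
    n, p = spec.n_trials, 1.0 / spec.n_classes
    # P(X >= k) = sf(k - 1); find the smallest such k
    ks = np.arange(n + 1)
    tail = sps.binom.sf(ks - 1, n, p)
    ok = np.nonzero(tail <= spec.alpha)[0]
    if len(ok) == 0:
        return 1.0
    return float(ks[ok[0]]) / n


def average_threshold(trial_counts, n_classes: int = 4,
                      alpha: float = 0.05) -> float:
    """Mean of the per-participant thresholds for their trial counts."""
    return float(np.mean([
        binomial_threshold(SignificanceSpec(int(n), n_classes, alpha))
        for n in trial_counts]))


# ---------------------------------------------------------------------------
# basic tests

def wilcoxon_paired(x, y) -> tuple[float, float]:
    """Paired signed-rank test; (statistic, p).

    Identical samples (all differences zero) return p = 1: there is no
    evidence of a difference.  Exact null for small samples, normal
    approximation above n = 25.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    d = x - y
    if np.allclose(d, 0.0):
        return 0.0, 1.0
    method = "exact" if len(d) <= 25 else "approx"
    try:
        res = sps.wilcoxon(x, y, zero_method="wilcox", method=method)
    except ValueError:
        res = sps.wilcoxon(x, y, zero_method="wilcox", method="approx")
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# physiological peak-response comparisons

def _participant_peaks(epoch_sets, window_s, mode: str) -> pd.DataFrame:
    rows = []
    for pid, es in enumerate(epoch_sets):
        kept = es.kept() if hasattr(es, "kept") else es
        t = kept.t_axis
        m = (t >= window_s[0] - 1e-9) & (t <= window_s[1] + 1e-9)
        for c in np.unique(kept.labels):
            trace = kept.data[kept.labels == c].mean(axis=0)[m]
            val = trace.max() if mode == "max" else trace.min()
            rows.append({"participant": pid, "condition": str(c),
                         "peak": float(val)})
    return pd.DataFrame(rows)


def peak_response_tests(pupil_epoch_sets: list[PupilEpochSet],
                        hr_epoch_sets: list[HREpochSet],
                        alpha: float = 0.05) -> pd.DataFrame:
    """Error-vs-correct peak-response comparisons, FDR-corrected.

    Pupil: participant-level maxima of the condition-average dilation in
    [0.5, 0.8] s, each error condition paired against the correct-condition
    maximum.  Heart rate: minima in [0.7, 1.7] s, analogously.  FDR runs
    across the three conditions within each modality.
    """
    frames = []
    for modality, sets, window, mode in (
            ("pupil", pupil_epoch_sets, PUPIL_PEAK_WINDOW_S, "max"),
            ("hr", hr_epoch_sets, HR_DECEL_WINDOW_S, "min")):
        if not sets:
            continue
        peaks = _participant_peaks(sets, window, mode)
        wide = peaks.pivot(index="participant", columns="condition",
                           values="peak")
        rows = []
        for cond in ("target", "passive", "active"):
            if cond not in wide or "correct" not in wide:
                continue
            stat, p = wilcoxon_paired(wide[cond], wide["correct"])
            rows.append({"modality": modality, "contrast": f"{cond}_vs_correct",
                         "statistic": stat, "p_raw": p})
        df = pd.DataFrame(rows)
        df["p_fdr"] = fdr_adjust(df["p_raw"].to_numpy())
        df["significant"] = df["p_fdr"] < alpha
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# decoder comparisons

def samplewise_comparison(acc_a: np.ndarray, acc_b: np.ndarray,
                          times_s: np.ndarray,
                          alpha: float = 0.05) -> pd.DataFrame:
    """Per-evaluation-time paired signed-rank test between two methods.

    ``acc_a``/``acc_b`` are (n_participants, n_times) accuracy traces; FDR
    correction runs across evaluation times.
    """
    acc_a = np.asarray(acc_a)
    acc_b = np.asarray(acc_b)
    if acc_a.shape != acc_b.shape:
        raise ValueError("traces must be paired by participant and time")
    rows = []
    for k, t in enumerate(times_s):
        stat, p = wilcoxon_paired(acc_a[:, k], acc_b[:, k])
        rows.append({"time_s": float(t), "statistic": stat, "p_raw": p})
    df = pd.DataFrame(rows)
    df["p_fdr"] = fdr_adjust(df["p_raw"].to_numpy())
    df["significant"] = df["p_fdr"] < alpha
    return df


def compare_decoders(traces_per_method: dict, times_s: np.ndarray,
                     metrics_per_method: dict, alpha: float = 0.05) -> dict:
    """Full decoder comparison: sample-wise contrast + omnibus on metrics.

    ``traces_per_method`` maps method -> (n_participants, n_times) accuracy
    traces; the first two methods are contrasted sample-wise (signed-rank,
    FDR across times).  ``metrics_per_method`` maps method -> per-participant
    scalar metric (e.g. peak accuracy); all methods enter the Friedman
    omnibus with gated Nemenyi post-hoc comparisons.
    """
    methods = list(traces_per_method)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods")
    a, b = methods[:2]
    return {
        "samplewise": samplewise_comparison(traces_per_method[a],
                                            traces_per_method[b],
                                            times_s, alpha),
        "samplewise_contrast": (a, b),
        "omnibus": friedman_nemenyi(metrics_per_method, alpha),
    }


def nemenyi_posthoc(values: np.ndarray) -> np.ndarray:
    """Nemenyi all-pairs post-hoc p-values after a Friedman test.

    ``values`` is (n_participants, k_methods).  Mean within-participant
    ranks are compared with the studentized-range null:
    q = |R_i - R_j| / sqrt(k(k+1) / (12 n)), p = SF_q(q * sqrt(2); k, inf).
    """
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    ranks = sps.rankdata(values, axis=1).mean(axis=0)
    se = np.sqrt(k * (k + 1) / (12.0 * n))
    pmat = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(ranks[i] - ranks[j]) / se
            p = float(sps.studentized_range.sf(q * np.sqrt(2.0), k, np.inf))
            pmat[i, j] = pmat[j, i] = min(1.0, p)
    return pmat


def friedman_nemenyi(metric_per_method: dict, alpha: float = 0.05) -> dict:
    """Friedman omnibus across methods + gated Nemenyi post-hoc.

    ``metric_per_method`` maps method name -> per-participant metric array
    (paired).  Post-hoc p-values are computed only when the omnibus test is
    significant.
    """
    methods = list(metric_per_method)
    if len(methods) < 2:
        raise ValueError("need at least 2 methods")
    mat = np.column_stack([np.asarray(metric_per_method[m], dtype=float)
                           for m in methods])
    if np.allclose(mat, mat[:, :1]):
        stat, p = 0.0, 1.0
    elif mat.shape[1] == 2:
        # two methods: the omnibus reduces to a paired signed-rank test
        stat, p = wilcoxon_paired(mat[:, 0], mat[:, 1])
    else:
        stat, p = sps.friedmanchisquare(*(mat[:, j] for j in range(mat.shape[1])))
        stat, p = float(stat), float(p)
    out = {"methods": methods, "statistic": stat, "p": p, "posthoc": None}
    if p < alpha:
        pmat = nemenyi_posthoc(mat)
        out["posthoc"] = pd.DataFrame(pmat, index=methods, columns=methods)
    return out
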