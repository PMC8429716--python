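"""Evaluation scores for subclonal reconstruction and signature deconvolution.

Clustering side: score1b compares clone numbers, score1c is a Wasserstein
similarity between weighted CCF distributions, score2a compares binary
co-clustering matrices (Pearson, Matthews and V-measure, each rescaled
against the better of two degenerate baselines), and score2c scores the
clonal/subclonal classification.  Signature side: score_sig_1a/1b are
Euclidean distances between 96-type profiles, score_sig_1c scores presence
detection by AUC, score_sig_1d is per-SNV signature assignment accuracy,
and score_sig_1e summarizes per-SNV cosine distances between true and
reconstructed clone profiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import pearsonr, wasserstein_distance
from sklearn.metrics import (
    matthews_corrcoef,
    roc_auc_score,
    v_measure_score,
)

from .core import SignatureMatrix

_SCORE2A_MAX_N = 20_000


@dataclass
class ClusteringTruthPair:
    """True and predicted clone labels / CCFs per SNV."""

    true_labels: np.ndarray
    pred_labels: np.ndarray
    true_ccfs: np.ndarray  # per clone, indexed by label
    pred_ccfs: np.ndarray
    pred_clonal_prob: Optional[np.ndarray] = None  # P(SNV in max-CCF clone)

    def __post_init__(self) -> None:
        self.true_labels = np.asarray(self.true_labels, dtype=int)
        self.pred_labels = np.asarray(self.pred_labels, dtype=int)
        self.true_ccfs = np.asarray(self.true_ccfs, dtype=float)
        self.pred_ccfs = np.asarray(self.pred_ccfs, dtype=float)
        if self.true_labels.shape != self.pred_labels.shape:
            raise ValueError("label vectors must have equal length")


def score1b(J_true: int, J_pred: int) -> float:
    """Agreement of clone numbers:
    (J_true + 1 - min(J_true + 1, |J_pred - J_true|)) / (J_true + 1)."""
    if J_true < 1 or J_pred < 1:
        raise ValueError("clone counts must be >= 1")
    top = J_true + 1 - min(J_true + 1, abs(J_pred - J_true))
    return top / (J_true + 1)


def _clone_weights(labels: np.ndarray, n_clones: int) -> np.ndarray:
    counts = np.bincount(labels, minlength=n_clones).astype(float)
    return counts / counts.sum()


def score1c(pair: ClusteringTruthPair) -> float:
    """1 minus the Wasserstein distance between the weighted CCF
    point-mass distributions of truth and prediction."""
    w_true = _clone_weights(pair.true_labels, len(pair.true_ccfs))
    w_pred = _clone_weights(pair.pred_labels, len(pair.pred_ccfs))
    d = wasserstein_distance(
        pair.true_ccfs, pair.pred_ccfs, u_weights=w_true, v_weights=w_pred
    )
    return 1.0 - float(d)


def _co_clustering(labels: np.ndarray) -> np.ndarray:
    return (labels[:, None] == labels[None, :]).astype(float)


def _pearson_flat(a: np.ndarray, b: np.ndarray) -> float:
    # correlation against a constant vector is undefined; anchor it at 0
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(pearsonr(a, b).statistic)


def _score2a_raw(true_labels: np.ndarray, pred_labels: np.ndarray) -> np.ndarray:
    m_true = _co_clustering(true_labels).ravel()
    m_pred = _co_clustering(pred_labels).ravel()
    pcc = _pearson_flat(m_true, m_pred)
    mcc = float(matthews_corrcoef(m_true.astype(int), m_pred.astype(int)))
    vm = float(v_measure_score(true_labels, pred_labels))
    return np.array([pcc, mcc, vm])


def score2a(pair: ClusteringTruthPair) -> float:
    """Co-clustering agreement: mean of Pearson, Matthews and V-measure,
    each rescaled so that the better of the two degenerate baselines
    (all-in-one-cluster, all-singletons) maps to 0 and perfection to 1."""
    n = pair.true_labels.size
    if n > _SCORE2A_MAX_N:
        raise ValueError(
            f"score2a builds an N x N co-clustering matrix; N={n} exceeds "
            f"{_SCORE2A_MAX_N} - subsample the SNVs first"
        )
    raw = _score2a_raw(pair.true_labels, pair.pred_labels)
    one_cluster = _score2a_raw(pair.true_labels, np.zeros(n, dtype=int))
    singletons = _score2a_raw(pair.true_labels, np.arange(n))
    bad = np.minimum(one_cluster, singletons)
    rescaled = np.maximum(0.0, (raw - bad) / (1.0 - bad))
    return float(rescaled.mean())


@dataclass
class ClassificationScores:
    accuracy: float
    auc: Optional[float]
    sensitivity: float
    specificity: float


def _binary_scores(truth: np.ndarray, pred: np.ndarray, prob=None) -> ClassificationScores:
    tp = int(np.sum(truth & pred))
    tn = int(np.sum(~truth & ~pred))
    fp = int(np.sum(~truth & pred))
    fn = int(np.sum(truth & ~pred))
    accuracy = (tp + tn) / truth.size
    sensitivity = tp / (tp + fn) if (tp + fn) else float("nan")
    specificity = tn / (tn + fp) if (tn + fp) else float("nan")
    if truth.all() or not truth.any():
        auc = None
    else:
        score = prob if prob is not None else pred.astype(float)
        auc = float(roc_auc_score(truth, score))
    return ClassificationScores(accuracy, auc, sensitivity, specificity)


def score2c(pair: ClusteringTruthPair) -> ClassificationScores:
    """Clonal-vs-subclonal classification scores.

    An SNV is clonal when it belongs to the maximal-CCF clone of its side.
    AUC uses the predicted clonal-membership probability when available.
    """
    true_clonal = pair.true_labels == int(np.argmax(pair.true_ccfs))
    pred_clonal = pair.pred_labels == int(np.argmax(pair.pred_ccfs))
    return _binary_scores(true_clonal, pred_clonal, pair.pred_clonal_prob)


# ---------------------------------------------------------------------------
# signature-deconvolution scores


def score_sig_1a(
    empirical_type_counts: np.ndarray,
    estimated_activities: np.ndarray,
    sigs: SignatureMatrix,
) -> float:
    """Euclidean distance between the normalized empirical mutation-type
    counts and the activity-weighted signature mixture."""
    counts = np.asarray(empirical_type_counts, dtype=float)
    if counts.shape != (96,):
        raise ValueError("need a length-96 count vector")
    profile = counts / counts.sum()
    reconstructed = np.asarray(estimated_activities) @ sigs.mu
    return float(np.linalg.norm(profile - reconstructed))


def score_sig_1b(
    true_activities: np.ndarray,
    estimated_activities: np.ndarray,
    sigs: SignatureMatrix,
) -> float:
    """Euclidean distance between the true and estimated 96-type profiles
    (activity-weighted sums over signatures)."""
    a = np.asarray(true_activities) @ sigs.mu
    b = np.asarray(estimated_activities) @ sigs.mu
    return float(np.linalg.norm(a - b))


def signature_present(activities: np.ndarray, threshold: float = 0.95) -> np.ndarray:
    """Presence calls: signatures in decreasing activity order until the
    cumulative sum reaches the threshold (the crossing one included)."""
    activities = np.asarray(activities, dtype=float)
    order = np.argsort(-activities, kind="stable")
    cum = np.cumsum(activities[order])
    n_keep = int(np.searchsorted(cum, threshold - 1e-12) + 1)
    n_keep = min(n_keep, activities.size)
    present = np.zeros(activities.size, dtype=bool)
    present[order[:n_keep]] = True
    return present


def score_sig_1c(
    true_present: np.ndarray, estimated_activities: np.ndarray
) -> ClassificationScores:
    """Detection of present signatures: AUC of estimated activity as a score
    for true presence, plus threshold metrics via :func:`signature_present`."""
    truth = np.asarray(true_present, dtype=bool)
    est = np.asarray(estimated_activities, dtype=float)
    pred = signature_present(est)
    return _binary_scores(truth, pred, prob=est)


def score_sig_1d(true_sig_per_snv: np.ndarray, map_sig_per_snv: np.ndarray) -> float:
    """Fraction of SNVs whose MAP signature equals the generating one."""
    a = np.asarray(true_sig_per_snv)
    b = np.asarray(map_sig_per_snv)
    if a.shape != b.shape:
        raise ValueError("signature vectors must have equal length")
    return float(np.mean(a == b))


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 minus cosine similarity."""
    return float(1.0 - (a @ b) / (np.linalg.norm(a) * np.linalg.norm(b)))


@dataclass
class DistanceSummary:
    median: float
    min: float
    max: float
    std: float
    frac_below_005: float
    frac_below_01: float


def score_sig_1e(
    true_clone_per_snv: np.ndarray,
    pred_clone_per_snv: np.ndarray,
    true_pi: np.ndarray,
    pred_pi: np.ndarray,
    sigs: SignatureMatrix,
    pred_sigs: Optional[SignatureMatrix] = None,
) -> DistanceSummary:
    """Summary of per-SNV cosine distances between the mutation-type profile
    of the SNV's true clone and that of its predicted clone."""
    true_profiles = np.asarray(true_pi) @ sigs.mu
    pred_profiles = np.asarray(pred_pi) @ (pred_sigs or sigs).mu
    t = true_profiles[np.asarray(true_clone_per_snv, dtype=int)]
    p = pred_profiles[np.asarray(pred_clone_per_snv, dtype=int)]
    dots = np.einsum("ij,ij->i", t, p)
    dist = 1.0 - dots / (np.linalg.norm(t, axis=1) * np.linalg.norm(p, axis=1))
    return DistanceSummary(
        median=float(np.median(dist)),
        min=float(dist.min()),
        max=float(dist.max()),
        std=float(dist.std()),
        frac_below_005=float(np.mean(dist < 0.05)),
        frac_below_01=float(np.mean(dist < 0.1)),
    )


def sample_level_activities(xi: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Sample-level signature activities: clone-weight average of exposures."""
    return np.asarray(xi) @ np.asarray(pi)
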