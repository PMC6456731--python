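"""Clustering-quality metrics and per-cell uncertainty flags.

Agreement with a reference labelling is scored by the Hubert–Arabie adjusted
Rand index and by best-matched accuracy; stability under feature removal by
the average proportion of non-overlap (APN); cluster tightness by silhouette
width; assignment uncertainty by the posterior-probability threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.metrics import adjusted_rand_score, silhouette_samples

__all__ = [
    "EvaluationReport",
    "adjusted_rand_index",
    "matched_accuracy",
    "apn",
    "silhouette",
    "flag_vague_cells",
    "proportion_distances",
    "evaluate",
]


@dataclass
class EvaluationReport:
    ari: Optional[float] = None
    accuracy: Optional[float] = None
    apn: Optional[float] = None
    mean_silhouette: Optional[float] = None
    aic: Optional[float] = None
    bic: Optional[float] = None
    n_vague: Optional[int] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def _check_pair(a, b):
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    return a, b


def adjusted_rand_index(a, b) -> float:
    """Hubert–Arabie chance-corrected Rand agreement between two partitions;
    1 for identical partitions (up to renaming), ~0 for independent ones."""
    a, b = _check_pair(a, b)
    if a.size < 2:
        raise ValueError("need at least two observations")
    return float(adjusted_rand_score(a, b))


def matched_accuracy(pred, truth) -> float:
    """Fraction of correctly placed cells under the best one-to-one matching
    of predicted clusters to reference clusters (optimal assignment on the
    contingency table)."""
    pred, truth = _check_pair(pred, truth)
    pu, pi = np.unique(pred, return_inverse=True)
    tu, ti = np.unique(truth, return_inverse=True)
    m = np.zeros((pu.size, tu.size))
    np.add.at(m, (pi, ti), 1.0)
    rows, cols = linear_sum_assignment(m, maximize=True)
    return float(m[rows, cols].sum() / pred.size)


def apn(full_labels, reduced_labels: Sequence) -> float:
    """Average proportion of non-overlap between a reference clustering and
    clusterings of reduced data.

    For observation ``o`` and reduction ``r`` the score is
    ``1 - |C_full(o) ∩ C_r(o)| / |C_full(o)|`` where ``C(o)`` is the set of
    observations sharing ``o``'s cluster; APN averages over observations and
    reductions. 0 means perfectly stable.
    """
    full = np.asarray(full_labels)
    if len(reduced_labels) == 0:
        raise ValueError("need at least one reduced clustering")
    fu, fi = np.unique(full, return_inverse=True)
    n_full = np.bincount(fi).astype(float)
    total = 0.0
    for red in reduced_labels:
        red = np.asarray(red)
        if red.shape != full.shape:
            raise ValueError("reduced labelling length mismatch")
        ru, ri = np.unique(red, return_inverse=True)
        m = np.zeros((fu.size, ru.size))
        np.add.at(m, (fi, ri), 1.0)
        overlap = m[fi, ri] / n_full[fi]  # per-observation co-membership
        total += float(np.mean(1.0 - overlap))
    return total / len(reduced_labels)


def silhouette(labels, distances):
    """Per-observation silhouette widths and their mean from a precomputed
    symmetric distance matrix; singleton clusters score 0, and a single
    cluster overall yields all zeros with a warning."""
    labels = np.asarray(labels)
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] != labels.size:
        raise ValueError("distances must be a square matrix matching labels")
    if not np.allclose(d, d.T) or np.any(np.diag(d) != 0) or np.any(d < 0):
        raise ValueError("distances must be symmetric, non-negative, zero-diagonal")
    if np.unique(labels).size < 2:
        warnings.warn("single cluster: silhouette undefined, returning zeros")
        s = np.zeros(labels.size)
        return s, 0.0
    s = silhouette_samples(d, labels, metric="precomputed")
    return s, float(s.mean())


def proportion_distances(dataset) -> np.ndarray:
    """Pairwise Euclidean distances between per-cell gene-proportion vectors
    (the default silhouette space for count data)."""
    from scipy.spatial.distance import pdist, squareform

    x = dataset.pooled_counts().T.astype(float)
    t = np.maximum(x.sum(axis=1), 1.0)
    return squareform(pdist(x / t[:, None]))


def flag_vague_cells(posterior, threshold: float = 0.95) -> np.ndarray:
    """Cells whose largest posterior cluster probability is strictly below
    the threshold; such assignments are considered uncertain."""
    p = np.asarray(posterior, dtype=float)
    if p.ndim != 2:
        raise ValueError("posterior must be cells x K")
    if np.any(p < -1e-9) or not np.allclose(p.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("posterior rows must be probabilities summing to 1")
    return p.max(axis=1) < threshold


def evaluate(pred_labels, truth_labels=None, posterior=None,
             reduced_labels=None, distances=None,
             aic: Optional[float] = None, bic: Optional[float] = None,
             vague_threshold: float = 0.95) -> EvaluationReport:
    """Assemble an :class:`EvaluationReport` from whatever inputs are given."""
    report = EvaluationReport(aic=aic, bic=bic)
    pred = np.asarray(pred_labels)
    if truth_labels is not None:
        report.ari = adjusted_rand_index(pred, truth_labels)
        report.accuracy = matched_accuracy(pred, truth_labels)
    if reduced_labels is not None:
        report.apn = apn(pred, reduced_labels)
    if distances is not None:
        _, report.mean_silhouette = silhouette(pred, distances)
    if posterior is not None:
        report.n_vague = int(flag_vague_cells(posterior, vague_threshold).sum())
    return report
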