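"""Minimal-redundancy-maximal-relevance (mRMR) feature selection.

Relevance of a feature is its mutual information with the class label;
redundancy is its average mutual information with the features already
selected.  Greedy forward selection maximises, at each step, the difference

    I(x_j; c) - (1/|selected|) * sum_{x_s in selected} I(x_j; x_s)

(the MID form of the criterion).  Continuous features are discretised into
three states at mean +/- one population standard deviation before any mutual
information is computed, the convention of the original mRMR software.

Two selection outputs are kept distinct:

* :func:`mrmr_rank` — the greedy mRMR ranking (with scores at pick time);
* :func:`threshold_select` — columns whose *relevance alone* exceeds a
  threshold, in original column order, which is how the final feature subset
  of the pipeline is defined (the ranked list is diagnostic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .types import FeatureMatrix, StrandclassError

logger = logging.getLogger(__name__)


def discretize(column: np.ndarray) -> np.ndarray:
    """Discretise a numeric vector into 3 states at mean +/- population sigma.

    State 0: value <= mean - sigma; state 2: value >= mean + sigma; state 1
    otherwise.  Boundaries are inclusive so that a balanced two-valued column
    keeps its two states (its extremes sit exactly at mean +/- sigma); a
    constant column maps to the single state 1.  Deterministic.
    """
    column = np.asarray(column, dtype=float)
    if column.size < 2:
        raise StrandclassError("discretize needs at least 2 values")
    mean = column.mean()
    sigma = column.std()  # population sigma
    if sigma == 0:
        return np.ones(column.size, dtype=int)
    states = np.ones(column.size, dtype=int)
    states[column <= mean - sigma] = 0
    states[column >= mean + sigma] = 2
    return states


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information, in bits, of two integer state vectors.

    Computed from the empirical joint distribution; I(a; a) equals the
    empirical entropy of ``a`` and exactly independent empirical joints give 0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise StrandclassError(
            f"mutual_information: shape mismatch {a.shape} vs {b.shape}"
        )
    n = a.size
    if n < 2:
        raise StrandclassError("mutual_information needs at least 2 observations")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    joint = np.zeros((ai.max() + 1, bi.max() + 1))
    np.add.at(joint, (ai, bi), 1.0)
    joint /= n
    pa = joint.sum(axis=1, keepdims=True)
    pb = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    ratio = joint[mask] / (pa @ pb)[mask]
    return float(np.sum(joint[mask] * np.log2(ratio)))


def entropy(a: np.ndarray) -> float:
    """Empirical Shannon entropy in bits."""
    _, counts = np.unique(np.asarray(a), return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


@dataclass
class MRMRResult:
    """Greedy mRMR ranking over a feature matrix.

    ``ranked_columns[k]`` is the k-th pick; ``relevance`` maps every scored
    column to I(x_i; c); ``mrmr_score`` records the selection criterion value
    at the moment each ranked column was picked (for the first pick this is
    its relevance).
    """

    ranked_columns: List[str]
    relevance: Dict[str, float]
    mrmr_score: Dict[str, float]


def _discretized_columns(matrix: FeatureMatrix) -> np.ndarray:
    return np.stack(
        [discretize(matrix.values[:, j]) for j in range(matrix.n_columns)], axis=1
    )


def relevance_scores(matrix: FeatureMatrix) -> Dict[str, float]:
    """I(x_i; c) for every column, after 3-state discretisation."""
    y = matrix.y()
    if len(set(y.tolist())) < 2:
        raise StrandclassError("relevance needs both classes present")
    disc = _discretized_columns(matrix)
    return {
        col: mutual_information(disc[:, j], y)
        for j, col in enumerate(matrix.columns)
    }


def mrmr_rank(matrix: FeatureMatrix, k: int) -> MRMRResult:
    """Rank ``k`` columns by greedy mRMR forward selection.

    The first pick maximises relevance; each later pick maximises
    relevance minus mean mutual information with the already-selected set.
    Ties break toward the lower column index.
    """
    if k < 1 or k > matrix.n_columns:
        raise StrandclassError(
            f"k must be in 1..{matrix.n_columns}, got {k}"
        )
    y = matrix.y()
    if len(set(y.tolist())) < 2:
        raise StrandclassError("mRMR needs both classes present in the labels")
    disc = _discretized_columns(matrix)
    p = matrix.n_columns
    rel = np.array([mutual_information(disc[:, j], y) for j in range(p)])

    selected: List[int] = []
    scores: Dict[str, float] = {}
    # pairwise MI with selected columns, filled lazily
    redundancy_sum = np.zeros(p)
    remaining = list(range(p))
    for _ in range(k):
        if not selected:
            crit = rel.copy()
        else:
            crit = rel - redundancy_sum / len(selected)
        best = None
        best_val = -np.inf
        for j in remaining:
            v = crit[j]
            if v > best_val:  # strict: exact ties keep the lower column index
                best, best_val = j, v
        assert best is not None
        selected.append(best)
        remaining.remove(best)
        scores[matrix.columns[best]] = float(best_val)
        for j in remaining:
            redundancy_sum[j] += mutual_information(disc[:, j], disc[:, best])

    return MRMRResult(
        ranked_columns=[matrix.columns[j] for j in selected],
        relevance={matrix.columns[j]: float(rel[j]) for j in range(p)},
        mrmr_score=scores,
    )


@dataclass
class ThresholdSelection:
    """Result of relevance thresholding: the filtered matrix plus the
    (threshold, retained-count) pair used for sweep plots."""

    matrix: FeatureMatrix
    threshold: float
    retained: int
    relevance: Dict[str, float]


def threshold_select(
    matrix: FeatureMatrix,
    threshold: float,
    relevance: Optional[Dict[str, float]] = None,
) -> ThresholdSelection:
    """Keep exactly the columns whose relevance I(x_i; c) exceeds ``threshold``,
    preserving original column order.  An empty result is allowed (logged)."""
    if threshold < 0:
        raise StrandclassError(f"threshold must be >= 0, got {threshold}")
    rel = relevance if relevance is not None else relevance_scores(matrix)
    keep = [c for c in matrix.columns if rel[c] > threshold]
    if not keep:
        logger.warning(
            "relevance threshold %g retains no columns (max relevance %g)",
            threshold,
            max(rel.values()) if rel else float("nan"),
        )
    sub = matrix.subset_columns(keep)
    return ThresholdSelection(
        matrix=sub, threshold=threshold, retained=len(keep), relevance=dict(rel)
    )


def threshold_sweep(
    matrix: FeatureMatrix, thresholds: Sequence[float]
) -> List[Tuple[float, int]]:
    """Retained-column counts across a threshold grid (one relevance pass)."""
    rel = relevance_scores(matrix)
    return [
        (float(t), sum(1 for v in rel.values() if v > t)) for t in thresholds
    ]
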