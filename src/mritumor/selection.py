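"""Entropy-based controlled feature selection.

Each feature column gets a Shannon entropy from a 10-bin equal-width
histogram of its min-max-normalized values: high entropy means the
feature spreads its values (informative), near-zero entropy means it is
almost constant. Features are then ranked greedily, seeded by the
max-entropy column; every subsequent candidate is scored by

    score = min(d_curr, d_prev) * entropy

where d_curr is the Euclidean distance between the standardized candidate
and the most recently ranked column and d_prev the minimum distance to
all earlier ranked columns, so an exact duplicate of anything already
ranked scores 0. A threshold T (the score of the lowest-entropy feature,
or a score quantile) decides which ranked features are kept: the seed
always, then every feature whose score strictly exceeds T, in ranking
order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .texture import FeatureTable

__all__ = ["FeatureScore", "SelectionResult", "feature_entropy", "select_features"]


@dataclass
class FeatureScore:
    index: int
    name: str
    entropy: float
    d_prev: float
    d_curr: float
    weight: float
    score: float


@dataclass
class SelectionResult:
    kept: list[int]
    kept_names: list[str]
    threshold: float
    scores: list[FeatureScore] = field(default_factory=list)


def feature_entropy(values: np.ndarray, bins: int = 10) -> tuple[np.ndarray, float]:
    """Histogram probabilities and Shannon entropy (bits) of one column.

    The column is min-max normalized and binned into ``bins`` equal-width
    bins on [0, 1]; a constant column has entropy 0.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        p = np.zeros(bins)
        p[0] = 1.0
        return p, 0.0
    u = (v - lo) / (hi - lo)
    counts, _ = np.histogram(u, bins=bins, range=(0.0, 1.0))
    p = counts / counts.sum()
    nz = p > 0
    return p, float(-np.sum(p[nz] * np.log2(p[nz])))


def _standardize(col: np.ndarray) -> np.ndarray:
    mu, sd = col.mean(), col.std()
    return (col - mu) / sd if sd > 0 else np.zeros_like(col)


def select_features(
    table: FeatureTable,
    bins: int = 10,
    threshold_mode: str = "max_prob",
    threshold_param: float = 0.5,
) -> SelectionResult:
    """Greedy entropy/redundancy feature selection.

    ``max_prob`` sets the threshold to the score of the single
    lowest-entropy (highest-probability-mass) feature; ``quantile`` uses
    the ``threshold_param`` quantile of all scores. Deterministic; ties
    resolve to the lower column index.
    """
    if threshold_mode not in ("max_prob", "quantile"):
        raise ValueError(f"unknown threshold_mode: {threshold_mode!r}")
    X = table.data.to_numpy(dtype=float)
    names = table.feature_names
    n, d = X.shape
    if d == 0:
        raise ValueError("feature table has no feature columns")

    entropies = np.array([feature_entropy(X[:, j], bins)[1] for j in range(d)])
    if np.all(entropies == 0):
        warnings.warn("all features are constant; keeping the first column")
        score = FeatureScore(0, names[0], 0.0, 0.0, 0.0, 1.0, 0.0)
        return SelectionResult([0], [names[0]], 0.0, [score])

    Z = np.column_stack([_standardize(X[:, j]) for j in range(d)])

    seed = int(np.argmax(entropies))
    ranked = [seed]
    scores: dict[int, FeatureScore] = {
        seed: FeatureScore(seed, names[seed], float(entropies[seed]),
                           0.0, 0.0, 1.0, float(entropies[seed]))
    }
    remaining = [j for j in range(d) if j != seed]
    while remaining:
        last = ranked[-1]
        earlier = ranked[:-1]
        best_j, best = None, None
        for j in remaining:
            d_curr = float(np.linalg.norm(Z[:, j] - Z[:, last]))
            if earlier:
                d_prev = min(
                    float(np.linalg.norm(Z[:, j] - Z[:, e])) for e in earlier
                )
            else:
                d_prev = d_curr
            w = min(d_curr, d_prev)
            sc = FeatureScore(j, names[j], float(entropies[j]),
                              d_prev, d_curr, w, w * float(entropies[j]))
            if best is None or sc.score > best.score:
                best_j, best = j, sc
        ranked.append(best_j)
        scores[best_j] = best
        remaining.remove(best_j)

    all_scores = [scores[j] for j in ranked]
    if threshold_mode == "max_prob":
        low = int(np.argmin(entropies))
        threshold = scores[low].score
    else:
        threshold = float(
            np.quantile([s.score for s in all_scores], threshold_param)
        )

    kept = [seed] + [j for j in ranked[1:] if scores[j].score > threshold]
    return SelectionResult(
        kept=kept,
        kept_names=[names[j] for j in kept],
        threshold=threshold,
        scores=all_scores,
    )
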