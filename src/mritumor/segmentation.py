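"""Fuzzy c-means segmentation with optional spatial regularization.

The segmenter clusters pixel intensities with fuzzy c-means (FCM): each
pixel l holds memberships s_kl in [0, 1] over the c clusters, summing to
1, and centroids T_k are membership-weighted means. The "improved"
variant adds two pieces on top of plain FCM:

* a histogram-driven initialization built from a gray-level co-occurrence
  matrix I of the quantized image and a coarse feature map F_xy (a
  frequency-weighted local maximum of the image), from which the initial
  centroids are the c most frequent gray-level midpoints; and
* a spatial regularizer applied to the membership matrix each iteration:
  s'_kl ∝ s_kl^p * h_kl^q, where h_kl is the mean membership of cluster k
  over a small window around pixel l, renormalized so columns sum to 1.
  Neighbourhood agreement thus pulls isolated noisy pixels toward the
  label of their surroundings.

Iteration alternates membership and centroid updates until the maximum
elementwise membership change drops to eps. A plain K-means baseline is
provided for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .image_io import GrayImage, quantize

__all__ = [
    "SegmentationConfig",
    "InitContext",
    "FuzzyPartition",
    "LabelMap",
    "build_init_context",
    "update_membership",
    "update_centroids",
    "spatial_regularize",
    "weighted_objective",
    "segment",
    "extract_tumor_mask",
    "kmeans_baseline",
]


@dataclass
class SegmentationConfig:
    """Knobs of the fuzzy segmenter.

    c            number of clusters
    m            fuzzifier (> 1); m -> 1 approaches hard K-means
    eps          convergence tolerance on the max membership change, (0, 1]
    max_iter     iteration cap
    spatial_enabled / spatial_p / spatial_q / window
                 membership-neighbourhood regularizer s^p * h^q over an
                 odd window
    W            gray levels used by the histogram initialization
    init         "histogram" (co-occurrence marginal modes), "kmeans"
                 (hard K-means centers, robust when a tissue intensity
                 sits on a quantization bin edge) or "random"
    init_centroids  explicit initial centroids (overrides init)
    seed         RNG seed for random initialization
    """

    c: int = 3
    m: float = 2.0
    eps: float = 1e-3
    max_iter: int = 200
    spatial_enabled: bool = False
    spatial_p: float = 1.0
    spatial_q: float = 1.0
    window: int = 3
    W: int = 8
    init: str = "histogram"
    init_centroids: np.ndarray | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.c < 1:
            raise ValueError("c must be >= 1")
        if not self.m > 1:
            raise ValueError("fuzzifier m must exceed 1")
        if not (0 < self.eps <= 1):
            raise ValueError("eps must lie in (0, 1]")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.spatial_p < 0 or self.spatial_q < 0:
            raise ValueError("spatial exponents must be non-negative")
        if self.init not in ("histogram", "kmeans", "random"):
            raise ValueError(f"unknown init mode: {self.init!r}")


@dataclass
class InitContext:
    """State of the histogram-driven initialization."""

    I: np.ndarray  # W x W co-occurrence counts over the 4-neighborhood
    coarse: np.ndarray  # coarse feature map F_xy, same shape as the image
    centroids0: np.ndarray  # length-c initial centers in [0, 1]


@dataclass
class FuzzyPartition:
    membership: np.ndarray  # c x n, columns sum to 1
    centroids: np.ndarray  # length c
    objective_trace: list[float] = field(default_factory=list)
    iterations: int = 0
    converged: bool = False
    # worst per-pixel deviation of the membership column sum from 1,
    # tracked across every iteration (diagnostic invariant)
    max_colsum_err: float = 0.0


@dataclass
class LabelMap:
    labels: np.ndarray  # 2-D int array in [0, c-1]
    cluster_order: np.ndarray  # cluster indices sorted by ascending centroid


def build_init_context(
    img: GrayImage, W: int = 8, window: int = 3, c: int = 3
) -> InitContext:
    """Build the co-occurrence matrix, coarse map and initial centroids.

    I counts ordered pairs of quantized levels over the 4-neighborhood.
    The coarse map is a window local maximum of the image weighted by the
    relative marginal frequency of each pixel's level in I. Initial
    centroids are the midpoints of the c most frequent levels of I's
    marginal, sorted ascending; if fewer than c levels occur, the list is
    padded with evenly spaced image quantiles.
    """
    if W < 2:
        raise ValueError("W must be at least 2")
    q = quantize(img, W).levels
    I = np.zeros((W, W), dtype=np.int64)
    # ordered pairs for the right and down neighbors plus their reverses
    for a, b in (
        (q[:, :-1], q[:, 1:]),
        (q[:-1, :], q[1:, :]),
    ):
        np.add.at(I, (a.ravel(), b.ravel()), 1)
        np.add.at(I, (b.ravel(), a.ravel()), 1)

    marginal = I.sum(axis=1).astype(float)
    total = marginal.sum()
    freq = marginal / total if total > 0 else marginal
    wmap = freq[q]
    coarse = ndimage.maximum_filter(img.pixels * wmap, size=window, mode="nearest")

    order = np.argsort(marginal, kind="stable")[::-1]
    present = [k for k in order if marginal[k] > 0][:c]
    centers = [(k + 0.5) / W for k in present]
    if len(centers) < c:
        pad = np.quantile(img.pixels, np.linspace(0.1, 0.9, c - len(centers)))
        centers.extend(float(v) for v in pad)
    return InitContext(I=I, coarse=coarse, centroids0=np.sort(np.asarray(centers)))


def update_membership(x: np.ndarray, centroids: np.ndarray, m: float) -> np.ndarray:
    """Standard FCM membership update s_kl = 1 / sum_j (d_kl/d_jl)^(2/(m-1)).

    Pixels at zero distance from one or more centroids get membership
    split equally among those centroids (1 for a unique closest).
    """
    x = np.asarray(x, float).ravel()
    T = np.asarray(centroids, float).reshape(-1, 1)
    d = np.abs(x[None, :] - T)  # c x n
    zero = d == 0.0
    any_zero = zero.any(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d ** (-2.0 / (m - 1.0))
        s = inv / inv.sum(axis=0, keepdims=True)
    if any_zero.any():
        cols = np.where(any_zero)[0]
        s[:, cols] = zero[:, cols] / zero[:, cols].sum(axis=0, keepdims=True)
    return s


def update_centroids(
    x: np.ndarray,
    membership: np.ndarray,
    m: float,
    prev: np.ndarray | None = None,
) -> np.ndarray:
    """FCM center update T_k = sum_l s_kl^m x_l / sum_l s_kl^m."""
    x = np.asarray(x, float).ravel()
    w = membership**m
    denom = w.sum(axis=1)
    T = np.empty(membership.shape[0])
    dead = denom == 0.0
    safe = ~dead
    T[safe] = (w[safe] @ x) / denom[safe]
    if dead.any():
        if prev is None:
            raise ValueError("all-zero membership row with no previous centroid")
        warnings.warn("cluster with all-zero membership kept at previous centroid")
        T[dead] = np.asarray(prev, float)[dead]
    return T


def spatial_regularize(
    membership: np.ndarray,
    labels_shape: tuple[int, int],
    window: int = 3,
    p: float = 1.0,
    q: float = 1.0,
) -> np.ndarray:
    """Reweight memberships by local membership agreement: s' ∝ s^p h^q.

    h_kl is the mean membership of cluster k over the window centred on
    pixel l (reflect boundary). Columns are renormalized to sum to 1.
    """
    c = membership.shape[0]
    h = np.empty_like(membership)
    for k in range(c):
        grid = membership[k].reshape(labels_shape)
        h[k] = ndimage.uniform_filter(grid, size=window, mode="reflect").ravel()
    out = membership**p * h**q
    colsum = out.sum(axis=0, keepdims=True)
    bad = colsum[0] == 0.0
    if bad.any():
        out[:, bad] = 1.0 / c
        colsum = out.sum(axis=0, keepdims=True)
    return out / colsum


def weighted_objective(
    x: np.ndarray,
    membership: np.ndarray,
    centroids: np.ndarray,
    m: float,
    spatial_penalty: float = 0.0,
) -> float:
    """Weighted within-cluster objective (1/2) sum_kl s_kl^m (x_l - T_k)^2."""
    x = np.asarray(x, float).ravel()
    d2 = (x[None, :] - np.asarray(centroids, float)[:, None]) ** 2
    return 0.5 * float(np.sum(membership**m * d2)) + spatial_penalty


def _initial_centroids(img: GrayImage, cfg: SegmentationConfig) -> np.ndarray:
    if cfg.init_centroids is not None:
        T0 = np.asarray(cfg.init_centroids, float)
        if T0.size != cfg.c:
            raise ValueError("init_centroids length must equal c")
        return T0
    if cfg.init == "random":
        rng = np.random.default_rng(cfg.seed)
        lo, hi = float(img.pixels.min()), float(img.pixels.max())
        return np.sort(rng.uniform(lo, hi, size=cfg.c))
    if cfg.init == "kmeans":
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=cfg.c, n_init=10, random_state=cfg.seed)
        km.fit(img.pixels.reshape(-1, 1))
        return np.sort(km.cluster_centers_.ravel())
    ctx = build_init_context(img, W=cfg.W, window=cfg.window, c=cfg.c)
    return ctx.centroids0


def segment(img: GrayImage, cfg: SegmentationConfig) -> tuple[FuzzyPartition, LabelMap]:
    """Run the fuzzy segmenter on pixel intensities.

    Each iteration recomputes centroids from the current (optionally
    spatially regularized) membership, then the membership from the new
    centroids; convergence is max elementwise membership change <= eps.
    Deterministic given the config seed. If max_iter is reached without
    convergence the partition is returned with ``converged=False`` and a
    warning, not an exception.
    """
    cfg.validate()
    x = img.pixels.ravel()
    shape = img.pixels.shape
    T = _initial_centroids(img, cfg)

    def memb(T: np.ndarray) -> np.ndarray:
        s = update_membership(x, T, cfg.m)
        if cfg.spatial_enabled:
            s = spatial_regularize(s, shape, cfg.window, cfg.spatial_p, cfg.spatial_q)
        return s

    s = memb(T)
    trace: list[float] = []
    converged = False
    iterations = 0
    colsum_err = float(np.max(np.abs(s.sum(axis=0) - 1.0)))
    for v in range(1, cfg.max_iter + 1):
        T = update_centroids(x, s, cfg.m, prev=T)
        trace.append(weighted_objective(x, s, T, cfg.m))
        s_new = memb(T)
        colsum_err = max(colsum_err, float(np.max(np.abs(s_new.sum(axis=0) - 1.0))))
        iterations = v
        if np.max(np.abs(s_new - s)) <= cfg.eps:
            s = s_new
            converged = True
            break
        s = s_new
    if not converged:
        warnings.warn(f"segmentation did not converge in {cfg.max_iter} iterations")

    part = FuzzyPartition(
        membership=s,
        centroids=T,
        objective_trace=trace,
        iterations=iterations,
        converged=converged,
        max_colsum_err=colsum_err,
    )
    labels = np.argmax(s, axis=0).reshape(shape)  # ties -> lower cluster index
    lmap = LabelMap(labels=labels, cluster_order=np.argsort(T, kind="stable"))
    return part, lmap


def extract_tumor_mask(
    labelmap: LabelMap,
    partition: FuzzyPartition,
    rule: str = "brightest",
) -> np.ndarray:
    """Pick the tumor cluster from a partition and return its binary mask.

    ``brightest`` takes the cluster with the highest centroid (tumors are
    hyperintense on the target sequences); ``largest_nonbackground``
    takes the largest connected component among pixels outside the
    lowest-centroid cluster. A warning is emitted when the mask covers
    more than half of the image (no distinct bright cluster).
    """
    c = partition.centroids.size
    if c < 2:
        raise ValueError("tumor extraction requires at least 2 clusters")
    if rule == "brightest":
        k = int(np.argmax(partition.centroids))
        mask = labelmap.labels == k
    elif rule == "largest_nonbackground":
        bg = int(np.argmin(partition.centroids))
        fg = labelmap.labels != bg
        comp, ncomp = ndimage.label(fg)
        if ncomp == 0:
            mask = np.zeros_like(fg)
        else:
            sizes = ndimage.sum_labels(fg, comp, index=np.arange(1, ncomp + 1))
            mask = comp == (1 + int(np.argmax(sizes)))
    else:
        raise ValueError(f"unknown tumor rule: {rule!r}")
    if mask.mean() > 0.5:
        warnings.warn("tumor mask covers more than half the image")
    return mask.astype(bool)


def kmeans_baseline(img: GrayImage, c: int, seed: int = 0) -> LabelMap:
    """Hard K-means on intensities (Lloyd iterations), for comparison."""
    from sklearn.cluster import KMeans

    x = img.pixels.reshape(-1, 1)
    km = KMeans(n_clusters=c, n_init=10, random_state=seed).fit(x)
    labels = km.labels_.reshape(img.pixels.shape)
    centers = km.cluster_centers_.ravel()
    return LabelMap(labels=labels, cluster_order=np.argsort(centers, kind="stable"))
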