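"""First-order, co-occurrence (GLCM), neighborhood-difference (NGTDM) and
shape descriptors over a region of interest.

All texture features operate on the W-level quantized image. First-order
features come from the gray-level histogram; GLCM features from the
normalized co-occurrence matrix averaged over the four distance-1 Haralick
directions; busyness and strength from the neighborhood gray-tone
difference matrix (per level i: s_i sums |i - neighborhood mean| over the
pixels of that level). Shape descriptors are computed on the largest
connected component of a binary mask. No randomness anywhere: feature
extraction is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import ndimage

from .image_io import GrayImage, QuantizedImage, quantize

__all__ = [
    "GrayHistogram",
    "GLCMatrix",
    "NGTDMatrix",
    "FeatureVector",
    "FeatureTable",
    "DEFAULT_OFFSETS",
    "histogram",
    "first_order_features",
    "glcm",
    "glcm_features",
    "ngtdm",
    "ngtdm_features",
    "shape_features",
    "extract_features",
]

# distance-1 offsets at 0, 45, 90, 135 degrees, (drow, dcol)
DEFAULT_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))


@dataclass
class GrayHistogram:
    p: np.ndarray  # length-W probability vector
    W: int
    mean: float  # k-bar
    sd: float  # S


@dataclass
class GLCMatrix:
    P: np.ndarray  # W x W, normalized joint probabilities
    offsets: tuple[tuple[int, int], ...]
    symmetric: bool
    normalized: bool
    marginal_mean: float  # M
    marginal_sd: float  # S4


@dataclass
class NGTDMatrix:
    s: np.ndarray  # per-level neighborhood-difference sums s_i
    p: np.ndarray  # per-level probabilities p_i
    present: np.ndarray  # bool, levels occurring in the region


@dataclass
class FeatureVector:
    """The named feature set of one sample (one image/ROI)."""

    sd: float
    skewness: float
    kurtosis: float
    energy_hist: float
    entropy_hist: float
    glcm_contrast: float
    glcm_correlation: float
    glcm_homogeneity: float
    glcm_energy: float
    ngtdm_busyness: float
    ngtdm_strength: float
    shape_area: float
    shape_perimeter: float
    shape_eccentricity: float
    shape_solidity: float
    roi_pixels: int

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @staticmethod
    def names() -> list[str]:
        return [f.name for f in fields(FeatureVector) if f.name != "roi_pixels"]


@dataclass
class FeatureTable:
    """samples x features matrix with class labels; CSV round-trippable."""

    data: pd.DataFrame  # feature columns only
    labels: pd.Series

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out["label"] = self.labels.values
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ValueError("feature CSV must contain a 'label' column")
        return cls(data=df.drop(columns=["label"]), labels=df["label"])

    @classmethod
    def from_vectors(
        cls, vectors: list[FeatureVector], labels: list[str]
    ) -> "FeatureTable":
        df = pd.DataFrame([v.to_dict() for v in vectors])
        df = df.drop(columns=["roi_pixels"])
        return cls(data=df, labels=pd.Series(labels))


def _levels_in_roi(q: QuantizedImage, mask: np.ndarray | None) -> np.ndarray:
    lv = q.levels if mask is None else q.levels[mask]
    if lv.size == 0:
        raise ValueError("empty region of interest")
    return np.asarray(lv).ravel()


def histogram(q: QuantizedImage, mask: np.ndarray | None = None) -> GrayHistogram:
    """Gray-level probability histogram p(k) over the ROI."""
    lv = _levels_in_roi(q, mask)
    counts = np.bincount(lv, minlength=q.W).astype(float)
    p = counts / counts.sum()
    k = np.arange(q.W)
    mean = float(np.sum(k * p))
    sd = float(np.sqrt(np.sum((k - mean) ** 2 * p)))
    return GrayHistogram(p=p, W=q.W, mean=mean, sd=sd)


def first_order_features(h: GrayHistogram) -> dict[str, float]:
    """sd, skewness, kurtosis, energy and entropy of the level histogram.

    skewness = (1/S^3) sum (k - kbar)^3 p(k); kurtosis the fourth-power
    analogue (not excess); entropy in bits with 0 log 0 := 0. Skewness
    and kurtosis are 0 by convention when S = 0.
    """
    k = np.arange(h.W)
    d = k - h.mean
    p = h.p
    sd = h.sd
    if sd > 0:
        skew = float(np.sum(d**3 * p) / sd**3)
        kurt = float(np.sum(d**4 * p) / sd**4)
    else:
        skew = kurt = 0.0
    nz = p > 0
    entropy = float(-np.sum(p[nz] * np.log2(p[nz])))
    energy = float(np.sum(p**2))
    return {
        "sd": sd,
        "skewness": skew,
        "kurtosis": kurt,
        "energy_hist": energy,
        "entropy_hist": entropy,
    }


def glcm(
    q: QuantizedImage,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    symmetric: bool = True,
    normalize: bool = True,
    mask: np.ndarray | None = None,
) -> GLCMatrix:
    """Co-occurrence matrix of level pairs, averaged over offsets.

    Pairs are counted where both pixels fall inside the image (and the
    mask, when given); ``symmetric`` adds the transpose; each offset
    matrix is normalized before averaging.
    """
    W = q.W
    lv = q.levels
    rows, cols = lv.shape
    mats = []
    for dr, dc in offsets:
        if abs(dr) >= rows or abs(dc) >= cols:
            raise ValueError(f"offset {(dr, dc)} larger than image")
        r0 = slice(max(0, -dr), rows - max(0, dr))
        r1 = slice(max(0, dr), rows - max(0, -dr))
        c0 = slice(max(0, -dc), cols - max(0, dc))
        c1 = slice(max(0, dc), cols - max(0, -dc))
        a, b = lv[r0, c0].ravel(), lv[r1, c1].ravel()
        if mask is not None:
            keep = mask[r0, c0].ravel() & mask[r1, c1].ravel()
            a, b = a[keep], b[keep]
        P = np.zeros((W, W), dtype=float)
        np.add.at(P, (a, b), 1.0)
        if symmetric:
            P = P + P.T
        total = P.sum()
        if total == 0:
            raise ValueError(f"no valid pixel pairs for offset {(dr, dc)}")
        if normalize:
            P = P / total
        mats.append(P)
    P = np.mean(mats, axis=0)
    # marginal of the (symmetric) normalized matrix
    pk = P.sum(axis=1) / P.sum()
    k = np.arange(W)
    M = float(np.sum(k * pk))
    S4 = float(np.sqrt(np.sum((k - M) ** 2 * pk)))
    return GLCMatrix(
        P=P,
        offsets=tuple(offsets),
        symmetric=symmetric,
        normalized=normalize,
        marginal_mean=M,
        marginal_sd=S4,
    )


def glcm_features(g: GLCMatrix) -> dict[str, float]:
    """Contrast, correlation, homogeneity and energy of a normalized GLCM."""
    if not g.normalized:
        raise ValueError("glcm_features requires a normalized GLCM")
    W = g.P.shape[0]
    k = np.arange(W)[:, None]
    l = np.arange(W)[None, :]
    diff2 = (k - l) ** 2
    contrast = float(np.sum(g.P * diff2))
    homogeneity = float(np.sum(g.P / (1.0 + diff2)))
    energy = float(np.sum(g.P**2))
    if g.marginal_sd > 0:
        corr = float(
            np.sum(g.P * (k - g.marginal_mean) * (l - g.marginal_mean))
            / g.marginal_sd**2
        )
    else:
        corr = 0.0
    return {
        "glcm_contrast": contrast,
        "glcm_correlation": corr,
        "glcm_homogeneity": homogeneity,
        "glcm_energy": energy,
    }


def ngtdm(
    q: QuantizedImage, window: int = 3, mask: np.ndarray | None = None
) -> NGTDMatrix:
    """Neighborhood gray-tone difference matrix.

    For every pixel the neighborhood is the window intersected with the
    image (and mask), excluding the centre; s_i accumulates
    |i - neighborhood mean| over the pixels of level i that have at least
    one neighbor; p_i is the level probability over those pixels.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    if min(q.shape) < 2:
        raise ValueError("image too small for a neighborhood")
    valid = np.ones(q.shape, bool) if mask is None else np.asarray(mask, bool)
    lv_int = q.levels.astype(np.int64)
    vals = np.where(valid, lv_int, 0)
    cnt = valid.astype(np.int64)
    kernel = np.ones((window, window), dtype=np.int64)
    ksum = ndimage.correlate(vals, kernel, mode="constant", cval=0)
    kcnt = ndimage.correlate(cnt, kernel, mode="constant", cval=0)
    nb_sum = ksum - vals  # exclude centre
    nb_cnt = kcnt - cnt
    has_nb = valid & (nb_cnt > 0)
    lv = lv_int.astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        nb_mean = np.where(has_nb, nb_sum / np.maximum(nb_cnt, 1), 0.0)
    diff = np.abs(lv - nb_mean)

    W = q.W
    s = np.zeros(W)
    counts = np.zeros(W)
    idx = q.levels[has_nb]
    np.add.at(s, idx, diff[has_nb])
    np.add.at(counts, idx, 1.0)
    n = counts.sum()
    if n == 0:
        raise ValueError("empty region of interest")
    p = counts / n
    return NGTDMatrix(s=s, p=p, present=counts > 0)


def ngtdm_features(
    q: QuantizedImage, window: int = 3, mask: np.ndarray | None = None
) -> dict[str, float]:
    """Busyness and strength from the NGTDM.

    busyness = sum_i p_i s_i / sum_{i,j present} |i p_i - j p_j|
    strength = sum_{i,j present} (p_i + p_j)(i - j)^2 / sum_i s_i
    Both are 0 by convention when their denominator vanishes (single
    present level, or a perfectly flat region).
    """
    m = ngtdm(q, window=window, mask=mask)
    lv = np.where(m.present)[0].astype(float)
    if lv.size <= 1:
        return {"ngtdm_busyness": 0.0, "ngtdm_strength": 0.0}
    p = m.p[m.present]
    s = m.s[m.present]
    ipi = lv * p
    busy_den = float(np.sum(np.abs(ipi[:, None] - ipi[None, :])))
    busyness = float(np.sum(p * s) / busy_den) if busy_den > 0 else 0.0
    s_total = float(s.sum())
    if s_total > 0:
        strength = float(
            np.sum((p[:, None] + p[None, :]) * (lv[:, None] - lv[None, :]) ** 2)
            / s_total
        )
    else:
        strength = 0.0
    return {"ngtdm_busyness": busyness, "ngtdm_strength": strength}


def shape_features(mask: np.ndarray) -> dict[str, float]:
    """Area, perimeter, eccentricity and solidity of the largest component."""
    from skimage import measure

    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    comp = measure.label(mask, connectivity=2)
    props = max(measure.regionprops(comp), key=lambda r: r.area)
    return {
        "shape_area": float(props.area),
        "shape_perimeter": float(props.perimeter),
        "shape_eccentricity": float(props.eccentricity),
        "shape_solidity": float(props.solidity),
    }


def extract_features(
    img: GrayImage,
    mask: np.ndarray | None = None,
    W: int = 8,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    ngtdm_window: int = 3,
) -> FeatureVector:
    """All feature groups computed inside the mask (whole image if none).

    Gray levels are binned over the ROI's own intensity range (the usual
    radiomics convention), so texture features describe contrast *within*
    the region rather than the region's offset from the rest of the
    image. An all-false mask falls back to the whole image; shape
    descriptors are 0 in that case (there is no region to describe).
    """
    roi_sel = np.asarray(mask, bool) if mask is not None else None
    if roi_sel is not None and not roi_sel.any():
        roi_sel = None
    p = img.pixels
    roi_vals = p[roi_sel] if roi_sel is not None else p
    lo, hi = float(roi_vals.min()), float(roi_vals.max())
    norm = (p - lo) / (hi - lo) if hi > lo else np.zeros_like(p)
    q = quantize(GrayImage(np.clip(norm, 0.0, 1.0)), W)
    use_mask = roi_sel
    out: dict[str, float] = {}
    out.update(first_order_features(histogram(q, use_mask)))
    out.update(glcm_features(glcm(q, offsets=offsets, mask=use_mask)))
    out.update(ngtdm_features(q, window=ngtdm_window, mask=use_mask))
    if use_mask is not None:
        out.update(shape_features(use_mask))
        roi = int(use_mask.sum())
    else:
        out.update(
            {
                "shape_area": 0.0,
                "shape_perimeter": 0.0,
                "shape_eccentricity": 0.0,
                "shape_solidity": 0.0,
            }
        )
        roi = img.pixels.size
    return FeatureVector(roi_pixels=roi, **out)
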