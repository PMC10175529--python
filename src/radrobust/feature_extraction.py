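"""The 94-feature radiomics panel.

Computes 19 first-order statistics and 75 texture features (24 GLCM,
14 GLDM, 16 GLRLM, 16 GLSZM, 5 NGTDM) from a circular ROI of a single
2D slice, following the IBSI-aligned conventions popularized by the
common open-source extractors:

* fixed-bin-width discretization (default 25 HU) anchored at the ROI
  minimum, ``level = floor((x - min) / width) + 1``;
* symmetric co-occurrence and run-length matrices over the four in-plane
  directions at distance 1, features computed per direction and then
  averaged;
* size zones as 8-connected components of equal gray level;
* dependence counts over the 8-neighborhood with tolerance ``alpha``
  (the center pixel itself contributes 1, so dependence sizes run
  1..9);
* neighborhood gray-tone differences against the mean of the available
  in-ROI 8-neighbors.

Shape features are deliberately absent: the ROIs are fixed circles, so
shape carries no information here.  No resampling, filtering or
normalization is applied before discretization.

Degenerate inputs follow a fixed contract instead of propagating NaN:
constant ROIs give zero entropies/variances, uniformity 1, and
skewness/kurtosis 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .phantom_synth import PIXEL_SPACING_MM, SLICE_THICKNESS_MM, ScanImage
from .roi_tools import ROISet

__all__ = [
    "DiscretizedROI",
    "discretize",
    "first_order_features",
    "glcm_features",
    "glrlm_features",
    "glszm_features",
    "gldm_features",
    "ngtdm_features",
    "extract_all",
    "FIRSTORDER_NAMES",
    "GLCM_NAMES",
    "GLDM_NAMES",
    "GLRLM_NAMES",
    "GLSZM_NAMES",
    "NGTDM_NAMES",
    "CLASS_COUNTS",
    "FEATURE_CLASSES",
    "TOTAL_FEATURES",
]

DEFAULT_BIN_WIDTH = 25.0
DEFAULT_VOXEL_VOLUME = PIXEL_SPACING_MM ** 2 * SLICE_THICKNESS_MM

DIRECTIONS_2D = ((0, 1), (1, 0), (1, 1), (1, -1))
NEIGHBORS_8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))

FIRSTORDER_NAMES = (
    "Energy", "TotalEnergy", "Entropy", "Minimum", "10Percentile",
    "90Percentile", "Maximum", "Mean", "Median", "InterquartileRange",
    "Range", "MeanAbsoluteDeviation", "RobustMeanAbsoluteDeviation",
    "RootMeanSquared", "StandardDeviation", "Skewness", "Kurtosis",
    "Variance", "Uniformity")
GLCM_NAMES = (
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares", "MCC")
GLDM_NAMES = (
    "SmallDependenceEmphasis", "LargeDependenceEmphasis",
    "GrayLevelNonUniformity", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "GrayLevelVariance",
    "DependenceVariance", "DependenceEntropy", "LowGrayLevelEmphasis",
    "HighGrayLevelEmphasis", "SmallDependenceLowGrayLevelEmphasis",
    "SmallDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis",
    "LargeDependenceHighGrayLevelEmphasis")
GLRLM_NAMES = (
    "ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "GrayLevelVariance",
    "RunVariance", "RunEntropy", "LowGrayLevelRunEmphasis",
    "HighGrayLevelRunEmphasis", "ShortRunLowGrayLevelEmphasis",
    "ShortRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LongRunHighGrayLevelEmphasis")
GLSZM_NAMES = (
    "SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
    "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "ZonePercentage", "GrayLevelVariance",
    "ZoneVariance", "ZoneEntropy", "LowGrayLevelZoneEmphasis",
    "HighGrayLevelZoneEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LargeAreaHighGrayLevelEmphasis")
NGTDM_NAMES = ("Coarseness", "Contrast", "Busyness", "Complexity", "Strength")

FEATURE_CLASSES = ("firstorder", "glcm", "gldm", "glrlm", "glszm", "ngtdm")
CLASS_COUNTS = {"firstorder": 19, "glcm": 24, "gldm": 14, "glrlm": 16,
                "glszm": 16, "ngtdm": 5}
TOTAL_FEATURES = sum(CLASS_COUNTS.values())  # 94

_CLASS_NAMES = {"firstorder": FIRSTORDER_NAMES, "glcm": GLCM_NAMES,
                "gldm": GLDM_NAMES, "glrlm": GLRLM_NAMES,
                "glszm": GLSZM_NAMES, "ngtdm": NGTDM_NAMES}


@dataclass(frozen=True)
class DiscretizedROI:
    """Gray levels 1..ng on the ROI bounding box; 0 marks out-of-ROI."""

    levels: np.ndarray  # 2D int array, 0 sentinel outside the ROI
    ng: int
    bin_width: float
    min_value: float

    @property
    def n_pixels(self) -> int:
        return int((self.levels > 0).sum())

    def flat_levels(self) -> np.ndarray:
        """In-ROI levels in row-major order."""
        return self.levels[self.levels > 0]


def discretize(values_or_grid: np.ndarray, bin_width: float = DEFAULT_BIN_WIDTH,
               mask: np.ndarray | None = None) -> DiscretizedROI:
    """Fixed-bin-width gray-level discretization.

    ``level(x) = floor((x - min) / bin_width) + 1``, so the number of
    levels is ``floor((max - min) / bin_width) + 1``.  A 1D input is
    treated as a single row; a 2D input may come with a boolean ``mask``
    selecting the ROI (default: everything).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    arr = np.asarray(values_or_grid, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
        if mask is not None:
            mask = np.asarray(mask, bool)[None, :]
    if mask is None:
        mask = np.ones(arr.shape, dtype=bool)
    if not mask.any():
        raise ValueError("ROI is empty")
    vmin = float(arr[mask].min())
    levels = np.zeros(arr.shape, dtype=np.int64)
    levels[mask] = np.floor((arr[mask] - vmin) / bin_width).astype(np.int64) + 1
    return DiscretizedROI(levels=levels, ng=int(levels.max()),
                          bin_width=float(bin_width), min_value=vmin)


# ---------------------------------------------------------------------------
# first order


def first_order_features(raw_values: np.ndarray, discretized: DiscretizedROI,
                         voxel_volume: float = DEFAULT_VOXEL_VOLUME) -> dict[str, float]:
    """The 19 first-order statistics of the ROI intensity histogram.

    Entropy and Uniformity are computed on the discretized levels; Total
    Energy scales Energy by the voxel volume (in-plane spacing² × slice
    thickness).  Skewness and Kurtosis of a zero-variance ROI are 0.
    """
    x = np.asarray(raw_values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    n = x.size
    mean = x.mean()
    var = float(((x - mean) ** 2).mean())  # population variance
    p10, p25, median, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    sub = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(sub - sub.mean()).mean()) if sub.size else 0.0
    if var > 0:
        m = x - mean
        skew = float((m ** 3).mean() / var ** 1.5)
        kurt = float((m ** 4).mean() / var ** 2)
    else:
        skew = kurt = 0.0
    lv = discretized.flat_levels()
    p = np.bincount(lv, minlength=discretized.ng + 1)[1:] / lv.size
    pz = p[p > 0]
    entropy = float(-(pz * np.log2(pz)).sum())
    energy = float((x ** 2).sum())
    out = {
        "Energy": energy,
        "TotalEnergy": float(voxel_volume) * energy,
        "Entropy": entropy,
        "Minimum": float(x.min()),
        "10Percentile": float(p10),
        "90Percentile": float(p90),
        "Maximum": float(x.max()),
        "Mean": float(mean),
        "Median": float(median),
        "InterquartileRange": float(p75 - p25),
        "Range": float(x.max() - x.min()),
        "MeanAbsoluteDeviation": float(np.abs(x - mean).mean()),
        "RobustMeanAbsoluteDeviation": rmad,
        "RootMeanSquared": float(np.sqrt((x ** 2).mean())),
        "StandardDeviation": float(np.sqrt(var)),
        "Skewness": skew,
        "Kurtosis": kurt,
        "Variance": var,
        "Uniformity": float((p ** 2).sum()),
    }
    assert len(out) == 19
    return out


# ---------------------------------------------------------------------------
# GLCM


def glcm_matrix(levels: np.ndarray, ng: int,
                direction: tuple[int, int]) -> np.ndarray:
    """Symmetric gray-level co-occurrence counts for one direction."""
    dr, dc = direction
    H, W = levels.shape
    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
    valid = (a > 0) & (b > 0)
    P = np.zeros((ng, ng), dtype=float)
    np.add.at(P, (a[valid] - 1, b[valid] - 1), 1.0)
    return P + P.T


def _entropy2(p: np.ndarray) -> float:
    pz = p[p > 0]
    return float(-(pz * np.log2(pz)).sum())


def _glcm_single(p: np.ndarray) -> dict[str, float]:
    """All 24 co-occurrence features from one normalized symmetric matrix."""
    ng = p.shape[0]
    i = np.arange(1, ng + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    ux = float(i @ px)
    uy = float(i @ py)
    sigx = float(np.sqrt(((i - ux) ** 2) @ px))
    sigy = float(np.sqrt(((i - uy) ** 2) @ py))
    k_diff = np.abs(ii - jj).astype(int)
    p_diff = np.bincount(k_diff.ravel(), weights=p.ravel(), minlength=ng)
    kd = np.arange(p_diff.size, dtype=float)
    k_sum = (ii + jj).astype(int)
    p_sum = np.bincount(k_sum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)
    ks = np.arange(p_sum.size, dtype=float)

    autocorr = float((p * ii * jj).sum())
    da = float((kd * p_diff).sum())
    hx = _entropy2(px)
    hy = _entropy2(py)
    hxy = _entropy2(p)
    pxy = np.outer(px, py)
    ok = (p > 0) & (pxy > 0)
    hxy1 = float(-(p[ok] * np.log2(pxy[ok])).sum())
    okm = pxy > 0
    hxy2 = float(-(pxy[okm] * np.log2(pxy[okm])).sum())
    div = max(hx, hy)
    imc1 = 0.0 if div == 0 else (hxy - hxy1) / div
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))
    off = ii != jj

    if sigx * sigy > 0:
        correlation = (autocorr - ux * uy) / (sigx * sigy)
    else:
        correlation = 1.0  # single effective level: perfect linear agreement

    # MCC: second largest eigenvalue of Q(i,j) = sum_k p(i,k)p(j,k)/(px(i)py(k))
    keep = px > 0
    if keep.sum() <= 1:
        mcc = 1.0
    else:
        psub = p[np.ix_(keep, keep)]
        pxs = px[keep]
        pys = py[keep]
        Q = (psub / pxs[:, None]) @ (psub / pys[None, :]).T
        ev = np.sort(np.linalg.eigvals(Q).real)[::-1]
        mcc = float(np.sqrt(max(0.0, ev[1])))

    return {
        "Autocorrelation": autocorr,
        "JointAverage": ux,
        "ClusterProminence": float((p * (ii + jj - ux - uy) ** 4).sum()),
        "ClusterShade": float((p * (ii + jj - ux - uy) ** 3).sum()),
        "ClusterTendency": float((p * (ii + jj - ux - uy) ** 2).sum()),
        "Contrast": float((p * (ii - jj) ** 2).sum()),
        "Correlation": float(correlation),
        "DifferenceAverage": da,
        "DifferenceEntropy": _entropy2(p_diff),
        "DifferenceVariance": float(((kd - da) ** 2 * p_diff).sum()),
        "JointEnergy": float((p ** 2).sum()),
        "JointEntropy": hxy,
        "Imc1": float(imc1),
        "Imc2": imc2,
        "Idm": float((p / (1.0 + (ii - jj) ** 2)).sum()),
        "Idmn": float((p / (1.0 + (ii - jj) ** 2 / ng ** 2)).sum()),
        "Id": float((p / (1.0 + np.abs(ii - jj))).sum()),
        "Idn": float((p / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "InverseVariance": float((p[off] / (ii - jj)[off] ** 2).sum()),
        "MaximumProbability": float(p.max()),
        "SumAverage": float((ks * p_sum).sum()),
        "SumEntropy": _entropy2(p_sum),
        "SumSquares": float((p * (ii - ux) ** 2).sum()),
        "MCC": mcc,
    }


def glcm_features(discretized: DiscretizedROI, distance: int = 1) -> dict[str, float]:
    """24 GLCM features: per-direction values averaged over 4 directions."""
    levels, ng = discretized.levels, discretized.ng
    per_dir = []
    for dr, dc in DIRECTIONS_2D:
        P = glcm_matrix(levels, ng, (dr * distance, dc * distance))
        tot = P.sum()
        if tot == 0:
            continue
        per_dir.append(_glcm_single(P / tot))
    if not per_dir:
        # single-pixel ROI: treat as a one-cell matrix
        per_dir = [_glcm_single(np.array([[1.0]]))]
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLCM_NAMES}


# ---------------------------------------------------------------------------
# GLRLM


def _lines(levels: np.ndarray, direction: tuple[int, int]):
    """Yield the 1D scan lines of ``levels`` along one direction."""
    if direction == (0, 1):
        yield from levels
    elif direction == (1, 0):
        yield from levels.T
    elif direction == (1, 1):
        H, W = levels.shape
        for off in range(-(H - 1), W):
            yield np.diagonal(levels, offset=off)
    elif direction == (1, -1):
        yield from _lines(levels[:, ::-1], (1, 1))
    else:
        raise ValueError(f"unsupported direction {direction}")


def glrlm_matrix(levels: np.ndarray, ng: int,
                 direction: tuple[int, int]) -> np.ndarray:
    """Run-length counts P[i, l-1]; runs are broken by out-of-ROI pixels."""
    max_run = max(levels.shape)
    P = np.zeros((ng, max_run), dtype=float)
    for line in _lines(levels, direction):
        run_val = 0
        run_len = 0
        for v in line:
            if v == run_val and v > 0:
                run_len += 1
            else:
                if run_val > 0:
                    P[run_val - 1, run_len - 1] += 1
                run_val = int(v)
                run_len = 1 if v > 0 else 0
        if run_val > 0:
            P[run_val - 1, run_len - 1] += 1
    return P


def _glrlm_single(P: np.ndarray, n_pixels: int) -> dict[str, float] | None:
    nr = P.sum()
    if nr == 0:
        return None
    ng, lmax = P.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    l = np.arange(1, lmax + 1, dtype=float)[None, :]
    pg = P.sum(axis=1)  # per gray level
    pl = P.sum(axis=0)  # per run length
    pnorm = P / nr
    mu_i = float((pnorm * i).sum())
    mu_l = float((pnorm * l).sum())
    return {
        "ShortRunEmphasis": float((P / l ** 2).sum() / nr),
        "LongRunEmphasis": float((P * l ** 2).sum() / nr),
        "GrayLevelNonUniformity": float((pg ** 2).sum() / nr),
        "GrayLevelNonUniformityNormalized": float((pg ** 2).sum() / nr ** 2),
        "RunLengthNonUniformity": float((pl ** 2).sum() / nr),
        "RunLengthNonUniformityNormalized": float((pl ** 2).sum() / nr ** 2),
        "RunPercentage": float(nr / n_pixels),
        "GrayLevelVariance": float((pnorm * (i - mu_i) ** 2).sum()),
        "RunVariance": float((pnorm * (l - mu_l) ** 2).sum()),
        "RunEntropy": _entropy2(pnorm),
        "LowGrayLevelRunEmphasis": float((P / i ** 2).sum() / nr),
        "HighGrayLevelRunEmphasis": float((P * i ** 2).sum() / nr),
        "ShortRunLowGrayLevelEmphasis": float((P / (i ** 2 * l ** 2)).sum() / nr),
        "ShortRunHighGrayLevelEmphasis": float((P * i ** 2 / l ** 2).sum() / nr),
        "LongRunLowGrayLevelEmphasis": float((P * l ** 2 / i ** 2).sum() / nr),
        "LongRunHighGrayLevelEmphasis": float((P * i ** 2 * l ** 2).sum() / nr),
    }


def glrlm_features(discretized: DiscretizedROI) -> dict[str, float]:
    """16 run-length features averaged over the 4 in-plane directions."""
    levels, ng = discretized.levels, discretized.ng
    n_pix = discretized.n_pixels
    per_dir = []
    for d in DIRECTIONS_2D:
        f = _glrlm_single(glrlm_matrix(levels, ng, d), n_pix)
        if f is not None:
            per_dir.append(f)
    return {k: float(np.mean([d[k] for d in per_dir])) for k in GLRLM_NAMES}


# ---------------------------------------------------------------------------
# GLSZM

_STRUCTURE_8 = np.ones((3, 3), dtype=int)


def glszm_matrix(levels: np.ndarray, ng: int) -> np.ndarray:
    """Size-zone counts P[i, s-1]; zones are 8-connected equal-level blobs."""
    P = np.zeros((ng, int((levels > 0).sum()) or 1), dtype=float)
    for g in range(1, ng + 1):
        lab, nz = ndimage.label(levels == g, structure=_STRUCTURE_8)
        if nz == 0:
            continue
        sizes = np.bincount(lab.ravel())[1:]
        for s in sizes:
            P[g - 1, s - 1] += 1
    return P


def glszm_features(discretized: DiscretizedROI) -> dict[str, float]:
    """16 size-zone features from the single (direction-free) matrix."""
    P = glszm_matrix(discretized.levels, discretized.ng)
    n_pix = discretized.n_pixels
    nz = P.sum()
    ng, smax = P.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    s = np.arange(1, smax + 1, dtype=float)[None, :]
    pg = P.sum(axis=1)
    ps = P.sum(axis=0)
    pnorm = P / nz
    mu_i = float((pnorm * i).sum())
    mu_s = float((pnorm * s).sum())
    return {
        "SmallAreaEmphasis": float((P / s ** 2).sum() / nz),
        "LargeAreaEmphasis": float((P * s ** 2).sum() / nz),
        "GrayLevelNonUniformity": float((pg ** 2).sum() / nz),
        "GrayLevelNonUniformityNormalized": float((pg ** 2).sum() / nz ** 2),
        "SizeZoneNonUniformity": float((ps ** 2).sum() / nz),
        "SizeZoneNonUniformityNormalized": float((ps ** 2).sum() / nz ** 2),
        "ZonePercentage": float(nz / n_pix),
        "GrayLevelVariance": float((pnorm * (i - mu_i) ** 2).sum()),
        "ZoneVariance": float((pnorm * (s - mu_s) ** 2).sum()),
        "ZoneEntropy": _entropy2(pnorm),
        "LowGrayLevelZoneEmphasis": float((P / i ** 2).sum() / nz),
        "HighGrayLevelZoneEmphasis": float((P * i ** 2).sum() / nz),
        "SmallAreaLowGrayLevelEmphasis": float((P / (i ** 2 * s ** 2)).sum() / nz),
        "SmallAreaHighGrayLevelEmphasis": float((P * i ** 2 / s ** 2).sum() / nz),
        "LargeAreaLowGrayLevelEmphasis": float((P * s ** 2 / i ** 2).sum() / nz),
        "LargeAreaHighGrayLevelEmphasis": float((P * i ** 2 * s ** 2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# GLDM


def gldm_matrix(levels: np.ndarray, ng: int, alpha: float = 0.0,
                distance: int = 1) -> np.ndarray:
    """Dependence counts P[i, j-1].

    The dependence size j of a pixel is 1 + the number of in-ROI
    neighbors (Chebyshev distance <= ``distance``) whose level differs
    from the center level by at most ``alpha``.
    """
    if distance != 1:
        raise NotImplementedError("only distance=1 neighborhoods are supported")
    H, W = levels.shape
    inroi = levels > 0
    dep = np.zeros((H, W), dtype=np.int64)
    for dr, dc in NEIGHBORS_8:
        r0, r1 = max(0, -dr), H - max(0, dr)
        c0, c1 = max(0, -dc), W - max(0, dc)
        a = levels[r0:r1, c0:c1]
        b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        hit = (a > 0) & (b > 0) & (np.abs(a - b) <= alpha)
        dep[r0:r1, c0:c1] += hit
    P = np.zeros((ng, 9), dtype=float)
    np.add.at(P, (levels[inroi] - 1, dep[inroi]), 1.0)
    return P


def gldm_features(discretized: DiscretizedROI, alpha: float = 0.0,
                  distance: int = 1) -> dict[str, float]:
    """14 gray-level dependence features."""
    P = gldm_matrix(discretized.levels, discretized.ng, alpha, distance)
    nz = P.sum()  # equals the pixel count
    ng, jmax = P.shape
    i = np.arange(1, ng + 1, dtype=float)[:, None]
    j = np.arange(1, jmax + 1, dtype=float)[None, :]
    pg = P.sum(axis=1)
    pj = P.sum(axis=0)
    pnorm = P / nz
    mu_i = float((pnorm * i).sum())
    mu_j = float((pnorm * j).sum())
    return {
        "SmallDependenceEmphasis": float((P / j ** 2).sum() / nz),
        "LargeDependenceEmphasis": float((P * j ** 2).sum() / nz),
        "GrayLevelNonUniformity": float((pg ** 2).sum() / nz),
        "DependenceNonUniformity": float((pj ** 2).sum() / nz),
        "DependenceNonUniformityNormalized": float((pj ** 2).sum() / nz ** 2),
        "GrayLevelVariance": float((pnorm * (i - mu_i) ** 2).sum()),
        "DependenceVariance": float((pnorm * (j - mu_j) ** 2).sum()),
        "DependenceEntropy": _entropy2(pnorm),
        "LowGrayLevelEmphasis": float((P / i ** 2).sum() / nz),
        "HighGrayLevelEmphasis": float((P * i ** 2).sum() / nz),
        "SmallDependenceLowGrayLevelEmphasis": float((P / (i ** 2 * j ** 2)).sum() / nz),
        "SmallDependenceHighGrayLevelEmphasis": float((P * i ** 2 / j ** 2).sum() / nz),
        "LargeDependenceLowGrayLevelEmphasis": float((P * j ** 2 / i ** 2).sum() / nz),
        "LargeDependenceHighGrayLevelEmphasis": float((P * i ** 2 * j ** 2).sum() / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM


def ngtdm_table(levels: np.ndarray, ng: int) -> tuple[np.ndarray, np.ndarray]:
    """Counts n_i and summed absolute differences s_i per gray level.

    For each in-ROI pixel the mean of its available in-ROI 8-neighbors
    is computed; pixels with no in-ROI neighbor are excluded.
    """
    H, W = levels.shape
    inroi = levels > 0
    nbr_sum = np.zeros((H, W), dtype=float)
    nbr_cnt = np.zeros((H, W), dtype=np.int64)
    for dr, dc in NEIGHBORS_8:
        r0, r1 = max(0, -dr), H - max(0, dr)
        c0, c1 = max(0, -dc), W - max(0, dc)
        b = levels[r0 + dr:r1 + dr, c0 + dc:c1 + dc]
        hit = b > 0
        nbr_sum[r0:r1, c0:c1] += np.where(hit, b, 0)
        nbr_cnt[r0:r1, c0:c1] += hit
    valid = inroi & (nbr_cnt > 0)
    n = np.zeros(ng, dtype=float)
    s = np.zeros(ng, dtype=float)
    abar = np.zeros((H, W), dtype=float)
    abar[valid] = nbr_sum[valid] / nbr_cnt[valid]
    diff = np.abs(levels - abar)
    for g in range(1, ng + 1):
        sel = valid & (levels == g)
        n[g - 1] = sel.sum()
        s[g - 1] = diff[sel].sum()
    return n, s


def ngtdm_features(discretized: DiscretizedROI, distance: int = 1) -> dict[str, float]:
    """5 neighborhood gray-tone difference features."""
    if distance != 1:
        raise NotImplementedError("only distance=1 neighborhoods are supported")
    n, s = ngtdm_table(discretized.levels, discretized.ng)
    nvp = n.sum()
    ng = n.size
    p = n / nvp
    i = np.arange(1, ng + 1, dtype=float)
    present = p > 0
    ngp = int(present.sum())
    ii, jj = np.meshgrid(i[present], i[present], indexing="ij")
    pi, pj = np.meshgrid(p[present], p[present], indexing="ij")
    si, sj = np.meshgrid(s[present], s[present], indexing="ij")

    ps = float((p * s).sum())
    coarseness = 1.0 / ps if ps > 0 else 1e6
    if ngp <= 1:
        contrast = 0.0
    else:
        contrast = (float((pi * pj * (ii - jj) ** 2).sum())
                    / (ngp * (ngp - 1)) * float(s.sum()) / nvp)
    busy_den = float(np.abs(ii * pi - jj * pj).sum())
    busyness = ps / busy_den if busy_den > 0 else 0.0
    complexity = float((np.abs(ii - jj) * (pi * si + pj * sj) / (pi + pj)).sum()) / nvp
    s_sum = float(s.sum())
    strength = float(((pi + pj) * (ii - jj) ** 2).sum()) / s_sum if s_sum > 0 else 0.0
    return {"Coarseness": coarseness, "Contrast": contrast,
            "Busyness": busyness, "Complexity": complexity,
            "Strength": strength}


# ---------------------------------------------------------------------------
# panel driver

FEATURE_TABLE_COLUMNS = ["platform_id", "image_type", "repeat_idx", "roi_id",
                         "feature_class", "feature_name", "value"]


def extract_roi_panel(pixels: np.ndarray, mask: np.ndarray,
                      bin_width: float = DEFAULT_BIN_WIDTH,
                      voxel_volume: float = DEFAULT_VOXEL_VOLUME,
                      gldm_alpha: float = 0.0) -> dict[tuple[str, str], float]:
    """All 94 features of one ROI, keyed by (feature_class, feature_name)."""
    rows, cols = np.where(mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    sub = pixels[r0:r1, c0:c1]
    submask = mask[r0:r1, c0:c1]
    disc = discretize(sub, bin_width, mask=submask)
    raw = sub[submask]
    out: dict[tuple[str, str], float] = {}
    for name, v in first_order_features(raw, disc, voxel_volume).items():
        out[("firstorder", name)] = v
    for name, v in glcm_features(disc).items():
        out[("glcm", name)] = v
    for name, v in gldm_features(disc, alpha=gldm_alpha).items():
        out[("gldm", name)] = v
    for name, v in glrlm_features(disc).items():
        out[("glrlm", name)] = v
    for name, v in glszm_features(disc).items():
        out[("glszm", name)] = v
    for name, v in ngtdm_features(disc).items():
        out[("ngtdm", name)] = v
    assert len(out) == TOTAL_FEATURES
    return out


def extract_all(image: ScanImage, roi_set: ROISet,
                bin_width: float = DEFAULT_BIN_WIDTH,
                voxel_volume: float = DEFAULT_VOXEL_VOLUME) -> pd.DataFrame:
    """Feature table for one scan: 16 ROIs × 94 features, long format.

    The image is used as-is — no resampling, filtering or normalization
    precedes discretization.
    """
    missing = [rid for rid in range(1, 17) if rid not in roi_set.masks]
    if missing:
        raise ValueError(f"missing ROI ids: {missing}")
    records = []
    for rid in sorted(roi_set.roi_ids):
        panel = extract_roi_panel(image.pixels, roi_set.masks[rid],
                                  bin_width=bin_width, voxel_volume=voxel_volume)
        for (fclass, fname), v in panel.items():
            records.append((image.platform_id, image.image_type,
                            image.repeat_idx, rid, fclass, fname, v))
    return pd.DataFrame.from_records(records, columns=FEATURE_TABLE_COLUMNS)


def validate_feature_table(table: pd.DataFrame) -> None:
    """Check the 94-feature contract per (platform, image_type, repeat, roi)."""
    grouped = table.groupby(["platform_id", "image_type", "repeat_idx",
                             "roi_id"], sort=False)
    for key, g in grouped:
        counts = g["feature_class"].value_counts().to_dict()
        if counts != CLASS_COUNTS:
            raise ValueError(f"feature class counts wrong for {key}: {counts}")
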