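"""Handcrafted radiomics features over the 3D tumour ROI.

The default catalogue has 431 named features:

* 19 first-order intensity statistics,
* 17 shape/size descriptors of the binary mask,
* 27 grey-level co-occurrence (GLCM) texture statistics, and
* 8 x (19 + 27) = 368 first-order + GLCM statistics of the eight bands of a
  single-level stationary (undecimated) 3D wavelet transform.

The undecimated transform keeps every band aligned with the original ROI
mask, so band statistics are taken over exactly the same voxels as the raw
intensities.  The GLCM catalogue comprises 25 distinct co-occurrence
statistics plus the two historical aliases (``dissimilarity`` for
difference average, ``homogeneity`` for inverse difference) that radiomics
catalogues conventionally carry.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import stats as sps
from skimage import measure

from .core import FeatureVector, VolumeWithMask

#: 13 unique 3D direction offsets at Chebyshev distance 1 (one per +/- pair).
DEFAULT_OFFSETS: tuple[tuple[int, int, int], ...] = tuple(
    d for d in itertools.product((0, 1, -1), repeat=3)
    if d != (0, 0, 0) and (d > (0, 0, 0))
)

FIRST_ORDER_NAMES = [
    "mean", "median", "minimum", "maximum", "range", "variance", "std",
    "mad", "skewness", "kurtosis", "energy", "rms", "entropy", "uniformity",
    "p10", "p90", "iqr", "rmad", "cov",
]

SHAPE_NAMES = [
    "volume_mm3", "surface_area_mm2", "surface_to_volume_ratio", "sphericity",
    "compactness1", "compactness2", "spherical_disproportion",
    "max_diameter_mm", "major_axis_mm", "minor_axis_mm", "least_axis_mm",
    "elongation", "flatness", "bbox_x_mm", "bbox_y_mm", "bbox_z_mm", "extent",
]

GLCM_NAMES = [
    "autocorrelation", "cluster_prominence", "cluster_shade",
    "cluster_tendency", "contrast", "correlation", "difference_average",
    "difference_entropy", "difference_variance", "dissimilarity",
    "homogeneity", "id", "idm", "idmn", "idn", "imc1", "imc2",
    "inverse_variance", "joint_average", "joint_energy", "joint_entropy",
    "joint_variance", "maximum_probability", "mcc", "sum_average",
    "sum_entropy", "sum_variance",
]

WAVELET_BANDS = ["LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH"]


@dataclass
class HCConfig:
    """Extraction settings: discretisation, offsets, wavelet family."""

    n_bins: int = 32
    offsets: tuple[tuple[int, int, int], ...] = DEFAULT_OFFSETS
    wavelet: str = "coif1"
    entropy_bins: int = 32  # fixed-bin first-order entropy/uniformity


# ---------------------------------------------------------------- first order

def _first_order_stats(x: np.ndarray, entropy_bins: int = 32) -> dict[str, float]:
    x = np.asarray(x, dtype=float)
    mean = float(x.mean())
    med = float(np.median(x))
    std = float(x.std())
    rng = float(x.max() - x.min())
    if rng > 0:
        hist, _ = np.histogram(x, bins=entropy_bins, range=(x.min(), x.max()))
        p = hist / hist.sum()
        p = p[p > 0]
        entropy = float(-(p * np.log2(p)).sum())
        uniformity = float((p ** 2).sum())
        skew = float(sps.skew(x))
        kurt = float(sps.kurtosis(x))
    else:
        entropy, uniformity, skew, kurt = 0.0, 1.0, 0.0, 0.0
    p10, p90 = (float(q) for q in np.percentile(x, [10, 90]))
    mid = x[(x >= p10) & (x <= p90)]
    rmad = float(np.abs(mid - mid.mean()).mean()) if mid.size else 0.0
    return {
        "mean": mean,
        "median": med,
        "minimum": float(x.min()),
        "maximum": float(x.max()),
        "range": rng,
        "variance": float(x.var()),
        "std": std,
        "mad": float(np.median(np.abs(x - med))),
        "skewness": skew,
        "kurtosis": kurt,
        "energy": float((x ** 2).sum()),
        "rms": float(np.sqrt((x ** 2).mean())),
        "entropy": entropy,
        "uniformity": uniformity,
        "p10": p10,
        "p90": p90,
        "iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "rmad": rmad,
        "cov": std / mean if mean != 0 else 0.0,
    }


def first_order(vm: VolumeWithMask, entropy_bins: int = 32) -> FeatureVector:
    """19 first-order statistics of the ROI intensity distribution."""
    stats = _first_order_stats(vm.roi_values, entropy_bins)
    return FeatureVector(
        values=[stats[n] for n in FIRST_ORDER_NAMES],
        names=[f"firstorder.{n}" for n in FIRST_ORDER_NAMES],
        block="HC",
    )


# ---------------------------------------------------------------------- shape

def _exposed_face_area(mask: np.ndarray, spacing: tuple[float, ...]) -> float:
    """Total area of foreground voxel faces adjacent to background (mm^2)."""
    padded = np.pad(mask, 1)
    area = 0.0
    face_areas = (
        spacing[1] * spacing[2],
        spacing[0] * spacing[2],
        spacing[0] * spacing[1],
    )
    for axis, fa in enumerate(face_areas):
        diff = np.diff(padded.astype(np.int8), axis=axis)
        area += np.count_nonzero(diff) * fa
    return area


def _mesh_area(mask: np.ndarray, spacing: tuple[float, ...]) -> float:
    """Marching-cubes surface area (mm^2), robust to voxel staircase."""
    padded = np.pad(mask.astype(float), 1)
    verts, faces, *_ = measure.marching_cubes(padded, level=0.5, spacing=spacing)
    return float(measure.mesh_surface_area(verts, faces))


def _max_diameter(mask: np.ndarray, spacing: tuple[float, ...]) -> float:
    """Largest pairwise distance between surface voxel centres (mm)."""
    padded = np.pad(mask, 1)
    interior = np.ones_like(padded)
    for axis in (0, 1, 2):
        for shift in (1, -1):
            interior &= np.roll(padded, shift, axis=axis)
    surface = padded & ~interior
    pts = np.argwhere(surface[1:-1, 1:-1, 1:-1]) * np.asarray(spacing)
    if len(pts) == 1:
        return 0.0
    # chunked pairwise max to bound memory on large surfaces
    best = 0.0
    for i in range(0, len(pts), 512):
        d2 = ((pts[i:i + 512, None, :] - pts[None, :, :]) ** 2).sum(-1)
        best = max(best, float(d2.max()))
    return float(np.sqrt(best))


def shape_features(vm: VolumeWithMask) -> FeatureVector:
    """17 geometric descriptors of the binary ROI.

    The ``surface_area_mm2`` feature is the exposed voxel-face area; the
    sphericity/compactness family uses a marching-cubes mesh area instead,
    which tracks the true surface of smooth shapes far better than the
    voxel staircase does.
    """
    mask, spacing = vm.mask, vm.spacing
    voxvol = float(np.prod(spacing))
    volume = float(mask.sum()) * voxvol
    face_area = _exposed_face_area(mask, spacing)
    mesh_area = _mesh_area(mask, spacing)

    sphericity = (np.pi ** (1 / 3)) * ((6 * volume) ** (2 / 3)) / mesh_area
    compactness1 = volume / (np.sqrt(np.pi) * mesh_area ** 1.5)
    compactness2 = 36 * np.pi * volume ** 2 / mesh_area ** 3
    r_eq = (3 * volume / (4 * np.pi)) ** (1 / 3)
    disproportion = mesh_area / (4 * np.pi * r_eq ** 2)

    pts = np.argwhere(mask) * np.asarray(spacing)
    if len(pts) > 1:
        eig = np.sort(np.linalg.eigvalsh(np.cov(pts.T)))[::-1]
        eig = np.clip(eig, 0, None)
    else:
        eig = np.zeros(3)
    axes = 4 * np.sqrt(eig)
    elongation = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 1.0
    flatness = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 1.0

    idx = np.argwhere(mask)
    bbox_extent = (idx.max(0) - idx.min(0) + 1) * np.asarray(spacing)
    bbox_vol = float(np.prod(bbox_extent))

    vals = {
        "volume_mm3": volume,
        "surface_area_mm2": face_area,
        "surface_to_volume_ratio": face_area / volume,
        "sphericity": float(sphericity),
        "compactness1": float(compactness1),
        "compactness2": float(compactness2),
        "spherical_disproportion": float(disproportion),
        "max_diameter_mm": _max_diameter(mask, spacing),
        "major_axis_mm": float(axes[0]),
        "minor_axis_mm": float(axes[1]),
        "least_axis_mm": float(axes[2]),
        "elongation": elongation,
        "flatness": flatness,
        "bbox_x_mm": float(bbox_extent[0]),
        "bbox_y_mm": float(bbox_extent[1]),
        "bbox_z_mm": float(bbox_extent[2]),
        "extent": volume / bbox_vol,
    }
    return FeatureVector(
        values=[vals[n] for n in SHAPE_NAMES],
        names=[f"shape.{n}" for n in SHAPE_NAMES],
        block="HC",
    )


# ----------------------------------------------------------------------- GLCM

def quantise(values: np.ndarray, n_bins: int) -> np.ndarray:
    """Equal-width quantisation of ``values`` over their own range.

    Returns integer levels in ``0..n_bins-1``; a constant input maps
    entirely to level 0.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.zeros(values.shape, dtype=np.intp)
    lev = np.floor((values - lo) / (hi - lo) * n_bins).astype(np.intp)
    return np.clip(lev, 0, n_bins - 1)


def glcm_matrix(levels: np.ndarray, mask: np.ndarray, n_bins: int,
                offsets: tuple[tuple[int, int, int], ...]) -> np.ndarray:
    """Symmetric, normalised co-occurrence matrix over in-ROI voxel pairs.

    Counts are accumulated across all offsets and normalised once, i.e. a
    pair-count-weighted average over directions.
    """
    counts = np.zeros((n_bins, n_bins), dtype=float)
    shape = np.asarray(levels.shape)
    for off in offsets:
        src = tuple(slice(max(0, -o), int(s) - max(0, o))
                    for o, s in zip(off, shape))
        dst = tuple(slice(max(0, o), int(s) - max(0, -o))
                    for o, s in zip(off, shape))
        valid = mask[src] & mask[dst]
        if not valid.any():
            continue
        a = levels[src][valid]
        b = levels[dst][valid]
        counts += np.bincount(a * n_bins + b,
                              minlength=n_bins * n_bins).reshape(n_bins, n_bins)
    counts = counts + counts.T
    total = counts.sum()
    if total == 0:
        raise ValueError("no in-ROI voxel pairs for any offset "
                         "(single-voxel or disconnected ROI)")
    return counts / total


def glcm_stats(P: np.ndarray) -> dict[str, float]:
    """The 27 co-occurrence statistics of a normalised symmetric GLCM."""
    n = P.shape[0]
    i = np.arange(1, n + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = np.sqrt(sigma2)

    diff = np.abs(ii - jj)
    p_diff = np.array([P[diff == k].sum() for k in range(n)])
    ks = np.arange(n, dtype=float)
    p_sum = np.array([P[(ii + jj) == s].sum() for s in range(2, 2 * n + 1)])
    ss = np.arange(2, 2 * n + 1, dtype=float)

    def _ent(p):
        p = p[p > 0]
        return float(-(p * np.log2(p)).sum()) if p.size else 0.0

    autocorr = float((ii * jj * P).sum())
    contrast = float(((ii - jj) ** 2 * P).sum())
    corr = ((autocorr - mu * mu) / sigma2) if sigma2 > 0 else 1.0
    diff_avg = float((ks * p_diff).sum())
    sum_avg = float((ss * p_sum).sum())

    HX = _ent(px)
    HXY = _ent(P.ravel())
    pxpy = np.outer(px, px)
    nz = (P > 0) & (pxpy > 0)
    HXY1 = float(-(P[nz] * np.log2(pxpy[nz])).sum())
    nz2 = pxpy > 0
    HXY2 = float(-(pxpy[nz2] * np.log2(pxpy[nz2])).sum())
    imc1 = (HXY - HXY1) / HX if HX > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1 - np.exp(-2 * (HXY2 - HXY)))))

    # Maximal correlation coefficient: sqrt of the second-largest eigenvalue
    # of Q(i,j) = sum_k P(i,k) P(j,k) / (px(i) px(k)).
    keep = px > 0
    if keep.sum() >= 2:
        Pk = P[np.ix_(keep, keep)]
        pxk = px[keep]
        Q = (Pk / pxk[:, None]) @ (Pk / pxk[None, :]).T
        ev = np.sort(np.real(np.linalg.eigvals(Q)))
        mcc = float(np.sqrt(np.clip(ev[-2], 0.0, 1.0)))
    else:
        mcc = 1.0

    inv_var_mask = diff > 0
    return {
        "autocorrelation": autocorr,
        "cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * P).sum()),
        "cluster_shade": float(((ii + jj - 2 * mu) ** 3 * P).sum()),
        "cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * P).sum()),
        "contrast": contrast,
        "correlation": float(corr),
        "difference_average": diff_avg,
        "difference_entropy": _ent(p_diff),
        "difference_variance": float(((ks - diff_avg) ** 2 * p_diff).sum()),
        "dissimilarity": float((diff * P).sum()),
        "homogeneity": float((P / (1 + diff)).sum()),
        "id": float((P / (1 + diff)).sum()),
        "idm": float((P / (1 + diff ** 2)).sum()),
        "idmn": float((P / (1 + (diff / n) ** 2)).sum()),
        "idn": float((P / (1 + diff / n)).sum()),
        "imc1": float(imc1),
        "imc2": imc2,
        "inverse_variance": float((P[inv_var_mask] /
                                   diff[inv_var_mask] ** 2).sum()),
        "joint_average": mu,
        "joint_energy": float((P ** 2).sum()),
        "joint_entropy": HXY,
        "joint_variance": float(((ii - mu) ** 2 * P).sum()),
        "maximum_probability": float(P.max()),
        "mcc": mcc,
        "sum_average": sum_avg,
        "sum_entropy": _ent(p_sum),
        "sum_variance": float(((ss - sum_avg) ** 2 * p_sum).sum()),
    }


def _glcm_from_band(band: np.ndarray, mask: np.ndarray,
                    cfg: HCConfig) -> dict[str, float]:
    levels = quantise(band[mask], cfg.n_bins)
    full = np.zeros(band.shape, dtype=np.intp)
    full[mask] = levels
    return glcm_stats(glcm_matrix(full, mask, cfg.n_bins, cfg.offsets))


def glcm_features(vm: VolumeWithMask, n_bins: int = 32,
                  offsets: tuple[tuple[int, int, int], ...] = DEFAULT_OFFSETS
                  ) -> FeatureVector:
    """27 co-occurrence texture statistics of the quantised ROI."""
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if vm.mask.sum() < 2:
        raise ValueError("GLCM needs an ROI with at least 2 voxels")
    cfg = HCConfig(n_bins=n_bins, offsets=offsets)
    stats = _glcm_from_band(vm.intensities, vm.mask, cfg)
    return FeatureVector(
        values=[stats[k] for k in GLCM_NAMES],
        names=[f"glcm.{k}" for k in GLCM_NAMES],
        block="HC",
    )


# -------------------------------------------------------------------- wavelet

def wavelet_bands(volume: np.ndarray, wavelet: str = "coif1"
                  ) -> dict[str, np.ndarray]:
    """Single-level undecimated 3D wavelet transform, 8 bands LLL..HHH.

    Band arrays keep the input shape, so the original ROI mask applies
    unchanged.  Axes are edge-padded to even length before the transform
    and cropped back.
    """
    w = pywt.Wavelet(wavelet)
    if min(volume.shape) < w.dec_len:
        short = int(np.argmin(volume.shape))
        raise ValueError(
            f"axis {short} (length {volume.shape[short]}) shorter than the "
            f"{wavelet} filter length {w.dec_len}"
        )
    pad = [(0, s % 2) for s in volume.shape]
    padded = np.pad(volume, pad, mode="edge")
    coeffs = pywt.swtn(padded, wavelet, level=1)[0]
    crop = tuple(slice(0, s) for s in volume.shape)
    out = {}
    for key, band in coeffs.items():
        name = key.upper().replace("A", "L").replace("D", "H")
        out[name] = band[crop]
    return {b: out[b] for b in WAVELET_BANDS}


def wavelet_features(vm: VolumeWithMask, config: HCConfig | None = None
                     ) -> FeatureVector:
    """First-order + GLCM statistics on each of the 8 wavelet bands (368)."""
    cfg = config or HCConfig()
    bands = wavelet_bands(vm.intensities, cfg.wavelet)
    values: list[float] = []
    names: list[str] = []
    for bname, band in bands.items():
        fo = _first_order_stats(band[vm.mask], cfg.entropy_bins)
        values += [fo[n] for n in FIRST_ORDER_NAMES]
        names += [f"wavelet.{bname}.firstorder.{n}" for n in FIRST_ORDER_NAMES]
        gl = _glcm_from_band(band, vm.mask, cfg)
        values += [gl[n] for n in GLCM_NAMES]
        names += [f"wavelet.{bname}.glcm.{n}" for n in GLCM_NAMES]
    return FeatureVector(values=values, names=names, block="HC")


# ------------------------------------------------------------------ catalogue

def extract_hc(vm: VolumeWithMask, config: HCConfig | None = None
               ) -> FeatureVector:
    """The full 431-feature handcrafted catalogue for one patient."""
    cfg = config or HCConfig()
    fv = first_order(vm, cfg.entropy_bins)
    fv = fv.concat(shape_features(vm))
    fv = fv.concat(glcm_features(vm, cfg.n_bins, cfg.offsets))
    fv = fv.concat(wavelet_features(vm, cfg))
    return fv


def hc_feature_names(config: HCConfig | None = None) -> list[str]:
    """Names of the default catalogue in extraction order (length 431)."""
    names = [f"firstorder.{n}" for n in FIRST_ORDER_NAMES]
    names += [f"shape.{n}" for n in SHAPE_NAMES]
    names += [f"glcm.{n}" for n in GLCM_NAMES]
    for b in WAVELET_BANDS:
        names += [f"wavelet.{b}.firstorder.{n}" for n in FIRST_ORDER_NAMES]
        names += [f"wavelet.{b}.glcm.{n}" for n in GLCM_NAMES]
    return names
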