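"""Radiomic feature formulas.

Each family function maps its count structure to an ordered dict of named
feature values. Formulas follow the standard reference definitions for
2D, mask-respecting analysis; logarithms are base 2; population (biased)
moments are used throughout.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage import measure

from ..preprocess import ROIMask
from .matrices import NGTDMData

_EPS = np.spacing(1.0)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------- intensity

def intensity_statistics(img: np.ndarray, mask: ROIMask) -> dict[str, float]:
    """18 intensity-based statistical features on in-mask intensities."""
    x = np.asarray(img, dtype=float)[mask.mask]
    if x.size == 0:
        raise ValueError("empty mask")
    mean = x.mean()
    var = x.var()
    sd = np.sqrt(var)
    cm3 = ((x - mean) ** 3).mean()
    cm4 = ((x - mean) ** 4).mean()
    skew = cm3 / sd**3 if sd > 0 else 0.0
    kurt = cm4 / var**2 - 3.0 if var > 0 else 0.0
    p10, q1, med, q3, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    return {
        "stat_mean": float(mean),
        "stat_variance": float(var),
        "stat_skewness": float(skew),
        "stat_kurtosis": float(kurt),
        "stat_median": float(med),
        "stat_minimum": float(x.min()),
        "stat_p10": float(p10),
        "stat_p90": float(p90),
        "stat_maximum": float(x.max()),
        "stat_interquartile_range": float(q3 - q1),
        "stat_range": float(x.max() - x.min()),
        "stat_mean_absolute_deviation": float(np.abs(x - mean).mean()),
        "stat_robust_mean_absolute_deviation":
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "stat_median_absolute_deviation": float(np.abs(x - med).mean()),
        "stat_coefficient_of_variation": float(sd / mean) if mean != 0 else 0.0,
        "stat_quartile_coefficient_of_dispersion":
            float((q3 - q1) / (q3 + q1)) if (q3 + q1) != 0 else 0.0,
        "stat_energy": float((x**2).sum()),
        "stat_root_mean_square": float(np.sqrt((x**2).mean())),
    }


def _disc_kernel(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (yy**2 + xx**2 <= radius**2).astype(float)


def feature_intensity_range(img: np.ndarray, mask: ROIMask) -> float:
    """Max minus min of in-mask intensities."""
    x = np.asarray(img, dtype=float)[mask.mask]
    if x.size == 0:
        raise ValueError("empty mask")
    return float(x.max() - x.min())


def feature_local_intensity_peak(img: np.ndarray, mask: ROIMask,
                                 radius_px: int = 5) -> float:
    """Mean intensity over in-mask pixels within a disc of the global
    maximum pixel (ties resolved to the smallest row-major index)."""
    img = np.asarray(img, dtype=float)
    m = mask.mask
    if not m.any():
        raise ValueError("empty mask")
    masked = np.where(m, img, -np.inf)
    idx = np.unravel_index(np.argmax(masked), img.shape)
    yy, xx = np.mgrid[0:img.shape[0], 0:img.shape[1]]
    disc = ((yy - idx[0])**2 + (xx - idx[1])**2 <= radius_px**2) & m
    return float(img[disc].mean())


def feature_global_intensity_peak(img: np.ndarray, mask: ROIMask,
                                  radius_px: int = 5) -> float:
    """Largest disc-neighborhood mean over all in-mask center pixels."""
    img = np.asarray(img, dtype=float)
    m = mask.mask.astype(float)
    kern = _disc_kernel(radius_px)
    num = ndimage.convolve(img * m, kern, mode="constant")
    den = ndimage.convolve(m, kern, mode="constant")
    means = np.where(den > 0, num / np.maximum(den, _EPS), -np.inf)
    return float(means[mask.mask].max())


def local_intensity(img: np.ndarray, mask: ROIMask,
                    radius_px: int = 5) -> dict[str, float]:
    return {
        "loc_intensity_peak_local": feature_local_intensity_peak(img, mask, radius_px),
        "loc_intensity_peak_global": feature_global_intensity_peak(img, mask, radius_px),
    }


# ---------------------------------------------------------------- histogram

def intensity_histogram(levels_in_mask: np.ndarray, n_levels: int) -> dict[str, float]:
    """23 intensity-histogram features on the discretized levels."""
    h = np.asarray(levels_in_mask, dtype=float)
    if h.size == 0:
        raise ValueError("empty mask")
    n_i = np.bincount(h.astype(int), minlength=n_levels + 1)[1:].astype(float)
    p = n_i / h.size
    mean = h.mean()
    var = h.var()
    sd = np.sqrt(var)
    skew = ((h - mean) ** 3).mean() / sd**3 if sd > 0 else 0.0
    kurt = ((h - mean) ** 4).mean() / var**2 - 3.0 if var > 0 else 0.0
    p10, q1, med, q3, p90 = np.percentile(h, [10, 25, 50, 75, 90])
    robust = h[(h >= p10) & (h <= p90)]
    mode = float(np.argmax(n_i) + 1)  # lowest level wins ties via argmax
    # histogram gradient on occurrence counts, central differences
    if n_levels >= 2:
        grad = np.gradient(n_i)
    else:
        grad = np.zeros(1)
    return {
        "ih_mean": float(mean),
        "ih_variance": float(var),
        "ih_skewness": float(skew),
        "ih_kurtosis": float(kurt),
        "ih_median": float(med),
        "ih_minimum": float(h.min()),
        "ih_p10": float(p10),
        "ih_p90": float(p90),
        "ih_maximum": float(h.max()),
        "ih_mode": mode,
        "ih_interquartile_range": float(q3 - q1),
        "ih_range": float(h.max() - h.min()),
        "ih_mean_absolute_deviation": float(np.abs(h - mean).mean()),
        "ih_robust_mean_absolute_deviation":
            float(np.abs(robust - robust.mean()).mean()) if robust.size else 0.0,
        "ih_median_absolute_deviation": float(np.abs(h - med).mean()),
        "ih_coefficient_of_variation": float(sd / mean) if mean != 0 else 0.0,
        "ih_quartile_coefficient_of_dispersion":
            float((q3 - q1) / (q3 + q1)) if (q3 + q1) != 0 else 0.0,
        "ih_entropy": _entropy(p),
        "ih_uniformity": float((p**2).sum()),
        "ih_max_histogram_gradient": float(grad.max()),
        "ih_max_histogram_gradient_level": float(np.argmax(grad) + 1),
        "ih_min_histogram_gradient": float(grad.min()),
        "ih_min_histogram_gradient_level": float(np.argmin(grad) + 1),
    }


# ---------------------------------------------------------------- GLCM

def glcm_features(P: np.ndarray) -> dict[str, float]:
    """25 co-occurrence features on a normalized symmetric GLCM."""
    ng = P.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)                       # marginal (symmetric: px == py)
    mu = float((ii * P).sum())               # joint average
    var = float(((ii - mu) ** 2 * P).sum())  # joint variance
    # diagonal and cross-diagonal probabilities
    k_diff = np.arange(0, ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), P.ravel())
    k_sum = np.arange(2, 2 * ng + 1)
    p_sum = np.zeros(2 * ng - 1)
    np.add.at(p_sum, (ii + jj).ravel() - 2, P.ravel())
    diff_avg = float((k_diff * p_diff).sum())
    sum_avg = float((k_sum * p_sum).sum())
    hxy = _entropy(P.ravel())
    hx = _entropy(px)
    pxpy = np.outer(px, px)
    with np.errstate(divide="ignore"):
        hxy1 = float(-(P[pxpy > 0] * np.log2(pxpy[pxpy > 0])).sum())
        hxy2 = _entropy(pxpy.ravel())
    ic1 = (hxy - hxy1) / hx if hx > 0 else 0.0
    ic2 = np.sqrt(max(0.0, 1.0 - 2.0 ** (-2.0 * (hxy2 - hxy)))) if hxy2 >= hxy else 0.0
    inv_var_mask = ii != jj
    corr = float(((ii - mu) * (jj - mu) * P).sum() / var) if var > 0 else 1.0
    return {
        "glcm_joint_maximum": float(P.max()),
        "glcm_joint_average": mu,
        "glcm_joint_variance": var,
        "glcm_joint_entropy": hxy,
        "glcm_difference_average": diff_avg,
        "glcm_difference_variance": float(((k_diff - diff_avg) ** 2 * p_diff).sum()),
        "glcm_difference_entropy": _entropy(p_diff),
        "glcm_sum_average": sum_avg,
        "glcm_sum_variance": float(((k_sum - sum_avg) ** 2 * p_sum).sum()),
        "glcm_sum_entropy": _entropy(p_sum),
        "glcm_angular_second_moment": float((P**2).sum()),
        "glcm_contrast": float(((ii - jj) ** 2 * P).sum()),
        "glcm_dissimilarity": float((np.abs(ii - jj) * P).sum()),
        "glcm_inverse_difference": float((P / (1.0 + np.abs(ii - jj))).sum()),
        "glcm_inverse_difference_normalised":
            float((P / (1.0 + np.abs(ii - jj) / ng)).sum()),
        "glcm_inverse_difference_moment": float((P / (1.0 + (ii - jj) ** 2)).sum()),
        "glcm_inverse_difference_moment_normalised":
            float((P / (1.0 + (ii - jj) ** 2 / ng**2)).sum()),
        "glcm_inverse_variance":
            float((P[inv_var_mask] / (ii - jj)[inv_var_mask] ** 2).sum()),
        "glcm_correlation": corr,
        "glcm_autocorrelation": float((ii * jj * P).sum()),
        "glcm_cluster_tendency": float(((ii + jj - 2 * mu) ** 2 * P).sum()),
        "glcm_cluster_shade": float(((ii + jj - 2 * mu) ** 3 * P).sum()),
        "glcm_cluster_prominence": float(((ii + jj - 2 * mu) ** 4 * P).sum()),
        "glcm_information_correlation_1": float(ic1),
        "glcm_information_correlation_2": float(ic2),
    }


# ------------------------------------------------- run/zone/distance families

def _rl_style_features(P: np.ndarray, n_pixels: int, prefix: str,
                       j_name: str, n_denominator: int) -> dict[str, float]:
    """Shared 16-feature block for GLRLM/GLSZM/GLDZM-style matrices.

    ``P`` holds counts indexed by (gray level i, attribute j) where the
    attribute is run length, zone size or zone distance; ``n_denominator``
    is the pixel budget for the percentage feature (pixel count times the
    number of merged directions for runs, the plain pixel count for zones).
    """
    ns = P.sum()
    if ns <= 0:
        raise ValueError("empty count matrix")
    ng, jm = P.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, jm + 1)[None, :]
    p = P / ns
    si = P.sum(axis=1)
    sj = P.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    return {
        f"{prefix}_short_{j_name}_emphasis": float((P / j**2).sum() / ns),
        f"{prefix}_long_{j_name}_emphasis": float((P * j**2).sum() / ns),
        f"{prefix}_low_gray_level_emphasis": float((P / i**2).sum() / ns),
        f"{prefix}_high_gray_level_emphasis": float((P * i**2).sum() / ns),
        f"{prefix}_short_{j_name}_low_gray_level_emphasis":
            float((P / (i**2 * j**2)).sum() / ns),
        f"{prefix}_short_{j_name}_high_gray_level_emphasis":
            float((P * i**2 / j**2).sum() / ns),
        f"{prefix}_long_{j_name}_low_gray_level_emphasis":
            float((P * j**2 / i**2).sum() / ns),
        f"{prefix}_long_{j_name}_high_gray_level_emphasis":
            float((P * i**2 * j**2).sum() / ns),
        f"{prefix}_gray_level_nonuniformity": float((si**2).sum() / ns),
        f"{prefix}_gray_level_nonuniformity_normalised": float((si**2).sum() / ns**2),
        f"{prefix}_{j_name}_nonuniformity": float((sj**2).sum() / ns),
        f"{prefix}_{j_name}_nonuniformity_normalised": float((sj**2).sum() / ns**2),
        f"{prefix}_{j_name}_percentage": float(ns / n_denominator),
        f"{prefix}_gray_level_variance": float(((i - mu_i) ** 2 * p).sum()),
        f"{prefix}_{j_name}_variance": float(((j - mu_j) ** 2 * p).sum()),
        f"{prefix}_{j_name}_entropy": _entropy(p.ravel()),
    }


def glrlm_features(P: np.ndarray, n_pixels: int,
                   n_directions: int = 4) -> dict[str, float]:
    """16 run-length features (merged over directions)."""
    return _rl_style_features(P, n_pixels, "glrlm", "run",
                              n_pixels * n_directions)


def glszm_features(P: np.ndarray, n_pixels: int) -> dict[str, float]:
    """16 size-zone features."""
    return _rl_style_features(P, n_pixels, "glszm", "zone", n_pixels)


def gldzm_features(P: np.ndarray, n_pixels: int) -> dict[str, float]:
    """16 distance-zone features."""
    return _rl_style_features(P, n_pixels, "gldzm", "distance", n_pixels)


def feature_sre(glrlm: np.ndarray) -> float:
    """Short runs emphasis: (1/N_r) Σ P(i,j)/j² — low for long, organized
    linear collagen networks, high for fragmented ECM structure."""
    ns = glrlm.sum()
    if ns <= 0:
        raise ValueError("empty run-length matrix")
    j = np.arange(1, glrlm.shape[1] + 1)[None, :]
    return float((glrlm / j**2).sum() / ns)


# ---------------------------------------------------------------- NGTDM

def ngtdm_features(data: NGTDMData) -> dict[str, float]:
    """5 neighborhood gray-tone difference features."""
    p, s, n = data.p_i, data.s_i, data.n_i
    nv = data.n_valid
    present = p > 0
    ngp = int(present.sum())
    i = np.arange(1, p.size + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pp = np.outer(p, p)
    pair = np.outer(present, present)
    coarse_den = float((p * s).sum())
    coarseness = 1.0 / coarse_den if coarse_den > 0 else 1e6
    if ngp > 1 and nv > 0:
        contrast = (float((pp[pair] * (ii - jj)[pair] ** 2).sum())
                    / (ngp * (ngp - 1))) * (s.sum() / nv)
    else:
        contrast = 0.0
    busy_den = float(np.abs((i * p)[present][:, None]
                            - (i * p)[present][None, :]).sum())
    busyness = coarse_den / busy_den if busy_den > 0 else 0.0
    if nv > 0:
        with np.errstate(invalid="ignore"):
            num = np.abs(ii - jj) * (np.outer(p * s, np.ones_like(p))
                                     + np.outer(np.ones_like(p), p * s))
            den = np.outer(p, np.ones_like(p)) + np.outer(np.ones_like(p), p)
            complexity = float((num[pair] / den[pair]).sum()) / nv
    else:
        complexity = 0.0
    strength_num = float(((np.outer(p, np.ones_like(p))
                           + np.outer(np.ones_like(p), p))[pair]
                          * (ii - jj)[pair] ** 2).sum())
    strength = strength_num / (_EPS + s.sum())
    return {
        "ngtdm_coarseness": float(coarseness),
        "ngtdm_contrast": float(contrast),
        "ngtdm_busyness": float(busyness),
        "ngtdm_complexity": float(complexity),
        "ngtdm_strength": float(strength),
    }


def feature_texture_strength(data: NGTDMData) -> float:
    """Texture strength — large when coarse, high-contrast structure (e.g.
    bundled collagen) stands out from the background."""
    return ngtdm_features(data)["ngtdm_strength"]


# ---------------------------------------------------------------- NGLDM

def ngldm_features(S: np.ndarray, n_pixels: int) -> dict[str, float]:
    """17 neighboring gray-level dependence features."""
    ns = S.sum()
    if ns <= 0:
        raise ValueError("empty dependence matrix")
    ng, jm = S.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, jm + 1)[None, :]
    p = S / ns
    si = S.sum(axis=1)
    sj = S.sum(axis=0)
    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    return {
        "ngldm_low_dependence_emphasis": float((S / j**2).sum() / ns),
        "ngldm_high_dependence_emphasis": float((S * j**2).sum() / ns),
        "ngldm_low_gray_level_count_emphasis": float((S / i**2).sum() / ns),
        "ngldm_high_gray_level_count_emphasis": float((S * i**2).sum() / ns),
        "ngldm_low_dependence_low_gray_level_emphasis":
            float((S / (i**2 * j**2)).sum() / ns),
        "ngldm_low_dependence_high_gray_level_emphasis":
            float((S * i**2 / j**2).sum() / ns),
        "ngldm_high_dependence_low_gray_level_emphasis":
            float((S * j**2 / i**2).sum() / ns),
        "ngldm_high_dependence_high_gray_level_emphasis":
            float((S * i**2 * j**2).sum() / ns),
        "ngldm_gray_level_nonuniformity": float((si**2).sum() / ns),
        "ngldm_gray_level_nonuniformity_normalised": float((si**2).sum() / ns**2),
        "ngldm_dependence_count_nonuniformity": float((sj**2).sum() / ns),
        "ngldm_dependence_count_nonuniformity_normalised":
            float((sj**2).sum() / ns**2),
        "ngldm_dependence_count_percentage": float(ns / n_pixels),
        "ngldm_gray_level_variance": float(((i - mu_i) ** 2 * p).sum()),
        "ngldm_dependence_count_variance": float(((j - mu_j) ** 2 * p).sum()),
        "ngldm_dependence_count_entropy": _entropy(p.ravel()),
        "ngldm_dependence_count_energy": float((p**2).sum()),
    }


def feature_hdhge(S: np.ndarray, n_pixels: int) -> float:
    """High dependence high gray level emphasis: (1/N_v) Σ s(i,j) i² j² —
    large for bright, homogeneous neighborhoods."""
    if S.sum() <= 0:
        raise ValueError("empty dependence matrix")
    i = np.arange(1, S.shape[0] + 1)[:, None]
    j = np.arange(1, S.shape[1] + 1)[None, :]
    return float((S * i**2 * j**2).sum() / n_pixels)


# ---------------------------------------------------------------- morphology

def morphology_features(mask: ROIMask) -> dict[str, float]:
    """14 two-dimensional shape features of the ROI mask."""
    m = mask.mask
    if not m.any():
        raise ValueError("empty mask")
    props = measure.regionprops(m.astype(np.uint8))[0]
    area = float(props.area)
    perim = float(measure.perimeter(m)) or _EPS
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    return {
        "morph_area": area,
        "morph_perimeter": perim,
        "morph_perimeter_to_area": perim / area,
        "morph_circularity": 4.0 * np.pi * area / perim**2,
        "morph_equivalent_diameter": float(props.equivalent_diameter_area),
        "morph_major_axis_length": major,
        "morph_minor_axis_length": minor,
        "morph_elongation": minor / major if major > 0 else 1.0,
        "morph_eccentricity": float(props.eccentricity),
        "morph_solidity": float(props.solidity),
        "morph_convex_area": float(props.area_convex),
        "morph_extent": float(props.extent),
        "morph_euler_number": float(props.euler_number),
        "morph_feret_diameter_max": float(props.feret_diameter_max),
    }
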