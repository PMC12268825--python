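"""Texture count matrices on discretized 2D images.

All matrices follow the standard mask-respecting 2D conventions:

* neighborhoods are the 8-connected (Chebyshev radius 1) pixels, restricted
  to the mask;
* directional matrices (GLCM, GLRLM) are computed for the four planar
  directions 0°, 45°, 90°, 135° and summed ("merged" aggregation) before
  features are derived;
* zones (GLSZM, GLDZM) are 8-connected components of equal gray level;
* zone distance is the city-block distance to the ROI border, border
  pixels having distance 1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from .discretize import DiscretizedImage

#: (dr, dc) steps for 0, 45, 90, 135 degrees
DIRECTIONS: dict[int, tuple[int, int]] = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
}

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


@dataclasses.dataclass
class NGTDMData:
    """Per-level occurrence counts, probabilities and summed differences."""

    n_i: np.ndarray   # (N_g,) valid-pixel counts per level
    p_i: np.ndarray   # (N_g,) probabilities, sum 1
    s_i: np.ndarray   # (N_g,) summed |level - neighborhood mean|
    n_valid: int      # pixels with >= 1 in-mask neighbor


@dataclasses.dataclass
class TextureMatrices:
    """All texture count structures of one discretized channel."""

    glcm: np.ndarray          # (N_g, N_g) merged, symmetric, normalized
    glrlm: np.ndarray         # (N_g, R_max) merged run-length counts
    glszm: np.ndarray         # (N_g, S_max) zone-size counts
    gldzm: np.ndarray         # (N_g, D_max) zone-distance counts
    ngtdm: NGTDMData
    ngldm: np.ndarray         # (N_g, J_max) dependence counts
    n_pixels: int
    n_levels: int


def _pairs_for_offset(levels: np.ndarray, dr: int, dc: int) -> tuple[np.ndarray, np.ndarray]:
    """In-mask level pairs (a, b) for one displacement."""
    h, w = levels.shape
    r0s, r0e = max(0, -dr), min(h, h - dr)
    c0s, c0e = max(0, -dc), min(w, w - dc)
    a = levels[r0s:r0e, c0s:c0e]
    b = levels[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    ok = (a > 0) & (b > 0)
    return a[ok], b[ok]


def compute_glcm(d: DiscretizedImage, distance: int = 1) -> np.ndarray:
    """Direction-merged, symmetrized, normalized co-occurrence matrix."""
    ng = d.n_levels
    counts = np.zeros((ng, ng), dtype=float)
    for dr, dc in DIRECTIONS.values():
        a, b = _pairs_for_offset(d.levels, dr * distance, dc * distance)
        np.add.at(counts, (a - 1, b - 1), 1.0)
        np.add.at(counts, (b - 1, a - 1), 1.0)
    total = counts.sum()
    if total > 0:
        counts /= total
    return counts


def _lines_for_direction(levels: np.ndarray, angle: int) -> list[np.ndarray]:
    if angle == 0:
        return list(levels)
    if angle == 90:
        return list(levels.T)
    if angle == 45:
        flipped = np.fliplr(levels)
        return [np.diagonal(flipped, k)
                for k in range(-levels.shape[0] + 1, levels.shape[1])]
    if angle == 135:
        return [np.diagonal(levels, k)
                for k in range(-levels.shape[0] + 1, levels.shape[1])]
    raise ValueError(f"unsupported direction {angle}")


def _runs_1d(line: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(level, run_length) of maximal equal-level runs; level 0 runs dropped."""
    line = np.asarray(line)
    if line.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    change = np.flatnonzero(np.diff(line) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change + 1, [line.size]])
    vals = line[starts]
    lens = ends - starts
    keep = vals > 0
    return vals[keep].astype(np.int64), lens[keep].astype(np.int64)


def compute_glrlm(d: DiscretizedImage, direction: int | None = None) -> np.ndarray:
    """Run-length counts P(i, j); merged over directions if none given.

    Rows index gray level 1..N_g, columns run length 1..R_max. Out-of-mask
    pixels break runs.
    """
    angles = [direction] if direction is not None else list(DIRECTIONS)
    rmax = max(d.levels.shape)
    mat = np.zeros((d.n_levels, rmax), dtype=float)
    for angle in angles:
        for line in _lines_for_direction(d.levels, angle):
            vals, lens = _runs_1d(line)
            np.add.at(mat, (vals - 1, lens - 1), 1.0)
    # trim trailing all-zero run-length columns (keep at least one column)
    nz = np.flatnonzero(mat.sum(axis=0))
    last = nz[-1] if nz.size else 0
    return mat[:, :last + 1]


def _zone_matrix(d: DiscretizedImage, metric: str) -> np.ndarray:
    """Zone-size (metric='size') or zone-distance (metric='distance') counts."""
    levels = d.levels
    if metric == "distance":
        padded = np.pad(d.mask.mask, 1)
        dist = ndimage.distance_transform_cdt(padded, metric="taxicab")[1:-1, 1:-1]
    rows: list[tuple[int, int]] = []
    for lev in np.unique(levels[levels > 0]):
        lab, n_zones = cc_label(levels == lev, connectivity=2, return_num=True)
        if n_zones == 0:
            continue
        if metric == "size":
            sizes = np.bincount(lab.ravel())[1:]
            rows.extend((int(lev), int(s)) for s in sizes)
        else:
            mins = ndimage.minimum(dist, labels=lab, index=np.arange(1, n_zones + 1))
            rows.extend((int(lev), int(m)) for m in np.atleast_1d(mins))
    if not rows:
        return np.zeros((d.n_levels, 1))
    jmax = max(j for _, j in rows)
    mat = np.zeros((d.n_levels, jmax), dtype=float)
    for lev, j in rows:
        mat[lev - 1, j - 1] += 1.0
    return mat


def compute_glszm(d: DiscretizedImage) -> np.ndarray:
    """Gray-level size-zone counts (level x zone size)."""
    return _zone_matrix(d, "size")


def compute_gldzm(d: DiscretizedImage) -> np.ndarray:
    """Gray-level distance-zone counts (level x city-block border distance)."""
    return _zone_matrix(d, "distance")


def compute_ngtdm(d: DiscretizedImage) -> NGTDMData:
    """Neighborhood gray-tone difference data.

    For every in-mask pixel with at least one in-mask 8-neighbor, the
    absolute difference between its level and the mean level of those
    neighbors is accumulated per level.
    """
    m = d.mask.mask.astype(float)
    lev = d.levels.astype(float)
    nb_sum = ndimage.convolve(lev * m, _NEIGHBOR_KERNEL, mode="constant")
    nb_cnt = ndimage.convolve(m, _NEIGHBOR_KERNEL, mode="constant")
    valid = d.mask.mask & (nb_cnt > 0)
    ng = d.n_levels
    n_i = np.zeros(ng)
    s_i = np.zeros(ng)
    diffs = np.abs(lev[valid] - nb_sum[valid] / nb_cnt[valid])
    levs = d.levels[valid]
    np.add.at(n_i, levs - 1, 1.0)
    np.add.at(s_i, levs - 1, diffs)
    n_valid = int(valid.sum())
    p_i = n_i / n_valid if n_valid else n_i
    return NGTDMData(n_i=n_i, p_i=p_i, s_i=s_i, n_valid=n_valid)


def compute_ngldm(d: DiscretizedImage, alpha: float = 0.0,
                  chebyshev_radius: int = 1) -> np.ndarray:
    """Dependence counts s(i, j).

    A pixel of level i has dependence count j = 1 + number of in-mask
    neighbors (Chebyshev radius 1) whose level differs by at most alpha.
    """
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    if chebyshev_radius != 1:
        raise NotImplementedError("only Chebyshev radius 1 is supported")
    if d.n_pixels == 0:
        raise ValueError("empty mask")
    lev = d.levels
    m = d.mask.mask
    dep = np.zeros(lev.shape, dtype=np.int64)
    h, w = lev.shape
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            r0s, r0e = max(0, -dr), min(h, h - dr)
            c0s, c0e = max(0, -dc), min(w, w - dc)
            a = lev[r0s:r0e, c0s:c0e]
            b = lev[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
            bm = m[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
            dep[r0s:r0e, c0s:c0e] += (bm & (np.abs(a - b) <= alpha)).astype(np.int64)
    j = dep[m] + 1
    i = lev[m]
    mat = np.zeros((d.n_levels, int(j.max())), dtype=float)
    np.add.at(mat, (i - 1, j - 1), 1.0)
    return mat


def compute_all_matrices(d: DiscretizedImage, alpha: float = 0.0) -> TextureMatrices:
    return TextureMatrices(
        glcm=compute_glcm(d),
        glrlm=compute_glrlm(d),
        glszm=compute_glszm(d),
        gldzm=compute_gldzm(d),
        ngtdm=compute_ngtdm(d),
        ngldm=compute_ngldm(d, alpha=alpha),
        n_pixels=d.n_pixels,
        n_levels=d.n_levels,
    )
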