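"""Independent brute-force oracles for texture features.

Everything here is written as naive per-pixel / per-pair enumeration in
plain Python, deliberately sharing no code with the package's vectorized
implementations.
"""

from __future__ import annotations

import math

import numpy as np

NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)]

STEPS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def oracle_discretize(img, mask, n_levels):
    vals = [img[r, c] for r in range(img.shape[0])
            for c in range(img.shape[1]) if mask[r, c]]
    lo, hi = min(vals), max(vals)
    out = np.zeros(img.shape, dtype=int)
    for r in range(img.shape[0]):
        for c in range(img.shape[1]):
            if not mask[r, c]:
                continue
            if hi == lo:
                out[r, c] = 1
            else:
                out[r, c] = min(n_levels,
                                math.floor(n_levels * (img[r, c] - lo) / (hi - lo)) + 1)
    return out


def oracle_glrlm(levels, n_levels, direction):
    """Run-length counts by explicit line walking."""
    h, w = levels.shape
    dr, dc = STEPS[direction]
    # line starts: cells with no predecessor along (dr, dc)
    runs = {}
    for r0 in range(h):
        for c0 in range(w):
            pr, pc = r0 - dr, c0 - dc
            if 0 <= pr < h and 0 <= pc < w:
                continue  # not a line start
            r, c = r0, c0
            prev, length = 0, 0
            while 0 <= r < h and 0 <= c < w:
                v = levels[r, c]
                if v == prev and v > 0:
                    length += 1
                else:
                    if prev > 0:
                        runs[(prev, length)] = runs.get((prev, length), 0) + 1
                    prev, length = v, (1 if v > 0 else 0)
                r, c = r + dr, c + dc
            if prev > 0:
                runs[(prev, length)] = runs.get((prev, length), 0) + 1
    rmax = max((j for _, j in runs), default=1)
    mat = np.zeros((n_levels, rmax))
    for (i, j), n in runs.items():
        mat[i - 1, j - 1] = n
    return mat


def oracle_glrlm_merged(levels, n_levels):
    mats = [oracle_glrlm(levels, n_levels, d) for d in STEPS]
    rmax = max(m.shape[1] for m in mats)
    out = np.zeros((n_levels, rmax))
    for m in mats:
        out[:, :m.shape[1]] += m
    return out


def oracle_sre(glrlm):
    ns = glrlm.sum()
    total = 0.0
    for i in range(glrlm.shape[0]):
        for j in range(glrlm.shape[1]):
            total += glrlm[i, j] / (j + 1) ** 2
    return total / ns


def oracle_glcm(levels, n_levels):
    counts = np.zeros((n_levels, n_levels))
    h, w = levels.shape
    for r in range(h):
        for c in range(w):
            if levels[r, c] == 0:
                continue
            for dr, dc in STEPS.values():
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and levels[rr, cc] > 0:
                    counts[levels[r, c] - 1, levels[rr, cc] - 1] += 1
                    counts[levels[rr, cc] - 1, levels[r, c] - 1] += 1
    return counts / counts.sum() if counts.sum() else counts


def oracle_ngldm(levels, mask, n_levels, alpha=0.0):
    h, w = levels.shape
    entries = []
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            j = 1
            for dr, dc in NEIGHBORS8:
                rr, cc = r + dr, c + dc
                if (0 <= rr < h and 0 <= cc < w and mask[rr, cc]
                        and abs(int(levels[rr, cc]) - int(levels[r, c])) <= alpha):
                    j += 1
            entries.append((levels[r, c], j))
    jmax = max(j for _, j in entries)
    mat = np.zeros((n_levels, jmax))
    for i, j in entries:
        mat[i - 1, j - 1] += 1
    return mat


def oracle_hdhge(levels, mask, n_levels, alpha=0.0):
    mat = oracle_ngldm(levels, mask, n_levels, alpha)
    nv = int(mask.sum())
    total = 0.0
    for i in range(mat.shape[0]):
        for j in range(mat.shape[1]):
            total += mat[i, j] * (i + 1) ** 2 * (j + 1) ** 2
    return total / nv


def oracle_ngtdm(levels, mask, n_levels):
    h, w = levels.shape
    n_i = np.zeros(n_levels)
    s_i = np.zeros(n_levels)
    n_valid = 0
    for r in range(h):
        for c in range(w):
            if not mask[r, c]:
                continue
            nb = [int(levels[r + dr, c + dc]) for dr, dc in NEIGHBORS8
                  if 0 <= r + dr < h and 0 <= c + dc < w and mask[r + dr, c + dc]]
            if not nb:
                continue
            n_valid += 1
            i = int(levels[r, c])
            n_i[i - 1] += 1
            s_i[i - 1] += abs(i - sum(nb) / len(nb))
    p_i = n_i / n_valid if n_valid else n_i
    return n_i, p_i, s_i, n_valid


def oracle_texture_strength(levels, mask, n_levels):
    _, p, s, _ = oracle_ngtdm(levels, mask, n_levels)
    num = 0.0
    for i in range(n_levels):
        for j in range(n_levels):
            if p[i] > 0 and p[j] > 0:
                num += (p[i] + p[j]) * (i - j) ** 2
    return num / (np.spacing(1.0) + s.sum())


def oracle_glszm(levels, n_levels):
    """Zone sizes by breadth-first flood fill (8-connected)."""
    h, w = levels.shape
    seen = np.zeros((h, w), dtype=bool)
    zones = []
    for r in range(h):
        for c in range(w):
            if levels[r, c] == 0 or seen[r, c]:
                continue
            lev = levels[r, c]
            stack, size = [(r, c)], 0
            seen[r, c] = True
            while stack:
                rr, cc = stack.pop()
                size += 1
                for dr, dc in NEIGHBORS8:
                    nr, nc = rr + dr, cc + dc
                    if (0 <= nr < h and 0 <= nc < w and not seen[nr, nc]
                            and levels[nr, nc] == lev):
                        seen[nr, nc] = True
                        stack.append((nr, nc))
            zones.append((lev, size))
    smax = max(s for _, s in zones)
    mat = np.zeros((n_levels, smax))
    for i, s in zones:
        mat[i - 1, s - 1] += 1
    return mat


def oracle_intensity_range(img, mask):
    vals = [img[r, c] for r in range(img.shape[0])
            for c in range(img.shape[1]) if mask[r, c]]
    return max(vals) - min(vals)


def oracle_local_intensity_peak(img, mask, radius):
    h, w = img.shape
    best, best_pos = -np.inf, None
    for r in range(h):
        for c in range(w):
            if mask[r, c] and img[r, c] > best:
                best, best_pos = img[r, c], (r, c)
    vals = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and ((r - best_pos[0]) ** 2
                               + (c - best_pos[1]) ** 2) <= radius ** 2:
                vals.append(img[r, c])
    return sum(vals) / len(vals)


def oracle_bin(img, factor):
    h = (img.shape[0] // factor) * factor
    w = (img.shape[1] // factor) * factor
    out = np.zeros((h // factor, w // factor))
    for r in range(out.shape[0]):
        for c in range(out.shape[1]):
            block = [img[r * factor + i, c * factor + j]
                     for i in range(factor) for j in range(factor)]
            out[r, c] = sum(block) / len(block)
    return out


def oracle_mrmr_scores(disc_features, y, selected, candidate):
    """mRMR score of one candidate given already-selected columns."""
    def mi(a, b):
        a = np.asarray(a)
        b = np.asarray(b)
        total = 0.0
        n = len(a)
        for va in set(a.tolist()):
            for vb in set(b.tolist()):
                p_ab = ((a == va) & (b == vb)).sum() / n
                if p_ab == 0:
                    continue
                p_a = (a == va).sum() / n
                p_b = (b == vb).sum() / n
                total += p_ab * math.log(p_ab / (p_a * p_b))
        return total

    rel = mi(disc_features[candidate], y)
    if not selected:
        return rel
    red = sum(mi(disc_features[candidate], disc_features[s]) for s in selected)
    return rel - red / len(selected)
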