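"""Fixed-bin-number intensity discretization.

Texture matrices are defined on images quantized to a small number of
gray levels. The fixed-bin-number scheme is used (appropriate for
arbitrary-unit microscopy intensities): in-mask intensities are mapped to
levels 1..N_g by

    level = min(N_g, floor(N_g * (x - min) / (max - min)) + 1)

computed within the mask; a constant region maps entirely to level 1.
Pixels outside the mask carry level 0 and are excluded everywhere.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ..preprocess import ROIMask


@dataclasses.dataclass
class DiscretizedImage:
    """Integer level image (1..n_levels in-mask, 0 outside) plus its mask."""

    levels: np.ndarray
    n_levels: int
    mask: ROIMask

    @property
    def in_mask_levels(self) -> np.ndarray:
        return self.levels[self.mask.mask]

    @property
    def n_pixels(self) -> int:
        return self.mask.n_pixels


def discretize(img: np.ndarray, mask: ROIMask, n_levels: int = 32) -> DiscretizedImage:
    """Quantize in-mask intensities to ``n_levels`` gray levels."""
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    m = mask.mask
    if not m.any():
        raise ValueError("empty mask")
    img = np.asarray(img, dtype=float)
    vals = img[m]
    lo, hi = vals.min(), vals.max()
    levels = np.zeros(img.shape, dtype=np.int64)
    if hi == lo:
        levels[m] = 1
    else:
        q = np.floor(n_levels * (img[m] - lo) / (hi - lo)).astype(np.int64) + 1
        levels[m] = np.minimum(q, n_levels)
    return DiscretizedImage(levels=levels, n_levels=n_levels, mask=mask)
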