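"""MPM plane preprocessing: binning, normalization, masking.

Feature extraction operates on masked, normalized planes. Masks are made
per channel by automated (Otsu) or fixed thresholding followed by a
morphological opening, and the working ROI mask is the pixelwise OR of
the SHG and TPEF masks — the TPEF signal extends laterally beyond the
SHG signal, so the union captures the full tissue footprint at the cost
of admitting some background into the SHG channel.
"""

from __future__ import annotations

import dataclasses
import enum

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening

from .synthetic.mpm import MPMPlane


class MaskSource(str, enum.Enum):
    SHG_AUTO = "shg_auto"
    TPEF_AUTO = "tpef_auto"
    OR_COMBINED = "or_combined"
    MANUAL = "manual"


@dataclasses.dataclass
class ROIMask:
    """Boolean region-of-interest mask for one plane."""

    mask: np.ndarray
    source: MaskSource

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclasses.dataclass(frozen=True)
class PreprocessConfig:
    """Binning / normalization / masking settings."""

    bin_factor: int = 1
    normalization: str = "minmax"          # minmax | zscore | none
    auto_threshold: str = "otsu"           # otsu | fixed
    fixed_threshold: float | None = None
    morph_open_radius_px: int = 1

    def validate(self) -> None:
        if self.bin_factor < 1:
            raise ValueError("bin_factor must be >= 1")
        if self.normalization not in ("minmax", "zscore", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if self.auto_threshold not in ("otsu", "fixed"):
            raise ValueError(f"unknown auto_threshold {self.auto_threshold!r}")
        if self.auto_threshold == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed_threshold required when auto_threshold='fixed'")
        if self.morph_open_radius_px < 0:
            raise ValueError("morph_open_radius_px must be >= 0")


class EmptyMaskError(ValueError):
    """Raised when thresholding leaves no foreground pixels."""


def bin_image(img: np.ndarray, factor: int) -> np.ndarray:
    """Downsample by block averaging over ``factor`` x ``factor`` blocks.

    If ``factor`` does not divide a dimension the image is cropped to the
    largest divisible region first.
    """
    if factor < 1:
        raise ValueError("bin factor must be >= 1")
    img = np.asarray(img, dtype=float)
    if factor == 1:
        return img.copy()
    h = (img.shape[0] // factor) * factor
    w = (img.shape[1] // factor) * factor
    img = img[:h, :w]
    return img.reshape(h // factor, factor, w // factor, factor).mean(axis=(1, 3))


def normalize_channel(img: np.ndarray, method: str = "minmax") -> np.ndarray:
    """Per-plane intensity normalization.

    ``minmax`` maps the in-plane minimum to 0 and maximum to 1 (a constant
    image maps to all zeros); ``zscore`` maps to mean 0, sd 1; ``none``
    returns a copy.
    """
    img = np.asarray(img, dtype=float)
    if not np.all(np.isfinite(img)):
        raise ValueError("image must be finite")
    if method == "none":
        return img.copy()
    if method == "minmax":
        lo, hi = img.min(), img.max()
        if hi == lo:
            return np.zeros_like(img)
        return (img - lo) / (hi - lo)
    if method == "zscore":
        sd = img.std()
        if sd == 0:
            return np.zeros_like(img)
        return (img - img.mean()) / sd
    raise ValueError(f"unknown normalization {method!r}")


def auto_mask(img: np.ndarray, cfg: PreprocessConfig,
              source: MaskSource = MaskSource.MANUAL) -> ROIMask:
    """Threshold a normalized channel into a foreground mask.

    Otsu's method (or the configured fixed threshold) selects foreground,
    then a binary opening with the configured disk radius removes speckle.
    An all-background result raises :class:`EmptyMaskError`.
    """
    cfg.validate()
    img = np.asarray(img, dtype=float)
    if cfg.auto_threshold == "fixed":
        thr = float(cfg.fixed_threshold)
    else:
        if img.max() == img.min():
            raise EmptyMaskError("constant image has no foreground")
        thr = threshold_otsu(img)
    mask = img > thr
    if cfg.morph_open_radius_px > 0 and mask.any():
        mask = opening(mask, disk(cfg.morph_open_radius_px))
    if not mask.any():
        raise EmptyMaskError("thresholding produced an empty mask")
    return ROIMask(mask=mask, source=source)


def combine_masks_or(m1: ROIMask, m2: ROIMask) -> ROIMask:
    """Pixelwise OR of two masks (the default training mask)."""
    if m1.shape != m2.shape:
        raise ValueError("masks must share a shape")
    return ROIMask(mask=m1.mask | m2.mask, source=MaskSource.OR_COMBINED)


@dataclasses.dataclass
class PreprocessedPlane:
    """Binned, normalized plane plus its per-channel and combined masks."""

    plane: MPMPlane
    shg: np.ndarray
    tpef: np.ndarray
    mask_shg: ROIMask
    mask_tpef: ROIMask
    mask: ROIMask


def preprocess_plane(plane: MPMPlane,
                     cfg: PreprocessConfig | None = None) -> PreprocessedPlane:
    """Full per-plane chain: bin → normalize → per-channel mask → OR."""
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    shg = normalize_channel(bin_image(plane.shg, cfg.bin_factor), cfg.normalization)
    tpef = normalize_channel(bin_image(plane.tpef, cfg.bin_factor), cfg.normalization)
    m_shg = auto_mask(shg, cfg, MaskSource.SHG_AUTO)
    m_tpef = auto_mask(tpef, cfg, MaskSource.TPEF_AUTO)
    return PreprocessedPlane(plane=plane, shg=shg, tpef=tpef,
                             mask_shg=m_shg, mask_tpef=m_tpef,
                             mask=combine_masks_or(m_shg, m_tpef))
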