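"""Feature registry and per-plane extraction.

The default registry assembles 152 features per channel:

==========================  =====
local intensity                 2
intensity-based statistics     18
intensity histogram            23
GLCM (direction-merged)        25
GLRLM                          16
GLSZM                          16
GLDZM                          16
NGTDM                           5
NGLDM                          17
2D morphology of the mask      14
==========================  =====

Both channels of a plane are extracted on the shared (OR-combined by
default) mask, giving 304 features per plane.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np
import pandas as pd

from ..preprocess import (
    MaskSource,
    PreprocessConfig,
    PreprocessedPlane,
    ROIMask,
    preprocess_plane,
)
from ..synthetic.mpm import MPMPlane
from . import features as F
from .discretize import discretize
from .matrices import DIRECTIONS, compute_all_matrices

REGISTRY_VERSION = "1.0"

_FAMILY_COUNTS = {
    "loc": 2, "stat": 18, "ih": 23, "glcm": 25, "glrlm": 16,
    "glszm": 16, "gldzm": 16, "ngtdm": 5, "ngldm": 17, "morph": 14,
}


@dataclasses.dataclass(frozen=True)
class FeatureConfig:
    """Extraction knobs: discretization depth, NGLDM alpha, peak radius."""

    n_levels: int = 32
    ngldm_alpha: float = 0.0
    peak_radius_px: int = 5
    registry_version: str = REGISTRY_VERSION


def registry_feature_names(cfg: FeatureConfig | None = None) -> list[str]:
    """The ordered 152 feature names of the default registry."""
    dummy = np.zeros((8, 8))
    dummy[2:6, 2:6] = np.arange(16).reshape(4, 4)
    mask = ROIMask(mask=np.ones((8, 8), dtype=bool), source=MaskSource.MANUAL)
    vec = extract_channel(dummy, mask, cfg or FeatureConfig())
    return list(vec)


def extract_channel(img: np.ndarray, mask: ROIMask,
                    cfg: FeatureConfig | None = None) -> dict[str, float]:
    """All 152 registry features of one channel on one mask."""
    cfg = cfg or FeatureConfig()
    if not mask.mask.any():
        raise ValueError("empty mask")
    out: dict[str, float] = {}
    out.update(F.local_intensity(img, mask, cfg.peak_radius_px))
    out.update(F.intensity_statistics(img, mask))
    d = discretize(img, mask, cfg.n_levels)
    out.update(F.intensity_histogram(d.in_mask_levels, cfg.n_levels))
    mats = compute_all_matrices(d, alpha=cfg.ngldm_alpha)
    out.update(F.glcm_features(mats.glcm))
    out.update(F.glrlm_features(mats.glrlm, mats.n_pixels, len(DIRECTIONS)))
    out.update(F.glszm_features(mats.glszm, mats.n_pixels))
    out.update(F.gldzm_features(mats.gldzm, mats.n_pixels))
    out.update(F.ngtdm_features(mats.ngtdm))
    out.update(F.ngldm_features(mats.ngldm, mats.n_pixels))
    out.update(F.morphology_features(mask))
    bad = [k for k, v in out.items() if not np.isfinite(v)]
    if bad:
        raise ValueError(f"non-finite feature value(s): {', '.join(bad)}")
    expected = sum(_FAMILY_COUNTS.values())
    if len(out) != expected:
        raise RuntimeError(f"registry produced {len(out)} features, "
                           f"expected {expected}")
    return out


def extract_all(plane: MPMPlane, mask: ROIMask,
                cfg: FeatureConfig | None = None,
                pre: PreprocessedPlane | None = None,
                ) -> tuple[dict[str, float], dict[str, float]]:
    """Extract (SHG vector, TPEF vector) for one plane on a shared mask.

    If ``pre`` is given its normalized channels are used; otherwise the raw
    plane channels are.
    """
    shg = pre.shg if pre is not None else plane.shg
    tpef = pre.tpef if pre is not None else plane.tpef
    return (extract_channel(shg, mask, cfg), extract_channel(tpef, mask, cfg))


def feature_columns(cfg: FeatureConfig | None = None) -> list[str]:
    """The 304 combined column names, SHG block first."""
    names = registry_feature_names(cfg)
    return [f"SHG__{n}" for n in names] + [f"TPEF__{n}" for n in names]


def extract_table(planes: Sequence[MPMPlane],
                  label_table: pd.DataFrame,
                  pre_cfg: PreprocessConfig | None = None,
                  feat_cfg: FeatureConfig | None = None,
                  mask_mode: str = "or") -> pd.DataFrame:
    """Build the per-plane FeatureTable (metadata + 304 feature columns).

    ``mask_mode`` selects the extraction mask: ``or`` (default) uses the
    OR-combined SHG/TPEF mask, ``shg``/``tpef`` a single channel's mask.
    """
    if mask_mode not in ("or", "shg", "tpef"):
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    feat_cfg = feat_cfg or FeatureConfig()
    rows = []
    for plane, (_, meta) in zip(planes, label_table.iterrows()):
        pre = preprocess_plane(plane, pre_cfg)
        mask = {"or": pre.mask, "shg": pre.mask_shg, "tpef": pre.mask_tpef}[mask_mode]
        shg_vec, tpef_vec = extract_all(plane, mask, feat_cfg, pre=pre)
        row = {
            "plane_id": meta["plane_id"],
            "roi_id": meta["roi_id"],
            "tissue_class": meta["tissue_class"],
            "binary_label": meta["binary_label"],
        }
        row.update({f"SHG__{k}": v for k, v in shg_vec.items()})
        row.update({f"TPEF__{k}": v for k, v in tpef_vec.items()})
        rows.append(row)
    table = pd.DataFrame(rows)
    n_feat = len([c for c in table.columns if "__" in c])
    assert n_feat == 2 * sum(_FAMILY_COUNTS.values())
    return table


def dump_registry(path: str, cfg: FeatureConfig | None = None) -> None:
    """Write the registry (version, config, ordered names) as JSON."""
    cfg = cfg or FeatureConfig()
    payload = {
        "registry_version": cfg.registry_version,
        "n_levels": cfg.n_levels,
        "ngldm_alpha": cfg.ngldm_alpha,
        "peak_radius_px": cfg.peak_radius_px,
        "features": registry_feature_names(cfg),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
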