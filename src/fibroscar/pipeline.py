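"""End-to-end pipeline orchestration with validated YAML config.

A run executes the enabled stages in order — simulate MPM cohorts →
preprocess → extract features → train the binary ensemble → evaluate on
the held-out cohort, and simulate Raman spectra → preprocess → PLS-DA
with leave-one-out evaluation — and writes a RunReport JSON with
per-stage provenance (config hash, seeds) and all metrics. A single root
seed is fanned out to the stages through ``numpy.random.SeedSequence``
spawn keys, so identical config + seed reproduces every number.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import pathlib
import sys
import time
from typing import Any, Mapping

import numpy as np
import yaml

from . import ml as ml_mod
from . import raman as raman_mod
from .radiomics.registry import FeatureConfig, extract_table
from .synthetic.mpm import (
    CohortSpec,
    default_test_spec,
    default_training_spec,
    generate_mpm_cohort,
)
from .synthetic.raman import generate_raman_set
from .preprocess import PreprocessConfig
from .tissue import as_tissue_class


class ConfigError(ValueError):
    """Config validation failure, reported with the offending key path."""


@dataclasses.dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    seed: int = 0
    out_dir: str = "run_output"
    mpm_enabled: bool = True
    raman_enabled: bool = True
    train_planes_per_class: dict[str, int] | None = None
    test_planes_per_class: dict[str, int] | None = None
    n_train_rois: int = 3
    n_test_rois: int = 6
    image_size: tuple[int, int] = (256, 256)
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    features: FeatureConfig = dataclasses.field(default_factory=FeatureConfig)
    d: int = 9
    n_folds: int = 20
    validation_fraction: float = 0.2
    smote_k: int = 5
    raman_n_per_class: int = 40
    raman_n_components: int = 4
    save_figures: bool = True

    def config_hash(self) -> str:
        """Hash of the analysis-relevant configuration (paths excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("out_dir")
        payload["preprocess"] = dataclasses.asdict(self.preprocess)
        payload["features"] = dataclasses.asdict(self.features)
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


_SCHEMA: dict[str, Any] = {
    "seed": int,
    "out_dir": str,
    "save_figures": bool,
    "mpm": {
        "enabled": bool,
        "train_planes_per_class": dict,
        "test_planes_per_class": dict,
        "n_train_rois": int,
        "n_test_rois": int,
        "image_size": list,
        "preprocess": {
            "bin_factor": int, "normalization": str, "auto_threshold": str,
            "fixed_threshold": float, "morph_open_radius_px": int,
        },
        "features": {"n_levels": int, "ngldm_alpha": float,
                     "peak_radius_px": int},
        "ml": {"d": int, "n_folds": int, "validation_fraction": float,
               "smote_k": int},
    },
    "raman": {
        "enabled": bool,
        "n_per_class": int,
        "n_components": int,
    },
}


def _check_unknown(raw: Mapping, schema: Mapping, path: str = "") -> None:
    for key, val in raw.items():
        here = f"{path}.{key}" if path else key
        if key not in schema:
            raise ConfigError(f"unknown config key: {here}")
        if isinstance(schema[key], dict) and isinstance(val, Mapping):
            _check_unknown(val, schema[key], here)


def validate_config(raw: "Mapping | str | None") -> RunConfig:
    """Build a :class:`RunConfig` from a YAML string/mapping.

    Defaults are injected for everything absent; unknown keys and
    cross-field violations are rejected with the offending key path.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, Mapping):
        raise ConfigError("config must be a mapping")
    _check_unknown(raw, _SCHEMA)
    mpm = dict(raw.get("mpm", {}))
    raman = dict(raw.get("raman", {}))
    cfg = RunConfig(
        seed=int(raw.get("seed", 0)),
        out_dir=str(raw.get("out_dir", "run_output")),
        save_figures=bool(raw.get("save_figures", True)),
        mpm_enabled=bool(mpm.get("enabled", True)),
        raman_enabled=bool(raman.get("enabled", True)),
        train_planes_per_class=mpm.get("train_planes_per_class"),
        test_planes_per_class=mpm.get("test_planes_per_class"),
        n_train_rois=int(mpm.get("n_train_rois", 3)),
        n_test_rois=int(mpm.get("n_test_rois", 6)),
        image_size=tuple(mpm.get("image_size", (256, 256))),
        preprocess=PreprocessConfig(**mpm.get("preprocess", {})),
        features=FeatureConfig(**mpm.get("features", {})),
        d=int(mpm.get("ml", {}).get("d", 9)),
        n_folds=int(mpm.get("ml", {}).get("n_folds", 20)),
        validation_fraction=float(mpm.get("ml", {}).get("validation_fraction", 0.2)),
        smote_k=int(mpm.get("ml", {}).get("smote_k", 5)),
        raman_n_per_class=int(raman.get("n_per_class", 40)),
        raman_n_components=int(raman.get("n_components", 4)),
    )
    cfg.preprocess.validate()
    n_feature_cols = 304
    if not 1 <= cfg.d <= n_feature_cols:
        raise ConfigError(f"mpm.ml.d must be in [1, {n_feature_cols}], got {cfg.d}")
    if cfg.features.n_levels < 2:
        raise ConfigError("mpm.features.n_levels must be >= 2")
    return cfg


def _cohort_spec(planes_per_class: Mapping[str, int] | None, n_rois: int,
                 shape: tuple[int, int], seed: int,
                 default_factory) -> CohortSpec:
    if planes_per_class is None:
        spec = default_factory(seed)
        return dataclasses.replace(spec, shape=shape, n_rois=n_rois)
    return CohortSpec(
        planes_per_class={as_tissue_class(k): int(v)
                          for k, v in planes_per_class.items()},
        n_rois=n_rois, shape=shape, seed=seed)


def _log(stage: str, msg: str) -> None:
    print(f"[{stage}] {msg}", file=sys.stderr)


def run_pipeline(config: RunConfig) -> dict:
    """Execute enabled stages; write and return the RunReport dict."""
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2**31))
                   for name, s in zip(
                       ("mpm_train", "mpm_test", "ml", "raman"), ss.spawn(4))}
    report: dict = {
        "config_hash": config.config_hash(),
        "root_seed": config.seed,
        "stage_seeds": stage_seeds,
        "stages": [],
    }
    t0 = time.time()
    if config.mpm_enabled:
        _log("simulate-mpm", "generating training and test cohorts")
        train_spec = _cohort_spec(config.train_planes_per_class,
                                  config.n_train_rois, config.image_size,
                                  stage_seeds["mpm_train"],
                                  default_training_spec)
        test_spec = _cohort_spec(config.test_planes_per_class,
                                 config.n_test_rois, config.image_size,
                                 stage_seeds["mpm_test"], default_test_spec)
        train_planes, train_labels = generate_mpm_cohort(train_spec)
        test_planes, test_labels = generate_mpm_cohort(test_spec)
        _log("extract", f"extracting features for {len(train_planes)} train "
                        f"+ {len(test_planes)} test planes")
        train_table = extract_table(train_planes, train_labels,
                                    config.preprocess, config.features)
        test_table = extract_table(test_planes, test_labels,
                                   config.preprocess, config.features)
        _log("train", f"fitting ensemble: d={config.d}, "
                      f"{config.n_folds} MC folds")
        model = ml_mod.ScarClassifier(
            train_table, d=config.d, n_folds=config.n_folds,
            validation_fraction=config.validation_fraction,
            smote_k=config.smote_k)
        results = model.fit(seed=stage_seeds["ml"])
        pooled = results.pooled_validation_metrics()
        _log("evaluate", "scoring held-out cohort")
        test_metrics = results.evaluate(test_table)
        predictions = results.predict(test_table)
        predictions.to_csv(out / "mpm_predictions.csv", index=False)
        report["mpm"] = {
            "n_train_planes": len(train_planes),
            "n_test_planes": len(test_planes),
            "pooled_validation": pooled.as_dict(),
            "test": test_metrics.as_dict(),
            "mean_rho_by_class": {
                cls: float(grp["rho"].mean())
                for cls, grp in predictions.groupby("tissue_class")},
            "selection_frequency_top5":
                results.selection_frequency().head(5).to_dict(),
        }
        report["stages"] += ["simulate-mpm", "extract", "train", "evaluate"]
        if config.save_figures:
            from .plotting import rho_boxplot
            rho_boxplot(predictions, out / "rho_boxplot.png")
            report["figures"] = [str(out / "rho_boxplot.png")]
    if config.raman_enabled:
        _log("simulate-raman", f"{config.raman_n_per_class} spectra/class")
        raw = generate_raman_set(config.raman_n_per_class,
                                 seed=stage_seeds["raman"])
        processed = raman_mod.preprocess_spectra(raw)
        _log("raman-train", f"PLS-DA with {config.raman_n_components} LVs")
        plsda = raman_mod.PLSDA.from_spectrum_set(
            processed, config.raman_n_components)
        plsda_res = plsda.fit()
        loo = raman_mod.loo_cross_validate(processed,
                                           config.raman_n_components)
        report["raman"] = {
            "n_spectra": processed.n_spectra,
            "loo": loo.as_dict(),
        }
        report["stages"] += ["simulate-raman", "raman-train", "raman-evaluate"]
        if config.save_figures:
            from .plotting import loading_plot, score_plot
            score_plot(plsda_res, out / "plsda_scores.png")
            loading_plot(plsda_res, out / "plsda_loadings.png")
            report.setdefault("figures", []).extend(
                [str(out / "plsda_scores.png"), str(out / "plsda_loadings.png")])
    report["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    _log("run", f"report written to {out / 'run_report.json'}")
    return report
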