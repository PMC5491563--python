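"""End-to-end pipeline: simulate -> extract -> classify -> evaluate.

A single RunConfig (loadable from a YAML file) governs every stage; the run
directory receives all intermediate artifacts, reports and a manifest
(package version, seed, resolved configuration and its hash) sufficient to
reproduce the run bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .dataset import PixelDataset
from .evaluation import evaluate_loo, exclusion_sweep, subset_search
from .features import FeatureConfig, cohort_dataset
from .io import write_label_map, write_loop, write_rois
from .synthetic import PhantomConfig, generate_cohort

__all__ = ["RunConfig", "run_pipeline"]

DEFAULT_SUBSET = ("r", "mu", "kappa", "PT")


@dataclass
class RunConfig:
    out_dir: str = "run"
    seed: int = 0
    n_prostates: int = 4
    planes_per_prostate: tuple[int, int] | int = (1, 2)
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    subset: tuple[str, ...] = DEFAULT_SUBSET
    # stage toggles
    simulate: bool = True
    extract: bool = True
    classify: bool = True
    search: bool = False
    search_max_size: int = 2
    exclude: bool = True
    write_loops: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = cls()
        phantom = raw.pop("phantom", None)
        feats = raw.pop("features", None)
        if phantom:
            cfg.phantom = _update_dataclass(PhantomConfig(), phantom)
        if feats:
            cfg.features = _update_dataclass(FeatureConfig(), feats)
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise ValueError(f"unknown config key {k!r}")
            setattr(cfg, k, tuple(v) if isinstance(v, list) else v)
        return cfg


def _update_dataclass(obj, values: dict):
    for k, v in values.items():
        if not hasattr(obj, k):
            raise ValueError(f"unknown config key {k!r} for {type(obj).__name__}")
        cur = getattr(obj, k)
        if dataclasses.is_dataclass(cur) and isinstance(v, dict):
            v = _update_dataclass(cur, v)
        elif isinstance(v, list):
            v = tuple(v)
        obj = dataclasses.replace(obj, **{k: v}) if dataclasses.is_dataclass(obj) else obj
        if not dataclasses.is_dataclass(obj):
            setattr(obj, k, v)
    return obj


def _config_dict(cfg: RunConfig) -> dict:
    return json.loads(json.dumps(asdict(cfg), default=lambda o: list(o) if isinstance(o, tuple) else str(o)))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory.

    Stage dependencies are enforced (classification needs extracted
    features).  Failures abort with the failing stage named; artifacts of
    completed stages are retained.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    resolved = _config_dict(config)
    manifest = {
        "package": "mpdceus",
        "version": __version__,
        "seed": config.seed,
        "config": resolved,
        "config_sha256": hashlib.sha256(
            json.dumps(resolved, sort_keys=True).encode()
        ).hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")

    planes = None
    dataset: PixelDataset | None = None

    if config.simulate:
        try:
            phantom = dataclasses.replace(config.phantom, seed=config.seed)
            planes = generate_cohort(
                phantom, config.n_prostates, config.planes_per_prostate, seed=config.seed
            )
        except Exception as exc:
            raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc
        if config.write_loops:
            for p in planes:
                stem = out / "loops" / f"prostate{p.prostate_id}_plane{p.plane_id}"
                write_loop(stem.with_suffix(".tif"), p.loop)
                write_label_map(stem.with_name(stem.name + "_labels.tif"), p.truth.label_map)
            write_rois(out / "loops" / "rois.csv", [r for p in planes for r in p.truth.rois])

    if config.extract:
        if planes is None:
            raise RuntimeError("stage 'extract' requires stage 'simulate' (or loaded loops)")
        try:
            dataset = cohort_dataset(planes, config.features)
        except Exception as exc:
            raise RuntimeError(f"stage 'extract' failed: {exc}") from exc
        table = dataset.features.copy()
        table["label"] = dataset.labels
        table["prostate_id"] = dataset.prostate_id
        table["plane_id"] = dataset.plane_id
        table["roi_id"] = dataset.roi_id
        table = table.join(dataset.aux)
        table.to_csv(out / "pixel_features.csv", index=False)

    if config.classify:
        if dataset is None:
            raise RuntimeError("stage 'classify' requires stage 'extract'")
        try:
            loo = evaluate_loo(dataset, config.subset, seed=config.seed)
        except Exception as exc:
            raise RuntimeError(f"stage 'classify' failed: {exc}") from exc
        loo.per_prostate.to_csv(out / "loo_per_prostate.csv")
        report = {
            "subset": list(loo.subset),
            "mean": loo.mean,
            "sd": loo.sd,
            "pooled": loo.pooled.as_dict(),
        }
        (out / "loo_report.json").write_text(
            json.dumps(report, indent=2, default=float), encoding="utf-8"
        )

        if config.exclude:
            curve = exclusion_sweep(loo, dataset, "confidence")
            exc_table = curve.metrics.copy()
            exc_table.insert(0, "threshold", curve.thresholds)
            exc_table["retained_fraction"] = curve.retained_fraction
            exc_table["retained_benign"] = curve.retained_benign
            exc_table["retained_malignant"] = curve.retained_malignant
            exc_table.to_csv(out / "exclusion_confidence.csv", index=False)

    if config.search:
        if dataset is None:
            raise RuntimeError("stage 'search' requires stage 'extract'")
        ranking = subset_search(dataset, config.search_max_size, seed=config.seed)
        ranking.to_csv(out / "subset_ranking.csv", index=False)

    return out
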