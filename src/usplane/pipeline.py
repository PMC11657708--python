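"""End-to-end orchestration: simulate/load -> preprocess -> extract ->
select -> train -> evaluate, with per-stage seeding and artifacts.

Every stage draws its seed deterministically from the global run seed,
so a rerun with the same configuration reproduces the selected mask
and the trained model byte for byte.  Artifacts written to the output
directory: ``features.csv``, ``mask.json``, ``model.json``,
``report.json`` and a ``manifest.json`` recording configs, seeds and
per-stage wall time.  A failing stage leaves a ``<stage>.failed``
marker beside any partial outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split

from . import __version__
from .evalmetrics import macro_report
from .fast_rbfnn import FastRBFConfig, FastRBFModel, fit_multiclass
from .imgproc import LabeledDataset, PreprocessConfig, balance_classes, preprocess_dataset
from .io import load_manifest
from .swarm_select import SelectConfig, SelectionResult, select_features
from .synthdata import DEFAULT_CLASS_SPECS, generate_dataset
from .texture import FeatureTable, TextureConfig, build_feature_table

__all__ = ["SimulateConfig", "BalanceConfig", "RunConfig", "run_pipeline", "load_config"]

_STAGE_OFFSETS = {"simulate": 1, "balance": 2, "split": 3, "select": 4, "train": 5}


def stage_seed(global_seed: int, stage: str) -> int:
    return (int(global_seed) * 1000003 + _STAGE_OFFSETS[stage]) % (2**31)


@dataclass
class SimulateConfig:
    enabled: bool = True
    n_per_class: int | None = 30
    imbalance_counts: tuple | None = None
    h: int = 64
    w: int = 64
    speckle_variance: float | None = None  # None keeps each spec's own value


@dataclass
class BalanceConfig:
    enabled: bool = False
    target_per_class: int = 1050


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "run"
    manifest: str | None = None  # image manifest CSV when simulate is disabled
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    balance: BalanceConfig = field(default_factory=BalanceConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    select_enabled: bool = True
    select: SelectConfig = field(default_factory=SelectConfig)
    train: FastRBFConfig = field(default_factory=FastRBFConfig)
    holdout_fraction: float = 0.3


def load_config(path) -> RunConfig:
    """RunConfig from a JSON or TOML file of nested sections."""
    path = Path(path)
    if path.suffix == ".toml":
        import tomllib

        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
    else:
        with open(path) as fh:
            raw = json.load(fh)
    return _config_from_dict(raw)


def _config_from_dict(raw: dict) -> RunConfig:
    def build(cls, section):
        data = dict(raw.get(section, {}))
        for key in ("angles", "descriptors", "stages", "imbalance_counts", "crop"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    top = {k: v for k, v in raw.items() if not isinstance(v, dict)}
    return RunConfig(
        simulate=build(SimulateConfig, "simulate"),
        preprocess=build(PreprocessConfig, "preprocess"),
        balance=build(BalanceConfig, "balance"),
        texture=build(TextureConfig, "texture"),
        select=build(SelectConfig, "select"),
        train=build(FastRBFConfig, "train"),
        **top,
    )


def _json_dump(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, sort_keys=True, indent=1)


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in order and return the run manifest."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": int(cfg.seed),
        "stage_seeds": {s: stage_seed(cfg.seed, s) for s in _STAGE_OFFSETS},
        "config": _serializable(cfg),
        "timings_s": {},
        "stages": [],
    }
    current = "setup"
    try:
        # ---- simulate / load ------------------------------------------
        current = "simulate"
        t0 = time.perf_counter()
        if cfg.simulate.enabled:
            specs = DEFAULT_CLASS_SPECS
            if cfg.simulate.speckle_variance is not None:
                specs = tuple(
                    dataclasses.replace(s, speckle_variance=cfg.simulate.speckle_variance)
                    for s in specs
                )
            data = generate_dataset(
                specs,
                n_per_class=cfg.simulate.n_per_class,
                imbalance_counts=cfg.simulate.imbalance_counts,
                h=cfg.simulate.h,
                w=cfg.simulate.w,
                seed=stage_seed(cfg.seed, "simulate"),
            )
        else:
            if cfg.manifest is None:
                raise ValueError("simulate disabled and no image manifest given")
            data = load_manifest(cfg.manifest)
        manifest["timings_s"]["simulate"] = time.perf_counter() - t0
        manifest["stages"].append("simulate")

        # ---- balance ---------------------------------------------------
        if cfg.balance.enabled:
            current = "balance"
            t0 = time.perf_counter()
            data = balance_classes(
                data, cfg.balance.target_per_class, stage_seed(cfg.seed, "balance")
            )
            manifest["timings_s"]["balance"] = time.perf_counter() - t0
            manifest["stages"].append("balance")

        # ---- preprocess ------------------------------------------------
        current = "preprocess"
        t0 = time.perf_counter()
        data = preprocess_dataset(data, cfg.preprocess)
        manifest["timings_s"]["preprocess"] = time.perf_counter() - t0
        manifest["stages"].append("preprocess")

        # ---- extract ---------------------------------------------------
        current = "extract"
        t0 = time.perf_counter()
        table = build_feature_table(data, cfg.texture)
        table.to_csv(outdir / "features.csv")
        manifest["timings_s"]["extract"] = time.perf_counter() - t0
        manifest["stages"].append("extract")

        # ---- split -----------------------------------------------------
        current = "split"
        idx = np.arange(len(table.y))
        train_idx, test_idx = train_test_split(
            idx,
            test_size=cfg.holdout_fraction,
            stratify=table.y,
            random_state=stage_seed(cfg.seed, "split") % (2**32),
        )
        train_table = FeatureTable(
            table.X[train_idx], table.y[train_idx], table.feature_names
        )

        # ---- select ----------------------------------------------------
        current = "select"
        t0 = time.perf_counter()
        if cfg.select_enabled:
            sel_cfg = dataclasses.replace(cfg.select, seed=stage_seed(cfg.seed, "select"))
            result = select_features(train_table, sel_cfg)
            mask = result.mask
            _json_dump(result.to_dict(), outdir / "mask.json")
        else:
            mask = np.ones(table.n_features, dtype=bool)
            _json_dump(
                {"algorithm": None, "mask": [1] * table.n_features,
                 "n_selected": table.n_features, "fitness": None, "history": []},
                outdir / "mask.json",
            )
        manifest["timings_s"]["select"] = time.perf_counter() - t0
        manifest["stages"].append("select")

        # ---- train -----------------------------------------------------
        current = "train"
        t0 = time.perf_counter()
        train_cfg = dataclasses.replace(cfg.train, seed=stage_seed(cfg.seed, "train"))
        model = fit_multiclass(train_table, mask, train_cfg)
        model.to_json(outdir / "model.json")
        manifest["timings_s"]["train"] = time.perf_counter() - t0
        manifest["stages"].append("train")

        # ---- evaluate --------------------------------------------------
        current = "evaluate"
        t0 = time.perf_counter()
        pred = model.predict(table.X[test_idx])
        report = macro_report(table.y[test_idx], pred, sorted(model.classes.tolist()))
        report_payload = {
            "macro": report.macro,
            "per_class": {
                str(c): m for c, m in report.per_class.items()
            },
            "n_test": int(len(test_idx)),
        }
        _json_dump(report_payload, outdir / "report.json")
        manifest["timings_s"]["evaluate"] = time.perf_counter() - t0
        manifest["stages"].append("evaluate")
        manifest["macro_accuracy"] = report.macro["accuracy"]
    except Exception as exc:
        (outdir / f"{current}.failed").write_text(f"{type(exc).__name__}: {exc}\n")
        raise RuntimeError(f"pipeline stage '{current}' failed: {exc}") from exc

    _json_dump(manifest, outdir / "manifest.json")
    return manifest


def _serializable(cfg: RunConfig) -> dict:
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.generic):
            return obj.item()
        return obj

    return clean(cfg)
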