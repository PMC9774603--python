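"""End-to-end experiment orchestration: synth -> prepare -> train -> evaluate.

A single RunConfig (nested dict, YAML-serializable) drives every stage; one
global seed fans out to per-stage seeds by stable hashing so any stage can
be re-run in isolation and reproduce its part of the pipeline.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import pspi
from .data import load_dataset, read_manifest
from .evaluation import EvalReport, evaluate_model
from .model import ModelConfig, ParallelPainModel, train
from .synth import SyntheticSpec, generate_dataset

__all__ = ["RunConfig", "stage_seed", "run_experiment", "run_ablation",
           "prepare_manifests", "DEFAULT_CONFIG"]

log = logging.getLogger("painattn")

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "determinism": True,
    "stages": ["synth", "prepare", "train", "evaluate"],
    "synth": {
        "frames_per_level": {lvl: 100 for lvl in range(6)},
        "image_size": 64,
        "background": "flat",
        "deformation_strength": 1.0,
    },
    "prepare": {"keep_every": 10, "train_fraction": 0.8},
    "model": {},
    "train": {"epochs": 20, "batch_size": 32, "lr": 1e-3, "val_fraction": 0.1},
}


class RunConfig:
    """Nested configuration with YAML round-trip and per-stage seeds."""

    def __init__(self, values: dict | None = None):
        self.values = _deep_merge(DEFAULT_CONFIG, values or {})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.values, sort_keys=True))

    def __getitem__(self, key: str):
        return self.values[key]

    def get(self, key: str, default=None):
        return self.values.get(key, default)


def _deep_merge(base: dict, override: dict) -> dict:
    out = {}
    for k, v in base.items():
        if k in override and isinstance(v, dict) and isinstance(override[k], dict):
            out[k] = _deep_merge(v, override[k])
        else:
            out[k] = override.get(k, v)
    for k, v in override.items():
        out.setdefault(k, v)
    return out


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed derived from the global seed (below 2**31)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def prepare_manifests(records: Sequence[pspi.FrameRecord], out_dir: Path,
                      keep_every: int = 10, train_fraction: float = 0.8,
                      seed: int = 0) -> dict[str, Path]:
    """Rebalance level 0, split stratified, write manifests + frequency report."""
    out_dir.mkdir(parents=True, exist_ok=True)
    balanced = pspi.rebalance_level0(records, keep_every=keep_every, seed=seed)
    train_recs, test_recs = pspi.stratified_split(balanced, train_fraction, seed=seed)
    paths = {}
    for name, recs in (("train", train_recs), ("test", test_recs), ("balanced", balanced)):
        path = out_dir / f"{name}_manifest.csv"
        pspi.records_to_frame(recs).to_csv(path, index=False)
        paths[name] = path
    freq = pspi.frequency_table(balanced)
    freq.to_frame().to_csv(out_dir / "frequency_report.csv", index=False)
    lines = [f"total frames: {freq.total}"]
    for lvl in sorted(freq.clustered_counts):
        lines.append(
            f"clustered level {lvl}: {freq.clustered_counts[lvl]} frames "
            f"({freq.clustered_frequencies[lvl]:.4f}%)"
        )
    (out_dir / "frequency_report.txt").write_text("\n".join(lines) + "\n")
    paths["frequency_report"] = out_dir / "frequency_report.csv"
    return paths


def run_experiment(config: RunConfig, out_dir: str | Path,
                   force: bool = False) -> Path:
    """Execute the configured stage list into one run directory."""
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not force:
            raise FileExistsError(
                f"run directory {out_dir} is not empty (pass force=True to overwrite)"
            )
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "config.yaml")
    seed = int(config["seed"])
    stages = list(config["stages"])
    manifest_path = None
    train_manifest = test_manifest = None
    checkpoint = out_dir / "model.npz"

    try:
        if "synth" in stages:
            synth_cfg = dict(config["synth"])
            synth_cfg["frames_per_level"] = {
                int(k): int(v) for k, v in synth_cfg["frames_per_level"].items()
            }
            spec = SyntheticSpec(seed=stage_seed(seed, "synth"), **synth_cfg)
            records, manifest_path = generate_dataset(spec, out_dir / "data")
            log.info("synth: %d frames -> %s", len(records), manifest_path)
        if "prepare" in stages:
            if manifest_path is None:
                manifest_path = Path(config["prepare"]["labels"])
            records = pspi.read_label_table(manifest_path)
            paths = prepare_manifests(
                records, out_dir / "prepared",
                keep_every=int(config["prepare"]["keep_every"]),
                train_fraction=float(config["prepare"]["train_fraction"]),
                seed=stage_seed(seed, "prepare"),
            )
            train_manifest, test_manifest = paths["train"], paths["test"]
        report = None
        if "train" in stages:
            report = _train_and_evaluate(
                config, train_manifest, test_manifest, checkpoint, seed,
                evaluate="evaluate" in stages,
            )
        if report is not None:
            report.save(out_dir / "eval_report.json")
            pd.DataFrame(report.confusion).to_csv(out_dir / "confusion.csv", index=False)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed in {out_dir}: {exc}") from exc
    _write_artifact_manifest(out_dir)
    return out_dir


def _train_and_evaluate(config: RunConfig, train_manifest: Path | None,
                        test_manifest: Path | None, checkpoint: Path,
                        seed: int, evaluate: bool = True) -> EvalReport | None:
    if train_manifest is None:
        raise ValueError("train stage requires a prepared train manifest")
    model_cfg = ModelConfig(seed=stage_seed(seed, "init"), **config["model"])
    model = ParallelPainModel(model_cfg)
    train_recs = read_manifest(train_manifest)
    tr_cfg = config["train"]
    history = train(
        model, train_recs,
        epochs=int(tr_cfg["epochs"]), batch_size=int(tr_cfg["batch_size"]),
        lr=float(tr_cfg["lr"]), val_fraction=float(tr_cfg["val_fraction"]),
        seed=stage_seed(seed, "train"), checkpoint_path=checkpoint,
    )
    history.to_frame().to_csv(checkpoint.parent / "history.csv", index=False)
    if not evaluate or test_manifest is None:
        return None
    test_recs = read_manifest(test_manifest)
    X, y = load_dataset(test_recs, model_cfg.input_size)
    return evaluate_model(model, X, y)


def run_ablation(config: RunConfig, arms: Sequence[str], out_dir: str | Path,
                 force: bool = False) -> pd.DataFrame:
    """Train each arm on identical data/seeds; emit a metric table.

    Arms are model variants: ``cnna`` / ``cnnb`` / ``parallel`` select the
    branch structure, ``ca`` / ``sa`` / ``ca_sa`` / ``sa_ca`` select the
    attention composition on the full parallel model.
    """
    if len(arms) < 2:
        raise ValueError("ablation requires at least 2 arms")
    known_branch = {"cnna", "cnnb", "parallel"}
    known_attention = {"ca", "sa", "ca_sa", "sa_ca"}
    for arm in arms:
        if arm not in known_branch | known_attention:
            raise ValueError(f"unknown ablation arm {arm!r}")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"ablation directory {out_dir} is not empty")
    out_dir.mkdir(parents=True, exist_ok=True)

    # shared data: synth + prepare once
    base = RunConfig(dict(config.values))
    base.values["stages"] = ["synth", "prepare"]
    data_dir = run_experiment(base, out_dir / "data_run", force=force)
    train_manifest = data_dir / "prepared" / "train_manifest.csv"
    test_manifest = data_dir / "prepared" / "test_manifest.csv"
    seed = int(config["seed"])

    rows = []
    for arm in arms:
        arm_cfg = RunConfig(dict(config.values))
        model_over = dict(arm_cfg.values.get("model", {}))
        if arm in known_branch:
            model_over["arm"] = arm
        else:
            model_over["arm"] = "parallel"
            model_over["attention_order"] = arm
        arm_cfg.values["model"] = model_over
        checkpoint = out_dir / arm / "model.npz"
        checkpoint.parent.mkdir(parents=True, exist_ok=True)
        report = _train_and_evaluate(arm_cfg, train_manifest, test_manifest,
                                     checkpoint, seed)
        report.save(out_dir / arm / "eval_report.json")
        rows.append({"arm": arm, "rmse": report.rmse, "pcc": report.pcc,
                     "accuracy": report.accuracy, "n": report.n})
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "ablation.csv", index=False)
    return table


def _write_artifact_manifest(out_dir: Path) -> None:
    entries = {}
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "artifacts.json":
            entries[str(path.relative_to(out_dir))] = hashlib.sha256(
                path.read_bytes()
            ).hexdigest()
    (out_dir / "artifacts.json").write_text(json.dumps(entries, indent=2, sort_keys=True))
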