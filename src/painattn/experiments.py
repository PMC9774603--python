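"""Canned end-to-end study conditions used by the acceptance checks.

Two experiments are packaged so they can be reproduced from a single seed:

* label recovery on the easy synthetic regime — strong deformation, flat
  backgrounds, ~500 frames, reduced-width model; and
* background robustness — the same model with and without regional masking,
  trained and tested on flat vs cluttered backgrounds, reporting the
  accuracy drop the clutter causes for each variant.

Problem sizes (frame counts, image size, epochs) are fixed here as the
package's CPU-scale study conditions; they are deliberately far below the
scale of clinical-archive training.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .data import load_dataset
from .evaluation import EvalReport, evaluate_model
from .model import ModelConfig, ParallelPainModel, train
from .pspi import stratified_split
from .synth import SyntheticSpec, generate_dataset

__all__ = ["RECOVERY_CONDITIONS", "ROBUSTNESS_CONDITIONS",
           "recovery_experiment", "background_robustness_experiment"]

RECOVERY_CONDITIONS = dict(
    frames_per_level=84,       # 504 frames total
    image_size=48,
    epochs=25,
    batch_size=32,
    lr=2e-3,
    cnna_stages=((8,), (16,), (32,)),
    resnet_widths=(8, 16, 32),
)

ROBUSTNESS_CONDITIONS = dict(
    frames_per_level=60,       # 360 frames per background condition
    image_size=40,
    epochs=28,
    batch_size=32,
    lr=2e-3,
    cnna_stages=((8,), (16,)),
    resnet_widths=(8, 16),
)


def _train_eval(records, conditions: dict, seed: int, masking: bool,
                workdir: Path | None = None) -> EvalReport:
    size = conditions["image_size"]
    train_recs, test_recs = stratified_split(records, 0.8, seed=seed)
    Xtr, ytr = load_dataset(train_recs, size)
    Xte, yte = load_dataset(test_recs, size)
    cfg = ModelConfig(
        input_size=size,
        cnna_stages=conditions["cnna_stages"],
        resnet_widths=conditions["resnet_widths"],
        masking_enabled=masking,
        seed=seed,
    )
    model = ParallelPainModel(cfg)
    train(model, train_recs, epochs=conditions["epochs"],
          batch_size=conditions["batch_size"], lr=conditions["lr"],
          seed=seed, data=(Xtr, ytr), val_fraction=0.1)
    return evaluate_model(model, Xte, yte)


def _make_dataset(conditions: dict, background: str, seed: int,
                  out_dir: Path):
    spec = SyntheticSpec(
        frames_per_level={lvl: conditions["frames_per_level"] for lvl in range(6)},
        image_size=conditions["image_size"],
        background=background,
        deformation_strength=1.0,
        seed=seed,
    )
    records, _ = generate_dataset(spec, out_dir)
    return records


def recovery_experiment(seed: int, workdir: str | Path | None = None) -> EvalReport:
    """Train the parallel model on the easy regime; return its test report."""
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(workdir) if workdir is not None else Path(tmp)
        records = _make_dataset(RECOVERY_CONDITIONS, "flat", seed, base / "data")
        return _train_eval(records, RECOVERY_CONDITIONS, seed, masking=True)


@dataclass
class RobustnessResult:
    masked_drops: list[float]
    unmasked_drops: list[float]
    accuracies: dict

    @property
    def masked_median_drop(self) -> float:
        return float(np.median(self.masked_drops))

    @property
    def unmasked_median_drop(self) -> float:
        return float(np.median(self.unmasked_drops))


def background_robustness_experiment(seeds=(1, 2, 3),
                                     workdir: str | Path | None = None,
                                     ) -> RobustnessResult:
    """Accuracy drop from flat to cluttered backgrounds, with/without masking.

    For each seed, four models are trained (masking on/off x flat/clutter
    data) under identical conditions; the drop is flat-test accuracy minus
    clutter-test accuracy of the matching model.
    """
    acc: dict = {}
    with tempfile.TemporaryDirectory() as tmp:
        base = Path(workdir) if workdir is not None else Path(tmp)
        for seed in seeds:
            for background in ("flat", "clutter"):
                records = _make_dataset(ROBUSTNESS_CONDITIONS, background,
                                        300 + seed, base / f"{background}_{seed}")
                for masking in (True, False):
                    report = _train_eval(records, ROBUSTNESS_CONDITIONS, seed, masking)
                    acc[(seed, background, masking)] = report.accuracy
    masked = [acc[(s, "flat", True)] - acc[(s, "clutter", True)] for s in seeds]
    unmasked = [acc[(s, "flat", False)] - acc[(s, "clutter", False)] for s in seeds]
    return RobustnessResult(masked, unmasked, acc)
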