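"""Evaluation metrics and diagnostics for frame-level pain estimation.

Predicted and ground-truth intensities are compared on the clustered 0-5
label space.  RMSE measures the per-frame deviation, the Pearson
correlation coefficient (PCC) measures how well the predicted sequence
tracks the temporal progression of pain, and the 6x6 confusion matrix plus
overall accuracy summarise the classification view.  Grad-CAM heatmaps show
where in the image the model's evidence for a class concentrates.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn.autograd import Tensor
from .pspi import N_CLUSTERED_LEVELS

__all__ = ["EvalReport", "rmse", "pcc", "confusion_and_accuracy", "evaluate_model",
           "grad_cam"]


def rmse(pred, truth) -> float:
    """Root-mean-square error between two equal-length intensity sequences."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size < 1:
        raise ValueError("sequences must have length >= 1")
    return float(np.sqrt(np.mean((pred - truth) ** 2)))


def pcc(pred, truth) -> float:
    """Pearson correlation coefficient; NaN (flagged missing) if either
    sequence is constant, where the denominator is undefined."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    if pred.size < 2:
        raise ValueError("sequences must have length >= 2")
    dp = pred - pred.mean()
    dt = truth - truth.mean()
    denom = np.sqrt((dp**2).sum() * (dt**2).sum())
    if denom == 0.0:
        return float("nan")
    return float((dp * dt).sum() / denom)


def confusion_and_accuracy(pred_levels, truth_levels,
                           n_levels: int = N_CLUSTERED_LEVELS,
                           ) -> tuple[np.ndarray, float]:
    """(n x n count matrix indexed [truth, pred], accuracy percent)."""
    pred_levels = np.asarray(pred_levels, dtype=int)
    truth_levels = np.asarray(truth_levels, dtype=int)
    if pred_levels.shape != truth_levels.shape:
        raise ValueError("prediction/truth length mismatch")
    for name, arr in (("pred", pred_levels), ("truth", truth_levels)):
        if arr.size and (arr.min() < 0 or arr.max() >= n_levels):
            raise ValueError(f"{name} levels outside 0..{n_levels - 1}")
    confusion = np.zeros((n_levels, n_levels), dtype=int)
    np.add.at(confusion, (truth_levels, pred_levels), 1)
    accuracy = 100.0 * np.trace(confusion) / max(confusion.sum(), 1)
    return confusion, float(accuracy)


@dataclass
class EvalReport:
    """Serializable summary of one evaluation run."""

    rmse: float
    pcc: float | None
    accuracy: float
    confusion: list[list[int]]
    n: int
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_predictions(cls, pred_levels, truth_levels, **extras) -> "EvalReport":
        confusion, accuracy = confusion_and_accuracy(pred_levels, truth_levels)
        r = pcc(pred_levels, truth_levels) if len(np.atleast_1d(pred_levels)) >= 2 else float("nan")
        return cls(
            rmse=rmse(pred_levels, truth_levels),
            pcc=None if math.isnan(r) else r,
            accuracy=accuracy,
            confusion=confusion.tolist(),
            n=int(len(np.atleast_1d(truth_levels))),
            extras=dict(extras),
        )

    def to_json(self) -> str:
        payload = {
            "rmse": self.rmse,
            "pcc": self.pcc,
            "accuracy": self.accuracy,
            "confusion": self.confusion,
            "n": self.n,
            "extras": self.extras,
        }
        return json.dumps(payload, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvalReport":
        d = json.loads(text)
        return cls(rmse=d["rmse"], pcc=d["pcc"], accuracy=d["accuracy"],
                   confusion=d["confusion"], n=d["n"], extras=d.get("extras", {}))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def evaluate_model(model, X: np.ndarray, y: np.ndarray,
                   batch_size: int = 64) -> EvalReport:
    """Run the model on preprocessed images and build an EvalReport."""
    from .model import predict_levels

    pred = predict_levels(model, X, batch_size=batch_size)
    return EvalReport.from_predictions(pred, y)


def grad_cam(model, image: np.ndarray, layer: str = "attention",
             target_class: int | None = None) -> np.ndarray:
    """Gradient-weighted class-activation heatmap in [0, 1] at image size.

    ``layer`` names one of the CNNA branch's captured activations
    (``stage1``, ``stage2``, ..., ``attention``, ``masked``).  The heatmap is
    ReLU(sum_c alpha_c * A_c) with alpha_c the spatial mean of the class
    score's gradient at channel c, upsampled (nearest) to the input size and
    min-max normalised; an all-zero map stays all-zero.
    """
    from .data import preprocess
    from .model import ParallelPainModel

    if not isinstance(model, ParallelPainModel) or model.cnna is None:
        raise ValueError("grad_cam requires a model with a CNNA branch")
    size = model.cfg.input_size
    image = np.asarray(image)
    x = preprocess(image, size) if image.ndim == 3 and image.shape[2] == 3 \
        else image.astype(np.float64)
    model.eval()
    logits = model(Tensor(x[None]))
    if layer not in model.cnna.captured:
        raise ValueError(
            f"unknown layer {layer!r}; valid locators: {sorted(model.cnna.captured)}"
        )
    activation = model.cnna.captured[layer]
    cls = int(np.argmax(logits.data[0])) if target_class is None else int(target_class)
    seed = np.zeros_like(logits.data)
    seed[0, cls] = 1.0
    logits.backward(seed)
    grads = activation.grad[0]          # (C, h, w)
    acts = activation.data[0]
    alpha = grads.mean(axis=(1, 2))
    cam = np.maximum((alpha[:, None, None] * acts).sum(axis=0), 0.0)
    cam = _upsample_nearest(cam, size)
    lo, hi = cam.min(), cam.max()
    if hi > lo:
        cam = (cam - lo) / (hi - lo)
    return cam


def _upsample_nearest(cam: np.ndarray, size: int) -> np.ndarray:
    h, w = cam.shape
    rows = np.clip((np.arange(size) * h / size).astype(int), 0, h - 1)
    cols = np.clip((np.arange(size) * w / size).astype(int), 0, w - 1)
    return cam[np.ix_(rows, cols)]
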