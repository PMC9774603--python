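"""Parallel two-branch CNN with bilinear fusion for 6-level pain estimation.

Branch A ("CNNA") is a VGG-style stack of 3x3 convolutions whose spatial
downsampling is anti-aliased (BlurPool) and which carries a channel/spatial
attention block plus attention-driven regional masking at a shallow stage —
this branch concentrates on core (facial) regions.  Branch B ("CNNB") is a
residual network with identity shortcuts that supplements global context
lost in branch A.  The two pooled feature vectors are fused by a bilinear
outer product (signed square root + L2 normalisation) and classified by a
linear softmax head over the six clustered pain levels.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .attention import AttentionBlock
from .blurpool import BlurPool
from .data import load_dataset, preprocess
from .masking import DropBlockConfig, RegionalMasking
from .nn import (
    Adam,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool2d,
    Module,
    ReLU,
    Sequential,
    Tensor,
    cross_entropy,
    l2_normalize,
    log_softmax,
)
from .pspi import N_CLUSTERED_LEVELS, FrameRecord

__all__ = ["BranchDescriptor", "ModelConfig", "CnnaBranch", "CnnbBranch",
           "ParallelPainModel", "bilinear_fuse", "predict", "train",
           "save_checkpoint", "load_checkpoint", "TrainHistory"]

ARMS = ("parallel", "cnna", "cnnb")

# channel widths per stage; the reduced default is a narrow VGG16-shaped
# stack that trains on a single CPU
REDUCED_CNNA_STAGES = ((8, 8), (16, 16), (32, 32))
REDUCED_RESNET_WIDTHS = (8, 16, 32)


@dataclass
class BranchDescriptor:
    """Declarative description of one branch, validated on construction."""

    backbone: str
    feature_dim: int = 0
    blurpool: bool | None = None
    attention_order: str | None = None
    masking_enabled: bool | None = None
    masking_stage: int | None = None

    def __post_init__(self) -> None:
        problems = []
        if self.backbone == "vgg16_modified":
            if self.blurpool is None:
                problems.append("vgg16_modified requires an explicit blurpool flag")
            if self.attention_order is None:
                problems.append("vgg16_modified requires attention_order")
        elif self.backbone == "resnet":
            for name in ("masking_enabled", "masking_stage", "attention_order", "blurpool"):
                if getattr(self, name) is not None:
                    problems.append(f"resnet branch does not accept {name}")
        else:
            problems.append(f"unknown backbone {self.backbone!r}")
        if problems:
            raise ValueError("invalid branch descriptor: " + "; ".join(problems))


@dataclass
class ModelConfig:
    input_size: int = 64
    n_classes: int = N_CLUSTERED_LEVELS
    arm: str = "parallel"
    cnna_stages: tuple[tuple[int, ...], ...] = REDUCED_CNNA_STAGES
    resnet_widths: tuple[int, ...] = REDUCED_RESNET_WIDTHS
    attention_order: str = "ca_sa"
    attention_reduction: int = 4
    spatial_kernel: int = 7
    blurpool: bool = True
    blurpool_kernel: int = 3
    blurpool_stride: int = 2
    masking_enabled: bool = True
    masking_stage: int = 2
    dropblock: DropBlockConfig = field(default_factory=DropBlockConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if isinstance(self.dropblock, dict):
            db = dict(self.dropblock)
            if "threshold_range" in db:
                db["threshold_range"] = tuple(db["threshold_range"])
            self.dropblock = DropBlockConfig(**db)
        self.cnna_stages = tuple(tuple(s) for s in self.cnna_stages)
        self.resnet_widths = tuple(self.resnet_widths)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dropblock"]["threshold_range"] = list(d["dropblock"]["threshold_range"])
        d["cnna_stages"] = [list(s) for s in self.cnna_stages]
        d["resnet_widths"] = list(self.resnet_widths)
        return d


class CnnaBranch(Module):
    """VGG-style attention branch with BlurPool downsampling and masking."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cfg = cfg
        stages = []
        in_ch = 3
        for widths in cfg.cnna_stages:
            convs = []
            for w in widths:
                convs.extend([Conv2d(in_ch, w, 3, rng=rng), ReLU()])
                in_ch = w
            stages.append(Sequential(*convs))
        self.stages = stages
        if cfg.blurpool:
            self.pools = [BlurPool(cfg.blurpool_kernel, cfg.blurpool_stride)
                          for _ in stages]
        else:
            self.pools = [MaxPool2d(2, cfg.blurpool_stride) for _ in stages]
        att_stage = min(cfg.masking_stage, len(stages))
        self.att_stage = att_stage
        att_channels = cfg.cnna_stages[att_stage - 1][-1]
        self.attention = AttentionBlock(
            att_channels, cfg.attention_order, cfg.attention_reduction,
            cfg.spatial_kernel, rng,
        )
        self.masking = (
            RegionalMasking(cfg.dropblock, seed=int(rng.integers(2**31)))
            if cfg.masking_enabled else None
        )
        self.gap = GlobalAvgPool()
        self.feature_dim = cfg.cnna_stages[-1][-1]
        self.captured: dict[str, Tensor] = {}

    def forward(self, x: Tensor) -> Tensor:
        self.captured = {}
        for i, (stage, pool) in enumerate(zip(self.stages, self.pools), start=1):
            x = stage(x)
            self.captured[f"stage{i}"] = x
            if i == self.att_stage:
                x = self.attention(x)
                self.captured["attention"] = x
                # regional masking is a training-time regularizer: identity
                # at inference, like the DropBlock it embeds
                if self.masking is not None and self.training:
                    cw, sw = self.attention.channel_weights, self.attention.spatial_weights
                    if cw is not None and sw is not None:
                        mult = self.masking.multiplier(cw, sw, x.data, True)
                        x = x * Tensor(mult)
                    self.captured["masked"] = x
            x = pool(x)
        return self.gap(x)


class _ResidualBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng=rng)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng=rng)
        self.project = Conv2d(in_ch, out_ch, 1, rng=rng, bias=False) if in_ch != out_ch else None

    def forward(self, x: Tensor) -> Tensor:
        shortcut = self.project(x) if self.project is not None else x
        h = self.conv2(self.conv1(x).relu())
        return (h + shortcut).relu()


class CnnbBranch(Module):
    """Residual branch: plain stem + identity-shortcut blocks + global pool."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.stem = Sequential(Conv2d(3, cfg.resnet_widths[0], 3, rng=rng), ReLU())
        blocks = []
        in_ch = cfg.resnet_widths[0]
        for w in cfg.resnet_widths:
            blocks.append(_ResidualBlock(in_ch, w, rng))
            in_ch = w
        self.blocks = blocks
        self.pool = MaxPool2d(2, 2)
        self.gap = GlobalAvgPool()
        self.feature_dim = cfg.resnet_widths[-1]

    def forward(self, x: Tensor) -> Tensor:
        x = self.pool(self.stem(x))
        for block in self.blocks:
            x = self.pool(block(x))
        return self.gap(x)


def build_branch(desc: BranchDescriptor, cfg: ModelConfig | None = None,
                 rng: np.random.Generator | None = None) -> Module:
    """Construct a feature extractor from a validated descriptor."""
    cfg = cfg or ModelConfig()
    rng = rng or np.random.default_rng(cfg.seed)
    if desc.backbone == "vgg16_modified":
        branch_cfg = ModelConfig(**{**cfg.to_dict(), **dict(
            blurpool=bool(desc.blurpool),
            attention_order=desc.attention_order or cfg.attention_order,
            masking_enabled=bool(desc.masking_enabled),
            masking_stage=desc.masking_stage or cfg.masking_stage,
        )})
        return CnnaBranch(branch_cfg, rng)
    return CnnbBranch(cfg, rng)


def bilinear_fuse(fa, fb):
    """Bilinear fusion of two feature vectors.

    Outer product fa fb^T flattened row-major, then signed square root,
    then L2 normalisation.  Accepts 1-D arrays (returns an array) or
    batched (N, d) Tensors (returns a Tensor); all-zero input fuses to the
    zero vector.
    """
    if isinstance(fa, Tensor) or isinstance(fb, Tensor):
        n, da = fa.shape
        db = fb.shape[1]
        outer = fa.reshape(n, da, 1) * fb.reshape(n, 1, db)
        fused = outer.reshape(n, da * db).signed_sqrt()
        return l2_normalize(fused, axis=1)
    fa = np.asarray(fa, dtype=np.float64)
    fb = np.asarray(fb, dtype=np.float64)
    flat = np.outer(fa, fb).ravel()
    ss = np.sign(flat) * np.sqrt(np.abs(flat))
    norm = np.linalg.norm(ss)
    return ss / norm if norm > 0 else ss


class ParallelPainModel(Module):
    """The quadruple (fA, fB, bilinear fusion, softmax classifier)."""

    def __init__(self, cfg: ModelConfig | None = None):
        cfg = cfg or ModelConfig()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.cnna = CnnaBranch(cfg, rng) if cfg.arm in ("parallel", "cnna") else None
        self.cnnb = CnnbBranch(cfg, rng) if cfg.arm in ("parallel", "cnnb") else None
        da = self.cnna.feature_dim if self.cnna else 1
        db = self.cnnb.feature_dim if self.cnnb else 1
        self.head = Linear(da * db, cfg.n_classes, rng=rng)

    def features(self, x: Tensor) -> Tensor:
        n = x.shape[0]
        # an absent branch is ablated to a frozen all-ones feature, so the
        # bilinear fusion degrades gracefully to the remaining branch
        fa = self.cnna(x) if self.cnna else Tensor(np.ones((n, 1)))
        fb = self.cnnb(x) if self.cnnb else Tensor(np.ones((n, 1)))
        return bilinear_fuse(fa, fb)

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.features(x))


def predict(model: ParallelPainModel, image: np.ndarray) -> np.ndarray:
    """Class probabilities over the 6 clustered levels for one image.

    ``image`` is either a (H, W, 3) uint8 frame (preprocessed automatically)
    or an already-preprocessed (3, S, S) array matching the configured input
    size.  Inference mode: DropBlock is inactive and the output is
    deterministic given fixed parameters.
    """
    size = model.cfg.input_size
    image = np.asarray(image)
    if image.ndim == 3 and image.shape[2] == 3 and image.dtype == np.uint8:
        x = preprocess(image, size)
    elif image.shape == (3, size, size):
        x = image.astype(np.float64)
    else:
        raise ValueError(
            f"expected (H, W, 3) uint8 or (3, {size}, {size}) preprocessed image, "
            f"got shape {image.shape} dtype {image.dtype}"
        )
    model.eval()
    logits = model(Tensor(x[None]))
    return np.exp(log_softmax(logits, axis=1).data[0])


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.epochs)


def train(
    model: ParallelPainModel,
    records: Sequence[FrameRecord],
    epochs: int = 20,
    batch_size: int = 32,
    lr: float = 1e-3,
    val_fraction: float = 0.1,
    seed: int = 0,
    root: str | Path | None = None,
    checkpoint_path: str | Path | None = None,
    data: tuple[np.ndarray, np.ndarray] | None = None,
    verbose: bool = False,
) -> TrainHistory:
    """Minimise cross-entropy over the clustered levels with Adam.

    A ``val_fraction`` tail of a seeded shuffle is held out for
    checkpoint selection (best validation accuracy; falls back to training
    accuracy when the holdout is empty).  ``data`` may supply preloaded
    (X, y) arrays to skip image I/O.  Fully deterministic under ``seed``.
    """
    if data is None:
        if not records:
            raise ValueError("empty training manifest")
        X, y = load_dataset(records, model.cfg.input_size, root=root)
    else:
        X, y = data
        if len(X) == 0:
            raise ValueError("empty training data")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(X))
    n_val = int(len(X) * val_fraction)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    Xtr, ytr = X[train_idx], y[train_idx]
    Xva, yva = X[val_idx], y[val_idx]

    opt = Adam(model.parameters(), lr=lr)
    history = TrainHistory()
    best_metric = -np.inf
    best_state = None
    for epoch in range(epochs):
        model.train()
        order = rng.permutation(len(Xtr))
        losses, correct = [], 0
        for start in range(0, len(Xtr), batch_size):
            idx = order[start:start + batch_size]
            xb, yb = Tensor(Xtr[idx]), ytr[idx]
            logits = model(xb)
            loss = cross_entropy(logits, yb)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: {loss.data!r}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            correct += int((logits.data.argmax(axis=1) == yb).sum())
        train_acc = correct / len(Xtr)
        entry = {
            "epoch": epoch,
            "loss": float(np.mean(losses)),
            "accuracy": train_acc,
        }
        if len(Xva):
            va_pred = _batched_logits(model, Xva, batch_size)
            entry["val_accuracy"] = float((va_pred.argmax(axis=1) == yva).mean())
            metric = entry["val_accuracy"]
        else:
            metric = train_acc
        history.epochs.append(entry)
        if verbose:
            print(f"epoch {epoch}: " + ", ".join(f"{k}={v:.4f}" for k, v in entry.items() if k != "epoch"))
        if metric >= best_metric:
            best_metric = metric
            best_state = {k: v.copy() for k, v in model.state_dict().items()}
    if best_state is not None:
        model.load_state_dict(best_state)
    if checkpoint_path is not None:
        save_checkpoint(model, checkpoint_path, history)
    return history


def _batched_logits(model: ParallelPainModel, X: np.ndarray,
                    batch_size: int) -> np.ndarray:
    model.eval()
    outs = []
    for start in range(0, len(X), batch_size):
        outs.append(model(Tensor(X[start:start + batch_size])).data)
    return np.concatenate(outs)


def predict_levels(model: ParallelPainModel, X: np.ndarray,
                   batch_size: int = 64) -> np.ndarray:
    """Argmax clustered level for a stack of preprocessed images."""
    return _batched_logits(model, X, batch_size).argmax(axis=1)


def save_checkpoint(model: ParallelPainModel, path: str | Path,
                    history: TrainHistory | None = None) -> None:
    """Write parameters + embedded config (npz with a JSON config entry)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": model.cfg.to_dict(),
        "history": history.epochs if history else [],
        "saved_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "format_version": 1,
    }
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path: str | Path) -> tuple[ParallelPainModel, dict]:
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        state = {k: npz[k] for k in npz.files if k != "__meta__"}
    cfg_dict = meta["config"]
    model = ParallelPainModel(ModelConfig(**cfg_dict))
    model.load_state_dict(state)
    return model, meta
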