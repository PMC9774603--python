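"""Attention-driven regional masking and DropBlock background shielding.

The attention gates tell us where the informative (facial) content lives:
channels with low channel-attention weight carry little foreground signal,
and pixels with low spatial-attention weight belong to the background.  This
module turns those weights into a core/non-core partition — the lowest
quartile of channels is selected for filtering, and pixels whose spatial
weight falls below the first-quartile threshold are declared non-core — and
shields the non-core content of the filtered channels with a DropBlock-style
stochastic mask during training.  Inference is always the identity.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DropBlockConfig",
    "q1_position",
    "select_filter_channels",
    "spatial_threshold",
    "make_core_mask",
    "apply_region_mask",
    "dropblock_gamma",
    "dropblock_shield",
    "RegionalMasking",
]


@dataclass
class DropBlockConfig:
    """Parameters of the background-shielding stage.

    ``variant`` selects between the activation-threshold mask (per-call
    threshold drawn uniformly from ``threshold_range`` and applied to the
    strongest channel's activations) and the classical gamma-driven
    Bernoulli-seed-and-stamp DropBlock parameterised by ``keep_prob`` and
    ``block_size``.
    """

    keep_prob: float = 0.9
    block_size: int = 3
    threshold_range: tuple[float, float] = (0.6, 0.9)
    mode: str = "training"
    variant: str = "algorithm1"
    broadcast: bool = True
    fixed_theta: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.keep_prob <= 1.0:
            raise ValueError(f"keep_prob must be in (0, 1], got {self.keep_prob}")
        if self.block_size < 1:
            raise ValueError(f"block_size must be >= 1, got {self.block_size}")
        lo, hi = self.threshold_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError(f"threshold_range must satisfy 0 <= lo <= hi <= 1, got {self.threshold_range}")
        if self.mode not in ("training", "inference"):
            raise ValueError(f"mode must be 'training' or 'inference', got {self.mode!r}")
        if self.variant not in ("algorithm1", "gamma_stamp"):
            raise ValueError(f"variant must be 'algorithm1' or 'gamma_stamp', got {self.variant!r}")


def q1_position(n: int, quantile: float = 0.25) -> float:
    """1-based position of the first quartile among n sorted values: (n+1)/4.

    ``quantile`` generalises the rule (e.g. 0.75 selects the third-quartile
    position instead).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    return (n + 1) * quantile


def _round_half_down(x: float) -> int:
    # 2.5 -> 2 (not banker's rounding): ceil(x - 0.5)
    return int(math.ceil(x - 0.5))


def select_filter_channels(weights: np.ndarray, quantile: float = 0.25) -> np.ndarray:
    """Indices of the lowest-quartile channels by attention weight.

    Weights are sorted ascending and the first round(Q1) original channel
    indices are returned; ties break toward the lower original index.  The
    fractional quartile position is rounded half-down so the selected set is
    an integer cardinality in [0, C].
    """
    weights = np.asarray(weights, dtype=np.float64).ravel()
    if not np.all(np.isfinite(weights)):
        raise ValueError("channel weights must be finite")
    n = len(weights)
    count = min(max(_round_half_down(q1_position(n, quantile)), 0), n)
    order = np.argsort(weights, kind="stable")  # stable: ties by original index
    return np.sort(order[:count])


def spatial_threshold(sweights: np.ndarray, quantile: float = 0.25) -> float:
    """First-quartile value of the spatial attention map (linear interpolation).

    The HxW map is flattened, sorted ascending, and the value at 1-based
    position (n+1)/4 is returned, interpolating linearly between neighbours
    when the position is fractional.  ``quantile`` moves the cut (0.75 would
    shield everything below the third quartile instead).
    """
    flat = np.sort(np.asarray(sweights, dtype=np.float64).ravel())
    n = len(flat)
    if n < 1:
        raise ValueError("spatial weight map must be non-empty")
    pos = q1_position(n, quantile)  # 1-based
    lo = max(int(math.floor(pos)), 1)
    hi = min(lo + 1, n)
    frac = pos - lo
    if pos <= 1:
        return float(flat[0])
    return float(flat[lo - 1] * (1 - frac) + flat[hi - 1] * frac)


def make_core_mask(sweights: np.ndarray, threshold: float) -> np.ndarray:
    """Binary core-region mask: 1 where the spatial weight >= threshold.

    Core pixels (1) are retained when the mask multiplies a feature map;
    non-core pixels (0) are shielded.
    """
    sweights = np.asarray(sweights, dtype=np.float64)
    return (sweights >= threshold).astype(np.float64)


def apply_region_mask(fmap: np.ndarray, mask: np.ndarray,
                      channels: np.ndarray) -> np.ndarray:
    """Multiply the selected filter channels by the binary mask.

    Non-selected channels pass through unchanged.
    """
    fmap = np.asarray(fmap, dtype=np.float64)
    mask = np.asarray(mask, dtype=np.float64)
    if fmap.shape[-2:] != mask.shape:
        raise ValueError(f"mask shape {mask.shape} != feature map spatial shape {fmap.shape[-2:]}")
    channels = np.asarray(channels, dtype=int)
    if channels.size and (channels.min() < 0 or channels.max() >= fmap.shape[0]):
        raise ValueError(f"channel indices {channels} out of range for C={fmap.shape[0]}")
    out = fmap.copy()
    out[channels] = out[channels] * mask
    return out


def dropblock_gamma(cfg: DropBlockConfig, feat_size: int) -> float:
    """Seed probability gamma for gamma-stamp DropBlock.

    gamma = (1 - keep_prob) / block_size^2 * feat_size^2 / (feat_size - block_size + 1)^2.
    At block_size=1 this collapses to 1 - keep_prob (ordinary dropout).
    """
    if cfg.block_size > feat_size:
        raise ValueError(
            f"block_size ({cfg.block_size}) must be <= feat_size ({feat_size})"
        )
    return (
        (1.0 - cfg.keep_prob)
        / cfg.block_size**2
        * feat_size**2
        / (feat_size - cfg.block_size + 1) ** 2
    )


def dropblock_shield(channels: np.ndarray, cfg: DropBlockConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Stochastically shield background activations in the filter channels.

    ``channels`` is the (K, H, W) stack of filter-channel activations.  In
    inference mode (or for an empty stack) the input is returned unchanged.
    In training mode with the ``algorithm1`` variant: the channel with the
    largest mean activation anchors the mask; a threshold theta is drawn
    uniformly from ``threshold_range``; units of the anchor channel strictly
    above theta times its peak activation survive (mask 1) and the mask is
    broadcast over every filter channel.  The ``gamma_stamp`` variant is
    the standard DropBlock: Bernoulli(gamma) seed points dilated to
    block_size x block_size zero blocks, shared across the stack.
    """
    channels = np.asarray(channels, dtype=np.float64)
    if channels.size == 0:
        return channels
    if channels.ndim != 3:
        raise ValueError(f"expected (K, H, W) channel stack, got shape {channels.shape}")
    if cfg.mode == "inference":
        return channels
    if cfg.variant == "algorithm1":
        return _shield_algorithm1(channels, cfg, rng)
    return _shield_gamma_stamp(channels, cfg, rng)


def _shield_algorithm1(channels: np.ndarray, cfg: DropBlockConfig,
                       rng: np.random.Generator) -> np.ndarray:
    means = channels.mean(axis=(1, 2))
    k = int(np.argmax(means))
    anchor = channels[k]
    peak = anchor.max()
    if peak <= 0:
        warnings.warn("all filter-channel activations are <= 0; shield degenerates to identity",
                      stacklevel=2)
        return channels
    lo, hi = cfg.threshold_range
    theta = cfg.fixed_theta if cfg.fixed_theta is not None else rng.uniform(lo, hi)
    if cfg.broadcast:
        mask = (anchor > theta * peak).astype(np.float64)
        return channels * mask[None]
    # per-channel variant: each channel masked against its own peak
    peaks = channels.max(axis=(1, 2), keepdims=True)
    safe = np.where(peaks > 0, peaks, 1.0)
    mask = (channels > theta * safe) | (peaks <= 0)
    return channels * mask.astype(np.float64)


def _shield_gamma_stamp(channels: np.ndarray, cfg: DropBlockConfig,
                        rng: np.random.Generator) -> np.ndarray:
    _, H, W = channels.shape
    feat_size = min(H, W)
    gamma = dropblock_gamma(cfg, feat_size)
    bs = cfg.block_size
    # seed centres restricted so stamped blocks stay inside the map
    valid_h, valid_w = H - bs + 1, W - bs + 1
    seeds = rng.random((valid_h, valid_w)) < gamma
    keep = np.ones((H, W))
    hs, ws = np.nonzero(seeds)
    for i, j in zip(hs, ws):
        keep[i:i + bs, j:j + bs] = 0.0
    return channels * keep[None]


class RegionalMasking:
    """Full masking stage wired between attention and the next conv stack.

    Consumes the captured channel weights (N, C) and spatial weights
    (N, H, W), derives per-sample filter channels, core masks and the
    DropBlock shield, and returns the constant 0/1 multiplier to apply to
    the feature map.  The multiplier treats masks as constants (no gradient
    flows through the thresholding), matching how structured dropout is
    trained.
    """

    def __init__(self, dropblock: DropBlockConfig | None = None,
                 quantile: float = 0.25, seed: int | None = None):
        self.dropblock = dropblock or DropBlockConfig()
        self.quantile = quantile
        self.rng = np.random.default_rng(seed)

    def multiplier(self, channel_weights: np.ndarray, spatial_weights: np.ndarray,
                   fmap_values: np.ndarray, training: bool) -> np.ndarray:
        """0/1 multiplier of shape (N, C, H, W) for the feature map."""
        N, C, H, W = fmap_values.shape
        mult = np.ones((N, C, H, W))
        for i in range(N):
            chans = select_filter_channels(channel_weights[i], self.quantile)
            if chans.size == 0:
                continue
            thr = spatial_threshold(spatial_weights[i], self.quantile)
            core = make_core_mask(spatial_weights[i], thr)
            mult[i, chans] = core[None]
            if training and self.dropblock.mode == "training":
                # shield what the core mask keeps of the background channels
                masked = fmap_values[i, chans] * core[None]
                if masked.max() <= 0:
                    continue
                shielded = dropblock_shield(masked, self.dropblock, self.rng)
                with np.errstate(invalid="ignore", divide="ignore"):
                    drop = np.where(masked != 0, shielded / np.where(masked == 0, 1.0, masked), 1.0)
                mult[i, chans] = core[None] * drop
        return mult
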