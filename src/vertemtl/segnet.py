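"""Dual-decoder residual U-Net: mask segmentation + boundary heat regression.

One weight-sharing residual encoder feeds two symmetric decoders. The
boundary decoder regresses the soft heat-map target (mean squared error);
its penultimate feature block is concatenated into the segmentation
decoder just before the mask head (a one-way cascade), sharpening the
predicted contour. The mask head ends in a sigmoid, the boundary head is
linear clamped to [0, 1].
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor


@dataclass
class SegNetConfig:
    in_size: int = 224
    base_channels: int = 4
    depth: int = 3               # number of resolution scales (>= 3)
    use_boundary: bool = True    # boundary decoder + cascade detachable

    def validate(self):
        if self.depth < 3:
            raise ValueError("depth must be >= 3")
        if self.in_size % (2 ** (self.depth - 1)) != 0:
            raise ValueError("in_size must be divisible by 2**(depth-1)")


@dataclass
class SegOutput:
    mask_prob: Tensor          # (N, 1, H, W) in [0, 1]
    boundary_heat: Tensor | None  # (N, 1, H, W) in [0, 1]
    decoder_features: list = field(default_factory=list)  # mask-decoder maps, coarse->fine


class _Decoder(nn.Module):
    def __init__(self, rng, chans):
        super().__init__()
        # chans: encoder channel list, fine -> coarse
        self.blocks = [
            nn.ResidualBlock(rng, chans[i + 1] + chans[i], chans[i])
            for i in reversed(range(len(chans) - 1))
        ]

    def forward(self, feats):
        h = feats[-1]
        outs = []
        for block, skip in zip(self.blocks, reversed(feats[:-1])):
            h = block(nn.concat([nn.upsample_nearest(h, 2), skip], axis=1))
            outs.append(h)
        return h, outs  # full-res penultimate features, per-scale features


class SegNet(nn.Module):
    def __init__(self, rng, config: SegNetConfig | None = None):
        super().__init__()
        self.config = config or SegNetConfig()
        self.config.validate()
        c, d = self.config.base_channels, self.config.depth
        chans = [c * 2 ** i for i in range(d)]
        self.enc_blocks = [nn.ResidualBlock(rng, 1, chans[0])]
        for cin, cout in zip(chans[:-1], chans[1:]):
            self.enc_blocks.append(nn.ResidualBlock(rng, cin, cout))
        self.mask_decoder = _Decoder(rng, chans)
        self.boundary_decoder = _Decoder(rng, chans) if self.config.use_boundary else None
        fuse_in = chans[0] * (2 if self.config.use_boundary else 1)
        self.fuse = nn.Conv2d(rng, fuse_in, chans[0], 3)
        self.mask_head = nn.Conv2d(rng, chans[0], 1, 1, padding=0)
        if self.config.use_boundary:
            self.boundary_head = nn.Conv2d(rng, chans[0], 1, 1, padding=0)
        self.channels = chans

    def forward(self, x: Tensor) -> SegOutput:
        if x.data.shape[-1] != self.config.in_size:
            raise ValueError(f"expected {self.config.in_size}-px input, "
                             f"got {x.data.shape[-1]}")
        feats = []
        h = x
        for i, block in enumerate(self.enc_blocks):
            if i > 0:
                h = nn.max_pool2d(h, 2)
            h = block(h)
            feats.append(h)
        mask_pen, mask_scales = self.mask_decoder(feats)
        boundary_heat = None
        if self.boundary_decoder is not None:
            bd_pen, _ = self.boundary_decoder(feats)
            boundary_heat = nn.clip(self.boundary_head(bd_pen), 0.0, 1.0)
            fused = self.fuse(nn.concat([mask_pen, bd_pen], axis=1))
        else:
            fused = self.fuse(mask_pen)
        mask_prob = nn.sigmoid(self.mask_head(nn.relu(fused)))
        return SegOutput(mask_prob, boundary_heat, mask_scales)


# --------------------------------------------------------------------------
# losses
# --------------------------------------------------------------------------
def dice_loss(mask_prob: Tensor, truth_mask: np.ndarray, smooth: float = 1.0) -> Tensor:
    """Soft Dice loss 1 - (2*sum(p*g) + s) / (sum(p) + sum(g) + s)."""
    g = Tensor(np.asarray(truth_mask, dtype=np.float32).reshape(mask_prob.data.shape))
    inter = (mask_prob * g).sum()
    return 1.0 - (2.0 * inter + smooth) / (mask_prob.sum() + g.sum() + smooth)


def boundary_mse(boundary_heat: Tensor, heat_label: np.ndarray) -> Tensor:
    """Mean squared error against the normalized boundary heat target."""
    t = Tensor(np.asarray(heat_label, dtype=np.float32).reshape(boundary_heat.data.shape))
    diff = boundary_heat - t
    return (diff * diff).mean()


def dice_coefficient(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Hard Dice 2TP / (2TP + FP + FN) between binary masks."""
    p = np.asarray(pred_mask, dtype=bool)
    g = np.asarray(truth_mask, dtype=bool)
    tp = float(np.logical_and(p, g).sum())
    denom = 2 * tp + float(np.logical_and(p, ~g).sum()) + float(np.logical_and(~p, g).sum())
    return 2 * tp / denom if denom > 0 else 1.0


def iou_score(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """Jaccard TP / (TP + FP + FN) between binary masks."""
    p = np.asarray(pred_mask, dtype=bool)
    g = np.asarray(truth_mask, dtype=bool)
    inter = float(np.logical_and(p, g).sum())
    union = float(np.logical_or(p, g).sum())
    return inter / union if union > 0 else 1.0
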