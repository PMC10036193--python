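"""Gated-attention classification backbone with segmentation-feature cascade.

Channel attention is the gated channel transformation (GCT): an L2
embedding per channel, cross-channel normalization, and a tanh gate,

    s_c    = alpha_c * (sum_{HW} x_c^2 + eps)^(1/2)
    s_hat_c = sqrt(C) * s_c / (sum_c s_c^2 + n)^(1/2)
    x_hat_c = x_c * (1 + tanh(gamma_c * s_hat_c + beta_c))

applied in front of each residual block's conv stack. Mask-decoder
feature maps from the segmentation network are fused into matching-scale
stages with a 1x1 conv over the channel concatenation. Global average
pooling plus a linear projection yields the fixed 2048-d per-vertebra
embedding regardless of backbone width.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

EMBED_DIM = 2048


@dataclass
class GCTParams:
    alpha: Tensor
    gamma: Tensor
    beta: Tensor
    eps: float = 1e-5
    norm_eps: float = 1e-5

    @classmethod
    def create(cls, channels: int, eps: float = 1e-5, norm_eps: float = 1e-5):
        # alpha=1, gamma=beta=0: the module starts as an exact identity
        return cls(Tensor(np.ones(channels, np.float32), requires_grad=True),
                   Tensor(np.zeros(channels, np.float32), requires_grad=True),
                   Tensor(np.zeros(channels, np.float32), requires_grad=True),
                   eps, norm_eps)


def gct(x: Tensor, p: GCTParams) -> Tensor:
    """Gated channel transformation; preserves shape (N, C, H, W)."""
    n_ch = x.data.shape[1]
    if p.alpha.data.shape[0] != n_ch:
        raise ValueError("channel count does not match GCT parameters")
    sq = (x * x).sum(axis=(2, 3))                        # (N, C)
    s = nn.reshape(p.alpha, (1, n_ch)) * nn.sqrt(sq + p.eps)
    norm = nn.sqrt((s * s).sum(axis=1, keepdims=True) + p.norm_eps)
    s_hat = float(np.sqrt(n_ch)) * s / norm
    gate = 1.0 + nn.tanh(nn.reshape(p.gamma, (1, n_ch)) * s_hat
                         + nn.reshape(p.beta, (1, n_ch)))
    return x * nn.reshape(gate, (x.data.shape[0], n_ch, 1, 1))


class GatedResidualBlock(nn.Module):
    """GCT -> conv-norm-ReLU -> conv-norm -> identity add (projection on
    shape change) -> ReLU. With gamma = beta = 0 this is a plain residual
    block. Group normalization by default: the classification path trains
    on small mixed batches, where batch statistics are unreliable."""

    def __init__(self, rng, in_ch, out_ch, stride=1, use_gct=True,
                 norm="group"):
        super().__init__()
        self.gct_params = GCTParams.create(in_ch) if use_gct else None
        self.body = nn.ResidualBlock(rng, in_ch, out_ch, stride, norm=norm)

    def parameters(self):
        params = super().parameters()
        if self.gct_params is not None:
            params.extend([self.gct_params.alpha, self.gct_params.gamma,
                           self.gct_params.beta])
        return params

    def forward(self, x):
        h = gct(x, self.gct_params) if self.gct_params is not None else x
        return self.body(h)


class CascadeFuse(nn.Module):
    """1x1-conv fusion of classifier features y with segmentation features s:
    y_hat = Conv1x1(Concat(y, s)), output channels = channels of y."""

    def __init__(self, rng, y_ch, s_ch):
        super().__init__()
        self.conv = nn.Conv2d(rng, y_ch + s_ch, y_ch, 1, padding=0)

    def forward(self, y: Tensor, s: Tensor) -> Tensor:
        if y.data.shape[2:] != s.data.shape[2:]:
            raise ValueError("spatial sizes must match after alignment")
        return self.conv(nn.concat([y, s], axis=1))


def align_spatial(s: Tensor, target_hw) -> Tensor:
    """Average-pool (or nearest-upsample) seg features to a target size."""
    h = s.data.shape[2]
    th = target_hw[0]
    if h == th:
        return s
    if h > th:
        if h % th:
            raise ValueError("non-integer pooling factor")
        return nn.avg_pool2d(s, h // th)
    if th % h:
        raise ValueError("non-integer upsampling factor")
    return nn.upsample_nearest(s, th // h)


@dataclass
class ClsNetConfig:
    in_size: int = 224
    base_width: int = 8
    stage_blocks: tuple = (1, 1, 1, 1)   # residual blocks per stage 2..5
    use_gct: bool = True
    cascade_stages: tuple = (0, 2)       # stage indices receiving seg features
    seg_channels: tuple = ()             # channels of the cascaded seg maps
    detach_seg: bool = True


class ClsNet(nn.Module):
    """Stem + four gated-residual stages + global pool + 2048-d projection.

    Stage spatial sizes for a 224 input: 56, 28, 14, 7 (stem stride 4).
    ``seg_channels[i]`` gives the channel count of the segmentation feature
    cascaded into ``cascade_stages[i]``.
    """

    def __init__(self, rng, config: ClsNetConfig | None = None):
        super().__init__()
        self.config = cfg = config or ClsNetConfig()
        w = cfg.base_width
        widths = (w, 2 * w, 4 * w, 8 * w)
        self.stem = nn.ConvBNReLU(rng, 1, w, 3, stride=2, norm="group")
        self.stages = []
        cin = w
        for si, (cout, nblocks) in enumerate(zip(widths, cfg.stage_blocks)):
            blocks = []
            for bi in range(nblocks):
                stride = 2 if (bi == 0 and si > 0) else 1
                blocks.append(GatedResidualBlock(rng, cin, cout, stride,
                                                 use_gct=cfg.use_gct))
                cin = cout
            self.stages.append(blocks)
        self.fusers = {}
        fuser_list = []
        for stage_idx, s_ch in zip(cfg.cascade_stages, cfg.seg_channels):
            f = CascadeFuse(rng, widths[stage_idx], s_ch)
            self.fusers[stage_idx] = f
            fuser_list.append(f)
        self._fuser_list = fuser_list  # registered for parameters()
        self.proj = nn.Linear(rng, widths[-1], EMBED_DIM)
        # damp the wide projection so the 2048-d embedding (and hence the
        # curvature of the downstream fc) stays O(1) in norm
        self.proj.weight.data *= 0.125

    def forward(self, x: Tensor, seg_features=None) -> Tensor:
        """224-px crop (N, 1, H, W) -> (N, 2048) embedding.

        ``seg_features`` is a list matching ``config.cascade_stages`` order;
        entries are aligned spatially and fused after the stage output.
        """
        cfg = self.config
        h = nn.max_pool2d(self.stem(x), 2)
        for si, blocks in enumerate(self.stages):
            for block in blocks:
                h = block(h)
            if si in self.fusers and seg_features is not None:
                pos = list(cfg.cascade_stages).index(si)
                s = seg_features[pos]
                if cfg.detach_seg:
                    s = s.detach()
                s = align_spatial(s, h.data.shape[2:])
                h = self.fusers[si](h, s)
        pooled = h.mean(axis=(2, 3))          # (N, C)
        return self.proj(pooled)
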