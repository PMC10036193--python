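"""Assembly of the four network stages into one joint model.

The classifier backbone is shared between the two vertebral levels (one
set of weights, two forward passes); the segmentation decoder's feature
maps are cascaded into it at matching scales. Three ablation toggles
mirror the framework's components: ``lf`` (layered fusion of
segmentation features into the classifier), ``gc`` (gated channel
transformation in the classifier blocks) and ``ff`` (adaptive
two-vertebra feature fusion; off = fixed 0.5/0.5 weights).
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .clsnet import ClsNet, ClsNetConfig
from .fusion_head import FusionHead
from .localizer import LocalizerNet
from .segnet import SegNet, SegNetConfig


@dataclass
class JointConfig:
    image_size: int = 512
    seg: SegNetConfig = field(default_factory=SegNetConfig)
    cls_width: int = 8
    lf: bool = True   # cascade segmentation features into the classifier
    gc: bool = True   # gated channel transformation
    ff: bool = True   # adaptive two-vertebra fusion
    detach_seg: bool = True
    heat_sigma: float = 2.0
    seed: int = 0

    def to_dict(self):
        return asdict(self)

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        if "seg" in d and isinstance(d["seg"], dict):
            d["seg"] = SegNetConfig(**d["seg"])
        return cls(**d)


class JointModel(nn.Module):
    def __init__(self, config: JointConfig | None = None):
        super().__init__()
        self.config = cfg = config or JointConfig()
        rng = np.random.default_rng(cfg.seed)
        self.localizer = LocalizerNet(rng, cfg.image_size)
        self.segnet = SegNet(rng, cfg.seg)
        c = cfg.seg.base_channels
        if cfg.lf:
            cls_cfg = ClsNetConfig(base_width=cfg.cls_width, use_gct=cfg.gc,
                                   cascade_stages=(0, 2),
                                   seg_channels=(c, 2 * c),
                                   detach_seg=cfg.detach_seg)
        else:
            cls_cfg = ClsNetConfig(base_width=cfg.cls_width, use_gct=cfg.gc,
                                   cascade_stages=(), seg_channels=())
        self.clsnet = ClsNet(rng, cls_cfg)
        self.fusion = FusionHead(rng, adaptive=cfg.ff)

    def cascade_features(self, seg_out):
        """Pick the mask-decoder maps routed into the classifier:
        the finest (full-res) map for stage 0 and the next-coarser map for
        stage 2; returns None when layered fusion is off."""
        if not self.config.lf:
            return None
        scales = seg_out.decoder_features
        return [scales[-1], scales[0]]

    def embed_crop(self, crop_tensor, seg_out):
        return self.clsnet(crop_tensor, self.cascade_features(seg_out))

    # -- persistence --------------------------------------------------------
    def save(self, path):
        path = Path(path)
        arrays = self.state_arrays()
        np.savez_compressed(path, **arrays)
        path.with_suffix(".json").write_text(json.dumps(self.config.to_dict()))

    @classmethod
    def load(cls, path):
        path = Path(path)
        cfg = JointConfig.from_dict(json.loads(path.with_suffix(".json").read_text()))
        model = cls(cfg)
        with np.load(path if path.suffix == ".npz" else str(path) + ".npz") as data:
            model.load_state_arrays({k: data[k] for k in data.files})
        return model
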