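"""I/O, configuration, and the end-to-end inference pipeline.

Stage order per study: preprocess both slices -> locate the vertebral
body -> 224-px crop -> dual-decoder segmentation -> optional level-set
refinement of the mask -> gated-attention embedding (with segmentation
feature cascade) -> adaptive two-vertebra fusion -> 3-class posterior.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
import pandas as pd
import yaml
from skimage.transform import resize

from . import levelset as ls
from . import localizer as loc
from . import nn
from .fusion_head import CLASS_NAMES, FusionWeights, StudyPrediction
from .model import JointConfig, JointModel
from .nn import Tensor
from .sampler import MixConfig
from .segnet import SegNetConfig
from .trainer import TrainerConfig, _seg_features

log = logging.getLogger("vertemtl")

TARGET_SIZE = 512


class CaseSkipped(RuntimeError):
    """Raised when a stage cannot produce output for a case."""


def preprocess(image: np.ndarray, value_range=None) -> np.ndarray:
    """Normalize to [0, 1] and resize to 512 x 512 (bilinear).

    The intensity rescale uses the container's nominal range: 8-bit /255,
    16-bit /65535, float min-max (or an explicit ``value_range``).
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if value_range is not None:
        lo, hi = value_range
    elif img.dtype == np.uint8:
        lo, hi = 0.0, 255.0
    elif img.dtype == np.uint16:
        lo, hi = 0.0, 65535.0
    elif img.min() >= 0.0 and img.max() <= 1.0:
        lo, hi = 0.0, 1.0   # float container already on the nominal scale
    else:
        lo, hi = float(img.min()), float(img.max())
    img = img.astype(np.float64)
    img = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    if img.shape != (TARGET_SIZE, TARGET_SIZE):
        img = resize(img, (TARGET_SIZE, TARGET_SIZE), order=1, mode="edge",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


@dataclass
class PipelineResult:
    case_id: str
    boxes: dict                     # level -> (cx, cy, w, h, score)
    crops: dict                     # level -> 224x224 float image
    cnn_masks: dict                 # level -> bool mask (crop frame)
    refined_masks: dict             # level -> bool mask or None
    heat_maps: dict                 # level -> float heat map or None
    prediction: StudyPrediction
    metadata: dict = field(default_factory=dict)


def config_hash(cfg: JointConfig) -> str:
    return hashlib.sha256(
        json.dumps(cfg.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(slice_l1, slice_l2, model: JointModel, case_id: str = "case",
                 refine: bool = True, levelset_params: ls.LevelSetParams | None = None,
                 obj_threshold: float = 0.3) -> PipelineResult:
    """Full inference for one paired-slice study.

    Both slices are required; a failed detection raises
    :class:`CaseSkipped` with the stage recorded.
    """
    if slice_l1 is None or slice_l2 is None:
        raise ValueError(f"{case_id}: both L1 and L2 slices are required")
    model.eval()
    levels = {"l1": preprocess(slice_l1), "l2": preprocess(slice_l2)}
    boxes, crops, cnn_masks, refined, heats, embeds = {}, {}, {}, {}, {}, {}
    for level, img in levels.items():
        box = loc.detect(img, model.localizer, obj_threshold=obj_threshold)
        if box is None:
            log.warning("%s [%s] detect: no box above threshold", case_id, level)
            raise CaseSkipped(f"{case_id}/{level}: vertebra not found")
        log.info("%s [%s] detect: (%.1f, %.1f)", case_id, level, box.p_x, box.p_y)
        boxes[level] = (box.p_x, box.p_y, box.p_w, box.p_h, box.score)
        crop = loc.crop_center(img, box.p_x, box.p_y)
        crops[level] = crop
        ct = Tensor(crop[None, None])
        with nn.no_grad():
            seg_out = model.segnet(ct)
            embeds[level] = model.embed_crop(ct, seg_out)
        mask = seg_out.mask_prob.data[0, 0] > 0.5
        cnn_masks[level] = mask
        heats[level] = (seg_out.boundary_heat.data[0, 0]
                        if seg_out.boundary_heat is not None else None)
        if refine and mask.any():
            refined[level], _ = ls.evolve(crop, mask, levelset_params)
            log.info("%s [%s] refine: %d -> %d px", case_id, level,
                     int(mask.sum()), int(refined[level].sum()))
        else:
            refined[level] = None
    with nn.no_grad():
        fused, w1, w2 = model.fusion.fuse(embeds["l1"], embeds["l2"])
        post = nn.softmax(model.fusion.logits(fused), axis=1).data[0]
    pred = StudyPrediction(post.copy(),
                           FusionWeights(float(w1.data[0, 0]), float(w2.data[0, 0])),
                           CLASS_NAMES[int(np.argmax(post))])
    log.info("%s classify: %s", case_id, pred.predicted_label)
    return PipelineResult(case_id, boxes, crops, cnn_masks, refined, heats, pred,
                          metadata={"config_hash": config_hash(model.config),
                                    "seed": model.config.seed})


def run_batch(cases, model: JointModel, **kwargs):
    """Run the pipeline over many cases; a failed case is logged and
    skipped, never aborting the batch. Returns (results, skipped ids)."""
    results, skipped = [], []
    for case in cases:
        try:
            results.append(run_pipeline(case.slice_l1, case.slice_l2, model,
                                        case_id=case.case_id, **kwargs))
        except CaseSkipped as exc:
            log.warning("skipped %s: %s", case.case_id, exc)
            skipped.append(case.case_id)
    return results, skipped


# --------------------------------------------------------------------------
# artifact persistence
# --------------------------------------------------------------------------
def write_results(results, outdir) -> None:
    outdir = Path(outdir)
    (outdir / "masks").mkdir(parents=True, exist_ok=True)
    (outdir / "heat").mkdir(exist_ok=True)
    rows, boxes = [], {}
    for r in results:
        for level in ("l1", "l2"):
            if r.cnn_masks[level] is not None:
                imageio.imwrite(outdir / "masks" / f"{r.case_id}_{level}_cnn.png",
                                r.cnn_masks[level].astype(np.uint8) * 255)
            if r.refined_masks[level] is not None:
                imageio.imwrite(outdir / "masks" / f"{r.case_id}_{level}_refined.png",
                                r.refined_masks[level].astype(np.uint8) * 255)
            if r.heat_maps[level] is not None:
                np.save(outdir / "heat" / f"{r.case_id}_{level}.npy",
                        r.heat_maps[level].astype(np.float32))
            cx, cy, w, h, score = r.boxes[level]
            boxes[f"{r.case_id}_{level}"] = {"cx": cx, "cy": cy, "w": w,
                                             "h": h, "score": score}
        p = r.prediction
        rows.append({"case_id": r.case_id,
                     "p_normal": p.posterior[0], "p_osteopenia": p.posterior[1],
                     "p_osteoporosis": p.posterior[2],
                     "w1": p.weights.w1, "w2": p.weights.w2,
                     "label": p.predicted_label})
    with open(outdir / "boxes.json", "w") as fh:
        json.dump(boxes, fh, indent=1)
    pd.DataFrame(rows).to_csv(outdir / "predictions.csv", index=False)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------
def load_config(path=None) -> dict:
    """Resolve the YAML run configuration into typed config objects."""
    raw = {}
    if path is not None:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    model_raw = dict(raw.get("model", {}))
    seg_raw = model_raw.pop("seg", {})
    joint = JointConfig(seg=SegNetConfig(**seg_raw), **model_raw)
    trainer_raw = dict(raw.get("trainer", {}))
    sampler_raw = dict(raw.get("sampler", {}))
    mix = MixConfig(alpha=sampler_raw.get("alpha", 0.1),
                    exponent_n=sampler_raw.get("exponent_n", 1.0))
    trainer = TrainerConfig(mix=mix, **trainer_raw)
    lsp = ls.LevelSetParams(**raw.get("levelset", {}))
    return {"joint": joint, "trainer": trainer, "levelset": lsp, "raw": raw}


def write_resolved_config(cfgs: dict, outdir) -> None:
    out = {"model": cfgs["joint"].to_dict(),
           "trainer": {k: v for k, v in vars(cfgs["trainer"]).items()
                       if not hasattr(v, "__dict__")},
           "levelset": vars(cfgs["levelset"])}
    Path(outdir).mkdir(parents=True, exist_ok=True)
    with open(Path(outdir) / "resolved_config.yaml", "w") as fh:
        yaml.safe_dump(out, fh)
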