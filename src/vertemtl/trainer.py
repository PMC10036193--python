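"""Multitask training: adaptive loss weighting, the SGD loop, and metrics.

The six loss terms (box IoU, detection class, objectness, Dice, boundary
MSE, classification cross-entropy) are combined with learned
homoscedastic-uncertainty weights,

    L = sum_i exp(-s_i) * L_i + s_i,

where each log-variance s_i is an SGD-trainable scalar; exp(-s_i) is the
effective weight of term i. The s_i are clamped to [-5, 5] so no term's
weight can collapse or explode.

Classification batches are drawn with the instance/class mixed sampler;
the mixed (image, soft-label) pair feeds only the cross-entropy term,
while the unmixed instance sample supplies the geometric targets (boxes,
masks, heat maps).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from . import boundary as bd
from . import localizer as loc
from . import nn
from .fusion_head import CLASS_NAMES
from .model import JointConfig, JointModel
from .nn import Tensor
from .sampler import MixConfig, TrainingSet, draw_mixed
from .segnet import boundary_mse, dice_loss

LOSS_TERMS = ("ioc", "det_cls", "det_obj", "dice", "boundary", "cls")


class LossWeights:
    """Six trainable log-variance scalars, one per loss term."""

    def __init__(self, init: float = 0.0):
        self.s = {name: Tensor(np.float32(init), requires_grad=True)
                  for name in LOSS_TERMS}

    def parameters(self):
        return list(self.s.values())

    def effective_weight(self, name: str) -> float:
        return float(np.exp(-self.s[name].data))

    def clamp(self, lo: float = -2.0, hi: float = 5.0):
        """Bound the log-variances: effective weights stay in
        [exp(-hi), exp(-lo)], so no term collapses (or explodes)."""
        for t in self.s.values():
            t.data = np.clip(t.data, lo, hi)


def multitask_loss(terms: dict, lw: LossWeights):
    """Total loss sum_i exp(-s_i) L_i + s_i over the non-None terms.

    Returns (total Tensor, {name: float L_i}). A non-finite term raises,
    naming the offending term.
    """
    total = None
    breakdown = {}
    for name in LOSS_TERMS:
        term = terms.get(name)
        if term is None:
            continue
        val = float(term.data)
        if not np.isfinite(val):
            raise FloatingPointError(f"loss term '{name}' is not finite: {val}")
        breakdown[name] = val
        piece = nn.exp(-lw.s[name]) * term + lw.s[name]
        total = piece if total is None else total + piece
    if total is None:
        raise ValueError("all loss terms masked")
    return total, breakdown


# --------------------------------------------------------------------------
# training data preparation
# --------------------------------------------------------------------------
@dataclass
class TrainerConfig:
    lr: float = 1e-3
    momentum: float = 0.9
    epochs: int = 20
    batch_size: int = 4
    mix: MixConfig = field(default_factory=MixConfig)
    cls_batch_size: int = 8   # mixed draws per step feeding the CE term
    cls_lr_scale: float = 2.0  # classifier+fusion lr multiplier: the CE
                               # term converges slowest at desk scale
    loc_lr_scale: float = 1.0  # detection-head lr multiplier
    avg_tail_frac: float = 0.3  # Polyak-Ruppert: final weights = uniform
                                # average of the iterates over the last
                                # fraction of steps (0 disables)
    crop_jitter: float = 12.0  # px; classification crops are re-cut each
    s_min: float = -2.0        # epoch around a jittered centre so the
                               # classifier tolerates detector error
    s_max: float = 5.0
    grad_clip: float = 50.0   # safety net against spikes; loose enough not
    seed: int = 0             # to starve low-gradient heads


class _Prepared:
    """Per-case precomputed crops, masks, heat labels and truth boxes."""

    def __init__(self, case, heat_sigma: float):
        self.label_idx = CLASS_NAMES.index(case.label)
        self.slices = (case.slice_l1, case.slice_l2)
        self.boxes = (case.box_l1, case.box_l2)
        self.crops, self.mask_crops, self.heats = [], [], []
        for sl, mk, box in ((case.slice_l1, case.mask_l1, case.box_l1),
                            (case.slice_l2, case.mask_l2, case.box_l2)):
            crop = loc.crop_center(sl, box[0], box[1])
            mcrop = loc.crop_center(mk.astype(np.float32), box[0], box[1]) > 0.5
            self.crops.append(crop.astype(np.float32))
            self.mask_crops.append(mcrop.astype(np.float32))
            self.heats.append(
                bd.heat_label_for_mask(mcrop, heat_sigma).heat.astype(np.float32))

    def jittered_crops(self, rng: np.random.Generator, jitter: float) -> np.ndarray:
        """(2, 224, 224) crop pair re-cut around a randomly shifted centre."""
        out = []
        for sl, box in zip(self.slices, self.boxes):
            h, w = sl.shape
            cx = float(np.clip(box[0] + rng.uniform(-jitter, jitter), 0, w - 1))
            cy = float(np.clip(box[1] + rng.uniform(-jitter, jitter), 0, h - 1))
            out.append(loc.crop_center(sl, cx, cy).astype(np.float32))
        return np.stack(out)


def prepare_cases(cases, heat_sigma: float = 2.0):
    return [_Prepared(c, heat_sigma) for c in cases]


def _seg_features(model: JointModel, crops: Tensor):
    """Segmentation forward for the classifier cascade. Detached (run
    outside the graph) unless the config asks for joint gradients."""
    if not model.config.lf:
        return None
    if model.config.detach_seg:
        with nn.no_grad():
            out = model.segnet(crops)
        return [Tensor(f.data) for f in model.cascade_features(out)]
    return model.cascade_features(model.segnet(crops))


def _soft_ce(logits: Tensor, soft_labels: np.ndarray) -> Tensor:
    logp = nn.log_softmax(logits, axis=1)
    return -(Tensor(soft_labels.astype(np.float32)) * logp).sum(axis=1).mean()


# --------------------------------------------------------------------------
# the loop
# --------------------------------------------------------------------------
def train(cases, manifest: pd.DataFrame, joint_config: JointConfig | None = None,
          trainer_config: TrainerConfig | None = None, outdir=None):
    """Train the joint model on the manifest's train split.

    Returns (model, history DataFrame). With ``outdir`` set, writes
    ``checkpoint.npz(+.json)`` and ``history.csv`` there.
    """
    tc = trainer_config or TrainerConfig()
    model = JointModel(joint_config)
    lw = LossWeights()
    rng = np.random.default_rng(tc.seed)

    by_id = {c.case_id: c for c in cases}
    train_ids = manifest[manifest["split"] == "train"]["case_id"].tolist()
    val_ids = manifest[manifest["split"] == "val"]["case_id"].tolist()
    if not train_ids:
        raise ValueError("empty train split")
    prepared = {cid: _Prepared(by_id[cid], model.config.heat_sigma)
                for cid in train_ids + val_ids}

    train_prep = [prepared[cid] for cid in train_ids]
    present = sorted({p.label_idx for p in train_prep})

    def class_crops(jitter_rng=None):
        """Per-class lists of (2, 224, 224) crop pairs for the sampler."""
        by_class = [[] for _ in CLASS_NAMES]
        for p in train_prep:
            pair = (np.stack(p.crops) if jitter_rng is None
                    else p.jittered_crops(jitter_rng, tc.crop_jitter))
            by_class[p.label_idx].append(pair)
        # drop empty classes (the sampler requires positive counts)
        return TrainingSet([by_class[k] for k in present])

    cls_params = model.clsnet.parameters() + model.fusion.parameters()
    loc_params = model.localizer.parameters()
    scaled_ids = {id(p) for p in cls_params} | {id(p) for p in loc_params}
    base_params = [p for p in model.parameters() if id(p) not in scaled_ids]
    opt = nn.SGD(base_params, lr=tc.lr, momentum=tc.momentum,
                 clip_norm=tc.grad_clip)
    opt_cls = nn.SGD(cls_params, lr=tc.lr * tc.cls_lr_scale,
                     momentum=tc.momentum, clip_norm=tc.grad_clip)
    opt_loc = nn.SGD(loc_params, lr=tc.lr * tc.loc_lr_scale,
                     momentum=tc.momentum, clip_norm=tc.grad_clip)
    # the six log-variances get their own momentum-free, slower SGD: momentum
    # makes the effective per-term learning rates oscillate, which visibly
    # stalls the classification term
    opt_s = nn.SGD(lw.parameters(), lr=tc.lr * 0.5, momentum=0.0)
    history = []
    n_steps = max(1, int(np.ceil(len(train_ids) / tc.batch_size)))
    # Polyak-Ruppert averaging: with mixed sampling and uncertainty
    # weighting the effective per-term gradients stay O(1) near the
    # optimum, so the SGD iterates orbit it; the tail average is the
    # converged centre of that orbit.
    total_steps = tc.epochs * n_steps
    avg_start = int(np.ceil(total_steps * (1.0 - tc.avg_tail_frac)))
    model_params = model.parameters()
    avg_sum = [np.zeros_like(p.data) for p in model_params]
    avg_count = 0
    global_step = 0
    for epoch in range(tc.epochs):
        model.train()
        ts = class_crops(rng if tc.crop_jitter > 0 else None)
        order = rng.permutation(len(train_ids))
        epoch_terms = {n: 0.0 for n in LOSS_TERMS}
        epoch_total = 0.0
        for step in range(n_steps):
            idx = order[step * tc.batch_size : (step + 1) * tc.batch_size]
            if idx.size == 0:
                continue
            inst = [prepared[train_ids[i]] for i in idx]
            level = step % 2  # alternate L1/L2 for the (costly) seg targets
            # the detection head is cheap: give it both levels every step
            loc_imgs = np.stack([p.slices[lv] for p in inst
                                 for lv in (0, 1)])[:, None]
            truth_boxes = [p.boxes[lv] for p in inst for lv in (0, 1)]
            seg_crops = np.stack([p.crops[level] for p in inst])[:, None]
            seg_masks = np.stack([p.mask_crops[level] for p in inst])
            seg_heats = np.stack([p.heats[level] for p in inst])

            raw = model.localizer(Tensor(loc_imgs))
            l_ioc, l_det_cls, l_obj = loc.localizer_loss(raw, truth_boxes,
                                                         model.localizer)
            seg_out = model.segnet(Tensor(seg_crops))
            l_dice = dice_loss(seg_out.mask_prob, seg_masks)
            l_mse = (boundary_mse(seg_out.boundary_heat, seg_heats)
                     if seg_out.boundary_heat is not None else None)

            # mixed classification batch
            xs, ys = [], []
            for _ in range(tc.cls_batch_size):
                x_mix, y_mix, _, _, _ = draw_mixed(ts, tc.mix, rng)
                y_full = np.zeros(len(CLASS_NAMES), np.float32)
                y_full[np.asarray(present)] = y_mix
                xs.append(x_mix)
                ys.append(y_full)
            xs = np.stack(xs)  # (B, 2, 224, 224)
            c1 = Tensor(xs[:, :1])
            c2 = Tensor(xs[:, 1:])
            e1 = model.clsnet(c1, _seg_features(model, c1))
            e2 = model.clsnet(c2, _seg_features(model, c2))
            logits, _, _ = model.fusion(e1, e2)
            l_ce = _soft_ce(logits, np.stack(ys))

            terms = {"ioc": l_ioc, "det_cls": l_det_cls, "det_obj": l_obj,
                     "dice": l_dice, "boundary": l_mse, "cls": l_ce}
            total, breakdown = multitask_loss(terms, lw)
            opt.zero_grad()
            opt_cls.zero_grad()
            opt_loc.zero_grad()
            opt_s.zero_grad()
            total.backward()
            opt.step()
            opt_cls.step()
            opt_loc.step()
            opt_s.step()
            lw.clamp(tc.s_min, tc.s_max)
            global_step += 1
            if tc.avg_tail_frac > 0 and global_step > avg_start:
                for acc, p in zip(avg_sum, model_params):
                    acc += p.data
                avg_count += 1
            for n, v in breakdown.items():
                epoch_terms[n] += v / n_steps
            epoch_total += float(total.data) / n_steps

        # batch-norm recalibration serves the segnet/localizer paths only
        # (the classifier is group-normalized); refreshing every few epochs
        # keeps the validation curve meaningful at a fraction of the cost
        if (epoch + 1) % 5 == 0 or epoch == tc.epochs - 1:
            calibrate_batchnorm(model, [prepared[c] for c in train_ids])
        val_acc = (_teacher_forced_accuracy(model, [prepared[c] for c in val_ids])
                   if val_ids else np.nan)
        row = {"epoch": epoch, "total": epoch_total, "val_acc": val_acc}
        row.update({f"loss_{n}": epoch_terms[n] for n in LOSS_TERMS})
        row.update({f"weight_{n}": lw.effective_weight(n) for n in LOSS_TERMS})
        history.append(row)
        if epoch == 4 and history[4]["total"] >= history[0]["total"]:
            warnings.warn("total loss has not decreased over the first 5 epochs")

    if avg_count > 0:
        for acc, p in zip(avg_sum, model_params):
            p.data = (acc / avg_count).astype(p.data.dtype)
        calibrate_batchnorm(model, [prepared[c] for c in train_ids])

    history = pd.DataFrame(history)
    if outdir is not None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        model.save(outdir / "checkpoint.npz")
        history.to_csv(outdir / "history.csv", index=False, float_format="%.6g")
    return model, history


def calibrate_batchnorm(model: JointModel, prepared_list, batch_size: int = 6):
    """Refresh all batch-norm running statistics with their exact cumulative
    means over the (unmixed) training crops and slices.

    Training batches are small and include intensity-mixed images, so EMA
    running stats can drift away from the statistics of clean inputs; a
    calibration pass makes eval-mode behaviour match the data actually
    seen at inference.
    """
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm2d)]
    saved = [bn.momentum for bn in bns]
    model.train()
    crops = [p.crops[lvl] for p in prepared_list for lvl in (0, 1)]
    slices = [p.slices[lvl] for p in prepared_list for lvl in (0, 1)]
    n_batches = int(np.ceil(len(crops) / batch_size))
    with nn.no_grad():
        for i in range(n_batches):
            for bn in bns:
                bn.momentum = 1.0 / (i + 1)
            cb = np.stack(crops[i * batch_size : (i + 1) * batch_size])[:, None]
            sb = np.stack(slices[i * batch_size : (i + 1) * batch_size])[:, None]
            ct = Tensor(cb)
            seg_out = model.segnet(ct)
            model.clsnet(ct, model.cascade_features(seg_out)
                         if model.config.lf else None)
            model.localizer(Tensor(sb))
    for bn, m in zip(bns, saved):
        bn.momentum = m


def _teacher_forced_accuracy(model: JointModel, prepared_list) -> float:
    """Classification accuracy using ground-truth-centred crops."""
    if not prepared_list:
        return np.nan
    preds = predict_from_crops(model, prepared_list)
    truth = np.array([p.label_idx for p in prepared_list])
    return float((preds.argmax(axis=1) == truth).mean())


def predict_from_crops(model: JointModel, prepared_list) -> np.ndarray:
    """Posterior (n, 3) for prepared cases, ground-truth crops."""
    model.eval()
    posts = []
    with nn.no_grad():
        for p in prepared_list:
            c1 = Tensor(p.crops[0][None, None])
            c2 = Tensor(p.crops[1][None, None])
            e1 = model.clsnet(c1, _seg_features(model, c1))
            e2 = model.clsnet(c2, _seg_features(model, c2))
            logits, _, _ = model.fusion(e1, e2)
            posts.append(nn.softmax(logits, axis=1).data[0])
    model.train()
    return np.array(posts)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------
@dataclass
class MetricReport:
    confusion: np.ndarray
    per_class: dict
    overall_accuracy: float


def confusion_matrix(y_true, y_pred, n_classes: int = 3) -> np.ndarray:
    cm = np.zeros((n_classes, n_classes), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[int(t), int(p)] += 1
    return cm


def _safe_div(a: float, b: float):
    return a / b if b > 0 else None


def overlap_metrics(tp: float, fp: float, fn: float):
    """(IoU, Dice) from a TP/FP/FN triple; Dice = 2 IoU / (1 + IoU)."""
    iou = _safe_div(tp, tp + fp + fn)
    dice = _safe_div(2 * tp, 2 * tp + fp + fn)
    return iou, dice


def classification_metrics(confusion: np.ndarray,
                           class_names=CLASS_NAMES) -> MetricReport:
    """One-vs-rest accuracy / sensitivity / specificity / F1 per class.

    Undefined rates (zero denominator) are reported as None, never as 0.
    """
    cm = np.asarray(confusion)
    if cm.min() < 0 or not np.issubdtype(cm.dtype, np.integer):
        raise ValueError("confusion matrix must be nonnegative integers")
    total = cm.sum()
    per_class = {}
    for k, name in enumerate(class_names):
        tp = cm[k, k]
        fn = cm[k].sum() - tp
        fp = cm[:, k].sum() - tp
        tn = total - tp - fn - fp
        prec = _safe_div(tp, tp + fp)
        rec = _safe_div(tp, tp + fn)
        f1 = (None if prec is None or rec is None or prec + rec == 0
              else 2 * prec * rec / (prec + rec))
        per_class[name] = {
            "accuracy": _safe_div(tp + tn, total),
            "sensitivity": rec,
            "specificity": _safe_div(tn, tn + fp),
            "f1": f1,
            "support": int(cm[k].sum()),
        }
    overall = _safe_div(int(np.trace(cm)), int(total))
    return MetricReport(cm, per_class, overall)


def roc_auc(scores: np.ndarray, truths, class_names=CLASS_NAMES) -> dict:
    """Trapezoidal one-vs-rest AUC per class.

    ``scores``: (n, K) class scores; ``truths``: integer labels. A class
    absent from (or filling) the truth set is undefined and raises.
    """
    truths = np.asarray(truths)
    out = {}
    for k, name in enumerate(class_names):
        pos = truths == k
        if pos.all() or not pos.any():
            raise ValueError(f"AUC undefined for class '{name}': single-class truth")
        out[name] = float(roc_auc_score(pos.astype(int), scores[:, k]))
    return out
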