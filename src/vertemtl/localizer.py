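"""Vertebral-body localization on the 512 x 512 slice.

A small single-scale anchor detector: a strided conv backbone reduces the
slice to a coarse grid; at every cell, nine anchor boxes regress
(t_x, t_y, t_w, t_h) plus objectness and a single-class "vertebra" score.
Boxes decode as

    p_x = sigma(t_x) + a_x,   p_w = a_w * exp(t_w)   (same for y / h)

so the centre offset stays inside one grid cell. The winning box centre
drives a 224 x 224 crop that feeds segmentation and classification.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor

CROP = 224
HALF = CROP // 2

#: default anchor (w, h) sizes in pixels: 3 x 3 grid of side lengths
DEFAULT_ANCHOR_SIZES = tuple((w, h) for w in (90.0, 130.0, 170.0)
                             for h in (90.0, 130.0, 170.0))


@dataclass
class AnchorBox:
    a_x: float
    a_y: float
    a_w: float
    a_h: float


@dataclass
class BoxRegression:
    t_x: float
    t_y: float
    t_w: float
    t_h: float
    q: float = 1.0           # objectness in [0, 1]
    q_cla1: float = 1.0      # single-class "vertebra" score


@dataclass
class PredictedBox:
    p_x: float
    p_y: float
    p_w: float
    p_h: float
    score: float = 0.0

    def as_xyxy(self):
        return (self.p_x - self.p_w / 2, self.p_y - self.p_h / 2,
                self.p_x + self.p_w / 2, self.p_y + self.p_h / 2)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def decode_box(anchor: AnchorBox, reg: BoxRegression) -> PredictedBox:
    """Invert the regression parameterization (total function)."""
    return PredictedBox(
        p_x=float(_sigmoid(reg.t_x) + anchor.a_x),
        p_y=float(_sigmoid(reg.t_y) + anchor.a_y),
        p_w=float(anchor.a_w * np.exp(reg.t_w)),
        p_h=float(anchor.a_h * np.exp(reg.t_h)),
        score=float(reg.q),
    )


def box_iou(a, b) -> float:
    """IoU of two (cx, cy, w, h) boxes."""
    ax0, ay0 = a[0] - a[2] / 2, a[1] - a[3] / 2
    ax1, ay1 = a[0] + a[2] / 2, a[1] + a[3] / 2
    bx0, by0 = b[0] - b[2] / 2, b[1] - b[3] / 2
    bx1, by1 = b[0] + b[2] / 2, b[1] + b[3] / 2
    iw = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    ih = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = iw * ih
    union = a[2] * a[3] + b[2] * b[3] - inter
    return inter / union if union > 0 else 0.0


def nms(boxes, iou_threshold: float = 0.5):
    """Greedy non-maximum suppression; ties broken by lower (y, x)."""
    order = sorted(boxes, key=lambda b: (-b.score, b.p_y, b.p_x))
    kept = []
    for b in order:
        if all(box_iou((b.p_x, b.p_y, b.p_w, b.p_h),
                       (k.p_x, k.p_y, k.p_w, k.p_h)) <= iou_threshold
               for k in kept):
            kept.append(b)
    return kept


# --------------------------------------------------------------------------
# detection network
# --------------------------------------------------------------------------
class LocalizerNet(nn.Module):
    """Six-block strided conv backbone + 1x1 detection head, single scale.

    Input 512x512 is average-pooled 4x, then four stride-2 blocks give an
    8x8 grid (stride 64 px). The head emits 6 numbers per anchor per cell:
    t_x, t_y, t_w, t_h, objectness logit, class logit.
    """

    def __init__(self, rng, image_size: int = 512,
                 anchor_sizes=DEFAULT_ANCHOR_SIZES, widths=(8, 16, 32, 32)):
        super().__init__()
        self.image_size = image_size
        self.anchor_sizes = tuple(anchor_sizes)
        self.n_anchors = len(self.anchor_sizes)
        blocks = [nn.ConvBNReLU(rng, 1, widths[0], 3, stride=1),
                  nn.ConvBNReLU(rng, widths[0], widths[0], 3, stride=2)]
        for cin, cout in zip(widths[:-1], widths[1:]):
            blocks.append(nn.ConvBNReLU(rng, cin, cout, 3, stride=2))
        self.blocks = blocks
        self.head = nn.Conv2d(rng, widths[-1], self.n_anchors * 6, 1, padding=0)
        self.grid = image_size // (4 * 2 ** len(widths))
        self.stride = image_size // self.grid

    def forward(self, x: Tensor) -> Tensor:
        h = nn.avg_pool2d(x, 4)
        for b in self.blocks:
            h = b(h)
        return self.head(h)  # (N, A*6, G, G)


def decode_grid(raw: np.ndarray, net: LocalizerNet):
    """Decode every anchor of a raw head output (A*6, G, G) into pixel boxes.

    Returns (boxes, objectness, cls) arrays of shape (A*G*G, 4) / (A*G*G,).
    Anchor centres sit at grid-cell corners: p = (sigma(t) + cell) * stride.
    """
    a, g, s = net.n_anchors, net.grid, net.stride
    raw = raw.reshape(a, 6, g, g)
    cell_x = np.arange(g)[None, None, :]
    cell_y = np.arange(g)[None, :, None]
    px = (_sigmoid(raw[:, 0]) + cell_x) * s
    py = (_sigmoid(raw[:, 1]) + cell_y) * s
    sizes = np.array(net.anchor_sizes)  # (A, 2)
    pw = sizes[:, 0, None, None] * np.exp(np.clip(raw[:, 2], -6, 6))
    ph = sizes[:, 1, None, None] * np.exp(np.clip(raw[:, 3], -6, 6))
    obj = _sigmoid(raw[:, 4])
    cls = _sigmoid(raw[:, 5])
    boxes = np.stack([px, py, pw, ph], axis=-1).reshape(-1, 4)
    return boxes, obj.ravel(), cls.ravel()


def detect(image: np.ndarray, net: LocalizerNet, obj_threshold: float = 0.3,
           iou_threshold: float = 0.5) -> PredictedBox | None:
    """Best decoded box after NMS, or None when nothing clears the
    objectness threshold."""
    net.eval()
    with nn.no_grad():
        raw = net(Tensor(image[None, None])).data[0]
    boxes, obj, _ = decode_grid(raw, net)
    keep = obj >= obj_threshold
    if not keep.any():
        return None
    cands = [PredictedBox(*b, score=float(o))
             for b, o in zip(boxes[keep], obj[keep])]
    return nms(cands, iou_threshold)[0]


# --------------------------------------------------------------------------
# cropping
# --------------------------------------------------------------------------
def crop_center(image: np.ndarray, p_x: float, p_y: float) -> np.ndarray:
    """224 x 224 window centred at (p_x, p_y) with reflect padding at the
    image border. The centre must lie inside the image."""
    h, w = image.shape
    if not (0 <= p_x < w and 0 <= p_y < h):
        raise ValueError("crop centre outside the image")
    padded = np.pad(image, HALF, mode="reflect")
    x0 = int(round(p_x))  # padded coords: + HALF - HALF
    y0 = int(round(p_y))
    return padded[y0 : y0 + CROP, x0 : x0 + CROP].copy()


# --------------------------------------------------------------------------
# training targets and losses
# --------------------------------------------------------------------------
def assign_target(truth_box, net: LocalizerNet):
    """Responsible (anchor index, cell row, cell col) for a truth box:
    the cell containing the centre, the anchor of closest shape IoU."""
    cx, cy, w, h = truth_box
    s = net.stride
    col = min(int(cx // s), net.grid - 1)
    row = min(int(cy // s), net.grid - 1)
    best, best_iou = 0, -1.0
    for i, (aw, ah) in enumerate(net.anchor_sizes):
        iou = box_iou((0, 0, aw, ah), (0, 0, w, h))
        if iou > best_iou:
            best, best_iou = i, iou
    return best, row, col


def _bce(logits: Tensor, target: np.ndarray) -> Tensor:
    p = nn.clip(nn.sigmoid(logits), 1e-6, 1.0 - 1e-6)
    t = Tensor(target)
    return -(t * nn.log(p) + (1.0 - t) * nn.log(1.0 - p)).mean()


def _t_minimum(a: Tensor, b: Tensor) -> Tensor:
    return b - nn.relu(b - a)


def _t_maximum(a: Tensor, b: Tensor) -> Tensor:
    return b + nn.relu(a - b)


def differentiable_iou(px, py, pw, ph, truth_box) -> Tensor:
    """IoU between a decoded box (Tensors) and a fixed truth box."""
    tx, ty, tw, th = (float(v) for v in truth_box)
    ix0 = _t_maximum(px - pw * 0.5, Tensor(tx - tw / 2))
    iy0 = _t_maximum(py - ph * 0.5, Tensor(ty - th / 2))
    ix1 = _t_minimum(px + pw * 0.5, Tensor(tx + tw / 2))
    iy1 = _t_minimum(py + ph * 0.5, Tensor(ty + th / 2))
    inter = nn.relu(ix1 - ix0) * nn.relu(iy1 - iy0)
    union = pw * ph + tw * th - inter
    return inter / (union + 1e-8)


def localizer_loss(raw: Tensor, truth_boxes, net: LocalizerNet):
    """Detection losses for a batch: (L_IOC, L_cls, L_obj).

    L_IOC = mean(1 - IoU) over the responsible anchors; objectness and the
    single-class score use binary cross-entropy (negatives down-weighted
    0.5 so the lone positive per image is not drowned out).
    """
    n = raw.data.shape[0]
    a, g, s = net.n_anchors, net.grid, net.stride
    r = nn.reshape(raw, (n, a, 6, g, g))
    obj_target = np.zeros((n, a, g, g), dtype=np.float32)
    iou_terms = []
    cls_terms = []
    for b, truth in enumerate(truth_boxes):
        ai, row, col = assign_target(truth, net)
        obj_target[b, ai, row, col] = 1.0
        sl = _slice4(r, b, ai, row, col)
        px = (nn.sigmoid(sl[0]) + float(col)) * s
        py = (nn.sigmoid(sl[1]) + float(row)) * s
        pw = nn.exp(nn.clip(sl[2], -6.0, 6.0)) * float(net.anchor_sizes[ai][0])
        ph = nn.exp(nn.clip(sl[3], -6.0, 6.0)) * float(net.anchor_sizes[ai][1])
        iou_terms.append(1.0 - differentiable_iou(px, py, pw, ph, truth))
        cls_terms.append(_bce(sl[5], np.ones(())))
    l_ioc = _mean_scalars(iou_terms)
    l_cls = _mean_scalars(cls_terms)

    obj_logits = _gather_channel(r, 4)
    p = nn.clip(nn.sigmoid(obj_logits), 1e-6, 1.0 - 1e-6)
    t = Tensor(obj_target)
    bce = -(t * nn.log(p) + (1.0 - t) * nn.log(1.0 - p))
    # balance the lone positive anchor against the sea of negatives:
    # mean over positives + 0.5 * mean over negatives
    n_pos = float(max(obj_target.sum(), 1.0))
    n_neg = float(max((obj_target == 0).sum(), 1.0))
    pos_mask = Tensor(obj_target)
    neg_mask = Tensor((obj_target == 0).astype(np.float32))
    l_obj = (bce * pos_mask).sum() / n_pos + 0.5 * ((bce * neg_mask).sum() / n_neg)
    return l_ioc, l_cls, l_obj


def _slice4(r: Tensor, b: int, ai: int, row: int, col: int):
    """Six scalar Tensors r[b, ai, :, row, col] (autodiff-tracked)."""
    out = []
    for ch in range(6):
        mask = np.zeros(r.data.shape, dtype=np.float32)
        mask[b, ai, ch, row, col] = 1.0
        out.append((r * Tensor(mask)).sum())
    return out


def _gather_channel(r: Tensor, ch: int) -> Tensor:
    n, a, _, g, _ = r.data.shape
    mask = np.zeros(r.data.shape, dtype=np.float32)
    mask[:, :, ch] = 1.0
    return nn.reshape((r * Tensor(mask)).sum(axis=2), (n, a, g, g))


def _mean_scalars(terms):
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total * (1.0 / len(terms))


# --------------------------------------------------------------------------
# metric
# --------------------------------------------------------------------------
def average_precision(predictions, truths, iou_threshold: float = 0.5) -> float:
    """All-point-interpolated average precision.

    ``predictions``: list of (image_id, (cx, cy, w, h), score);
    ``truths``: dict image_id -> list of (cx, cy, w, h) boxes.
    Predictions are matched greedily in descending score to the unmatched
    truth box of highest IoU (>= threshold).
    """
    n_truth = sum(len(v) for v in truths.values())
    if n_truth == 0:
        raise ValueError("empty truth set: AP undefined")
    order = sorted(predictions, key=lambda p: -p[2])
    matched = {k: [False] * len(v) for k, v in truths.items()}
    tp = np.zeros(len(order))
    for i, (img_id, box, _) in enumerate(order):
        best_iou, best_j = 0.0, -1
        for j, tbox in enumerate(truths.get(img_id, [])):
            if matched[img_id][j]:
                continue
            iou = box_iou(box, tbox)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold:
            tp[i] = 1.0
            matched[img_id][best_j] = True
    if len(order) == 0:
        return 0.0
    cum_tp = np.cumsum(tp)
    recall = cum_tp / n_truth
    precision = cum_tp / np.arange(1, len(order) + 1)
    # precision envelope + all-point integration
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[0.0], precision, [0.0]])
    for i in range(len(p) - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    idx = np.nonzero(np.diff(r))[0]
    return float(np.sum((r[idx + 1] - r[idx]) * p[idx + 1]))
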