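"""Synthetic paired-vertebra CT phantoms.

Each case mimics the axial centre planes of the first and second lumbar
vertebrae (L1/L2): a single elliptical vertebral body with a thin bright
cortical rim and a darker cancellous interior whose mean gray level is an
affine, strictly increasing function of the case's bone mineral density
(BMD, mg/cm^3). The BMD is thresholded at 120 and 80 mg/cm^3 into the
three clinical classes (normal / osteopenia / osteoporosis), so every
downstream stage — localization, segmentation, boundary regression and
classification — has exact ground truth.

Coordinates are 0-based, pixel-centred, x to the right and y down; boxes
are stored as (center_x, center_y, width, height) in pixels.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v2 as imageio
import numpy as np
import pandas as pd
from scipy import ndimage

LABELS = ("normal", "osteopenia", "osteoporosis")

#: BMD class cut points, mg/cm^3: > 120 normal, 80..120 osteopenia, < 80 osteoporosis
BMD_NORMAL_THRESHOLD = 120.0
BMD_OSTEOPOROSIS_THRESHOLD = 80.0

#: train/validation/test fractions used for manifest split assignment
SPLIT_FRACTIONS = {"train": 0.5, "val": 0.1, "test": 0.4}


def classify_bmd(bmd: float) -> str:
    """Map a BMD value (mg/cm^3) to its bone-state label.

    The osteopenia interval is closed: 80 <= bmd <= 120.
    """
    if bmd > BMD_NORMAL_THRESHOLD:
        return "normal"
    if bmd >= BMD_OSTEOPOROSIS_THRESHOLD:
        return "osteopenia"
    return "osteoporosis"


@dataclass
class PhantomConfig:
    """Generation parameters for the synthetic cohort.

    Intensities are in normalized gray units ([0, 1]); the intensity map
    converts BMD (mg/cm^3) into interior gray via
    ``slope * bmd + intercept``.
    """

    image_size: int = 512
    vertebra_axes_range: tuple = (45.0, 80.0)  # semi-axis range, px
    bmd_class_means: dict = field(default_factory=lambda: {
        "osteoporosis": 60.0, "osteopenia": 100.0, "normal": 150.0})
    bmd_noise_sd: float = 12.0  # SD of the class-conditional BMD draw, mg/cm^3
    intensity_map_slope: float = 0.003
    intensity_map_intercept: float = 0.10
    background_mean: float = 0.22
    background_texture_sd: float = 0.02
    rim_thickness: float = 3.0  # cortical rim, px (0 disables the rim)
    rim_intensity: float = 0.88
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 64:
            raise ValueError("image_size must be >= 64")
        means = self.bmd_class_means
        if not (means["osteoporosis"] < means["osteopenia"] < means["normal"]):
            raise ValueError("class means must be ordered osteoporosis < osteopenia < normal")
        if self.intensity_map_slope <= 0:
            raise ValueError("intensity_map_slope must be > 0")
        lo, hi = self.vertebra_axes_range
        if not (0 < lo <= hi):
            raise ValueError("vertebra_axes_range must be positive and ordered")


@dataclass
class PhantomCase:
    case_id: str
    slice_l1: np.ndarray
    slice_l2: np.ndarray
    mask_l1: np.ndarray
    mask_l2: np.ndarray
    box_l1: tuple  # (cx, cy, w, h) px
    box_l2: tuple
    bmd: float
    label: str


# --------------------------------------------------------------------------
# geometry helpers
# --------------------------------------------------------------------------
def _ellipse_mask(size: int, cx: float, cy: float, ax: float, ay: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    xr = (xx - cx) * np.cos(theta) + (yy - cy) * np.sin(theta)
    yr = -(xx - cx) * np.sin(theta) + (yy - cy) * np.cos(theta)
    return (xr / ax) ** 2 + (yr / ay) ** 2 <= 1.0


def tight_box(mask: np.ndarray) -> tuple:
    """Tight (cx, cy, w, h) box around the nonzero pixels of ``mask``."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask has no box")
    x0, x1 = xs.min(), xs.max()
    y0, y1 = ys.min(), ys.max()
    return ((x0 + x1) / 2.0, (y0 + y1) / 2.0, float(x1 - x0 + 1), float(y1 - y0 + 1))


def interior_mask(mask: np.ndarray, rim_thickness: float) -> np.ndarray:
    """Cancellous interior: the body mask eroded by the cortical rim."""
    if rim_thickness <= 0:
        return mask.astype(bool)
    it = int(round(rim_thickness))
    return ndimage.binary_erosion(mask, iterations=it)


def _sample_bmd(cfg: PhantomConfig, label: str, rng: np.random.Generator) -> float:
    """Class-conditional truncated normal: guarantees label consistency."""
    intervals = {
        "osteoporosis": (10.0, np.nextafter(BMD_OSTEOPOROSIS_THRESHOLD, 0.0)),
        "osteopenia": (BMD_OSTEOPOROSIS_THRESHOLD, BMD_NORMAL_THRESHOLD),
        "normal": (np.nextafter(BMD_NORMAL_THRESHOLD, np.inf), 250.0),
    }
    lo, hi = intervals[label]
    mean = cfg.bmd_class_means[label]
    if cfg.bmd_noise_sd <= 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        v = rng.normal(mean, cfg.bmd_noise_sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


def _render_slice(cfg: PhantomConfig, bmd: float, rng: np.random.Generator):
    size = cfg.image_size
    lo, hi = cfg.vertebra_axes_range
    ax = rng.uniform(lo, hi)
    ay = rng.uniform(lo, hi)
    jitter = size * 0.08
    cx = size / 2.0 + rng.uniform(-jitter, jitter)
    cy = size / 2.0 + rng.uniform(-jitter, jitter)
    theta = rng.uniform(-0.3, 0.3)

    mask = _ellipse_mask(size, cx, cy, ax, ay, theta)
    interior = interior_mask(mask, cfg.rim_thickness)

    img = np.full((size, size), cfg.background_mean, dtype=np.float64)
    if cfg.background_texture_sd > 0:
        img += rng.normal(0.0, cfg.background_texture_sd, size=img.shape)
    body_gray = cfg.intensity_map_slope * bmd + cfg.intensity_map_intercept
    img[mask] = cfg.rim_intensity
    img[interior] = body_gray
    if cfg.background_texture_sd > 0:
        img[interior] += rng.normal(0.0, cfg.background_texture_sd,
                                    size=int(interior.sum()))
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return img, mask.astype(np.uint8)


def generate_case(cfg: PhantomConfig, rng: np.random.Generator,
                  case_id: str = "case", label: str | None = None) -> PhantomCase:
    """Generate one paired-slice case.

    Both slices share the same BMD (the clinical diagnosis averages the two
    vertebral measurements); geometry is drawn independently per slice.
    """
    cfg.validate()
    if label is None:
        label = str(rng.choice(LABELS))
    bmd = _sample_bmd(cfg, label, rng)
    assert classify_bmd(bmd) == label
    s1, m1 = _render_slice(cfg, bmd, rng)
    s2, m2 = _render_slice(cfg, bmd, rng)
    return PhantomCase(case_id, s1, s2, m1, m2,
                       tight_box(m1), tight_box(m2), bmd, label)


def split_counts(n: int) -> dict:
    """Largest-remainder apportionment of n cases into 50/10/40 train/val/test."""
    exact = {k: n * f for k, f in SPLIT_FRACTIONS.items()}
    counts = {k: int(np.floor(v)) for k, v in exact.items()}
    short = n - sum(counts.values())
    order = sorted(exact, key=lambda k: exact[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


def generate_dataset(cfg: PhantomConfig, n_per_class, rng: np.random.Generator):
    """Generate a cohort with the requested per-class counts.

    Returns (cases, manifest) where manifest is a DataFrame with columns
    case_id, label, bmd, split; split is stratified 50/10/40 per class.
    """
    counts = dict(zip(LABELS, n_per_class))
    cases, rows = [], []
    idx = 0
    for label in LABELS:
        n = counts[label]
        if n < 0:
            raise ValueError("per-class counts must be >= 0")
        splits = split_counts(n)
        assignment = (["train"] * splits["train"] + ["val"] * splits["val"]
                      + ["test"] * splits["test"])
        for split in assignment:
            case = generate_case(cfg, rng, case_id=f"case_{idx:04d}", label=label)
            cases.append(case)
            rows.append({"case_id": case.case_id, "label": label,
                         "bmd": case.bmd, "split": split})
            idx += 1
    manifest = pd.DataFrame(rows, columns=["case_id", "label", "bmd", "split"])
    return cases, manifest


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------
def augment(image: np.ndarray, mask: np.ndarray, mode: str,
            rng: np.random.Generator | None = None, *,
            angle: float | None = None, factor: float | None = None):
    """Apply the same geometric transform to an image and its mask.

    Modes: ``flip`` (horizontal), ``rotate`` (degrees, drawn in +-15 when not
    given), ``scale`` (zoom about the centre, drawn in 0.9..1.1 when not
    given). Image is interpolated bilinearly, mask nearest-neighbour.
    """
    if image.shape != mask.shape:
        raise ValueError("image and mask must share a shape")
    if mode == "flip":
        return image[:, ::-1].copy(), mask[:, ::-1].copy()
    if mode == "rotate":
        if angle is None:
            angle = float(rng.uniform(-15.0, 15.0))
        if angle == 0.0:
            return image.copy(), mask.copy()
        img = ndimage.rotate(image, angle, reshape=False, order=1,
                             mode="nearest")
        msk = ndimage.rotate(mask.astype(np.uint8), angle, reshape=False,
                             order=0, mode="constant")
        return img.astype(image.dtype), msk.astype(mask.dtype)
    if mode == "scale":
        if factor is None:
            factor = float(rng.uniform(0.9, 1.1))
        if factor == 1.0:
            return image.copy(), mask.copy()
        h, w = image.shape
        img = ndimage.zoom(image, factor, order=1, mode="nearest")
        msk = ndimage.zoom(mask.astype(np.uint8), factor, order=0)
        img = _center_fit(img, h, w, fill=float(np.median(image)))
        msk = _center_fit(msk, h, w, fill=0)
        return img.astype(image.dtype), msk.astype(mask.dtype)
    raise ValueError(f"unknown augmentation mode: {mode!r}")


def _center_fit(arr: np.ndarray, h: int, w: int, fill=0.0) -> np.ndarray:
    """Crop or pad ``arr`` symmetrically to (h, w)."""
    out = np.full((h, w), fill, dtype=arr.dtype)
    ah, aw = arr.shape
    ys, yd = max(0, (ah - h) // 2), max(0, (h - ah) // 2)
    xs, xd = max(0, (aw - w) // 2), max(0, (w - aw) // 2)
    ch, cw = min(h, ah), min(w, aw)
    out[yd:yd + ch, xd:xd + cw] = arr[ys:ys + ch, xs:xs + cw]
    return out


# --------------------------------------------------------------------------
# on-disk layout
# --------------------------------------------------------------------------
def save_dataset(cases, manifest: pd.DataFrame, outdir, nifti: bool = False) -> None:
    """Write slices/masks as 8-bit PNG, boxes as JSON, manifest as CSV.

    With ``nifti=True`` each slice is additionally written as a float32
    NIfTI volume (identity affine) under ``nifti/``.
    """
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    (outdir / "masks").mkdir(exist_ok=True)
    if nifti:
        import nibabel as nib

        (outdir / "nifti").mkdir(exist_ok=True)
    boxes = {}
    for case in cases:
        for level, sl, mk, box in (("l1", case.slice_l1, case.mask_l1, case.box_l1),
                                   ("l2", case.slice_l2, case.mask_l2, case.box_l2)):
            imageio.imwrite(outdir / "images" / f"{case.case_id}_{level}.png",
                            np.round(sl * 255).astype(np.uint8))
            if nifti:
                img = nib.Nifti1Image(sl.astype(np.float32), np.eye(4))
                nib.save(img, outdir / "nifti" / f"{case.case_id}_{level}.nii.gz")
            imageio.imwrite(outdir / "masks" / f"{case.case_id}_{level}.png",
                            (mk > 0).astype(np.uint8) * 255)
            boxes[f"{case.case_id}_{level}"] = {
                "cx": box[0], "cy": box[1], "w": box[2], "h": box[3]}
    with open(outdir / "boxes.json", "w") as fh:
        json.dump(boxes, fh, indent=1)
    manifest.to_csv(outdir / "manifest.csv", index=False)


def load_dataset(indir):
    """Re-read a saved cohort; inverse of :func:`save_dataset`."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv")
    with open(indir / "boxes.json") as fh:
        boxes = json.load(fh)
    cases = []
    for row in manifest.itertuples():
        arrs = {}
        for level in ("l1", "l2"):
            img = imageio.imread(indir / "images" / f"{row.case_id}_{level}.png")
            msk = imageio.imread(indir / "masks" / f"{row.case_id}_{level}.png")
            b = boxes[f"{row.case_id}_{level}"]
            arrs[level] = (img.astype(np.float32) / 255.0, (msk > 0).astype(np.uint8),
                           (b["cx"], b["cy"], b["w"], b["h"]))
        cases.append(PhantomCase(row.case_id, arrs["l1"][0], arrs["l2"][0],
                                 arrs["l1"][1], arrs["l2"][1],
                                 arrs["l1"][2], arrs["l2"][2],
                                 float(row.bmd), row.label))
    return cases, manifest
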