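"""Soft boundary heat-map targets for the boundary-regression decoder.

The regression target is built from the ground-truth binary mask in two
steps: (1) a separable Canny detector extracts the one-pixel boundary of
the mask; (2) a unit-peak Gaussian is centred on every edge pixel and the
stack is composed with the probabilistic-OR "Heatsum" rule

    Heatsum(a, b) = 1 - (1 - a)(1 - b)

which keeps the target in [0, 1] and saturates where Gaussians overlap,
giving a soft band around the true contour instead of a hard edge label.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class EdgeMap:
    edges: np.ndarray        # bool image of edge pixels
    magnitude: np.ndarray    # gradient amplitude A(x, y)
    direction: np.ndarray    # gradient direction a(x, y), radians in (-pi/2, pi/2]


@dataclass
class HeatLabel:
    heat: np.ndarray         # G_bd in [0, 1]
    gaussian_sigma: float


def canny_edges(mask_label: np.ndarray, gaussian_sigma: float = 1.0,
                low_thr: float = 0.1, high_thr: float = 0.2) -> EdgeMap:
    """Separable Canny edge detection on a binary label image.

    E_x and E_y come from derivative-of-Gaussian filtering applied as two
    1-D passes; the amplitude A = sqrt(E_x^2 + E_y^2) is thinned by
    non-maximum suppression along the gradient direction and linked by
    dual-threshold hysteresis. ``low_thr``/``high_thr`` are fractions of
    the maximum amplitude.
    """
    if high_thr < low_thr:
        raise ValueError("high_thr must be >= low_thr")
    img = np.asarray(mask_label, dtype=np.float64)
    # separable derivative-of-Gaussian: smooth one axis, differentiate the other
    ex = ndimage.gaussian_filter1d(img, gaussian_sigma, axis=1, order=1)
    ex = ndimage.gaussian_filter1d(ex, gaussian_sigma, axis=0, order=0)
    ey = ndimage.gaussian_filter1d(img, gaussian_sigma, axis=0, order=1)
    ey = ndimage.gaussian_filter1d(ey, gaussian_sigma, axis=1, order=0)
    amp = np.hypot(ex, ey)
    with np.errstate(divide="ignore", invalid="ignore"):
        direction = np.arctan(np.where(ex == 0.0, np.inf, ey / ex))
    direction = np.where((ex == 0.0) & (ey == 0.0), 0.0, direction)
    # fold into (-pi/2, pi/2]
    direction = np.where(direction <= -np.pi / 2, direction + np.pi, direction)

    thin = _non_maximum_suppression(amp, direction)
    amax = amp.max()
    if amax == 0.0:
        return EdgeMap(np.zeros_like(thin, dtype=bool), amp, direction)
    strong = thin > high_thr * amax
    weak = thin > low_thr * amax
    labels, n = ndimage.label(weak, structure=np.ones((3, 3)))
    keep = np.zeros(n + 1, dtype=bool)
    keep[np.unique(labels[strong])] = True
    keep[0] = False
    return EdgeMap(keep[labels], amp, direction)


def _non_maximum_suppression(amp: np.ndarray, direction: np.ndarray) -> np.ndarray:
    """Zero out amplitudes that are not local maxima along the gradient."""
    h, w = amp.shape
    padded = np.pad(amp, 1)
    # quantize gradient direction into 4 sectors; offsets along the gradient
    deg = np.degrees(direction)
    sector = np.zeros_like(amp, dtype=np.int8)
    sector[(deg > 22.5) & (deg <= 67.5)] = 1     # diagonal /
    sector[(deg > 67.5) | (deg <= -67.5)] = 2    # vertical gradient
    sector[(deg > -67.5) & (deg <= -22.5)] = 3   # diagonal \
    offsets = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (-1, 1)}
    out = np.zeros_like(amp)
    for s, (dy, dx) in offsets.items():
        m = sector == s
        n1 = padded[1 + dy : 1 + dy + h, 1 + dx : 1 + dx + w]
        n2 = padded[1 - dy : 1 - dy + h, 1 - dx : 1 - dx + w]
        # strict on one side so a symmetric two-pixel plateau (a binary
        # step smoothed by the Gaussian) thins to a single pixel
        ok = m & (amp > n1) & (amp >= n2)
        out[ok] = amp[ok]
    return out


def heatsum(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
    """Probabilistic-OR composition 1 - (1 - h1)(1 - h2), elementwise."""
    h1, h2 = np.asarray(h1, dtype=np.float64), np.asarray(h2, dtype=np.float64)
    if h1.shape != h2.shape:
        raise ValueError("heat maps must share a shape")
    for h in (h1, h2):
        if h.min() < 0.0 or h.max() > 1.0:
            raise ValueError("heat values must lie in [0, 1]")
    return 1.0 - (1.0 - h1) * (1.0 - h2)


def gaussian_heat(shape: tuple, points, sigma: float) -> np.ndarray:
    """Heatsum fold of unit-peak Gaussians centred at ``points`` (y, x).

    Each Gaussian is evaluated on a truncated +-4 sigma window; the fold is
    carried as the running product prod(1 - G), which is associative and
    order-independent, then inverted.
    """
    prod = np.ones(shape, dtype=np.float64)
    r = int(np.ceil(4.0 * sigma))
    ax = np.arange(-r, r + 1, dtype=np.float64)
    g1d = np.exp(-(ax ** 2) / (2.0 * sigma ** 2))
    g2d = np.outer(g1d, g1d)
    h, w = shape
    for (py, px) in points:
        y0, y1 = max(0, py - r), min(h, py + r + 1)
        x0, x1 = max(0, px - r), min(w, px + r + 1)
        prod[y0:y1, x0:x1] *= 1.0 - g2d[y0 - py + r : y1 - py + r,
                                        x0 - px + r : x1 - px + r]
    return 1.0 - prod


def build_heat_label(edges: EdgeMap, gaussian_sigma: float = 2.0) -> HeatLabel:
    """Compose the normalized boundary heat map G_bd from an edge map."""
    ys, xs = np.nonzero(edges.edges)
    if ys.size == 0:
        raise ValueError("empty edge set: no boundary target definable")
    heat = gaussian_heat(edges.edges.shape, zip(ys.tolist(), xs.tolist()),
                         gaussian_sigma)
    lo, hi = heat.min(), heat.max()
    heat = (heat - lo) / (hi - lo) if hi > lo else np.ones_like(heat)
    return HeatLabel(heat, gaussian_sigma)


def heat_label_for_mask(mask: np.ndarray, gaussian_sigma: float = 2.0,
                        canny_sigma: float = 1.0) -> HeatLabel:
    """Convenience: mask -> Canny edges -> normalized heat label."""
    return build_heat_label(canny_edges(mask, canny_sigma), gaussian_sigma)
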