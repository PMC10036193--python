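"""Instance/class mixed sampling for imbalanced training sets.

A single knob ``n`` interpolates between instance-based sampling
(p_j proportional to the class size M_j, n = 1) and class-based sampling
(uniform over classes, n = 0) via p_j = M_j^n / sum_k M_k^n. Training
draws one sample under each regime and mixes them with a Beta(alpha, 1)
convex combination of both image and one-hot label, which synthesises
points around sparsely populated minority classes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class MixConfig:
    alpha: float = 0.1
    beta: float = 1.0
    exponent_n: float = 1.0
    seed: int = 0

    def validate(self):
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta shapes must be > 0")


@dataclass
class TrainingSet:
    """Samples grouped by class: ``by_class[k]`` is a list of items of class k."""

    by_class: list

    @property
    def n_classes(self) -> int:
        return len(self.by_class)

    @property
    def class_counts(self) -> np.ndarray:
        return np.array([len(c) for c in self.by_class])

    @property
    def total(self) -> int:
        return int(self.class_counts.sum())


def class_probabilities(class_counts, exponent_n: float) -> np.ndarray:
    """p_j = M_j^n / sum_k M_k^n over classes j."""
    counts = np.asarray(class_counts, dtype=np.float64)
    if np.any(counts <= 0) and exponent_n <= 0:
        raise ValueError("zero class count with non-positive exponent")
    w = counts ** exponent_n
    return w / w.sum()


def draw_index(ts: TrainingSet, exponent_n: float, rng: np.random.Generator):
    """Draw (class, within-class index) under the exponent-n strategy."""
    p = class_probabilities(ts.class_counts, exponent_n)
    k = int(rng.choice(ts.n_classes, p=p))
    i = int(rng.integers(len(ts.by_class[k])))
    return k, i


def draw_mixed(ts: TrainingSet, cfg: MixConfig, rng: np.random.Generator,
               lam: float | None = None):
    """One mixed training example.

    Draws (x_I, y_I) instance-based (n=1) and (x_C, y_C) class-based (n=0),
    lambda ~ Beta(alpha, beta), and returns

        x_hat = lam*x_I + (1-lam)*x_C,  y_hat = lam*y_I + (1-lam)*y_C

    with y one-hot encoded, plus the two drawn (class, index) pairs so the
    caller can route the *unmixed* instance sample to geometric losses.
    """
    cfg.validate()
    if ts.total == 0:
        raise ValueError("empty training set")
    kI, iI = draw_index(ts, 1.0, rng)
    kC, iC = draw_index(ts, 0.0, rng)
    if lam is None:
        lam = float(rng.beta(cfg.alpha, cfg.beta))
    xI, xC = ts.by_class[kI][iI], ts.by_class[kC][iC]
    xI_arr, xC_arr = np.asarray(xI, dtype=np.float32), np.asarray(xC, dtype=np.float32)
    if xI_arr.shape != xC_arr.shape:
        raise ValueError("drawn images have mismatched shapes")
    k = ts.n_classes
    yI = np.eye(k, dtype=np.float32)[kI]
    yC = np.eye(k, dtype=np.float32)[kC]
    x_mix = lam * xI_arr + (1.0 - lam) * xC_arr
    y_mix = lam * yI + (1.0 - lam) * yC
    return x_mix, y_mix, lam, (kI, iI), (kC, iC)
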