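"""Adaptive two-vertebra fusion and the final 3-class posterior.

A single two-layer perceptron scores each vertebra's 2048-d embedding;
the two scores pass through a softmax, giving fusion weights
W1 + W2 = 1 that weigh how much each level contributes. The weighted
embeddings are concatenated (4096-d) and a fully connected layer plus
softmax yields P(class | study). Sharing the scorer makes the weights
exactly symmetric under swapping the two vertebrae.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .clsnet import EMBED_DIM
from .nn import Tensor

CLASS_NAMES = ("normal", "osteopenia", "osteoporosis")


@dataclass
class FusionWeights:
    w1: float
    w2: float


@dataclass
class StudyPrediction:
    posterior: np.ndarray           # 3-vector, sums to 1
    weights: FusionWeights
    predicted_label: str


class FusionHead(nn.Module):
    def __init__(self, rng, embed_dim: int = EMBED_DIM, hidden: int = 256,
                 n_classes: int = 3, adaptive: bool = True):
        super().__init__()
        self.adaptive = adaptive
        self.score1 = nn.Linear(rng, embed_dim, hidden)
        self.score2 = nn.Linear(rng, hidden, 1)
        self.fc = nn.Linear(rng, 2 * embed_dim, n_classes)

    def _score(self, x: Tensor) -> Tensor:
        return self.score2(nn.relu(self.score1(x)))  # (N, 1)

    def fuse(self, x1: Tensor, x2: Tensor):
        """Weighted concatenation (N, 4096) plus the fusion weights.

        The two-way softmax reduces to a logistic of the score gap:
        w1 = 1 / (1 + exp(-(F(x1) - F(x2)))).
        """
        if x1.data.shape != x2.data.shape:
            raise ValueError("embedding shapes must match")
        if self.adaptive:
            w1 = nn.sigmoid(self._score(x1) - self._score(x2))  # (N, 1)
            w2 = 1.0 - w1
        else:
            half = np.full((x1.data.shape[0], 1), 0.5, np.float32)
            w1, w2 = Tensor(half), Tensor(half)
        fused = nn.concat([w1 * x1, w2 * x2], axis=1)
        return fused, w1, w2

    def logits(self, fused: Tensor) -> Tensor:
        return self.fc(fused)

    def forward(self, x1: Tensor, x2: Tensor):
        fused, w1, w2 = self.fuse(x1, x2)
        return self.logits(fused), w1, w2


def classify(head: FusionHead, fused: Tensor) -> list:
    """Posterior over the three bone states for each study in the batch."""
    post = nn.softmax(head.logits(fused), axis=1).data
    out = []
    for row in post:
        out.append(StudyPrediction(row.copy(), FusionWeights(np.nan, np.nan),
                                   CLASS_NAMES[int(np.argmax(row))]))
    return out


def predict_study(head: FusionHead, x1: Tensor, x2: Tensor) -> list:
    """End-to-end fusion + classification with recorded weights."""
    with nn.no_grad():
        fused, w1, w2 = head.fuse(x1, x2)
        post = nn.softmax(head.logits(fused), axis=1).data
    out = []
    for i, row in enumerate(post):
        fw = FusionWeights(float(w1.data[i, 0]), float(w2.data[i, 0]))
        out.append(StudyPrediction(row.copy(), fw,
                                   CLASS_NAMES[int(np.argmax(row))]))
    return out
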