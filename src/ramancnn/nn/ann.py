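"""The small dense ANN used for reduced-feature classification.

Three layers: input -> hidden(h1) -> hidden(h2) -> 2 logits, rectifier
activations and dropout (default 20%) on the hidden layers.  The default
hidden width of 22 neurons came from a grid search over
{10, 12, 14, 16, 18, 22}; :func:`grid_search_hidden_size` reproduces that
search on a validation split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Dense, Dropout, Param, ReLU, softmax

HIDDEN_GRID = (10, 12, 14, 16, 18, 22)


@dataclass(frozen=True)
class AnnSpec:
    hidden_sizes: tuple[int, int] = (22, 22)
    dropout_rate: float = 0.2

    def validate(self) -> None:
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")


class DenseNet:
    """Feed-forward classifier over (N, F) feature tables."""

    def __init__(self, spec: AnnSpec, n_features: int, seed: int = 0,
                 n_classes: int = 2) -> None:
        spec.validate()
        if n_features < 1:
            raise ValueError("n_features must be >= 1")
        self.spec = spec
        rng = np.random.default_rng(seed)
        h1, h2 = spec.hidden_sizes
        self.fc1 = Dense(n_features, h1, rng=rng, name="fc1")
        self.relu1 = ReLU()
        self.drop1 = Dropout(spec.dropout_rate, rng)
        self.fc2 = Dense(h1, h2, rng=rng, name="fc2")
        self.relu2 = ReLU()
        self.drop2 = Dropout(spec.dropout_rate, rng)
        self.fc3 = Dense(h2, n_classes, rng=rng, name="fc3")

    def params(self) -> list[Param]:
        return self.fc1.params() + self.fc2.params() + self.fc3.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.fc1.forward(np.asarray(x, dtype=float), train)
        h = self.relu1.forward(h, train)
        h = self.drop1.forward(h, train)
        h = self.fc2.forward(h, train)
        h = self.relu2.forward(h, train)
        h = self.drop2.forward(h, train)
        return self.fc3.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = self.fc3.backward(dlogits)
        g = self.drop2.backward(g)
        g = self.relu2.backward(g)
        g = self.fc2.backward(g)
        g = self.drop1.backward(g)
        g = self.relu1.backward(g)
        return self.fc1.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def predict(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        return self.predict_proba(x).argmax(axis=1)


def build_ann(spec: AnnSpec, n_features: int, seed: int = 0) -> DenseNet:
    return DenseNet(spec, n_features, seed=seed)


def grid_search_hidden_size(
    train_fn,
    sizes: tuple[int, ...] = HIDDEN_GRID,
    dropout_rate: float = 0.2,
) -> tuple[int, dict[int, float]]:
    """Pick the hidden width maximising validation F1.

    ``train_fn(spec) -> validation F1`` trains and scores one candidate;
    ties go to the smaller width.  Returns the winner and all scores.
    """
    scores: dict[int, float] = {}
    for h in sizes:
        scores[h] = float(train_fn(AnnSpec(hidden_sizes=(h, h), dropout_rate=dropout_rate)))
    best = max(sorted(scores), key=lambda h: scores[h])
    return best, scores
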