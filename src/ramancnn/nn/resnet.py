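"""The 1-D residual network and its multi-channel input adaptation.

The body follows the standard pre-activation residual design: an initial
convolution, then ``n_blocks`` residual blocks (BN - ReLU - conv - BN - ReLU
- conv with an identity shortcut; blocks after the first downsample by
stride 2 with a 1x1 projection shortcut), then BN - ReLU - global average
pooling and a linear 2-class head.

Multi-channel adaptation duplicates the pretrained single-channel first-layer
kernel across input channels (literal duplication, no rescaling by default),
copies all body weights verbatim, and re-initialises the classification head
when the class count changes.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np

from .core import BatchNorm1d, Conv1d, Dense, GlobalAvgPool1d, Param, ReLU, softmax

logger = logging.getLogger(__name__)


class SpecError(ValueError):
    """Model specification is internally inconsistent."""


class LoadError(ValueError):
    """Stored weights are incompatible with the requested specification."""


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters of the residual network.

    Defaults match the published single-channel design this work adapts
    (6 blocks, 100 filters, kernel 5); tests use a 2-block/16-filter spec.
    """

    in_channels: int = 8
    n_blocks: int = 6
    hidden_filters: int = 100
    kernel_size: int = 5
    n_classes: int = 2
    input_length: int = 1015

    def validate(self) -> None:
        if self.in_channels < 1:
            raise SpecError("in_channels must be >= 1")
        if self.n_blocks < 1 or self.hidden_filters < 1 or self.kernel_size < 1:
            raise SpecError("n_blocks, hidden_filters and kernel_size must be >= 1")
        if self.n_classes < 2:
            raise SpecError("n_classes must be >= 2")
        # blocks after the first halve the length; require >= 2 points left
        if self.input_length // 2 ** (self.n_blocks - 1) < 2:
            raise SpecError(
                f"input_length {self.input_length} too short for {self.n_blocks} "
                "stride-2 downsampling stages"
            )


#: desk-scale spec used throughout the test suite
SMALL_SPEC = ModelSpec(in_channels=8, n_blocks=2, hidden_filters=16, kernel_size=5)


class _ResBlock:
    def __init__(self, filters: int, kernel_size: int, stride: int,
                 rng: np.random.Generator, name: str) -> None:
        self.bn1 = BatchNorm1d(filters, name=f"{name}.bn1")
        self.relu1 = ReLU()
        self.conv1 = Conv1d(filters, filters, kernel_size, stride=stride, rng=rng,
                            name=f"{name}.conv1")
        self.bn2 = BatchNorm1d(filters, name=f"{name}.bn2")
        self.relu2 = ReLU()
        self.conv2 = Conv1d(filters, filters, kernel_size, stride=1, rng=rng,
                            name=f"{name}.conv2")
        self.proj = (
            Conv1d(filters, filters, 1, stride=stride, rng=rng, name=f"{name}.proj")
            if stride > 1
            else None
        )

    def layers(self):
        out = [self.bn1, self.conv1, self.bn2, self.conv2]
        if self.proj is not None:
            out.append(self.proj)
        return out

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        t = self.bn1.forward(x, train)
        t = self.relu1.forward(t, train)
        t = self.conv1.forward(t, train)
        t = self.bn2.forward(t, train)
        t = self.relu2.forward(t, train)
        t = self.conv2.forward(t, train)
        sc = self.proj.forward(x, train) if self.proj is not None else x
        return t + sc

    def backward(self, grad: np.ndarray) -> np.ndarray:
        gt = self.conv2.backward(grad)
        gt = self.relu2.backward(gt)
        gt = self.bn2.backward(gt)
        gt = self.conv1.backward(gt)
        gt = self.relu1.backward(gt)
        gt = self.bn1.backward(gt)
        gsc = self.proj.backward(grad) if self.proj is not None else grad
        return gt + gsc


class ResNet1D:
    """Pre-activation 1-D residual classifier over (N, C, W) inputs."""

    def __init__(self, spec: ModelSpec, seed: int = 0) -> None:
        spec.validate()
        self.spec = spec
        rng = np.random.default_rng(seed)
        f = spec.hidden_filters
        self.conv0 = Conv1d(spec.in_channels, f, spec.kernel_size, rng=rng, name="conv0")
        self.blocks = [
            _ResBlock(f, spec.kernel_size, stride=(2 if i > 0 else 1), rng=rng,
                      name=f"block{i}")
            for i in range(spec.n_blocks)
        ]
        self.bn_out = BatchNorm1d(f, name="bn_out")
        self.relu_out = ReLU()
        self.gap = GlobalAvgPool1d()
        self.head = Dense(f, spec.n_classes, rng=rng, name="head")

    # -- parameter plumbing -------------------------------------------------
    def params(self) -> list[Param]:
        out = self.conv0.params()
        for b in self.blocks:
            for layer in b.layers():
                out.extend(layer.params())
        out.extend(self.bn_out.params())
        out.extend(self.head.params())
        return out

    def n_parameters(self) -> int:
        return sum(p.value.size for p in self.params())

    def batchnorms(self) -> list[BatchNorm1d]:
        out = []
        for b in self.blocks:
            out.extend([b.bn1, b.bn2])
        out.append(self.bn_out)
        return out

    # -- forward / backward -------------------------------------------------
    def first_layer_preactivation(self, x: np.ndarray) -> np.ndarray:
        """Output of the initial convolution (pre-BN, pre-activation)."""
        return self.conv0.forward(np.asarray(x, dtype=float), train=False)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = self.conv0.forward(np.asarray(x, dtype=float), train)
        for b in self.blocks:
            h = b.forward(h, train)
        h = self.bn_out.forward(h, train)
        h = self.relu_out.forward(h, train)
        h = self.gap.forward(h, train)
        return self.head.forward(h, train)

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = self.head.backward(dlogits)
        g = self.gap.backward(g)
        g = self.relu_out.backward(g)
        g = self.bn_out.backward(g)
        for b in reversed(self.blocks):
            g = b.backward(g)
        return self.conv0.backward(g)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(softmax(self.forward(x[i : i + batch_size], train=False)))
        return np.concatenate(out) if out else np.empty((0, self.spec.n_classes))

    def predict(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)

    def input_gradient(self, x: np.ndarray, target_class: np.ndarray | int) -> np.ndarray:
        """d(logit of target class)/d(input), evaluated in inference mode.

        Parameter gradients accumulated during this pass are discarded.
        """
        x = np.asarray(x, dtype=float)
        logits = self.forward(x, train=False)
        onehot = np.zeros_like(logits)
        targets = np.broadcast_to(np.asarray(target_class, dtype=int), (x.shape[0],))
        onehot[np.arange(x.shape[0]), targets] = 1.0
        for p in self.params():
            p.grad[...] = 0.0
        dx = self.backward(onehot)
        for p in self.params():
            p.grad[...] = 0.0
        return dx


def build_resnet(spec: ModelSpec, seed: int = 0) -> ResNet1D:
    """Construct a residual network with seeded He-normal initialisation."""
    return ResNet1D(spec, seed=seed)


def adapt_first_layer(weights: np.ndarray, target_channels: int) -> np.ndarray:
    """Tile a single-input-channel first-layer kernel across input channels.

    Literal duplication, no rescaling — a multi-channel input whose channels
    are all equal then produces ``target_channels`` times the single-channel
    pre-activation (linearity of convolution).
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim != 3 or w.shape[1] != 1:
        raise ValueError(f"expected a (out, 1, k) kernel, got shape {w.shape}")
    if target_channels < 1:
        raise ValueError("target_channels must be >= 1")
    return np.tile(w, (1, target_channels, 1))


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def _state_dict(model: ResNet1D) -> dict[str, np.ndarray]:
    state = {p.name: p.value for p in model.params()}
    for i, bn in enumerate(model.batchnorms()):
        state[f"__running_mean_{i}"] = bn.running_mean
        state[f"__running_var_{i}"] = bn.running_var
    return state


def save_model(model: ResNet1D, path) -> None:
    np.savez(path, __spec__=json.dumps(asdict(model.spec)), **_state_dict(model))


def load_pretrained(path, spec: ModelSpec, seed: int = 0, *,
                    scale_duplicated: bool = False) -> ResNet1D:
    """Initialise a model from stored weights, adapting the first layer and
    the head to ``spec``; with no path, fall back to seeded random weights.

    ``scale_duplicated`` divides duplicated first-layer kernels by the number
    of input channels, preserving the single-channel response magnitude.
    """
    spec.validate()
    model = build_resnet(spec, seed=seed)
    if path is None:
        logger.info("no pretrained weights supplied; using from-scratch initialisation")
        return model
    with np.load(path, allow_pickle=False) as data:
        stored_spec = ModelSpec(**json.loads(str(data["__spec__"])))
        state = {k: data[k] for k in data.files if k != "__spec__"}
    mismatches = []
    for p in model.params():
        if p.name not in state:
            mismatches.append(f"{p.name}: missing from file")
            continue
        stored = state[p.name]
        if p.name == "conv0.weight" and stored.shape[1] != spec.in_channels:
            if stored.shape[1] != 1:
                mismatches.append(
                    f"conv0.weight: cannot adapt {stored.shape[1]}-channel kernel"
                )
                continue
            stored = adapt_first_layer(stored, spec.in_channels)
            if scale_duplicated:
                stored = stored / spec.in_channels
        if p.name.startswith("head.") and stored.shape != p.value.shape:
            # class count changed: keep the fresh seeded head
            logger.info("re-initialising classification head (%s)", p.name)
            continue
        if stored.shape != p.value.shape:
            mismatches.append(f"{p.name}: file {stored.shape} vs model {p.value.shape}")
            continue
        p.value[...] = stored
    if mismatches:
        raise LoadError("incompatible body layers: " + "; ".join(mismatches))
    for i, bn in enumerate(model.batchnorms()):
        rm, rv = state.get(f"__running_mean_{i}"), state.get(f"__running_var_{i}")
        if rm is not None and rm.shape == bn.running_mean.shape:
            bn.running_mean[...] = rm
            bn.running_var[...] = rv
    return model
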