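"""The smear-classification CNN: specification, construction, persistence.

The reference architecture accepts a 1-channel 256 x 256 tile and applies
five convolution blocks — (256, 7x7), (128, 5x5), (64, 3x3), (32, 3x3),
(16, 3x3), each stride 1 with same padding, followed by ReLU, batch
normalization and 2x2/stride-2 max pooling — then flattens the 8 x 8 x 16
feature map into three fully connected blocks (ReLU, batch normalization,
20 % dropout) ending in a task head: softmax scores over 3 storage classes
or 4 deformability bins, or a single linear output predicting the rigidity
score.  ``channel_scale`` and ``input_size`` shrink the network uniformly
for desk-scale experiments without changing its shape grammar; audits of the
reference architecture use channel_scale 1 and input_size 256.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from fractions import Fraction
from pathlib import Path

import numpy as np

from .layers import (
    BatchNorm,
    Conv2d,
    Dropout,
    Flatten,
    Layer,
    Linear,
    MaxPool2d,
    ReLU,
    Sequential,
    softmax,
)

TASKS = {"storage-3": 3, "deformability-4": 4, "regression": 1}

N_POOL_STAGES = 5


class SpecError(ValueError):
    """The network specification is internally inconsistent."""


@dataclass(frozen=True)
class CnnSpec:
    """Layer-by-layer description of the network.

    ``channel_scale`` multiplies every convolutional channel count and must
    yield integers; ``input_size`` must survive five 2x2 poolings.
    """

    input_size: int = 256
    conv_channels: tuple[int, ...] = (256, 128, 64, 32, 16)
    conv_kernels: tuple[int, ...] = (7, 5, 3, 3, 3)
    fc_widths: tuple[int, ...] = (512, 128)
    dropout: float = 0.20
    channel_scale: float = 1.0

    def __post_init__(self) -> None:
        if len(self.conv_channels) != len(self.conv_kernels):
            raise SpecError("conv_channels and conv_kernels lengths differ")
        if self.input_size % (2**N_POOL_STAGES) != 0 or self.input_size <= 0:
            raise SpecError(
                f"input_size must be a positive multiple of {2**N_POOL_STAGES}"
            )
        if self.channel_scale <= 0:
            raise SpecError("channel_scale must be positive")
        self.scaled_channels  # validates integrality

    @property
    def scaled_channels(self) -> tuple[int, ...]:
        scale = Fraction(self.channel_scale).limit_denominator(1024)
        scaled = []
        for c in self.conv_channels:
            s = Fraction(c) * scale
            if s.denominator != 1 or s <= 0:
                raise SpecError(
                    f"channel_scale {self.channel_scale} gives non-integer "
                    f"channel count for {c}"
                )
            scaled.append(int(s))
        return tuple(scaled)

    @property
    def feature_map_size(self) -> int:
        return self.input_size // (2**N_POOL_STAGES)

    @property
    def flatten_length(self) -> int:
        return self.feature_map_size**2 * self.scaled_channels[-1]

    def conv_parameter_counts(self) -> list[int]:
        """Weights + biases per conv layer: (cin * k^2 + 1) * cout."""
        counts = []
        cin = 1
        for cout, k in zip(self.scaled_channels, self.conv_kernels):
            counts.append((cin * k * k + 1) * cout)
            cin = cout
        return counts


@dataclass
class Model:
    """A (possibly trained) network instance with its spec and task."""

    spec: CnnSpec
    task: str
    net: Sequential
    seed: int
    training_history: dict = field(default_factory=dict)
    # Regression targets are standardized during fitting; predictions are
    # mapped back through these statistics.
    target_mean: float = 0.0
    target_std: float = 1.0

    @property
    def head_size(self) -> int:
        return TASKS[self.task]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2:] != (
            self.spec.input_size,
            self.spec.input_size,
        ):
            raise ValueError(
                f"expected input of shape (N, 1, {self.spec.input_size}, "
                f"{self.spec.input_size}), got {x.shape}"
            )
        # Layers run channel-last internally; the public contract is NCHW.
        return self.net.forward(np.ascontiguousarray(x.transpose(0, 2, 3, 1)), train=train)

    def backward_to_input(self, dout: np.ndarray) -> np.ndarray:
        """Backpropagate a head gradient down to the input, returned as NCHW."""
        dx = self.net.backward(np.asarray(dout, dtype=np.float32))
        return dx.transpose(0, 3, 1, 2)

    def predict_logits(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [
            self.forward(x[i : i + batch_size])
            for i in range(0, len(x), batch_size)
        ]
        return np.concatenate(outs)

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        if self.task == "regression":
            raise ValueError("probabilities are undefined for the regression head")
        return softmax(self.predict_logits(x, batch_size))

    def predict(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        logits = self.predict_logits(x, batch_size)
        if self.task == "regression":
            return logits.reshape(-1) * self.target_std + self.target_mean
        return logits.argmax(axis=1)

    # -- introspection ------------------------------------------------------

    @property
    def conv_layers(self) -> list[Conv2d]:
        return [l for l in self.net.layers if isinstance(l, Conv2d)]

    @property
    def fc_layers(self) -> list[Linear]:
        return [l for l in self.net.layers if isinstance(l, Linear)]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.net.parameters()))

    def summary(self) -> str:
        lines = [
            f"task: {self.task}   input: 1 x {self.spec.input_size} x "
            f"{self.spec.input_size}   channel_scale: {self.spec.channel_scale}",
            f"{'layer':<28}{'output channels/width':>22}{'params':>12}",
        ]
        for i, conv in enumerate(self.conv_layers):
            name = f"conv{i + 1} {conv.k}x{conv.k} +ReLU+BN+pool"
            lines.append(f"{name:<28}{conv.cout:>22}{conv.n_parameters:>12}")
        for i, fc in enumerate(self.fc_layers):
            name = "head" if i == len(self.fc_layers) - 1 else f"fc{i + 1} +ReLU+BN+dropout"
            lines.append(f"{name:<28}{fc.out_features:>22}{fc.n_parameters:>12}")
        lines.append(f"{'total':<28}{'':>22}{self.n_parameters():>12}")
        return "\n".join(lines)

    # -- persistence --------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Save weights (npz) plus a JSON architecture sidecar for audit."""
        path = Path(path)
        arrays = {}
        for i, layer in enumerate(self.net.layers):
            for j, p in enumerate(layer.params):
                arrays[f"layer{i}_param{j}"] = p
            if isinstance(layer, BatchNorm):
                arrays[f"layer{i}_running_mean"] = layer.running_mean
                arrays[f"layer{i}_running_var"] = layer.running_var
        np.savez_compressed(path, **arrays)
        sidecar = {
            "spec": asdict(self.spec),
            "task": self.task,
            "seed": self.seed,
            "n_parameters": self.n_parameters(),
            "target_mean": self.target_mean,
            "target_std": self.target_std,
            "training_history": self.training_history,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_model(path: str | Path) -> Model:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec_dict = dict(sidecar["spec"])
    for key in ("conv_channels", "conv_kernels", "fc_widths"):
        spec_dict[key] = tuple(spec_dict[key])
    spec = CnnSpec(**spec_dict)
    model = build_model(spec, sidecar["task"], seed=sidecar["seed"])
    model.training_history = sidecar.get("training_history", {})
    model.target_mean = sidecar.get("target_mean", 0.0)
    model.target_std = sidecar.get("target_std", 1.0)
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    for i, layer in enumerate(model.net.layers):
        for j in range(len(layer.params)):
            layer.params[j][...] = data[f"layer{i}_param{j}"]
        if isinstance(layer, BatchNorm):
            layer.running_mean[...] = data[f"layer{i}_running_mean"]
            layer.running_var[...] = data[f"layer{i}_running_var"]
    return model


def build_model(spec: CnnSpec, task: str, seed: int = 0) -> Model:
    """Instantiate an untrained network for a task.

    The layer sequence is exactly: [Conv -> ReLU -> BN -> MaxPool] x 5 ->
    Flatten -> [Linear -> ReLU -> BN -> Dropout] x len(fc_widths) ->
    Linear head.  Weight initialization is He-normal from ``seed``.
    """
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; choose from {sorted(TASKS)}")
    rng = np.random.default_rng(seed)
    layers: list[Layer] = []
    cin = 1
    for cout, k in zip(spec.scaled_channels, spec.conv_kernels):
        layers += [Conv2d(cin, cout, k, rng), ReLU(), BatchNorm(cout), MaxPool2d()]
        cin = cout
    layers.append(Flatten())
    fin = spec.flatten_length
    for width in spec.fc_widths:
        layers += [Linear(fin, width, rng), ReLU(), BatchNorm(width), Dropout(spec.dropout, rng)]
        fin = width
    head = Linear(fin, TASKS[task], rng)
    # Zero-initialized head: an untrained classifier outputs the uniform
    # distribution and an untrained regressor predicts zero (the standardized
    # target mean), independent of the random feature stack.
    head.params[0][...] = 0.0
    layers.append(head)
    return Model(spec=spec, task=task, net=Sequential(layers), seed=seed)
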