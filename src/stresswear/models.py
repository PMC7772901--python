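"""Declarative builders for the two network architectures.

Chest model: one identical 3-layer 1-D convolutional block per input channel
(8 blocks with the accelerometer axes, 5 without), each block being
conv(8 filters, k=15, s=2) → maxpool(4/4) → conv(16, k=7, s=2) → maxpool(4/4)
→ conv(32, k=3, s=1) → maxpool(2/2), all ReLU; block outputs are flattened,
concatenated and fed through dense 32 → dense 16 → output head.

Wrist model: BVP branch dense 64 → 32, ACC branch (three axes flattened
axis-major to one 480-vector at 5 s windows) dense 32, both ReLU; branch
outputs are concatenated with the raw 4 Hz EDA and TEMP vectors (width
32 + 32 + 20 + 20 = 104) and fed through three dense layers whose middle
width is 8.

Both heads end in 1 sigmoid unit (binary stress detection) or 3 softmax
units (3-class emotion classification); that last layer is the only
difference between the two tasks.

All convolution/pooling arithmetic is valid (no padding) with floor
rounding: out = floor((in − kernel) / stride) + 1.  Under the published
hyperparameters a 3500-sample input yields 32 maps of length 25; a variant
whose final pool is 3/3 (``CHEST_BLOCK_SHORT_OUTPUT``) yields maps of
length 17 and is shipped as a named alternate configuration.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import nn

__all__ = [
    "ConvLayerSpec",
    "ConvBlockSpec",
    "DenseSpec",
    "BranchSpec",
    "ModelGraph",
    "WristConfig",
    "CHEST_CHANNELS",
    "CHEST_BLOCK_DEFAULT",
    "CHEST_BLOCK_SHORT_OUTPUT",
    "layer_out_len",
    "conv_block_output_shape",
    "build_chest_cnn",
    "build_wrist_mlp",
    "apply_activation",
    "graph_diff",
    "instantiate",
    "chest_channels",
]

CHEST_CHANNELS = ("ECG", "EDA", "EMG", "RESP", "TEMP", "ACC_X", "ACC_Y", "ACC_Z")

TASKS = ("binary", "three_class")


def chest_channels(include_acc: bool = True) -> Tuple[str, ...]:
    """The chest input channel list, with or without the three ACC axes."""
    if include_acc:
        return CHEST_CHANNELS
    return tuple(c for c in CHEST_CHANNELS if not c.startswith("ACC"))


# ---------------------------------------------------------------------------
# layer specs and arithmetic


@dataclass(frozen=True)
class ConvLayerSpec:
    """One conv + max-pool stage of a block."""

    n_filters: int
    kernel: int
    stride: int
    pool: int
    pool_stride: int
    activation: str = "relu"

    def __post_init__(self):
        for name in ("n_filters", "kernel", "stride", "pool", "pool_stride"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.activation != "relu":
            raise ValueError("conv layers use ReLU")


@dataclass(frozen=True)
class ConvBlockSpec:
    """A 3-stage 1-D convolutional block and its input length."""

    layers: Tuple[ConvLayerSpec, ConvLayerSpec, ConvLayerSpec]
    input_len: int

    def __post_init__(self):
        if len(self.layers) != 3:
            raise ValueError("a conv block has exactly 3 conv+pool stages")
        conv_block_output_shape(self)  # raises if any stage is infeasible


def layer_out_len(input_len: int, kernel: int, stride: int) -> int:
    """Output length of a valid (no padding) sliding window.

    floor((input_len − kernel) / stride) + 1; the same arithmetic covers
    convolution and max pooling.
    """
    if kernel > input_len:
        raise ValueError(
            f"kernel {kernel} exceeds input length {input_len}: stage infeasible")
    return (input_len - kernel) // stride + 1


def conv_block_output_shape(spec: ConvBlockSpec) -> Tuple[int, int]:
    """(n_maps, map_len) after chaining conv and pool through all stages."""
    length = spec.input_len
    for i, ls in enumerate(spec.layers, start=1):
        try:
            length = layer_out_len(length, ls.kernel, ls.stride)
            length = layer_out_len(length, ls.pool, ls.pool_stride)
        except ValueError as exc:
            raise ValueError(f"conv block stage {i}: {exc}") from None
    return spec.layers[-1].n_filters, length


#: published hyperparameters: kernels 15/7/3, conv strides 2/2/1, pools 4/4/2
CHEST_BLOCK_DEFAULT = ConvBlockSpec(
    layers=(ConvLayerSpec(8, 15, 2, 4, 4),
            ConvLayerSpec(16, 7, 2, 4, 4),
            ConvLayerSpec(32, 3, 1, 2, 2)),
    input_len=3500,
)

#: single-change variant (final pool 3/3) whose output maps are 17 long
CHEST_BLOCK_SHORT_OUTPUT = ConvBlockSpec(
    layers=(ConvLayerSpec(8, 15, 2, 4, 4),
            ConvLayerSpec(16, 7, 2, 4, 4),
            ConvLayerSpec(32, 3, 1, 3, 3)),
    input_len=3500,
)


# ---------------------------------------------------------------------------
# graphs


@dataclass(frozen=True)
class DenseSpec:
    units: int
    activation: str  # relu | sigmoid | softmax | linear


@dataclass(frozen=True)
class BranchSpec:
    """One named input branch: a conv block, a dense stack, or a passthrough."""

    name: str
    kind: str  # conv_block | mlp | passthrough
    input_len: int
    block: Optional[ConvBlockSpec] = None
    dense: Tuple[DenseSpec, ...] = ()

    @property
    def output_width(self) -> int:
        if self.kind == "conv_block":
            n_maps, map_len = conv_block_output_shape(self.block)
            return n_maps * map_len
        if self.kind == "mlp":
            return self.dense[-1].units
        return self.input_len

    @property
    def parameter_count(self) -> int:
        if self.kind == "conv_block":
            total, c_in = 0, 1
            for ls in self.block.layers:
                total += (ls.kernel * c_in + 1) * ls.n_filters
                c_in = ls.n_filters
            return total
        if self.kind == "mlp":
            total, d = 0, self.input_len
            for ds in self.dense:
                total += (d + 1) * ds.units
                d = ds.units
            return total
        return 0


@dataclass(frozen=True)
class ModelGraph:
    """A built network as data: branches, fused head, task, parameter count."""

    branches: Tuple[BranchSpec, ...]
    head: Tuple[DenseSpec, ...]
    task: str

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"task must be one of {TASKS}")
        last = self.head[-1]
        if self.task == "binary" and (last.units, last.activation) != (1, "sigmoid"):
            raise ValueError("binary head must end in 1 sigmoid unit")
        if self.task == "three_class" and (last.units, last.activation) != (3, "softmax"):
            raise ValueError("three-class head must end in 3 softmax units")

    @property
    def concat_width(self) -> int:
        return sum(b.output_width for b in self.branches)

    @property
    def parameter_count(self) -> int:
        total = sum(b.parameter_count for b in self.branches)
        d = self.concat_width
        for ds in self.head:
            total += (d + 1) * ds.units
            d = ds.units
        return total

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ModelGraph":
        raw = json.loads(text)
        branches = tuple(
            BranchSpec(b["name"], b["kind"], b["input_len"],
                       (ConvBlockSpec(tuple(ConvLayerSpec(**l)
                                            for l in b["block"]["layers"]),
                                      b["block"]["input_len"])
                        if b["block"] else None),
                       tuple(DenseSpec(**d) for d in b["dense"]))
            for b in raw["branches"])
        head = tuple(DenseSpec(**d) for d in raw["head"])
        return cls(branches, head, raw["task"])


def _head(task: str, hidden: Sequence[DenseSpec]) -> Tuple[DenseSpec, ...]:
    if task == "binary":
        return tuple(hidden) + (DenseSpec(1, "sigmoid"),)
    return tuple(hidden) + (DenseSpec(3, "softmax"),)


def build_chest_cnn(block: ConvBlockSpec = CHEST_BLOCK_DEFAULT,
                    channels: Sequence[str] = CHEST_CHANNELS,
                    task: str = "three_class") -> ModelGraph:
    """One identical conv block per chest channel, fused by dense 32 → 16.

    Each of the (usually 8) input channels gets its own copy of ``block``;
    flattened block outputs are concatenated in the given channel order.
    """
    if not channels:
        raise ValueError("channel list is empty")
    branches = tuple(BranchSpec(name, "conv_block", block.input_len, block=block)
                     for name in channels)
    head = _head(task, (DenseSpec(32, "relu"), DenseSpec(16, "relu")))
    return ModelGraph(branches, head, task)


@dataclass(frozen=True)
class WristConfig:
    """Wrist model dimensions at 5 s windows and its free head width.

    The first fused dense width is not pinned down by the architecture
    description; 64 is the package default.
    """

    bvp_len: int = 320
    acc_len: int = 480  # 3 axes x 160, flattened axis-major
    eda_len: int = 20
    temp_len: int = 20
    bvp_hidden: Tuple[int, ...] = (64, 32)
    acc_hidden: Tuple[int, ...] = (32,)
    head_first: int = 64
    head_mid: int = 8


def build_wrist_mlp(config: Optional[WristConfig] = None,
                    task: str = "three_class",
                    include_acc: bool = True) -> ModelGraph:
    """BVP and ACC dense branches concatenated with raw EDA/TEMP vectors."""
    cfg = config or WristConfig()
    branches = [BranchSpec("BVP", "mlp", cfg.bvp_len,
                           dense=tuple(DenseSpec(u, "relu") for u in cfg.bvp_hidden))]
    if include_acc:
        branches.append(BranchSpec("ACC", "mlp", cfg.acc_len,
                                   dense=tuple(DenseSpec(u, "relu")
                                               for u in cfg.acc_hidden)))
    branches += [BranchSpec("EDA", "passthrough", cfg.eda_len),
                 BranchSpec("TEMP", "passthrough", cfg.temp_len)]
    head = _head(task, (DenseSpec(cfg.head_first, "relu"),
                        DenseSpec(cfg.head_mid, "relu")))
    return ModelGraph(tuple(branches), head, task)


def apply_activation(name: str, v: np.ndarray) -> np.ndarray:
    """relu / sigmoid / softmax on a vector (softmax is max-shifted)."""
    if name == "relu":
        return nn.relu(v)
    if name == "sigmoid":
        return nn.sigmoid(v)
    if name == "softmax":
        return nn.softmax(v)
    raise ValueError(f"unknown activation {name!r}")


def graph_diff(a: ModelGraph, b: ModelGraph) -> List[str]:
    """Structural differences between two graphs, as dotted-path strings.

    Ignores the task tag itself; an empty list means the architectures are
    identical layer for layer.
    """
    diffs: List[str] = []
    if len(a.branches) != len(b.branches):
        diffs.append("branches.count")
    else:
        for i, (ba, bb) in enumerate(zip(a.branches, b.branches)):
            if ba != bb:
                diffs.append(f"branches[{i}]({ba.name})")
    if len(a.head) != len(b.head):
        diffs.append("head.count")
    else:
        for i, (ha, hb) in enumerate(zip(a.head, b.head)):
            if ha.units != hb.units:
                diffs.append(f"head[{i}].units")
            if ha.activation != hb.activation:
                diffs.append(f"head[{i}].activation")
    return diffs


# ---------------------------------------------------------------------------
# instantiation on the NumPy engine


def instantiate(graph: ModelGraph, seed: int) -> nn.Network:
    """Materialize a graph into a seeded network with real parameter arrays.

    Parameters are drawn branch by branch in the declared order from one
    ``default_rng(seed)`` stream, so instantiation is reproducible.
    """
    rng = np.random.default_rng(seed)
    branches = []
    for br in graph.branches:
        layers: list = []
        if br.kind == "conv_block":
            c_in = 1
            for ls in br.block.layers:
                layers.append(nn.Conv1D(c_in, ls.n_filters, ls.kernel,
                                        ls.stride, ls.activation, rng))
                layers.append(nn.MaxPool1D(ls.pool, ls.pool_stride))
                c_in = ls.n_filters
            layers.append(nn.Flatten())
        elif br.kind == "mlp":
            d = br.input_len
            for ds in br.dense:
                layers.append(nn.Dense(d, ds.units, ds.activation, rng))
                d = ds.units
        elif br.kind != "passthrough":
            raise ValueError(f"unknown branch kind {br.kind!r}")
        branches.append((br.name, layers))
    head = []
    d = graph.concat_width
    for ds in graph.head:
        act = "relu" if ds.activation == "relu" else "linear"
        head.append(nn.Dense(d, ds.units, act, rng))
        d = ds.units
    return nn.Network(branches, head,
                      out_activation=graph.head[-1].activation,
                      task=graph.task)
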