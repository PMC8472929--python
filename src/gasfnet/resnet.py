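"""Baseline ResNet-50 and the improved residual network, built declaratively.

The improved variant modifies canonical ResNet-50 in four ways:

* five auxiliary 1x1-convolution shortcut groups are added — one around
  each residual stage (strides 1, 2, 2, 2) and one around all four stages
  (stride 8) — each merged by addition with the path it bridges;
* downsampling moves from the first 1x1 trunk convolution to the 3x3
  convolution, avoiding the 3/4 information loss of a strided 1x1;
* the bypass of each downsampling block becomes 2x2 average pooling
  (stride 2) followed by a stride-1 1x1 convolution; the first stage keeps
  a plain 1x1 projection since its spatial size does not change;
* batch normalization and activation are pre-positioned in the trunk
  (pre-activation bottlenecks), and SELU replaces ReLU.

A :class:`ModelSpec` describes a network; :func:`materialize` turns it
into a trainable numpy model; :func:`forward_shapes` traces spatial sizes
and channel widths without allocating parameters.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _nn
from ._nn import SELU_ALPHA, SELU_LAMBDA

__all__ = [
    "ActivationParams",
    "BlockSpec",
    "ShortcutSpec",
    "StagePlan",
    "ModelSpec",
    "relu",
    "selu",
    "build_baseline_resnet50",
    "build_improved_resnet",
    "count_parameters",
    "forward_shapes",
    "materialize",
    "NumpyModel",
]

STAGE_NAMES = ("Conv2_x", "Conv3_x", "Conv4_x", "Conv5_x")
#: Canonical ResNet-50 (mid, out) channel widths per stage.
STAGE_WIDTHS = ((64, 256), (128, 512), (256, 1024), (512, 2048))
RESNET50_BLOCKS = (3, 4, 6, 3)


# ---------------------------------------------------------------------------
# Activations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActivationParams:
    """Activation choice; SELU carries its fixed-point constants."""

    kind: str = "SELU"
    alpha: float = SELU_ALPHA
    lam: float = SELU_LAMBDA

    def __post_init__(self):
        if self.kind not in ("ReLU", "SELU"):
            raise ValueError(f"unknown activation kind {self.kind!r}")


def relu(x):
    """Rectified linear unit, max(x, 0), elementwise."""
    return np.maximum(np.asarray(x, dtype=float), 0.0)


def selu(x, params: ActivationParams | None = None):
    """Scaled exponential linear unit.

    ``lam * x`` for x >= 0 and ``lam * (alpha * e^x - alpha)`` for x < 0;
    with the default constants (alpha ~ 1.6733, lam ~ 1.0507) iterated
    application drives activations toward zero mean and unit variance.
    """
    p = params or ActivationParams()
    x = np.asarray(x, dtype=float)
    return np.where(x >= 0, p.lam * x, p.lam * (p.alpha * np.exp(np.minimum(x, 0.0)) - p.alpha))


def _act_layer(params: ActivationParams) -> _nn.Layer:
    if params.kind == "ReLU":
        return _nn.ReLU()
    return _nn.SELU(params.alpha, params.lam)


# ---------------------------------------------------------------------------
# Declarative specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockSpec:
    """One bottleneck residual block (1x1 -> 3x3 -> 1x1 trunk)."""

    in_ch: int
    mid_ch: int
    out_ch: int
    stride: int = 1
    preactivation: bool = False
    #: "identity", "conv1x1" or "avgpool2x2+conv1x1"
    bypass: str = "identity"
    #: which trunk conv carries the stride: "conv1x1" (canonical) or "conv3x3"
    downsample_on: str = "conv1x1"

    def __post_init__(self):
        if self.bypass not in ("identity", "conv1x1", "avgpool2x2+conv1x1"):
            raise ValueError(f"unknown bypass {self.bypass!r}")
        if self.downsample_on not in ("conv1x1", "conv3x3"):
            raise ValueError(f"unknown downsample placement {self.downsample_on!r}")
        if self.bypass == "identity" and (self.in_ch != self.out_ch or self.stride != 1):
            raise ValueError("identity bypass requires matching channels and stride 1")

    @property
    def trunk_strides(self) -> tuple[int, int, int]:
        if self.downsample_on == "conv3x3":
            return (1, self.stride, 1)
        return (self.stride, 1, 1)


@dataclass(frozen=True)
class ShortcutSpec:
    """An auxiliary 1x1-conv branch bridging a span of the network."""

    span: str
    in_ch: int
    out_ch: int
    stride: int
    kernel: int = 1


@dataclass(frozen=True)
class StagePlan:
    name: str
    blocks: tuple[BlockSpec, ...]
    shortcut: ShortcutSpec | None = None


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a whole network."""

    name: str
    stages: tuple[StagePlan, ...]
    activation: ActivationParams
    n_classes: int = 7
    in_channels: int = 1
    stem_channels: int = 64
    global_shortcut: ShortcutSpec | None = None
    #: pre-activation nets need a final BN + activation before the head
    final_bn_act: bool = False

    @property
    def block_counts(self) -> tuple[int, ...]:
        return tuple(len(s.blocks) for s in self.stages)

    @property
    def auxiliary_shortcuts(self) -> tuple[ShortcutSpec, ...]:
        sc = [s.shortcut for s in self.stages if s.shortcut is not None]
        if self.global_shortcut is not None:
            sc.append(self.global_shortcut)
        return tuple(sc)

    @property
    def out_channels(self) -> int:
        return self.stages[-1].blocks[-1].out_ch


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def _scaled_widths(width: float) -> tuple[int, tuple[tuple[int, int], ...]]:
    stem = max(4, int(round(64 * width)))
    widths = tuple(
        (max(4, int(round(m * width))), max(8, int(round(o * width))))
        for m, o in STAGE_WIDTHS
    )
    return stem, widths


def _stage_plan(name, n_blocks, in_ch, mid, out, stride, *, improved) -> tuple[BlockSpec, ...]:
    blocks = []
    for b in range(n_blocks):
        first = b == 0
        s = stride if first else 1
        if not first:
            bypass = "identity"
        elif improved and s == 2:
            bypass = "avgpool2x2+conv1x1"
        else:
            bypass = "conv1x1"
        blocks.append(
            BlockSpec(
                in_ch=in_ch if first else out,
                mid_ch=mid,
                out_ch=out,
                stride=s,
                preactivation=improved,
                bypass=bypass,
                downsample_on="conv3x3" if improved else "conv1x1",
            )
        )
    return tuple(blocks)


def build_baseline_resnet50(
    n_classes: int = 7,
    activation: ActivationParams | None = None,
    in_channels: int = 1,
    blocks: Sequence[int] = RESNET50_BLOCKS,
    width: float = 1.0,
) -> ModelSpec:
    """Canonical ResNet-50: post-activation bottlenecks, strided first 1x1
    conv in downsampling blocks, 1x1-conv bypasses, no auxiliary shortcuts.

    ``blocks`` and ``width`` allow reduced-depth/width variants for small
    experiments; the defaults are the canonical (3, 4, 6, 3) plan at full
    width.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    act = activation or ActivationParams("ReLU")
    stem, widths = _scaled_widths(width)
    stages = []
    in_ch = stem
    for name, n, (mid, out), stride in zip(STAGE_NAMES, blocks, widths, (1, 2, 2, 2)):
        stages.append(
            StagePlan(name, _stage_plan(name, n, in_ch, mid, out, stride, improved=False))
        )
        in_ch = out
    return ModelSpec(
        name="baseline-resnet50",
        stages=tuple(stages),
        activation=act,
        n_classes=n_classes,
        in_channels=in_channels,
        stem_channels=stem,
    )


def build_improved_resnet(
    n_classes: int = 7,
    activation: ActivationParams | None = None,
    in_channels: int = 1,
    blocks: Sequence[int] = RESNET50_BLOCKS,
    width: float = 1.0,
) -> ModelSpec:
    """The improved variant: pre-activation bottlenecks, stride on the 3x3
    trunk convs, average-pool bypasses in downsampling blocks, and five
    auxiliary 1x1 shortcut groups (per-stage strides 1, 2, 2, 2; global
    stride 8).  SELU is the default activation.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 classes")
    act = activation or ActivationParams("SELU")
    stem, widths = _scaled_widths(width)
    stages = []
    in_ch = stem
    for name, n, (mid, out), stride in zip(STAGE_NAMES, blocks, widths, (1, 2, 2, 2)):
        plan = _stage_plan(name, n, in_ch, mid, out, stride, improved=True)
        shortcut = ShortcutSpec(span=name, in_ch=in_ch, out_ch=out, stride=stride)
        stages.append(StagePlan(name, plan, shortcut))
        in_ch = out
    global_sc = ShortcutSpec(span="Conv2_x..Conv5_x", in_ch=stem, out_ch=in_ch, stride=8)
    return ModelSpec(
        name="improved-resnet",
        stages=tuple(stages),
        activation=act,
        n_classes=n_classes,
        in_channels=in_channels,
        stem_channels=stem,
        global_shortcut=global_sc,
        final_bn_act=True,
    )


# ---------------------------------------------------------------------------
# Spec-level analysis
# ---------------------------------------------------------------------------

def count_parameters(spec: ModelSpec) -> int:
    """Learnable-parameter count as a pure function of the spec.

    Convolutions are bias-free (batch norm supplies the shift); each BN
    contributes a scale and a shift per channel; the linear head has a
    bias.  Matches the materialized model's array sizes exactly.
    """
    n = spec.in_channels * spec.stem_channels * 49 + 2 * spec.stem_channels
    for stage in spec.stages:
        for b in stage.blocks:
            n += b.in_ch * b.mid_ch + b.mid_ch * b.mid_ch * 9 + b.mid_ch * b.out_ch
            if b.preactivation:
                n += 2 * (b.in_ch + b.mid_ch + b.mid_ch)
            else:
                n += 2 * (b.mid_ch + b.mid_ch + b.out_ch)
            if b.bypass != "identity":
                n += b.in_ch * b.out_ch + 2 * b.out_ch
        if stage.shortcut is not None:
            sc = stage.shortcut
            n += sc.in_ch * sc.out_ch * sc.kernel ** 2 + 2 * sc.out_ch
    if spec.global_shortcut is not None:
        sc = spec.global_shortcut
        n += sc.in_ch * sc.out_ch * sc.kernel ** 2 + 2 * sc.out_ch
    if spec.final_bn_act:
        n += 2 * spec.out_channels
    n += spec.out_channels * spec.n_classes + spec.n_classes
    return n


def forward_shapes(spec: ModelSpec, input_shape: tuple[int, int, int] | None = None):
    """Trace (stage, spatial side, channels) through the network.

    ``input_shape`` is (channels, side, side); the side must be divisible
    by 32 (stem /4 plus three stride-2 stages).  Raises on any channel or
    merge-shape inconsistency, naming the offending branch.
    """
    if input_shape is None:
        input_shape = (spec.in_channels, 224, 224)
    c, h, w = input_shape
    if h != w:
        raise ValueError(f"input must be square, got {h}x{w}")
    if h % 32:
        raise ValueError(f"input side must be divisible by 32, got {h}")
    if c != spec.in_channels:
        raise ValueError(f"spec expects {spec.in_channels} input channel(s), got {c}")
    trace = [("input", h, c)]
    side = h // 4  # stem: 7x7 stride-2 conv, then 3x3 stride-2 max pool
    ch = spec.stem_channels
    trace.append(("stem", side, ch))
    stem_side = side
    for stage in spec.stages:
        for i, b in enumerate(stage.blocks):
            if b.in_ch != ch:
                raise ValueError(
                    f"{stage.name} block {i}: expects {b.in_ch} channels, gets {ch}"
                )
            side //= b.stride
            ch = b.out_ch
        if stage.shortcut is not None:
            sc = stage.shortcut
            sc_side = trace[-1][1] // sc.stride
            if sc_side != side or sc.out_ch != ch:
                raise ValueError(
                    f"stage shortcut {sc.span}: produces ({sc_side}, {sc.out_ch}), "
                    f"trunk produces ({side}, {ch})"
                )
        trace.append((stage.name, side, ch))
    if spec.global_shortcut is not None:
        sc = spec.global_shortcut
        # stride-8 1x1 conv: side = floor((s - 1) / 8) + 1
        sc_side = (stem_side - 1) // sc.stride + 1
        if sc_side != side or sc.out_ch != ch:
            raise ValueError(
                f"global shortcut: produces ({sc_side}, {sc.out_ch}), "
                f"trunk produces ({side}, {ch})"
            )
    trace.append(("logits", 0, spec.n_classes))
    return trace


def describe(spec: ModelSpec, input_side: int = 224) -> str:
    """Human-readable architecture summary with the shape trace."""
    lines = [
        f"{spec.name}: stages {spec.block_counts}, activation {spec.activation.kind}, "
        f"{spec.n_classes} classes, {count_parameters(spec):,} parameters",
        f"auxiliary shortcut groups: {len(spec.auxiliary_shortcuts)}",
    ]
    for sc in spec.auxiliary_shortcuts:
        lines.append(
            f"  {sc.span}: 1x1 conv, {sc.in_ch}->{sc.out_ch} channels, stride {sc.stride}"
        )
    for name, side, ch in forward_shapes(spec, (spec.in_channels, input_side, input_side)):
        spatial = f"{side}x{side}" if side else "-"
        lines.append(f"  {name:<16} {spatial:>9}  {ch} ch")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Materialization
# ---------------------------------------------------------------------------

class _Bottleneck:
    """A materialized bottleneck block: trunk + bypass, summed."""

    def __init__(self, bs: BlockSpec, act: ActivationParams, rng, gain, dtype):
        self.spec = bs
        s1, s2, s3 = bs.trunk_strides
        conv = lambda i, o, k, s, p: _nn.Conv2d(i, o, k, s, p, rng=rng, gain=gain, dtype=dtype)
        if bs.preactivation:
            self.trunk = _nn.Sequential(
                _nn.BatchNorm2d(bs.in_ch, dtype=dtype), _act_layer(act),
                conv(bs.in_ch, bs.mid_ch, 1, s1, 0),
                _nn.BatchNorm2d(bs.mid_ch, dtype=dtype), _act_layer(act),
                conv(bs.mid_ch, bs.mid_ch, 3, s2, 1),
                _nn.BatchNorm2d(bs.mid_ch, dtype=dtype), _act_layer(act),
                conv(bs.mid_ch, bs.out_ch, 1, s3, 0),
            )
            self.post_act = None
        else:
            self.trunk = _nn.Sequential(
                conv(bs.in_ch, bs.mid_ch, 1, s1, 0),
                _nn.BatchNorm2d(bs.mid_ch, dtype=dtype), _act_layer(act),
                conv(bs.mid_ch, bs.mid_ch, 3, s2, 1),
                _nn.BatchNorm2d(bs.mid_ch, dtype=dtype), _act_layer(act),
                conv(bs.mid_ch, bs.out_ch, 1, s3, 0),
                _nn.BatchNorm2d(bs.out_ch, dtype=dtype),
            )
            self.post_act = _act_layer(act)
        if bs.bypass == "identity":
            self.bypass = None
        elif bs.bypass == "conv1x1":
            self.bypass = _nn.Sequential(
                conv(bs.in_ch, bs.out_ch, 1, bs.stride, 0),
                _nn.BatchNorm2d(bs.out_ch, dtype=dtype),
            )
        else:  # avgpool2x2 (stride 2) + stride-1 1x1 conv
            self.bypass = _nn.Sequential(
                _nn.AvgPool2x2(),
                conv(bs.in_ch, bs.out_ch, 1, 1, 0),
                _nn.BatchNorm2d(bs.out_ch, dtype=dtype),
            )

    def forward(self, x):
        t = self.trunk.forward(x)
        b = self.bypass.forward(x) if self.bypass is not None else x
        y = t + b
        if self.post_act is not None:
            y = self.post_act.forward(y)
        return y

    def backward(self, dout):
        if self.post_act is not None:
            dout = self.post_act.backward(dout)
        dx = self.trunk.backward(dout)
        if self.bypass is not None:
            dx = dx + self.bypass.backward(dout)
        else:
            dx = dx + dout
        return dx

    def layers(self):
        out = list(_nn.iter_layers(self.trunk))
        if self.post_act is not None:
            out.append(self.post_act)
        if self.bypass is not None:
            out.extend(_nn.iter_layers(self.bypass))
        return out


class _Stage:
    """Residual blocks plus an optional stage-level shortcut branch."""

    def __init__(self, plan: StagePlan, act, rng, gain, dtype):
        self.plan = plan
        self.blocks = [_Bottleneck(b, act, rng, gain, dtype) for b in plan.blocks]
        if plan.shortcut is not None:
            sc = plan.shortcut
            self.shortcut = _nn.Sequential(
                _nn.Conv2d(sc.in_ch, sc.out_ch, sc.kernel, sc.stride, 0, rng=rng, gain=gain, dtype=dtype),
                _nn.BatchNorm2d(sc.out_ch, dtype=dtype),
            )
        else:
            self.shortcut = None

    def forward(self, x):
        y = x
        for blk in self.blocks:
            y = blk.forward(y)
        if self.shortcut is not None:
            y = y + self.shortcut.forward(x)
        return y

    def backward(self, dout):
        dsc = self.shortcut.backward(dout) if self.shortcut is not None else None
        dx = dout
        for blk in reversed(self.blocks):
            dx = blk.backward(dx)
        if dsc is not None:
            dx = dx + dsc
        return dx

    def layers(self):
        out = []
        for blk in self.blocks:
            out.extend(blk.layers())
        if self.shortcut is not None:
            out.extend(_nn.iter_layers(self.shortcut))
        return out


class NumpyModel:
    """A trainable model materialized from a :class:`ModelSpec`."""

    def __init__(self, spec: ModelSpec, seed: int = 0, dtype=_nn.DEFAULT_DTYPE):
        forward_shapes(spec, (spec.in_channels, 64, 64))  # validate wiring
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        gain = np.sqrt(2.0) if spec.activation.kind == "ReLU" else 1.0
        self.stem = _nn.Sequential(
            _nn.Conv2d(spec.in_channels, spec.stem_channels, 7, 2, 3, rng=rng, gain=gain, dtype=dtype),
            _nn.BatchNorm2d(spec.stem_channels, dtype=dtype),
            _act_layer(spec.activation),
            _nn.MaxPool2d(3, 2, 1),
        )
        self.stages = [_Stage(p, spec.activation, rng, gain, dtype) for p in spec.stages]
        if spec.global_shortcut is not None:
            sc = spec.global_shortcut
            self.global_shortcut = _nn.Sequential(
                _nn.Conv2d(sc.in_ch, sc.out_ch, sc.kernel, sc.stride, 0, rng=rng, gain=gain, dtype=dtype),
                _nn.BatchNorm2d(sc.out_ch, dtype=dtype),
            )
        else:
            self.global_shortcut = None
        if spec.final_bn_act:
            self.final = _nn.Sequential(
                _nn.BatchNorm2d(spec.out_channels, dtype=dtype), _act_layer(spec.activation)
            )
        else:
            self.final = None
        self.pool = _nn.GlobalAvgPool()
        self.fc = _nn.Linear(spec.out_channels, spec.n_classes, rng=rng, dtype=dtype)
        self._layers = list(_nn.iter_layers(self.stem))
        for st in self.stages:
            self._layers.extend(st.layers())
        if self.global_shortcut is not None:
            self._layers.extend(_nn.iter_layers(self.global_shortcut))
        if self.final is not None:
            self._layers.extend(_nn.iter_layers(self.final))
        self._layers.extend([self.pool, self.fc])

    # -- modes and parameters ------------------------------------------------

    def train_mode(self, flag: bool = True):
        _nn.set_training(self._layers, flag)
        return self

    def param_slots(self):
        return _nn.param_slots(self._layers)

    @property
    def num_params(self) -> int:
        return sum(layer.params[k].size for layer, k in self.param_slots())

    def checksum(self) -> str:
        h = hashlib.sha256()
        for layer, k in self.param_slots():
            h.update(np.ascontiguousarray(layer.params[k], dtype=np.float64).tobytes())
        return h.hexdigest()

    def state_arrays(self):
        """All parameter and BN running-stat arrays, keyed for (de)serialization."""
        out = {}
        for i, (layer, k) in enumerate(self.param_slots()):
            out[f"p{i}_{k}"] = layer.params[k]
        for j, layer in enumerate(self._layers):
            if isinstance(layer, _nn.BatchNorm2d):
                out[f"bn{j}_mean"] = layer.running_mean
                out[f"bn{j}_var"] = layer.running_var
        return out

    def save(self, path):
        np.savez_compressed(path, **self.state_arrays())

    def load(self, path):
        with np.load(path) as npz:
            for key, arr in self.state_arrays().items():
                arr[...] = npz[key]
        return self

    # -- forward / backward --------------------------------------------------

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[:, None, :, :]
        t = self.stem.forward(x)
        y = t
        for stage in self.stages:
            y = stage.forward(y)
        if self.global_shortcut is not None:
            y = y + self.global_shortcut.forward(t)
        if self.final is not None:
            y = self.final.forward(y)
        return self.fc.forward(self.pool.forward(y))

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dy = self.pool.backward(self.fc.backward(dlogits))
        if self.final is not None:
            dy = self.final.backward(dy)
        dt_extra = None
        if self.global_shortcut is not None:
            dt_extra = self.global_shortcut.backward(dy)
        for stage in reversed(self.stages):
            dy = stage.backward(dy)
        if dt_extra is not None:
            dy = dy + dt_extra
        return self.stem.backward(dy)

    def loss_and_grad(self, x: np.ndarray, targets: np.ndarray) -> float:
        logits = self.forward(x)
        loss, dlogits = _nn.softmax_cross_entropy(logits, targets)
        self.backward(dlogits)
        return loss

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        self.train_mode(False)
        x = np.asarray(x)
        if x.ndim == 3:
            x = x[:, None, :, :]
        out = []
        for i in range(0, x.shape[0], batch_size):
            out.append(_nn.softmax(self.forward(x[i : i + batch_size])))
        return np.concatenate(out, axis=0)

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=1)


def materialize(spec: ModelSpec, seed: int = 0, dtype=_nn.DEFAULT_DTYPE) -> NumpyModel:
    """Materialize a spec into a trainable model.

    The same spec and seed always produce identical initial parameters;
    the parameter count is a pure function of the spec (see
    :func:`count_parameters`).  An inconsistent spec raises a
    ``ValueError`` naming the offending branch.
    """
    model = NumpyModel(spec, seed=seed, dtype=dtype)
    expected = count_parameters(spec)
    if model.num_params != expected:
        raise AssertionError(
            f"materialized parameter count {model.num_params} != spec count {expected}"
        )
    return model
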