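"""DC-ResNet-style backbone: grouped residual bottlenecks followed by
dilation-2 residual stages that keep the feature-map size fixed.

The network follows the ResNeXt bottleneck pattern (cardinality 32) in its
first three stages and a DetNet-style dilated bottleneck in the last two, so
the deepest maps retain the stride-16 resolution that small cells need.  The
classifier head is three fully connected layers (1024 / 256 / 2), each
followed by dropout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .nn.layers import GeometryError


class ConfigurationError(ValueError):
    """Raised for inconsistent stage/channel/group plans."""


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ConvLayerSpec:
    """Geometry of one convolution; used by the output-size arithmetic."""

    kernel: int
    stride: int = 1
    padding: int = 0
    dilation: int = 1
    groups: int = 1
    in_channels: int = 1
    out_channels: int = 1

    def __post_init__(self):
        if min(self.kernel, self.stride, self.dilation, self.groups,
               self.in_channels, self.out_channels) < 1 or self.padding < 0:
            raise ConfigurationError(f"non-positive field in {self}")
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise ConfigurationError(
                f"channels not divisible by groups in {self}")

    @property
    def effective_kernel(self) -> int:
        return self.kernel + (self.kernel - 1) * (self.dilation - 1)


def conv_output_size(x: int, spec: ConvLayerSpec) -> int:
    """Output size floor((x - k - (k-1)(d-1) + 2p)/s) + 1 of a convolution.

    Raises :class:`cytodet.nn.GeometryError` if the result would not be a
    positive integer for input size ``x``.
    """
    y = (x - spec.kernel - (spec.kernel - 1) * (spec.dilation - 1)
         + 2 * spec.padding) // spec.stride + 1
    if y <= 0:
        raise GeometryError(f"input size {x} inadmissible for {spec}")
    return y


def conv_param_count(spec: ConvLayerSpec) -> int:
    """Weight count of a (bias-free) convolution: out*in/g*k^2."""
    return (spec.out_channels * spec.in_channels // spec.groups
            * spec.kernel ** 2)


GROUPED, DILATED = "grouped", "dilated"


@dataclass(frozen=True)
class StageSpec:
    """One residual stage.

    ``grouped`` stages are ``multiplicity`` identical bottlenecks with a
    grouped 3x3; ``dilated`` stages are one variant-B block (extra residual
    1x1) followed by ``multiplicity - 1`` variant-A blocks, all stride 1.
    """

    kind: str
    multiplicity: int
    channels: tuple[int, int, int]
    groups: int = 1
    dilation: int = 1
    stride: int = 1  # entry stride of the first block

    def __post_init__(self):
        if self.kind not in (GROUPED, DILATED):
            raise ConfigurationError(f"unknown stage kind {self.kind!r}")
        if self.multiplicity < 1:
            raise ConfigurationError("multiplicity must be >= 1")
        if self.kind == DILATED and self.stride != 1:
            raise ConfigurationError(
                "dilated stages are stride-1: they preserve feature size")


@dataclass(frozen=True)
class BackboneConfig:
    stem_channels: int = 64
    stages: tuple[StageSpec, ...] = ()
    head_dims: tuple[int, ...] = (1024, 256, 2)
    dropout: float = 0.5
    input_size: int = 224
    # per-channel normalization constants, typically refit on training data
    input_mean: tuple[float, float, float] = (0.5, 0.5, 0.5)
    input_std: tuple[float, float, float] = (0.25, 0.25, 0.25)

    def __post_init__(self):
        if len(self.head_dims) != 3:
            raise ConfigurationError(
                "classifier head must have exactly three fc layers")


def default_config() -> BackboneConfig:
    """The full-size stage plan: grouped 3/4/6 then two dilated stages."""
    return BackboneConfig(stages=(
        StageSpec(GROUPED, 3, (128, 128, 256), groups=32, stride=1),
        StageSpec(GROUPED, 4, (256, 256, 512), groups=32, stride=2),
        StageSpec(GROUPED, 6, (512, 512, 1024), groups=32, stride=2),
        StageSpec(DILATED, 3, (1024, 256, 1024), dilation=2),
        StageSpec(DILATED, 3, (1024, 256, 1024), dilation=2),
    ))


@dataclass
class FeatureMapSet:
    """Ordered multi-scale maps F1..Fn with strides relative to the input."""

    maps: dict[int, np.ndarray] = field(default_factory=dict)
    strides: dict[int, int] = field(default_factory=dict)

    @property
    def levels(self) -> list[int]:
        return sorted(self.maps)

    def channels(self, level: int) -> int:
        return self.maps[level].shape[1]

    def spatial(self, level: int) -> tuple[int, int]:
        return self.maps[level].shape[2:]


# --------------------------------------------------------------------------
# blocks
# --------------------------------------------------------------------------

def _conv_bn(in_ch, out_ch, k, s=1, p=0, d=1, g=1, rng=None, dtype=np.float32):
    return [nn.Conv2d(in_ch, out_ch, k, stride=s, padding=p, dilation=d,
                      groups=g, bias=False, rng=rng, dtype=dtype),
            nn.BatchNorm2d(out_ch, dtype=dtype)]


class Bottleneck(nn.Module):
    """1x1 -> 3x3 (grouped or dilated) -> 1x1 with residual add.

    ``projection`` is a 1x1 Conv-BN shortcut used where channels or stride
    change (or for the dilated variant B); otherwise the shortcut is the
    identity and in/out channels must agree.
    """

    def __init__(self, in_ch: int, channels: tuple[int, int, int],
                 stride: int = 1, groups: int = 1, dilation: int = 1,
                 projection: bool = False, *, rng=None, dtype=np.float32):
        super().__init__()
        c1, c2, c3 = channels
        if c1 % groups or c2 % groups:
            raise ConfigurationError(
                f"bottleneck channels {channels} not divisible by g={groups}")
        pad = dilation  # keeps the 3x3 size-preserving at stride 1
        self.main = nn.Sequential(
            *_conv_bn(in_ch, c1, 1, rng=rng, dtype=dtype), nn.ReLU(),
            *_conv_bn(c1, c2, 3, s=stride, p=pad, d=dilation, g=groups,
                      rng=rng, dtype=dtype), nn.ReLU(),
            *_conv_bn(c2, c3, 1, rng=rng, dtype=dtype),
        )
        if projection:
            self.shortcut = nn.Sequential(
                *_conv_bn(in_ch, c3, 1, s=stride, rng=rng, dtype=dtype))
        else:
            if in_ch != c3 or stride != 1:
                raise ConfigurationError(
                    f"identity shortcut needs in=out and stride 1, got "
                    f"{in_ch}->{c3} stride {stride}")
            self.shortcut = None
        self.out_channels = c3

    def forward(self, x):
        main = self.main.forward(x)
        short = self.shortcut.forward(x) if self.shortcut else x
        y = main + short
        self._mask = y > 0
        return y * self._mask

    def backward(self, dy):
        d = dy * self._mask
        dx = self.main.backward(d)
        if self.shortcut:
            dx = dx + self.shortcut.backward(d)
        else:
            dx = dx + d
        return dx

    def conv_specs(self) -> list[ConvLayerSpec]:
        """Main-path conv geometries, then the projection (if any)."""
        specs = []
        for layer in self.main:
            if isinstance(layer, nn.Conv2d):
                specs.append(ConvLayerSpec(
                    layer.kernel_size, layer.stride, layer.padding,
                    layer.dilation, layer.groups,
                    layer.in_channels, layer.out_channels))
        if self.shortcut:
            conv = self.shortcut.layers[0]
            specs.append(ConvLayerSpec(1, conv.stride, 0, 1, 1,
                                       conv.in_channels, conv.out_channels))
        return specs


def residual_group_block(in_ch: int, mid_ch: int, out_ch: int,
                         groups: int = 32, stride: int = 1, *,
                         rng=None, dtype=np.float32) -> Bottleneck:
    """Grouped bottleneck: 1x1 reduce, 3x3 grouped, 1x1 expand."""
    projection = in_ch != out_ch or stride != 1
    return Bottleneck(in_ch, (mid_ch, mid_ch, out_ch), stride=stride,
                      groups=groups, projection=projection, rng=rng,
                      dtype=dtype)


def residual_dilated_block(variant: str, in_ch: int,
                           channels: tuple[int, int, int], dilation: int = 2,
                           *, rng=None, dtype=np.float32) -> Bottleneck:
    """Dilation-``d`` bottleneck; variant B carries a residual 1x1 conv."""
    if variant not in ("A", "B"):
        raise ConfigurationError(f"dilated variant must be A or B, got {variant!r}")
    return Bottleneck(in_ch, channels, stride=1, dilation=dilation,
                      projection=(variant == "B"), rng=rng, dtype=dtype)


# --------------------------------------------------------------------------
# the backbone
# --------------------------------------------------------------------------

class DCResNet(nn.Module):
    def __init__(self, config: BackboneConfig | None = None, seed: int = 0,
                 dtype=np.float32):
        super().__init__()
        self.config = config or default_config()
        rng = np.random.default_rng(seed)
        cfg = self.config

        self.stem_conv, self.stem_bn = _conv_bn(
            3, cfg.stem_channels, 7, s=2, p=3, rng=rng, dtype=dtype)
        self.stem_relu = nn.ReLU()
        self.stem_pool = nn.MaxPool2d(3, 2, 1)

        self.stages: list[list[Bottleneck]] = []
        ch = cfg.stem_channels
        for spec in cfg.stages:
            blocks = []
            for i in range(spec.multiplicity):
                if spec.kind == GROUPED:
                    c1, c2, c3 = spec.channels
                    blocks.append(residual_group_block(
                        ch, c2, c3, groups=spec.groups,
                        stride=spec.stride if i == 0 else 1,
                        rng=rng, dtype=dtype))
                else:
                    variant = "B" if i == 0 else "A"
                    blocks.append(residual_dilated_block(
                        variant, ch, spec.channels, dilation=spec.dilation,
                        rng=rng, dtype=dtype))
                ch = blocks[-1].out_channels
            self.stages.append(blocks)
        self.feature_channels = ch

        d1, d2, d3 = cfg.head_dims
        self.pool = nn.GlobalAvgPool()
        self.fc = [nn.Linear(ch, d1, rng=rng, dtype=dtype),
                   nn.Linear(d1, d2, rng=rng, dtype=dtype),
                   nn.Linear(d2, d3, rng=rng, dtype=dtype)]
        self.drops = [nn.Dropout(cfg.dropout, rng=np.random.default_rng(
            rng.integers(2**31))) for _ in self.fc]
        self.relu_head = [nn.ReLU(), nn.ReLU()]

    # -- inference -------------------------------------------------------

    def normalize(self, images: np.ndarray) -> np.ndarray:
        """Standardize NCHW float images with the configured channel stats."""
        mean = np.asarray(self.config.input_mean, dtype=images.dtype)
        std = np.asarray(self.config.input_std, dtype=images.dtype)
        return (images - mean[None, :, None, None]) / std[None, :, None, None]

    def forward_stem(self, x):
        x = self.stem_conv.forward(x)
        x = self.stem_bn.forward(x)
        x = self.stem_relu.forward(x)
        return self.stem_pool.forward(x)

    def forward_features(self, x: np.ndarray) -> FeatureMapSet:
        """Run the stem and all stages; return the stage outputs F1..Fn."""
        if x.ndim != 4 or x.shape[1] != 3:
            raise GeometryError(f"expected NCHW RGB input, got {x.shape}")
        min_size = self.total_stride()
        if x.shape[2] < min_size or x.shape[3] < min_size:
            raise GeometryError(
                f"input {x.shape[2]}x{x.shape[3]} smaller than the deepest "
                f"stride {min_size}; no full-stride cell would remain")
        out = FeatureMapSet()
        h = self.forward_stem(x)
        stride = 4
        for level, blocks in enumerate(self.stages, start=1):
            for i, block in enumerate(blocks):
                h = block.forward(h)
                if i == 0:
                    stride *= self._entry_stride(block)
            out.maps[level] = h
            out.strides[level] = stride
        return out

    @staticmethod
    def _entry_stride(block: Bottleneck) -> int:
        return next(s.stride for s in block.conv_specs() if s.kernel == 3)

    def total_stride(self) -> int:
        stride = 4  # stem conv + max-pool
        for blocks in self.stages:
            stride *= self._entry_stride(blocks[0])
        return stride

    def backward_features(self, grads: dict[int, np.ndarray]) -> None:
        """Backpropagate per-level output gradients through stages and stem."""
        n_levels = len(self.stages)
        dh = None
        for level in range(n_levels, 0, -1):
            g = grads.get(level)
            if g is not None:
                dh = g if dh is None else dh + g
            if dh is None:
                continue
            for block in reversed(self.stages[level - 1]):
                dh = block.backward(dh)
        if dh is not None:
            dh = self.stem_pool.backward(dh)
            dh = self.stem_relu.backward(dh)
            dh = self.stem_bn.backward(dh)
            self.stem_conv.backward(dh)

    def forward_classify(self, x: np.ndarray) -> np.ndarray:
        """Class scores (logits, shape (N, n_classes)) for fixed-size crops."""
        expected = self.config.input_size
        if x.shape[2] != expected or x.shape[3] != expected:
            raise GeometryError(
                f"classifier expects {expected}x{expected} input, got "
                f"{x.shape[2]}x{x.shape[3]}")
        feats = self.forward_features(x)
        h = self.pool.forward(feats.maps[len(self.stages)])
        for i, (fc, drop) in enumerate(zip(self.fc, self.drops)):
            h = fc.forward(h)
            if i < len(self.relu_head):
                h = self.relu_head[i].forward(h)
            h = drop.forward(h)
        return h

    def backward_classify(self, dlogits: np.ndarray) -> None:
        dh = dlogits
        for i in range(len(self.fc) - 1, -1, -1):
            dh = self.drops[i].backward(dh)
            if i < len(self.relu_head):
                dh = self.relu_head[i].backward(dh)
            dh = self.fc[i].backward(dh)
        dh = self.pool.backward(dh)
        self.backward_features({len(self.stages): dh})

    # -- introspection ---------------------------------------------------

    def all_conv_layers(self):
        """(kind, Conv2d) pairs; kind in {stem, main, projection}."""
        yield "stem", self.stem_conv
        for blocks in self.stages:
            for block in blocks:
                for layer in block.main:
                    if isinstance(layer, nn.Conv2d):
                        yield "main", layer
                if block.shortcut:
                    yield "projection", block.shortcut.layers[0]


def count_conv_layers(backbone: DCResNet, *, include_stem: bool = True,
                      include_projections: bool = False,
                      head_as_single_layer: bool = True) -> int:
    """Layer count under the depth-naming convention.

    The default convention counts the stem convolution, every main-path
    convolution inside the residual blocks, and the classifier head as a
    single output layer; shortcut projection convolutions are excluded.
    Under these defaults the same rule names ResNet-50 "50" and ResNet-101
    "101", and reports 59 for the full stage plan here.
    """
    n = 0
    for kind, _ in backbone.all_conv_layers():
        if kind == "stem":
            n += 1 if include_stem else 0
        elif kind == "main":
            n += 1
        elif kind == "projection":
            n += 1 if include_projections else 0
    if head_as_single_layer:
        n += 1
    return n
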