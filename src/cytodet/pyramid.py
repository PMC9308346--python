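"""Feature-pyramid fusion: top-down upsample-and-add over selected levels.

Each selected backbone map gets a 1x1 lateral projection to a common
channel width; starting from the deepest selected level the running map is
upsampled (nearest-neighbour, identity when the sizes already agree — the
dilated stages keep stride 16) and added to the next shallower lateral.
A 3x3 smoothing convolution follows each merge by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .backbone import FeatureMapSet
from .nn.layers import GeometryError


class PyramidConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PyramidConfig:
    """Which backbone levels to fuse and at what width.

    ``selected_levels`` uses the F-list notation, e.g. (1, 2, 3, 4, 5) or
    (1, 2, 4, 5); at least two levels, ascending.
    """

    selected_levels: tuple[int, ...] = (1, 2, 3, 4, 5)
    out_channels: int = 256
    smooth: bool = True

    def __post_init__(self):
        lv = self.selected_levels
        if len(lv) < 2:
            raise PyramidConfigError("select at least two pyramid levels")
        if list(lv) != sorted(set(lv)):
            raise PyramidConfigError(
                f"levels must be strictly ascending, got {lv}")


def lateral_project(conv: nn.Conv2d, feature: np.ndarray) -> np.ndarray:
    """Apply a 1x1 lateral projection; spatial size is unchanged."""
    if conv.kernel_size != 1:
        raise PyramidConfigError("lateral projection must be a 1x1 conv")
    return conv.forward(feature)


def identity_lateral(channels: int, dtype=np.float32) -> nn.Conv2d:
    """A width-preserving lateral initialized to the exact identity."""
    conv = nn.Conv2d(channels, channels, 1, bias=False, dtype=dtype)
    conv.weight.data[...] = 0.0
    for c in range(channels):
        conv.weight.data[c, c, 0, 0] = 1.0
    return conv


def top_down_merge(deep: np.ndarray, shallow: np.ndarray) -> np.ndarray:
    """Upsample ``deep`` to ``shallow``'s spatial size and add.

    The shallow size must be an integer multiple of the deep size (equal
    sizes use the identity).  Channel widths must agree.
    """
    factor = _merge_factor(deep.shape, shallow.shape)
    return nn.upsample_nearest(deep, factor) + shallow


def _merge_factor(deep_shape, shallow_shape) -> int:
    if deep_shape[1] != shallow_shape[1]:
        raise GeometryError(
            f"channel mismatch in merge: {deep_shape[1]} vs {shallow_shape[1]}")
    fh, rh = divmod(shallow_shape[2], deep_shape[2])
    fw, rw = divmod(shallow_shape[3], deep_shape[3])
    if rh or rw or fh != fw or fh < 1:
        raise GeometryError(
            f"non-commensurate merge sizes {deep_shape[2:]} -> "
            f"{shallow_shape[2:]}")
    return fh


class FeaturePyramid(nn.Module):
    """Fusion network over a fixed set of backbone levels."""

    def __init__(self, in_channels: dict[int, int],
                 config: PyramidConfig | None = None, *,
                 rng: np.random.Generator | None = None, dtype=np.float32):
        super().__init__()
        self.config = config or PyramidConfig()
        missing = [l for l in self.config.selected_levels
                   if l not in in_channels]
        if missing:
            raise PyramidConfigError(
                f"selected levels {missing} absent from backbone maps")
        rng = rng or np.random.default_rng()
        c = self.config.out_channels
        self.laterals = {l: nn.Conv2d(in_channels[l], c, 1, rng=rng,
                                      dtype=dtype)
                         for l in self.config.selected_levels}
        self.smoothers = {l: nn.Conv2d(c, c, 3, padding=1, rng=rng,
                                       dtype=dtype)
                          for l in self.config.selected_levels} \
            if self.config.smooth else {}

    @property
    def levels(self) -> list[int]:
        return list(self.config.selected_levels)

    def forward(self, features: FeatureMapSet) -> dict[int, np.ndarray]:
        """Fused maps {level: array}, one per selected level; the map at
        level i keeps the spatial size of backbone map i."""
        levels = self.levels
        lat = {l: lateral_project(self.laterals[l], features.maps[l])
               for l in levels}
        merged: dict[int, np.ndarray] = {}
        self._factors: dict[int, int] = {}
        for idx in range(len(levels) - 1, -1, -1):
            l = levels[idx]
            if idx == len(levels) - 1:
                merged[l] = lat[l]
            else:
                deeper = levels[idx + 1]
                self._factors[l] = _merge_factor(merged[deeper].shape,
                                                 lat[l].shape)
                merged[l] = nn.upsample_nearest(
                    merged[deeper], self._factors[l]) + lat[l]
        if self.smoothers:
            return {l: self.smoothers[l].forward(merged[l]) for l in levels}
        return dict(merged)

    def backward(self, grads: dict[int, np.ndarray]) -> dict[int, np.ndarray]:
        """Propagate per-level output gradients back to the backbone maps.

        ``grads`` maps level -> gradient of that fused output (missing
        levels are treated as zero).  Must follow a ``forward`` call.
        Shallow levels feed gradient into deeper merged maps through the
        upsample adjoint, so levels are processed shallow-to-deep.
        """
        levels = self.levels
        dinput: dict[int, np.ndarray] = {}
        carry = None  # gradient flowing into the next deeper merged map
        for idx, l in enumerate(levels):
            g = grads.get(l)
            if g is not None and self.smoothers:
                g = self.smoothers[l].backward(g)
            if g is None:
                total = carry
            elif carry is None:
                total = g
            else:
                total = g + carry
            if total is None:  # no signal reaches this shallow level
                _, x_shape, _, ho, wo = self.laterals[l]._cache
                total = np.zeros(
                    (x_shape[0], self.config.out_channels, ho, wo),
                    dtype=self.laterals[l].weight.data.dtype)
            dinput[l] = self.laterals[l].backward(total)
            if idx < len(levels) - 1:
                carry = nn.upsample_nearest_backward(total, self._factors[l])
        return dinput
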