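"""Coordinate attention (CA) and feature coordinate attention (FCA).

Coordinate attention pools the feature map separately along height and width,
so the resulting gates keep positional information in each direction: the two
directional profiles are concatenated, squeezed through a shared 1x1
reduction (ratio ``r``), then expanded back per direction and passed through
a sigmoid. The input is reweighted by both directional gate maps.

FCA aggregates CA-gated features taken at several network depths: each tap is
globally average-pooled to a vector, linearly projected to a common width,
and fused (sum by default, concatenation optionally) into the feature the
classifier sees.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat
from .nn import BatchNorm2d, Conv2d, Linear, Module

__all__ = [
    "CoordAtt",
    "FeatureCoordAtt",
    "channel_global_pool",
    "directional_pools",
    "coordatt_forward",
    "fca_forward",
]


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def channel_global_pool(x) -> Tensor:
    """Average each channel over its full spatial extent: (N,C,H,W) -> (N,C)."""
    x = _as_tensor(x)
    if x.ndim != 4:
        raise ValueError(f"expected a rank-4 input, got shape {x.shape}")
    if x.shape[2] < 1 or x.shape[3] < 1:
        raise ValueError(f"empty spatial extent in shape {x.shape}")
    return x.mean(axis=(2, 3))


def directional_pools(x) -> tuple[Tensor, Tensor]:
    """Height profile (N,C,H,1) and width profile (N,C,1,W) of the input."""
    x = _as_tensor(x)
    if x.ndim != 4:
        raise ValueError(f"expected a rank-4 input, got shape {x.shape}")
    h_profile = x.mean(axis=3, keepdims=True)   # pool over width
    w_profile = x.mean(axis=2, keepdims=True)   # pool over height
    return h_profile, w_profile


class CoordAtt(Module):
    """Coordinate-attention gate with channel-reduction parameter ``r``."""

    def __init__(self, channels: int, r: int = 8, bn_after_reduce: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        reduced = channels // r
        if reduced < 1:
            raise ValueError(
                f"channel reduction {channels}//{r} is zero; lower r"
            )
        rng = rng or np.random.default_rng()
        self.channels, self.r, self.reduced = channels, r, reduced
        self.reduce = Conv2d(channels, reduced, 1, bias=True, rng=rng)
        self.bn = BatchNorm2d(reduced) if bn_after_reduce else None
        self.expand_h = Conv2d(reduced, channels, 1, bias=True, rng=rng)
        self.expand_w = Conv2d(reduced, channels, 1, bias=True, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return coordatt_forward(x, self)

    def _summary(self, in_shape):
        c, h, w = in_shape
        red = self.reduced
        params = (c * red + red) + 2 * (red * c + c)
        if self.bn is not None:
            params += 2 * red
        macs = (h + w) * red * c + h * c * red + w * c * red
        return [("", f"CoordAtt r={self.r}", params, macs, in_shape)], in_shape


def coordatt_forward(x, p: CoordAtt) -> Tensor:
    """Gate ``x`` by its two directional attention maps; shape is preserved."""
    x = _as_tensor(x)
    if x.shape[1] != p.channels:
        raise ValueError(
            f"channel mismatch: input has {x.shape[1]} channels, "
            f"CA block expects {p.channels}"
        )
    n, c, h, w = x.shape
    h_profile, w_profile = directional_pools(x)
    # stack both profiles along one spatial axis: (N, C, H+W, 1)
    stacked = concat([h_profile, w_profile.transpose(0, 1, 3, 2)], axis=2)
    y = p.reduce(stacked)
    if p.bn is not None:
        y = p.bn(y)
    y = y.relu()
    gate_h = p.expand_h(y[:, :, :h, :]).sigmoid()                      # N,C,H,1
    gate_w = p.expand_w(y[:, :, h:, :]).sigmoid().transpose(0, 1, 3, 2)  # N,C,1,W
    return x * gate_h * gate_w


class FeatureCoordAtt(Module):
    """Fuses pooled CA taps from several depths into one feature vector.

    ``stage_channels`` lists the channel width of each tapped feature map; a
    ``None`` projection entry means the tap is used as-is (identity), which
    requires its width to equal ``out_features`` in ``sum`` mode.
    """

    def __init__(self, stage_channels: list[int], out_features: int,
                 fusion: str = "sum", identity: list[bool] | None = None,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if fusion not in ("sum", "concat"):
            raise ValueError(f"unknown fusion mode {fusion!r}")
        rng = rng or np.random.default_rng()
        identity = identity or [False] * len(stage_channels)
        self.stage_channels = list(stage_channels)
        self.out_features, self.fusion = out_features, fusion
        self.projections: list[Linear | None] = []
        for i, (c, ident) in enumerate(zip(stage_channels, identity)):
            if ident:
                if fusion == "sum" and c != out_features:
                    raise ValueError(
                        f"identity projection of width {c} cannot be summed "
                        f"into width {out_features}"
                    )
                self.projections.append(None)
            else:
                proj = Linear(c, out_features, rng=rng)
                self.register(f"proj{i}", proj)
                self.projections.append(proj)

    @property
    def fused_width(self) -> int:
        if self.fusion == "sum":
            return self.out_features
        return sum(self.out_features if p is not None else c
                   for p, c in zip(self.projections, self.stage_channels))

    def forward(self, stage_features: list) -> Tensor:
        return fca_forward(stage_features, self)

    def _summary(self, in_shape=None):
        params = sum(p.in_features * p.out_features + p.out_features
                     for p in self.projections if p is not None)
        macs = sum(p.in_features * p.out_features
                   for p in self.projections if p is not None)
        shape = (self.fused_width,)
        return [("", f"FCA fusion={self.fusion}", params, macs, shape)], shape


def fca_forward(stage_features: list, p: FeatureCoordAtt) -> Tensor:
    """Pool each tapped stage to 1x1, project, and fuse into (N, D)."""
    if not stage_features:
        raise ValueError("need at least one stage feature")
    if len(stage_features) != len(p.projections):
        raise ValueError(
            f"got {len(stage_features)} stage features but "
            f"{len(p.projections)} projections"
        )
    vecs = []
    for feat, proj, c in zip(stage_features, p.projections, p.stage_channels):
        feat = _as_tensor(feat)
        v = channel_global_pool(feat) if feat.ndim == 4 else feat
        if v.shape[1] != c:
            raise ValueError(
                f"stage width {v.shape[1]} does not match configured width {c}"
            )
        vecs.append(proj(v) if proj is not None else v)
    if p.fusion == "concat":
        return concat(vecs, axis=1)
    out = vecs[0]
    for v in vecs[1:]:
        out = out + v
    return out
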