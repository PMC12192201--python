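"""PatchNet: per-patch 3D CNN feature extractor with spatial attention.

Four 3x3x3 convolutional layers (batch-norm + ReLU after each) with a 2x2x2
max-pool between the second and third adjust a W-cube patch down to
C x w x w x w feature maps (w = floor(W/2)).  A spatial attention block then
pools the maps across channels (max and average), passes the concatenated
pair through a 2->1 channel 3x3x3 convolution and a sigmoid, and rescales
every channel voxel-wise.  A second branch turns the attended maps into a
scalar effect score — the patch's capacity to activate the bag label — via
global average pooling and a linear map.

Channel counts, kernel size and the effect-head form are architecture
hyperparameters; defaults are 32-64-128-128.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _engine as eng
from ._engine import Tensor
from .volio import Patch, ValidationError

__all__ = [
    "PatchFeatures",
    "SpatialAttentionMap",
    "EffectScore",
    "channel_max_pool",
    "channel_avg_pool",
    "spatial_attention",
    "apply_spatial_attention",
    "SpatialAttention",
    "PatchNet",
    "patchnet_forward",
]


@dataclass
class PatchFeatures:
    """C feature channels over a w-cube spatial grid."""

    maps: np.ndarray  # (C, w, w, w)

    def __post_init__(self):
        self.maps = np.asarray(self.maps)
        if self.maps.ndim != 4 or self.maps.shape[0] < 1:
            raise ValidationError(
                f"feature maps must be (C, w, w, w) with C >= 1, got {self.maps.shape}"
            )
        if not np.all(np.isfinite(self.maps)):
            raise ValidationError("feature maps contain non-finite values")

    @property
    def C(self) -> int:
        return self.maps.shape[0]

    @property
    def w(self) -> int:
        return self.maps.shape[1]


@dataclass
class SpatialAttentionMap:
    """Sigmoid-range spatial weights over a w-cube."""

    values: np.ndarray  # (w, w, w), all in (0, 1)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.all((self.values > 0) & (self.values < 1)):
            raise ValidationError("spatial attention values must lie strictly in (0, 1)")


@dataclass
class EffectScore:
    value: float

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValidationError("effect score must be finite")


# ---------------------------------------------------------------------------
# functional ops (numpy arrays in, numpy arrays out)


def channel_max_pool(F: PatchFeatures | np.ndarray) -> np.ndarray:
    """Voxel-wise maximum across channels -> (w, w, w)."""
    maps = F.maps if isinstance(F, PatchFeatures) else np.asarray(F)
    return maps.max(axis=0)


def channel_avg_pool(F: PatchFeatures | np.ndarray) -> np.ndarray:
    """Voxel-wise mean across channels -> (w, w, w)."""
    maps = F.maps if isinstance(F, PatchFeatures) else np.asarray(F)
    return maps.mean(axis=0)


def spatial_attention(
    F: PatchFeatures | np.ndarray, module: "SpatialAttention"
) -> SpatialAttentionMap:
    """sigma(Conv([F_max; F_avg])) with the module's 2->1 channel conv."""
    maps = F.maps if isinstance(F, PatchFeatures) else np.asarray(F)
    x = Tensor(maps[None])  # (1, C, w, w, w)
    return SpatialAttentionMap(module(x).data[0, 0])


def apply_spatial_attention(
    F: PatchFeatures | np.ndarray, A: SpatialAttentionMap | np.ndarray
) -> PatchFeatures:
    """Multiply every channel voxel-wise by the attention map."""
    maps = F.maps if isinstance(F, PatchFeatures) else np.asarray(F)
    values = A.values if isinstance(A, SpatialAttentionMap) else np.asarray(A)
    if maps.shape[1:] != values.shape:
        raise ValidationError(
            f"attention shape {values.shape} does not match features {maps.shape[1:]}"
        )
    return PatchFeatures(maps * values[None])


# ---------------------------------------------------------------------------
# trainable modules


class SpatialAttention(eng.Module):
    """Channel max/avg pooling -> concat -> 3x3x3 conv (2->1) -> sigmoid."""

    def __init__(self, rng: np.random.Generator | None = None, dtype=np.float64):
        super().__init__()
        self.conv = eng.Conv3d(2, 1, kernel=3, pad=1, rng=rng, dtype=dtype)

    def __call__(self, F: Tensor) -> Tensor:
        """F: (N, C, w, w, w) -> attention (N, 1, w, w, w) in (0, 1)."""
        if F.ndim != 5:
            raise ValidationError(f"expected (N, C, w, w, w) features, got {F.shape}")
        f_max = F.max(axis=1, keepdims=True)
        f_avg = F.mean(axis=1, keepdims=True)
        cat = eng.concatenate([f_max, f_avg], axis=1)
        return eng.conv3d(cat, self.conv.weight, self.conv.bias, pad=1).sigmoid()


class PatchNet(eng.Module):
    """The instance-level transform f of the bag classifier g(phi(f(X)))."""

    def __init__(
        self,
        patch_width: int,
        channels: tuple[int, int, int, int] = (32, 64, 128, 128),
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ):
        super().__init__()
        if patch_width < 2:
            raise ValidationError(
                f"patch width {patch_width} too small for the 2x2x2 pooling stage"
            )
        rng = rng or np.random.default_rng(0)
        c1, c2, c3, c4 = channels
        self.patch_width = patch_width
        self.channels = tuple(channels)
        self.feature_width = patch_width // 2
        self.conv1 = eng.Conv3d(1, c1, rng=rng, dtype=dtype)
        self.bn1 = eng.BatchNorm3d(c1, dtype=dtype)
        self.conv2 = eng.Conv3d(c1, c2, rng=rng, dtype=dtype)
        self.bn2 = eng.BatchNorm3d(c2, dtype=dtype)
        self.conv3 = eng.Conv3d(c2, c3, rng=rng, dtype=dtype)
        self.bn3 = eng.BatchNorm3d(c3, dtype=dtype)
        self.conv4 = eng.Conv3d(c3, c4, rng=rng, dtype=dtype)
        self.bn4 = eng.BatchNorm3d(c4, dtype=dtype)
        self.attention = SpatialAttention(rng=rng, dtype=dtype)
        # zero-init: effect scores start at 0 so patch attention gates open
        # at exactly sigmoid(0) = 0.5 and training sets their direction
        self.effect_head = eng.Linear(c4, 1, rng=rng, dtype=dtype)
        self.effect_head.weight.data[:] = 0

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """x: (N, 1, W, W, W) patches -> attended maps (N, C4, w, w, w), effect (N,).

        Layer order is conv -> batch-norm -> ReLU; the max-pool sits between
        conv2 and conv3.
        """
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h)).relu()
        h = eng.maxpool3d(h)
        h = self.bn3(self.conv3(h)).relu()
        F = self.bn4(self.conv4(h)).relu()
        A = self.attention(F)
        F_att = F * A  # broadcast over channels
        gap = F_att.mean(axis=(2, 3, 4))  # (N, C4)
        effect = self.effect_head(gap).reshape(-1)
        return F_att, effect


def patchnet_forward(p: Patch, net: PatchNet) -> tuple[PatchFeatures, EffectScore]:
    """Run one patch through a PatchNet in inference mode.

    Deterministic given the network's parameters: normalisation layers use
    their running statistics.
    """
    if p.data.shape != (net.patch_width,) * 3:
        raise ValidationError(
            f"patch shape {p.data.shape} does not match configured width "
            f"{net.patch_width}"
        )
    was_training = net.training
    net.eval()
    try:
        x = Tensor(np.asarray(p.data, dtype=net.conv1.weight.data.dtype)[None, None])
        F_att, effect = net(x)
    finally:
        if was_training:
            net.train()
    return PatchFeatures(F_att.data[0]), EffectScore(float(effect.data[0]))
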