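"""Attention MIL pooling (A-MIDL).

Each patch's C feature channels are compressed to a single w-cube map by
channel-average pooling and stacked into a bag-level global feature with one
map per patch.  Global average and global max pooling reduce each map to a
scalar descriptor; a shared two-layer 1x1x1 conv stack (a per-patch MLP —
no cross-patch mixing, so the pooling is permutation-equivariant) turns the
two descriptor vectors into pre-sigmoid attention vectors A_average and
A_max.  These are summed with the effect vector a and squashed:

    A_patch = sigmoid(A_average + A_max + a)

and the global feature's maps are rescaled patch-wise by A_patch.  The
attention map doubles as an interpretability output: high-weight patches
mark candidate problematic sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _engine as eng
from ._engine import Tensor
from .patchnet import PatchFeatures
from .volio import PatchCoord, ValidationError

__all__ = [
    "GlobalFeature",
    "PatchAttentionMap",
    "compress_and_stack",
    "fuse_attention",
    "apply_patch_attention",
    "DescriptorAttention",
    "AMIDLPooling",
    "descriptor_attention",
    "amidl_pool",
    "export_attention_csv",
]


@dataclass
class GlobalFeature:
    """One compressed w-cube map per patch, stacked in bag order."""

    maps: np.ndarray  # (k, w, w, w)

    def __post_init__(self):
        self.maps = np.asarray(self.maps)
        if self.maps.ndim != 4:
            raise ValidationError(f"global feature must be (k, w, w, w), got {self.maps.shape}")
        if not np.all(np.isfinite(self.maps)):
            raise ValidationError("global feature contains non-finite values")

    @property
    def k(self) -> int:
        return self.maps.shape[0]


@dataclass
class PatchAttentionMap:
    """Per-patch attention weights in (0, 1), plus the fused components."""

    weights: np.ndarray  # (k,)
    a_average: np.ndarray = field(default=None, repr=False)
    a_max: np.ndarray = field(default=None, repr=False)
    effect: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValidationError("attention weights must be a vector")
        if not np.all((self.weights > 0) & (self.weights < 1)):
            raise ValidationError("attention weights must lie strictly in (0, 1)")

    @property
    def k(self) -> int:
        return len(self.weights)


# ---------------------------------------------------------------------------
# functional ops


def compress_and_stack(features: list[PatchFeatures | np.ndarray]) -> GlobalFeature:
    """Channel-average each patch's maps to one w-cube; stack in bag order."""
    if len(features) < 1:
        raise ValidationError("need at least one patch")
    maps = [f.maps if isinstance(f, PatchFeatures) else np.asarray(f) for f in features]
    shapes = {m.shape for m in maps}
    if len(shapes) != 1:
        raise ValidationError(f"patches must share (C, w, w, w) shape, got {sorted(shapes)}")
    return GlobalFeature(np.stack([m.mean(axis=0) for m in maps]))


def fuse_attention(
    a_average: np.ndarray, a_max: np.ndarray, effect: np.ndarray
) -> PatchAttentionMap:
    """sigmoid(A_average + A_max + a), element-wise over the k patches."""
    a_average = np.asarray(a_average, dtype=float)
    a_max = np.asarray(a_max, dtype=float)
    effect = np.asarray(effect, dtype=float)
    if not (a_average.shape == a_max.shape == effect.shape):
        raise ValidationError(
            f"attention component lengths differ: {a_average.shape}, "
            f"{a_max.shape}, {effect.shape}"
        )
    s = a_average + a_max + effect
    # sigmoid saturates to exactly 0/1 in floating point for |s| > ~37;
    # nudge into the open interval the mathematical sigmoid maps to
    w = np.clip(1.0 / (1.0 + np.exp(-s)), np.nextafter(0.0, 1.0), np.nextafter(1.0, 0.0))
    return PatchAttentionMap(w, a_average=a_average, a_max=a_max, effect=effect)


def apply_patch_attention(G: GlobalFeature, A: PatchAttentionMap) -> GlobalFeature:
    """Scale patch i's compressed map by weight_i."""
    if G.k != A.k:
        raise ValidationError(f"bag sizes differ: {G.k} maps vs {A.k} weights")
    return GlobalFeature(G.maps * A.weights[:, None, None, None])


# ---------------------------------------------------------------------------
# trainable modules


class DescriptorAttention(eng.Module):
    """Shared per-patch two-layer MLP over GAP/GMP scalar descriptors.

    Each patch's descriptor scalar passes independently through
    linear(1 -> hidden) -> ReLU -> linear(hidden -> 1); by default the GAP
    and GMP paths share the weights (set ``shared=False`` for separate
    stacks).  Per-patch application keeps the pooling permutation-
    equivariant.
    """

    def __init__(
        self,
        hidden: int = 4,
        shared: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.hidden = hidden
        self.shared = shared
        self.fc0 = eng.Linear(1, hidden, rng=rng, dtype=dtype)
        self.fc1 = eng.Linear(hidden, 1, rng=rng, dtype=dtype)
        # zero-init the output layer: descriptor attention starts neutral
        # (weights exactly 0.5 through the sigmoid) and learns a direction
        self.fc1.weight.data[:] = 0
        if not shared:
            self.fc0_max = eng.Linear(1, hidden, rng=rng, dtype=dtype)
            self.fc1_max = eng.Linear(hidden, 1, rng=rng, dtype=dtype)
            self.fc1_max.weight.data[:] = 0

    def _mlp(self, x: Tensor, for_max: bool) -> Tensor:
        if self.shared or not for_max:
            fc0, fc1 = self.fc0, self.fc1
        else:
            fc0, fc1 = self.fc0_max, self.fc1_max
        return fc1(fc0(x).relu())

    def __call__(self, G: Tensor) -> tuple[Tensor, Tensor]:
        """G: (k, w, w, w) -> pre-sigmoid attention vectors (k,), (k,)."""
        gap = G.mean(axis=(1, 2, 3)).reshape(-1, 1)  # (k, 1)
        gmp = G.reshape(G.shape[0], -1).max(axis=1, keepdims=True)  # (k, 1)
        a_avg = self._mlp(gap, for_max=False).reshape(-1)
        a_max = self._mlp(gmp, for_max=True).reshape(-1)
        return a_avg, a_max


class AMIDLPooling(eng.Module):
    """compress -> descriptor attention -> fuse with effect -> rescale."""

    def __init__(
        self,
        hidden: int = 4,
        shared_descriptor_mlp: bool = True,
        rng: np.random.Generator | None = None,
        dtype=np.float64,
    ):
        super().__init__()
        self.descriptor = DescriptorAttention(
            hidden=hidden, shared=shared_descriptor_mlp, rng=rng, dtype=dtype
        )

    def __call__(self, features: Tensor, effect: Tensor) -> tuple[Tensor, Tensor]:
        """features: (k, C, w, w, w); effect: (k,) -> weighted (k, w, w, w), weights (k,)."""
        G = features.mean(axis=1)  # (k, w, w, w) compressed maps
        a_avg, a_max = self.descriptor(G)
        weights = (a_avg + a_max + effect).sigmoid()  # (k,)
        weighted = G * weights.reshape(-1, 1, 1, 1)
        return weighted, weights


def descriptor_attention(
    G: GlobalFeature, module: DescriptorAttention
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-sigmoid A_average and A_max vectors for a compressed global feature."""
    a_avg, a_max = module(Tensor(G.maps))
    return a_avg.data.copy(), a_max.data.copy()


def amidl_pool(
    features: list[PatchFeatures | np.ndarray],
    effect: np.ndarray,
    module: AMIDLPooling,
) -> tuple[GlobalFeature, PatchAttentionMap]:
    """Full pooling composition on numpy inputs (inference mode)."""
    effect = np.asarray(effect, dtype=float)
    if len(features) != len(effect):
        raise ValidationError(
            f"bag size mismatch: {len(features)} patches vs {len(effect)} effect scores"
        )
    G = compress_and_stack(features)
    a_avg, a_max = descriptor_attention(G, module.descriptor)
    A = fuse_attention(a_avg, a_max, effect)
    return apply_patch_attention(G, A), A


def export_attention_csv(
    path: str | Path, coords: list[PatchCoord], A: PatchAttentionMap
) -> Path:
    """Write per-patch attention as ``rank,ox,oy,oz,weight`` (rank = bag order)."""
    df = pd.DataFrame(
        {
            "rank": np.arange(A.k),
            "ox": [c.origin[0] for c in coords],
            "oy": [c.origin[1] for c in coords],
            "oz": [c.origin[2] for c in coords],
            "weight": A.weights,
        }
    )
    df.to_csv(path, index=False)
    return Path(path)
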