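"""Discriminative patch location proposal from a group-difference p-value map.

The volume is partitioned into non-overlapping W-cubes; at each location a
two-sample Welch t-test compares the two groups, p-values are min-max
normalised over the map, and the k lowest-scoring locations define the bag
layout shared by every subject.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .volio import (
    Patch,
    PatchCoord,
    ValidationError,
    Volume3D,
    extract_patch,
    partition_volume,
)

__all__ = [
    "PValueMap",
    "BagSpec",
    "PatchBag",
    "group_ttest_map",
    "normalize_pvalues",
    "select_bag_locations",
    "build_bag",
]

logger = logging.getLogger(__name__)


@dataclass
class PValueMap:
    """Per-location raw and min-max-normalised two-sided p-values."""

    coords: list[PatchCoord]
    p_raw: np.ndarray
    p_norm: np.ndarray
    width: int
    group_sizes: tuple[int, int]

    def __post_init__(self):
        self.p_raw = np.asarray(self.p_raw, dtype=float)
        self.p_norm = np.asarray(self.p_norm, dtype=float)
        if not (len(self.coords) == len(self.p_raw) == len(self.p_norm)):
            raise ValidationError("coords and p-value arrays must have equal length")
        if np.any((self.p_raw < 0) | (self.p_raw > 1)):
            raise ValidationError("raw p-values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.coords)

    def __getitem__(self, coord: PatchCoord) -> tuple[float, float]:
        i = self.coords.index(coord)
        return float(self.p_raw[i]), float(self.p_norm[i])

    def to_csv(self, path: str | Path) -> Path:
        df = pd.DataFrame(
            {
                "ox": [c.origin[0] for c in self.coords],
                "oy": [c.origin[1] for c in self.coords],
                "oz": [c.origin[2] for c in self.coords],
                "W": self.width,
                "p_raw": self.p_raw,
                "p_norm": self.p_norm,
            }
        )
        df.to_csv(path, index=False)
        return Path(path)

    @classmethod
    def from_csv(cls, path: str | Path, group_sizes=(0, 0)) -> "PValueMap":
        df = pd.read_csv(path)
        width = int(df["W"].iloc[0])
        coords = [
            PatchCoord((int(r.ox), int(r.oy), int(r.oz)), width)
            for r in df.itertuples()
        ]
        return cls(coords, df["p_raw"].to_numpy(), df["p_norm"].to_numpy(),
                   width, tuple(group_sizes))


@dataclass
class BagSpec:
    """Ordered bag layout: the k locations every subject's bag is built from."""

    coords: list[PatchCoord]
    width: int

    def __post_init__(self):
        if len(self.coords) < 1:
            raise ValidationError("a bag needs at least one location")
        if len(set(self.coords)) != len(self.coords):
            raise ValidationError("bag locations must be pairwise distinct")

    @property
    def k(self) -> int:
        return len(self.coords)

    def to_csv(self, path: str | Path) -> Path:
        df = pd.DataFrame(
            {
                "ox": [c.origin[0] for c in self.coords],
                "oy": [c.origin[1] for c in self.coords],
                "oz": [c.origin[2] for c in self.coords],
                "W": self.width,
                "rank": np.arange(len(self.coords)),
            }
        )
        df.to_csv(path, index=False)
        return Path(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BagSpec":
        df = pd.read_csv(path).sort_values("rank")
        width = int(df["W"].iloc[0])
        coords = [
            PatchCoord((int(r.ox), int(r.oy), int(r.oz)), width)
            for r in df.itertuples()
        ]
        return cls(coords, width)


@dataclass
class PatchBag:
    """A subject's MIL bag: k same-width patches plus one bag label."""

    patches: list[Patch] = field(repr=False)
    coords: list[PatchCoord] = field(default_factory=list)
    label: int | None = None
    subject_id: str = ""

    def __post_init__(self):
        if not self.coords:
            self.coords = [p.coord for p in self.patches]

    @property
    def k(self) -> int:
        return len(self.patches)

    def stacked(self, dtype=np.float64) -> np.ndarray:
        """(k, W, W, W) array of the bag's patch intensities."""
        return np.stack([p.data for p in self.patches]).astype(dtype)


def _patch_summaries(
    volumes: list[Volume3D], coords: list[PatchCoord], voxelwise: bool
) -> np.ndarray:
    """Per-subject, per-location summary: patch mean or full voxel block."""
    w = coords[0].width
    if voxelwise:
        out = np.empty((len(volumes), len(coords), w**3))
        for i, v in enumerate(volumes):
            for j, c in enumerate(coords):
                out[i, j] = extract_patch(v, c).data.reshape(-1)
        return out
    out = np.empty((len(volumes), len(coords)))
    for i, v in enumerate(volumes):
        for j, c in enumerate(coords):
            out[i, j] = extract_patch(v, c).data.mean()
    return out


def group_ttest_map(
    group_a: list[Volume3D],
    group_b: list[Volume3D],
    width: int,
    statistic: str = "patch_mean",
) -> PValueMap:
    """Welch two-sample t-test at every patch location.

    ``statistic="patch_mean"`` tests the per-subject mean intensity inside
    each cube (group evaluation on patch-level structure).
    ``statistic="voxelwise"`` instead tests every voxel and scores the
    location by the mean voxel p-value.  Locations where both groups have
    zero variance get p = 1 with a logged warning.  Normalised scores are
    filled in by :func:`normalize_pvalues`.
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("need at least 2 volumes per group")
    shapes = {v.shape for v in group_a + group_b}
    if len(shapes) != 1:
        raise ValidationError(f"volumes must share one shape, got {sorted(shapes)}")
    if statistic not in ("patch_mean", "voxelwise"):
        raise ValidationError(f"unknown test statistic {statistic!r}")

    coords = partition_volume(group_a[0], width)
    voxelwise = statistic == "voxelwise"
    sa = _patch_summaries(group_a, coords, voxelwise)
    sb = _patch_summaries(group_b, coords, voxelwise)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # scipy warns on zero-variance slices
        res = stats.ttest_ind(sa, sb, axis=0, equal_var=False)
    pvals = np.asarray(res.pvalue)

    degenerate = (sa.var(axis=0) == 0) & (sb.var(axis=0) == 0)
    if np.any(degenerate):
        logger.warning(
            "zero within-group variance in both groups at %d location(s)/voxel(s); "
            "p-value set to 1 there",
            int(degenerate.sum()),
        )
    pvals = np.where(degenerate, 1.0, pvals)
    pvals = np.nan_to_num(pvals, nan=1.0)
    if voxelwise:
        pvals = pvals.mean(axis=-1)

    m = PValueMap(coords, pvals, np.zeros_like(pvals), width,
                  (len(group_a), len(group_b)))
    return normalize_pvalues(m)


def normalize_pvalues(m: PValueMap) -> PValueMap:
    """Min-max normalise raw p-values: (p - MIN) / (MAX - MIN).

    If all raw values coincide the normalised scores are defined as 0.
    """
    if len(m) < 1:
        raise ValidationError("p-value map is empty")
    lo, hi = float(m.p_raw.min()), float(m.p_raw.max())
    if hi == lo:
        norm = np.zeros_like(m.p_raw)
    else:
        norm = (m.p_raw - lo) / (hi - lo)
    return PValueMap(list(m.coords), m.p_raw.copy(), norm, m.width, m.group_sizes)


def select_bag_locations(m: PValueMap, k: int) -> BagSpec:
    """The k most discriminative locations: smallest normalised score first.

    Ties are broken by lexicographic coordinate order, so the selection is
    invariant to the insertion order of the map's entries.
    """
    if k < 1:
        raise ValidationError(f"bag size must be >= 1, got {k}")
    if k > len(m):
        raise ValidationError(f"bag size {k} exceeds map size {len(m)}")
    order = sorted(range(len(m)), key=lambda i: (m.p_norm[i], m.coords[i]))
    return BagSpec([m.coords[i] for i in order[:k]], m.width)


def build_bag(v: Volume3D, spec: BagSpec) -> PatchBag:
    """Extract a subject's bag in the spec's fixed patch order.

    The order is identical across subjects, which downstream attention
    fusion relies on to align effect vectors with patch positions.
    """
    patches = [extract_patch(v, c) for c in spec.coords]
    return PatchBag(patches=patches, coords=list(spec.coords),
                    subject_id=v.subject_id)
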