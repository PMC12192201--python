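"""Synthetic two-group 3D cohorts with known discriminative lesion cubes.

Every subject shares one smooth low-frequency base volume (a Gaussian-blurred
random field standing in for common anatomy); subject-specific i.i.d. voxel
noise is added on top, and group-1 ("disease") subjects have their mean
intensity shifted inside each lesion cube by ``effect_size * noise_sd`` —
negative by default, mimicking atrophy-driven signal loss.  The lesion
coordinates are returned as ground truth so patch proposal and attention can
be scored against them.

The generator emulates the group-contrast structure of registered,
skull-stripped cohorts, not brain anatomy itself: there are no bias fields,
registration errors or anatomical boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volio import PatchCoord, ValidationError, Volume3D, write_volume

__all__ = ["SyntheticConfig", "generate_cohort", "write_cohort"]


@dataclass
class SyntheticConfig:
    """Desk-scale defaults: 48-cubes, one 12-cube lesion, 60 subjects/group.

    ``effect_size`` is the standardised per-voxel mean difference d (shift =
    d * noise_sd); 1.5 corresponds to a strong focal contrast against unit
    voxel noise.  ``smoothness`` is the Gaussian blur sigma (voxels) of the
    shared base field.  ``lesion_sign`` -1 lowers intensity in the disease
    group (atrophy-like); +1 raises it.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    n_per_group: int = 60
    lesion_regions: list[PatchCoord] = field(
        default_factory=lambda: [PatchCoord((24, 24, 24), 12)]
    )
    effect_size: float = 1.5
    noise_sd: float = 1.0
    smoothness: float = 6.0
    lesion_sign: int = -1
    seed: int = 0

    def __post_init__(self):
        if self.effect_size < 0:
            raise ValidationError("effect size must be >= 0")
        if self.n_per_group < 2:
            raise ValidationError("need at least 2 subjects per group")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        for c in self.lesion_regions:
            c.validate_against(self.shape)


def generate_cohort(
    cfg: SyntheticConfig,
) -> tuple[list[Volume3D], np.ndarray, list[PatchCoord]]:
    """Return (volumes, labels, ground-truth lesion coords), seed-reproducible.

    Subjects 0..n-1 are controls (label 0), n..2n-1 carry the lesion shift
    (label 1).
    """
    rng = np.random.default_rng(cfg.seed)
    base = rng.standard_normal(cfg.shape)
    if cfg.smoothness > 0:
        base = gaussian_filter(base, cfg.smoothness)
        sd = base.std()
        if sd > 0:  # keep the anatomy proxy at unit scale after blurring
            base = base / sd

    shift = np.zeros(cfg.shape)
    for c in cfg.lesion_regions:
        (x, y, z), w = c.origin, c.width
        shift[x:x + w, y:y + w, z:z + w] = (
            cfg.lesion_sign * cfg.effect_size * cfg.noise_sd
        )

    volumes: list[Volume3D] = []
    labels = np.concatenate(
        [np.zeros(cfg.n_per_group, dtype=int), np.ones(cfg.n_per_group, dtype=int)]
    )
    for i, label in enumerate(labels):
        data = base + rng.standard_normal(cfg.shape) * cfg.noise_sd
        if label == 1:
            data = data + shift
        volumes.append(Volume3D(data=data, subject_id=f"sub-{i:03d}"))
    return volumes, labels, list(cfg.lesion_regions)


def write_cohort(
    volumes: list[Volume3D],
    labels: np.ndarray,
    out_dir: str | Path,
    ground_truth: list[PatchCoord] | None = None,
) -> Path:
    """Write NIfTI volumes plus a ``subject_id,path,label`` manifest.

    Returns the manifest path; ground-truth lesion coords (if given) go to
    ``ground_truth.csv`` alongside.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for v, label in zip(volumes, labels):
        path = out_dir / f"{v.subject_id}.nii.gz"
        try:
            write_volume(v, path)
        except OSError as e:
            raise OSError(f"failed writing {path}: {e}") from e
        rows.append({"subject_id": v.subject_id, "path": str(path), "label": int(label)})
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    if ground_truth is not None:
        pd.DataFrame(
            {
                "ox": [c.origin[0] for c in ground_truth],
                "oy": [c.origin[1] for c in ground_truth],
                "oz": [c.origin[2] for c in ground_truth],
                "W": [c.width for c in ground_truth],
            }
        ).to_csv(out_dir / "ground_truth.csv", index=False)
    return manifest
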