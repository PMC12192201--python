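"""Volumetric image I/O and deterministic cubic patch partitioning.

Volumes are handled in file-native axis order: cohorts are assumed to be
co-registered upstream, so within-study consistency is what matters, not a
canonical anatomical frame.  Patch coordinates are 0-based voxel indices and
patches are half-open cubes ``[origin, origin + width)`` on every axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ValidationError",
    "Volume3D",
    "PatchCoord",
    "Patch",
    "read_volume",
    "write_volume",
    "partition_volume",
    "extract_patch",
]


class ValidationError(ValueError):
    """An input violated a documented contract."""


@dataclass
class Volume3D:
    """A 3D voxel grid with spacing metadata.

    The canonical template space for registered brain scans is
    181 x 217 x 181 voxels, but any positive shape is accepted.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    subject_id: str = ""

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValidationError(
                f"volume data must be 3D, got {self.data.ndim} dimensions"
            )
        if any(s < 1 for s in self.data.shape):
            raise ValidationError(f"all dimensions must be >= 1, got {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("volume data contains NaN or Inf voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass(frozen=True, order=True)
class PatchCoord:
    """Corner voxel index and cube width of one patch location."""

    origin: tuple[int, int, int]
    width: int

    def __post_init__(self):
        if any(o < 0 for o in self.origin):
            raise ValidationError(f"origin components must be >= 0, got {self.origin}")
        if self.width < 1:
            raise ValidationError(f"patch width must be >= 1, got {self.width}")

    def validate_against(self, shape: tuple[int, int, int]) -> None:
        for o, s in zip(self.origin, shape):
            if o + self.width > s:
                raise ValidationError(
                    f"patch at {self.origin} with width {self.width} "
                    f"exceeds volume shape {shape}"
                )


@dataclass
class Patch:
    coord: PatchCoord
    data: np.ndarray = field(repr=False)

    def __post_init__(self):
        w = self.coord.width
        if self.data.shape != (w, w, w):
            raise ValidationError(
                f"patch data shape {self.data.shape} != ({w}, {w}, {w})"
            )


def read_volume(path: str | Path) -> Volume3D:
    """Load a NIfTI-1 volume (optionally .gz), keeping native axis order.

    Raises :class:`ValidationError` for non-3D images or non-finite voxels
    and the usual I/O errors for missing/unreadable files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3D image, got shape {data.shape}")
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"{path}: volume contains NaN or Inf voxels")
    zooms = img.header.get_zooms()[:3]
    return Volume3D(data=data, spacing=tuple(float(z) for z in zooms),
                    subject_id=path.name.split(".")[0])


def write_volume(v: Volume3D, path: str | Path) -> Path:
    """Write a volume as NIfTI-1 with spacing stored in the header zooms."""
    path = Path(path)
    affine = np.diag(list(v.spacing) + [1.0])
    img = nib.Nifti1Image(np.asarray(v.data), affine)
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))
    return path


def partition_volume(v: Volume3D, width: int) -> list[PatchCoord]:
    """All non-overlapping width-cubes fully inside the volume.

    Coordinates are multiples of ``width`` in lexicographic (x, y, z) order;
    trailing voxels that do not fill a complete cube are dropped, so the
    count is prod(floor(dim / width)) — e.g. 181x217x181 at width 25 gives
    7*8*7 = 392 locations.
    """
    shape = v.shape
    if width < 1:
        raise ValidationError(f"patch width must be >= 1, got {width}")
    if any(width > s for s in shape):
        raise ValidationError(
            f"patch width {width} exceeds volume dimension(s) {shape}"
        )
    counts = [s // width for s in shape]
    return [
        PatchCoord((i * width, j * width, k * width), width)
        for i in range(counts[0])
        for j in range(counts[1])
        for k in range(counts[2])
    ]


def extract_patch(v: Volume3D, c: PatchCoord) -> Patch:
    """Crop the half-open cube ``[origin, origin + width)`` from a volume."""
    c.validate_against(v.shape)
    (x, y, z), w = c.origin, c.width
    return Patch(coord=c, data=np.ascontiguousarray(v.data[x:x + w, y:y + w, z:z + w]))
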