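"""Volume/mask containers, NIfTI I/O and cohort manifests.

All grids are stored in a single internal axis convention (closest-to-RAS,
0-based voxel indices); files are reoriented at the I/O boundary so that
every downstream convolution and ranking operates on consistent axes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Volume",
    "BinaryMask",
    "AtlasDatabase",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_manifest",
    "write_manifest",
    "load_databases",
]

#: internal axis convention tag; arrays are reoriented to this on load
AXES_TAG = "RAS"


def _check_geometry_fields(data: np.ndarray, spacing: Sequence[float]) -> None:
    if data.ndim != 3:
        raise ValueError(f"expected a 3D grid, got {data.ndim}D with shape {data.shape}")
    if min(data.shape) < 1:
        raise ValueError(f"all dimensions must be >= 1, got shape {data.shape}")
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be three strictly positive values, got {spacing}")


@dataclass
class Volume:
    """A 3D scalar image with voxel-spacing metadata.

    Parameters
    ----------
    data
        3D array of real intensities (promoted to floating point).
    spacing
        Physical voxel size per axis, in mm.
    origin
        Physical coordinate of voxel (0, 0, 0).
    axcodes
        Axis-order convention tag (internally always ``"RAS"``).
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axcodes: str = AXES_TAG

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float64)
        _check_geometry_fields(arr, self.spacing)
        if not np.all(np.isfinite(arr)):
            raise ValueError("volume contains non-finite values (NaN/Inf)")
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def like(self, data: np.ndarray) -> "Volume":
        """New volume with the same geometry metadata but different data."""
        return replace(self, data=np.asarray(data))


@dataclass
class BinaryMask:
    """A 3D {0,1} grid sharing the geometry conventions of :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axcodes: str = AXES_TAG

    def __post_init__(self) -> None:
        arr = (np.asarray(self.data) != 0).astype(np.uint8)
        _check_geometry_fields(arr, self.spacing)
        self.data = arr
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_foreground(self) -> int:
        return int(self.data.sum())

    def as_bool(self) -> np.ndarray:
        return self.data.astype(bool)


def same_geometry(a: Volume | BinaryMask, b: Volume | BinaryMask, atol: float = 1e-5) -> bool:
    return (
        a.data.shape == b.data.shape
        and np.allclose(a.spacing, b.spacing, atol=atol)
        and np.allclose(a.origin, b.origin, atol=atol)
    )


def _load_canonical(path: str | os.PathLike) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    img = nib.load(str(path))
    if len(img.shape) == 4 and img.shape[3] == 1:
        # tolerate trailing singleton dimension written by some tools
        img = nib.Nifti1Image(
            np.asanyarray(img.dataobj)[..., 0], img.affine, img.header
        )
    if len(img.shape) != 3:
        raise ValueError(
            f"{path}: expected a 3D image, got shape {img.shape} "
            "(4D/cine inputs are not supported)"
        )
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return data, spacing, origin


def read_volume(path: str | os.PathLike) -> Volume:
    """Read a NIfTI-1/2 volume; integer-typed files are promoted to float."""
    data, spacing, origin = _load_canonical(path)
    if not np.issubdtype(data.dtype, np.floating):
        data = data.astype(np.float32)
    data = np.ascontiguousarray(data, dtype=np.float64)
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path}: volume contains non-finite values")
    return Volume(data, spacing, origin)


def read_mask(path: str | os.PathLike) -> BinaryMask:
    """Read a NIfTI mask; any nonzero voxel is foreground."""
    data, spacing, origin = _load_canonical(path)
    return BinaryMask(data, spacing, origin)


def _affine_from(spacing: Sequence[float], origin: Sequence[float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    aff[:3, 3] = origin
    return aff


def write_volume(v: Volume, path: str | os.PathLike) -> None:
    """Write a volume as 32-bit float NIfTI (lossless at float32 precision)."""
    if not np.all(np.isfinite(v.data)):
        raise ValueError("refusing to write a volume with non-finite values")
    img = nib.Nifti1Image(v.data.astype(np.float32), _affine_from(v.spacing, v.origin))
    img.header.set_zooms(v.spacing)
    nib.save(img, str(path))


def write_mask(m: BinaryMask, path: str | os.PathLike) -> None:
    """Write a mask as uint8 NIfTI (bit-exact round trip)."""
    img = nib.Nifti1Image(m.data.astype(np.uint8), _affine_from(m.spacing, m.origin))
    img.header.set_zooms(m.spacing)
    nib.save(img, str(path))


@dataclass
class AtlasDatabase:
    """The paired set of intensity volumes and heart masks for one condition."""

    condition: str
    images: list[Volume] = field(default_factory=list)
    masks: list[BinaryMask] = field(default_factory=list)
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.images) != len(self.masks):
            raise ValueError(
                f"database {self.condition!r}: {len(self.images)} images vs "
                f"{len(self.masks)} masks"
            )
        if not self.subject_ids:
            self.subject_ids = [f"{self.condition}{i:03d}" for i in range(len(self.images))]
        for img, msk in zip(self.images, self.masks):
            if img.data.shape != msk.data.shape:
                raise ValueError(
                    f"database {self.condition!r}: image/mask shape mismatch "
                    f"{img.data.shape} vs {msk.data.shape}"
                )

    def __len__(self) -> int:
        return len(self.images)


MANIFEST_COLUMNS = ["subject_id", "condition", "image_path", "mask_path"]


def read_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read a cohort manifest CSV (subject_id, condition, image_path, mask_path)."""
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest {path} is missing columns: {missing}")
    return df[MANIFEST_COLUMNS].copy()


def write_manifest(rows: Iterable[Mapping[str, str]], path: str | os.PathLike) -> None:
    pd.DataFrame(list(rows), columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def load_databases(manifest_path: str | os.PathLike) -> dict[str, AtlasDatabase]:
    """Load all atlas databases referenced by a cohort manifest.

    Relative paths in the manifest are resolved against the manifest location.
    """
    manifest_path = Path(manifest_path)
    df = read_manifest(manifest_path)
    root = manifest_path.parent

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else root / q

    out: dict[str, AtlasDatabase] = {}
    for condition, grp in df.groupby("condition", sort=True):
        out[str(condition)] = AtlasDatabase(
            condition=str(condition),
            images=[read_volume(_resolve(p)) for p in grp["image_path"]],
            masks=[read_mask(_resolve(p)) for p in grp["mask_path"]],
            subject_ids=[str(s) for s in grp["subject_id"]],
        )
    return out
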