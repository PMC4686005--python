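"""Mapping atlases into target space behind a pluggable backend.

Three backends are supported:

* ``identity`` — the atlas is assumed pre-aligned with the target grid
  (phantom cohorts generated on a common grid); resample-only.
* ``builtin_affine`` — a 12-parameter affine (translation, rotation,
  anisotropic scale, shear) maximising NCC by multi-resolution
  derivative-free (Powell) search.  Images are resampled linearly, masks
  nearest-neighbour.
* ``external`` — a subprocess contract for a deformable engine; the command
  template receives ``{ref}``, ``{flo}``, ``{mask}`` and ``{out}``
  placeholders and must write ``{out}_img.nii.gz`` / ``{out}_mask.nii.gz``
  in target geometry.

The two-stage scheme: stage 1 maps every atlas affinely and fuses the mapped
masks at threshold 0.5 into a rough target heart mask; stage 2 refines each
mapping with the metric restricted to that rough mask.  Atlases are
registered atlas-to-target directly, so the mapped masks land in target
space without transform inversion.  The parameters of a previously validated
free-form-deformation setup (coarse-to-fine levels, iteration caps, bending
energy) are carried in :class:`RegistrationConfig` for the external backend;
the deformable engine itself is intentionally not re-implemented here.
"""

from __future__ import annotations

import logging
import subprocess
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
from scipy import ndimage, optimize

from .io import AtlasDatabase, BinaryMask, Volume, read_mask, read_volume, write_mask, write_volume
from .preprocess import fuse_masks

__all__ = [
    "RegistrationConfig",
    "MappedAtlas",
    "register_atlas",
    "map_all",
]

logger = logging.getLogger(__name__)

BACKENDS = ("identity", "builtin_affine", "external")


@dataclass
class RegistrationConfig:
    """Backend choice plus the two-stage parameters.

    The rigid/affine/non-rigid level and iteration fields mirror the
    validated external free-form-deformation setup; the built-in affine
    backend uses the level counts and its own Powell iteration budget.
    """

    backend: str = "identity"
    rigid_levels: int = 3
    rigid_max_iterations: int = 5
    affine_levels: int = 3
    affine_max_iterations: int = 8
    nonrigid_levels: int = 3
    nonrigid_max_iterations: int = 300
    bending_energy: float = 0.005
    stage2_metric: str = "NMI"
    external_command: Optional[str] = None

    def __post_init__(self) -> None:
        if self.backend not in BACKENDS:
            raise ValueError(f"backend must be one of {BACKENDS}, got {self.backend!r}")
        for name in (
            "rigid_max_iterations",
            "affine_max_iterations",
            "nonrigid_max_iterations",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.bending_energy < 0:
            raise ValueError("bending_energy must be >= 0")
        if self.backend == "external" and not self.external_command:
            raise ValueError("external backend requires external_command")


@dataclass
class MappedAtlas:
    """One atlas resampled into target space."""

    condition: str
    image_in_target: Volume
    mask_in_target: BinaryMask
    provenance: dict = field(default_factory=dict)


def _arr(v) -> np.ndarray:
    return np.asarray(getattr(v, "data", v), dtype=np.float64)


def _ncc(a: np.ndarray, b: np.ndarray, mask: Optional[np.ndarray] = None) -> float:
    if mask is not None:
        a = a[mask]
        b = b[mask]
    else:
        a = a.ravel()
        b = b.ravel()
    ad = a - a.mean()
    bd = b - b.mean()
    denom = np.sqrt((ad * ad).sum() * (bd * bd).sum())
    if denom == 0:
        return 0.0
    return float((ad * bd).sum() / denom)


def _affine_matrix(params: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """12 parameters -> (3x3 matrix, translation).

    Layout: translation (3), Euler rotations in radians (3), log-scales (3),
    shears (3).
    """
    t = np.asarray(params[:3], dtype=np.float64)
    rx, ry, rz = params[3:6]
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    S = np.diag(np.exp(np.asarray(params[6:9], dtype=np.float64)))
    h0, h1, h2 = params[9:12]
    H = np.array([[1, h0, h1], [0, 1, h2], [0, 0, 1]])
    return Rz @ Ry @ Rx @ H @ S, t


def _resample(
    moving: np.ndarray, params: np.ndarray, out_shape: tuple[int, ...], order: int
) -> np.ndarray:
    """Sample ``moving`` at A(x - c) + c + t for output voxels x (c = centre)."""
    A, t = _affine_matrix(params)
    c = (np.asarray(out_shape, dtype=np.float64) - 1) / 2.0
    offset = c + t - A @ c
    return ndimage.affine_transform(
        moving, A, offset=offset, output_shape=out_shape, order=order, mode="nearest"
    )


def _downsample(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return arr
    smoothed = ndimage.gaussian_filter(arr, sigma=factor / 2.0)
    return smoothed[tuple(slice(None, None, factor) for _ in range(arr.ndim))]


def _fit_affine(
    atlas: np.ndarray,
    target: np.ndarray,
    mask: Optional[np.ndarray],
    levels: int,
    maxiter: int = 60,
) -> np.ndarray:
    """Multi-resolution Powell search over the 12 affine parameters."""
    params = np.zeros(12)
    factors = [2**k for k in range(levels - 1, -1, -1)]  # e.g. [4, 2, 1]
    for factor in factors:
        tgt = _downsample(target, factor)
        mov = _downsample(atlas, factor)
        msk = None
        if mask is not None:
            msk = _downsample(mask.astype(np.float64), factor) > 0.5
            if msk.sum() < 32:
                msk = None

        def cost(p, scale=factor, tgt=tgt, mov=mov, msk=msk):
            q = p.copy()
            q[:3] = q[:3] / scale  # translation expressed in full-res voxels
            resampled = _resample(mov, q, tgt.shape, order=1)
            return -_ncc(tgt, resampled, msk)

        # translation-only first at the coarsest level to avoid local minima
        stages = [np.arange(3), np.arange(6), np.arange(12)] if factor == factors[0] else [np.arange(12)]
        for active in stages:
            def sub_cost(sub, active=active):
                p = params.copy()
                p[active] = sub
                return cost(p)

            res = optimize.minimize(
                sub_cost,
                params[active],
                method="Powell",
                options={"maxiter": maxiter, "xtol": 1e-3, "ftol": 1e-7},
            )
            params = params.copy()
            params[active] = res.x
    return params


def register_atlas(
    atlas_image: Volume,
    atlas_mask: BinaryMask,
    target: Volume,
    target_roi: Optional[BinaryMask] = None,
    cfg: Optional[RegistrationConfig] = None,
) -> MappedAtlas:
    """Map one atlas (intensity + mask) into target space."""
    cfg = cfg or RegistrationConfig()
    tgt = _arr(target)
    if float(tgt.min()) == float(tgt.max()):
        raise ValueError("constant target image: registration undefined")
    atl = _arr(atlas_image)
    msk = np.asarray(getattr(atlas_mask, "data", atlas_mask)) != 0

    if cfg.backend == "identity":
        if atl.shape != tgt.shape:
            raise ValueError(
                f"identity backend requires a shared grid: atlas {atl.shape} vs target {tgt.shape}"
            )
        return MappedAtlas(
            condition="",
            image_in_target=Volume(atl.copy(), target.spacing, target.origin),
            mask_in_target=BinaryMask(msk.copy(), target.spacing, target.origin),
            provenance={"backend": "identity"},
        )

    if cfg.backend == "builtin_affine":
        roi_arr = None
        if target_roi is not None:
            roi_arr = np.asarray(getattr(target_roi, "data", target_roi)) != 0
        params = _fit_affine(atl, tgt, roi_arr, levels=cfg.affine_levels)
        mapped_img = _resample(atl, params, tgt.shape, order=1)
        ncc_fit = _ncc(tgt, mapped_img, roi_arr)
        ncc_id = _ncc(tgt, _resample(atl, np.zeros(12), tgt.shape, order=1), roi_arr)
        if ncc_fit <= ncc_id + 1e-12:
            warnings.warn(
                "affine optimisation did not improve over identity; falling back to identity",
                RuntimeWarning,
                stacklevel=2,
            )
            params = np.zeros(12)
            mapped_img = _resample(atl, params, tgt.shape, order=1)
        mapped_msk = _resample(msk.astype(np.float64), params, tgt.shape, order=0) > 0.5
        return MappedAtlas(
            condition="",
            image_in_target=Volume(mapped_img, target.spacing, target.origin),
            mask_in_target=BinaryMask(mapped_msk, target.spacing, target.origin),
            provenance={
                "backend": "builtin_affine",
                "params": [float(p) for p in params],
                "levels": cfg.affine_levels,
            },
        )

    # external subprocess contract
    return _register_external(atlas_image, atlas_mask, target, target_roi, cfg)


def _register_external(
    atlas_image: Volume,
    atlas_mask: BinaryMask,
    target: Volume,
    target_roi: Optional[BinaryMask],
    cfg: RegistrationConfig,
) -> MappedAtlas:
    assert cfg.external_command
    with tempfile.TemporaryDirectory(prefix="voxar_reg_") as tmp:
        tmp_path = Path(tmp)
        ref = tmp_path / "ref.nii.gz"
        flo = tmp_path / "flo.nii.gz"
        flo_mask = tmp_path / "flo_mask.nii.gz"
        roi = tmp_path / "roi.nii.gz"
        out = tmp_path / "out"
        write_volume(target, ref)
        write_volume(atlas_image, flo)
        write_mask(atlas_mask, flo_mask)
        if target_roi is not None:
            write_mask(target_roi, roi)
        cmd = cfg.external_command.format(
            ref=ref, flo=flo, flo_mask=flo_mask, mask=roi, out=out,
            levels=cfg.nonrigid_levels, iterations=cfg.nonrigid_max_iterations,
            bending_energy=cfg.bending_energy,
        )
        proc = subprocess.run(cmd, shell=True, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(
                f"external registration failed (exit {proc.returncode}):\n"
                f"stdout:\n{proc.stdout}\nstderr:\n{proc.stderr}"
            )
        out_img = Path(f"{out}_img.nii.gz")
        out_mask = Path(f"{out}_mask.nii.gz")
        if not out_img.exists() or not out_mask.exists():
            raise RuntimeError(
                f"external registration produced no output at {out}_img/_mask.nii.gz:\n"
                f"stdout:\n{proc.stdout}\nstderr:\n{proc.stderr}"
            )
        image = read_volume(out_img)
        mask = read_mask(out_mask)
    if image.data.shape != target.data.shape:
        raise RuntimeError(
            f"external output geometry {image.data.shape} does not match target {target.data.shape}"
        )
    return MappedAtlas(
        condition="",
        image_in_target=image,
        mask_in_target=mask,
        provenance={"backend": "external", "command": cfg.external_command},
    )


def map_all(
    databases: Mapping[str, AtlasDatabase],
    target: Volume,
    cfg: Optional[RegistrationConfig] = None,
    affine_fusion_threshold: float = 0.5,
) -> tuple[dict[str, list[MappedAtlas]], BinaryMask]:
    """Two-stage mapping of every database into target space.

    Stage 1 maps each atlas and fuses the mapped masks (threshold 0.5) into
    a rough target heart mask; stage 2 re-registers with the metric
    restricted to that mask (a no-op for the identity backend).  Individual
    atlas failures are logged and the atlas dropped; a database losing all
    atlases is an error.
    """
    cfg = cfg or RegistrationConfig()
    for cond, db in databases.items():
        if len(db) == 0:
            raise ValueError(f"database {cond!r} is empty")

    stage1: dict[str, list[tuple[int, MappedAtlas]]] = {}
    for cond in sorted(databases):
        db = databases[cond]
        mapped: list[tuple[int, MappedAtlas]] = []
        for i, (img, msk) in enumerate(zip(db.images, db.masks)):
            try:
                m = register_atlas(img, msk, target, target_roi=None, cfg=cfg)
            except Exception as exc:  # drop semantics: log and continue
                logger.warning("stage-1 mapping failed for %s atlas %d: %s", cond, i, exc)
                continue
            m.condition = cond
            mapped.append((i, m))
        if not mapped:
            raise RuntimeError(f"all atlases of database {cond!r} failed to register")
        stage1[cond] = mapped

    all_masks = [m.mask_in_target for pairs in stage1.values() for _, m in pairs]
    rough = fuse_masks(all_masks, affine_fusion_threshold)
    rough_mask = BinaryMask(rough, target.spacing, target.origin)

    if cfg.backend == "identity":
        return {c: [m for _, m in pairs] for c, pairs in stage1.items()}, rough_mask

    out: dict[str, list[MappedAtlas]] = {}
    for cond, pairs in stage1.items():
        db = databases[cond]
        refined: list[MappedAtlas] = []
        for i, _ in pairs:
            try:
                m = register_atlas(
                    db.images[i], db.masks[i], target, target_roi=rough_mask, cfg=cfg
                )
            except Exception as exc:
                logger.warning("stage-2 mapping failed for %s atlas %d: %s", cond, i, exc)
                continue
            m.condition = cond
            refined.append(m)
        if not refined:
            raise RuntimeError(f"all atlases of database {cond!r} failed at stage 2")
        out[cond] = refined
    return out, rough_mask
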