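"""Synthetic multi-condition cardiac-like phantoms.

The generator produces 3D cohorts with the statistical structure the rating
machinery assumes: each condition has a distinct great-vessel morphology,
subjects within a condition differ by a random smooth deformation, and every
image carries a multiplicative bias field plus additive Gaussian noise over a
textured background.

Anatomy of a template (all coordinates in fractions of the grid):

* an outer "pericardial" envelope ellipsoid of intermediate intensity — the
  structure support used as the ground-truth heart mask, common to all
  conditions so that per-condition mask fusion and the cross-condition ROI
  intersection retain the vessel region;
* a bright "body" ellipsoid (the cardiac blood pool);
* two tube-like "great vessels" leaving the body towards the top of the
  grid, whose spatial arrangement encodes the condition;
* optionally a connecting slab between the vessels (a "baffle").

The default condition set mimics the topology changes of the two surgical
repairs of transposed great arteries relative to a normal heart:

* ``normal``    — two parallel vessels;
* ``switch_a``  — the vessels cross (translocated arteries);
* ``switch_b``  — parallel vessels plus a connecting baffle.

A fourth morphology, ``novel``, with a widely spread vessel pair of larger
calibre, is available for missing-pathology experiments.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .io import BinaryMask, Volume

__all__ = [
    "TubePath",
    "ConditionShape",
    "PhantomSpec",
    "PhantomSubject",
    "DEFAULT_SHAPES",
    "default_spec",
    "condition_template",
    "generate_subject",
    "generate_cohort",
]


@dataclass(frozen=True)
class TubePath:
    """A straight tube segment; endpoints as (x, y) fractions at the bottom
    and top of the vessel z-band."""

    x0: float
    y0: float
    x1: float
    y1: float


@dataclass(frozen=True)
class ConditionShape:
    """Structural parameters of one condition's template."""

    tubes: tuple[TubePath, ...]
    baffle: bool = False
    tube_radius: float = 0.050  # fraction of grid size
    tube_intensity: float = 150.0
    baffle_intensity: float = 135.0


DEFAULT_SHAPES: dict[str, ConditionShape] = {
    "normal": ConditionShape(
        tubes=(TubePath(0.38, 0.42, 0.38, 0.42), TubePath(0.62, 0.58, 0.62, 0.58)),
    ),
    "switch_a": ConditionShape(
        tubes=(TubePath(0.38, 0.42, 0.62, 0.42), TubePath(0.62, 0.58, 0.38, 0.58)),
    ),
    "switch_b": ConditionShape(
        tubes=(TubePath(0.38, 0.42, 0.38, 0.42), TubePath(0.62, 0.58, 0.62, 0.58)),
        baffle=True,
    ),
    "novel": ConditionShape(
        tubes=(TubePath(0.30, 0.50, 0.30, 0.50), TubePath(0.70, 0.50, 0.70, 0.50)),
        tube_radius=0.068,
    ),
}

# vessel z-band and ellipsoid geometry (fractions)
_TUBE_Z = (0.40, 0.88)
_BAFFLE_Z = (0.55, 0.68)
_BAFFLE_HALF_Y = 0.04
_ENVELOPE = ((0.50, 0.50, 0.55), (0.36, 0.32, 0.42))
_BODY = ((0.50, 0.50, 0.42), (0.28, 0.24, 0.20))


@dataclass
class PhantomSpec:
    """Study conditions of a synthetic cohort.

    Defaults are chosen to emulate routine whole-heart angiography at a small
    grid: within-condition anatomical variability on the order of a vessel
    radius (deformation amplitude 2.5 voxels, smoothness 5 voxels), moderate
    additive noise (sigma 8 against a structure/background contrast of about
    80, SNR ~ 10), a 10% smooth intensity inhomogeneity, and a textured
    nonzero background so that rough-mask extraction is nontrivial.
    """

    shape: tuple[int, int, int] = (48, 48, 48)
    conditions: tuple[str, ...] = ("normal", "switch_a", "switch_b")
    shapes: Mapping[str, ConditionShape] = field(default_factory=lambda: dict(DEFAULT_SHAPES))
    deformation_amplitude: float = 2.5  # voxels, max displacement magnitude
    deformation_smoothness: float = 5.0  # voxels, Gaussian sigma of the field
    noise_sigma: float = 8.0  # intensity units
    bias_amplitude: float = 0.10  # relative multiplicative inhomogeneity
    bias_smoothness: float = 16.0  # voxels
    background: float = 20.0
    texture_amplitude: float = 4.0
    texture_sigma: float = 3.0
    envelope_intensity: float = 65.0
    body_intensity: float = 100.0
    edge_sigma: float = 0.8  # voxels, softening of structure boundaries
    voxel_size: float = 1.5  # mm, isotropic
    seed: int = 0  # drives the deterministic per-condition background texture

    def __post_init__(self) -> None:
        self.shape = tuple(int(n) for n in self.shape)
        if min(self.shape) < 24:
            raise ValueError(f"grid must be >= 24 per axis for default structures, got {self.shape}")
        if len(self.conditions) < 2:
            raise ValueError("need at least two conditions")
        if len(set(self.conditions)) != len(self.conditions):
            raise ValueError("condition labels must be distinct")
        missing = [c for c in self.conditions if c not in self.shapes]
        if missing:
            raise ValueError(f"no structural parameters for conditions: {missing}")
        seen = {}
        for c in self.conditions:
            key = self.shapes[c]
            if key in seen:
                raise ValueError(
                    f"conditions {seen[key]!r} and {c!r} have identical structural parameters"
                )
            seen[key] = c
        if self.deformation_amplitude < 0 or self.deformation_amplitude > 0.08 * min(self.shape):
            raise ValueError(
                "deformation amplitude must be small relative to the grid "
                f"(got {self.deformation_amplitude} voxels for shape {self.shape})"
            )


def default_spec(**overrides) -> PhantomSpec:
    """The default three-condition phantom specification."""
    return PhantomSpec(**overrides)


@dataclass
class PhantomSubject:
    """One synthesised subject: condition label, image and ground-truth mask."""

    subject_id: str
    condition: str
    image: Volume
    true_mask: BinaryMask
    seed: int


def _ellipsoid(fx, fy, fz, center, semi) -> np.ndarray:
    return (
        ((fx - center[0]) / semi[0]) ** 2
        + ((fy - center[1]) / semi[1]) ** 2
        + ((fz - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _condition_rng(spec: PhantomSpec, condition: str) -> np.random.Generator:
    return np.random.default_rng([spec.seed, zlib.crc32(condition.encode())])


def condition_template(spec: PhantomSpec, condition: str) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic noise-free structural template of a condition.

    Returns ``(intensity, support)`` where ``support`` (the envelope) is the
    ground-truth structure mask.
    """
    if condition not in spec.shapes:
        raise KeyError(f"unknown condition {condition!r}")
    shape_params = spec.shapes[condition]
    nx, ny, nz = spec.shape
    ix, iy, iz = np.meshgrid(
        np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij", sparse=True
    )
    fx = ix / (nx - 1)
    fy = iy / (ny - 1)
    fz = iz / (nz - 1)

    envelope = _ellipsoid(fx, fy, fz, *_ENVELOPE)
    body = _ellipsoid(fx, fy, fz, *_BODY)

    z0, z1 = _TUBE_Z
    in_band = (fz >= z0) & (fz <= z1)
    tt = np.clip((fz - z0) / (z1 - z0), 0.0, 1.0)
    tubes = np.zeros(spec.shape, dtype=bool)
    r2 = shape_params.tube_radius**2
    for tube in shape_params.tubes:
        cx = tube.x0 + (tube.x1 - tube.x0) * tt
        cy = tube.y0 + (tube.y1 - tube.y0) * tt
        tubes |= (((fx - cx) ** 2 + (fy - cy) ** 2) <= r2) & in_band

    baffle = np.zeros(spec.shape, dtype=bool)
    if shape_params.baffle:
        xs = [t.x0 for t in shape_params.tubes] + [t.x1 for t in shape_params.tubes]
        ys = [t.y0 for t in shape_params.tubes] + [t.y1 for t in shape_params.tubes]
        ymid = float(np.mean(ys))
        baffle = (
            (fx >= min(xs))
            & (fx <= max(xs))
            & (np.abs(fy - ymid) <= _BAFFLE_HALF_Y)
            & (fz >= _BAFFLE_Z[0])
            & (fz <= _BAFFLE_Z[1])
        )

    intensity = np.full(spec.shape, spec.background, dtype=np.float64)
    rng = _condition_rng(spec, condition)
    texture = ndimage.gaussian_filter(rng.standard_normal(spec.shape), spec.texture_sigma)
    sd = texture.std()
    if sd > 0:
        texture *= spec.texture_amplitude / sd
    intensity += texture * (~envelope)
    intensity[envelope] = spec.envelope_intensity
    intensity[body] = spec.body_intensity
    intensity[baffle] = shape_params.baffle_intensity
    intensity[tubes] = shape_params.tube_intensity
    if spec.edge_sigma > 0:
        intensity = ndimage.gaussian_filter(intensity, spec.edge_sigma)
    return intensity, envelope


def generate_subject(spec: PhantomSpec, condition: str, seed: int) -> PhantomSubject:
    """Generate one subject: template, random smooth warp, bias field, noise.

    Deterministic (bit-exact) for a fixed ``(spec, condition, seed)``.
    """
    if condition not in spec.conditions:
        raise ValueError(f"condition {condition!r} not in {spec.conditions}")
    template, support = condition_template(spec, condition)
    rng = np.random.default_rng([int(seed), zlib.crc32(condition.encode())])

    if spec.deformation_amplitude > 0:
        disp = [
            ndimage.gaussian_filter(rng.standard_normal(spec.shape), spec.deformation_smoothness)
            for _ in range(3)
        ]
        mag = np.sqrt(sum(d * d for d in disp))
        peak = float(mag.max())
        scale = spec.deformation_amplitude / peak if peak > 0 else 0.0
        coords = np.meshgrid(*(np.arange(n, dtype=np.float64) for n in spec.shape), indexing="ij")
        coords = [c + d * scale for c, d in zip(coords, disp)]
        image = ndimage.map_coordinates(template, coords, order=1, mode="nearest")
        warped_support = (
            ndimage.map_coordinates(support.astype(np.float64), coords, order=1, mode="nearest")
            > 0.5
        )
    else:
        image = template.copy()
        warped_support = support.copy()

    if spec.bias_amplitude > 0:
        bias = ndimage.gaussian_filter(rng.standard_normal(spec.shape), spec.bias_smoothness)
        peak = float(np.abs(bias).max())
        if peak > 0:
            bias *= spec.bias_amplitude / peak
        image = image * (1.0 + bias)

    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, spec.shape)

    spacing = (spec.voxel_size,) * 3
    return PhantomSubject(
        subject_id=f"{condition}-s{seed}",
        condition=condition,
        image=Volume(image, spacing=spacing),
        true_mask=BinaryMask(warped_support, spacing=spacing),
        seed=int(seed),
    )


def generate_cohort(
    spec: PhantomSpec, counts: Mapping[str, int], seed: int
) -> list[PhantomSubject]:
    """Generate a labelled cohort; per-subject seeds derive from the master seed."""
    if not counts:
        raise ValueError("empty condition set")
    for cond, n in counts.items():
        if cond not in spec.conditions:
            raise ValueError(f"condition {cond!r} not in {spec.conditions}")
        if int(n) < 1:
            raise ValueError(f"count for {cond!r} must be >= 1, got {n}")
    rng = np.random.default_rng(int(seed))
    subjects: list[PhantomSubject] = []
    for cond in sorted(counts):
        for i in range(int(counts[cond])):
            sub_seed = int(rng.integers(0, 2**31 - 1))
            subject = generate_subject(spec, cond, sub_seed)
            subjects.append(replace(subject, subject_id=f"{cond}{i:03d}"))
    return subjects
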