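"""Voxelwise atlas rating: pooled cross-database ranking, the rating map,
the rating histogram and the diagnosis.

At each ROI voxel the LNCC values of *all* atlases from *all* databases are
ranked together (descending).  With ``A_w(x)`` the number of atlases of
condition ``w`` among the top ``T`` at ``x``, the rating map is

    R(x) = argmax_w A_w(x)   if max_w A_w(x) >= ceil(T/2 + 1)
    R(x) = UNASSIGNED        otherwise

so only a condition holding the absolute majority of the top-T slots is
assigned.  For T = 7 the threshold is 5.  Because the threshold exceeds
T/2, two conditions can never tie above it, so the argmax of an assigned
voxel is unique.  The diagnosis is the condition with the highest share of
assigned voxels; the gap between the top two histogram bins serves as a
confidence proxy.

Tie-breaking in the pooled ranking is stable by (condition name, atlas
index); the threshold is exposed for sensitivity analyses via
``majority_threshold``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .isa import rank_values
from .report import STATUS_OK, STATUS_REFUSED, DiagnosisReport, RatingHistogram
from .similarity import SimilarityMap, TargetMoments

__all__ = [
    "UNASSIGNED",
    "OUTSIDE",
    "PooledRanking",
    "ConditionCounts",
    "RatingMap",
    "majority_threshold",
    "pool_rank",
    "count_conditions",
    "build_rating_map",
    "rating_histogram",
    "voxar_diagnose",
]

logger = logging.getLogger(__name__)

#: label codes in a rating map
UNASSIGNED = -1
OUTSIDE = -2


def majority_threshold(T: int) -> int:
    """Absolute-majority guard ``ceil(T/2 + 1)`` in exact integer arithmetic."""
    if T < 1:
        raise ValueError("T must be >= 1")
    return (T + 1) // 2 + 1


@dataclass
class PooledRanking:
    """Per-voxel ordering of all atlases pooled across databases.

    ``ranks[a, v]`` is the descending-LNCC rank of atlas ``a`` at ROI voxel
    ``v`` (undefined entries carry -1); ``top[a, v]`` flags membership in
    the top ``min(T, n_defined(v))``.
    """

    ranks: np.ndarray
    top: np.ndarray
    atlas_conditions: np.ndarray  # (A,) condition index per atlas row
    conditions: tuple[str, ...]
    n_defined: np.ndarray  # (V,)
    T: int
    roi_index: np.ndarray
    shape: tuple[int, int, int]


@dataclass
class ConditionCounts:
    """``counts[c, v]``: atlases of condition ``c`` among the top-T at voxel v."""

    counts: np.ndarray
    conditions: tuple[str, ...]
    n_defined: np.ndarray
    T: int
    roi_index: np.ndarray
    shape: tuple[int, int, int]


@dataclass
class RatingMap:
    """Per-voxel condition assignment over the ROI.

    ``labels_flat`` holds condition indices (or :data:`UNASSIGNED`) per ROI
    voxel; :meth:`as_grid` expands to the full grid with :data:`OUTSIDE`
    beyond the ROI.
    """

    labels_flat: np.ndarray
    conditions: tuple[str, ...]
    roi_index: np.ndarray
    shape: tuple[int, int, int]

    def as_grid(self) -> np.ndarray:
        grid = np.full(int(np.prod(self.shape)), OUTSIDE, dtype=np.int16)
        grid[self.roi_index] = self.labels_flat
        return grid.reshape(self.shape)

    def legend(self) -> dict[int, str]:
        out = {OUTSIDE: "<outside ROI>", UNASSIGNED: "<unassigned>"}
        out.update({i: c for i, c in enumerate(self.conditions)})
        return out


def pool_rank(
    sim_maps: Mapping[str, Sequence[SimilarityMap]],
    roi,
    T: int = 7,
) -> PooledRanking:
    """Rank the LNCC of every atlas from every database jointly per voxel."""
    if T < 1:
        raise ValueError("T must be >= 1")
    conditions = tuple(sorted(sim_maps))
    maps: list[SimilarityMap] = []
    cond_idx: list[int] = []
    for ci, cond in enumerate(conditions):
        for m in sim_maps[cond]:
            maps.append(m)
            cond_idx.append(ci)
    if not maps:
        raise ValueError("no similarity maps provided")
    shape = maps[0].values.shape
    roi_arr = np.asarray(getattr(roi, "data", roi)) != 0
    if roi_arr.shape != shape:
        raise ValueError(f"ROI shape {roi_arr.shape} does not match maps {shape}")
    idx = np.flatnonzero(roi_arr.ravel())
    values = np.stack([m.values.ravel()[idx] for m in maps])
    defined = np.stack([m.defined.ravel()[idx] for m in maps])
    return pool_rank_values(
        values, defined, np.asarray(cond_idx), conditions, T, roi_index=idx, shape=shape
    )


def pool_rank_values(
    values: np.ndarray,
    defined: np.ndarray,
    atlas_conditions: np.ndarray,
    conditions: tuple[str, ...],
    T: int,
    roi_index: Optional[np.ndarray] = None,
    shape: Optional[tuple[int, int, int]] = None,
) -> PooledRanking:
    """Array-level pooled ranking (rows pre-ordered by (condition, atlas))."""
    n_atlases, n_vox = values.shape
    n_defined = defined.sum(axis=0)
    if not n_defined.any():
        raise ValueError("no defined atlas at any ROI voxel")
    if n_atlases < T:
        logger.warning(
            "only %d atlases pooled for T=%d; top-T saturates at the atlas count",
            n_atlases,
            T,
        )
    ranks = rank_values(values, defined)
    top = (ranks >= 0) & (ranks < np.minimum(T, n_defined)[None, :])
    if roi_index is None:
        roi_index = np.arange(n_vox)
    if shape is None:
        shape = (n_vox, 1, 1)
    return PooledRanking(
        ranks=ranks,
        top=top,
        atlas_conditions=np.asarray(atlas_conditions),
        conditions=tuple(conditions),
        n_defined=n_defined,
        T=int(T),
        roi_index=roi_index,
        shape=shape,
    )


def count_conditions(p: PooledRanking) -> ConditionCounts:
    """Count, per voxel and condition, the atlases among the top-T."""
    n_cond = len(p.conditions)
    counts = np.zeros((n_cond, p.top.shape[1]), dtype=np.int32)
    for c in range(n_cond):
        rows = p.atlas_conditions == c
        if rows.any():
            counts[c] = p.top[rows].sum(axis=0)
    return ConditionCounts(
        counts=counts,
        conditions=p.conditions,
        n_defined=p.n_defined,
        T=p.T,
        roi_index=p.roi_index,
        shape=p.shape,
    )


def build_rating_map(c: ConditionCounts, T: Optional[int] = None) -> RatingMap:
    """Apply the absolute-majority rule to per-voxel condition counts."""
    T = c.T if T is None else int(T)
    tstar = majority_threshold(T)
    max_count = c.counts.max(axis=0)
    arg = c.counts.argmax(axis=0).astype(np.int16)
    assigned = max_count >= tstar
    # the guard exceeds T/2, so an assigned argmax is necessarily unique
    if assigned.any():
        n_at_max = (c.counts[:, assigned] == max_count[assigned]).sum(axis=0)
        if (n_at_max != 1).any():
            raise AssertionError("absolute-majority guard violated: tied argmax assigned")
    labels = np.where(assigned, arg, np.int16(UNASSIGNED))
    return RatingMap(
        labels_flat=labels, conditions=c.conditions, roi_index=c.roi_index, shape=c.shape
    )


def rating_histogram(r: RatingMap) -> RatingHistogram:
    """Percentage of assigned voxels per condition; unassigned counted apart."""
    n_unassigned = int((r.labels_flat == UNASSIGNED).sum())
    counts = {
        cond: int((r.labels_flat == i).sum()) for i, cond in enumerate(r.conditions)
    }
    counts = {c: n for c, n in counts.items() if n > 0}
    return RatingHistogram.from_counts(counts, n_unassigned)


def voxar_diagnose(
    target,
    databases_mapped: Mapping[str, Sequence],
    roi,
    T: int = 7,
    sigma_g: float = 2.0,
) -> DiagnosisReport:
    """Full rating pipeline: LNCC, pooled ranking, rating map, histogram.

    ``databases_mapped`` maps each condition to its mapped atlases
    (:class:`~voxar.registration.MappedAtlas` or bare image arrays).  The
    report is refused (status ``refused``) when no voxel reaches the
    absolute majority.
    """
    if len(databases_mapped) < 2:
        raise ValueError("need at least two conditions to diagnose")
    for cond, atlases in databases_mapped.items():
        if len(atlases) == 0:
            raise ValueError(f"condition {cond!r} has no mapped atlases")
    roi_arr = np.asarray(getattr(roi, "data", roi)) != 0
    tm = TargetMoments(target, sigma_g)
    sims = {
        cond: [
            tm.lncc_to(getattr(a, "image_in_target", a), roi=roi_arr)
            for a in databases_mapped[cond]
        ]
        for cond in databases_mapped
    }
    pooled = pool_rank(sims, roi_arr, T=T)
    rmap = build_rating_map(count_conditions(pooled))
    hist = rating_histogram(rmap)
    params = {"T": T, "sigma_g": sigma_g, "majority_threshold": majority_threshold(T)}
    if hist.empty:
        return DiagnosisReport(
            method="VoxAR",
            predicted=None,
            status=STATUS_REFUSED,
            histogram=hist,
            parameters=params,
            warnings=["no voxel reached the absolute majority; diagnosis refused"],
        )
    return DiagnosisReport(
        method="VoxAR",
        predicted=hist.argmax(),
        status=STATUS_OK,
        histogram=hist,
        parameters=params,
    )
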