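"""Image Synthesis Approach (ISA): rank-weighted fusion and global ranking.

For each condition's database, per-voxel LNCC values are ranked across the
database's atlases (rank 0 = most similar), converted to weights by an
exponential decay ``alpha = exp(-beta * rank)`` with ``beta = 0.5``, and
used to fuse the (z-score normalised) mapped atlas intensities into a
synthetic image.  The synthetic images are ranked by their global NCC to the
(normalised) target; the top-ranked condition is the diagnosis.

Rank origin: the best atlas gets rank 0, hence weight ``exp(0) = 1``.
Starting ranks at 1 would scale every weight by ``exp(-beta)``, which
cancels in the normalised weighted average, so the choice is
diagnosis-neutral.  Voxels where an atlas's LNCC is undefined are excluded
from that database's ranking (the remaining atlases are ranked among
themselves); voxels with no defined atlas carry no synthetic intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .report import STATUS_OK, DiagnosisReport
from .similarity import SimilarityMap, TargetMoments, zscore

__all__ = [
    "RankField",
    "SyntheticImage",
    "rank_in_database",
    "ranks_to_weights",
    "synthesize",
    "isa_diagnose",
    "rank_values",
]

UNDEFINED_RANK = -1


@dataclass
class RankField:
    """Per-voxel rank of each atlas within one database.

    ``ranks`` has shape (n_atlases, n_voxels); rank 0 is the most similar
    atlas at that voxel and :data:`UNDEFINED_RANK` marks voxels where the
    atlas's similarity is undefined.  At every voxel the defined ranks form
    a permutation of ``0..K-1`` over the ``K`` atlases defined there.
    """

    ranks: np.ndarray
    roi_index: np.ndarray  # flat indices of the ROI voxels within the grid
    shape: tuple[int, int, int]


@dataclass
class SyntheticImage:
    """Rank-weight fused synthetic image for one condition."""

    condition: str
    values: np.ndarray  # flat over ROI voxels, NaN where no atlas defined
    defined: np.ndarray
    ncc: Optional[float] = None


def rank_values(values: np.ndarray, defined: np.ndarray) -> np.ndarray:
    """Rank rows of ``values`` (descending) per column among defined entries.

    Ties are broken by row order (stable); undefined entries get
    :data:`UNDEFINED_RANK`.
    """
    filled = np.where(defined, values, -np.inf)
    order = np.argsort(-filled, axis=0, kind="stable")
    ranks = np.empty(values.shape, dtype=np.int32)
    np.put_along_axis(ranks, order, np.arange(values.shape[0], dtype=np.int32)[:, None], axis=0)
    ranks[~defined] = UNDEFINED_RANK
    return ranks


def _stack_maps(sim_maps: Sequence[SimilarityMap], roi) -> tuple[np.ndarray, np.ndarray, np.ndarray, tuple]:
    if len(sim_maps) == 0:
        raise ValueError("need at least one similarity map")
    shape = sim_maps[0].values.shape
    roi_arr = np.asarray(getattr(roi, "data", roi)) != 0
    if roi_arr.shape != shape:
        raise ValueError(f"ROI shape {roi_arr.shape} does not match maps {shape}")
    idx = np.flatnonzero(roi_arr.ravel())
    values = np.stack([m.values.ravel()[idx] for m in sim_maps])
    defined = np.stack([m.defined.ravel()[idx] for m in sim_maps])
    return values, defined, idx, shape


def rank_in_database(sim_maps: Sequence[SimilarityMap], roi) -> RankField:
    """Rank one database's LNCC maps per voxel (0 = most similar)."""
    values, defined, idx, shape = _stack_maps(sim_maps, roi)
    if not defined.any():
        raise ValueError("all similarity maps are undefined at every ROI voxel")
    return RankField(ranks=rank_values(values, defined), roi_index=idx, shape=shape)


def ranks_to_weights(r: RankField | np.ndarray, beta: float = 0.5) -> np.ndarray:
    """Exponential-decay weights ``exp(-beta * rank)``; 0 where undefined."""
    if beta <= 0:
        raise ValueError("beta must be > 0")
    ranks = r.ranks if isinstance(r, RankField) else np.asarray(r)
    weights = np.exp(-beta * np.clip(ranks, 0, None).astype(np.float64))
    weights[ranks == UNDEFINED_RANK] = 0.0
    return weights


def fuse_weighted(values: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalised weighted average along axis 0; NaN where total weight is 0."""
    wsum = weights.sum(axis=0)
    defined = wsum > 0
    fused = np.full(values.shape[1:], np.nan)
    np.divide((weights * values).sum(axis=0), wsum, out=fused, where=defined)
    return fused, defined


def synthesize(
    mapped_images: Sequence,
    weights: np.ndarray,
    roi,
    condition: str = "",
    normalise: bool = True,
) -> SyntheticImage:
    """Fuse mapped atlas intensities with per-voxel weights over the ROI.

    Atlas images are z-score normalised within the ROI before fusion (the
    intensity scale of the source modality is not standardised).
    """
    roi_arr = np.asarray(getattr(roi, "data", roi)) != 0
    idx = np.flatnonzero(roi_arr.ravel())
    rows = []
    for img in mapped_images:
        arr = np.asarray(getattr(img, "data", img), dtype=np.float64)
        if arr.shape != roi_arr.shape:
            raise ValueError(f"image shape {arr.shape} does not match ROI {roi_arr.shape}")
        if normalise:
            arr = zscore(arr, roi_arr)
        rows.append(arr.ravel()[idx])
    values = np.stack(rows)
    if weights.shape != values.shape:
        raise ValueError(f"weights shape {weights.shape} does not match stacked images {values.shape}")
    fused, defined = fuse_weighted(values, weights)
    if not defined.any():
        raise ValueError("zero total weight at every ROI voxel")
    # fusion convexity: the weighted mean stays within the contributing range
    return SyntheticImage(condition=condition, values=fused, defined=defined)


def isa_diagnose(
    databases_mapped: Mapping[str, Sequence],
    target,
    roi,
    beta: float = 0.5,
    sigma_g: float = 2.0,
) -> DiagnosisReport:
    """Synthesise one image per condition and diagnose by global NCC.

    ``databases_mapped`` maps each condition to its mapped atlases
    (:class:`~voxar.registration.MappedAtlas` or bare image arrays).
    """
    if len(databases_mapped) < 2:
        raise ValueError("need at least two conditions to diagnose")
    roi_arr = np.asarray(getattr(roi, "data", roi)) != 0
    idx = np.flatnonzero(roi_arr.ravel())
    tm = TargetMoments(target, sigma_g)
    target_norm = zscore(tm.arr, roi_arr).ravel()[idx]

    warnings_list: list[str] = []
    scores: dict[str, float] = {}
    for cond in sorted(databases_mapped):
        atlases = databases_mapped[cond]
        images = [getattr(a, "image_in_target", a) for a in atlases]
        sims = [tm.lncc_to(img, roi=roi_arr) for img in images]
        ranks = rank_in_database(sims, roi_arr)
        weights = ranks_to_weights(ranks, beta)
        synth = synthesize(images, weights, roi_arr, condition=cond)
        sel = synth.defined
        x = target_norm[sel]
        y = synth.values[sel]
        xd, yd = x - x.mean(), y - y.mean()
        denom = np.sqrt((xd * xd).sum() * (yd * yd).sum())
        if denom == 0:
            raise ValueError(f"constant synthetic image for condition {cond!r}")
        scores[cond] = float((xd * yd).sum() / denom)

    best = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
    if len(best) > 1 and abs(best[0][1] - best[1][1]) < 1e-10:
        warnings_list.append(
            f"NCC tie between {best[0][0]!r} and {best[1][0]!r}; "
            "broken by condition-name order"
        )
    return DiagnosisReport(
        method="ISA",
        predicted=best[0][0],
        status=STATUS_OK,
        ncc_scores=scores,
        parameters={"beta": beta, "sigma_g": sigma_g},
        warnings=warnings_list,
    )
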