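"""Local and global image similarity.

The local normalised correlation coefficient (LNCC) between a target image
``I`` and a mapped atlas image ``J`` at voxel ``x`` is

    LNCC(x) = <I, J>(x) / (sigma_I(x) * sigma_J(x))

where local means, variances and the covariance are obtained by convolving
with an isotropic Gaussian kernel ``G_sigma`` (sigma expressed in voxels):

    mean_I   = G * I
    var_I    = G * I^2 - mean_I^2          (clamped at 0)
    <I, J>   = G * (I J) - mean_I mean_J

Boundary rule: the convolution uses zero padding and renormalises by the
convolved all-ones field, i.e. near edges the Gaussian weights are
renormalised over in-grid voxels only, avoiding edge attenuation bias inside
the ROI.  The kernel is truncated at 4 sigma.

Voxels where the product of local standard deviations falls below
``tau = 1e-6 * (global intensity scale)^2`` are flagged undefined (the
correlation is a 0/0 form in locally flat regions) and carry NaN.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "SimilarityMap",
    "LocalMoments",
    "TargetMoments",
    "local_moments",
    "lncc",
    "zscore",
    "global_ncc",
]

_TRUNCATE = 4.0
_SIGMA_EPS = 1e-6  # relative threshold defining "locally flat"


def _as_array(v) -> np.ndarray:
    arr = np.asarray(getattr(v, "data", v), dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D grid, got shape {arr.shape}")
    return arr


def _as_roi(roi, shape) -> np.ndarray:
    if roi is None:
        return np.ones(shape, dtype=bool)
    arr = np.asarray(getattr(roi, "data", roi)) != 0
    if arr.shape != shape:
        raise ValueError(f"ROI shape {arr.shape} does not match image shape {shape}")
    return arr


def _smooth(arr: np.ndarray, sigma: float) -> np.ndarray:
    return ndimage.gaussian_filter(arr, sigma, mode="constant", cval=0.0, truncate=_TRUNCATE)


_weight_cache: dict[tuple[tuple[int, ...], float], np.ndarray] = {}


def _boundary_weights(shape: tuple[int, ...], sigma: float) -> np.ndarray:
    """Convolved all-ones field used to renormalise zero-padded convolutions."""
    key = (tuple(shape), float(sigma))
    w = _weight_cache.get(key)
    if w is None:
        w = _smooth(np.ones(shape, dtype=np.float64), sigma)
        if len(_weight_cache) > 16:
            _weight_cache.clear()
        _weight_cache[key] = w
    return w


@dataclass
class SimilarityMap:
    """Per-voxel LNCC between the target and one mapped atlas.

    ``values`` is a full-grid float array with NaN at undefined voxels
    (outside the ROI or where either image is locally flat); ``defined``
    is the corresponding boolean mask.
    """

    values: np.ndarray
    defined: np.ndarray
    sigma_g: float
    atlas_id: Optional[str] = None
    condition: Optional[str] = None


@dataclass
class LocalMoments:
    """Gaussian-windowed local moments of an image pair."""

    mean_a: np.ndarray
    mean_b: np.ndarray
    std_a: np.ndarray
    std_b: np.ndarray
    cov: np.ndarray


class TargetMoments:
    """Cached Gaussian moments of a fixed target image.

    Computing LNCC of one target against many atlases only needs the target's
    smoothed fields once; this cache is what the evaluation harness reuses.
    """

    def __init__(self, target, sigma_g: float = 2.0):
        if sigma_g <= 0:
            raise ValueError("sigma_g must be > 0")
        self.sigma_g = float(sigma_g)
        self.arr = _as_array(target)
        self.w = _boundary_weights(self.arr.shape, self.sigma_g)
        self.mean = _smooth(self.arr, self.sigma_g) / self.w
        var = _smooth(self.arr * self.arr, self.sigma_g) / self.w - self.mean**2
        self.var = np.clip(var, 0.0, None)
        self.std = np.sqrt(self.var)

    def moments_with(self, other) -> LocalMoments:
        b = _as_array(other)
        if b.shape != self.arr.shape:
            raise ValueError(f"geometry mismatch: {self.arr.shape} vs {b.shape}")
        mean_b = _smooth(b, self.sigma_g) / self.w
        var_b = np.clip(_smooth(b * b, self.sigma_g) / self.w - mean_b**2, 0.0, None)
        cov = _smooth(self.arr * b, self.sigma_g) / self.w - self.mean * mean_b
        return LocalMoments(
            mean_a=self.mean,
            mean_b=mean_b,
            std_a=self.std,
            std_b=np.sqrt(var_b),
            cov=cov,
        )

    def lncc_to(self, other, roi=None) -> SimilarityMap:
        b = _as_array(other)
        roi_arr = _as_roi(roi, self.arr.shape)
        if not roi_arr.any():
            raise ValueError("empty ROI")
        m = self.moments_with(b)
        denom = m.std_a * m.std_b
        scale = max(
            float(np.ptp(self.arr[roi_arr])), float(np.ptp(b[roi_arr])), np.finfo(float).tiny
        )
        tau = _SIGMA_EPS * scale**2
        defined = (denom > tau) & roi_arr
        values = np.full(self.arr.shape, np.nan)
        np.divide(m.cov, denom, out=values, where=defined)
        return SimilarityMap(values=values, defined=defined, sigma_g=self.sigma_g)


def local_moments(a, b, sigma_g: float) -> LocalMoments:
    """Gaussian-windowed mean/std/covariance fields of two images."""
    return TargetMoments(a, sigma_g).moments_with(b)


def lncc(target, mapped, roi=None, sigma_g: float = 2.0) -> SimilarityMap:
    """Local normalised correlation coefficient map inside ``roi``.

    Defaults to a Gaussian window of 2 voxels, small enough to capture
    localised morphological differences between target and atlas.
    """
    return TargetMoments(target, sigma_g).lncc_to(mapped, roi=roi)


def zscore(v, roi=None) -> np.ndarray:
    """Standard-score normalisation with statistics taken over the ROI.

    The mean and population standard deviation are computed over ROI voxels;
    voxels outside the ROI are transformed with the same affine map.
    """
    arr = _as_array(v)
    roi_arr = _as_roi(roi, arr.shape)
    if not roi_arr.any():
        raise ValueError("empty ROI")
    vals = arr[roi_arr]
    mu = float(vals.mean())
    sd = float(vals.std())
    if sd == 0.0:
        raise ValueError("zero intensity variance inside the ROI; z-score undefined")
    return (arr - mu) / sd


def global_ncc(a, b, roi=None) -> float:
    """Pearson correlation of two images over ROI voxels (in [-1, 1])."""
    arr_a, arr_b = _as_array(a), _as_array(b)
    if arr_a.shape != arr_b.shape:
        raise ValueError(f"geometry mismatch: {arr_a.shape} vs {arr_b.shape}")
    roi_arr = _as_roi(roi, arr_a.shape)
    if not roi_arr.any():
        raise ValueError("empty ROI")
    x = arr_a[roi_arr]
    y = arr_b[roi_arr]
    xd = x - x.mean()
    yd = y - y.mean()
    nx = float(np.sqrt((xd * xd).sum()))
    ny = float(np.sqrt((yd * yd).sum()))
    if nx == 0.0 or ny == 0.0:
        raise ValueError("constant image inside the ROI; NCC undefined")
    return float((xd * yd).sum() / (nx * ny))
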