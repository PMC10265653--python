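"""Hessian tube filtering of AFM height maps.

Filamentous (curvilinear) structures are bright ridges: at the right
scale, the Hessian of a Gaussian-smoothed height map has one strongly
negative eigenvalue across the ridge and one near zero along it. The tube
filter keeps |lambda_2| (the more-negative eigenvalue) where it is
negative, normalizes by scale^2 and takes the per-pixel maximum over
scales. Thresholding the response yields a filament mask from which
background-corrected pixel heights are pooled into a height distribution;
its mode is the single-filament height, with an overlap tail above it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.filters import threshold_otsu

log = logging.getLogger(__name__)


@dataclass
class HeightMap:
    """AFM height field in nm with optional mask and pooled height profile."""

    heights: np.ndarray
    pixel_size_nm: float
    mask: np.ndarray | None = None
    profile: np.ndarray | None = field(default=None)

    def __post_init__(self):
        self.heights = np.asarray(self.heights, float)
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("height map contains non-finite values")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, bool)
            if self.mask.shape != self.heights.shape:
                raise ValueError("mask shape must match height map")


def tubeness(image: np.ndarray, scales: list[float],
             pixel_size: float = 1.0) -> np.ndarray:
    """Multi-scale bright-ridge strength from Hessian eigenvalues.

    ``scales`` are ridge half-widths in the same physical unit as
    ``pixel_size`` (pass pixel_size=1 for scales in pixels). Per scale the
    response is scale^2 * max(-lambda_2, 0) with lambda_2 the more-negative
    Hessian eigenvalue of the Gaussian-smoothed image; the final field is
    the per-pixel maximum over scales.
    """
    image = np.asarray(image, float)
    if image.ndim != 2:
        raise ValueError("tubeness expects a 2D image")
    if len(scales) == 0 or any(s <= 0 for s in scales):
        raise ValueError("scales must be a non-empty list of positive values")
    out = np.zeros_like(image)
    for s in scales:
        sig = s / pixel_size
        H = hessian_matrix(image, sigma=sig, order="rc", mode="reflect",
                           use_gaussian_derivatives=True)
        ev = hessian_matrix_eigvals(H)  # decreasing order; ev[-1] most negative
        resp = sig**2 * np.maximum(-ev[-1], 0.0)
        np.maximum(out, resp, out=out)
    return out


def mask_and_extract(image: np.ndarray, tube_response: np.ndarray,
                     threshold_method: str | float = "otsu"
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Threshold the tube response into a mask; background-correct the image.

    The mask is ``tube_response`` above an Otsu threshold computed on the
    nonzero response values (or above the given quantile of nonzero values
    when ``threshold_method`` is a float in (0, 1)). The background level is
    the median of the unmasked pixels and is subtracted from the whole
    image. Returns (mask, corrected image zeroed outside the mask, profile
    of corrected masked heights).
    """
    image = np.asarray(image, float)
    tube_response = np.asarray(tube_response, float)
    if image.shape != tube_response.shape:
        raise ValueError("image and tube response must have the same shape")
    nz = tube_response[tube_response > 0]
    if nz.size == 0:
        log.warning("tube response is empty; returning empty mask")
        return (np.zeros(image.shape, bool), np.zeros_like(image),
                np.empty(0))
    if threshold_method == "otsu":
        thr = threshold_otsu(nz)
    else:
        q = float(threshold_method)
        if not 0.0 < q < 1.0:
            raise ValueError("quantile threshold must lie in (0, 1)")
        thr = np.quantile(nz, q)
    mask = tube_response > thr
    if not mask.any():
        log.warning("tube mask is empty at the chosen threshold")
        return mask, np.zeros_like(image), np.empty(0)
    background = np.median(image[~mask]) if (~mask).any() else 0.0
    corrected = image - background
    out = np.where(mask, corrected, 0.0)
    return mask, out, corrected[mask]


def height_distribution(maps: list[HeightMap], bin_nm: float = 1.0
                        ) -> tuple[np.ndarray, np.ndarray, float]:
    """Pooled pixel-wise height histogram over maps, and its mode.

    Bins are ``bin_nm`` wide and centered on integer multiples of
    ``bin_nm`` so a nominal filament height lands mid-bin. Returns
    (counts, bin edges, mode = center of the highest bin).
    """
    profiles = [m.profile for m in maps
                if m.profile is not None and m.profile.size]
    if not profiles:
        raise ValueError("all height profiles are empty")
    pooled = np.concatenate(profiles)
    lo = np.floor(pooled.min() / bin_nm) * bin_nm - bin_nm / 2.0
    hi = np.ceil(pooled.max() / bin_nm) * bin_nm + bin_nm / 2.0
    edges = np.arange(lo, hi + bin_nm / 2.0, bin_nm)
    counts, edges = np.histogram(pooled, bins=edges)
    mode = float((edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]) / 2.0)
    return counts, edges, mode


def analyze_height_map(heights: np.ndarray, pixel_size_nm: float,
                       scales_nm: list[float] | None = None,
                       threshold_method: str | float = "otsu") -> HeightMap:
    """Full single-map pipeline: tubeness -> mask -> background -> profile."""
    if scales_nm is None:
        scales_nm = [5.0, 10.0, 15.0]
    resp = tubeness(heights, scales_nm, pixel_size=pixel_size_nm)
    mask, _, profile = mask_and_extract(heights, resp, threshold_method)
    return HeightMap(heights=np.asarray(heights, float),
                     pixel_size_nm=pixel_size_nm, mask=mask, profile=profile)
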