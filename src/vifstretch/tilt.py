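"""Tilt correction of z-stacks taken on free-standing elastomer sheets.

A free-standing sheet tilts and bows, so a single confocal slice is partly
out of focus. The correction builds a per-pixel sharpness measure from the
squared Laplacian of each slice, normalizes it along z, finds the
best-in-focus slice on a coarse grid, fits a second-order polynomial
surface z(x, y) to those grid points and interpolates the stack onto the
fitted surface, producing one everywhere-in-focus image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .synthetic import focus_surface_eval

log = logging.getLogger(__name__)

LAPLACIAN_KERNEL = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], float)


@dataclass
class FocusSurface:
    """Second-order polynomial focus surface fitted to grid best-z points."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    best_z: np.ndarray
    coeffs: np.ndarray  # c0 + c1 x + c2 y + c3 x^2 + c4 x y + c5 y^2
    residual_rms: float

    def __call__(self, x, y):
        return focus_surface_eval(self.coeffs, x, y)


def sharpness_stack(zstack: np.ndarray, window: int = 9) -> np.ndarray:
    """Per-slice, per-pixel sharpness, normalized along z.

    Sharpness is the squared response of the 4-neighbor discrete Laplacian,
    averaged over a ``window`` x ``window`` boxcar, then divided by the
    per-pixel sum over z (where that sum is positive), so each pixel's
    sharpness profile along z sums to one.
    """
    zstack = np.asarray(zstack, float)
    if zstack.ndim != 3 or zstack.shape[0] < 3:
        raise ValueError("need a z-stack of at least three slices")
    sharp = np.empty_like(zstack)
    for i, sl in enumerate(zstack):
        lap = ndi.convolve(sl, LAPLACIAN_KERNEL, mode="nearest")
        sharp[i] = ndi.uniform_filter(lap**2, window)
    total = sharp.sum(axis=0)
    flat = total <= 0
    if flat.all():
        log.warning("constant stack: no sharpness signal anywhere")
        return sharp
    with np.errstate(invalid="ignore", divide="ignore"):
        sharp = np.where(flat[None], sharp, sharp / np.where(flat, 1.0, total)[None])
    return sharp


def best_focus_surface(sharpness: np.ndarray,
                       grid_size: tuple[int, int] = (8, 8)) -> FocusSurface:
    """Fit the polynomial focus surface to per-cell best-in-focus indices.

    The stack is divided into ``grid_size`` cells; each cell's best z is
    the argmax of the aggregated normalized sharpness, refined to sub-slice
    precision by a parabola through the argmax and its neighbors, and a
    second-order polynomial in (x, y) is fitted to the cell centers by
    ordinary least squares.
    """
    sharpness = np.asarray(sharpness, float)
    nz, h, w = sharpness.shape
    gy, gx = grid_size
    if gy < 2 or gx < 2:
        raise ValueError("grid must be at least 2x2")
    if sharpness.sum() <= 0:
        raise ValueError("no focus signal: sharpness is zero everywhere")
    ys = np.linspace(0, h, gy + 1).astype(int)
    xs = np.linspace(0, w, gx + 1).astype(int)
    cx, cy, bz = [], [], []
    for iy in range(gy):
        for ix in range(gx):
            cell = sharpness[:, ys[iy]:ys[iy + 1], xs[ix]:xs[ix + 1]]
            prof = cell.sum(axis=(1, 2))
            if prof.sum() <= 0:
                continue
            k = int(np.argmax(prof))
            z = float(k)
            if 0 < k < nz - 1:  # parabolic sub-slice refinement
                denom = prof[k - 1] - 2 * prof[k] + prof[k + 1]
                if denom < 0:
                    z = k + 0.5 * (prof[k - 1] - prof[k + 1]) / denom
            cx.append((xs[ix] + xs[ix + 1] - 1) / 2.0)
            cy.append((ys[iy] + ys[iy + 1] - 1) / 2.0)
            bz.append(z)
    cx, cy, bz = np.array(cx), np.array(cy), np.array(bz)
    M = np.column_stack([np.ones_like(cx), cx, cy, cx**2, cx * cy, cy**2])
    coeffs, *_ = np.linalg.lstsq(M, bz, rcond=None)
    resid = M @ coeffs - bz
    return FocusSurface(grid_x=cx, grid_y=cy, best_z=bz, coeffs=coeffs,
                        residual_rms=float(np.sqrt(np.mean(resid**2))))


def correct_tilt(zstack: np.ndarray, surface: FocusSurface) -> np.ndarray:
    """Interpolate the stack along z onto the focus surface.

    Output pixel (x, y) is the linear interpolation of the stack at
    z = surface(x, y), clipped (with a log message) to the stack's z-range.
    """
    zstack = np.asarray(zstack, float)
    nz, h, w = zstack.shape
    yy, xx = np.mgrid[0:h, 0:w]
    z = surface(xx, yy)
    if z.min() < 0 or z.max() > nz - 1:
        log.warning("focus surface leaves the stack z-range; clipping")
    z = np.clip(z, 0, nz - 1)
    lo = np.floor(z).astype(int)
    hi = np.minimum(lo + 1, nz - 1)
    frac = z - lo
    out = ((1 - frac) * np.take_along_axis(zstack, lo[None], 0)[0]
           + frac * np.take_along_axis(zstack, hi[None], 0)[0])
    return out
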