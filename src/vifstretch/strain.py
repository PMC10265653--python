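"""Substrate strain fields from fiducial bead tracking.

Fluorescent beads embedded in the elastomer sheet act as fiducial markers:
tracking them across motor positions yields a displacement field from
which the longitudinal and lateral Cauchy strains (eps = dL / L relative
to the unstretched state), the substrate's Poisson ratio, the best-fit
affine transform, and the zero-strain direction are derived.

Coordinate convention: image row index = y (the stretch axis), column = x;
angles are measured from the +y axis in degrees.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.optimize import brentq
from skimage.feature import peak_local_max

log = logging.getLogger(__name__)


@dataclass
class BeadTrackSet:
    """Sub-pixel bead positions across motor-position steps.

    ``positions`` has shape (n_beads, n_steps, 2) in (x, y) pixel
    coordinates; every retained bead is present at every step. The
    reference bead is the one with minimal total displacement — the bead
    closest to the stretch center, against which displacements are measured.
    """

    positions: np.ndarray
    pixel_size: float = 1.0
    reference_bead_id: int = field(init=False, default=0)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 2:
            raise ValueError("positions must have shape (n_beads, n_steps, 2)")
        disp = np.linalg.norm(self.positions - self.positions[:, :1], axis=2)
        self.reference_bead_id = int(np.argmin(disp.sum(axis=1)))

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def n_steps(self) -> int:
        return self.positions.shape[1]

    def relative_to_reference(self) -> np.ndarray:
        """Positions with the reference bead's motion subtracted per step."""
        ref = self.positions[self.reference_bead_id]
        return self.positions - ref[None, :, :]

    def to_frame(self) -> pd.DataFrame:
        rows = [(b, k, *self.positions[b, k])
                for b in range(self.n_beads) for k in range(self.n_steps)]
        return pd.DataFrame(rows, columns=["bead_id", "step", "x_px", "y_px"])


@dataclass
class StrainSeries:
    """Per-step longitudinal (eps_yy) and lateral (eps_xx) Cauchy strains."""

    eps_yy: np.ndarray
    eps_xx: np.ndarray
    method: str = "pairwise-cauchy"

    def __post_init__(self):
        self.eps_yy = np.asarray(self.eps_yy, float)
        self.eps_xx = np.asarray(self.eps_xx, float)
        if abs(self.eps_yy[0]) > 1e-12 or abs(self.eps_xx[0]) > 1e-12:
            raise ValueError("strains at step 0 must be exactly zero")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"step": np.arange(len(self.eps_yy)),
                             "eps_yy": self.eps_yy, "eps_xx": self.eps_xx})


# ---------------------------------------------------------------------------
# detection and tracking


def _detect_beads(frame: np.ndarray, expected_radius_px: float) -> np.ndarray:
    """Sub-pixel bead centers in one frame, (n, 2) in (x, y)."""
    smoothed = ndi.gaussian_filter(frame, expected_radius_px / 2.0)
    thr = smoothed.mean() + 3.0 * smoothed.std()
    peaks = peak_local_max(smoothed, min_distance=int(2 * expected_radius_px),
                           threshold_abs=thr)
    if len(peaks) == 0:
        return np.empty((0, 2))
    centers = []
    r = int(np.ceil(3 * expected_radius_px))
    h, w = frame.shape
    for py, px in peaks:
        y0, y1 = max(py - r, 0), min(py + r + 1, h)
        x0, x1 = max(px - r, 0), min(px + r + 1, w)
        win = frame[y0:y1, x0:x1] - frame[y0:y1, x0:x1].min()
        tot = win.sum()
        if tot <= 0:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        centers.append(((xx * win).sum() / tot, (yy * win).sum() / tot))
    return np.asarray(centers)


def detect_and_track_beads(stack: np.ndarray, expected_radius_px: float = 2.0,
                           link_mode: str = "nearest",
                           pixel_size: float = 1.0) -> BeadTrackSet:
    """Detect beads in every frame and link them across motor positions.

    Detections use blob finding (smoothed local maxima) with center-of-mass
    sub-pixel refinement. Links are formed frame to frame by nearest
    neighbor; ``link_mode='affine_predicted'`` first warps the previous
    positions by the affine estimated from the already-linked steps, which
    keeps identities through the large jumps of fast single-step stretches.
    Beads that are lost in any frame are dropped (count logged).
    """
    stack = np.asarray(stack, float)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("need a stack of at least two frames")
    if link_mode not in ("nearest", "affine_predicted"):
        raise ValueError("unknown link_mode")
    detections = []
    for k, frame in enumerate(stack):
        det = _detect_beads(frame, expected_radius_px)
        if len(det) == 0:
            raise ValueError(f"no beads detected in frame {k}")
        detections.append(det)

    tracks = [detections[0]]  # list of (n_tracked, 2) per step
    for k in range(1, len(detections)):
        prev = tracks[-1]
        cur = detections[k]
        if link_mode == "affine_predicted":
            link = _link_affine_icp(prev, cur)
        else:
            link = _greedy_link(prev, cur)
        keep = link >= 0
        if not np.all(keep):
            log.info("dropped %d beads lost at step %d", int((~keep).sum()), k)
        tracks = [tr[keep] for tr in tracks]
        link = link[keep]
        tracks.append(cur[link])
    positions = np.stack(tracks, axis=1)  # (n_beads, n_steps, 2)
    return BeadTrackSet(positions=positions, pixel_size=pixel_size)


def _greedy_link(pred: np.ndarray, cur: np.ndarray) -> np.ndarray:
    """Greedy one-to-one nearest-neighbor assignment; -1 for unmatched."""
    d = np.linalg.norm(pred[:, None, :] - cur[None, :, :], axis=2)
    link = np.full(len(pred), -1)
    used = np.zeros(len(cur), bool)
    for i in np.argsort(d.min(axis=1)):
        free = np.where(used, np.inf, d[i])
        j = int(np.argmin(free))
        if np.isfinite(free[j]):
            link[i] = j
            used[j] = True
    return link


def _link_affine_icp(prev: np.ndarray, cur: np.ndarray,
                     max_iter: int = 8) -> np.ndarray:
    """Link through large displacements by alternating linking and affine fits.

    Starting from plain nearest neighbor, the affine map implied by the
    current links (refit after trimming links with residual > 3x median)
    pre-warps the previous positions and linking is repeated until stable.
    """
    link = _greedy_link(prev, cur)
    for _ in range(max_iter):
        got = link >= 0
        if got.sum() < 3:
            break
        A, t = _lstsq_affine(prev[got], cur[link[got]])
        resid = np.linalg.norm(prev[got] @ A.T + t - cur[link[got]], axis=1)
        good = resid <= 3.0 * max(np.median(resid), 1e-6)
        if good.sum() >= 3:
            A, t = _lstsq_affine(prev[got][good], cur[link[got]][good])
        new_link = _greedy_link(prev @ A.T + t, cur)
        if np.array_equal(new_link, link):
            break
        link = new_link
    return link


# ---------------------------------------------------------------------------
# strain computation


def cauchy_strain_series(tracks: BeadTrackSet,
                         axis_tol_deg: float = 15.0) -> StrainSeries:
    """Pairwise Cauchy strains eps = d(separation) / separation(step 0).

    For the longitudinal strain, bead pairs whose step-0 separation vector
    lies within ``axis_tol_deg`` of the y axis contribute dL/L of their
    y separations, pooled with separation weights (sum of length changes
    over sum of reference lengths), so short pairs — whose noisy reference
    separation would otherwise bias the ratio — do not dominate;
    analogously for the lateral strain along x. Displacements are measured
    relative to the reference bead.
    """
    pos = tracks.relative_to_reference()
    n, n_steps = tracks.n_beads, tracks.n_steps
    if n < 2:
        raise ValueError("need at least two beads")
    iu, ju = np.triu_indices(n, k=1)
    sep0 = pos[iu, 0] - pos[ju, 0]  # (n_pairs, 2)
    ang_from_y = np.degrees(np.arctan2(np.abs(sep0[:, 0]), np.abs(sep0[:, 1])))
    y_pairs = (ang_from_y <= axis_tol_deg) & (np.abs(sep0[:, 1]) > 1e-9)
    x_pairs = (ang_from_y >= 90.0 - axis_tol_deg) & (np.abs(sep0[:, 0]) > 1e-9)
    if not y_pairs.any():
        raise ValueError("no bead pairs aligned with the y (stretch) axis")
    if not x_pairs.any():
        raise ValueError("no bead pairs aligned with the x (lateral) axis")
    eps_yy = np.zeros(n_steps)
    eps_xx = np.zeros(n_steps)
    for k in range(1, n_steps):
        sep = pos[iu, k] - pos[ju, k]
        dy0 = np.abs(sep0[y_pairs, 1])
        dx0 = np.abs(sep0[x_pairs, 0])
        eps_yy[k] = np.sum(np.abs(sep[y_pairs, 1]) - dy0) / np.sum(dy0)
        eps_xx[k] = np.sum(np.abs(sep[x_pairs, 0]) - dx0) / np.sum(dx0)
    return StrainSeries(eps_yy=eps_yy, eps_xx=eps_xx, method="pairwise-cauchy")


def _lstsq_affine(p0: np.ndarray, pk: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares affine map pk ~= p0 @ A.T + t."""
    n = len(p0)
    M = np.column_stack([p0, np.ones(n)])
    if np.linalg.matrix_rank(M) < 3:
        raise ValueError("beads are collinear: affine fit is rank-deficient")
    sol, *_ = np.linalg.lstsq(M, pk, rcond=None)
    return sol[:2].T, sol[2]


def estimate_affine_strain(tracks: BeadTrackSet
                           ) -> tuple[StrainSeries, list[np.ndarray]]:
    """Per-step least-squares affine fit of bead correspondences.

    The strain series is read from the diagonal of the linear part minus
    identity. Returns (series, list of 2x2 linear parts per step).
    """
    pos = tracks.positions
    if tracks.n_beads < 3:
        raise ValueError("need at least three non-collinear beads")
    transforms = []
    eps_yy = np.zeros(tracks.n_steps)
    eps_xx = np.zeros(tracks.n_steps)
    for k in range(tracks.n_steps):
        if k == 0:
            A = np.eye(2)
        else:
            A, _ = _lstsq_affine(pos[:, 0], pos[:, k])
        transforms.append(A)
        eps_xx[k] = A[0, 0] - 1.0
        eps_yy[k] = A[1, 1] - 1.0
    return StrainSeries(eps_yy=eps_yy, eps_xx=eps_xx, method="affine"), transforms


def poisson_ratio(series: StrainSeries, step: int = -1) -> float:
    """nu = -eps_xx / eps_yy at the given step."""
    eyy = float(series.eps_yy[step])
    if eyy == 0:
        raise ValueError("Poisson ratio undefined at zero longitudinal strain")
    return -float(series.eps_xx[step]) / eyy


# ---------------------------------------------------------------------------
# zero-strain direction


def zero_strain_angle(eps_yy: float, eps_xx: float) -> float:
    """Direction (deg from the stretch axis) of zero length change.

    A uniaxially stretched, laterally compressed sheet maps the unit circle
    onto an ellipse with semi-axes a = 1 + eps_xx along x and b = 1 + eps_yy
    along y. Where that ellipse crosses the unit circle, material line
    elements keep their length: with the angle alpha measured from the
    y axis, sin^2(alpha) = (1 - b^-2) / (a^-2 - b^-2).
    """
    a, b = 1.0 + eps_xx, 1.0 + eps_yy
    if eps_yy == 0 and eps_xx < 0:
        return 0.0
    if eps_xx == 0 and eps_yy > 0:
        return 90.0
    if not (eps_yy > 0 > eps_xx):
        raise ValueError("uniform expansion/compression: no zero-strain direction")
    s2 = (1.0 - b**-2) / (a**-2 - b**-2)
    return float(np.degrees(np.arcsin(np.sqrt(s2))))


def zero_strain_angle_numeric(eps_yy: float, eps_xx: float) -> float:
    """Root-finder check of the closed form: intersect circle and ellipse."""
    a, b = 1.0 + eps_xx, 1.0 + eps_yy
    if not (eps_yy > 0 > eps_xx):
        raise ValueError("uniform expansion/compression: no zero-strain direction")

    def f(alpha):  # point on unit circle at alpha from y axis, ellipse eq.
        return (np.sin(alpha) / a) ** 2 + (np.cos(alpha) / b) ** 2 - 1.0

    root = brentq(f, 1e-12, np.pi / 2 - 1e-12, xtol=1e-12)
    return float(np.degrees(root))
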