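"""Synthetic data generation for the stretch-analysis pipeline.

Every downstream module (tilt correction, bead strain fields, filament
tracing, AFM tube filtering, FRAP fitting) is exercised against images and
curves produced here, with exact ground truth attached. The generators
emulate the statistical structure of uniaxial-stretcher experiments:

* fiducial beads carried by a diagonal affine map (longitudinal Cauchy
  strain up to +33%, lateral down to −12% at the last motor position),
* worm-like-chain filaments preferentially aligned with the stretch axis
  whose contour length grows by a tunable fraction ``kappa`` of the
  substrate strain,
* entangled filament height maps with a single-filament height of 10 nm
  and additive stacking at crossings,
* Soumpasis-shaped fluorescence-recovery curves (250 frames, 54 ms apart),
* tilted z-stacks whose best-focus surface is a second-order polynomial.

All randomness flows through ``numpy.random.default_rng(seed)``; a fixed
seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .frap import soumpasis_model

# Strain-transfer coefficients matching the two stretching speeds studied:
# slow (v = 20 um/s) and fast (v = 750 um/s) substrate actuation.
KAPPA_SLOW = 0.16
KAPPA_FAST = 0.26

DEFAULT_TUBE_HEIGHT_NM = 10.0


@dataclass
class StretchConfig:
    """Motor-position schedule of the uniaxial stretcher.

    Per-step Cauchy strains are linear in the step index; step 0 is the
    unstretched state (strains exactly zero).

    Parameters
    ----------
    n_steps : number of motor positions (mp 0..n_steps-1).
    eps_yy_max : longitudinal strain at the last step (fraction, > 0).
    eps_xx_max : lateral strain at the last step (fraction, < 0).
    pixel_size : um per pixel of the rendered images.
    seed : generator seed.
    """

    n_steps: int = 11
    eps_yy_max: float = 0.33
    eps_xx_max: float = -0.12
    pixel_size: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_steps < 2:
            raise ValueError("need at least two motor positions")
        if not self.eps_yy_max > 0:
            raise ValueError("longitudinal strain at full stretch must be positive")
        if not self.eps_xx_max < 0:
            raise ValueError("lateral strain at full stretch must be negative")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    def strains(self) -> tuple[np.ndarray, np.ndarray]:
        """(eps_yy, eps_xx) arrays over steps, linear in step index."""
        f = np.arange(self.n_steps) / (self.n_steps - 1)
        return self.eps_yy_max * f, self.eps_xx_max * f

    def affine(self, step: int) -> np.ndarray:
        """Diagonal linear part diag(1+eps_xx, 1+eps_yy) at ``step`` (x, y order)."""
        eyy, exx = self.strains()
        return np.diag([1.0 + exx[step], 1.0 + eyy[step]])


@dataclass
class FilamentTruth:
    """Ground truth for one synthetic filament.

    ``backbone`` is an ordered (n, 2) array of (x, y) points in um at step 0
    whose polyline arc length equals ``L0``. ``kappa`` is the fraction of
    substrate strain transmitted into contour elongation.
    """

    backbone: np.ndarray
    Lp_true: float
    L0: float
    mean_angle: float
    kappa: float

    def __post_init__(self):
        self.backbone = np.asarray(self.backbone, float)
        if self.backbone.ndim != 2 or len(self.backbone) < 2:
            raise ValueError("backbone needs at least two 2D points")
        if self.L0 <= 0:
            raise ValueError("L0 must be positive")
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        arc = polyline_length(self.backbone)
        if abs(arc - self.L0) > 1e-3 * self.L0:
            raise ValueError("backbone arc length inconsistent with L0")


@dataclass
class AFMTruth:
    """Ground truth for a synthetic AFM height map (all lengths in nm)."""

    tubes: list = field(default_factory=list)
    tube_height: float = DEFAULT_TUBE_HEIGHT_NM
    tube_width_sigma: float = 12.0
    overlap_rule: str = "additive"
    noise_sigma: float = 0.5

    def __post_init__(self):
        if self.tube_height <= 0:
            raise ValueError("tube_height must be positive")
        if self.overlap_rule not in ("additive", "max"):
            raise ValueError("overlap_rule must be 'additive' or 'max'")


@dataclass
class FRAPTruth:
    """Ground truth for a synthetic fluorescence-recovery curve."""

    tau_D: float = 2.0**2 / (4 * 1.4)  # s; w=2 um at D=1.4 um^2/s
    w: float = 2.0  # bleach-spot radius, um
    mobile_fraction: float = 0.91
    F0: float = 0.15  # normalized intensity right after the bleach
    F_pre: float = 1.0  # normalized pre-bleach level
    frame_interval: float = 0.054  # s
    n_frames: int = 250
    noise_sigma: float = 0.02

    def __post_init__(self):
        if self.tau_D <= 0:
            raise ValueError("tau_D must be positive")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must lie in [0, 1]")
        if self.n_frames < 2:
            raise ValueError("need at least two frames")


# ---------------------------------------------------------------------------
# small geometry helpers shared by the generators


def polyline_length(points: np.ndarray) -> float:
    points = np.asarray(points, float)
    return float(np.sum(np.hypot(*np.diff(points, axis=0).T)))


def wlc_backbone(L0: float, Lp: float, start: np.ndarray, theta0: float,
                 rng: np.random.Generator, ds: float = 0.05) -> np.ndarray:
    """Discrete 2D worm-like chain of arc length exactly ``L0``.

    Tangent angle performs a random walk with variance ds/Lp per step, which
    yields the 2D tangent correlation <cos dtheta(s)> = exp(-s / (2 Lp)).
    ``theta0`` is measured from the +y axis.
    """
    n = max(int(np.ceil(L0 / ds)), 2)
    step = L0 / n
    dtheta = rng.normal(0.0, np.sqrt(step / Lp), size=n)
    theta = theta0 + np.concatenate([[0.0], np.cumsum(dtheta[:-1])])
    # angle from +y axis: (x, y) increments are (sin, cos)
    deltas = step * np.column_stack([np.sin(theta), np.cos(theta)])
    pts = np.concatenate([[start], start + np.cumsum(deltas, axis=0)])
    return pts


def render_points(shape: tuple[int, int], xy_px: np.ndarray,
                  amplitudes: np.ndarray, psf_sigma: float) -> np.ndarray:
    """Deposit weighted sub-pixel points bilinearly, then blur with a Gaussian PSF."""
    img = np.zeros(shape, float)
    x = np.asarray(xy_px)[:, 0]
    y = np.asarray(xy_px)[:, 1]
    a = np.broadcast_to(np.asarray(amplitudes, float), x.shape)
    x0 = np.floor(x).astype(int)
    y0 = np.floor(y).astype(int)
    fx, fy = x - x0, y - y0
    for dy in (0, 1):
        for dx in (0, 1):
            w = (fx if dx else 1 - fx) * (fy if dy else 1 - fy)
            xs, ys = x0 + dx, y0 + dy
            ok = (xs >= 0) & (xs < shape[1]) & (ys >= 0) & (ys < shape[0])
            np.add.at(img, (ys[ok], xs[ok]), (a * w)[ok])
    if psf_sigma > 0:
        img = ndi.gaussian_filter(img, psf_sigma)
    return img


def resample_polyline(points: np.ndarray, spacing: float) -> np.ndarray:
    """Resample a polyline at uniform arc-length spacing (endpoints kept)."""
    points = np.asarray(points, float)
    seg = np.hypot(*np.diff(points, axis=0).T)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    n = max(int(np.round(total / spacing)), 1)
    si = np.linspace(0.0, total, n + 1)
    x = np.interp(si, s, points[:, 0])
    y = np.interp(si, s, points[:, 1])
    return np.column_stack([x, y])


# ---------------------------------------------------------------------------
# bead series


def make_bead_series(cfg: StretchConfig, n_beads: int = 50,
                     shape: tuple[int, int] = (512, 512),
                     bead_sigma_px: float = 2.0, noise: float = 0.01,
                     jitter_px: float = 0.1, min_separation_px: float = 15.0,
                     ) -> tuple[np.ndarray, pd.DataFrame]:
    """Render fiducial beads carried by the stretcher's affine map.

    Bead centers at step k are the step-0 centers mapped by
    (x, y) -> ((1+eps_xx,k) x, (1+eps_yy,k) y) about the field center,
    rendered as Gaussian spots of width ``bead_sigma_px``. ``jitter_px``
    adds independent sub-pixel positional noise per bead and step (the
    rendered positions; the truth table records the noiseless affine
    positions). Beads are placed with at least ``min_separation_px``
    between centers, as in a real fiducial field where markers must stay
    individually resolvable. Returns the (n_steps, H, W) stack and a truth
    table with columns bead_id, step, x_px, y_px.
    """
    if n_beads < 1:
        raise ValueError("need at least one bead")
    eyy, exx = cfg.strains()
    if np.any(np.diff(np.abs(eyy)) < -1e-12) or np.any(np.diff(np.abs(exx)) < -1e-12):
        raise ValueError("strain schedule must be monotone in magnitude")
    rng = np.random.default_rng(cfg.seed)
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    # keep beads inside the frame at maximum stretch
    max_sy = 1.0 + eyy[-1]
    margin = 6 * bead_sigma_px
    placed = []
    attempts = 0
    while len(placed) < n_beads:
        attempts += 1
        if attempts > 1000 * n_beads:
            raise RuntimeError("cannot place beads at the requested density")
        cand = np.array([rng.uniform(-(w / 2 - margin), w / 2 - margin),
                         rng.uniform(-(h / 2 - margin) / max_sy,
                                     (h / 2 - margin) / max_sy)])
        if placed and min(np.hypot(*(cand - p)) for p in placed) < min_separation_px:
            continue
        placed.append(cand)
    x0 = np.array([p[0] for p in placed])
    y0 = np.array([p[1] for p in placed])

    frames, rows = [], []
    for k in range(cfg.n_steps):
        xk = (1.0 + exx[k]) * x0 + cx
        yk = (1.0 + eyy[k]) * y0 + cy
        xr = xk + rng.normal(0.0, jitter_px, n_beads) if jitter_px > 0 else xk
        yr = yk + rng.normal(0.0, jitter_px, n_beads) if jitter_px > 0 else yk
        img = np.zeros(shape, float)
        for xb, yb in zip(xr, yr):
            _stamp_gaussian(img, xb, yb, bead_sigma_px)
        if noise > 0:
            img += rng.normal(0.0, noise, shape)
        frames.append(img)
        for i in range(n_beads):
            rows.append((i, k, xk[i], yk[i]))
    truth = pd.DataFrame(rows, columns=["bead_id", "step", "x_px", "y_px"])
    return np.stack(frames), truth


def _stamp_gaussian(img: np.ndarray, x: float, y: float, sigma: float,
                    amplitude: float = 1.0) -> None:
    r = int(np.ceil(4 * sigma))
    h, w = img.shape
    xa = np.arange(max(int(x) - r, 0), min(int(x) + r + 1, w))
    ya = np.arange(max(int(y) - r, 0), min(int(y) + r + 1, h))
    if len(xa) == 0 or len(ya) == 0:
        return
    gx = np.exp(-((xa - x) ** 2) / (2 * sigma**2))
    gy = np.exp(-((ya - y) ** 2) / (2 * sigma**2))
    img[np.ix_(ya, xa)] += amplitude * np.outer(gy, gx)


# ---------------------------------------------------------------------------
# filament series


def axial_angle_deg(v: np.ndarray) -> float:
    """Axial (sign-free) angle of a 2D vector from the +y axis, in [0, 90]."""
    a = np.degrees(np.arctan2(abs(v[0]), abs(v[1])))
    return float(a)


def _deformed_angle(alpha0: float, sx: float, sy: float) -> float:
    """Signed angle (rad, from +y) of a material line at ``alpha0`` after diag(sx, sy)."""
    return float(np.arctan2(sx * np.sin(alpha0), sy * np.cos(alpha0)))


def make_filament_series(cfg: StretchConfig, n_filaments: int = 30,
                         Lp_true: float = 2.0, kappa: float = KAPPA_SLOW,
                         mode: str = "decoupled",
                         L0_mean: float = 10.0, L0_sd: float = 2.0,
                         angle_spread_deg: float = 30.0,
                         psf_sigma: float = 1.5, noise: float = 0.03,
                         shape: tuple[int, int] = (900, 900),
                         pin_spacing: float = 0.5,
                         min_separation_um: float = 1.0,
                         smooth_um: float = 0.15,
                         ) -> tuple[np.ndarray, list[FilamentTruth], pd.DataFrame]:
    """Render worm-like-chain filaments that elongate under substrate stretch.

    Two deformation modes:

    ``decoupled``
        At step k the filament keeps its step-0 shape, uniformly rescaled so
        its contour length is L0 * (1 + kappa * eps_yy,k); its axis is
        rotated to the angle a material line at its mean angle attains under
        the full substrate affine, and its centroid rides the full affine.
        The recoverable strain-transfer slope equals ``kappa`` exactly.

    ``affine_pinned``
        Pinning points every ``pin_spacing`` um along the backbone are
        displaced by the scaled affine I + kappa * diag(eps_xx, eps_yy)
        about the field center and the backbone is re-interpolated through
        them piecewise-linearly.

    Filament axial angles are drawn from a normal distribution about the
    stretch (+y) axis with ``angle_spread_deg`` standard deviation.
    Filaments are placed with rejection sampling so that backbones keep
    ``min_separation_um`` clearance (no crossings), mirroring the sparse
    single-filament regime the tracer is built for.

    Backbones are band-limited with a Gaussian of ``smooth_um`` along arc
    length before their ground-truth contour length is fixed: undulations
    below the optical resolution carry arc length no tracer can observe,
    so leaving them in would make the recorded truth lengths unmeasurable
    by construction. ``L0`` is the arc length of the band-limited backbone.

    Returns (stack of n_steps frames, truths at step 0, truth-length table
    with columns filament_id, step, L_um).
    """
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [0, 1]")
    if mode not in ("decoupled", "affine_pinned"):
        raise ValueError("mode must be 'decoupled' or 'affine_pinned'")
    rng = np.random.default_rng(cfg.seed)
    eyy, exx = cfg.strains()
    h, w = shape
    fov_x = w * cfg.pixel_size
    fov_y = h * cfg.pixel_size
    center = np.array([fov_x / 2.0, fov_y / 2.0])

    truths: list[FilamentTruth] = []
    # clearance is enforced on the deformed backbones at several steps:
    # filaments rotate toward the stretch axis as the strain grows, so a
    # pair that is clear at step 0 can collide later in the series
    check_steps = sorted({0, cfg.n_steps // 2, cfg.n_steps - 1})
    occupied: dict[int, list[np.ndarray]] = {k: [] for k in check_steps}
    attempts = 0
    while len(truths) < n_filaments:
        attempts += 1
        if attempts > 200 * n_filaments:
            raise RuntimeError("could not place filaments without crossings; "
                               "reduce density or min_separation_um")
        L0 = float(np.clip(rng.normal(L0_mean, L0_sd), 2.0, None))
        theta0 = np.radians(rng.normal(0.0, angle_spread_deg))
        if rng.random() < 0.5:
            theta0 += np.pi  # axial symmetry: either direction along the axis
        # keep the whole filament in frame at maximum stretch
        max_sy = 1.0 + eyy[-1]
        pad = L0 / 1.6 + 2.0
        start = np.array([rng.uniform(pad, fov_x - pad),
                          rng.uniform(center[1] - (fov_y / 2 - pad) / max_sy,
                                      center[1] + (fov_y / 2 - pad) / max_sy)])
        bb = wlc_backbone(L0, Lp_true, start, theta0, rng)
        if smooth_um > 0:
            bb = _bandlimit_backbone(bb, smooth_um)
        if bb[:, 0].min() < 1 or bb[:, 0].max() > fov_x - 1:
            continue
        if _self_approaches(bb, min_separation_um):
            continue  # hairpins closer than the resolution are untraceable
        ee = bb[-1] - bb[0]
        cand = FilamentTruth(backbone=bb, Lp_true=Lp_true,
                             L0=polyline_length(bb),
                             mean_angle=axial_angle_deg(ee), kappa=kappa)
        coarse = {}
        clear = True
        for k in check_steps:
            dk = _deform_backbone(cand, 1.0 + exx[k], 1.0 + eyy[k], eyy[k],
                                  kappa, mode, center, pin_spacing)
            ck = resample_polyline(dk, 0.25)
            coarse[k] = ck
            for occ in occupied[k]:
                d = np.min(np.hypot(*(ck[:, None, :] - occ[None, :, :]).T))
                if d < min_separation_um:
                    clear = False
                    break
            if not clear:
                break
        if not clear:
            continue
        for k in check_steps:
            occupied[k].append(coarse[k])
        truths.append(cand)

    frames, rows = [], []
    for k in range(cfg.n_steps):
        sx, sy = 1.0 + exx[k], 1.0 + eyy[k]
        img = np.zeros(shape, float)
        for i, tr in enumerate(truths):
            bb = _deform_backbone(tr, sx, sy, eyy[k], kappa, mode, center,
                                  pin_spacing)
            rows.append((i, k, polyline_length(bb)))
            pts = resample_polyline(bb, 0.3 * cfg.pixel_size)
            img += render_points(shape, pts / cfg.pixel_size,
                                 np.full(len(pts), 1.0), 0.0)
        if psf_sigma > 0:
            img = ndi.gaussian_filter(img, psf_sigma)
        peak = img.max()
        if peak > 0:
            img /= peak
        if noise > 0:
            img += rng.normal(0.0, noise, shape)
        frames.append(img)
    lengths = pd.DataFrame(rows, columns=["filament_id", "step", "L_um"])
    return np.stack(frames), truths, lengths


def _self_approaches(bb: np.ndarray, clearance_um: float,
                     arc_skip_um: float = 1.5) -> bool:
    """True if two stretches of the backbone separated by more than
    ``arc_skip_um`` of arc come closer than ``clearance_um`` in space."""
    pts = resample_polyline(bb, 0.25)
    skip = int(arc_skip_um / 0.25)
    d = np.hypot(*(pts[:, None, :] - pts[None, :, :]).T)
    ii, jj = np.triu_indices(len(pts), k=skip)
    return bool(np.any(d[ii, jj] < clearance_um))


def _bandlimit_backbone(bb: np.ndarray, sigma_um: float,
                        ds: float = 0.02) -> np.ndarray:
    """Gaussian low-pass of a backbone along arc length (nearest-end padding)."""
    pts = resample_polyline(bb, ds)
    s = sigma_um / ds
    return np.column_stack([ndi.gaussian_filter1d(pts[:, 0], s, mode="nearest"),
                            ndi.gaussian_filter1d(pts[:, 1], s, mode="nearest")])


def _deform_backbone(tr: FilamentTruth, sx: float, sy: float, eps_yy: float,
                     kappa: float, mode: str, center: np.ndarray,
                     pin_spacing: float) -> np.ndarray:
    bb0 = tr.backbone
    if mode == "decoupled":
        centroid0 = bb0.mean(axis=0)
        ee = bb0[-1] - bb0[0]
        alpha0 = np.arctan2(ee[0], ee[1])  # signed, from +y
        dalpha = _deformed_angle(alpha0, sx, sy) - alpha0
        scale = 1.0 + kappa * eps_yy
        c, s = np.cos(dalpha), np.sin(dalpha)
        # rotation in (x, y) with angles measured from +y: standard rotation
        rot = np.array([[c, s], [-s, c]])
        rel = (bb0 - centroid0) @ rot.T * scale
        centroid_k = center + np.array([sx, sy]) * (centroid0 - center)
        return centroid_k + rel
    # affine_pinned: displace pins by I + kappa*diag(eps), re-interpolate
    pins = resample_polyline(bb0, pin_spacing)
    scale = np.array([1.0 + kappa * (sx - 1.0), 1.0 + kappa * (sy - 1.0)])
    pins_k = center + scale * (pins - center)
    return resample_polyline(pins_k, 0.05)


# ---------------------------------------------------------------------------
# AFM height maps


def make_entangled_tubes(rng: np.random.Generator, n_tubes: int = 10,
                         field_nm: float = 2000.0, Lp_nm: float = 2000.0,
                         length_nm: float = 2500.0) -> list[np.ndarray]:
    """Random worm-like-chain centerlines criss-crossing a square field (nm)."""
    tubes = []
    for _ in range(n_tubes):
        edge = rng.integers(0, 4)
        t = rng.uniform(0.1, 0.9) * field_nm
        if edge == 0:
            start, theta = np.array([t, 0.0]), rng.uniform(-0.6, 0.6)
        elif edge == 1:
            start, theta = np.array([t, field_nm]), np.pi + rng.uniform(-0.6, 0.6)
        elif edge == 2:
            start, theta = np.array([0.0, t]), np.pi / 2 + rng.uniform(-0.6, 0.6)
        else:
            start, theta = np.array([field_nm, t]), -np.pi / 2 + rng.uniform(-0.6, 0.6)
        tubes.append(wlc_backbone(length_nm, Lp_nm, start, theta, rng, ds=20.0))
    return tubes


def make_afm_map(truth: AFMTruth, shape: tuple[int, int] = (500, 500),
                 pixel_size_nm: float = 4.0, seed: int = 0,
                 expected_density: float | None = None,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Render an AFM height map (nm) from tube centerlines.

    Each tube has a Gaussian cross-section of peak ``tube_height`` and width
    ``tube_width_sigma``; overlaps stack additively (or take the pixel-wise
    max with ``overlap_rule='max'``). Returns (height map, boolean
    ground-truth centerline mask).
    """
    if expected_density and not truth.tubes:
        raise ValueError("empty tube list with nonzero requested density")
    rng = np.random.default_rng(seed)
    h, w = shape
    sig_px = truth.tube_width_sigma / pixel_size_nm
    hmap = np.zeros(shape, float)
    mask = np.zeros(shape, bool)
    ds = min(0.3 * truth.tube_width_sigma, pixel_size_nm)
    for tube in truth.tubes:
        pts = resample_polyline(np.asarray(tube, float), ds) / pixel_size_nm
        amp = (truth.tube_height * (ds / pixel_size_nm)
               * np.sqrt(2 * np.pi) * sig_px)
        layer = render_points(shape, pts, np.full(len(pts), amp), 0.0)
        layer = ndi.gaussian_filter(layer, sig_px)
        if truth.overlap_rule == "additive":
            hmap += layer
        else:
            hmap = np.maximum(hmap, layer)
        ij = np.round(pts[:, ::-1]).astype(int)
        ok = (ij[:, 0] >= 0) & (ij[:, 0] < h) & (ij[:, 1] >= 0) & (ij[:, 1] < w)
        mask[ij[ok, 0], ij[ok, 1]] = True
    if truth.noise_sigma > 0:
        hmap += rng.normal(0.0, truth.noise_sigma, shape)
    return hmap, mask


# ---------------------------------------------------------------------------
# FRAP curves


def make_frap_curve(truth: FRAPTruth, seed: int = 0
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Times (s) and normalized intensities of a diffusion-limited recovery.

    intensity(t) = F0 + (F_inf - F0) * f_S(t; tau_D) + noise, with the
    plateau F_inf = F0 + mobile_fraction * (F_pre - F0).
    """
    rng = np.random.default_rng(seed)
    t = (np.arange(truth.n_frames) + 1) * truth.frame_interval
    f_inf = truth.F0 + truth.mobile_fraction * (truth.F_pre - truth.F0)
    y = truth.F0 + (f_inf - truth.F0) * soumpasis_model(t, truth.tau_D)
    if truth.noise_sigma > 0:
        y = y + rng.normal(0.0, truth.noise_sigma, truth.n_frames)
    return t, y


# ---------------------------------------------------------------------------
# tilted z-stacks


def focus_surface_eval(coeffs, x, y):
    """Second-order polynomial z(x, y) = c0 + c1 x + c2 y + c3 x^2 + c4 x y + c5 y^2."""
    c0, c1, c2, c3, c4, c5 = coeffs
    return c0 + c1 * x + c2 * y + c3 * x**2 + c4 * x * y + c5 * y**2


def make_tilted_stack(base_image: np.ndarray, tilt_coeffs, n_slices: int = 11,
                      blur_per_defocus: float = 0.6, noise: float = 0.0,
                      seed: int = 0) -> np.ndarray:
    """Simulate a z-stack of a tilted sheet.

    The in-focus z index at pixel (x, y) follows the polynomial surface
    ``tilt_coeffs``; each slice is blurred with a Gaussian whose sigma grows
    as ``blur_per_defocus * |z - focus(x, y)|``. The spatially varying blur
    is realized by blending copies blurred at quantized sigma levels.
    """
    if n_slices < 3:
        raise ValueError("need at least three slices")
    base = np.asarray(base_image, float)
    h, w = base.shape
    yy, xx = np.mgrid[0:h, 0:w]
    focus = focus_surface_eval(tilt_coeffs, xx, yy)
    if focus.min() < 0 or focus.max() > n_slices - 1:
        raise ValueError("focus surface leaves the z-range of the stack")
    rng = np.random.default_rng(seed)
    max_sigma = blur_per_defocus * max(focus.max(), (n_slices - 1) - focus.min())
    levels = np.arange(0.0, max_sigma + 0.5, 0.5)
    blurred = np.stack([base if s == 0 else ndi.gaussian_filter(base, s)
                        for s in levels])
    stack = np.empty((n_slices, h, w))
    for z in range(n_slices):
        sig = blur_per_defocus * np.abs(z - focus)
        idx = np.clip(sig / 0.5, 0, len(levels) - 1)
        lo = np.floor(idx).astype(int)
        hi = np.minimum(lo + 1, len(levels) - 1)
        frac = idx - lo
        sl = ((1 - frac) * np.take_along_axis(blurred, lo[None], 0)[0]
              + frac * np.take_along_axis(blurred, hi[None], 0)[0])
        if noise > 0:
            sl = sl + rng.normal(0.0, noise, (h, w))
        stack[z] = sl
    return stack


def texture_image(shape: tuple[int, int] = (256, 256), seed: int = 0,
                  smooth: float = 1.0) -> np.ndarray:
    """High-frequency random texture, a convenient base for focus tests."""
    rng = np.random.default_rng(seed)
    img = rng.random(shape)
    if smooth > 0:
        img = ndi.gaussian_filter(img, smooth)
    return img / img.max()
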