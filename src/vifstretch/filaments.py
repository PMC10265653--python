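"""Filament tracing, contour-length strain, angular segmentation, Lp.

Single membrane-bound filaments are traced from fluorescence images as
sub-pixel polylines. Their contour length L_C at each motor position
yields the filament strain

    eps_VIF = (L_C,mp - L_C,0) / L_C,0,

whose linear regression against the substrate strain gives the
strain-transfer slope (how much substrate stretch is transmitted into
filament elongation). Traces are further cut into straight segments
wherever the tangent direction drifts more than 5 deg from the segment's
starting tangent, giving polar statistics of segment orientations, and
the tangent-angle correlation over arc length yields an apparent
persistence length.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.morphology import skeletonize

from .synthetic import polyline_length, resample_polyline
from .tubefilter import tubeness

log = logging.getLogger(__name__)

LP_CAP_UM = 1e3  # reported for non-decaying tangent correlations


@dataclass
class FilamentTrace:
    """Ordered sub-pixel points of one traced filament at one step."""

    filament_id: int
    step: int
    points_px: np.ndarray
    pixel_size: float  # um / px

    def __post_init__(self):
        self.points_px = np.asarray(self.points_px, float)
        if len(self.points_px) < 2:
            raise ValueError("a trace needs at least two points")
        if np.any(np.all(np.diff(self.points_px, axis=0) == 0, axis=1)):
            raise ValueError("repeated consecutive points in trace")

    @property
    def points_um(self) -> np.ndarray:
        return self.points_px * self.pixel_size

    @property
    def contour_length_um(self) -> float:
        return contour_length(self)


@dataclass
class SegmentSet:
    """Angular segmentation of one trace: index ranges, angles, lengths."""

    trace: FilamentTrace
    start_idx: np.ndarray
    end_idx: np.ndarray
    angles_deg: np.ndarray  # axial, from +y, in [0, 90]
    lengths_um: np.ndarray

    @property
    def n_segments(self) -> int:
        return len(self.angles_deg)


# ---------------------------------------------------------------------------
# tracing


def contour_length(trace: FilamentTrace) -> float:
    """Polyline arc length in um."""
    return polyline_length(trace.points_um)


def _neighbor_count(skel: np.ndarray) -> np.ndarray:
    from scipy.ndimage import convolve
    k = np.ones((3, 3))
    k[1, 1] = 0
    return convolve(skel.astype(int), k, mode="constant")


def _prune_spurs(skel: np.ndarray, max_spur_px: int = 8,
                 n_pass: int = 3) -> np.ndarray:
    """Remove short endpoint branches hanging off skeleton junctions.

    Skeletonization of a noisy tube mask sprouts short side twigs whose
    junctions would otherwise split one filament into fragments. A spur is
    a branch component shorter than ``max_spur_px`` that contains a free
    end and touches a junction; removing it (and re-evaluating) restores a
    single degree-2 path through the filament.
    """
    from scipy.ndimage import binary_dilation, label

    skel = skel.copy()
    struct = np.ones((3, 3), bool)
    for _ in range(n_pass):
        deg = _neighbor_count(skel)
        junctions = skel & (deg > 2)
        if not junctions.any():
            break
        branches = skel & ~junctions
        lab, nlab = label(branches, structure=struct)
        ends = skel & (deg == 1)
        junc_zone = binary_dilation(junctions, structure=struct)
        removed = False
        for i in range(1, nlab + 1):
            comp = lab == i
            if comp.sum() > max_spur_px:
                continue
            if (comp & ends).any() and (comp & junc_zone).any():
                skel[comp] = False
                removed = True
        if not removed:
            break
    return skel


def _order_path(coords: set[tuple[int, int]]) -> list[tuple[int, int]] | None:
    """Order an 8-connected simple path of pixels from one endpoint."""
    nbrs = {}
    for (r, c) in coords:
        nbrs[(r, c)] = [(r + dr, c + dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                        if (dr or dc) and (r + dr, c + dc) in coords]
    ends = [p for p, nb in nbrs.items() if len(nb) == 1]
    if not ends:
        return None  # loop; skip
    path = [ends[0]]
    seen = {ends[0]}
    cur = ends[0]
    while True:
        nxt = [p for p in nbrs[cur] if p not in seen]
        if not nxt:
            break
        # prefer 4-connected continuation to avoid diagonal shortcuts
        nxt.sort(key=lambda p: abs(p[0] - cur[0]) + abs(p[1] - cur[1]))
        cur = nxt[0]
        path.append(cur)
        seen.add(cur)
    if len(path) < len(coords) * 0.9:
        return None  # not a simple path
    return path


def _smooth_path(path_xy: np.ndarray, smoothing_px: float = 0.6,
                 oversample: int = 4) -> np.ndarray:
    """Smoothing-spline fit of the pixel chain, sampled densely.

    Removes the half-pixel staircase of the skeleton so that arc lengths
    are not inflated by jagged steps.
    """
    n = len(path_xy)
    if n < 8:
        return path_xy
    s = n * smoothing_px**2
    try:
        tck, _ = interpolate.splprep(path_xy.T, s=s, k=3)
        u = np.linspace(0, 1, oversample * n)
        return np.column_stack(interpolate.splev(u, tck))
    except Exception:  # degenerate geometry; keep the raw chain
        return path_xy


def _refine_to_ridge(xy: np.ndarray, image: np.ndarray,
                     half_width_px: float = 2.0) -> np.ndarray:
    """Shift each point along the local normal onto the intensity ridge.

    Samples the image at offsets (-h, 0, +h) perpendicular to the local
    tangent and applies a parabolic sub-pixel correction toward the
    intensity maximum; corrections are capped at +-h. This centers the
    polyline on the ridge independently of the skeleton's pixel grid.
    """
    from scipy.ndimage import map_coordinates

    tang = np.gradient(xy, axis=0)
    norm = np.linalg.norm(tang, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    tang /= norm
    nvec = np.column_stack([-tang[:, 1], tang[:, 0]])
    h = half_width_px

    def sample(offs):
        p = xy + offs * nvec
        return map_coordinates(image, [p[:, 1], p[:, 0]], order=1,
                               mode="nearest")

    vm, v0, vp = sample(-h), sample(0.0), sample(h)
    denom = vm - 2 * v0 + vp
    with np.errstate(invalid="ignore", divide="ignore"):
        delta = np.where(denom < 0, 0.5 * h * (vm - vp) / denom, 0.0)
    delta = np.clip(np.nan_to_num(delta), -h, h)
    return xy + delta[:, None] * nvec


def _extend_ends(xy: np.ndarray, image: np.ndarray, step_px: float = 0.25,
                 max_ext_px: float = 15.0, frac: float = 0.5) -> np.ndarray:
    """Extend both trace ends along their tangents to the half-max point.

    Skeletonization retracts filament ends by a few pixels. For a line
    convolved with a symmetric PSF the intensity at the true endpoint is
    half the on-filament plateau, so walking outward until the sampled
    intensity drops below ``frac`` of the trace's median intensity restores
    the lost length with sub-pixel accuracy.
    """
    from scipy.ndimage import map_coordinates

    def sample(pts):
        return map_coordinates(image, [pts[:, 1], pts[:, 0]], order=1,
                               mode="nearest")

    plateau = np.median(sample(xy))
    if plateau <= 0:
        return xy
    out = xy
    for end in (0, -1):
        p = out[end]
        inner = out[4] if end == 0 else out[-5]
        tang = p - inner
        norm = np.linalg.norm(tang)
        if norm == 0:
            continue
        tang /= norm
        steps = np.arange(step_px, max_ext_px + step_px, step_px)
        probes = p[None] + steps[:, None] * tang[None]
        vals = sample(probes)
        below = np.nonzero(vals < frac * plateau)[0]
        n_ext = below[0] if len(below) else len(steps)
        if n_ext > 0:
            ext = probes[:n_ext]
            out = (np.vstack([ext[::-1], out]) if end == 0
                   else np.vstack([out, ext]))
    return out


def trace_filaments(image: np.ndarray, pixel_size_um: float,
                    min_length_um: float = 2.0,
                    tubeness_scales_px: tuple = (1.5, 2.5),
                    step: int = 0,
                    threshold_factor: float = 1.0,
                    extend_ends: bool = True) -> list[FilamentTrace]:
    """Trace filaments in a fluorescence image as sub-pixel polylines.

    Pipeline: Hessian ridge enhancement -> Otsu threshold -> skeletonize ->
    break at junctions -> order each branch into a pixel chain -> smoothing
    spline -> half-max end extension -> drop traces shorter than
    ``min_length_um``.
    """
    image = np.asarray(image, float)
    resp = tubeness(image, list(tubeness_scales_px))
    nz = resp[resp > 1e-12 * max(resp.max(), 1e-30)]
    if nz.size == 0 or resp.max() <= 0:
        return []
    thr = threshold_otsu(nz) * threshold_factor
    mask = resp > thr
    skel = skeletonize(mask)
    skel = _prune_spurs(skel)
    # break at junction pixels (more than two neighbors)
    deg = _neighbor_count(skel)
    branches = skel & (deg <= 2)
    from scipy.ndimage import label
    lab, nlab = label(branches, structure=np.ones((3, 3)))
    traces = []
    fid = 0
    for i in range(1, nlab + 1):
        rc = np.argwhere(lab == i)
        if len(rc) < 5:
            continue
        path = _order_path(set(map(tuple, rc)))
        if path is None:
            continue
        xy = np.array([(c, r) for r, c in path], float)
        xy = _smooth_path(xy)
        if len(xy) > 8:
            xy = _refine_to_ridge(xy, image)
            xy = _smooth_path(xy, smoothing_px=0.3, oversample=1)
        if extend_ends and len(xy) > 8:
            xy = _extend_ends(xy, image)
        if polyline_length(xy) * pixel_size_um < min_length_um:
            continue
        traces.append(FilamentTrace(filament_id=fid, step=step,
                                    points_px=xy, pixel_size=pixel_size_um))
        fid += 1
    return traces


def match_traces(ref: list[FilamentTrace], cur: list[FilamentTrace],
                 affine: np.ndarray | None = None,
                 center_px: np.ndarray | None = None,
                 max_dist_px: float = 30.0) -> list[tuple[int, int]]:
    """Greedy nearest-endpoint matching of traces across steps.

    Step-0 traces are first mapped through the substrate affine (2x2 linear
    part about ``center_px``) so that matching distances stay small even at
    large stretch. Returns (index in ref, index in cur) pairs; unmatched
    traces are left out (logged).
    """
    if not ref or not cur:
        return []

    def endpoints(tr, warp):
        e = tr.points_px[[0, -1]]
        if warp is not None:
            e = (e - center_px) @ warp.T + center_px
        return e

    re = [endpoints(t, affine) for t in ref]
    ce = [endpoints(t, None) for t in cur]
    # distance: best pairing of the two endpoints
    d = np.full((len(ref), len(cur)), np.inf)
    for i, a in enumerate(re):
        for j, b in enumerate(ce):
            d1 = np.linalg.norm(a[0] - b[0]) + np.linalg.norm(a[1] - b[1])
            d2 = np.linalg.norm(a[0] - b[1]) + np.linalg.norm(a[1] - b[0])
            d[i, j] = min(d1, d2) / 2.0
    pairs = []
    used_i, used_j = set(), set()
    for idx in np.argsort(d, axis=None):
        i, j = np.unravel_index(idx, d.shape)
        if i in used_i or j in used_j or d[i, j] > max_dist_px:
            continue
        pairs.append((int(i), int(j)))
        used_i.add(i)
        used_j.add(j)
    if len(pairs) < len(ref):
        log.info("unmatched traces: %d of %d", len(ref) - len(pairs), len(ref))
    return pairs


# ---------------------------------------------------------------------------
# strain and strain transfer


def filament_strain(L_now: float, L_ref: float) -> float:
    """Filament strain eps_VIF = (L_now - L_ref) / L_ref."""
    if L_ref <= 0:
        raise ValueError("reference contour length must be positive")
    return (L_now - L_ref) / L_ref


@dataclass
class StrainTransferFit:
    """OLS fit of filament strain against substrate strain."""

    slope: float
    intercept: float
    slope_se: float
    slope_ci95: tuple[float, float]
    n: int
    dof: int
    residual_var: float
    x_mean: float
    sxx: float

    def predict(self, x: float) -> float:
        return self.intercept + self.slope * x

    def confidence_band(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise 95% confidence band of the fitted line."""
        x = np.asarray(x, float)
        tcrit = stats.t.ppf(0.975, self.dof) if self.dof > 0 else np.inf
        se = np.sqrt(self.residual_var *
                     (1.0 / self.n + (x - self.x_mean) ** 2 / self.sxx))
        yhat = self.intercept + self.slope * x
        return yhat - tcrit * se, yhat + tcrit * se


def fit_strain_transfer(eps_substrate: np.ndarray,
                        eps_filament: np.ndarray) -> StrainTransferFit:
    """Ordinary least squares of eps_VIF on substrate strain, with 95% CI."""
    x = np.asarray(eps_substrate, float)
    y = np.asarray(eps_filament, float)
    if len(x) < 3 or len(np.unique(x)) < 2:
        raise ValueError("need >= 3 pairs spanning >= 2 substrate strains")
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx <= 0:
        raise ValueError("degenerate x-variance")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    dof = len(x) - 2
    s2 = float(resid @ resid / dof) if dof > 0 else 0.0
    se = float(np.sqrt(s2 / sxx))
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else np.inf
    return StrainTransferFit(slope=slope, intercept=intercept, slope_se=se,
                             slope_ci95=(slope - tcrit * se, slope + tcrit * se),
                             n=len(x), dof=dof, residual_var=s2,
                             x_mean=float(x.mean()), sxx=sxx)


# ---------------------------------------------------------------------------
# angular segmentation


def _tangent_angles(points: np.ndarray) -> np.ndarray:
    """Signed tangent angles (rad) from the +y axis of consecutive chords."""
    d = np.diff(points, axis=0)
    return np.arctan2(d[:, 0], d[:, 1])


def segment_by_angle(trace: FilamentTrace, threshold_deg: float = 5.0,
                     rule: str = "cumulative",
                     resample_um: float = 0.1) -> SegmentSet:
    """Cut a trace into segments by the 5-degree tangent rule.

    The trace is resampled at ``resample_um`` arc spacing (making the rule
    independent of pixel sampling) and walked from one end. With the
    default ``cumulative`` rule a new segment starts at the first point
    whose tangent deviates more than ``threshold_deg`` from the tangent at
    the current segment's start; the ``successive`` rule compares
    consecutive tangent pairs instead. Each segment's angle is the axial
    angle of its end-to-end vector from the +y axis. Segment lengths are
    measured along the original polyline, so they sum exactly to L_C.
    """
    if rule not in ("cumulative", "successive"):
        raise ValueError("rule must be 'cumulative' or 'successive'")
    pts_um = trace.points_um
    seg_len = np.hypot(*np.diff(pts_um, axis=0).T)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    total = arc[-1]
    rs = resample_polyline(pts_um, resample_um)
    # arc positions of the resampled points along the original polyline
    rs_arc = np.linspace(0.0, total, len(rs))
    theta = _tangent_angles(rs)
    thr = np.radians(threshold_deg)
    starts = [0]
    ref_angle = theta[0]
    prev_angle = theta[0]
    for i in range(1, len(theta)):
        base = ref_angle if rule == "cumulative" else prev_angle
        dev = np.abs((theta[i] - base + np.pi) % (2 * np.pi) - np.pi)
        if dev > thr:
            starts.append(i)
            ref_angle = theta[i]
        prev_angle = theta[i]
    starts = np.array(starts)
    ends = np.concatenate([starts[1:], [len(theta)]])  # tangent index ranges
    # tangent i spans resampled points i..i+1, so segment point range is
    # [start, end] inclusive in resampled-point indices
    angles, lengths = [], []
    for s, e in zip(starts, ends):
        v = rs[e] - rs[s]
        angles.append(np.degrees(np.arctan2(abs(v[0]), abs(v[1]))))
        lengths.append(rs_arc[e] - rs_arc[s])
    return SegmentSet(trace=trace, start_idx=starts, end_idx=ends,
                      angles_deg=np.array(angles),
                      lengths_um=np.array(lengths))


def segment_polar_stats(segsets: list[SegmentSet], bin_deg: float = 5.0
                        ) -> pd.DataFrame:
    """Polar histogram of segment counts and mean +- STD segment length.

    Bins cover [0, 90] deg in ``bin_deg`` steps; returns a table with
    columns bin_lo, bin_hi, n_seg, mean_L_um, std_L_um.
    """
    angles = np.concatenate([s.angles_deg for s in segsets if s.n_segments])
    lengths = np.concatenate([s.lengths_um for s in segsets if s.n_segments])
    if angles.size == 0:
        raise ValueError("no segments to histogram")
    edges = np.arange(0.0, 90.0 + bin_deg / 2.0, bin_deg)
    idx = np.clip(np.digitize(angles, edges) - 1, 0, len(edges) - 2)
    rows = []
    for b in range(len(edges) - 1):
        sel = idx == b
        ls = lengths[sel]
        rows.append((edges[b], edges[b + 1], int(sel.sum()),
                     float(ls.mean()) if ls.size else np.nan,
                     float(ls.std()) if ls.size else np.nan))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "n_seg",
                                       "mean_L_um", "std_L_um"])


# ---------------------------------------------------------------------------
# apparent persistence length


def apparent_persistence_length(traces: list[FilamentTrace],
                                ds_um: float = 0.1
                                ) -> tuple[float, bool]:
    """Apparent Lp from the 2D tangent-angle correlation.

    Fits <cos dtheta(s)> = exp(-s / (2 Lp)) over arc separations up to half
    the mean contour length, by least squares on the log of the positive
    correlations. Returns (Lp in um, flagged) where ``flagged`` marks a
    non-decaying correlation (Lp reported at the cap, a lower bound).
    """
    if len(traces) < 10:
        log.warning("fewer than 10 traces: Lp estimate will be noisy")
    mean_lc = np.mean([t.contour_length_um for t in traces])
    max_k = max(int((mean_lc / 2.0) / ds_um), 2)
    sums = np.zeros(max_k + 1)
    counts = np.zeros(max_k + 1)
    for t in traces:
        rs = resample_polyline(t.points_um, ds_um)
        theta = _tangent_angles(rs)
        for k in range(0, min(max_k, len(theta) - 1) + 1):
            d = theta[k:] - theta[: len(theta) - k]
            sums[k] += np.cos(d).sum()
            counts[k] += d.size
    ok = counts > 0
    corr = sums[ok] / counts[ok]
    s = np.arange(max_k + 1)[ok] * ds_um
    pos = corr > 0.05
    if pos.sum() < 3:
        return LP_CAP_UM, True
    coef = np.polyfit(s[pos], np.log(corr[pos]), 1)
    if coef[0] >= -1.0 / (2.0 * LP_CAP_UM):
        return LP_CAP_UM, True
    return float(-1.0 / (2.0 * coef[0])), False
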