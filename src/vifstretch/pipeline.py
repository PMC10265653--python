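"""End-to-end orchestration: simulate -> analyze -> report.

``run_stretch_analysis`` drives the full stage graph on synthetic data
(or, stage by stage, on user-supplied files through the CLI): bead
tracking and strain fields, filament tracing and strain-transfer fitting,
AFM tube filtering, orientation fields, FRAP fitting. Every stage writes
its table to the output directory and the run ends with a machine-readable
summary JSON carrying the seed and parameters.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field as dfield
from pathlib import Path

import numpy as np

from . import filaments as fil
from . import frap as frapmod
from . import io as vio
from . import strain as strainmod
from . import synthetic as syn
from . import tubefilter as tf

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full synthetic end-to-end run."""

    outdir: str = "vifstretch_run"
    seed: int = 0
    pixel_size_um: float = 0.1
    n_steps: int = 11
    eps_yy_max: float = 0.33
    eps_xx_max: float = -0.12
    n_beads: int = 30
    n_filaments: int = 8
    kappa: float = syn.KAPPA_SLOW
    filament_shape: tuple = (512, 512)
    n_afm_maps: int = 3
    frap_truth: dict = dfield(default_factory=dict)
    overrides: dict = dfield(default_factory=dict)

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("missing or invalid field: pixel_size_um")


def analyze_filament_series(stack: np.ndarray, pixel_size_um: float,
                            eps_yy: np.ndarray, eps_xx: np.ndarray,
                            center_px: np.ndarray | None = None,
                            min_length_um: float = 3.0,
                            ) -> tuple[fil.StrainTransferFit, list]:
    """Trace every frame, match traces to step 0, fit strain transfer.

    ``eps_yy``/``eps_xx`` are the per-step substrate strains (from bead
    tracking or the known schedule); they supply both the regression
    abscissa and the affine used to pre-warp step-0 traces for matching.
    Returns the OLS fit and the list of (eps_substrate, eps_filament) pairs.
    """
    n_steps = stack.shape[0]
    if center_px is None:
        center_px = (np.array([stack.shape[2], stack.shape[1]], float) - 1) / 2
    ref_traces = fil.trace_filaments(stack[0], pixel_size_um,
                                     min_length_um=min_length_um)
    if not ref_traces:
        raise RuntimeError("no filaments traced in the reference frame")
    ref_len = {i: t.contour_length_um for i, t in enumerate(ref_traces)}
    pairs_xy = []
    for k in range(1, n_steps):
        cur = fil.trace_filaments(stack[k], pixel_size_um,
                                  min_length_um=min_length_um)
        A = np.diag([1.0 + eps_xx[k], 1.0 + eps_yy[k]])
        matches = fil.match_traces(ref_traces, cur, affine=A,
                                   center_px=center_px)
        for i, j in matches:
            e = fil.filament_strain(cur[j].contour_length_um, ref_len[i])
            pairs_xy.append((float(eps_yy[k]), e))
    if len(pairs_xy) < 3:
        raise RuntimeError("too few matched traces to fit strain transfer")
    x, y = np.array(pairs_xy).T
    return fil.fit_strain_transfer(x, y), pairs_xy


def run_stretch_analysis(cfg: RunConfig) -> dict:
    """Execute the full synthetic pipeline and write a report bundle."""
    t0 = time.time()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    summary: dict = {"seed": cfg.seed, "parameters": {
        "n_steps": cfg.n_steps, "eps_yy_max": cfg.eps_yy_max,
        "eps_xx_max": cfg.eps_xx_max, "n_beads": cfg.n_beads,
        "n_filaments": cfg.n_filaments, "kappa": cfg.kappa,
        "pixel_size_um": cfg.pixel_size_um, "n_afm_maps": cfg.n_afm_maps}}

    # --- substrate strain from beads -------------------------------------
    stage = "beads"
    try:
        scfg = syn.StretchConfig(n_steps=cfg.n_steps,
                                 eps_yy_max=cfg.eps_yy_max,
                                 eps_xx_max=cfg.eps_xx_max,
                                 pixel_size=cfg.pixel_size_um,
                                 seed=int(rng.integers(2**31)))
        stack, truth = syn.make_bead_series(scfg, n_beads=cfg.n_beads)
        vio.write_stack(out / "beads.tif", stack,
                        pixel_size_um=cfg.pixel_size_um)
        tracks = strainmod.detect_and_track_beads(stack)
        vio.write_table(out / "bead_tracks.csv", tracks.to_frame())
        series = strainmod.cauchy_strain_series(tracks)
        vio.write_table(out / "strain_series.csv", series.to_frame())
        nu = strainmod.poisson_ratio(series)
        alpha0 = strainmod.zero_strain_angle(float(series.eps_yy[-1]),
                                             float(series.eps_xx[-1]))
        summary["strain"] = {
            "eps_yy_final": float(series.eps_yy[-1]),
            "eps_xx_final": float(series.eps_xx[-1]),
            "poisson_ratio": nu, "zero_strain_angle_deg": alpha0}
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    # --- filament strain transfer ----------------------------------------
    stage = "filaments"
    try:
        fcfg = syn.StretchConfig(n_steps=cfg.n_steps,
                                 eps_yy_max=cfg.eps_yy_max,
                                 eps_xx_max=cfg.eps_xx_max,
                                 pixel_size=cfg.pixel_size_um,
                                 seed=int(rng.integers(2**31)))
        fstack, truths, lengths = syn.make_filament_series(
            fcfg, n_filaments=cfg.n_filaments, kappa=cfg.kappa,
            shape=cfg.filament_shape)
        vio.write_stack(out / "filaments.tif", fstack,
                        pixel_size_um=cfg.pixel_size_um)
        vio.write_table(out / "filament_truth_lengths.csv", lengths)
        eyy, exx = fcfg.strains()
        fit, pairs = analyze_filament_series(fstack, cfg.pixel_size_um,
                                             eyy, exx)
        traces0 = fil.trace_filaments(fstack[0], cfg.pixel_size_um,
                                      min_length_um=3.0)
        segs = [fil.segment_by_angle(t) for t in traces0]
        vio.write_table(out / "segment_polar_stats.csv",
                        fil.segment_polar_stats(segs))
        summary["filaments"] = {
            "slope": fit.slope, "intercept": fit.intercept,
            "slope_ci95": list(fit.slope_ci95), "n_pairs": fit.n,
            "eps_vif_at_max_percent": 100.0 * fit.predict(eyy[-1])}
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    # --- AFM height maps ---------------------------------------------------
    stage = "tubefilter"
    try:
        maps = []
        for i in range(cfg.n_afm_maps):
            s = int(rng.integers(2**31))
            tubes = syn.make_entangled_tubes(np.random.default_rng(s))
            truth_afm = syn.AFMTruth(tubes=tubes)
            hmap, _ = syn.make_afm_map(truth_afm, seed=s + 1)
            maps.append(tf.analyze_height_map(hmap, pixel_size_nm=4.0))
        counts, edges, mode = tf.height_distribution(maps)
        vio.write_table(out / "height_histogram.csv",
                        __import__("pandas").DataFrame(
                            {"bin_lo_nm": edges[:-1], "bin_hi_nm": edges[1:],
                             "count": counts}))
        summary["afm"] = {"height_mode_nm": mode}
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    # --- FRAP --------------------------------------------------------------
    stage = "frap"
    try:
        ftruth = syn.FRAPTruth(**cfg.frap_truth)
        t, y = syn.make_frap_curve(ftruth, seed=int(rng.integers(2**31)))
        curve = frapmod.FRAPCurve(times=t, intensities=y, w=ftruth.w,
                                  F_pre=ftruth.F_pre)
        ffit = frapmod.fit_frap(curve)
        summary["frap"] = {"tau_D_s": ffit.tau_D, "D_um2_s": ffit.D,
                           "mobile_fraction": ffit.mobile_fraction}
    except Exception as exc:
        raise RuntimeError(f"stage '{stage}' failed: {exc}") from exc

    log.info("run completed in %.1f s", time.time() - t0)
    vio.write_json(out / "summary.json", summary)
    return summary
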