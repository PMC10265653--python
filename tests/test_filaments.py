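"""Tracing, contour length, filament strain, segmentation, Lp."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage as ndi

from vifstretch import filaments as fil
from vifstretch import synthetic as syn


def trace_from_points(points, pixel_size=0.1, fid=0, step=0):
    return fil.FilamentTrace(filament_id=fid, step=step,
                             points_px=np.asarray(points, float),
                             pixel_size=pixel_size)


def render_polyline(points_px, shape, psf_sigma=1.5):
    pts = syn.resample_polyline(np.asarray(points_px, float), 0.3)
    img = syn.render_points(shape, pts, np.ones(len(pts)), 0.0)
    img = ndi.gaussian_filter(img, psf_sigma)
    return img / img.max()


class TestContourLength:
    def test_two_points(self):
        tr = trace_from_points([[0, 0], [0, 50]], pixel_size=0.1)
        assert fil.contour_length(tr) == pytest.approx(5.0)

    @given(angle=st.floats(0, 2 * np.pi))
    @settings(derandomize=True, max_examples=25)
    def test_rotation_isometry(self, angle):
        rng = np.random.default_rng(7)
        pts = np.cumsum(rng.normal(0, 1, (40, 2)), axis=0)
        c, s = np.cos(angle), np.sin(angle)
        rot = pts @ np.array([[c, -s], [s, c]]).T
        a = fil.contour_length(trace_from_points(pts))
        b = fil.contour_length(trace_from_points(rot))
        assert abs(a - b) < 1e-9

    def test_semicircle_arc_length(self):
        th = np.linspace(0, np.pi, 100)
        r = 30.0
        pts = np.column_stack([r * np.cos(th), r * np.sin(th)])
        tr = trace_from_points(pts, pixel_size=1.0)
        assert fil.contour_length(tr) == pytest.approx(np.pi * r, rel=1e-3)


class TestFilamentStrain:
    @pytest.mark.parametrize("l_now, l_ref, expected",
                             [(100, 100, 0.0), (105, 100, 0.05),
                              (95, 100, -0.05)])
    def test_definition(self, l_now, l_ref, expected):
        assert fil.filament_strain(l_now, l_ref) == pytest.approx(expected)

    def test_non_positive_reference_rejected(self):
        with pytest.raises(ValueError):
            fil.filament_strain(10, 0)

    def test_truth_lengths_give_kappa_eps_exactly(self, small_filament_series):
        """Contour-ratio strain on decoupled truth lengths equals
        kappa * eps_yy to machine precision."""
        cfg, _, _, lengths = small_filament_series
        eyy, _ = cfg.strains()
        l0 = lengths[lengths.step == 0].set_index("filament_id").L_um
        for k in range(1, cfg.n_steps):
            lk = lengths[lengths.step == k].set_index("filament_id").L_um
            for fid in l0.index:
                eps = fil.filament_strain(lk[fid], l0[fid])
                assert eps == pytest.approx(0.16 * eyy[k], abs=1e-9)


class TestStrainTransferFit:
    def test_exact_line(self):
        x = np.array([0.0, 0.1, 0.2, 0.3])
        fit = fil.fit_strain_transfer(x, 0.2 * x)
        assert fit.slope == pytest.approx(0.2, abs=1e-12)
        assert fit.slope_ci95[1] - fit.slope_ci95[0] == pytest.approx(0.0,
                                                                      abs=1e-9)

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        x = np.repeat(np.linspace(0, 0.3, 5), 4)
        y = 0.2 * x + rng.normal(0, 0.01, x.size)
        perm = rng.permutation(x.size)
        a = fil.fit_strain_transfer(x, y)
        b = fil.fit_strain_transfer(x[perm], y[perm])
        assert a.slope == pytest.approx(b.slope, abs=1e-12)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            fil.fit_strain_transfer([0.1, 0.1, 0.1], [1, 2, 3])

    def test_confidence_band_contains_truth_on_synthetic(self):
        rng = np.random.default_rng(3)
        x = np.repeat(np.linspace(0, 0.34, 11), 30)
        y = 0.16 * x + rng.normal(0, 0.01, x.size)
        fit = fil.fit_strain_transfer(x, y)
        assert fit.slope_ci95[0] <= 0.16 <= fit.slope_ci95[1]


class TestSegmentation:
    def test_straight_trace_single_segment(self):
        tr = trace_from_points(np.column_stack([np.zeros(80),
                                                np.arange(80.0)]))
        seg = fil.segment_by_angle(tr)
        assert seg.n_segments == 1
        assert seg.lengths_um.sum() == pytest.approx(tr.contour_length_um)
        assert seg.angles_deg[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_kink_two_segments(self):
        a = np.column_stack([np.zeros(40), np.arange(40.0)])
        th = np.radians(10)
        b = a[-1] + np.column_stack([np.sin(th) * np.arange(1, 41),
                                     np.cos(th) * np.arange(1, 41)])
        tr = trace_from_points(np.vstack([a, b]))
        seg = fil.segment_by_angle(tr, threshold_deg=5)
        assert seg.n_segments == 2

    def test_circular_arc_segments_match_brute_force(self):
        """On an arc whose tangent turns 1 deg per resampled point, the
        cumulative 5-deg rule starts a new segment every 6th tangent."""
        dtheta = np.radians(0.999)  # just off 1 deg: no exact-threshold ties
        r_um = 0.05 / np.sin(dtheta / 2)  # chord length exactly 0.1 um
        th = np.arange(0, 60) * dtheta
        pts_um = r_um * np.column_stack([1 - np.cos(th), np.sin(th)])
        tr = trace_from_points(pts_um / 0.1, pixel_size=0.1)
        seg = fil.segment_by_angle(tr, threshold_deg=5, resample_um=0.1)
        # independent brute-force application of the rule to the tangents
        tang = np.diff(syn.resample_polyline(pts_um, 0.1), axis=0)
        ang = np.degrees(np.arctan2(tang[:, 0], tang[:, 1]))
        starts, ref = [0], ang[0]
        for i in range(1, len(ang)):
            if abs(ang[i] - ref) > 5.0:
                starts.append(i)
                ref = ang[i]
        assert seg.start_idx.tolist() == starts
        assert np.all(np.diff(seg.start_idx) == 6)

    def test_length_conservation_and_threshold_monotonicity(
            self, small_filament_series):
        cfg, stack, _, _ = small_filament_series
        traces = fil.trace_filaments(stack[0], cfg.pixel_size,
                                     min_length_um=3.0)
        assert traces
        for tr in traces:
            prev = None
            for thr in (20.0, 10.0, 5.0, 2.0):
                seg = fil.segment_by_angle(tr, threshold_deg=thr)
                assert seg.lengths_um.sum() == pytest.approx(
                    tr.contour_length_um, abs=1e-6)
                assert np.all((seg.angles_deg >= 0)
                              & (seg.angles_deg <= 90))
                if prev is not None:
                    assert seg.n_segments >= prev
                prev = seg.n_segments

    def test_successive_rule_ignores_slow_drift(self):
        """On a smooth arc turning 1 deg per point the successive rule sees
        only sub-threshold increments (one segment), while the cumulative
        rule cuts whenever the total drift exceeds the threshold."""
        dtheta = np.radians(0.999)
        r_um = 0.05 / np.sin(dtheta / 2)
        th = np.arange(0, 60) * dtheta
        pts_um = r_um * np.column_stack([1 - np.cos(th), np.sin(th)])
        tr = trace_from_points(pts_um / 0.1, pixel_size=0.1)
        suc = fil.segment_by_angle(tr, threshold_deg=5, rule="successive",
                                   resample_um=0.1)
        cum = fil.segment_by_angle(tr, threshold_deg=5, rule="cumulative",
                                   resample_um=0.1)
        assert suc.n_segments == 1
        assert cum.n_segments > 5


class TestSegmentPolarStats:
    def test_axial_segments_fill_first_bin(self):
        tr = trace_from_points(np.column_stack([np.zeros(50),
                                                np.arange(50.0)]))
        seg = fil.segment_by_angle(tr)
        stats = fil.segment_polar_stats([seg])
        assert stats.n_seg.iloc[0] == 1
        assert stats.n_seg.iloc[1:].sum() == 0

    def test_counts_conserved(self, small_filament_series):
        cfg, stack, _, _ = small_filament_series
        traces = fil.trace_filaments(stack[0], cfg.pixel_size,
                                     min_length_um=3.0)
        segs = [fil.segment_by_angle(t) for t in traces]
        stats = fil.segment_polar_stats(segs)
        assert stats.n_seg.sum() == sum(s.n_segments for s in segs)

    def test_uniform_orientations_near_uniform_counts(self):
        rng = np.random.default_rng(0)
        n = 10_000
        angles = rng.uniform(0, 90, n)
        segs = []
        for a in angles:
            th = np.radians(a)
            pts = np.array([[0, 0], [np.sin(th), np.cos(th)]]) * 20
            seg = fil.segment_by_angle(trace_from_points(pts,
                                                         pixel_size=0.1),
                                       threshold_deg=180)
            segs.append(seg)
        stats = fil.segment_polar_stats(segs, bin_deg=5)
        expect = n / 18
        sd = np.sqrt(n * (1 / 18) * (17 / 18))
        assert np.all(np.abs(stats.n_seg - expect) < 4 * sd)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fil.segment_polar_stats([])


class TestTracing:
    def test_blank_image_empty(self):
        assert fil.trace_filaments(np.zeros((128, 128)), 0.1) == []

    def test_straight_filament_length_within_2_percent(self):
        pts = np.column_stack([np.full(2, 60.0), [30.0, 230.0]])
        img = render_polyline(pts, (260, 120))
        traces = fil.trace_filaments(img, 0.1, min_length_um=3.0)
        assert len(traces) == 1
        assert traces[0].contour_length_um == pytest.approx(20.0, rel=0.02)

    def test_recall_on_sparse_field(self, small_filament_series):
        cfg, stack, truths, _ = small_filament_series
        traces = fil.trace_filaments(stack[0], cfg.pixel_size,
                                     min_length_um=3.0)
        assert len(traces) >= 0.9 * len(truths)

    def test_end_to_end_slope_recovery_within_ci(self, small_filament_series):
        """Full trace -> strain -> fit pipeline recovers kappa on a small
        synthetic series (kappa inside the fit's 95% CI, slope within 0.03)."""
        from vifstretch.pipeline import analyze_filament_series
        cfg, stack, _, _ = small_filament_series
        eyy, exx = cfg.strains()
        fit, _ = analyze_filament_series(stack, cfg.pixel_size, eyy, exx)
        assert fit.slope == pytest.approx(0.16, abs=0.03)
        lo, hi = fit.slope_ci95
        assert lo - 0.01 <= 0.16 <= hi + 0.01


class TestPersistenceLength:
    def test_straight_traces_capped_and_flagged(self):
        traces = [trace_from_points(np.column_stack([np.zeros(60),
                                                     np.arange(60.0)]),
                                    fid=i) for i in range(12)]
        lp, flagged = fil.apparent_persistence_length(traces)
        assert flagged and lp >= fil.LP_CAP_UM

    def test_wlc_ensemble_recovers_lp(self):
        rng = np.random.default_rng(3)
        traces = [
            trace_from_points(
                syn.wlc_backbone(10.0, 2.0, np.zeros(2),
                                 rng.uniform(0, 2 * np.pi), rng) / 0.1,
                fid=i)
            for i in range(100)]
        lp, flagged = fil.apparent_persistence_length(traces)
        assert not flagged
        assert lp == pytest.approx(2.0, rel=0.15)

    def test_zero_separation_correlation_is_one(self):
        rng = np.random.default_rng(0)
        tr = trace_from_points(
            syn.wlc_backbone(5.0, 2.0, np.zeros(2), 0.0, rng) / 0.1)
        rs = syn.resample_polyline(tr.points_um, 0.1)
        theta = fil._tangent_angles(rs)
        assert np.mean(np.cos(theta - theta)) == 1.0
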