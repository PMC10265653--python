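"""Ground-truth contracts of the synthetic-data generators."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vifstretch import synthetic as syn


class TestStretchConfig:
    def test_strains_linear_and_zero_at_origin(self):
        cfg = syn.StretchConfig()
        eyy, exx = cfg.strains()
        assert eyy[0] == 0 and exx[0] == 0
        assert np.allclose(np.diff(eyy), eyy[1]) and eyy[-1] == 0.33
        assert np.all(np.diff(np.abs(eyy)) > 0)
        assert np.all(np.diff(np.abs(exx)) > 0)

    @given(eyy=st.floats(-0.5, 0.0), exx=st.floats(-0.3, -0.01))
    @settings(derandomize=True, max_examples=20)
    def test_rejects_non_positive_longitudinal(self, eyy, exx):
        with pytest.raises(ValueError):
            syn.StretchConfig(eps_yy_max=eyy, eps_xx_max=exx)

    def test_rejects_positive_lateral(self):
        with pytest.raises(ValueError):
            syn.StretchConfig(eps_xx_max=0.05)


class TestBeadSeries:
    def test_affine_truth_positions(self):
        """A bead on the stretch axis at +100 px lands at +133 px; a corner
        bead at (100, 100) lands at (88, 133) under eps = (-0.12, 0.33)."""
        cfg = syn.StretchConfig(seed=0)
        _, truth = syn.make_bead_series(cfg, n_beads=20, shape=(512, 512),
                                        jitter_px=0, noise=0)
        t0 = truth[truth.step == 0]
        t10 = truth[truth.step == 10]
        cx = cy = (512 - 1) / 2
        for b in range(20):
            x0 = t0[t0.bead_id == b].x_px.iloc[0] - cx
            y0 = t0[t0.bead_id == b].y_px.iloc[0] - cy
            x1 = t10[t10.bead_id == b].x_px.iloc[0] - cx
            y1 = t10[t10.bead_id == b].y_px.iloc[0] - cy
            assert x1 == pytest.approx(0.88 * x0, abs=1e-9)
            assert y1 == pytest.approx(1.33 * y0, abs=1e-9)

    def test_zero_strain_gives_identical_frames(self):
        cfg = syn.StretchConfig(eps_yy_max=1e-12, eps_xx_max=-1e-12, seed=1)
        stack, _ = syn.make_bead_series(cfg, n_beads=5, jitter_px=0, noise=0)
        for k in range(1, cfg.n_steps):
            np.testing.assert_allclose(stack[k], stack[0], atol=1e-12)

    def test_bit_reproducible(self):
        cfg = syn.StretchConfig(seed=9)
        a, ta = syn.make_bead_series(cfg, n_beads=10)
        b, tb = syn.make_bead_series(syn.StretchConfig(seed=9), n_beads=10)
        np.testing.assert_array_equal(a, b)
        assert ta.equals(tb)


class TestFilamentSeries:
    def test_kappa_zero_lengths_constant(self):
        cfg = syn.StretchConfig(seed=2)
        _, _, lengths = syn.make_filament_series(cfg, n_filaments=3,
                                                 kappa=0.0, shape=(512, 512))
        for fid, grp in lengths.groupby("filament_id"):
            np.testing.assert_allclose(grp.L_um, grp.L_um.iloc[0], rtol=1e-9)

    def test_decoupled_truth_scaling(self, small_filament_series):
        """Decoupled-mode truth lengths are L0 (1 + kappa eps_yy) exactly."""
        cfg, _, _, lengths = small_filament_series
        eyy, _ = cfg.strains()
        l0 = lengths[lengths.step == 0].set_index("filament_id").L_um
        for k in range(cfg.n_steps):
            lk = lengths[lengths.step == k].set_index("filament_id").L_um
            np.testing.assert_allclose(lk, l0 * (1 + 0.16 * eyy[k]),
                                       rtol=1e-9)

    def test_decoupled_straight_definition(self):
        """Straight axial filament, L0=100, kappa=0.26, eps=0.341 -> 108.87."""
        bb = np.column_stack([np.zeros(101), np.linspace(0, 100.0, 101)])
        tr = syn.FilamentTruth(backbone=bb, Lp_true=1e6, L0=100.0,
                               mean_angle=0.0, kappa=0.26)
        out = syn._deform_backbone(tr, 1.0, 1.341, 0.341, 0.26, "decoupled",
                                   np.array([0.0, 50.0]), 0.5)
        assert syn.polyline_length(out) == pytest.approx(108.866, abs=1e-2)

    def test_affine_pinned_straight_exact(self):
        """kappa=1 straight axial filament: contour ratio = 1 + eps_yy."""
        bb = np.column_stack([np.zeros(201), np.linspace(0, 10.0, 201)])
        tr = syn.FilamentTruth(backbone=bb, Lp_true=1e6, L0=10.0,
                               mean_angle=0.0, kappa=1.0)
        out = syn._deform_backbone(tr, 0.88, 1.33, 0.33, 1.0, "affine_pinned",
                                   np.array([0.0, 5.0]), 0.5)
        ratio = syn.polyline_length(out) / 10.0
        assert ratio == pytest.approx(1.33, rel=1e-9)

    def test_rejects_kappa_out_of_range(self):
        cfg = syn.StretchConfig(seed=0)
        with pytest.raises(ValueError):
            syn.make_filament_series(cfg, n_filaments=1, kappa=1.5)

    def test_angles_concentrate_on_stretch_axis(self):
        """Stiff filaments (end-to-end axis ~ initial tangent) show the
        flush-induced bias toward the stretch axis."""
        cfg = syn.StretchConfig(seed=6)
        _, truths, _ = syn.make_filament_series(cfg, n_filaments=20,
                                                Lp_true=50.0,
                                                shape=(700, 700))
        angles = np.array([t.mean_angle for t in truths])
        assert np.mean(angles <= 45.0) > 0.6

    def test_truth_lengths_non_decreasing(self, small_filament_series):
        cfg, _, _, lengths = small_filament_series
        for fid, grp in lengths.groupby("filament_id"):
            assert np.all(np.diff(grp.sort_values("step").L_um) >= -1e-12)


class TestWLC:
    def test_backbone_arc_length_exact(self):
        rng = np.random.default_rng(0)
        bb = syn.wlc_backbone(7.3, 2.0, np.zeros(2), 0.3, rng)
        assert syn.polyline_length(bb) == pytest.approx(7.3, rel=1e-6)

    def test_filament_truth_validates_arc_length(self):
        bb = np.array([[0.0, 0.0], [0.0, 5.0]])
        with pytest.raises(ValueError):
            syn.FilamentTruth(backbone=bb, Lp_true=2.0, L0=6.0,
                              mean_angle=0.0, kappa=0.5)


class TestAFM:
    def test_zero_tubes_zero_noise_all_zero(self):
        hmap, mask = syn.make_afm_map(syn.AFMTruth(tubes=[], noise_sigma=0))
        assert np.all(hmap == 0) and not mask.any()

    def test_empty_tubes_with_density_rejected(self):
        with pytest.raises(ValueError):
            syn.make_afm_map(syn.AFMTruth(tubes=[], noise_sigma=0),
                             expected_density=1.0)

    def test_single_tube_peak_height(self):
        tube = [np.array([[0.0, 1000.0], [2000.0, 1000.0]])]
        hmap, _ = syn.make_afm_map(syn.AFMTruth(tubes=tube, noise_sigma=0))
        assert hmap.max() == pytest.approx(10.0, rel=0.01)

    def test_crossing_tubes_stack_additively(self):
        tubes = [np.array([[0.0, 1000.0], [2000.0, 1000.0]]),
                 np.array([[1000.0, 0.0], [1000.0, 2000.0]])]
        hmap, _ = syn.make_afm_map(syn.AFMTruth(tubes=tubes, noise_sigma=0))
        assert hmap[250, 250] == pytest.approx(20.0, rel=0.02)

    def test_max_rule_caps_at_single_height(self):
        tubes = [np.array([[0.0, 1000.0], [2000.0, 1000.0]]),
                 np.array([[1000.0, 0.0], [1000.0, 2000.0]])]
        hmap, _ = syn.make_afm_map(
            syn.AFMTruth(tubes=tubes, noise_sigma=0, overlap_rule="max"))
        assert hmap.max() == pytest.approx(10.0, rel=0.02)


class TestFRAPCurve:
    def test_value_at_tau_d(self):
        truth = syn.FRAPTruth(noise_sigma=0, tau_D=1.0, frame_interval=0.5,
                              n_frames=10)
        t, y = syn.make_frap_curve(truth)
        f_inf = truth.F0 + truth.mobile_fraction * (truth.F_pre - truth.F0)
        expected = truth.F0 + 0.5238 * (f_inf - truth.F0)
        assert y[1] == pytest.approx(expected, abs=1e-3)  # t[1] = 1.0 = tau_D

    def test_immobile_curve_is_flat(self):
        truth = syn.FRAPTruth(noise_sigma=0, mobile_fraction=0.0)
        _, y = syn.make_frap_curve(truth)
        np.testing.assert_allclose(y, truth.F0, atol=1e-12)

    def test_long_time_full_recovery(self):
        truth = syn.FRAPTruth(noise_sigma=0, mobile_fraction=1.0, tau_D=0.01,
                              frame_interval=10.0)
        _, y = syn.make_frap_curve(truth)
        assert abs(y[-1] - truth.F_pre) < 1e-2


class TestTiltedStack:
    def test_zero_tilt_all_pixels_sharpest_at_same_slice(self, texture):
        stack = syn.make_tilted_stack(texture, [3.0, 0, 0, 0, 0, 0],
                                      n_slices=7)
        # slice 3 is unblurred, others blurred
        variances = [np.var(np.diff(s, axis=0)) for s in stack]
        assert np.argmax(variances) == 3

    def test_focus_surface_out_of_range_rejected(self, texture):
        with pytest.raises(ValueError):
            syn.make_tilted_stack(texture, [10.0, 0.5, 0, 0, 0, 0],
                                  n_slices=5)

    def test_needs_three_slices(self, texture):
        with pytest.raises(ValueError):
            syn.make_tilted_stack(texture, [0.0, 0, 0, 0, 0, 0], n_slices=2)
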