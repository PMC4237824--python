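"""Kinetic analysis chain: registration, smoothing, SPGR inversion, AIF
extraction, Patlak fitting, rendering, masking and compliance filters."""

import math

import numpy as np
import pytest

import plaquedce as p
from plaquedce.kinetics import (estimate_noise_variance, polygon_mask,
                                wall_mask_with_exclusion)
from plaquedce.synth import tissue_concentration

from oracles import patlak_normal_equations


# --------------------------------------------------------------------------
# registration

class TestRegistration:
    def test_zero_motion_zero_shifts(self, clean_series):
        _, shifts, skipped = p.register_series(clean_series)
        assert np.all(np.abs(shifts) < 0.1 * clean_series.protocol.pixel_size)
        assert skipped == []

    def test_known_shift_recovered(self, clean_series):
        s = p.DCESeries(clean_series.data.copy(), clean_series.protocol)
        s.data[0, :, :, 5] = np.roll(s.data[0, :, :, 5], 1, axis=1)  # +1 px in x
        reg, shifts, _ = p.register_series(s)
        px = s.protocol.pixel_size
        assert shifts[0, 5, 1] == pytest.approx(-px)
        assert np.allclose(reg.data, clean_series.data)

    def test_idempotent(self, clean_series):
        once, _, _ = p.register_series(clean_series)
        _, shifts2, _ = p.register_series(once)
        assert np.all(np.abs(shifts2) < 0.1 * clean_series.protocol.pixel_size)

    def test_all_zero_frame_skipped(self, clean_series):
        s = p.DCESeries(clean_series.data.copy(), clean_series.protocol)
        s.data[0, :, :, 7] = 0.0
        _, shifts, skipped = p.register_series(s)
        assert (0, 7) in skipped
        assert np.all(shifts[0, 7] == 0.0)


# --------------------------------------------------------------------------
# Kalman smoothing

class TestKalmanSmooth:
    def test_constant_curve_is_fixed_point(self, ge_protocol):
        data = np.full((1, 4, 4, 18), 3.7)
        s = p.DCESeries(data, ge_protocol)
        out = p.kalman_smooth(s, process_var=1.0, obs_var=1.0)
        assert np.allclose(out.data, 3.7)

    def test_perfect_observation_limit(self, clean_series):
        out = p.kalman_smooth(clean_series, process_var=1.0, obs_var=1e-14)
        assert np.allclose(out.data, clean_series.data, atol=1e-8)

    def test_white_noise_variance_reduced(self, ge_protocol):
        rng = np.random.default_rng(0)
        data = rng.normal(0.0, 1.0, size=(1, 100, 100, 18))  # 10^4 curves
        s = p.DCESeries(data, ge_protocol)
        out = p.kalman_smooth(s, process_var=0.01, obs_var=1.0)
        assert out.data.var(axis=-1).mean() < data.var(axis=-1).mean()

    def test_rejects_nonpositive_variances(self, clean_series):
        with pytest.raises(ValueError):
            p.kalman_smooth(clean_series, process_var=0.0, obs_var=1.0)

    def test_auto_smoothing_identity_on_noise_free(self, clean_series):
        out = p.smooth_series_auto(clean_series)
        assert out.data is clean_series.data
        assert estimate_noise_variance(clean_series) == 0.0


# --------------------------------------------------------------------------
# SPGR inversion

class TestSignalToConcentration:
    def test_baseline_only_signal_maps_to_zero(self, ge_protocol):
        sig = p.spgr_signal(np.zeros((1, 4, 4, 18)), 1000.0, 1.0, 4.5,
                            ge_protocol.tr, ge_protocol.flip_angle)
        s = p.DCESeries(sig, ge_protocol)
        conc = p.signal_to_concentration(s, 1000.0, 4.5)
        assert np.all(np.abs(conc.conc) < 1e-8)

    def test_forward_inverse_round_trip(self, phantom, aif, clean_series):
        conc_true = tissue_concentration(phantom.ktrans_true, phantom.vp_true,
                                         aif)
        rec = p.signal_to_concentration(clean_series, phantom.t10, phantom.r1)
        assert np.abs(rec.conc[0] - conc_true).max() < 1e-6

    def test_doubling_relaxivity_halves_concentration(self, phantom,
                                                      clean_series):
        c1 = p.signal_to_concentration(clean_series, phantom.t10, 4.5)
        c2 = p.signal_to_concentration(clean_series, phantom.t10, 9.0)
        assert np.allclose(c2.conc, c1.conc / 2.0, atol=1e-12)

    def test_out_of_range_signal_flagged_not_extrapolated(self, phantom,
                                                          clean_series):
        s = p.DCESeries(clean_series.data.copy(), clean_series.protocol)
        s.data[0, 0, 0, 10] = 1e6  # beyond the invertible SPGR branch
        conc = p.signal_to_concentration(s, phantom.t10, phantom.r1)
        assert not conc.valid_mask[0, 0, 0]
        assert np.isfinite(conc.conc).all()


# --------------------------------------------------------------------------
# AIF extraction

@pytest.fixture(scope="module")
def conc(phantom, clean_series):
    return p.signal_to_concentration(clean_series, phantom.t10, phantom.r1)


class TestExtractAIF:
    def test_closed_loop_recovery(self, conc, phantom, aif):
        rec = p.extract_aif(conc, phantom.lumen_contour, hematocrit=0.0)
        post = aif.cp > 0
        assert np.all(np.abs(rec.cp[post] - aif.cp[post]) / aif.cp[post] < 0.02)
        assert np.allclose(rec.cp[~post], 0.0, atol=1e-12)

    def test_hematocrit_scaling(self, conc, phantom):
        blood = p.extract_aif(conc, phantom.lumen_contour, hematocrit=0.0)
        plasma = p.extract_aif(conc, phantom.lumen_contour, hematocrit=0.42)
        assert np.allclose(plasma.cp, blood.cp / 0.58)

    def test_flat_lumen_gives_zero_curve(self, ge_protocol, phantom):
        flat = p.DCESeries(np.full((1, 64, 64, 18), 0.2), ge_protocol)
        conc = p.signal_to_concentration(flat, 1000.0, 4.5)
        rec = p.extract_aif(conc, phantom.lumen_contour, hematocrit=0.0)
        assert np.allclose(rec.cp, 0.0, atol=1e-10)

    def test_empty_roi_rejected(self, conc):
        far = np.array([[0.1, 0.1], [0.3, 0.1], [0.3, 0.3], [0.1, 0.3]])
        with pytest.raises(ValueError):
            p.extract_aif(conc, far)


# --------------------------------------------------------------------------
# Patlak fit

class TestPatlakFit:
    def test_zero_pixel_gives_zero_estimates(self, conc, aif, phantom):
        kmap = p.patlak_fit(conc, aif)
        bg = ~(phantom.lumen_mask | phantom.wall_mask)
        assert np.abs(kmap.ktrans[0][bg]).max() < 1e-10
        assert np.abs(kmap.vp[0][bg]).max() < 1e-10

    def test_noise_free_recovery_of_generating_values(self, conc, aif,
                                                      phantom):
        kmap = p.patlak_fit(conc, aif)
        wall = phantom.wall_mask
        assert np.abs(kmap.ktrans[0][wall] - 0.062).max() < 1e-8
        assert np.abs(kmap.vp[0][wall] - 0.067).max() < 1e-8

    def test_pure_vp_signal_exact(self, aif, ge_protocol):
        v = 0.31
        conc_arr = np.broadcast_to(v * aif.cp, (1, 4, 4, 18)).copy()
        conc = p.ConcentrationSeries(conc=conc_arr, baseline_frames=np.array([0, 1]),
                                     frame_times=aif.times, protocol=ge_protocol)
        kmap = p.patlak_fit(conc, aif)
        assert np.abs(kmap.vp - v).max() < 1e-10
        assert np.abs(kmap.ktrans).max() < 1e-10

    def test_matches_normal_equations_oracle(self, aif, ge_protocol):
        """OLS estimates equal a brute-force normal-equations solve on every
        pixel of a 16x16 fixture with noisy concentrations."""
        rng = np.random.default_rng(12)
        k = rng.uniform(0.0, 0.2, (16, 16))
        v = rng.uniform(0.0, 0.4, (16, 16))
        conc_arr = tissue_concentration(k, v, aif)[None]
        conc_arr = conc_arr + rng.normal(0, 0.02, conc_arr.shape)
        conc = p.ConcentrationSeries(conc=conc_arr, baseline_frames=np.array([0, 1]),
                                     frame_times=aif.times, protocol=ge_protocol)
        kmap = p.patlak_fit(conc, aif)
        for i in range(16):
            for j in range(16):
                k_o, v_o = patlak_normal_equations(conc_arr[0, i, j], aif.cp,
                                                   aif.times)
                assert kmap.ktrans[0, i, j] == pytest.approx(k_o, abs=1e-10)
                assert kmap.vp[0, i, j] == pytest.approx(v_o, abs=1e-10)

    def test_singular_design_flagged(self, ge_protocol):
        zero_aif = p.AIFCurve(times=ge_protocol.frame_times,
                              cp=np.zeros(18))
        conc = p.ConcentrationSeries(conc=np.zeros((1, 4, 4, 18)),
                                     baseline_frames=np.array([0, 1]),
                                     frame_times=ge_protocol.frame_times,
                                     protocol=ge_protocol)
        kmap = p.patlak_fit(conc, zero_aif)
        assert not kmap.valid_mask.any()


# --------------------------------------------------------------------------
# V-V rendering

class TestRenderVV:
    def _map(self, kt, vp):
        arr_k = np.full((2, 2), kt)
        arr_v = np.full((2, 2), vp)
        return p.KineticMap(ktrans=arr_k, vp=arr_v,
                            fit_residual=np.zeros((2, 2)),
                            valid_mask=np.ones((2, 2), bool))

    @pytest.mark.parametrize("kt,vp,expected", [
        (0.2, 0.0, (0.0, 1.0, 0.0)),   # full-range Ktrans -> saturated green
        (0.0, 0.0, (0.0, 0.0, 0.0)),   # zero map -> black
        (0.4, 0.0, (0.0, 1.0, 0.0)),   # clamped above the display range
        (0.1, 0.5, (0.5, 0.5, 0.0)),   # mid-range mixture
    ])
    def test_channel_mapping(self, kt, vp, expected):
        img = p.render_vv_image(self._map(kt, vp))
        assert tuple(img[0, 0]) == pytest.approx(expected)

    def test_idempotent_on_clamped_and_order_invariant(self):
        rng = np.random.default_rng(0)
        kmap = p.KineticMap(ktrans=rng.uniform(0, 0.2, (5, 5)),
                            vp=rng.uniform(0, 1, (5, 5)),
                            fit_residual=np.zeros((5, 5)),
                            valid_mask=np.ones((5, 5), bool))
        img = p.render_vv_image(kmap)
        # rendering the rendered values (already clamped) changes nothing
        again = p.render_vv_image(p.KineticMap(
            ktrans=img[..., 1] * 0.2, vp=img[..., 0],
            fit_residual=np.zeros((5, 5)), valid_mask=np.ones((5, 5), bool)))
        assert np.allclose(again, img)
        # per-pixel map: permuting pixels permutes output identically
        perm = rng.permutation(25)
        kmap_p = p.KineticMap(ktrans=kmap.ktrans.ravel()[perm].reshape(5, 5),
                              vp=kmap.vp.ravel()[perm].reshape(5, 5),
                              fit_residual=np.zeros((5, 5)),
                              valid_mask=np.ones((5, 5), bool))
        img_p = p.render_vv_image(kmap_p)
        assert np.allclose(img_p.reshape(25, 3),
                           img.reshape(25, 3)[perm])


# --------------------------------------------------------------------------
# wall mask and measurement

def _circle(cx, cy, r, n=256):
    th = np.linspace(0, 2 * math.pi, n, endpoint=False)
    return np.column_stack([cx + r * np.cos(th), cy + r * np.sin(th)])


class TestWallMask:
    px = 0.625
    shape = (64, 64)
    # generic center: a lattice-aligned circle maximizes ring pixelization error
    c = 20.17

    def test_exclusion_ring_area(self):
        lumen = _circle(self.c, self.c, 3.0)
        outer = _circle(self.c, self.c, 5.0)
        mask = wall_mask_with_exclusion(lumen, outer, self.px, self.shape,
                                        exclusion_mm=1.0)
        analytic = math.pi * (5.0 ** 2 - 4.0 ** 2)
        assert mask.sum() * self.px ** 2 == pytest.approx(analytic, rel=0.05)

    def test_no_exclusion_keeps_full_annulus(self):
        lumen = _circle(self.c, self.c, 3.0)
        outer = _circle(self.c, self.c, 5.0)
        full = wall_mask_with_exclusion(lumen, outer, self.px, self.shape,
                                        exclusion_mm=0.0)
        analytic = math.pi * (25.0 - 9.0)
        assert full.sum() * self.px ** 2 == pytest.approx(analytic, rel=0.05)

    def test_wall_thinner_than_exclusion_empty(self):
        lumen = _circle(self.c, self.c, 3.0)
        outer = _circle(self.c, self.c, 3.8)
        mask = wall_mask_with_exclusion(lumen, outer, self.px, self.shape,
                                        exclusion_mm=1.0)
        assert mask.sum() == 0

    def test_monotone_in_exclusion(self):
        lumen = _circle(self.c, self.c, 3.0)
        outer = _circle(self.c, self.c, 6.0)
        prev = None
        for excl in (0.0, 0.5, 1.0, 1.5, 2.0):
            mask = wall_mask_with_exclusion(lumen, outer, self.px, self.shape,
                                            exclusion_mm=excl)
            if prev is not None:
                assert not np.any(mask & ~prev)  # never adds pixels
            prev = mask

    def test_crossing_contours_rejected(self):
        lumen = _circle(self.c, self.c, 5.0)
        outer = _circle(self.c + 6.0, self.c, 5.0)
        with pytest.raises(ValueError):
            wall_mask_with_exclusion(lumen, outer, self.px, self.shape)

    def test_max_wall_thickness_concentric(self):
        lumen = _circle(self.c, self.c, 3.0)
        outer = _circle(self.c, self.c, 5.0)
        assert p.max_wall_thickness(lumen, outer) == pytest.approx(2.0, abs=0.01)


class TestMeasurePlaque:
    def _kmap(self, kt):
        kt = np.asarray(kt, float)
        return p.KineticMap(ktrans=kt, vp=kt * 0.5,
                            fit_residual=np.zeros_like(kt),
                            valid_mask=np.ones(kt.shape, bool))

    def test_constant_field_mean_exact(self):
        kmap = self._kmap(np.full((10, 10), 0.05))
        mask = np.ones((10, 10), bool)
        m = p.measure_plaque(kmap, mask, pixel_size=0.625)
        assert m.mean_ktrans == pytest.approx(0.05, rel=1e-12)

    def test_area_from_pixel_count(self):
        kmap = self._kmap(np.zeros((10, 10)))
        mask = np.zeros((10, 10), bool)
        mask.ravel()[:64] = True
        m = p.measure_plaque(kmap, mask, pixel_size=0.625)
        assert m.analyzed_area == pytest.approx(25.0)

    def test_arithmetic_mean(self):
        field = np.concatenate([np.full(50, 0.02), np.full(50, 0.10)])
        kmap = self._kmap(field.reshape(10, 10))
        m = p.measure_plaque(kmap, np.ones((10, 10), bool), pixel_size=0.625)
        assert m.mean_ktrans == pytest.approx(0.06)

    def test_empty_mask_marked_missing(self):
        kmap = self._kmap(np.full((4, 4), 0.1))
        m = p.measure_plaque(kmap, np.zeros((4, 4), bool), pixel_size=0.625)
        assert m.missing and math.isnan(m.mean_ktrans)
        assert m.analyzed_area == 0.0


# --------------------------------------------------------------------------
# protocol compliance and inclusion

class TestComplianceFilters:
    def test_clean_record_compliant(self, ge_protocol):
        rec = p.ScanRecord(subject_id="s", scan_index=1, vendor="GE")
        assert p.check_protocol(rec, ge_protocol).compliant

    def test_too_few_frames_flagged(self, ge_protocol):
        rec = p.ScanRecord(subject_id="s", scan_index=1, vendor="GE",
                           n_frames_actual=12)
        rep = p.check_protocol(rec, ge_protocol)
        assert rep.too_few_time_frames
        assert "too few time frames" in rep.violations

    def test_roster_yields_ten_noncompliant(self, ge_protocol):
        roster = p.generate_roster_fixture(seed=0)
        compliance = p.subject_protocol_compliance(roster, ge_protocol)
        assert sum(not ok for ok in compliance.values()) == 10

    @pytest.mark.parametrize("thickness,included", [(1.0, False), (1.1, True)])
    def test_strict_thickness_threshold(self, thickness, included):
        m = p.PlaqueMeasurement(subject_id="s", scan_index=1, mean_ktrans=0.06,
                                mean_vp=0.07, analyzed_area=20.0,
                                max_wall_thickness=thickness)
        assert bool(p.apply_inclusion([m])) is included

    def test_empty_input(self):
        assert p.apply_inclusion([]) == []
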