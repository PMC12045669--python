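"""Calibration fitting, R1/concentration mapping and amount integration."""

import numpy as np
import pytest

import lungquant as lq
from lungquant.core import AcquisitionParams
from lungquant.quantify import fit_pre_calibration, r1_post_map


def _synth_signals(a, t1, params):
    return [lq.ute_signal(a, alpha, params.tr_ms, t1) for alpha in params.flip_angles_deg]


class TestPreCalibration:
    def test_noiseless_recovery(self, params):
        signals = _synth_signals(1000.0, 800.0, params)
        calib = fit_pre_calibration(signals, params)
        assert calib.A == pytest.approx(1000.0, rel=1e-6)
        assert calib.r1_pre == pytest.approx(1.25, rel=1e-6)
        assert calib.fit_residual < 1e-8

    def test_two_point_closed_form_oracle(self):
        # with two angles the model is exactly determined; solve it by
        # hand from the signal ratio and compare with the fit
        params = AcquisitionParams(flip_angles_deg=(5.0, 25.0))
        a_true, t1_true = 740.0, 620.0
        s1, s2 = _synth_signals(a_true, t1_true, params)
        r1a, r2a = np.deg2rad(5.0), np.deg2rad(25.0)
        # S1/S2 = sin a1 (1 - cos a2 E) / (sin a2 (1 - cos a1 E)) -> linear in E
        rho = s1 / s2
        e1 = (rho * np.sin(r2a) - np.sin(r1a)) / (
            rho * np.sin(r2a) * np.cos(r1a) - np.sin(r1a) * np.cos(r2a)
        )
        t1_oracle = -params.tr_ms / np.log(e1)
        calib = fit_pre_calibration([s1, s2], params)
        assert calib.r1_pre == pytest.approx(1000.0 / t1_oracle, rel=1e-8)
        assert calib.A == pytest.approx(a_true, rel=1e-8)

    def test_scale_equivariance(self, params):
        signals = np.asarray(_synth_signals(1500.0, 400.0, params))
        base = fit_pre_calibration(signals, params)
        scaled = fit_pre_calibration(7.5 * signals, params)
        assert scaled.A == pytest.approx(7.5 * base.A, rel=1e-8)
        assert scaled.r1_pre == pytest.approx(base.r1_pre, rel=1e-8)

    def test_degenerate_series_rejected(self):
        params = AcquisitionParams(flip_angles_deg=(10.0, 10.0), post_flip_angle_deg=10.0)
        with pytest.raises(ValueError, match="distinct"):
            fit_pre_calibration([5.0, 5.0], params)
        with pytest.raises(ValueError, match="> 0"):
            fit_pre_calibration([5.0, -1.0, 3.0, 2.0], AcquisitionParams())


class TestR1AndConcentration:
    def test_uniform_t1_inversion(self, params):
        s = lq.ute_signal(1000.0, 25.0, params.tr_ms, 170.0)
        vol = lq.Volume3D(np.full((6, 6, 6), s), (1, 1, 1))
        calib = lq.PreCalibration(r1_pre=1.25, A=1000.0, fit_residual=0.0)
        res = r1_post_map(vol, calib, params, np.ones((6, 6, 6), bool))
        np.testing.assert_allclose(res.r1_map.data, 1000.0 / 170.0, rtol=1e-12)
        assert res.r1_map.data.flat[0] == pytest.approx(5.882, abs=1e-3)

    def test_ceiling_voxels_flagged(self, params):
        data = np.full((4, 4, 4), 50.0)
        data[0, 0, :2] = 1e6
        calib = lq.PreCalibration(r1_pre=1.25, A=1000.0, fit_residual=0.0)
        res = r1_post_map(lq.Volume3D(data, (1, 1, 1)), calib, params, np.ones(data.shape, bool))
        assert res.invalid_voxel_count == 2
        conc = lq.concentration_map(res, calib, params)
        assert conc.invalid_voxel_count == 2

    def test_empty_mask_rejected(self, params):
        calib = lq.PreCalibration(r1_pre=1.25, A=1000.0, fit_residual=0.0)
        vol = lq.Volume3D(np.full((3, 3, 3), 50.0), (1, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            r1_post_map(vol, calib, params, np.zeros((3, 3, 3), bool))

    def test_relaxivity_relation_value(self, params):
        # R1_post = 5.882 s^-1, R1_pre = 0.5 s^-1, r1 = 3 -> C ~ 1.794 mM
        calib = lq.PreCalibration(r1_pre=0.5, A=1000.0, fit_residual=0.0)
        s = lq.ute_signal(1000.0, 25.0, params.tr_ms, 170.0)
        vol = lq.Volume3D(np.full((3, 3, 3), s), (1, 1, 1))
        res = r1_post_map(vol, calib, params, np.ones((3, 3, 3), bool))
        conc = lq.concentration_map(res, calib, params)
        assert conc.c_map.data.flat[0] == pytest.approx(1.794, abs=1e-3)

    def test_no_enhancement_gives_zero_and_clamping_counts(self, params):
        calib = lq.PreCalibration(r1_pre=1000.0 / 170.0, A=1000.0, fit_residual=0.0)
        s = lq.ute_signal(1000.0, 25.0, params.tr_ms, 170.0)
        data = np.full((4, 4, 4), s)
        data[0, 0, 0] = s * 0.9  # longer T1 than pre -> negative raw C
        res = r1_post_map(lq.Volume3D(data, (1, 1, 1)), calib, params, np.ones(data.shape, bool))
        conc = lq.concentration_map(res, calib, params)
        np.testing.assert_allclose(conc.c_map.data[1:], 0.0, atol=1e-12)
        assert conc.negative_clamped_count == 1
        assert conc.c_map_clamped.data[0, 0, 0] == 0.0
        assert conc.c_map.data[0, 0, 0] < 0.0  # raw map preserved

    def test_rescaling_pre_and_post_leaves_concentration_unchanged(self, params):
        rng = np.random.default_rng(5)
        t1_field = rng.uniform(100.0, 900.0, size=(5, 5, 5))
        post = lq.ute_signal(1000.0, 25.0, params.tr_ms, t1_field)
        pre_signals = np.asarray(_synth_signals(1000.0, 800.0, params))
        mask = np.ones(t1_field.shape, bool)

        def chain(scale):
            calib = fit_pre_calibration(scale * pre_signals, params)
            res = r1_post_map(lq.Volume3D(scale * post, (1, 1, 1)), calib, params, mask)
            return lq.concentration_map(res, calib, params).c_map.data

        np.testing.assert_allclose(chain(1.0), chain(11.0), rtol=1e-6)


class TestAmounts:
    def test_uniform_concentration_amount(self):
        # 318 voxels of 0.1 mL at 4.6 mM -> 31.8 mL x 4.6 mM = 146.28 umol
        shape = (318, 1, 1)
        spacing = (10.0, 10.0, 1.0)
        labels = lq.RegionLabels(np.full(shape, 2, dtype=np.int16))
        conc = lq.ConcentrationResult(
            c_map=lq.Volume3D(np.full(shape, 4.6), spacing),
            r1_post=lq.Volume3D(np.full(shape, 5.0), spacing),
            r1_pre=0.5,
            invalid_voxel_count=0,
            negative_clamped_count=0,
        )
        amount = lq.gd_amount(conc, labels, spacing, "enhanced")
        assert amount == pytest.approx(31.8 * 4.6, rel=1e-12)
        assert amount == pytest.approx(146.3, abs=0.05)

    def test_additivity_over_regions(self, full_phantom):
        ds = full_phantom
        conc = lq.ConcentrationResult(
            c_map=ds.truth_concentration,
            r1_post=ds.truth_t1_post.with_data(1000.0 / ds.truth_t1_post.data),
            r1_pre=1.25,
            invalid_voxel_count=0,
            negative_clamped_count=0,
        )
        spacing = ds.spec.spacing
        q_per = lq.gd_amount(conc, ds.truth_labels, spacing, "PER")
        q_cer = lq.gd_amount(conc, ds.truth_labels, spacing, "CER")
        q_enh = lq.gd_amount(conc, ds.truth_labels, spacing, "enhanced")
        assert q_per + q_cer == pytest.approx(q_enh, rel=1e-12)

    def test_unknown_region_rejected(self, toy_concentration):
        conc, labels, spacing = toy_concentration
        with pytest.raises(ValueError, match="unknown region"):
            lq.gd_amount(conc, labels, spacing, "LUNG")


class TestInstilledAmount:
    def test_protocol_mixture_is_100_umol(self):
        assert lq.instilled_gd_amount(2.7, 0.27, 500.0, 2.2) == pytest.approx(100.0)

    def test_zero_delivered_is_zero(self):
        assert lq.instilled_gd_amount(2.7, 0.27, 500.0, 0.0) == 0.0

    def test_dilution_symmetry(self):
        a = lq.instilled_gd_amount(2.7, 0.27, 500.0, 2.2)
        b = lq.instilled_gd_amount(5.4, 0.54, 500.0, 2.2)
        assert a == pytest.approx(b)

    def test_overdelivery_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            lq.instilled_gd_amount(1.0, 0.1, 500.0, 2.0)
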