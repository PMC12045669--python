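"""Digital-thorax generator: geometry, ground truth, rendering."""

import dataclasses

import numpy as np
import pytest

import lungquant as lq
from lungquant.phantom import PhantomSpec, build_geometry, assign_concentration, render_mri


class TestGeometry:
    def test_default_tree_has_four_generations(self, full_phantom):
        assert full_phantom.geometry.generations_built == 4

    def test_single_generation_is_one_cylinder(self):
        spec = PhantomSpec(seed=0, airway_generations=1).with_resolution((72, 72, 56))
        geo = build_geometry(spec)
        assert len(geo.tree) == 1
        assert geo.generations_built == 1

    def test_geometry_that_cannot_fit_is_rejected(self):
        with pytest.raises(ValueError, match="field of view"):
            build_geometry(PhantomSpec(shape=(32, 32, 32)))

    def test_deterministic_for_fixed_seed(self):
        spec = PhantomSpec(seed=11).with_resolution((72, 72, 56))
        a = build_geometry(spec)
        b = build_geometry(spec)
        np.testing.assert_array_equal(a.labels.labels, b.labels.labels)

    def test_balanced_asymmetry_gives_balanced_voxel_counts(self):
        """right_fraction = 0.5 -> near-equal peripheral volume per lung,
        pooled over several seeds."""
        r = l = 0
        for seed in range(10):
            spec = PhantomSpec(seed=seed, right_fraction=0.5).with_resolution((72, 72, 56))
            geo = build_geometry(spec)
            per = geo.labels.per_mask
            r += int((per & (geo.lung_side == 1)).sum())
            l += int((per & (geo.lung_side == 2)).sum())
        assert abs(r - l) / (r + l) < 0.05

    def test_region_labels_structurally_valid(self, full_phantom):
        labels = full_phantom.truth_labels
        assert np.all(labels.tlv_mask[labels.enhanced_mask])
        assert not (labels.per_mask & labels.cer_mask).any()


class TestConcentrationField:
    def test_zero_outside_enhanced_region(self, full_phantom):
        ds = full_phantom
        outside = ~ds.truth_labels.enhanced_mask
        assert np.all(ds.truth_concentration.data[outside] == 0.0)

    def test_total_amount_is_exact(self, full_phantom):
        ds = full_phantom
        vox_ml = np.prod(ds.spec.spacing) / 1000.0
        total = ds.truth_concentration.data.sum() * vox_ml
        assert total == pytest.approx(ds.spec.total_gd_umol, rel=1e-3)

    def test_truth_pdf_hits_target(self, full_phantom):
        ds = full_phantom
        assert ds.truth_report.pdf_pct == pytest.approx(
            ds.spec.peripheral_amount_fraction_pct, abs=0.5
        )

    def test_linearity_in_total_amount(self):
        spec = PhantomSpec(seed=2).with_resolution((72, 72, 56))
        geo = build_geometry(spec)
        c1 = assign_concentration(geo)
        c2 = assign_concentration(geo, dataclasses.replace(spec, total_gd_umol=200.0))
        np.testing.assert_allclose(c2.data, 2.0 * c1.data, rtol=1e-12)

    def test_zero_gradient_gives_uniform_per_concentration(self):
        spec = PhantomSpec(seed=2, dependent_gradient=0.0, right_fraction=0.5).with_resolution((72, 72, 56))
        geo = build_geometry(spec)
        conc = assign_concentration(geo)
        per_values = conc.data[geo.labels.per_mask]
        assert per_values.std() / per_values.mean() < 1e-12
        vox_ml = np.prod(spec.spacing) / 1000.0
        assert conc.data.sum() * vox_ml == pytest.approx(100.0, rel=1e-12)

    def test_right_fraction_controls_amount_split(self, full_phantom):
        ds = full_phantom
        vox_ml = np.prod(ds.spec.spacing) / 1000.0
        per = ds.truth_labels.per_mask
        right = float(ds.truth_concentration.data[per & (ds.geometry.lung_side == 1)].sum()) * vox_ml
        total = float(ds.truth_concentration.data[per].sum()) * vox_ml
        # asymmetry is placement-driven, so the amount share tracks the
        # right-lung volume share rather than hitting the dial exactly
        assert right / total == pytest.approx(ds.spec.right_fraction, abs=0.06)

    def test_grid_refinement_conserves_total(self):
        base = PhantomSpec(seed=4).with_resolution((72, 72, 56))
        fine = base.with_resolution((108, 108, 84))
        totals = []
        for spec in (base, fine):
            geo = build_geometry(spec)
            conc = assign_concentration(geo)
            totals.append(conc.data.sum() * np.prod(spec.spacing) / 1000.0)
        assert totals[0] == pytest.approx(totals[1], rel=5e-3)


class TestRendering:
    def test_no_contrast_post_equals_pre(self):
        spec = PhantomSpec(seed=5, total_gd_umol=0.0).with_resolution((72, 72, 56))
        geo = build_geometry(spec)
        conc = lq.Volume3D(np.zeros(spec.shape), spec.spacing)
        ds = render_mri(geo, conc)
        idx = list(ds.params.flip_angles_deg).index(ds.params.post_flip_angle_deg)
        np.testing.assert_array_equal(ds.post_volume.data, ds.pre_volumes[idx].data)

    def test_contrast_shortens_t1_by_relaxivity_relation(self, full_phantom):
        ds = full_phantom
        r1_expected = 1000.0 / ds.spec.t1_pre_ms + ds.params.r1 * ds.truth_concentration.data
        enhanced = ds.truth_labels.enhanced_mask
        np.testing.assert_allclose(
            1000.0 / ds.truth_t1_post.data[enhanced], r1_expected[enhanced], rtol=1e-12
        )

    def test_same_seed_bit_identical_different_noise_seed_same_truth(self):
        spec = PhantomSpec(seed=6).with_resolution((72, 72, 56))
        geo = build_geometry(spec)
        conc = assign_concentration(geo)
        a = render_mri(geo, conc, noise_sd=2.0, noise_seed=1)
        b = render_mri(geo, conc, noise_sd=2.0, noise_seed=1)
        c = render_mri(geo, conc, noise_sd=2.0, noise_seed=2)
        np.testing.assert_array_equal(a.post_volume.data, b.post_volume.data)
        assert not np.array_equal(a.post_volume.data, c.post_volume.data)
        np.testing.assert_array_equal(a.truth_concentration.data, c.truth_concentration.data)

    def test_enhancement_increases_with_flip_angle(self, full_phantom):
        """At TR << T1 the signal enhancement grows with flip angle, the
        ordering seen when imaging the contrast bolus at 5..25 degrees."""
        ds = full_phantom
        mean_c = ds.truth_report.mean_concentration_mm
        t1_post = 1000.0 / (1000.0 / ds.spec.t1_pre_ms + ds.params.r1 * mean_c)
        se = []
        for alpha in ds.params.flip_angles_deg:
            s_pre = lq.ute_signal(ds.spec.a_tissue, alpha, ds.params.tr_ms, ds.spec.t1_pre_ms)
            s_post = lq.ute_signal(ds.spec.a_tissue, alpha, ds.params.tr_ms, t1_post)
            se.append((s_post - s_pre) / s_pre)
        assert np.all(np.diff(se) > 0)

    def test_negative_noise_rejected(self):
        spec = PhantomSpec(seed=7).with_resolution((72, 72, 56))
        geo = build_geometry(spec)
        conc = assign_concentration(geo)
        with pytest.raises(ValueError, match="noise"):
            render_mri(geo, conc, noise_sd=-1.0)


class TestEndToEndTruth:
    def test_noiseless_pipeline_reproduces_truth_report(self, full_phantom):
        """Full chain on truth labels reproduces the truth metrics ~exactly."""
        ds = full_phantom
        analysis = lq.analyze_specimen(
            ds.pre_volumes, ds.post_volume, ds.truth_labels, ds.params,
            ds.default_calibration_roi(),
        )
        truth = ds.truth_report
        got = analysis.report
        assert got.gd_amount_umol == pytest.approx(truth.gd_amount_umol, rel=1e-3)
        assert got.pdf_pct == pytest.approx(truth.pdf_pct, abs=0.1)
        assert got.mean_t1_post_ms == pytest.approx(truth.mean_t1_post_ms, rel=1e-3)
        assert got.pvf_pct == truth.pvf_pct
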