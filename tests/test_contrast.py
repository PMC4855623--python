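"""Tests of the gray-white contrast measure, boundary sampling, the
analytic contrast-change prediction, and the thickness regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphosynth.contrast import (
    ContrastRatios,
    ContrastSample,
    compute_contrast,
    predict_contrast_change,
    regress_delta,
    sample_boundary,
)
from morphosynth.mprage import synthesize, synthesize_set
from morphosynth.phantom import (
    DEFAULT_TISSUES,
    LABELS,
    PhantomGeometry,
    build_phantom,
)
from morphosynth.protocols import DEFAULT_MPRAGE


class TestComputeContrast:
    def test_equal_intensities_give_zero(self):
        assert compute_contrast(ContrastSample(50.0, 50.0, 0)) == 0.0

    def test_hand_computed_value(self):
        c = compute_contrast(ContrastSample(100.0, 80.0, 0))
        assert c == pytest.approx(20.0 / 90.0)

    def test_antisymmetric_under_swap(self):
        a = compute_contrast(ContrastSample(100.0, 80.0, 0))
        b = compute_contrast(ContrastSample(80.0, 100.0, 0))
        assert a == pytest.approx(-b)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            ContrastSample(0.0, 10.0, 0)

    @given(wm=st.floats(0.01, 1e3), gm=st.floats(0.01, 1e3),
           k=st.floats(0.01, 1e3))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_invariant_under_global_scaling(self, wm, gm, k):
        a = compute_contrast(ContrastSample(wm, gm, 0))
        b = compute_contrast(ContrastSample(k * wm, k * gm, 0))
        assert b == pytest.approx(a, rel=1e-9, abs=1e-12)
        assert -2.0 < a < 2.0


class TestSampleBoundary:
    def test_homogeneous_tissues_give_identical_samples(self, geometry32, phantom32):
        maps, labels = phantom32
        img = synthesize(maps, DEFAULT_MPRAGE, {"R1"})
        samples, skipped = sample_boundary(img, labels, geometry32)
        assert skipped == 0
        assert len(samples) > 0
        wm_vals = {round(s.wm_intensity, 12) for s in samples}
        assert len(wm_vals) == 1
        contrasts = {round(compute_contrast(s), 10) for s in samples}
        assert len(contrasts) == 2  # cortical and sensorimotor columns

    def test_gm_sampled_at_35pct_depth(self):
        """10-voxel cortex: the GM sample sits at the 4th voxel above the
        border (round(0.35 * 10) = 4)."""
        geo = PhantomGeometry(shape=(64, 64, 64), gm_thickness=10, slab_border_z=38)
        maps, labels = build_phantom(geo)
        img = synthesize(maps, DEFAULT_MPRAGE, {"R1"})
        # tag the expected sampling plane with a recognisable intensity
        marked = img.intensity.copy()
        z_expected = geo.slab_border_z + 4 - 1
        marked[:, :, z_expected] *= 1.5
        marked_img = type(img)(intensity=marked, modality=img.modality,
                               protocol=img.protocol)
        samples, _ = sample_boundary(marked_img, labels, geo)
        base, _ = sample_boundary(img, labels, geo)
        for s_m, s_b in zip(samples, base):
            assert s_m.gm_intensity == pytest.approx(1.5 * s_b.gm_intensity)
            assert s_m.wm_intensity == s_b.wm_intensity

    def test_sites_without_gm_are_skipped_and_counted(self, geometry32, phantom32):
        maps, labels = phantom32
        broken = labels.copy()
        x0, y0 = next(iter(geometry32.slab_columns()))
        broken[x0, y0, geometry32.slab_border_z:] = LABELS["csf"]
        img = synthesize(maps, DEFAULT_MPRAGE, {"R1"})
        samples, skipped = sample_boundary(img, broken, geometry32)
        full, _ = sample_boundary(img, labels, geometry32)
        assert skipped == 1
        assert len(samples) == len(full) - 1


class TestPredictContrastChange:
    def test_no_pd_contrast_means_no_change(self):
        r = ContrastRatios(r_pd=1.0, r_t1w_r1=0.7)
        assert predict_contrast_change(r, "printed") == 0.0
        assert predict_contrast_change(r, "derived") == 0.0

    def test_frozen_example_values(self):
        """R_PD=1.2, R_T1=0.7: the two closed forms differ in magnitude."""
        r = ContrastRatios(r_pd=1.2, r_t1w_r1=0.7)
        assert predict_contrast_change(r, "printed") == pytest.approx(0.14973262, abs=1e-7)
        assert predict_contrast_change(r, "derived") == pytest.approx(0.17902813, abs=1e-7)

    @given(rpd=st.floats(0.5, 2.0), rt1=st.floats(0.3, 1.5))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_forms_agree_in_sign(self, rpd, rt1):
        r = ContrastRatios(r_pd=rpd, r_t1w_r1=rt1)
        a = predict_contrast_change(r, "printed")
        b = predict_contrast_change(r, "derived")
        assert np.sign(a) == np.sign(b) == np.sign(rpd - 1.0)

    def test_derived_form_equals_pipeline_difference(self, phantom32):
        """The derived closed form reproduces the brute-force contrast
        difference between synthesized images to 1e-12 at every site."""
        maps, labels = phantom32
        geo = PhantomGeometry.create((32, 32, 32))
        imgs = synthesize_set(maps, DEFAULT_MPRAGE)
        s_r1, _ = sample_boundary(imgs["r1"], labels, geo)
        s_r1pd, _ = sample_boundary(imgs["r1pd"], labels, geo)
        for a, b in zip(s_r1, s_r1pd):
            c_r1 = compute_contrast(a)
            c_r1pd = compute_contrast(b)
            rt1 = a.gm_intensity / a.wm_intensity
            rpd = (b.gm_intensity / b.wm_intensity) / rt1
            pred = predict_contrast_change(
                ContrastRatios(r_pd=rpd, r_t1w_r1=rt1), "derived"
            )
            assert abs(pred - (c_r1 - c_r1pd)) < 1e-12

    def test_pd_inclusion_reduces_contrast_when_rpd_above_one(self, phantom32):
        """sign(C({R1}) - C({R1,PD})) = sign(R_PD - 1) at every site."""
        maps, labels = phantom32
        geo = PhantomGeometry.create((32, 32, 32))
        imgs = synthesize_set(maps, DEFAULT_MPRAGE)
        s_r1, _ = sample_boundary(imgs["r1"], labels, geo)
        s_r1pd, _ = sample_boundary(imgs["r1pd"], labels, geo)
        wm_pd = DEFAULT_TISSUES["wm"].pd
        for a, b, (x, y) in zip(s_r1, s_r1pd, geo.slab_columns()):
            gm_name = "sensorimotor_gm" if geo.column_is_sensorimotor(x, y) else "cortical_gm"
            rpd = DEFAULT_TISSUES[gm_name].pd / wm_pd
            diff = compute_contrast(a) - compute_contrast(b)
            assert np.sign(diff) == np.sign(rpd - 1.0)


class TestRegressDelta:
    def test_perfect_fit(self):
        x = np.linspace(-1, 1, 50)
        res = regress_delta(2.0 * x, x)
        assert res.beta == pytest.approx(2.0)
        assert res.zero_residual_variance
        assert np.isinf(res.t_value)
        assert np.allclose(res.residuals, 0.0)

    def test_noisy_slope_within_3_se(self):
        """beta-hat lies within 3 analytic SEs of the true slope 2."""
        rng = np.random.default_rng(77)
        x = rng.uniform(-1, 1, 500)
        sigma = 0.3
        y = 2.0 * x + sigma * rng.standard_normal(500)
        res = regress_delta(y, x)
        se = sigma / np.sqrt(np.sum(x**2))
        assert abs(res.beta - 2.0) < 3 * se

    def test_orthogonal_inputs_give_zero_slope(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        res = regress_delta(y, x)
        assert res.beta == 0.0

    def test_matches_normal_equation(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(40)
        y = rng.standard_normal(40)
        res = regress_delta(y, x)
        assert res.beta == pytest.approx(np.dot(x, y) / np.dot(x, x), rel=1e-14)

    def test_all_zero_contrast_rejected(self):
        with pytest.raises(ValueError, match="slope undefined"):
            regress_delta(np.ones(5), np.zeros(5))
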