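import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from honeyspec.preprocess import (
    SNV,
    Baseline,
    CenteringModel,
    MeanCenter,
    PipelineError,
    SavGol,
    apply_centering,
    apply_pipeline,
    baseline_poly,
    fit_centering,
    fit_pipeline,
    msc,
    sg_derivative,
    snv,
)
from honeyspec.spectra_io import Platform, RegionSet, SpectralBlock


def block_of(x, axis=None):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if axis is None:
        axis = np.arange(x.shape[1], dtype=float) + 1.0
    return SpectralBlock(Platform.FTMIR, axis, x, [f"s{i}" for i in range(x.shape[0])])


class TestSNV:
    def test_three_point_example(self):
        out = snv(block_of([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.intensities[0], [-1.0, 0.0, 1.0])

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        b = block_of(rng.normal(size=(4, 30)))
        once = snv(b)
        np.testing.assert_allclose(snv(once).intensities, once.intensities, atol=1e-12)

    def test_constant_spectrum_errors_with_sample_name(self):
        with pytest.raises(ValueError, match="s1"):
            snv(block_of([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rows_standardised(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(5, 40)) * rng.uniform(0.5, 5) + rng.uniform(-3, 3)
        out = snv(block_of(x)).intensities
        assert np.all(np.abs(out.mean(axis=1)) < 1e-10)
        assert np.all(np.abs(out.std(axis=1, ddof=1) - 1) < 1e-10)


class TestMSC:
    def test_affine_distortion_inverted(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(size=50)
        out = msc(block_of(3.0 + 2.0 * ref), reference=ref)
        np.testing.assert_allclose(out.intensities[0], ref, atol=1e-10)

    def test_reference_spectrum_unchanged(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(size=50)
        out = msc(block_of(ref), reference=ref)
        np.testing.assert_allclose(out.intensities[0], ref, atol=1e-10)

    def test_orthogonal_spectrum_degenerate(self):
        # Gram-Schmidt: remove the centered-reference component so the fitted
        # gain is exactly zero
        rng = np.random.default_rng(3)
        ref = rng.normal(size=50)
        rc = ref - ref.mean()
        x = rng.normal(size=50)
        x = x - (x @ rc) / (rc @ rc) * rc
        b_oracle = ((x - x.mean()) @ rc) / (rc @ rc)
        assert abs(b_oracle) < 1e-12
        with pytest.raises(ValueError, match="degenerate scatter fit"):
            msc(block_of(x), reference=ref)

    def test_snv_and_msc_agree_on_scatter_perturbed_spectra(self):
        """The two scatter corrections are near-exchangeable on offset/gain data."""
        rng = np.random.default_rng(4)
        base = np.exp(-0.5 * ((np.arange(120) - 50) / 12.0) ** 2) + \
            0.6 * np.exp(-0.5 * ((np.arange(120) - 85) / 8.0) ** 2)
        rows = [rng.uniform(-0.5, 0.5) + rng.uniform(0.7, 1.3) * base + rng.normal(0, 0.01, 120)
                for _ in range(25)]
        block = block_of(np.array(rows))
        a, b = snv(block).intensities, msc(block).intensities
        for i in range(a.shape[0]):
            assert np.corrcoef(a[i], b[i])[0, 1] > 0.99


class TestSavitzkyGolay:
    def test_linear_spectrum_derivative_constant(self):
        axis = np.arange(20.0)
        out = sg_derivative(block_of(2.0 * axis + 5.0, axis=axis), 1, 2, 9)
        np.testing.assert_allclose(out.intensities[0], 2.0, atol=1e-10)

    def test_quadratic_center_derivative(self):
        axis = np.arange(9.0)
        out = sg_derivative(block_of(axis**2, axis=axis), 1, 2, 9)
        assert out.intensities[0, 4] == pytest.approx(8.0, abs=1e-10)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            sg_derivative(block_of(np.zeros(20)), 1, 2, 8)

    def test_window_longer_than_axis_rejected(self):
        with pytest.raises(ValueError):
            sg_derivative(block_of(np.zeros(5)), 1, 2, 9)

    @pytest.mark.parametrize("degree", [0, 1, 2])
    def test_smoothing_reproduces_low_degree_polynomials(self, degree):
        axis = np.linspace(0, 10, 40)
        x = axis**degree
        out = sg_derivative(block_of(x, axis=axis), 0, 2, 9)
        np.testing.assert_allclose(out.intensities[0], x, atol=1e-8)

    def test_gap_in_axis_filtered_per_segment(self):
        # a region-selected axis: two uniform runs separated by a gap
        axis = np.concatenate([np.arange(0.0, 100.0, 4.0), np.arange(300.0, 400.0, 4.0)])
        x = 3.0 * axis
        out = sg_derivative(block_of(x, axis=axis), 1, 2, 9)
        np.testing.assert_allclose(out.intensities[0], 3.0, atol=1e-9)


class TestBaseline:
    anchors = RegionSet([(0, 8), (20, 28), (45, 55), (70, 78), (92, 100)])

    def test_pure_cubic_removed(self):
        axis = np.linspace(0, 100, 200)
        x = 0.5 + 0.01 * axis - 2e-4 * axis**2 + 3e-6 * axis**3
        out = baseline_poly(block_of(x, axis=axis), self.anchors, order=3)
        assert np.max(np.abs(out.intensities)) < 1e-8 * np.max(np.abs(x))

    def test_peak_outside_anchors_recovered(self):
        axis = np.linspace(0, 100, 400)
        cubic = 1.0 - 0.02 * axis + 1e-4 * axis**2 + 2e-6 * axis**3
        peak = 2.0 * np.exp(-0.5 * ((axis - 35.0) / 2.5) ** 2)
        out = baseline_poly(block_of(cubic + peak, axis=axis), self.anchors, order=3)
        # oracle: the same least-squares polynomial fitted directly on the anchors
        mask = self.anchors.mask(axis)
        coef = np.polynomial.Polynomial.fit(axis[mask], (cubic + peak)[mask], 3)
        residual_oracle = cubic + peak - coef(axis)
        np.testing.assert_allclose(out.intensities[0], residual_oracle, atol=1e-8)
        assert np.max(np.abs(out.intensities[0] - peak)) < 0.01 * peak.max()

    def test_underdetermined_anchor_set_rejected(self):
        axis = np.linspace(0, 100, 101)
        narrow = RegionSet([(0, 0.5), (50, 50.5), (100, 100.4)])  # 3 channels
        with pytest.raises(ValueError):
            baseline_poly(block_of(np.zeros(101), axis=axis), narrow, order=3)


class TestCentering:
    def test_autoscale_two_point_column(self):
        b = block_of([[1.0, 2.0], [3.0, 2.0]])
        with pytest.raises(ValueError, match="zero-variance"):
            fit_centering(b, autoscale=True)
        model = fit_centering(b, autoscale=True, drop_constant=True)
        out = apply_centering(b, model)
        np.testing.assert_allclose(out.intensities[:, 0], [-0.7071067811865475, 0.7071067811865475])
        assert out.n_channels == 1  # constant column dropped

    def test_mean_center_idempotent(self):
        rng = np.random.default_rng(5)
        b = block_of(rng.normal(size=(6, 12)))
        once = apply_centering(b, fit_centering(b))
        twice = apply_centering(once, fit_centering(once))
        np.testing.assert_allclose(once.intensities, twice.intensities, atol=1e-12)

    def test_test_row_at_training_mean_maps_to_zero(self):
        rng = np.random.default_rng(6)
        train = block_of(rng.normal(size=(8, 10)))
        model = fit_centering(train)
        probe = block_of(model.mean[None, :])
        np.testing.assert_allclose(apply_centering(probe, model).intensities, 0.0, atol=1e-12)


class TestPipelines:
    def test_single_step_equals_direct_call(self):
        rng = np.random.default_rng(7)
        b = block_of(rng.normal(size=(4, 30)))
        np.testing.assert_array_equal(apply_pipeline(b, [SNV()]).intensities,
                                      snv(b).intensities)

    def test_deterministic_bit_identical(self):
        rng = np.random.default_rng(8)
        b = block_of(rng.normal(size=(6, 40)))
        steps = (SNV(), SavGol(1, 2, 9), MeanCenter())
        a1, _ = fit_pipeline(b, steps)
        a2, _ = fit_pipeline(b, steps)
        assert np.array_equal(a1.intensities, a2.intensities)

    def test_no_test_set_statistics(self):
        """Permuting test rows permutes outputs identically: the fitted pipeline
        carries only training statistics."""
        rng = np.random.default_rng(9)
        train = block_of(rng.normal(size=(10, 40)))
        test = block_of(rng.normal(size=(6, 40)))
        steps = (SNV(), SavGol(1, 2, 9), MeanCenter())
        _, fitted = fit_pipeline(train, steps)
        perm = [3, 1, 5, 0, 4, 2]
        out = fitted.apply(test).intensities
        out_perm = fitted.apply(test.take(perm)).intensities
        # equality up to float round-off: the batched edge fit in the smoother
        # may re-block the linear algebra when row order changes
        np.testing.assert_allclose(out[perm], out_perm, rtol=0, atol=1e-12)

    def test_step_errors_carry_step_index(self):
        b = block_of([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]])
        with pytest.raises(PipelineError, match=r"step 0 \(SNV\)"):
            fit_pipeline(b, (SNV(), MeanCenter()))
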