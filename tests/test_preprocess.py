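import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lvforce.core import AcquisitionMeta, VelocityField
from lvforce.preprocess import (
    apply_background,
    fit_background,
    preprocess,
    static_tissue_weights,
    unwrap_velocity,
    wrap_velocity,
)
from oracles import unwrap_series_bruteforce


def _field_from_series(series, venc=1.0):
    """Embed a single-voxel time series into a minimal field."""
    n = len(series)
    values = np.zeros((n, 3, 1, 1, 1))
    values[:, 0, 0, 0, 0] = series
    meta = AcquisitionMeta(venc=venc, voxel_size=(3.0, 3.0, 3.0), n_frames=n, rr_interval=n * 25.0)
    return VelocityField(values, meta)


class TestUnwrap:
    def test_single_alias_restored(self):
        # true 1.3 m/s at venc 1.0 stores as 1.3 - 2*1.0 = -0.7
        series = np.array([0.1, 0.8, 1.0, -0.7, 1.0, 0.8, 0.1, 0.0])
        out = unwrap_velocity(_field_from_series(series))
        assert out.values[3, 0, 0, 0, 0] == pytest.approx(1.3)
        np.testing.assert_allclose(out.values[[0, 1, 2, 4, 5, 6, 7], 0, 0, 0, 0],
                                   series[[0, 1, 2, 4, 5, 6, 7]])

    def test_identity_for_smooth_low_speeds(self, small_field):
        out = unwrap_velocity(small_field)
        np.testing.assert_array_equal(out.values, small_field.values)

    def test_wrap_then_unwrap_is_identity(self):
        t = np.linspace(0, 2 * np.pi, 10, endpoint=False)
        series = 1.4 * np.sin(t)  # exceeds venc, smooth jumps < venc
        field = _field_from_series(series)
        restored = unwrap_velocity(wrap_velocity(field))
        np.testing.assert_allclose(restored.values, field.values, atol=1e-9)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_exhaustive_oracle(self, seed):
        # cyclic-smooth truth (harmonics): frame-to-frame jumps < venc, the
        # regime the temporal unwrap is specified for
        rng = np.random.default_rng(seed)
        n, venc = 6, 1.0
        t = 2 * np.pi * np.arange(n) / n
        true = rng.uniform(-2, 2) * np.sin(t + rng.uniform(0, 2 * np.pi))
        true += rng.uniform(-0.5, 0.5) * np.sin(2 * t + rng.uniform(0, 2 * np.pi))
        jumps = np.abs(np.diff(np.concatenate([true, true[:1]])))
        if jumps.max() >= 0.9 * venc:
            true *= 0.85 * venc / jumps.max()
        stored = np.mod(true + venc, 2 * venc) - venc
        ours = unwrap_velocity(_field_from_series(stored)).values[:, 0, 0, 0, 0]
        oracle = unwrap_series_bruteforce(stored, venc)
        np.testing.assert_allclose(ours, oracle, atol=1e-9)


class TestStaticWeights:
    def test_constant_velocity_weight_one(self):
        field = _field_from_series(np.full(8, 0.3))
        assert static_tissue_weights(field)[0, 0, 0] == pytest.approx(1.0)

    def test_sd_equal_scale_gives_exp_minus_one(self):
        # speed alternating 0/2s -> SD = s = scale
        scale = 0.05
        series = np.array([0.0, 2 * scale] * 4)
        w = static_tissue_weights(_field_from_series(series), sd_scale=scale)
        assert w[0, 0, 0] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_moving_blood_low_static_high(self):
        rng = np.random.default_rng(0)
        values = np.zeros((10, 3, 8, 8, 8))
        values[:, 0, :4] = 0.5 * np.sin(
            2 * np.pi * np.arange(10) / 10
        )[:, None, None, None]  # moving half
        values += 0.002 * rng.standard_normal(values.shape)
        meta = AcquisitionMeta(venc=1.0, voxel_size=(3.0,) * 3, n_frames=10, rr_interval=1000.0)
        w = static_tissue_weights(VelocityField(values, meta))
        assert w[:4].mean() < 0.1
        assert w[4:].mean() > 0.9


def _poly_offset_field(shape, vox, coeffs3):
    """Evaluate a degree-<=4 polynomial offset the same way the fitter does."""
    from lvforce.preprocess import _design_matrix

    half = np.array([(shape[ax] - 1) * vox[ax] / 2.0 for ax in range(3)])
    A, terms = _design_matrix(shape, vox, 4, half)
    return (A @ coeffs3.T).T.reshape((3,) + shape), terms


class TestBackground:
    shape = (12, 12, 12)
    vox = (3.0, 3.0, 3.0)

    def _static_field(self, offsets, n_frames=6, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        values = np.broadcast_to(offsets[None, :, :, :, :], (n_frames, 3) + self.shape).copy()
        if noise:
            values += rng.normal(0, noise, values.shape)
        meta = AcquisitionMeta(venc=1.0, voxel_size=self.vox, n_frames=n_frames, rr_interval=600.0)
        return VelocityField(values, meta)

    def test_exact_degree4_offset_recovered(self):
        rng = np.random.default_rng(1)
        coeffs = rng.normal(0, 0.01, (3, 35))
        offsets, _ = _poly_offset_field(self.shape, self.vox, coeffs)
        field = self._static_field(offsets)
        model = fit_background(field, np.ones(self.shape))
        corrected = apply_background(field, model)
        assert np.abs(corrected.values).max() < 1e-9
        np.testing.assert_allclose(model.coefficients, coeffs, atol=1e-9)

    def test_zero_offset_gives_zero_coefficients(self):
        field = self._static_field(np.zeros((3,) + self.shape))
        model = fit_background(field, np.ones(self.shape))
        assert np.abs(model.coefficients).max() < 1e-12

    def test_noisy_recovery_rmse_below_noise(self):
        rng = np.random.default_rng(2)
        coeffs = rng.normal(0, 0.01, (3, 35))
        offsets, _ = _poly_offset_field((20, 20, 20), self.vox, coeffs)
        meta = AcquisitionMeta(venc=1.0, voxel_size=self.vox, n_frames=6, rr_interval=600.0)
        values = np.broadcast_to(offsets[None], (6, 3, 20, 20, 20)).copy()
        values += rng.normal(0, 0.01, values.shape)
        field = VelocityField(values, meta)
        model = fit_background(field, np.ones((20, 20, 20)))
        rmse = np.sqrt(np.mean((model.evaluate() - offsets) ** 2))
        assert rmse < 0.01  # below the injected noise SD

    def test_correction_is_linear(self):
        rng = np.random.default_rng(3)
        ca, cb = rng.normal(0, 0.01, (2, 3, 35))
        field = self._static_field(np.zeros((3,) + self.shape))
        w = np.ones(self.shape)
        ma = fit_background(self._static_field(_poly_offset_field(self.shape, self.vox, ca)[0]), w)
        mb = fit_background(self._static_field(_poly_offset_field(self.shape, self.vox, cb)[0]), w)
        one_then_other = apply_background(apply_background(field, ma), mb)
        import dataclasses

        mab = dataclasses.replace(ma, coefficients=ma.coefficients + mb.coefficients)
        both = apply_background(field, mab)
        np.testing.assert_allclose(one_then_other.values, both.values, atol=1e-12)

    def test_refit_of_corrected_field_is_null(self):
        rng = np.random.default_rng(4)
        coeffs = rng.normal(0, 0.01, (3, 35))
        field = self._static_field(_poly_offset_field(self.shape, self.vox, coeffs)[0])
        w = np.ones(self.shape)
        corrected = apply_background(field, fit_background(field, w))
        refit = fit_background(corrected, w)
        assert np.abs(refit.evaluate()).max() < 1e-9

    def test_rank_deficient_support_raises(self):
        from lvforce.core import DomainError

        field = self._static_field(np.zeros((3,) + self.shape))
        w = np.zeros(self.shape)
        w[0, 0, :] = 1.0  # 12 voxels on a line << 35 terms
        with pytest.raises(DomainError):
            fit_background(field, w)


def test_preprocess_identity_on_clean_field():
    """Neither wraps nor offsets: the full correction chain is the identity."""
    rng = np.random.default_rng(5)
    values = np.zeros((8, 3, 10, 10, 10))
    values[:, 0, 4:6, 4:6, 4:6] = 0.4 * np.sin(
        2 * np.pi * np.arange(8) / 8
    )[:, None, None, None]
    meta = AcquisitionMeta(venc=1.0, voxel_size=(3.0,) * 3, n_frames=8, rr_interval=800.0)
    field = VelocityField(values, meta)
    out = preprocess(field)
    np.testing.assert_allclose(out.values, field.values, atol=1e-12)
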