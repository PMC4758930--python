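import numpy as np
import pytest

from lvforce.core import AcquisitionMeta, DomainError, MaskSeries, VelocityField
from lvforce.hemodynamics import (
    ForceTrace,
    PressureGradientField,
    compute_force,
    integrate_force,
    pressure_gradient,
)
from lvforce.phantom import analytic_field, momentum_oracle_force
from oracles import surface_integral_pressure

RHO = 1060.0


def _grad_field(values, transient, convective, viscous, valid):
    return PressureGradientField(
        values, transient, convective, viscous, valid,
        term_valid={"transient": valid, "convective": valid, "viscous": valid},
    )


class TestUniformOscillation:
    def test_matches_discrete_closed_form(self):
        ph = analytic_field("uniform_oscillation", grid=32, n_frames=20, voxel_mm=2.0)
        tr = compute_force(ph.field, ph.mask)
        # uniform velocity: only the transient term, whose cyclic central
        # difference of a sinusoid is the closed form times sin(w dt)/(w dt),
        # integrated over the voxelized ball
        expect = (
            ph.analytic_force.F[:, 0]
            * ph.info["discrete_time_factor"]
            * ph.info["volume_discrete_m3"]
            / ph.info["volume_m3"]
        )
        np.testing.assert_allclose(tr.F[:, 0], expect, rtol=1e-9)
        assert np.abs(tr.F[:, 1:]).max() < 1e-12

    def test_peak_value_scale(self):
        # peak |F| ~ rho * A * (2 pi / T) * V = 1060*0.5*2pi*1e-4 ~ 0.333 N
        ph = analytic_field("uniform_oscillation", grid=32, n_frames=40, voxel_mm=2.0)
        tr = compute_force(ph.field, ph.mask)
        assert np.abs(tr.F[:, 0]).max() == pytest.approx(0.333, abs=0.01)

    def test_temporal_refinement_is_second_order(self):
        errs = []
        for nf in (10, 20, 40):
            ph = analytic_field("uniform_oscillation", grid=16, n_frames=nf, voxel_mm=4.0)
            tr = compute_force(ph.field, ph.mask)
            exact = ph.analytic_force.F[:, 0] * ph.info["volume_discrete_m3"] / ph.info["volume_m3"]
            i = np.argmax(np.abs(exact))
            errs.append(abs(tr.F[i, 0] - exact[i]) / abs(exact[i]))
        ratios = np.array(errs[:-1]) / np.array(errs[1:])
        assert np.all(ratios > 3.0) and np.all(ratios < 5.0)


def test_static_fluid_gives_exact_zero():
    ph = analytic_field("rigid_static", grid=16, n_frames=6, voxel_mm=4.0)
    grads = pressure_gradient(ph.field, ph.mask)
    assert np.abs(grads.values).max() == 0.0
    tr = integrate_force(grads, ph.mask, ph.field.meta)
    assert np.abs(tr.F).max() == 0.0


def test_poiseuille_viscous_gradient_exact():
    ph = analytic_field("poiseuille", grid=32, voxel_mm=1.0)
    grads = pressure_gradient(ph.field, ph.mask)
    inside = ph.mask.occupancy[0] & grads.valid[0]
    gz = grads.values[0, 2][inside]
    # grad p_z = -4 mu vmax / R^2 = -160 Pa/m, exact for a quadratic profile
    np.testing.assert_allclose(gz, -160.0, rtol=1e-9)
    assert np.abs(grads.transient).max() == 0.0
    assert np.abs(grads.convective).max() < 1e-9
    tr = integrate_force(grads, ph.mask, ph.field.meta)
    np.testing.assert_allclose(tr.F[:, 2], -160.0 * tr.lv_volume, rtol=1e-9)


class TestIntegration:
    def test_uniform_gradient_times_volume(self, small_meta):
        # 100 mL at grad p = (-3330.1, 0, 0) Pa/m -> F_x ~ -0.333 N
        shape = (10, 10, 10)
        n = small_meta.n_frames
        occ = np.ones((n,) + shape, dtype=bool)
        mask = MaskSeries(occ, small_meta.voxel_size)
        voxvol = small_meta.voxel_volume_m3
        scale = 1.0e-4 / (occ[0].sum() * voxvol)  # pretend-normalize to 100 mL
        values = np.zeros((n, 3) + shape)
        values[:, 0] = -3330.1
        zeros = np.zeros_like(values)
        grads = _grad_field(values, values, zeros, zeros, np.ones((n,) + shape, bool))
        tr = integrate_force(grads, mask, small_meta)
        assert tr.F[0, 0] * scale == pytest.approx(-0.333, abs=0.001)

    def test_zero_gradient_zero_force(self, small_meta, ball_mask):
        shape = ball_mask.spatial_shape
        n = small_meta.n_frames
        z = np.zeros((n, 3) + shape)
        grads = _grad_field(z, z, z.copy(), z.copy(), np.ones((n,) + shape, bool))
        tr = integrate_force(grads, ball_mask, small_meta)
        assert np.abs(tr.F).max() == 0.0

    def test_no_valid_voxels_raises(self, small_meta, ball_mask):
        shape = ball_mask.spatial_shape
        n = small_meta.n_frames
        z = np.zeros((n, 3) + shape)
        grads = _grad_field(z, z, z.copy(), z.copy(), np.zeros((n,) + shape, bool))
        with pytest.raises(DomainError):
            integrate_force(grads, ball_mask, small_meta)

    def test_term_additivity(self, small_field, ball_mask):
        grads = pressure_gradient(small_field, ball_mask)
        np.testing.assert_allclose(
            grads.values, grads.transient + grads.convective + grads.viscous, atol=1e-12
        )
        tr = integrate_force(grads, ball_mask, small_field.meta)
        np.testing.assert_allclose(
            tr.F, tr.terms["transient"] + tr.terms["convective"] + tr.terms["viscous"],
            atol=1e-15,
        )


def test_single_frame_raises(small_meta):
    meta = AcquisitionMeta(venc=1.0, voxel_size=(3.0,) * 3, n_frames=1, rr_interval=800.0)
    field = VelocityField(np.zeros((1, 3, 4, 4, 4)), meta)
    mask = MaskSeries(np.ones((1, 4, 4, 4), bool), meta.voxel_size)
    with pytest.raises(DomainError):
        pressure_gradient(field, mask)


def test_divergence_theorem_small_grid():
    """Volume integral of grad(alpha x) over a voxelized ball vs a brute-force
    surface integral of p n_hat over a triangulated sphere."""
    alpha, radius_mm, grid, vox = 10.0, 12.0, 32, 1.0
    ax = (np.arange(grid) - (grid - 1) / 2.0) * vox
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    ball = X**2 + Y**2 + Z**2 <= radius_mm**2
    volume_integral = alpha * ball.sum() * vox**3  # mm^3 * alpha, x-component
    surface = surface_integral_pressure(alpha, radius_mm, grid, vox)
    assert surface[0] == pytest.approx(volume_integral, rel=0.02)
    assert abs(surface[1]) < 0.02 * abs(volume_integral)
    assert abs(surface[2]) < 0.02 * abs(volume_integral)


def test_momentum_consistency_noflux_phantom():
    """For a no-flux apodized pulse, F ~ -rho d/dt(momentum) within
    discretization tolerance."""
    n, g = 16, 20
    meta = AcquisitionMeta(venc=5.0, voxel_size=(3.0,) * 3, n_frames=n,
                           rr_interval=1000.0, mu=0.0)
    ax = np.arange(g) * 3.0
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    c = (g - 1) * 3.0 / 2
    q = np.sqrt((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2) / 24.0
    w = np.where(q < 1, np.cos(0.5 * np.pi * np.minimum(q, 1.0) ** 3) ** 2, 0.0)
    amp = 0.3 * np.sin(2 * np.pi * np.arange(n) / n)
    values = np.zeros((n, 3, g, g, g))
    values[:, 0] = amp[:, None, None, None] * w
    field = VelocityField(values, meta)
    mask = MaskSeries(np.broadcast_to(q < 1, (n, g, g, g)).copy(), meta.voxel_size)
    tr = compute_force(field, mask, include_viscous=False)
    F_mom = momentum_oracle_force(field, mask)
    peak = np.abs(F_mom[:, 0]).max()
    assert np.abs(tr.F[:, 0] - F_mom[:, 0]).max() < 0.05 * peak


def test_force_trace_invariants(small_field, ball_mask):
    tr = compute_force(small_field, ball_mask)
    assert np.all(np.isfinite(tr.F))
    assert np.all(tr.lv_volume > 0)
    assert isinstance(tr, ForceTrace)
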