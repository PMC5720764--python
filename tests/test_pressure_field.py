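import numpy as np
import pytest

from pivload.body_geometry import BodyMask
from pivload.exceptions import EmptyFieldError, InvalidInputError
from pivload.grids import FluidProperties, GridSpec, PressureGradientFrame, VelocitySequence
from pivload.pressure_field import (
    integrate_pressure,
    path_estimates,
    pressure_gradient,
    pressure_sequence,
    ring_pressure,
)
from pivload.synthetic_flows import (
    make_solid_body_rotation,
    make_taylor_green,
    make_uniform_flow,
)

from .conftest import tg_grid


def circle_mask(center, R, n=64):
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return BodyMask(np.column_stack([center[0] + R * np.cos(th), center[1] + R * np.sin(th)]))


def normalized_rms_error(p_est, p_exact, defined=None):
    """Gauge-align (mean) then normalize RMS difference by exact peak-to-peak."""
    if defined is None:
        defined = np.isfinite(p_est)
    a = p_est[defined] - np.nanmean(p_est[defined])
    b = p_exact[defined] - np.mean(p_exact[defined])
    return np.sqrt(np.mean((a - b) ** 2)) / np.ptp(b)


class TestPressureGradient:
    def test_uniform_flow_zero_gradient(self, grid32, water):
        vel, _ = make_uniform_flow(grid32, (0.3, 0.0), water)
        grad = pressure_gradient(vel, vel, vel, water, 0.01)
        assert np.allclose(grad.dpdx, 0.0) and np.allclose(grad.dpdy, 0.0)
        assert grad.valid.all()

    def test_solid_body_closed_form(self, inviscid):
        # rho omega^2 (x, y): at (0.1, 0) expect (400, 0) Pa/m
        grid = GridSpec.centered(0.5, 21)  # dx = 0.05: (0.1, 0) is a node
        vel, _ = make_solid_body_rotation(grid, 2.0, inviscid)
        grad = pressure_gradient(vel, vel, vel, inviscid, 0.01)
        X, Y = grid.meshgrid()
        i, j = 10, 12
        assert np.isclose(X[i, j], 0.1) and Y[i, j] == 0.0
        assert np.isclose(grad.dpdx[i, j], 400.0, rtol=1e-9)
        assert np.isclose(grad.dpdy[i, j], 0.0, atol=1e-9)
        exact_x = 1000.0 * 4.0 * X
        exact_y = 1000.0 * 4.0 * Y
        interior = np.zeros(X.shape, dtype=bool)
        interior[1:-1, 1:-1] = True
        assert np.allclose(grad.dpdx[interior], exact_x[interior], rtol=1e-9)
        assert np.allclose(grad.dpdy[interior], exact_y[interior], rtol=1e-9)

    def test_taylor_green_gradient_accuracy(self):
        fluid = FluidProperties(rho=1000.0, nu=1e-3)
        g = tg_grid(128)
        dt = 0.01
        prev, _ = make_taylor_green(g, 0.0, fluid)
        cur, _ = make_taylor_green(g, dt, fluid)
        nxt, _ = make_taylor_green(g, 2 * dt, fluid)
        grad = pressure_gradient(prev, cur, nxt, fluid, dt)
        X, Y = g.meshgrid()
        decay = np.exp(-4.0 * fluid.nu * dt)
        exact_x = (fluid.rho / 2.0) * np.sin(2 * X) * decay
        exact_y = (fluid.rho / 2.0) * np.sin(2 * Y) * decay
        err = np.sqrt(
            np.mean((grad.dpdx - exact_x) ** 2 + (grad.dpdy - exact_y) ** 2)
        ) / np.sqrt(np.mean(exact_x**2 + exact_y**2))
        assert err < 0.02

    def test_requires_a_temporal_neighbor(self, grid32, water):
        vel, _ = make_uniform_flow(grid32, (0.3, 0.0), water)
        with pytest.raises(InvalidInputError):
            pressure_gradient(None, vel, None, water, 0.01)

    def test_rejects_bad_dt_and_grid_mismatch(self, grid32, grid64, water):
        vel32, _ = make_uniform_flow(grid32, (0.3, 0.0), water)
        vel64, _ = make_uniform_flow(grid64, (0.3, 0.0), water)
        with pytest.raises(InvalidInputError):
            pressure_gradient(vel32, vel32, vel32, water, 0.0)
        with pytest.raises(InvalidInputError):
            pressure_gradient(vel64, vel32, None, water, 0.01)

    def test_one_sided_next_to_invalid_nodes(self, grid32, inviscid):
        # invalidate one node; its neighbors stay valid via one-sided stencils
        vel, _ = make_solid_body_rotation(grid32, 2.0, inviscid)
        vel.valid[16, 16] = False
        grad = pressure_gradient(vel, vel, vel, inviscid, 0.01)
        assert not grad.valid[16, 16]
        assert grad.valid[16, 15] and grad.valid[16, 17]
        assert grad.valid[15, 16] and grad.valid[17, 16]


class TestIntegratePressure:
    def test_zero_gradient_zero_pressure(self, grid32):
        grad = PressureGradientFrame(
            grid=grid32,
            dpdx=np.zeros(grid32.shape),
            dpdy=np.zeros(grid32.shape),
            valid=np.ones(grid32.shape, dtype=bool),
        )
        p = integrate_pressure(grad)
        assert p.defined.all()
        assert np.allclose(p.p, 0.0, atol=1e-14)

    def test_zero_gradient_with_mask(self, grid32):
        grad = PressureGradientFrame(
            grid=grid32,
            dpdx=np.zeros(grid32.shape),
            dpdy=np.zeros(grid32.shape),
            valid=np.ones(grid32.shape, dtype=bool),
        )
        mask = circle_mask((0.0, 0.0), 0.15)
        p = integrate_pressure(grad, mask=mask)
        inside = mask.nodes_inside(grid32)
        assert not p.defined[inside].any()
        assert np.allclose(p.p[~inside], 0.0, atol=1e-14)

    def test_solid_body_oracle_64(self, grid64, inviscid):
        vel, exact = make_solid_body_rotation(grid64, 2.0, inviscid)
        grad = pressure_gradient(vel, vel, vel, inviscid, 0.01)
        p = integrate_pressure(grad)
        assert normalized_rms_error(p.p, exact.p) < 0.02

    def test_all_masked_raises(self, grid32):
        grad = PressureGradientFrame(
            grid=grid32,
            dpdx=np.zeros(grid32.shape),
            dpdy=np.zeros(grid32.shape),
            valid=np.zeros(grid32.shape, dtype=bool),
        )
        with pytest.raises(EmptyFieldError):
            integrate_pressure(grad)

    def test_direction_count_validation(self, grid32):
        grad = PressureGradientFrame(
            grid=grid32,
            dpdx=np.zeros(grid32.shape),
            dpdy=np.zeros(grid32.shape),
            valid=np.ones(grid32.shape, dtype=bool),
        )
        with pytest.raises(InvalidInputError):
            integrate_pressure(grad, n_directions=5)
        integrate_pressure(grad, n_directions=4)  # allowed

    def test_gauge_invariance(self, grid64, inviscid):
        # shifting all ray seeds by a constant shifts the polled field by
        # that constant; after ring-median gauge fixing the result is equal
        vel, _ = make_solid_body_rotation(grid64, 2.0, inviscid)
        grad = pressure_gradient(vel, vel, vel, inviscid, 0.01)
        valid = grad.valid
        seeds = ring_pressure(grad, valid)
        c = 123.456
        est0 = np.nanmedian(np.stack(path_estimates(grad, valid, seeds)), axis=0)
        est1 = np.nanmedian(np.stack(path_estimates(grad, valid, seeds + c)), axis=0)
        assert np.allclose(est1, est0 + c, atol=1e-9)
        g0 = est0 - np.median(np.concatenate([est0[0], est0[-1], est0[:, 0], est0[:, -1]]))
        g1 = est1 - np.median(np.concatenate([est1[0], est1[-1], est1[:, 0], est1[:, -1]]))
        assert np.allclose(g0, g1, atol=1e-9)

    def test_median_robust_to_one_corrupt_family(self, grid64, inviscid):
        vel, exact = make_solid_body_rotation(grid64, 2.0, inviscid)
        grad = pressure_gradient(vel, vel, vel, inviscid, 0.01)
        seeds = ring_pressure(grad, grad.valid)
        fams = path_estimates(grad, grad.valid, seeds)
        rng = np.random.default_rng(7)
        fams[3] = fams[3] + rng.normal(0.0, 50.0 * np.ptp(exact.p), fams[3].shape)
        p = np.nanmedian(np.stack(fams), axis=0)
        assert normalized_rms_error(p, exact.p) < 0.05

    def test_mask_opacity(self, grid32):
        # plant a huge gradient discontinuity inside the mask: the outside
        # field must be unaffected because no path crosses masked nodes
        shape = grid32.shape
        gx = np.zeros(shape)
        gy = np.zeros(shape)
        mask = circle_mask((0.0, 0.0), 0.2)
        inside = mask.nodes_inside(grid32)
        gx[inside] = 1e6
        gy[inside] = -1e6
        grad = PressureGradientFrame(
            grid=grid32, dpdx=gx, dpdy=gy, valid=np.ones(shape, dtype=bool)
        )
        p = integrate_pressure(grad, mask=mask)
        assert np.allclose(p.p[~inside], 0.0, atol=1e-12)

    def test_convergence_on_taylor_green(self):
        # truncation error must drop monotonically under grid refinement
        fluid = FluidProperties(rho=1000.0, nu=1e-3)
        errs = []
        for n in (32, 64, 128):
            g = tg_grid(n)
            vel, exact = make_taylor_green(g, 0.0, fluid)
            velp, _ = make_taylor_green(g, 0.0, fluid)
            grad = pressure_gradient(velp, vel, velp, fluid, 0.01)
            p = integrate_pressure(grad)
            errs.append(normalized_rms_error(p.p, exact.p))
        assert errs[0] > errs[1] > errs[2]

    def test_solid_body_near_exact_at_all_resolutions(self, inviscid):
        # stronger than monotone: linear velocity + linear gradient means the
        # whole discrete chain is exact to roundoff at every resolution
        for n in (16, 32, 64):
            g = GridSpec.centered(0.5, n)
            vel, exact = make_solid_body_rotation(g, 2.0, inviscid)
            grad = pressure_gradient(vel, vel, vel, inviscid, 0.01)
            p = integrate_pressure(grad)
            assert normalized_rms_error(p.p, exact.p) < 1e-10


class TestPressureSequence:
    def test_uniform_sequence_zero(self, grid32, water):
        frames = [make_uniform_flow(grid32, (0.3, 0.0), water, t=0.01 * k)[0] for k in range(5)]
        seq = VelocitySequence(frames=frames, dt=0.01)
        out = pressure_sequence(seq, masks=None, fluid=water, dt_calc=0.01)
        assert len(out) == 5
        for pf in out:
            assert np.allclose(pf.p, 0.0, atol=1e-12)

    def test_subsampling_arithmetic(self, grid32, water):
        frames = [make_uniform_flow(grid32, (0.1, 0.0), water, t=0.002 * k)[0] for k in range(100)]
        seq = VelocitySequence(frames=frames, dt=0.002)
        out = pressure_sequence(seq, masks=None, fluid=water, dt_calc=0.01)
        assert len(out) == 20
        assert np.allclose(np.diff([pf.t for pf in out]), 0.01)

    def test_non_multiple_dt_calc_rejected(self, grid32, water):
        frames = [make_uniform_flow(grid32, (0.1, 0.0), water, t=0.003 * k)[0] for k in range(4)]
        seq = VelocitySequence(frames=frames, dt=0.003)
        with pytest.raises(InvalidInputError, match="0.01"):
            pressure_sequence(seq, masks=None, fluid=water, dt_calc=0.01)

    def test_taylor_green_sequence_accuracy(self):
        fluid = FluidProperties(rho=1000.0, nu=1e-3)
        g = tg_grid(128)
        dt = 0.002
        frames = [make_taylor_green(g, k * dt, fluid)[0] for k in range(26)]
        seq = VelocitySequence(frames=frames, dt=dt)
        out = pressure_sequence(seq, masks=None, fluid=fluid, dt_calc=0.01)
        assert len(out) == 6
        for pf in out:
            _, exact = make_taylor_green(g, pf.t, fluid)
            assert normalized_rms_error(pf.p, exact.p) < 0.05
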