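"""Analytic flows, flapping-plate kinematics and end-to-end test scenes.

Everything downstream (pressure solver, geometry, load integration) is
validated against fields generated here, so each generator carries a
closed-form pressure and the plate scenes compute their reference loads with
an independent divergence-theorem oracle (polygon area/centroid), never with
the loop-integration code under test.

Pitch sign convention: positive pitch rotates the leading edge
counter-clockwise in the (x, y) plane viewed from +z.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon

from .body_geometry import ControlSurface, Midline, SpanProfile, boundary_pair
from .exceptions import InvalidInputError
from .grids import FluidProperties, GridSpec, PressureFrame, VelocityFrame, VelocitySequence
from .loads import LoadSeries

__all__ = [
    "KinematicsProgram",
    "make_uniform_flow",
    "make_solid_body_rotation",
    "make_taylor_green",
    "taylor_green_fields",
    "make_flapping_midline",
    "make_plate_scene",
    "PlateScene",
    "PRESSURE_LAWS",
    "add_velocity_noise",
]

log = logging.getLogger(__name__)

HEAVE = "heave"
ZERO_AOA = "zero_aoa"


@dataclass(frozen=True)
class KinematicsProgram:
    """Flapping-plate motion program.

    ``heave`` translates the rigid chord laterally without pitch;
    ``zero_aoa`` additionally pitches the leading edge so it stays aligned
    with the instantaneous relative flow (pitch = -arctan(dy_LE/dt / U)).
    """

    program: str
    heave_amplitude: float
    frequency: float
    flow_speed: float
    chord: float

    def __post_init__(self) -> None:
        if self.program not in (HEAVE, ZERO_AOA):
            raise InvalidInputError(f"unknown program {self.program!r}")
        if self.frequency <= 0 or self.flow_speed <= 0 or self.chord <= 0:
            raise InvalidInputError("frequency, flow_speed and chord must be > 0")
        if self.heave_amplitude < 0:
            raise InvalidInputError("heave amplitude must be >= 0")

    @property
    def period(self) -> float:
        return 1.0 / self.frequency

    def heave_position(self, t: float) -> float:
        return self.heave_amplitude * np.sin(2.0 * np.pi * self.frequency * t)

    def heave_velocity(self, t: float) -> float:
        w = 2.0 * np.pi * self.frequency
        return self.heave_amplitude * w * np.cos(w * t)

    def pitch(self, t: float) -> float:
        if self.program == HEAVE:
            return 0.0
        return float(-np.arctan(self.heave_velocity(t) / self.flow_speed))


def make_uniform_flow(
    grid: GridSpec, U: Sequence[float], fluid: FluidProperties, t: float = 0.0
) -> tuple[VelocityFrame, PressureFrame]:
    """Uniform steady flow; zero gauge pressure everywhere."""
    U = np.asarray(U, dtype=float)
    if U.shape != (2,) or not np.all(np.isfinite(U)):
        raise InvalidInputError("U must be a finite 2-vector")
    shape = grid.shape
    vel = VelocityFrame(grid=grid, u=np.full(shape, U[0]), v=np.full(shape, U[1]), t=t)
    prs = PressureFrame(grid=grid, p=np.zeros(shape), t=t)
    return vel, prs


def make_solid_body_rotation(
    grid: GridSpec,
    omega: float,
    fluid: FluidProperties,
    center: Sequence[float] = (0.0, 0.0),
    t: float = 0.0,
) -> tuple[VelocityFrame, PressureFrame]:
    """Rigid rotation about ``center``: u = (-w (y-yc), w (x-xc)).

    The closed-form pressure is ``p = rho w^2 r^2 / 2`` plus a constant; the
    gauge is chosen so min(p) = 0.
    """
    if not np.isfinite(omega):
        raise InvalidInputError("omega must be finite")
    cx, cy = float(center[0]), float(center[1])
    X, Y = grid.meshgrid()
    u = -omega * (Y - cy)
    v = omega * (X - cx)
    p = 0.5 * fluid.rho * omega**2 * ((X - cx) ** 2 + (Y - cy) ** 2)
    p -= p.min()
    return (
        VelocityFrame(grid=grid, u=u, v=v, t=t),
        PressureFrame(grid=grid, p=p, t=t),
    )


def taylor_green_fields(
    X: np.ndarray, Y: np.ndarray, t: float, fluid: FluidProperties
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decaying Taylor-Green vortex sheet on the 2-pi periodic box.

    u = cos(x) sin(y) e^(-2 nu t), v = -sin(x) cos(y) e^(-2 nu t),
    p = -(rho/4) (cos 2x + cos 2y) e^(-4 nu t)  (zero spatial mean).
    The pressure expression is verified against the discrete momentum
    equation in the test suite.
    """
    decay = np.exp(-2.0 * fluid.nu * t)
    u = np.cos(X) * np.sin(Y) * decay
    v = -np.sin(X) * np.cos(Y) * decay
    p = -(fluid.rho / 4.0) * (np.cos(2.0 * X) + np.cos(2.0 * Y)) * decay**2
    return u, v, p


def make_taylor_green(
    grid: GridSpec, t: float, fluid: FluidProperties
) -> tuple[VelocityFrame, PressureFrame]:
    """Taylor-Green vortex frame on a grid spanning one 2-pi period per axis.

    The grid must start at the origin and have ``n*d = 2*pi`` per axis (the
    periodic image of the first node is one spacing past the last node).
    """
    if t < 0:
        raise InvalidInputError("t must be >= 0")
    two_pi = 2.0 * np.pi
    if (
        abs(grid.x0) > 1e-9
        or abs(grid.y0) > 1e-9
        or abs(grid.nx * grid.dx - two_pi) > 1e-6
        or abs(grid.ny * grid.dy - two_pi) > 1e-6
    ):
        raise InvalidInputError("Taylor-Green grid must span [0, 2*pi) per axis")
    X, Y = grid.meshgrid()
    u, v, p = taylor_green_fields(X, Y, t, fluid)
    return (
        VelocityFrame(grid=grid, u=u, v=v, t=t),
        PressureFrame(grid=grid, p=p, t=t),
    )


def make_flapping_midline(
    kin: KinematicsProgram,
    n_points: int,
    t: float,
    bend_amplitude: float = 0.0,
) -> tuple[Midline, float]:
    """Rigid-chord midline under a motion program; returns (midline, pitch).

    The leading edge sits at ``(0, h sin(2 pi f t))`` and the chord extends
    downstream (+x), rotated about the leading edge by the program's pitch.
    ``bend_amplitude`` adds an optional quadratic-envelope traveling-wave
    lateral deflection (a design extension; default rigid).
    """
    if n_points < 2:
        raise InvalidInputError("n_points must be >= 2")
    theta = kin.pitch(t)
    y_le = kin.heave_position(t)
    s = np.linspace(0.0, kin.chord, n_points)
    lateral = np.zeros_like(s)
    if bend_amplitude != 0.0:
        phase = 2.0 * np.pi * (kin.frequency * t - s / kin.chord)
        lateral = bend_amplitude * (s / kin.chord) ** 2 * np.sin(phase)
    x = s * np.cos(theta) - lateral * np.sin(theta)
    y = y_le + s * np.sin(theta) + lateral * np.cos(theta)
    return Midline(np.column_stack([x, y]), t=t), theta


def _law_uniform(X, Y, value=0.0):
    return np.full_like(X, value)


def _law_linear_x(X, Y, slope=10.0):
    return slope * X


def _law_linear_y(X, Y, slope=10.0):
    return slope * Y


def _law_solid_body(X, Y, rho=1000.0, omega=2.0):
    return 0.5 * rho * omega**2 * (X**2 + Y**2)


PRESSURE_LAWS = {
    "uniform": _law_uniform,
    "linear-in-x": _law_linear_x,
    "linear-in-y": _law_linear_y,
    "solid-body": _law_solid_body,
}


def _analytic_loads_for_polygon(
    poly: Polygon, law: str, span: float, reference: np.ndarray, **law_kw
) -> tuple[float, float, float]:
    """Divergence-theorem oracle: F = -(integral of grad p over area) * span.

    Uses polygon area and centroid (shoelace moments), never the loop sum.
    """
    A = poly.area
    cx, cy = poly.centroid.x, poly.centroid.y
    rx, ry = float(reference[0]), float(reference[1])
    if law == "uniform":
        return 0.0, 0.0, 0.0
    if law == "linear-in-x":
        a = law_kw.get("slope", 10.0)
        Fx, Fy = -a * A * span, 0.0
        Tz = -span * (-a * A * (cy - ry))  # -(integral (r-ref) x grad p)_z
        return Fx, Fy, Tz
    if law == "linear-in-y":
        a = law_kw.get("slope", 10.0)
        Fx, Fy = 0.0, -a * A * span
        Tz = -span * (a * A * (cx - rx))
        return Fx, Fy, Tz
    if law == "solid-body":
        rho = law_kw.get("rho", 1000.0)
        omega = law_kw.get("omega", 2.0)
        k = rho * omega**2
        Fx, Fy = -k * A * cx * span, -k * A * cy * span
        # (r-ref) x grad p = (x-rx) k y - (y-ry) k x = k (ry x - rx y)
        Tz = -span * k * A * (ry * cx - rx * cy)
        return Fx, Fy, Tz
    raise InvalidInputError(f"unknown pressure law {law!r}")


@dataclass
class PlateScene:
    """End-to-end fixture: motion, prescribed pressure, and oracle loads."""

    kin: KinematicsProgram
    velocity: VelocitySequence
    midlines: list[Midline]
    thetas: list[float]
    pressures: list[PressureFrame]
    surfaces: list[ControlSurface]
    analytic: LoadSeries
    pressure_law: str
    span: float
    Re: float


def make_plate_scene(
    kin: KinematicsProgram,
    grid: GridSpec,
    fluid: FluidProperties,
    pressure_law: str = "linear-in-x",
    n_frames: int = 200,
    dt: float = 0.01,
    span: float = 0.05,
    surface_factor: float = 1.64,
    n_surface_points: int = 200,
    noise_sd: float = 0.0,
    seed: int | None = None,
    **law_kw,
) -> PlateScene:
    """Flapping-plate scene with a prescribed analytic pressure field.

    Per frame: midline from the motion program, pressure from the chosen
    law on the full grid, a control surface at ``surface_factor * delta99``
    from the midline, and reference loads from the divergence-theorem
    oracle with the torque reference at the leading edge.  The uniform
    background velocity sequence carries optional seeded Gaussian noise.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be > 0")
    if pressure_law not in PRESSURE_LAWS:
        raise InvalidInputError(f"unknown pressure law {pressure_law!r}")
    if n_frames * dt < kin.period:
        log.warning(
            "scene spans %.3f s, less than one motion cycle (%.3f s)",
            n_frames * dt,
            kin.period,
        )
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    if noise_sd > 0 and seed is None:
        raise InvalidInputError("a seed is mandatory when velocity noise is enabled")
    if fluid.nu <= 0:
        raise InvalidInputError("plate scenes need nu > 0 to define a Reynolds number")
    Re = kin.flow_speed * kin.chord / fluid.nu

    law_fn = PRESSURE_LAWS[pressure_law]
    X, Y = grid.meshgrid()
    rng = np.random.default_rng(seed) if noise_sd > 0 else None

    frames, midlines, thetas, pressures, surfaces = [], [], [], [], []
    t_list, fx_list, fy_list, tz_list = [], [], [], []
    span_profile = SpanProfile.constant(span)
    for k in range(n_frames):
        t = k * dt
        mid, theta = make_flapping_midline(kin, 32, t)
        u = np.full(grid.shape, kin.flow_speed)
        v = np.zeros(grid.shape)
        if rng is not None:
            u = u + rng.normal(0.0, noise_sd, grid.shape)
            v = v + rng.normal(0.0, noise_sd, grid.shape)
        frames.append(VelocityFrame(grid=grid, u=u, v=v, t=t))
        pressures.append(PressureFrame(grid=grid, p=law_fn(X, Y, **law_kw), t=t))
        _, surf = boundary_pair(
            mid,
            kin.chord,
            Re,
            span_profile=span_profile,
            surface_factor=surface_factor,
            n_points=n_surface_points,
        )
        midlines.append(mid)
        thetas.append(theta)
        surfaces.append(surf)
        Fx, Fy, Tz = _analytic_loads_for_polygon(
            surf.polygon, pressure_law, span, mid.leading_edge, **law_kw
        )
        t_list.append(t)
        fx_list.append(Fx)
        fy_list.append(Fy)
        tz_list.append(Tz)

    analytic = LoadSeries.from_arrays(
        t_list,
        fx_list,
        fy_list,
        tz_list,
        theta=thetas,
        cycle_period=kin.period,
        provenance="measured",
    )
    return PlateScene(
        kin=kin,
        velocity=VelocitySequence(frames=frames, dt=dt),
        midlines=midlines,
        thetas=thetas,
        pressures=pressures,
        surfaces=surfaces,
        analytic=analytic,
        pressure_law=pressure_law,
        span=span,
        Re=Re,
    )


def add_velocity_noise(
    frame: VelocityFrame, sd: float, seed: int | None
) -> VelocityFrame:
    """Seeded Gaussian perturbation of a velocity frame (robustness tests)."""
    if sd < 0:
        raise InvalidInputError("sd must be >= 0")
    if sd > 0 and seed is None:
        raise InvalidInputError("a seed is mandatory when noise is enabled")
    rng = np.random.default_rng(seed)
    return VelocityFrame(
        grid=frame.grid,
        u=frame.u + rng.normal(0.0, sd, frame.grid.shape),
        v=frame.v + rng.normal(0.0, sd, frame.grid.shape),
        t=frame.t,
        valid=frame.valid.copy(),
    )
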