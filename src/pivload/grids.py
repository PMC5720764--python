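"""Core gridded-field containers shared by the flow, pressure and load stages.

All quantities are SI: coordinates in meters, velocities in m/s, pressure in
Pa (gauge), time in seconds.  Arrays are laid out ``(ny, nx)`` with the x
coordinate varying along axis 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidInputError

__all__ = [
    "GridSpec",
    "FluidProperties",
    "VelocityFrame",
    "VelocitySequence",
    "PressureGradientFrame",
    "PressureFrame",
]


@dataclass(frozen=True)
class GridSpec:
    """A regular rectangular grid of sample nodes.

    Node coordinates are ``x_j = x0 + j*dx`` (j = 0..nx-1) and
    ``y_i = y0 + i*dy``; both families are strictly increasing.
    """

    x0: float
    y0: float
    dx: float
    dy: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x0) and np.isfinite(self.y0)):
            raise InvalidInputError("grid origin must be finite")
        if self.dx <= 0 or self.dy <= 0:
            raise InvalidInputError("grid spacings dx, dy must be > 0")
        if self.nx < 8 or self.ny < 8:
            raise InvalidInputError("grid must have at least 8 nodes per axis")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    @property
    def x(self) -> np.ndarray:
        return self.x0 + self.dx * np.arange(self.nx)

    @property
    def y(self) -> np.ndarray:
        return self.y0 + self.dy * np.arange(self.ny)

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """Return ``(X, Y)`` node-coordinate arrays of shape ``(ny, nx)``."""
        return np.meshgrid(self.x, self.y)

    @classmethod
    def centered(cls, half_extent: float, n: int) -> "GridSpec":
        """Square grid of ``n`` x ``n`` nodes spanning ``[-h, h]`` per axis."""
        d = 2.0 * half_extent / (n - 1)
        return cls(x0=-half_extent, y0=-half_extent, dx=d, dy=d, nx=n, ny=n)


@dataclass(frozen=True)
class FluidProperties:
    """Density ``rho`` (kg/m^3) and kinematic viscosity ``nu`` (m^2/s)."""

    rho: float
    nu: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.rho) and np.isfinite(self.nu)):
            raise InvalidInputError("fluid properties must be finite")
        if self.rho <= 0:
            raise InvalidInputError("rho must be > 0")
        if self.nu < 0:
            raise InvalidInputError("nu must be >= 0")

    @property
    def mu(self) -> float:
        """Dynamic viscosity, derived as ``rho * nu`` (Pa s)."""
        return self.rho * self.nu


def _check_field(grid: GridSpec, arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape != grid.shape:
        raise InvalidInputError(
            f"{name} has shape {arr.shape}, expected {grid.shape}"
        )
    return arr


@dataclass
class VelocityFrame:
    """Planar velocity samples on a regular grid at one instant.

    Invalid nodes (``valid == False``) carry no velocity information and are
    never read by downstream stages.
    """

    grid: GridSpec
    u: np.ndarray
    v: np.ndarray
    t: float = 0.0
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.u = _check_field(self.grid, self.u, "u")
        self.v = _check_field(self.grid, self.v, "v")
        if self.valid is None:
            self.valid = np.ones(self.grid.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.grid.shape:
                raise InvalidInputError("valid mask shape mismatch")
        if not np.all(np.isfinite(self.u[self.valid])) or not np.all(
            np.isfinite(self.v[self.valid])
        ):
            raise InvalidInputError("velocity must be finite on valid nodes")


@dataclass
class VelocitySequence:
    """An ordered, uniformly-sampled list of velocity frames."""

    frames: list[VelocityFrame]
    dt: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidInputError("dt must be > 0")
        if not self.frames:
            raise InvalidInputError("sequence must contain at least one frame")
        g0 = self.frames[0].grid
        t0 = self.frames[0].t
        for k, f in enumerate(self.frames):
            if f.grid != g0:
                raise InvalidInputError(f"frame {k} grid differs from frame 0")
            if abs(f.t - (t0 + k * self.dt)) > 1e-9 + 1e-6 * self.dt:
                raise InvalidInputError(
                    f"frame {k} timestamp {f.t} != t0 + k*dt = {t0 + k * self.dt}"
                )

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def grid(self) -> GridSpec:
        return self.frames[0].grid

    @property
    def times(self) -> np.ndarray:
        return np.array([f.t for f in self.frames])


@dataclass
class PressureGradientFrame:
    """Per-node pressure gradient (Pa/m) with a validity mask."""

    grid: GridSpec
    dpdx: np.ndarray
    dpdy: np.ndarray
    valid: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.dpdx = _check_field(self.grid, self.dpdx, "dpdx")
        self.dpdy = _check_field(self.grid, self.dpdy, "dpdy")
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.grid.shape:
            raise InvalidInputError("valid mask shape mismatch")


@dataclass
class PressureFrame:
    """Gauge pressure (Pa) per node; NaN and ``defined == False`` inside masks."""

    grid: GridSpec
    p: np.ndarray
    defined: np.ndarray = field(default=None)  # type: ignore[assignment]
    t: float = 0.0

    def __post_init__(self) -> None:
        self.p = _check_field(self.grid, self.p, "p")
        if self.defined is None:
            self.defined = np.isfinite(self.p)
        else:
            self.defined = np.asarray(self.defined, dtype=bool)
            if self.defined.shape != self.grid.shape:
                raise InvalidInputError("defined mask shape mismatch")
        if not np.all(np.isfinite(self.p[self.defined])):
            raise InvalidInputError("pressure must be finite on defined nodes")
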