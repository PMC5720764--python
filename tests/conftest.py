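import numpy as np
import pytest

from pivload.body_geometry import ControlSurface, Midline
from pivload.grids import FluidProperties, GridSpec


@pytest.fixture
def water() -> FluidProperties:
    return FluidProperties(rho=1000.0, nu=1e-6)


@pytest.fixture
def inviscid() -> FluidProperties:
    return FluidProperties(rho=1000.0, nu=0.0)


@pytest.fixture
def grid32() -> GridSpec:
    return GridSpec.centered(0.5, 32)


@pytest.fixture
def grid64() -> GridSpec:
    return GridSpec.centered(0.5, 64)


@pytest.fixture
def straight_midline() -> Midline:
    return Midline(np.array([[0.0, 0.0], [0.1, 0.0]]))


def circle_surface(
    R: float = 0.1,
    n: int = 200,
    span: float = 0.05,
    center=(0.0, 0.0),
    r0=(0.0, 0.0),
) -> ControlSurface:
    """Analytic circular control surface (exact normals, forward dl)."""
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + R * np.cos(th), center[1] + R * np.sin(th)])
    normals = np.column_stack([np.cos(th), np.sin(th)])
    dl = np.hypot(*(np.roll(pts, -1, axis=0) - pts).T)
    return ControlSurface(pts, normals, dl, np.full(n, span), np.asarray(r0, dtype=float))


@pytest.fixture
def circle200() -> ControlSurface:
    return circle_surface()


def tg_grid(n: int = 128) -> GridSpec:
    d = 2.0 * np.pi / n
    return GridSpec(0.0, 0.0, d, d, n, n)
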