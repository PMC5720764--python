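"""Gauge-pressure reconstruction from planar velocity sequences.

The pressure gradient is evaluated per node from the Navier-Stokes momentum
balance (material acceleration plus viscous term; viscosity is retained by
default) and then line-integrated from the domain edge inward along several
straight ray families.  Every node collects one pressure estimate per family
and keeps the median, which suppresses errors accumulated along individual
paths.  Paths never cross masked or invalid nodes: estimates downstream of a
blockage are discarded rather than bridged.

Ray seeds are made mutually consistent by first integrating the tangential
gradient around the outer ring of the domain (closure error distributed
linearly along the perimeter), so all families share one gauge.  The final
gauge is fixed so that the median pressure on the outermost defined ring is
zero.
"""

from __future__ import annotations

import warnings

import numpy as np

from .body_geometry import BodyMask
from .exceptions import EmptyFieldError, InvalidInputError
from .grids import (
    FluidProperties,
    GridSpec,
    PressureFrame,
    PressureGradientFrame,
    VelocityFrame,
    VelocitySequence,
)

__all__ = [
    "pressure_gradient",
    "integrate_pressure",
    "pressure_sequence",
    "path_estimates",
    "ring_pressure",
]

_DIRECTIONS_8 = [(0, 1), (0, -1), (1, 0), (-1, 0), (1, 1), (1, -1), (-1, 1), (-1, -1)]


def _first_derivative(f: np.ndarray, valid: np.ndarray, h: float, axis: int):
    """First derivative with validity-aware stencils.

    Central differences where both neighbors are valid, one-sided next to
    invalid nodes or the domain edge, invalid where no valid neighbor exists.
    Returns (derivative, validity).
    """
    fwd_f = np.roll(f, -1, axis=axis)
    bwd_f = np.roll(f, 1, axis=axis)
    fwd_ok = valid & np.roll(valid, -1, axis=axis)
    bwd_ok = valid & np.roll(valid, 1, axis=axis)
    # np.roll wraps; kill the wrapped slices
    idx_last = [slice(None)] * f.ndim
    idx_last[axis] = -1
    idx_first = [slice(None)] * f.ndim
    idx_first[axis] = 0
    fwd_ok[tuple(idx_last)] = False
    bwd_ok[tuple(idx_first)] = False

    fwd = np.where(fwd_ok, (fwd_f - f) / h, 0.0)
    bwd = np.where(bwd_ok, (f - bwd_f) / h, 0.0)
    both = fwd_ok & bwd_ok
    deriv = np.where(both, 0.5 * (fwd + bwd), fwd + bwd)
    ok = fwd_ok | bwd_ok
    return np.where(ok, deriv, 0.0), ok


def _second_derivative(f: np.ndarray, valid: np.ndarray, h: float, axis: int) -> np.ndarray:
    """Central second derivative where the full stencil is valid, else 0.

    Only feeds the (small) viscous term, so missing stencils degrade
    gracefully to a zero contribution instead of invalidating the node.
    """
    up = np.roll(f, -1, axis=axis)
    dn = np.roll(f, 1, axis=axis)
    ok = valid & np.roll(valid, -1, axis=axis) & np.roll(valid, 1, axis=axis)
    idx = [slice(None)] * f.ndim
    idx[axis] = 0
    ok[tuple(idx)] = False
    idx[axis] = -1
    ok[tuple(idx)] = False
    return np.where(ok, (up - 2.0 * f + dn) / h**2, 0.0)


def pressure_gradient(
    prev: VelocityFrame | None,
    cur: VelocityFrame,
    nxt: VelocityFrame | None,
    fluid: FluidProperties,
    dt: float,
    viscous: bool = True,
) -> PressureGradientFrame:
    """Evaluate the momentum-balance pressure gradient at one instant.

    ``grad p = -rho (du/dt + (u . grad) u) + rho nu laplacian(u)``, with
    central differences in space, a central difference in time when both
    temporal neighbors exist and one-sided otherwise.  A node is valid only
    where every required stencil value is available; nodes adjacent to
    invalid (masked) nodes fall back to one-sided spatial differences.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be > 0")
    if prev is None and nxt is None:
        raise InvalidInputError("at least one temporal neighbor is required")
    for other in (prev, nxt):
        if other is not None and other.grid != cur.grid:
            raise InvalidInputError("all frames must share one grid")

    g = cur.grid
    u, v, valid = cur.u, cur.v, cur.valid

    # temporal derivative
    if prev is not None and nxt is not None:
        dudt = (nxt.u - prev.u) / (2.0 * dt)
        dvdt = (nxt.v - prev.v) / (2.0 * dt)
        t_ok = prev.valid & nxt.valid
    elif nxt is not None:
        dudt = (nxt.u - u) / dt
        dvdt = (nxt.v - v) / dt
        t_ok = nxt.valid
    else:
        assert prev is not None
        dudt = (u - prev.u) / dt
        dvdt = (v - prev.v) / dt
        t_ok = prev.valid

    dudx, okux = _first_derivative(u, valid, g.dx, axis=1)
    dudy, okuy = _first_derivative(u, valid, g.dy, axis=0)
    dvdx, okvx = _first_derivative(v, valid, g.dx, axis=1)
    dvdy, okvy = _first_derivative(v, valid, g.dy, axis=0)

    conv_x = u * dudx + v * dudy
    conv_y = u * dvdx + v * dvdy

    gx = -fluid.rho * (dudt + conv_x)
    gy = -fluid.rho * (dvdt + conv_y)

    if viscous and fluid.nu > 0:
        mu = fluid.mu
        lap_u = _second_derivative(u, valid, g.dx, 1) + _second_derivative(u, valid, g.dy, 0)
        lap_v = _second_derivative(v, valid, g.dx, 1) + _second_derivative(v, valid, g.dy, 0)
        gx = gx + mu * lap_u
        gy = gy + mu * lap_v

    ok = valid & t_ok & okux & okuy & okvx & okvy
    gx = np.where(ok, gx, 0.0)
    gy = np.where(ok, gy, 0.0)
    return PressureGradientFrame(grid=g, dpdx=gx, dpdy=gy, valid=ok, t=cur.t)


def _ring_indices(ny: int, nx: int) -> tuple[np.ndarray, np.ndarray]:
    """Perimeter node indices walked CCW from (0, 0), no repeats."""
    ii = np.concatenate(
        [
            np.zeros(nx - 1, dtype=int),
            np.arange(0, ny - 1),
            np.full(nx - 1, ny - 1, dtype=int),
            np.arange(ny - 1, 0, -1),
        ]
    )
    jj = np.concatenate(
        [
            np.arange(0, nx - 1),
            np.full(ny - 1, nx - 1, dtype=int),
            np.arange(nx - 1, 0, -1),
            np.zeros(ny - 1, dtype=int),
        ]
    )
    return ii, jj


def ring_pressure(grad: PressureGradientFrame, valid: np.ndarray) -> np.ndarray:
    """Pressure on the outer domain ring, gauge-anchored at node (0, 0).

    Trapezoidal integration of the tangential gradient around the perimeter;
    the closure error is distributed linearly along arc length so the loop
    closes exactly.  Entries are NaN on (and beyond contiguity of) invalid
    ring nodes.  Returned as a full (ny, nx) array, NaN off the ring.
    """
    g = grad.grid
    ii, jj = _ring_indices(g.ny, g.nx)
    n = ii.size
    gx = grad.dpdx[ii, jj]
    gy = grad.dpdy[ii, jj]
    ok = valid[ii, jj]
    x = g.x0 + jj * g.dx
    y = g.y0 + ii * g.dy
    nxt = np.roll(np.arange(n), -1)
    dxs = x[nxt] - x
    dys = y[nxt] - y
    inc = 0.5 * ((gx + gx[nxt]) * dxs + (gy + gy[nxt]) * dys)
    inc = np.where(ok & ok[nxt], inc, np.nan)

    p = np.full(n, np.nan)
    if ok[0]:
        p[0] = 0.0
        cum = np.concatenate([[0.0], np.cumsum(inc)])  # length n+1, last closes loop
        p = cum[:-1]
        if np.all(np.isfinite(inc)):
            arclen = np.concatenate([[0.0], np.cumsum(np.hypot(dxs, dys))])
            p = p - cum[-1] * arclen[:-1] / arclen[-1]
        p[~ok] = np.nan
    else:
        # anchor at the first valid ring node instead
        start = np.argmax(ok)
        if ok[start]:
            rolled_inc = np.roll(inc, -start)
            cum = np.concatenate([[0.0], np.cumsum(rolled_inc)])[:-1]
            p = np.roll(cum, start)
            p[~ok] = np.nan
    out = np.full(g.shape, np.nan)
    out[ii, jj] = p
    return out


def _march(
    gx: np.ndarray,
    gy: np.ndarray,
    valid: np.ndarray,
    seeds: np.ndarray,
    di: int,
    dj: int,
    dx: float,
    dy: float,
) -> np.ndarray:
    """One ray family: accumulate trapezoidal increments along (di, dj).

    Rays start at the upwind domain edge with the ring-pressure seed of the
    edge node; NaN (invalid node or invalid seed) propagates downstream so
    blocked rays contribute no estimates past the blockage.
    """
    ny, nx = gx.shape
    est = np.full((ny, nx), np.nan)
    # seed cells: predecessor lies outside the domain
    if dj > 0:
        est[:, 0] = seeds[:, 0]
    elif dj < 0:
        est[:, -1] = seeds[:, -1]
    if di > 0:
        est[0, :] = seeds[0, :]
    elif di < 0:
        est[-1, :] = seeds[-1, :]
    est[~valid] = np.nan

    step_x = dj * dx
    step_y = di * dy
    pred_gx = np.roll(np.roll(gx, di, axis=0), dj, axis=1)
    pred_gy = np.roll(np.roll(gy, di, axis=0), dj, axis=1)
    pred_ok = np.roll(np.roll(valid, di, axis=0), dj, axis=1)
    inc = 0.5 * ((pred_gx + gx) * step_x + (pred_gy + gy) * step_y)
    inc = np.where(valid & pred_ok, inc, np.nan)

    if di == 0:
        cols = range(1, nx) if dj > 0 else range(nx - 2, -1, -1)
        for j in cols:
            est[:, j] = est[:, j - dj] + inc[:, j]
    elif dj == 0:
        rows = range(1, ny) if di > 0 else range(ny - 2, -1, -1)
        for i in rows:
            est[i, :] = est[i - di, :] + inc[i, :]
    else:
        rows = range(1, ny) if di > 0 else range(ny - 2, -1, -1)
        for i in rows:
            if dj > 0:
                est[i, 1:] = est[i - di, :-1] + inc[i, 1:]
            else:
                est[i, :-1] = est[i - di, 1:] + inc[i, :-1]
    return est


def path_estimates(
    grad: PressureGradientFrame,
    valid: np.ndarray,
    seeds: np.ndarray,
    n_directions: int = 8,
) -> list[np.ndarray]:
    """Per-family pressure estimate arrays (NaN where a family has none)."""
    if n_directions not in (4, 8):
        raise InvalidInputError("n_directions must be 4 or 8 (evenly rotated families)")
    g = grad.grid
    out = []
    for di, dj in _DIRECTIONS_8[:n_directions]:
        out.append(_march(grad.dpdx, grad.dpdy, valid, seeds, di, dj, g.dx, g.dy))
    return out


def _gauge_offset(p: np.ndarray, defined: np.ndarray) -> float:
    ny, nx = p.shape
    ring = np.zeros_like(defined)
    ring[0, :] = ring[-1, :] = True
    ring[:, 0] = ring[:, -1] = True
    sel = ring & defined
    if not sel.any():
        sel = defined
    return float(np.median(p[sel]))


def integrate_pressure(
    grad: PressureGradientFrame,
    mask: BodyMask | None = None,
    n_directions: int = 8,
    gauge: str = "ring_median",
) -> PressureFrame:
    """Median-polled multi-path integration of a pressure-gradient field.

    Parameters
    ----------
    grad : per-node pressure gradient with validity.
    mask : optional body mask; nodes inside are excluded and never crossed.
    n_directions : 4 (axis-aligned) or 8 (default, adds diagonals) ray
        families, evenly rotated.
    gauge : ``"ring_median"`` (default) subtracts the median pressure over
        the outermost defined ring; ``"none"`` keeps the seed gauge.
    """
    valid = grad.valid.copy()
    if mask is not None:
        valid &= ~mask.nodes_inside(grad.grid)
    if not valid.any():
        raise EmptyFieldError("no valid node to integrate")

    seeds = ring_pressure(grad, valid)
    estimates = path_estimates(grad, valid, seeds, n_directions)
    stack = np.stack(estimates)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns inside masks
        p = np.nanmedian(stack, axis=0)
    p[~valid] = np.nan
    defined = np.isfinite(p)
    if not defined.any():
        raise EmptyFieldError("integration produced no defined node")
    if gauge == "ring_median":
        p = p - _gauge_offset(p, defined)
    elif gauge != "none":
        raise InvalidInputError(f"unknown gauge {gauge!r}")
    p[~defined] = np.nan
    return PressureFrame(grid=grad.grid, p=p, defined=defined, t=grad.t)


def pressure_sequence(
    seq: VelocitySequence,
    masks: list[BodyMask] | None = None,
    fluid: FluidProperties | None = None,
    dt_calc: float = 0.01,
    n_directions: int = 8,
    viscous: bool = True,
) -> list[PressureFrame]:
    """Reconstruct pressure for a velocity sequence at interval ``dt_calc``.

    ``dt_calc`` must be an integer multiple of the sequence time step; frames
    are subsampled accordingly and temporal derivatives taken between the
    retained frames.  ``masks`` (one per *input* frame, or None) remove body
    interiors before integration.
    """
    if fluid is None:
        raise InvalidInputError("fluid properties are required")
    ratio = dt_calc / seq.dt
    step = int(round(ratio))
    if step < 1 or abs(ratio - step) > 1e-6:
        raise InvalidInputError(
            f"dt_calc={dt_calc} is not an integer multiple of sequence dt={seq.dt}"
        )
    if masks is not None and len(masks) != len(seq):
        raise InvalidInputError("need one mask per frame (or masks=None)")

    keep = list(range(0, len(seq), step))

    def _frame(k: int | None) -> VelocityFrame | None:
        """Frame k with its own body mask blanked out of the validity."""
        if k is None:
            return None
        f = seq.frames[k]
        if masks is None or masks[k] is None:
            return f
        inside = masks[k].nodes_inside(seq.grid)
        return VelocityFrame(grid=f.grid, u=f.u, v=f.v, t=f.t, valid=f.valid & ~inside)

    out: list[PressureFrame] = []
    for pos, k in enumerate(keep):
        prev = _frame(keep[pos - 1]) if pos > 0 else None
        nxt = _frame(keep[pos + 1]) if pos + 1 < len(keep) else None
        cur = _frame(k)
        mask = masks[k] if masks is not None else None
        grad = pressure_gradient(prev, cur, nxt, fluid, dt_calc, viscous=viscous)
        out.append(integrate_pressure(grad, mask=mask, n_directions=n_directions))
    return out
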