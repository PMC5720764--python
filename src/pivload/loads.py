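"""Control-surface pressure integration into force/torque time series.

Sign convention: loads are those exerted BY the fluid ON the body, so with
+x pointing downstream thrust appears as negative Fx.  The shear (viscous
stress) contribution to surface loads is intentionally omitted — that is the
method's central approximation — and every series produced here is tagged
``pressure-only`` via its provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .body_geometry import ControlSurface
from .exceptions import InvalidInputError, UndefinedPressureError
from .grids import PressureFrame

__all__ = [
    "LoadRecord",
    "LoadSeries",
    "NondimScale",
    "sample_pressure",
    "integrate_loads",
    "nondimensionalize",
    "load_series",
    "shear_term",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LoadRecord:
    """One instant of force (N) and torque about +z (N m)."""

    t: float
    Fx: float
    Fy: float
    Tz: float
    theta: float | None = None
    Fx_star: float | None = None
    Fy_star: float | None = None
    Tz_star: float | None = None

    def __post_init__(self) -> None:
        for name in ("t", "Fx", "Fy", "Tz"):
            if not np.isfinite(getattr(self, name)):
                raise InvalidInputError(f"{name} must be finite")


@dataclass
class LoadSeries:
    """Uniformly sampled force/torque trace with provenance.

    ``provenance`` is one of ``measured``, ``estimated``, ``rod`` or
    ``foil-only``; estimated series carry the implicit ``pressure-only``
    qualification (see :func:`shear_term`).
    """

    records: list[LoadRecord]
    cycle_period: float | None = None
    provenance: str = "estimated"

    def __post_init__(self) -> None:
        t = self.t
        if len(t) > 1:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise InvalidInputError("timestamps must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
                raise InvalidInputError("timestamps must be uniformly spaced")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def t(self) -> np.ndarray:
        return np.array([r.t for r in self.records])

    def column(self, name: str) -> np.ndarray:
        vals = [getattr(r, name) for r in self.records]
        return np.array([np.nan if v is None else v for v in vals])

    @property
    def Fx(self) -> np.ndarray:
        return self.column("Fx")

    @property
    def Fy(self) -> np.ndarray:
        return self.column("Fy")

    @property
    def Tz(self) -> np.ndarray:
        return self.column("Tz")

    @classmethod
    def from_arrays(
        cls,
        t: Sequence[float],
        Fx: Sequence[float],
        Fy: Sequence[float],
        Tz: Sequence[float],
        theta: Sequence[float] | None = None,
        cycle_period: float | None = None,
        provenance: str = "estimated",
    ) -> "LoadSeries":
        recs = [
            LoadRecord(
                t=float(ti),
                Fx=float(a),
                Fy=float(b),
                Tz=float(c),
                theta=None if theta is None else float(theta[k]),
            )
            for k, (ti, a, b, c) in enumerate(zip(t, Fx, Fy, Tz))
        ]
        return cls(records=recs, cycle_period=cycle_period, provenance=provenance)


@dataclass(frozen=True)
class NondimScale:
    """Scales for nondimensionalization: F* = F/(rho s c v^2), T* = T/(rho s c^2 v^2)."""

    rho: float
    span: float
    chord: float
    speed: float

    def __post_init__(self) -> None:
        for name in ("rho", "span", "chord", "speed"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"{name} must be > 0")


def sample_pressure(
    p: PressureFrame, surface: ControlSurface, max_fallback_cells: float = 2.0
) -> np.ndarray:
    """Pressure at each surface point by defined-node bilinear interpolation.

    Weights of undefined corner nodes are dropped and the remainder
    renormalized; if all four corners are undefined the nearest defined node
    within ``max_fallback_cells`` grid cells is used instead (the number of
    such fallbacks is logged — it is a data-quality signal normally managed
    by mask sizing).
    """
    g = p.grid
    pts = surface.points
    fx = (pts[:, 0] - g.x0) / g.dx
    fy = (pts[:, 1] - g.y0) / g.dy
    if np.any(fx < 0) or np.any(fx > g.nx - 1) or np.any(fy < 0) or np.any(fy > g.ny - 1):
        bad = int(np.argmax((fx < 0) | (fx > g.nx - 1) | (fy < 0) | (fy > g.ny - 1)))
        raise UndefinedPressureError(f"surface point {bad} lies outside the grid extent")
    j0 = np.clip(np.floor(fx).astype(int), 0, g.nx - 2)
    i0 = np.clip(np.floor(fy).astype(int), 0, g.ny - 2)
    tx = fx - j0
    ty = fy - i0

    corners_p = np.stack(
        [p.p[i0, j0], p.p[i0, j0 + 1], p.p[i0 + 1, j0], p.p[i0 + 1, j0 + 1]]
    )
    corners_d = np.stack(
        [
            p.defined[i0, j0],
            p.defined[i0, j0 + 1],
            p.defined[i0 + 1, j0],
            p.defined[i0 + 1, j0 + 1],
        ]
    )
    w = np.stack(
        [(1 - tx) * (1 - ty), tx * (1 - ty), (1 - tx) * ty, tx * ty]
    )
    w = np.where(corners_d, w, 0.0)
    wsum = w.sum(axis=0)
    out = np.full(pts.shape[0], np.nan)
    usable = wsum > 0
    with np.errstate(invalid="ignore"):
        num = np.nansum(np.where(corners_d, w * corners_p, 0.0), axis=0)
    out[usable] = num[usable] / wsum[usable]

    n_fallback = 0
    if not np.all(usable):
        ii, jj = np.nonzero(p.defined)
        if ii.size == 0:
            raise UndefinedPressureError("pressure frame has no defined node")
        gx = g.x0 + jj * g.dx
        gy = g.y0 + ii * g.dy
        for k in np.nonzero(~usable)[0]:
            d2 = ((gx - pts[k, 0]) / g.dx) ** 2 + ((gy - pts[k, 1]) / g.dy) ** 2
            best = int(np.argmin(d2))
            if d2[best] > max_fallback_cells**2:
                raise UndefinedPressureError(
                    f"surface point {k} farther than {max_fallback_cells} cells "
                    "from any defined pressure node"
                )
            out[k] = p.p[ii[best], jj[best]]
            n_fallback += 1
        log.info("sample_pressure: %d nearest-node fallbacks", n_fallback)
    return out


def integrate_loads(
    surface: ControlSurface,
    pressures: Sequence[float],
    reference: Sequence[float] | None = None,
) -> tuple[float, float, float]:
    """Loop sums ``F = -sum p n dl s`` and ``Tz = -sum p [(r - ref) x n]_z dl s``."""
    pvals = np.asarray(pressures, dtype=float)
    if pvals.shape != (surface.n_points,):
        raise InvalidInputError("pressure list length must match surface points")
    if np.any(~np.isfinite(pvals)):
        raise InvalidInputError("NaN pressure on surface; resolve undefined values upstream")
    ref = surface.r0 if reference is None else np.asarray(reference, dtype=float)
    if not np.all(np.isfinite(ref)):
        raise InvalidInputError("reference point must be finite")
    wda = pvals * surface.dl * surface.span  # p * dA per segment
    F = -(surface.normals * wda[:, None]).sum(axis=0)
    arm = surface.points - ref
    cross = arm[:, 0] * surface.normals[:, 1] - arm[:, 1] * surface.normals[:, 0]
    Tz = -float(np.dot(cross, wda))
    return float(F[0]), float(F[1]), Tz


def nondimensionalize(record: LoadRecord, scale: NondimScale) -> LoadRecord:
    """Attach F* = F/(rho s c v^2) and T* = T/(rho s c^2 v^2) to a record."""
    f_ref = scale.rho * scale.span * scale.chord * scale.speed**2
    t_ref = f_ref * scale.chord
    return replace(
        record,
        Fx_star=record.Fx / f_ref,
        Fy_star=record.Fy / f_ref,
        Tz_star=record.Tz / t_ref,
    )


def load_series(
    pressures: Sequence[PressureFrame],
    surfaces: Sequence[ControlSurface],
    references: Sequence[Sequence[float]] | None = None,
    scale: NondimScale | None = None,
    thetas: Sequence[float] | None = None,
    cycle_period: float | None = None,
) -> LoadSeries:
    """Per-frame sampling + integration assembled into a LoadSeries.

    ``references`` defaults to each surface's own reference point (the
    leading edge when built by :func:`pivload.body_geometry.boundary_pair`).
    """
    if len(pressures) != len(surfaces):
        raise InvalidInputError("need one surface per pressure frame")
    if references is not None and len(references) != len(pressures):
        raise InvalidInputError("need one reference per frame")
    if thetas is not None and len(thetas) != len(pressures):
        raise InvalidInputError("need one pitch angle per frame")
    records = []
    for k, (pf, surf) in enumerate(zip(pressures, surfaces)):
        pvals = sample_pressure(pf, surf)
        ref = None if references is None else references[k]
        Fx, Fy, Tz = integrate_loads(surf, pvals, reference=ref)
        rec = LoadRecord(
            t=pf.t, Fx=Fx, Fy=Fy, Tz=Tz, theta=None if thetas is None else float(thetas[k])
        )
        if scale is not None:
            rec = nondimensionalize(rec, scale)
        records.append(rec)
    return LoadSeries(records=records, cycle_period=cycle_period, provenance="estimated")


def shear_term(surface: ControlSurface) -> tuple[float, float, float]:
    """Viscous-stress contribution to surface loads: intentionally zero.

    The method estimates loads from the pressure term alone; this stub
    records the omission explicitly so reports can state "pressure-only".
    """
    return 0.0, 0.0, 0.0
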