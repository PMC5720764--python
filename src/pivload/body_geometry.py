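"""Deforming-body geometry: midlines, masks and control surfaces.

A body midline (an ordered polyline in meters) is dilated on both sides by a
boundary-layer-scaled halfwidth to produce two nested closed loops: a body
mask (inside which pressure is undefined) and a control surface on which
pressure is sampled and integrated into net loads.

Two dilation pathways are provided: exact geometric buffering (default,
resolution-independent) and a raster pathway (rasterize, binary-dilate,
trace the boundary) kept as a cross-check; they agree to within the raster
cell size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import shapely
from shapely.geometry import LineString, Polygon
from shapely.geometry.polygon import orient

from .exceptions import DetectionFailureError, InvalidInputError
from .grids import GridSpec

__all__ = [
    "Midline",
    "BodyMask",
    "ControlSurface",
    "SpanProfile",
    "delta99",
    "extend_leading_edge",
    "offset_boundary",
    "offset_boundary_raster",
    "boundary_pair",
    "surface_sweep",
    "detect_midline",
]


@dataclass
class Midline:
    """Ordered body centerline, leading edge first, in meters."""

    points: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise InvalidInputError("midline points must have shape (n, 2)")
        if self.points.shape[0] < 2:
            raise InvalidInputError("midline needs at least 2 points")
        if not np.all(np.isfinite(self.points)):
            raise InvalidInputError("midline points must be finite")
        seg = np.diff(self.points, axis=0)
        if np.any(np.hypot(seg[:, 0], seg[:, 1]) == 0):
            raise InvalidInputError("midline has duplicate consecutive points")

    @property
    def leading_edge(self) -> np.ndarray:
        return self.points[0]

    @property
    def arc_positions(self) -> np.ndarray:
        """Cumulative arc length from the leading edge, per point (m)."""
        seg = np.diff(self.points, axis=0)
        return np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])

    @property
    def length(self) -> float:
        return float(self.arc_positions[-1])


@dataclass
class BodyMask:
    """Closed simple loop enclosing the body; pressure is undefined inside."""

    boundary: np.ndarray  # (n, 2), closed implicitly (no repeated last point)

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2:
            raise InvalidInputError("mask boundary must have shape (n, 2)")
        poly = Polygon(self.boundary)
        if not poly.is_valid:
            raise InvalidInputError("mask boundary must be a simple closed loop")
        self._poly = poly

    @property
    def polygon(self) -> Polygon:
        return self._poly

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorized point-in-mask predicate (boundary counts as inside)."""
        return shapely.covers(self._poly, shapely.points(x, y))

    def nodes_inside(self, grid: GridSpec) -> np.ndarray:
        """Boolean (ny, nx) array of grid nodes lying inside the mask."""
        X, Y = grid.meshgrid()
        return self.contains(X.ravel(), Y.ravel()).reshape(grid.shape)


class SpanProfile:
    """Chordwise arc-position (m) -> local span (m) mapping.

    Constant for rectangular bodies; a piecewise-linear table supports
    tail-shaped planforms.  Evaluation outside the tabulated range clamps to
    the end values (spans must stay positive over the body).
    """

    def __init__(self, fn: Callable[[np.ndarray], np.ndarray]):
        self._fn = fn

    def __call__(self, s: np.ndarray) -> np.ndarray:
        out = np.asarray(self._fn(np.asarray(s, dtype=float)), dtype=float)
        if np.any(out <= 0):
            raise InvalidInputError("span must be > 0 over the body")
        return out

    @classmethod
    def constant(cls, span: float) -> "SpanProfile":
        if span <= 0:
            raise InvalidInputError("span must be > 0")
        return cls(lambda s: np.full_like(np.atleast_1d(s), span, dtype=float))

    @classmethod
    def from_table(cls, arc: Sequence[float], span: Sequence[float]) -> "SpanProfile":
        arc = np.asarray(arc, dtype=float)
        span = np.asarray(span, dtype=float)
        if arc.ndim != 1 or arc.shape != span.shape or arc.size < 2:
            raise InvalidInputError("arc/span table must be matching 1-D arrays")
        if np.any(np.diff(arc) <= 0):
            raise InvalidInputError("arc positions must be strictly increasing")
        return cls(lambda s: np.interp(s, arc, span))


@dataclass
class ControlSurface:
    """Closed integration loop with outward normals and per-segment spans.

    ``points`` omit the repeated closing vertex; segment ``i`` joins point
    ``i`` to point ``(i+1) mod n`` and ``dl[i]`` is its length.  ``span[i]``
    is the local out-of-plane body depth used to convert loop length into
    area.  ``r0`` is the torque reference point.
    """

    points: np.ndarray
    normals: np.ndarray
    dl: np.ndarray
    span: np.ndarray
    r0: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        self.dl = np.asarray(self.dl, dtype=float)
        self.span = np.asarray(self.span, dtype=float)
        self.r0 = np.asarray(self.r0, dtype=float)
        n = self.points.shape[0]
        if self.normals.shape != (n, 2) or self.dl.shape != (n,) or self.span.shape != (n,):
            raise InvalidInputError("control surface array shapes inconsistent")
        if np.any(self.dl <= 0) or np.any(self.span <= 0):
            raise InvalidInputError("segment lengths and spans must be > 0")
        nrm = np.hypot(self.normals[:, 0], self.normals[:, 1])
        if not np.allclose(nrm, 1.0, atol=1e-8):
            raise InvalidInputError("normals must be unit vectors")

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    def enclosed_area(self) -> float:
        """Signed-area magnitude by the shoelace formula (m^2)."""
        x, y = self.points[:, 0], self.points[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    def with_reference(self, r0: Sequence[float]) -> "ControlSurface":
        return ControlSurface(self.points, self.normals, self.dl, self.span, np.asarray(r0))


def delta99(x: float, Re: float) -> float:
    """99% boundary-layer (shear-layer) thickness: ``5 * x / sqrt(Re)``.

    Parameters
    ----------
    x : chord length (m), >= 0.
    Re : Reynolds number, > 0.
    """
    if Re <= 0:
        raise InvalidInputError("Re must be > 0")
    if x < 0:
        raise InvalidInputError("chord length must be >= 0")
    return 5.0 * x / np.sqrt(Re)


def extend_leading_edge(m: Midline, length: float) -> Midline:
    """Prepend a straight segment of ``length`` upstream of the first point.

    The extension runs along the reversed tangent of the first midline
    segment, standing in for a portion of the body hidden by its actuation
    rod.
    """
    if length < 0:
        raise InvalidInputError("extension length must be >= 0")
    if length == 0:
        return Midline(m.points.copy(), t=m.t)
    tangent = m.points[1] - m.points[0]
    norm = np.hypot(*tangent)
    if norm == 0:
        raise InvalidInputError("degenerate first midline segment")
    new_first = m.points[0] - tangent / norm * length
    return Midline(np.vstack([new_first, m.points]), t=m.t)


def _resample_closed(coords: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a closed loop to ``n_points`` equally spaced in arc length."""
    closed = np.vstack([coords, coords[0]])
    seg = np.diff(closed, axis=0)
    cum = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    total = cum[-1]
    targets = np.linspace(0.0, total, n_points, endpoint=False)
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    return np.column_stack([x, y])


def _smooth_closed(coords: np.ndarray, span: int) -> np.ndarray:
    """Centered moving average along a closed loop, x and y separately."""
    if span <= 1:
        return coords
    if span % 2 == 0:
        raise InvalidInputError("smoothing span must be odd")
    kernel = np.ones(span) / span
    half = span // 2
    out = np.empty_like(coords)
    for k in range(2):
        padded = np.concatenate([coords[-half:, k], coords[:, k], coords[:half, k]])
        out[:, k] = np.convolve(padded, kernel, mode="valid")
    return out


def _loop_normals(coords: np.ndarray) -> np.ndarray:
    """Outward unit normals of a CCW closed loop via central-difference tangents."""
    tangent = np.roll(coords, -1, axis=0) - np.roll(coords, 1, axis=0)
    tnorm = np.hypot(tangent[:, 0], tangent[:, 1])
    tangent /= tnorm[:, None]
    # CCW traversal: outward normal is tangent rotated -90 degrees
    return np.column_stack([tangent[:, 1], -tangent[:, 0]])


def _orient_outward(coords: np.ndarray, normals: np.ndarray, m: Midline) -> np.ndarray:
    """Flip any normal pointing toward its nearest midline point."""
    d = coords[:, None, :] - m.points[None, :, :]
    idx = np.argmin(np.einsum("ijk,ijk->ij", d, d), axis=1)
    away = coords - m.points[idx]
    flip = np.einsum("ij,ij->i", normals, away) < 0
    normals = normals.copy()
    normals[flip] *= -1.0
    return normals


def offset_boundary(
    m: Midline,
    halfwidth: float,
    n_points: int = 200,
    smooth_span: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Closed loop at distance ``halfwidth`` from the midline, with normals.

    The midline is dilated by a disk of radius ``halfwidth`` (exact geometric
    buffering), the resulting boundary resampled to ``n_points`` at equal arc
    spacing, then smoothed with a centered moving average of ``smooth_span``
    points (circular wrap).  Normals are recomputed after smoothing and point
    away from the nearest midline point.

    Returns
    -------
    (points, normals) : two ``(n_points, 2)`` arrays; the loop is traversed
    counter-clockwise and the closing vertex is not repeated.
    """
    if halfwidth <= 0:
        raise InvalidInputError("halfwidth must be > 0")
    if n_points < 16:
        raise InvalidInputError("n_points must be >= 16")
    buffered = LineString(m.points).buffer(halfwidth, quad_segs=32)
    if not isinstance(buffered, Polygon):  # pragma: no cover - defensive
        buffered = max(buffered.geoms, key=lambda g: g.area)
    ring = orient(buffered, sign=1.0).exterior  # CCW
    coords = np.asarray(ring.coords)[:-1]
    loop = _resample_closed(coords, n_points)
    loop = _smooth_closed(loop, smooth_span)
    # smoothing compresses spacing at high-curvature caps; restore equal
    # arc-length spacing without altering the smoothed shape
    loop = _resample_closed(loop, n_points)
    normals = _loop_normals(loop)
    normals = _orient_outward(loop, normals, m)
    return loop, normals


def offset_boundary_raster(
    m: Midline,
    halfwidth: float,
    n_points: int = 200,
    smooth_span: int = 5,
    cell: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Raster pathway for :func:`offset_boundary` (cross-check).

    Rasterizes the midline onto a fine grid, applies binary disk dilation and
    traces the black-white boundary with marching squares; agrees with the
    geometric pathway to within the raster cell size.
    """
    from skimage import measure, morphology

    if halfwidth <= 0:
        raise InvalidInputError("halfwidth must be > 0")
    if cell is None:
        cell = halfwidth / 10.0
    if halfwidth < cell:
        raise InvalidInputError(
            f"halfwidth {halfwidth} smaller than raster cell {cell}; use a finer raster"
        )
    pad = 2.0 * halfwidth
    xmin, ymin = m.points.min(axis=0) - pad
    xmax, ymax = m.points.max(axis=0) + pad
    nxp = int(np.ceil((xmax - xmin) / cell)) + 1
    nyp = int(np.ceil((ymax - ymin) / cell)) + 1
    img = np.zeros((nyp, nxp), dtype=bool)
    # draw the midline densely sampled onto pixels
    arc = m.arc_positions
    dense_s = np.linspace(0.0, arc[-1], max(4 * max(nxp, nyp), 64))
    px = np.interp(dense_s, arc, m.points[:, 0])
    py = np.interp(dense_s, arc, m.points[:, 1])
    ii = np.clip(np.round((py - ymin) / cell).astype(int), 0, nyp - 1)
    jj = np.clip(np.round((px - xmin) / cell).astype(int), 0, nxp - 1)
    img[ii, jj] = True
    radius = int(round(halfwidth / cell))
    dilated = morphology.dilation(img, morphology.disk(radius))
    contours = measure.find_contours(dilated.astype(float), 0.5)
    contour = max(contours, key=len)  # rows, cols
    coords = np.column_stack(
        [xmin + contour[:, 1] * cell, ymin + contour[:, 0] * cell]
    )
    if Polygon(coords).exterior.is_ccw is False:
        coords = coords[::-1]
    loop = _resample_closed(coords[:-1], n_points)
    loop = _smooth_closed(loop, smooth_span)
    loop = _resample_closed(loop, n_points)
    normals = _orient_outward(loop, _loop_normals(loop), m)
    return loop, normals


def _surface_from_loop(
    loop: np.ndarray,
    normals: np.ndarray,
    m: Midline,
    span_profile: SpanProfile,
    r0: Sequence[float] | None,
) -> ControlSurface:
    dl = np.hypot(*(np.roll(loop, -1, axis=0) - loop).T)
    # span evaluated at the nearest midline arc position of each loop point
    d = loop[:, None, :] - m.points[None, :, :]
    idx = np.argmin(np.einsum("ijk,ijk->ij", d, d), axis=1)
    span = span_profile(m.arc_positions[idx])
    ref = m.leading_edge if r0 is None else np.asarray(r0, dtype=float)
    return ControlSurface(loop, normals, dl, span, ref)


def boundary_pair(
    m: Midline,
    chord: float,
    Re: float,
    span_profile: SpanProfile | None = None,
    mask_factor: float = 1.1,
    surface_factor: float = 1.64,
    n_points: int = 200,
) -> tuple[BodyMask, ControlSurface]:
    """Body mask and control surface at boundary-layer-scaled halfwidths.

    The mask sits at ``mask_factor * delta99(chord, Re)`` from the midline
    and the control surface at ``surface_factor * delta99``; the surface
    strictly encloses the mask.
    """
    if mask_factor <= 0 or surface_factor <= mask_factor:
        raise InvalidInputError("need surface_factor > mask_factor > 0")
    d99 = delta99(chord, Re)
    if d99 <= 0:
        raise InvalidInputError("delta99 must be > 0 (zero chord?)")
    if span_profile is None:
        span_profile = SpanProfile.constant(chord)
    mask_loop, _ = offset_boundary(m, mask_factor * d99, n_points=n_points)
    surf_loop, surf_normals = offset_boundary(m, surface_factor * d99, n_points=n_points)
    mask = BodyMask(mask_loop)
    surface = _surface_from_loop(surf_loop, surf_normals, m, span_profile, None)
    return mask, surface


def surface_sweep(
    m: Midline,
    chord: float,
    Re: float,
    factors: Sequence[float],
    span_profile: SpanProfile | None = None,
    n_points: int = 200,
) -> list[ControlSurface]:
    """One control surface per delta99 multiple; loops are nested ascending."""
    factors = list(factors)
    if any(b <= a for a, b in zip(factors, factors[1:])):
        raise InvalidInputError("factors must be sorted ascending")
    if span_profile is None:
        span_profile = SpanProfile.constant(chord)
    d99 = delta99(chord, Re)
    out = []
    for f in factors:
        loop, normals = offset_boundary(m, f * d99, n_points=n_points)
        out.append(_surface_from_loop(loop, normals, m, span_profile, None))
    return out


def detect_midline(
    image: np.ndarray, threshold: float, pixel_size: float = 1.0, t: float = 0.0
) -> Midline:
    """Detect a bright horizontal body as a per-column intensity centroid.

    For each image column containing above-threshold pixels, the midline row
    is the intensity-weighted centroid of those pixels; columns without
    signal inside the body extent are filled by linear interpolation.
    Coordinates are scaled by ``pixel_size`` (m per pixel).
    """
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise InvalidInputError("image is empty")
    above = image >= threshold
    cols = np.where(above.any(axis=0))[0]
    if cols.size == 0:
        raise DetectionFailureError("no pixel above threshold")
    rows = np.arange(image.shape[0], dtype=float)
    centroids = np.full(image.shape[1], np.nan)
    for j in cols:
        w = np.where(above[:, j], image[:, j], 0.0)
        centroids[j] = np.dot(rows, w) / w.sum()
    j0, j1 = cols[0], cols[-1]
    span_cols = np.arange(j0, j1 + 1)
    filled = np.interp(span_cols, cols, centroids[cols])
    pts = np.column_stack([span_cols * pixel_size, filled * pixel_size])
    return Midline(pts, t=t)
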