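"""On-disk dialects, run configuration and the end-to-end pipeline.

All text outputs are CSV with ``#``-prefixed comment headers that embed the
package version and the configuration hash; floats are written in scientific
notation with 9 significant digits so identical runs are byte-identical.

Formats
-------
velocity frame   x,y,u,v[,valid] — one row per node of a complete regular
                 grid, SI units declared in the header.
manifest (JSON)  {"dt": ..., "frames": [paths...]} ordering the frames.
pressure frame   x,y,p,defined.
loop             index,x,y,nx,ny,dl,span (+ reference point in the header).
midline          t,index,x,y (several frames per file, grouped by t).
load series      t,Fx,Fy,Tz,Fx_star,Fy_star,Tz_star,theta,provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .body_geometry import BodyMask, ControlSurface, Midline, SpanProfile, boundary_pair
from .exceptions import ConfigError, FormatError, InvalidInputError
from .grids import FluidProperties, GridSpec, PressureFrame, VelocityFrame, VelocitySequence
from .loads import LoadRecord, LoadSeries, NondimScale, load_series
from .pressure_field import pressure_sequence
from .signal_metrics import compare_traces
from .synthetic_flows import KinematicsProgram, make_plate_scene, make_uniform_flow

__all__ = [
    "FLOAT_FMT",
    "RunConfig",
    "write_velocity_frame",
    "read_velocity_frame",
    "write_velocity_sequence",
    "read_velocity_sequence",
    "write_velocity_sequence_h5",
    "read_velocity_sequence_h5",
    "write_pressure_frame",
    "read_pressure_frame",
    "write_loop",
    "read_loop",
    "write_midlines",
    "read_midlines",
    "write_load_series",
    "read_load_series",
    "run_pipeline",
]

log = logging.getLogger(__name__)

FLOAT_FMT = "%.9e"

_UNITS_LINE = "# units: x=m y=m u=m/s v=m/s p=Pa F=N T=N*m t=s"


def _fmt(x: float) -> str:
    return FLOAT_FMT % x


def _header(config_hash: str | None) -> list[str]:
    tag = config_hash if config_hash else "none"
    return [f"# pivload v{__version__} config={tag}", _UNITS_LINE]


def _read_table(path: Path, required: Sequence[str]) -> pd.DataFrame:
    lines = path.read_text().splitlines()
    units_seen = any(line.startswith("# units:") for line in lines if line.startswith("#"))
    if not units_seen:
        raise FormatError(f"{path}: missing '# units:' header line")
    body = [ln for ln in lines if not ln.startswith("#")]
    from io import StringIO

    try:
        df = pd.read_csv(StringIO("\n".join(body)))
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: {exc}") from exc
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    for col in required:
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad) and col not in ("valid", "defined"):
            raise FormatError(f"{path}: malformed value in column {col!r}, row {bad[0] + 2}")
    return df


def _grid_from_xy(x: np.ndarray, y: np.ndarray, path: Path) -> GridSpec:
    ux = np.unique(x)
    uy = np.unique(y)
    if ux.size * uy.size != x.size:
        raise FormatError(f"{path}: node set is not a complete regular grid (ragged)")
    dxs = np.diff(ux)
    dys = np.diff(uy)
    if not (np.allclose(dxs, dxs[0], rtol=1e-6) and np.allclose(dys, dys[0], rtol=1e-6)):
        raise FormatError(f"{path}: node spacing is not uniform")
    return GridSpec(
        x0=float(ux[0]), y0=float(uy[0]), dx=float(dxs[0]), dy=float(dys[0]),
        nx=ux.size, ny=uy.size,
    )


def write_velocity_frame(
    frame: VelocityFrame, path: str | Path, config_hash: str | None = None
) -> None:
    path = Path(path)
    X, Y = frame.grid.meshgrid()
    rows = ["x,y,u,v,valid"]
    for xi, yi, ui, vi, ok in zip(
        X.ravel(), Y.ravel(), frame.u.ravel(), frame.v.ravel(), frame.valid.ravel()
    ):
        rows.append(f"{_fmt(xi)},{_fmt(yi)},{_fmt(ui)},{_fmt(vi)},{int(ok)}")
    path.write_text("\n".join(_header(config_hash) + [f"# t={_fmt(frame.t)}"] + rows) + "\n")


def read_velocity_frame(path: str | Path, t: float | None = None) -> VelocityFrame:
    path = Path(path)
    df = _read_table(path, ["x", "y", "u", "v"])
    if t is None:
        t = 0.0
        for line in path.read_text().splitlines():
            if line.startswith("# t="):
                t = float(line[4:])
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    grid = _grid_from_xy(x, y, path)
    order = np.lexsort((x, y))
    shape = grid.shape
    u = df["u"].to_numpy(float)[order].reshape(shape)
    v = df["v"].to_numpy(float)[order].reshape(shape)
    if "valid" in df.columns:
        valid = df["valid"].to_numpy()[order].astype(bool).reshape(shape)
    else:
        valid = np.ones(shape, dtype=bool)
    return VelocityFrame(grid=grid, u=u, v=v, t=float(t), valid=valid)


def write_velocity_sequence(
    seq: VelocitySequence, directory: str | Path, config_hash: str | None = None
) -> Path:
    """Write one CSV per frame plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = []
    for k, frame in enumerate(seq.frames):
        name = f"frame_{k:04d}.csv"
        write_velocity_frame(frame, directory / name, config_hash)
        names.append(name)
    manifest = directory / "manifest.json"
    manifest.write_text(
        json.dumps({"dt": seq.dt, "t0": float(seq.frames[0].t), "frames": names}, indent=1)
    )
    return manifest


def read_velocity_sequence(manifest_path: str | Path) -> VelocitySequence:
    manifest_path = Path(manifest_path)
    meta = json.loads(manifest_path.read_text())
    for key in ("dt", "frames"):
        if key not in meta:
            raise FormatError(f"{manifest_path}: manifest missing {key!r}")
    t0 = float(meta.get("t0", 0.0))
    dt = float(meta["dt"])
    frames = []
    for k, name in enumerate(meta["frames"]):
        fpath = manifest_path.parent / name
        if not fpath.exists():
            raise FormatError(f"{manifest_path}: missing frame index {k} ({name})")
        frames.append(read_velocity_frame(fpath, t=t0 + k * dt))
    return VelocitySequence(frames=frames, dt=dt)


def write_velocity_sequence_h5(seq: VelocitySequence, path: str | Path) -> None:
    """Binary container variant of the velocity sequence (HDF5)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["version"] = __version__
        f.attrs["dt"] = seq.dt
        f.attrs["t0"] = float(seq.frames[0].t)
        g = seq.grid
        for k in ("x0", "y0", "dx", "dy", "nx", "ny"):
            f.attrs[k] = getattr(g, k)
        f.create_dataset("u", data=np.stack([fr.u for fr in seq.frames]))
        f.create_dataset("v", data=np.stack([fr.v for fr in seq.frames]))
        f.create_dataset("valid", data=np.stack([fr.valid for fr in seq.frames]))


def read_velocity_sequence_h5(path: str | Path) -> VelocitySequence:
    import h5py

    with h5py.File(path, "r") as f:
        grid = GridSpec(
            x0=float(f.attrs["x0"]), y0=float(f.attrs["y0"]),
            dx=float(f.attrs["dx"]), dy=float(f.attrs["dy"]),
            nx=int(f.attrs["nx"]), ny=int(f.attrs["ny"]),
        )
        dt = float(f.attrs["dt"])
        t0 = float(f.attrs["t0"])
        u = f["u"][...]
        v = f["v"][...]
        valid = f["valid"][...].astype(bool)
    frames = [
        VelocityFrame(grid=grid, u=u[k], v=v[k], valid=valid[k], t=t0 + k * dt)
        for k in range(u.shape[0])
    ]
    return VelocitySequence(frames=frames, dt=dt)


def write_pressure_frame(
    frame: PressureFrame, path: str | Path, config_hash: str | None = None
) -> None:
    path = Path(path)
    X, Y = frame.grid.meshgrid()
    rows = ["x,y,p,defined"]
    for xi, yi, pi, ok in zip(
        X.ravel(), Y.ravel(), frame.p.ravel(), frame.defined.ravel()
    ):
        val = _fmt(pi) if ok else "nan"
        rows.append(f"{_fmt(xi)},{_fmt(yi)},{val},{int(ok)}")
    path.write_text("\n".join(_header(config_hash) + [f"# t={_fmt(frame.t)}"] + rows) + "\n")


def read_pressure_frame(path: str | Path) -> PressureFrame:
    path = Path(path)
    df = _read_table(path, ["x", "y"])
    if "p" not in df.columns:
        raise FormatError(f"{path}: missing column 'p'")
    t = 0.0
    for line in path.read_text().splitlines():
        if line.startswith("# t="):
            t = float(line[4:])
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)
    grid = _grid_from_xy(x, y, path)
    order = np.lexsort((x, y))
    p = pd.to_numeric(df["p"], errors="coerce").to_numpy(float)[order].reshape(grid.shape)
    if "defined" in df.columns:
        defined = df["defined"].to_numpy()[order].astype(bool).reshape(grid.shape)
    else:
        defined = np.isfinite(p)
    return PressureFrame(grid=grid, p=p, defined=defined, t=t)


def write_loop(
    surface: ControlSurface, path: str | Path, config_hash: str | None = None
) -> None:
    path = Path(path)
    rows = ["index,x,y,nx,ny,dl,span"]
    for i in range(surface.n_points):
        rows.append(
            ",".join(
                [str(i)]
                + [
                    _fmt(v)
                    for v in (
                        surface.points[i, 0], surface.points[i, 1],
                        surface.normals[i, 0], surface.normals[i, 1],
                        surface.dl[i], surface.span[i],
                    )
                ]
            )
        )
    ref = f"# r0={_fmt(surface.r0[0])},{_fmt(surface.r0[1])}"
    path.write_text("\n".join(_header(config_hash) + [ref] + rows) + "\n")


def read_loop(path: str | Path) -> ControlSurface:
    path = Path(path)
    df = _read_table(path, ["x", "y", "nx", "ny", "dl", "span"])
    r0 = np.zeros(2)
    for line in path.read_text().splitlines():
        if line.startswith("# r0="):
            r0 = np.array([float(v) for v in line[5:].split(",")])
    return ControlSurface(
        points=df[["x", "y"]].to_numpy(float),
        normals=df[["nx", "ny"]].to_numpy(float),
        dl=df["dl"].to_numpy(float),
        span=df["span"].to_numpy(float),
        r0=r0,
    )


def write_midlines(
    midlines: Sequence[Midline], path: str | Path, config_hash: str | None = None
) -> None:
    path = Path(path)
    rows = ["t,index,x,y"]
    for m in midlines:
        for i, (x, y) in enumerate(m.points):
            rows.append(f"{_fmt(m.t)},{i},{_fmt(x)},{_fmt(y)}")
    path.write_text("\n".join(_header(config_hash) + rows) + "\n")


def read_midlines(path: str | Path) -> list[Midline]:
    path = Path(path)
    df = _read_table(path, ["t", "x", "y"])
    out = []
    for t, group in df.groupby("t", sort=True):
        group = group.sort_values("index") if "index" in group.columns else group
        out.append(Midline(group[["x", "y"]].to_numpy(float), t=float(t)))
    return out


def write_load_series(
    series: LoadSeries, path: str | Path, config_hash: str | None = None
) -> None:
    path = Path(path)
    rows = ["t,Fx,Fy,Tz,Fx_star,Fy_star,Tz_star,theta,provenance"]
    for r in series.records:
        opt = [
            "" if v is None else _fmt(v)
            for v in (r.Fx_star, r.Fy_star, r.Tz_star, r.theta)
        ]
        rows.append(
            ",".join([_fmt(r.t), _fmt(r.Fx), _fmt(r.Fy), _fmt(r.Tz)] + opt + [series.provenance])
        )
    extra = []
    if series.cycle_period is not None:
        extra.append(f"# cycle_period={_fmt(series.cycle_period)}")
    path.write_text("\n".join(_header(config_hash) + extra + rows) + "\n")


def read_load_series(path: str | Path) -> LoadSeries:
    path = Path(path)
    df = _read_table(path, ["t", "Fx", "Fy", "Tz"])
    period = None
    for line in path.read_text().splitlines():
        if line.startswith("# cycle_period="):
            period = float(line.split("=", 1)[1])
    records = []
    for idx, row in df.iterrows():
        try:
            rec = LoadRecord(
                t=float(row["t"]), Fx=float(row["Fx"]), Fy=float(row["Fy"]),
                Tz=float(row["Tz"]),
                theta=None if pd.isna(row.get("theta")) else float(row["theta"]),
                Fx_star=None if pd.isna(row.get("Fx_star")) else float(row["Fx_star"]),
                Fy_star=None if pd.isna(row.get("Fy_star")) else float(row["Fy_star"]),
                Tz_star=None if pd.isna(row.get("Tz_star")) else float(row["Tz_star"]),
            )
        except (TypeError, ValueError, InvalidInputError) as exc:
            raise FormatError(f"{path}: malformed row {idx + 2}: {exc}") from exc
        records.append(rec)
    provenance = str(df["provenance"].iloc[0]) if "provenance" in df.columns and len(df) else "estimated"
    return LoadSeries(records=records, cycle_period=period, provenance=provenance)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


def _require(d: dict, keys: Sequence[str], section: str) -> None:
    for key in keys:
        if key not in d:
            raise ConfigError(f"config section {section!r} missing required key {key!r}")


def _reject_unknown(d: dict, allowed: Sequence[str], section: str) -> None:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in config section {section!r}")


@dataclass
class RunConfig:
    """Validated pipeline configuration (strict: unknown keys rejected)."""

    fluid: FluidProperties
    chord: float
    span: float
    Re: float | None
    mask_factor: float
    surface_factor: float
    n_points: int
    dt_calc: float
    directions: int
    viscous: bool
    out_dir: Path
    seed: int | None
    synth: dict | None
    inputs: dict | None
    raw: dict = field(repr=False, default_factory=dict)

    @classmethod
    def from_dict(cls, cfg: dict) -> "RunConfig":
        _reject_unknown(
            cfg, ["fluid", "geometry", "solver", "output", "seed", "synth", "inputs"], "<root>"
        )
        _require(cfg, ["fluid", "geometry", "output"], "<root>")
        fl = cfg["fluid"]
        _reject_unknown(fl, ["rho", "nu"], "fluid")
        _require(fl, ["rho", "nu"], "fluid")
        fluid = FluidProperties(rho=float(fl["rho"]), nu=float(fl["nu"]))

        geo = cfg["geometry"]
        _reject_unknown(
            geo, ["chord", "span", "Re", "mask_factor", "surface_factor", "n_points"], "geometry"
        )
        _require(geo, ["chord", "span"], "geometry")

        sol = cfg.get("solver", {})
        _reject_unknown(sol, ["dt_calc", "directions", "viscous"], "solver")

        out = cfg["output"]
        _reject_unknown(out, ["dir"], "output")
        _require(out, ["dir"], "output")

        synth = cfg.get("synth")
        if synth is not None:
            _reject_unknown(
                synth,
                [
                    "scene", "program", "heave_amplitude", "frequency", "flow_speed",
                    "n_frames", "dt", "pressure_law", "grid", "noise_sd",
                ],
                "synth",
            )
            _require(synth, ["scene", "grid"], "synth")
            _reject_unknown(synth["grid"], ["x0", "y0", "dx", "dy", "nx", "ny"], "synth.grid")
            if float(synth.get("noise_sd", 0.0)) > 0 and cfg.get("seed") is None:
                raise ConfigError("a seed is mandatory when synth.noise_sd > 0")

        inputs = cfg.get("inputs")
        if inputs is not None:
            _reject_unknown(
                inputs, ["velocity_manifest", "midlines", "reference_loads", "period"], "inputs"
            )
            _require(inputs, ["velocity_manifest", "midlines"], "inputs")
        if synth is None and inputs is None:
            raise ConfigError("config must provide either 'synth' or 'inputs'")

        return cls(
            fluid=fluid,
            chord=float(geo["chord"]),
            span=float(geo["span"]),
            Re=None if geo.get("Re") is None else float(geo["Re"]),
            mask_factor=float(geo.get("mask_factor", 1.1)),
            surface_factor=float(geo.get("surface_factor", 1.64)),
            n_points=int(geo.get("n_points", 200)),
            dt_calc=float(sol.get("dt_calc", 0.01)),
            directions=int(sol.get("directions", 8)),
            viscous=bool(sol.get("viscous", True)),
            out_dir=Path(out["dir"]),
            seed=None if cfg.get("seed") is None else int(cfg["seed"]),
            synth=synth,
            inputs=inputs,
            raw=cfg,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        cfg = yaml.safe_load(Path(path).read_text())
        if not isinstance(cfg, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(cfg)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _grid_from_cfg(g: dict) -> GridSpec:
    return GridSpec(
        x0=float(g["x0"]), y0=float(g["y0"]), dx=float(g["dx"]), dy=float(g["dy"]),
        nx=int(g["nx"]), ny=int(g["ny"]),
    )


def _compare_series(
    measured: LoadSeries, estimated: LoadSeries, period: float
) -> dict[str, dict]:
    """Component-wise comparison reports; constant reference traces skipped."""
    fs = 1.0 / float(np.diff(estimated.t)[0])
    n = min(len(measured), len(estimated))
    reports: dict[str, dict] = {}
    for comp in ("Fx", "Fy", "Tz"):
        M = measured.column(comp)[:n]
        C = estimated.column(comp)[:n]
        scaleM = np.max(np.abs(M)) if np.max(np.abs(M)) > 0 else 1.0
        scaleC = np.max(np.abs(C)) if np.max(np.abs(C)) > 0 else 1.0
        if np.ptp(M) <= 1e-3 * scaleM or np.ptp(C) <= 1e-3 * scaleC:
            log.info("compare: %s trace (near-)constant; skipped", comp)
            continue
        try:
            reports[comp] = compare_traces(M, C, period, fs).to_dict()
        except InvalidInputError as exc:
            log.info("compare: %s skipped (%s)", comp, exc)
    return reports


def run_pipeline(config: RunConfig | dict) -> dict[str, Any]:
    """Execute the full chain and write artifacts under ``config.output.dir``.

    Stages: obtain velocity + midlines (synthetic scene or files), build
    masks/control surfaces, reconstruct pressure (unless the scene
    prescribes it), integrate loads, and compare against a reference load
    series when one is available.  Returns a summary dict (also written as
    ``summary.json``).
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig.from_dict(config)
    chash = cfg.config_hash
    outdir = cfg.out_dir
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict[str, Any] = {"config_hash": chash, "version": __version__, "stages": {}}

    scale = None
    reference: LoadSeries | None = None
    period = None

    if cfg.synth is not None:
        scene_kind = cfg.synth["scene"]
        grid = _grid_from_cfg(cfg.synth["grid"])
        if scene_kind == "plate":
            kin = KinematicsProgram(
                program=cfg.synth.get("program", "zero_aoa"),
                heave_amplitude=float(cfg.synth.get("heave_amplitude", 0.015)),
                frequency=float(cfg.synth.get("frequency", 1.5)),
                flow_speed=float(cfg.synth.get("flow_speed", 0.3)),
                chord=cfg.chord,
            )
            scene = make_plate_scene(
                kin,
                grid,
                cfg.fluid,
                pressure_law=cfg.synth.get("pressure_law", "linear-in-x"),
                n_frames=int(cfg.synth.get("n_frames", 200)),
                dt=float(cfg.synth.get("dt", 0.01)),
                span=cfg.span,
                surface_factor=cfg.surface_factor,
                n_surface_points=cfg.n_points,
                noise_sd=float(cfg.synth.get("noise_sd", 0.0)),
                seed=cfg.seed,
            )
            pressures = scene.pressures
            surfaces = scene.surfaces
            midlines = scene.midlines
            thetas = scene.thetas
            reference = scene.analytic
            period = kin.period
            scale = NondimScale(
                rho=cfg.fluid.rho, span=cfg.span, chord=cfg.chord, speed=kin.flow_speed
            )
            write_velocity_sequence(scene.velocity, outdir / "velocity", chash)
            summary["stages"]["synth"] = {
                "scene": "plate", "frames": len(scene.velocity), "Re": scene.Re,
            }
        elif scene_kind == "uniform":
            speed = float(cfg.synth.get("flow_speed", 0.3))
            n_frames = int(cfg.synth.get("n_frames", 5))
            dt = float(cfg.synth.get("dt", cfg.dt_calc))
            frames = [
                make_uniform_flow(grid, (speed, 0.0), cfg.fluid, t=k * dt)[0]
                for k in range(n_frames)
            ]
            seq = VelocitySequence(frames=frames, dt=dt)
            write_velocity_sequence(seq, outdir / "velocity", chash)
            pressures = pressure_sequence(
                seq, masks=None, fluid=cfg.fluid, dt_calc=cfg.dt_calc,
                n_directions=cfg.directions, viscous=cfg.viscous,
            )
            # no body: integrate over a fixed centered straight chord
            mid = Midline(
                np.array([[grid.x0 + 2 * grid.dx, 0.0], [grid.x0 + 2 * grid.dx + cfg.chord, 0.0]])
            )
            Re = cfg.Re if cfg.Re is not None else speed * cfg.chord / max(cfg.fluid.nu, 1e-12)
            _, surf = boundary_pair(
                mid, cfg.chord, Re,
                span_profile=SpanProfile.constant(cfg.span),
                mask_factor=cfg.mask_factor, surface_factor=cfg.surface_factor,
                n_points=cfg.n_points,
            )
            surfaces = [surf] * len(pressures)
            midlines = [mid] * len(pressures)
            thetas = [0.0] * len(pressures)
            scale = NondimScale(rho=cfg.fluid.rho, span=cfg.span, chord=cfg.chord, speed=speed)
            summary["stages"]["synth"] = {"scene": "uniform", "frames": n_frames}
        else:
            raise ConfigError(f"unknown synth scene {scene_kind!r}")
    else:
        assert cfg.inputs is not None
        seq = read_velocity_sequence(cfg.inputs["velocity_manifest"])
        midlines_all = read_midlines(cfg.inputs["midlines"])
        if len(midlines_all) != len(seq):
            raise ConfigError(
                f"{len(midlines_all)} midlines for {len(seq)} velocity frames"
            )
        Re = cfg.Re
        if Re is None:
            raise ConfigError("geometry.Re is required for file inputs")
        span_profile = SpanProfile.constant(cfg.span)
        masks: list[BodyMask] = []
        surfaces_all: list[ControlSurface] = []
        for m in midlines_all:
            mask, surf = boundary_pair(
                m, cfg.chord, Re, span_profile=span_profile,
                mask_factor=cfg.mask_factor, surface_factor=cfg.surface_factor,
                n_points=cfg.n_points,
            )
            masks.append(mask)
            surfaces_all.append(surf)
        pressures = pressure_sequence(
            seq, masks=masks, fluid=cfg.fluid, dt_calc=cfg.dt_calc,
            n_directions=cfg.directions, viscous=cfg.viscous,
        )
        step = int(round(cfg.dt_calc / seq.dt))
        keep = list(range(0, len(seq), step))
        surfaces = [surfaces_all[k] for k in keep]
        midlines = [midlines_all[k] for k in keep]
        thetas = [0.0] * len(pressures)
        speed = float(np.nanmean([np.nanmean(f.u[f.valid]) for f in seq.frames]))
        scale = NondimScale(
            rho=cfg.fluid.rho, span=cfg.span, chord=cfg.chord, speed=max(abs(speed), 1e-9)
        )
        if cfg.inputs.get("reference_loads"):
            reference = read_load_series(cfg.inputs["reference_loads"])
            period = cfg.inputs.get("period", reference.cycle_period)
        summary["stages"]["read"] = {"frames": len(seq)}

    # write geometry + pressure artifacts
    geo_dir = outdir / "geometry"
    prs_dir = outdir / "pressure"
    geo_dir.mkdir(exist_ok=True)
    prs_dir.mkdir(exist_ok=True)
    for k, (pf, surf, mid) in enumerate(zip(pressures, surfaces, midlines)):
        write_pressure_frame(pf, prs_dir / f"pressure_{k:04d}.csv", chash)
        write_loop(surf, geo_dir / f"surface_{k:04d}.csv", chash)
    write_midlines(midlines, geo_dir / "midlines.csv", chash)
    summary["stages"]["pressure"] = {
        "frames": len(pressures),
        "masked_nodes": int(sum((~pf.defined).sum() for pf in pressures)),
    }

    series = load_series(
        pressures, surfaces, scale=scale, thetas=thetas, cycle_period=period
    )
    write_load_series(series, outdir / "loads.csv", chash)
    summary["stages"]["loads"] = {"records": len(series), "provenance": series.provenance}

    if reference is not None and period is not None:
        write_load_series(reference, outdir / "reference_loads.csv", chash)
        reports = _compare_series(reference, series, float(period))
        (outdir / "comparison.json").write_text(json.dumps(reports, indent=1))
        summary["stages"]["compare"] = reports
    else:
        summary["stages"]["compare"] = "skipped (no reference series)"

    (outdir / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    for stage, info in summary["stages"].items():
        log.info("stage %s: %s", stage, info)
    return summary
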