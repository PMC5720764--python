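# pivload

Non-invasive load estimation for fish-like swimmers from planar velocimetry:
reconstruct 2D gauge-pressure fields from time-resolved velocity fields,
build control surfaces around a deforming body midline, integrate pressure
into force/torque time series, and score agreement against reference traces.

## How it works

1. **`synthetic_flows`** — analytic velocity/pressure generators (uniform
   flow, solid-body rotation, decaying Taylor–Green vortex) and
   flapping-plate scenes under two motion programs (`heave`, `zero_aoa`)
   with prescribed pressure laws and divergence-theorem reference loads.
2. **`body_geometry`** — midline → body mask and control surface by
   dilating the midline by multiples of the boundary-layer thickness
   `δ99 = 5·c/√Re` (mask at 1.1 δ99, surface at 1.64 δ99 by default),
   resampled to 200 equally spaced points and smoothed with a 5-point
   circular moving average. Exact geometric buffering is the default
   pathway; a rasterize/dilate/trace pathway is kept as a cross-check.
3. **`pressure_field`** — evaluates the Navier–Stokes pressure gradient
   per node (viscous term retained by default) and line-integrates it from
   the domain edge inward along 8 evenly rotated straight-ray families.
   Each node keeps the **median** of its per-family estimates; paths never
   cross masked nodes (estimates beyond a blockage are discarded, not
   bridged). Gauge: zero median pressure on the outermost defined ring.
   Frames are subsampled to a calculation interval (default 0.01 s).
4. **`loads`** — bilinear pressure sampling on the control surface, then
   `F = −Σ p·n·Δl·s` and `Tz = −Σ p·[(r−r0)×n]_z·Δl·s` (torque reference
   defaults to the leading edge), plus nondimensionalization
   `F* = F/(ρ·s·c·v²)`, `T* = T/(ρ·s·c²·v²)`.
5. **`signal_metrics`** — force resolution by pitch angle, zero-phase
   dual-pass Butterworth filtering with the multi-pass cutoff correction
   (7 Hz desired → 8.73 Hz per pass at order 2, two passes), rod-trace
   subtraction, phase averaging, and the comparison suite: Pearson r with
   Fisher-z 95% CI, RMSE% (normalized by the estimated trace's range), and
   cross-correlation phase lag as a % of cycle period.
6. **`cli_io`** (`pivload.io`) — text formats (CSV + JSON manifest, plus an
   HDF5 container), strict YAML run configuration, and the full pipeline.

### Conventions

- SI units everywhere; pixel inputs need an explicit meters-per-pixel scale.
- Loads are exerted **by fluid on body**; +x points downstream, so thrust is
  negative Fx. Shear (viscous surface stress) loads are intentionally
  omitted — every estimated series is pressure-only.
- Positive pitch = leading edge rotated counter-clockwise (viewed from +z).
- Positive phase lag = estimated trace lags the measured trace.
- Seeds are mandatory for any stochastic generator option.

## CLI

```sh
# generate a flapping-plate fixture scene (velocity, pressure, midlines, oracle loads)
pivload synth --scene plate --program zero_aoa -f 1.5 -u 0.3 --chord 0.18 \
    --frames 200 --grid "-0.1,-0.2,0.00635,0.00635,64,64" --out scene/

# midlines -> masks + control surfaces
pivload geometry --midlines scene/midlines.csv --chord 0.18 --re 54000 \
    --span 0.05 --out geo/

# velocity sequence -> pressure frames
pivload pressure --manifest scene/velocity/manifest.json --dt-calc 0.01 --out prs/

# pressure + surfaces -> load series
pivload loads --pressure-dir scene/pressure --surface-dir geo/ \
    --span 0.05 --chord 0.18 --speed 0.3 --out loads.csv

# metric suite between two load series
pivload compare --measured scene/analytic_loads.csv --estimated loads.csv \
    --period 0.6667 --component Tz

# or the whole chain from a config file
pivload run config.yaml
```

Example `config.yaml`:

```yaml
fluid: {rho: 1000.0, nu: 1.0e-6}
geometry: {chord: 0.18, span: 0.05}
solver: {dt_calc: 0.01, directions: 8, viscous: true}
output: {dir: out}
synth:
  scene: plate
  program: zero_aoa
  heave_amplitude: 0.015
  frequency: 1.5
  flow_speed: 0.3
  n_frames: 200
  dt: 0.01
  pressure_law: linear-in-x
  grid: {x0: -0.1, y0: -0.2, dx: 0.00635, dy: 0.00635, nx: 64, ny: 64}
```

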