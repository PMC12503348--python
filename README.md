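# rhangio

Hybrid phase-field / agent-based simulator of retinal tumor growth and
tumor-induced angiogenesis.

A diffuse-interface capillary field evolving under split Cahn–Hilliard
dynamics is coupled to discrete chemotactic tip-cell agents and a
quasi-steady angiogenic-factor (AF) reaction–diffusion field, driven by a
prescribed, slowly growing tumor ellipsoid. The package also includes
adaptive implicit time stepping with activation-time bisection, a
bisection estimator of the minimal tumor size capable of triggering
sprouting, and reconstruction of a 3D initial capillary field from a
binary 2D vessel segmentation.

## Model summary

* **Units.** Everything internal runs in simulation units: `sau` (space,
  800 µm), `tau` (time, 26 min), `afau` (AF concentration, 6000 pg/mL).
  Physical quantities with explicit unit strings are converted at I/O
  boundaries (`rhangio.units`).
* **Tumor.** An ellipsoid indicator field with equal lateral semiaxes,
  growing 35 % in volume per year (`rhangio.geometry`).
* **AF field.** Quasi-steady linear elliptic balance with production in
  the avascular tumor, uptake inside vessels, degradation everywhere,
  zero-flux boundaries (`rhangio.af_solver`).
* **Capillaries.** Phase field `c` (≈ +1 vessel / −1 tissue) advanced by
  backward Euler on the split (c, µ) Cahn–Hilliard system with Newton
  iterations; mass is conserved exactly and the discrete free energy is
  dissipated (`rhangio.capillary`).
* **Tip cells.** Activation by concentration/gradient thresholds with
  Notch minimum-distance exclusion, speed-capped chemotactic motion, and
  a phase-field imprint carrying stalk-cell proliferation
  (`rhangio.tip_cells`).
* **Driver.** Deactivate → activate → velocities → imprint → move →
  capillary step; adaptive `dt` when no tips are active, with bisection
  for the earliest possible activation inside a large step
  (`rhangio.driver`).

## CLI

```sh
rhangio synth --size 800 --n-vessels 6 --seed 1 --out plexus.png
rhangio reconstruct plexus.png --h 7 --depth 200 --out initial_field.vtk
rhangio simulate --scenario 2d_sprouting --steps 100 --out run_out/
rhangio minimal-size --scenario 2d_sprouting --vpt 6,9,12.3 --vuc 50,300,1000 --out grid.csv
```

`simulate` writes legacy-VTK field snapshots (view the capillaries at the
`c = 0` isosurface and the tumor at `phi = 0.5`), a history CSV and a JSON
run record. `simulate --config run.yaml` accepts a YAML config with
`domain`, `tumor`, `vessels`, `parameters` and `run` sections.

## Layout

```
src/rhangio/
  units.py        unit system, parameter table, converters, loader
  geometry.py     domain/grid and tumor ellipsoid
  operators.py    Neumann Laplacian, quadrature weights, gradients
  af_solver.py    quasi-steady AF solve
  capillary.py    split Cahn–Hilliard stepper, energy/mass diagnostics
  tip_cells.py    agent layer
  driver.py       time loop, adaptive dt, minimal-size estimator
  vessel_init.py  synthetic plexus + 2D-mask → 2D/3D field reconstruction
  io_viz.py       VTK/CSV/JSON writers and readers
  fixtures.py     deterministic scenario registry
  cli.py          command-line interface
```
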