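# cpmsim

A scriptable 2D cellular Potts model (CPM) engine with Metropolis
copy-attempt dynamics, a modular Hamiltonian, process plugins, a
Game-of-Life mode, and declarative benchmark runners.

Cells are sets of lattice pixels sharing an integer identity (0 is the
background). Dynamics proceed by stochastic attempts to copy one pixel's
identity onto a neighboring pixel; an attempt with energy effect ΔH is
accepted with probability 1 when ΔH ≤ 0 and e^(−ΔH/T) otherwise. One Monte
Carlo Step (MCS) is width × height attempt resolutions followed by a
one-unit decay of every protrusion-activity value.

## Features

- **Lattice** (`cpmsim.lattice`) — toroidal or bounded axes (independently
  per axis), Moore / von Neumann neighborhood kernels, exact incremental
  per-cell volume and perimeter bookkeeping, plain-text grid dumps.
- **Energy** (`cpmsim.energy`) — adhesion matrix `J` over kind pairs,
  quadratic volume and perimeter constraints (per-cell target-volume
  overrides for proliferation), and the kinetic protrusion ("Act") term
  based on the geometric mean of decaying pixel activities. `total_H` is a
  global reference evaluation; `delta_H` is the exact local increment.
- **Dynamics** (`cpmsim.dynamics`) — target-then-source attempt sampling,
  Metropolis acceptance, per-MCS hooks, fully reproducible from a seed.
  The inner sweep runs through numba when available (the pure-Python
  fallback consumes identical pre-drawn randomness, so trajectories are
  bit-identical either way).
- **Processes** (`cpmsim.processes`) — circular seeding with optional
  burn-in growth, immutable disc obstacles, target-volume growth with
  centroid-line cell division (minor-axis or random orientation).
- **Game of Life** (`cpmsim.ca`) — synchronous Conway updates on the same
  grid geometry.
- **Stats** (`cpmsim.stats`) — torus-aware centroids (circular-mean
  unwrapping), heterotypic interface counts, connectivity checks, tidy CSV
  logging.
- **Experiments** (`cpmsim.experiments`) — versioned YAML presets for the
  four benchmarks (`game_of_life`, `cell_sorting`, `protrusion`,
  `cell_division`) plus the adaptive-grid scalability sweep
  (side = 1.5·√P_tot, seeding radius 0.8·√(P_tot/π), no drawing).
- **I/O** (`cpmsim.config`, `cpmsim.render`, `cpmsim.cli`) — schema-validated
  YAML/JSON configs (all violations reported at once), deterministic PNG
  frames (fill-by-kind, fill-by-cell, borders-only), run manifests.

## CLI

```sh
# run a packaged benchmark
cpmsim experiment cell_sorting --out runs/sorting --seed 1
cpmsim experiment game_of_life --out runs/gol

# run any config file
cpmsim run my_model.yaml --out runs/mine --seed 7 --mcs 500 --no-draw

# timed scalability sweep (images disabled)
cpmsim scalability --cells 1 --cells 10 --cells 100 --mcs 100 --out scal.csv
```

Each run writes PNG frames (`frame_<mcs>.png`, including MCS 0), CSV logs
(`cells.csv` with per-cell centroids/volumes, `summary.csv` with cell count
and heterotypic interface) and a `manifest.json` recording the full config,
seed, wall time and MCS/s, from which the run can be reproduced exactly.

A config file looks like:

```yaml
grid: {width: 100, height: 100}
kinds:
  - {name: cell}
hamiltonian:
  temperature: 20
  adhesion: {J: [[0, 20], [20, 0]]}
  volume: {lambda: [0, 50], target: [0, 500]}
processes:
  - {type: seed_disc, kind: 1, radius: 12.6}
schedule: {n_mcs: 1000, seed: 0}
outputs: {png_every: 100, log_every: 10}
```

Per-kind vectors include the background at index 0. See
`src/cpmsim/presets/*.yaml` for complete examples.

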