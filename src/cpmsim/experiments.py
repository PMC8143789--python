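"""Declarative benchmark runners and the scalability sweep.

Five named experiments ship with the package: ``game_of_life``,
``cell_sorting``, ``protrusion``, ``cell_division`` (versioned YAML presets
under ``cpmsim/presets/``) and ``scalability``. Energy parameters live only in
the preset files; changing them never requires code changes.
"""

from __future__ import annotations

import json
import math
import time
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ca import gol_random_init, gol_step
from .config import (
    GrowDivideConfig,
    ObstaclesConfig,
    SeedCircleConfig,
    SeedDiscConfig,
    SimulationConfig,
    dump_config,
    load_config,
    parse_config,
)
from .dynamics import Simulation
from .errors import ConfigurationError
from .lattice import GridSpec, LatticeState, make_disc_cell
from .processes import (
    DivisionRule,
    GrowthDivision,
    ObstacleSpec,
    SeedingPlan,
    place_obstacles,
    seed_cells_in_circle,
)
from .render import FrameWriter, render_ca_frame
from .stats import StatsLogger

EXPERIMENT_NAMES = ("game_of_life", "protrusion", "cell_sorting", "cell_division", "scalability")
DEFAULT_SCALABILITY_CELLS = (1, 5, 10, 50, 100, 500, 1000)


def preset_config(name: str) -> SimulationConfig:
    """Load one of the packaged benchmark configurations."""
    ref = resources.files("cpmsim").joinpath(f"presets/{name}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError:
        raise ConfigurationError(f"no preset named {name!r}") from None
    import yaml

    return parse_config(yaml.safe_load(text))


def build_simulation(
    config: SimulationConfig, seed: int | None = None, no_draw: bool = False, out_dir=None
) -> tuple[Simulation, StatsLogger | None, FrameWriter | None]:
    """Construct state, Hamiltonian, processes and logging hooks from a config.

    Initial processes (seeding, obstacles) are applied in their declared
    order; per-MCS processes are registered as hooks. Burn-in MCS requested by
    seeding plans run here and do not count toward the schedule.
    """
    if seed is None:
        seed = config.schedule.seed
    rng = np.random.default_rng(seed)
    state = LatticeState(
        config.grid_spec(),
        n_kinds=config.n_kinds,
        kernel=config.neighborhood(),
        immutable_kinds=config.immutable_kinds(),
    )
    ham = config.to_hamiltonian()
    sim = Simulation(state, ham, rng)
    for proc in config.processes:
        if isinstance(proc, SeedCircleConfig):
            plan = SeedingPlan(
                n_cells_per_kind=dict(proc.counts),
                region_center=proc.center,
                region_radius=proc.radius,
                burn_in_mcs=proc.burn_in,
            )
            seed_cells_in_circle(state, plan, rng, hamiltonian=ham)
        elif isinstance(proc, SeedDiscConfig):
            center = proc.center
            if center is None:
                mx, my = state.spec.midpoint()
                center = (int(round(mx)), int(round(my)))
            cid = state.register_cell(proc.kind)
            make_disc_cell(state, center, proc.radius, cid)
        elif isinstance(proc, ObstaclesConfig):
            place_obstacles(
                state, ObstacleSpec(centers=list(proc.centers), radius=proc.radius, kind=proc.kind)
            )
        elif isinstance(proc, GrowDivideConfig):
            rule = DivisionRule(
                growth_rate=proc.growth_rate,
                division_volume=proc.division_volume,
                axis_mode=proc.axis_mode,
                kinds=tuple(proc.kinds),
            )
            sim.add_hook(GrowthDivision(rule, ham, rng))
    logger = writer = None
    if config.outputs.log_every:
        logger = StatsLogger(config.outputs.log_every)
        sim.add_hook(logger)
    if config.outputs.png_every and not no_draw:
        if out_dir is None:
            raise ConfigurationError("PNG output requested but no output directory given")
        writer = FrameWriter(
            Path(out_dir),
            config.outputs.png_every,
            palette=config.palette(),
            draw_mode=config.outputs.draw_mode,
            zoom=config.outputs.zoom,
        )
        sim.add_hook(writer)
    return sim, logger, writer


def run_experiment(
    config: SimulationConfig,
    out_dir,
    seed: int | None = None,
    n_mcs: int | None = None,
    no_draw: bool = False,
) -> dict:
    """Execute a configured run; writes PNG frames, CSV logs and a manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if seed is None:
        seed = config.schedule.seed
    if n_mcs is None:
        n_mcs = config.schedule.n_mcs
    t0 = time.perf_counter()
    sim, logger, writer = build_simulation(config, seed=seed, no_draw=no_draw, out_dir=out_dir)
    sim.fire_hooks()  # MCS 0: initial log row and frame
    sweep_s = sim.run(n_mcs)
    wall_s = time.perf_counter() - t0
    if logger is not None:
        logger.write(out_dir)
    manifest = {
        "package_version": __version__,
        "config": dump_config(config),
        "seed": seed,
        "n_mcs": n_mcs,
        "wall_time_s": wall_s,
        "sweep_time_s": sweep_s,
        "mcs_per_s": (n_mcs / sweep_s) if sweep_s > 0 else float("nan"),
        "n_frames": writer.n_written if writer is not None else 0,
        "n_cells_final": len(sim.state.cell_ids()),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def run_game_of_life(
    out_dir,
    seed: int = 0,
    width: int = 50,
    height: int = 50,
    n_steps: int = 500,
    png_every: int = 20,
    density: float = 0.5,
    no_draw: bool = False,
) -> dict:
    """Game-of-Life benchmark: random init, synchronous steps, PNG frames."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    state = gol_random_init(GridSpec(width, height), density, rng)
    rows = []
    n_frames = 0
    t0 = time.perf_counter()
    for step in range(n_steps + 1):
        if step:
            state = gol_step(state)
        if png_every and not no_draw and step % png_every == 0:
            render_ca_frame(state).save(out_dir / f"frame_{step:06d}.png")
            n_frames += 1
        rows.append({"step": step, "population": state.population})
    wall_s = time.perf_counter() - t0
    pd.DataFrame(rows).to_csv(out_dir / "population.csv", index=False)
    manifest = {
        "package_version": __version__,
        "experiment": "game_of_life",
        "seed": seed,
        "grid": [width, height],
        "n_steps": n_steps,
        "density": density,
        "wall_time_s": wall_s,
        "n_frames": n_frames,
        "final_population": state.population,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def scalability_config(
    cells_per_kind: int,
    target_volume: float = 40.0,
    fill_factor: float = 1.5,
    seed_radius_factor: float = 0.8,
    n_mcs: int = 100,
) -> SimulationConfig:
    """Cell-sorting config sized by the adaptive rule: the square grid side is
    ``fill_factor * sqrt(P_tot)`` and cells seed within a radius
    ``seed_radius_factor * sqrt(P_tot / pi)`` of the midpoint, with ``P_tot``
    the summed target volume of all cells."""
    base = preset_config("cell_sorting")
    p_tot = 2 * cells_per_kind * target_volume
    side = int(math.ceil(fill_factor * math.sqrt(p_tot)))
    if side < 3:
        raise ConfigurationError(f"derived grid side {side} is below the 3-pixel minimum")
    radius = seed_radius_factor * math.sqrt(p_tot / math.pi)
    raw = dump_config(base)
    raw["grid"] = {"width": side, "height": side, "torus_x": True, "torus_y": True}
    raw["hamiltonian"]["volume"]["target"] = [0, target_volume, target_volume]
    raw["processes"] = [
        {
            "type": "seed_circle",
            "counts": {1: cells_per_kind, 2: cells_per_kind},
            "radius": radius,
            "burn_in": 20,
        }
    ]
    raw["schedule"] = {"n_mcs": n_mcs, "seed": 0}
    raw["outputs"] = {"png_every": 0, "log_every": 0}
    return parse_config(raw)


def scalability_sweep(
    cells_per_kind=DEFAULT_SCALABILITY_CELLS,
    target_volume: float = 40.0,
    fill_factor: float = 1.5,
    seed_radius_factor: float = 0.8,
    n_mcs: int = 100,
    seed: int = 0,
    out_path=None,
) -> pd.DataFrame:
    """Time the cell-sorting model at increasing size, with drawing disabled.

    Returns a frame with one row per cell count: grid side, total pixels,
    cell pixel budget and simulation speed in MCS per second.
    """
    rows = []
    for n in cells_per_kind:
        config = scalability_config(n, target_volume, fill_factor, seed_radius_factor, n_mcs)
        sim, _, _ = build_simulation(config, seed=seed, no_draw=True)
        sweep_s = sim.run(n_mcs, with_hooks=False)
        side = config.grid.width
        rows.append(
            {
                "cells_per_kind": n,
                "grid_side": side,
                "grid_pixels": side * side,
                "p_tot": 2 * n * target_volume,
                "mcs": n_mcs,
                "mcs_per_second": n_mcs / sweep_s if sweep_s > 0 else float("nan"),
            }
        )
    frame = pd.DataFrame(rows)
    if out_path is not None:
        Path(out_path).parent.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_path, index=False)
    return frame


def run_named_experiment(name: str, out_dir, seed: int | None = None, **overrides) -> dict:
    """Dispatch one of the packaged benchmarks by name."""
    if name == "game_of_life":
        return run_game_of_life(out_dir, seed=seed if seed is not None else 0, **overrides)
    if name == "scalability":
        frame = scalability_sweep(
            seed=seed if seed is not None else 0,
            out_path=Path(out_dir) / "scalability.csv",
            **overrides,
        )
        return {"experiment": "scalability", "rows": frame.to_dict("records")}
    if name not in EXPERIMENT_NAMES:
        raise ConfigurationError(f"unknown experiment {name!r}; expected one of {EXPERIMENT_NAMES}")
    return run_experiment(preset_config(name), out_dir, seed=seed, **overrides)
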