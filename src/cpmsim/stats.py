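"""Observables logged during runs: centroids, volumes, counts, interfaces.

Centroids are torus-aware: on a periodic axis a circular-mean estimate locates
the cell, coordinates are unwrapped to the half-grid window around it and then
averaged arithmetically — exact for compact cells and geometrically correct
for cells straddling the wrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .lattice import LatticeState, neighbors, shift_grid


def _axis_centroid(vals: np.ndarray, n: int, torus: bool) -> float:
    if not torus:
        return float(vals.mean())
    theta = vals * (2 * np.pi / n)
    c, s = np.cos(theta).sum(), np.sin(theta).sum()
    if abs(c) < 1e-12 and abs(s) < 1e-12:
        # pixels uniformly spread around the ring: no meaningful wrap; fall back
        return float(vals.mean())
    est = np.arctan2(s, c) * n / (2 * np.pi) % n
    unwrapped = est + ((vals - est + n / 2) % n - n / 2)
    return float(unwrapped.mean() % n)


def centroid(state: LatticeState, cell_id: int) -> tuple[float, float]:
    ys, xs = np.nonzero(state.identity == cell_id)
    if len(xs) == 0:
        raise ConfigurationError(f"cell {cell_id} has no pixels")
    return (
        _axis_centroid(xs.astype(float), state.spec.width, state.spec.torus_x),
        _axis_centroid(ys.astype(float), state.spec.height, state.spec.torus_y),
    )


def heterotypic_interface(state: LatticeState) -> int:
    """Unordered kernel-neighbor pairs joining two different non-background kinds."""
    kind_grid = state.kind_arr[state.identity]
    count = 0
    for dx, dy in state.kernel.half:
        shifted, valid = shift_grid(kind_grid, state.spec, dx, dy)
        mask = valid & (kind_grid != 0) & (shifted != 0) & (kind_grid != shifted)
        count += int(mask.sum())
    return count


def is_connected(state: LatticeState, cell_id: int) -> bool:
    """True iff the cell's pixels form one kernel-connected component (torus-aware)."""
    ys, xs = np.nonzero(state.identity == cell_id)
    if len(xs) == 0:
        raise ConfigurationError(f"cell {cell_id} has no pixels")
    members = set(zip(xs.tolist(), ys.tolist()))
    stack = [next(iter(members))]
    seen = {stack[0]}
    while stack:
        site = stack.pop()
        for nb in neighbors(state.spec, site, state.kernel):
            if nb in members and nb not in seen:
                seen.add(nb)
                stack.append(nb)
    return len(seen) == len(members)


@dataclass
class StatRecord:
    mcs: int
    per_cell: dict[int, tuple[float, float, int, int]]  # id -> (x, y, volume, kind)
    global_stats: dict[str, float]


def record_stats(state: LatticeState, mcs: int) -> StatRecord:
    per_cell = {}
    for cid in state.cell_ids():
        cx, cy = centroid(state, cid)
        per_cell[cid] = (cx, cy, state.volume_of(cid), state.kind_of(cid))
    global_stats = {
        "cell_count": float(len(per_cell)),
        "heterotypic_interface": float(heterotypic_interface(state)),
        "background": float(state.volume_of(0)),
    }
    return StatRecord(mcs=mcs, per_cell=per_cell, global_stats=global_stats)


class StatsLogger:
    """Per-MCS hook accumulating tidy records; written as two CSVs.

    ``cells.csv``: one row per (mcs, cell) with columns
    mcs, cell, kind, x, y, volume. ``summary.csv``: one row per mcs with
    columns mcs, cell_count, heterotypic_interface, background.
    """

    def __init__(self, every: int) -> None:
        if every < 1:
            raise ConfigurationError("logging interval must be >= 1")
        self.every = every
        self.cell_rows: list[dict] = []
        self.summary_rows: list[dict] = []

    def __call__(self, state: LatticeState, mcs: int) -> None:
        if mcs % self.every:
            return
        rec = record_stats(state, mcs)
        for cid, (x, y, vol, kind) in rec.per_cell.items():
            self.cell_rows.append(
                {"mcs": mcs, "cell": cid, "kind": kind, "x": x, "y": y, "volume": vol}
            )
        self.summary_rows.append({"mcs": mcs, **rec.global_stats})

    def cells_frame(self) -> pd.DataFrame:
        cols = ["mcs", "cell", "kind", "x", "y", "volume"]
        return pd.DataFrame(self.cell_rows, columns=cols)

    def summary_frame(self) -> pd.DataFrame:
        cols = ["mcs", "cell_count", "heterotypic_interface", "background"]
        return pd.DataFrame(self.summary_rows, columns=cols)

    def write(self, out_dir) -> None:
        self.cells_frame().to_csv(out_dir / "cells.csv", index=False)
        self.summary_frame().to_csv(out_dir / "summary.csv", index=False)
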