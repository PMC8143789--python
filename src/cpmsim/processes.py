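"""Non-Hamiltonian model processes: seeding, obstacles, growth and division."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dynamics import run_mcs
from .energy import Hamiltonian
from .errors import ConfigurationError
from .lattice import LatticeState, Site, make_disc_cell


@dataclass
class SeedingPlan:
    """Seed single-pixel cells uniformly inside a disc, optionally followed by
    a burn-in phase that grows them toward target volume."""

    n_cells_per_kind: dict[int, int]
    region_center: Site | None = None  # None -> grid midpoint
    region_radius: float = 0.0
    burn_in_mcs: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_cells_per_kind.values()):
            raise ConfigurationError("cell counts must be non-negative")
        if self.burn_in_mcs < 0:
            raise ConfigurationError("burn_in_mcs must be non-negative")


def _disc_sites(state: LatticeState, center: tuple[float, float], radius: float) -> np.ndarray:
    """(n, 2) array of (x, y) sites within torus-metric distance radius of center."""
    spec = state.spec
    dx = np.arange(spec.width, dtype=float) - center[0]
    dy = np.arange(spec.height, dtype=float) - center[1]
    if spec.torus_x:
        dx = (dx + spec.width / 2) % spec.width - spec.width / 2
    if spec.torus_y:
        dy = (dy + spec.height / 2) % spec.height - spec.height / 2
    dist2 = dy[:, None] ** 2 + dx[None, :] ** 2
    ys, xs = np.nonzero(dist2 <= radius * radius + 1e-12)
    return np.column_stack([xs, ys])


def seed_cells_in_circle(
    state: LatticeState,
    plan: SeedingPlan,
    rng: np.random.Generator,
    hamiltonian: Hamiltonian | None = None,
) -> list[int]:
    """Place the planned cells as single-pixel seeds at uniform random free
    sites inside the disc; returns the new cell ids.

    When ``plan.burn_in_mcs > 0`` a Hamiltonian (with its volume constraint)
    must be supplied; the burn-in MCS grow the seeds and do not count toward
    the run schedule.
    """
    if plan.region_radius > min(state.spec.width, state.spec.height) / 2:
        raise ConfigurationError("seeding radius exceeds half the smaller grid dimension")
    center = plan.region_center if plan.region_center is not None else state.spec.midpoint()
    sites = _disc_sites(state, center, plan.region_radius)
    free = sites[state.identity[sites[:, 1], sites[:, 0]] == 0]
    total = sum(plan.n_cells_per_kind.values())
    if total > len(free):
        raise ConfigurationError(
            f"{total} cells requested but only {len(free)} free sites in the seeding region"
        )
    order = rng.permutation(len(free))[:total]
    chosen = free[order]
    new_ids = []
    i = 0
    for kind, count in plan.n_cells_per_kind.items():
        for _ in range(count):
            cid = state.register_cell(kind)
            x, y = int(chosen[i, 0]), int(chosen[i, 1])
            state.set_pixel((x, y), cid)
            new_ids.append(cid)
            i += 1
    if plan.burn_in_mcs:
        if hamiltonian is None:
            raise ConfigurationError("burn-in requires a hamiltonian")
        for _ in range(plan.burn_in_mcs):
            run_mcs(state, hamiltonian, rng)
    return new_ids


@dataclass
class ObstacleSpec:
    """Immutable discs: pixels that the dynamics may never mutate or copy."""

    centers: list[Site]
    radius: float
    kind: int


def place_obstacles(state: LatticeState, spec: ObstacleSpec) -> list[int]:
    """Assign each disc to a fresh immutable cell of the obstacle kind."""
    if not state.immutable_kind[spec.kind]:
        raise ConfigurationError(f"obstacle kind {spec.kind} is not flagged immutable")
    ids = []
    for center in spec.centers:
        sites = _disc_sites(state, (float(center[0]), float(center[1])), spec.radius)
        occupied = state.identity[sites[:, 1], sites[:, 0]]
        if np.any(occupied != 0):
            raise ConfigurationError(f"obstacle at {center} overlaps existing cells")
        cid = state.register_cell(spec.kind)
        make_disc_cell(state, center, spec.radius, cid)
        ids.append(cid)
    return ids


@dataclass
class DivisionRule:
    """Target-volume growth plus threshold division along a centroid line."""

    growth_rate: float
    division_volume: int
    axis_mode: str = "minor-axis"  # split line = minor axis, i.e. perpendicular to the principal axis
    kinds: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.division_volume < 2:
            raise ConfigurationError("division_volume must be >= 2")
        if self.axis_mode not in ("minor-axis", "random"):
            raise ConfigurationError(f"unknown axis_mode {self.axis_mode!r}")


def _unwrapped_coords(state: LatticeState, cid: int) -> np.ndarray:
    """Cell pixel coordinates as floats, unwrapped across torus seams so the
    pixel cloud is contiguous around its centroid. Columns: x, y."""
    ys, xs = np.nonzero(state.identity == cid)
    coords = np.column_stack([xs, ys]).astype(float)
    spec = state.spec
    for axis, (n, torus) in enumerate([(spec.width, spec.torus_x), (spec.height, spec.torus_y)]):
        if not torus:
            continue
        theta = coords[:, axis] * (2 * np.pi / n)
        est = np.arctan2(np.sin(theta).sum(), np.cos(theta).sum()) * n / (2 * np.pi) % n
        coords[:, axis] = est + ((coords[:, axis] - est + n / 2) % n - n / 2)
    return coords


def divide_cell(
    state: LatticeState,
    cid: int,
    rule: DivisionRule,
    rng: np.random.Generator,
    reset_target: float | None = None,
) -> int | None:
    """Split one cell by a line through its centroid; returns the new cell id.

    In ``minor-axis`` mode the split line is the minor axis (perpendicular to
    the principal axis of the pixel second central moments), so daughters
    separate along the cell's long direction. Pixels are ordered by signed
    distance to the line with lexicographic tie-breaking, and the far half
    (rounded down) becomes the new cell — this balances daughter volumes.
    """
    if state.volume_of(cid) < 2:
        warnings.warn(f"cell {cid} has volume < 2; division skipped")
        return None
    coords = _unwrapped_coords(state, cid)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    if rule.axis_mode == "random":
        angle = rng.uniform(0, 2 * np.pi)
        axis = np.array([np.cos(angle), np.sin(angle)])
    else:
        cov = centered.T @ centered / len(centered)
        evals, evecs = np.linalg.eigh(cov)
        axis = evecs[:, int(np.argmax(evals))]  # principal (major) axis
    s = centered @ axis
    order = np.lexsort((centered[:, 1], centered[:, 0], s))
    take = len(coords) // 2
    new_id = state.register_cell(state.kind_of(cid))
    for idx in order[len(coords) - take :]:
        x, y = coords[idx]
        site = state.spec.wrap(int(round(x)), int(round(y)))
        state.set_pixel(site, new_id)
    if reset_target is not None:
        state.target_volume_arr[cid] = reset_target
        state.target_volume_arr[new_id] = reset_target
    return new_id


class GrowthDivision:
    """Per-MCS hook: raise per-cell target volumes by ``growth_rate`` (capped
    at the division threshold) and divide cells whose actual volume reaches
    ``division_volume``. Daughters inherit the kind and reset to the base
    target volume."""

    def __init__(self, rule: DivisionRule, hamiltonian: Hamiltonian, rng: np.random.Generator):
        if hamiltonian.volume is None:
            raise ConfigurationError("growth/division requires an active volume constraint")
        self.rule = rule
        self.hamiltonian = hamiltonian
        self.rng = rng
        self.n_divisions = 0

    def _base_target(self, state: LatticeState, cid: int) -> float:
        return float(self.hamiltonian.volume.target[state.kind_of(cid)])

    def __call__(self, state: LatticeState, mcs: int) -> None:
        kinds = state.kind_arr
        vol = state.volume_arr
        tv = state.target_volume_arr
        grow = np.zeros(state.n_cells, dtype=bool)
        for kind in self.rule.kinds:
            grow |= (kinds == kind) & (vol > 0)
        grow[0] = False
        ids = np.nonzero(grow)[0]
        if len(ids) == 0:
            return
        base = self.hamiltonian.volume.target[kinds[ids]]
        current = np.where(tv[ids] >= 0, tv[ids], base)
        tv[ids] = np.minimum(current + self.rule.growth_rate, self.rule.division_volume)
        for cid in ids[vol[ids] >= self.rule.division_volume]:
            if divide_cell(state, int(cid), self.rule, self.rng,
                           reset_target=self._base_target(state, int(cid))) is not None:
                self.n_divisions += 1
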