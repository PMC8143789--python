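"""2D pixel lattice with toroidal or bounded axes and per-cell bookkeeping.

The lattice stores one integer identity per pixel (0 = background) plus
incrementally maintained caches: per-cell volume (pixel count), per-cell
perimeter (ordered member/non-member neighbor pairs under the configured
kernel), and per-pixel activity values used by the protrusion energy term.

Sites are ``(x, y)`` tuples with ``0 <= x < width`` and ``0 <= y < height``;
the backing arrays are indexed ``[y, x]`` so that they map directly onto
raster images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

Site = tuple[int, int]


@dataclass(frozen=True)
class GridSpec:
    """Grid geometry: dimensions plus independent per-axis torus flags."""

    width: int
    height: int
    torus_x: bool = True
    torus_y: bool = True

    def __post_init__(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ConfigurationError(f"grid must be at least 3x3, got {self.width}x{self.height}")

    @property
    def n_sites(self) -> int:
        return self.width * self.height

    def contains(self, x: int, y: int) -> bool:
        return 0 <= x < self.width and 0 <= y < self.height

    def wrap(self, x: int, y: int) -> Site | None:
        """Canonicalise a raw coordinate; ``None`` when it falls off a bounded axis."""
        if self.torus_x:
            x %= self.width
        elif not 0 <= x < self.width:
            return None
        if self.torus_y:
            y %= self.height
        elif not 0 <= y < self.height:
            return None
        return (x, y)

    def midpoint(self) -> tuple[float, float]:
        return ((self.width - 1) / 2.0, (self.height - 1) / 2.0)


@dataclass(frozen=True)
class NeighborhoodKernel:
    """Ordered list of (dx, dy) offsets; excludes (0, 0)."""

    offsets: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.offsets:
            raise ConfigurationError("kernel must have at least one offset")
        if (0, 0) in self.offsets:
            raise ConfigurationError("kernel must not contain (0, 0)")

    def __len__(self) -> int:
        return len(self.offsets)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.offsets, dtype=np.int64)

    @property
    def half(self) -> tuple[tuple[int, int], ...]:
        """One offset per unordered direction pair (for symmetric kernels)."""
        return tuple(o for o in self.offsets if o[1] > 0 or (o[1] == 0 and o[0] > 0))


MOORE = NeighborhoodKernel(
    ((-1, -1), (0, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (0, 1), (1, 1))
)
VON_NEUMANN = NeighborhoodKernel(((0, -1), (-1, 0), (1, 0), (0, 1)))


def neighbors(spec: GridSpec, site: Site, kernel: NeighborhoodKernel = MOORE) -> list[Site]:
    """Kernel offsets applied to ``site``, wrapped on torus axes, dropped off bounded edges."""
    x, y = site
    out = []
    for dx, dy in kernel.offsets:
        wrapped = spec.wrap(x + dx, y + dy)
        if wrapped is not None:
            out.append(wrapped)
    return out


def torus_delta(spec: GridSpec, a: Site, b: Site) -> tuple[float, float]:
    """Shortest displacement b - a, taking wrapping into account per axis."""
    dx = b[0] - a[0]
    dy = b[1] - a[1]
    if spec.torus_x:
        dx = (dx + spec.width / 2) % spec.width - spec.width / 2
    if spec.torus_y:
        dy = (dy + spec.height / 2) % spec.height - spec.height / 2
    return (dx, dy)


class LatticeState:
    """Grid of pixel identities with exact incremental per-cell caches.

    Cell ids are allocated monotonically by :meth:`register_cell` and never
    reused. Id 0 is the background, a first-class identity of kind 0 whose
    volume and perimeter are tracked like any other (its energy weights are
    always zero). Kinds flagged immutable (obstacles/barriers) are never
    mutated by the dynamics.
    """

    def __init__(
        self,
        spec: GridSpec,
        n_kinds: int = 2,
        kernel: NeighborhoodKernel = MOORE,
        immutable_kinds: tuple[int, ...] = (),
    ) -> None:
        if n_kinds < 1:
            raise ConfigurationError("need at least the background kind")
        self.spec = spec
        self.kernel = kernel
        self.n_kinds = n_kinds
        self.identity = np.zeros((spec.height, spec.width), dtype=np.int64)
        self.activity = np.zeros((spec.height, spec.width), dtype=np.int64)
        self.immutable_kind = np.zeros(n_kinds, dtype=bool)
        for k in immutable_kinds:
            if not 0 < k < n_kinds:
                raise ConfigurationError(f"immutable kind {k} out of range")
            self.immutable_kind[k] = True
        cap = 16
        self._kind = np.zeros(cap, dtype=np.int64)
        self._volume = np.zeros(cap, dtype=np.int64)
        self._perimeter = np.zeros(cap, dtype=np.int64)
        self._target_volume = np.full(cap, -1.0)
        self._volume[0] = spec.n_sites
        self.n_cells = 1  # background

    # -- cell registry -------------------------------------------------

    def _ensure_capacity(self, cid: int) -> None:
        cap = len(self._kind)
        if cid < cap:
            return
        new = max(cap * 2, cid + 1)
        for name in ("_kind", "_volume", "_perimeter"):
            arr = getattr(self, name)
            grown = np.zeros(new, dtype=arr.dtype)
            grown[: len(arr)] = arr
            setattr(self, name, grown)
        tv = np.full(new, -1.0)
        tv[: len(self._target_volume)] = self._target_volume
        self._target_volume = tv

    def register_cell(self, kind: int) -> int:
        if not 0 < kind < self.n_kinds:
            raise ConfigurationError(f"kind {kind} not registered (n_kinds={self.n_kinds})")
        cid = self.n_cells
        self._ensure_capacity(cid)
        self._kind[cid] = kind
        self.n_cells += 1
        return cid

    # -- array views used by the fast kernel ---------------------------

    @property
    def kind_arr(self) -> np.ndarray:
        return self._kind[: self.n_cells]

    @property
    def volume_arr(self) -> np.ndarray:
        return self._volume[: self.n_cells]

    @property
    def perimeter_arr(self) -> np.ndarray:
        return self._perimeter[: self.n_cells]

    @property
    def target_volume_arr(self) -> np.ndarray:
        return self._target_volume[: self.n_cells]

    # -- per-cell accessors --------------------------------------------

    def kind_of(self, cid: int) -> int:
        self._check_id(cid)
        return int(self._kind[cid])

    def volume_of(self, cid: int) -> int:
        self._check_id(cid)
        return int(self._volume[cid])

    def perimeter_of(self, cid: int) -> int:
        self._check_id(cid)
        return int(self._perimeter[cid])

    def _check_id(self, cid: int) -> None:
        if not 0 <= cid < self.n_cells:
            raise ConfigurationError(f"cell id {cid} not registered")

    def cell_ids(self, with_pixels: bool = True) -> list[int]:
        """Non-background cell ids, by default only those that still own pixels."""
        ids = range(1, self.n_cells)
        if with_pixels:
            return [c for c in ids if self._volume[c] > 0]
        return list(ids)

    def cell_volumes(self) -> dict[int, int]:
        return {c: int(self._volume[c]) for c in range(self.n_cells)}

    # -- pixel access ---------------------------------------------------

    def get(self, site: Site) -> int:
        x, y = site
        return int(self.identity[y, x])

    def kind_at(self, site: Site) -> int:
        return int(self._kind[self.get(site)])

    def set_pixel(self, site: Site, new_id: int, activity: int = 0) -> None:
        """Overwrite one pixel's identity, keeping all caches exact.

        Volume and perimeter caches of every affected cell (including the
        background) are updated incrementally. The pixel's activity is set to
        ``activity`` (dynamics pass the copying kind's max_act on accepted
        copies; plain edits reset it to 0).
        """
        self._check_id(new_id)
        x, y = site
        old = int(self.identity[y, x])
        if old == new_id:
            return
        spec = self.spec
        for dx, dy in self.kernel.offsets:
            wrapped = spec.wrap(x + dx, y + dy)
            if wrapped is None:
                continue
            nid = int(self.identity[wrapped[1], wrapped[0]])
            if nid != old:
                self._perimeter[old] -= 1
            if nid != new_id:
                self._perimeter[new_id] += 1
            # the neighbour's own (n, site) pair flips status
            self._perimeter[nid] += (1 if nid != new_id else 0) - (1 if nid != old else 0)
        self._volume[old] -= 1
        self._volume[new_id] += 1
        self.identity[y, x] = new_id
        self.activity[y, x] = activity

    def decay_activity(self) -> None:
        np.maximum(self.activity - 1, 0, out=self.activity)

    # -- bulk construction / verification -------------------------------

    def recompute_caches(self) -> None:
        """Rebuild volume and perimeter caches from the identity grid."""
        counts = np.bincount(self.identity.ravel(), minlength=self.n_cells)
        self._volume[: self.n_cells] = counts[: self.n_cells]
        self._volume[self.n_cells :] = 0
        per = np.zeros(self.n_cells, dtype=np.int64)
        for dx, dy in self.kernel.offsets:
            shifted, valid = shift_grid(self.identity, self.spec, dx, dy)
            boundary = valid & (self.identity != shifted)
            per += np.bincount(self.identity[boundary], minlength=self.n_cells)[: self.n_cells]
        self._perimeter[: self.n_cells] = per
        self._perimeter[self.n_cells :] = 0

    @classmethod
    def from_identity_matrix(
        cls,
        spec: GridSpec,
        matrix: np.ndarray,
        kind_of: dict[int, int],
        n_kinds: int | None = None,
        kernel: NeighborhoodKernel = MOORE,
        immutable_kinds: tuple[int, ...] = (),
    ) -> "LatticeState":
        """Build a state from a plain integer matrix plus an id -> kind map."""
        matrix = np.asarray(matrix, dtype=np.int64)
        if matrix.shape != (spec.height, spec.width):
            raise ConfigurationError(
                f"matrix shape {matrix.shape} does not match grid {spec.height}x{spec.width}"
            )
        kinds = dict(kind_of)
        kinds.setdefault(0, 0)
        max_id = max(int(matrix.max()), max(kinds))
        if n_kinds is None:
            n_kinds = max(kinds.values()) + 1
        state = cls(spec, n_kinds=n_kinds, kernel=kernel, immutable_kinds=immutable_kinds)
        for cid in range(1, max_id + 1):
            if cid not in kinds:
                raise ConfigurationError(f"cell id {cid} missing from kind map")
            state.register_cell(kinds[cid])
        present = np.unique(matrix)
        for cid in present:
            if cid and int(cid) not in kinds:
                raise ConfigurationError(f"matrix contains unregistered id {int(cid)}")
        state.identity[:, :] = matrix
        state.recompute_caches()
        return state

    def to_matrix_text(self) -> str:
        """Row-major whitespace-separated dump of the identity grid."""
        return "\n".join(" ".join(str(int(v)) for v in row) for row in self.identity)

    @staticmethod
    def matrix_from_text(text: str) -> np.ndarray:
        rows = [[int(tok) for tok in line.split()] for line in text.strip().splitlines()]
        return np.asarray(rows, dtype=np.int64)


def shift_grid(grid: np.ndarray, spec: GridSpec, dx: int, dy: int) -> tuple[np.ndarray, np.ndarray]:
    """Return (neighbor-value grid at offset (dx, dy), validity mask).

    ``shifted[y, x]`` holds ``grid`` at ``(x + dx, y + dy)``; on bounded axes
    positions whose neighbor falls off the grid are masked out.
    """
    shifted = np.roll(np.roll(grid, -dy, axis=0), -dx, axis=1)
    valid = np.ones(grid.shape, dtype=bool)
    h, w = grid.shape
    if not spec.torus_x and dx:
        if dx > 0:
            valid[:, w - dx :] = False
        else:
            valid[:, : -dx] = False
    if not spec.torus_y and dy:
        if dy > 0:
            valid[h - dy :, :] = False
        else:
            valid[: -dy, :] = False
    return shifted, valid


def make_disc_cell(state: LatticeState, center: Site, radius: float, cell_id: int) -> None:
    """Assign every site within torus-metric Euclidean distance ``radius`` of
    ``center`` to ``cell_id`` (test fixtures and deterministic seeding)."""
    state._check_id(cell_id)
    spec = state.spec
    r2 = radius * radius
    xs = np.arange(spec.width, dtype=float)
    ys = np.arange(spec.height, dtype=float)
    dx = xs - center[0]
    dy = ys - center[1]
    if spec.torus_x:
        dx = (dx + spec.width / 2) % spec.width - spec.width / 2
    if spec.torus_y:
        dy = (dy + spec.height / 2) % spec.height - spec.height / 2
    dist2 = dy[:, None] ** 2 + dx[None, :] ** 2
    for y, x in np.argwhere(dist2 <= r2 + 1e-12):
        state.set_pixel((int(x), int(y)), cell_id)
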