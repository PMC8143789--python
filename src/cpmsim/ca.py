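"""Conway's Game of Life on the shared lattice geometry.

A non-CPM benchmark model: synchronous Moore-neighborhood updates, torus
boundaries by default (bounded axes treat off-grid sites as dead).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .lattice import MOORE, GridSpec, shift_grid


@dataclass
class CAState:
    spec: GridSpec
    alive: np.ndarray  # bool, shape (height, width)

    def __post_init__(self) -> None:
        self.alive = np.asarray(self.alive, dtype=bool)
        if self.alive.shape != (self.spec.height, self.spec.width):
            raise ConfigurationError("alive grid does not match the grid spec")

    @property
    def population(self) -> int:
        return int(self.alive.sum())


def gol_random_init(spec: GridSpec, density: float, rng: np.random.Generator) -> CAState:
    """Each site independently alive with probability ``density``."""
    if not 0 <= density <= 1:
        raise ConfigurationError(f"density must be in [0, 1], got {density}")
    return CAState(spec, rng.random((spec.height, spec.width)) < density)


def gol_step(state: CAState) -> CAState:
    """One synchronous update: survive on 2-3 live neighbors, birth on exactly 3."""
    counts = np.zeros(state.alive.shape, dtype=np.int64)
    for dx, dy in MOORE.offsets:
        shifted, valid = shift_grid(state.alive, state.spec, dx, dy)
        counts += np.where(valid, shifted, False)
    alive = state.alive
    nxt = (alive & ((counts == 2) | (counts == 3))) | (~alive & (counts == 3))
    return CAState(state.spec, nxt)
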