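"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately avoid the package's vectorised code paths:
they recount and re-sum with plain Python loops and their own coordinate
wrapping, so they stay independent of what they check.
"""

from __future__ import annotations

import numpy as np
import pytest

from cpmsim.lattice import MOORE, GridSpec, LatticeState


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def wrap_coord(spec: GridSpec, x: int, y: int):
    if spec.torus_x:
        x %= spec.width
    elif not 0 <= x < spec.width:
        return None
    if spec.torus_y:
        y %= spec.height
    elif not 0 <= y < spec.height:
        return None
    return x, y


def brute_volumes(state: LatticeState) -> dict[int, int]:
    counts: dict[int, int] = {}
    for y in range(state.spec.height):
        for x in range(state.spec.width):
            cid = int(state.identity[y, x])
            counts[cid] = counts.get(cid, 0) + 1
    return counts


def brute_perimeters(state: LatticeState) -> dict[int, int]:
    per: dict[int, int] = {}
    for y in range(state.spec.height):
        for x in range(state.spec.width):
            cid = int(state.identity[y, x])
            for dx, dy in state.kernel.offsets:
                nb = wrap_coord(state.spec, x + dx, y + dy)
                if nb is None:
                    continue
                if int(state.identity[nb[1], nb[0]]) != cid:
                    per[cid] = per.get(cid, 0) + 1
    return per


def naive_total_H(state: LatticeState, J=None, lam_v=None, tgt_v=None, lam_p=None, tgt_p=None):
    """Pure-python global energy: adhesion + volume + perimeter terms."""
    H = 0.0
    kinds = state.kind_arr
    if J is not None:
        s = 0.0
        for y in range(state.spec.height):
            for x in range(state.spec.width):
                a = int(state.identity[y, x])
                for dx, dy in state.kernel.offsets:
                    nb = wrap_coord(state.spec, x + dx, y + dy)
                    if nb is None:
                        continue
                    b = int(state.identity[nb[1], nb[0]])
                    if a != b:
                        s += J[kinds[a]][kinds[b]]
        H += s / 2.0  # every unordered pair visited twice
    if lam_v is not None:
        vols = brute_volumes(state)
        for cid in range(1, state.n_cells):
            lam = lam_v[kinds[cid]]
            if lam:
                tv = state.target_volume_arr[cid]
                if tv < 0:
                    tv = tgt_v[kinds[cid]]
                H += lam * (vols.get(cid, 0) - tv) ** 2
    if lam_p is not None:
        pers = brute_perimeters(state)
        for cid in range(1, state.n_cells):
            lam = lam_p[kinds[cid]]
            if lam:
                H += lam * (pers.get(cid, 0) - tgt_p[kinds[cid]]) ** 2
    return H


def random_blob_state(rng, width=20, height=20, n_kinds=3, n_cells=6,
                      torus_x=True, torus_y=True, kernel=MOORE) -> LatticeState:
    """A lattice with several random rectangular/round patches of cells."""
    spec = GridSpec(width, height, torus_x, torus_y)
    state = LatticeState(spec, n_kinds=n_kinds, kernel=kernel)
    for _ in range(n_cells):
        kind = int(rng.integers(1, n_kinds))
        cid = state.register_cell(kind)
        cx, cy = int(rng.integers(width)), int(rng.integers(height))
        r = int(rng.integers(1, 4))
        for dy in range(-r, r + 1):
            for dx in range(-r, r + 1):
                if dx * dx + dy * dy <= r * r:
                    site = spec.wrap(cx + dx, cy + dy)
                    if site is not None:
                        state.set_pixel(site, cid)
    return state


def valid_attempt_pairs(state: LatticeState, rng, n: int):
    """Up to n random (source, target) kernel-neighbor pairs with differing ids."""
    pairs = []
    tries = 0
    while len(pairs) < n and tries < 50 * n:
        tries += 1
        x, y = int(rng.integers(state.spec.width)), int(rng.integers(state.spec.height))
        k = int(rng.integers(len(state.kernel)))
        dx, dy = state.kernel.offsets[k]
        src = state.spec.wrap(x + dx, y + dy)
        if src is None:
            continue
        if state.get(src) != state.get((x, y)):
            pairs.append((src, (x, y)))
    return pairs
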