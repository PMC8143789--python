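"""Metropolis copy-attempt kinetics and the Monte Carlo Step clock.

One MCS performs ``width * height`` attempt resolutions (null attempts count),
then decays every positive activity value by 1. Attempts pick a uniform random
target site and a uniform random kernel neighbor as the copy source. All
randomness flows through a single ``numpy.random.Generator``, so a trajectory
is a pure function of (configuration, seed).
"""

from __future__ import annotations

import time
from dataclasses import dataclass

import numpy as np

from . import _kernel
from .energy import Hamiltonian, acceptance_probability, delta_H
from .lattice import LatticeState, Site


@dataclass
class CopyAttempt:
    source: Site
    target: Site
    delta: float | None = None
    accepted: bool | None = None


def propose_attempt(state: LatticeState, rng: np.random.Generator) -> CopyAttempt | None:
    """Draw one candidate copy; ``None`` for null attempts (same identity,
    off-grid source on a bounded axis, or an immutable kind involved)."""
    spec = state.spec
    t = int(rng.integers(spec.n_sites))
    ty, tx = divmod(t, spec.width)
    k = int(rng.integers(len(state.kernel)))
    dx, dy = state.kernel.offsets[k]
    src = spec.wrap(tx + dx, ty + dy)
    if src is None:
        return None
    a = int(state.identity[ty, tx])
    b = int(state.identity[src[1], src[0]])
    if a == b:
        return None
    if state.immutable_kind[state.kind_arr[a]] or state.immutable_kind[state.kind_arr[b]]:
        return None
    return CopyAttempt(source=src, target=(tx, ty))


def step_attempt(
    state: LatticeState,
    spec: Hamiltonian,
    attempt: CopyAttempt,
    rng: np.random.Generator,
) -> CopyAttempt:
    """Resolve one attempt in place: Metropolis-accept and apply the copy."""
    attempt.delta = delta_H(state, spec, attempt.source, attempt.target)
    p = acceptance_probability(attempt.delta, spec.temperature)
    attempt.accepted = p >= 1.0 or rng.random() < p
    if attempt.accepted:
        b = state.get(attempt.source)
        act = 0
        if b != 0 and spec.act is not None:
            act = int(spec.act.max_act[state.kind_arr[b]])
        state.set_pixel(attempt.target, b, activity=act)
    return attempt


def run_mcs(state: LatticeState, spec: Hamiltonian, rng: np.random.Generator) -> int:
    """Run one Monte Carlo Step; returns the number of accepted copies.

    The per-attempt random draws are generated as arrays up front and handed
    to the sweep kernel, which mutates the state's arrays in place.
    """
    spec.check_state(state)
    n = state.spec.n_sites
    tidx = rng.integers(0, n, size=n)
    oidx = rng.integers(0, len(state.kernel), size=n)
    unif = rng.random(n)
    J, lam_v, tgt_v, lam_p, tgt_p, lam_act, max_act = spec.param_arrays()
    immutable = np.zeros(spec.n_kinds(), dtype=np.bool_)
    immutable[: state.n_kinds] = state.immutable_kind
    return int(
        _kernel.sweep(
            state.identity,
            state.activity,
            np.ascontiguousarray(state.kind_arr),
            state.volume_arr,
            state.perimeter_arr,
            state.target_volume_arr,
            immutable,
            J,
            lam_v,
            tgt_v,
            lam_p,
            tgt_p,
            lam_act,
            max_act,
            state.kernel.array,
            state.spec.torus_x,
            state.spec.torus_y,
            float(spec.temperature),
            tidx,
            oidx,
            unif,
        )
    )


class Simulation:
    """State + Hamiltonian + RNG + ordered per-MCS hooks.

    Hooks are callables ``hook(state, mcs_index)`` fired after each MCS in
    registration order (division, logging, rendering...).
    """

    def __init__(
        self,
        state: LatticeState,
        hamiltonian: Hamiltonian,
        rng: np.random.Generator,
        hooks: list | None = None,
    ) -> None:
        self.state = state
        self.hamiltonian = hamiltonian
        self.rng = rng
        self.hooks = list(hooks or [])
        self.mcs = 0

    def add_hook(self, hook) -> None:
        self.hooks.append(hook)

    def fire_hooks(self) -> None:
        for hook in self.hooks:
            hook(self.state, self.mcs)

    def run(self, n_mcs: int, with_hooks: bool = True) -> float:
        """Advance ``n_mcs`` steps; returns wall-clock seconds spent in sweeps."""
        sweep_time = 0.0
        for _ in range(n_mcs):
            t0 = time.perf_counter()
            run_mcs(self.state, self.hamiltonian, self.rng)
            sweep_time += time.perf_counter() - t0
            self.mcs += 1
            if with_hooks:
                self.fire_hooks()
        return sweep_time
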