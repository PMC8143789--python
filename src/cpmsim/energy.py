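"""Hamiltonian terms and incremental energy differences for copy attempts.

``total_H`` is the slow, global evaluation used as the reference; ``delta_H``
recomputes only the locally affected contributions and matches the global
difference exactly for integer parameters.

The protrusion ("Act") term is kinetic: it biases copy attempts but has no
global energy, so it contributes to ``delta_H`` and never to ``total_H``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .lattice import LatticeState, Site, neighbors, shift_grid


@dataclass
class Adhesion:
    """Symmetric per-kind-pair interface energies, background included at index 0."""

    J: np.ndarray

    def __post_init__(self) -> None:
        self.J = np.asarray(self.J, dtype=float)
        if self.J.ndim != 2 or self.J.shape[0] != self.J.shape[1]:
            raise ConfigurationError("J must be a square matrix")
        if not np.array_equal(self.J, self.J.T):
            bad = np.argwhere(self.J != self.J.T)[0]
            raise ConfigurationError(
                f"J must be symmetric; J[{bad[0]}][{bad[1]}] != J[{bad[1]}][{bad[0]}]"
            )


@dataclass
class VolumeConstraint:
    """Quadratic penalty lambda * (volume - target)^2 per cell."""

    lam: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        _check_per_kind(self.lam, self.target, "volume")


@dataclass
class PerimeterConstraint:
    """Quadratic penalty lambda * (perimeter - target)^2 per cell."""

    lam: np.ndarray
    target: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        _check_per_kind(self.lam, self.target, "perimeter")


@dataclass
class ActModel:
    """Protrusion bias: recently gained pixels carry an activity value that
    decays by 1 per MCS from ``max_act``; copies from active regions into less
    active ones are favoured."""

    lam: np.ndarray
    max_act: np.ndarray

    def __post_init__(self) -> None:
        self.lam = np.asarray(self.lam, dtype=float)
        self.max_act = np.asarray(self.max_act, dtype=np.int64)
        if len(self.lam) != len(self.max_act):
            raise ConfigurationError("act lambda and max_act must have equal length")
        if np.any(self.lam < 0) or np.any(self.max_act < 0):
            raise ConfigurationError("act parameters must be non-negative")
        if np.any((self.lam > 0) & (self.max_act == 0)):
            raise ConfigurationError("act term enabled (lambda > 0) but max_act == 0")
        if self.lam[0] != 0 or self.max_act[0] != 0:
            raise ConfigurationError("background kind must have act disabled")


def _check_per_kind(lam: np.ndarray, target: np.ndarray, name: str) -> None:
    if len(lam) != len(target):
        raise ConfigurationError(f"{name} lambda and target must have equal length")
    if np.any(lam < 0):
        raise ConfigurationError(f"{name} lambda must be non-negative")
    if lam[0] != 0:
        raise ConfigurationError(f"background kind must have {name} lambda == 0")


@dataclass
class Hamiltonian:
    """The energy function: an ordered set of terms plus the noise temperature."""

    temperature: float
    adhesion: Adhesion | None = None
    volume: VolumeConstraint | None = None
    perimeter: PerimeterConstraint | None = None
    act: ActModel | None = None

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ConfigurationError(f"temperature must be > 0, got {self.temperature}")
        if not self.terms:
            raise ConfigurationError("hamiltonian needs at least one term")

    @property
    def terms(self) -> list:
        return [t for t in (self.adhesion, self.volume, self.perimeter, self.act) if t is not None]

    def n_kinds(self) -> int:
        ns = []
        if self.adhesion is not None:
            ns.append(self.adhesion.J.shape[0])
        if self.volume is not None:
            ns.append(len(self.volume.lam))
        if self.perimeter is not None:
            ns.append(len(self.perimeter.lam))
        if self.act is not None:
            ns.append(len(self.act.lam))
        if len(set(ns)) > 1:
            raise ConfigurationError(f"terms disagree on the number of kinds: {ns}")
        return ns[0]

    def check_state(self, state: LatticeState) -> None:
        if state.n_kinds > self.n_kinds():
            raise ConfigurationError(
                f"state has {state.n_kinds} kinds but hamiltonian only {self.n_kinds()}"
            )

    def param_arrays(self) -> tuple[np.ndarray, ...]:
        """Dense per-kind parameter arrays for the fast sweep kernel."""
        n = self.n_kinds()
        J = self.adhesion.J if self.adhesion is not None else np.zeros((n, n))
        zeros = np.zeros(n)
        lam_v = self.volume.lam if self.volume is not None else zeros
        tgt_v = self.volume.target if self.volume is not None else zeros
        lam_p = self.perimeter.lam if self.perimeter is not None else zeros
        tgt_p = self.perimeter.target if self.perimeter is not None else zeros
        lam_act = self.act.lam if self.act is not None else zeros
        max_act = (
            self.act.max_act if self.act is not None else np.zeros(n, dtype=np.int64)
        )
        return (
            np.ascontiguousarray(J, dtype=np.float64),
            np.ascontiguousarray(lam_v, dtype=np.float64),
            np.ascontiguousarray(tgt_v, dtype=np.float64),
            np.ascontiguousarray(lam_p, dtype=np.float64),
            np.ascontiguousarray(tgt_p, dtype=np.float64),
            np.ascontiguousarray(lam_act, dtype=np.float64),
            np.ascontiguousarray(max_act, dtype=np.int64),
        )


# -- global evaluation (the slow reference path) ------------------------


def total_H(state: LatticeState, spec: Hamiltonian) -> float:
    """Global energy: adhesion + volume + perimeter. Act is kinetic-only."""
    spec.check_state(state)
    H = 0.0
    kinds = state.kind_arr
    if spec.adhesion is not None:
        J = spec.adhesion.J
        kind_grid = kinds[state.identity]
        for dx, dy in state.kernel.half:
            shifted_id, valid = shift_grid(state.identity, state.spec, dx, dy)
            shifted_kind, _ = shift_grid(kind_grid, state.spec, dx, dy)
            differs = valid & (state.identity != shifted_id)
            H += float(J[kind_grid[differs], shifted_kind[differs]].sum())
    if spec.volume is not None:
        for c in state.cell_ids(with_pixels=False):
            lam = spec.volume.lam[kinds[c]]
            if lam:
                H += lam * (state.volume_of(c) - _cell_target_volume(state, spec, c)) ** 2
    if spec.perimeter is not None:
        for c in state.cell_ids(with_pixels=False):
            lam = spec.perimeter.lam[kinds[c]]
            if lam:
                H += lam * (state.perimeter_of(c) - spec.perimeter.target[kinds[c]]) ** 2
    return H


def _cell_target_volume(state: LatticeState, spec: Hamiltonian, cid: int) -> float:
    tv = state.target_volume_arr[cid]
    if tv >= 0:
        return float(tv)
    return float(spec.volume.target[state.kind_arr[cid]])


# -- incremental evaluation --------------------------------------------


def delta_H(state: LatticeState, spec: Hamiltonian, source: Site, target: Site) -> float:
    """Energy change of copying the identity at ``source`` onto ``target``.

    Exactly equals ``total_H(after) - total_H(before)`` for the global terms,
    plus the kinetic Act contribution.
    """
    spec.check_state(state)
    a = state.get(target)
    b = state.get(source)
    if a == b:
        raise ConfigurationError("delta_H requires differing identities at source and target")
    if source not in neighbors(state.spec, target, state.kernel):
        raise ConfigurationError("source and target must be kernel neighbors")
    ka = int(state.kind_arr[a])
    kb = int(state.kind_arr[b])
    dH = 0.0

    # local neighbourhood scan shared by adhesion and perimeter
    perim_delta: dict[int, int] = {a: 0, b: 0}
    for site in neighbors(state.spec, target, state.kernel):
        nid = state.get(site)
        kn = int(state.kind_arr[nid])
        if spec.adhesion is not None:
            if nid != a:
                dH -= spec.adhesion.J[ka, kn]
            if nid != b:
                dH += spec.adhesion.J[kb, kn]
        if nid != a:
            perim_delta[a] = perim_delta.get(a, 0) - 1
        if nid != b:
            perim_delta[b] = perim_delta.get(b, 0) + 1
        d = (1 if nid != b else 0) - (1 if nid != a else 0)
        if d:
            perim_delta[nid] = perim_delta.get(nid, 0) + d

    if spec.volume is not None:
        if a != 0 and spec.volume.lam[ka]:
            v, tv = state.volume_of(a), _cell_target_volume(state, spec, a)
            dH += spec.volume.lam[ka] * ((v - 1 - tv) ** 2 - (v - tv) ** 2)
        if b != 0 and spec.volume.lam[kb]:
            v, tv = state.volume_of(b), _cell_target_volume(state, spec, b)
            dH += spec.volume.lam[kb] * ((v + 1 - tv) ** 2 - (v - tv) ** 2)

    if spec.perimeter is not None:
        for cid, dp in perim_delta.items():
            if cid == 0 or dp == 0:
                continue
            kc = int(state.kind_arr[cid])
            lam = spec.perimeter.lam[kc]
            if lam:
                p, tp = state.perimeter_of(cid), spec.perimeter.target[kc]
                dH += lam * ((p + dp - tp) ** 2 - (p - tp) ** 2)

    if spec.act is not None:
        dH += delta_act(state, spec.act, source, target)
    return dH


def geometric_mean_activity(state: LatticeState, site: Site) -> float:
    """Geometric mean of activity over ``site`` and its same-cell kernel
    neighbors; 0 for background sites (and whenever any factor is 0)."""
    cid = state.get(site)
    if cid == 0:
        return 0.0
    prod = float(state.activity[site[1], site[0]])
    count = 1
    for n in neighbors(state.spec, site, state.kernel):
        if state.get(n) == cid:
            prod *= float(state.activity[n[1], n[0]])
            count += 1
    if prod == 0.0:
        return 0.0
    return prod ** (1.0 / count)


def delta_act(state: LatticeState, params: ActModel, source: Site, target: Site) -> float:
    """Kinetic protrusion bias: -(lambda/max_act) * (GM(source) - GM(target)).

    Parameters are taken from the copying (source) cell's kind; when that kind
    has the term disabled, the receiving (target) kind's parameters apply, so
    retraction of an active cell is penalised symmetrically.
    """
    kb = state.kind_at(source)
    ka = state.kind_at(target)
    lam, mx = float(params.lam[kb]), int(params.max_act[kb])
    if lam == 0.0 or mx == 0:
        lam, mx = float(params.lam[ka]), int(params.max_act[ka])
    if lam == 0.0 or mx == 0:
        return 0.0
    gm_s = geometric_mean_activity(state, source)
    gm_t = geometric_mean_activity(state, target)
    return -(lam / mx) * (gm_s - gm_t)


def acceptance_probability(delta: float, temperature: float) -> float:
    """Metropolis rule: 1 for delta <= 0, else exp(-delta / T)."""
    if temperature <= 0:
        raise ConfigurationError(f"temperature must be > 0, got {temperature}")
    if delta <= 0:
        return 1.0
    return float(np.exp(-delta / temperature))
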