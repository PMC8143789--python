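"""Declarative run configuration: schema, validation, YAML/JSON loading.

Kinds are declared in order and get ids 1..n; kind 0 is the implicit
background. All per-kind parameter vectors (J rows, lambdas, targets) include
the background at index 0. Validation is collected — a bad file reports every
violation, not just the first.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Annotated, Literal, Union

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .energy import ActModel, Adhesion, Hamiltonian, PerimeterConstraint, VolumeConstraint
from .errors import ConfigFileError
from .lattice import MOORE, VON_NEUMANN, GridSpec, NeighborhoodKernel
from .render import DRAW_MODES, default_palette


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class GridConfig(_Model):
    width: int = Field(ge=3)
    height: int = Field(ge=3)
    torus_x: bool = True
    torus_y: bool = True


class KindConfig(_Model):
    name: str
    color: tuple[int, int, int] | None = None
    immutable: bool = False


class AdhesionConfig(_Model):
    J: list[list[float]]

    @model_validator(mode="after")
    def _symmetric(self):
        n = len(self.J)
        if any(len(row) != n for row in self.J):
            raise ValueError("J must be square")
        for i in range(n):
            for j in range(i):
                if self.J[i][j] != self.J[j][i]:
                    raise ValueError(f"J is not symmetric: J[{i}][{j}] != J[{j}][{i}]")
        return self


class VolumeConfig(_Model):
    lam: list[float] = Field(alias="lambda")
    target: list[float]
    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class PerimeterConfig(VolumeConfig):
    pass


class ActConfig(_Model):
    lam: list[float] = Field(alias="lambda")
    max_act: list[int]
    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class HamiltonianConfig(_Model):
    temperature: float = Field(gt=0)
    adhesion: AdhesionConfig | None = None
    volume: VolumeConfig | None = None
    perimeter: PerimeterConfig | None = None
    act: ActConfig | None = None

    @model_validator(mode="after")
    def _nonempty(self):
        if not any((self.adhesion, self.volume, self.perimeter, self.act)):
            raise ValueError("hamiltonian needs at least one term")
        return self


class SeedCircleConfig(_Model):
    type: Literal["seed_circle"]
    counts: dict[int, int]
    radius: float = Field(ge=0)
    center: tuple[int, int] | None = None
    burn_in: int = Field(default=0, ge=0)


class SeedDiscConfig(_Model):
    type: Literal["seed_disc"]
    kind: int
    center: tuple[int, int] | None = None
    radius: float = Field(ge=0)


class ObstaclesConfig(_Model):
    type: Literal["obstacles"]
    kind: int
    centers: list[tuple[int, int]]
    radius: float = Field(gt=0)


class GrowDivideConfig(_Model):
    type: Literal["grow_divide"]
    kinds: list[int]
    growth_rate: float = Field(gt=0)
    division_volume: int = Field(ge=2)
    axis_mode: Literal["minor-axis", "random"] = "minor-axis"


ProcessConfig = Annotated[
    Union[SeedCircleConfig, SeedDiscConfig, ObstaclesConfig, GrowDivideConfig],
    Field(discriminator="type"),
]


class ScheduleConfig(_Model):
    n_mcs: int = Field(ge=1)
    seed: int = 0


class OutputConfig(_Model):
    png_every: int = Field(default=0, ge=0)  # 0 disables
    log_every: int = Field(default=0, ge=0)
    draw_mode: Literal["kind", "cell", "border"] = "kind"
    zoom: int = Field(default=1, ge=1)


class SimulationConfig(_Model):
    grid: GridConfig
    kinds: list[KindConfig]
    hamiltonian: HamiltonianConfig
    processes: list[ProcessConfig] = Field(default_factory=list)
    schedule: ScheduleConfig
    outputs: OutputConfig = Field(default_factory=OutputConfig)
    kernel: Literal["moore", "von_neumann"] = "moore"

    @model_validator(mode="after")
    def _consistent(self):
        n = len(self.kinds) + 1
        errors = []
        ham = self.hamiltonian
        if ham.adhesion is not None and len(ham.adhesion.J) != n:
            errors.append(f"J must be {n}x{n} (background + {n - 1} kinds)")
        for name in ("volume", "perimeter", "act"):
            term = getattr(ham, name)
            if term is None:
                continue
            for field_name in ("lam", "target", "max_act"):
                vec = getattr(term, field_name, None)
                if vec is not None and len(vec) != n:
                    errors.append(f"hamiltonian.{name}.{field_name} must have length {n}")
        for i, proc in enumerate(self.processes):
            kinds_used = []
            if isinstance(proc, SeedCircleConfig):
                kinds_used = list(proc.counts)
            elif isinstance(proc, (ObstaclesConfig, SeedDiscConfig)):
                kinds_used = [proc.kind]
            elif isinstance(proc, GrowDivideConfig):
                kinds_used = list(proc.kinds)
            for k in kinds_used:
                if not 0 < k < n:
                    errors.append(f"processes[{i}] references unknown kind {k}")
            if isinstance(proc, ObstaclesConfig) and 0 < proc.kind < n:
                if not self.kinds[proc.kind - 1].immutable:
                    errors.append(f"processes[{i}]: obstacle kind {proc.kind} must be immutable")
        if errors:
            raise ValueError("; ".join(errors))
        return self

    # -- object construction -------------------------------------------

    @property
    def n_kinds(self) -> int:
        return len(self.kinds) + 1

    def grid_spec(self) -> GridSpec:
        g = self.grid
        return GridSpec(g.width, g.height, g.torus_x, g.torus_y)

    def neighborhood(self) -> NeighborhoodKernel:
        return MOORE if self.kernel == "moore" else VON_NEUMANN

    def immutable_kinds(self) -> tuple[int, ...]:
        return tuple(i + 1 for i, k in enumerate(self.kinds) if k.immutable)

    def to_hamiltonian(self) -> Hamiltonian:
        ham = self.hamiltonian
        return Hamiltonian(
            temperature=ham.temperature,
            adhesion=Adhesion(np.asarray(ham.adhesion.J)) if ham.adhesion else None,
            volume=VolumeConstraint(ham.volume.lam, ham.volume.target) if ham.volume else None,
            perimeter=(
                PerimeterConstraint(ham.perimeter.lam, ham.perimeter.target)
                if ham.perimeter
                else None
            ),
            act=ActModel(ham.act.lam, ham.act.max_act) if ham.act else None,
        )

    def palette(self) -> list[tuple[int, int, int]]:
        colors = default_palette(self.n_kinds)
        for i, kind in enumerate(self.kinds):
            if kind.color is not None:
                colors[i + 1] = tuple(kind.color)
        return colors


def load_config(path) -> SimulationConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigFileError([f"config file not found: {path}"])
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    return parse_config(raw)


def parse_config(raw: dict) -> SimulationConfig:
    try:
        return SimulationConfig.model_validate(raw)
    except ValidationError as exc:
        violations = [
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigFileError(violations) from exc


def dump_config(config: SimulationConfig) -> dict:
    """Canonical plain-dict form; dump(load(x)) is a fixed point."""
    return config.model_dump(by_alias=True, exclude_none=True)
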