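"""Schema-validated run configuration (TOML on disk, pydantic in memory).

Every physics constant that parametrizes a run — cutoff, restraint spring,
temperatures, timesteps, slab layers and lattice constant — lives here
with the standard study values as defaults, and the full configuration
(defaults included) is echoed into every output directory so a run is
reproducible from its echo plus its seed alone.
"""

from __future__ import annotations

import json
import tomllib
from pathlib import Path

from pydantic import BaseModel, Field

from .analysis import AnalysisThresholds
from .md import MDConfig
from .search import StunBhConfig

__all__ = ["RunConfig", "SlabSpec", "SearchSpec", "MDSpec", "AnalysisSpec",
           "load_run_config"]


class SlabSpec(BaseModel):
    element: str = "Au"
    lattice_constant: float = 4.08
    miller: tuple[int, int, int] = (1, 1, 1)
    layers: int = 6
    repeats: tuple[int, int] = (8, 8)

    def build(self):
        from .slab import build_fcc_slab
        return build_fcc_slab(self.element, self.lattice_constant,
                              tuple(self.miller), self.layers,
                              tuple(self.repeats))


class SearchSpec(BaseModel):
    n_initial_conformations: int = Field(default=1000, ge=1)
    iterations_per_start: int = Field(default=200, ge=1)
    gamma: float | None = None
    metropolis_temperature: float = 0.15
    cg_tol: float = 1e-4
    cg_max_iter: int = 500
    placement_height: tuple[float, float] = (3.0, 8.0)
    perturb_temperature: float = 500.0
    perturb_steps: int = 300
    perturb_timestep: float = 2.0

    def to_stunbh(self, seed: int = 0) -> StunBhConfig:
        return StunBhConfig(
            n_initial_conformations=self.n_initial_conformations,
            iterations_per_start=self.iterations_per_start,
            gamma=self.gamma,
            metropolis_temperature=self.metropolis_temperature,
            cg_tol=self.cg_tol, cg_max_iter=self.cg_max_iter,
            perturb_md=MDConfig(timestep=self.perturb_timestep,
                                n_steps=self.perturb_steps,
                                temperature=self.perturb_temperature,
                                stride=max(1, self.perturb_steps)),
            seed=seed, placement_height=tuple(self.placement_height))


class MDSpec(BaseModel):
    timestep: float = 0.5
    n_steps: int = 2000
    temperature: float = 300.0
    thermostat: str = "nose-hoover"
    coupling: float = 100.0
    stride: int = 10
    restraint_spring: float = 10.0     # kcal/mol/Å², conformation-keeping stage
    restraint_duration_fs: float = 500.0

    def to_mdconfig(self, seed: int = 0) -> MDConfig:
        return MDConfig(timestep=self.timestep, n_steps=self.n_steps,
                        temperature=self.temperature,
                        thermostat=self.thermostat, coupling=self.coupling,
                        seed=seed, stride=self.stride)


class AnalysisSpec(BaseModel):
    flat_tilt: float = 20.0
    stand_tilt: float = 60.0
    contact_height: float = 4.5
    detach_height: float = 6.0
    registry_tol: float = 0.8
    planarity_rms: float = 0.25

    def to_thresholds(self) -> AnalysisThresholds:
        return AnalysisThresholds(**self.model_dump())


class RunConfig(BaseModel):
    sequence: str = "Ac-SSFPQPN-NH2"
    forcefield: str = "embedded"
    seed: int = 0
    output_dir: str = "runs"
    slab: SlabSpec = Field(default_factory=SlabSpec)
    search: SearchSpec = Field(default_factory=SearchSpec)
    md: MDSpec = Field(default_factory=MDSpec)
    analysis: AnalysisSpec = Field(default_factory=AnalysisSpec)

    def echo(self) -> dict:
        """Full configuration with all defaults filled in."""
        return self.model_dump()

    def write_echo(self, directory) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        out = directory / "config_echo.json"
        out.write_text(json.dumps(self.echo(), indent=2) + "\n")
        return out


def load_run_config(path) -> RunConfig:
    with open(path, "rb") as fh:
        return RunConfig.model_validate(tomllib.load(fh))
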