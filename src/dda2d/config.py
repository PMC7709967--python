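"""Run configuration: schema-validated YAML sections and scene builders.

The reference scenario (all defaults) is the breast-imaging bench case:
81 x 81 dipoles over a 40 cm square (5.0 mm node spacing), a 16-antenna
ring of diameter 15.2 cm, a 6 cm cylinder (eps_r 40, sigma 1.0 S/m) at the
origin in a glycerin-water bath (eps_bath 22, sigma 1.0 S/m), background
permittivity offset to 21.99, operating frequency 1.3 GHz.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, Field, model_validator

from . import geometry, physics
from .assembly import FastOperator, assemble_dense

__all__ = [
    "RunConfig", "default_config", "load_config", "dump_config", "save_config",
    "config_digest", "omega", "build_grid_from_config", "build_antennas",
    "build_phantom", "build_medium", "build_alpha", "build_operator",
]


class GridSection(BaseModel):
    n_side: int = 81
    extent_m: float = 0.40


class AntennaSection(BaseModel):
    count: int = 16
    diameter_m: float = 0.152
    start_angle_deg: float = 0.0


class BackgroundSection(BaseModel):
    eps_bk: float = 21.99
    sigma: float = 1.0
    frequency_hz: float = 1.3e9


class BathSection(BaseModel):
    eps_bath: float = 22.0
    sigma: float = 1.0


class InclusionSection(BaseModel):
    center_m: tuple[float, float] = (0.0, 0.0)
    diameter_m: float = 0.06
    eps_r: float = 40.0
    sigma: float = 1.0


class PhantomSection(BaseModel):
    imaging_radius_m: float = 0.076
    inclusions: list[InclusionSection] = Field(
        default_factory=lambda: [InclusionSection()])


class SourceSection(BaseModel):
    I0: float = 1.0


class PolarizabilitySection(BaseModel):
    # "calibrated": alpha = h^2 (k^2 - k_bk^2)  (converges to the physical field)
    # "maxwell-garnett": dimensionless contrast (eps_t - eps_b)/(eps_t + eps_b)
    scheme: str = "calibrated"
    dimension_factor: float = 1.0


class SolverSection(BaseModel):
    method: str = "cocg"            # direct | cocg | cocr
    backend: str = "fft"            # dense | fft
    tolerance: float = 1e-5
    max_iterations: int = 5000
    power_of_two_padding: bool = True
    matvec_strategy: str = "full2d"  # full2d | block1d


class OutputSection(BaseModel):
    directory: str = "dda2d-out"
    formats: list[str] = Field(default_factory=lambda: ["csv"])


class RunConfig(BaseModel):
    grid: GridSection = Field(default_factory=GridSection)
    antennas: AntennaSection = Field(default_factory=AntennaSection)
    background: BackgroundSection = Field(default_factory=BackgroundSection)
    bath: BathSection = Field(default_factory=BathSection)
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    source: SourceSection = Field(default_factory=SourceSection)
    polarizability: PolarizabilitySection = Field(
        default_factory=PolarizabilitySection)
    solver: SolverSection = Field(default_factory=SolverSection)
    output: OutputSection = Field(default_factory=OutputSection)

    @model_validator(mode="after")
    def _check_offset(self):
        if self.background.eps_bk == self.bath.eps_bath:
            raise ValueError(
                "background.eps_bk must differ from bath.eps_bath "
                "(the bath/background offset keeps every 1/alpha finite)")
        return self


def default_config() -> RunConfig:
    return RunConfig()


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.model_validate(data)


def dump_config(cfg: RunConfig) -> str:
    return yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False)


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(dump_config(cfg))


def config_digest(cfg: RunConfig) -> str:
    """Stable short hash of the fully resolved configuration."""
    blob = json.dumps(cfg.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------- builders

def omega(cfg: RunConfig) -> float:
    return 2.0 * np.pi * cfg.background.frequency_hz


def build_grid_from_config(cfg: RunConfig) -> geometry.Grid2D:
    return geometry.build_grid(cfg.grid.n_side, cfg.grid.extent_m)


def build_antennas(cfg: RunConfig) -> geometry.AntennaArray:
    return geometry.build_antenna_ring(cfg.antennas.count, cfg.antennas.diameter_m,
                                       start_angle_deg=cfg.antennas.start_angle_deg)


def build_phantom(cfg: RunConfig, eps_bk: float | None = None) -> geometry.PhantomSpec:
    incs = tuple(geometry.Inclusion(center=tuple(i.center_m), diameter=i.diameter_m,
                                    eps_r=i.eps_r, sigma=i.sigma)
                 for i in cfg.phantom.inclusions)
    return geometry.PhantomSpec(
        imaging_radius=cfg.phantom.imaging_radius_m,
        inclusions=incs,
        bath=(cfg.bath.eps_bath, cfg.bath.sigma),
        background=(eps_bk if eps_bk is not None else cfg.background.eps_bk,
                    cfg.background.sigma))


def build_medium(cfg: RunConfig, eps_bk: float | None = None,
                 grid: geometry.Grid2D | None = None) -> physics.MediumMap:
    grid = grid if grid is not None else build_grid_from_config(cfg)
    return geometry.rasterize_phantom(grid, build_phantom(cfg, eps_bk), omega(cfg))


def build_alpha(cfg: RunConfig, medium: physics.MediumMap) -> np.ndarray:
    return physics.polarizability_map(
        medium, scheme=cfg.polarizability.scheme,
        dimension_factor=cfg.polarizability.dimension_factor)


def build_operator(cfg: RunConfig, grid, alpha, background):
    """System operator per solver.backend: FastOperator or dense matrix."""
    if cfg.solver.backend == "fft":
        return FastOperator(grid, alpha, background,
                            strategy=cfg.solver.matvec_strategy,
                            power_of_two=cfg.solver.power_of_two_padding)
    return assemble_dense(grid, alpha, background)
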