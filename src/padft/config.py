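"""Run configuration: one YAML/JSON document with strict validation.

Blocks: system (dielectric, temperature, wall charge, salt concentration),
architecture (r, b, d), grid (dz), solver (Picard controls) and scan
(separation schedule).  Unknown keys anywhere are an error.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .model import Grid, SystemParams, build_linear_alternating
from .scf_solver import SolverControls

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SystemBlock(_Strict):
    epsilon_r: float = 78.3
    T: float = 298.0
    sigma: float = -1.0 / 70.0
    c_salt_mM: float = Field(gt=0, description="bulk salt concentration, mM per species")


class ArchitectureBlock(_Strict):
    r: int = 1
    b: float = 4.0
    d: float = 4.0


class GridBlock(_Strict):
    dz: float = 0.25


class SolverBlock(_Strict):
    alpha: float = 0.05
    donnan_damping: float = 1.0
    tol: float = 1e-7
    resid_tol: float = 1e-8
    max_iter: int = 400_000


class ScanBlock(_Strict):
    h_min: float = 10.0
    h_max: float | None = None  # default: max(300, 40 λ_D), rounded to dz
    n_points: int = 40
    spacing: str = "linear"  # or "geometric"


class RunConfig(_Strict):
    system: SystemBlock
    architecture: ArchitectureBlock = ArchitectureBlock()
    grid: GridBlock = GridBlock()
    solver: SolverBlock = SolverBlock()
    scan: ScanBlock = ScanBlock()

    def system_params(self) -> SystemParams:
        arch = build_linear_alternating(
            self.architecture.r, +1, b=self.architecture.b, d=self.architecture.d)
        return SystemParams(cation_arch=arch,
                            c_salt=self.system.c_salt_mM * 1e-3,
                            sigma=self.system.sigma,
                            epsilon_r=self.system.epsilon_r,
                            T=self.system.T)

    def make_grid(self, h: float) -> Grid:
        return Grid(h=h, dz=self.grid.dz, d=self.architecture.d,
                    b=self.architecture.b)

    def solver_controls(self) -> SolverControls:
        s = self.solver
        return SolverControls(alpha=s.alpha, donnan_damping=s.donnan_damping,
                              tol=s.tol, resid_tol=s.resid_tol,
                              max_iter=s.max_iter)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML (or JSON) run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping of blocks")
    return RunConfig.model_validate(raw)
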