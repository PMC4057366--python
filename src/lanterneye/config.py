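"""Run configuration: every fixed constant of the pipeline in one place.

Defaults are the study conventions: Grafen rho = 2.5, 100 random polytomy
resolutions at 1e-6 branch length with 10 selected for analysis, absorption
coefficient k = 0.035 um^-1, flash intensity E = 1e10 photons at r = 1 m
with attenuation alpha = 0.05 m^-1, and the 10x10 um frame on a 320x320 um
grid as the reference sampling design.  A single run seed fans out into
deterministic per-stage child seeds.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .optics import OpticalConstants
from .stereology import SamplingDesign

__all__ = ["RunConfig"]

_STAGES = ("simulate", "stereology", "map", "sensitivity", "signal", "pgls")


@dataclass
class RunConfig:
    seed: int = 0
    # tree preparation
    grafen_rho: float = 2.5
    n_resolutions: int = 100
    n_selected_trees: int = 10
    resolution_branch_length: float = 1e-6
    # optics
    k_um: float = 0.035
    E_photons: float = 1e10
    r_m: float = 1.0
    alpha_m: float = 0.05
    # sampling design (um)
    frame_w: float = 10.0
    frame_h: float = 10.0
    grid_dx: float = 320.0
    grid_dy: float = 320.0
    # map smoothing: sigma in mm; None -> grid step
    sigma_mm: float | None = None
    # paths
    tree_path: str | None = None
    traits_path: str | None = None
    sample_path: str | None = None
    output_dir: str = "lanterneye_out"

    def design(self) -> SamplingDesign:
        return SamplingDesign(self.frame_w, self.frame_h, self.grid_dx, self.grid_dy)

    def constants(self) -> OpticalConstants:
        return OpticalConstants(k=self.k_um, E=self.E_photons, r=self.r_m, alpha=self.alpha_m)

    def child_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the run seed."""
        if stage not in _STAGES:
            raise ValueError(f"unknown stage {stage!r}")
        ss = np.random.SeedSequence([int(self.seed), _STAGES.index(stage)])
        return int(ss.generate_state(1)[0] % (2**31))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)
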