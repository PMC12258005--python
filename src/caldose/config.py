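"""Configuration objects for the simulation and evaluation pipeline.

All knobs of the data-generating process live in :class:`SimulationConfig`;
nested blocks hold the plan-construction model and the ground-truth
estimand geometry.  Configs are plain dataclasses that round-trip through
flat YAML/JSON mappings so experiments are fully described by one file
plus a seed.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml

__all__ = [
    "PlanModelConfig",
    "EstimandConfig",
    "SimulationConfig",
    "load_config",
    "save_config",
    "config_hash",
]


@dataclass
class PlanModelConfig:
    """Structural equations mapping the confounder C to plan parameters,
    and the geometry of the planned dose itself.

    V_T and V_O are Gaussian fall-off scales in pixel units; their base
    scales default to fixed fractions of the grid so that a 25x25 grid is
    the same scene as a 10x10 grid at higher resolution.  M_O controls how
    much dose the plan allows on the organ ray (larger M_O = less
    suppression at the OAR).
    """

    vt_base_frac: float = 0.22     # base tumor fall-off, fraction of min(Nx,Ny)
    vt_slope: float = 0.3          # C -> log V_T
    vo_base_frac: float = 0.15     # base organ-ray fall-off, fraction of grid
    vo_slope: float = 0.3          # C -> -log V_O
    mo_intercept: float = 1.0      # softplus argument offset for M_O
    mo_slope: float = 0.5          # C -> M_O (through softplus)
    param_noise_var: float = 0.1   # variance of each plan-parameter noise term
    halo_frac: float = 0.25        # amplitude of the wide dose bath, rel. dose_max
    halo_width_mult: float = 3.0   # halo width as a multiple of V_T


@dataclass
class EstimandConfig:
    """Geometry and amplitude of the ground-truth effect arrays.

    theta (per-pixel dose response) and xi (per-pixel confounder
    interaction) are Gaussian bumps truncated to a disk whose center sits
    on the organ ray, offset from the OAR.  Radii and widths are fractions
    of min(Nx,Ny) so the non-zero region is sparse at any resolution.
    """

    amplitude_theta: float = 12.0
    amplitude_xi: float = 0.1
    radius_frac: float = 0.30      # disk radius, fraction of min(Nx,Ny)
    width_frac: float = 0.20       # Gaussian width s, fraction of min(Nx,Ny)
    center_offset_frac: float = 0.2  # offset of disk center along the ray


@dataclass
class SimulationConfig:
    """All knobs of the data-generating process.

    Uncertainty parameters follow the simulation study's parameter table:
    ``sigma2_ud`` is the per-pixel white-noise (dosimetric) variance,
    ``m_gp`` the magnitude of the Gaussian-process motion field,
    ``sigma2_gp`` the RBF-kernel parameter of that field, and ``sigma2_l``
    the variance of the rigid setup shift in each axis.
    """

    nx: int = 10
    ny: int = 10
    n_obs: int = 500
    sigma2_ud: float = 3e-2
    m_gp: float = 3e-2
    sigma2_gp: float = 3e-2
    sigma2_l: float = 3e-2
    sigma2_uy: float = 1.0
    seed: int = 0
    oar_center: Optional[Tuple[int, int]] = None  # default: grid center
    dose_max: float = 10.0
    tumor_exclusion_radius: int = 2
    # "length_scale_sq": sigma2_gp is the squared length-scale of the RBF
    # kernel (field has unit marginal variance, scaled by m_gp).
    # "variance": sigma2_gp additionally scales the field's variance, with a
    # fixed unit length-scale.
    gp_sigma2_role: str = "length_scale_sq"
    confounded: bool = True        # False severs the C -> (V_O, M_O, V_T) links
    plan: PlanModelConfig = field(default_factory=PlanModelConfig)
    estimand: EstimandConfig = field(default_factory=EstimandConfig)

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid dimensions must be positive integers")
        if self.n_obs < 1:
            raise ValueError("n_obs must be >= 1")
        for name in ("sigma2_ud", "m_gp", "sigma2_l", "sigma2_uy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.sigma2_gp <= 0:
            raise ValueError("sigma2_gp must be positive")
        if self.dose_max <= 0:
            raise ValueError("dose_max must be positive")
        if self.gp_sigma2_role not in ("length_scale_sq", "variance"):
            raise ValueError("gp_sigma2_role must be 'length_scale_sq' or 'variance'")
        if self.oar_center is not None:
            i, j = self.oar_center
            if not (0 <= i < self.nx and 0 <= j < self.ny):
                raise ValueError("oar_center must lie inside the grid")
            self.oar_center = (int(i), int(j))
        if isinstance(self.plan, dict):
            self.plan = PlanModelConfig(**self.plan)
        if isinstance(self.estimand, dict):
            self.estimand = EstimandConfig(**self.estimand)

    @property
    def grid_shape(self) -> Tuple[int, int]:
        return (self.nx, self.ny)

    @property
    def n_pixels(self) -> int:
        return self.nx * self.ny

    def resolved_oar_center(self) -> Tuple[int, int]:
        if self.oar_center is not None:
            return self.oar_center
        return (self.nx // 2, self.ny // 2)

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["oar_center"] is not None:
            d["oar_center"] = list(d["oar_center"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown configuration key(s): {sorted(unknown)}")
        if d.get("oar_center") is not None:
            d["oar_center"] = tuple(d["oar_center"])
        return cls(**d)


def load_config(path) -> SimulationConfig:
    """Read a :class:`SimulationConfig` from a YAML (or JSON) file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return SimulationConfig.from_dict(data)


def save_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: SimulationConfig) -> int:
    """Stable 31-bit hash of a config, used to derive per-setting seed
    streams that are reproducible across processes."""
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return zlib.crc32(payload) & 0x7FFFFFFF
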