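"""Synthetic radiotherapy cohort generator.

Implements the structural causal model behind the simulation study:

    C  ->  (V_O, M_O, V_T)  ->  D_plan  ->  D_del  ->  Y  <-  C

A scalar patient covariate C (e.g. concurrent chemotherapy dose)
personalizes the treatment plan through three clinical parameters — tumor
dose fall-off V_T, organ-ray fall-off V_O and organ-ray dose magnitude
M_O — and simultaneously affects the outcome directly, making it a
confounder of the dose–outcome relationship.  Plans place a Gaussian dose
peak on a randomly located tumor while suppressing dose along a fixed
"organ ray" through the OAR.  Delivery perturbs the plan with three
uncertainty mechanisms: a rigid setup shift, a spatially correlated
Gaussian-process motion field, and per-pixel white dosimetric noise.
The outcome is linear in the delivered dose:

    Y = 5 C + U_Y + sum_ij [ D_ij theta_ij + (C/2) D_ij xi_ij ]

with sparse ground-truth effect (theta) and interaction (xi) arrays.
Because Var(C) = 1, the per-patient effect theta_ij + (C/2) xi_ij has
variance xi_ij^2 / 4 and expectation theta_ij, so theta is both the ATE
and the CATE at C = 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage

from .config import SimulationConfig

__all__ = [
    "Patient",
    "EstimandArrays",
    "Cohort",
    "sample_confounder",
    "sample_plan_parameters",
    "place_tumor",
    "plan_dose",
    "gp_cholesky",
    "apply_uncertainties",
    "make_estimand_arrays",
    "generate_outcome",
    "outcome_from_components",
    "simulate_cohort",
]

# Plan-parameter noise floor keeps exp/softplus arguments finite.
_C_COEF = 5.0  # fixed direct C -> Y coefficient of the outcome model


@dataclass
class EstimandArrays:
    """Ground truth: per-pixel ATE array theta and interaction array xi."""

    theta: np.ndarray
    xi: np.ndarray

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.xi = np.asarray(self.xi, dtype=float)
        if self.theta.shape != self.xi.shape:
            raise ValueError("theta and xi must share a shape")


@dataclass
class Patient:
    """One simulated treatment."""

    C: float
    V_O: float
    M_O: float
    V_T: float
    tumor_center: Tuple[int, int]
    D_plan: np.ndarray
    D_del: np.ndarray
    Y: float


@dataclass
class Cohort:
    """A simulated cohort stored column-wise, with ground truth attached."""

    config: SimulationConfig
    C: np.ndarray                # (n,)
    V_O: np.ndarray              # (n,)
    M_O: np.ndarray              # (n,)
    V_T: np.ndarray              # (n,)
    tumor_centers: np.ndarray    # (n, 2) int
    D_plan: np.ndarray           # (n, nx, ny)
    D_del: np.ndarray            # (n, nx, ny)
    U_Y: np.ndarray              # (n,)
    Y: np.ndarray                # (n,)
    estimands: EstimandArrays

    @property
    def n_obs(self) -> int:
        return len(self.Y)

    @property
    def grid_shape(self) -> Tuple[int, int]:
        return self.D_plan.shape[1:]

    def patient(self, k: int) -> Patient:
        return Patient(
            C=float(self.C[k]),
            V_O=float(self.V_O[k]),
            M_O=float(self.M_O[k]),
            V_T=float(self.V_T[k]),
            tumor_center=(int(self.tumor_centers[k, 0]), int(self.tumor_centers[k, 1])),
            D_plan=self.D_plan[k],
            D_del=self.D_del[k],
            Y=float(self.Y[k]),
        )

    def plan_params(self) -> np.ndarray:
        """(n, 3) array of [V_O, M_O, V_T], the back-door adjustment block."""
        return np.column_stack([self.V_O, self.M_O, self.V_T])


def sample_confounder(n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n confounder values C ~ Normal(0, 1).

    Unit variance is forced by the outcome model: with the (C/2)
    interaction, the per-patient effect variance must equal xi^2/4.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    return rng.standard_normal(n)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def sample_plan_parameters(
    C: np.ndarray,
    rng: np.random.Generator,
    config: SimulationConfig,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample (V_O, M_O, V_T) as positive, non-linear, noisy functions of C.

    V_T and V_O are lognormal in C (opposite slopes: patients receiving
    e.g. more chemotherapy get tighter organ sparing but broader tumor
    margins); M_O is a softplus, keeping all three strictly positive.
    When ``config.confounded`` is False, the C links are severed and the
    parameters are sampled around C = 0 (interventional ablation).
    """
    C = np.asarray(C, dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("C must be finite")
    p = config.plan
    scale = min(config.nx, config.ny)
    c_eff = C if config.confounded else np.zeros_like(C)
    sd = np.sqrt(p.param_noise_var)
    eps_t = rng.normal(0.0, sd, size=C.shape)
    eps_o = rng.normal(0.0, sd, size=C.shape)
    eps_m = rng.normal(0.0, sd, size=C.shape)
    V_T = p.vt_base_frac * scale * np.exp(p.vt_slope * c_eff + eps_t)
    V_O = p.vo_base_frac * scale * np.exp(-p.vo_slope * c_eff + eps_o)
    M_O = _softplus(p.mo_intercept + p.mo_slope * c_eff + eps_m)
    return V_O, M_O, V_T


def place_tumor(
    rng: np.random.Generator,
    config: SimulationConfig,
    exclusion_radius: Optional[int] = None,
) -> Tuple[int, int]:
    """Uniformly place the tumor on the grid, outside a Chebyshev
    exclusion zone around the (fixed) OAR."""
    if exclusion_radius is None:
        exclusion_radius = config.tumor_exclusion_radius
    oi, oj = config.resolved_oar_center()
    ii, jj = np.meshgrid(np.arange(config.nx), np.arange(config.ny), indexing="ij")
    allowed = np.maximum(np.abs(ii - oi), np.abs(jj - oj)) > exclusion_radius
    if exclusion_radius <= 0:
        allowed = np.ones((config.nx, config.ny), dtype=bool)
    idx = np.flatnonzero(allowed)
    if idx.size == 0:
        raise ValueError("tumor exclusion radius covers the whole grid")
    k = idx[rng.integers(idx.size)]
    return (int(k // config.ny), int(k % config.ny))


def plan_dose(
    tumor_center: Tuple[int, int],
    V_O: float,
    M_O: float,
    V_T: float,
    config: SimulationConfig,
) -> np.ndarray:
    """Construct the planned dose for one patient (deterministic).

    The plan is a Gaussian peak of height ``dose_max`` at the tumor (width
    V_T) riding on a wide low-amplitude halo (the entrance/exit dose bath
    of a rotational delivery), multiplied by a suppression factor along
    the organ ray — the horizontal line of pixels through the OAR:

        D = dose_max * [G_T + halo] * (1 - exp(-M_O) * exp(-d_R^2 / 2 V_O^2))

    Larger M_O permits more dose on the ray; larger V_O widens the sparing
    trough; larger V_T gives a shallower tumor fall-off.
    """
    if V_O <= 0 or V_T <= 0:
        raise ValueError("fall-off parameters V_O and V_T must be positive")
    if M_O < 0:
        raise ValueError("M_O must be non-negative")
    ti, tj = tumor_center
    if not (0 <= ti < config.nx and 0 <= tj < config.ny):
        raise ValueError("tumor_center outside grid")
    oi, _ = config.resolved_oar_center()
    p = config.plan
    ii, jj = np.meshgrid(np.arange(config.nx), np.arange(config.ny), indexing="ij")
    d2_t = (ii - ti) ** 2.0 + (jj - tj) ** 2.0
    core = np.exp(-d2_t / (2.0 * V_T**2))
    halo = p.halo_frac * np.exp(-d2_t / (2.0 * (p.halo_width_mult * V_T) ** 2))
    d_r = np.abs(ii - oi)  # perpendicular distance to the organ ray (a row)
    suppression = 1.0 - np.exp(-M_O) * np.exp(-(d_r**2.0) / (2.0 * V_O**2))
    dose = config.dose_max * (core + halo) * suppression
    return np.clip(dose, 0.0, None)


def gp_cholesky(config: SimulationConfig) -> np.ndarray:
    """Cholesky factor of the RBF covariance over pixel coordinates.

    k(x, x') = exp(-||x - x'||^2 / (2 sigma2_gp)) with unit diagonal, so
    the sampled field has unit marginal variance before scaling by m_gp.
    Under the alternative 'variance' role, the kernel has unit length
    scale and the field is later scaled by sqrt(sigma2_gp) as well.
    """
    ii, jj = np.meshgrid(np.arange(config.nx), np.arange(config.ny), indexing="ij")
    coords = np.column_stack([ii.ravel(), jj.ravel()]).astype(float)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    if config.gp_sigma2_role == "length_scale_sq":
        ls2 = config.sigma2_gp
    else:
        ls2 = 1.0
    K = np.exp(-d2 / (2.0 * ls2))
    K[np.diag_indices_from(K)] += 1e-10
    return np.linalg.cholesky(K)


def _gp_scale(config: SimulationConfig) -> float:
    if config.gp_sigma2_role == "variance":
        return config.m_gp * np.sqrt(config.sigma2_gp)
    return config.m_gp


def apply_uncertainties(
    D_plan: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
    gp_chol: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Perturb a planned dose into a delivered dose.

    Order of application: rigid setup shift of the planned field
    (continuous (Lx, Ly) ~ N(0, sigma2_l), bilinear interpolation with
    edge-clamped boundary), then the additive GP motion field, then
    per-pixel white dosimetric noise.  Negative values are kept: the
    estimators are linear and clipping would distort the causal model.
    """
    D_plan = np.asarray(D_plan, dtype=float)
    if D_plan.shape != (config.nx, config.ny):
        raise ValueError("D_plan shape does not match config grid")
    lx, ly = rng.normal(0.0, np.sqrt(config.sigma2_l), size=2)
    shifted = ndimage.shift(D_plan, (lx, ly), order=1, mode="nearest")
    out = shifted
    scale = _gp_scale(config)
    if scale > 0:
        if gp_chol is None:
            gp_chol = gp_cholesky(config)
        z = rng.standard_normal(config.n_pixels)
        out = out + scale * (gp_chol @ z).reshape(config.nx, config.ny)
    if config.sigma2_ud > 0:
        out = out + rng.normal(0.0, np.sqrt(config.sigma2_ud), size=D_plan.shape)
    return out


def make_estimand_arrays(config: SimulationConfig) -> EstimandArrays:
    """Build the sparse ground-truth effect arrays (deterministic).

    theta is a truncated Gaussian bump A_theta * exp(-d^2 / 2 s^2) on a
    disk of radius r centered on the organ ray, offset from the OAR; xi is
    the same bump with amplitude A_xi.  Radii/widths scale with the grid
    so fewer than half the pixels are non-zero at any resolution.
    """
    e = config.estimand
    scale = min(config.nx, config.ny)
    oi, oj = config.resolved_oar_center()
    cj = min(config.ny - 1, oj + int(round(e.center_offset_frac * config.ny)))
    ci = oi
    r = e.radius_frac * scale
    s = e.width_frac * scale
    ii, jj = np.meshgrid(np.arange(config.nx), np.arange(config.ny), indexing="ij")
    d2 = (ii - ci) ** 2.0 + (jj - cj) ** 2.0
    disk = d2 <= r**2
    bump = np.exp(-d2 / (2.0 * s**2)) * disk
    return EstimandArrays(theta=e.amplitude_theta * bump, xi=e.amplitude_xi * bump)


def outcome_from_components(
    C: np.ndarray,
    D_del: np.ndarray,
    estimands: EstimandArrays,
    U_Y: np.ndarray,
) -> np.ndarray:
    """Deterministic part of the outcome model given the noise draw."""
    C = np.atleast_1d(np.asarray(C, dtype=float))
    D = np.asarray(D_del, dtype=float)
    if D.ndim == 2:
        D = D[None, :, :]
    if D.shape[1:] != estimands.theta.shape:
        raise ValueError("dose and estimand shapes disagree")
    if D.shape[0] != C.shape[0]:
        raise ValueError("number of dose arrays does not match C")
    dose_effect = np.tensordot(D, estimands.theta, axes=([1, 2], [0, 1]))
    interaction = np.tensordot(D, estimands.xi, axes=([1, 2], [0, 1]))
    return _C_COEF * C + np.asarray(U_Y, dtype=float) + dose_effect + (C / 2.0) * interaction


def generate_outcome(
    C: np.ndarray,
    D_del: np.ndarray,
    estimands: EstimandArrays,
    sigma2_uy: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw outcomes Y = 5C + U_Y + sum_ij [D_ij theta_ij + (C/2) D_ij xi_ij].

    Returns ``(Y, U_Y)`` so that outcomes can be regenerated exactly from
    the stored noise.
    """
    if sigma2_uy < 0:
        raise ValueError("sigma2_uy must be non-negative")
    C = np.atleast_1d(np.asarray(C, dtype=float))
    U_Y = rng.normal(0.0, np.sqrt(sigma2_uy), size=C.shape)
    return outcome_from_components(C, D_del, estimands, U_Y), U_Y


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a full cohort by chaining the SCM, from one seeded stream.

    Pure function of (config, config.seed): identical configs produce
    bitwise-identical cohorts.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_obs
    C = sample_confounder(n, rng)
    V_O, M_O, V_T = sample_plan_parameters(C, rng, config)
    centers = np.empty((n, 2), dtype=int)
    D_plan = np.empty((n, config.nx, config.ny))
    for k in range(n):
        centers[k] = place_tumor(rng, config)
        D_plan[k] = plan_dose(tuple(centers[k]), V_O[k], M_O[k], V_T[k], config)
    chol = gp_cholesky(config) if _gp_scale(config) > 0 else None
    D_del = np.empty_like(D_plan)
    for k in range(n):
        D_del[k] = apply_uncertainties(D_plan[k], config, rng, gp_chol=chol)
    estimands = make_estimand_arrays(config)
    Y, U_Y = generate_outcome(C, D_del, estimands, config.sigma2_uy, rng)
    return Cohort(
        config=config,
        C=C,
        V_O=V_O,
        M_O=M_O,
        V_T=V_T,
        tumor_centers=centers,
        D_plan=D_plan,
        D_del=D_del,
        U_Y=U_Y,
        Y=Y,
        estimands=estimands,
    )
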