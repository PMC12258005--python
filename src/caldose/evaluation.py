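"""Monte Carlo evaluation harness.

For each (simulation setting, estimator) pair the harness repeats
simulate -> fit ``n_sim`` times with derived per-replicate seeds and
summarizes the per-pixel estimates against the ground-truth array:

    B_ij     = mean_k theta_hat_ijk - theta_ij          (bias array)
    MSE_ij   = mean_k (theta_hat_ijk - theta_ij)^2      (per-pixel MSE)
    MSE_tot  = sum_ij MSE_ij                            (global metric)

Non-converged replicates are excluded from the averages and counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cohort import make_estimand_arrays, simulate_cohort
from .config import SimulationConfig, config_hash
from .estimators import METHODS, EffectEstimate

__all__ = [
    "EvaluationSummary",
    "parameter_grid",
    "uncertainty_subset",
    "replicate_seed",
    "monte_carlo",
    "run_grid",
    "bias_map_report",
    "STUDY_UNCERTAINTY_VALUES",
]

# The study's tested values for each uncertainty parameter / cohort size / grid.
STUDY_UNCERTAINTY_VALUES = (3e-12, 3e-2, 3e-1, 3.0)
STUDY_N_OBS_VALUES = (50, 100, 500)
STUDY_GRID_SIZES = (10, 25)


@dataclass
class EvaluationSummary:
    """Monte Carlo summary for one (method, setting) pair."""

    method: str
    setting: SimulationConfig
    n_sim: int
    n_converged: int
    theta_hat_bar: Optional[np.ndarray]
    bias: Optional[np.ndarray]
    mse: Optional[np.ndarray]
    mse_tot: Optional[float]
    valid: bool
    estimates: List[EffectEstimate] = field(default_factory=list, repr=False)

    def setting_key(self) -> Tuple[float, float, float, float]:
        s = self.setting
        return (s.sigma2_ud, s.m_gp, s.sigma2_gp, s.sigma2_l)


def replicate_seed(master_seed: int, setting: SimulationConfig, k: int) -> int:
    """Derive a 31-bit replicate seed from (master seed, setting, index)."""
    ss = np.random.SeedSequence([int(master_seed), config_hash(setting), int(k)])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def monte_carlo(
    setting: SimulationConfig,
    method: str,
    n_sim: int,
    seed: int,
    keep_estimates: bool = False,
) -> EvaluationSummary:
    """Run n_sim simulate->fit cycles and summarize bias / MSE / MSE_tot."""
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if method not in METHODS:
        raise KeyError(f"unknown method {method!r}; valid: {sorted(METHODS)}")
    theta_true = make_estimand_arrays(setting).theta
    fitter = METHODS[method]
    thetas = []
    estimates: List[EffectEstimate] = []
    n_conv = 0
    for k in range(n_sim):
        rseed = replicate_seed(seed, setting, k)
        cohort = simulate_cohort(setting.replace(seed=rseed))
        est = fitter(cohort, rseed + 1)
        if keep_estimates:
            estimates.append(est)
        if est.converged and est.theta_hat is not None:
            thetas.append(np.asarray(est.theta_hat, dtype=float))
            n_conv += 1
    if n_conv == 0:
        return EvaluationSummary(
            method=method, setting=setting, n_sim=n_sim, n_converged=0,
            theta_hat_bar=None, bias=None, mse=None, mse_tot=None,
            valid=False, estimates=estimates,
        )
    stack = np.stack(thetas)
    theta_bar = stack.mean(axis=0)
    bias = theta_bar - theta_true
    mse = ((stack - theta_true) ** 2).mean(axis=0)
    return EvaluationSummary(
        method=method, setting=setting, n_sim=n_sim, n_converged=n_conv,
        theta_hat_bar=theta_bar, bias=bias, mse=mse,
        mse_tot=float(mse.sum()), valid=True, estimates=estimates,
    )


def parameter_grid(
    base: Optional[SimulationConfig] = None,
    n_obs_values: Sequence[int] = STUDY_N_OBS_VALUES,
    grid_sizes: Sequence[int] = STUDY_GRID_SIZES,
    uncertainty_values: Sequence[float] = STUDY_UNCERTAINTY_VALUES,
) -> List[SimulationConfig]:
    """Full factorial grid of settings (the full-scale study sweep).

    At default arguments and one grid size this enumerates
    3 * 4^4 = 768 settings per method.
    """
    if base is None:
        base = SimulationConfig()
    settings = []
    for g in grid_sizes:
        for n in n_obs_values:
            for ud in uncertainty_values:
                for mgp in uncertainty_values:
                    for sgp in uncertainty_values:
                        for sl in uncertainty_values:
                            settings.append(base.replace(
                                nx=g, ny=g, n_obs=n, oar_center=None,
                                sigma2_ud=ud, m_gp=mgp, sigma2_gp=sgp, sigma2_l=sl,
                            ))
    if not settings:
        raise ValueError("empty parameter grid")
    return settings


def uncertainty_subset(
    base: Optional[SimulationConfig] = None,
    grid_size: int = 10,
    n_obs: int = 500,
    baseline: float = 3e-2,
    sweep_values: Sequence[float] = (3e-12, 3e-1, 3.0),
) -> List[SimulationConfig]:
    """One-at-a-time sweep spanning the tested uncertainty values.

    Each of the four uncertainty parameters is swept over
    ``sweep_values`` while the others sit at ``baseline`` — 12 settings
    covering all four tabulated values of every parameter.
    """
    if base is None:
        base = SimulationConfig()
    base = base.replace(nx=grid_size, ny=grid_size, n_obs=n_obs, oar_center=None,
                        sigma2_ud=baseline, m_gp=baseline,
                        sigma2_gp=baseline, sigma2_l=baseline)
    settings = []
    for param in ("sigma2_ud", "m_gp", "sigma2_gp", "sigma2_l"):
        for v in sweep_values:
            settings.append(base.replace(**{param: v}))
    return settings


def representative_subset_25(
    base: Optional[SimulationConfig] = None,
    n_obs: int = 500,
    baseline: float = 3e-2,
) -> List[SimulationConfig]:
    """Three representative 25x25 uncertainty settings: the moderate
    baseline, large dosimetric noise, and large setup shifts."""
    if base is None:
        base = SimulationConfig()
    base = base.replace(nx=25, ny=25, n_obs=n_obs, oar_center=None,
                        sigma2_ud=baseline, m_gp=baseline,
                        sigma2_gp=baseline, sigma2_l=baseline)
    return [base, base.replace(sigma2_ud=3.0), base.replace(sigma2_l=3.0)]


def run_grid(
    settings: Iterable[SimulationConfig],
    methods: Sequence[str],
    n_sim: int,
    seed: int,
    on_error: str = "log",
) -> Tuple[pd.DataFrame, List[EvaluationSummary]]:
    """Evaluate each method on each setting; returns a long-format table
    plus the underlying summaries.  Per-setting failures are logged and
    skipped rather than aborting the sweep."""
    settings = list(settings)
    if not settings:
        raise ValueError("empty settings list")
    rows = []
    summaries = []
    for setting in settings:
        for method in methods:
            try:
                summ = monte_carlo(setting, method, n_sim, seed)
            except Exception as exc:
                if on_error == "raise":
                    raise
                print(f"[run_grid] {method} failed on setting "
                      f"{config_hash(setting)}: {exc}")
                continue
            summaries.append(summ)
            rows.append({
                "method": method,
                "n_obs": setting.n_obs,
                "nx": setting.nx,
                "ny": setting.ny,
                "sigma2_ud": setting.sigma2_ud,
                "m_gp": setting.m_gp,
                "sigma2_gp": setting.sigma2_gp,
                "sigma2_l": setting.sigma2_l,
                "n_sim": n_sim,
                "n_converged": summ.n_converged,
                "mse_tot": summ.mse_tot if summ.valid else np.nan,
            })
    return pd.DataFrame(rows), summaries


def _setting_tag(summary: EvaluationSummary) -> str:
    ud, mgp, sgp, sl = summary.setting_key()
    return f"sud{ud:g}_mgp{mgp:g}_sgp{sgp:g}_sl{sl:g}"


def bias_map_report(
    summaries: Sequence[EvaluationSummary],
    out_dir=None,
    render: bool = False,
) -> Dict[str, np.ndarray]:
    """Collect bias arrays keyed by the uncertainty-parameter tuple
    {sigma2_ud, m_gp, sigma2_gp, sigma2_l}; optionally dump .npy files
    and rendered heatmaps."""
    out: Dict[str, np.ndarray] = {}
    for summ in summaries:
        if not summ.valid:
            continue
        key = f"{summ.method}_{_setting_tag(summ)}"
        out[key] = summ.bias
    if out_dir is not None:
        from pathlib import Path

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for key, arr in out.items():
            np.save(out_dir / f"bias_{key}.npy", arr)
        if render:
            import matplotlib

            matplotlib.use("Agg")
            import matplotlib.pyplot as plt

            for key, arr in out.items():
                fig, ax = plt.subplots(figsize=(4, 3.5))
                im = ax.imshow(arr, origin="upper", cmap="RdBu_r")
                fig.colorbar(im, ax=ax)
                ax.set_title(key, fontsize=8)
                fig.savefig(out_dir / f"bias_{key}.png", dpi=120)
                plt.close(fig)
    return out
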