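"""Per-pixel causal-effect estimators.

Five estimators of the per-pixel average treatment effect (ATE) of dose
on outcome are provided, as scikit-learn style estimator classes plus
thin cohort-level convenience functions:

* ``PixelwiseRegressor`` — the field's de-facto voxel-based analysis: an
  independent univariate OLS of outcome on dose at each pixel, with no
  covariate adjustment.  Run on planned or delivered dose.
* ``CausalLinearRegressor`` — one multivariable OLS of outcome on every
  delivered-dose pixel plus the back-door adjustment covariates
  {V_O, M_O, V_T}; isolates the causal framework without sparsity.
* ``AdaptiveLasso`` — a weighted lasso with data-driven per-column
  penalties w_j = 1/|beta*_j|^gamma, the pilot beta* coming from a
  cross-validated ridge regression; selected columns enjoy the oracle
  property.  Columns may be forced in (weight exactly zero).
* ``CausalAdaptiveLasso`` (CAL) — the adaptive lasso on the full
  adjustment set, with {V_O, M_O, V_T} forced in; one fit yields the
  whole effect array.
* ``PixelwiseCausalAdaptiveLasso`` — Nx*Ny separate adaptive-lasso fits;
  fit (i, j) additionally forces in the dose column D_ij.

The weighted-lasso penalty is implemented exactly by column rescaling:
unpenalized columns are projected out (Frisch–Waugh–Lovell), each
penalized column j is scaled by 1/w_j, a standard lasso is solved, and
coefficients are back-scaled.  For a fixed penalty this reproduces the
joint minimizer of

    sum_i (y_i - b0 - sum_j X_ij b_j)^2 + lam * sum_j w_j |b_j|.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Lasso, LassoCV
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .cohort import Cohort

__all__ = [
    "DesignMatrix",
    "AdaptiveLassoFit",
    "EffectEstimate",
    "PixelwiseRegressor",
    "CausalLinearRegressor",
    "AdaptiveLasso",
    "adaptive_weights_from_pilot",
    "CausalAdaptiveLasso",
    "PixelwiseCausalAdaptiveLasso",
    "build_adjustment_set",
    "build_design_matrix",
    "compute_adaptive_weights",
    "fit_adaptive_lasso",
    "fit_pixelwise",
    "fit_causal_no_sparsity",
    "fit_cal",
    "fit_pixelwise_cal",
    "METHODS",
]

WEIGHT_TOL = 1e-8  # |beta*| below this => column excluded from the lasso


def adaptive_weights_from_pilot(
    beta_star: np.ndarray, gamma: float = 1.0, tol: float = WEIGHT_TOL
) -> np.ndarray:
    """w_j = 1 / |beta*_j|^gamma; infinite where the pilot coefficient is
    numerically zero (such columns are excluded from the lasso)."""
    beta_star = np.asarray(beta_star, dtype=float)
    w = np.full(beta_star.shape, np.inf)
    ok = np.abs(beta_star) >= tol
    w[ok] = 1.0 / np.abs(beta_star[ok]) ** gamma
    return w


# ---------------------------------------------------------------------------
# Domain containers


@dataclass
class DesignMatrix:
    """A regression design: features, labels, outcome and penalty mask
    (1 = penalized, 0 = forced in / unpenalized)."""

    X: np.ndarray
    feature_labels: List[str]
    y: np.ndarray
    penalty_mask: np.ndarray

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.penalty_mask = np.asarray(self.penalty_mask)
        if self.X.shape[1] != len(self.feature_labels):
            raise ValueError("labels do not match design columns")
        if self.X.shape[1] != self.penalty_mask.shape[0]:
            raise ValueError("penalty mask does not match design columns")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts disagree")


@dataclass
class AdaptiveLassoFit:
    """Result of one adaptive-lasso regression (original column order)."""

    beta_hat: np.ndarray
    weights: np.ndarray
    lambda_ridge: Optional[float]
    lambda_lasso: float
    support: np.ndarray
    intercept: float


@dataclass
class EffectEstimate:
    """One estimator's per-pixel ATE array for one cohort."""

    theta_hat: Optional[np.ndarray]
    method: str
    converged: bool
    diagnostics: Dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Adjustment sets and design construction


def pixel_label(i: int, j: int) -> str:
    return f"D_{i}_{j}"


def build_adjustment_set(
    pixel: Tuple[int, int],
    grid_shape: Tuple[int, int],
    variant: str = "b",
) -> List[str]:
    """Back-door adjustment set for the ATE of D_ij on Y.

    Variant 'a' adjusts for all other dose pixels plus the confounder C;
    variant 'b' (the default, more robust to direct plan-parameter
    effects) replaces C with the plan parameters {V_O, M_O, V_T}.
    """
    nx, ny = grid_shape
    i, j = pixel
    if not (0 <= i < nx and 0 <= j < ny):
        raise ValueError(f"pixel {pixel} outside {grid_shape} grid")
    if variant not in ("a", "b"):
        raise ValueError("variant must be 'a' or 'b'")
    labels = [pixel_label(a, b) for a in range(nx) for b in range(ny) if (a, b) != (i, j)]
    labels += ["C"] if variant == "a" else ["V_O", "M_O", "V_T"]
    return labels


def build_design_matrix(
    cohort: Cohort,
    which_dose: str = "delivered",
    forced_pixel: Optional[Tuple[int, int]] = None,
) -> DesignMatrix:
    """Full-adjustment design: all dose pixels plus {V_O, M_O, V_T}.

    The plan-parameter columns are always unpenalized; ``forced_pixel``
    additionally unpenalizes one dose column (pixel-wise CAL).
    """
    nx, ny = cohort.grid_shape
    dose = cohort.D_plan if which_dose == "planned" else cohort.D_del
    X = np.column_stack([dose.reshape(cohort.n_obs, -1), cohort.plan_params()])
    labels = [pixel_label(i, j) for i in range(nx) for j in range(ny)]
    labels += ["V_O", "M_O", "V_T"]
    mask = np.ones(X.shape[1], dtype=int)
    mask[-3:] = 0
    if forced_pixel is not None:
        i, j = forced_pixel
        if not (0 <= i < nx and 0 <= j < ny):
            raise ValueError(f"pixel {forced_pixel} outside grid")
        mask[i * ny + j] = 0
    return DesignMatrix(X=X, feature_labels=labels, y=cohort.Y, penalty_mask=mask)


# ---------------------------------------------------------------------------
# Pixel-wise (voxel-based) regression


class PixelwiseRegressor(BaseEstimator, RegressorMixin):
    """Voxel-based analysis: univariate OLS slope of y on each dose column.

    Parameters
    ----------
    grid_shape : (nx, ny) or None
        If given, ``theta_hat_`` is reshaped to the dose grid.
    var_tol : float
        Dose columns with variance below this are flagged degenerate and
        assigned a zero slope.
    """

    def __init__(self, grid_shape: Optional[Tuple[int, int]] = None, var_tol: float = 1e-12):
        self.grid_shape = grid_shape
        self.var_tol = var_tol

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim == 3:  # (n, nx, ny) dose stack accepted directly
            X = X.reshape(X.shape[0], -1)
        n = X.shape[0]
        if n < 3:
            raise ValueError("need at least 3 observations")
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        var = (Xc**2).sum(axis=0) / n
        degenerate = var <= self.var_tol
        cov = Xc.T @ yc / n
        slopes = np.zeros(X.shape[1])
        ok = ~degenerate
        slopes[ok] = cov[ok] / var[ok]
        if self.grid_shape is not None:
            slopes = slopes.reshape(self.grid_shape)
            degenerate = degenerate.reshape(self.grid_shape)
        self.theta_hat_ = slopes
        self.degenerate_mask_ = degenerate
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        # Per-pixel slopes do not form a joint predictive model; expose the
        # mean response under the fitted marginal slopes for completeness.
        check_is_fitted(self, "theta_hat_")
        X = np.asarray(X, dtype=float)
        if X.ndim == 3:
            X = X.reshape(X.shape[0], -1)
        return X @ np.ravel(self.theta_hat_)


# ---------------------------------------------------------------------------
# Causal regression without sparsity


class CausalLinearRegressor(BaseEstimator, RegressorMixin):
    """OLS on the full adjustment design [D pixels | V_O, M_O, V_T].

    Declares non-convergence (``converged_ = False``) when the design with
    intercept is rank-deficient or has at least as many features as
    observations — no pseudo-inverse fallback, mirroring the breakdown of
    an unregularized regression at high resolution.
    """

    def __init__(self, grid_shape: Optional[Tuple[int, int]] = None):
        self.grid_shape = grid_shape

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        Z = np.column_stack([np.ones(n), X])
        self.n_features_in_ = p
        if p >= n or np.linalg.matrix_rank(Z) < p + 1:
            self.converged_ = False
            self.coef_ = None
            self.intercept_ = None
            self.theta_hat_ = None
            return self
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        self.converged_ = True
        self.intercept_ = beta[0]
        self.coef_ = beta[1:]
        theta = self.coef_[: p - 3] if p > 3 else self.coef_.copy()
        self.theta_hat_ = theta.reshape(self.grid_shape) if self.grid_shape else theta
        return self

    def predict(self, X):
        check_is_fitted(self, "converged_")
        if not self.converged_:
            raise RuntimeError("fit did not converge; no predictions available")
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_


# ---------------------------------------------------------------------------
# Adaptive lasso


def _residualizer(Z: np.ndarray):
    """Return functions projecting onto / out of span(Z) via QR."""
    Q, _ = np.linalg.qr(Z)

    def residualize(A: np.ndarray) -> np.ndarray:
        return A - Q @ (Q.T @ A)

    return residualize


def _lasso_alpha_grid(Xw: np.ndarray, yr: np.ndarray, n_alphas: int, eps: float) -> np.ndarray:
    n = Xw.shape[0]
    alpha_max = np.max(np.abs(Xw.T @ yr)) / n
    if alpha_max <= 0:
        alpha_max = 1.0
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max * eps), n_alphas)


def _ridge_cv_path(
    X: np.ndarray,
    y: np.ndarray,
    alphas: np.ndarray,
    cv_folds: int,
    random_state: int,
) -> Tuple[np.ndarray, float]:
    """K-fold CV ridge over an alpha grid, one SVD per fold.

    Minimizes ||y - X b||^2 + alpha ||b||^2 (no intercept: inputs are
    pre-residualized).  Returns (coefficients at best alpha, best alpha).
    """
    n = X.shape[0]
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=random_state)
    cv_err = np.zeros(len(alphas))
    for tr, va in kf.split(X):
        U, s, Vt = np.linalg.svd(X[tr], full_matrices=False)
        Uty = U.T @ y[tr]
        XvV = X[va] @ Vt.T
        for a_idx, a in enumerate(alphas):
            d = s / (s**2 + a)
            pred = XvV @ (d * Uty)
            cv_err[a_idx] += np.sum((y[va] - pred) ** 2)
    best = int(np.argmin(cv_err))
    alpha = float(alphas[best])
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    coef = Vt.T @ ((s / (s**2 + alpha)) * (U.T @ y))
    return coef, alpha


class AdaptiveLasso(BaseEstimator, RegressorMixin):
    """Adaptive lasso with ridge-derived weights and forced-in columns.

    The two-stage procedure: (1) a ridge regression over the penalized
    columns, its penalty chosen by K-fold cross-validation on a 100-point
    logarithmic grid, provides pilot coefficients beta*; (2) a lasso with
    per-column penalties lam * w_j, w_j = 1/|beta*_j|^gamma, its penalty
    likewise CV-chosen (rule: minimize mean CV squared error).  Columns
    whose pilot coefficient is below ``WEIGHT_TOL`` in magnitude receive
    an effectively infinite weight and are excluded (coefficient 0).

    Parameters
    ----------
    gamma : float
        Weight exponent; 1 by default.
    cv : int
        Number of CV folds for both stages (default 10).
    n_alphas, alpha_min_ratio : int, float
        Penalty grids: 100 log-spaced points down to 1e-4 of the maximum.
    penalty_free : sequence of int, optional
        Column indices never penalized (weight exactly 0); handled by
        exact projection (FWL), so they are always in the model.
    alpha_lasso, alpha_ridge : float, optional
        Fix either penalty instead of cross-validating it.  An
        ``alpha_lasso`` of 0 gives the OLS solution on retained columns.
    random_state : int, optional
        Seed for the CV fold shuffles (both stages draw independent folds
        from this seed).
    """

    def __init__(
        self,
        gamma: float = 1.0,
        cv: int = 10,
        n_alphas: int = 100,
        alpha_min_ratio: float = 1e-4,
        penalty_free: Optional[Sequence[int]] = None,
        alpha_lasso: Optional[float] = None,
        alpha_ridge: Optional[float] = None,
        weights: Optional[Sequence[float]] = None,
        random_state: Optional[int] = None,
        max_iter: int = 50_000,
    ):
        self.gamma = gamma
        self.cv = cv
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.penalty_free = penalty_free
        self.alpha_lasso = alpha_lasso
        self.alpha_ridge = alpha_ridge
        self.weights = weights
        self.random_state = random_state
        self.max_iter = max_iter

    # -- stage 1 -----------------------------------------------------------
    def _pilot_weights(self, Xr, yr, pen_idx, rs):
        """Ridge pilot on standardized residualized columns -> weights."""
        sd = Xr.std(axis=0)
        keep = sd > 1e-12
        Xs = np.zeros_like(Xr)
        Xs[:, keep] = Xr[:, keep] / sd[keep]
        n, p = Xs.shape
        if self.alpha_ridge is not None:
            U, s, Vt = np.linalg.svd(Xs[:, keep], full_matrices=False)
            coef_std = Vt.T @ ((s / (s**2 + self.alpha_ridge)) * (U.T @ yr))
            alpha_r = float(self.alpha_ridge)
        else:
            r_max = float(n * max(keep.sum(), 1))  # total SS of standardized design
            grid = np.logspace(np.log10(r_max), np.log10(r_max * self.alpha_min_ratio),
                               self.n_alphas)
            coef_std, alpha_r = _ridge_cv_path(Xs[:, keep], yr, grid, self.cv, rs)
        beta_star = np.zeros(p)
        beta_star[keep] = coef_std / sd[keep]  # back to original units
        w = adaptive_weights_from_pilot(beta_star, self.gamma)
        return w, beta_star, alpha_r

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        needs_cv = self.alpha_lasso is None or (
            self.weights is None and self.alpha_ridge is None
        )
        if needs_cv and (self.cv < 2 or n // self.cv < 2):
            raise ValueError("cross-validation folds must each hold >= 2 observations")
        forced = np.zeros(p, dtype=bool)
        if self.penalty_free is not None:
            forced[np.asarray(list(self.penalty_free), dtype=int)] = True
        pen_idx = np.flatnonzero(~forced)
        rs = self.random_state if self.random_state is not None else 0

        Z = np.column_stack([np.ones(n), X[:, forced]])
        residualize = _residualizer(Z)
        yr = residualize(y)
        Xr = residualize(X[:, pen_idx])

        if self.weights is not None:
            w_pen = np.asarray(self.weights, dtype=float)
            if w_pen.shape[0] == p:
                if np.any(w_pen[forced] != 0):
                    raise ValueError("forced-in columns must have zero weight")
                w_pen = w_pen[pen_idx]
            beta_star, alpha_r = None, None
        else:
            w_pen, beta_star, alpha_r = self._pilot_weights(Xr, yr, pen_idx, rs)
        if np.any(w_pen < 0):
            raise ValueError("adaptive weights must be non-negative")

        active = np.isfinite(w_pen) & (w_pen > 0)
        zero_w = np.isfinite(w_pen) & (w_pen == 0)  # unpenalized but not projected
        if np.any(zero_w):
            # treat explicitly-zero-weight penalized columns as forced-in
            raise ValueError(
                "zero weights on penalized columns are not supported; "
                "pass such columns via penalty_free"
            )
        Xw = Xr[:, active] / w_pen[active]  # column j scaled by 1/w_j

        beta_pen = np.zeros(len(pen_idx))
        if Xw.shape[1] > 0:
            if self.alpha_lasso is not None and self.alpha_lasso == 0:
                b, *_ = np.linalg.lstsq(Xw, yr, rcond=None)
                alpha_l = 0.0
            elif self.alpha_lasso is not None:
                model = Lasso(alpha=self.alpha_lasso, fit_intercept=False,
                              max_iter=self.max_iter, tol=1e-10)
                model.fit(Xw, yr)
                b = model.coef_
                alpha_l = float(self.alpha_lasso)
            else:
                grid = _lasso_alpha_grid(Xw, yr, self.n_alphas, self.alpha_min_ratio)
                kf = KFold(n_splits=self.cv, shuffle=True, random_state=rs + 1)
                model = LassoCV(alphas=grid, fit_intercept=False, cv=kf,
                                max_iter=self.max_iter, n_jobs=None)
                model.fit(Xw, yr)
                b = model.coef_
                alpha_l = float(model.alpha_)
            beta_pen[active] = b / w_pen[active]
        else:
            alpha_l = 0.0

        # recover the unpenalized block exactly given the penalized fit
        resid_target = y - X[:, pen_idx] @ beta_pen
        gamma_hat, *_ = np.linalg.lstsq(Z, resid_target, rcond=None)

        coef = np.zeros(p)
        coef[pen_idx] = beta_pen
        coef[forced] = gamma_hat[1:]
        self.coef_ = coef
        self.intercept_ = float(gamma_hat[0])
        full_w = np.zeros(p)
        full_w[pen_idx] = w_pen
        self.weights_ = full_w
        self.beta_star_ = beta_star
        self.alpha_ridge_ = alpha_r
        self.alpha_lasso_ = alpha_l
        # objective-scale penalty: our objective uses sum of squares, sklearn 1/(2n)
        self.lambda_lasso_ = 2.0 * n * alpha_l
        self.support_ = np.flatnonzero((coef != 0) | forced)
        self.forced_mask_ = forced
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "coef_")
        return self.intercept_ + np.asarray(X, dtype=float) @ self.coef_

    def to_fit_result(self) -> AdaptiveLassoFit:
        check_is_fitted(self, "coef_")
        return AdaptiveLassoFit(
            beta_hat=self.coef_,
            weights=self.weights_,
            lambda_ridge=self.alpha_ridge_,
            lambda_lasso=self.lambda_lasso_,
            support=self.support_,
            intercept=self.intercept_,
        )


class CausalAdaptiveLasso(BaseEstimator, RegressorMixin):
    """CAL: one adaptive-lasso fit on the full back-door design.

    ``fit(X, y)`` expects the columns ``[all dose pixels | V_O, M_O, V_T]``
    (as built by :func:`build_design_matrix`); the plan parameters are
    forced in, the dose coefficients form ``theta_hat_``.
    """

    def __init__(
        self,
        grid_shape: Optional[Tuple[int, int]] = None,
        gamma: float = 1.0,
        cv: int = 10,
        n_alphas: int = 100,
        alpha_min_ratio: float = 1e-4,
        random_state: Optional[int] = None,
        forced_pixel: Optional[Tuple[int, int]] = None,
    ):
        self.grid_shape = grid_shape
        self.gamma = gamma
        self.cv = cv
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.random_state = random_state
        self.forced_pixel = forced_pixel

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        p = X.shape[1]
        n_dose = p - 3
        free = [p - 3, p - 2, p - 1]
        if self.forced_pixel is not None:
            if self.grid_shape is None:
                raise ValueError("forced_pixel requires grid_shape")
            i, j = self.forced_pixel
            free = [i * self.grid_shape[1] + j] + free
        self.lasso_ = AdaptiveLasso(
            gamma=self.gamma,
            cv=self.cv,
            n_alphas=self.n_alphas,
            alpha_min_ratio=self.alpha_min_ratio,
            penalty_free=free,
            random_state=self.random_state,
        ).fit(X, y)
        theta = self.lasso_.coef_[:n_dose]
        self.theta_hat_ = theta.reshape(self.grid_shape) if self.grid_shape else theta
        self.coef_ = self.lasso_.coef_
        self.intercept_ = self.lasso_.intercept_
        self.converged_ = True
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "lasso_")
        return self.lasso_.predict(X)


class PixelwiseCausalAdaptiveLasso(BaseEstimator, RegressorMixin):
    """Pixel-wise CAL: one adaptive-lasso fit per pixel.

    Fit (i, j) forces in {D_ij, V_O, M_O, V_T}; theta_hat_[i, j] is the
    D_ij coefficient from its own fit.  Per-pixel failures are flagged in
    ``pixel_converged_`` without aborting the array.
    """

    def __init__(
        self,
        grid_shape: Tuple[int, int] = (10, 10),
        gamma: float = 1.0,
        cv: int = 10,
        n_alphas: int = 100,
        alpha_min_ratio: float = 1e-4,
        random_state: Optional[int] = None,
    ):
        self.grid_shape = grid_shape
        self.gamma = gamma
        self.cv = cv
        self.n_alphas = n_alphas
        self.alpha_min_ratio = alpha_min_ratio
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        nx, ny = self.grid_shape
        p = X.shape[1]
        theta = np.zeros((nx, ny))
        ok = np.zeros((nx, ny), dtype=bool)
        fits: Dict[Tuple[int, int], AdaptiveLassoFit] = {}
        for i in range(nx):
            for j in range(ny):
                col = i * ny + j
                free = [col, p - 3, p - 2, p - 1]
                try:
                    sub = AdaptiveLasso(
                        gamma=self.gamma,
                        cv=self.cv,
                        n_alphas=self.n_alphas,
                        alpha_min_ratio=self.alpha_min_ratio,
                        penalty_free=free,
                        random_state=self.random_state,
                    ).fit(X, y)
                    theta[i, j] = sub.coef_[col]
                    ok[i, j] = True
                    fits[(i, j)] = sub.to_fit_result()
                except Exception:  # pragma: no cover - defensive per-pixel guard
                    theta[i, j] = np.nan
        self.theta_hat_ = theta
        self.pixel_converged_ = ok
        self.pixel_fits_ = fits
        self.converged_ = bool(ok.all())
        self.n_features_in_ = p
        return self

    def predict(self, X):
        # Average of the per-pixel models' predictions is not meaningful;
        # expose the marginal effect surface applied to the dose block.
        check_is_fitted(self, "theta_hat_")
        X = np.asarray(X, dtype=float)
        return X[:, : self.theta_hat_.size] @ self.theta_hat_.ravel()


# ---------------------------------------------------------------------------
# Cohort-level convenience functions (the module operations)


def compute_adaptive_weights(
    design: DesignMatrix,
    gamma: float = 1.0,
    cv_folds: int = 10,
    random_state: Optional[int] = None,
    alpha_ridge: Optional[float] = None,
) -> Tuple[np.ndarray, Optional[float]]:
    """Ridge-pilot adaptive weights for a design: w_j = 1/|beta*_j|^gamma,
    zero on forced-in columns, infinite (column excluded) where the pilot
    coefficient is numerically zero."""
    model = AdaptiveLasso(
        gamma=gamma,
        cv=cv_folds,
        penalty_free=np.flatnonzero(design.penalty_mask == 0),
        random_state=random_state,
        alpha_ridge=alpha_ridge,
        alpha_lasso=0.0,  # weights only; skip the expensive lasso CV
        n_alphas=100,
    )
    # run only the pilot stage: replicate fit()'s preprocessing
    X, y = design.X, design.y
    n, p = X.shape
    forced = design.penalty_mask == 0
    Z = np.column_stack([np.ones(n), X[:, forced]])
    residualize = _residualizer(Z)
    yr = residualize(y)
    Xr = residualize(X[:, ~forced])
    rs = random_state if random_state is not None else 0
    w_pen, _, a_ridge = model._pilot_weights(Xr, yr, np.flatnonzero(~forced), rs)
    w = np.zeros(p)
    w[~forced] = w_pen
    return w, a_ridge


def fit_adaptive_lasso(
    design: DesignMatrix,
    weights: np.ndarray,
    cv_folds: int = 10,
    alpha: Optional[float] = None,
    random_state: Optional[int] = None,
) -> AdaptiveLassoFit:
    """Solve the weighted-lasso objective for a design with externally
    supplied weights (zero on forced-in columns)."""
    model = AdaptiveLasso(
        cv=cv_folds,
        penalty_free=np.flatnonzero(design.penalty_mask == 0),
        weights=weights,
        alpha_lasso=alpha,
        random_state=random_state,
    )
    model.fit(design.X, design.y)
    return model.to_fit_result()


def fit_pixelwise(
    cohort: Cohort,
    which_dose: str = "planned",
    var_tol: float = 1e-12,
) -> EffectEstimate:
    """Voxel-based analysis on planned or delivered dose."""
    if which_dose not in ("planned", "delivered"):
        raise ValueError("which_dose must be 'planned' or 'delivered'")
    dose = cohort.D_plan if which_dose == "planned" else cohort.D_del
    reg = PixelwiseRegressor(grid_shape=cohort.grid_shape, var_tol=var_tol)
    reg.fit(dose, cohort.Y)
    return EffectEstimate(
        theta_hat=reg.theta_hat_,
        method=f"pixelwise_{which_dose}",
        converged=True,
        diagnostics={"n_degenerate": int(reg.degenerate_mask_.sum())},
    )


def fit_causal_no_sparsity(cohort: Cohort) -> EffectEstimate:
    """Unregularized back-door regression on the full adjustment set."""
    design = build_design_matrix(cohort)
    reg = CausalLinearRegressor(grid_shape=cohort.grid_shape)
    reg.fit(design.X, design.y)
    return EffectEstimate(
        theta_hat=reg.theta_hat_,
        method="causal_no_sparsity",
        converged=reg.converged_,
        diagnostics={"p": design.X.shape[1], "n": cohort.n_obs},
    )


def fit_cal(cohort: Cohort, random_state: Optional[int] = None, cv: int = 10) -> EffectEstimate:
    """The Causal Adaptive Lasso on a cohort's delivered dose."""
    design = build_design_matrix(cohort)
    model = CausalAdaptiveLasso(grid_shape=cohort.grid_shape, cv=cv, random_state=random_state)
    model.fit(design.X, design.y)
    support_size = int(np.count_nonzero(model.theta_hat_))
    return EffectEstimate(
        theta_hat=model.theta_hat_,
        method="cal",
        converged=True,
        diagnostics={
            "alpha_ridge": model.lasso_.alpha_ridge_,
            "alpha_lasso": model.lasso_.alpha_lasso_,
            "support_size": support_size,
        },
    )


def fit_pixelwise_cal(
    cohort: Cohort, random_state: Optional[int] = None, cv: int = 10
) -> EffectEstimate:
    """Pixel-wise CAL: Nx*Ny adaptive-lasso fits, one per pixel."""
    design = build_design_matrix(cohort)
    model = PixelwiseCausalAdaptiveLasso(
        grid_shape=cohort.grid_shape, cv=cv, random_state=random_state
    )
    model.fit(design.X, design.y)
    return EffectEstimate(
        theta_hat=model.theta_hat_,
        method="pixelwise_cal",
        converged=model.converged_,
        diagnostics={"n_fits": len(model.pixel_fits_)},
    )


METHODS = {
    "pixelwise_planned": lambda cohort, rs: fit_pixelwise(cohort, "planned"),
    "pixelwise_delivered": lambda cohort, rs: fit_pixelwise(cohort, "delivered"),
    "causal_no_sparsity": lambda cohort, rs: fit_causal_no_sparsity(cohort),
    "cal": lambda cohort, rs: fit_cal(cohort, random_state=rs),
    "pixelwise_cal": lambda cohort, rs: fit_pixelwise_cal(cohort, random_state=rs),
}
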