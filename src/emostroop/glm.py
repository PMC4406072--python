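"""Subject-level GLM with AR(1) prewhitening and t contrasts.

Serial correlation in the BOLD time series is removed by iterated
Cochrane-Orcutt prewhitening: an initial OLS fit yields residuals whose
lag-1 autocorrelation estimates the AR(1) coefficient rho; data and design
are transformed by the AR(1) whitening filter and refit, iterating until
rho converges.  Contrast t statistics use the whitened design's covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.linalg import matrix_rank
from scipy import stats

from .task_design import DesignMatrix

__all__ = ["GlmFit", "ContrastSpec", "StatResult", "fit_glm_ar1", "compute_contrast"]

CONTRAST_MAX_CONFLICT = "cI_cC"
CONTRAST_GENERAL = "I_C"


@dataclass(frozen=True)
class StatResult:
    """A point estimate with its t statistic and two-sided p-value."""

    estimate: float
    t_value: float
    dof: float
    p_two_sided: float


@dataclass(frozen=True)
class ContrastSpec:
    """Named contrast given as weights over task regressors.

    Weights over motion/intercept/drift columns are implicitly zero.
    """

    name: str
    weights: dict[str, float]

    def __post_init__(self):
        if not any(w != 0 for w in self.weights.values()):
            raise ValueError("contrast must have at least one nonzero weight")

    def vector(self, regressor_names: list[str]) -> np.ndarray:
        w = np.zeros(len(regressor_names))
        for name, weight in self.weights.items():
            if name not in regressor_names:
                raise ValueError(
                    f"unknown regressor {name!r}; available: {regressor_names}"
                )
            w[regressor_names.index(name)] = weight
        return w


#: cI - cC, the maximum-conflict contrast (post-congruent incongruent minus
#: post-congruent congruent).
MAX_CONFLICT = ContrastSpec(CONTRAST_MAX_CONFLICT, {"cI": 1.0, "cC": -1.0})
#: I - C, the general-conflict contrast, mean-difference scaled.
GENERAL_CONFLICT = ContrastSpec(
    CONTRAST_GENERAL, {"cI": 0.5, "iI": 0.5, "iC": -0.5, "cC": -0.5}
)


@dataclass
class GlmFit:
    """Fitted GLM for one time series."""

    betas: np.ndarray
    regressor_names: list[str]
    residual_variance: float
    ar1_rho: float
    dof: float
    xtx_inv: np.ndarray  # (X'X)^-1 of the whitened design
    converged: bool = True

    def beta(self, name: str) -> float:
        return float(self.betas[self.regressor_names.index(name)])


def _whiten(y: np.ndarray, X: np.ndarray, rho: float):
    """AR(1) whitening transform; first row scaled by sqrt(1 - rho^2)."""
    yw = np.empty_like(y, dtype=float)
    Xw = np.empty_like(X, dtype=float)
    s = np.sqrt(1.0 - rho * rho)
    yw[0] = s * y[0]
    Xw[0] = s * X[0]
    yw[1:] = y[1:] - rho * y[:-1]
    Xw[1:] = X[1:] - rho * X[:-1]
    return yw, Xw


def _lag1_autocorr(r: np.ndarray) -> float:
    r = r - r.mean()
    denom = float(r @ r)
    if denom <= 0:
        return 0.0
    return float(r[1:] @ r[:-1] / denom)


def fit_glm_ar1(
    series: np.ndarray,
    design: DesignMatrix | np.ndarray,
    regressor_names: list[str] | None = None,
    max_iter: int = 20,
    tol: float = 1e-4,
    rho: float | None = None,
) -> GlmFit | list[GlmFit]:
    """Fit the GLM with iterated AR(1) prewhitening (Cochrane-Orcutt).

    Parameters
    ----------
    series : 1-D time vector, or an (n_roi, n_time) matrix, in which case a
        list of per-row fits is returned.
    rho : fix the AR(1) coefficient instead of estimating it (``rho=0``
        reduces to OLS).

    Returns betas, whitened residual variance, rho, and
    dof = n - rank(design).
    """
    if isinstance(design, DesignMatrix):
        X = design.values
        names = design.regressor_names
    else:
        X = np.asarray(design, dtype=float)
        names = regressor_names or [f"x{i}" for i in range(X.shape[1])]
    series = np.asarray(series, dtype=float)
    if series.ndim == 2:
        return [
            fit_glm_ar1(row, X, names, max_iter=max_iter, tol=tol, rho=rho)
            for row in series
        ]
    n, p = X.shape
    if series.shape[0] != n:
        raise ValueError(f"series length {series.shape[0]} != design rows {n}")
    # all-zero columns (e.g. an error regressor with no error trials) are
    # dropped from the fit and reported with beta = 0
    nonzero = np.flatnonzero(np.any(X != 0, axis=0))
    X_fit = X[:, nonzero]
    rank = matrix_rank(X_fit)
    if rank < X_fit.shape[1]:
        bad = _collinear_columns(X_fit, [names[j] for j in nonzero])
        raise ValueError(f"rank-deficient design (rank {rank} < {p} columns): {bad}")
    dof = n - rank
    X = X_fit

    import warnings

    if rho is not None:
        rho_hat, fixed = float(rho), True
    else:
        rho_hat, fixed = 0.0, False
    converged = True
    beta = None
    for it in range(max_iter):
        yw, Xw = _whiten(series, X, rho_hat)
        beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
        resid_raw = series - X @ beta
        if fixed:
            break
        # near-perfect fits leave only float dust; call that white
        if resid_raw.var() < 1e-12 * max(series.var(), 1e-30):
            rho_new = 0.0
        else:
            rho_new = float(np.clip(_lag1_autocorr(resid_raw), -0.99, 0.99))
        if abs(rho_new - rho_hat) < tol:
            rho_hat = rho_new
            break
        rho_hat = rho_new
    else:
        converged = False
        warnings.warn(f"AR(1) estimate did not converge in {max_iter} iterations")

    yw, Xw = _whiten(series, X, rho_hat)
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    sigma2 = float(resid_w @ resid_w) / dof
    xtx_inv_fit = np.linalg.inv(Xw.T @ Xw)
    beta_full = np.zeros(p)
    beta_full[nonzero] = beta
    xtx_inv = np.zeros((p, p))
    xtx_inv[np.ix_(nonzero, nonzero)] = xtx_inv_fit
    return GlmFit(
        betas=beta_full,
        regressor_names=list(names),
        residual_variance=sigma2,
        ar1_rho=rho_hat,
        dof=float(dof),
        xtx_inv=xtx_inv,
        converged=converged,
    )


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        if matrix_rank(np.column_stack([others, X[:, j]])) == matrix_rank(others):
            bad.append(names[j])
    return bad or ["<undetermined>"]


def fit_contrast_maps(
    data: np.ndarray,
    design: DesignMatrix,
    contrasts: list[ContrastSpec],
) -> dict[str, np.ndarray]:
    """Voxelwise contrast-estimate maps for one subject's 4D volume.

    A single OLS fit is run for all voxels at once; serial correlation is
    handled with one spatially pooled AR(1) coefficient (the median of the
    voxelwise residual lag-1 autocorrelations) and one whitened refit —
    cheap enough for whole volumes while removing the bulk of the serial
    correlation.

    Parameters
    ----------
    data : (x, y, z, t) array.

    Returns
    -------
    dict mapping contrast name to a 3-D estimate map.
    """
    shape = data.shape[:3]
    n = data.shape[3]
    X = design.values
    if X.shape[0] != n:
        raise ValueError(f"time dim {n} != design rows {X.shape[0]}")
    Y = data.reshape(-1, n).T  # time x voxels
    beta, _, _, _ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    r = resid - resid.mean(axis=0, keepdims=True)
    denom = np.einsum("ij,ij->j", r, r)
    num = np.einsum("ij,ij->j", r[1:], r[:-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        rhos = np.where(denom > 0, num / denom, 0.0)
    rho = float(np.clip(np.median(rhos), -0.99, 0.99))
    Yw, Xw = _whiten(Y, X, rho)
    beta, _, _, _ = np.linalg.lstsq(Xw, Yw, rcond=None)
    out = {}
    for spec in contrasts:
        w = spec.vector(design.regressor_names)
        out[spec.name] = (w @ beta).reshape(shape)
    return out


def compute_contrast(fit: GlmFit, spec: ContrastSpec) -> StatResult:
    """Evaluate a t contrast on a fitted GLM.

    estimate = w'beta; t = w'beta / sqrt(sigma^2 w'(X'X)^-1 w) with the
    whitened design; p is two-sided from Student's t at the fit's dof.
    """
    w = spec.vector(fit.regressor_names)
    est = float(w @ fit.betas)
    var = float(fit.residual_variance * (w @ fit.xtx_inv @ w))
    if var <= 0:
        t = 0.0 if est == 0 else np.sign(est) * np.inf
    else:
        t = est / np.sqrt(var)
    p = 2.0 * stats.t.sf(abs(t), fit.dof)
    return StatResult(estimate=est, t_value=float(t), dof=fit.dof, p_two_sided=float(p))
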