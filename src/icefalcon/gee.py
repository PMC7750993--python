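"""Marginal regression for twin pairs: GEE with exchangeable working correlation.

The estimator behind all three co-twin regression models.  Clusters are
twin pairs (size exactly 2), which admits a closed-form inverse of the
working correlation matrix and therefore a fully vectorized solver:

* coefficients solve ``sum_i X_i' R(rho)^-1 (y_i - X_i b) = 0`` with
  ``R(rho)`` the 2x2 exchangeable correlation;
* ``rho`` is the moment estimator from Pearson residuals (denominator =
  number of pairs), iterated with the coefficient update to convergence;
* standard errors are robust sandwich estimates clustered on pair.

For bootstrap resampling the per-pair sufficient statistics are computed
once and replicates are fitted from weighted sums, so a replicate refit
costs O(n_pairs * p^2) with no Python-level loop over pairs.

The Gaussian family is solved natively; the binomial family is delegated
to ``statsmodels`` GEE with the same working structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .twin_data import DoubleEnteredFrame

__all__ = ["ModelFit", "fit_gee", "GEEConvergenceError", "RankDeficientError", "PairedStats"]

_TOL = 1e-8
_MAX_ITER = 100
_RHO_CLIP = 0.99


class GEEConvergenceError(RuntimeError):
    """Iteration between coefficients and working correlation failed."""

    def __init__(self, message, last_fit=None):
        super().__init__(message)
        self.last_fit = last_fit


class RankDeficientError(ValueError):
    """The design matrix is not full rank."""


@dataclass
class ModelFit:
    """Result of one exchangeable-GEE fit on double-entered pairs."""

    coefficients: pd.Series
    robust_se: pd.Series
    working_correlation: float
    scale: float
    n_pairs: int
    n_obs: int
    converged: bool
    n_iter: int
    family: str = "gaussian"
    se_type: str = "robust (sandwich, clustered on pair)"

    @property
    def zvalues(self) -> pd.Series:
        return self.coefficients / self.robust_se

    @property
    def pvalues(self) -> pd.Series:
        """Two-sided normal-theory p-values for the coefficients."""
        return pd.Series(
            2 * spstats.norm.sf(np.abs(self.zvalues.to_numpy())),
            index=self.coefficients.index,
        )

    def to_dict(self) -> dict:
        return {
            "coefficients": self.coefficients.to_dict(),
            "robust_se": self.robust_se.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "working_correlation": self.working_correlation,
            "scale": self.scale,
            "n_pairs": self.n_pairs,
            "n_obs": self.n_obs,
            "converged": self.converged,
            "family": self.family,
            "se_type": self.se_type,
        }

    def summary(self) -> str:
        lines = [
            f"GEE ({self.family}, exchangeable working correlation)",
            f"pairs={self.n_pairs}  obs={self.n_obs}  "
            f"rho_working={self.working_correlation:.4f}  converged={self.converged}",
            f"SEs: {self.se_type}",
            f"{'term':<12}{'est':>12}{'se':>12}{'z':>10}{'p':>12}",
        ]
        for name in self.coefficients.index:
            lines.append(
                f"{name:<12}{self.coefficients[name]:>12.5f}{self.robust_se[name]:>12.5f}"
                f"{self.zvalues[name]:>10.3f}{self.pvalues[name]:>12.4g}"
            )
        return "\n".join(lines)


class PairedStats:
    """Per-pair sufficient statistics for the Gaussian exchangeable GEE.

    Given the pair-shaped outcome ``Y`` (n, 2) and design ``X`` (n, 2, p),
    stores the per-pair blocks needed to fit the model from weighted sums,
    enabling O(n p^2) bootstrap refits.
    """

    def __init__(self, Y: np.ndarray, X: np.ndarray, names: list[str]):
        self.Y = Y
        self.X = X
        self.names = list(names)
        self.n_pairs, _, self.p = X.shape
        x1, x2 = X[:, 0, :], X[:, 1, :]
        y1, y2 = Y[:, 0], Y[:, 1]
        # (n, p, p) blocks
        self.xx_sum = np.einsum("np,nq->npq", x1, x1) + np.einsum("np,nq->npq", x2, x2)
        cross = np.einsum("np,nq->npq", x1, x2)
        self.xx_cross = cross + cross.transpose(0, 2, 1)
        self.xy_sum = x1 * y1[:, None] + x2 * y2[:, None]
        self.xy_cross = x1 * y2[:, None] + x2 * y1[:, None]
        self.yy_sum = y1**2 + y2**2
        self.yy_cross = y1 * y2

    def contract(self, weights: np.ndarray | None = None):
        """Weighted sums of the per-pair blocks (weights default to 1)."""
        if weights is None:
            return (
                self.xx_sum.sum(0), self.xx_cross.sum(0),
                self.xy_sum.sum(0), self.xy_cross.sum(0),
                float(self.yy_sum.sum()), float(self.yy_cross.sum()),
                float(self.n_pairs),
            )
        w = np.asarray(weights, float)
        return (
            np.tensordot(w, self.xx_sum, axes=1),
            np.tensordot(w, self.xx_cross, axes=1),
            w @ self.xy_sum,
            w @ self.xy_cross,
            float(w @ self.yy_sum),
            float(w @ self.yy_cross),
            float(w.sum()),
        )


def _solve_gee(contracted, p, fixed_rho=None):
    """Fixed-point iteration for (beta, rho) on contracted moments.

    Returns (beta, rho, scale, converged, n_iter).
    """
    A, B, a, b, syy, cyy, n_pairs = contracted
    n_obs = 2.0 * n_pairs
    try:
        beta = np.linalg.solve(A, a)
    except np.linalg.LinAlgError as exc:
        raise RankDeficientError(f"singular design: {exc}") from exc
    rho = 0.0 if fixed_rho is None else fixed_rho
    phi = 1.0
    converged = False
    it = 0
    for it in range(1, _MAX_ITER + 1):
        rss = syy - 2.0 * beta @ a + beta @ A @ beta
        cross = cyy - beta @ b + 0.5 * beta @ B @ beta
        dof = max(n_obs - p, 1.0)
        phi = rss / dof
        if fixed_rho is None:
            if phi <= 1e-14:  # perfect fit: residuals vanish
                rho = 0.0
                converged = True
                break
            rho_new = cross / (n_pairs * phi)
            if abs(rho_new) > _RHO_CLIP:
                warnings.warn(
                    f"working correlation estimate {rho_new:.3f} clipped to +/-{_RHO_CLIP}")
                rho_new = float(np.clip(rho_new, -_RHO_CLIP, _RHO_CLIP))
            rho = rho_new
        beta_new = np.linalg.solve(A - rho * B, a - rho * b)
        delta = np.max(np.abs(beta_new - beta)) / max(np.max(np.abs(beta_new)), 1e-10)
        beta = beta_new
        if delta < _TOL:
            converged = True
            break
    return beta, float(rho), float(phi), converged, it


def _design_arrays(frame: DoubleEnteredFrame, outcome: str, predictors: list[str]):
    Y = frame.paired(outcome)
    n = Y.shape[0]
    X = np.empty((n, 2, len(predictors) + 1))
    X[:, :, 0] = 1.0
    for j, name in enumerate(predictors, start=1):
        X[:, :, j] = frame.paired(name)
    names = ["intercept"] + list(predictors)
    return Y, X, names


def _check_rank(X: np.ndarray, names: list[str]):
    flat = X.reshape(-1, X.shape[-1])
    rank = np.linalg.matrix_rank(flat)
    if rank < flat.shape[1]:
        # identify involved columns by dropping each in turn
        collinear = []
        for j in range(flat.shape[1]):
            sub = np.delete(flat, j, axis=1)
            if np.linalg.matrix_rank(sub) == rank:
                collinear.append(names[j])
        raise RankDeficientError(f"design is rank deficient; collinear columns: {collinear}")


def fit_from_stats(stats: PairedStats, weights=None, fixed_rho=None) -> np.ndarray:
    """Point estimates only, from (optionally reweighted) sufficient stats.

    The bootstrap fast path: no standard errors.  Raises
    GEEConvergenceError on non-convergence.
    """
    contracted = stats.contract(weights)
    beta, rho, phi, converged, _ = _solve_gee(contracted, stats.p, fixed_rho)
    if not converged:
        raise GEEConvergenceError("GEE did not converge")
    return beta


def fit_gee(
    frame: DoubleEnteredFrame,
    outcome: str,
    predictors: list[str],
    family: str = "gaussian",
    fixed_rho: float | None = None,
) -> ModelFit:
    """Fit a marginal regression on the double-entered frame.

    Parameters
    ----------
    frame
        Double-entered twin data (two rows per pair).
    outcome, predictors
        Column names; an intercept is always included.
    family
        ``"gaussian"`` (native solver) or ``"binomial"`` (logit link,
        via statsmodels GEE).
    fixed_rho
        If given, the working correlation is held at this value instead of
        being estimated (``fixed_rho=0`` reproduces OLS point estimates).
    """
    predictors = list(predictors)
    n_coef = len(predictors) + 1
    if frame.n_pairs < n_coef + 2:
        raise ValueError(
            f"need at least {n_coef + 2} pairs to fit {n_coef} coefficients")
    if family == "binomial":
        return _fit_binomial(frame, outcome, predictors)
    if family != "gaussian":
        raise ValueError(f"unknown family {family!r}")

    Y, X, names = _design_arrays(frame, outcome, predictors)
    _check_rank(X, names)
    stats = PairedStats(Y, X, names)
    contracted = stats.contract()
    beta, rho, phi, converged, it = _solve_gee(contracted, stats.p, fixed_rho)

    # robust sandwich, clustered on pair (phi cancels between bread and meat)
    E = Y - np.einsum("ntp,p->nt", X, beta)
    e1, e2 = E[:, 0], E[:, 1]
    x1, x2 = X[:, 0, :], X[:, 1, :]
    g = x1 * (e1 - rho * e2)[:, None] + x2 * (e2 - rho * e1)[:, None]
    A, B = contracted[0], contracted[1]
    bread = A - rho * B  # (1 - rho^2) factor cancels in the sandwich
    M = g.T @ g
    bread_inv = np.linalg.inv(bread)
    cov = bread_inv @ M @ bread_inv.T
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))

    fit = ModelFit(
        coefficients=pd.Series(beta, index=names),
        robust_se=pd.Series(se, index=names),
        working_correlation=rho,
        scale=phi,
        n_pairs=stats.n_pairs,
        n_obs=2 * stats.n_pairs,
        converged=converged,
        n_iter=it,
    )
    if not converged:
        raise GEEConvergenceError("GEE did not converge within 100 iterations", last_fit=fit)
    return fit


def _fit_binomial(frame: DoubleEnteredFrame, outcome: str, predictors: list[str]) -> ModelFit:
    import statsmodels.api as sm

    y = frame.frame[outcome].to_numpy(float)
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binomial outcome must be coded 0/1")
    X = sm.add_constant(frame.frame[predictors].to_numpy(float), has_constant="add")
    names = ["intercept"] + list(predictors)
    model = sm.GEE(
        y, X, groups=frame.frame["pair_id"].to_numpy(),
        family=sm.families.Binomial(),
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    res = model.fit()
    rho = float(model.cov_struct.dep_params)
    return ModelFit(
        coefficients=pd.Series(res.params, index=names),
        robust_se=pd.Series(res.bse, index=names),
        working_correlation=rho,
        scale=float(res.scale),
        n_pairs=frame.n_pairs,
        n_obs=frame.n_obs,
        converged=bool(getattr(res, "converged", True)),
        n_iter=-1,
        family="binomial",
    )
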