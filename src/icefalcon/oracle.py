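"""Population-limit coefficients of the co-twin regression models.

For a zero-mean Gaussian twin model with known 4x4 covariance over
(X_self, Y_self, X_cotwin, Y_cotwin), this module computes the probability
limit of the exchangeable-GEE estimator fitted to double-entered pairs:
the fixed point of

    beta(rho) = E[X' R(rho)^-1 X]^-1  E[X' R(rho)^-1 y]
    rho(beta) = Corr of the two within-pair model residuals

with all expectations evaluated in closed form from the covariance
entries.  Accounting for the within-pair outcome correlation through the
working correlation is what "in effect conditions on" the co-twin's
outcome, so these limits reproduce the collider-driven signatures: e.g.
under a pure X -> Y diagram, Model 2's cross-pair slope is nonzero with
the sign of (rho_X - rho_Y), while Model 3's vanishes exactly.

This is the ground truth that large-sample GEE fits must match, and the
basis of the expected qualitative pattern table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import ScenarioSpec, ImpliedCovariance, implied_covariance

__all__ = [
    "PopulationCoefficients",
    "population_coefficients",
    "population_model",
    "expected_pattern",
    "OracleConvergenceError",
]

_IDX = {"x": (0, 2), "y": (1, 3)}  # (self of twin 1, self of twin 2)


class OracleConvergenceError(RuntimeError):
    def __init__(self, message, trajectory):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass(frozen=True)
class PopulationCoefficients:
    """Population analogues of the three models' slopes (one direction)."""

    beta_self: float
    beta_cotwin: float
    beta_self_prime: float
    beta_cotwin_prime: float
    working_correlation: dict  # per model: limit of the working rho

    @property
    def delta_self(self) -> float:
        return self.beta_self_prime - self.beta_self

    @property
    def delta_cotwin(self) -> float:
        return self.beta_cotwin_prime - self.beta_cotwin


def population_model(
    cov: ImpliedCovariance | np.ndarray,
    predictors_row1: list[int],
    outcome_row1: int,
    tol: float = 1e-12,
    max_iter: int = 500,
):
    """Probability limit of one exchangeable-GEE fit.

    ``predictors_row1`` and ``outcome_row1`` index the observed 4-vector
    for the first double-entered row; the second row is obtained by the
    self <-> co-twin relabeling (index i -> (i + 2) mod 4).

    Returns (beta, rho_limit).
    """
    sigma = cov.matrix if isinstance(cov, ImpliedCovariance) else np.asarray(cov, float)
    swap = lambda i: (i + 2) % 4
    p = len(predictors_row1)
    P1 = np.zeros((p, 4))
    P2 = np.zeros((p, 4))
    for j, idx in enumerate(predictors_row1):
        P1[j, idx] = 1.0
        P2[j, swap(idx)] = 1.0
    s1 = np.zeros(4); s1[outcome_row1] = 1.0
    s2 = np.zeros(4); s2[swap(outcome_row1)] = 1.0

    A = P1 @ sigma @ P1.T + P2 @ sigma @ P2.T
    B = P1 @ sigma @ P2.T + P2 @ sigma @ P1.T
    a = P1 @ sigma @ s1 + P2 @ sigma @ s2
    b = P1 @ sigma @ s2 + P2 @ sigma @ s1
    syy = s1 @ sigma @ s1 + s2 @ sigma @ s2
    cyy = s1 @ sigma @ s2

    beta = np.linalg.solve(A, a)
    rho = 0.0
    trajectory = []
    for _ in range(max_iter):
        # residual second moments, closed form in the covariance
        var_sum = syy - 2.0 * beta @ a + beta @ A @ beta   # E e1^2 + E e2^2
        cross = cyy - beta @ b + 0.5 * beta @ B @ beta      # E e1 e2
        phi = var_sum / 2.0
        if phi <= 1e-15:
            rho_new = 0.0
        else:
            rho_new = float(np.clip(cross / phi, -0.999999, 0.999999))
        beta_new = np.linalg.solve(A - rho_new * B, a - rho_new * b)
        trajectory.append((beta_new.copy(), rho_new))
        if max(np.max(np.abs(beta_new - beta)), abs(rho_new - rho)) < tol:
            return beta_new, rho_new
        beta, rho = beta_new, rho_new
    raise OracleConvergenceError("population fixed point did not converge", trajectory)


def population_coefficients(
    cov: ImpliedCovariance | np.ndarray, predictor: str = "x", outcome: str = "y"
) -> PopulationCoefficients:
    """Population Model 1-3 slopes for one predictor -> outcome direction."""
    px1, _ = _IDX[predictor]
    oy1, _ = _IDX[outcome]
    pco1 = (px1 + 2) % 4
    b1, r1 = population_model(cov, [px1], oy1)
    b2, r2 = population_model(cov, [pco1], oy1)
    b3, r3 = population_model(cov, [px1, pco1], oy1)
    return PopulationCoefficients(
        beta_self=float(b1[0]),
        beta_cotwin=float(b2[0]),
        beta_self_prime=float(b3[0]),
        beta_cotwin_prime=float(b3[1]),
        working_correlation={"model1": r1, "model2": r2, "model3": r3},
    )


def _qual(value: float, tol: float = 1e-8) -> str:
    return "association" if abs(value) > tol else "null"


def expected_pattern(spec: ScenarioSpec, tol: float = 1e-8) -> dict:
    """Threshold the population coefficients into qualitative entries.

    Returns, for the X -> Y direction, the qualitative status of each
    slope plus the attenuation relations between Model 3 and Models 1-2 —
    the entries of the expected-pattern table for the generating diagram.
    """
    cov = implied_covariance(spec)
    pop = population_coefficients(cov, "x", "y")
    out = {
        "beta_self": _qual(pop.beta_self, tol),
        "beta_cotwin": _qual(pop.beta_cotwin, tol),
        "beta_self_prime": _qual(pop.beta_self_prime, tol),
        "beta_cotwin_prime": _qual(pop.beta_cotwin_prime, tol),
        "beta_cotwin_sign": int(np.sign(pop.beta_cotwin)) if abs(pop.beta_cotwin) > tol else 0,
        "beta_cotwin_prime_sign": (
            int(np.sign(pop.beta_cotwin_prime)) if abs(pop.beta_cotwin_prime) > tol else 0
        ),
        "self_attenuated": abs(pop.beta_self_prime) < abs(pop.beta_self) - tol,
        "self_unchanged": abs(pop.beta_self_prime - pop.beta_self) <= tol,
        "cotwin_attenuated": abs(pop.beta_cotwin_prime) < abs(pop.beta_cotwin) - tol,
        "population": pop,
    }
    if min(abs(pop.beta_self), abs(pop.beta_cotwin)) > tol:
        out["proportional_change_equal"] = (
            abs(pop.beta_self_prime / pop.beta_self
                - pop.beta_cotwin_prime / pop.beta_cotwin) <= tol
        )
    return out
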