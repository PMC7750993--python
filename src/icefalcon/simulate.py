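"""Generate twin-pair trait data from latent path diagrams.

Four standardized causal diagrams relate two traits X and Y measured on
both members of a twin pair:

* ``a`` — familial confounding only: a shared latent cause ``S_XY`` loads
  on both traits in both twins; no causal arrow between X and Y.
* ``b`` — X causes Y: a shared latent ``S_X`` makes X correlated within
  pairs and X has a direct effect ``causal_beta`` on Y within each
  individual.
* ``c`` — Y causes X: the mirror image of ``b``.
* ``d`` — mixture: both the shared confounder ``S_XY`` and a causal
  X -> Y arrow contribute to the X–Y association.

All latents (shared causes ``S_X``, ``S_Y``, ``S_XY``, the
individual-specific confounder ``U`` and trait residuals) are independent
standard Gaussians; loadings are standardized path coefficients, and
residual variances are solved so that every observed trait has unit
variance. The implied 4x4 covariance over
``(X_self, Y_self, X_cotwin, Y_cotwin)`` is therefore available in closed
form by path tracing, which the analytic oracle and all tests rely on.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import yaml

from .twin_data import TwinPairDataset

__all__ = [
    "ScenarioSpec",
    "ImpliedCovariance",
    "implied_covariance",
    "simulate_pairs",
    "calibrate",
    "SpecValidationError",
    "InfeasibleTargetsError",
]

#: index order of the observed vector
OBS_ORDER = ("x_1", "y_1", "x_2", "y_2")

#: independent standard-normal latents underlying one twin pair
_LATENTS = ("S_X", "S_Y", "S_XY", "U_1", "U_2", "E_X1", "E_Y1", "E_X2", "E_Y2")


class SpecValidationError(ValueError):
    """The loadings do not define a valid (unit-variance) covariance."""


class InfeasibleTargetsError(ValueError):
    """No standardized loadings reproduce the requested correlations."""


@dataclass(frozen=True)
class ScenarioSpec:
    """A parameterized causal diagram for bivariate twin data.

    Parameters
    ----------
    diagram
        One of ``'a'`` (familial confounding), ``'b'`` (X causes Y),
        ``'c'`` (Y causes X), ``'d'`` (confounding + X causes Y).
    loading_sx, loading_sy
        Standardized loadings of the trait-specific shared causes S_X on X
        and S_Y on Y (identical for both twins).
    loading_sxy_x, loading_sxy_y
        Loadings of the shared familial confounder S_XY on X and on Y.
    causal_beta
        Standardized causal coefficient (X -> Y for diagrams b/d,
        Y -> X for diagram c; must be 0 for diagram a).
    loading_u
        Loading of the individual-specific confounder U on both traits;
        defaults to 0 (the worked scenarios do not use U).
    n_pairs, seed
        Sample size (pairs) and RNG seed for :func:`simulate_pairs`.
    """

    diagram: str
    loading_sx: float = 0.0
    loading_sy: float = 0.0
    loading_sxy_x: float = 0.0
    loading_sxy_y: float = 0.0
    causal_beta: float = 0.0
    loading_u: float = 0.0
    n_pairs: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.diagram not in ("a", "b", "c", "d"):
            raise SpecValidationError(f"unknown diagram {self.diagram!r}")
        if self.diagram == "a" and self.causal_beta != 0.0:
            raise SpecValidationError("diagram 'a' has no causal arrow; causal_beta must be 0")
        if self.n_pairs < 1:
            raise SpecValidationError("n_pairs must be >= 1")
        # validate the variance budget now so invalid specs fail at construction
        _loading_matrix(self)

    # -- serialization --------------------------------------------------
    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "ScenarioSpec":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, ValueError):
                data = yaml.safe_load(io.StringIO(str(source)))
        return cls(**data)

    def with_(self, **kwargs) -> "ScenarioSpec":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ImpliedCovariance:
    """Closed-form covariance of (X_self, Y_self, X_cotwin, Y_cotwin)."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("implied covariance must be 4x4")
        object.__setattr__(self, "matrix", m)

    @property
    def rho_x(self) -> float:
        return self.matrix[0, 2] / np.sqrt(self.matrix[0, 0] * self.matrix[2, 2])

    @property
    def rho_y(self) -> float:
        return self.matrix[1, 3] / np.sqrt(self.matrix[1, 1] * self.matrix[3, 3])

    @property
    def r_xy(self) -> float:
        """Within-individual cross-trait correlation."""
        return self.matrix[0, 1] / np.sqrt(self.matrix[0, 0] * self.matrix[1, 1])

    @property
    def cross_twin_cross_trait(self) -> float:
        """Cov(X_self, Y_cotwin) (= Cov(Y_self, X_cotwin) by symmetry)."""
        return self.matrix[0, 3]


def _loading_matrix(spec: ScenarioSpec) -> np.ndarray:
    """4x9 loading matrix of the observed vector on the latent vector.

    Rows follow OBS_ORDER, columns follow _LATENTS.  Residual loadings are
    solved so the observed variances are exactly 1.
    """
    sx, sy = spec.loading_sx, spec.loading_sy
    cx, cy = spec.loading_sxy_x, spec.loading_sxy_y
    u, b = spec.loading_u, spec.causal_beta

    def base_x(twin):  # structural loadings of X before any causal arrow
        row = np.zeros(9)
        row[0] = sx
        row[2] = cx
        row[2 + twin] = u  # U_1 at idx 3, U_2 at idx 4
        return row

    def base_y(twin):
        row = np.zeros(9)
        row[1] = sy
        row[2] = cy
        row[2 + twin] = u
        return row

    ex_idx = {1: 5, 2: 7}
    ey_idx = {1: 6, 2: 8}

    L = np.zeros((4, 9))
    rows = {}
    if spec.diagram == "c":
        # Y is exogenous (given its residual), X receives the causal arrow
        for t in (1, 2):
            yrow = base_y(t)
            ey2 = 1.0 - yrow @ yrow
            if ey2 < -1e-12:
                raise SpecValidationError(
                    f"implied residual variance of Y is negative ({ey2:.4g}); "
                    "reduce the Y loadings")
            yrow[ey_idx[t]] = np.sqrt(max(ey2, 0.0))
            xrow = base_x(t) + b * yrow
            ex2 = 1.0 - xrow @ xrow
            if ex2 < -1e-12:
                raise SpecValidationError(
                    f"implied residual variance of X is negative ({ex2:.4g}); "
                    "reduce the X loadings or causal_beta")
            xrow[ex_idx[t]] = np.sqrt(max(ex2, 0.0))
            rows[("x", t)] = xrow
            rows[("y", t)] = yrow
    else:
        # diagrams a, b, d: X exogenous; b/d add a causal X -> Y arrow
        for t in (1, 2):
            xrow = base_x(t)
            ex2 = 1.0 - xrow @ xrow
            if ex2 < -1e-12:
                raise SpecValidationError(
                    f"implied residual variance of X is negative ({ex2:.4g}); "
                    "reduce the X loadings")
            xrow[ex_idx[t]] = np.sqrt(max(ex2, 0.0))
            yrow = base_y(t) + b * xrow
            ey2 = 1.0 - yrow @ yrow
            if ey2 < -1e-12:
                raise SpecValidationError(
                    f"implied residual variance of Y is negative ({ey2:.4g}); "
                    "reduce the Y loadings or causal_beta")
            yrow[ey_idx[t]] = np.sqrt(max(ey2, 0.0))
            rows[("x", t)] = xrow
            rows[("y", t)] = yrow

    L[0] = rows[("x", 1)]
    L[1] = rows[("y", 1)]
    L[2] = rows[("x", 2)]
    L[3] = rows[("y", 2)]
    return L


def implied_covariance(spec: ScenarioSpec) -> ImpliedCovariance:
    """Exact covariance of the observed 4-vector under the diagram.

    Assembled by path tracing through the loading matrix (no simulation):
    shared latents are common to both twins with unit variance,
    individual-specific residuals and U are independent across twins, and
    a causal arrow contributes products of path coefficients.
    """
    L = _loading_matrix(spec)
    return ImpliedCovariance(L @ L.T)


def simulate_matrix(spec: ScenarioSpec, rng: np.random.Generator | None = None) -> np.ndarray:
    """(n_pairs, 4) draw of (x_1, y_1, x_2, y_2); the array core of
    :func:`simulate_pairs`, used on hot paths to avoid frame overhead."""
    L = _loading_matrix(spec)
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    z = rng.standard_normal((spec.n_pairs, 9))
    return z @ L.T


def simulate_pairs(spec: ScenarioSpec) -> TwinPairDataset:
    """Draw ``spec.n_pairs`` independent twin pairs from the diagram.

    Pairs are iid zero-mean Gaussian with the implied covariance;
    reproducible from ``spec.seed``.
    """
    obs = simulate_matrix(spec)  # columns: x_1, y_1, x_2, y_2
    import pandas as pd

    frame = pd.DataFrame(
        {
            "pair_id": np.arange(1, spec.n_pairs + 1),
            "x_1": obs[:, 0],
            "y_1": obs[:, 1],
            "x_2": obs[:, 2],
            "y_2": obs[:, 3],
        }
    )
    return TwinPairDataset(frame)


def calibrate(
    rho_x: float,
    rho_y: float,
    r_xy: float,
    diagram: str,
    mixture_weight_confounding: float = 0.0,
    n_pairs: int = 100,
    seed: int = 0,
) -> ScenarioSpec:
    """Solve the standardized path equations for the loadings that
    reproduce target within-pair correlations and the within-individual
    cross-trait correlation.

    * diagram ``b``: ``causal_beta = r_xy``, ``loading_sx = sqrt(rho_x)``,
      ``loading_sy^2 = rho_y - r_xy^2 * rho_x``.
    * diagram ``c``: the mirror image.
    * diagram ``a``: symmetric confounder loadings
      ``sqrt(|r_xy|)`` reproduce ``r_xy``; trait-specific shared loadings
      absorb the rest of the within-pair correlations.
    * diagram ``d``: the X_self–Y_self covariance is split as
      ``w * r_xy`` through the S_XY path and ``(1 - w) * r_xy`` through
      the causal path, with ``w = mixture_weight_confounding``.

    Raises
    ------
    InfeasibleTargetsError
        if a solved squared loading is negative, naming the violated
        inequality.
    """
    for name, v in (("rho_x", rho_x), ("rho_y", rho_y)):
        if not 0.0 <= v < 1.0:
            raise InfeasibleTargetsError(f"{name}={v} outside [0, 1)")
    if not -1.0 < r_xy < 1.0:
        raise InfeasibleTargetsError(f"r_xy={r_xy} outside (-1, 1)")
    w = mixture_weight_confounding

    def _sqrt(val, what):
        if val < -1e-12:
            raise InfeasibleTargetsError(f"infeasible targets: {what} = {val:.6g} < 0")
        return float(np.sqrt(max(val, 0.0)))

    if diagram == "b":
        sx = _sqrt(rho_x, "rho_x")
        sy = _sqrt(rho_y - r_xy**2 * rho_x, "rho_y - r_xy^2 * rho_x")
        spec = ScenarioSpec("b", loading_sx=sx, loading_sy=sy,
                            causal_beta=r_xy, n_pairs=n_pairs, seed=seed)
    elif diagram == "c":
        sy = _sqrt(rho_y, "rho_y")
        sx = _sqrt(rho_x - r_xy**2 * rho_y, "rho_x - r_xy^2 * rho_y")
        spec = ScenarioSpec("c", loading_sx=sx, loading_sy=sy,
                            causal_beta=r_xy, n_pairs=n_pairs, seed=seed)
    elif diagram == "a":
        c = _sqrt(abs(r_xy), "|r_xy|")
        cy = float(np.sign(r_xy)) * c if r_xy != 0 else 0.0
        sx = _sqrt(rho_x - abs(r_xy), "rho_x - |r_xy|")
        sy = _sqrt(rho_y - abs(r_xy), "rho_y - |r_xy|")
        spec = ScenarioSpec("a", loading_sx=sx, loading_sy=sy,
                            loading_sxy_x=c, loading_sxy_y=cy,
                            n_pairs=n_pairs, seed=seed)
    elif diagram == "d":
        if not 0.0 <= w <= 1.0:
            raise InfeasibleTargetsError(f"mixture weight {w} outside [0, 1]")
        conf = w * r_xy
        beta = (1.0 - w) * r_xy
        if conf < 0:
            raise InfeasibleTargetsError("diagram 'd' calibration requires r_xy >= 0")
        c = _sqrt(conf, "w * r_xy")
        sx = _sqrt(rho_x - conf, "rho_x - w*r_xy")
        sy = _sqrt(rho_y - conf - beta**2 * rho_x - 2 * beta * conf,
                   "rho_y - w*r_xy - beta^2*rho_x - 2*beta*w*r_xy")
        spec = ScenarioSpec("d", loading_sx=sx, loading_sy=sy,
                            loading_sxy_x=c, loading_sxy_y=c,
                            causal_beta=beta, n_pairs=n_pairs, seed=seed)
    else:
        raise ValueError(f"unknown diagram {diagram!r}")
    return spec
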