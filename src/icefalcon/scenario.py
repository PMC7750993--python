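"""Empirical test of fit between observed coefficient changes and a
hypothesized causal scenario.

The null hypothesis is that the tested scenario (a calibrated causal
diagram, same number of pairs and correlational structure as the observed
data) is consistent with the observed results.  The scenario is simulated
many times; each simulated dataset is run through the full three-model
pipeline (double entry + exchangeable GEE) in both directions, yielding a
change vector d = (delta_self, delta_cotwin) per direction.  The test
statistic is the Mahalanobis distance of the observed change vector from
the simulated mean, using the simulated covariance — so the expected
sampling variation of the estimates is built into the metric — and the
p-value is empirical with the add-one rule, (r + 1) / (n_sims + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import gee
from .core import IceFalconResult, fit_three_models
from .simulate import ScenarioSpec, simulate_matrix, simulate_pairs
from .twin_data import TwinPairDataset, within_pair_correlation

__all__ = [
    "ScenarioFitResult",
    "scenario_test",
    "scenario_test_from_changes",
    "changes_from_matrix",
    "observed_structure",
    "calibrate_to_data",
]


@dataclass
class ScenarioFitResult:
    """Consistency of observed changes with one simulated scenario."""

    scenario: ScenarioSpec
    statistic: float
    empirical_p: float
    n_sims: int
    seed: int
    sim_mean: np.ndarray
    sim_cov: np.ndarray
    observed_changes: np.ndarray
    statistic_name: str = "mahalanobis distance of the change vector"

    def verdict_line(self, alpha: float = 0.05) -> str:
        if self.empirical_p < alpha:
            return (f"scenario '{self.scenario.diagram}' is inconsistent with the "
                    f"observed results (empirical p = {self.empirical_p:.3g})")
        return (f"no evidence that scenario '{self.scenario.diagram}' is inconsistent "
                f"with the observed results (empirical p = {self.empirical_p:.3g})")

    def to_dict(self) -> dict:
        return {
            "diagram": self.scenario.diagram,
            "statistic": self.statistic,
            "statistic_name": self.statistic_name,
            "empirical_p": self.empirical_p,
            "n_sims": self.n_sims,
            "seed": self.seed,
            "observed_changes": list(map(float, self.observed_changes)),
            "sim_mean": list(map(float, self.sim_mean)),
        }


def observed_structure(data: TwinPairDataset) -> dict:
    """Within-pair correlations and the pooled within-individual
    cross-trait correlation of a dataset — the calibration targets."""
    rho_x = within_pair_correlation(data, "x").estimate
    rho_y = within_pair_correlation(data, "y").estimate
    x = data.trait("x").reshape(-1)
    y = data.trait("y").reshape(-1)
    r_xy = float(np.corrcoef(x, y)[0, 1])
    return {"rho_x": rho_x, "rho_y": rho_y, "r_xy": r_xy, "n_pairs": data.n_pairs}


def calibrate_to_data(
    data: TwinPairDataset,
    diagram: str,
    mixture_weight_confounding: float = 0.0,
    seed: int = 0,
) -> ScenarioSpec:
    """Calibrate a diagram to a dataset's observed correlational structure."""
    from .simulate import calibrate

    s = observed_structure(data)
    return calibrate(
        s["rho_x"], s["rho_y"], s["r_xy"], diagram,
        mixture_weight_confounding=mixture_weight_confounding,
        n_pairs=s["n_pairs"], seed=seed,
    )


def _change_vector(data: TwinPairDataset, directions) -> np.ndarray:
    d = []
    for predictor, outcome in directions:
        m1, m2, m3 = fit_three_models(data, predictor, outcome)
        d.append(m3.coefficients.iloc[1] - m1.coefficients.iloc[1])
        d.append(m3.coefficients.iloc[2] - m2.coefficients.iloc[1])
    return np.asarray(d, float)


# column indices of (x_1, y_1, x_2, y_2) in the simulation matrix
_COLS = {"x": (0, 2), "y": (1, 3)}


def changes_from_matrix(obs: np.ndarray, directions) -> np.ndarray:
    """Change vector (delta_self, delta_cotwin per direction) computed
    directly from a raw (n, 4) pair matrix — the simulation hot path,
    equivalent to running double entry + the three GEE fits."""
    n = obs.shape[0]
    ones = np.ones((n, 2))
    d = []
    for predictor, outcome in directions:
        p1, p2 = _COLS[predictor]
        o1, o2 = _COLS[outcome]
        Y = obs[:, [o1, o2]]
        x_self = obs[:, [p1, p2]]
        x_co = obs[:, [p2, p1]]
        X1 = np.stack([ones, x_self], axis=2)
        X2 = np.stack([ones, x_co], axis=2)
        X3 = np.stack([ones, x_self, x_co], axis=2)
        b1 = gee.fit_from_stats(gee.PairedStats(Y, X1, ["intercept", "self"]))
        b2 = gee.fit_from_stats(gee.PairedStats(Y, X2, ["intercept", "cotwin"]))
        b3 = gee.fit_from_stats(gee.PairedStats(Y, X3, ["intercept", "self", "cotwin"]))
        d.append(b3[1] - b1[1])
        d.append(b3[2] - b2[1])
    return np.asarray(d, float)


def scenario_test(
    observed,
    scenario: ScenarioSpec,
    n_sims: int = 1000,
    seed: int = 0,
) -> ScenarioFitResult:
    """Test whether observed changes are consistent with a scenario.

    Parameters
    ----------
    observed
        Either a pair ``(forward, reverse)`` of :class:`IceFalconResult`
        (change vector is then the 4-vector over both directions) or a
        single result (2-vector).
    scenario
        The calibrated diagram to simulate (its ``n_pairs`` should match
        the observed dataset).
    n_sims, seed
        Number of scenario simulations and RNG seed.
    """
    if isinstance(observed, IceFalconResult):
        results = (observed,)
    else:
        results = tuple(observed)
    directions = [(r.predictor, r.outcome) for r in results]
    d_obs = np.asarray(
        [v for r in results for v in (r.delta_self, r.delta_cotwin)], float)
    return scenario_test_from_changes(d_obs, directions, scenario, n_sims=n_sims, seed=seed)


def scenario_test_from_changes(
    d_obs: np.ndarray,
    directions,
    scenario: ScenarioSpec,
    n_sims: int = 1000,
    seed: int = 0,
) -> ScenarioFitResult:
    """Scenario test given an already-computed observed change vector."""
    d_obs = np.asarray(d_obs, float)
    rng = np.random.default_rng(seed)
    sims = np.empty((n_sims, len(d_obs)))
    for i in range(n_sims):
        obs_i = simulate_matrix(scenario, rng=rng)
        sims[i] = changes_from_matrix(obs_i, directions)

    mean = sims.mean(axis=0)
    cov = np.cov(sims, rowvar=False)
    cov = np.atleast_2d(cov)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular simulated covariance; ridge-regularized")
        ridge = 1e-8 * np.trace(cov) / cov.shape[0]
        cov_inv = np.linalg.inv(cov + ridge * np.eye(cov.shape[0]))

    def maha(v):
        diff = v - mean
        return float(diff @ cov_inv @ diff)

    stat_obs = maha(d_obs)
    stats_sim = np.einsum("ij,jk,ik->i", sims - mean, cov_inv, sims - mean)
    r = int(np.sum(stats_sim >= stat_obs))
    p = (r + 1) / (n_sims + 1)
    return ScenarioFitResult(
        scenario=scenario,
        statistic=stat_obs,
        empirical_p=float(p),
        n_sims=n_sims,
        seed=seed,
        sim_mean=mean,
        sim_cov=cov,
        observed_changes=d_obs,
    )
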