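"""The co-twin regression procedure: three models, bootstrap, interpretation.

For a predictor trait X and outcome trait Y measured on both members of
twin pairs, three marginal models are fitted to the double-entered data
by exchangeable GEE:

* Model 1: ``E(Y_self) = a + b_self * X_self``
* Model 2: ``E(Y_self) = a + b_cotwin * X_cotwin``
* Model 3: ``E(Y_self) = a + b'_self * X_self + b'_cotwin * X_cotwin``

Inference about causation rests on the *changes* ``delta_self = b'_self -
b_self`` and ``delta_cotwin = b'_cotwin - b_cotwin``: familial confounding
attenuates both slopes in Model 3 to a similar proportional extent,
whereas a causal X -> Y effect leaves the self slope unchanged and drives
the cross-pair slope to zero.  Uncertainty in the changes comes from a
nonparametric bootstrap that resamples whole pairs with replacement and
refits all three models per replicate; the reported standard error of a
change is the standard deviation of that change across replicates, and
the one-sided p-value tests change in the direction of attenuation toward
the null.  Running both the X -> Y and Y -> X directions and comparing
the joint significance pattern with the expected pattern table yields the
qualitative verdict.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from . import gee
from .twin_data import TwinPairDataset, double_enter

__all__ = [
    "IceFalconResult",
    "PatternCall",
    "fit_three_models",
    "bootstrap_changes",
    "bidirectional",
    "interpret",
    "information_metric",
    "attenuation_percent",
    "BootstrapError",
]


def attenuation_percent(marginal: float, conditional: float) -> float:
    """Signed percent attenuation ``100 * (b - b') / b`` of a conditional
    coefficient relative to its marginal counterpart."""
    if marginal == 0:
        raise ValueError("marginal coefficient must be nonzero")
    return 100.0 * (marginal - conditional) / marginal


class BootstrapError(RuntimeError):
    """Too many bootstrap replicates failed to converge."""


@dataclass
class IceFalconResult:
    """Three-model coefficients, changes and bootstrap inference for one direction."""

    predictor: str
    outcome: str
    model1: gee.ModelFit
    model2: gee.ModelFit
    model3: gee.ModelFit
    n_boot: int
    seed: int
    boot_delta_self: np.ndarray = field(repr=False)
    boot_delta_cotwin: np.ndarray = field(repr=False)
    n_boot_failed: int = 0

    # -- coefficients ---------------------------------------------------
    @property
    def beta_self(self) -> float:
        return float(self.model1.coefficients.iloc[1])

    @property
    def beta_cotwin(self) -> float:
        return float(self.model2.coefficients.iloc[1])

    @property
    def beta_self_prime(self) -> float:
        return float(self.model3.coefficients.iloc[1])

    @property
    def beta_cotwin_prime(self) -> float:
        return float(self.model3.coefficients.iloc[2])

    @property
    def delta_self(self) -> float:
        return self.beta_self_prime - self.beta_self

    @property
    def delta_cotwin(self) -> float:
        return self.beta_cotwin_prime - self.beta_cotwin

    @property
    def n_pairs(self) -> int:
        return self.model1.n_pairs

    # -- bootstrap inference on the changes ------------------------------
    @property
    def se_delta_self(self) -> float:
        return float(np.std(self.boot_delta_self, ddof=1))

    @property
    def se_delta_cotwin(self) -> float:
        return float(np.std(self.boot_delta_cotwin, ddof=1))

    def _one_sided_p(self, delta: float, se: float, marginal: float) -> float:
        # alternative: change in the direction of attenuation toward the null,
        # i.e. delta with sign opposite the marginal coefficient
        if se <= 0:
            return float("nan")
        direction = math.copysign(1.0, marginal) if marginal != 0 else 1.0
        return float(spstats.norm.cdf(direction * delta / se))

    @property
    def p_delta_self(self) -> float:
        return self._one_sided_p(self.delta_self, self.se_delta_self, self.beta_self)

    @property
    def p_delta_cotwin(self) -> float:
        return self._one_sided_p(self.delta_cotwin, self.se_delta_cotwin, self.beta_cotwin)

    @property
    def z_delta_cotwin(self) -> float:
        """Test statistic for the change in the cross-pair coefficient."""
        return self.delta_cotwin / self.se_delta_cotwin

    def percentile_interval(self, which: str = "cotwin", level: float = 0.95):
        """Bootstrap percentile interval of a change (diagnostic)."""
        reps = self.boot_delta_cotwin if which == "cotwin" else self.boot_delta_self
        lo, hi = np.quantile(reps, [(1 - level) / 2, (1 + level) / 2])
        return float(lo), float(hi)

    # -- attenuation ------------------------------------------------------
    @property
    def attenuation_self(self) -> float:
        """Signed percent attenuation of the self slope, 100*(b - b')/b."""
        return attenuation_percent(self.beta_self, self.beta_self_prime)

    @property
    def attenuation_cotwin(self) -> float:
        return attenuation_percent(self.beta_cotwin, self.beta_cotwin_prime)

    @property
    def p_attenuation_difference(self) -> float:
        """Two-sided bootstrap p for unequal proportional attenuation.

        Compares delta_self/beta_self with delta_cotwin/beta_cotwin using
        the bootstrap spread of their difference; NaN when a marginal
        slope is too close to zero for the proportion to be stable.
        """
        bs, bc = self.beta_self, self.beta_cotwin
        scale = max(abs(bs), abs(bc))
        if min(abs(bs), abs(bc)) < 0.05 * scale or scale == 0:
            return float("nan")
        diff_obs = self.delta_self / bs - self.delta_cotwin / bc
        diff_reps = self.boot_delta_self / bs - self.boot_delta_cotwin / bc
        se = float(np.std(diff_reps, ddof=1))
        if se <= 0:
            return float("nan")
        return float(2 * spstats.norm.sf(abs(diff_obs) / se))

    # -- reporting --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Table mirroring the standard report layout: one row per slope,
        columns for Models 1-3 and the change (est, SE, p)."""
        m1, m2, m3 = self.model1, self.model2, self.model3
        rows = [
            {
                "coefficient": "beta_self",
                "model1_est": self.beta_self,
                "model1_se": float(m1.robust_se.iloc[1]),
                "model1_p": float(m1.pvalues.iloc[1]),
                "model3_est": self.beta_self_prime,
                "model3_se": float(m3.robust_se.iloc[1]),
                "model3_p": float(m3.pvalues.iloc[1]),
                "change_est": self.delta_self,
                "change_se": self.se_delta_self,
                "change_p_one_sided": self.p_delta_self,
            },
            {
                "coefficient": "beta_cotwin",
                "model2_est": self.beta_cotwin,
                "model2_se": float(m2.robust_se.iloc[1]),
                "model2_p": float(m2.pvalues.iloc[1]),
                "model3_est": self.beta_cotwin_prime,
                "model3_se": float(m3.robust_se.iloc[2]),
                "model3_p": float(m3.pvalues.iloc[2]),
                "change_est": self.delta_cotwin,
                "change_se": self.se_delta_cotwin,
                "change_p_one_sided": self.p_delta_cotwin,
            },
        ]
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        return {
            "predictor": self.predictor,
            "outcome": self.outcome,
            "n_pairs": self.n_pairs,
            "n_boot": self.n_boot,
            "n_boot_failed": self.n_boot_failed,
            "seed": self.seed,
            "beta_self": self.beta_self,
            "beta_cotwin": self.beta_cotwin,
            "beta_self_prime": self.beta_self_prime,
            "beta_cotwin_prime": self.beta_cotwin_prime,
            "delta_self": self.delta_self,
            "delta_cotwin": self.delta_cotwin,
            "se_delta_self": self.se_delta_self,
            "se_delta_cotwin": self.se_delta_cotwin,
            "p_delta_self": self.p_delta_self,
            "p_delta_cotwin": self.p_delta_cotwin,
            "attenuation_self_pct": self.attenuation_self,
            "attenuation_cotwin_pct": self.attenuation_cotwin,
            "p_attenuation_difference": self.p_attenuation_difference,
            "models": {
                "model1": self.model1.to_dict(),
                "model2": self.model2.to_dict(),
                "model3": self.model3.to_dict(),
            },
        }


@dataclass(frozen=True)
class PatternCall:
    """Qualitative verdict mapped from the joint significance pattern."""

    verdict: str  # familial confounding | X causes Y | Y causes X | mixture | indeterminate
    forward_pattern: str
    reverse_pattern: str
    alpha: float
    evidence: tuple

    def __str__(self):
        lines = [f"verdict: {self.verdict} (alpha={self.alpha})"]
        lines += [f"  - {e}" for e in self.evidence]
        return "\n".join(lines)


def _direction_columns(predictor: str, outcome: str):
    if {predictor, outcome} != {"x", "y"}:
        raise ValueError("predictor/outcome must be 'x' and 'y' (distinct)")
    return (
        f"{outcome}_self",
        f"{predictor}_self",
        f"{predictor}_cotwin",
    )


def fit_three_models(
    data: TwinPairDataset,
    predictor: str = "x",
    outcome: str = "y",
    covariates: list[str] = (),
) -> tuple[gee.ModelFit, gee.ModelFit, gee.ModelFit]:
    """Fit Models 1-3 for one direction on the double-entered data.

    Covariates (self values) are included in all three models.
    """
    frame = double_enter(data)
    out_col, self_col, co_col = _direction_columns(predictor, outcome)
    covs = list(covariates)
    m1 = gee.fit_gee(frame, out_col, [self_col] + covs)
    m2 = gee.fit_gee(frame, out_col, [co_col] + covs)
    m3 = gee.fit_gee(frame, out_col, [self_col, co_col] + covs)
    return m1, m2, m3


def bootstrap_changes(
    data: TwinPairDataset,
    predictor: str = "x",
    outcome: str = "y",
    covariates: list[str] = (),
    n_boot: int = 1000,
    seed: int = 0,
) -> IceFalconResult:
    """Fit the three models and bootstrap the coefficient changes.

    The resampling unit is the twin pair: each replicate draws n_pairs
    pairs with replacement, refits Models 1-3, and records
    (delta_self, delta_cotwin).  The bootstrap SE of a change is the
    standard deviation across replicates.  Replicates where the GEE fails
    to converge are dropped (error if more than 1% fail).  Fully
    reproducible from ``seed``.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    m1, m2, m3 = fit_three_models(data, predictor, outcome, covariates)

    frame = double_enter(data)
    out_col, self_col, co_col = _direction_columns(predictor, outcome)
    covs = list(covariates)
    stats1 = _paired_stats(frame, out_col, [self_col] + covs)
    stats2 = _paired_stats(frame, out_col, [co_col] + covs)
    stats3 = _paired_stats(frame, out_col, [self_col, co_col] + covs)

    n = frame.n_pairs
    rng = np.random.default_rng(seed)
    d_self = np.empty(n_boot)
    d_cotwin = np.empty(n_boot)
    ok = np.ones(n_boot, bool)
    for r in range(n_boot):
        w = rng.multinomial(n, np.full(n, 1.0 / n)).astype(float)
        try:
            b1 = gee.fit_from_stats(stats1, w)
            b2 = gee.fit_from_stats(stats2, w)
            b3 = gee.fit_from_stats(stats3, w)
        except (gee.GEEConvergenceError, np.linalg.LinAlgError, gee.RankDeficientError):
            ok[r] = False
            continue
        d_self[r] = b3[1] - b1[1]
        d_cotwin[r] = b3[2] - b2[1]
    n_failed = int((~ok).sum())
    if n_failed > 0.01 * n_boot:
        raise BootstrapError(
            f"{n_failed}/{n_boot} bootstrap replicates failed to converge")
    return IceFalconResult(
        predictor=predictor,
        outcome=outcome,
        model1=m1,
        model2=m2,
        model3=m3,
        n_boot=n_boot,
        seed=seed,
        boot_delta_self=d_self[ok],
        boot_delta_cotwin=d_cotwin[ok],
        n_boot_failed=n_failed,
    )


def _paired_stats(frame, outcome, predictors):
    Y, X, names = gee._design_arrays(frame, outcome, predictors)
    return gee.PairedStats(Y, X, names)


def derive_direction_seeds(seed: int) -> tuple[int, int]:
    """Deterministic per-direction bootstrap seeds from a master seed."""
    rng = np.random.default_rng(seed)
    s = rng.integers(0, 2**31 - 1, size=2)
    return int(s[0]), int(s[1])


def bidirectional(
    data: TwinPairDataset,
    covariates: list[str] = (),
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[IceFalconResult, IceFalconResult]:
    """Run the procedure in both directions (X -> Y, then Y -> X) with
    independent bootstrap streams derived from a master seed."""
    s_fwd, s_rev = derive_direction_seeds(seed)
    fwd = bootstrap_changes(data, "x", "y", covariates, n_boot, s_fwd)
    rev = bootstrap_changes(data, "y", "x", covariates, n_boot, s_rev)
    return fwd, rev


def information_metric(z: float, n: int) -> float:
    """Information-per-subject measure z / sqrt(n).

    ``z`` is the test statistic carrying the causal evidence (here the
    change in the cross-pair coefficient; for an instrumental-variable
    analysis, the instrument-outcome statistic) and ``n`` the number of
    individuals; the ratio allows a per-subject comparison of methods.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    return z / math.sqrt(n)


def _classify_direction(res: IceFalconResult, alpha: float) -> str:
    """Qualitative pattern of one direction against the expected table."""
    m1_sig = float(res.model1.pvalues.iloc[1]) < alpha
    m2_sig = float(res.model2.pvalues.iloc[1]) < alpha
    prime_co_sig = float(res.model3.pvalues.iloc[2]) < alpha
    d_self_sig = res.p_delta_self < alpha
    d_co_sig = res.p_delta_cotwin < alpha
    d_co_changed = (
        d_co_sig
        or min(res.p_delta_cotwin, 1 - res.p_delta_cotwin) * 2 < alpha
    )  # two-sided view for emergence, where the change is away from null

    if not m1_sig and not m2_sig:
        return "null"
    if m2_sig and d_co_sig and not prime_co_sig and not d_self_sig:
        return "predictor_causes_outcome"
    if not m2_sig and d_co_changed and prime_co_sig:
        return "outcome_causes_predictor"
    if not m2_sig and d_co_changed:
        return "outcome_causes_predictor_weak"
    if d_self_sig and d_co_sig:
        p_diff = res.p_attenuation_difference
        if not math.isnan(p_diff) and p_diff < alpha:
            return "mixture"
        return "confounding"
    return "other"


def interpret(
    results: tuple[IceFalconResult, IceFalconResult], alpha: float = 0.05
) -> PatternCall:
    """Map the bidirectional significance/sign pattern to a verdict.

    The verdict is a pure function of the pattern at level ``alpha``:

    * both directions show proportional attenuation of both slopes ->
      familial confounding;
    * the forward direction shows the causal signature (cross-pair slope
      attenuates to null, self slope unchanged) while the reverse shows
      the mirror (null cross-pair slope that emerges conditionally) ->
      "X causes Y" (and symmetrically "Y causes X");
    * both changes significant with unequal proportional attenuation ->
      mixture of confounding and causation;
    * anything else -> indeterminate.
    """
    fwd, rev = results
    if {fwd.predictor, rev.predictor} != {"x", "y"}:
        raise ValueError("results must cover both directions")
    if fwd.predictor != "x":
        fwd, rev = rev, fwd
    pf = _classify_direction(fwd, alpha)
    pr = _classify_direction(rev, alpha)
    evidence = [
        f"x->y: beta_self={fwd.beta_self:.4g}, beta_cotwin={fwd.beta_cotwin:.4g}, "
        f"delta_cotwin={fwd.delta_cotwin:.4g} (one-sided p={fwd.p_delta_cotwin:.3g}), "
        f"pattern={pf}",
        f"y->x: beta_self={rev.beta_self:.4g}, beta_cotwin={rev.beta_cotwin:.4g}, "
        f"delta_cotwin={rev.delta_cotwin:.4g} (one-sided p={rev.p_delta_cotwin:.3g}), "
        f"pattern={pr}",
    ]
    rev_causal = ("outcome_causes_predictor", "outcome_causes_predictor_weak")

    if pf == "predictor_causes_outcome" and pr in rev_causal + ("null",):
        verdict = "X causes Y"
    elif pr == "predictor_causes_outcome" and pf in rev_causal + ("null",):
        verdict = "Y causes X"
    elif pf in rev_causal and pr not in ("predictor_causes_outcome",):
        verdict = "Y causes X"
    elif pr in rev_causal and pf not in ("predictor_causes_outcome",):
        verdict = "X causes Y"
    elif pf == "confounding" and pr == "confounding":
        verdict = "familial confounding"
    elif "mixture" in (pf, pr):
        verdict = "mixture"
    elif pf == "null" and pr == "null":
        verdict = "indeterminate"
        evidence.append("no marginal association in either direction")
    else:
        verdict = "indeterminate"
    return PatternCall(
        verdict=verdict,
        forward_pattern=pf,
        reverse_pattern=pr,
        alpha=alpha,
        evidence=tuple(evidence),
    )
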