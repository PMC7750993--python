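"""Read, validate, reshape and residualize twin-pair trait data.

The analysis input is one row per pair with both co-twins' trait values
(:class:`TwinPairDataset`).  Regressions operate on the *double-entered*
view (:class:`DoubleEnteredFrame`): each individual appears once as
"self", with the co-twin's trait values attached, so every pair
contributes two rows and the data are symmetric in twin labels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "TwinPairDataset",
    "DoubleEnteredFrame",
    "CorrelationEstimate",
    "read_pairs",
    "residualize",
    "double_enter",
    "within_pair_correlation",
    "ConfigurationError",
    "ValidationError",
]

_CORE_WIDE = ("pair_id", "x_1", "y_1", "x_2", "y_2")


class ConfigurationError(ValueError):
    """A required column is missing or the column map is wrong."""


class ValidationError(ValueError):
    """The file content violates the pair structure."""


@dataclass(frozen=True)
class CorrelationEstimate:
    """A within-pair correlation with a Fisher-z confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    n_pairs: int

    def __post_init__(self):
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError("CI must bracket the estimate")


class TwinPairDataset:
    """Paired observations of two traits (plus covariates) per twin pair.

    Internally a wide frame: one row per pair with columns ``pair_id``,
    ``x_1, y_1, x_2, y_2`` and, for each covariate ``c``, ``c_1`` and
    ``c_2``.  Twin order within a pair is arbitrary and carries no
    meaning.
    """

    def __init__(self, frame: pd.DataFrame, n_dropped: int = 0):
        missing = [c for c in _CORE_WIDE if c not in frame.columns]
        if missing:
            raise ConfigurationError(f"missing required columns: {missing}")
        if frame["pair_id"].duplicated().any():
            dup = frame.loc[frame["pair_id"].duplicated(), "pair_id"].iloc[0]
            raise ValidationError(f"duplicated pair_id {dup!r}")
        self.frame = frame.reset_index(drop=True)
        self.n_dropped = int(n_dropped)

    # -- basic accessors -------------------------------------------------
    @property
    def n_pairs(self) -> int:
        return len(self.frame)

    @property
    def n_individuals(self) -> int:
        return 2 * len(self.frame)

    @property
    def covariates(self) -> list[str]:
        names = set()
        for col in self.frame.columns:
            if col in _CORE_WIDE or col == "zygosity":
                continue
            if col.endswith("_1") and col[:-2] + "_2" in self.frame.columns:
                names.add(col[:-2])
        return sorted(names)

    def trait(self, trait: str) -> np.ndarray:
        """(n_pairs, 2) array of a trait's values, one column per twin."""
        if trait not in ("x", "y") and trait not in self.covariates:
            raise KeyError(f"unknown trait {trait!r}")
        return self.frame[[f"{trait}_1", f"{trait}_2"]].to_numpy(float)

    def with_trait(self, trait: str, values: np.ndarray) -> "TwinPairDataset":
        frame = self.frame.copy()
        frame[f"{trait}_1"] = values[:, 0]
        frame[f"{trait}_2"] = values[:, 1]
        return TwinPairDataset(frame, self.n_dropped)

    def to_file(self, path) -> None:
        """Round-trip the validated wide layout to delimited text."""
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
        self.frame.to_csv(path, sep=sep, index=False)

    def __repr__(self):
        return f"TwinPairDataset(n_pairs={self.n_pairs}, covariates={self.covariates})"


class DoubleEnteredFrame:
    """One row per individual: self traits plus the co-twin's traits.

    Row order is deterministic (pair_id, then twin index) and the frame is
    invariant, up to row order, under swapping twin labels within a pair.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {"pair_id", "twin", "x_self", "y_self", "x_cotwin", "y_cotwin"}
        missing = required - set(frame.columns)
        if missing:
            raise ConfigurationError(f"double-entered frame missing {sorted(missing)}")
        self.frame = frame.reset_index(drop=True)

    @property
    def n_pairs(self) -> int:
        return self.frame["pair_id"].nunique()

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    def paired(self, column: str) -> np.ndarray:
        """(n_pairs, 2) array of a column grouped by pair, twin 1 then 2."""
        return self.frame[column].to_numpy(float).reshape(-1, 2)


def _detect_sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_pairs(path, layout: str = "wide", column_map: dict | None = None) -> TwinPairDataset:
    """Read a delimited twin file and validate the pair structure.

    Parameters
    ----------
    path
        CSV (``.csv``) or tab-delimited (``.tsv``/``.txt``) file with a
        header row.
    layout
        ``"wide"``: one row per pair with columns
        ``pair_id, x_1, y_1, x_2, y_2 [, cov_1, cov_2 ...]``.
        ``"long"``: one row per individual with columns
        ``pair_id, twin_id, x, y [, covariates]``.
    column_map
        Optional mapping from the canonical names above to the file's
        column names, e.g. ``{"x": "bmi", "y": "methylation"}``.

    Pairs with a missing member or missing X/Y values are dropped and
    counted (``.n_dropped``); a warning records how many.
    """
    if layout not in ("wide", "long"):
        raise ConfigurationError(f"layout must be 'wide' or 'long', got {layout!r}")
    raw = pd.read_csv(path, sep=_detect_sep(path))
    cmap = dict(column_map or {})
    rename = {v: k for k, v in cmap.items() if v in raw.columns}
    missing_map = [v for v in cmap.values() if v not in raw.columns]
    if missing_map:
        raise ConfigurationError(f"mapped columns not in file: {missing_map}")
    raw = raw.rename(columns=rename)

    if layout == "wide":
        missing = [c for c in _CORE_WIDE if c not in raw.columns]
        if missing:
            raise ConfigurationError(f"wide layout requires columns {missing}")
        wide = raw
    else:
        for c in ("pair_id", "twin_id", "x", "y"):
            if c not in raw.columns:
                raise ConfigurationError(f"long layout requires column {c!r}")
        sizes = raw.groupby("pair_id").size()
        bad = sizes[sizes > 2]
        if len(bad):
            raise ValidationError(
                f"pair {bad.index[0]!r} has {bad.iloc[0]} rows (expected 2)")
        covs = [c for c in raw.columns if c not in ("pair_id", "twin_id", "x", "y")]
        rows = []
        for pid, grp in raw.groupby("pair_id", sort=True):
            if len(grp) != 2:
                rows.append({"pair_id": pid, "_incomplete": True})
                continue
            grp = grp.sort_values("twin_id")
            rec = {"pair_id": pid, "_incomplete": False}
            for i, (_, r) in enumerate(grp.iterrows(), start=1):
                rec[f"x_{i}"] = r["x"]
                rec[f"y_{i}"] = r["y"]
                for c in covs:
                    rec[f"{c}_{i}"] = r[c]
            rows.append(rec)
        wide = pd.DataFrame(rows)
        incomplete = wide.pop("_incomplete")
        n_member_dropped = int(incomplete.sum())
        wide = wide[~incomplete.to_numpy(bool)]
        if n_member_dropped:
            logger.warning("dropped %d pair(s) with a missing member", n_member_dropped)

    # drop pairs with missing X or Y for either member
    core = [c for c in ("x_1", "y_1", "x_2", "y_2") if c in wide.columns]
    complete = wide[core].notna().all(axis=1) if core else pd.Series(True, index=wide.index)
    n_dropped = int((~complete).sum())
    if layout == "long":
        n_dropped += n_member_dropped
    if int((~complete).sum()):
        logger.warning("dropped %d pair(s) with missing trait values", int((~complete).sum()))
    wide = wide[complete]
    return TwinPairDataset(wide.reset_index(drop=True), n_dropped=n_dropped)


def residualize(data: TwinPairDataset, trait: str, covariates: list[str]) -> TwinPairDataset:
    """Replace a trait by OLS residuals on covariates, pooled over individuals.

    The fit stacks both twins (2 x n_pairs observations) and includes an
    intercept, so the residuals have mean zero; pair clustering is ignored
    here (it is the GEE's job downstream).  With an empty covariate list
    the trait is simply centred.  Constant covariates are dropped from the
    design with a warning.
    """
    y = data.trait(trait).reshape(-1)  # stacked: pair-major, twin-minor
    cols = [np.ones_like(y)]
    for cov in covariates:
        v = data.trait(cov).reshape(-1)
        if np.isnan(v).any():
            raise ValidationError(f"covariate {cov!r} has missing values")
        if np.ptp(v) == 0:
            warnings.warn(f"covariate {cov!r} is constant; dropped from residualization")
            continue
        cols.append(v)
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return data.with_trait(trait, resid.reshape(-1, 2))


def double_enter(data: TwinPairDataset) -> DoubleEnteredFrame:
    """Build the double-entered view: one row per individual.

    Each individual appears once as "self" with the co-twin's X and Y
    attached; covariates enter as the self values.  Rows are ordered by
    pair_id then twin index.
    """
    wide = data.frame.sort_values("pair_id")
    covs = data.covariates
    parts = []
    for self_i, co_i in ((1, 2), (2, 1)):
        part = pd.DataFrame(
            {
                "pair_id": wide["pair_id"].to_numpy(),
                "twin": self_i,
                "x_self": wide[f"x_{self_i}"].to_numpy(float),
                "y_self": wide[f"y_{self_i}"].to_numpy(float),
                "x_cotwin": wide[f"x_{co_i}"].to_numpy(float),
                "y_cotwin": wide[f"y_{co_i}"].to_numpy(float),
            }
        )
        for c in covs:
            part[c] = wide[f"{c}_{self_i}"].to_numpy(float)
        parts.append(part)
    out = pd.concat(parts, ignore_index=True)
    out = out.sort_values(["pair_id", "twin"], kind="stable").reset_index(drop=True)
    return DoubleEnteredFrame(out)


def within_pair_correlation(data: TwinPairDataset, trait: str) -> CorrelationEstimate:
    """Within-pair Pearson correlation on the double-entered pairing.

    Each pair contributes both orderings, which makes the estimate exactly
    symmetric in twin labels (it equals the intraclass-style moment
    estimator about the grand mean).  The CI is Fisher-z with effective
    sample size equal to the number of pairs.
    """
    vals = data.trait(trait)
    n = vals.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 pairs for a within-pair correlation")
    flat = vals.reshape(-1)
    m = flat.mean()
    d1 = vals[:, 0] - m
    d2 = vals[:, 1] - m
    denom = np.sum(d1**2) + np.sum(d2**2)
    if denom == 0:
        raise ValidationError(f"trait {trait!r} has zero variance")
    r = float(2.0 * np.sum(d1 * d2) / denom)
    r = float(np.clip(r, -1.0, 1.0))
    if n > 3 and abs(r) < 1.0:
        z = np.arctanh(r)
        half = stats.norm.ppf(0.975) / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    else:
        lo, hi = -1.0, 1.0
    return CorrelationEstimate(r, float(min(lo, r)), float(max(hi, r)), n)
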