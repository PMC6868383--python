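"""Regression layer: Pearson correlations with t-test p-values, multiple OLS
with an F-test against the intercept-only model, and the Proportional
Reduction in Error (PRE) statistic.

PRE quantifies the contribution of one predictor to a multiple regression as
the relative drop in residual sum of squares when that predictor is added to
the model already containing all the others:

    PRE_j = (RSS_without_j - RSS_full) / RSS_without_j

with both models containing an intercept.  All p-values are two-sided and
reported raw (no multiple-testing correction).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "PREDICTOR_ORDER",
    "pearson",
    "pearson_pvalue",
    "ols",
    "pre_test",
    "correlation_screen",
    "build_system_table",
]

#: Canonical predictor order of the interaction frequencies.
PREDICTOR_ORDER = ("sc_b1", "sc_b2", "sc_b3", "stack12", "stack23", "stack13")


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t_statistic: float
    p_value: float


@dataclass
class RegressionResult:
    """OLS fit with intercept: coefficients, R^2, overall F-test and PRE values."""

    coefficients: np.ndarray  # intercept first
    std_errors: np.ndarray  # aligned with coefficients
    r_squared: float
    f_statistic: float
    f_p_value: float
    residuals: np.ndarray
    rss: float
    pre: dict[int, float] = field(default_factory=dict)

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def slopes(self) -> np.ndarray:
        return self.coefficients[1:]


def pearson_pvalue(r: float, n: int) -> tuple[float, float]:
    """Two-sided t-test p-value for a Pearson coefficient at sample size n.

    t = r * sqrt(n - 2) / sqrt(1 - r^2), referred to a t distribution with
    n - 2 degrees of freedom (the survival function evaluates the
    regularized incomplete beta function; no table lookup).
    """
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if not -1.0 <= r <= 1.0:
        raise ValueError(f"correlation must lie in [-1, 1], got {r}")
    if abs(r) == 1.0:
        return np.inf if r > 0 else -np.inf, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return float(t), float(min(p, 1.0))


def pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson correlation with its two-sided t-test p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length vectors, got {x.shape} vs {y.shape}")
    n = x.size
    if n < 3:
        raise ValueError(f"need n >= 3 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    t, p = pearson_pvalue(r, n)
    return CorrelationResult(r=r, n=n, t_statistic=t, p_value=p)


def _design(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    return x


def ols(x: np.ndarray, y: np.ndarray, compute_pre: bool = False) -> RegressionResult:
    """Multiple linear regression of y on x with an intercept.

    The overall F-test compares the full model against the intercept-only
    model (the model is assumed to contain a constant term).  With
    ``compute_pre`` the PRE value of every predictor is attached.
    """
    x = _design(x)
    y = np.asarray(y, dtype=float)
    n, k = x.shape
    if y.shape != (n,):
        raise ValueError(f"y must have length {n}, got {y.shape}")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1 observations (n={n}, k={k})")
    design = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(design)
    if rank < k + 1:
        corr = np.corrcoef(x, rowvar=False)
        pairs = [
            (i, j)
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 1 - 1e-10
        ] if k > 1 else []
        raise ValueError(
            f"design matrix is rank-deficient (rank {rank} < {k + 1}); "
            f"collinear predictor pairs: {pairs or 'constant column present'}"
        )
    fit = sm.OLS(y, design).fit()
    result = RegressionResult(
        coefficients=np.asarray(fit.params, dtype=float),
        std_errors=np.asarray(fit.bse, dtype=float),
        r_squared=float(fit.rsquared),
        f_statistic=float(fit.fvalue),
        f_p_value=float(fit.f_pvalue),
        residuals=np.asarray(fit.resid, dtype=float),
        rss=float(fit.ssr),
    )
    if compute_pre:
        result.pre = {j: pre_test(x, y, j) for j in range(k)}
    return result


def pre_test(x: np.ndarray, y: np.ndarray, j: int) -> float:
    """Proportional Reduction in Error of predictor ``j``.

    Fits the full model and the model with column ``j`` removed (both with
    intercept) and returns (RSS_reduced - RSS_full) / RSS_reduced.  For a
    single-predictor model the reduced model is intercept-only and PRE
    equals R^2.
    """
    x = _design(x)
    if not 0 <= j < x.shape[1]:
        raise ValueError(f"predictor index {j} out of range for {x.shape[1]} predictors")
    y = np.asarray(y, dtype=float)
    full = ols(x, y)
    reduced_x = np.delete(x, j, axis=1)
    if reduced_x.shape[1] == 0:
        rss_reduced = float(((y - y.mean()) ** 2).sum())
    else:
        rss_reduced = ols(reduced_x, y).rss
    if rss_reduced <= 0:
        return 0.0
    return float((rss_reduced - full.rss) / rss_reduced)


def correlation_screen(
    table: pd.DataFrame,
    response: str,
    predictors: list[str],
    strata: str | None = None,
) -> pd.DataFrame:
    """Per-stratum Pearson correlations of a response with each predictor.

    Returns a tidy frame with columns (stratum, predictor, r, n, t, p,
    computable).  Strata with fewer than 3 complete observations — or a
    constant response/predictor — are flagged not-computable rather than
    erroring.  Rows with NaN in the response or predictor (e.g. a flagged
    undefined preference) are dropped listwise per cell.
    """
    missing = [c for c in [response, *predictors] if c not in table.columns]
    if missing:
        raise KeyError(f"columns not present in table: {missing}")
    if strata is not None and strata not in table.columns:
        raise KeyError(f"strata column {strata!r} not present in table")
    groups = [("all", table)] if strata is None else list(table.groupby(strata, sort=True))
    rows = []
    for name, sub in groups:
        for predictor in predictors:
            pair = sub[[response, predictor]].dropna()
            record = {
                "stratum": name, "predictor": predictor,
                "r": np.nan, "n": len(pair), "t": np.nan, "p": np.nan,
                "computable": False,
            }
            if len(pair) >= 3 and pair[response].nunique() > 1 and pair[predictor].nunique() > 1:
                res = pearson(pair[predictor].to_numpy(), pair[response].to_numpy())
                record.update(r=res.r, t=res.t_statistic, p=res.p_value, computable=True)
            rows.append(record)
    return pd.DataFrame(rows)


def build_system_table(records: list[dict]) -> pd.DataFrame:
    """Assemble per-system analysis records into the cross-system table.

    Each record holds the SystemDescriptor fields, mean relative exposure,
    state fractions and preference, and the seven interaction frequencies;
    optional annotation columns (hydrolysis half-life, affinity scales, ...)
    pass through unchanged.  Duplicate system keys are rejected.
    """
    table = pd.DataFrame(records)
    key_cols = ["triplet", "amino_acid", "attachment", "chirality"]
    present = [c for c in key_cols if c in table.columns]
    if present and table.duplicated(subset=present).any():
        dupes = table.loc[table.duplicated(subset=present), present]
        raise ValueError(f"duplicated system keys:\n{dupes}")
    return table
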