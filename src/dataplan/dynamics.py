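"""Lag-1 dynamic factor model on factor-score series.

Each factor at occasion *t* is regressed (per-equation OLS) on every factor at
occasion *t-1*; with standardized inputs the coefficients are standardized
betas, so the diagonal reads as temporal stability (autoregression) and the
off-diagonal as one dimension driving another (cross-prediction).  Per-equation
OLS gives the same point estimates as a saturated joint VAR(1) fit.  Lag pairs
that span a missed survey occasion are dropped; the nominal spacing of one lag
is about 6 hours under a 4-per-day schedule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import ConditioningError, SampleSizeError
from .ptechnique import FactorScoreSeries
from .scoring import DynamicModel

MIN_LAG_PAIRS = 30
DEFAULT_ALPHA = 0.05  #: significance level for retaining cross-predictions


@dataclass
class PathEstimate:
    """One standardized lag-1 path with its uncertainty."""

    source_factor: str
    target_factor: str
    beta: float
    se: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")

    @property
    def is_autoregression(self) -> bool:
        return self.source_factor == self.target_factor


def _lag_pairs(
    fscores: FactorScoreSeries, drop_overnight: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Row positions (t-1, t) of usable consecutive-occasion pairs."""
    occ = fscores.occasion_index
    prev = np.arange(len(occ) - 1)
    keep = occ[1:] == occ[:-1] + 1  # consecutive on the scheduled grid
    if drop_overnight:
        days = fscores.timestamps.normalize()
        keep &= (days[1:] == days[:-1]).to_numpy()
    prev = prev[keep]
    return prev, prev + 1


class DynamicFactorModel:
    """Lag-1 vector-autoregressive model of the factor-score series.

    Parameters
    ----------
    fscores
        Standardized factor scores with their scheduled-grid occasion index.
    drop_overnight
        When True, pairs whose two occasions fall on different calendar days
        are excluded (the overnight gap is much longer than the nominal lag).
    """

    def __init__(self, fscores: FactorScoreSeries, drop_overnight: bool = False):
        self.fscores = fscores
        self.drop_overnight = drop_overnight

    def fit(self) -> "DynamicFactorResults":
        prev, curr = _lag_pairs(self.fscores, self.drop_overnight)
        if len(prev) < MIN_LAG_PAIRS:
            raise SampleSizeError(
                f"only {len(prev)} usable lag pairs; need at least {MIN_LAG_PAIRS}"
            )
        factors = self.fscores.factor_ids
        vals = self.fscores.scores.to_numpy()
        X = vals[prev]  # predictors at t-1
        Y = vals[curr]  # outcomes at t
        k = len(factors)

        if k > 1:
            cond = np.linalg.cond(np.corrcoef(X, rowvar=False))
            if not np.isfinite(cond) or cond > 1e8:
                raise ConditioningError("collinear lagged predictors")

        sx = X.std(axis=0, ddof=1)
        sy = Y.std(axis=0, ddof=1)
        if (sx == 0).any() or (sy == 0).any():
            raise ConditioningError("constant factor-score series over lag pairs")

        beta = np.empty((k, k))  # source x target
        se = np.empty((k, k))
        pval = np.empty((k, k))
        Xd = sm.add_constant(X)
        for j in range(k):
            res = sm.OLS(Y[:, j], Xd).fit()
            # standardized betas: raw slope * sd(x)/sd(y); t/p unchanged by scaling
            beta[:, j] = res.params[1:] * sx / sy[j]
            se[:, j] = res.bse[1:] * sx / sy[j]
            pval[:, j] = res.pvalues[1:]

        estimates = [
            PathEstimate(factors[i], factors[j], float(beta[i, j]), float(se[i, j]),
                         float(pval[i, j]))
            for i in range(k)
            for j in range(k)
        ]
        return DynamicFactorResults(
            model=self,
            paths=pd.DataFrame(beta, index=factors, columns=factors),
            standard_errors=pd.DataFrame(se, index=factors, columns=factors),
            p_values=pd.DataFrame(pval, index=factors, columns=factors),
            estimates=estimates,
            n_lag_pairs=len(prev),
        )


@dataclass
class DynamicFactorResults:
    """Estimated lag-1 paths (source rows, target columns) with uncertainties."""

    model: DynamicFactorModel
    paths: pd.DataFrame
    standard_errors: pd.DataFrame
    p_values: pd.DataFrame
    estimates: list[PathEstimate]
    n_lag_pairs: int

    def prune(self, alpha: float = DEFAULT_ALPHA) -> DynamicModel:
        """Mask non-significant cross-predictions; autoregressions always stay."""
        retained = self.p_values < alpha
        np.fill_diagonal(retained.values, True)
        return DynamicModel(
            paths=self.paths.copy(),
            retained=retained,
            lag_description="one observation (~6 hours)",
        )

    def summary(self) -> str:
        rows = []
        for e in self.estimates:
            kind = "AR" if e.is_autoregression else "cross"
            rows.append(
                f"  {e.source_factor}(t-1) -> {e.target_factor}(t)  "
                f"beta = {e.beta:+.3f}  se = {e.se:.3f}  p = {e.p_value:.4f}  [{kind}]"
            )
        return "\n".join(
            [
                f"Lag-1 dynamic factor model ({self.n_lag_pairs} lag pairs, "
                "per-equation OLS, standardized betas)",
                *rows,
            ]
        )


def fit_var1(fscores: FactorScoreSeries, drop_overnight: bool = False) -> DynamicFactorResults:
    """Convenience wrapper around :class:`DynamicFactorModel`."""
    return DynamicFactorModel(fscores, drop_overnight=drop_overnight).fit()


def prune_paths(
    results: DynamicFactorResults | DynamicModel, alpha: float = DEFAULT_ALPHA
) -> DynamicModel:
    """Functional form of :meth:`DynamicFactorResults.prune`.

    Accepts an already-pruned :class:`DynamicModel` too, in which case the mask
    is simply preserved (pruning is idempotent).
    """
    if isinstance(results, DynamicModel):
        return DynamicModel(
            paths=results.paths.copy(),
            retained=results.retained.copy(),
            lag_description=results.lag_description,
        )
    return results.prune(alpha)
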