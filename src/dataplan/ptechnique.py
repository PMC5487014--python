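"""Person-specific (P-technique) factor analysis of a single participant's series.

Factor analysis is applied to one person's occasion-by-item matrix (occasions
playing the role cases play in conventional R-technique), so the latent
dimensions are idiographic: they describe how *this* participant's symptoms
covary over time.  Extraction is maximum likelihood on the Pearson correlation
matrix of completed occasions, with oblique (oblimin) rotation because the
downstream lag-1 dynamic model assumes the dimensions may correlate.

The estimator follows the classic concentrated-likelihood formulation: the
discrepancy is minimized over the item uniquenesses alone, the loadings being
available in closed form from the eigendecomposition of the rescaled
correlation matrix at any candidate uniqueness vector.  Rotation uses the
oblique gradient-projection algorithm.

Chi-square-based fit indices assume independent rows; intensively sampled
occasions are serially dependent, so TLI/CFI/SRMR are approximate here (a
:class:`~dataplan.exceptions.SerialDependenceWarning` is emitted once per fit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .ema import EmaSeries
from .exceptions import (
    ConditioningError,
    ConvergenceError,
    SampleSizeError,
    SchemaError,
    SerialDependenceWarning,
    ValidationError,
)
from .scoring import FactorSolution

DEFAULT_SALIENCE = 0.30  #: loadings below this magnitude are treated as absent

#: conventional strict fit cutoffs: CFI >= .95, TLI >= .95, SRMR <= .08
FIT_CUTOFFS = {"cfi": 0.95, "tli": 0.95, "srmr": 0.08}


@dataclass
class FitIndices:
    """Global fit of an implied vs. observed correlation structure."""

    chi2_model: float
    df_model: int
    chi2_null: float
    df_null: int
    tli: float
    cfi: float
    srmr: float
    n_obs: int

    def meets_cutoffs(self, cutoffs: dict | None = None) -> bool:
        c = dict(FIT_CUTOFFS)
        if cutoffs:
            c.update(cutoffs)
        return self.cfi >= c["cfi"] and self.tli >= c["tli"] and self.srmr <= c["srmr"]

    def to_dict(self) -> dict:
        return {
            "chi2_model": self.chi2_model,
            "df_model": self.df_model,
            "chi2_null": self.chi2_null,
            "df_null": self.df_null,
            "tli": self.tli,
            "cfi": self.cfi,
            "srmr": self.srmr,
            "n_obs": self.n_obs,
        }


@dataclass
class FactorScoreSeries:
    """Standardized per-factor scores at each completed occasion.

    ``occasion_index`` locates each row on the scheduled survey grid so that
    the dynamic model can tell genuinely consecutive occasions from pairs that
    span a missed survey.
    """

    scores: pd.DataFrame  # occasions x factors, DatetimeIndex
    occasion_index: np.ndarray

    def __post_init__(self) -> None:
        if len(self.scores) != len(self.occasion_index):
            raise ValidationError("occasion_index length must match score rows")
        self.occasion_index = np.asarray(self.occasion_index, dtype=int)

    @property
    def factor_ids(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.DatetimeIndex(self.scores.index)


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------


def fit_indices(
    sample_corr: np.ndarray,
    implied_corr: np.ndarray,
    n_obs: int,
    df_model: int,
) -> FitIndices:
    """TLI, CFI and SRMR from sample and model-implied correlation matrices.

    The ML discrepancy is ``F = ln|Sigma| - ln|S| + tr(S Sigma^-1) - p`` and the
    model chi-square is ``(n - 1) F``.  The null (baseline) model is mutually
    uncorrelated items.  SRMR is the root mean square of residual correlations
    over the lower triangle including the diagonal.
    """
    S = np.asarray(sample_corr, dtype=float)
    Sigma = np.asarray(implied_corr, dtype=float)
    p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_m <= 0:
        raise ConditioningError("implied correlation matrix is not positive definite")
    if sign_s <= 0:
        raise ConditioningError("sample correlation matrix is not positive definite")
    f_ml = logdet_m - logdet_s + float(np.trace(S @ np.linalg.inv(Sigma))) - p
    chi2_m = max((n_obs - 1) * f_ml, 0.0)
    # null model: Sigma = I, so F0 = -ln|S| + tr(S) - p = -ln|S| for correlations
    chi2_0 = max((n_obs - 1) * (-logdet_s + float(np.trace(S)) - p), 0.0)
    df_0 = p * (p - 1) // 2

    ratio_0 = chi2_0 / df_0 if df_0 > 0 else 0.0
    if chi2_m == 0.0 or df_model <= 0 or ratio_0 == 1.0:
        tli = 1.0  # perfect (or saturated) model; TLI degenerate, convention 1
    else:
        tli = (ratio_0 - chi2_m / df_model) / (ratio_0 - 1.0)
    num = max(chi2_m - df_model, 0.0)
    den = max(chi2_m - df_model, chi2_0 - df_0, 0.0)
    cfi = 1.0 - num / den if den > 0 else 1.0

    resid = S - Sigma
    tril = np.tril_indices(p)
    srmr = float(np.sqrt(np.mean(resid[tril] ** 2)))
    return FitIndices(
        chi2_model=float(chi2_m),
        df_model=int(df_model),
        chi2_null=float(chi2_0),
        df_null=int(df_0),
        tli=float(tli),
        cfi=float(cfi),
        srmr=srmr,
        n_obs=int(n_obs),
    )


# ---------------------------------------------------------------------------
# ML extraction and oblimin rotation
# ---------------------------------------------------------------------------


def _ml_objective(log_psi: np.ndarray, R: np.ndarray, k: int) -> float:
    psi = np.exp(log_psi)
    d = 1.0 / np.sqrt(psi)
    Rstar = R * np.outer(d, d)
    eigvals = np.linalg.eigvalsh(Rstar)[::-1]
    tail = np.clip(eigvals[k:], 1e-12, None)
    return float(np.sum(tail - np.log(tail) - 1.0))


def _ml_loadings(psi: np.ndarray, R: np.ndarray, k: int) -> np.ndarray:
    d = 1.0 / np.sqrt(psi)
    Rstar = R * np.outer(d, d)
    vals, vecs = np.linalg.eigh(Rstar)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order][:k], vecs[:, order][:, :k]
    scale = np.sqrt(np.clip(vals - 1.0, 0.0, None))
    return (vecs * scale) * np.sqrt(psi)[:, None]


def ml_extract(
    R: np.ndarray, n_factors: int, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray, float]:
    """Maximum-likelihood factor extraction from a correlation matrix.

    Returns ``(unrotated loadings, uniquenesses, discrepancy F_ML)``.  The
    discrepancy is concentrated over uniquenesses: for a fixed uniqueness
    vector the optimal loadings come from the top eigenpairs of
    ``diag(psi)^-1/2 R diag(psi)^-1/2``.
    """
    p = R.shape[0]
    k = n_factors
    if k < 1:
        raise ValidationError("n_factors must be >= 1")
    if ((p - k) ** 2 - (p + k)) < 0:
        raise ValidationError(f"{k} factors is over-parameterized for {p} items")
    # factanal-style start: scaled inverse diagonal of R^-1
    try:
        inv_diag = np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError as exc:
        raise ConditioningError("singular correlation matrix") from exc
    start = np.clip((1.0 - 0.5 * k / p) / inv_diag, 0.005, 1.0)
    bounds = [(np.log(0.005), 0.0)] * p
    res = optimize.minimize(
        _ml_objective,
        np.log(start),
        args=(R, k),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
    )
    if not res.success and res.status != 0:
        # L-BFGS-B occasionally reports precision loss at an acceptable optimum
        if "ABNORMAL" in str(res.message).upper() or res.nit >= max_iter:
            raise ConvergenceError(
                f"ML factor extraction did not converge: {res.message}",
                diagnostics={"nit": res.nit, "fun": float(res.fun)},
            )
    psi = np.exp(res.x)
    loadings = _ml_loadings(psi, R, k)
    return loadings, psi, float(res.fun)


def _oblimin_criterion(L: np.ndarray, gamma: float = 0.0) -> tuple[float, np.ndarray]:
    """Oblimin criterion value and gradient with respect to the pattern matrix."""
    p, k = L.shape
    L2 = L ** 2
    N = np.ones((k, k)) - np.eye(k)
    if gamma != 0.0:
        C = np.eye(p) - (gamma / p) * np.ones((p, p))
        M = C @ L2 @ N
    else:
        M = L2 @ N
    f = float(np.sum(L2 * M)) / 4.0
    grad = L * M
    return f, grad


def oblimin_rotate(
    A: np.ndarray,
    gamma: float = 0.0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> tuple[np.ndarray, np.ndarray]:
    """Oblique gradient-projection rotation of an unrotated loading matrix.

    Returns ``(pattern, phi)`` where ``pattern = A (T')^-1`` and
    ``phi = T'T`` is the factor correlation matrix.
    """
    k = A.shape[1]
    if k == 1:
        return A.copy(), np.ones((1, 1))
    T = np.eye(k)
    al = 1.0
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _oblimin_criterion(L, gamma)
    G = -(L.T @ Gq @ Ti).T
    for _ in range(max_iter):
        Gp = G - T @ np.diag(np.sum(T * G, axis=0))
        s = np.sqrt(np.sum(Gp ** 2))
        if s < tol:
            break
        al *= 2.0
        for _ in range(20):
            X = T - al * Gp
            v = 1.0 / np.sqrt(np.sum(X ** 2, axis=0))
            Tt = X * v
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = _oblimin_criterion(L, gamma)
            if ft < f - 0.5 * s ** 2 * al:
                break
            al /= 2.0
        T = Tt
        f = ft
        G = -(L.T @ Gq @ Ti).T
    phi = T.T @ T
    return L, phi


def _tidy_solution(
    pattern: np.ndarray, phi: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fix sign (dominant loadings positive) and order factors by variance share."""
    signs = np.sign(pattern.sum(axis=0))
    signs[signs == 0] = 1.0
    pattern = pattern * signs
    phi = phi * np.outer(signs, signs)
    order = np.argsort(-np.sum(pattern ** 2, axis=0), kind="stable")
    return pattern[:, order], phi[np.ix_(order, order)]


def parallel_analysis(
    R: np.ndarray,
    n_obs: int,
    n_reps: int = 50,
    quantile: float = 0.95,
    seed: int = 0,
) -> int:
    """Horn's parallel analysis: factors whose eigenvalues beat random data.

    Compares the eigenvalues of the observed correlation matrix against the
    ``quantile`` of eigenvalues from correlation matrices of random normal data
    of the same shape; returns the retained count (at least 1).
    """
    rng = np.random.default_rng(seed)
    p = R.shape[0]
    obs = np.sort(np.linalg.eigvalsh(R))[::-1]
    sims = np.empty((n_reps, p))
    for r in range(n_reps):
        X = rng.standard_normal((n_obs, p))
        sims[r] = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    ref = np.quantile(sims, quantile, axis=0)
    n = int(np.sum(obs > ref))
    return max(n, 1)


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------


class PTechniqueModel:
    """Person-specific factor model for one participant's EMA series.

    Parameters
    ----------
    series
        :class:`~dataplan.ema.EmaSeries` (or a plain occasions x items
        DataFrame) for a single participant.
    n_factors
        Number of latent dimensions; ``None`` selects it by parallel analysis.
    items
        Subset of columns to analyze (defaults to all).
    salience_threshold
        Loadings below this magnitude are reported as absent.
    rotation
        ``"oblimin"`` (default) or ``"none"``.
    """

    def __init__(
        self,
        series: EmaSeries | pd.DataFrame,
        n_factors: int | None = None,
        items: list[str] | None = None,
        salience_threshold: float = DEFAULT_SALIENCE,
        rotation: str = "oblimin",
        seed: int = 0,
    ):
        if isinstance(series, pd.DataFrame):
            series = EmaSeries(series)
        if items is not None:
            series = series.subset(list(items))
        self.series = series
        self.n_factors = n_factors
        self.salience_threshold = float(salience_threshold)
        if rotation not in ("oblimin", "none"):
            raise ValidationError(f"unknown rotation: {rotation!r}")
        self.rotation = rotation
        self.seed = seed

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "PTechniqueModel":
        return cls(EmaSeries(frame), **kwargs)

    def _correlation(self) -> tuple[np.ndarray, pd.DataFrame]:
        complete = self.series.complete_rows()
        p = complete.shape[1]
        if len(complete) <= p:
            raise SampleSizeError(
                f"need more completed occasions ({len(complete)}) than items ({p})"
            )
        sds = complete.std(axis=0, ddof=1)
        zero_var = list(sds.index[sds == 0])
        if zero_var:
            raise ConditioningError(
                f"zero-variance items: {zero_var}", items=zero_var
            )
        R = np.corrcoef(complete.to_numpy(), rowvar=False)
        sign, logdet = np.linalg.slogdet(R)
        if sign <= 0 or np.linalg.cond(R) > 1e10:
            worst = complete.columns[np.argmin(np.diag(np.linalg.pinv(R)))]
            raise ConditioningError(
                f"near-singular correlation matrix (check redundant items, e.g. {worst!r})",
                items=[worst],
            )
        return R, complete

    def fit(self) -> "PTechniqueResults":
        R, complete = self._correlation()
        n_obs, p = complete.shape
        k = self.n_factors
        if k is None:
            k = parallel_analysis(R, n_obs, seed=self.seed)
        warnings.warn(
            "fit indices treat occasions as independent; EMA rows are serially "
            "dependent, so chi-square-based indices are approximate",
            SerialDependenceWarning,
            stacklevel=2,
        )
        A, psi, f_ml = ml_extract(R, k)
        if self.rotation == "oblimin":
            pattern, phi = oblimin_rotate(A)
        else:
            pattern, phi = A.copy(), np.eye(k)
        pattern, phi = _tidy_solution(pattern, phi)

        implied = pattern @ phi @ pattern.T
        np.fill_diagonal(implied, 1.0)
        df_model = ((p - k) ** 2 - (p + k)) // 2
        fit = fit_indices(R, implied, n_obs, df_model)

        factor_ids = [f"F{i + 1}" for i in range(k)]
        items = list(complete.columns)
        full = pd.DataFrame(pattern, index=items, columns=factor_ids)
        # oblique pattern coefficients can overshoot 1 slightly; the reported
        # solution honors the standardized [-1, 1] contract
        masked = full.clip(-1.0, 1.0).where(full.abs() >= self.salience_threshold)
        pct = pd.Series(np.sum(pattern ** 2, axis=0) / p, index=factor_ids)
        solution = FactorSolution(
            loadings=masked,
            pct_variance=pct,
            fit=fit,
            excluded_items=[],
            structure=pd.DataFrame(pattern @ phi, index=items, columns=factor_ids),
            phi=pd.DataFrame(phi, index=factor_ids, columns=factor_ids),
        )
        return PTechniqueResults(
            model=self,
            solution=solution,
            full_loadings=full,
            uniquenesses=pd.Series(psi, index=items),
            sample_corr=pd.DataFrame(R, index=items, columns=items),
            discrepancy=f_ml,
        )


@dataclass
class PTechniqueResults:
    """Fitted person-specific factor solution with fit indices and scoring."""

    model: PTechniqueModel
    solution: FactorSolution
    full_loadings: pd.DataFrame
    uniquenesses: pd.Series
    sample_corr: pd.DataFrame
    discrepancy: float

    @property
    def fit_indices(self) -> FitIndices:
        return self.solution.fit

    def factor_scores(self) -> FactorScoreSeries:
        """Regression-method (Thurstone) factor scores, z-scored per factor."""
        return factor_scores(self.model.series, self.solution)

    def summary(self) -> str:
        fit = self.solution.fit
        lines = [
            "Person-specific factor analysis (ML extraction, "
            f"{self.model.rotation} rotation)",
            f"  occasions used: {fit.n_obs}   items: {len(self.solution.item_ids)}   "
            f"factors: {self.solution.n_factors}",
            "",
            "Pattern loadings (|loading| >= "
            f"{self.model.salience_threshold:.2f} shown):",
            self.solution.loadings.round(2).fillna("").to_string(),
            "",
            "Percent of total variance: "
            + "  ".join(
                f"{f}: {100 * v:.0f}%" for f, v in self.solution.pct_variance.items()
            ),
            f"Fit: chi2({fit.df_model}) = {fit.chi2_model:.1f}, TLI = {fit.tli:.3f}, "
            f"CFI = {fit.cfi:.3f}, SRMR = {fit.srmr:.3f}",
        ]
        return "\n".join(lines)


def fit_factor_model(
    series: EmaSeries | pd.DataFrame,
    n_factors: int | None = None,
    items: list[str] | None = None,
    **kwargs,
) -> FactorSolution:
    """Convenience wrapper: build, fit, and return the FactorSolution."""
    return PTechniqueModel(series, n_factors=n_factors, items=items, **kwargs).fit().solution


# ---------------------------------------------------------------------------
# avoidance-item retention
# ---------------------------------------------------------------------------


def avoidance_retention(
    series: EmaSeries | pd.DataFrame,
    core_items: list[str],
    avoidance_items: list[str],
    n_factors: int | None = None,
    cutoffs: dict | None = None,
    **kwargs,
) -> FactorSolution:
    """Two-step retention test for avoidance items.

    Fits the factor model twice — without and with the avoidance items — and
    keeps the avoidance items only when they increase the total share of
    symptom variance explained *and* the augmented model still meets the fit
    cutoffs (CFI >= .95, TLI >= .95, SRMR <= .08 by default).  The returned
    solution records any excluded items.
    """
    if set(core_items) & set(avoidance_items):
        raise SchemaError("core and avoidance item sets must be disjoint")
    if isinstance(series, pd.DataFrame):
        series = EmaSeries(series)
    core_res = PTechniqueModel(
        series, n_factors=n_factors, items=core_items, **kwargs
    ).fit()
    with_res = PTechniqueModel(
        series, n_factors=n_factors, items=core_items + list(avoidance_items), **kwargs
    ).fit()
    gain = with_res.solution.pct_variance.sum() > core_res.solution.pct_variance.sum()
    fits = with_res.solution.fit.meets_cutoffs(cutoffs)
    if gain and fits:
        with_res.solution.excluded_items = []
        return with_res.solution
    core_res.solution.excluded_items = list(avoidance_items)
    return core_res.solution


# ---------------------------------------------------------------------------
# factor scoring
# ---------------------------------------------------------------------------


def factor_scores(series: EmaSeries, solution: FactorSolution) -> FactorScoreSeries:
    """Score the original time series on the fitted factors.

    Thurstone regression weights ``W = R^-1 S`` (S the structure matrix) applied
    to z-scored items over completed occasions, then each factor series is
    re-standardized to mean 0, sd 1 (population sd).  Hand-built solutions
    lacking a structure matrix get loading-weighted composites instead (absent
    entries as 0), so an identity loading matrix maps items to scores directly.
    """
    complete = series.complete_rows()
    missing = [i for i in solution.item_ids if i not in complete.columns]
    if missing:
        raise SchemaError(f"series lacks items from the solution: {missing}")
    complete = complete[solution.item_ids]
    Z = (complete - complete.mean(axis=0)) / complete.std(axis=0, ddof=1)
    if solution.structure is not None:
        R = np.corrcoef(complete.to_numpy(), rowvar=False)
        if complete.shape[1] == 1:
            R = np.asarray([[1.0]])
        W = np.linalg.solve(R, solution.structure.to_numpy())
    else:
        W = solution.loadings.fillna(0.0).to_numpy()
    raw = Z.to_numpy() @ W
    raw = (raw - raw.mean(axis=0)) / raw.std(axis=0)
    scores = pd.DataFrame(raw, index=complete.index, columns=solution.factor_ids)
    occ = series.occasion_index()
    return FactorScoreSeries(scores=scores, occasion_index=occ)
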