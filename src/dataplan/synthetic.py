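"""Seeded generator of EMA-like symptom series with known latent structure.

The generator emulates the study conditions the pipeline is built for: four
surveys per day for at least 30 days, 0-100 visual-analog items, a small number
of latent dimensions following a stationary lag-1 vector autoregression, and
occasions missed completely at random down to a target completion rate.  It
exists so that every stage — factor recovery, dynamic-path recovery, scoring —
is testable end-to-end against known ground truth without any external data.

Latent dynamics: ``eta_t = B' eta_{t-1} + zeta_t`` with ``B`` the source x
target path matrix; the process is rescaled internally so each factor's
stationary variance is exactly 1, which makes the generating ``B`` directly
comparable to the standardized betas the dynamics module estimates.  Items:
``y_t = baseline + item_sd * (Lambda eta_t + eps_t)``, clipped to [0, 100]
(defaults are chosen so clipping never activates).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .ema import EmaSeries, SURVEYS_PER_DAY
from .exceptions import StationarityError, ValidationError
from .scoring import DynamicModel, FactorSolution, ItemStats


@dataclass
class SimSpec:
    """Ground-truth specification for one simulated participant.

    ``paths`` follows the same convention as :class:`~dataplan.scoring.DynamicModel`:
    rows are the factor at t-1 (source), columns the factor at t (target).
    ``item_sd`` scales the combined latent-plus-noise signal onto the VAS;
    with the default baseline 50 and item_sd <= 12 the [0, 100] clipping is
    inert.
    """

    loadings: np.ndarray  # items x factors
    paths: np.ndarray  # factors x factors, source x target
    innovation_corr: np.ndarray | None = None  # factor innovation correlations
    noise_sd: float = 0.5  # unique item noise, on the latent (unit) scale
    baseline: float | np.ndarray = 50.0
    item_sd: float | np.ndarray = 10.0
    n_days: int = 30
    surveys_per_day: int = SURVEYS_PER_DAY
    seed: int = 0
    item_ids: list[str] | None = None
    factor_ids: list[str] | None = None
    start: str = "2023-01-02 09:00"

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        self.paths = np.asarray(self.paths, dtype=float)
        k = self.loadings.shape[1]
        if self.paths.shape != (k, k):
            raise ValidationError("paths must be n_factors x n_factors")
        if self.item_ids is None:
            self.item_ids = [f"item{i + 1:02d}" for i in range(self.loadings.shape[0])]
        if self.factor_ids is None:
            self.factor_ids = [f"F{i + 1}" for i in range(k)]
        if self.innovation_corr is None:
            self.innovation_corr = np.eye(k)

    @property
    def n_occasions(self) -> int:
        return self.n_days * self.surveys_per_day

    def spectral_radius(self) -> float:
        return float(np.max(np.abs(np.linalg.eigvals(self.paths))))


def _stationary_transform(spec: SimSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rescale the process so each factor's stationary variance is 1.

    Returns ``(A, chol_Q, Sigma)`` where ``A`` is the transition matrix acting
    on column vectors (``eta_t = A eta_{t-1} + zeta``), ``chol_Q`` the Cholesky
    factor of the innovation covariance, and ``Sigma`` the unit-diagonal
    stationary covariance.
    """
    A = spec.paths.T  # source x target convention -> transition on column vectors
    rho = spec.spectral_radius()
    if rho >= 1.0:
        raise StationarityError(f"path matrix spectral radius {rho:.3f} >= 1")
    Q0 = np.asarray(spec.innovation_corr, dtype=float)
    Sigma0 = linalg.solve_discrete_lyapunov(A, Q0)
    d = 1.0 / np.sqrt(np.diag(Sigma0))
    D = np.diag(d)
    A = D @ A @ np.diag(1.0 / d)
    Q = D @ Q0 @ D
    Sigma = D @ Sigma0 @ D
    return A, np.linalg.cholesky(Q), Sigma


def generate_ema(spec: SimSpec) -> EmaSeries:
    """Simulate one participant's complete scheduled EMA grid.

    The latent series starts from an exact draw of its stationary distribution
    (no burn-in needed); identical seeds give bit-identical output.  The
    fraction of VAS-clipped cells is recorded as ``series.clipped_fraction``.
    """
    rng = np.random.default_rng(spec.seed)
    A, cholQ, Sigma = _stationary_transform(spec)
    n = spec.n_occasions
    k = A.shape[0]
    p = spec.loadings.shape[0]

    eta = np.empty((n, k))
    eta[0] = np.linalg.cholesky(Sigma) @ rng.standard_normal(k)
    shocks = rng.standard_normal((n - 1, k))
    for t in range(1, n):
        eta[t] = A @ eta[t - 1] + cholQ @ shocks[t - 1]

    eps = rng.standard_normal((n, p)) * spec.noise_sd
    latent = eta @ spec.loadings.T + eps
    values = np.asarray(spec.baseline) + np.asarray(spec.item_sd) * latent
    clipped = np.mean((values < 0) | (values > 100))
    values = np.clip(values, 0.0, 100.0)

    # waking-hours schedule, e.g. 09:00/13:00/17:00/21:00 for four surveys/day
    if spec.surveys_per_day > 1:
        hours = np.linspace(9.0, 21.0, spec.surveys_per_day)
    else:
        hours = np.array([9.0])
    day0 = pd.Timestamp(spec.start).normalize()
    stamps = pd.DatetimeIndex(
        [
            day0 + pd.Timedelta(days=d, hours=float(h))
            for d in range(spec.n_days)
            for h in hours
        ]
    )
    frame = pd.DataFrame(values, index=stamps, columns=spec.item_ids)
    series = EmaSeries(frame, participant_id=f"sim-{spec.seed}")
    series.clipped_fraction = float(clipped)
    series.sim_spec = spec
    return series


def apply_missingness(series: EmaSeries, completion_rate: float, seed: int = 0) -> EmaSeries:
    """Blank whole occasions completely at random down to ``completion_rate``.

    The number of missed occasions is the deterministic ``round((1 - rate) *
    scheduled)``; which occasions are missed is drawn without replacement from
    the seeded generator.  A rate of 1.0 returns the series unchanged.
    """
    if not 0.0 < completion_rate <= 1.0:
        raise ValidationError(f"completion rate must be in (0, 1]: {completion_rate}")
    n = len(series.data)
    n_miss = int(round((1.0 - completion_rate) * n))
    if n_miss == 0:
        return EmaSeries(series.data.copy(), series.participant_id, series.scheduled_count)
    rng = np.random.default_rng(seed)
    miss = rng.choice(n, size=n_miss, replace=False)
    data = series.data.copy()
    data.iloc[miss] = np.nan
    return EmaSeries(data, series.participant_id, series.scheduled_count)


# ---------------------------------------------------------------------------
# study-condition factories
# ---------------------------------------------------------------------------


def make_study_spec(
    seed: int,
    n_items: int = 9,
    n_factors: int = 3,
    loading_range: tuple[float, float] = (0.4, 0.9),
    ar_range: tuple[float, float] = (0.3, 0.7),
    cross: float = 0.25,
    n_cross: int = 1,
    n_days: int = 30,
    surveys_per_day: int = SURVEYS_PER_DAY,
) -> SimSpec:
    """Random generator spec under the study's default conditions.

    Simple structure: items are split evenly across factors, each loading on
    exactly one factor with magnitude drawn from ``loading_range``.
    Autoregressions are drawn from ``ar_range``; ``n_cross`` cross-paths of
    size ``cross`` are placed between distinct random factor pairs.
    """
    rng = np.random.default_rng(seed)
    lam = np.zeros((n_items, n_factors))
    owner = np.arange(n_items) % n_factors
    lam[np.arange(n_items), owner] = rng.uniform(*loading_range, size=n_items)
    B = np.diag(rng.uniform(*ar_range, size=n_factors))
    placed = 0
    while placed < n_cross and n_factors > 1:
        i, j = rng.integers(n_factors, size=2)
        if i != j and B[i, j] == 0:
            B[i, j] = cross
            placed += 1
    return SimSpec(
        loadings=lam,
        paths=B,
        seed=int(rng.integers(2 ** 31 - 1)),
        n_days=n_days,
        surveys_per_day=surveys_per_day,
    )


def make_separated_spec(
    seed: int,
    n_items: int = 9,
    n_factors: int = 3,
    loading_levels: tuple[float, ...] = (0.88, 0.68, 0.42),
    jitter: float = 0.02,
    ar_levels: tuple[float, ...] = (0.70, 0.45, 0.25),
    cross: float = 0.25,
) -> SimSpec:
    """Well-separated generator: distinct variance shares and path strengths.

    Items split evenly across factors with loadings at ``loading_levels``
    (plus a small uniform jitter), giving per-factor variance shares whose
    pairwise gaps exceed 0.08; autoregressions at ``ar_levels`` keep path gaps
    of at least 0.2.  One cross-path of size ``cross`` runs from the first to
    the second factor.  Used for ranking-recovery checks, where the factor
    ordering implied by the generator should be recoverable end-to-end.
    """
    rng = np.random.default_rng(seed)
    per = n_items // n_factors
    lam = np.zeros((n_items, n_factors))
    for f in range(n_factors):
        rows = range(f * per, (f + 1) * per if f < n_factors - 1 else n_items)
        level = loading_levels[f % len(loading_levels)]
        for i in rows:
            lam[i, f] = level + rng.uniform(-jitter, jitter)
    B = np.diag([ar_levels[f % len(ar_levels)] for f in range(n_factors)])
    if n_factors > 1:
        B[0, 1] = cross
    return SimSpec(loadings=lam, paths=B, seed=int(rng.integers(2 ** 31 - 1)))


def true_raw_factor_scores(spec: SimSpec) -> np.ndarray:
    """Generator-implied per-factor raw scores (variance share x squared paths / k)."""
    k = spec.paths.shape[0]
    pct = (spec.loadings ** 2).sum(axis=0) / spec.loadings.shape[0]
    return pct * (spec.paths ** 2).sum(axis=1) / k


# ---------------------------------------------------------------------------
# participant-021 fixture
# ---------------------------------------------------------------------------

ANALYSIS_ITEMS = [
    "Felt irritable",
    "Felt restless",
    "Felt worried",
    "Felt worthless or guilty",
    "Experienced loss of interest or pleasure",
    "Felt hopeless",
    "Felt down or depressed",
    "Felt fatigued",
    "Experienced muscle tension",
    "Had difficulty concentrating",
    "Avoided activities",
    "Sought reassurance",
    "Procrastinated",
]

AVOIDANCE_ITEMS = ["Avoided activities", "Sought reassurance", "Procrastinated"]


def participant021_fixture() -> tuple[FactorSolution, DynamicModel, ItemStats]:
    """Published worked example: a three-factor solution for one participant.

    The salient loadings, the per-factor variance shares (30/24/22%), the
    negative-affect autoregression (.58) and the NA -> Worry cross-prediction
    (.26) are transcribed from the published case.  Everything else —
    the Worry and Fatigue autoregressions (0.40, 0.64) and all item means —
    was never printed and is SYNTHETIC placeholder data, chosen once so the
    published qualitative facts hold: NA is the strongest factor (normalized
    factor score 1) and the anhedonia item's mean is 67% of the highest item
    mean.  Placeholders must not be used to validate against published values.
    """
    factors = ["NA", "Worry", "Fatigue"]
    items = [
        "Felt irritable",
        "Felt restless",
        "Felt worried",
        "Felt worthless or guilty",
        "Experienced loss of interest or pleasure",
        "Felt hopeless",
        "Felt down or depressed",
        "Felt fatigued",
        "Experienced muscle tension",
    ]
    nan = np.nan
    loadings = pd.DataFrame(
        [
            # NA    Worry  Fatigue
            [0.91, nan, nan],  # irritable
            [0.35, nan, 0.52],  # restless
            [nan, 0.97, nan],  # worried
            [0.49, 0.49, nan],  # worthless/guilty
            [0.42, nan, 0.47],  # loss of interest (anhedonia)
            [0.55, 0.34, nan],  # hopeless
            [0.50, 0.38, nan],  # down/depressed
            [nan, nan, 0.78],  # fatigued
            [nan, nan, 0.61],  # muscle tension
        ],
        index=items,
        columns=factors,
    )
    pct = pd.Series([0.30, 0.24, 0.22], index=factors)
    solution = FactorSolution(
        loadings=loadings,
        pct_variance=pct,
        excluded_items=["Had difficulty concentrating"] + AVOIDANCE_ITEMS,
    )

    paths = pd.DataFrame(0.0, index=factors, columns=factors)
    paths.loc["NA", "NA"] = 0.58  # published
    paths.loc["NA", "Worry"] = 0.26  # published
    paths.loc["Worry", "Worry"] = 0.40  # synthetic placeholder
    paths.loc["Fatigue", "Fatigue"] = 0.64  # synthetic placeholder
    retained = paths != 0.0
    dyn = DynamicModel(paths=paths, retained=retained)

    # synthetic placeholder means; only the anhedonia/max ratio (0.67) is published
    means = pd.Series(
        {
            "Felt irritable": 45.0,
            "Felt restless": 38.0,
            "Felt worried": 60.0,  # the highest mean
            "Felt worthless or guilty": 42.0,
            "Experienced loss of interest or pleasure": 40.2,  # 0.67 * 60
            "Felt hopeless": 35.0,
            "Felt down or depressed": 48.0,
            "Felt fatigued": 55.0,
            "Experienced muscle tension": 50.0,
        }
    )
    return solution, dyn, ItemStats(means=means)
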