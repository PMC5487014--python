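"""Treatment-module scoring: the seven-equation core of the algorithm.

Given a person-specific factor solution, a lag-1 dynamic factor model, and mean
symptom severities, each factor receives a score combining its within-time share
of symptom variance with its across-time predictive power (autoregression plus
outgoing cross-predictions); items inherit score through their loadings weighted
by severity; a binary item-module matching matrix then aggregates item scores
into a final per-module score, and modules are ordered into a treatment plan.

Module numbering follows the Unified Protocol (UP): Modules 2-7 are scored;
Module 1 (motivation enhancement) and Module 8 (relapse prevention) are
rule-assigned from compliance and diagnosis-recurrence data respectively.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd

from .ema import ComplianceRecord, DiagnosisRecord, COMPLIANCE_THRESHOLD, PROTOCOL_DAYS
from .exceptions import (
    DegenerateInputWarning,
    DegenerateSeverityError,
    EmptyModelError,
    IdentifierMismatchError,
    SchemaError,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .ptechnique import FitIndices

logger = logging.getLogger(__name__)

MODULE_MOTIVATION = 1  #: UP Module 1, assigned from compliance data
MODULE_RELAPSE = 8  #: UP Module 8, assigned from diagnosis recurrence


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------


@dataclass
class FactorSolution:
    """Standardized item x factor pattern loadings with per-factor variance shares.

    ``loadings`` uses NaN for non-salient entries (an item not loading on a
    factor).  ``pct_variance`` holds each factor's proportion of total symptom
    variance in [0, 1].  ``structure`` and ``phi`` (factor correlations) are
    optional extras carried by fitted solutions for factor scoring.
    """

    loadings: pd.DataFrame  # items x factors, NaN = absent
    pct_variance: pd.Series  # per factor
    fit: "FitIndices | None" = None
    excluded_items: list[str] = field(default_factory=list)
    structure: pd.DataFrame | None = None
    phi: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.loadings = self.loadings.astype(float)
        self.pct_variance = self.pct_variance.astype(float)
        if list(self.pct_variance.index) != list(self.loadings.columns):
            self.pct_variance = self.pct_variance.reindex(self.loadings.columns)
        if self.pct_variance.isna().any():
            raise ValidationError("pct_variance missing for some factors")
        if (self.pct_variance < 0).any() or self.pct_variance.sum() > 1 + 1e-9:
            raise ValidationError("pct_variance entries must be >= 0 and sum to <= 1")
        if (self.loadings.abs() > 1 + 1e-6).any().any():
            raise ValidationError("standardized loadings must lie in [-1, 1]")
        if self.loadings.index.has_duplicates:
            raise ValidationError("duplicate item identifiers in loadings")
        empty = self.loadings.index[self.loadings.isna().all(axis=1)]
        if len(empty):
            logger.warning("items with no salient loading on any factor: %s", list(empty))

    @property
    def item_ids(self) -> list[str]:
        return list(self.loadings.index)

    @property
    def factor_ids(self) -> list[str]:
        return list(self.loadings.columns)

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]


@dataclass
class DynamicModel:
    """Standardized lag-1 path matrix between factors.

    ``paths`` rows index the factor at t-1 (source), columns the factor at t
    (target); the diagonal holds autoregressions, off-diagonal entries
    cross-predictions.  ``retained`` masks the paths kept after pruning; the
    diagonal is always retained.
    """

    paths: pd.DataFrame  # source (t-1) x target (t)
    retained: pd.DataFrame | None = None
    lag_description: str = "one observation (~6 hours)"

    def __post_init__(self) -> None:
        self.paths = self.paths.astype(float)
        if list(self.paths.index) != list(self.paths.columns):
            raise ValidationError("paths must be square with identical row/column factor ids")
        if self.retained is None:
            self.retained = pd.DataFrame(
                True, index=self.paths.index, columns=self.paths.columns
            )
        self.retained = self.retained.astype(bool)
        np.fill_diagonal(self.retained.values, True)  # autoregressions always kept
        if (self.paths.abs() > 1 + 1e-6).any().any():
            raise ValidationError("standardized paths must lie in [-1, 1]")

    @property
    def factor_ids(self) -> list[str]:
        return list(self.paths.index)

    def autoregressions(self) -> pd.Series:
        return pd.Series(np.diag(self.paths.values), index=self.factor_ids)


@dataclass
class ItemStats:
    """Per-item mean severity over completed occasions, on the 0-100 VAS."""

    means: pd.Series

    def __post_init__(self) -> None:
        self.means = self.means.astype(float)
        if ((self.means < 0) | (self.means > 100)).any():
            raise ValidationError("item means must lie in [0, 100]")

    @property
    def max_mean(self) -> float:
        return float(self.means.max())

    @classmethod
    def from_series(cls, series, items: Iterable[str] | None = None) -> "ItemStats":
        """Means over completed occasions of an :class:`~dataplan.ema.EmaSeries`."""
        frame = series.complete_rows()
        if items is not None:
            frame = frame[list(items)]
        return cls(frame.mean(axis=0))


@dataclass
class ItemModuleMatrix:
    """Binary incidence matrix declaring which treatment modules target which items."""

    entries: pd.DataFrame  # items x modules, values 0/1; columns are module numbers

    def __post_init__(self) -> None:
        vals = self.entries.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValidationError("item-module matrix cells must be 0 or 1")
        self.entries = self.entries.astype(int)
        if self.entries.columns.has_duplicates:
            raise ValidationError("duplicate module columns")
        if self.entries.index.has_duplicates:
            raise ValidationError("duplicate item rows")

    @property
    def item_ids(self) -> list[str]:
        return list(self.entries.index)

    @property
    def module_ids(self) -> list[int]:
        return [int(m) for m in self.entries.columns]

    def items_for(self, module: int) -> list[str]:
        col = self.entries[module]
        return list(col.index[col == 1])


@dataclass
class ScoreTable:
    """All intermediate and final scores for one participant."""

    raw_factor_scores: pd.Series
    norm_factor_scores: pd.Series
    raw_item_scores: pd.Series
    norm_item_scores: pd.Series
    item_avg_module: pd.Series
    raw_sum_module: pd.Series
    final_module: pd.Series
    n_items_present: pd.Series

    def to_dict(self) -> dict:
        return {
            "factor_scores": {
                "raw": self.raw_factor_scores.to_dict(),
                "normalized": self.norm_factor_scores.to_dict(),
            },
            "item_scores": {
                "raw": self.raw_item_scores.to_dict(),
                "normalized": self.norm_item_scores.to_dict(),
            },
            "module_scores": {
                "item_average": {int(k): v for k, v in self.item_avg_module.items()},
                "raw_sum": {int(k): v for k, v in self.raw_sum_module.items()},
                "final": {int(k): v for k, v in self.final_module.items()},
                "n_items_present": {int(k): int(v) for k, v in self.n_items_present.items()},
            },
        }


@dataclass
class TreatmentPlan:
    """Ordered module sequence plus the score table it came from."""

    ordered_modules: list[int]
    included_module1: bool
    included_module8: bool
    score_table: ScoreTable | None = None

    def __post_init__(self) -> None:
        if len(set(self.ordered_modules)) != len(self.ordered_modules):
            raise ValidationError("duplicate modules in plan")
        if self.included_module1 and (
            not self.ordered_modules or self.ordered_modules[0] != MODULE_MOTIVATION
        ):
            raise ValidationError("Module 1, when included, must come first")
        if self.included_module8 and (
            not self.ordered_modules or self.ordered_modules[-1] != MODULE_RELAPSE
        ):
            raise ValidationError("Module 8, when included, must come last")

    @property
    def plan_string(self) -> str:
        """Hyphen-separated module numbers, e.g. ``"2-3-5-6-4"``."""
        return "-".join(str(m) for m in self.ordered_modules)

    def to_dict(self) -> dict:
        out = {
            "ordered_modules": self.ordered_modules,
            "plan": self.plan_string,
            "included_module1": self.included_module1,
            "included_module8": self.included_module8,
        }
        if self.score_table is not None:
            out["scores"] = self.score_table.to_dict()
        return out


# ---------------------------------------------------------------------------
# the seven equations
# ---------------------------------------------------------------------------


def raw_factor_scores(solution: FactorSolution, dyn: DynamicModel) -> pd.Series:
    """Per-factor raw score: variance share times squared predictive paths.

    ``score_f = pct_variance_f * (AR_f^2 + sum of squared retained outgoing
    cross-predictions) / n_factors``.  The outgoing set for factor *f* is every
    retained path from *f* at t-1 to any other factor at t.  The 1/n_factors
    term is constant across factors, so it cancels under normalization; it is
    kept for interpretability (the result reads as a share of predictive
    variance).
    """
    if list(solution.factor_ids) != list(dyn.factor_ids):
        raise IdentifierMismatchError(
            f"factor sets differ: {solution.factor_ids} vs {dyn.factor_ids}"
        )
    n = solution.n_factors
    if n == 0:
        raise EmptyModelError("factor solution has zero factors")
    B = dyn.paths.values * dyn.retained.values
    dynamic_term = np.square(B).sum(axis=1)  # row sum: AR^2 + outgoing crosses^2
    scores = solution.pct_variance.values * dynamic_term / n
    return pd.Series(scores, index=solution.factor_ids)


def normalize(values: pd.Series) -> pd.Series:
    """Divide by the maximum, fixing the top score at 1.

    All-zero input maps to all zeros with a :class:`DegenerateInputWarning`
    rather than a division error, so degenerate participants surface loudly but
    do not break the pipeline.
    """
    values = pd.Series(values, dtype=float)
    if (values < 0).any():
        raise ValidationError("scores to normalize must be nonnegative")
    top = values.max() if len(values) else 0.0
    if not len(values) or top == 0:
        warnings.warn(
            "all scores are zero; normalized scores set to 0", DegenerateInputWarning,
            stacklevel=2,
        )
        return values * 0.0
    return values / top


def raw_item_scores(
    solution: FactorSolution, fs_norm: pd.Series, stats: ItemStats
) -> pd.Series:
    """Per-item raw score: relative severity times loading-weighted factor strength.

    ``score_i = (mean_i / max_mean) * sum_f FS_N[f] * |loading_{i,f}|``, the sum
    running over the factors where item *i* has a salient (present) loading.
    Items excluded during factor fitting receive no score.
    """
    items = solution.item_ids
    missing = [i for i in items if i not in stats.means.index]
    if missing:
        raise SchemaError(f"no mean severity for items: {missing}")
    if stats.max_mean == 0:
        raise DegenerateSeverityError("all item means are zero")
    fs_norm = fs_norm.reindex(solution.factor_ids)
    if fs_norm.isna().any():
        raise IdentifierMismatchError("normalized factor scores missing for some factors")
    weight = solution.loadings.abs().fillna(0.0).to_numpy() @ fs_norm.to_numpy()
    rel_severity = stats.means.reindex(items).to_numpy() / stats.max_mean
    scores = pd.Series(rel_severity * weight, index=items)
    for item in scores.index[weight == 0]:
        logger.info("item %r has no salient loading; raw item score 0", item)
    return scores


def module_scores(
    is_norm: pd.Series, matrix: ItemModuleMatrix, present_items: Iterable[str] | None = None
) -> tuple[pd.Series, pd.Series, pd.Series, pd.Series]:
    """Aggregate normalized item scores into per-module scores.

    For each module, over its matched items *present in the factor model*:
    the raw sum (favoring broad modules), the item average (the module's
    central tendency, insensitive to item count), and the final score — the
    mean of the two after each is normalized across modules.  A module with no
    present items scores 0 on all three.

    Returns ``(item_avg, raw_sum, final, n_items_present)`` indexed by module.
    """
    present = set(is_norm.index) if present_items is None else set(present_items)
    unknown = present - set(matrix.item_ids)
    if unknown:
        raise SchemaError(f"items absent from the item-module matrix: {sorted(unknown)}")
    modules = matrix.module_ids
    raw_sum = {}
    item_avg = {}
    n_present = {}
    for m in modules:
        matched = [i for i in matrix.items_for(m) if i in present]
        n_present[m] = len(matched)
        s = float(is_norm.reindex(matched).fillna(0.0).sum()) if matched else 0.0
        raw_sum[m] = s
        item_avg[m] = s / len(matched) if matched else 0.0
    raw_sum = pd.Series(raw_sum, dtype=float)
    item_avg = pd.Series(item_avg, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateInputWarning)
        final = (normalize(item_avg) + normalize(raw_sum)) / 2.0
    return item_avg, raw_sum, final, pd.Series(n_present, dtype=int)


def compute_scores(
    solution: FactorSolution,
    dyn: DynamicModel,
    stats: ItemStats,
    matrix: ItemModuleMatrix,
) -> ScoreTable:
    """Run the full scoring chain and collect every intermediate result."""
    raw_fs = raw_factor_scores(solution, dyn)
    fs_norm = normalize(raw_fs)
    raw_is = raw_item_scores(solution, fs_norm, stats)
    is_norm = normalize(raw_is)
    item_avg, raw_sum, final, n_present = module_scores(
        is_norm, matrix, present_items=solution.item_ids
    )
    return ScoreTable(
        raw_factor_scores=raw_fs,
        norm_factor_scores=fs_norm,
        raw_item_scores=raw_is,
        norm_item_scores=is_norm,
        item_avg_module=item_avg,
        raw_sum_module=raw_sum,
        final_module=final,
        n_items_present=n_present,
    )


# ---------------------------------------------------------------------------
# plan construction
# ---------------------------------------------------------------------------


def needs_motivation_module(
    compliance: ComplianceRecord,
    threshold: float = COMPLIANCE_THRESHOLD,
    protocol_days: int = PROTOCOL_DAYS,
) -> bool:
    """Module-1 rule: reminder call, sub-threshold completion, or a slow start.

    True when the participant received a reminder call, completed fewer than
    the threshold share of scheduled surveys, or needed more than the nominal
    protocol length (30 days) to reach the required completion count.
    """
    if compliance.received_reminder:
        return True
    if not compliance.meets_threshold(threshold):
        return True
    if compliance.days_to_threshold is not None and compliance.days_to_threshold > protocol_days:
        return True
    return False


def build_plan(
    scores: ScoreTable,
    compliance: ComplianceRecord | None = None,
    diagnosis: DiagnosisRecord | None = None,
) -> TreatmentPlan:
    """Order scored modules into a treatment plan and apply the rule-based ends.

    Modules with final score > 0 are sorted descending (ties broken by
    ascending module number, mirroring the UP's canonical sequence); zero-score
    modules are dropped.  Module 1 is prepended when the compliance rule fires;
    Module 8 is appended for recurrent diagnoses.
    """
    finals = scores.final_module
    scored = finals[finals > 0]
    if scored.empty:
        warnings.warn(
            "all final module scores are zero; plan contains only rule-assigned modules",
            DegenerateInputWarning,
            stacklevel=2,
        )
    order = sorted(scored.index, key=lambda m: (-scored[m], int(m)))
    ordered = [int(m) for m in order]

    include1 = compliance is not None and needs_motivation_module(compliance)
    include8 = diagnosis is not None and diagnosis.recurrent
    if include1:
        ordered = [MODULE_MOTIVATION] + ordered
    if include8:
        ordered = ordered + [MODULE_RELAPSE]
    return TreatmentPlan(
        ordered_modules=ordered,
        included_module1=include1,
        included_module8=include8,
        score_table=scores,
    )


def variance_explained(beta: float) -> int:
    """Percent of variance a standardized path predicts: round(100 * beta^2).

    This is the r -> r^2 relationship for standardized coefficients; e.g. a
    0.58 autoregression predicts 34% of next-occasion variance.
    """
    if abs(beta) > 1:
        raise ValidationError(f"standardized coefficient out of [-1, 1]: {beta}")
    return int(np.floor(100.0 * beta * beta + 0.5))
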