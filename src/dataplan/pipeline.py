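"""End-to-end orchestration: series -> factor solution -> dynamics -> scores -> plan."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .dataio import RunConfig, default_matrix
from .dynamics import DynamicFactorModel
from .ema import ComplianceRecord, DiagnosisRecord, EmaSeries, compliance_check
from .ptechnique import PTechniqueModel, avoidance_retention, factor_scores
from .scoring import (
    DynamicModel,
    FactorSolution,
    ItemModuleMatrix,
    ItemStats,
    ScoreTable,
    TreatmentPlan,
    build_plan,
    compute_scores,
)
from .synthetic import ANALYSIS_ITEMS, AVOIDANCE_ITEMS

logger = logging.getLogger(__name__)


@dataclass
class PipelineReport:
    """Everything a full run produced, ready for serialization."""

    participant_id: str
    solution: FactorSolution
    dynamics: DynamicModel
    stats: ItemStats
    scores: ScoreTable
    plan: TreatmentPlan
    compliance: ComplianceRecord
    config: RunConfig

    def to_dict(self) -> dict:
        fit = self.solution.fit
        return {
            "participant_id": self.participant_id,
            "config": self.config.to_dict(),
            "compliance": {
                "completed": self.compliance.completed,
                "scheduled": self.compliance.scheduled,
                "completion_rate": self.compliance.completion_rate,
                "received_reminder": self.compliance.received_reminder,
                "days_to_threshold": self.compliance.days_to_threshold,
            },
            "factor_solution": {
                "loadings": {
                    item: {
                        f: v
                        for f, v in row.items()
                        if v == v  # drop NaN (non-salient)
                    }
                    for item, row in self.solution.loadings.to_dict("index").items()
                },
                "pct_variance": self.solution.pct_variance.to_dict(),
                "excluded_items": self.solution.excluded_items,
                "fit": fit.to_dict() if fit is not None else None,
            },
            "dynamic_model": {
                "paths": self.dynamics.paths.to_dict("index"),
                "retained": {
                    s: {t: bool(v) for t, v in row.items()}
                    for s, row in self.dynamics.retained.to_dict("index").items()
                },
                "lag": self.dynamics.lag_description,
            },
            "item_means": self.stats.means.to_dict(),
            "plan": self.plan.to_dict(),
        }


def run_pipeline(
    series: EmaSeries,
    matrix: ItemModuleMatrix | None = None,
    config: RunConfig | None = None,
    received_reminder: bool = False,
    recurrent: bool = False,
    core_items: list[str] | None = None,
    avoidance_items: list[str] | None = None,
) -> PipelineReport:
    """Run the full assessment-to-plan pipeline for one participant.

    Fits the person-specific factor model with the two-step avoidance-item
    retention test, scores the series on the retained factors, fits and prunes
    the lag-1 dynamic model, runs the seven-equation scoring chain against the
    item-module matrix, and assembles the treatment plan with the rule-based
    Modules 1 and 8.
    """
    config = config or RunConfig()
    matrix = matrix or default_matrix()
    if avoidance_items is None:
        avoidance_items = [i for i in AVOIDANCE_ITEMS if i in series.item_ids]
    if core_items is None:
        core_items = [
            i for i in series.item_ids
            if i in set(ANALYSIS_ITEMS) and i not in set(avoidance_items)
        ] or [i for i in series.item_ids if i not in set(avoidance_items)]

    logger.info(
        "run config: salience=%s alpha=%s n_factors=%s compliance_threshold=%s "
        "fit_cutoffs=%s drop_overnight=%s seed=%s",
        config.salience_threshold, config.alpha, config.n_factors,
        config.compliance_threshold, config.fit_cutoffs, config.drop_overnight,
        config.seed,
    )

    if avoidance_items:
        solution = avoidance_retention(
            series,
            core_items=core_items,
            avoidance_items=avoidance_items,
            n_factors=config.n_factors,
            cutoffs=config.fit_cutoffs,
            salience_threshold=config.salience_threshold,
            seed=config.seed,
        )
    else:
        model = PTechniqueModel(
            series,
            n_factors=config.n_factors,
            items=core_items,
            salience_threshold=config.salience_threshold,
            seed=config.seed,
        )
        solution = model.fit().solution

    retained_items = solution.item_ids
    fscores = factor_scores(series.subset(retained_items), solution)
    dyn_results = DynamicFactorModel(fscores, drop_overnight=config.drop_overnight).fit()
    dyn = dyn_results.prune(config.alpha)

    stats = ItemStats.from_series(series, items=retained_items)
    scores = compute_scores(solution, dyn, stats, matrix)

    compliance = compliance_check(
        series,
        threshold=config.compliance_threshold,
        received_reminder=received_reminder,
    )
    plan = build_plan(scores, compliance, DiagnosisRecord(recurrent=recurrent))
    return PipelineReport(
        participant_id=series.participant_id,
        solution=solution,
        dynamics=dyn,
        stats=stats,
        scores=scores,
        plan=plan,
        compliance=compliance,
        config=config,
    )
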