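"""File formats: EMA CSV, item-module matrix CSV, score/plan JSON, run configuration."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamics import DEFAULT_ALPHA
from .ema import COMPLIANCE_THRESHOLD, EmaSeries
from .exceptions import ValidationError
from .ptechnique import DEFAULT_SALIENCE, FIT_CUTOFFS
from .scoring import (
    DynamicModel,
    FactorSolution,
    ItemModuleMatrix,
    ItemStats,
    ScoreTable,
    TreatmentPlan,
)

TIMESTAMP_COLUMN = "timestamp"


def read_ema_csv(path: str | Path, participant_id: str | None = None) -> EmaSeries:
    """Read a wide EMA CSV: timestamp column plus one column per symptom item.

    Blank cells become missing values; rows are ordered by timestamp.  Values
    outside [0, 100] and duplicate timestamps raise a validation error naming
    the offending cell.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    if TIMESTAMP_COLUMN not in frame.columns:
        raise ValidationError(f"missing {TIMESTAMP_COLUMN!r} column in {path}")
    frame[TIMESTAMP_COLUMN] = pd.to_datetime(frame[TIMESTAMP_COLUMN])
    frame = frame.set_index(TIMESTAMP_COLUMN)
    frame.index.name = None
    for col in frame.columns:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric cell in column {col!r} of {path}") from exc
    return EmaSeries(frame, participant_id=participant_id or path.stem)


def write_ema_csv(series: EmaSeries, path: str | Path) -> None:
    """Write a series in the same wide format ``read_ema_csv`` expects."""
    out = series.data.copy()
    out.index.name = TIMESTAMP_COLUMN
    out.to_csv(path)


def read_matrix_csv(path: str | Path) -> ItemModuleMatrix:
    """Read an item-module matching matrix CSV.

    First column holds item ids; remaining column headers are module ids
    (plain numbers or ``"Module N"``); cells must be 0/1.
    """
    frame = pd.read_csv(path, index_col=0)
    cols = []
    for c in frame.columns:
        token = str(c).strip()
        if token.lower().startswith("module"):
            token = token.split()[-1]
        try:
            cols.append(int(token))
        except ValueError as exc:
            raise ValidationError(f"module column {c!r} is not a module number") from exc
    frame.columns = cols
    return ItemModuleMatrix(entries=frame)


def default_matrix() -> ItemModuleMatrix:
    """The bundled 13-item x Modules-2-7 matching matrix."""
    with resources.as_file(
        resources.files("dataplan").joinpath("data/item_module_matrix.csv")
    ) as p:
        return read_matrix_csv(p)


# ---------------------------------------------------------------------------
# loadings / dynamics / means CSV (for the `score` CLI entry point)
# ---------------------------------------------------------------------------


def read_loadings_csv(path: str | Path) -> tuple[pd.DataFrame, pd.Series]:
    """Read a loadings CSV: item rows, factor columns, plus a ``pct_variance`` row.

    Blank cells mark non-salient loadings.  The ``pct_variance`` row may carry
    either proportions (0.30) or percentages (30).
    """
    # only blanks are missing: "NA" is a legitimate factor label (negative affect)
    frame = pd.read_csv(path, index_col=0, keep_default_na=False, na_values=[""])
    if "pct_variance" not in frame.index:
        raise ValidationError(f"loadings file {path} needs a 'pct_variance' row")
    pct = frame.loc["pct_variance"].astype(float)
    if pct.sum() > 1.0 + 1e-9:  # percentages, not proportions
        pct = pct / 100.0
    loadings = frame.drop(index="pct_variance").astype(float)
    return loadings, pct


def read_dynamics_csv(path: str | Path) -> DynamicModel:
    """Read a lag-1 path matrix CSV (source rows, target columns); zeros are
    treated as absent paths (except autoregressions, which always count)."""
    frame = pd.read_csv(path, index_col=0, keep_default_na=False, na_values=[""])
    frame = frame.astype(float)
    return DynamicModel(paths=frame, retained=frame != 0.0)


def read_means_csv(path: str | Path) -> ItemStats:
    """Read per-item means: two columns, item id and mean."""
    frame = pd.read_csv(path, index_col=0, keep_default_na=False, na_values=[""])
    return ItemStats(means=frame.iloc[:, 0])


# ---------------------------------------------------------------------------
# JSON round-trips
# ---------------------------------------------------------------------------


def plan_to_json(plan: TreatmentPlan, path: str | Path | None = None) -> str:
    text = json.dumps(plan.to_dict(), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def plan_from_json(source: str | Path) -> TreatmentPlan:
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        try:
            if Path(text).exists():
                text = Path(text).read_text()
        except OSError:
            pass
    payload = json.loads(text)
    if "ordered_modules" not in payload and isinstance(payload.get("plan"), dict):
        payload = payload["plan"]  # a full pipeline report wraps the plan
    scores = payload.get("scores")
    table = None
    if scores:
        table = ScoreTable(
            raw_factor_scores=pd.Series(scores["factor_scores"]["raw"], dtype=float),
            norm_factor_scores=pd.Series(scores["factor_scores"]["normalized"], dtype=float),
            raw_item_scores=pd.Series(scores["item_scores"]["raw"], dtype=float),
            norm_item_scores=pd.Series(scores["item_scores"]["normalized"], dtype=float),
            item_avg_module=_int_series(scores["module_scores"]["item_average"]),
            raw_sum_module=_int_series(scores["module_scores"]["raw_sum"]),
            final_module=_int_series(scores["module_scores"]["final"]),
            n_items_present=_int_series(scores["module_scores"]["n_items_present"]).astype(int),
        )
    return TreatmentPlan(
        ordered_modules=[int(m) for m in payload["ordered_modules"]],
        included_module1=bool(payload["included_module1"]),
        included_module8=bool(payload["included_module8"]),
        score_table=table,
    )


def _int_series(mapping: dict) -> pd.Series:
    return pd.Series({int(k): v for k, v in mapping.items()}, dtype=float).sort_index()


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Tunable defaults for a full pipeline run."""

    salience_threshold: float = DEFAULT_SALIENCE
    alpha: float = DEFAULT_ALPHA
    fit_cutoffs: dict = field(default_factory=lambda: dict(FIT_CUTOFFS))
    n_factors: int | None = None  # None = parallel analysis
    compliance_threshold: float = COMPLIANCE_THRESHOLD
    drop_overnight: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.salience_threshold < 1.0:
            raise ValidationError("salience_threshold must lie in [0, 1)")
        if not 0.0 < self.alpha < 1.0:
            raise ValidationError("alpha must lie in (0, 1)")
        if not 0.0 < self.compliance_threshold <= 1.0:
            raise ValidationError("compliance_threshold must lie in (0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)
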