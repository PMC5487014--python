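"""Ecological momentary assessment (EMA) series container and compliance bookkeeping.

An :class:`EmaSeries` holds one participant's multivariate symptom time series:
one row per *scheduled* survey occasion, one column per symptom item, values on a
0-100 visual-analog scale, ``NaN`` for missed responses.  Missed occasions stay in
the grid as all-NaN rows so that occasion indices (which define the lag structure
downstream) are preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

VAS_MIN = 0.0
VAS_MAX = 100.0

#: default protocol: at least 80% of surveys over a 30-day, 4-per-day schedule
COMPLIANCE_THRESHOLD = 0.80
PROTOCOL_DAYS = 30
SURVEYS_PER_DAY = 4


@dataclass
class EmaSeries:
    """One participant's scheduled EMA grid.

    Parameters
    ----------
    data
        DataFrame indexed by timestamp (strictly increasing), one column per
        symptom item, float values in [0, 100] or NaN for missed responses.
    participant_id
        Identifier carried through reports.
    scheduled_count
        Number of scheduled occasions; defaults to ``len(data)``.
    """

    data: pd.DataFrame
    participant_id: str = "participant"
    scheduled_count: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.data.index, pd.DatetimeIndex):
            self.data = self.data.copy()
            self.data.index = pd.to_datetime(self.data.index)
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValidationError(f"duplicate timestamps: {list(map(str, dupes[:5]))}")
        if not self.data.index.is_monotonic_increasing:
            self.data = self.data.sort_index()
        vals = self.data.to_numpy(dtype=float)
        bad = np.where((vals < VAS_MIN) | (vals > VAS_MAX))
        if bad[0].size:
            r, c = bad[0][0], bad[1][0]
            raise ValidationError(
                f"value {vals[r, c]} out of [0, 100] at row {self.data.index[r]}, "
                f"column {self.data.columns[c]!r}"
            )
        if self.scheduled_count is None:
            self.scheduled_count = len(self.data)

    @property
    def item_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return self.data.index

    def complete_rows(self) -> pd.DataFrame:
        """Occasions with every item answered (listwise deletion)."""
        return self.data.dropna(axis=0, how="any")

    def complete_mask(self) -> np.ndarray:
        return self.data.notna().all(axis=1).to_numpy()

    @property
    def n_completed(self) -> int:
        return int(self.complete_mask().sum())

    def occasion_index(self) -> np.ndarray:
        """Positional index of completed occasions within the scheduled grid."""
        return np.flatnonzero(self.complete_mask())

    def subset(self, items: list[str]) -> "EmaSeries":
        missing = [i for i in items if i not in self.data.columns]
        if missing:
            raise ValidationError(f"items not in series: {missing}")
        return EmaSeries(self.data[items].copy(), self.participant_id, self.scheduled_count)


@dataclass
class ComplianceRecord:
    """Survey-completion bookkeeping used by the Module-1 rule.

    ``days_to_threshold`` is the number of study days needed before cumulative
    completed surveys reach the required share of the nominal protocol
    (80% of 30 days x 4/day by default); ``None`` when never reached.
    """

    completed: int
    scheduled: int
    received_reminder: bool = False
    days_to_threshold: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.completed <= self.scheduled:
            raise ValidationError(
                f"completed ({self.completed}) must lie in [0, scheduled={self.scheduled}]"
            )

    @property
    def completion_rate(self) -> float:
        return self.completed / self.scheduled if self.scheduled else 0.0

    def meets_threshold(self, threshold: float = COMPLIANCE_THRESHOLD) -> bool:
        """Inclusive: exactly 80% counts as compliant ("at least 80%")."""
        return self.completion_rate >= threshold


@dataclass
class DiagnosisRecord:
    """Recurrence flag from the clinical interview (recurrent GAD/MDD)."""

    recurrent: bool = False


def compliance_check(
    series: EmaSeries,
    threshold: float = COMPLIANCE_THRESHOLD,
    received_reminder: bool = False,
    protocol_days: int = PROTOCOL_DAYS,
    surveys_per_day: int = SURVEYS_PER_DAY,
) -> ComplianceRecord:
    """Summarize compliance for a series against the protocol requirement.

    The required count is ``threshold * protocol_days * surveys_per_day``
    completed surveys; ``days_to_threshold`` is the first study day (1-based,
    counted from the first scheduled timestamp) on which the running total of
    completed surveys reaches that count.
    """
    if series.scheduled_count is None or series.scheduled_count <= 0:
        raise ValidationError("scheduled_count must be positive")
    completed_mask = series.complete_mask()
    completed = int(completed_mask.sum())

    required = threshold * protocol_days * surveys_per_day
    days_to_threshold: int | None = None
    if completed >= required and len(series.data):
        day0 = series.timestamps[0].normalize()
        day_of = ((series.timestamps.normalize() - day0).days + 1).to_numpy()
        cum = np.cumsum(completed_mask)
        reached = np.flatnonzero(cum >= required)
        if reached.size:
            days_to_threshold = int(day_of[reached[0]])

    return ComplianceRecord(
        completed=completed,
        scheduled=int(series.scheduled_count),
        received_reminder=received_reminder,
        days_to_threshold=days_to_threshold,
    )
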