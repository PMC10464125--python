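"""Sign-consistency validation against experimental labels.

Each experimental label records that a metabolite was observed up or down
in a disease.  A prediction is *consistent* when the sign of its S_as
agrees with the observation (UP ⇔ S_as > 0, DOWN ⇔ S_as < 0); magnitudes
are not compared — the claim being checked is about direction only.  Pairs
with S_as exactly 0 count as inconsistent with either observation.

The summary fraction is computed over labeled pairs that were scored AND
meaningful; labels absent from the scored output or below the thresholds
are reported as NOT_SCORED and excluded from the denominator.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .model import (
    ExperimentalLabel,
    ObservedDirection,
    ScoredAssociation,
    ValidationInputError,
    round_half_away,
)


class PairStatus(enum.Enum):
    CONSISTENT = "consistent"
    INCONSISTENT = "inconsistent"
    NOT_SCORED = "not_scored"


@dataclass(frozen=True)
class ValidationRow:
    disease_id: str
    metabolite_id: int
    observed_direction: ObservedDirection
    s_as: Optional[float]
    meaningful: Optional[bool]
    status: PairStatus


@dataclass
class ValidationReport:
    """Per-pair agreement rows plus the summary consistency fraction."""

    rows: List[ValidationRow]
    n_experimental: int
    n_scored_meaningful: int
    n_consistent: int

    @property
    def consistency_fraction(self) -> Optional[float]:
        """n_consistent / n_scored_meaningful, or None when undefined."""
        if self.n_scored_meaningful == 0:
            return None
        return self.n_consistent / self.n_scored_meaningful

    @property
    def consistency_percent(self) -> Optional[float]:
        """The fraction as a percentage to one decimal (half away from zero)."""
        f = self.consistency_fraction
        if f is None:
            return None
        return round_half_away(100.0 * f, 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "disease_id": r.disease_id,
                    "metabolite_id": r.metabolite_id,
                    "observed_direction": r.observed_direction.value,
                    "s_as": "" if r.s_as is None else repr(r.s_as),
                    "meaningful": "" if r.meaningful is None else str(r.meaningful).lower(),
                    "status": r.status.value,
                }
                for r in self.rows
            ],
            columns=[
                "disease_id",
                "metabolite_id",
                "observed_direction",
                "s_as",
                "meaningful",
                "status",
            ],
        )

    def summary_text(self) -> str:
        pct = self.consistency_percent
        pct_str = "undefined (no meaningful scored pairs)" if pct is None else f"{pct:.1f}%"
        return (
            f"experimental pairs:        {self.n_experimental}\n"
            f"scored and meaningful:     {self.n_scored_meaningful}\n"
            f"direction-consistent:      {self.n_consistent}\n"
            f"consistency:               {pct_str}\n"
        )


def compare_directions(
    scored: Sequence[ScoredAssociation],
    labels: Sequence[ExperimentalLabel],
) -> ValidationReport:
    """Compare predicted score signs against experimental directions.

    Duplicate label rows for the same pair with conflicting directions are
    a validation-input error; exact duplicates are collapsed.
    """
    by_pair: Dict[Tuple[str, int], ExperimentalLabel] = {}
    for label in labels:
        prev = by_pair.get(label.key)
        if prev is not None and prev.observed_direction != label.observed_direction:
            raise ValidationInputError(
                f"conflicting observed directions for pair {label.key}"
            )
        by_pair.setdefault(label.key, label)

    scored_by_pair = {(s.disease_id, s.metabolite_id): s for s in scored}

    rows: List[ValidationRow] = []
    n_meaningful = 0
    n_consistent = 0
    for key in sorted(by_pair):
        label = by_pair[key]
        s = scored_by_pair.get(key)
        if s is None or not s.meaningful:
            rows.append(
                ValidationRow(
                    disease_id=label.disease_id,
                    metabolite_id=label.metabolite_id,
                    observed_direction=label.observed_direction,
                    s_as=None if s is None else s.s_as,
                    meaningful=None if s is None else s.meaningful,
                    status=PairStatus.NOT_SCORED,
                )
            )
            continue
        n_meaningful += 1
        consistent = (
            label.observed_direction is ObservedDirection.UP and s.s_as > 0
        ) or (label.observed_direction is ObservedDirection.DOWN and s.s_as < 0)
        if consistent:
            n_consistent += 1
        rows.append(
            ValidationRow(
                disease_id=label.disease_id,
                metabolite_id=label.metabolite_id,
                observed_direction=label.observed_direction,
                s_as=s.s_as,
                meaningful=True,
                status=PairStatus.CONSISTENT if consistent else PairStatus.INCONSISTENT,
            )
        )

    return ValidationReport(
        rows=rows,
        n_experimental=len(by_pair),
        n_scored_meaningful=n_meaningful,
        n_consistent=n_consistent,
    )
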