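"""Confidence scores and specific prey selection.

For each reproducible bait prey ``j`` with marginal inclusion probability
``p_B`` over the bait's reproducible replicates and ``p_C`` over the
control's, the confidence score is the sign of the bait-control contrast
weighted by the bait-side inclusion:

    CS(j) = sign(p_B - p_C) * p_B          (0 when p_B == p_C)

so CS is in [-1, 1]; positive scores mark bait-specific preys, negative
scores contaminants better explained by the control, and the singular point
``p_B == p_C`` (including 0/0) is scored 0, i.e. non-specific.  Preys absent
from the control table count as ``p_C = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ProteinStageSet
from .exceptions import ValidationError
from .reproducibility import InclusionTable


@dataclass
class ConfidenceScoreTable:
    """Per-prey bait/control inclusion probabilities and confidence scores."""

    frame: pd.DataFrame  # index protein_id; columns p_bait, p_control, cs
    cutoff: float | None = None

    @property
    def scores(self) -> pd.Series:
        return self.frame["cs"]

    def discoveries(self, cutoff) -> int:
        """Number of preys with CS >= cutoff (vectorized over the table)."""
        return int((self.frame["cs"].to_numpy() >= cutoff).sum())


@dataclass(frozen=True)
class SpecificPreySet:
    proteins: frozenset[str]
    cutoff_used: float

    @property
    def cardinality(self) -> int:
        return len(self.proteins)

    def stage_set(self) -> ProteinStageSet:
        return ProteinStageSet(stage="S", protein_ids=self.proteins)


def confidence_scores(bait_table: InclusionTable, control_table: InclusionTable,
                      proteins: ProteinStageSet) -> ConfidenceScoreTable:
    """Confidence scores for the given (reproducible bait) prey proteins."""
    prots = sorted(proteins.protein_ids)
    p_bait = np.array([bait_table.get(p) for p in prots])
    p_control = np.array([control_table.get(p) for p in prots])
    diff = p_bait - p_control
    cs = np.where(diff == 0.0, 0.0, np.sign(diff) * p_bait)
    frame = pd.DataFrame(
        {"p_bait": p_bait, "p_control": p_control, "cs": cs},
        index=pd.Index(prots, name="protein_id"),
    )
    return ConfidenceScoreTable(frame=frame)


def select_specific_preys(table: ConfidenceScoreTable, cutoff: float) -> SpecificPreySet:
    """Preys with CS >= cutoff; the cutoff must lie in the open interval (0, 1).

    The positive-range restriction avoids the singular endpoints: CS = 0
    marks non-specific preys and CS = 1 is attained exactly.
    """
    if not (0.0 < cutoff < 1.0):
        raise ValidationError(f"confidence-score cutoff must lie in (0, 1), got {cutoff}")
    sel = table.frame.index[table.frame["cs"] >= cutoff]
    return SpecificPreySet(proteins=frozenset(sel), cutoff_used=float(cutoff))
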