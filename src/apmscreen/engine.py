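"""Internal single-side screening engine.

Runs the identification chain for one experiment side (bait, control, or a
decoy assembled from control data): prefilter at the score threshold, RI
profile and RIT, indicator candidates, indicator selection at ``p_min``,
reproducible replicates F, reproducible prey proteins R, and the marginal
inclusion probabilities over F that feed the confidence score.  Shared by
the public model and by the Monte-Carlo decoy false-discovery estimator,
which reruns this chain on every decoy sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ProteinStageSet
from .exceptions import EstimationError
from .prefilter import prefilter_proteins
from .reproducibility import (
    DEFAULT_PMIN_GRID,
    InclusionTable,
    IndicatorSelection,
    PresenceMatrix,
    ReproducibilityProfile,
    admissible_pmin_lower_bound,
    indicator_selection,
    marginal_inclusion,
    reproducibility_profile,
    reproducible_prey_proteins,
    select_indicator_candidates,
)


@dataclass
class SideScreen:
    """Everything the pipeline derives for one experiment side."""

    role: str
    mst: float
    n_naive: int  # stage-N protein count (before prefilter)
    matrix: PresenceMatrix  # prefiltered occurrence matrix
    profile: ReproducibilityProfile
    candidates: ProteinStageSet  # stage Q candidates (score >= RIT)
    marginals_all: InclusionTable  # candidate marginals over all K replicates
    selection: IndicatorSelection
    pmin_requested: float
    pmin_bound: float | None  # admissible lower bound (computed when needed)
    r_set: ProteinStageSet  # stage R
    r_marginals: InclusionTable  # p' over the reproducible replicates F

    @property
    def p_count(self) -> int:
        return len(self.matrix.proteins)


def screen_side(evidence: pd.DataFrame, replicate_ids, role: str, mst: float,
                p_min: float, pmin_grid=DEFAULT_PMIN_GRID,
                adjust_pmin: bool = False) -> SideScreen:
    """Run the full single-side chain on raw evidence.

    If ``p_min`` yields no reproducible replicate, the admissible lower
    bound of the threshold is computed; with ``adjust_pmin`` the selection is
    redone at that bound, otherwise an :class:`EstimationError` reports it.
    """
    n_naive = evidence["protein_id"].nunique()
    from .data import ExperimentSet  # local import to avoid cycle at module load

    expset = ExperimentSet(role=role, bait_id="", replicate_ids=list(replicate_ids),
                           evidence=evidence)
    pre = prefilter_proteins(expset, mst)
    matrix = PresenceMatrix.from_evidence(pre.evidence, replicate_ids)
    profile = reproducibility_profile(matrix)
    candidates = select_indicator_candidates(matrix, profile.rit)
    marginals_all = marginal_inclusion(matrix, candidates)
    selection = indicator_selection(matrix, candidates, p_min, table=marginals_all)
    pmin_bound = None
    if selection.l_hat == 0:
        pmin_bound = admissible_pmin_lower_bound(matrix, candidates, grid=pmin_grid)
        if not adjust_pmin:
            raise EstimationError(
                f"{role}: no reproducible replicate at p_min={p_min}; "
                f"the admissible lower bound is {pmin_bound} (see the marginal-"
                "inclusion threshold constraint)")
        selection = indicator_selection(matrix, candidates, pmin_bound, table=marginals_all)
    r_set = reproducible_prey_proteins(matrix, selection)
    r_marginals = marginal_inclusion(matrix, r_set, selection.reproducible_replicates,
                                     stage="R")
    return SideScreen(
        role=role, mst=float(mst), n_naive=int(n_naive), matrix=matrix,
        profile=profile, candidates=candidates, marginals_all=marginals_all,
        selection=selection, pmin_requested=float(p_min), pmin_bound=pmin_bound,
        r_set=r_set, r_marginals=r_marginals,
    )
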