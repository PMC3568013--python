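"""Reproducibility index, indicator prey proteins and reproducible replicates.

Given K replicated purifications prefiltered at a score threshold, the
reproducibility index at a score threshold ``s`` is the average
per-replicate occurrence frequency of the proteins whose best peptide score
reaches ``s``:

    RI(s) = 1 / (K * P(s)) * sum_j sum_k I(P_j in E_k and Score_k(P_j) >= s)

where ``P(s)`` counts the proteins whose best peptide score (anywhere)
reaches ``s`` and an occurrence counts only when the protein has a peptide
scoring ``>= s`` in that replicate (``Score_k``, the per-replicate max
peptide score) — occurrences are counted across the peptides that clear the
threshold, not carried over from other replicates.  RI is in [0, 1]
and is deliberately NOT monotone in ``s``: raising the threshold removes
sporadic low-scoring identifications (raising RI) until it starts removing
reproducible proteins as well.  The score threshold maximizing RI (the RIT)
defines the indicator candidates; candidates whose marginal inclusion
probability (occurrence frequency across the K replicates) reaches a
threshold ``p_min`` become indicator prey proteins.  The replicates that
contain every indicator simultaneously are the reproducible replicates F;
the rest are outliers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExperimentSet, ProteinStageSet
from .exceptions import EstimationError, ValidationError

#: default marginal-inclusion threshold grid, 0.00 .. 1.00 step 0.05
DEFAULT_PMIN_GRID = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 2))


@dataclass
class PresenceMatrix:
    """Boolean protein x replicate occurrence matrix with protein max scores.

    The canonical in-memory object the reproducibility math runs on; built
    from (usually prefiltered) evidence.  Row order is sorted protein id,
    column order follows the experiment set's replicate order.
    """

    proteins: np.ndarray  # (n,) protein ids, sorted
    replicates: np.ndarray  # (K,) replicate ids in experiment order
    matrix: np.ndarray  # (n, K) bool occurrence
    max_score: np.ndarray  # (n,) protein-level max peptide score
    rep_max_score: np.ndarray  # (n, K) per-replicate max peptide score, -inf if absent

    @classmethod
    def from_evidence(cls, evidence: pd.DataFrame, replicate_ids) -> "PresenceMatrix":
        replicates = np.asarray(list(replicate_ids), dtype=object)
        rep_max = (evidence.groupby(["protein_id", "replicate_id"])["score"].max()
                   .unstack(fill_value=-np.inf)
                   .reindex(columns=replicates, fill_value=-np.inf)
                   .sort_index())
        rep_max_arr = rep_max.to_numpy(float)
        return cls(
            proteins=rep_max.index.to_numpy(dtype=object),
            replicates=replicates,
            matrix=np.isfinite(rep_max_arr),
            max_score=rep_max_arr.max(axis=1),
            rep_max_score=rep_max_arr,
        )

    @classmethod
    def from_experiment(cls, expset: ExperimentSet, mst: float = -np.inf) -> "PresenceMatrix":
        ev = expset.evidence
        if np.isfinite(mst):
            ev = ev[ev["score"] >= mst]
        return cls.from_evidence(ev, expset.replicate_ids)

    @property
    def k(self) -> int:
        return len(self.replicates)

    def protein_index(self, proteins) -> np.ndarray:
        idx = {p: i for i, p in enumerate(self.proteins)}
        return np.asarray([idx[p] for p in proteins], dtype=int)

    def replicate_index(self, replicates) -> np.ndarray:
        idx = {r: i for i, r in enumerate(self.replicates)}
        return np.asarray([idx[r] for r in replicates], dtype=int)


@dataclass
class ReproducibilityProfile:
    """RI evaluated on the grid of distinct protein max-peptide scores."""

    s_grid: np.ndarray
    ri: np.ndarray
    p_of_s: np.ndarray
    rit: float
    ri_at_rit: float


@dataclass
class InclusionTable:
    """Per-protein marginal inclusion probabilities over a replicate basis."""

    stage: str
    entries: pd.Series  # protein_id -> occurrence frequency in [0, 1]
    k_basis: int

    def get(self, protein_id: str, default: float = 0.0) -> float:
        return float(self.entries.get(protein_id, default))


@dataclass
class IndicatorSelection:
    """Indicator proteins at a marginal threshold and the replicates they flag."""

    p_min: float
    indicators: frozenset[str]
    reproducible_replicates: tuple
    p_joint: float

    @property
    def q_selected(self) -> int:
        return len(self.indicators)

    @property
    def l_hat(self) -> int:
        return len(self.reproducible_replicates)


def reproducibility_index(matrix: PresenceMatrix | ExperimentSet, s: float) -> float:
    """RI at score threshold ``s``; NaN when no protein reaches ``s``."""
    if isinstance(matrix, ExperimentSet):
        matrix = PresenceMatrix.from_experiment(matrix)
    p_of_s = int((matrix.max_score >= s).sum())
    if p_of_s == 0:
        return float("nan")
    # an occurrence with per-replicate max >= s implies the protein's global
    # max >= s, so no row restriction is needed in the numerator
    occurrences = int((matrix.rep_max_score >= s).sum())
    return float(occurrences / (matrix.k * p_of_s))


def reproducibility_profile(matrix: PresenceMatrix | ExperimentSet,
                            mst: float = -np.inf) -> ReproducibilityProfile:
    """Evaluate RI on the distinct protein max-score grid and locate the RIT.

    The RIT is the smallest grid score attaining the maximal RI (ties break
    toward the most inclusive threshold).
    """
    if isinstance(matrix, ExperimentSet):
        matrix = PresenceMatrix.from_experiment(matrix, mst=mst)
    scores = matrix.max_score
    keep = scores >= mst if np.isfinite(mst) else np.ones(len(scores), bool)
    if not keep.any():
        raise EstimationError("no protein passes the prefilter threshold; RI undefined")
    s_grid = np.unique(scores[keep])
    # occurrence counts: number of (protein, replicate) cells with per-replicate
    # max >= s; such a cell always belongs to a protein with global max >= s
    cell_scores = np.sort(matrix.rep_max_score[keep][matrix.matrix[keep]])
    sorted_max = np.sort(scores[keep])
    n = len(sorted_max)
    occurrences = len(cell_scores) - np.searchsorted(cell_scores, s_grid, side="left")
    p_of_s = n - np.searchsorted(sorted_max, s_grid, side="left")
    ri = occurrences / (matrix.k * p_of_s)
    imax = int(np.argmax(ri))  # first occurrence of the max -> smallest s
    return ReproducibilityProfile(
        s_grid=s_grid, ri=ri, p_of_s=p_of_s,
        rit=float(s_grid[imax]), ri_at_rit=float(ri[imax]),
    )


def select_indicator_candidates(matrix: PresenceMatrix, rit: float) -> ProteinStageSet:
    """Proteins whose max-peptide score reaches the RIT (indicator candidates)."""
    sel = matrix.max_score >= rit
    if not sel.any():
        raise EstimationError(f"no protein reaches the score threshold {rit}")
    return ProteinStageSet(stage="Q", protein_ids=frozenset(matrix.proteins[sel]))


def marginal_inclusion(matrix: PresenceMatrix, proteins, replicates=None,
                       stage: str = "N") -> InclusionTable:
    """Empirical occurrence frequency of each protein over a replicate basis.

    ``replicates`` defaults to all replicates of the matrix; proteins absent
    from the matrix get frequency 0.
    """
    if replicates is None:
        cols = np.arange(matrix.k)
    else:
        replicates = list(replicates)
        if len(replicates) == 0:
            raise ValidationError("replicate basis must be non-empty")
        cols = matrix.replicate_index(replicates)
    prots = sorted(proteins.protein_ids if isinstance(proteins, ProteinStageSet) else proteins)
    known = {p: i for i, p in enumerate(matrix.proteins)}
    counts = np.zeros(len(prots))
    sub = matrix.matrix[:, cols]
    for j, p in enumerate(prots):
        i = known.get(p)
        if i is not None:
            counts[j] = sub[i].sum()
    entries = pd.Series(counts / len(cols), index=pd.Index(prots, name="protein_id"))
    return InclusionTable(stage=stage, entries=entries, k_basis=len(cols))


def select_indicators(table: InclusionTable, candidates: ProteinStageSet,
                      p_min: float) -> frozenset[str]:
    """Candidates whose marginal inclusion probability reaches ``p_min`` (closed)."""
    if not (0.0 <= p_min <= 1.0):
        raise ValidationError(f"p_min must lie in [0, 1], got {p_min}")
    sel = table.entries[table.entries >= p_min]
    return frozenset(sel.index) & candidates.protein_ids


def joint_inclusion(table: InclusionTable, indicators) -> float:
    """Joint inclusion probability of an indicator set.

    Estimated as the product of the indicators' marginal inclusion
    probabilities (independence working assumption); the empty set has joint
    probability 1.
    """
    missing = set(indicators) - set(table.entries.index)
    if missing:
        raise ValidationError(f"indicators missing from inclusion table: {sorted(missing)}")
    if not indicators:
        return 1.0
    return float(np.prod([table.entries[p] for p in sorted(indicators)]))


def reproducible_replicates(matrix: PresenceMatrix, indicators) -> tuple:
    """Replicates containing ALL indicators simultaneously (the F set).

    An empty indicator set flags every replicate as reproducible.
    """
    if not indicators:
        return tuple(matrix.replicates)
    rows = matrix.protein_index(sorted(indicators))
    mask = matrix.matrix[rows].all(axis=0)
    return tuple(matrix.replicates[mask])


def indicator_selection(matrix: PresenceMatrix, candidates: ProteinStageSet,
                        p_min: float, table: InclusionTable | None = None) -> IndicatorSelection:
    """Select indicators at ``p_min`` and derive F, L-hat and the joint inclusion."""
    if table is None:
        table = marginal_inclusion(matrix, candidates)
    indicators = select_indicators(table, candidates, p_min)
    f_set = reproducible_replicates(matrix, indicators)
    return IndicatorSelection(
        p_min=float(p_min), indicators=indicators,
        reproducible_replicates=f_set,
        p_joint=joint_inclusion(table, indicators),
    )


def admissible_pmin_lower_bound(matrix: PresenceMatrix, candidates: ProteinStageSet,
                                grid=DEFAULT_PMIN_GRID) -> float:
    """Smallest grid threshold yielding a strictly positive number of
    reproducible replicates; every threshold at or above it is admissible."""
    grid = sorted(grid)
    if any(not (0.0 <= g <= 1.0) for g in grid):
        raise ValidationError("p_min grid values must lie in [0, 1]")
    table = marginal_inclusion(matrix, candidates)
    for g in grid:
        indicators = select_indicators(table, candidates, g)
        if len(reproducible_replicates(matrix, indicators)) > 0:
            return float(g)
    raise EstimationError(
        "no threshold on the grid yields a reproducible replicate; "
        "include 1.0 in the grid or check the candidate set")


def reproducible_prey_proteins(matrix: PresenceMatrix,
                               selection: IndicatorSelection) -> ProteinStageSet:
    """Prefiltered proteins occurring in at least one reproducible replicate."""
    if selection.l_hat == 0:
        raise ValidationError("no reproducible replicates (L-hat = 0); "
                              "raise p_min to its admissible lower bound")
    cols = matrix.replicate_index(selection.reproducible_replicates)
    present = matrix.matrix[:, cols].any(axis=1)
    return ProteinStageSet(stage="R", protein_ids=frozenset(matrix.proteins[present]))
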