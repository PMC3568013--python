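"""Reference-list validation statistics.

Overlap between a selected prey list and an external reference list is
modelled hypergeometrically: drawing the reference list of size B from a
universe of N proteins of which S are selected, the number of common
proteins X has pmf

    P(X = x | N, S, B) = C(S, x) * C(N - S, B - x) / C(N, B).

Two reporting conventions are provided: ``point`` evaluates the pmf at the
observed overlap (the convention this package's reference results use), and
``upper`` reports the enrichment tail P(X >= x) (the standard competitive
test; ``strict`` gives P(X > x)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .data import ExperimentSet, ProteinStageSet
from .exceptions import ValidationError
from .ontology import list_semantic_similarity  # re-export  # noqa: F401
from .reproducibility import PresenceMatrix

CONVENTIONS = ("point", "upper", "strict")


@dataclass(frozen=True)
class OverlapResult:
    n_universe: int
    n_selected: int
    n_reference: int
    n_common: int
    p_value: float
    convention: str = "point"


def hypergeom_overlap_pvalue(n_universe: int, n_selected: int, n_reference: int,
                             n_common: int, convention: str = "point") -> float:
    """Hypergeometric overlap significance between two protein lists."""
    if convention not in CONVENTIONS:
        raise ValidationError(f"unknown convention {convention!r}; expected {CONVENTIONS}")
    ok = (0 <= n_common <= min(n_selected, n_reference) <= n_universe
          and n_selected <= n_universe and n_reference <= n_universe)
    if not ok:
        raise ValidationError(
            f"inconsistent overlap counts: N={n_universe}, S={n_selected}, "
            f"B={n_reference}, X={n_common}")
    if convention == "point":
        return float(hypergeom.pmf(n_common, n_universe, n_selected, n_reference))
    if convention == "upper":
        return float(hypergeom.sf(n_common - 1, n_universe, n_selected, n_reference))
    return float(hypergeom.sf(n_common, n_universe, n_selected, n_reference))


def overlap_test(universe, selected, reference, convention: str = "point") -> OverlapResult:
    """Convenience wrapper computing the counts from protein sets."""
    universe, selected, reference = set(universe), set(selected), set(reference)
    if not selected <= universe or not reference <= universe:
        raise ValidationError("selected and reference lists must lie within the universe")
    x = len(selected & reference)
    p = hypergeom_overlap_pvalue(len(universe), len(selected), len(reference), x,
                                 convention)
    return OverlapResult(len(universe), len(selected), len(reference), x, p, convention)


def stagewise_cv(expset: ExperimentSet, stage_sets) -> dict[str, float]:
    """Coefficient of variation of per-replicate mean occurrence, per stage.

    For each stage's protein set, each replicate's mean occurrence indicator
    over those proteins is computed from the raw evidence; the CV is the
    sample standard deviation across replicates divided by their mean
    (NaN when the mean is zero).  A screen whose later stages do not inflate
    this CV is not trading reproducibility for specificity.
    """
    matrix = PresenceMatrix.from_experiment(expset)
    known = {p: i for i, p in enumerate(matrix.proteins)}
    out: dict[str, float] = {}
    for stage_set in stage_sets:
        prots = sorted(stage_set.protein_ids)
        if not prots:
            out[stage_set.stage] = float("nan")
            continue
        rows = [known[p] for p in prots if p in known]
        sub = matrix.matrix[rows] if rows else np.zeros((0, matrix.k), bool)
        per_rep = sub.sum(axis=0) / len(prots)  # absent proteins count 0 occurrences
        mean = per_rep.mean()
        if mean == 0.0:
            out[stage_set.stage] = float("nan")
        else:
            sd = per_rep.std(ddof=1) if matrix.k > 1 else 0.0
            out[stage_set.stage] = float(sd / mean)
    return out


def aggregate_fdr_from_posteriors(posteriors) -> float:
    """Average local FDR ``mean(1 - p)`` of a selection scored by posteriors."""
    p = np.asarray(list(posteriors), dtype=float)
    if p.size == 0:
        raise ValidationError("empty posterior list")
    if np.any((p < 0) | (p > 1)):
        raise ValidationError("posterior probabilities must lie in [0, 1]")
    return float(np.mean(1.0 - p))
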