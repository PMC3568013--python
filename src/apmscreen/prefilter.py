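"""Score threshold (MST) estimation and prey-protein prefiltering.

High-throughput search engines report a peptide identification score whose
relation to the peptide identification probability is monotone but dataset
specific.  The prefiltering threshold (the "median score threshold", MST) is
the smallest score at which the fitted median identification probability
reaches a target (default 0.5).  The median-versus-score relation is fitted
by quantile regression on a cubic B-spline basis and projected onto the
monotone cone, because a median curve of a probability against a reliability
score should not decrease.

Prefiltering then retains every protein with at least one peptide scoring at
or above the MST (closed comparison), and drops evidence rows below the MST
from all downstream views.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from sklearn.isotonic import IsotonicRegression

from .data import ExperimentSet, ProteinStageSet
from .exceptions import EstimationError, ValidationError

MIN_PAIRED_RECORDS = 20


@dataclass
class ScoreProbabilityCurve:
    """Fitted median (and optional quartile) probability as a function of score."""

    score_grid: np.ndarray
    median_prob: np.ndarray
    lower_q: np.ndarray | None = None
    upper_q: np.ndarray | None = None


@dataclass
class PrefilterResult:
    mst: float
    retained_proteins: ProteinStageSet  # stage "P"
    evidence: pd.DataFrame  # rows with score >= mst only

    @property
    def p_count(self) -> int:
        """Number of prefiltered prey proteins P."""
        return self.retained_proteins.cardinality


def _spline_design(x: np.ndarray, knots: np.ndarray, lo: float, hi: float) -> np.ndarray:
    t = np.concatenate([[lo] * 4, knots, [hi] * 4])
    xc = np.clip(x, lo, hi)
    return BSpline.design_matrix(xc, t, 3).toarray()


def fit_median_curve(evidence: pd.DataFrame, n_interior_knots: int = 5,
                     grid_size: int = 201) -> ScoreProbabilityCurve:
    """Fit the median identification probability as a function of score.

    Quantile regression (tau = 0.5, plus quartile curves) on a cubic
    B-spline basis with ``n_interior_knots`` interior knots placed at score
    quantiles, followed by an isotonic (monotone non-decreasing) projection
    and clipping to [0, 1].

    Requires at least 20 evidence rows carrying both score and probability;
    otherwise raises :class:`EstimationError` suggesting a user-supplied MST.
    """
    paired = evidence.dropna(subset=["score", "probability"])
    if len(paired) < MIN_PAIRED_RECORDS:
        raise EstimationError(
            f"only {len(paired)} evidence rows have both score and probability "
            f"(need >= {MIN_PAIRED_RECORDS}); supply an explicit score threshold (--mst)")
    x = paired["score"].to_numpy(float)
    y = paired["probability"].to_numpy(float)
    lo, hi = float(x.min()), float(x.max())
    grid = np.linspace(lo, hi, grid_size)

    if np.ptp(y) == 0.0 or lo == hi:
        const = np.full(grid_size, float(np.median(y)))
        return ScoreProbabilityCurve(grid, const.copy(), const.copy(), const.copy())

    qs = np.linspace(0, 1, n_interior_knots + 2)[1:-1]
    knots = np.unique(np.quantile(x, qs))
    X = _spline_design(x, knots, lo, hi)
    Xg = _spline_design(grid, knots, lo, hi)

    from statsmodels.regression.quantile_regression import QuantReg

    curves = {}
    for tau in (0.25, 0.5, 0.75):
        params = QuantReg(y, X).fit(q=tau).params
        fitted = Xg @ params
        iso = IsotonicRegression(increasing=True).fit(grid, fitted)
        curves[tau] = np.clip(iso.predict(grid), 0.0, 1.0)
    return ScoreProbabilityCurve(grid, curves[0.5], curves[0.25], curves[0.75])


def compute_mst(curve: ScoreProbabilityCurve, prob_threshold: float = 0.5) -> float:
    """Smallest grid score at which the fitted median reaches ``prob_threshold``."""
    if not (0.0 < prob_threshold < 1.0):
        raise ValidationError(f"prob_threshold must lie in (0, 1), got {prob_threshold}")
    hits = np.nonzero(curve.median_prob >= prob_threshold)[0]
    if len(hits) == 0:
        raise EstimationError(
            f"fitted median probability never reaches {prob_threshold}; "
            "MST undefined; supply an explicit score threshold (--mst)")
    return float(curve.score_grid[hits[0]])


def prefilter_proteins(expset: ExperimentSet, mst: float) -> PrefilterResult:
    """Retain proteins with at least one peptide of score >= ``mst``.

    Evidence rows below the MST are dropped from the returned view, so all
    downstream occurrence counts refer to prefiltered evidence only.
    """
    if not np.isfinite(mst):
        raise ValidationError(f"score threshold must be finite, got {mst}")
    kept = expset.evidence[expset.evidence["score"] >= mst]
    retained = frozenset(kept["protein_id"])
    if not retained:
        raise ValidationError(
            f"no protein has a peptide with score >= {mst}; nothing to analyse")
    return PrefilterResult(
        mst=float(mst),
        retained_proteins=ProteinStageSet(stage="P", protein_ids=retained),
        evidence=kept.reset_index(drop=True),
    )
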