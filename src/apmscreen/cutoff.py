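"""Automatic confidence-score cutoff estimation.

Two objective criteria are controlled simultaneously over a cutoff grid
(default (0, 0.2] in steps of 0.01 — in practice the optimum falls in this
short positive range):

* a Monte-Carlo decoy false-discovery rate: repeated samples of ``N_B``
  proteins (the bait's naive universe size) are drawn without replacement
  from the control's naive protein universe, assembled into a decoy bait
  carrying the bait's replicate-count structure, and the ENTIRE
  identification chain is rerun on each decoy; every decoy prey scoring at
  or above a cutoff is counted a false positive, and
  ``FDR(c) = mean decoy count / observed bait discoveries at c`` (capped at 1);

* a semantic-similarity distance: at each cutoff, the distance
  ``d(c) = LB_S(c) - UB_N(c)`` between approximate 100(1-theta)% confidence
  intervals of the median bait-prey Resnik similarity for the selected
  (specific-stage) preys versus size-matched random samples from the naive
  prey universe.  ``d > 0`` marks a significant gain in biological coherence.

The estimated cutoff is the grid value with the lowest FDR, ties broken by
the largest ``d``; if no candidate has ``d > 0`` the minimum-FDR cutoff is
returned with a warning flag.

The median CI uses McGill's notched-boxplot approximation
``M +- c * IQR / (1.08 * sqrt(n))`` with ``c`` in [1.386, 1.960]: 1.386 when
group sizes and spreads are comparable, escalated to the conservative 1.960
when either differs by more than a factor of two.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import screen_side
from .exceptions import ApmscreenError, EstimationError, ValidationError
from .ontology import Ontology, bait_prey_similarity
from .reproducibility import InclusionTable
from .scoring import ConfidenceScoreTable, confidence_scores

#: default cutoff grid (0, 0.2] step 0.01
DEFAULT_CUTOFF_GRID = tuple(np.round(np.arange(0.01, 0.2001, 0.01), 2))

C_COEF_SIMILAR = 1.386
C_COEF_CONSERVATIVE = 1.960


@dataclass
class FdrCurve:
    cutoff_grid: np.ndarray
    fp_hat: np.ndarray  # mean decoy discovery count per cutoff
    discoveries: np.ndarray  # observed bait discoveries per cutoff
    fdr_hat: np.ndarray  # FP/discoveries capped at 1; NaN when discoveries = 0
    se: np.ndarray
    n_mc: int
    seed: int

    @property
    def log10_fdr(self) -> np.ndarray:
        """Diagnostic scale log10(1e-3 + FDR) used for plotting."""
        return np.log10(1e-3 + self.fdr_hat)


@dataclass
class SimilarityDistanceCurve:
    cutoff_grid: np.ndarray
    d: np.ndarray  # LB_S - UB_N; NaN where the selection is empty/unannotated
    ci_n: np.ndarray  # (len(grid), 2)
    ci_s: np.ndarray  # (len(grid), 2)
    b_reps: int
    theta: float
    c_coef: np.ndarray  # per-cutoff McGill coefficient actually used


@dataclass
class CutoffEstimate:
    cs_cutoff_hat: float
    min_fdr: float
    d_at_cutoff: float  # NaN if no similarity curve
    no_positive_d: bool  # warning flag: estimate not backed by d > 0
    fdr_curve: FdrCurve
    d_curve: SimilarityDistanceCurve | None


def median_ci(values, theta: float = 0.05, c_coef: float = C_COEF_SIMILAR):
    """Approximate 100(1-theta)% CI of the median, McGill's notch form.

    Returns ``(M - h, M + h)`` with ``h = c_coef * IQR / (1.08 * sqrt(n))``.
    """
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        raise ValidationError("median_ci needs at least one value")
    if not (C_COEF_SIMILAR <= c_coef <= C_COEF_CONSERVATIVE):
        raise ValidationError(
            f"c_coef must lie in [{C_COEF_SIMILAR}, {C_COEF_CONSERVATIVE}], got {c_coef}")
    med = float(np.median(values))
    iqr = float(np.percentile(values, 75) - np.percentile(values, 25))
    h = c_coef * iqr / (1.08 * np.sqrt(values.size))
    return (med - h, med + h)


def _choose_c(n1: int, n2: int, sd1: float, sd2: float) -> float:
    """McGill coefficient: 1.386 for comparable groups, else 1.960."""
    if min(n1, n2) == 0:
        return C_COEF_CONSERVATIVE
    if max(n1, n2) / min(n1, n2) > 2.0:
        return C_COEF_CONSERVATIVE
    lo, hi = sorted((abs(sd1), abs(sd2)))
    if lo == 0.0:
        return C_COEF_SIMILAR if hi == 0.0 else C_COEF_CONSERVATIVE
    if hi / lo > 2.0:
        return C_COEF_CONSERVATIVE
    return C_COEF_SIMILAR


def estimate_fdr_curve(bait_cs: ConfidenceScoreTable,
                       control_evidence: pd.DataFrame,
                       control_replicate_ids,
                       control_r_marginals: InclusionTable,
                       n_bait_universe: int,
                       k_bait: int,
                       mst_control: float,
                       p_min: float,
                       grid=DEFAULT_CUTOFF_GRID,
                       n_mc: int = 200,
                       seed: int = 0) -> FdrCurve:
    """Monte-Carlo decoy FDR estimate over a cutoff grid.

    Each replicate draws ``n_bait_universe`` proteins from the control's
    naive universe (without replacement when possible), keeps the control
    evidence of those proteins on ``k_bait`` sampled control replicates, and
    reruns the whole identification chain on that decoy bait; decoys where
    the chain degenerates (nothing passes prefiltering, no reproducible
    replicate even at threshold 1) contribute zero discoveries.
    """
    if n_mc < 1:
        raise ValidationError(f"n_mc must be >= 1, got {n_mc}")
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    universe = np.array(sorted(set(control_evidence["protein_id"])), dtype=object)
    replicates = np.asarray(list(control_replicate_ids), dtype=object)
    replace_proteins = len(universe) < n_bait_universe
    if replace_proteins:
        warnings.warn(
            f"control universe ({len(universe)}) smaller than the bait universe "
            f"({n_bait_universe}); decoy proteins sampled WITH replacement")
    replace_reps = len(replicates) < k_bait

    counts = np.zeros((n_mc, len(grid)))
    for m in range(n_mc):
        prots = rng.choice(universe, size=n_bait_universe, replace=replace_proteins)
        reps = rng.choice(replicates, size=k_bait, replace=replace_reps)
        mask = (control_evidence["protein_id"].isin(set(prots))
                & control_evidence["replicate_id"].isin(set(reps)))
        decoy_ev = control_evidence[mask]
        try:
            decoy = screen_side(decoy_ev, list(dict.fromkeys(reps)), role="bait",
                                mst=mst_control, p_min=p_min, adjust_pmin=True)
        except ApmscreenError:
            continue  # degenerate decoy: no discoveries
        cs = confidence_scores(decoy.r_marginals, control_r_marginals, decoy.r_set)
        scores = cs.frame["cs"].to_numpy()
        counts[m] = (scores[:, None] >= grid[None, :]).sum(axis=0)

    fp_hat = counts.mean(axis=0)
    discoveries = np.array([bait_cs.discoveries(c) for c in grid])
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(discoveries > 0, np.minimum(fp_hat / discoveries, 1.0), np.nan)
        se_counts = counts.std(axis=0, ddof=1) / np.sqrt(n_mc) if n_mc > 1 else np.zeros(len(grid))
        se = np.where(discoveries > 0, se_counts / discoveries, np.nan)
    return FdrCurve(cutoff_grid=grid, fp_hat=fp_hat, discoveries=discoveries,
                    fdr_hat=fdr, se=se, n_mc=n_mc, seed=seed)


def similarity_distance_curve(ont: Ontology, bait_id: str,
                              stage_n_proteins,
                              cs_table: ConfidenceScoreTable,
                              aspect: str = "MF",
                              grid=DEFAULT_CUTOFF_GRID,
                              b_reps: int = 1024,
                              theta: float = 0.05,
                              c_coef: float | None = None,
                              seed: int = 0) -> SimilarityDistanceCurve:
    """Distance between median-similarity CIs of selected vs naive preys.

    At each cutoff the "S side" takes the bait-prey similarities of the preys
    selected at that cutoff, and the "N side" takes ``b_reps`` size-matched
    random samples (without replacement) from the naive prey universe, whose
    per-sample medians and IQRs are averaged before forming the CI.  ``d``
    is missing wherever the selection is empty or entirely unannotated.
    """
    if b_reps < 2:
        raise ValidationError(f"b_reps must be >= 2, got {b_reps}")
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    n_prots = np.array(sorted(stage_n_proteins), dtype=object)
    sims = np.array([np.nan if (v := bait_prey_similarity(ont, bait_id, p, aspect)) is None
                     else v for p in n_prots], dtype=float)
    sim_of = dict(zip(n_prots, sims))

    d = np.full(len(grid), np.nan)
    ci_n = np.full((len(grid), 2), np.nan)
    ci_s = np.full((len(grid), 2), np.nan)
    c_used = np.full(len(grid), np.nan)
    cs_scores = cs_table.frame["cs"]
    for i, c in enumerate(grid):
        selected = cs_scores.index[cs_scores >= c]
        n_sel = len(selected)
        if n_sel == 0:
            continue
        s_vals = np.array([sim_of.get(p, np.nan) for p in selected], dtype=float)
        s_vals = s_vals[~np.isnan(s_vals)]
        if s_vals.size == 0:
            continue
        take = min(n_sel, len(n_prots))
        meds, iqrs, null_pool = [], [], []
        for _ in range(b_reps):
            sample = sims[rng.choice(len(n_prots), size=take, replace=False)]
            sample = sample[~np.isnan(sample)]
            if sample.size == 0:
                continue
            meds.append(np.median(sample))
            iqrs.append(np.percentile(sample, 75) - np.percentile(sample, 25))
            null_pool.append(sample)
        if not meds:
            continue
        m_n, iqr_n = float(np.mean(meds)), float(np.mean(iqrs))
        pooled = np.concatenate(null_pool)
        if c_coef is None:
            cc = _choose_c(s_vals.size, take, float(np.std(s_vals)), float(np.std(pooled)))
        else:
            cc = float(c_coef)
        lb_s, ub_s = median_ci(s_vals, theta, cc)
        h_n = cc * iqr_n / (1.08 * np.sqrt(take))
        ci_s[i] = (lb_s, ub_s)
        ci_n[i] = (m_n - h_n, m_n + h_n)
        c_used[i] = cc
        d[i] = lb_s - (m_n + h_n)
    return SimilarityDistanceCurve(cutoff_grid=grid, d=d, ci_n=ci_n, ci_s=ci_s,
                                   b_reps=b_reps, theta=theta, c_coef=c_used)


def estimate_optimal_cutoff(fdr: FdrCurve,
                            dcurve: SimilarityDistanceCurve | None) -> CutoffEstimate:
    """Cutoff with the lowest estimated FDR; ties resolved by the largest d.

    If no cutoff attains ``d > 0`` (or no similarity curve is available) the
    minimum-FDR cutoff is returned flagged with ``no_positive_d``.
    """
    grid = fdr.cutoff_grid
    if dcurve is not None and (len(dcurve.cutoff_grid) != len(grid)
                               or not np.allclose(dcurve.cutoff_grid, grid)):
        raise ValidationError("FDR and similarity curves must share the cutoff grid")
    defined = ~np.isnan(fdr.fdr_hat)
    if not defined.any():
        raise EstimationError("FDR undefined on the whole grid (no bait discoveries); "
                              "cannot estimate a cutoff")
    fmin = np.nanmin(fdr.fdr_hat)
    ties = defined & (fdr.fdr_hat == fmin)
    d = dcurve.d if dcurve is not None else np.full(len(grid), np.nan)
    d_ties = np.where(ties, d, np.nan)
    if np.isnan(d_ties).all():
        # no similarity information to break the tie: prefer specificity
        # (the FDR criterion controls false positives; take the most
        # conservative cutoff among the equally good ones)
        idx = int(np.nonzero(ties)[0][-1])
    else:
        idx = int(np.nanargmax(d_ties))
    d_at = float(d[idx])
    return CutoffEstimate(
        cs_cutoff_hat=float(grid[idx]),
        min_fdr=float(fmin),
        d_at_cutoff=d_at,
        no_positive_d=bool(np.isnan(d_at) or d_at <= 0.0),
        fdr_curve=fdr,
        d_curve=dcurve,
    )
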