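"""Statsmodels-style model/results interface to the full screen.

:class:`InteractionScreen` holds the data and the screen's configuration;
:meth:`InteractionScreen.fit` runs the two-step procedure — replicate
reproducibility screening on both sides, confidence scoring, and (when
requested) automatic cutoff estimation — and returns a
:class:`ScreenResults` carrying estimates, diagnostics and a ``summary()``
table.  Stage sets satisfy S ⊆ R ⊆ N on both axes by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import cutoff as cutoff_mod
from .cutoff import (DEFAULT_CUTOFF_GRID, CutoffEstimate, FdrCurve,
                     SimilarityDistanceCurve)
from .data import ExperimentSet, ProteinStageSet, write_results
from .engine import SideScreen, screen_side
from .exceptions import EstimationError, ValidationError
from .ontology import Ontology
from .prefilter import ScoreProbabilityCurve, compute_mst, fit_median_curve
from .scoring import (ConfidenceScoreTable, SpecificPreySet, confidence_scores,
                      select_specific_preys)
from .stability import StabilityCurve, multiscale_joint_inclusion
from .validation import stagewise_cv


class InteractionScreen:
    """Two-step reproducibility-and-specificity screen for one bait.

    Parameters
    ----------
    bait, control
        Experiment sets (see :func:`apmscreen.data.read_evidence_table`).
    ontology
        Optional ontology + annotations enabling the semantic-similarity
        criterion of the automatic cutoff and list-level validation.
    mst_bait, mst_control
        Score thresholds; ``"auto"`` fits the median score-probability
        curve per side and takes the score where it reaches
        ``prob_threshold``.
    pmin_bait, pmin_control
        Marginal inclusion probability thresholds for indicator selection
        (default 0.75).  Thresholds below the admissible lower bound (no
        reproducible replicate) raise an error unless ``adjust_pmin`` is
        set, in which case the bound itself is used.
    """

    def __init__(self, bait: ExperimentSet, control: ExperimentSet,
                 ontology: Ontology | None = None, *,
                 mst_bait: float | str = "auto", mst_control: float | str = "auto",
                 prob_threshold: float = 0.5,
                 pmin_bait: float = 0.75, pmin_control: float = 0.75,
                 aspect: str = "MF", adjust_pmin: bool = False) -> None:
        if bait.role != "bait" or control.role != "control":
            raise ValidationError("expected a bait-role and a control-role experiment set")
        self.bait = bait
        self.control = control
        self.ontology = ontology
        self.mst_bait = mst_bait
        self.mst_control = mst_control
        self.prob_threshold = prob_threshold
        self.pmin_bait = pmin_bait
        self.pmin_control = pmin_control
        self.aspect = aspect
        self.adjust_pmin = adjust_pmin

    @classmethod
    def from_files(cls, bait_path, control_path, edges_path=None,
                   annotations_path=None, bait_id: str = "", **kwargs) -> "InteractionScreen":
        from .data import read_evidence_table
        from .ontology import read_ontology
        bait = read_evidence_table(bait_path, role="bait", bait_id=bait_id)
        control = read_evidence_table(control_path, role="control")
        ont = None
        if edges_path is not None and annotations_path is not None:
            ont = read_ontology(edges_path, annotations_path)
        return cls(bait, control, ont, **kwargs)

    def _resolve_mst(self, expset: ExperimentSet, requested) -> tuple[float, ScoreProbabilityCurve | None]:
        if requested != "auto":
            return float(requested), None
        curve = fit_median_curve(expset.evidence)
        return compute_mst(curve, self.prob_threshold), curve

    def fit(self, cs_cutoff: float | str = "auto", *,
            cutoff_grid=DEFAULT_CUTOFF_GRID, n_mc: int = 200, b_reps: int = 1024,
            theta: float = 0.05, c_coef: float | None = None,
            seed: int = 0) -> "ScreenResults":
        """Run the screen; ``cs_cutoff="auto"`` triggers cutoff estimation."""
        mst_b, curve_b = self._resolve_mst(self.bait, self.mst_bait)
        mst_c, curve_c = self._resolve_mst(self.control, self.mst_control)

        side_b = screen_side(self.bait.evidence, self.bait.replicate_ids, "bait",
                             mst_b, self.pmin_bait, adjust_pmin=self.adjust_pmin)
        side_c = screen_side(self.control.evidence, self.control.replicate_ids,
                             "control", mst_c, self.pmin_control,
                             adjust_pmin=self.adjust_pmin)

        cs_table = confidence_scores(side_b.r_marginals, side_c.r_marginals,
                                     side_b.r_set)

        estimate: CutoffEstimate | None = None
        if cs_cutoff == "auto":
            fdr = cutoff_mod.estimate_fdr_curve(
                cs_table, self.control.evidence, self.control.replicate_ids,
                side_c.r_marginals, n_bait_universe=side_b.n_naive,
                k_bait=self.bait.k, mst_control=mst_c, p_min=self.pmin_bait,
                grid=cutoff_grid, n_mc=n_mc, seed=seed)
            dcurve = None
            if self.ontology is not None and self.bait.bait_id:
                dcurve = cutoff_mod.similarity_distance_curve(
                    self.ontology, self.bait.bait_id,
                    side_b.matrix.proteins, cs_table, aspect=self.aspect,
                    grid=cutoff_grid, b_reps=b_reps, theta=theta,
                    c_coef=c_coef, seed=seed + 1)
            estimate = cutoff_mod.estimate_optimal_cutoff(fdr, dcurve)
            cutoff_used = estimate.cs_cutoff_hat
        else:
            cutoff_used = float(cs_cutoff)
        specific = select_specific_preys(cs_table, cutoff_used)
        cs_table.cutoff = cutoff_used

        return ScreenResults(model=self, mst_bait=mst_b, mst_control=mst_c,
                             curve_bait=curve_b, curve_control=curve_c,
                             side_bait=side_b, side_control=side_c,
                             cs_table=cs_table, cutoff_used=cutoff_used,
                             cutoff_estimate=estimate, specific=specific,
                             seed=seed)


@dataclass
class ScreenResults:
    """Fitted screen: thresholds, stage sets, scores and diagnostics."""

    model: InteractionScreen
    mst_bait: float
    mst_control: float
    curve_bait: ScoreProbabilityCurve | None
    curve_control: ScoreProbabilityCurve | None
    side_bait: SideScreen
    side_control: SideScreen
    cs_table: ConfidenceScoreTable
    cutoff_used: float
    cutoff_estimate: CutoffEstimate | None
    specific: SpecificPreySet
    seed: int

    # -- stage sets ---------------------------------------------------------
    @property
    def stage_n(self) -> ProteinStageSet:
        return self.model.bait.stage_n()

    @property
    def stage_r(self) -> ProteinStageSet:
        return self.side_bait.r_set

    @property
    def stage_s(self) -> ProteinStageSet:
        return self.specific.stage_set()

    @property
    def rit_bait(self) -> float:
        return self.side_bait.profile.rit

    @property
    def rit_control(self) -> float:
        return self.side_control.profile.rit

    def stage_cardinalities(self) -> dict[str, int]:
        """The six stage counts the workflow logs: N, P, Q, L-hat, R, S (bait side)."""
        return {
            "N": self.stage_n.cardinality,
            "P": self.side_bait.p_count,
            "Q": self.side_bait.selection.q_selected,
            "L_hat": self.side_bait.selection.l_hat,
            "R": self.stage_r.cardinality,
            "S": self.stage_s.cardinality,
        }

    def stagewise_cv(self) -> dict[str, float]:
        """CV diagnostic of mean marginal inclusion across the N/R/S stages."""
        return stagewise_cv(self.model.bait,
                            [self.stage_n, self.stage_r, self.stage_s])

    def stability(self, k_grid=None, b1: int | None = 10, b2: int = 128,
                  seed: int | None = None) -> StabilityCurve:
        """Multiscale-bootstrap stability of the bait-side joint inclusion."""
        k = self.model.bait.k
        if k_grid is None:
            k_grid = range(2, k + 1)
        return multiscale_joint_inclusion(
            self.side_bait.matrix, self.side_bait.selection.p_min, k_grid,
            b1=b1, b2=b2, seed=self.seed if seed is None else seed,
            rit=self.side_bait.profile.rit)

    # -- exports ------------------------------------------------------------
    def frames(self) -> dict[str, pd.DataFrame]:
        sel = self.side_bait.selection
        indicators = pd.DataFrame({
            "protein_id": sorted(sel.indicators),
            "marginal_inclusion": [self.side_bait.marginals_all.get(p)
                                   for p in sorted(sel.indicators)],
        })
        reps = pd.DataFrame({"replicate_id": list(sel.reproducible_replicates)})
        cs = self.cs_table.frame.reset_index()
        spec = pd.DataFrame({"protein_id": sorted(self.specific.proteins)})
        spec["cs"] = [self.cs_table.frame.loc[p, "cs"] for p in spec["protein_id"]]
        return {"indicator_proteins": indicators,
                "reproducible_replicates": reps,
                "confidence_scores": cs,
                "specific_preys": spec}

    def run_summary(self) -> dict:
        est = self.cutoff_estimate
        return {
            "bait_id": self.model.bait.bait_id,
            "k_bait": self.model.bait.k,
            "k_control": self.model.control.k,
            "mst_bait": self.mst_bait,
            "mst_control": self.mst_control,
            "rit_bait": self.rit_bait,
            "rit_control": self.rit_control,
            "pmin_bait": self.side_bait.selection.p_min,
            "pmin_control": self.side_control.selection.p_min,
            "pmin_bait_bound": self.side_bait.pmin_bound,
            "p_joint_bait": self.side_bait.selection.p_joint,
            "p_joint_control": self.side_control.selection.p_joint,
            "cs_cutoff": self.cutoff_used,
            "cs_cutoff_auto": est is not None,
            "min_fdr": None if est is None else est.min_fdr,
            "d_at_cutoff": None if est is None else est.d_at_cutoff,
            "no_positive_d": None if est is None else est.no_positive_d,
            "seed": self.seed,
            "stages_bait": self.stage_cardinalities(),
            "stages_control": {
                "N": self.side_control.n_naive,
                "P": self.side_control.p_count,
                "Q": self.side_control.selection.q_selected,
                "L_hat": self.side_control.selection.l_hat,
                "R": self.side_control.r_set.cardinality,
            },
        }

    def save(self, out_dir) -> list[str]:
        """Write the TSV result tables and the JSON run summary; return manifest."""
        return write_results(self.frames(), self.run_summary(), out_dir)

    def summary(self) -> str:
        """Human-readable fit summary."""
        s = self.run_summary()
        est = self.cutoff_estimate
        lines = [
            "Interaction screen results",
            "=" * 54,
            f"bait id:              {s['bait_id'] or '(unnamed)'}",
            f"replicates (K):       bait {s['k_bait']}, control {s['k_control']}",
            f"score threshold MST:  bait {self.mst_bait:.3f}, control {self.mst_control:.3f}",
            f"RI threshold RIT:     bait {self.rit_bait:.3f}, control {self.rit_control:.3f}",
            f"p_min (marginal):     bait {s['pmin_bait']:.2f}, control {s['pmin_control']:.2f}",
            f"joint inclusion:      bait {s['p_joint_bait']:.3f}, control {s['p_joint_control']:.3f}",
            f"CS cutoff:            {self.cutoff_used:.3f}"
            + (" (auto)" if est is not None else " (fixed)"),
        ]
        if est is not None:
            lines.append(f"  min FDR-hat:        {est.min_fdr:.4f}")
            d = est.d_at_cutoff
            lines.append(f"  d at cutoff:        {'n/a' if np.isnan(d) else f'{d:.4f}'}"
                         + ("  [warning: no d > 0]" if est.no_positive_d else ""))
        st = s["stages_bait"]
        lines += [
            "-" * 54,
            "stage cardinalities (bait side):",
            f"  naive N = {st['N']}, prefiltered P = {st['P']}, "
            f"indicators Q = {st['Q']}",
            f"  reproducible replicates L-hat = {st['L_hat']} "
            f"of {s['k_bait']}",
            f"  reproducible preys R = {st['R']}, specific preys S = {st['S']}",
        ]
        return "\n".join(lines)

    # -- plots (optional; require matplotlib) -------------------------------
    def plot_reproducibility(self, ax=None):
        """RI against the score-threshold grid with the RIT marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        prof = self.side_bait.profile
        ax.step(prof.s_grid, prof.ri, where="post")
        ax.axvline(prof.rit, ls="--", color="crimson",
                   label=f"RIT = {prof.rit:.2f}")
        ax.set_xlabel("score threshold s")
        ax.set_ylabel("reproducibility index RI(s)")
        ax.legend()
        return ax

    def plot_fdr(self, ax=None):
        """log10(1e-3 + FDR-hat) against the cutoff grid."""
        import matplotlib.pyplot as plt

        if self.cutoff_estimate is None:
            raise EstimationError("no FDR curve: the cutoff was fixed, not estimated")
        if ax is None:
            _, ax = plt.subplots()
        fdr = self.cutoff_estimate.fdr_curve
        ax.plot(fdr.cutoff_grid, fdr.log10_fdr, marker="o")
        ax.axvline(self.cutoff_used, ls="--", color="crimson",
                   label=f"cutoff = {self.cutoff_used:.2f}")
        ax.set_xlabel("confidence-score cutoff")
        ax.set_ylabel("log10(1e-3 + FDR-hat)")
        ax.legend()
        return ax
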