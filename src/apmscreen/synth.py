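"""Synthetic AP-MS data generator with planted ground truth.

The generator emulates the structure the screen exploits in real
pull-down series:

* **bait-specific preys** occur only in bait replicates, at a high
  per-replicate inclusion probability, with reliable (high) identification
  scores — the signal to be recovered;
* **background contaminants** occur in bait and control replicates at the
  same per-protein inclusion probability drawn from a configurable range.
  Contaminants above a frequency threshold model the ubiquitous
  matrix/tag binders (keratin-like "core" background): abundant proteins
  that also identify reliably.  The sporadic remainder carries noise-level
  scores, mirroring real control series where the large majority of
  background identifications are rare and low-scoring;
* **outlier replicates** (bait side) have every inclusion probability
  multiplied by ``1 - outlier_depression`` — degraded purifications the
  replicate screen should exclude.

Protein presence is independent Bernoulli per (protein, replicate); each
present protein contributes 1-3 peptide rows with Gamma-distributed scores
(class-specific location) and identification probabilities generated
through a logistic link of the score, so the score-probability calibration
the prefilter fits is exactly recoverable.  Everything is reproducible from
the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import ExperimentSet
from .exceptions import ValidationError

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the generator; defaults model a small pull-down study."""

    k_bait: int = 8
    k_control: int = 40
    n_specific: int = 20
    n_contaminant: int = 200
    outlier_fraction: float = 0.25
    specific_inclusion: float = 0.99
    contaminant_inclusion_range: tuple[float, float] = (0.02, 0.98)
    #: contaminants at or above this inclusion are "core" background with
    #: reliable scores; the sporadic rest scores at noise level
    reliable_inclusion_threshold: float = 0.93
    outlier_depression: float = 0.6
    score_shape: float = 4.0
    score_location_reliable: float = 80.0
    score_location_noise: float = 8.0
    prob_link_midpoint: float = 25.0
    prob_link_slope: float = 0.5
    peptides_per_protein: tuple[int, int] = (1, 3)
    seed: int = 0

    def validate(self) -> None:
        if self.k_bait < 1 or self.k_control < 1:
            raise ValidationError("replicate counts must be >= 1")
        if self.n_specific + self.n_contaminant < 1:
            raise ValidationError("the configuration generates zero proteins")
        if not (0.0 <= self.outlier_fraction < 1.0):
            raise ValidationError("outlier_fraction must lie in [0, 1)")
        if not (0.0 < self.specific_inclusion <= 1.0):
            raise ValidationError("specific_inclusion must lie in (0, 1]")
        lo, hi = self.contaminant_inclusion_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValidationError("contaminant_inclusion_range must satisfy 0 < lo <= hi < 1")
        if not (0.0 < self.outlier_depression <= 1.0):
            raise ValidationError("outlier_depression must lie in (0, 1]")
        plo, phi = self.peptides_per_protein
        if not (1 <= plo <= phi):
            raise ValidationError("peptides_per_protein must be a range of positive ints")


@dataclass(frozen=True)
class TruthLabels:
    specific_ids: frozenset[str]
    contaminant_ids: frozenset[str]
    outlier_replicates: frozenset[str]

    def __post_init__(self):
        if self.specific_ids & self.contaminant_ids:
            raise ValidationError("a protein cannot be both specific and contaminant")


def _peptide_catalog(rng: np.random.Generator, n_proteins: int, max_pep: int) -> np.ndarray:
    lengths = rng.integers(8, 16, size=(n_proteins, max_pep))
    return np.array([
        ["".join(rng.choice(AMINO_ACIDS, size=L)) for L in row] for row in lengths
    ], dtype=object)


def _emit_rows(rng, cfg: SynthConfig, rows: list, replicate: str, protein: str,
               peptides: np.ndarray, reliable: bool) -> None:
    lo, hi = cfg.peptides_per_protein
    n_pep = int(rng.integers(lo, hi + 1))
    chosen = rng.choice(len(peptides), size=n_pep, replace=False)
    loc = cfg.score_location_reliable if reliable else cfg.score_location_noise
    scale = loc / cfg.score_shape
    for idx in chosen:
        score = float(rng.gamma(cfg.score_shape, scale))
        prob = 1.0 / (1.0 + np.exp(-cfg.prob_link_slope * (score - cfg.prob_link_midpoint)))
        rows.append((replicate, protein, peptides[idx], score, prob, 1))


def generate_apms(config: SynthConfig) -> tuple[ExperimentSet, ExperimentSet, TruthLabels]:
    """Generate (bait, control, truth) fully determined by ``config.seed``."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    specific_ids = [f"SPEC{i + 1:04d}" for i in range(cfg.n_specific)]
    contaminant_ids = [f"CONT{i + 1:04d}" for i in range(cfg.n_contaminant)]
    lo, hi = cfg.contaminant_inclusion_range
    cont_incl = rng.uniform(lo, hi, size=cfg.n_contaminant)
    cont_reliable = cont_incl >= cfg.reliable_inclusion_threshold

    max_pep = cfg.peptides_per_protein[1]
    spec_peps = _peptide_catalog(rng, cfg.n_specific, max_pep)
    cont_peps = _peptide_catalog(rng, cfg.n_contaminant, max_pep)

    bait_reps = [f"B{i + 1:03d}" for i in range(cfg.k_bait)]
    control_reps = [f"C{i + 1:03d}" for i in range(cfg.k_control)]
    n_out = int(round(cfg.outlier_fraction * cfg.k_bait))
    outliers = set(rng.choice(bait_reps, size=n_out, replace=False)) if n_out else set()

    bait_rows: list = []
    for rep in bait_reps:
        depress = (1.0 - cfg.outlier_depression) if rep in outliers else 1.0
        for pid, peps in zip(specific_ids, spec_peps):
            if rng.random() < cfg.specific_inclusion * depress:
                _emit_rows(rng, cfg, bait_rows, rep, pid, peps, reliable=True)
        for pid, peps, incl, rel in zip(contaminant_ids, cont_peps, cont_incl,
                                        cont_reliable):
            if rng.random() < incl * depress:
                _emit_rows(rng, cfg, bait_rows, rep, pid, peps, reliable=bool(rel))

    control_rows: list = []
    for rep in control_reps:
        for pid, peps, incl, rel in zip(contaminant_ids, cont_peps, cont_incl,
                                        cont_reliable):
            if rng.random() < incl:
                _emit_rows(rng, cfg, control_rows, rep, pid, peps, reliable=bool(rel))

    columns = ["replicate_id", "protein_id", "peptide_seq", "score", "probability",
               "spectral_count"]
    bait_ev = pd.DataFrame(bait_rows, columns=columns)
    control_ev = pd.DataFrame(control_rows, columns=columns)
    if bait_ev.empty or control_ev.empty:
        raise ValidationError("configuration generated an empty experiment; "
                              "increase inclusion probabilities or replicate counts")
    bait = ExperimentSet(role="bait", bait_id="BAIT", replicate_ids=bait_reps,
                         evidence=bait_ev)
    control = ExperimentSet(role="control", bait_id="", replicate_ids=control_reps,
                            evidence=control_ev)
    truth = TruthLabels(specific_ids=frozenset(specific_ids),
                        contaminant_ids=frozenset(contaminant_ids),
                        outlier_replicates=frozenset(outliers))
    return bait, control, truth


def evaluate_against_truth(result_proteins, reproducible_replicates,
                           truth: TruthLabels) -> dict:
    """Precision/recall of specific-prey recovery and outlier exclusion.

    Precision is reported as NaN for an empty selection; the
    outlier-exclusion rate is NaN when no outliers were planted.
    """
    selected = set(getattr(result_proteins, "proteins", result_proteins))
    f_set = set(reproducible_replicates)
    tp = len(selected & truth.specific_ids)
    fp = len(selected - truth.specific_ids)
    fn = len(truth.specific_ids - selected)
    n_out = len(truth.outlier_replicates)
    excluded = len(truth.outlier_replicates - f_set)
    return {
        "tp": tp, "fp": fp, "fn": fn,
        "precision": tp / (tp + fp) if selected else float("nan"),
        "recall": tp / (tp + fn) if (tp + fn) else float("nan"),
        "n_outliers": n_out,
        "n_outliers_excluded": excluded,
        "outlier_exclusion_rate": excluded / n_out if n_out else float("nan"),
    }
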