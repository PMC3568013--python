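"""Shared fixtures: tiny hand-built experiment sets and toy ontologies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import apmscreen as aps

COLUMNS = ["replicate_id", "protein_id", "peptide_seq", "score", "probability",
           "spectral_count"]


def evidence_frame(rows) -> pd.DataFrame:
    """Rows of (replicate, protein, peptide, score[, probability[, count]])."""
    full = []
    for r in rows:
        r = list(r) + [None] * (6 - len(r))
        full.append(r)
    df = pd.DataFrame(full, columns=COLUMNS)
    df["score"] = df["score"].astype(float)
    df["probability"] = pd.to_numeric(df["probability"])
    return df


def make_expset(pattern: dict, n_replicates: int, role: str = "bait",
                bait_id: str = "", score=50.0) -> aps.ExperimentSet:
    """Build an experiment set from ``protein -> replicate indices`` (or
    ``protein -> {replicate index: score}``)."""
    replicate_ids = [f"R{i}" for i in range(n_replicates)]
    rows = []
    for protein, reps in pattern.items():
        items = reps.items() if isinstance(reps, dict) else ((r, score) for r in reps)
        for r, s in items:
            rows.append((f"R{r}", protein, "PEPTIDEK", float(s), None, 1))
    return aps.ExperimentSet(role=role, bait_id=bait_id, replicate_ids=replicate_ids,
                             evidence=evidence_frame(rows))


@pytest.fixture
def table2_expset() -> aps.ExperimentSet:
    """Nine-replicate bait set with the occurrence pattern 8x(9/9), 1x(8/9),
    2x(7/9), arranged so the reproducible replicates number exactly five."""
    pattern = {f"P{i:02d}": set(range(9)) for i in range(8)}
    pattern["P08"] = set(range(9)) - {0}
    pattern["P09"] = set(range(9)) - {0, 1}
    pattern["P10"] = set(range(9)) - {2, 3}
    return make_expset(pattern, 9)


@pytest.fixture
def chain_ontology(tmp_path):
    """root -> a -> b chain with annotations p1:b, p2:a, p3:root."""
    edges = tmp_path / "edges.tsv"
    edges.write_text("a\troot\nb\ta\n")
    ann = tmp_path / "ann.tsv"
    ann.write_text("p1\tb\tMF\np2\ta\tMF\np3\troot\tMF\n")
    return aps.read_ontology(edges, ann)


def write_branching_ontology(tmp_path):
    """Two branches under root with term-rich annotations for similarity tests."""
    edges = tmp_path / "bedges.tsv"
    edges.write_text(
        "left\troot\nright\troot\n"
        "l1\tleft\nl2\tleft\nl1a\tl1\n"
        "r1\tright\nr2\tright\n"
    )
    ann = tmp_path / "bann.tsv"
    ann.write_text("\n".join([
        "pA\tl1a\tMF", "pA\tl2\tMF",
        "pB\tl1\tMF", "pB\tl1a\tMF",
        "pC\tr1\tMF", "pD\tr2\tMF",
        "pE\tleft\tMF", "pF\troot\tMF",
        "pG\tl1\tBP",
    ]) + "\n")
    return aps.read_ontology(edges, ann)


def toy_ontology_for_truth(truth: aps.TruthLabels, tmp_path) -> aps.Ontology:
    """Synthetic-run ontology: bait and planted preys share a deep complex
    term; contaminants are annotated to unrelated background branches."""
    edges = tmp_path / "sedges.tsv"
    edges.write_text(
        "binding\troot\ncomplex_assembly\tbinding\nbait_complex\tcomplex_assembly\n"
        "background\troot\nstructural\tbackground\nmetabolic\tbackground\n"
    )
    lines = ["BAIT\tbait_complex\tMF"]
    for p in sorted(truth.specific_ids):
        lines.append(f"{p}\tbait_complex\tMF")
    for i, p in enumerate(sorted(truth.contaminant_ids)):
        lines.append(f"{p}\t{'structural' if i % 2 else 'metabolic'}\tMF")
    ann = tmp_path / "sann.tsv"
    ann.write_text("\n".join(lines) + "\n")
    return aps.read_ontology(edges, ann)


def random_presence_expset(rng: np.random.Generator, n_proteins: int = 20,
                           n_replicates: int = 5) -> aps.ExperimentSet:
    """Random fixture: each protein present in a random replicate subset with
    random peptide scores (possibly several peptides per occurrence)."""
    rows = []
    for j in range(n_proteins):
        protein = f"P{j:03d}"
        present = rng.random(n_replicates) < rng.uniform(0.2, 0.9)
        if not present.any():
            present[rng.integers(n_replicates)] = True
        for k in np.nonzero(present)[0]:
            for _ in range(rng.integers(1, 3)):
                rows.append((f"R{k}", protein, "PEPTIDEK",
                             float(rng.uniform(10, 100)), None, 1))
    return aps.ExperimentSet(role="bait", bait_id="",
                             replicate_ids=[f"R{i}" for i in range(n_replicates)],
                             evidence=evidence_frame(rows))
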