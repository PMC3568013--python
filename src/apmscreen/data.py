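"""Domain types and readers/writers for AP-MS peptide-evidence tables.

The atomic record is one identified peptide occurrence in one experimental
replicate (a row of a tab-separated evidence table).  Replicated bait or
control purifications are grouped into an :class:`ExperimentSet`.  Protein
identity is the accession string verbatim; no isoform collapsing is done.

Evidence tables are TSV with a header.  Required columns:
``replicate_id``, ``protein_id``, ``peptide_seq``, ``score``.  Optional:
``probability`` (peptide identification probability in [0, 1]) and
``spectral_count``.  Extra columns are ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

REQUIRED_COLUMNS = ("replicate_id", "protein_id", "peptide_seq", "score")
OPTIONAL_COLUMNS = ("probability", "spectral_count")

#: procedural stages: N (naive), P (prefiltered), Q (indicator candidates),
#: R (reproducible), S (specific)
STAGES = ("N", "P", "Q", "R", "S")


@dataclass(frozen=True)
class PeptideEvidence:
    """One identified peptide occurrence in one replicate."""

    replicate_id: str
    protein_id: str
    peptide_seq: str
    score: float
    probability: float | None = None
    spectral_count: int | None = None

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValidationError(f"negative identification score: {self.score}")
        if self.probability is not None and not (0.0 <= self.probability <= 1.0):
            raise ValidationError(f"probability outside [0, 1]: {self.probability}")
        if not self.peptide_seq:
            raise ValidationError("empty peptide sequence")


@dataclass
class ExperimentSet:
    """A bait or control collection of K uniquely identified replicates.

    ``evidence`` is a DataFrame with the evidence-table columns; duplicate
    (replicate, protein, peptide) rows are kept as distinct spectra.
    """

    role: str  # "bait" or "control"
    bait_id: str
    replicate_ids: list[str]
    evidence: pd.DataFrame

    def __post_init__(self) -> None:
        if self.role not in ("bait", "control"):
            raise ValidationError(f"role must be 'bait' or 'control', got {self.role!r}")
        if len(self.replicate_ids) < 1:
            raise ValidationError("an experiment set needs at least one replicate (K >= 1)")
        if len(set(self.replicate_ids)) != len(self.replicate_ids):
            raise ValidationError("replicate ids are not unique")
        known = set(self.replicate_ids)
        stray = set(self.evidence["replicate_id"].astype(str)) - known
        if stray:
            raise ValidationError(f"evidence references unknown replicates: {sorted(stray)}")

    @property
    def k(self) -> int:
        """Number of experimental replicates K."""
        return len(self.replicate_ids)

    @property
    def protein_ids(self) -> frozenset[str]:
        """Distinct proteins identified anywhere in the set (stage N universe)."""
        return frozenset(self.evidence["protein_id"])

    def stage_n(self) -> "ProteinStageSet":
        return ProteinStageSet(stage="N", protein_ids=self.protein_ids)


@dataclass(frozen=True)
class ProteinStageSet:
    """A set of proteins labelled with its procedural stage."""

    stage: str
    protein_ids: frozenset[str]

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(f"unknown stage {self.stage!r}; expected one of {STAGES}")
        object.__setattr__(self, "protein_ids", frozenset(self.protein_ids))

    @property
    def cardinality(self) -> int:
        return len(self.protein_ids)

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.protein_ids

    def __len__(self) -> int:
        return self.cardinality


@dataclass
class ScoreList:
    """An externally scored, ordered protein list (e.g. another scorer's output)."""

    method: str
    entries: pd.DataFrame  # columns: protein_id, score
    is_posterior: bool = False

    def __post_init__(self) -> None:
        if self.is_posterior:
            s = self.entries["score"].to_numpy(float)
            if np.any((s < 0) | (s > 1)):
                raise ValidationError(f"{self.method}: posterior probabilities outside [0, 1]")


def _require_columns(df: pd.DataFrame, required: Iterable[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")


def read_evidence_table(path: str | Path, role: str, bait_id: str = "") -> ExperimentSet:
    """Read a TSV evidence table into an :class:`ExperimentSet`.

    Replicate ids are taken in file order of first appearance.  Rows failing
    validation are reported with their file row number (header = row 1).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"evidence table not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"replicate_id": str, "protein_id": str,
                                            "peptide_seq": str})
    _require_columns(df, REQUIRED_COLUMNS, path)
    if len(df) == 0:
        raise ValidationError(f"{path}: no evidence rows")
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)].copy()
    df["score"] = pd.to_numeric(df["score"])
    df["probability"] = pd.to_numeric(df["probability"])

    bad = df.index[df["score"] < 0]
    if len(bad):
        raise ValidationError(f"{path}: negative score at row {bad[0] + 2}")
    prob = df["probability"]
    bad = df.index[prob.notna() & ((prob < 0) | (prob > 1))]
    if len(bad):
        raise ValidationError(f"{path}: probability outside [0, 1] at row {bad[0] + 2}")
    bad = df.index[df["peptide_seq"].isna() | (df["peptide_seq"].astype(str) == "")]
    if len(bad):
        raise ValidationError(f"{path}: empty peptide sequence at row {bad[0] + 2}")

    replicate_ids = list(dict.fromkeys(df["replicate_id"]))
    return ExperimentSet(role=role, bait_id=bait_id, replicate_ids=replicate_ids, evidence=df)


def write_evidence_table(expset: ExperimentSet, path: str | Path) -> None:
    """Write an evidence table as TSV (round-trips through :func:`read_evidence_table`)."""
    expset.evidence.to_csv(path, sep="\t", index=False)


def read_score_list(path: str | Path, method: str = "", is_posterior: bool = False) -> ScoreList:
    """Read a 2-column TSV (protein_id, score) external score list."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"score list not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    _require_columns(df, ("protein_id", "score"), path)
    df["score"] = pd.to_numeric(df["score"])
    return ScoreList(method=method or path.stem, entries=df, is_posterior=is_posterior)


def write_results(tables: Mapping[str, pd.DataFrame], summary: Mapping,
                  out_dir: str | Path) -> list[str]:
    """Write result tables as TSV plus a JSON run summary; return the file manifest.

    ``tables`` maps a basename (without extension) to a DataFrame; each is
    written as ``<name>.tsv``.  The summary (thresholds, cutoffs, seeds,
    stage counts) is written as ``summary.json``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        manifest: list[str] = []
        for name, df in tables.items():
            p = out_dir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            manifest.append(str(p))
        p = out_dir / "summary.json"
        with open(p, "w") as fh:
            json.dump(_jsonable(summary), fh, indent=2, sort_keys=True)
        manifest.append(str(p))
    except OSError as exc:
        raise OSError(f"cannot write results under {out_dir}: {exc}") from exc
    return sorted(manifest)


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
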