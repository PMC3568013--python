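"""Toy-scale ontology handling and Resnik semantic similarity.

An ontology is a DAG of terms (child -> parent ``is_a`` edges, as a 2-column
TSV edge list) plus a protein annotation table (3-column TSV: protein, term,
aspect).  The information content of a term is computed from the annotation
corpus supplied with the ontology:

    IC(c) = -log( n(c) / n(root corpus) )

where ``n(c)`` counts distinct proteins annotated to ``c`` or any of its
descendants.  The root(s) thereby carry IC = 0 and IC is non-increasing
along child -> ancestor paths.  Real GO corpora plug in through the same
two files; nothing here downloads or parses OBO.

The Resnik similarity of two terms is the IC of their most informative
common ancestor (MICA), where each term counts among its own ancestors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

ASPECTS = ("BP", "MF", "CC")


@dataclass
class Ontology:
    """Term DAG with annotations and corpus-derived information content."""

    graph: nx.DiGraph  # edges child -> parent
    annotations: dict[str, dict[str, frozenset[str]]]  # protein -> aspect -> terms
    ic: dict[str, float]
    _ancestors: dict[str, frozenset[str]] = field(default_factory=dict, repr=False)

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    def ancestors(self, term: str) -> frozenset[str]:
        """Reflexive ancestor closure of ``term`` (includes the term itself)."""
        if term not in self.graph:
            raise ValidationError(f"unknown ontology term: {term}")
        cached = self._ancestors.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self.graph, term)) | {term}
            self._ancestors[term] = cached
        return cached

    def terms_for(self, protein_id: str, aspect: str) -> frozenset[str]:
        if aspect not in ASPECTS:
            raise ValidationError(f"unknown aspect {aspect!r}; expected one of {ASPECTS}")
        return self.annotations.get(protein_id, {}).get(aspect, frozenset())


def read_ontology(edges_path: str | Path, annotations_path: str | Path) -> Ontology:
    """Build an :class:`Ontology` from an edge list and an annotation table.

    The edge file is a headerless 2-column TSV ``child<TAB>parent``; the
    annotation file a headerless 3-column TSV ``protein<TAB>term<TAB>aspect``.
    """
    edges_path, annotations_path = Path(edges_path), Path(annotations_path)
    edges = pd.read_csv(edges_path, sep="\t", header=None, names=["child", "parent"],
                        dtype=str)
    graph = nx.DiGraph()
    graph.add_edges_from(edges.itertuples(index=False, name=None))
    if not nx.is_directed_acyclic_graph(graph):
        cycle = nx.find_cycle(graph)
        raise FormatError(f"{edges_path}: ontology edges contain a cycle: {cycle}")

    ann = pd.read_csv(annotations_path, sep="\t", header=None,
                      names=["protein", "term", "aspect"], dtype=str)
    unknown = set(ann["term"]) - set(graph.nodes)
    if unknown:
        raise ValidationError(
            f"{annotations_path}: annotation to unknown term(s): {sorted(unknown)}")
    bad_aspect = set(ann["aspect"]) - set(ASPECTS)
    if bad_aspect:
        raise ValidationError(
            f"{annotations_path}: unknown aspect(s): {sorted(bad_aspect)}")

    annotations: dict[str, dict[str, set[str]]] = {}
    for protein, term, aspect in ann.itertuples(index=False, name=None):
        annotations.setdefault(protein, {}).setdefault(aspect, set()).add(term)
    frozen = {p: {a: frozenset(ts) for a, ts in d.items()} for p, d in annotations.items()}

    ont = Ontology(graph=graph, annotations=frozen, ic={})
    ont.ic = _information_content(ont, ann)
    return ont


def _information_content(ont: Ontology, ann: pd.DataFrame) -> dict[str, float]:
    # descendant-closure counts: a protein annotated to c supports c and every
    # ancestor of c; counts are distinct proteins per term.
    supporters: dict[str, set[str]] = {}
    for protein, term in ann[["protein", "term"]].itertuples(index=False, name=None):
        for anc in ont.ancestors(term):
            supporters.setdefault(anc, set()).add(protein)
    total = ann["protein"].nunique()
    return {t: -np.log(len(s) / total) for t, s in supporters.items()}


def resnik_term_similarity(ont: Ontology, c1: str, c2: str) -> float:
    """IC of the most informative common ancestor of two terms.

    Each term subsumes itself, so ``sim(c, c) = IC(c)``.  Terms whose only
    common ancestry is the root score 0.
    """
    common = ont.ancestors(c1) & ont.ancestors(c2)
    ics = [ont.ic[t] for t in common if t in ont.ic]
    return max(ics, default=0.0)


def bait_prey_similarity(ont: Ontology, bait: str, prey: str, aspect: str) -> float | None:
    """Max-pair Resnik similarity between bait and prey annotation terms.

    Returns ``None`` (missing) if either protein is unannotated in the aspect.
    """
    tb = ont.terms_for(bait, aspect)
    tp = ont.terms_for(prey, aspect)
    if not tb or not tp:
        return None
    return max(resnik_term_similarity(ont, a, b) for a in tb for b in tp)


def _pair_similarity_normalized(ont: Ontology, t1: str, t2: str) -> float:
    """Resnik similarity normalized per pair into [0, 1].

    The MICA's IC is scaled by the larger of the two terms' ICs, so a term is
    maximally (1.0) similar to itself and root-only common ancestry scores 0.
    """
    mica = resnik_term_similarity(ont, t1, t2)
    denom = max(ont.ic.get(t1, 0.0), ont.ic.get(t2, 0.0))
    if denom == 0.0:
        return 1.0 if t1 == t2 else 0.0
    return mica / denom


def list_semantic_similarity(ont: Ontology, list1, list2, aspect: str) -> float | None:
    """Best-match-average semantic similarity between two protein lists in [0, 1].

    The two lists' annotation term sets are pooled per list; each term is
    matched to its best (pairwise-normalized Resnik) partner on the other
    side and the matches are averaged over both directions.  Symmetric;
    identical lists score 1.  Returns ``None`` if either list carries no
    annotation in the aspect.
    """
    if not list1 or not list2:
        raise ValidationError("both protein lists must be non-empty")
    t1 = frozenset().union(*(ont.terms_for(p, aspect) for p in list1))
    t2 = frozenset().union(*(ont.terms_for(p, aspect) for p in list2))
    if not t1 or not t2:
        return None
    sim = {(a, b): _pair_similarity_normalized(ont, a, b) for a in t1 for b in t2}
    fwd = [max(sim[(a, b)] for b in t2) for a in t1]
    rev = [max(sim[(a, b)] for a in t1) for b in t2]
    return (sum(fwd) + sum(rev)) / (len(t1) + len(t2))
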