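"""Equivalence axioms that let subsumption cross species boundaries.

Two sources: (1) Uberon cross-references onto species anatomy ontologies
(ZFA, MA, FMA), excluding Uberon's very general ``upper_level`` classes;
(2) lexical alignment of phenotype labels between two pre-composed
ontologies (the HP/MP alignment mechanism).  Both are pure functions of
the input graphs — deterministic and order-independent.
"""
from __future__ import annotations

import re
from dataclasses import dataclass

from .ontology_core import OntologyGraph, curie_prefix

PROVENANCE_UBERON_XREF = "uberon_xref"
PROVENANCE_LEXICAL = "lexical"
PROVENANCE_ASSERTED = "asserted"

DEFAULT_BRIDGE_PREFIXES = frozenset({"ZFA", "MA", "FMA"})
UPPER_LEVEL_SUBSET = "upper_level"

_PUNCT_RE = re.compile(r"[^\w\s]")


@dataclass(frozen=True)
class EquivalenceAxiom:
    left: str
    right: str
    provenance: str = PROVENANCE_ASSERTED

    def __post_init__(self):
        if self.left == self.right:
            raise ValueError(f"self-equivalence: {self.left}")

    def unordered(self) -> tuple[str, str]:
        return tuple(sorted((self.left, self.right)))


def build_uberon_bridge(uberon: OntologyGraph,
                        target_prefixes=DEFAULT_BRIDGE_PREFIXES) -> list[EquivalenceAxiom]:
    """One axiom per (Uberon class, xref) with a species-anatomy prefix.

    Only xrefs declared on the Uberon class are used, and classes in the
    ``upper_level`` subset (very general terms such as "tissue") are
    excluded from bridging.
    """
    axioms: list[EquivalenceAxiom] = []
    seen: set[tuple[str, str]] = set()
    for curie in sorted(uberon.classes):
        if UPPER_LEVEL_SUBSET in uberon.subset_membership.get(curie, ()):
            continue
        for xref in sorted(uberon.xref_map.get(curie, ())):
            if curie_prefix(xref) not in target_prefixes or xref == curie:
                continue
            key = tuple(sorted((curie, xref)))
            if key in seen:
                continue
            seen.add(key)
            axioms.append(EquivalenceAxiom(curie, xref, PROVENANCE_UBERON_XREF))
    return axioms


def normalize_label(label: str) -> str:
    """Lowercase, strip punctuation, collapse whitespace."""
    return " ".join(_PUNCT_RE.sub(" ", label.lower()).split())


def _label_index(graph: OntologyGraph, include_synonyms: bool) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for curie in sorted(graph.classes):
        texts = []
        if graph.labels.get(curie):
            texts.append(graph.labels[curie])
        if include_synonyms:
            texts.extend(sorted(graph.synonym_map.get(curie, ())))
        for text in texts:
            norm = normalize_label(text)
            if norm:
                index.setdefault(norm, set()).add(curie)
    return index


def lexical_align(left_onto: OntologyGraph, right_onto: OntologyGraph,
                  include_synonyms: bool = False) -> list[EquivalenceAxiom]:
    """Exact-label equivalences between two ontologies.

    A normalized label matching more than one class on either side yields
    no axiom (ambiguity guard), and classes sharing an ontology prefix are
    never linked.
    """
    left_idx = _label_index(left_onto, include_synonyms)
    right_idx = _label_index(right_onto, include_synonyms)
    axioms: list[EquivalenceAxiom] = []
    for norm in sorted(set(left_idx) & set(right_idx)):
        lefts, rights = left_idx[norm], right_idx[norm]
        if len(lefts) != 1 or len(rights) != 1:
            continue
        (l,), (r,) = lefts, rights
        if l == r or curie_prefix(l) == curie_prefix(r):
            continue
        axioms.append(EquivalenceAxiom(l, r, PROVENANCE_LEXICAL))
    return axioms


def write_axioms_tsv(axioms, path) -> None:
    with open(path, "w") as fh:
        for ax in sorted(axioms, key=lambda a: (a.left, a.right, a.provenance)):
            fh.write(f"{ax.left}\t{ax.right}\t{ax.provenance}\n")


def read_axioms_tsv(path) -> list[EquivalenceAxiom]:
    axioms = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            left, right, provenance = line.split("\t")
            axioms.append(EquivalenceAxiom(left, right, provenance))
    return axioms
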