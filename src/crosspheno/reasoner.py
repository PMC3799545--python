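"""Structural subsumption over EQ definitions — the classification step.

Phenotype classes are class expressions of the shape
``has_part some (Q and inheres_in some E and towards some T and
qualifier some abnormal)``.  Because every phenotype class shares the
``has_part`` wrapper, pairwise subsumption in this fragment reduces to
componentwise entailment over the merged building-block closure:

* quality(a) must be subsumed by quality(b) (mandatory);
* an absent slot on the subsumer is entailed by anything (existential
  semantics: fewer conjuncts = more general);
* a present slot on the subsumer needs the corresponding slot on the
  subsumee, subsumed under the merged closure — bearer entities optionally
  via is_a+part_of reachability, everything else via is_a only;
* every extra differentia of the subsumer must be entailed by some extra
  differentia of the subsumee under the same relation kind.

Classification is pairwise O(n^2) with the cheap quality check first; the
EQ fragment has no role chains, so this is complete for the fragment and
trivially checkable against a brute-force oracle.  Asserted is_a edges
inside the pre-composed ontologies and asserted (e.g. lexical) equivalences
are unioned with the inferred pairs, then everything is transitively
closed; equivalence groups are the strongly connected components.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .eq_model import EQDefinition, REL_INHERES_IN
from .ontology_core import ENTITY_MODE_IS_A, OntologyGraph, SubclassClosure
from .reports import BuildReport


@dataclass(frozen=True)
class SubsumptionResult:
    """Transitively closed subclass relation plus its equivalence partition."""

    subclass_pairs: frozenset
    equivalence_groups: tuple

    def is_subclass_of(self, a: str, b: str) -> bool:
        return (a, b) in self.subclass_pairs

    def group_of(self, curie: str) -> frozenset:
        for g in self.equivalence_groups:
            if curie in g:
                return g
        raise KeyError(f"unknown phenotype class: {curie}")


def _entails(a: str, b: str, closure: SubclassClosure, mode: str,
             report: BuildReport | None) -> bool:
    """a ⊑ b under the merged closure; unknown classes entail only themselves."""
    if a == b:
        return True
    missing = [c for c in (a, b) if not closure.has_class(c)]
    if missing:
        if report is not None:
            for c in missing:
                report.skip_once("reasoner.unknown_classes", c,
                                 "not in merged closure; treated as entailing only itself")
        return False
    return closure.is_subclass_of(a, b, mode)


def eq_subsumes(a: EQDefinition, b: EQDefinition, closure: SubclassClosure,
                entity_mode: str = ENTITY_MODE_IS_A,
                report: BuildReport | None = None) -> bool:
    """True iff definition ``a`` is structurally subsumed by definition ``b``."""
    # quality first: mandatory on both sides and the cheapest rejection
    if not _entails(a.quality, b.quality, closure, ENTITY_MODE_IS_A, report):
        return False
    if b.bearer is not None:
        if a.bearer is None or not _entails(a.bearer, b.bearer, closure,
                                            entity_mode, report):
            return False
    if b.towards is not None:
        if a.towards is None or not _entails(a.towards, b.towards, closure,
                                             ENTITY_MODE_IS_A, report):
            return False
    if b.qualifier is not None:
        if a.qualifier is None or not _entails(a.qualifier, b.qualifier, closure,
                                               ENTITY_MODE_IS_A, report):
            return False
    for rel_b, filler_b in b.extra_entities:
        mode = entity_mode if rel_b == REL_INHERES_IN else ENTITY_MODE_IS_A
        if not any(rel_a == rel_b and _entails(filler_a, filler_b, closure,
                                               mode, report)
                   for rel_a, filler_a in a.extra_entities):
            return False
    return True


def classify(defs, asserted_graph: OntologyGraph, closure: SubclassClosure,
             asserted_equivalences=(), entity_mode: str = ENTITY_MODE_IS_A,
             report: BuildReport | None = None) -> SubsumptionResult:
    """Classify all phenotype classes.

    ``defs`` carry the logical definitions (at most one per class);
    ``asserted_graph`` holds every phenotype class — defined or not — with
    the asserted is_a edges of its home ontology.  Undefined classes
    participate only through those asserted edges.  Asserted equivalences
    (e.g. lexical HP/MP alignments) contribute both subclass directions.
    """
    by_class: dict[str, EQDefinition] = {}
    for d in defs:
        if d.defined_class in by_class:
            raise ValueError(f"multiple definitions for {d.defined_class}")
        by_class[d.defined_class] = d

    nodes = set(asserted_graph.classes) | set(by_class)
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for child, parent in asserted_graph.is_a_edges:
        if child in nodes and parent in nodes:
            g.add_edge(child, parent)
    for ax in asserted_equivalences:
        if ax.left in nodes and ax.right in nodes:
            g.add_edge(ax.left, ax.right)
            g.add_edge(ax.right, ax.left)
        elif report is not None:
            report.skip_once("reasoner.skipped_equivalences",
                             f"{ax.left}={ax.right}", "class not under classification")

    ordered = sorted(by_class)
    for ca in ordered:
        da = by_class[ca]
        for cb in ordered:
            if ca == cb:
                continue
            if eq_subsumes(da, by_class[cb], closure, entity_mode, report):
                g.add_edge(ca, cb)

    pairs: set[tuple[str, str]] = set()
    for n in nodes:
        pairs.add((n, n))
        for m in nx.descendants(g, n):
            pairs.add((n, m))
    groups = tuple(sorted((frozenset(s) for s in nx.strongly_connected_components(g)),
                          key=lambda s: min(s)))
    return SubsumptionResult(subclass_pairs=frozenset(pairs),
                             equivalence_groups=groups)


def write_subclass_pairs(result: SubsumptionResult, path) -> None:
    """Debug dump of the non-reflexive subclass pairs."""
    with open(path, "w") as fh:
        for a, b in sorted(result.subclass_pairs):
            if a != b:
                fh.write(f"{a}\t{b}\n")
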