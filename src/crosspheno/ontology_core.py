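"""In-memory multi-ontology graph and its reflexive-transitive subclass closure.

This is the substrate every reasoning step runs on: the asserted class
hierarchies of all building-block ontologies (PATO, ChEBI, GO, anatomy
ontologies, Uberon) plus the bridging equivalences that let subsumption
cross species boundaries.

``part_of`` edges are stored but NOT folded into the subclass closure by
default; the ``is_a+part_of`` entity mode exposes the liberal reading
(is_a union part_of reachability) for bearer-entity subsumption only.
Cycles created solely by asserted equivalences are contracted silently;
any remaining is_a cycle aborts the build.
"""
from __future__ import annotations

import networkx as nx

from .reports import BuildReport

ENTITY_MODE_IS_A = "is_a"
ENTITY_MODE_IS_A_PART_OF = "is_a+part_of"
ENTITY_MODES = (ENTITY_MODE_IS_A, ENTITY_MODE_IS_A_PART_OF)


class OntologyCycleError(ValueError):
    """An is_a cycle among non-equivalent classes."""


def curie_prefix(curie: str) -> str:
    return curie.split(":", 1)[0]


class OntologyGraph:
    """A DAG of named classes with is_a/part_of edges, xrefs and subsets."""

    def __init__(self):
        self.labels: dict[str, str | None] = {}
        self.is_a_edges: set[tuple[str, str]] = set()
        self.part_of_edges: set[tuple[str, str]] = set()
        self.subset_membership: dict[str, set[str]] = {}
        self.xref_map: dict[str, set[str]] = {}
        self.synonym_map: dict[str, set[str]] = {}  # EXACT synonyms only
        self.merged_equivalences: set[tuple[str, str]] = set()

    # -- construction -------------------------------------------------
    def add_class(self, curie: str, label: str | None = None) -> None:
        if curie not in self.labels or self.labels[curie] is None:
            self.labels[curie] = label
        elif label is not None and self.labels[curie] is None:
            self.labels[curie] = label

    def add_is_a(self, child: str, parent: str) -> None:
        self.add_class(child)
        self.add_class(parent)
        self.is_a_edges.add((child, parent))

    def add_part_of(self, part: str, whole: str) -> None:
        self.add_class(part)
        self.add_class(whole)
        self.part_of_edges.add((part, whole))

    def add_subset(self, curie: str, subset: str) -> None:
        self.subset_membership.setdefault(curie, set()).add(subset)

    def add_xref(self, curie: str, xref: str) -> None:
        self.xref_map.setdefault(curie, set()).add(xref)

    def add_synonym(self, curie: str, text: str) -> None:
        self.synonym_map.setdefault(curie, set()).add(text)

    def add_equivalence(self, a: str, b: str) -> None:
        if a != b:
            self.merged_equivalences.add(tuple(sorted((a, b))))

    @property
    def classes(self) -> set[str]:
        return set(self.labels)

    def __contains__(self, curie: str) -> bool:
        return curie in self.labels

    @classmethod
    def from_obo(cls, doc, part_of_relations=frozenset({"part_of", "BFO:0000050"})):
        """Build a graph from an :class:`~crosspheno.obo_io.OboDocument`.

        Obsolete terms are skipped entirely; only relationships named in
        ``part_of_relations`` become part_of edges, everything else is
        ignored at graph level.
        """
        g = cls()
        for st in doc.stanzas:
            if st.is_obsolete:
                continue
            g.add_class(st.id, st.name)
            for p in st.is_a:
                g.add_is_a(st.id, p)
            for rel, filler in st.relationships:
                if rel in part_of_relations:
                    g.add_part_of(st.id, filler)
            for s in st.subsets:
                g.add_subset(st.id, s)
            for x in st.xrefs:
                g.add_xref(st.id, x)
            for text, scope in st.synonyms:
                if scope == "EXACT":
                    g.add_synonym(st.id, text)
        return g

    def subclass_closure(self) -> "SubclassClosure":
        return SubclassClosure(self)


class SubclassClosure:
    """Queryable reflexive-transitive subclass relation over a graph.

    Equivalent classes (``merged_equivalences``) are contracted into one
    group and are mutually substitutable.  Queries are memoized per
    representative, so repeated lookups are O(1) after the first.
    """

    def __init__(self, graph: OntologyGraph):
        self._graph = graph
        parent: dict[str, str] = {c: c for c in graph.labels}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in sorted(graph.merged_equivalences):
            if a in parent and b in parent:
                ra, rb = find(a), find(b)
                if ra != rb:
                    # deterministic representative: lexicographically smallest
                    lo, hi = sorted((ra, rb))
                    parent[hi] = lo
        self._rep = {c: find(c) for c in parent}
        self._members: dict[str, set[str]] = {}
        for c, r in self._rep.items():
            self._members.setdefault(r, set()).add(c)

        g_isa = nx.DiGraph()
        g_isa.add_nodes_from(self._members)
        for child, par in graph.is_a_edges:
            rc, rp = self._rep[child], self._rep[par]
            if rc != rp:
                g_isa.add_edge(rc, rp)
        if not nx.is_directed_acyclic_graph(g_isa):
            cycle = nx.find_cycle(g_isa)
            raise OntologyCycleError(
                "is_a cycle among non-equivalent classes: "
                + " -> ".join(e[0] for e in cycle)
            )
        g_both = g_isa.copy()
        for part, whole in graph.part_of_edges:
            rc, rp = self._rep[part], self._rep[whole]
            if rc != rp:
                g_both.add_edge(rc, rp)
        self._g = {ENTITY_MODE_IS_A: g_isa, ENTITY_MODE_IS_A_PART_OF: g_both}
        self._cache: dict[str, dict[str, frozenset]] = {m: {} for m in ENTITY_MODES}

    def rep(self, curie: str) -> str:
        try:
            return self._rep[curie]
        except KeyError:
            raise KeyError(f"unknown class: {curie}") from None

    def has_class(self, curie: str) -> bool:
        return curie in self._rep

    def _reach(self, r: str, mode: str) -> frozenset:
        cache = self._cache[mode]
        if r not in cache:
            cache[r] = frozenset(nx.descendants(self._g[mode], r)) | {r}
        return cache[r]

    def ancestors(self, curie: str, mode: str = ENTITY_MODE_IS_A) -> set[str]:
        """All classes subsuming ``curie`` (including itself and equivalents)."""
        reach = self._reach(self.rep(curie), mode)
        out: set[str] = set()
        for r in reach:
            out |= self._members[r]
        return out

    def is_subclass_of(self, a: str, b: str, mode: str = ENTITY_MODE_IS_A) -> bool:
        if mode not in self._g:
            raise ValueError(f"unknown entity mode: {mode}")
        ra, rb = self.rep(a), self.rep(b)
        return ra == rb or rb in self._reach(ra, mode)

    def equivalent(self, a: str, b: str) -> bool:
        return self.rep(a) == self.rep(b)


def merge_graphs(graphs, equivalences=(), report: BuildReport | None = None) -> OntologyGraph:
    """Union a list of graphs and record bridging equivalences on the result.

    An equivalence axiom referencing a class absent from the union is
    skipped with a report entry (not a hard error) — real bridge files
    routinely mention classes from ontology versions not loaded.
    """
    merged = OntologyGraph()
    for g in graphs:
        for c in sorted(g.labels):
            merged.add_class(c, g.labels[c])
        merged.is_a_edges |= g.is_a_edges
        merged.part_of_edges |= g.part_of_edges
        for c, subs in g.subset_membership.items():
            for s in subs:
                merged.add_subset(c, s)
        for c, xs in g.xref_map.items():
            for x in xs:
                merged.add_xref(c, x)
        for c, syns in g.synonym_map.items():
            for s in syns:
                merged.add_synonym(c, s)
        merged.merged_equivalences |= g.merged_equivalences
    for ax in equivalences:
        left, right = ax.left, ax.right
        if left not in merged.labels or right not in merged.labels:
            if report is not None:
                missing = left if left not in merged.labels else right
                report.skip("merge.skipped_equivalences", f"{left}={right}",
                            f"unknown class {missing}")
            continue
        merged.add_equivalence(left, right)
    return merged
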