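"""Independent brute-force oracles and random-case generators for the tests.

Everything here is deliberately re-implemented from first principles —
plain DFS reachability, Floyd-Warshall transitive closure, mutual-
reachability partitioning, direct enumeration of the structural-
subsumption conditions — so the oracles share no code path with the
package implementation they check.
"""
from __future__ import annotations

import random
import string

from crosspheno.bridging import EquivalenceAxiom
from crosspheno.eq_model import EQDefinition, PATO_ABNORMAL, REL_INHERES_IN
from crosspheno.obo_io import OboDocument, TermStanza
from crosspheno.ontology_core import OntologyGraph


# ---------------------------------------------------------------------------
# reachability with equivalence contraction, written independently
# ---------------------------------------------------------------------------

def oracle_groups(nodes, equiv_pairs):
    """Merge nodes into equivalence groups by naive repeated unioning."""
    group_of = {n: frozenset([n]) for n in nodes}
    changed = True
    while changed:
        changed = False
        for a, b in equiv_pairs:
            if a in group_of and b in group_of and group_of[a] != group_of[b]:
                merged = group_of[a] | group_of[b]
                for m in merged:
                    group_of[m] = merged
                changed = True
    return group_of


def oracle_reachability(graph: OntologyGraph, mode: str):
    """node -> set of reachable nodes (reflexive), via plain DFS."""
    nodes = set(graph.labels)
    group_of = oracle_groups(nodes, graph.merged_equivalences)
    edges = set(graph.is_a_edges)
    if mode == "is_a+part_of":
        edges |= graph.part_of_edges
    succ: dict[frozenset, set[frozenset]] = {g: set() for g in group_of.values()}
    for child, parent in edges:
        succ[group_of[child]].add(group_of[parent])

    reach: dict[str, set[str]] = {}
    for n in nodes:
        seen = {group_of[n]}
        stack = [group_of[n]]
        while stack:
            for nxt in succ[stack.pop()]:
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        reach[n] = set().union(*seen)
    return reach


def make_entails(graph: OntologyGraph, mode: str):
    reach = oracle_reachability(graph, mode)
    known = set(graph.labels)

    def entails(a, b):
        if a == b:
            return True
        if a not in known or b not in known:
            return False
        return b in reach[a]

    return entails


# ---------------------------------------------------------------------------
# structural subsumption by direct condition enumeration
# ---------------------------------------------------------------------------

def oracle_eq_subsumes(a: EQDefinition, b: EQDefinition, entails_isa, entails_entity):
    if not entails_isa(a.quality, b.quality):
        return False
    if b.bearer is not None and not (
            a.bearer is not None and entails_entity(a.bearer, b.bearer)):
        return False
    if b.towards is not None and not (
            a.towards is not None and entails_isa(a.towards, b.towards)):
        return False
    if b.qualifier is not None and not (
            a.qualifier is not None and entails_isa(a.qualifier, b.qualifier)):
        return False
    for rel_b, filler_b in b.extra_entities:
        fn = entails_entity if rel_b == REL_INHERES_IN else entails_isa
        if not any(rel_a == rel_b and fn(filler_a, filler_b)
                   for rel_a, filler_a in a.extra_entities):
            return False
    return True


def oracle_classify(defs, asserted_graph: OntologyGraph, building_blocks: OntologyGraph,
                    equivalences, entity_mode: str):
    """Pairwise enumeration + Floyd-Warshall + mutual-reachability partition."""
    entails_isa = make_entails(building_blocks, "is_a")
    entails_entity = make_entails(building_blocks, entity_mode)
    by_class = {d.defined_class: d for d in defs}
    nodes = sorted(set(asserted_graph.labels) | set(by_class))
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    m = [[False] * n for _ in range(n)]
    for i in range(n):
        m[i][i] = True
    for child, parent in asserted_graph.is_a_edges:
        if child in idx and parent in idx:
            m[idx[child]][idx[parent]] = True
    for ax in equivalences:
        if ax.left in idx and ax.right in idx:
            m[idx[ax.left]][idx[ax.right]] = True
            m[idx[ax.right]][idx[ax.left]] = True
    for ca, da in by_class.items():
        for cb, db in by_class.items():
            if ca != cb and oracle_eq_subsumes(da, db, entails_isa, entails_entity):
                m[idx[ca]][idx[cb]] = True
    for k in range(n):
        for i in range(n):
            if m[i][k]:
                for j in range(n):
                    if m[k][j]:
                        m[i][j] = True
    pairs = frozenset((nodes[i], nodes[j]) for i in range(n) for j in range(n)
                      if m[i][j])
    groups = set()
    for i in range(n):
        groups.add(frozenset(nodes[j] for j in range(n) if m[i][j] and m[j][i]))
    return pairs, groups


# ---------------------------------------------------------------------------
# random reasoning cases (<= 8 phenotype classes)
# ---------------------------------------------------------------------------

def random_reasoning_case(rng: random.Random, max_defs: int = 8):
    g = OntologyGraph()
    ents = [f"E:{i}" for i in range(rng.randint(2, 6))]
    quals = [f"Q:{i}" for i in range(rng.randint(2, 4))]
    for pool, with_part_of in ((ents, True), (quals, False)):
        for i, c in enumerate(pool):
            g.add_class(c)
            for j in range(i):
                r = rng.random()
                if r < 0.35:
                    g.add_is_a(c, pool[j])
                elif with_part_of and r < 0.5:
                    g.add_part_of(c, pool[j])
    g.add_class(PATO_ABNORMAL)
    # species-specific aliases bridged onto canonical entities
    for i, e in enumerate(list(ents)):
        if rng.random() < 0.4:
            alias = f"A:{i}"
            g.add_class(alias)
            g.add_equivalence(alias, e)
            ents.append(alias)

    n_defs = rng.randint(2, max_defs)
    prefixes = ["HP", "MP", "ZP"]
    defs, class_ids = [], []
    for i in range(n_defs):
        cid = f"{prefixes[i % 3]}:{7000 + i}"
        class_ids.append(cid)
        extras = ()
        if rng.random() < 0.25:
            extras = (("toward_kin", rng.choice(ents)),)
        towards = rng.choice([None, None] + quals + ents)
        if rng.random() < 0.1:
            towards = "X:missing"  # exercises the unknown-class path
        defs.append(EQDefinition(
            defined_class=cid,
            quality=rng.choice(quals),
            bearer=rng.choice([None] + ents),
            towards=towards,
            qualifier=PATO_ABNORMAL,
            extra_entities=extras,
        ))
    asserted = OntologyGraph()
    for cid in class_ids:
        asserted.add_class(cid, f"label {cid}")
    for i, a in enumerate(class_ids):
        for b in class_ids[:i]:
            if a.split(":")[0] == b.split(":")[0] and rng.random() < 0.25:
                asserted.add_is_a(a, b)
    equivs = []
    for i, a in enumerate(class_ids):
        for b in class_ids[:i]:
            if a.split(":")[0] != b.split(":")[0] and rng.random() < 0.1:
                equivs.append(EquivalenceAxiom(a, b))
    mode = rng.choice(["is_a", "is_a+part_of"])
    return g, defs, asserted, equivs, mode


# ---------------------------------------------------------------------------
# random OBO documents for round-trip checks
# ---------------------------------------------------------------------------

_NAME_CHARS = string.ascii_letters + string.digits + " ()-_,"


def random_obo_document(rng: random.Random, max_terms: int = 50) -> OboDocument:
    doc = OboDocument(header=[("format-version", "1.2"),
                              ("ontology", f"toy{rng.randint(0, 99)}")])
    ids = [f"T{rng.randint(0, 9)}:{i:05d}" for i in range(rng.randint(1, max_terms))]
    ids = sorted(set(ids))
    rng.shuffle(ids)
    for i, cid in enumerate(ids):
        st = TermStanza(id=cid)
        if rng.random() < 0.9:
            st.name = "".join(rng.choice(_NAME_CHARS)
                              for _ in range(rng.randint(1, 25))).strip() or "x"
        others = ids[:i]
        st.is_a = sorted(rng.sample(others, min(len(others), rng.randint(0, 2))))
        if rng.random() < 0.3:
            st.alt_ids = [f"ALT:{rng.randint(0, 999):04d}"
                          for _ in range(rng.randint(1, 3))]
        if rng.random() < 0.3:
            st.xrefs = [f"X:{rng.randint(0, 999):04d}"]
        if rng.random() < 0.2:
            st.subsets = ["upper_level"]
        if rng.random() < 0.2 and others:
            st.relationships = [("part_of", rng.choice(others))]
        if rng.random() < 0.3 and others:
            st.intersection_of = [("", rng.choice(others)),
                                  ("inheres_in", rng.choice(others))]
        if rng.random() < 0.2:
            st.synonyms = [("toy synonym %d" % rng.randint(0, 9), "EXACT")]
        if rng.random() < 0.15:
            st.other_tags = [("comment", "a preserved comment %d" % rng.randint(0, 9))]
        if rng.random() < 0.05:
            st.is_obsolete = True
            st.is_a = []
        doc.stanzas.append(st)
    return doc
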