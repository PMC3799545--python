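import random

import pytest

from crosspheno.merge_export import (ExportError, ROOT_ID, choose_primary,
                                     export_cross_species, merge_clusters,
                                     primary_lookup)
from crosspheno.obo_io import parse_obo, write_obo
from crosspheno.ontology_core import OntologyGraph
from crosspheno.reasoner import classify
from helpers_oracles import random_reasoning_case


def _classified(seed):
    g, defs, asserted, equivs, mode = random_reasoning_case(random.Random(seed))
    labels = {c: f"label {c}" for c in set(asserted.labels) | {d.defined_class
                                                               for d in defs}}
    return classify(defs, asserted, g.subclass_closure(), equivs, mode), labels


def test_hp_identifier_is_primary_when_present():
    assert choose_primary({"ZP:0004170", "HP:0005609"}) == "HP:0005609"
    assert choose_primary({"MP:9", "HP:2", "ZP:1"}) == "HP:2"


def test_mp_outranks_zp_without_hp_and_ties_break_lexicographically():
    assert choose_primary({"MP:5", "ZP:1"}) == "MP:5"
    assert choose_primary({"MP:5", "MP:3"}) == "MP:3"


def test_gallbladder_style_cluster_gets_alt_id():
    from crosspheno.reasoner import SubsumptionResult
    result = SubsumptionResult(
        subclass_pairs=frozenset([("HP:0005609", "HP:0005609"),
                                  ("ZP:0004170", "ZP:0004170"),
                                  ("HP:0005609", "ZP:0004170"),
                                  ("ZP:0004170", "HP:0005609")]),
        equivalence_groups=(frozenset({"HP:0005609", "ZP:0004170"}),))
    clusters, dag = merge_clusters(result, {"HP:0005609": "Gallbladder dysfunction"})
    (c,) = clusters
    assert c.primary_id == "HP:0005609"
    assert c.alt_ids == frozenset({"ZP:0004170"})
    doc = export_cross_species(clusters, dag)
    assert doc.term("HP:0005609").alt_ids == ["ZP:0004170"]


def test_all_singleton_groups_give_transitive_reduction_of_input():
    result, labels = _classified(0)
    clusters, dag = merge_clusters(result, labels)
    # no edge in the reduced DAG is implied by two others
    for u, v in dag.edges:
        assert not any(dag.has_edge(u, w) and dag.has_edge(w, v)
                       for w in dag.nodes)


@pytest.mark.parametrize("seed", range(15))
def test_every_class_appears_exactly_once_as_primary_or_alt(seed):
    result, labels = _classified(seed)
    clusters, dag = merge_clusters(result, labels)
    doc = export_cross_species(clusters, dag)
    seen = []
    for st in doc.stanzas:
        if st.id != ROOT_ID:
            seen.append(st.id)
            seen.extend(st.alt_ids)
    all_classes = set().union(*result.equivalence_groups)
    assert sorted(seen) == sorted(all_classes)


@pytest.mark.parametrize("seed", range(15))
def test_export_closure_reproduces_reasoner_subsumption(seed):
    """Re-parsing the export and closing its is_a edges gives back exactly
    the phenotype subsumption the reasoner computed."""
    result, labels = _classified(seed)
    clusters, dag = merge_clusters(result, labels)
    doc = parse_obo(write_obo(export_cross_species(clusters, dag)))
    g = OntologyGraph()
    for st in doc.stanzas:
        g.add_class(st.id)
        for p in st.is_a:
            g.add_is_a(st.id, p)
    closure = g.subclass_closure()
    lookup = primary_lookup(clusters)
    for a in lookup:
        for b in lookup:
            expected = (a, b) in result.subclass_pairs
            assert closure.is_subclass_of(lookup[a], lookup[b]) == expected


def test_export_is_byte_identical_under_shuffled_input():
    result, labels = _classified(3)
    clusters, dag = merge_clusters(result, labels)
    text = write_obo(export_cross_species(clusters, dag))
    for seed in range(5):
        shuffled = list(clusters)
        random.Random(seed).shuffle(shuffled)
        assert write_obo(export_cross_species(shuffled, dag)) == text


def test_export_contains_no_building_block_prefixes(fig1_result):
    banned = ("PATO:", "CHEBI:", "UBERON:", "ZFA:", "MA:", "FMA:", "GO:")
    for st in fig1_result.export_doc.stanzas:
        assert not st.id.startswith(banned)


def test_empty_cluster_list_gives_header_only_document():
    import networkx as nx
    doc = export_cross_species([], nx.DiGraph())
    assert doc.stanzas == []
    assert doc.header


def test_dag_edge_to_non_primary_is_hard_error():
    import networkx as nx
    from crosspheno.merge_export import PhenoCluster
    clusters = [PhenoCluster(frozenset({"HP:1"}), "HP:1", frozenset(), "x")]
    dag = nx.DiGraph([("HP:1", "ZP:9")])
    with pytest.raises(ExportError, match="ZP:9"):
        export_cross_species(clusters, dag)
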