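import random

from crosspheno.bridging import EquivalenceAxiom
from crosspheno.eq_model import EQDefinition, PATO_ABNORMAL
from crosspheno.ontology_core import OntologyGraph
from crosspheno.reasoner import classify, eq_subsumes
from crosspheno.reports import BuildReport
from helpers_oracles import oracle_classify, random_reasoning_case


def hypoglycemia_world():
    g = OntologyGraph()
    g.add_is_a("CHEBI:17234", "CHEBI:33917")  # glucose is_a aldohexose
    g.add_class("FMA:9670")
    g.add_class("PATO:0001163")
    g.add_class(PATO_ABNORMAL)
    hypo = EQDefinition("HP:0001943", "PATO:0001163", bearer="FMA:9670",
                        towards="CHEBI:17234", qualifier=PATO_ABNORMAL)
    dec_aldo = EQDefinition("HP:9000001", "PATO:0001163", bearer="FMA:9670",
                            towards="CHEBI:33917", qualifier=PATO_ABNORMAL)
    return g, hypo, dec_aldo


def test_hypoglycemia_subsumed_via_chebi_edge():
    g, hypo, dec_aldo = hypoglycemia_world()
    closure = g.subclass_closure()
    assert eq_subsumes(hypo, dec_aldo, closure)
    assert not eq_subsumes(dec_aldo, hypo, closure)


def test_definition_subsumes_itself():
    g, hypo, _ = hypoglycemia_world()
    assert eq_subsumes(hypo, hypo, g.subclass_closure())


def test_quality_only_superclass_subsumes_anatomy_specific():
    """Absent bearer on the subsumer is entailed (existential semantics)."""
    g = OntologyGraph()
    g.add_class("PATO:1")
    g.add_class("E:1")
    narrow = EQDefinition("HP:1", "PATO:1", bearer="E:1")
    broad = EQDefinition("HP:2", "PATO:1")
    closure = g.subclass_closure()
    assert eq_subsumes(narrow, broad, closure)
    assert not eq_subsumes(broad, narrow, closure)


def test_unknown_class_entails_only_itself_and_reports_once():
    g = OntologyGraph()
    g.add_class("PATO:1")
    a = EQDefinition("HP:1", "PATO:1", towards="GHOST:1")
    b = EQDefinition("HP:2", "PATO:1", towards="GHOST:2")
    same = EQDefinition("HP:3", "PATO:1", towards="GHOST:1")
    report = BuildReport()
    closure = g.subclass_closure()
    assert not eq_subsumes(a, b, closure, report=report)
    assert eq_subsumes(a, same, closure, report=report)
    assert eq_subsumes(a, b, closure, report=report) is False
    assert report.counts["reasoner.unknown_classes"] == 2  # one entry per CURIE


def test_part_of_mode_yields_superset_of_is_a_only():
    for seed in range(30):
        g, defs, asserted, equivs, _ = random_reasoning_case(random.Random(seed))
        closure = g.subclass_closure()
        strict = classify(defs, asserted, closure, equivs, "is_a")
        liberal = classify(defs, asserted, closure, equivs, "is_a+part_of")
        assert strict.subclass_pairs <= liberal.subclass_pairs


def test_identical_definitions_form_one_equivalence_group():
    g = OntologyGraph()
    g.add_class("PATO:1")
    g.add_class("E:1")
    hp = EQDefinition("HP:1", "PATO:1", bearer="E:1", qualifier=PATO_ABNORMAL)
    zp = EQDefinition("ZP:1", "PATO:1", bearer="E:1", qualifier=PATO_ABNORMAL)
    asserted = OntologyGraph()
    asserted.add_class("HP:1")
    asserted.add_class("ZP:1")
    result = classify([hp, zp], asserted, g.subclass_closure())
    assert result.group_of("HP:1") == frozenset({"HP:1", "ZP:1"})


def test_asserted_equivalences_merge_undefined_classes():
    asserted = OntologyGraph()
    asserted.add_class("HP:1")
    asserted.add_class("MP:1")
    result = classify([], asserted, OntologyGraph().subclass_closure(),
                      [EquivalenceAxiom("HP:1", "MP:1")])
    assert result.is_subclass_of("HP:1", "MP:1")
    assert result.is_subclass_of("MP:1", "HP:1")
    assert result.group_of("HP:1") == frozenset({"HP:1", "MP:1"})


def test_classification_is_transitively_closed():
    for seed in range(20):
        g, defs, asserted, equivs, mode = random_reasoning_case(random.Random(seed))
        result = classify(defs, asserted, g.subclass_closure(), equivs, mode)
        pairs = result.subclass_pairs
        closed = {(a, d) for a, b in pairs for c, d in pairs if b == c}
        assert closed <= pairs


def test_classify_matches_brute_force_oracle_on_small_cases():
    for seed in range(40):
        g, defs, asserted, equivs, mode = random_reasoning_case(random.Random(seed))
        result = classify(defs, asserted, g.subclass_closure(), equivs, mode)
        pairs, groups = oracle_classify(defs, asserted, g, equivs, mode)
        assert result.subclass_pairs == pairs
        assert set(result.equivalence_groups) == groups


def test_incomparable_qualities_give_only_reflexive_and_asserted_pairs():
    g = OntologyGraph()
    g.add_class("Q:1")
    g.add_class("Q:2")
    defs = [EQDefinition("HP:1", "Q:1"), EQDefinition("HP:2", "Q:2")]
    asserted = OntologyGraph()
    asserted.add_class("HP:1")
    asserted.add_class("HP:2")
    result = classify(defs, asserted, g.subclass_closure())
    assert result.subclass_pairs == frozenset({("HP:1", "HP:1"), ("HP:2", "HP:2")})
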