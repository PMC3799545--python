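import random

import pytest

from crosspheno.bridging import EquivalenceAxiom
from crosspheno.ontology_core import (OntologyCycleError, OntologyGraph,
                                      merge_graphs)
from helpers_oracles import make_entails


def chebi_fixture():
    g = OntologyGraph()
    g.add_is_a("CHEBI:17234", "CHEBI:33917")  # glucose is_a aldohexose
    g.add_is_a("CHEBI:33917", "CHEBI:16646")
    return g


def random_dag(rng, n):
    g = OntologyGraph()
    nodes = [f"N:{i}" for i in range(n)]
    for i, c in enumerate(nodes):
        g.add_class(c)
        for j in rng.sample(range(i), min(i, rng.randint(0, 3))):
            g.add_is_a(c, nodes[j])
        if i and rng.random() < 0.2:
            g.add_part_of(c, nodes[rng.randrange(i)])
    return g


def test_closure_is_reflexive():
    closure = chebi_fixture().subclass_closure()
    assert closure.is_subclass_of("CHEBI:17234", "CHEBI:17234")


def test_glucose_is_subclass_of_aldohexose():
    closure = chebi_fixture().subclass_closure()
    assert closure.is_subclass_of("CHEBI:17234", "CHEBI:33917")
    assert closure.is_subclass_of("CHEBI:17234", "CHEBI:16646")  # transitive
    assert not closure.is_subclass_of("CHEBI:33917", "CHEBI:17234")


def test_unknown_curie_raises_keyerror_naming_it():
    closure = chebi_fixture().subclass_closure()
    with pytest.raises(KeyError, match="NOPE:1"):
        closure.is_subclass_of("NOPE:1", "CHEBI:33917")


def test_closure_matches_brute_force_reachability_on_random_dags():
    for seed, n in [(0, 30), (1, 60), (2, 200)]:
        g = random_dag(random.Random(seed), n)
        closure = g.subclass_closure()
        for mode in ("is_a", "is_a+part_of"):
            entails = make_entails(g, mode)
            for a in g.classes:
                for b in g.classes:
                    assert closure.is_subclass_of(a, b, mode) == entails(a, b)


def test_part_of_not_in_default_closure_but_in_liberal_mode():
    g = OntologyGraph()
    g.add_part_of("Z:part", "Z:whole")
    closure = g.subclass_closure()
    assert not closure.is_subclass_of("Z:part", "Z:whole")
    assert closure.is_subclass_of("Z:part", "Z:whole", "is_a+part_of")


def test_merge_disjoint_graphs_is_plain_union():
    a, b = random_dag(random.Random(3), 10), OntologyGraph()
    b.add_is_a("M:1", "M:2")
    merged = merge_graphs([a, b])
    assert merged.classes == a.classes | b.classes
    closure = merged.subclass_closure()
    assert closure.is_subclass_of("M:1", "M:2")
    assert not closure.is_subclass_of("M:1", "N:0")


def test_bridge_equivalence_contracts_classes():
    """Subclasses of a bridged species class gain the Uberon parents."""
    zfa = OntologyGraph()
    zfa.add_is_a("ZFA:lens", "ZFA:eye")
    uberon = OntologyGraph()
    uberon.add_is_a("UBERON:eye", "UBERON:organ")
    merged = merge_graphs([zfa, uberon],
                          [EquivalenceAxiom("UBERON:eye", "ZFA:eye")])
    closure = merged.subclass_closure()
    assert closure.is_subclass_of("ZFA:lens", "UBERON:organ")
    assert closure.equivalent("ZFA:eye", "UBERON:eye")
    assert closure.is_subclass_of("ZFA:eye", "UBERON:eye")
    assert closure.is_subclass_of("UBERON:eye", "ZFA:eye")


def test_unknown_equivalence_is_skipped_with_report():
    from crosspheno.reports import BuildReport
    report = BuildReport()
    merged = merge_graphs([chebi_fixture()],
                          [EquivalenceAxiom("CHEBI:17234", "GHOST:1")],
                          report)
    assert merged.merged_equivalences == set()
    assert report.counts["merge.skipped_equivalences"] == 1


def test_contracted_closure_matches_brute_force_with_equivalences():
    rng = random.Random(11)
    for _ in range(20):
        g = random_dag(rng, 15)
        nodes = sorted(g.classes)
        for _ in range(3):
            g.add_equivalence(rng.choice(nodes), rng.choice(nodes))
        try:
            closure = g.subclass_closure()
        except OntologyCycleError:
            continue  # contraction disagreed with the hierarchy; legitimately fatal
        entails = make_entails(g, "is_a")
        for a in nodes:
            for b in nodes:
                assert closure.is_subclass_of(a, b) == entails(a, b)


def test_is_a_cycle_aborts_but_equivalence_cycle_contracts():
    bad = OntologyGraph()
    bad.add_is_a("A:1", "A:2")
    bad.add_is_a("A:2", "A:1")
    with pytest.raises(OntologyCycleError):
        bad.subclass_closure()

    ok = OntologyGraph()
    ok.add_is_a("A:1", "A:2")
    ok.add_equivalence("A:1", "A:2")  # two-way reachability via bridging
    closure = ok.subclass_closure()
    assert closure.is_subclass_of("A:2", "A:1")


def test_adding_an_edge_never_removes_closure_pairs():
    rng = random.Random(5)
    g = random_dag(rng, 20)
    closure = g.subclass_closure()
    before = {(a, b) for a in g.classes for b in g.classes
              if closure.is_subclass_of(a, b)}
    g.add_is_a("N:19", "N:0")
    after_closure = g.subclass_closure()
    after = {(a, b) for a in g.classes for b in g.classes
             if after_closure.is_subclass_of(a, b)}
    assert before <= after
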