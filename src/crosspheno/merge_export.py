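"""Collapse equivalence clusters and export the cross-species ontology.

Each cluster of mutually subsuming phenotype classes becomes a single
class: the HPO id is primary when present (prefix priority HP > MP > ZP,
lexicographic tie-break within a prefix) and every other member id is
stored under ``alt_id``.  The subclass DAG is rewritten onto primary ids
and transitively reduced, building-block classes are filtered out, and a
single reserved root class keeps the export a connected DAG.  The result
is the ``crossSpeciesPheno.obo`` document.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .obo_io import OboDocument, TermStanza
from .ontology_core import curie_prefix
from .reasoner import SubsumptionResult

PHENOTYPE_PREFIXES = ("HP", "MP", "ZP")
_PREFIX_PRIORITY = {p: i for i, p in enumerate(PHENOTYPE_PREFIXES)}

ROOT_ID = "UPHENO:0000001"
ROOT_LABEL = "cross-species phenotypic abnormality"


class ExportError(ValueError):
    """Inconsistent cluster/DAG input — indicates a merge bug upstream."""


@dataclass(frozen=True)
class PhenoCluster:
    members: frozenset
    primary_id: str
    alt_ids: frozenset
    label: str | None


def choose_primary(members) -> str:
    return min(members, key=lambda c: (_PREFIX_PRIORITY.get(curie_prefix(c), 99), c))


def merge_clusters(result: SubsumptionResult, labels: dict):
    """Collapse equivalence groups; returns (clusters, reduced primary DAG).

    The reduced DAG contains every primary id as a node and no edge that is
    implied by two others; its transitive closure equals the phenotype
    subsumption computed by the reasoner.
    """
    primary_of: dict[str, str] = {}
    clusters: list[PhenoCluster] = []
    for group in result.equivalence_groups:
        primary = choose_primary(group)
        for m in group:
            primary_of[m] = primary
        clusters.append(PhenoCluster(
            members=frozenset(group),
            primary_id=primary,
            alt_ids=frozenset(group) - {primary},
            label=labels.get(primary),
        ))
    clusters.sort(key=lambda c: c.primary_id)

    g = nx.DiGraph()
    g.add_nodes_from(primary_of[m] for m in primary_of)
    for a, b in result.subclass_pairs:
        pa, pb = primary_of[a], primary_of[b]
        if pa != pb:
            g.add_edge(pa, pb)
    if not nx.is_directed_acyclic_graph(g):
        raise ExportError("cycle among non-equivalent clusters")
    reduced = nx.transitive_reduction(g)
    reduced.add_nodes_from(g.nodes)
    return clusters, reduced


def export_cross_species(clusters, dag, add_root: bool = True,
                         phenotype_prefixes=PHENOTYPE_PREFIXES) -> OboDocument:
    """Render clusters + reduced DAG as the crossSpeciesPheno.obo document.

    Only phenotype classes appear; any DAG edge touching a non-primary id
    is a hard error.  Parentless clusters are attached to a reserved root
    class so the export is a rooted DAG.
    """
    primaries = {c.primary_id for c in clusters}
    for u, v in dag.edges:
        if u not in primaries or v not in primaries:
            raise ExportError(f"DAG edge ({u}, {v}) touches a non-primary id")
    for c in clusters:
        if curie_prefix(c.primary_id) not in phenotype_prefixes:
            raise ExportError(f"non-phenotype primary id in export: {c.primary_id}")

    doc = OboDocument(header=[("ontology", "crossspeciespheno")])
    for c in sorted(clusters, key=lambda c: c.primary_id):
        parents = sorted(v for _, v in dag.out_edges(c.primary_id))
        if not parents and add_root:
            parents = [ROOT_ID]
        doc.stanzas.append(TermStanza(
            id=c.primary_id,
            name=c.label,
            alt_ids=sorted(c.alt_ids),
            is_a=parents,
        ))
    if clusters and add_root:
        doc.stanzas.append(TermStanza(id=ROOT_ID, name=ROOT_LABEL))
    return doc


def primary_lookup(clusters) -> dict:
    """member id (primary or alt) -> primary id."""
    out = {}
    for c in clusters:
        for m in c.members:
            out[m] = c.primary_id
    return out
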