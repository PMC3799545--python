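"""End-to-end build: from building-block ontologies and annotation tables
to crossSpeciesPheno.obo and the cross-species human-gene annotation file.

The four stages mirror the construction workflow:

1. load ontologies and cross-product files, generate bridging axioms
   (Uberon xrefs, lexical HP/MP alignment), normalize definitions;
2. synthesize the ZP ontology from post-composed zebrafish annotations;
3. classify all phenotype classes over the merged closure and collapse
   equivalence clusters (HPO-primary alt_id policy);
4. export the ontology and propagate annotations to human genes.

Everything is driven by a YAML config mapping input roles to file paths
(relative paths resolve against the config file's directory).  All
artifacts are written deterministically: rerunning on unchanged inputs
reproduces them byte for byte.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import annotation_transfer as at
from . import bridging, zp_builder
from .eq_model import normalize_definitions, parse_xp_file
from .merge_export import export_cross_species, merge_clusters, primary_lookup
from .obo_io import read_obo_file, write_obo_file
from .ontology_core import ENTITY_MODE_IS_A, OntologyGraph, merge_graphs
from .reasoner import classify, eq_subsumes, write_subclass_pairs
from .reports import BuildReport

REQUIRED_INPUTS = (
    "pato", "zfa", "ma", "uberon", "hp", "mp", "hp_xp", "mp_xp", "pheno_txt",
    "mouse_pheno", "mouse_ortho", "zfin_ortho", "phenotype_annotation", "mim2gene",
)
OPTIONAL_INPUTS = ("chebi", "go", "fma", "go_xp", "orphanet", "zp_idmap")
PHENOTYPE_PREFIXES = ("HP", "MP", "ZP")

EXPORT_FILENAME = "crossSpeciesPheno.obo"
ANNOTATION_FILENAME = "HSgenes_crossSpeciesPhenoAnnotation.txt"


class PipelineConfigError(ValueError):
    """A missing or unusable config entry; the message names the key."""


@dataclass
class PipelineResult:
    out_dir: Path
    merged_graph: OntologyGraph = None
    closure: object = None
    definitions: list = field(default_factory=list)
    bridge_axioms: list = field(default_factory=list)
    lexical_axioms: list = field(default_factory=list)
    zp_classes: list = field(default_factory=list)
    zp_annotations: list = field(default_factory=list)
    classification: object = None
    clusters: list = field(default_factory=list)
    dag: object = None
    export_doc: object = None
    labels: dict = field(default_factory=dict)
    annotations: list = field(default_factory=list)
    report: BuildReport = field(default_factory=BuildReport)

    def annotations_for(self, pheno_class: str) -> list:
        """All annotation records on a class or any of its inferred subclasses."""
        lookup = primary_lookup(self.clusters)
        if pheno_class not in lookup:
            raise KeyError(f"unknown phenotype class: {pheno_class}")
        members = self.clusters_for_primary(lookup[pheno_class])
        sub_primaries = {lookup[a] for a, b in self.classification.subclass_pairs
                         if b in members and a in lookup}
        return [r for r in self.annotations if r.pheno_class in sub_primaries]

    def clusters_for_primary(self, primary: str) -> frozenset:
        for c in self.clusters:
            if c.primary_id == primary:
                return c.members
        raise KeyError(primary)


def load_config(config_path) -> tuple[dict, Path]:
    config_path = Path(config_path)
    cfg = yaml.safe_load(config_path.read_text())
    if not isinstance(cfg, dict) or "inputs" not in cfg:
        raise PipelineConfigError("config must contain an 'inputs' mapping")
    return cfg, config_path.parent


def _resolve_inputs(cfg: dict, base: Path) -> dict[str, Path]:
    inputs = cfg.get("inputs", {})
    paths: dict[str, Path] = {}
    for key in REQUIRED_INPUTS:
        if key not in inputs:
            raise PipelineConfigError(f"missing required input for config key '{key}'")
    for key, rel in inputs.items():
        p = Path(rel)
        if not p.is_absolute():
            p = base / p
        if not p.exists():
            raise PipelineConfigError(f"input file for config key '{key}' not found: {p}")
        paths[key] = p
    return paths


def run_pipeline(config_path, out_dir=None, entity_mode: str | None = None) -> PipelineResult:
    """Execute the whole build; returns the in-memory result.

    ``out_dir`` defaults to ``<config dir>/build``; ``entity_mode``
    overrides the config option (``is_a`` or ``is_a+part_of``).
    """
    cfg, base = load_config(config_path)
    paths = _resolve_inputs(cfg, base)
    options = cfg.get("options") or {}
    mode = entity_mode or options.get("entity_mode", ENTITY_MODE_IS_A)
    out = Path(out_dir) if out_dir is not None else base / "build"
    out.mkdir(parents=True, exist_ok=True)

    report = BuildReport()
    res = PipelineResult(out_dir=out, report=report)

    # ---- step 1: ontologies, definitions, bridges -----------------------
    graphs: dict[str, OntologyGraph] = {}
    for key in ("pato", "chebi", "go", "fma", "ma", "zfa", "uberon", "hp", "mp"):
        if key in paths:
            graphs[key] = OntologyGraph.from_obo(read_obo_file(paths[key]))
            report.count(f"load.{key}_classes", len(graphs[key].classes))

    defs = []
    for key in ("hp_xp", "mp_xp", "go_xp"):
        if key in paths:
            defs.extend(parse_xp_file(read_obo_file(paths[key]), report))
    defs = normalize_definitions(defs, report=report)
    res.definitions = defs

    res.bridge_axioms = bridging.build_uberon_bridge(graphs["uberon"])
    report.count("bridge.uberon_axioms", len(res.bridge_axioms))
    if options.get("lexical_align", True):
        res.lexical_axioms = bridging.lexical_align(
            graphs["hp"], graphs["mp"],
            include_synonyms=bool(options.get("lexical_synonyms", False)))
        report.count("bridge.lexical_axioms", len(res.lexical_axioms))
    bridging.write_axioms_tsv(res.bridge_axioms, out / "bridge_axioms.tsv")
    bridging.write_axioms_tsv(res.lexical_axioms, out / "lexical_axioms.tsv")

    # ---- step 2: ZP synthesis -------------------------------------------
    pheno_annots = zp_builder.parse_pheno_file(paths["pheno_txt"].read_text(),
                                               report=report)
    id_map = zp_builder.read_id_map(paths["zp_idmap"]) if "zp_idmap" in paths else {}
    building_block_classes = set()
    for key in ("pato", "chebi", "go", "fma", "ma", "zfa", "uberon"):
        if key in graphs:
            building_block_classes |= graphs[key].classes
    res.zp_classes, res.zp_annotations, id_map = zp_builder.build_zp_ontology(
        pheno_annots, id_map=id_map, id_base=int(options.get("zp_id_base", 1)),
        known_classes=building_block_classes, report=report)
    write_obo_file(zp_builder.zp_ontology_document(res.zp_classes), out / "zp.obo")
    zp_builder.write_zp_annotations(res.zp_annotations, out / "zp.annot")
    zp_builder.write_id_map(id_map, out / "zp_idmap.tsv")

    # ---- step 3: merge + classify ---------------------------------------
    building_blocks = [graphs[k] for k in
                       ("pato", "chebi", "go", "fma", "ma", "zfa", "uberon")
                       if k in graphs]
    merged = merge_graphs(building_blocks, res.bridge_axioms, report)

    pheno_defs = [d for d in defs
                  if d.defined_class.split(":", 1)[0] in PHENOTYPE_PREFIXES]
    entity_defs = [d for d in defs if d not in pheno_defs]
    if entity_defs:
        # fold entity-level definitions (e.g. GO occurs_in cross-products)
        # into the closure as extra is_a edges before phenotype reasoning
        closure0 = merged.subclass_closure()
        for a in entity_defs:
            for b in entity_defs:
                if a is not b and eq_subsumes(a, b, closure0, mode, report):
                    merged.add_is_a(a.defined_class, b.defined_class)
    res.merged_graph = merged
    res.closure = merged.subclass_closure()

    pheno_defs.extend(zc.definition for zc in res.zp_classes)
    asserted = OntologyGraph()
    for key in ("hp", "mp"):
        for c in sorted(graphs[key].classes):
            asserted.add_class(c, graphs[key].labels[c])
        asserted.is_a_edges |= graphs[key].is_a_edges
    for zc in res.zp_classes:
        asserted.add_class(zc.zp_id, zc.label)
    res.classification = classify(pheno_defs, asserted, res.closure,
                                  asserted_equivalences=res.lexical_axioms,
                                  entity_mode=mode, report=report)
    write_subclass_pairs(res.classification, out / "subclass_pairs.tsv")

    res.labels = dict(asserted.labels)
    res.clusters, res.dag = merge_clusters(res.classification, res.labels)
    report.count("merge.clusters", len(res.clusters))
    report.count("merge.multi_member_clusters",
                 sum(1 for c in res.clusters if len(c.members) > 1))
    res.export_doc = export_cross_species(res.clusters, res.dag)
    write_obo_file(res.export_doc, out / EXPORT_FILENAME)
    for prefix in PHENOTYPE_PREFIXES:
        report.count(f"export.{prefix}_primary_classes",
                     sum(1 for c in res.clusters
                         if c.primary_id.startswith(prefix + ":")))

    # ---- step 4: annotation transfer ------------------------------------
    primary_of = primary_lookup(res.clusters)
    ortho = at.load_orthology(paths["mouse_ortho"].read_text(),
                              paths["zfin_ortho"].read_text(), report=report)
    mouse_annots = at.parse_mgi_pheno(paths["mouse_pheno"].read_text(), report=report)
    human_raw = at.human_gene_annotations(
        paths["phenotype_annotation"].read_text(),
        paths["mim2gene"].read_text(),
        paths["orphanet"].read_text() if "orphanet" in paths else None,
        report=report)
    human = at.resolve_human_records(human_raw, primary_of, report)
    model = at.transfer_model_annotations(mouse_annots, res.zp_annotations,
                                          ortho, primary_of, report)
    res.annotations = sorted(human + model, key=at._record_sort_key)
    at.write_annotation_table(res.annotations, res.labels, out / ANNOTATION_FILENAME)
    summary = at.annotation_summary(res.annotations)
    at.write_annotation_summary(summary, out / "annotation_summary.tsv")
    for key, value in summary.items():
        report.count(f"annotations.{key}", value)

    (out / "report.json").write_text(report.to_json())
    report.write_tsv(out / "skipped.tsv")
    return res
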