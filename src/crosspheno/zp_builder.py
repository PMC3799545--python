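"""Synthesize a pre-composed zebrafish phenotype ontology (ZP classes).

Zebrafish phenotypes are curated "post-composed": each annotation line in
the ZFIN ``pheno.txt`` dialect names an anatomical entity (ZFA), a quality
(PATO) and an abnormal/normal modifier, but no pre-minted phenotype class
exists.  For every unique abnormal (quality, entity) combination this
module mints one class in the ZP identifier space, labeled
``abnormal(ly) {quality} {entity}``, and records the gene-to-class
annotation rows (the ``zp.annot`` table).

ZP numbering is made stable across releases by a persisted id-map: a
two-column TSV of definition-content key to ZP id.  Previously seen
definitions keep their ids; novel definitions get the smallest unused
number at or above a configurable base.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .eq_model import EQDefinition, PATO_ABNORMAL, definition_to_stanza
from .obo_io import OboDocument
from .reports import BuildReport

#: the tested 8-column pheno.txt layout; the real export has more columns,
#: pass a different map to pick fields out of a wider file.
DEFAULT_PHENO_COLUMNS = {
    "gene_id": 0,
    "entrez": 1,
    "gene_symbol": 2,
    "entity": 3,
    "entity_label": 4,
    "quality": 5,
    "quality_label": 6,
    "modifier": 7,
}

MODIFIER_ABNORMAL = "abnormal"


@dataclass(frozen=True)
class PostComposedAnnotation:
    gene_id: str
    entrez: str
    gene_symbol: str
    entity: str
    entity_label: str
    quality: str
    quality_label: str
    modifier: str


@dataclass(frozen=True)
class ZPClass:
    zp_id: str
    label: str
    definition: EQDefinition


@dataclass(frozen=True)
class ZfinAnnotation:
    """One gene-to-ZP-class link, the row shape of zp.annot."""

    gene_id: str
    gene_symbol: str
    zp_id: str


def parse_pheno_file(text, column_map=DEFAULT_PHENO_COLUMNS,
                     report: BuildReport | None = None) -> list[PostComposedAnnotation]:
    """Parse the tab-separated pheno.txt dialect; malformed lines are
    skipped and reported (never a hard error)."""
    report = report if report is not None else BuildReport()
    if hasattr(text, "read"):
        text = text.read()
    n_needed = max(column_map.values()) + 1
    records: list[PostComposedAnnotation] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < n_needed:
            report.skip("pheno.malformed_lines", f"line {lineno}",
                        f"{len(fields)} columns, need {n_needed}")
            continue
        rec = PostComposedAnnotation(
            **{name: fields[idx].strip() for name, idx in column_map.items()})
        if not rec.entity or not rec.quality:
            report.skip("pheno.malformed_lines", f"line {lineno}",
                        "missing entity or quality")
            continue
        records.append(rec)
        report.count("pheno.parsed_lines")
    return records


def zp_label(quality_label: str, entity_label: str) -> str:
    return f"abnormal(ly) {quality_label} {entity_label}"


def format_zp_id(number: int) -> str:
    return f"ZP:{number:07d}"


def read_id_map(path) -> dict[str, str]:
    id_map: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        key, zp_id = line.split("\t")
        id_map[key] = zp_id
    return id_map


def write_id_map(id_map: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for key, zp_id in sorted(id_map.items()):
            fh.write(f"{key}\t{zp_id}\n")


def build_zp_ontology(annots, id_map: dict[str, str] | None = None,
                      id_base: int = 1, known_classes: set[str] | None = None,
                      report: BuildReport | None = None):
    """Mint ZP classes from post-composed annotations.

    Returns ``(zp_classes, zfin_annotations, id_map)`` where ``id_map`` is
    the updated definition-key -> ZP id table.  Only ``abnormal``-modifier
    lines participate; others are dropped with a report entry.  When
    ``known_classes`` is given, definitions referencing entities/qualities
    outside it are reported but the class is still created (reasoning will
    simply find no superclasses for it).
    """
    report = report if report is not None else BuildReport()
    id_map = dict(id_map or {})

    # deduplicate on definition content
    by_key: dict[str, dict] = {}
    links: set[tuple[str, str, str]] = set()  # (gene, symbol, def key)
    for rec in annots:
        if rec.modifier != MODIFIER_ABNORMAL:
            report.skip("zp.dropped_non_abnormal", rec.gene_id,
                        f"modifier {rec.modifier!r}")
            continue
        defn = EQDefinition(defined_class="", quality=rec.quality,
                            bearer=rec.entity, qualifier=PATO_ABNORMAL)
        key = defn.content_key()
        slot = by_key.setdefault(key, {"definition": defn, "labels": set()})
        slot["labels"].add((rec.quality_label, rec.entity_label))
        links.add((rec.gene_id, rec.gene_symbol, key))
        if known_classes is not None:
            for curie in (rec.quality, rec.entity):
                if curie not in known_classes:
                    report.skip_once("zp.unknown_component", curie,
                                     "not in loaded building-block graphs")

    used = {int(zp.split(":")[1]) for zp in id_map.values()}

    def next_number() -> int:
        n = id_base
        while n in used:
            n += 1
        used.add(n)
        return n

    classes: list[ZPClass] = []
    key_to_id: dict[str, str] = {}
    for key in sorted(by_key, key=lambda k: (by_key[k]["definition"].quality,
                                             by_key[k]["definition"].bearer or "")):
        if key in id_map:
            zp_id = id_map[key]
        else:
            zp_id = format_zp_id(next_number())
            id_map[key] = zp_id
        quality_label, entity_label = min(by_key[key]["labels"])
        defn = by_key[key]["definition"]
        classes.append(ZPClass(
            zp_id=zp_id,
            label=zp_label(quality_label, entity_label),
            definition=EQDefinition(defined_class=zp_id, quality=defn.quality,
                                    bearer=defn.bearer, qualifier=defn.qualifier),
        ))
        key_to_id[key] = zp_id

    annotations = sorted(
        {ZfinAnnotation(g, s, key_to_id[k]) for g, s, k in links},
        key=lambda a: (a.gene_id, a.zp_id))
    report.count("zp.classes_created", len(classes))
    report.count("zp.annotation_records", len(annotations))
    return classes, annotations, id_map


def zp_ontology_document(classes) -> OboDocument:
    """Render the ZP classes as an OBO document with their logical definitions."""
    doc = OboDocument(header=[("ontology", "zp")])
    for zc in sorted(classes, key=lambda c: c.zp_id):
        doc.stanzas.append(definition_to_stanza(zc.definition, label=zc.label))
    return doc


def write_zp_annotations(annotations, path) -> None:
    with open(path, "w") as fh:
        for a in sorted(annotations, key=lambda a: (a.gene_id, a.zp_id)):
            fh.write(f"{a.gene_id}\t{a.gene_symbol}\t{a.zp_id}\n")
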