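"""Cross-species human-gene annotation table.

Human genes acquire phenotype annotations three ways:

* **human**: disease-to-phenotype rows (phenotype_annotation.tab dialect)
  joined to disease-to-gene maps from OMIM (mim2gene dialect) and a
  simplified Orphanet table, with evidence sources unioned when both
  databases support the same (gene, term) pair;
* **mouse**: genotype-level MPO annotations (MGI_PhenoGenoMP dialect)
  resolved to markers, transferred to human genes over MGI orthology;
* **zebrafish**: the zp.annot table transferred over ZFIN orthology.

Phenotype ids are rewritten to cluster primary ids (alt_id resolution) so
no record references a class outside the merged ontology.  A model gene
with several human orthologs fans out to all of them (reported).
"""
from __future__ import annotations

from dataclasses import dataclass

from .reports import BuildReport

SPECIES_HUMAN = "human"
SPECIES_MOUSE = "mouse"
SPECIES_ZEBRAFISH = "zebrafish"

EVIDENCE_OMIM = "OMIM"
EVIDENCE_ORPHANET = "Orphanet"
EVIDENCE_MGI = "MGI"
EVIDENCE_ZFIN = "ZFIN"

#: 4th-column species tag in the output table (the zebrafish tag follows the
#: published row shape; the mouse tag is this build's declared choice)
SPECIES_TAG = {SPECIES_MOUSE: "MOUSE", SPECIES_ZEBRAFISH: "ZEBRAF"}

# default column maps for the supported TSV dialects
MOUSE_ORTHO_COLUMNS = {"human_symbol": 0, "human_entrez": 1,
                       "mouse_symbol": 2, "mgi_id": 3}
ZFIN_ORTHO_COLUMNS = {"zdb_id": 0, "zfin_symbol": 1,
                      "human_symbol": 2, "human_entrez": 3}
MGI_PHENO_COLUMNS = {"mp_id": 4, "markers": 6}
PHENOTYPE_ANNOTATION_COLUMNS = {"db": 0, "disease_id": 1, "hpo_id": 4}
MIM2GENE_COLUMNS = {"mim": 0, "entrez": 1, "symbol": 2}


@dataclass(frozen=True)
class AnnotationRecord:
    human_gene_entrez: int
    human_gene_symbol: str
    pheno_class: str
    source_species: str
    source_gene: tuple[str, str] | None = None  # (id, symbol)
    evidence_source: frozenset = frozenset()


@dataclass
class OrthologyMap:
    mouse_to_human: dict  # mgi id -> set of (entrez, human symbol)
    zebrafish_to_human: dict  # zdb id -> set of (entrez, human symbol)
    mouse_symbols: dict  # mgi id -> mouse symbol
    zebrafish_symbols: dict  # zdb id -> zfin symbol


def _rows(text, n_needed, stage, report):
    if hasattr(text, "read"):
        text = text.read()
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < n_needed:
            report.skip(stage, f"line {lineno}", f"{len(fields)} columns, need {n_needed}")
            continue
        yield fields


def load_orthology(mouse_table, zfin_table,
                   mouse_columns=MOUSE_ORTHO_COLUMNS,
                   zfin_columns=ZFIN_ORTHO_COLUMNS,
                   report: BuildReport | None = None) -> OrthologyMap:
    """Load and deduplicate the two orthology dialects."""
    report = report if report is not None else BuildReport()
    mouse: dict[str, set] = {}
    mouse_symbols: dict[str, str] = {}
    for f in _rows(mouse_table, max(mouse_columns.values()) + 1,
                   "orthology.mouse_skipped", report):
        try:
            entrez = int(f[mouse_columns["human_entrez"]])
        except ValueError:
            report.skip("orthology.mouse_skipped", f[mouse_columns["mgi_id"]],
                        "non-integer Entrez id")
            continue
        mgi = f[mouse_columns["mgi_id"]]
        mouse.setdefault(mgi, set()).add((entrez, f[mouse_columns["human_symbol"]]))
        mouse_symbols.setdefault(mgi, f[mouse_columns["mouse_symbol"]])

    fish: dict[str, set] = {}
    fish_symbols: dict[str, str] = {}
    for f in _rows(zfin_table, max(zfin_columns.values()) + 1,
                   "orthology.zfin_skipped", report):
        try:
            entrez = int(f[zfin_columns["human_entrez"]])
        except ValueError:
            report.skip("orthology.zfin_skipped", f[zfin_columns["zdb_id"]],
                        "non-integer Entrez id")
            continue
        zdb = f[zfin_columns["zdb_id"]]
        fish.setdefault(zdb, set()).add((entrez, f[zfin_columns["human_symbol"]]))
        fish_symbols.setdefault(zdb, f[zfin_columns["zfin_symbol"]])
    return OrthologyMap(mouse, fish, mouse_symbols, fish_symbols)


def parse_mgi_pheno(text, columns=MGI_PHENO_COLUMNS,
                    report: BuildReport | None = None) -> list[tuple[str, str]]:
    """Genotype-level MPO rows resolved to (marker id, MP id) pairs.

    The marker column lists every involved marker separated by commas or
    pipes; all of them receive the annotation (declared policy for
    multi-gene genotypes).
    """
    report = report if report is not None else BuildReport()
    pairs: set[tuple[str, str]] = set()
    for f in _rows(text, max(columns.values()) + 1, "mgi.skipped_lines", report):
        mp_id = f[columns["mp_id"]]
        markers = f[columns["markers"]].replace("|", ",")
        for marker in (m.strip() for m in markers.split(",")):
            if marker:
                pairs.add((marker, mp_id))
    return sorted(pairs)


def human_gene_annotations(disease_pheno, mim2gene, orphanet=None,
                           pheno_columns=PHENOTYPE_ANNOTATION_COLUMNS,
                           mim_columns=MIM2GENE_COLUMNS,
                           report: BuildReport | None = None) -> list[AnnotationRecord]:
    """Join disease-phenotype rows to disease-gene maps.

    The OMIM map is keyed ``OMIM:<mim>``; the simplified Orphanet table is
    two columns (disease id, gene symbol) with an optional third Entrez
    column — bare symbols resolve through the mim2gene symbol table.
    Records identical except for evidence are merged with evidence unioned.
    """
    report = report if report is not None else BuildReport()

    omim_genes: dict[str, set] = {}
    symbol_to_entrez: dict[str, int] = {}
    for f in _rows(mim2gene, max(mim_columns.values()) + 1, "mim2gene.skipped", report):
        try:
            entrez = int(f[mim_columns["entrez"]])
        except ValueError:
            report.skip("mim2gene.skipped", f[mim_columns["mim"]], "non-integer Entrez id")
            continue
        symbol = f[mim_columns["symbol"]]
        omim_genes.setdefault(f"OMIM:{f[mim_columns['mim']]}", set()).add((entrez, symbol))
        symbol_to_entrez.setdefault(symbol, entrez)

    orpha_genes: dict[str, set] = {}
    if orphanet is not None:
        for f in _rows(orphanet, 2, "orphanet.skipped", report):
            disease, symbol = f[0], f[1]
            if len(f) >= 3 and f[2]:
                entrez = int(f[2])
            elif symbol in symbol_to_entrez:
                entrez = symbol_to_entrez[symbol]
            else:
                report.skip("orphanet.skipped", symbol, "symbol not resolvable to Entrez")
                continue
            orpha_genes.setdefault(disease, set()).add((entrez, symbol))

    merged: dict[tuple[int, str, str], set] = {}
    diseases_without_gene: set[str] = set()
    for f in _rows(disease_pheno, max(pheno_columns.values()) + 1,
                   "phenotype_annotation.skipped", report):
        db, disease_local, hpo_id = (f[pheno_columns["db"]],
                                     f[pheno_columns["disease_id"]],
                                     f[pheno_columns["hpo_id"]])
        disease = disease_local if ":" in disease_local else f"{db}:{disease_local}"
        hits = [(EVIDENCE_OMIM, g) for g in omim_genes.get(disease, ())]
        hits += [(EVIDENCE_ORPHANET, g) for g in orpha_genes.get(disease, ())]
        if not hits:
            diseases_without_gene.add(disease)
            continue
        for evidence, (entrez, symbol) in hits:
            merged.setdefault((entrez, symbol, hpo_id), set()).add(evidence)
    report.count("human.diseases_without_gene", len(diseases_without_gene))

    return [AnnotationRecord(entrez, symbol, hpo_id, SPECIES_HUMAN, None,
                             frozenset(evidence))
            for (entrez, symbol, hpo_id), evidence in sorted(merged.items())]


def transfer_model_annotations(mouse_annots, zp_annots, ortho: OrthologyMap,
                               primary_of: dict,
                               report: BuildReport | None = None) -> list[AnnotationRecord]:
    """Transfer model-organism annotations to human genes over orthology.

    ``mouse_annots`` are (marker id, MP id) pairs; ``zp_annots`` are
    :class:`~crosspheno.zp_builder.ZfinAnnotation` rows.  Phenotype ids are
    rewritten to cluster primary ids; annotations without an ortholog or
    with an unresolvable phenotype id are dropped and counted.
    """
    report = report if report is not None else BuildReport()
    records: set[AnnotationRecord] = set()

    def resolve(pheno_id: str) -> str | None:
        primary = primary_of.get(pheno_id)
        if primary is None:
            report.skip_once("transfer.unresolvable_pheno", pheno_id,
                             "not in merged ontology")
        return primary

    for marker, mp_id in mouse_annots:
        primary = resolve(mp_id)
        if primary is None:
            continue
        orthologs = ortho.mouse_to_human.get(marker)
        if not orthologs:
            report.count("transfer.mouse_without_ortholog")
            continue
        if len(orthologs) > 1:
            report.count("transfer.mouse_fanout")
        symbol = ortho.mouse_symbols.get(marker, marker)
        for entrez, human_symbol in orthologs:
            records.add(AnnotationRecord(entrez, human_symbol, primary,
                                         SPECIES_MOUSE, (marker, symbol),
                                         frozenset({EVIDENCE_MGI})))

    for a in zp_annots:
        primary = resolve(a.zp_id)
        if primary is None:
            continue
        orthologs = ortho.zebrafish_to_human.get(a.gene_id)
        if not orthologs:
            report.count("transfer.zebrafish_without_ortholog")
            continue
        if len(orthologs) > 1:
            report.count("transfer.zebrafish_fanout")
        symbol = ortho.zebrafish_symbols.get(a.gene_id, a.gene_symbol)
        for entrez, human_symbol in orthologs:
            records.add(AnnotationRecord(entrez, human_symbol, primary,
                                         SPECIES_ZEBRAFISH, (a.gene_id, symbol),
                                         frozenset({EVIDENCE_ZFIN})))

    return sorted(records, key=_record_sort_key)


def _record_sort_key(r: AnnotationRecord):
    return (r.human_gene_entrez, r.pheno_class, r.source_species,
            r.source_gene or ("", ""))


def resolve_human_records(records, primary_of: dict,
                          report: BuildReport | None = None) -> list[AnnotationRecord]:
    """Rewrite human-sourced records onto cluster primary ids, merging evidence."""
    report = report if report is not None else BuildReport()
    merged: dict[tuple[int, str, str], set] = {}
    for r in records:
        primary = primary_of.get(r.pheno_class)
        if primary is None:
            report.skip_once("human.unresolvable_pheno", r.pheno_class,
                             "not in merged ontology")
            continue
        merged.setdefault((r.human_gene_entrez, r.human_gene_symbol, primary),
                          set()).update(r.evidence_source)
    return [AnnotationRecord(entrez, symbol, pheno, SPECIES_HUMAN, None,
                             frozenset(ev))
            for (entrez, symbol, pheno), ev in sorted(merged.items())]


def format_annotation_row(record: AnnotationRecord, labels: dict) -> str:
    """One tab-separated output row: entrez, symbol, "label (ID)", source."""
    label = labels.get(record.pheno_class) or record.pheno_class
    pheno_field = f"{label} ({record.pheno_class})"
    if record.source_species == SPECIES_HUMAN:
        source_field = ",".join(sorted(record.evidence_source))
    else:
        src_id, src_symbol = record.source_gene
        source_field = f"{src_symbol} ({src_id}/{SPECIES_TAG[record.source_species]})"
    return "\t".join([str(record.human_gene_entrez), record.human_gene_symbol,
                      pheno_field, source_field])


def write_annotation_table(records, labels: dict, path) -> None:
    with open(path, "w") as fh:
        for r in sorted(records, key=_record_sort_key):
            fh.write(format_annotation_row(r, labels) + "\n")


def annotation_summary(records) -> dict:
    """Per-source counts (the shape of the published statistics table)."""
    out = {
        "all": len(records),
        SPECIES_HUMAN: 0, SPECIES_MOUSE: 0, SPECIES_ZEBRAFISH: 0,
        "human_omim": 0, "human_orphanet": 0,
    }
    for r in records:
        out[r.source_species] += 1
        if r.source_species == SPECIES_HUMAN:
            if EVIDENCE_OMIM in r.evidence_source:
                out["human_omim"] += 1
            if EVIDENCE_ORPHANET in r.evidence_source:
                out["human_orphanet"] += 1
    return out


def write_annotation_summary(summary: dict, path) -> None:
    with open(path, "w") as fh:
        for key in sorted(summary):
            fh.write(f"{key}\t{summary[key]}\n")
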