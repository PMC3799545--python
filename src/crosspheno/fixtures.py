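"""Self-contained synthetic fixture sets for building and testing the pipeline.

A fixture directory holds everything a build needs: toy building-block
ontologies (PATO, ChEBI, GO, FMA, MA, ZFA, Uberon with bridging xrefs),
HP/MP cross-product files, a pheno.txt table, orthology tables, human
disease maps and a ready-to-run config.yaml.  Same seed, same bytes.

With ``include_fig1_cases`` the directory embeds two hand-built scenarios
with axioms sufficient for the expected inferences:

* the hypoglycemia case — Hypoglycemia (decreased concentration of
  glucose in blood) is inferable as a subclass of "Decreased aldohexose
  concentration (blood)" solely from the glucose is_a aldohexose edge;
* the microphthalmia case — a zebrafish "abnormal(ly) hypoplastic eye"
  class and a mouse "posterior microphthalmia" class are inferable as
  strict subclasses of the human "Bilateral microphthalmos" class, with
  genes in all three species (tcf7l1a / Prss56 / TCOF1 analogues) wired
  up through orthology and disease tables.

The random portion draws distinct (quality, canonical-anatomy) pairs per
phenotype ontology from a shared pool, so no two randomly generated
classes are accidentally equivalent, and labels carry their ontology tag
so lexical alignment never fires on them.
"""
from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import yaml

from .eq_model import EQDefinition, PATO_ABNORMAL, REL_INHERES_IN, REL_QUALIFIER, REL_TOWARDS
from .obo_io import OboDocument, TermStanza, write_obo_file

PATO_ROOT = "PATO:0000001"

# -- the hypoglycemia case (ids follow the published building blocks) ----
CHEBI_GLUCOSE = "CHEBI:17234"
CHEBI_ALDOHEXOSE = "CHEBI:33917"
FMA_BLOOD = "FMA:9670"
HP_HYPOGLYCEMIA = "HP:0001943"
HP_DECREASED_ALDOHEXOSE = "HP:9000001"

# -- the microphthalmia case ---------------------------------------------
ZFA_EYE = "ZFA:0000107"
MA_EYE = "MA:0000261"
UBERON_EYE = "UBERON:0000970"
HP_BILATERAL_MICROPHTHALMOS = "HP:0007633"
MP_POSTERIOR_MICROPHTHALMIA = "MP:9000001"
PATO_DECREASED_SIZE = "PATO:0000587"
PATO_HYPOPLASTIC = "PATO:0000645"
PATO_POSTERIORLY_HYPOPLASTIC = "PATO:9000010"  # synthetic differentia quality
TCF7L1A_ZDB = "ZDB-GENE-980605-30"
TCF7L1_ENTREZ = 83439
PRSS56_MGI = "MGI:3045301"
PRSS56_ENTREZ = 167681
TCOF1_ENTREZ = 6949
TCOF1_MIM = "154500"

# -- the gallbladder alt_id case -----------------------------------------
HP_GALLBLADDER_DYSFUNCTION = "HP:0005609"
ZFA_GALL_BLADDER = "ZFA:0000208"
UBERON_GALL_BLADDER = "UBERON:0002110"
PATO_DECREASED_FUNCTIONALITY = "PATO:0001624"

ZP_HYPOPLASTIC_EYE = "ZP:0003395"
ZP_GALLBLADDER = "ZP:0004170"


@dataclass(frozen=True)
class FixtureSpec:
    seed: int = 1
    n_entities: int = 6
    n_qualities: int = 4
    depth: int = 3
    n_pheno_classes: int = 3
    n_genes: int = 3
    bridge_fraction: float = 1.0
    include_fig1_cases: bool = True

    def __post_init__(self):
        for name in ("n_entities", "n_qualities", "depth", "n_pheno_classes", "n_genes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_entities * self.n_qualities < 3 * self.n_pheno_classes:
            raise ValueError("quality x entity pool too small for 3 distinct "
                             "definition sets; increase n_entities or n_qualities")


def _doc(name: str) -> OboDocument:
    return OboDocument(header=[("ontology", name)])


def _xp_stanza(class_id, quality, bearer=None, towards=None, qualifier=None,
               bearer_rel=REL_INHERES_IN):
    entries = [("", quality)]
    if bearer is not None:
        entries.append((bearer_rel, bearer))
    if towards is not None:
        entries.append((REL_TOWARDS, towards))
    if qualifier is not None:
        entries.append((REL_QUALIFIER, qualifier))
    return TermStanza(id=class_id, intersection_of=entries)


def generate_fixture(spec: FixtureSpec, out_dir) -> Path:
    """Write a complete fixture directory; returns the config.yaml path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = random.Random(spec.seed)

    # ---------------- toy anatomy (canonical tree mirrored per species) --
    n = spec.n_entities

    def anat_id(prefix, i):
        return f"{prefix}:9{100000 + i}"

    parents = {1: 0}
    node_depth = {0: 0, 1: 1}
    for i in range(2, n + 1):
        cand = [j for j in range(i) if node_depth[j] < spec.depth]
        p = rng.choice(cand)
        parents[i] = p
        node_depth[i] = node_depth[p] + 1

    n_bridged = round(spec.bridge_fraction * n)
    bridged = set(rng.sample(range(1, n + 1), n_bridged)) if n_bridged else set()

    species = {"UBERON": "uberon", "ZFA": "zfa", "MA": "ma", "FMA": "fma"}
    docs = {pfx: _doc(name) for pfx, name in species.items()}
    for pfx in species:
        suffix = "" if pfx == "UBERON" else f" ({pfx.lower()})"
        docs[pfx].stanzas.append(TermStanza(
            id=anat_id(pfx, 0), name=f"toy anatomical structure{suffix}"))
        for i in range(1, n + 1):
            st = TermStanza(id=anat_id(pfx, i),
                            name=f"toy anatomical structure {i}{suffix}",
                            is_a=[anat_id(pfx, parents[i])])
            if pfx == "UBERON" and i in bridged:
                st.xrefs = [anat_id(p, i) for p in ("ZFA", "MA", "FMA")]
            docs[pfx].stanzas.append(st)

    # ---------------- toy qualities --------------------------------------
    pato = _doc("pato")
    pato.stanzas.append(TermStanza(id=PATO_ROOT, name="quality"))
    pato.stanzas.append(TermStanza(id=PATO_ABNORMAL, name="abnormal",
                                   is_a=[PATO_ROOT]))

    def quality_id(i):
        return f"PATO:9{200000 + i}"

    q_parent = {}
    for i in range(1, spec.n_qualities + 1):
        q_parent[i] = rng.choice(range(i))  # 0 means the PATO root
        parent = PATO_ROOT if q_parent[i] == 0 else quality_id(q_parent[i])
        pato.stanzas.append(TermStanza(id=quality_id(i), name=f"toy quality {i}",
                                       is_a=[parent]))

    chebi, go = _doc("chebi"), _doc("go")
    go_xp = _doc("go_xp")
    chebi.stanzas.append(TermStanza(id="CHEBI:24431", name="chemical entity"))
    go.stanzas.append(TermStanza(id="GO:0008150", name="biological process"))

    hp, mp = _doc("hp"), _doc("mp")
    hp_xp, mp_xp = _doc("hp_xp"), _doc("mp_xp")
    pheno_lines: list[str] = []
    mouse_annot_rows: list[str] = []
    mouse_ortho_rows: list[str] = []
    zfin_ortho_rows: list[str] = []
    disease_rows: list[str] = []
    mim2gene_rows: list[str] = []
    orphanet_rows: list[str] = []
    id_map: dict[str, str] = {}

    # ---------------- random phenotype classes ---------------------------
    pool = [(q, e) for q in range(1, spec.n_qualities + 1)
            for e in range(1, n + 1)]
    pairs = rng.sample(pool, 3 * spec.n_pheno_classes)
    k = spec.n_pheno_classes
    hp_pairs, mp_pairs, zp_pairs = pairs[:k], pairs[k:2 * k], pairs[2 * k:]

    def pheno_id(prefix, i):
        return f"{prefix}:9{300000 + i}"

    random_hp, random_mp = [], []
    for i, (q, e) in enumerate(hp_pairs, 1):
        cid = pheno_id("HP", i)
        random_hp.append(cid)
        is_a = []
        if i > 1 and rng.random() < 0.4:
            is_a = [rng.choice(random_hp[:-1])]
        hp.stanzas.append(TermStanza(id=cid, name=f"toy HP phenotype {i}", is_a=is_a))
        hp_xp.stanzas.append(_xp_stanza(cid, quality_id(q),
                                        bearer=anat_id("UBERON", e),
                                        qualifier=PATO_ABNORMAL))
    for i, (q, e) in enumerate(mp_pairs, 1):
        cid = pheno_id("MP", i)
        random_mp.append(cid)
        is_a = []
        if i > 1 and rng.random() < 0.4:
            is_a = [rng.choice(random_mp[:-1])]
        mp.stanzas.append(TermStanza(id=cid, name=f"toy MP phenotype {i}", is_a=is_a))
        mp_xp.stanzas.append(_xp_stanza(cid, quality_id(q),
                                        bearer=anat_id("MA", e),
                                        qualifier=PATO_ABNORMAL))

    # ---------------- random genes and annotations ------------------------
    qlabel = {i: f"toy quality {i}" for i in range(1, spec.n_qualities + 1)}
    elabel = {i: f"toy anatomical structure {i} (zfa)" for i in range(1, n + 1)}
    for i in range(spec.n_genes):
        zdb = f"ZDB-GENE-970101-{i + 1}"
        entrez = 910000 + i
        zfin_ortho_rows.append(f"{zdb}\tzgene{i + 1}\tZGH{i + 1}\t{entrez}")
        for j, (q, e) in enumerate(zp_pairs):
            if j % spec.n_genes == i or rng.random() < 0.2:
                pheno_lines.append("\t".join([
                    zdb, str(entrez), f"zgene{i + 1}", anat_id("ZFA", e),
                    elabel[e], quality_id(q), qlabel[q], "abnormal"]))

        mgi = f"MGI:97{i:05d}"
        mouse_ortho_rows.append(f"MG{i + 1}H\t{920000 + i}\tmgene{i + 1}\t{mgi}")
        for j, cid in enumerate(random_mp):
            if j % spec.n_genes == i:
                mouse_annot_rows.append("\t".join([
                    f"mgene{i + 1}<m1>/mgene{i + 1}<m1>", f"mgene{i + 1}<m1>",
                    f"MGI:98{i:05d}", "involves: toy strain", cid,
                    str(10000000 + i), mgi]))

        mim = f"96{i:04d}"
        mim2gene_rows.append(f"{mim}\t{930000 + i}\tHG{i + 1}")
        for j, cid in enumerate(random_hp):
            if j % spec.n_genes == i:
                disease_rows.append("\t".join(
                    ["OMIM", mim, f"toy disease {i + 1}", "", cid] + [""] * 9))

    # ---------------- the worked-example cases ----------------------------
    if spec.include_fig1_cases:
        pato.stanzas += [
            TermStanza(id="PATO:0000033", name="concentration of", is_a=[PATO_ROOT]),
            TermStanza(id="PATO:0001163", name="decreased concentration",
                       is_a=["PATO:0000033"]),
            TermStanza(id=PATO_DECREASED_SIZE, name="decreased size", is_a=[PATO_ROOT]),
            TermStanza(id=PATO_HYPOPLASTIC, name="hypoplastic",
                       is_a=[PATO_DECREASED_SIZE]),
            TermStanza(id=PATO_POSTERIORLY_HYPOPLASTIC, name="posteriorly hypoplastic",
                       is_a=[PATO_HYPOPLASTIC]),
            TermStanza(id=PATO_DECREASED_FUNCTIONALITY, name="decreased functionality",
                       is_a=[PATO_ROOT]),
            TermStanza(id="PATO:0001507", name="disrupted", is_a=[PATO_ROOT]),
        ]
        chebi.stanzas += [
            TermStanza(id="CHEBI:16646", name="carbohydrate", is_a=["CHEBI:24431"]),
            TermStanza(id=CHEBI_ALDOHEXOSE, name="aldohexose", is_a=["CHEBI:16646"]),
            TermStanza(id=CHEBI_GLUCOSE, name="glucose", is_a=[CHEBI_ALDOHEXOSE]),
        ]
        fma = docs["FMA"]
        fma.stanzas += [
            TermStanza(id="FMA:62955", name="anatomical entity (fma)"),
            TermStanza(id=FMA_BLOOD, name="portion of blood", is_a=["FMA:62955"]),
        ]
        zfa = docs["ZFA"]
        zfa.stanzas += [
            TermStanza(id=ZFA_EYE, name="eye (zfa)", is_a=[anat_id("ZFA", 0)]),
            TermStanza(id=ZFA_GALL_BLADDER, name="gall bladder (zfa)",
                       is_a=[anat_id("ZFA", 0)]),
        ]
        docs["MA"].stanzas.append(TermStanza(id=MA_EYE, name="eye (ma)",
                                             is_a=[anat_id("MA", 0)]))
        uberon = docs["UBERON"]
        uberon.stanzas += [
            # very general term: bridged xref must be ignored (upper_level)
            TermStanza(id="UBERON:0001062", name="anatomical entity",
                       subsets=["upper_level"], xrefs=["FMA:62955"]),
            TermStanza(id=UBERON_EYE, name="eye", is_a=["UBERON:0001062"],
                       xrefs=[ZFA_EYE, MA_EYE]),
            TermStanza(id=UBERON_GALL_BLADDER, name="gall bladder",
                       is_a=["UBERON:0001062"], xrefs=[ZFA_GALL_BLADDER]),
            TermStanza(id="UBERON:0000178", name="blood", is_a=["UBERON:0001062"],
                       xrefs=[FMA_BLOOD]),
        ]
        go.stanzas += [
            TermStanza(id="GO:0043473", name="pigmentation", is_a=["GO:0008150"]),
            TermStanza(id="GO:0048069", name="eye pigmentation", is_a=["GO:0043473"]),
        ]
        go_xp.stanzas.append(_xp_stanza("GO:0048069", "GO:0043473",
                                        bearer=UBERON_EYE, bearer_rel="occurs_in"))

        hp.stanzas += [
            TermStanza(id="HP:0000001", name="All"),
            TermStanza(id="HP:0000118", name="Phenotypic abnormality",
                       is_a=["HP:0000001"]),
            TermStanza(id=HP_HYPOGLYCEMIA, name="Hypoglycemia", is_a=["HP:0000118"]),
            TermStanza(id=HP_DECREASED_ALDOHEXOSE,
                       name="Decreased aldohexose concentration (blood)",
                       is_a=["HP:0000118"]),
            TermStanza(id="HP:0000568", name="Microphthalmia", is_a=["HP:0000118"]),
            TermStanza(id=HP_BILATERAL_MICROPHTHALMOS, name="Bilateral microphthalmos",
                       is_a=["HP:0000568"]),
            TermStanza(id=HP_GALLBLADDER_DYSFUNCTION, name="Gallbladder dysfunction",
                       is_a=["HP:0000118"]),
            TermStanza(id="HP:9000002", name="Abnormal eye pigmentation",
                       is_a=["HP:0000118"]),
        ]
        hp_xp.stanzas += [
            _xp_stanza(HP_HYPOGLYCEMIA, "PATO:0001163", bearer=FMA_BLOOD,
                       towards=CHEBI_GLUCOSE, qualifier=PATO_ABNORMAL),
            # qualifier deliberately missing: exercises normalization
            _xp_stanza(HP_DECREASED_ALDOHEXOSE, "PATO:0001163", bearer=FMA_BLOOD,
                       towards=CHEBI_ALDOHEXOSE),
            _xp_stanza(HP_BILATERAL_MICROPHTHALMOS, PATO_DECREASED_SIZE,
                       bearer=UBERON_EYE, qualifier=PATO_ABNORMAL),
            _xp_stanza(HP_GALLBLADDER_DYSFUNCTION, PATO_DECREASED_FUNCTIONALITY,
                       bearer=UBERON_GALL_BLADDER),
            _xp_stanza("HP:9000002", "PATO:0001507", bearer="GO:0048069",
                       qualifier=PATO_ABNORMAL),
        ]
        mp.stanzas += [
            TermStanza(id="MP:0000001", name="mammalian phenotype"),
            TermStanza(id=MP_POSTERIOR_MICROPHTHALMIA, name="posterior microphthalmia",
                       is_a=["MP:0000001"]),
            # lexical twin of the HP class (case differs; alignment normalizes)
            TermStanza(id="MP:9000002", name="hypoglycemia", is_a=["MP:0000001"]),
            TermStanza(id="MP:9000003", name="abnormal pigmentation",
                       is_a=["MP:0000001"]),
        ]
        mp_xp.stanzas += [
            _xp_stanza(MP_POSTERIOR_MICROPHTHALMIA, PATO_POSTERIORLY_HYPOPLASTIC,
                       bearer=MA_EYE, qualifier=PATO_ABNORMAL),
            _xp_stanza("MP:9000003", "PATO:0001507", bearer="GO:0043473",
                       qualifier=PATO_ABNORMAL),
        ]

        # the published pheno.txt example row, tab-separated
        pheno_lines.append("\t".join([
            TCF7L1A_ZDB, str(TCF7L1_ENTREZ), "tcf7l1a", ZFA_EYE, "eye",
            PATO_HYPOPLASTIC, "hypoplastic", "abnormal"]))
        pheno_lines.append("\t".join([
            "ZDB-GENE-990415-1", "999", "gb1", ZFA_GALL_BLADDER, "gall bladder",
            PATO_DECREASED_FUNCTIONALITY, "decreased functionality", "abnormal"]))
        # a normal-modifier line: must be dropped from class synthesis
        pheno_lines.append("\t".join([
            "ZDB-GENE-990415-1", "999", "gb1", ZFA_EYE, "eye",
            PATO_DECREASED_SIZE, "decreased size", "normal"]))

        zfin_ortho_rows.append(f"{TCF7L1A_ZDB}\ttcf7l1a\tTCF7L1\t{TCF7L1_ENTREZ}")
        zfin_ortho_rows.append("ZDB-GENE-990415-1\tgb1\tGBH1\t999")
        mouse_ortho_rows.append(f"PRSS56\t{PRSS56_ENTREZ}\tPrss56\t{PRSS56_MGI}")
        mouse_annot_rows.append("\t".join([
            "Prss56<m1>/Prss56<m1>", "Prss56<m1>", "MGI:5000001",
            "involves: toy strain", MP_POSTERIOR_MICROPHTHALMIA, "12345678",
            PRSS56_MGI]))
        disease_rows.append("\t".join(
            ["OMIM", TCOF1_MIM, "toy craniofacial syndrome", "",
             HP_BILATERAL_MICROPHTHALMOS] + [""] * 9))
        disease_rows.append("\t".join(
            ["ORPHA", "ORPHA:861", "toy craniofacial syndrome", "",
             HP_BILATERAL_MICROPHTHALMOS] + [""] * 9))
        mim2gene_rows.append(f"{TCOF1_MIM}\t{TCOF1_ENTREZ}\tTCOF1")
        orphanet_rows.append("ORPHA:861\tTCOF1")

        # seed the persisted id-map so the published ZP ids are stable
        eye_def = EQDefinition("", PATO_HYPOPLASTIC, bearer=ZFA_EYE,
                               qualifier=PATO_ABNORMAL)
        gb_def = EQDefinition("", PATO_DECREASED_FUNCTIONALITY,
                              bearer=ZFA_GALL_BLADDER, qualifier=PATO_ABNORMAL)
        id_map[eye_def.content_key()] = ZP_HYPOPLASTIC_EYE
        id_map[gb_def.content_key()] = ZP_GALLBLADDER

    # ---------------- write everything ------------------------------------
    write_obo_file(pato, out / "pato.obo")
    write_obo_file(chebi, out / "chebi.obo")
    write_obo_file(go, out / "go.obo")
    write_obo_file(go_xp, out / "go-xp.obo")
    write_obo_file(docs["FMA"], out / "fma.obo")
    write_obo_file(docs["MA"], out / "ma.obo")
    write_obo_file(docs["ZFA"], out / "zfa.obo")
    write_obo_file(docs["UBERON"], out / "uberon.obo")
    write_obo_file(hp, out / "hp.obo")
    write_obo_file(mp, out / "mp.obo")
    write_obo_file(hp_xp, out / "hp-xp.obo")
    write_obo_file(mp_xp, out / "mp-xp.obo")

    def tsv(name, rows):
        (out / name).write_text("".join(r + "\n" for r in rows))

    tsv("pheno.txt", pheno_lines)
    tsv("MGI_PhenoGenoMP.rpt", mouse_annot_rows)
    tsv("HMD_HumanPhenotype.rpt", mouse_ortho_rows)
    tsv("ortho.txt", zfin_ortho_rows)
    tsv("phenotype_annotation.tab", disease_rows)
    tsv("mim2gene.txt", mim2gene_rows)
    tsv("orphanet.tsv", orphanet_rows)

    inputs = {
        "pato": "pato.obo", "chebi": "chebi.obo", "go": "go.obo",
        "fma": "fma.obo", "ma": "ma.obo", "zfa": "zfa.obo",
        "uberon": "uberon.obo", "hp": "hp.obo", "mp": "mp.obo",
        "hp_xp": "hp-xp.obo", "mp_xp": "mp-xp.obo", "go_xp": "go-xp.obo",
        "pheno_txt": "pheno.txt",
        "mouse_pheno": "MGI_PhenoGenoMP.rpt",
        "mouse_ortho": "HMD_HumanPhenotype.rpt",
        "zfin_ortho": "ortho.txt",
        "phenotype_annotation": "phenotype_annotation.tab",
        "mim2gene": "mim2gene.txt",
        "orphanet": "orphanet.tsv",
    }
    if id_map:
        tsv("zp_idmap.tsv", [f"{k}\t{v}" for k, v in sorted(id_map.items())])
        inputs["zp_idmap"] = "zp_idmap.tsv"
    config = {
        "inputs": inputs,
        "options": {"entity_mode": "is_a", "zp_id_base": 1, "lexical_align": True},
    }
    config_path = out / "config.yaml"
    config_path.write_text(yaml.safe_dump(config, sort_keys=True))
    return config_path
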