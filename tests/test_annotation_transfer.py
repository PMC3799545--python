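import random

from crosspheno.annotation_transfer import (annotation_summary,
                                            format_annotation_row,
                                            human_gene_annotations,
                                            load_orthology, parse_mgi_pheno,
                                            transfer_model_annotations)
from crosspheno.reports import BuildReport
from crosspheno.zp_builder import ZfinAnnotation

MOUSE_ORTHO = "PRSS56\t167681\tPrss56\tMGI:3045301\n"
ZFIN_ORTHO = "ZDB-GENE-980605-30\ttcf7l1a\tTCF7L1\t83439\n"


def test_orthology_rows_load_and_deduplicate():
    ortho = load_orthology(MOUSE_ORTHO + MOUSE_ORTHO, ZFIN_ORTHO + ZFIN_ORTHO)
    assert ortho.mouse_to_human["MGI:3045301"] == {(167681, "PRSS56")}
    assert ortho.zebrafish_to_human["ZDB-GENE-980605-30"] == {(83439, "TCF7L1")}


def test_empty_orthology_tables_give_empty_map():
    ortho = load_orthology("", "")
    assert ortho.mouse_to_human == {} and ortho.zebrafish_to_human == {}


def test_mgi_genotype_rows_resolve_every_involved_marker():
    line = ("a<1>/a<1>\ta<1>\tMGI:9\tinvolves: X\tMP:0001\t123\t"
            "MGI:100,MGI:200\n")
    assert parse_mgi_pheno(line) == [("MGI:100", "MP:0001"), ("MGI:200", "MP:0001")]


PHENO_TAB = ("OMIM\t100100\ttoy disease\t\tHP:0000001\t" + "\t" * 9 + "\n"
             "OMIM\t100100\ttoy disease\t\tHP:0000002\t" + "\t" * 9 + "\n")
MIM2GENE = "100100\t555\tGENEA\n"


def test_direct_omim_join_gives_one_record_per_term():
    records = human_gene_annotations(PHENO_TAB, MIM2GENE)
    assert len(records) == 2
    assert {r.pheno_class for r in records} == {"HP:0000001", "HP:0000002"}
    assert all(r.human_gene_entrez == 555 and r.evidence_source == {"OMIM"}
               for r in records)


def test_omim_and_orphanet_evidence_union_not_duplicate_records():
    orphanet = "OMIM:100100\tGENEA\n"
    records = human_gene_annotations(PHENO_TAB, MIM2GENE, orphanet)
    assert len(records) == 2
    assert all(r.evidence_source == {"OMIM", "Orphanet"} for r in records)


def test_disease_without_gene_is_dropped_and_counted():
    report = BuildReport()
    records = human_gene_annotations(
        "OMIM\t999999\torphan disease\t\tHP:0000003\t" + "\t" * 9 + "\n",
        MIM2GENE, report=report)
    assert records == []
    assert report.counts["human.diseases_without_gene"] == 1


def test_random_joins_match_brute_force_unique_gene_term_pairs():
    rng = random.Random(0)
    diseases = [f"{100000 + i}" for i in range(12)]
    pheno_rows, gene_rows, expected = [], [], set()
    genes = {d: rng.sample(range(500, 520), rng.randint(0, 2)) for d in diseases}
    for d in diseases:
        for g in genes[d]:
            gene_rows.append(f"{d}\t{g}\tSYM{g}")
        for t in rng.sample(range(10), rng.randint(1, 3)):
            pheno_rows.append(f"OMIM\t{d}\ttoy\t\tHP:{t:07d}" + "\t" * 9)
            for g in genes[d]:
                expected.add((g, f"HP:{t:07d}"))
    records = human_gene_annotations("\n".join(pheno_rows) + "\n",
                                     "\n".join(gene_rows) + "\n")
    assert {(r.human_gene_entrez, r.pheno_class) for r in records} == expected


def test_transfer_rewrites_to_primary_and_formats_published_row():
    ortho = load_orthology("", ZFIN_ORTHO)
    records = transfer_model_annotations(
        [], [ZfinAnnotation("ZDB-GENE-980605-30", "tcf7l1a", "ZP:0003395")],
        ortho, {"ZP:0003395": "ZP:0003395"})
    (rec,) = records
    row = format_annotation_row(rec, {"ZP:0003395": "abnormal(ly) hypoplastic eye"})
    assert row == ("83439\tTCF7L1\tabnormal(ly) hypoplastic eye (ZP:0003395)\t"
                   "tcf7l1a (ZDB-GENE-980605-30/ZEBRAF)")


def test_zp_class_merged_into_hp_cluster_reports_hp_primary():
    ortho = load_orthology("", ZFIN_ORTHO)
    primary_of = {"ZP:0004170": "HP:0005609", "HP:0005609": "HP:0005609"}
    (rec,) = transfer_model_annotations(
        [], [ZfinAnnotation("ZDB-GENE-980605-30", "tcf7l1a", "ZP:0004170")],
        ortho, primary_of)
    assert rec.pheno_class == "HP:0005609"


def test_model_gene_without_ortholog_yields_no_records():
    ortho = load_orthology("", "")
    report = BuildReport()
    records = transfer_model_annotations(
        [("MGI:1", "MP:1")], [ZfinAnnotation("ZDB-GENE-1", "g", "ZP:1")],
        ortho, {"MP:1": "MP:1", "ZP:1": "ZP:1"}, report)
    assert records == []
    assert report.counts["transfer.mouse_without_ortholog"] == 1
    assert report.counts["transfer.zebrafish_without_ortholog"] == 1


def test_multi_ortholog_gene_fans_out_to_every_human_gene():
    two = ZFIN_ORTHO + "ZDB-GENE-980605-30\ttcf7l1a\tTCF7L1B\t99999\n"
    ortho = load_orthology("", two)
    records = transfer_model_annotations(
        [], [ZfinAnnotation("ZDB-GENE-980605-30", "tcf7l1a", "ZP:1")],
        ortho, {"ZP:1": "ZP:1"})
    assert {r.human_gene_entrez for r in records} == {83439, 99999}


def test_source_species_partition_sums_to_total(fig1_result):
    summary = annotation_summary(fig1_result.annotations)
    assert summary["all"] == (summary["human"] + summary["mouse"]
                              + summary["zebrafish"])
    assert summary["all"] == len(fig1_result.annotations)
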