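"""Knowledge-table loading, validation and round-trip serialization."""

from __future__ import annotations

import pytest

from pgxcohort import knowledge
from pgxcohort.knowledge import (
    HIGH_EVIDENCE_LEVELS,
    LOW_EVIDENCE_LEVELS,
    KnowledgeError,
    is_high_evidence,
    load_allele_definitions,
    load_clinical_annotations,
    load_gene_drug_table,
    load_phenotype_map,
    write_allele_definitions,
    write_phenotype_map,
)

TOY_DEFS = """gene\tallele\tis_reference\tchrom\tpos\trsid\tref\talt\trequired_allele
G1\t*1\t1
G1\t*2\t0\t1\t100\trs100\tA\tG\tG
G1\t*3\t0\t1\t100\trs100\tA\tG\tG
G1\t*3\t0\t1\t200\trs200\tA\tG\tG
"""


def test_load_toy_definition_set(tmp_path):
    path = tmp_path / "defs.tsv"
    path.write_text(TOY_DEFS)
    defs = load_allele_definitions(path)
    assert set(defs.genes) == {"G1"}
    assert len(defs.genes["G1"]) == 3
    assert len(defs.sites["G1"]) == 2
    assert defs.reference_allele("G1").name == "*1"


def test_bundled_fixture_covers_the_14_genes(defs):
    expected = {
        "CFTR", "CYP2B6", "CYP2C19", "CYP2C9", "CYP2D6", "CYP3A5", "CYP4F2",
        "DPYD", "IFNL3", "NUDT15", "SLCO1B1", "TPMT", "UGT1A1", "VKORC1",
    }
    assert set(defs.genes) == expected
    # the VKORC1 promoter-variant gene has exactly the two promoter alleles
    assert {a.name for a in defs.genes["VKORC1"]} == {"-1639G", "-1639A"}


def test_duplicate_allele_definition_rejected(tmp_path):
    path = tmp_path / "dup.tsv"
    path.write_text(TOY_DEFS + "G1\t*2\t0\t1\t100\trs100\tA\tG\tG\n")
    with pytest.raises(KnowledgeError, match="duplicate"):
        load_allele_definitions(path)


def test_missing_reference_allele_rejected(tmp_path):
    path = tmp_path / "noref.tsv"
    path.write_text(
        "gene\tallele\tis_reference\tchrom\tpos\trsid\tref\talt\trequired_allele\n"
        "G1\t*2\t0\t1\t100\trs100\tA\tG\tG\n"
    )
    with pytest.raises(KnowledgeError, match="reference"):
        load_allele_definitions(path)


def test_definitions_round_trip(tmp_path, defs):
    out = tmp_path / "roundtrip.tsv"
    write_allele_definitions(defs, out)
    again = load_allele_definitions(out)
    assert set(again.genes) == set(defs.genes)
    for gene in defs.genes:
        assert {a.name: dict(a.defining) for a in again.genes[gene]} == {
            a.name: dict(a.defining) for a in defs.genes[gene]
        }
        assert again.sites[gene] == defs.sites[gene]


class TestPhenotypeMap:
    def test_lookup_is_symmetric_in_the_pair(self, pmap):
        a = pmap.lookup("VKORC1", "-1639A", "-1639A")
        assert a == "Decreased warfarin dose"
        assert pmap.is_nontypical("VKORC1", a)
        assert pmap.lookup("VKORC1", "-1639G", "-1639A") == pmap.lookup(
            "VKORC1", "-1639A", "-1639G"
        )

    def test_reserved_labels_cannot_be_nontypical(self, tmp_path):
        (tmp_path / "map.tsv").write_text(
            "gene\tallele1\tallele2\tphenotype\nG1\t*1\t*1\tNormal\n"
        )
        (tmp_path / "flags.tsv").write_text(
            "gene\tphenotype\tnontypical\nG1\tNormal\t0\nG1\tNot available\t1\n"
        )
        with pytest.raises(KnowledgeError, match="reserved"):
            load_phenotype_map(tmp_path / "map.tsv", tmp_path / "flags.tsv")

    def test_entry_without_flag_rejected(self, tmp_path):
        (tmp_path / "map.tsv").write_text(
            "gene\tallele1\tallele2\tphenotype\nG1\t*1\t*1\tOdd label\n"
        )
        (tmp_path / "flags.tsv").write_text("gene\tphenotype\tnontypical\n")
        with pytest.raises(KnowledgeError, match="no nontypical flag"):
            load_phenotype_map(tmp_path / "map.tsv", tmp_path / "flags.tsv")

    def test_round_trip(self, tmp_path, pmap):
        write_phenotype_map(pmap, tmp_path / "m.tsv", tmp_path / "f.tsv")
        again = load_phenotype_map(tmp_path / "m.tsv", tmp_path / "f.tsv")
        assert again.entries == pmap.entries
        assert again.nontypical == pmap.nontypical


class TestGeneDrugTable:
    def test_level_a_drug_lists(self, gene_drug):
        cyp2c19 = {p.drug for p in gene_drug if p.gene == "CYP2C19"}
        assert cyp2c19 == {
            "amitriptyline", "citalopram", "sertraline", "clopidogrel",
            "escitalopram", "imipramine", "clomipramine", "doxepin",
            "trimipramine", "voriconazole",
        }

    def test_default_filter_keeps_only_level_a(self, tmp_path):
        path = tmp_path / "gd.tsv"
        path.write_text(
            "gene\tdrug\tcpic_level\nG1\tdrugA\tA\nG1\tdrugB\tB\n"
        )
        pairs = load_gene_drug_table(path)
        assert [(p.gene, p.drug) for p in pairs] == [("G1", "druga")]

    def test_empty_file_gives_empty_list(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("gene\tdrug\tcpic_level\n")
        assert load_gene_drug_table(path) == []

    def test_unknown_level_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("gene\tdrug\tcpic_level\nG1\tdrugA\tZ\n")
        with pytest.raises(KnowledgeError, match="unknown CPIC level"):
            load_gene_drug_table(path)


class TestClinicalAnnotations:
    def test_bundled_rituximab_annotation(self, annotations):
        ann = next(a for a in annotations if a.annotation_id == "1444608384")
        assert ann.rsid == "rs396991"
        assert ann.gene == "FCGR3A"
        assert ann.evidence_level == "2B"
        assert ann.phenotype_category == "Efficacy"
        assert ann.drugs == ("rituximab",)
        assert ann.pediatric is False
        assert ann.high_evidence

    @pytest.mark.parametrize(
        "level,expected",
        [("1A", True), ("1B", True), ("2A", True), ("2B", True), ("3", False), ("4", False)],
    )
    def test_evidence_partition_is_exhaustive_and_disjoint(self, level, expected):
        assert is_high_evidence(level) is expected
        assert (level in HIGH_EVIDENCE_LEVELS) != (level in LOW_EVIDENCE_LEVELS)

    def test_unknown_tier_rejected(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "annotation_id\trsid\tgene\tevidence_level\tphenotype_category\tdrugs\tpediatric\n"
            "1\trs1\tG1\t5\tEfficacy\tdrugA\t0\n"
        )
        with pytest.raises(KnowledgeError, match="evidence level"):
            load_clinical_annotations(path)


def test_reference_allele_matches_only_all_reference_haplotype(defs):
    """Definition-set/caller consistency: the reference star allele matches the
    all-reference haplotype of its gene and no other allele does."""
    from pgxcohort.caller import match_haplotype

    for gene in defs.gene_names():
        n_sites = len(defs.sites[gene])
        match = match_haplotype([0] * n_sites, gene, defs)
        assert match.matched_alleles == (defs.reference_allele(gene).name,)
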