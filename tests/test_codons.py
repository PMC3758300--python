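"""Codon extraction, counting, RSCU and third-position bias."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from plastkit.codons import (
    FAMILY,
    SENSE_CODONS,
    CodonUsageTable,
    count_codons,
    extract_cds_codons,
    round_half_up,
    rscu,
    third_position_at_bias,
)
from plastkit.errors import SchemaError
from plastkit.fixtures import load_fixture
from plastkit.model import GeneAnnotation, Interval, PlastomeSequence


@pytest.fixture(scope="module")
def table2_counts():
    df = load_fixture("table2")
    counts = dict(zip(df["codon_dna"], df["count"]))
    return {c: counts.get(c, 0) for c in SENSE_CODONS}


@pytest.fixture(scope="module")
def table2_table(table2_counts):
    return rscu(CodonUsageTable(counts=dict(table2_counts)))


class TestExtract:
    def test_plus_strand_single_exon(self):
        seq = PlastomeSequence("t", "ATGAAATAA", circular=False)
        gene = GeneAnnotation("g", "protein_coding", (Interval(0, 9),))
        assert extract_cds_codons(seq, [gene]) == {"g": ["ATG", "AAA", "TAA"]}

    def test_minus_strand_reverse_complemented(self):
        # revcomp("GAACAT") == "ATGTTC"
        seq = PlastomeSequence("t", "GAACAT", circular=False)
        gene = GeneAnnotation("g", "protein_coding", (Interval(0, 6),), "-")
        assert extract_cds_codons(seq, [gene])["g"] == ["ATG", "TTC"]

    def test_splicing_restores_reading_frame(self):
        # exon boundary falls mid-codon; splice must equal the unspliced control
        cds = "ATGGCTAAATTCGGA"
        intron = "GTAAGTTTTAG"
        genomic = cds[:7] + intron + cds[7:]
        seq = PlastomeSequence("t", genomic, circular=False)
        split = GeneAnnotation(
            "g",
            "protein_coding",
            (Interval(0, 7), Interval(7 + len(intron), len(genomic))),
        )
        control = PlastomeSequence("t", cds, circular=False)
        whole = GeneAnnotation("g", "protein_coding", (Interval(0, len(cds)),))
        assert extract_cds_codons(seq, [split]) == extract_cds_codons(control, [whole])

    def test_pseudogenes_and_rna_genes_skipped(self):
        seq = PlastomeSequence("t", "ATGAAATAA", circular=False)
        pseudo = GeneAnnotation("p", "pseudogene", (Interval(0, 9),))
        trna = GeneAnnotation("t1", "tRNA", (Interval(0, 9),))
        assert extract_cds_codons(seq, [pseudo, trna]) == {}

    def test_remainder_truncated_with_warning(self):
        seq = PlastomeSequence("t", "ATGAAATA", circular=False)
        gene = GeneAnnotation("g", "protein_coding", (Interval(0, 8),))
        with pytest.warns(UserWarning, match="divisible by 3"):
            codons = extract_cds_codons(seq, [gene])
        assert codons["g"] == ["ATG", "AAA"]


class TestCount:
    def test_table2_amino_acid_totals(self, table2_table):
        assert table2_table.aa_totals["L"] == 2624  # leucine, the most prevalent
        assert table2_table.aa_totals["C"] == 323  # cysteine, the least

    def test_stop_codons_excluded(self):
        table = count_codons([["ATG", "TAA", "TGA", "TAG"]])
        assert table.total == 1 and table.counts["ATG"] == 1

    def test_empty_input_all_zero(self):
        table = count_codons([])
        assert table.total == 0

    def test_n_codons_dropped_and_tallied(self):
        table = count_codons([["ATG", "ANA"]])
        assert table.total == 1 and table.dropped_codons == 1

    def test_non_triplet_is_error(self):
        with pytest.raises(SchemaError):
            count_codons([["ATGA"]])

    def test_gene_order_invariance(self):
        lists = [["ATG", "AAA"], ["TTT", "TTC"], ["GGG"]]
        assert count_codons(lists).counts == count_codons(lists[::-1]).counts

    def test_totals_conserved(self, table2_table):
        assert sum(table2_table.aa_totals.values()) == table2_table.total


class TestRscu:
    def test_phe_two_fold_family_matches_print(self, table2_table):
        assert round_half_up(table2_table.rscu["TTT"]) == 1.23
        assert round_half_up(table2_table.rscu["TTC"]) == 0.77

    def test_all_two_fold_families_match_print(self, table2_table):
        df = load_fixture("table2")
        for _, row in df.iterrows():
            codon = row["codon_dna"]
            aa = {"Phe": "F", "Tyr": "Y", "His": "H", "Gln": "Q", "Asn": "N",
                  "Lys": "K", "Asp": "D", "Glu": "E", "Cys": "C"}.get(row["aa"])
            if aa is None:
                continue
            assert round_half_up(table2_table.rscu[codon]) == pytest.approx(
                row["rscu_printed"]
            ), codon

    def test_six_fold_family_standard_formula(self, table2_table):
        # printed 0.60 reflects a factor-2 convention; the standard formula
        # gives 785 * 6 / 2624
        assert round_half_up(table2_table.rscu["TTA"]) == 1.79

    def test_uniform_four_fold_family_is_one(self):
        counts = {c: 0 for c in SENSE_CODONS}
        for c in FAMILY["A"]:
            counts[c] = 7
        table = rscu(CodonUsageTable(counts=counts))
        assert all(table.rscu[c] == 1.0 for c in FAMILY["A"])

    def test_single_codon_families_are_one(self, table2_table):
        assert table2_table.rscu["ATG"] == 1.0
        assert table2_table.rscu["TGG"] == 1.0

    def test_zero_family_reported_missing(self):
        counts = {c: 0 for c in SENSE_CODONS}
        counts["TTT"] = 3
        table = rscu(CodonUsageTable(counts=counts))
        assert "GGA" not in table.rscu  # glycine uncounted -> missing, not 0

    @given(
        st.lists(st.integers(min_value=0, max_value=500), min_size=61, max_size=61)
    )
    def test_family_means_are_exactly_one(self, values):
        counts = dict(zip(SENSE_CODONS, values))
        table = rscu(CodonUsageTable(counts=counts))
        for aa, codons in FAMILY.items():
            total = sum(counts[c] for c in codons)
            if total == 0:
                continue
            mean = sum(
                Fraction(counts[c] * len(codons), total) for c in codons
            ) / len(codons)
            assert mean == 1


class TestThirdPositionBias:
    def test_only_at_ending_counted(self):
        counts = {c: 0 for c in SENSE_CODONS}
        counts["GCA"] = counts["GCT"] = 5
        assert third_position_at_bias(CodonUsageTable(counts=counts)) == 1.0

    def test_uniform_four_fold_is_half(self):
        counts = {c: 0 for c in SENSE_CODONS}
        for c in FAMILY["A"]:
            counts[c] = 9
        assert third_position_at_bias(CodonUsageTable(counts=counts)) == 0.5

    def test_fixture_shows_at_bias(self, table2_table):
        assert third_position_at_bias(table2_table) > 0.5
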