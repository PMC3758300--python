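"""Genome/annotation model, I/O and accounting operations."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

import _oracles
from plastkit.errors import (
    AlphabetError,
    CoordinateError,
    FormatError,
    SchemaError,
    UndefinedValueError,
)
from plastkit.model import (
    GeneAnnotation,
    Interval,
    PlastomeSequence,
    at_content,
    flag_truncated_copy,
    gc_content,
    gene_overlaps,
    read_annotation,
    read_genome,
    reverse_complement,
    write_annotation,
)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadGenome:
    def test_case_normalization(self, tmp_path):
        seq = read_genome(_write(tmp_path, "g.fa", ">g\nacgt\n"))
        assert seq.sequence == "ACGT" and len(seq) == 4

    def test_rna_mapped_to_dna(self, tmp_path):
        seq = read_genome(_write(tmp_path, "g.fa", ">g\nACGU\n"))
        assert seq.sequence == "ACGT"

    def test_empty_file_is_format_error(self, tmp_path):
        with pytest.raises(FormatError):
            read_genome(_write(tmp_path, "g.fa", ""))

    def test_bad_character_names_position(self, tmp_path):
        with pytest.raises(AlphabetError, match="position 2"):
            read_genome(_write(tmp_path, "g.fa", ">g\nACXGT\n"))


class TestAnnotationIO:
    def test_tsv_single_exon(self, tmp_path):
        path = _write(
            tmp_path, "a.tsv", "gene\tkind\texons\tstrand\tcopy_tag\n"
            "rps19\tprotein_coding\t10..288\t+\t\n"
        )
        (ann,) = read_annotation(path)
        assert ann.gene_name == "rps19"
        assert ann.intron_count == 0
        assert ann.total_length == 279  # 1-based inclusive span converted exactly

    def test_genbank_two_exons_one_intron(self, tmp_path):
        gbk = (
            "LOCUS       test                 100 bp    DNA     circular PLN 01-JAN-2000\n"
            "FEATURES             Location/Qualifiers\n"
            "     CDS             join(1..30,61..90)\n"
            '                     /gene="ycf3"\n'
            "ORIGIN\n"
            "        1 " + " ".join(["acgtacgtac"] * 6) + "\n"
            "       61 " + " ".join(["acgtacgtac"] * 4) + "\n"
            "//\n"
        )
        (ann,) = read_annotation(_write(tmp_path, "a.gbk", gbk))
        assert ann.intron_count == 1
        assert ann.feature_kind == "protein_coding"

    def test_end_before_start_is_coordinate_error(self, tmp_path):
        path = _write(tmp_path, "a.tsv", "g1\tprotein_coding\t50..10\t+\t\n")
        with pytest.raises(CoordinateError):
            read_annotation(path)

    def test_unknown_kind_is_schema_error(self, tmp_path):
        path = _write(tmp_path, "a.tsv", "g1\tmystery\t1..9\t+\t\n")
        with pytest.raises(SchemaError):
            read_annotation(path)

    def test_round_trip_identity(self, tmp_path):
        annotations = [
            GeneAnnotation("psbA", "protein_coding", (Interval(9, 288),), "-"),
            GeneAnnotation(
                "ycf3", "protein_coding", (Interval(300, 350), Interval(400, 460)), "+"
            ),
            GeneAnnotation("trnK", "tRNA", (Interval(500, 540),), "+", copy_tag="a"),
            GeneAnnotation("rps19", "pseudogene", (Interval(600, 774),), "+"),
        ]
        path = tmp_path / "round.tsv"
        write_annotation(annotations, path)
        assert read_annotation(path) == annotations

    def test_ir_duplicates_get_copy_tags(self, tmp_path):
        path = _write(
            tmp_path, "a.tsv",
            "ndhB\tprotein_coding\t1..30\t+\t\nndhB\tprotein_coding\t61..90\t-\t\n",
        )
        anns = read_annotation(path)
        assert {a.copy_tag for a in anns} == {"a", "b"}


class TestGeneOverlaps:
    def test_four_bp_overlap(self):
        atpB = GeneAnnotation("atpB", "protein_coding", (Interval(0, 100),))
        atpE = GeneAnnotation("atpE", "protein_coding", (Interval(96, 200),))
        assert gene_overlaps([atpB, atpE]) == [(("atpB", "atpE"), 4)]

    def test_disjoint_genes_empty(self):
        a = GeneAnnotation("a", "protein_coding", (Interval(0, 10),))
        b = GeneAnnotation("b", "protein_coding", (Interval(20, 30),))
        assert gene_overlaps([a, b]) == []

    def test_pseudo_ycf1_ndhF_57bp(self):
        # geometry of the pseudogene/ndhF junction overlap
        ndhF = GeneAnnotation("ndhF", "protein_coding", (Interval(1000, 3241),), "-")
        ycf1 = GeneAnnotation("ycf1", "pseudogene", (Interval(3184, 4300),), "+")
        assert gene_overlaps([ndhF, ycf1]) == [(("ndhF", "ycf1"), 57)]

    @given(st.permutations(range(4)))
    def test_permutation_invariance(self, order):
        genes = [
            GeneAnnotation("g1", "protein_coding", (Interval(0, 100),)),
            GeneAnnotation("g2", "protein_coding", (Interval(96, 200),)),
            GeneAnnotation("g3", "tRNA", (Interval(150, 260),)),
            GeneAnnotation("g4", "rRNA", (Interval(400, 500),)),
        ]
        shuffled = [genes[i] for i in order]
        assert gene_overlaps(shuffled) == gene_overlaps(genes)


class TestGcContent:
    @pytest.mark.parametrize(
        "text,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5)]
    )
    def test_known_values(self, text, expected):
        assert gc_content(PlastomeSequence("t", text)) == expected

    def test_matches_per_base_tally(self, rng, random_dna_factory):
        text = random_dna_factory(rng, 10_000)
        seq = PlastomeSequence("t", text)
        assert gc_content(seq) == pytest.approx(_oracles.gc_tally(text), abs=0)

    def test_complement_of_at_content(self, rng, random_dna_factory):
        seq = PlastomeSequence("t", random_dna_factory(rng, 5_000))
        assert gc_content(seq) + at_content(seq) == pytest.approx(1.0)

    def test_n_excluded_from_denominator(self):
        assert gc_content(PlastomeSequence("t", "GGNN")) == 1.0

    def test_zero_length_window_undefined(self):
        with pytest.raises(UndefinedValueError):
            gc_content(PlastomeSequence("t", "ACGT"), Interval(2, 2))


class TestTruncatedCopy:
    def test_rps19_fragment_geometry(self):
        fragment = GeneAnnotation("rps19", "protein_coding", (Interval(0, 174),))
        assert flag_truncated_copy(fragment, reference_length=279)

    @pytest.mark.parametrize("length,flagged", [(279, False), (280, False), (278, True)])
    def test_threshold_boundary(self, length, flagged):
        cand = GeneAnnotation("g", "protein_coding", (Interval(0, length),))
        assert flag_truncated_copy(cand, reference_length=279) is flagged


class TestSequenceBasics:
    def test_reverse_complement_involution(self, rng, random_dna_factory):
        text = random_dna_factory(rng, 300)
        assert reverse_complement(reverse_complement(text)) == text

    def test_circular_fetch_wraps(self):
        seq = PlastomeSequence("t", "ACGTAC", circular=True)
        assert seq.fetch(Interval(4, 8)) == "ACAC"

    def test_linear_fetch_out_of_range(self):
        seq = PlastomeSequence("t", "ACGTAC", circular=False)
        with pytest.raises(CoordinateError):
            seq.fetch(Interval(4, 8))
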