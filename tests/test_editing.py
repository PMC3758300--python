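"""Editing-site scoring, prediction, and summary statistics."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from plastkit.editing import (
    EditingSite,
    HomologPanel,
    classify_property_change,
    editing_score,
    predict_editing_sites,
    summarize_editing,
    validate_sites,
)
from plastkit.errors import AlphabetError, NotACandidateError, PanelAlignmentError
from plastkit.fixtures import load_fixture
from plastkit.simulate import make_homolog_panel


def _panel(gene, cols, n=10):
    return HomologPanel(target_gene=gene, columns=tuple(map(tuple, cols)), n_refs=n)


class TestScore:
    def test_full_support(self):
        panel = _panel("g", [["L"] * 10])
        assert editing_score(["TCA"], 0, 2, panel) == 1.0

    def test_no_support(self):
        panel = _panel("g", [["S"] * 10])
        assert editing_score(["TCA"], 0, 2, panel) == 0.0

    def test_boundary_eight_of_ten(self):
        panel = _panel("g", [["L"] * 8 + ["S"] * 2])
        assert editing_score(["TCA"], 0, 2, panel) == pytest.approx(0.8)

    def test_non_c_position_rejected(self):
        panel = _panel("g", [["L"] * 10])
        with pytest.raises(NotACandidateError):
            editing_score(["TCA"], 0, 1, panel)

    def test_silent_candidate_scores_zero(self):
        # ATC -> ATT is I -> I
        panel = _panel("g", [["L"] * 10])
        assert editing_score(["ATC"], 0, 3, panel) == 0.0

    def test_unrelated_residues_do_not_count(self):
        panel = _panel("g", [["K"] * 9 + ["L"]])
        assert editing_score(["TCA"], 0, 2, panel) == 1.0

    def test_gaps_excluded(self):
        panel = _panel("g", [["-"] * 10])
        assert editing_score(["TCA"], 0, 2, panel) == 0.0


class TestPredict:
    def test_acg_start_codon_restored(self):
        panel = _panel("ndhD", [["M"] * 10, ["K"] * 10])
        (site,) = predict_editing_sites(["ACG", "AAA"], panel)
        assert site.cds_position == 2
        assert site.codon_change == ("ACG", "ATG")
        assert site.aa_change == ("T", "M")

    def test_panel_identical_to_target_predicts_nothing(self):
        panel = _panel("g", [["S"], ["P"], ["K"]], n=1)
        assert predict_editing_sites(["TCA", "CCA", "AAA"], panel) == []

    def test_length_mismatch_is_alignment_error(self):
        panel = _panel("g", [["M"] * 10])
        with pytest.raises(PanelAlignmentError):
            predict_editing_sites(["ATG", "AAA"], panel)

    def test_planted_sites_fully_recovered(self):
        planted = [(i, 2 - (i % 2), 0.9) for i in range(3, 83, 4)]
        cds, panel, truth = make_homolog_panel(
            100, planted, panel_size=10, background_support=0.5, seed=11
        )
        sites = predict_editing_sites(cds, panel, cutoff=0.8)
        assert [s.cds_position for s in sites] == [t.cds_position for t in truth]
        assert len(sites) == 20

    @given(st.integers(0, 10))
    def test_cutoff_monotonicity(self, tenths):
        cutoff = max(tenths, 1) / 10
        cds, panel, _ = make_homolog_panel(
            40, [(5, 2, 0.6), (11, 1, 0.8), (17, 2, 1.0)], seed=4,
            background_support=0.3,
        )
        low = {s.cds_position for s in predict_editing_sites(cds, panel, cutoff)}
        higher = min(1.0, cutoff + 0.1)
        high = {s.cds_position for s in predict_editing_sites(cds, panel, higher)}
        assert high <= low


class TestPropertyChange:
    @pytest.mark.parametrize(
        "change,label",
        [
            (("S", "L"), "hydrophilic->hydrophobic"),
            (("P", "L"), "hydrophobic->hydrophobic"),
            (("P", "S"), "hydrophobic->hydrophilic"),
            (("D", "F"), "hydrophilic->hydrophobic"),
            (("H", "Y"), "hydrophilic->hydrophobic"),
        ],
    )
    def test_reported_transitions(self, change, label):
        assert classify_property_change(change) == label

    def test_unknown_residue(self):
        with pytest.raises(AlphabetError):
            classify_property_change(("S", "Z"))


@pytest.fixture(scope="module")
def table6():
    return load_fixture("table6")


class TestSummary:
    def test_confirmed_total_and_position_spectrum(self, table6):
        summary = summarize_editing(table6)
        assert summary.total == 75
        assert summary.by_codon_position == {1: 12, 2: 62, 3: 1}
        assert summary.position_percent[2] == 82.67

    def test_predicted_plus_unpredicted_partition_confirmed(self, table6):
        summary = summarize_editing(table6)
        assert summary.predicted_and_confirmed == 64
        assert summary.unpredicted_confirmed == 11
        assert summary.predicted_and_confirmed + summary.unpredicted_confirmed == 75

    def test_property_transitions(self, table6):
        summary = summarize_editing(table6)
        assert summary.property_transitions["hydrophilic->hydrophobic"] == 63
        assert summary.property_transitions["hydrophobic->hydrophobic"] == 11
        assert summary.property_transitions["hydrophobic->hydrophilic"] == 1

    def test_all_confirmed_changes_non_silent_and_c_to_u(self, table6):
        summary = summarize_editing(table6)
        assert summary.silent_count == 0
        assert summary.c_to_u_fraction == 1.0

    def test_position_counts_sum_to_total(self, table6):
        summary = summarize_editing(table6)
        assert sum(summary.by_codon_position.values()) == summary.total
        assert sum(summary.property_transitions.values()) == summary.total

    def test_partial_exclusion_changes_totals(self, table6):
        strict = summarize_editing(table6, confirmed_states={"edited"})
        assert strict.total < 75
        partials = sum(1 for s in table6 if s.rtpcr == "partial")
        assert strict.total + partials == 75

    def test_empty_input_all_zero(self):
        summary = summarize_editing([])
        assert summary.total == 0 and summary.predicted_and_confirmed == 0


class TestValidation:
    def test_printed_inconsistencies_flagged_not_corrected(self):
        table6 = load_fixture("table6")
        flags = validate_sites(table6)
        # matK 734 prints a synonymous codon change yet a D-F residue change
        assert any("matK:734" in f for f in flags)
        # ndhK 518 prints a T->C change, not C->T
        assert any("ndhK:518" in f for f in flags)
        # consistent rows are untouched
        assert not any("atpA:914" in f for f in flags)

    def test_consistent_site_passes(self):
        site = EditingSite(
            gene="g", cds_position=5, codon_change=("TCA", "TTA"),
            codon_position=2, aa_change=("S", "L"),
        )
        assert validate_sites([site]) == []
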