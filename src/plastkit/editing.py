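"""C-to-U RNA editing: conservation-based prediction and summary statistics.

Chloroplast transcripts of flowering plants undergo post-transcriptional
C-to-U editing, typically restoring codons for residues conserved in the
homologous proteins of other species.  The predictor here scores every
genomic C in a CDS by how strongly a panel of aligned homolog proteins
supports the *edited* translation over the unedited one:

    score = n_refs matching the edited residue
            / n_refs matching either the edited or the unedited residue

(0 when the denominator is 0, and 0 for silent candidates where editing
would not change the residue).  A site is called when score >= cutoff
(default 0.8, inclusive).

Summary statistics over observed-site tables (codon-position spectrum,
hydropathy-class transitions, predicted-and-confirmed tallies) use the
table's *printed* codon-position and amino-acid-change fields rather than
re-deriving them from the codon change, because published tables contain
internally inconsistent rows; :func:`validate_sites` flags such rows without
altering any count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .codons import round_half_up, translate
from .errors import AlphabetError, NotACandidateError, PanelAlignmentError

# Hydropathy classes: the minimal two-class table consistent with every
# transition reported for plastid editing sites (Y hydrophobic; D, S, T, H,
# R, G hydrophilic).
HYDROPHOBIC = frozenset("AVLIPFMWYC")
HYDROPHILIC = frozenset("RNDEQHKSTG")

RTPCR_STATES = ("edited", "partial", "unedited", "untested")
DEFAULT_CONFIRMED_STATES = frozenset({"edited", "partial"})

# Why a candidate C was not called.
REASON_BELOW_CUTOFF = "below_cutoff"
REASON_NO_PANEL = "gene_absent_from_panel"


@dataclass(frozen=True)
class EditingSite:
    """One candidate or observed C-to-U editing event."""

    gene: str
    cds_position: int  # 1-based nucleotide position within the CDS
    codon_change: tuple[str, str]  # genomic triplet -> edited triplet
    codon_position: int  # 1, 2 or 3
    aa_change: tuple[str, str]
    predicted: bool = False
    score: float | None = None
    rtpcr: str = "untested"
    shared_with_oil_palm: bool = False
    unpredicted_reason: str = ""

    def __post_init__(self):
        if self.codon_position not in (1, 2, 3):
            raise AlphabetError(f"codon_position must be 1..3, got {self.codon_position}")
        if self.rtpcr not in RTPCR_STATES:
            raise AlphabetError(f"unknown RT-PCR state {self.rtpcr!r}")


@dataclass(frozen=True)
class HomologPanel:
    """Aligned homolog residues per codon of a target gene.

    ``columns[i]`` holds the reference residues aligned to target codon
    ``i`` (0-based); gaps are '-'.
    """

    target_gene: str
    columns: tuple[tuple[str, ...], ...]
    n_refs: int

    def __post_init__(self):
        for i, col in enumerate(self.columns):
            if len(col) > self.n_refs:
                raise PanelAlignmentError(
                    f"column {i} has {len(col)} residues but panel declares "
                    f"{self.n_refs} references"
                )


@dataclass
class EditingSummary:
    """Aggregate statistics over a set of confirmed editing sites."""

    total: int = 0
    by_codon_position: dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})
    position_percent: dict[int, float] = field(
        default_factory=lambda: {1: 0.0, 2: 0.0, 3: 0.0}
    )
    c_to_u_fraction: float = 0.0
    silent_count: int = 0
    predicted_and_confirmed: int = 0
    unpredicted_confirmed: int = 0
    property_transitions: dict[str, int] = field(
        default_factory=lambda: {
            "hydrophilic->hydrophobic": 0,
            "hydrophobic->hydrophobic": 0,
            "hydrophilic->hydrophilic": 0,
            "hydrophobic->hydrophilic": 0,
        }
    )


def classify_property_change(aa_change: tuple[str, str]) -> str:
    """Hydropathy-class transition label for an amino-acid change."""
    labels = []
    for residue in aa_change:
        if residue in HYDROPHOBIC:
            labels.append("hydrophobic")
        elif residue in HYDROPHILIC:
            labels.append("hydrophilic")
        else:
            raise AlphabetError(f"unknown residue {residue!r}")
    return f"{labels[0]}->{labels[1]}"


def editing_score(
    cds_codons: list[str], codon_index: int, codon_position: int, panel: HomologPanel
) -> float:
    """Conservation support for editing the C at (codon_index, codon_position).

    Raises :class:`NotACandidateError` if the queried base is not a C.
    """
    codon = cds_codons[codon_index]
    if codon[codon_position - 1] != "C":
        raise NotACandidateError(
            f"codon {codon} position {codon_position} is "
            f"{codon[codon_position - 1]}, not C"
        )
    if codon_index >= len(panel.columns):
        raise PanelAlignmentError(
            f"codon index {codon_index} beyond panel of {len(panel.columns)} columns"
        )
    edited = codon[: codon_position - 1] + "T" + codon[codon_position:]
    aa_from, aa_to = translate(codon), translate(edited)
    if aa_from == aa_to:
        return 0.0
    refs = [r for r in panel.columns[codon_index] if r != "-"]
    support = sum(1 for r in refs if r == aa_to)
    against = sum(1 for r in refs if r == aa_from)
    if support + against == 0:
        return 0.0
    return support / (support + against)


def predict_editing_sites(
    cds_codons: list[str],
    panel: HomologPanel,
    cutoff: float = 0.8,
    include_unpredicted: bool = False,
) -> list[EditingSite]:
    """Evaluate every C of the CDS against the panel, calling sites at >= cutoff.

    Returns predicted sites in CDS-position order; with
    ``include_unpredicted=True`` sub-cutoff candidates are returned too,
    carrying a reason code.
    """
    if not 0 < cutoff <= 1:
        raise ValueError("cutoff must be in (0, 1]")
    if len(cds_codons) != len(panel.columns):
        raise PanelAlignmentError(
            f"CDS has {len(cds_codons)} codons but panel has "
            f"{len(panel.columns)} columns"
        )
    sites = []
    for idx, codon in enumerate(cds_codons):
        for pos in (1, 2, 3):
            if codon[pos - 1] != "C":
                continue
            score = editing_score(cds_codons, idx, pos, panel)
            edited = codon[: pos - 1] + "T" + codon[pos:]
            if translate(codon) == translate(edited):
                continue  # silent candidates are never called
            predicted = score >= cutoff
            if not predicted and not include_unpredicted:
                continue
            sites.append(
                EditingSite(
                    gene=panel.target_gene,
                    cds_position=idx * 3 + pos,
                    codon_change=(codon, edited),
                    codon_position=pos,
                    aa_change=(translate(codon), translate(edited)),
                    predicted=predicted,
                    score=score,
                    unpredicted_reason="" if predicted else REASON_BELOW_CUTOFF,
                )
            )
    return sites


def summarize_editing(
    sites: list[EditingSite],
    confirmed_states: frozenset[str] | set[str] = DEFAULT_CONFIRMED_STATES,
) -> EditingSummary:
    """Summary over sites whose RT-PCR state is in *confirmed_states*.

    Partial editing counts as confirmed by default.  Percentages are to two
    decimals; silent sites (printed amino-acid change with equal residues)
    are excluded from property transitions.  An empty input yields an
    all-zero summary.
    """
    confirmed = [s for s in sites if s.rtpcr in confirmed_states]
    summary = EditingSummary(total=len(confirmed))
    if not confirmed:
        return summary
    positions = Counter(s.codon_position for s in confirmed)
    for pos in (1, 2, 3):
        summary.by_codon_position[pos] = positions.get(pos, 0)
        summary.position_percent[pos] = round_half_up(
            100.0 * positions.get(pos, 0) / len(confirmed), 2
        )
    summary.c_to_u_fraction = sum(
        1
        for s in confirmed
        if _is_c_to_u(s.codon_change)
    ) / len(confirmed)
    summary.silent_count = sum(
        1 for s in confirmed if s.aa_change[0] == s.aa_change[1]
    )
    summary.predicted_and_confirmed = sum(1 for s in confirmed if s.predicted)
    summary.unpredicted_confirmed = sum(1 for s in confirmed if not s.predicted)
    for s in confirmed:
        if s.aa_change[0] == s.aa_change[1]:
            continue
        summary.property_transitions[classify_property_change(s.aa_change)] += 1
    return summary


def _is_c_to_u(codon_change: tuple[str, str]) -> bool:
    before, after = codon_change
    diffs = [(a, b) for a, b in zip(before, after) if a != b]
    return all(a == "C" and b == "T" for a, b in diffs) and bool(diffs)


def validate_sites(sites: list[EditingSite]) -> list[str]:
    """Flag rows whose printed fields are internally inconsistent.

    Checks that the codon change differs by exactly one C->T at the printed
    codon position and that the printed amino-acid change matches the codon
    change's translations.  Returns human-readable flags; never alters
    counts.
    """
    flags = []
    for s in sites:
        before, after = s.codon_change
        diffs = [i for i in range(3) if before[i] != after[i]]
        label = f"{s.gene}:{s.cds_position}"
        if diffs != [s.codon_position - 1]:
            flags.append(
                f"{label}: codon change {before}->{after} does not edit "
                f"printed codon position {s.codon_position}"
            )
        elif before[diffs[0]] != "C" or after[diffs[0]] != "T":
            flags.append(f"{label}: codon change {before}->{after} is not C->T")
        expected = (translate(before), translate(after))
        if expected != s.aa_change:
            flags.append(
                f"{label}: printed amino-acid change {s.aa_change[0]}-{s.aa_change[1]} "
                f"disagrees with codon change translation "
                f"{expected[0]}-{expected[1]}"
            )
    return flags
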