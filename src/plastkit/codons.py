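"""Codon counting and relative synonymous codon usage (RSCU).

Codons are gathered over the spliced exons of protein-coding genes only —
pseudogenes and RNA genes are skipped — and RSCU follows the standard
definition: the observed count of a codon times its synonymous-family size,
divided by the family total, so RSCU averages 1 within every family.

Plastid protein genes commonly start at non-AUG codons (ACG restored by RNA
editing, or GUG); such codons are counted as their literal triplets, and an
in-frame internal stop triggers a warning rather than an error, tolerating
annotation-level irregularities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction

from .errors import SchemaError
from .model import GeneAnnotation, PlastomeSequence, reverse_complement

log = logging.getLogger(__name__)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Standard genetic code over DNA triplets (identical to the plastid/bacterial
# code for amino-acid assignments of the 61 sense codons).
GENETIC_CODE: dict[str, str] = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            GENETIC_CODE[_b1 + _b2 + _b3] = _AA[_i * 16 + _j * 4 + _k]

SENSE_CODONS = tuple(sorted(c for c, a in GENETIC_CODE.items() if a != "*"))

FAMILY: dict[str, tuple[str, ...]] = {}
for _codon in SENSE_CODONS:
    FAMILY.setdefault(GENETIC_CODE[_codon], tuple())
FAMILY = {
    aa: tuple(c for c in SENSE_CODONS if GENETIC_CODE[c] == aa) for aa in FAMILY
}


def translate(codon: str) -> str:
    """One-letter amino acid (or '*' for a stop) of a DNA triplet."""
    return GENETIC_CODE[codon]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of printed codon tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CodonUsageTable:
    """Per-codon counts with optional RSCU values and per-amino-acid totals."""

    counts: dict[str, int]
    rscu: dict[str, float] | None = None
    source_gene_count: int = 0
    dropped_codons: int = 0  # codons containing N, excluded from counts

    @property
    def aa_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {aa: 0 for aa in FAMILY}
        for codon, count in self.counts.items():
            totals[GENETIC_CODE[codon]] += count
        return totals

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def extract_cds_codons(
    seq: PlastomeSequence, annotations: list[GeneAnnotation]
) -> dict[str, list[str]]:
    """Spliced, strand-corrected codon lists for every protein-coding gene.

    Exons are concatenated in ascending genomic order and reverse-complemented
    for minus-strand genes, restoring the reading frame across introns.  A
    concatenated length not divisible by 3 warns and drops the trailing
    remainder; codons containing N are dropped and tallied.
    """
    out: dict[str, list[str]] = {}
    for ann in annotations:
        if ann.feature_kind != "protein_coding":
            continue
        cds = "".join(seq.fetch(e) for e in ann.exons)
        if ann.strand == "-":
            cds = reverse_complement(cds)
        if len(cds) % 3:
            warnings.warn(
                f"gene {ann.key}: CDS length {len(cds)} not divisible by 3; "
                "truncating trailing remainder",
                stacklevel=2,
            )
            cds = cds[: len(cds) - len(cds) % 3]
        out[ann.key] = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    return out


def count_codons(gene_codons: dict[str, list[str]] | list[list[str]]) -> CodonUsageTable:
    """Aggregate codon counts over all genes, excluding stop codons.

    Codons containing N are dropped (tallied in ``dropped_codons``); an
    internal stop codon warns but counting continues.  Non-triplet tokens
    raise :class:`SchemaError`.
    """
    if isinstance(gene_codons, dict):
        gene_lists = list(gene_codons.values())
    else:
        gene_lists = list(gene_codons)
    counts = {c: 0 for c in SENSE_CODONS}
    dropped = 0
    for codons in gene_lists:
        for pos, codon in enumerate(codons):
            if len(codon) != 3 or not codon.isupper():
                raise SchemaError(f"not an uppercase DNA triplet: {codon!r}")
            if "N" in codon:
                dropped += 1
                continue
            if codon in STOP_CODONS:
                if pos != len(codons) - 1:
                    log.warning("internal stop codon %s at codon %d", codon, pos + 1)
                continue
            if codon not in counts:
                raise SchemaError(f"not a DNA codon: {codon!r}")
            counts[codon] += 1
    return CodonUsageTable(
        counts=counts, source_gene_count=len(gene_lists), dropped_codons=dropped
    )


def rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill the RSCU column: count * family size / family total.

    A family with zero total leaves its codons' RSCU missing (absent from the
    dict) rather than zero; single-codon families (Met, Trp) get RSCU 1 when
    counted at all.
    """
    totals = table.aa_totals
    values: dict[str, float] = {}
    for aa, codons in FAMILY.items():
        total = totals[aa]
        if total == 0:
            continue
        n_syn = len(codons)
        for codon in codons:
            values[codon] = float(Fraction(table.counts[codon] * n_syn, total))
    table.rscu = values
    return table


def third_position_at_bias(table: CodonUsageTable) -> float:
    """Fraction of synonymous third positions occupied by A or T.

    Computed over degenerate families only (Met and Trp excluded): the ratio
    of counts of codons ending in A/T to all counts in those families.
    """
    at = total = 0
    for aa, codons in FAMILY.items():
        if len(codons) == 1:
            continue
        for codon in codons:
            total += table.counts[codon]
            if codon[2] in "AT":
                at += table.counts[codon]
    if total == 0:
        from .errors import UndefinedValueError

        raise UndefinedValueError("no counted codons in degenerate families")
    return at / total


def usage_records(table: CodonUsageTable) -> list[dict]:
    """Flat per-codon records (codon, aa, count, rscu to 2 dp) for reporting."""
    rows = []
    for codon in SENSE_CODONS:
        aa = GENETIC_CODE[codon]
        value = None
        if table.rscu is not None and codon in table.rscu:
            value = round_half_up(table.rscu[codon], 2)
        rows.append(
            {"codon": codon, "aa": aa, "count": table.counts[codon], "rscu": value}
        )
    return rows
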