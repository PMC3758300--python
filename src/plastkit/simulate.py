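"""Seeded synthetic-data generators.

Every pipeline stage can be exercised without downloads: a quadripartite
genome builder with configurable LSC/SSC/IR lengths and repeat-free
single-copy regions, a repeat-fixture builder that embeds given repeat
units in repeat-free flanks, and a homolog-panel builder with planted
C-to-U edits at stated support fractions.  All generators are pure
functions of (spec, seed): the same inputs give byte-identical outputs.

Defaults mirror the dimensions of the coconut plastome (LSC 84,230 bp,
SSC 17,391 bp, IR 53,110 bp combined) and its AT-rich base composition
(GC ~0.37).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codons import SENSE_CODONS, translate
from .editing import EditingSite, HomologPanel
from .errors import GenerationError, SyntheticSpecError
from .model import Interval, PlastomeSequence, RegionPartition, reverse_complement
from .repeats import RepeatRecord

COCONUT_LSC = 84_230
COCONUT_SSC = 17_391
COCONUT_IR = 53_110  # combined length of both copies

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic quadripartite genome."""

    seed: int = 0
    lsc_length: int = COCONUT_LSC
    ssc_length: int = COCONUT_SSC
    ir_length: int = COCONUT_IR  # both copies combined; must be even
    gc: float = 0.37
    ir_free_floor: int = 40  # no unplanned inverted match at or above this length
    max_retries: int = 20

    def __post_init__(self):
        if min(self.lsc_length, self.ssc_length, self.ir_length) <= 0:
            raise SyntheticSpecError("region lengths must be positive")
        if self.ir_length % 2:
            raise SyntheticSpecError("combined IR length must split evenly into two copies")
        if not 0 < self.gc < 1:
            raise SyntheticSpecError("gc must be in (0, 1)")

    @property
    def genome_length(self) -> int:
        return self.lsc_length + self.ssc_length + self.ir_length


def _random_dna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def _inverted_matches(s: str, k: int):
    """Yield (i, j) pairs where s[i:i+k] == revcomp(s[j:j+k]), i <= j."""
    index: dict[str, list[int]] = {}
    for i in range(len(s) - k + 1):
        index.setdefault(s[i : i + k], []).append(i)
    rc = reverse_complement(s)
    n = len(s)
    for jr in range(n - k + 1):
        hits = index.get(rc[jr : jr + k])
        if not hits:
            continue
        j = n - jr - k  # inverted occurrence position on the forward strand
        for i in hits:
            if i <= j:
                yield i, j


def make_quadripartite_genome(
    spec: SyntheticSpec,
) -> tuple[PlastomeSequence, RegionPartition]:
    """Generate genome = LSC + IRb + SSC + revcomp(IRb) with its truth partition.

    Single-copy regions are resampled (bounded retries) until the only
    inverted self-matches of length >= ``spec.ir_free_floor`` are the planted
    IR pair itself, so IR detection at any floor above ``ir_free_floor``
    recovers the truth exactly.
    """
    if spec.ir_length >= spec.genome_length:
        raise SyntheticSpecError("IR cannot exceed the genome")
    rng = np.random.default_rng(spec.seed)
    half = spec.ir_length // 2
    lsc_iv = Interval(0, spec.lsc_length)
    irb_iv = Interval(spec.lsc_length, spec.lsc_length + half)
    ssc_iv = Interval(irb_iv.end, irb_iv.end + spec.ssc_length)
    ira_iv = Interval(ssc_iv.end, ssc_iv.end + half)
    for _ in range(spec.max_retries):
        lsc = _random_dna(rng, spec.lsc_length, spec.gc)
        irb = _random_dna(rng, half, spec.gc)
        ssc = _random_dna(rng, spec.ssc_length, spec.gc)
        genome = lsc + irb + ssc + reverse_complement(irb)
        # the planted pair must not be extensible by chance into its flanks:
        # extending IRb right pairs the SSC's first and last bases; extending
        # IRb left pairs the LSC's last base with the circular origin
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        extensible = (
            genome[ssc_iv.start] == comp[genome[ssc_iv.end - 1]]
            or genome[lsc_iv.end - 1] == comp[genome[0]]
        )
        if not extensible and _only_planted_inversions(
            genome, spec.ir_free_floor, irb_iv, ira_iv
        ):
            seq = PlastomeSequence("synthetic-plastome", genome, circular=True)
            truth = RegionPartition(
                lsc=lsc_iv,
                irb=irb_iv,
                ssc=ssc_iv,
                ira=ira_iv,
                genome_length=spec.genome_length,
                origin_offset=0,
            )
            return seq, truth
    raise GenerationError(
        f"could not generate IR-free single-copy regions in {spec.max_retries} tries"
    )


def _only_planted_inversions(
    genome: str, floor: int, irb: Interval, ira: Interval
) -> bool:
    k = min(floor, len(genome))
    for i, j in _inverted_matches(genome, k):
        i_ok = (irb.start <= i and i + k <= irb.end) or (
            ira.start <= i and i + k <= ira.end
        )
        j_ok = (irb.start <= j and j + k <= irb.end) or (
            ira.start <= j and j + k <= ira.end
        )
        if not (i_ok and j_ok):
            return False
    return True


# ---------------------------------------------------------------------------
# Repeat fixtures


def make_repeat_fixture(
    records: list[RepeatRecord],
    seed: int = 0,
    spacer: int = 60,
    gc: float = 0.37,
    min_period: int = 11,
    max_retries: int = 100,
) -> tuple[PlastomeSequence, list[RepeatRecord]]:
    """Embed repeat units in repeat-free flanks, preserving arrangement.

    Records are grouped into clusters of mutually overlapping placements
    (relative offsets inside a cluster are preserved exactly, so tandem
    spacing and nested units survive); clusters are laid out left to right
    separated by *spacer* bp.  Records flagged ``is_rc_partner`` embed the
    reverse complement of their unit.  Spacers and flanks are resampled
    until no k-mer of length *min_period* repeats (forward or inverted)
    outside the planted spans.

    Returns the sequence plus the truth records with remapped positions.
    """
    if not records:
        raise SyntheticSpecError("no records to embed")
    placements = []  # (orig_pos, unit_text, record_idx, copy_idx)
    for ri, rec in enumerate(records):
        text = reverse_complement(rec.unit) if rec.is_rc_partner else rec.unit
        for ci, pos in enumerate(rec.positions):
            placements.append((pos, text, ri, ci))
    placements.sort()

    # cluster by span overlap/adjacency in the original coordinates
    clusters: list[list[tuple[int, str, int, int]]] = []
    cluster_end = None
    for p in placements:
        if cluster_end is None or p[0] > cluster_end:
            clusters.append([p])
        else:
            clusters[-1].append(p)
        end = p[0] + len(p[1])
        cluster_end = end if cluster_end is None else max(cluster_end, end)

    # remap: lay clusters out with `spacer` bp between them and at both ends
    new_positions: dict[tuple[int, int], int] = {}
    chunks: list[tuple[int, str]] = []  # (new_pos, text)
    cursor = spacer
    for cluster in clusters:
        base = cluster[0][0]
        span_end = max(p[0] + len(p[1]) for p in cluster)
        for pos, text, ri, ci in cluster:
            new_pos = cursor + (pos - base)
            new_positions[(ri, ci)] = new_pos
            chunks.append((new_pos, text))
        cursor += (span_end - base) + spacer
    total = cursor

    # overlapping placements (nested units) must agree wherever they coincide
    written: dict[int, str] = {}
    for pos, text in chunks:
        for i, ch in enumerate(text):
            if written.get(pos + i, ch) != ch:
                raise SyntheticSpecError(
                    f"conflicting overlapping units at fixture position {pos + i}"
                )
            written[pos + i] = ch

    rng = np.random.default_rng(seed)
    # merge abutting/overlapping placements (tandem arrays, nested units)
    # into maximal planted blocks for the containment check below
    planted_spans: list[tuple[int, int]] = []
    for a, b in sorted((pos, pos + len(text)) for pos, text in chunks):
        if planted_spans and a <= planted_spans[-1][1]:
            planted_spans[-1] = (planted_spans[-1][0], max(planted_spans[-1][1], b))
        else:
            planted_spans.append((a, b))
    for _ in range(max_retries):
        background = list(_random_dna(rng, total, gc))
        for pos, ch in written.items():
            background[pos] = ch
        genome = "".join(background)
        if _collisions_confined(genome, min_period, planted_spans):
            truth = [
                RepeatRecord(
                    unit=rec.unit,
                    period=rec.period,
                    copies=rec.copies,
                    positions=tuple(
                        new_positions[(ri, ci)] for ci in range(len(rec.positions))
                    ),
                    repeat_type=rec.repeat_type,
                    region_note=rec.region_note,
                    is_rc_partner=rec.is_rc_partner,
                )
                for ri, rec in enumerate(records)
            ]
            return PlastomeSequence("repeat-fixture", genome, circular=False), truth
    raise GenerationError(
        f"could not generate repeat-free spacers in {max_retries} tries"
    )


def _collisions_confined(s: str, k: int, spans: list[tuple[int, int]]) -> bool:
    """Every duplicated k-mer (forward or inverted) must lie fully inside a
    planted span.

    Requiring containment (not mere overlap) also rejects backgrounds where a
    planted copy is extensible by chance into its flank, because the extended
    duplicate's boundary-crossing k-mers stick out of the spans.
    """

    def inside(pos: int) -> bool:
        return any(a <= pos and pos + k <= b for a, b in spans)

    index: dict[str, list[int]] = {}
    for i in range(len(s) - k + 1):
        index.setdefault(s[i : i + k], []).append(i)
    for kmer, positions in index.items():
        if len(positions) > 1 and not all(inside(p) for p in positions):
            return False
    rc = reverse_complement(s)
    n = len(s)
    for jr in range(n - k + 1):
        hits = index.get(rc[jr : jr + k])
        if not hits:
            continue
        j = n - jr - k
        for i in hits:
            if not (inside(i) and inside(j)):
                return False
    return True


# ---------------------------------------------------------------------------
# Homolog panels with planted edits


def make_homolog_panel(
    n_codons: int,
    planted_edits: list[tuple[int, int, float]],
    panel_size: int = 10,
    background_support: float = 0.0,
    seed: int = 0,
    gene: str = "synthetic-gene",
) -> tuple[list[str], HomologPanel, list[EditingSite]]:
    """CDS plus an aligned homolog panel with C-to-U edits planted.

    ``planted_edits`` is a list of (codon_index, codon_position, support):
    at each planted site the CDS carries a C whose C->T edit is non-silent,
    and ``floor(support * panel_size)`` references carry the *edited*
    residue (the rest the unedited one), so the conservation score equals
    the realised support exactly.  All other columns agree with the
    unedited translation, except that other editable Cs receive
    ``floor(background_support * panel_size)`` edited-residue references.

    Returns (cds codons, panel, truth sites); the truth site's ``score``
    field holds the realised support fraction.
    """
    if not 0 <= background_support <= 1:
        raise SyntheticSpecError("background_support must be in [0, 1]")
    rng = np.random.default_rng(seed)
    planted = {}
    for idx, pos, support in planted_edits:
        if not 0 <= idx < n_codons:
            raise SyntheticSpecError(f"planted codon index {idx} outside CDS")
        if pos not in (1, 2):
            raise SyntheticSpecError(
                "plantable C-to-U edits must be at codon position 1 or 2 "
                "(all third-position C->T changes are silent)"
            )
        if not 0 <= support <= 1:
            raise SyntheticSpecError("support fractions must be in [0, 1]")
        planted[idx] = (pos, support)

    def editable(codon: str, pos: int) -> bool:
        if codon[pos - 1] != "C":
            return False
        edited = codon[: pos - 1] + "T" + codon[pos:]
        return translate(edited) not in ("*", translate(codon))

    plantable = {
        pos: [c for c in SENSE_CODONS if editable(c, pos)] for pos in (1, 2)
    }
    background_codons = [c for c in SENSE_CODONS if c != "ATG"]

    cds: list[str] = []
    for idx in range(n_codons):
        if idx in planted:
            pos, _ = planted[idx]
            codon = plantable[pos][rng.integers(len(plantable[pos]))]
        elif idx == 0:
            codon = "ATG"
        else:
            codon = background_codons[rng.integers(len(background_codons))]
        cds.append(codon)

    columns = []
    truth = []
    for idx, codon in enumerate(cds):
        aa = translate(codon)
        if idx in planted:
            pos, support = planted[idx]
            edited = codon[: pos - 1] + "T" + codon[pos:]
            aa_to = translate(edited)
            n_edit = int(np.floor(support * panel_size))
            col = [aa_to] * n_edit + [aa] * (panel_size - n_edit)
            truth.append(
                EditingSite(
                    gene=gene,
                    cds_position=idx * 3 + pos,
                    codon_change=(codon, edited),
                    codon_position=pos,
                    aa_change=(aa, aa_to),
                    predicted=True,
                    score=n_edit / panel_size,
                )
            )
        else:
            col = [aa] * panel_size
            n_bg = int(np.floor(background_support * panel_size))
            if n_bg:
                for pos in (1, 2, 3):
                    if editable(codon, pos):
                        edited = codon[: pos - 1] + "T" + codon[pos:]
                        col = [translate(edited)] * n_bg + [aa] * (panel_size - n_bg)
                        break
        columns.append(tuple(col))
    panel = HomologPanel(target_gene=gene, columns=tuple(columns), n_refs=panel_size)
    return cds, panel, truth
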