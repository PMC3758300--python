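"""Core data model for plastid genomes.

Sequences, gene annotations and the quadripartite region partition, plus the
small accounting operations built directly on them (GC content, gene-pair
overlaps, truncated-copy flagging).

Coordinate convention: everything internal is 0-based, half-open.  The
GenBank / annotation-TSV convention (1-based, inclusive, ``start..end``) is
converted at the I/O boundary and nowhere else.  Features of a circular
genome may wrap the origin; a wrapping feature is stored as two intervals
with ``wraps=True``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

from Bio import SeqIO

from .errors import (
    AlphabetError,
    CoordinateError,
    FormatError,
    SchemaError,
    UndefinedValueError,
)

DNA_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_KINDS = ("protein_coding", "tRNA", "rRNA", "pseudogene")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval [start, end)."""

    start: int
    end: int

    def __post_init__(self):
        if self.end < self.start:
            raise CoordinateError(f"interval end {self.end} < start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "Interval") -> int:
        """Length of the intersection with *other* (0 when disjoint)."""
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass(frozen=True)
class PlastomeSequence:
    """A plastid genome sequence.

    Parameters
    ----------
    identifier:
        Free-text label (FASTA header word).
    sequence:
        Uppercase DNA over {A,C,G,T,N}.
    circular:
        Topology flag; positions on circular genomes are taken modulo the
        length where the operation supports wrapping.
    """

    identifier: str
    sequence: str
    circular: bool = True

    def __post_init__(self):
        if not self.sequence:
            raise FormatError("empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            pos = next(i for i, c in enumerate(self.sequence) if c in bad)
            raise AlphabetError(
                f"character {self.sequence[pos]!r} at position {pos} "
                f"is outside the DNA alphabet {{A,C,G,T,N}}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, interval: Interval) -> str:
        """Sequence of *interval*; wraps the origin on circular genomes."""
        n = len(self.sequence)
        if interval.end <= n:
            return self.sequence[interval.start : interval.end]
        if not self.circular:
            raise CoordinateError(f"interval {interval} outside linear genome of {n} bp")
        if len(interval) > n:
            raise CoordinateError("interval longer than the genome")
        return self.sequence[interval.start :] + self.sequence[: interval.end % n]

    def reverse_complement(self) -> "PlastomeSequence":
        return replace(self, sequence=reverse_complement(self.sequence))


@dataclass(frozen=True)
class GeneAnnotation:
    """One annotated feature (gene, tRNA, rRNA or pseudogene).

    ``exons`` are ascending genomic intervals; for a minus-strand gene the
    coding order is the reverse of the stored order.  ``intron_count`` always
    equals the number of gaps between exons.  ``copy_tag`` disambiguates
    IR-duplicated genes that share a name.
    """

    gene_name: str
    feature_kind: str
    exons: tuple[Interval, ...]
    strand: str = "+"
    copy_tag: str = ""
    wraps: bool = False

    def __post_init__(self):
        if self.feature_kind not in FEATURE_KINDS:
            raise SchemaError(
                f"unknown feature kind {self.feature_kind!r}; expected one of {FEATURE_KINDS}"
            )
        if not self.exons:
            raise SchemaError(f"gene {self.gene_name}: no exons")
        if self.strand not in "+-":
            raise SchemaError(f"gene {self.gene_name}: strand must be '+' or '-'")
        if not self.wraps:
            for a, b in zip(self.exons, self.exons[1:]):
                if b.start < a.end:
                    raise CoordinateError(
                        f"gene {self.gene_name}: exons overlap or are unordered"
                    )

    @property
    def intron_count(self) -> int:
        return len(self.exons) - 1

    @property
    def total_length(self) -> int:
        return sum(len(e) for e in self.exons)

    @property
    def span(self) -> Interval:
        return Interval(self.exons[0].start, self.exons[-1].end)

    @property
    def key(self) -> str:
        return f"{self.gene_name}#{self.copy_tag}" if self.copy_tag else self.gene_name


@dataclass(frozen=True)
class RegionPartition:
    """LSC / IRb / SSC / IRa decomposition of a circular plastid genome.

    Intervals are expressed in the canonical rotation (LSC starts at 0);
    ``origin_offset`` records the position in the original coordinate system
    that became canonical position 0, so annotations in original coordinates
    can be mapped with ``(pos - origin_offset) % genome_length``.
    """

    lsc: Interval
    irb: Interval
    ssc: Interval
    ira: Interval
    genome_length: int
    origin_offset: int = 0

    def __post_init__(self):
        total = len(self.lsc) + len(self.irb) + len(self.ssc) + len(self.ira)
        if total != self.genome_length:
            raise CoordinateError(
                f"regions sum to {total} but genome is {self.genome_length} bp"
            )

    @property
    def ir_length(self) -> int:
        """Combined length of both inverted-repeat copies."""
        return len(self.irb) + len(self.ira)

    @property
    def junctions(self) -> dict[str, int]:
        """Canonical-frame positions of the four junctions (point between regions)."""
        return {
            "LSC/IRb": self.lsc.end,
            "IRb/SSC": self.irb.end,
            "SSC/IRa": self.ssc.end,
            "IRa/LSC": self.ira.end % self.genome_length,
        }

    def to_dict(self) -> dict:
        return {
            "genome_length": self.genome_length,
            "origin_offset": self.origin_offset,
            "lsc": [self.lsc.start, self.lsc.end],
            "irb": [self.irb.start, self.irb.end],
            "ssc": [self.ssc.start, self.ssc.end],
            "ira": [self.ira.start, self.ira.end],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegionPartition":
        return cls(
            lsc=Interval(*d["lsc"]),
            irb=Interval(*d["irb"]),
            ssc=Interval(*d["ssc"]),
            ira=Interval(*d["ira"]),
            genome_length=d["genome_length"],
            origin_offset=d.get("origin_offset", 0),
        )


# ---------------------------------------------------------------------------
# I/O


def read_genome(path) -> PlastomeSequence:
    """Read the first record of a FASTA file as a plastid genome.

    The sequence is uppercased and RNA U is mapped to T.  Characters outside
    {A,C,G,T,N,U} raise :class:`AlphabetError` naming the offending position.
    """
    records = SeqIO.parse(str(path), "fasta")
    try:
        rec = next(records)
    except StopIteration:
        raise FormatError(f"{path}: no FASTA records found") from None
    seq = str(rec.seq).upper().replace("U", "T")
    return PlastomeSequence(identifier=rec.id or "genome", sequence=seq)


_EXON_RE = re.compile(r"^(\d+)\.\.(\d+)$")


def _parse_exon_field(text: str, gene: str, strand: str) -> tuple[Interval, ...]:
    exons = []
    for token in text.split(","):
        m = _EXON_RE.match(token.strip())
        if not m:
            raise SchemaError(f"gene {gene}: malformed exon token {token!r}")
        start1, end1 = int(m.group(1)), int(m.group(2))
        if end1 < start1:
            raise CoordinateError(
                f"gene {gene}: exon end {end1} < start {start1} on {strand} strand"
            )
        exons.append(Interval(start1 - 1, end1))  # 1-based inclusive -> 0-based half-open
    return tuple(sorted(exons, key=lambda e: e.start))


def read_annotation(path, genome_length: int | None = None) -> list[GeneAnnotation]:
    """Read gene annotations from a TSV table or a GenBank flat file.

    The TSV schema is ``gene  kind  exons  strand  copy_tag`` with exons as
    comma-separated ``start..end`` (1-based inclusive).  GenBank files are
    read through Biopython; CDS/tRNA/rRNA features are kept and features with
    a ``/pseudo`` qualifier become pseudogenes.  Duplicate gene names get
    ``copy_tag`` suffixes ("a", "b", ...) when the table does not supply one.
    """
    path = str(path)
    if path.endswith((".gb", ".gbk", ".genbank")):
        annotations = _read_genbank(path)
    else:
        annotations = _read_tsv(path)
    if genome_length is not None:
        for ann in annotations:
            for exon in ann.exons:
                if exon.end > genome_length:
                    raise CoordinateError(
                        f"gene {ann.gene_name}: exon {exon.start+1}..{exon.end} "
                        f"outside genome of {genome_length} bp"
                    )
    return _disambiguate(annotations)


def _read_tsv(path: str) -> list[GeneAnnotation]:
    annotations = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise SchemaError(f"{path}: expected >=4 tab-separated columns: {line!r}")
            gene, kind, exon_text, strand = fields[:4]
            copy_tag = fields[4] if len(fields) > 4 else ""
            exons = _parse_exon_field(exon_text, gene, strand)
            annotations.append(
                GeneAnnotation(gene, kind, exons, strand=strand, copy_tag=copy_tag)
            )
    return annotations


_GENBANK_KINDS = {"CDS": "protein_coding", "tRNA": "tRNA", "rRNA": "rRNA"}


def _read_genbank(path: str) -> list[GeneAnnotation]:
    try:
        rec = next(SeqIO.parse(path, "genbank"))
    except StopIteration:
        raise FormatError(f"{path}: no GenBank records found") from None
    annotations = []
    for feat in rec.features:
        if feat.type not in _GENBANK_KINDS:
            continue
        kind = _GENBANK_KINDS[feat.type]
        if "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers:
            kind = "pseudogene"
        name = feat.qualifiers.get("gene", feat.qualifiers.get("locus_tag", ["?"]))[0]
        strand = "-" if feat.location.strand == -1 else "+"
        exons = tuple(
            sorted(
                (Interval(int(p.start), int(p.end)) for p in feat.location.parts),
                key=lambda e: e.start,
            )
        )
        annotations.append(GeneAnnotation(name, kind, exons, strand=strand))
    return annotations


def _disambiguate(annotations: list[GeneAnnotation]) -> list[GeneAnnotation]:
    from collections import Counter

    names = Counter(a.gene_name for a in annotations if not a.copy_tag)
    seen: Counter = Counter()
    out = []
    for ann in annotations:
        if not ann.copy_tag and names[ann.gene_name] > 1:
            tag = chr(ord("a") + seen[ann.gene_name])
            seen[ann.gene_name] += 1
            ann = replace(ann, copy_tag=tag)
        out.append(ann)
    return out


def write_annotation(annotations: list[GeneAnnotation], path) -> None:
    """Write annotations to the TSV schema read by :func:`read_annotation`."""
    with open(path, "w") as fh:
        fh.write("gene\tkind\texons\tstrand\tcopy_tag\n")
        for ann in annotations:
            exon_text = ",".join(f"{e.start + 1}..{e.end}" for e in ann.exons)
            fh.write(
                f"{ann.gene_name}\t{ann.feature_kind}\t{exon_text}\t{ann.strand}\t{ann.copy_tag}\n"
            )


# ---------------------------------------------------------------------------
# Accounting operations


def gc_content(seq: PlastomeSequence, window: Interval | None = None) -> float:
    """GC fraction (G+C)/(A+C+G+T) over *window* (whole genome by default).

    N bases are excluded from the denominator.  A window with no A/C/G/T
    raises :class:`UndefinedValueError`.
    """
    text = seq.fetch(window) if window is not None else seq.sequence
    gc = text.count("G") + text.count("C")
    acgt = gc + text.count("A") + text.count("T")
    if acgt == 0:
        raise UndefinedValueError("GC content undefined: window contains no A/C/G/T")
    return gc / acgt


def at_content(seq: PlastomeSequence, window: Interval | None = None) -> float:
    """AT fraction; complements :func:`gc_content` for N-free sequences."""
    text = seq.fetch(window) if window is not None else seq.sequence
    at = text.count("A") + text.count("T")
    acgt = at + text.count("G") + text.count("C")
    if acgt == 0:
        raise UndefinedValueError("AT content undefined: window contains no A/C/G/T")
    return at / acgt


def gene_overlaps(
    annotations: list[GeneAnnotation],
) -> list[tuple[tuple[str, str], int]]:
    """All unordered pairs of distinct genes whose exons intersect.

    Returns ``((name_a, name_b), overlap_bp)`` sorted by overlap length
    descending (ties by name pair), where overlap_bp is the total number of
    bases covered by exons of both genes.
    """
    results = []
    anns = sorted(annotations, key=lambda a: a.key)
    for i, a in enumerate(anns):
        for b in anns[i + 1 :]:
            if a.span.overlap(b.span) == 0:
                continue
            bp = sum(ea.overlap(eb) for ea in a.exons for eb in b.exons)
            if bp > 0:
                results.append(((a.key, b.key), bp))
    results.sort(key=lambda r: (-r[1], r[0]))
    return results


def flag_truncated_copy(
    candidate: GeneAnnotation, reference_length: int, threshold: float = 1.0
) -> bool:
    """True iff the candidate's total exon length is shorter than
    ``threshold * reference_length``.

    This is the truncation evidence used to call an IR-junction gene fragment
    a likely pseudogene (e.g. a 174 bp rps19-like fragment against the 279 bp
    full-length gene).  It is a helper, not an automatic reclassifier:
    annotations marked pseudogene are taken as given.
    """
    if reference_length <= 0:
        raise UndefinedValueError("reference_length must be positive")
    return candidate.total_length < threshold * reference_length
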