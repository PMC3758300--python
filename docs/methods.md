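# Methods

This note documents the models, conventions and numerical choices behind
plastkit, and what the synthetic generators do and do not emulate.

## Coordinates and sequence model

All internal coordinates are 0-based half-open; the GenBank/TSV convention
(1-based inclusive `start..end`) is converted at the I/O boundary only, and
repeat reports are serialised 1-based to mirror the published table layout.
Genomes are circular by default; features may wrap the origin and are then
stored as two intervals with a wrap flag. The alphabet is {A,C,G,T,N}; N is
tolerated in sequences but treated as matching nothing in exact-identity
comparisons, so an N inside a claimed IR copy breaks the pair.

## Inverted-repeat detection and partitioning

The two IR copies are required to be exact reverse complements — the genome
is analysed as assembled, and a mismatch-tolerant mode is deliberately out
of scope. Detection is seed-and-extend: k-mer anchors (k = min(floor, 32))
between the genome and its reverse complement are grouped by diagonal and
extended maximally; the longest non-overlapping pair wins, with ties broken
by the smaller, then the larger, start coordinate. Circular genomes are
searched on the doubled sequence with arcs compared modulo the length. The
detection floor defaults to 1,000 bp: plastid IRs are tens of kb, and a
high floor excludes the short incidental inverted matches any AT-rich
sequence contains. The floor is a parameter, not a property of the data.

Partitioning labels the longer single-copy gap LSC and the shorter SSC
(tie: the segment following the first IR copy is the SSC), rotates the
circle so the LSC starts at 0, and records the rotation as
`origin_offset`. The published combined figure for the IRs (53,110 bp) is
interpreted as the sum of both copies (each 26,555 bp), which is the only
reading under which the four region lengths sum to the printed total of
154,731 bp.

Junction distances are measured from the nearer gene end to the nearer of
the four junctions; a junction falling strictly inside a gene takes
precedence and is reported as a negative distance equal to the smaller
overhang, which reproduces the convention of IR-boundary comparison
figures (e.g. a 174 bp rps19-like overhang into the IR reports −174).

## Codon usage

Codons are gathered over all exons of protein-coding genes, spliced in
genomic order and reverse-complemented for minus-strand genes; pseudogenes
and RNA genes are skipped. Stop codons are excluded from the usage table.
A CDS length not divisible by three warns and drops the remainder; an
internal stop warns but counting continues, since plastid annotations
legitimately contain non-AUG initiators (ACG starts restored by RNA
editing, GUG starts) and editing-dependent codons. Alternative start
codons are counted as their literal triplets — no editing-aware recoding
at the counting stage.

RSCU is the standard statistic, count × family size / family total,
computed in exact rational arithmetic before rounding, and reported to two
decimals with round-half-away-from-zero. The packaged codon table's
printed RSCU column follows a non-standard convention for families larger
than two (its values are consistent with a factor of 2 applied regardless
of family size); the package computes the standard definition and the
fixture retains the printed column verbatim for comparison. The two
conventions coincide exactly on two-fold families, which is where printed
values are asserted.

The third-position A/T bias is the fraction of counted codons ending in A
or T over degenerate families only (Met and Trp excluded).

## Repeat detection

Reported families satisfy: unit length ≥ 11 bp (the "longer than 10 bp"
rule, which also suppresses mono- and dinucleotide microsatellites),
period ≤ 500 bp, 100% identity between copies, and either ≥ 2 same-strand
copies or a reverse-complement partner. No alignment-score threshold is
applied: the published table's 12 bp × 3 families are incompatible with
the score-80 setting its methods section quotes, so the criteria the
results actually reflect take precedence.

Tandem arrays are found per period with a vectorised match-at-offset scan:
a maximal run of `s[i] == s[i+p]` of length ≥ p is an array of ⌊span/p⌋
full copies, reported at the smallest period of its span (sub-periodicity
spans contained in a smaller-period array are dropped). Dispersed families
come from an LCP-interval enumeration over `s#revcomp(s)$`: each
left-diverse interval is a maximal repeat — extending the unit on either
side would lose an occurrence — with forward and inverted occurrences
separated. Families are oriented toward their majority-copy side (tie:
first locus), so a 2-copies-plus-inverted-partner family reports the
same-strand pair as the primary direct/tandem record and the partner locus
as its own single-copy inverted record, matching the published table's
row convention; this orientation rule also makes T/D/I labels strand
symmetric. Dispersed candidates wholly contained in a reported tandem
array's span (the array's internal self-overlap) are suppressed, as are
units whose own minimal period is below the floor. Units longer than the
period cap are not reported — which is also why the IR pair itself never
appears as a "repeat". The detector is validated against a brute-force
per-length hashing oracle implementing the same contract on 50 seeded
200–500 bp sequences.

Classification from records alone (as when re-deriving the published
table): tandem if any two consecutive copies abut at exactly one period;
direct otherwise for ≥ 2 copies; a single-copy record is inverted when its
unit (or the unit's reverse complement) matches another record in the
batch, and is dropped with a warning otherwise.

## RNA editing

The predictor scores each genomic C by conservation of the *edited*
translation in a panel of aligned homolog proteins:
`support / (support + against)`, where support counts references equal to
the edited residue and against those equal to the unedited one; other
residues and gaps are uninformative, an empty denominator scores 0, and
silent candidates score 0 (all third-position C→T changes are silent, so
plantable edits are first/second-position). The cutoff comparison is
inclusive (≥ 0.8). This scoring function is the package's own definition
of conservation support; the published predictor's internals are not
public, and its absolute site count (83 predictions from a 35-gene
reference set) is correspondingly not a target.

Summary statistics over observed-site tables use the table's printed
codon-position and amino-acid-change fields rather than re-deriving them
from the codon change, because several published rows are internally
inconsistent (a synonymous codon change printed as non-silent, a T→C
change printed among C→U rows). `validate_sites` flags such rows; counts
are never silently corrected. Partial editing ("+/−") counts as confirmed
by default — the only convention under which the printed per-position
tallies (62/12/1 of 75) reproduce — and the `confirmed_states` parameter
makes this explicit and overridable.

Hydropathy classes are fixed as hydrophobic = {A,V,L,I,P,F,M,W,Y,C} and
hydrophilic = {R,N,D,E,Q,H,K,S,T,G} — the minimal two-class table
consistent with every transition the study reports (Y hydrophobic, D
hydrophilic, P→S hydrophobic→hydrophilic).

## Character parsimony

Minimum change counts use the unit-cost dynamic programme (Sankoff
recursion with 0/1 costs), which reduces to Fitch's set algorithm on
bifurcating trees and — unlike the naive intersection/union rule — remains
exact on polytomies; exhaustive enumeration over all internal labelings is
the test oracle on trees of ≤ 8 leaves. A constrained root state is
handled in the same programme. Independent origins of a derived state are
minimised lexicographically after tree length, via a combined scalar cost
(changes × M + origins with M larger than any possible origin count); an
unconstrained root assigned the derived state counts as one origin. The
number of most-parsimonious reconstructions is computed by a parallel
counting recursion and reported alongside ambiguous origin counts.

The packaged phylogeny is a transcription of the study's figure topology
(monocot backbone with Acorales, then Alismatales, then Asparagales, then
commelinids = (Arecales + Dasypogonaceae) sister to (Poales +
(Zingiberales + Commelinales)); palm subfamily arrangement with Calamus
diverging first and Cocos sister to Elaeis; magnoliids with Chloranthus
sister to ((Drimys, Piper), Magnolia)), not an inference. The figure's
eudicot placement is not fully specified in the text; the fixture places
the two eudicots sister to the monocots, a choice that does not affect the
mapped character results because the derived taxa sit in separate clades
either way. The overlap character marks all seven sampled palms plus the
two Dasypogonaceae (the study describes the overlap as a property of that
whole clade), Drimys and Chloranthus.

## Synthetic data

`make_quadripartite_genome` emits LSC + IRb + SSC + revcomp(IRb) with
i.i.d. bases at GC 0.37, matching the AT-rich composition of palm
plastomes (GC ≈ 37%). Single-copy regions are resampled until (a) the only
inverted matches at or above a 40 bp floor are the planted pair and (b)
the planted pair is not extensible by chance into its flanks, so detection
at any floor above 40 bp recovers the truth exactly. Defaults are the
coconut dimensions (84,230 / 17,391 / 53,110 bp).

`make_repeat_fixture` embeds given repeat units (reverse-complemented for
inverted-partner records) in generated flanks, preserving relative offsets
within clusters of overlapping placements and separating clusters by a
configurable spacer; backgrounds are resampled until every duplicated
11-mer — forward or inverted — lies wholly inside a planted block, which
simultaneously guarantees repeat-free spacers and non-extensible copies.
Generator/detector round-trips are exact for non-nested arrangements;
nested families (a short unit recurring inside a longer one) and units
that are rotations of each other's reverse complements are faithfully
embedded but produce additional or merged maximal families under the
detector's criteria, so the full 13-record arrangement is exercised
through classification of the records rather than re-detection.

`make_homolog_panel` plants edits at stated support fractions, realising
`floor(support × panel_size)` edited-residue references per planted
column (so support 0.79 on a panel of 10 realises 0.7 and stays below the
0.8 cutoff) and a configurable sub-cutoff background at other editable
positions.

All generators are pure functions of (spec, seed) and byte-deterministic.
They emulate composition and planted structure only — no gene content,
annotation noise, sequencing error or real spatial repeat distribution —
so passing tests demonstrate correctness of the algorithms under the
stated conditions, not performance on raw sequencing data.

## Problem sizes

Tests and the acceptance script run at the scales the analyses need:
full coconut dimensions (154,731 bp) for IR detection, a few-hundred-bp
fixture for the planted repeat family, 200–500 bp sequences for the
repeat oracle suite, and ≤ 8-leaf trees for the exhaustive parsimony
oracle. These sizes make each suite complete in seconds while exercising
the same code paths as full-genome runs.

## Known limitations

* IR detection assumes exactly one dominant inverted pair; genomes with a
  lost or highly diverged IR copy return the no-IR signal rather than a
  partial answer.
* The repeat detector's maximality semantics differ from alignment-based
  tandem repeat finders on mismatch-containing or nested arrays; only
  perfect repeats are in scope.
* Editing prediction quality depends entirely on the supplied homolog
  panel; the package does not build panels from databases.
* Gene counting conventions (IR duplicates, multi-copy pseudogenes) vary
  across published tables; the package reports raw counts under its own
  explicit convention and does not arbitrate between the published
  totals.
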