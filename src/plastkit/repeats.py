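"""Exact repeat detection and tandem/direct/inverted classification.

The detector reports perfect-identity repeat families in the style of the
classic tandem-repeat tables of plastome papers: a unit longer than 10 bp
(period cap 500 bp), occurring either as a tandem array (copies abutting at
exactly one period), as dispersed same-strand copies (direct), or paired with
a reverse-complement occurrence elsewhere (inverted, the partner locus
reported as its own single-copy record).

Two engines cooperate:

* a per-period vectorised scan finds maximal tandem arrays (runs where
  ``s[i] == s[i+p]`` for at least one full period), reported at the array's
  smallest period;
* a suffix-array / LCP-interval enumeration over ``s # revcomp(s) $`` finds
  dispersed maximal repeats — substrings that cannot be extended on either
  side without losing an occurrence — with forward and inverted occurrences
  tracked separately.

Dispersed candidates that are merely the internal self-overlap of a reported
tandem array (the ``uu``-at-two-offsets artefact) are suppressed, as are
units whose own smallest period is below the period floor (microsatellite
sub-periodicities).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .model import PlastomeSequence, reverse_complement

log = logging.getLogger(__name__)

DEFAULT_MIN_PERIOD = 11
DEFAULT_MAX_PERIOD = 500


@dataclass(frozen=True)
class RepeatRecord:
    """One repeat family.

    ``positions`` are 0-based starts of the copies (ascending); serialised
    reports are 1-based.  ``copies == 1`` is legal only for the inverted
    partner of another family.  ``is_rc_partner`` marks records whose locus
    holds the reverse complement of ``unit``.
    """

    unit: str
    period: int
    copies: int
    positions: tuple[int, ...]
    repeat_type: str = ""  # 'T', 'D', 'I' or '' when not yet classified
    region_note: str = ""
    is_rc_partner: bool = False

    def to_row(self) -> dict:
        return {
            "size": self.period,
            "positions": ",".join(str(p + 1) for p in self.positions),
            "copies": self.copies,
            "type": self.repeat_type,
            "sequence": self.unit,
            "region": self.region_note,
        }


# ---------------------------------------------------------------------------
# Suffix array / LCP machinery


def _suffix_array(text: str) -> np.ndarray:
    codes = np.frombuffer(text.encode("ascii"), dtype=np.uint8).astype(np.int64)
    n = len(codes)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    rank = codes
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r_ord, k_ord = rank[order], key2[order]
        changed = np.empty(n, dtype=np.int64)
        changed[0] = 0
        changed[1:] = (r_ord[1:] != r_ord[:-1]) | (k_ord[1:] != k_ord[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed)
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


def _lcp_array(text: str, sa: np.ndarray) -> np.ndarray:
    """lcp[i] = longest common prefix of suffixes sa[i-1] and sa[i] (Kasai)."""
    n = len(text)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sa[r - 1]
            while i + h < n and j + h < n and text[i + h] == text[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


def _lcp_intervals(lcp: np.ndarray):
    """Yield (depth, lb, rb) for every internal suffix-tree node (right-maximal set)."""
    n = len(lcp)
    stack: list[list[int]] = [[0, 0]]
    for i in range(1, n + 1):
        cur = lcp[i] if i < n else 0
        lb = i - 1
        while stack and stack[-1][0] > cur:
            depth, lbv = stack.pop()
            yield depth, lbv, i - 1
            lb = lbv
        if not stack or stack[-1][0] < cur:
            stack.append([cur, lb])


def _minimal_period(s: str) -> int:
    """Smallest p such that s[i] == s[i+p] for all valid i (KMP border)."""
    n = len(s)
    fail = [0] * (n + 1)
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k]
        if s[i] == s[k]:
            k += 1
        fail[i + 1] = k
    return n - fail[n]


# ---------------------------------------------------------------------------
# Tandem arrays


def _find_tandem_arrays(s: str, min_period: int, max_period: int) -> list[RepeatRecord]:
    a = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    n = len(a)
    raw: list[tuple[int, int, int]] = []  # (start, span_len, period)
    for p in range(min_period, min(max_period, n // 2) + 1):
        eq = a[: n - p] == a[p:]
        if not eq.any():
            continue
        padded = np.empty(len(eq) + 2, dtype=bool)
        padded[0] = padded[-1] = False
        padded[1:-1] = eq
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        starts, ends = edges[::2], edges[1::2]
        for i, j in zip(starts, ends):
            run = j - i
            if run >= p:
                raw.append((int(i), int(run + p), p))
    # Keep an array only at the smallest period of its span string.
    kept: list[tuple[int, int, int]] = []
    for start, span_len, p in raw:
        if _minimal_period(s[start : start + span_len]) == p:
            kept.append((start, span_len, p))
    # Drop spans contained in a kept span of smaller period (sub-periodicities).
    kept.sort(key=lambda t: (t[2], t[0]))
    final: list[tuple[int, int, int]] = []
    for start, span_len, p in kept:
        contained = any(
            s0 <= start and start + span_len <= s0 + l0 and p0 < p
            for s0, l0, p0 in final
        )
        if not contained:
            final.append((start, span_len, p))
    records = []
    for start, span_len, p in final:
        copies = span_len // p
        records.append(
            RepeatRecord(
                unit=s[start : start + p],
                period=p,
                copies=copies,
                positions=tuple(start + j * p for j in range(copies)),
                repeat_type="T",
            )
        )
    return records


# ---------------------------------------------------------------------------
# Dispersed maximal repeats


def _dispersed_families(
    s: str, min_period: int, max_period: int
) -> list[tuple[str, tuple[int, ...], tuple[int, ...]]]:
    """Maximal repeat families as (unit, forward starts, inverted starts)."""
    n = len(s)
    text = s + "#" + reverse_complement(s) + "$"
    sa = _suffix_array(text)
    lcp = _lcp_array(text, sa)
    seen: dict[tuple, None] = {}
    families = []
    for depth, lb, rb in _lcp_intervals(lcp):
        depth = int(depth)
        if depth < min_period or depth > max_period:
            continue
        occ = sa[lb : rb + 1]
        # left-diversity: not all occurrences preceded by the same character
        prev = {text[p - 1] if p > 0 else "^" for p in occ}
        if len(prev) == 1:
            continue
        fwd, rcocc = [], []
        for p in map(int, occ):
            if p + depth <= n:
                fwd.append(p)
            elif p >= n + 1 and (p - n - 1) + depth <= n:
                rcocc.append(n - (p - n - 1) - depth)
        unit = text[int(occ[0]) : int(occ[0]) + depth]
        if int(occ[0]) >= n + 1:
            unit = reverse_complement(unit)
            fwd, rcocc = rcocc, fwd
        # the same family surfaces once per orientation; canonicalise
        key = (min(unit, reverse_complement(unit)), tuple(sorted(fwd + rcocc)))
        if key in seen:
            continue
        seen[key] = None
        if unit == reverse_complement(unit):  # palindromic unit: one strand only
            fwd = sorted(set(fwd) | set(rcocc))
            rcocc = []
        if _minimal_period(unit) < min_period:
            continue
        # orient toward the majority-copy side (tie: the first genome locus),
        # so the same-strand copies form the primary record on either strand
        flip = len(rcocc) > len(fwd) or (
            rcocc and len(rcocc) == len(fwd) and min(rcocc) < min(fwd)
        )
        if flip:
            unit = reverse_complement(unit)
            fwd, rcocc = rcocc, fwd
        families.append((unit, tuple(sorted(fwd)), tuple(sorted(rcocc))))
    return families


# ---------------------------------------------------------------------------
# Public API


def find_exact_repeats(
    seq: PlastomeSequence,
    min_period: int = DEFAULT_MIN_PERIOD,
    max_period: int = DEFAULT_MAX_PERIOD,
    min_copies: int = 2,
) -> list[RepeatRecord]:
    """Find and classify all perfect repeat families of the genome.

    Returns tandem arrays plus dispersed direct/inverted families meeting the
    copy-number condition (``>= min_copies`` same-strand copies, or at least
    one forward copy paired with a reverse-complement occurrence).  Output is
    deterministic: sorted by first position, then period descending.
    """
    if min_period < 2:
        raise ValueError("min_period must be >= 2")
    s = seq.sequence
    if max_period > len(s):
        warnings.warn(
            f"max_period {max_period} exceeds genome length {len(s)}; clamping",
            stacklevel=2,
        )
        max_period = len(s)
    if max_period < min_period:
        return []

    tandems = _find_tandem_arrays(s, min_period, max_period)
    # Full matched span of each array including any trailing partial copy, so
    # the array's internal self-overlap artefacts are recognised below.
    spans = []
    for r in tandems:
        start = r.positions[0]
        end = start + r.copies * r.period
        while end < len(s) and s[end] == s[end - r.period]:
            end += 1
        spans.append((start, end))

    def in_tandem(pos: int, length: int) -> bool:
        return any(a <= pos and pos + length <= b for a, b in spans)

    records = list(tandems)
    for unit, fwd, rcocc in _dispersed_families(s, min_period, max_period):
        L = len(unit)
        if all(in_tandem(p, L) for p in fwd) and all(in_tandem(p, L) for p in rcocc):
            continue
        if len(fwd) >= min_copies:
            records.append(
                RepeatRecord(unit=unit, period=L, copies=len(fwd), positions=fwd)
            )
        elif not (fwd and rcocc):
            continue
        else:
            records.append(
                RepeatRecord(unit=unit, period=L, copies=len(fwd), positions=fwd)
            )
        if rcocc:
            records.append(
                RepeatRecord(
                    unit=unit,
                    period=L,
                    copies=len(rcocc),
                    positions=rcocc,
                    is_rc_partner=True,
                )
            )
    records = classify_repeats(records)
    records.sort(key=lambda r: (r.positions[0], -r.period))
    return records


def classify_repeats(records: list[RepeatRecord]) -> list[RepeatRecord]:
    """Assign T/D/I labels from unit, positions and copy counts alone.

    * T — at least one pair of consecutive copies abuts at exactly one period;
    * D — two or more same-strand copies, none abutting;
    * I — a reverse-complement partner: either the record is itself an
      rc-partner locus, or its unit (or the unit's reverse complement) matches
      another record in the batch while the record has a single copy.

    A single-copy record with no partner anywhere in the batch is dropped
    with a warning.
    """
    units = {r.unit for r in records}
    out = []
    for rec in records:
        if rec.repeat_type:
            out.append(rec)
            continue
        if rec.is_rc_partner:
            out.append(replace(rec, repeat_type="I"))
            continue
        if rec.copies >= 2:
            tandem = any(
                b - a == rec.period
                for a, b in zip(rec.positions, rec.positions[1:])
            )
            out.append(replace(rec, repeat_type="T" if tandem else "D"))
            continue
        # single copy: inverted iff a partner unit exists in the batch
        partner = any(
            (other is not rec)
            and other.unit in (rec.unit, reverse_complement(rec.unit))
            for other in records
        )
        if partner:
            out.append(replace(rec, repeat_type="I"))
        else:
            log.warning(
                "dropping single-occurrence unit %s with no inverted partner",
                rec.unit,
            )
    return out


def annotate_repeats(records, annotations, partition=None) -> list[RepeatRecord]:
    """Fill ``region_note`` with the containing gene or flanking-gene spacer."""
    anns = sorted(annotations, key=lambda a: a.span.start)
    out = []
    for rec in records:
        pos, end = rec.positions[0], rec.positions[0] + rec.period
        note = ""
        for ann in anns:
            if ann.span.start <= pos and end <= ann.span.end:
                note = f"{ann.gene_name} gene"
                break
        if not note:
            left = [a for a in anns if a.span.end <= pos]
            right = [a for a in anns if a.span.start >= end]
            lname = left[-1].gene_name if left else "origin"
            rname = right[0].gene_name if right else "origin"
            note = f"spacer between {lname} and {rname}"
        if partition is not None:
            p = (pos - partition.origin_offset) % partition.genome_length
            for label in ("lsc", "irb", "ssc", "ira"):
                if getattr(partition, label).contains(p):
                    note = f"{label.upper()}; {note}"
                    break
        out.append(replace(rec, region_note=note))
    return out
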