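"""Independent brute-force oracles for the property suites.

Everything here is deliberately naive — per-base tallies, quadratic scans,
exhaustive enumeration — so that agreement with the package's optimised
implementations is meaningful evidence of correctness.
"""

from __future__ import annotations

import itertools

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp(s: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(s))


def gc_tally(text: str) -> float:
    """Per-base GC recount."""
    gc = at = 0
    for c in text:
        if c in "GC":
            gc += 1
        elif c in "AT":
            at += 1
    return gc / (gc + at)


# ---------------------------------------------------------------------------
# Longest inverted pair (quadratic DP)


def longest_inverted_pair(s: str, min_length: int):
    """Longest (X, Y) with s[Y] == revcomp(s[X]), non-overlapping, linear scan.

    Quadratic common-substring DP between s and revcomp(s); returns
    ((x, x+L), (y, y+L)) or None.  Linear topology only.
    """
    n = len(s)
    rc = revcomp(s)
    best = None  # (L, x, y)
    prev = [0] * (n + 1)
    ends = {}  # (i_end, j_end) -> L for all match-ending cells
    for i in range(1, n + 1):
        cur = [0] * (n + 1)
        for j in range(1, n + 1):
            if s[i - 1] == rc[j - 1]:
                cur[j] = prev[j - 1] + 1
                L = cur[j]
                if L >= min_length:
                    x = i - L
                    y = n - j  # rc[j-L .. j) maps to s[n-j .. n-j+L)
                    a, b = min(x, y), max(x, y)
                    if a + L <= b:  # non-overlapping
                        cand = (L, -a, -b)
                        if best is None or cand > best:
                            best = cand
        prev = cur
    if best is None:
        return None
    L, na, nb = best
    a, b = -na, -nb
    return (a, a + L), (b, b + L)


# ---------------------------------------------------------------------------
# Repeat families (naive per-length hashing)


def _minimal_period(s: str) -> int:
    for p in range(1, len(s) + 1):
        if all(s[i] == s[i + p] for i in range(len(s) - p)):
            return p
    return len(s)


def brute_tandem_arrays(s: str, min_period: int, max_period: int):
    """Maximal tandem runs at their smallest period; (start, span_len, period)."""
    n = len(s)
    raw = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        i = 0
        while i < n - p:
            if s[i] == s[i + p]:
                j = i
                while j < n - p and s[j] == s[j + p]:
                    j += 1
                run = j - i
                if run >= p:
                    raw.append((i, run + p, p))
                i = j + 1
            else:
                i += 1
    kept = [
        (i, L, p) for (i, L, p) in raw if _minimal_period(s[i : i + L]) == p
    ]
    kept.sort(key=lambda t: (t[2], t[0]))
    final = []
    for i, L, p in kept:
        if not any(
            s0 <= i and i + L <= s0 + L0 and p0 < p for s0, L0, p0 in final
        ):
            final.append((i, L, p))
    return final


def brute_dispersed_families(s: str, min_period: int, max_period: int):
    """All maximal repeat families as (unit, fwd starts, inverted starts).

    A family is maximal when neither all left-context characters nor all
    right-context characters agree (sequence boundaries act as per-occurrence
    unique sentinels).  Inverted occurrences are loci holding the reverse
    complement of the unit; context characters for those loci are read on the
    unit's strand.  Families are reported in the orientation of the first
    genome locus; palindromic units collapse to forward-only occurrence sets.
    """
    n = len(s)
    families = {}
    for L in range(min_period, min(max_period, n) + 1):
        groups: dict[str, list[int]] = {}
        for i in range(n - L + 1):
            groups.setdefault(s[i : i + L], []).append(i)
        for unit, fwd in groups.items():
            rcu = revcomp(unit)
            rcocc = groups.get(rcu, []) if rcu != unit else []
            if len(fwd) + len(rcocc) < 2:
                continue
            # each family is handled once, in the orientation of its
            # majority-copy side (tie: the side holding the first locus)
            if len(fwd) < len(rcocc) or (
                len(fwd) == len(rcocc) and rcocc and min(rcocc) < min(fwd)
            ):
                continue
            lefts, rights = set(), set()
            for p in fwd:
                lefts.add(s[p - 1] if p > 0 else f"<{p}")
                rights.add(s[p + L] if p + L < n else f">{p}")
            for q in rcocc:
                # on the unit's strand the rc locus reads right-to-left
                lefts.add(COMPLEMENT[s[q + L]] if q + L < n else f"<r{q}")
                rights.add(COMPLEMENT[s[q - 1]] if q > 0 else f">r{q}")
            if len(lefts) < 2 or len(rights) < 2:
                continue
            if _minimal_period(unit) < min_period:
                continue
            if unit == rcu:
                fwd = sorted(set(fwd) | set(rcocc))
                rcocc = []
            key = (min(unit, rcu), tuple(sorted(fwd + rcocc)))
            families[key] = (unit, tuple(sorted(fwd)), tuple(sorted(rcocc)))
    return sorted(families.values(), key=lambda f: (f[1] + f[2], f[0]))


def brute_repeat_records(s: str, min_period=11, max_period=500, min_copies=2):
    """Full record list mirroring the published-table conventions.

    Returns tuples (unit, period, copies, positions, type, is_rc_partner)
    sorted by first position then period descending.
    """
    max_period = min(max_period, len(s))
    arrays = brute_tandem_arrays(s, min_period, max_period)
    spans = []
    for i, L, p in arrays:
        end = i + L
        while end < len(s) and s[end] == s[end - p]:
            end += 1
        spans.append((i, end))

    def in_tandem(pos, L):
        return any(a <= pos and pos + L <= b for a, b in spans)

    records = []
    for i, L, p in arrays:
        copies = L // p
        records.append(
            (
                s[i : i + p],
                p,
                copies,
                tuple(i + j * p for j in range(copies)),
                "T",
                False,
            )
        )
    for unit, fwd, rcocc in brute_dispersed_families(s, min_period, max_period):
        L = len(unit)
        if all(in_tandem(q, L) for q in fwd) and all(in_tandem(q, L) for q in rcocc):
            continue
        if len(fwd) < min_copies and not (fwd and rcocc):
            continue
        if len(fwd) >= 2:
            tandem = any(b - a == L for a, b in zip(fwd, fwd[1:]))
            rtype = "T" if tandem else "D"
        else:
            rtype = "I"
        records.append((unit, L, len(fwd), fwd, rtype, False))
        if rcocc:
            records.append((unit, L, len(rcocc), rcocc, "I", True))
    records.sort(key=lambda r: (r[3][0], -r[1]))
    return records


# ---------------------------------------------------------------------------
# Exhaustive parsimony


def enumerate_parsimony(tree, leaf_states, fixed_root_state=None, derived_state=None):
    """(min changes, min origins among minimum-change labelings).

    *tree* is a dendropy.Tree.  Exhaustive over all internal labelings; the
    alphabet is the set of observed states plus the fixed root state.
    Leaves with state '?' are free.  An origin is an edge from a non-derived
    parent into a derived child, plus one for a derived root unless the root
    is fixed there.
    """
    alphabet = sorted(
        {s for s in leaf_states.values() if s != "?"}
        | ({fixed_root_state} if fixed_root_state is not None else set())
    )
    internals = [n for n in tree.postorder_node_iter() if not n.is_leaf()]
    free_leaves = [
        leaf for leaf in tree.leaf_node_iter() if leaf_states[leaf.taxon.label] == "?"
    ]
    root = tree.seed_node
    best_changes, best_origins = None, None
    nodes = internals + free_leaves
    for combo in itertools.product(alphabet, repeat=len(nodes)):
        assign = {id(n): s for n, s in zip(nodes, combo)}
        if fixed_root_state is not None and assign[id(root)] != fixed_root_state:
            continue

        def state_of(node):
            if node.is_leaf() and leaf_states[node.taxon.label] != "?":
                return leaf_states[node.taxon.label]
            return assign[id(node)]

        changes = origins = 0
        for node in internals:
            s = state_of(node)
            for child in node.child_nodes():
                t = state_of(child)
                if t != s:
                    changes += 1
                    if derived_state is not None and t == derived_state:
                        origins += 1
        if derived_state is not None and state_of(root) == derived_state:
            if fixed_root_state != derived_state:
                origins += 1
        if best_changes is None or (changes, origins) < (best_changes, best_origins):
            best_changes, best_origins = changes, origins
        elif changes == best_changes and origins < best_origins:
            best_origins = origins
    return best_changes, best_origins
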