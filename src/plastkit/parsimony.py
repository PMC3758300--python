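"""Small-parsimony character mapping on a fixed phylogeny.

Gene gain, duplication, pseudogenization and loss events are mapped onto a
given tree by minimising the number of state changes under equal change
costs (Fitch parsimony).  Polytomies are permitted; the implementation uses
the unit-cost dynamic programme (Sankoff recursion with 0/1 costs), which
reduces to the classic Fitch set algorithm on bifurcating trees and remains
exact — unlike the naive intersection/union rule — on nodes of arbitrary
out-degree.  The root state may be constrained, e.g. to the ancestral
"absent" state when counting independent origins of a derived state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import dendropy

from .errors import CharacterStateError, FormatError

UNKNOWN = "?"

_INF = float("inf")


@dataclass
class PhyloTree:
    """A rooted tree with uniquely labeled leaves (branch lengths ignored)."""

    tree: dendropy.Tree

    @property
    def leaf_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def internal_nodes(self) -> list:
        return [n for n in self.tree.preorder_node_iter() if not n.is_leaf()]


@dataclass
class CharacterMatrix:
    """Taxon-by-character state table over a finite alphabet."""

    characters: list[str]
    states: dict[tuple[str, str], str]  # (taxon, character) -> state

    def column(self, character: str) -> dict[str, str]:
        if character not in self.characters:
            raise CharacterStateError(
                f"unknown character {character!r}; known: {self.characters}"
            )
        return {
            taxon: state
            for (taxon, char), state in self.states.items()
            if char == character
        }

    @property
    def taxa(self) -> list[str]:
        return sorted({taxon for taxon, _ in self.states})


def read_newick(source) -> PhyloTree:
    """Parse a newick tree from a path or a literal newick string."""
    text = str(source)
    if not text.lstrip().startswith("("):
        with open(text) as fh:
            text = fh.read()
    if text.count("(") != text.count(")"):
        raise FormatError(
            f"unbalanced parentheses: {text.count('(')} '(' vs {text.count(')')} ')'"
        )
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
    except Exception as exc:  # dendropy raises several parser error types
        raise FormatError(f"newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise FormatError(f"duplicate leaf labels: {sorted(dupes)}")
    return PhyloTree(tree=tree)


def write_newick(tree: PhyloTree, path=None) -> str:
    text = tree.tree.as_string(schema="newick", suppress_rooting=True).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


def read_character_matrix(path) -> CharacterMatrix:
    """Read a taxon-by-character TSV (first column taxon, header row names)."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        characters = header[1:]
        states: dict[tuple[str, str], str] = {}
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            taxon = fields[0]
            for char, state in zip(characters, fields[1:]):
                states[(taxon, char)] = state
    return CharacterMatrix(characters=characters, states=states)


def _leaf_costs(
    tree: PhyloTree, leaf_states: dict[str, str], alphabet: tuple[str, ...]
) -> None:
    index = {s: i for i, s in enumerate(alphabet)}
    for leaf in tree.tree.leaf_node_iter():
        label = leaf.taxon.label
        if label not in leaf_states:
            raise CharacterStateError(f"leaf {label!r} has no assigned state")
        state = leaf_states[label]
        if state == UNKNOWN:
            leaf._costs = [0.0] * len(alphabet)
        else:
            if state not in index:
                raise CharacterStateError(
                    f"leaf {label!r} state {state!r} outside alphabet {alphabet}"
                )
            leaf._costs = [0.0 if i == index[state] else _INF for i in range(len(alphabet))]


def _resolve_alphabet(
    leaf_states: dict[str, str], fixed_root_state: str | None, alphabet
) -> tuple[str, ...]:
    if alphabet is None:
        observed = {s for s in leaf_states.values() if s != UNKNOWN}
        if fixed_root_state is not None:
            observed.add(fixed_root_state)
        return tuple(sorted(observed))
    alphabet = tuple(alphabet)
    if fixed_root_state is not None and fixed_root_state not in alphabet:
        raise CharacterStateError(
            f"fixed root state {fixed_root_state!r} outside alphabet {alphabet}"
        )
    return alphabet


def _sankoff(tree: PhyloTree, alphabet: tuple[str, ...], edge_cost) -> dict:
    """Postorder unit-cost DP; returns node -> cost vector (list over alphabet)."""
    k = len(alphabet)
    costs: dict = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            costs[node] = node._costs
            continue
        vec = [0.0] * k
        for child in node.child_nodes():
            cvec = costs[child]
            for si in range(k):
                vec[si] += min(
                    cvec[ti] + edge_cost(si, ti) for ti in range(k)
                )
        costs[node] = vec
    return costs


def fitch_length(
    tree: PhyloTree,
    leaf_states: dict[str, str],
    fixed_root_state: str | None = None,
    alphabet=None,
) -> int:
    """Minimum number of state changes on the tree for one character.

    Leaves may carry the explicit unknown state ``'?'`` (free assignment).
    With ``fixed_root_state`` the root's label is constrained to that state.
    """
    alphabet = _resolve_alphabet(leaf_states, fixed_root_state, alphabet)
    if not alphabet:
        return 0
    _leaf_costs(tree, leaf_states, alphabet)
    costs = _sankoff(tree, alphabet, lambda s, t: 0.0 if s == t else 1.0)
    root_vec = costs[tree.tree.seed_node]
    if fixed_root_state is not None:
        value = root_vec[alphabet.index(fixed_root_state)]
    else:
        value = min(root_vec)
    if value == _INF:
        raise CharacterStateError("no labeling consistent with the constraints")
    return int(value)


@dataclass(frozen=True)
class CharacterMapping:
    """Result of mapping one character: tree length, origins of the derived
    state minimised over most-parsimonious reconstructions (MPRs), and the
    number of MPRs attaining the tree length."""

    parsimony_length: int
    origins: int
    mpr_count: int


def map_character(
    tree: PhyloTree,
    leaf_states: dict[str, str],
    derived_state: str,
    fixed_root_state: str | None = None,
    alphabet=None,
) -> CharacterMapping:
    """Tree length plus the minimum count of transitions into *derived_state*.

    Among all labelings attaining the minimum number of changes, the one(s)
    with the fewest transitions into the derived state (edges whose parent is
    not derived and whose child is) determine ``origins``; a derived root not
    constrained to be ancestral also counts as one origin.  ``mpr_count`` is
    the number of most-parsimonious labelings of the internal nodes.
    """
    alphabet = _resolve_alphabet(leaf_states, fixed_root_state, alphabet)
    if derived_state not in alphabet:
        # derived state absent from all leaves (and not forced at the root)
        return CharacterMapping(
            parsimony_length=fitch_length(tree, leaf_states, fixed_root_state, alphabet or None)
            if alphabet
            else 0,
            origins=0,
            mpr_count=1,
        )
    k = len(alphabet)
    d = alphabet.index(derived_state)
    # Scalar lexicographic cost: changes dominate, then origins.
    big = 4 * (tree.n_leaves + 2)

    def cost(s, t):
        c = 0.0 if s == t else big
        if t == d and s != d:
            c += 1.0
        return c

    _leaf_costs(tree, leaf_states, alphabet)
    costs = _sankoff(tree, alphabet, cost)
    root = tree.tree.seed_node
    root_vec = list(costs[root])
    # A derived root counts as one origin unless the caller fixed it there.
    if fixed_root_state is None:
        root_vec[d] += 1.0
        value = min(root_vec)
    else:
        value = root_vec[alphabet.index(fixed_root_state)]
    if value == _INF:
        raise CharacterStateError("no labeling consistent with the constraints")
    length = int(value // big)
    origins = int(value % big)
    mpr_count = _count_mprs(tree, alphabet, fixed_root_state)
    return CharacterMapping(
        parsimony_length=length, origins=origins, mpr_count=mpr_count
    )


def count_independent_origins(
    tree: PhyloTree,
    leaf_states: dict[str, str],
    derived_state: str,
    fixed_root_state: str | None = None,
    alphabet=None,
) -> int:
    """Minimum number of independent origins of *derived_state* over all MPRs."""
    return map_character(
        tree, leaf_states, derived_state, fixed_root_state, alphabet
    ).origins


def _count_mprs(
    tree: PhyloTree, alphabet: tuple[str, ...], fixed_root_state: str | None
) -> int:
    """Number of internal labelings attaining the minimum change count."""
    k = len(alphabet)
    costs: dict = {}
    ways: dict = {}
    for node in tree.tree.postorder_node_iter():
        if node.is_leaf():
            costs[node] = node._costs
            ways[node] = [1 if c == 0 else 0 for c in node._costs]
            continue
        vec = [0.0] * k
        wvec = [1] * k
        for child in node.child_nodes():
            cvec, cways = costs[child], ways[child]
            for si in range(k):
                options = [cvec[ti] + (0.0 if si == ti else 1.0) for ti in range(k)]
                m = min(options)
                vec[si] += m
                wvec[si] *= sum(
                    cways[ti] for ti in range(k) if options[ti] == m and cways[ti]
                )
        costs[node] = vec
        ways[node] = wvec
    root = tree.tree.seed_node
    root_vec, root_ways = costs[root], ways[root]
    if fixed_root_state is not None:
        return root_ways[alphabet.index(fixed_root_state)]
    m = min(root_vec)
    return sum(w for c, w in zip(root_vec, root_ways) if c == m)


def exhaustive_parsimony_length(
    tree: PhyloTree,
    leaf_states: dict[str, str],
    fixed_root_state: str | None = None,
    alphabet=None,
) -> int:
    """Brute-force minimum changes by enumerating all internal labelings.

    Exponential in the number of internal nodes; intended as an independent
    check on very small trees.
    """
    alphabet = _resolve_alphabet(leaf_states, fixed_root_state, alphabet)
    internals = [n for n in tree.tree.postorder_node_iter() if not n.is_leaf()]
    root = tree.tree.seed_node
    best = None
    for combo in itertools.product(alphabet, repeat=len(internals)):
        assign = dict(zip((id(n) for n in internals), combo))
        if fixed_root_state is not None and assign[id(root)] != fixed_root_state:
            continue
        ok = True
        changes = 0
        for node in internals:
            s = assign[id(node)]
            for child in node.child_nodes():
                if child.is_leaf():
                    t = leaf_states[child.taxon.label]
                    if t == UNKNOWN:
                        continue
                else:
                    t = assign[id(child)]
                if t != s:
                    changes += 1
        if ok and (best is None or changes < best):
            best = changes
    return 0 if best is None else best
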