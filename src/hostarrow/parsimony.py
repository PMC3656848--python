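"""Unordered (Fitch) maximum-parsimony ancestral reconstruction.

Implemented as unit-cost Sankoff dynamic programming, which generalizes the
classic Fitch passes to polytomies (Bayesian consensus trees contain them)
and yields, per node, the exact MPR state set: the union of that node's
states over *all* most-parsimonious reconstructions.  Reporting sets rather
than single ACCTRAN/DELTRAN assignments matters because ancestral nodes are
frequently ambiguous and that ambiguity is part of the result.

Missing tips carry the full state set (no information), the standard Fitch
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_formats import CharacterMatrix, RootedTree

__all__ = ["ParsimonyReconstruction", "fitch_score", "fitch_state_sets",
           "count_parsimony_changes"]

_INF = 10 ** 9


@dataclass(frozen=True)
class ParsimonyReconstruction:
    """Per-node MPR state sets plus the minimal change count.

    ``state_sets[v]`` is the non-empty set of state indices attainable at
    node ``v`` in at least one most-parsimonious reconstruction;
    ``edge_change[v]`` / ``edge_nochange[v]`` record whether some MPR does /
    does not place a change on the branch above ``v``.
    """

    tree: RootedTree
    state_labels: tuple[str, ...]
    score: int
    state_sets: tuple[frozenset[int], ...]
    edge_change: tuple[bool, ...]
    edge_nochange: tuple[bool, ...]


def _costs(tree: RootedTree, char: CharacterMatrix) -> np.ndarray:
    """down[v, s] = minimal changes in v's subtree given state s at v."""
    k = char.k
    down = np.zeros((tree.n_nodes, k), dtype=np.int64)
    for v in tree.postorder():
        if tree.is_tip(v):
            s = char.state_index(tree.labels[v])
            if s is not None:
                down[v] = _INF
                down[v, s] = 0
        else:
            for c in tree.children[v]:
                best = down[c].min()
                down[v] += np.minimum(down[c], best + 1)
    return down


def fitch_score(tree: RootedTree, char: CharacterMatrix) -> int:
    """Minimal number of state changes needed to explain the tip states."""
    missing = tree.tip_labels() - char.taxa
    if missing:
        raise KeyError(f"tips absent from character matrix: {sorted(missing)}")
    if all(char.is_missing(tree.labels[v]) for v in tree.tips()):
        warnings.warn("all tips missing; parsimony score is trivially 0")
        return 0
    down = _costs(tree, char)
    return int(down[tree.root].min())


def fitch_state_sets(tree: RootedTree, char: CharacterMatrix) -> ParsimonyReconstruction:
    """MPR state sets for every node (union over all MPRs).

    A state s belongs to node v's set iff some reconstruction achieving the
    global minimum assigns s to v; computed from subtree costs (down pass)
    combined with rest-of-tree costs (up pass).
    """
    k = char.k
    score = fitch_score(tree, char)
    down = _costs(tree, char)
    n = tree.n_nodes
    # up[v, s]: minimal changes outside v's subtree given state s at v
    # (including the branch above v); above[v, s]: same but conditioned on
    # v's PARENT having state s, before crossing v's branch.
    up = np.zeros((n, k), dtype=np.int64)
    above = np.zeros((n, k), dtype=np.int64)
    for v in reversed(tree.postorder()):  # pre-order
        kids = tree.children[v]
        if not kids:
            continue
        lifted = {c: np.minimum(down[c], down[c].min() + 1) for c in kids}
        for c in kids:
            base = up[v].copy()
            for sib in kids:
                if sib is not c:
                    base += lifted[sib]
            above[c] = base
            up[c] = np.minimum(base, base.min() + 1)
    sets: list[frozenset[int]] = []
    for v in range(n):
        total = down[v] + up[v]
        if tree.is_tip(v) and char.is_missing(tree.labels[v]):
            sets.append(frozenset(range(k)))
        else:
            sets.append(frozenset(int(s) for s in np.flatnonzero(total == score)))
    # per-branch change accounting over all MPRs
    change = [False] * n
    nochange = [False] * n
    for v in range(n):
        if v == tree.root:
            nochange[v] = True
            continue
        a, d = above[v], down[v]
        same = int((a + d).min())
        diff = _INF
        for s in range(k):
            others = np.delete(d, s)
            diff = min(diff, int(a[s] + 1 + others.min()))
        nochange[v] = same == score
        change[v] = diff == score
    return ParsimonyReconstruction(tree, char.state_labels, score, tuple(sets),
                                   tuple(change), tuple(nochange))


def count_parsimony_changes(recon: ParsimonyReconstruction) -> tuple[int, int]:
    """(unambiguous_changes, ambiguous_branches).

    A branch is an unambiguous change iff the parent and child MPR sets are
    disjoint (every MPR changes there); it is ambiguous iff the sets
    intersect but at least one MPR still places a change on it.
    """
    tree = recon.tree
    unambiguous = ambiguous = 0
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        p = int(tree.parent[v])
        disjoint = not (recon.state_sets[v] & recon.state_sets[p])
        if disjoint:
            unambiguous += 1
        elif recon.edge_change[v]:
            ambiguous += 1
    return unambiguous, ambiguous
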