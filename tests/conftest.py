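"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: likelihoods
by exhaustive enumeration over interior-node state assignments, parsimony
by brute-force minimization, posteriors by grid quadrature.
"""

import itertools

import numpy as np
import pytest

import hostarrow as ha
from hostarrow.mk_model import RateModel, transition_matrix


@pytest.fixture
def cherry():
    """Two-tip tree, both branches length 1."""
    return ha.parse_newick("(A:1.0,B:1.0);")


@pytest.fixture
def quartet():
    return ha.parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def host_table():
    return ha.load_reference_host_table()


def random_topology(n_tips: int, rng: np.random.Generator,
                    max_blen: float = 2.0) -> ha.RootedTree:
    """Random rooted topology (possibly with polytomies) and iid branch
    lengths, built by sequential random coalescence — independent of the
    package's Yule simulator."""
    parent: list[int] = []
    blen: list[float] = []
    labels: list[str | None] = []
    roots: list[int] = []
    for i in range(n_tips):
        parent.append(-1)
        blen.append(float(rng.uniform(0.05, max_blen)))
        labels.append(f"x{i}")
        roots.append(i)
    while len(roots) > 1:
        m = int(rng.integers(2, min(3, len(roots)) + 1))  # binary or trifurcating
        rng.shuffle(roots)
        group, roots = roots[:m], roots[m:]
        parent.append(-1)
        blen.append(float(rng.uniform(0.05, max_blen)))
        labels.append(None)
        new = len(parent) - 1
        for g in group:
            parent[g] = new
        roots.append(new)
    blen[roots[0]] = 0.0
    return ha.RootedTree(parent, blen, labels)


def brute_force_log_likelihood(tree: ha.RootedTree, model: RateModel,
                               char: ha.CharacterMatrix) -> float:
    """Sum over all interior-node state assignments of the product of edge
    transition probabilities times the root prior."""
    k = model.k
    interior = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    P = {v: transition_matrix(model, float(tree.branch_lengths[v]))
         for v in range(tree.n_nodes) if v != tree.root}
    pi = model.root_distribution()
    tip_state = {v: char.state_index(tree.labels[v]) for v in tree.tips()}
    missing = [v for v, s in tip_state.items() if s is None]
    fixed = {v: s for v, s in tip_state.items() if s is not None}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(interior)):
        st = dict(zip(interior, assign))
        # marginalize missing tips by summing their states explicitly
        for sub in itertools.product(range(k), repeat=len(missing)):
            states = dict(st)
            states.update(fixed)
            states.update(dict(zip(missing, sub)))
            lik = pi[states[tree.root]]
            for v in range(tree.n_nodes):
                if v != tree.root:
                    lik *= P[v][states[int(tree.parent[v])], states[v]]
            total += lik
    return float(np.log(total)) if total > 0 else -np.inf


def brute_force_parsimony(tree: ha.RootedTree, char: ha.CharacterMatrix):
    """(min score, per-node MPR sets) by enumerating all full assignments."""
    k = char.k
    interior = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    tip_state = {v: char.state_index(tree.labels[v]) for v in tree.tips()}
    missing = [v for v, s in tip_state.items() if s is None]
    fixed = {v: s for v, s in tip_state.items() if s is not None}
    best = None
    assignments = []
    free = interior + missing
    for assign in itertools.product(range(k), repeat=len(free)):
        states = dict(zip(free, assign))
        states.update(fixed)
        changes = sum(1 for v in range(tree.n_nodes) if v != tree.root
                      and states[v] != states[int(tree.parent[v])])
        if best is None or changes < best:
            best = changes
            assignments = [states]
        elif changes == best:
            assignments.append(states)
    sets = {v: frozenset(st[v] for st in assignments)
            for v in range(tree.n_nodes)}
    return best, sets


def quadrature_node_posteriors(tree, char, bound: float, n_grid: int = 60):
    """Node-state posteriors under a flat prior on (q01, q10) in
    [0, bound]^2, by 2-D grid quadrature (midpoint rule)."""
    grid = (np.arange(n_grid) + 0.5) * bound / n_grid
    num = np.zeros((tree.n_nodes, 2))
    den = 0.0
    for a in grid:
        for b in grid:
            model = RateModel.free(2, rates=(float(a), float(b)))
            lnl = ha.pruning_log_likelihood(tree, model, char)
            w = np.exp(lnl)
            num += w * ha.node_marginals(tree, model, char)
            den += w
    return num / den
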