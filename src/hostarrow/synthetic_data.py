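"""Generators for every input the pipeline consumes, with recorded truth.

The real study's inputs (a Bayesian posterior tree sample over Sphecodes
species and their host records) are emulated by:

* :func:`simulate_yule_tree` — pure-birth trees with exponential waiting
  times, the standard neutral-tree stand-in;
* :func:`emulate_tree_sample` — lognormal branch-length jitter around a base
  tree, a posterior-sample stand-in with fixed topology (a modeling
  convenience, not a claim about real posteriors);
* :func:`simulate_mk_character` — exact event-by-event CTMC simulation of a
  discrete character down the tree, so every true transition has a branch
  and a position (needed by switch-recovery tests; endpoint sampling from
  the transition matrix would lose this);
* :func:`simulate_host_table` — eight independent binary presence/absence
  host characters evolved on one tree, assembled into a host table with
  specificity annotations derived from the realized host sets.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import CharacterMatrix, RootedTree, TreeSample
from .mk_model import RateModel
from .specialization import (HOST_GENUS, HOST_LINEAGES, HostTable,
                             SpeciesHostRecord)

__all__ = ["SimulationTruth", "simulate_yule_tree", "emulate_tree_sample",
           "simulate_mk_character", "simulate_host_table"]


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth recorded by a simulator.

    ``node_states`` maps node id -> true state index (for host tables, one
    dict per host lineage under ``per_character``); ``events`` lists the
    realized transitions as (node_below_branch, time_from_branch_start,
    from_state, to_state) — for host tables, (host, node, time, from, to).
    """

    rates: tuple[float, ...]
    node_states: dict[int, int] = field(default_factory=dict)
    events: tuple = ()
    per_character: dict[str, dict[int, int]] = field(default_factory=dict)

    def validate(self, tree: RootedTree, char: CharacterMatrix | None = None) -> None:
        """Check internal consistency: tip states match the emitted matrix
        and every event connects its branch's endpoint states."""
        if char is not None:
            for v in tree.tips():
                assert self.node_states[v] == char.state_index(tree.labels[v])
        by_branch: dict[int, list] = {}
        for ev in self.events:
            by_branch.setdefault(ev[0], []).append(ev)
        for v in range(tree.n_nodes):
            if v == tree.root or v not in self.node_states:
                continue
            p = int(tree.parent[v])
            state = self.node_states[p]
            for ev in sorted(by_branch.get(v, []), key=lambda e: e[1]):
                assert ev[2] == state, "event chain broken"
                state = ev[3]
            assert state == self.node_states[v], "branch endpoint mismatch"


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0,
                       seed: int | np.random.Generator = 0) -> RootedTree:
    """Pure-birth (Yule) tree with ``n_tips`` extant tips.

    Starting from the root split (two lineages), each interval with k
    lineages lasts Exp(k * birth_rate) and ends with a uniformly chosen
    lineage splitting; a final Exp(n * birth_rate) interval separates the
    last split from the present, making the expected root-to-tip depth
    sum_{k=2}^{n} 1/(k * birth_rate).  The tree is ultrametric.
    """
    if n_tips < 2:
        raise ValueError("need at least two tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    parent = [-1, 0, 0]          # root and its two daughters
    birth = [0.0, 0.0, 0.0]      # time each branch starts
    split_time: dict[int, float] = {}
    active = [1, 2]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * birth_rate))
        split = active.pop(int(rng.integers(k)))
        split_time[split] = t
        for _ in range(2):
            parent.append(split)
            birth.append(t)
            active.append(len(parent) - 1)
    t += rng.exponential(1.0 / (n_tips * birth_rate))  # last split -> present

    n = len(parent)
    blen = np.zeros(n)
    labels: list[str | None] = [None] * n
    tip_no = 0
    for v in range(1, n):
        blen[v] = split_time.get(v, t) - birth[v]
    for v in range(n):
        if v != 0 and v not in split_time:  # leaf
            labels[v] = f"t{tip_no}"
            tip_no += 1
    return RootedTree(parent, blen, labels)


def emulate_tree_sample(base: RootedTree, n_trees: int,
                        length_jitter_sd: float = 0.2,
                        seed: int = 0, run_id: int = 0) -> TreeSample:
    """Posterior-like sample: copies of ``base`` with each branch length
    multiplied by an independent lognormal factor (log-sd as given; mean
    factor exp(sd^2 / 2)).  Topology is fixed; all lengths stay positive."""
    if length_jitter_sd < 0:
        raise ValueError("jitter sd must be non-negative")
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n_trees):
        if length_jitter_sd == 0:
            trees.append(base)
        else:
            factors = rng.lognormal(0.0, length_jitter_sd, base.n_nodes)
            bl = base.branch_lengths * factors
            bl[base.root] = 0.0
            trees.append(base.with_branch_lengths(bl))
    return TreeSample.from_trees(trees, run_id=run_id)


def simulate_mk_character(tree: RootedTree, model: RateModel,
                          seed: int | np.random.Generator = 0,
                          state_labels: tuple[str, ...] | None = None
                          ) -> tuple[CharacterMatrix, SimulationTruth]:
    """Evolve one discrete character by exact CTMC simulation.

    The root state is drawn from the model's root prior; along each branch
    the chain waits Exp(-q_ii) in state i and jumps with probabilities
    q_ij / -q_ii, until the branch is exhausted.  Every jump is recorded in
    the returned :class:`SimulationTruth`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Q = model.q_matrix()
    k = model.k
    if state_labels is None:
        state_labels = tuple(str(i) for i in range(k))
    node_states: dict[int, int] = {}
    events: list[tuple[int, float, int, int]] = []
    pi = model.root_distribution()
    node_states[tree.root] = int(rng.choice(k, p=pi))
    for v in reversed(tree.postorder()):  # pre-order
        if v == tree.root:
            continue
        state = node_states[int(tree.parent[v])]
        remaining = float(tree.branch_lengths[v])
        pos = 0.0
        while True:
            exit_rate = -Q[state, state]
            if exit_rate <= 0:
                break
            wait = rng.exponential(1.0 / exit_rate)
            if wait > remaining:
                break
            pos += wait
            remaining -= wait
            probs = Q[state].copy()
            probs[state] = 0.0
            probs = probs / probs.sum()
            new = int(rng.choice(k, p=probs))
            events.append((v, pos, state, new))
            state = new
        node_states[v] = state
    assignments = {tree.labels[v]: state_labels[node_states[v]]
                   for v in tree.tips()}
    char = CharacterMatrix(assignments, state_labels=state_labels)
    truth = SimulationTruth(rates=model.rates, node_states=node_states,
                            events=tuple(events))
    return char, truth


def simulate_host_table(tree: RootedTree,
                        per_host_models: dict[str, RateModel] | None = None,
                        seed: int = 0) -> tuple[HostTable, SimulationTruth]:
    """Evolve the eight host-lineage presence/absence characters
    independently on one tree and assemble a host table.

    Default per-host model: gain rate 0.3, loss rate 0.6 per unit branch
    length, root mostly absent (prior 0.9 absent / 0.1 present) — sparse
    host sets with occasional gains, echoing real host tables where most
    species use one or two lineages.  Annotations are derived from the
    realized host sets: ``eco_similar`` iff the hosts span a single genus,
    ``sporadic_extra`` never set (the simulator has no sporadic-use notion).
    Species with no realized hosts become unknown-host records.
    """
    rng = np.random.default_rng(seed)
    if per_host_models is None:
        base = RateModel.free(2, rates=(0.3, 0.6), root_prior=(0.9, 0.1))
        per_host_models = {h: base for h in HOST_LINEAGES}
    per_character: dict[str, dict[int, int]] = {}
    events: list[tuple] = []
    presence: dict[str, dict[str, int]] = {}
    all_rates: list[float] = []
    for host in HOST_LINEAGES:
        model = per_host_models[host]
        char, truth = simulate_mk_character(tree, model, rng,
                                            state_labels=("0", "1"))
        per_character[host] = dict(truth.node_states)
        all_rates.extend(model.rates)
        for (v, pos, a, b) in truth.events:
            events.append((host, v, pos, a, b))
        presence[host] = {t: char.state_index(t) for t in char.taxa}
    records = []
    for label in sorted(tree.tip_labels()):
        hosts = frozenset(h for h in HOST_LINEAGES if presence[h][label] == 1)
        genera = {HOST_GENUS[h] for h in hosts}
        records.append(SpeciesHostRecord(
            species=label, hosts=hosts,
            sporadic_extra=False,
            eco_similar=len(genera) == 1 and bool(hosts)))
    truth = SimulationTruth(rates=tuple(all_rates), events=tuple(events),
                            per_character=per_character)
    return HostTable(records), truth


def true_node_host_sets(truth: SimulationTruth) -> dict[int, frozenset[str]]:
    """Per-node host sets implied by the simulation truth (for switch-
    recovery tests against :func:`detect_host_switches`)."""
    nodes = set()
    for states in truth.per_character.values():
        nodes.update(states)
    return {v: frozenset(h for h, states in truth.per_character.items()
                         if states.get(v) == 1)
            for v in sorted(nodes)}
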