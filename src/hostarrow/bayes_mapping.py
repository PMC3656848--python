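"""Bayesian ancestral-state mapping over a posterior tree sample.

A Metropolis-Hastings chain explores the Mk rate parameters (and, with
reversible jump enabled, the rate-equality model) while integrating over
phylogenetic uncertainty by drawing a tree uniformly at random from the
posterior tree sample at every iteration.  At retained iterations the chain
records the data likelihood (for the harmonic-mean marginal likelihood) and
the marginal posterior state probabilities of addressable nodes, which are
averaged into mean node posteriors.

Priors
------
Each free rate carries an exponential prior whose mean is itself uniform on
a stated interval [a, b] and is resampled by its own Metropolis move (the
"exponential hyperprior on an interval" construction); with a == b the mean
is fixed.  A flat prior on [0, bound] is available for oracle comparisons.

Nodes are addressed as MRCAs of tip sets so that they remain identifiable
across the topologies in the sample; iterations whose current tree lacks
the tip set as a clade are skipped for that node's summary.

Model comparison uses the harmonic-mean estimator of the marginal
likelihood and the statistic 2 ln(BF) = 2[ln(HM1) - ln(HM2)] with support
thresholds 2 (positive), 6 (strong) and 10 (very strong).  The harmonic
mean is known to be high-variance; a jackknife standard error is reported
alongside it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .io_formats import CharacterMatrix, TreeSample
from .mk_model import PruningEngine, RateModel

__all__ = [
    "McmcConfig", "PosteriorSummary", "run_mcmc", "tune_ratedev",
    "harmonic_mean_log_marginal", "bayes_factor_2ln", "fixed_state_node_test",
]

NodeKey = frozenset


@dataclass(frozen=True)
class McmcConfig:
    """Chain settings.

    ``ratedev`` is the half-width of the uniform sliding-window proposal on
    each rate (reflected at zero); it is what :func:`tune_ratedev` adjusts
    until the rate-move acceptance rate falls in ``target_acceptance``
    (20-40% by default).  ``hyper_interval`` bounds the uniform hyperprior
    on the exponential rate-prior's mean.  ``thin`` fixes the retained-
    iteration spacing for summaries.
    """

    iterations: int = 100_000
    burnin_iterations: int = 20_000
    ratedev: float = 1.0
    hyper_interval: tuple[float, float] = (0.0, 20.0)
    seed: int = 0
    rj_enabled: bool = True
    target_acceptance: tuple[float, float] = (0.20, 0.40)
    thin: int = 100
    prior: str = "exponential_hyper"   # or "uniform"
    uniform_bound: float = 100.0

    def __post_init__(self):
        if self.burnin_iterations >= self.iterations:
            raise ValueError("burn-in must be shorter than the run")
        a, b = self.hyper_interval
        if not (0 <= a <= b):
            raise ValueError("hyperprior interval must satisfy 0 <= a <= b")
        if self.ratedev <= 0:
            raise ValueError("ratedev must be positive")


@dataclass(frozen=True)
class PosteriorSummary:
    """Averaged node posteriors and marginal-likelihood bookkeeping."""

    node_posteriors: dict[NodeKey, np.ndarray]
    node_counts: dict[NodeKey, int]
    acceptance_rate: float
    model_frequencies: dict[str, float]
    log_marginal_hm: float
    hm_jackknife_se: float
    n_retained: int
    retained_lnL: tuple[float, ...] = field(repr=False, default=())


# ---------------------------------------------------------------------------
# Harmonic means and Bayes factors
# ---------------------------------------------------------------------------

def harmonic_mean_log_marginal(retained_lnL: Sequence[float]) -> float:
    """ln of the harmonic mean of likelihoods: ln n - logsumexp(-lnL_i)."""
    lnl = np.asarray(retained_lnL, dtype=float)
    if lnl.size == 0:
        raise ValueError("need at least one retained likelihood")
    return float(np.log(lnl.size) - logsumexp(-lnl))


def _hm_jackknife_se(lnl: np.ndarray) -> float:
    n = lnl.size
    if n < 2:
        return float("nan")
    total = logsumexp(-lnl)
    loo = np.empty(n)
    for i in range(n):
        loo[i] = np.log(n - 1) - logsumexp(np.delete(-lnl, i))
    return float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))


_VERDICTS = ((10.0, "very_strong"), (6.0, "strong"), (2.0, "positive"))


def bayes_factor_2ln(lnHM1: float, lnHM2: float) -> tuple[float, str]:
    """2[ln(HM1) - ln(HM2)] and the conventional support verdict.

    Values below 2 indicate that model 1 is not significantly better than
    model 2 ('none'); above 2/6/10 positive/strong/very strong support.
    """
    stat = 2.0 * (lnHM1 - lnHM2)
    for cut, verdict in _VERDICTS:
        if stat > cut:
            return stat, verdict
    return stat, "none"


# ---------------------------------------------------------------------------
# The chain
# ---------------------------------------------------------------------------

def _reflect(x: float) -> float:
    return -x if x < 0 else x


class _Prior:
    def __init__(self, config: McmcConfig):
        self.kind = config.prior
        self.a, self.b = config.hyper_interval
        self.bound = config.uniform_bound

    def initial_mean(self, rng) -> float:
        if self.kind == "uniform":
            return float("nan")
        if self.a == self.b:
            return self.a if self.a > 0 else 1.0
        return float(rng.uniform(self.a, self.b))

    def log_density(self, rates: np.ndarray, mean: float) -> float:
        if self.kind == "uniform":
            if np.any(rates > self.bound):
                return -np.inf
            return 0.0
        if mean <= 0:
            return -np.inf
        return float(np.sum(-np.log(mean) - rates / mean))


def _default_nodes(sample: TreeSample) -> list[NodeKey]:
    ref = sample[0]
    keys = []
    for v in range(ref.n_nodes):
        if not ref.is_tip(v):
            keys.append(NodeKey(ref.clade_tips(v)))
    return keys


def _resolve_constraints(tree, node_constraints) -> dict[int, int] | None:
    if not node_constraints:
        return None
    resolved = {}
    for key, state in node_constraints.items():
        node = tree.find_clade(key)
        if node is None:
            return {}  # sentinel: constrained clade absent from this tree
        resolved[node] = state
    return resolved


def run_mcmc(sample: TreeSample, char: CharacterMatrix, template: RateModel,
             config: McmcConfig,
             node_constraints: Mapping[NodeKey, int] | None = None,
             nodes: Sequence[NodeKey] | None = None) -> PosteriorSummary:
    """Run the MH chain and summarize node posteriors and likelihoods.

    Reversible jump (when enabled and the template is a binary model with
    two free one-cell classes) flips between the equal-rates and
    distinct-rates models with a symmetric model proposal; the chain then
    reports the visited-model frequencies.

    ``node_constraints`` fossilizes nodes (addressed as tip-set MRCAs) at
    fixed states for Bayes-factor node tests.  An error is raised if a
    constrained clade is absent from more than half of the sampled trees.
    """
    if len(sample) == 0:
        raise ValueError("tree sample is empty")
    if char.k != template.k:
        raise ValueError("character/model state-count mismatch")
    rng = np.random.default_rng(config.seed)
    k = template.k
    rj_ok = (config.rj_enabled and k == 2 and template.n_classes == 2)
    prior = _Prior(config)

    engines = [PruningEngine(t, char, k=k) for t in sample]
    constraints_per_tree: list[dict[int, int] | None] = []
    if node_constraints:
        n_absent = 0
        for t in sample:
            res = _resolve_constraints(t, node_constraints)
            if res == {}:
                n_absent += 1
                constraints_per_tree.append({})
            else:
                constraints_per_tree.append(res)
        if n_absent > 0.5 * len(sample):
            raise ValueError("constrained node absent from >50% of sampled trees")
    else:
        constraints_per_tree = [None] * len(sample)

    if nodes is None:
        nodes = _default_nodes(sample)
    nodes = list(nodes)

    n_free = template.n_classes
    rates = np.full(max(n_free, 1), 1.0)
    equal_model = False  # RJ indicator: True => both cells share rates[0]
    hyper_mean = prior.initial_mean(rng)

    def current_rates() -> np.ndarray:
        if rj_ok and equal_model:
            return np.full(n_free, rates[0])
        return rates[:n_free]

    def free_rates() -> np.ndarray:
        # distinct parameters carrying prior mass in the current model
        if rj_ok and equal_model:
            return rates[:1]
        return rates[:n_free]

    def lnl_at(tree_idx: int, r: np.ndarray) -> float:
        c = constraints_per_tree[tree_idx]
        if c == {}:
            c = None  # likelihood without an unplaceable constraint
        return engines[tree_idx].log_likelihood(template.with_rates(r), c)

    tree_idx = int(rng.integers(len(sample)))
    cur_lnl = lnl_at(tree_idx, current_rates())

    rate_props = rate_accs = 0
    model_visits = {"equal": 0, "distinct": 0}
    post_sums: dict[NodeKey, np.ndarray] = {nk: np.zeros(k) for nk in nodes}
    post_counts: dict[NodeKey, int] = {nk: 0 for nk in nodes}
    retained: list[float] = []

    for it in range(config.iterations):
        # redraw the tree (tree uncertainty integration)
        new_idx = int(rng.integers(len(sample)))
        if new_idx != tree_idx:
            tree_idx = new_idx
            cur_lnl = lnl_at(tree_idx, current_rates())

        # rate sliding-window move, reflected at zero
        if n_free > 0:
            ci = int(rng.integers(n_free if not (rj_ok and equal_model) else 1))
            prop = rates.copy()
            prop[ci] = _reflect(rates[ci] + rng.uniform(-config.ratedev, config.ratedev))
            prop_full = (np.full(n_free, prop[0]) if rj_ok and equal_model
                         else prop[:n_free])
            new_lnl = lnl_at(tree_idx, prop_full)
            lp_new = prior.log_density(prop[:1] if rj_ok and equal_model
                                       else prop[:n_free], hyper_mean)
            lp_old = prior.log_density(free_rates(), hyper_mean)
            rate_props += 1
            if np.log(rng.uniform()) < (new_lnl + lp_new) - (cur_lnl + lp_old):
                rates = prop
                cur_lnl = new_lnl
                rate_accs += 1

        # hyperprior-mean move
        if prior.kind == "exponential_hyper" and prior.a < prior.b:
            m_new = float(rng.uniform(prior.a, prior.b))
            d = prior.log_density(free_rates(), m_new) - \
                prior.log_density(free_rates(), hyper_mean)
            if np.log(rng.uniform()) < d:
                hyper_mean = m_new

        # reversible-jump model flip
        if rj_ok and rng.uniform() < 0.2:
            if equal_model:
                r2 = float(rng.exponential(hyper_mean)) \
                    if prior.kind != "uniform" else float(rng.uniform(0, prior.bound))
                prop = np.array([rates[0], r2])
                new_lnl = lnl_at(tree_idx, prop)
                if np.log(rng.uniform()) < new_lnl - cur_lnl:
                    rates = prop
                    equal_model = False
                    cur_lnl = new_lnl
            else:
                prop_full = np.full(n_free, rates[0])
                new_lnl = lnl_at(tree_idx, prop_full)
                if np.log(rng.uniform()) < new_lnl - cur_lnl:
                    equal_model = True
                    cur_lnl = new_lnl

        # retention
        if it >= config.burnin_iterations and \
                (it - config.burnin_iterations) % config.thin == 0:
            retained.append(cur_lnl)
            model_visits["equal" if equal_model else "distinct"] += 1
            tree = sample[tree_idx]
            marg = engines[tree_idx].marginals(
                template.with_rates(current_rates()),
                None if constraints_per_tree[tree_idx] in (None, {})
                else constraints_per_tree[tree_idx])
            for nk in nodes:
                node = tree.find_clade(nk)
                if node is None:
                    continue
                post_sums[nk] += marg[node]
                post_counts[nk] += 1

    acc = rate_accs / rate_props if rate_props else 0.0
    n_ret = len(retained)
    node_post = {}
    for nk in nodes:
        c = post_counts[nk]
        node_post[nk] = post_sums[nk] / c if c else np.full(k, np.nan)
    lnl_arr = np.asarray(retained)
    total_visits = sum(model_visits.values()) or 1
    return PosteriorSummary(
        node_posteriors=node_post,
        node_counts=post_counts,
        acceptance_rate=acc,
        model_frequencies={m: v / total_visits for m, v in model_visits.items()},
        log_marginal_hm=harmonic_mean_log_marginal(lnl_arr),
        hm_jackknife_se=_hm_jackknife_se(lnl_arr),
        n_retained=n_ret,
        retained_lnL=tuple(retained),
    )


def tune_ratedev(sample: TreeSample, char: CharacterMatrix, template: RateModel,
                 config: McmcConfig, pilot_iterations: int = 10_000) -> float:
    """Double/halve ratedev until a pilot chain's rate-move acceptance rate
    falls inside the target window (too-high acceptance => larger steps).

    Deterministic given the config seed.  Raises if the window is not
    reached within 20 adjustments.
    """
    lo, hi = config.target_acceptance
    ratedev = config.ratedev
    burn = min(pilot_iterations // 5, pilot_iterations - 1)
    for _ in range(20):
        pilot = replace(config, iterations=pilot_iterations,
                        burnin_iterations=burn, ratedev=ratedev)
        acc = run_mcmc(sample, char, template, pilot).acceptance_rate
        if lo <= acc <= hi:
            return ratedev
        ratedev = ratedev * 2.0 if acc > hi else ratedev / 2.0
    raise RuntimeError("could not reach the target acceptance window in 20 steps")


def fixed_state_node_test(sample: TreeSample, char: CharacterMatrix,
                          template: RateModel, config: McmcConfig,
                          node: NodeKey,
                          states: tuple[int, int] = (0, 1)
                          ) -> tuple[float, int, tuple[PosteriorSummary, PosteriorSummary]]:
    """Bayes-factor test of a node's state via two fossilized chains.

    The node (an MRCA tip set) is fixed alternately at each candidate state;
    the two harmonic-mean marginal likelihoods are compared with 2 ln(BF).
    Returns (2lnBF of state[0] over state[1], favored state, summaries).
    """
    summaries = []
    for s in states:
        summaries.append(run_mcmc(sample, char, template, config,
                                  node_constraints={node: s}))
    stat, _ = bayes_factor_2ln(summaries[0].log_marginal_hm,
                               summaries[1].log_marginal_hm)
    favored = states[0] if stat >= 0 else states[1]
    return stat, favored, (summaries[0], summaries[1])
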