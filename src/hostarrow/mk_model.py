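"""Continuous-time Markov (Mk) models of discrete characters on rooted trees.

The Mk model evolves a k-state character along tree branches under a rate
matrix Q whose off-diagonal entries q_ij >= 0 are instantaneous transition
rates (events per unit branch length) and whose diagonal makes rows sum to
zero.  The character's likelihood on a tree is computed by the pruning
algorithm: a post-order recursion propagating per-state conditional
likelihoods from the tips to the root, where they are averaged over a root
prior (uniform over states by default).

Rate constraints are expressed as equality classes of off-diagonal cells
plus cells fixed to zero, which is how the irreversibility ("one-way")
models are built: the forbidden direction is a zero-fixed cell, and its
maximum likelihood lies on the boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from .io_formats import CharacterMatrix, RootedTree, TreeSample

__all__ = [
    "RateModel", "FitResult", "CharacterMatrix", "transition_matrix",
    "pruning_log_likelihood", "node_marginals", "fit_ml",
    "mean_lnL_over_sample", "RATE_LOWER", "RATE_UPPER",
]

RATE_LOWER = 1e-8
RATE_UPPER = 100.0

_ZERO = -2          # cell fixed to zero
_DIAG = -1          # diagonal marker in the cell-class matrix


@dataclass(frozen=True)
class RateModel:
    """A k-state rate matrix with equality/zero constraints and a root prior.

    ``cell_class[i, j]`` assigns each off-diagonal cell either an equality
    class index (>= 0, sharing one free rate) or the zero-fixed marker.
    ``rates`` holds one non-negative value per equality class.  The root
    prior policy is ``"uniform"``, ``"stationary"`` or an explicit vector.
    """

    k: int
    cell_class: tuple[tuple[int, ...], ...]
    rates: tuple[float, ...]
    root_prior: str | tuple[float, ...] = "uniform"

    def __post_init__(self):
        cc = np.asarray(self.cell_class)
        if cc.shape != (self.k, self.k):
            raise ValueError("cell_class must be k x k")
        classes = sorted({int(c) for c in cc.ravel() if c >= 0})
        if classes != list(range(len(classes))):
            raise ValueError("equality class indices must be 0..n_classes-1")
        if len(self.rates) != len(classes):
            raise ValueError("one rate per equality class required")
        if any(r < 0 or not np.isfinite(r) for r in self.rates):
            raise ValueError("rates must be finite and non-negative")

    # -- constructors -------------------------------------------------------
    @staticmethod
    def _grid(k: int) -> np.ndarray:
        return np.full((k, k), _DIAG, dtype=int)

    @classmethod
    def symmetric(cls, k: int = 2, rate: float = 1.0, **kw) -> "RateModel":
        """All off-diagonal cells share a single rate."""
        cc = cls._grid(k)
        cc[~np.eye(k, dtype=bool)] = 0
        return cls(k, _t(cc), (rate,), **kw)

    @classmethod
    def free(cls, k: int = 2, rates: tuple[float, ...] | None = None, **kw) -> "RateModel":
        """Every off-diagonal cell gets its own free rate (row-major order)."""
        cc = cls._grid(k)
        c = 0
        for i in range(k):
            for j in range(k):
                if i != j:
                    cc[i, j] = c
                    c += 1
        if rates is None:
            rates = tuple([1.0] * c)
        return cls(k, _t(cc), tuple(rates), **kw)

    @classmethod
    def one_way(cls, source: int, target: int, k: int = 2,
                rate: float = 1.0, **kw) -> "RateModel":
        """Binary-style irreversible model: only source -> target is allowed;
        every other off-diagonal cell is fixed to zero."""
        cc = cls._grid(k)
        cc[~np.eye(k, dtype=bool)] = _ZERO
        cc[source, target] = 0
        return cls(k, _t(cc), (rate,), **kw)

    # -- derived quantities -------------------------------------------------
    @property
    def n_classes(self) -> int:
        return len(self.rates)

    def with_rates(self, rates) -> "RateModel":
        return RateModel(self.k, self.cell_class, tuple(float(r) for r in rates),
                         self.root_prior)

    def q_matrix(self) -> np.ndarray:
        cc = np.asarray(self.cell_class)
        Q = np.zeros((self.k, self.k))
        for c, r in enumerate(self.rates):
            Q[cc == c] = r
        np.fill_diagonal(Q, 0.0)
        np.fill_diagonal(Q, -Q.sum(axis=1))
        return Q

    def root_distribution(self) -> np.ndarray:
        if isinstance(self.root_prior, str):
            if self.root_prior == "uniform":
                return np.full(self.k, 1.0 / self.k)
            if self.root_prior == "stationary":
                return self._stationary()
            raise ValueError(f"unknown root prior policy {self.root_prior!r}")
        pi = np.asarray(self.root_prior, dtype=float)
        if pi.shape != (self.k,) or abs(pi.sum() - 1) > 1e-9 or np.any(pi < 0):
            raise ValueError("fixed root prior must be a probability vector of length k")
        return pi

    def _stationary(self) -> np.ndarray:
        Q = self.q_matrix()
        if np.allclose(Q, 0):
            return np.full(self.k, 1.0 / self.k)
        A = np.vstack([Q.T, np.ones(self.k)])
        b = np.zeros(self.k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(A, b, rcond=None)
        pi = np.clip(pi, 0, None)
        return pi / pi.sum()


def _t(arr: np.ndarray) -> tuple[tuple[int, ...], ...]:
    return tuple(tuple(int(x) for x in row) for row in arr)


# ---------------------------------------------------------------------------
# Transition probabilities
# ---------------------------------------------------------------------------

def _p2(a: float, b: float, t) -> np.ndarray:
    """Closed-form 2-state transition matrix for rates q01=a, q10=b.

    ``t`` may be a scalar or an array; returns shape (..., 2, 2).
    """
    t = np.asarray(t, dtype=float)
    s = a + b
    out = np.zeros(t.shape + (2, 2))
    if s == 0:
        out[..., 0, 0] = 1.0
        out[..., 1, 1] = 1.0
        return out
    e = np.exp(-s * t)
    out[..., 0, 0] = (b + a * e) / s
    out[..., 0, 1] = a * (1 - e) / s
    out[..., 1, 0] = b * (1 - e) / s
    out[..., 1, 1] = (a + b * e) / s
    return out


def transition_matrix(model: RateModel, t: float) -> np.ndarray:
    """P(t) = exp(Qt): entry (i, j) is the probability of being in state j
    after duration t having started in state i.  Rows sum to 1."""
    if t < 0:
        raise ValueError("duration t must be non-negative")
    Q = model.q_matrix()
    if not np.all(np.isfinite(Q)):
        raise ValueError("non-finite rates")
    if model.k == 2:
        return _p2(Q[0, 1], Q[1, 0], float(t))
    return expm(Q * t)


# ---------------------------------------------------------------------------
# Pruning engine
# ---------------------------------------------------------------------------

class PruningEngine:
    """Caches the tree traversal and tip partials for repeated likelihood
    evaluations with different rates (the hot loop of ML fits and MCMC)."""

    def __init__(self, tree: RootedTree, char: CharacterMatrix, k: int | None = None):
        self.tree = tree
        self.k = char.k if k is None else k
        missing = tree.tip_labels() - char.taxa
        if missing:
            raise KeyError(f"tips absent from character matrix: {sorted(missing)}")
        n = tree.n_nodes
        self.tip_partials = np.ones((n, self.k))
        for v in tree.tips():
            s = char.state_index(tree.labels[v])
            if s is not None:
                if s >= self.k:
                    raise ValueError("state index exceeds k")
                self.tip_partials[v] = 0.0
                self.tip_partials[v, s] = 1.0
        self.post = tree.postorder()

    def _edge_P(self, model: RateModel) -> np.ndarray:
        Q = model.q_matrix()
        bl = self.tree.branch_lengths
        if self.k == 2:
            return _p2(Q[0, 1], Q[1, 0], bl)
        P = np.empty((self.tree.n_nodes, self.k, self.k))
        cache: dict[float, np.ndarray] = {}
        for v in range(self.tree.n_nodes):
            t = float(bl[v])
            if t not in cache:
                cache[t] = expm(Q * t)
            P[v] = cache[t]
        return P

    def _down(self, model: RateModel,
              constraints: dict[int, int] | None = None):
        """Post-order partials with per-node rescaling.

        Returns (partials, logscale) where ``partials[v]`` is the rescaled
        conditional likelihood of the data below v given the state at v and
        ``logscale[v]`` the accumulated log of its subtree's scale factors.
        ``constraints`` fossilizes nodes: states other than the fixed one get
        partial 0.
        """
        P = self._edge_P(model)
        n = self.tree.n_nodes
        down = np.empty((n, self.k))
        logscale = np.zeros(n)
        for v in self.post:
            kids = self.tree.children[v]
            if not kids:
                part = self.tip_partials[v].copy()
            else:
                part = np.ones(self.k)
                ls = 0.0
                for c in kids:
                    part = part * (P[c] @ down[c])
                    ls += logscale[c]
                logscale[v] = ls
            if constraints and v in constraints:
                mask = np.zeros(self.k)
                mask[constraints[v]] = 1.0
                part = part * mask
            m = part.max()
            if m > 0:
                part = part / m
                logscale[v] += np.log(m)
            else:
                logscale[v] = -np.inf
            down[v] = part
        return P, down, logscale

    def log_likelihood(self, model: RateModel,
                       constraints: dict[int, int] | None = None) -> float:
        _, down, logscale = self._down(model, constraints)
        root = self.tree.root
        pi = model.root_distribution()
        lik = float(pi @ down[root])
        if lik <= 0 or not np.isfinite(logscale[root]):
            return -np.inf
        return float(np.log(lik) + logscale[root])

    def marginals(self, model: RateModel,
                  constraints: dict[int, int] | None = None) -> np.ndarray:
        """Per-node marginal posterior state probabilities given the rates
        (inside-outside recursion); rows sum to 1."""
        P, down, _ = self._down(model, constraints)
        n = self.tree.n_nodes
        tree = self.tree
        out = np.zeros((n, self.k))
        out[tree.root] = model.root_distribution()
        # pre-order: parent's outside is complete before its children
        for v in reversed(self.post):
            kids = tree.children[v]
            if not kids:
                continue
            lifted = [P[c] @ down[c] for c in kids]
            for idx, c in enumerate(kids):
                sib = out[v].copy()
                for jdx, l in enumerate(lifted):
                    if jdx != idx:
                        sib = sib * l
                o = sib @ P[c]
                tot = o.sum()
                out[c] = o / tot if tot > 0 else o
        marg = out * down
        sums = marg.sum(axis=1, keepdims=True)
        sums[sums == 0] = 1.0
        return marg / sums


# ---------------------------------------------------------------------------
# Public likelihood / fitting API
# ---------------------------------------------------------------------------

def pruning_log_likelihood(tree: RootedTree, model: RateModel,
                           char: CharacterMatrix,
                           node_constraints: dict[int, int] | None = None) -> float:
    """Log-likelihood (nats) of the character on the tree under the model.

    Missing tips contribute all-ones partials (full marginalization), so a
    tree whose tips are all missing has likelihood 1 (lnL = 0).
    """
    if char.k != model.k:
        raise ValueError(f"character has k={char.k} but model has k={model.k}")
    return PruningEngine(tree, char).log_likelihood(model, node_constraints)


def node_marginals(tree: RootedTree, model: RateModel, char: CharacterMatrix,
                   node_constraints: dict[int, int] | None = None) -> np.ndarray:
    """Marginal posterior state probabilities for every node (rows sum to 1)."""
    if char.k != model.k:
        raise ValueError(f"character has k={char.k} but model has k={model.k}")
    return PruningEngine(tree, char).marginals(model, node_constraints)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood rates under a constrained template."""

    model: RateModel
    log_likelihood: float
    converged: bool
    n_evaluations: int

    @property
    def rates(self) -> tuple[float, ...]:
        return self.model.rates


_START_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)  # deterministic log-spaced starts


def _starts(n_classes: int) -> list[np.ndarray]:
    """Shared-value log-spaced starts plus, for multi-class templates,
    boundary-style starts (one class near zero, the rest at 1) — nested
    one-way optima live there and a purely shared grid can miss them."""
    starts = [np.full(n_classes, np.log10(s)) for s in _START_GRID]
    if n_classes > 1:
        for c in range(n_classes):
            x = np.zeros(n_classes)
            x[c] = -7.0
            starts.append(x)
    return starts


def fit_ml(tree: RootedTree, char: CharacterMatrix, model_template: RateModel,
           engine: PruningEngine | None = None) -> FitResult:
    """Maximize the pruning likelihood over the template's free rates.

    Bounded multi-start optimization (L-BFGS-B on log10 rates, bounds
    [1e-8, 100], deterministic start grid: five shared log-spaced values
    plus one near-zero-per-class boundary start each).  Non-convergence of
    every start yields a flagged result, not an exception.
    """
    if engine is None:
        engine = PruningEngine(tree, char, k=model_template.k)
    nc = model_template.n_classes
    if nc == 0:
        lnl = engine.log_likelihood(model_template)
        return FitResult(model_template, lnl, True, 1)

    evals = 0

    def nll(logr: np.ndarray) -> float:
        nonlocal evals
        evals += 1
        lnl = engine.log_likelihood(model_template.with_rates(10.0 ** logr))
        return 1e300 if not np.isfinite(lnl) else -lnl

    lb, ub = np.log10(RATE_LOWER), np.log10(RATE_UPPER)
    best = None
    any_ok = False
    for x0 in _starts(nc):
        res = minimize(nll, x0, method="L-BFGS-B", bounds=[(lb, ub)] * nc,
                       options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500})
        any_ok = any_ok or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    rates = tuple(float(r) for r in 10.0 ** best.x)
    return FitResult(model_template.with_rates(rates), -float(best.fun),
                     any_ok, evals)


def mean_lnL_over_sample(sample: TreeSample, char: CharacterMatrix,
                         model_template: RateModel) -> float:
    """Arithmetic mean of per-tree maximized log-likelihoods across a tree
    sample, each tree fitted independently (the averaging step of the
    irreversibility test).  Fails if more than 10% of trees fail to fit."""
    if len(sample) == 0:
        raise ValueError("tree sample is empty")
    lnls: list[float] = []
    failures = 0
    for tree in sample:
        try:
            fit = fit_ml(tree, char, model_template)
        except Exception as exc:
            warnings.warn(f"per-tree fit raised: {exc}")
            failures += 1
            continue
        if not fit.converged or not np.isfinite(fit.log_likelihood):
            warnings.warn("per-tree fit did not converge")
            failures += 1
            continue
        lnls.append(fit.log_likelihood)
    if failures > 0.10 * len(sample):
        raise RuntimeError(f"{failures}/{len(sample)} per-tree fits failed")
    return float(np.mean(lnls))
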