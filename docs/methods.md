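# Methods

## The model

A discrete character with k states evolves along the branches of a rooted
tree as a continuous-time Markov chain (the Mk family). The rate matrix Q
has off-diagonal entries q_ij ≥ 0 (expected transitions per unit branch
length) and diagonal entries making rows sum to zero; transition
probabilities over a branch of length t are P(t) = exp(Qt) (closed form for
k = 2, `scipy.linalg.expm` otherwise). Rate constraints are expressed as
equality classes of off-diagonal cells plus cells fixed to zero; the
"irreversible" one-way models are ordinary templates with the forbidden
cell zero-fixed, optimized on the boundary rather than reparameterized.

The likelihood of tip data is computed by the pruning algorithm: a
post-order recursion over per-state conditional likelihoods with per-node
rescaling, missing tips contributing all-ones partials. The root prior is
uniform over states by default. This is an assumption, not a theorem: the
upstream program whose behavior this package mirrors does not document its
root treatment, and the uniform choice makes the degenerate monomorphic
case exactly ln(1/k) under the shared-rate model. Stationary and fixed
vectors are available via `RateModel(root_prior=...)`.

Two consequences of the uniform root prior are worth knowing because they
shape the tests. With *distinct* rates, a monomorphic dataset (all tips in
state 0) does not force both rates to zero: a near-zero gain rate combined
with an arbitrarily large loss rate drives the likelihood to 1 (whichever
state the root takes, it is in state 0 before the first split), and the
root's marginal posterior tends to 1/2. Both effects were verified against
grid quadrature. Statements like "monomorphic data ⇒ every node posterior
near 1 for the observed state" therefore hold only when rate × depth is
small — short branches or a tight prior — and the corresponding tests are
phrased that way.

## Maximum-likelihood fitting

`fit_ml` maximizes the pruning likelihood over the free equality-class
rates with L-BFGS-B on log10 rates, bounds [1e-8, 100], and a
deterministic start grid: five shared log-spaced values (0.01, 0.1, 1, 10,
100) plus, for multi-parameter templates, one start per class with that
class near zero and the others at 1. The boundary starts matter: the
likelihood surface can hold a local optimum away from the boundary while
the global optimum has one rate at zero (the nested one-way solution), and
a purely shared-value grid can miss it, producing spurious negative LRs.
There is no stochastic restart, so fits are reproducible bit-for-bit. Non-convergence
is flagged on the result, not raised. `mean_lnL_over_sample` fits every
tree of a posterior sample independently and averages the maximized
log-likelihoods, failing if more than 10% of per-tree fits fail.

## Parsimony

Unordered parsimony is implemented as unit-cost Sankoff dynamic
programming, which handles polytomies (consensus trees contain them) and
yields for every node the exact MPR set — the union of its states over all
most-parsimonious reconstructions — via combined subtree and rest-of-tree
cost tables. Change counting distinguishes branches where parent and child
MPR sets are disjoint (a change in every MPR, "unambiguous") from branches
whose sets intersect but where at least one MPR still places a change
("ambiguous"). Both counts are reported; collapsing them into a single
switch total is left to the caller because the two conventions genuinely
differ. Missing tips carry the full state set.

## MCMC ancestral mapping

`run_mcmc` runs a Metropolis–Hastings chain over the free rates, with three
further ingredients:

* **Tree uncertainty.** At each iteration a tree is drawn uniformly at
  random (seeded) from the posterior sample. Nodes are addressed as MRCAs
  of tip sets so they remain identifiable across topologies; iterations
  whose current tree lacks the clade are skipped for that node's summary
  (and counted). A constrained node absent from more than half the sample
  is an error.
* **Priors.** Each rate gets an exponential prior whose mean is itself
  uniform on [a, b] and is resampled by its own Metropolis move — the
  "hyperprior on an interval" construction. With a = b the mean is fixed; a
  flat prior on [0, bound] exists for oracle comparisons, because a flat
  prior is what a grid quadrature over the rates integrates most
  transparently.
* **Reversible jump.** For a binary character with two free cells the
  model space is {equal rates, distinct rates}; the split move draws the
  second rate from its prior (so prior and proposal cancel and the
  acceptance ratio is the likelihood ratio), the merge move drops it.
  Visited-model frequencies are reported. Larger state spaces run with the
  model fixed — the per-host analyses are all binary, so nothing in the
  pipeline needs RJ beyond k = 2.

Rate proposals are uniform sliding windows of half-width `ratedev`
reflected at zero; `tune_ratedev` doubles/halves until a pilot chain's
rate-move acceptance lies in the 20–40% window. Summaries are taken every
100th retained iteration (a fixed, documented choice; the upstream
behavior is unstated): the data likelihood (for the harmonic mean) and the
marginal node posteriors by an inside–outside pass, averaged over retained
iterations.

The harmonic-mean marginal-likelihood estimator is used because it is what
the original analysis used; it is known to be high-variance, so a jackknife
standard error is reported alongside. Model comparison uses
2 ln BF = 2(ln HM₁ − ln HM₂) with thresholds 2/6/10. Node-state support
uses two fossilized chains (the node's partial likelihood masked to each
candidate state) compared the same way.

## Specificity classification

Host lineages LS/LO belong to the genus *Lasioglossum* and H/S to
*Halictus*; A, C, P, M are genera of their own. With `n_genera` derived
from a species' host-lineage flags, the rules are:

* **Distribution I** — specialist iff `n_genera == 1`, or all hosts
  outside one primary genus are used only sporadically
  (`sporadic_extra`). The "all extras sporadic" reading (rather than
  "exactly one extra") is required for internal consistency of the
  published per-species calls, which include a three-genus species rated
  specialist under this rule.
* **Distribution II** — as I, plus `eco_similar` (all hosts, including
  sporadic extras, ecologically similar).
* **Distribution III** — specialist iff `n_genera == 1` and `eco_similar`.
* No recorded hosts ⇒ unknown (missing data downstream).

The packaged table (`hostarrow/data/sphecodes_hosts.csv`) carries the 37
species' host-lineage flags and the two annotations, curated to be
consistent with the published per-species calls; the classifier is pure
rule logic and reproduces all 37 rows under all three rules. A
`sporadic_extra` flag on a single-genus record is rejected as
contradictory. The table has 7 species without host records; counts of
specialists and generalists are reported over the 30 known-host species.

## Irreversibility test

The LR statistic is formed from the *means* of per-tree maximized
log-likelihoods across the tree sample — not from per-tree LRs averaged;
the two differ and the former is the procedure being reproduced. Each
one-way model removes one free parameter, so LR = 2(⟨lnL_bi⟩ −
⟨lnL_one-way⟩) is referred to χ²₁ (`erfc(sqrt(x/2))`). The headline
p-value uses the plain χ²₁ reference even though the one-way null sits on
the zero-rate boundary; the boundary-respecting ½χ²₀ + ½χ²₁ mixture is
available behind `boundary_mixture=True` and clearly non-default. Small
negative LRs (|LR| < 1e-4, optimizer noise) are clamped to zero with a
warning; larger ones raise.

`likelihood_ratio_stage` is exposed separately so the LR/p arithmetic can
be run on already tabulated mean log-likelihoods.

## Synthetic data

The generators replace the study's unavailable upstream artifacts:

* **Yule trees** (`simulate_yule_tree`): exponential waiting times with a
  final interval to the present, so trees are ultrametric with expected
  root-to-tip depth Σ_{k=2}^n 1/(kλ).
* **Posterior-like samples** (`emulate_tree_sample`): lognormal
  multiplicative branch-length jitter around a base tree with fixed
  topology. This emulates branch-length uncertainty only; real posterior
  samples also vary in topology, so pipeline behavior under topological
  conflict is exercised only via the MRCA-addressing machinery, not by the
  generator.
* **Characters** (`simulate_mk_character`): exact event-by-event CTMC
  simulation (waiting times and jumps), not endpoint sampling, so every
  true transition has a branch and position — required by the
  switch-recovery tests.
* **Host tables** (`simulate_host_table`): eight independent binary
  presence/absence characters (default gain 0.3, loss 0.6 per unit branch
  length, root 90% absent — sparse tables with occasional gains, echoing
  real host records where most species use one or two lineages).
  Annotations derive from realized host sets: `eco_similar` iff the hosts
  span one genus, `sporadic_extra` never (the simulator has no notion of
  sporadic use).

Passing tests on these generators demonstrate correctness of the
algorithms under the stated models; they do not validate the ecological
annotations or the host-record curation, which are data, not code.

## Calibration checks and problem sizes

The suite's heavier checks, with the sizes chosen to keep the default run
in minutes:

* Pruning likelihood vs exhaustive enumeration on random trees ≤ 6 tips,
  k ≤ 3 (tolerance 1e-10); Fitch/MPR vs brute force on trees ≤ 7 tips,
  k ≤ 4, polytomies and missing data included.
* MCMC node posteriors vs 2-D grid quadrature under a flat rate prior
  (cherry at 200k iterations, 3-tip tree at 150k; sup-norm tolerance
  0.02).
* Rate recovery: 100 characters simulated with rates (2, 5) on fresh
  200-tip Yule trees; the truth must lie inside the empirical 95% band of
  the 100 ML estimates.
* LRT size at the boundary: 200 characters simulated under the true
  G→S-only model (rate 1) on 40-tip Yule trees; the plain χ²₁ test's
  rejection rate at α = 0.05 must not exceed 0.05 + 3·SE. Simulating under
  the one-way model is what makes this a size (type-I) check — under a
  bidirectional generator the one-way null is false and rejections measure
  power instead, which a companion test asserts exceeds the size.

## Known limitations

* The harmonic-mean marginal likelihood is a poor estimator; it is kept
  for fidelity, with a jackknife SE as a health indicator. Stepping-stone
  or path sampling are out of scope.
* Tree sampling is restricted to the provided posterior sample; there are
  no topology moves.
* The RJ model space is the binary pair {equal, distinct}; general
  k-state partition jumping is not implemented.
* Host-switch totals depend on the consensus topology of the original
  study, which is available only as a figure; the pipeline reproduces the
  counting semantics on synthetic data but not the empirical totals.
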