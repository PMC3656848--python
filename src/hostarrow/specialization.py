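"""Host specificity of Sphecodes cuckoo bees: classification, ancestral host
calls, switch counting and the irreversibility test.

*Sphecodes* cuckoo bees lay eggs in the nests of other bees; their recorded
hosts fall into eight lineages: Lasioglossum sensu stricto (LS), other
Lasioglossum (LO), Halictus subgenus Halictus (H), Halictus subgenus
Seladonia (S), Andrena (A), Colletes (C), Perdita (P) and Melitturga (M).
LS/LO belong to the genus Lasioglossum and H/S to Halictus; the remaining
four are genera of their own.

Each species is called specialist (S) or generalist (G) under three graded
rule sets of increasing strictness:

* Distribution I  — specialist iff the hosts span a single genus, or every
  host outside one primary genus is used only sporadically;
* Distribution II — as I, with the additional requirement that the hosts
  (including any sporadic extras) are ecologically similar;
* Distribution III — specialist iff the hosts are ecologically similar and
  belong to a single genus.

Species with no recorded hosts are 'unknown' and enter all reconstructions
as missing data.

The irreversibility test compares the mean (over a posterior tree sample)
of per-tree maximized log-likelihoods of a bidirectional model against the
two one-way models (G->S only; S->G only).  Each one-way model removes one
free parameter, so LR = 2 * (mean lnL_bidirectional - mean lnL_one-way) is
referred to a chi-square distribution with one degree of freedom.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .bayes_mapping import PosteriorSummary
from .io_formats import CharacterMatrix, RootedTree, TreeSample
from .mk_model import RateModel, mean_lnL_over_sample

logger = logging.getLogger(__name__)

__all__ = [
    "HOST_LINEAGES", "HOST_GENUS", "SpeciesHostRecord", "HostTable",
    "load_reference_host_table", "classify_specificity", "count_specificity",
    "build_host_datasets", "AncestralHostCalls", "call_ancestral_hosts",
    "detect_host_switches", "chi2_upper_tail_df1", "IrreversibilityResult",
    "likelihood_ratio_stage", "run_irreversibility_test",
]

HOST_LINEAGES = ("LS", "LO", "H", "S", "A", "C", "P", "M")

#: host lineage -> host genus (LS/LO are Lasioglossum; H/S are Halictus)
HOST_GENUS = {"LS": "Lasioglossum", "LO": "Lasioglossum",
              "H": "Halictus", "S": "Halictus",
              "A": "Andrena", "C": "Colletes", "P": "Perdita", "M": "Melitturga"}

SPECIALIST, GENERALIST, UNKNOWN = "S", "G", "unknown"


@dataclass(frozen=True)
class SpeciesHostRecord:
    """One species' host-association row.

    ``sporadic_extra`` flags species whose hosts outside one primary genus
    are all used only sporadically; ``eco_similar`` flags species whose
    hosts (including sporadic extras) are ecologically similar.
    """

    species: str
    hosts: frozenset[str]
    sporadic_extra: bool = False
    eco_similar: bool = False

    def __post_init__(self):
        bad = self.hosts - set(HOST_LINEAGES)
        if bad:
            raise ValueError(f"{self.species}: unknown host lineage(s) {sorted(bad)}")
        if self.sporadic_extra and self.n_genera < 2:
            raise ValueError(
                f"{self.species}: sporadic-extra flag requires at least two host genera")

    @property
    def n_genera(self) -> int:
        return len({HOST_GENUS[h] for h in self.hosts})


class HostTable:
    """An ordered collection of :class:`SpeciesHostRecord`."""

    def __init__(self, records: Sequence[SpeciesHostRecord]):
        names = [r.species for r in records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate species in host table")
        self.records: tuple[SpeciesHostRecord, ...] = tuple(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def species(self) -> list[str]:
        return [r.species for r in self.records]

    @classmethod
    def from_csv(cls, path) -> "HostTable":
        df = pd.read_csv(path)
        records = []
        for row in df.itertuples():
            hosts = frozenset(h for h in HOST_LINEAGES if int(getattr(row, h)))
            records.append(SpeciesHostRecord(
                species=row.species, hosts=hosts,
                sporadic_extra=bool(int(row.sporadic_extra)),
                eco_similar=bool(int(row.eco_similar))))
        return cls(records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {"species": r.species,
                   "spec_I": classify_specificity(r, "I"),
                   "spec_II": classify_specificity(r, "II"),
                   "spec_III": classify_specificity(r, "III")}
            row.update({h: int(h in r.hosts) for h in HOST_LINEAGES})
            row.update({"n_genera": r.n_genera,
                        "sporadic_extra": int(r.sporadic_extra),
                        "eco_similar": int(r.eco_similar)})
            rows.append(row)
        return pd.DataFrame(rows)


def load_reference_host_table() -> HostTable:
    """The packaged host-association table for the 37 analyzed Sphecodes
    species (host-lineage flags plus sporadic-use and ecological-similarity
    annotations curated from the published host catalogues)."""
    from importlib.resources import files
    return HostTable.from_csv(files("hostarrow.data") / "sphecodes_hosts.csv")


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify_specificity(record: SpeciesHostRecord, distribution: str) -> str:
    """Apply one of the three specialist/generalist rule sets (see module
    docstring); species without host records are 'unknown'."""
    if distribution not in ("I", "II", "III"):
        raise ValueError("distribution must be 'I', 'II' or 'III'")
    if not record.hosts:
        return UNKNOWN
    single_or_sporadic = record.n_genera == 1 or record.sporadic_extra
    if distribution == "I":
        return SPECIALIST if single_or_sporadic else GENERALIST
    if distribution == "II":
        return SPECIALIST if (record.eco_similar and single_or_sporadic) else GENERALIST
    return SPECIALIST if (record.n_genera == 1 and record.eco_similar) else GENERALIST


def count_specificity(table: HostTable, distribution: str) -> tuple[int, int, int]:
    """(n_specialist, n_generalist, n_unknown) under one rule set."""
    calls = [classify_specificity(r, distribution) for r in table]
    return (calls.count(SPECIALIST), calls.count(GENERALIST), calls.count(UNKNOWN))


def specificity_character(table: HostTable, distribution: str) -> CharacterMatrix:
    """Binary S/G character matrix (unknown species coded missing).

    State indices follow the lexicographic convention: G = 0, S = 1.
    """
    assignments = {}
    for r in table:
        call = classify_specificity(r, distribution)
        assignments[r.species] = None if call == UNKNOWN else call
    return CharacterMatrix(assignments, state_labels=("G", "S"))


def build_host_datasets(table: HostTable) -> dict[str, CharacterMatrix]:
    """One binary presence/absence character per host lineage.

    Species without any host record are missing in all eight matrices
    (state labels "0"/"1": absent = 0, present = 1).
    """
    out = {}
    for host in HOST_LINEAGES:
        assignments: dict[str, str | None] = {}
        for r in table:
            if not r.hosts:
                assignments[r.species] = None
            else:
                assignments[r.species] = "1" if host in r.hosts else "0"
        out[host] = CharacterMatrix(assignments, state_labels=("0", "1"))
    return out


# ---------------------------------------------------------------------------
# Ancestral host calls and switch counting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncestralHostCalls:
    """Per node (keyed by clade tip set): hosts whose mean posterior
    probability of presence exceeds the (strict) threshold."""

    calls: dict[frozenset, frozenset[str]]
    threshold: float = 0.7


def call_ancestral_hosts(posteriors: Mapping[str, PosteriorSummary],
                         threshold: float = 0.7) -> AncestralHostCalls:
    """Threshold the per-host presence posteriors into host sets per node.

    Presence is state index 1 of the binary per-host character; inclusion
    requires PP strictly greater than the threshold (a PP of exactly 0.7 is
    excluded).
    """
    node_sets: dict[frozenset, set[str]] = {}
    ref_nodes = None
    for host, summary in posteriors.items():
        nodes = set(summary.node_posteriors)
        if ref_nodes is None:
            ref_nodes = nodes
            node_sets = {nk: set() for nk in nodes}
        elif nodes != ref_nodes:
            raise ValueError("posterior summaries disagree on node addressing")
        for nk, pp in summary.node_posteriors.items():
            if np.isfinite(pp[1]) and pp[1] > threshold:
                node_sets[nk].add(host)
    return AncestralHostCalls(
        {nk: frozenset(s) for nk, s in node_sets.items()}, threshold)


def detect_host_switches(tree: RootedTree,
                         node_host_sets: Mapping[int, frozenset[str] | set[str]]
                         ) -> tuple[list[tuple[int, str]], int]:
    """Enumerate host switches as gains relative to the parent node.

    A switch is a host lineage present in a child's set but absent from its
    parent's non-empty set; several gains on one branch count separately.
    Branches whose parent set is empty carry no signal and are skipped (and
    logged).  Losses are not counted.  Returns ([(child_node, host), ...],
    total count).
    """
    switches: list[tuple[int, str]] = []
    skipped = 0
    for v in range(tree.n_nodes):
        if v == tree.root:
            continue
        p = int(tree.parent[v])
        parent_set = frozenset(node_host_sets.get(p, frozenset()))
        child_set = frozenset(node_host_sets.get(v, frozenset()))
        if not parent_set:
            skipped += 1
            continue
        for host in sorted(child_set - parent_set):
            switches.append((v, host))
    if skipped:
        logger.info("detect_host_switches: skipped %d branch(es) with an "
                    "empty parent host set", skipped)
    return switches, len(switches)


# ---------------------------------------------------------------------------
# Irreversibility test
# ---------------------------------------------------------------------------

def chi2_upper_tail_df1(x: float) -> float:
    """Upper tail (survival function) of chi-square with 1 df."""
    if x < 0:
        raise ValueError("chi-square statistic must be non-negative")
    return float(chi2.sf(x, df=1))


@dataclass(frozen=True)
class IrreversibilityResult:
    """Mean log-likelihoods of the three transition models and the two
    likelihood-ratio comparisons against the bidirectional model."""

    mean_lnl_bidirectional: float
    mean_lnl_g_to_s_only: float
    mean_lnl_s_to_g_only: float
    lr_g_to_s_only: float
    lr_s_to_g_only: float
    p_g_to_s_only: float
    p_s_to_g_only: float
    alpha: float = 0.05

    @property
    def reject_g_to_s_only(self) -> bool:
        return self.p_g_to_s_only < self.alpha

    @property
    def reject_s_to_g_only(self) -> bool:
        return self.p_s_to_g_only < self.alpha


def _lr(mean_bidir: float, mean_oneway: float) -> float:
    lr = 2.0 * (mean_bidir - mean_oneway)
    if lr < 0:
        if lr > -1e-4:
            warnings.warn("small negative LR clamped to 0 (optimizer noise)")
            return 0.0
        raise RuntimeError(f"LR = {lr:.6g} < 0: one-way fit beat the nested "
                           "bidirectional fit; check fit quality")
    return lr


def likelihood_ratio_stage(mean_lnl_bidirectional: float,
                           mean_lnl_g_to_s_only: float,
                           mean_lnl_s_to_g_only: float,
                           alpha: float = 0.05) -> IrreversibilityResult:
    """LR statistics and chi-square(1) p-values from mean log-likelihoods.

    Exposed separately so the statistic can be recomputed from already
    tabulated mean likelihoods.
    """
    lr_gs = _lr(mean_lnl_bidirectional, mean_lnl_g_to_s_only)
    lr_sg = _lr(mean_lnl_bidirectional, mean_lnl_s_to_g_only)
    return IrreversibilityResult(
        mean_lnl_bidirectional=mean_lnl_bidirectional,
        mean_lnl_g_to_s_only=mean_lnl_g_to_s_only,
        mean_lnl_s_to_g_only=mean_lnl_s_to_g_only,
        lr_g_to_s_only=lr_gs, lr_s_to_g_only=lr_sg,
        p_g_to_s_only=chi2_upper_tail_df1(lr_gs),
        p_s_to_g_only=chi2_upper_tail_df1(lr_sg),
        alpha=alpha)


# G = 0 and S = 1 under the lexicographic state convention.
def bidirectional_template() -> RateModel:
    return RateModel.free(2)


def g_to_s_only_template() -> RateModel:
    """Transitions allowed only generalist -> specialist (q_SG fixed to 0)."""
    return RateModel.one_way(source=0, target=1)


def s_to_g_only_template() -> RateModel:
    """Transitions allowed only specialist -> generalist (q_GS fixed to 0)."""
    return RateModel.one_way(source=1, target=0)


def run_irreversibility_test(sample: TreeSample, spec_char: CharacterMatrix,
                             alpha: float = 0.05,
                             boundary_mixture: bool = False) -> IrreversibilityResult:
    """Fit the three transition models tree-by-tree over the sample, average
    the maximized log-likelihoods, and compare via the LR test.

    The LR is formed from MEAN log-likelihoods across the tree sample, not
    from per-tree LRs averaged (the two differ).  The headline p-value uses
    the plain chi-square(1) reference; ``boundary_mixture=True`` instead
    applies the boundary-respecting 1/2 chi2(0) + 1/2 chi2(1) mixture
    (halving the tail), a non-default alternative since the zero-rate null
    lies on the parameter boundary.
    """
    if spec_char.k != 2:
        raise ValueError("the irreversibility test needs a binary S/G character")
    means = {}
    for name, tmpl in (("bi", bidirectional_template()),
                       ("gs", g_to_s_only_template()),
                       ("sg", s_to_g_only_template())):
        means[name] = mean_lnL_over_sample(sample, spec_char, tmpl)
    result = likelihood_ratio_stage(means["bi"], means["gs"], means["sg"], alpha)
    if boundary_mixture:
        result = IrreversibilityResult(
            mean_lnl_bidirectional=result.mean_lnl_bidirectional,
            mean_lnl_g_to_s_only=result.mean_lnl_g_to_s_only,
            mean_lnl_s_to_g_only=result.mean_lnl_s_to_g_only,
            lr_g_to_s_only=result.lr_g_to_s_only,
            lr_s_to_g_only=result.lr_s_to_g_only,
            p_g_to_s_only=0.5 * result.p_g_to_s_only
            if result.lr_g_to_s_only > 0 else 1.0,
            p_s_to_g_only=0.5 * result.p_s_to_g_only
            if result.lr_s_to_g_only > 0 else 1.0,
            alpha=alpha)
    return result
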