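"""Specificity classification, host datasets, switch counting and the
irreversibility LR machinery."""

import numpy as np
import pandas as pd
import pytest
from importlib.resources import files
from scipy.integrate import quad
from scipy.stats import chi2 as chi2_dist

import hostarrow as ha
from hostarrow.specialization import (HOST_LINEAGES, SpeciesHostRecord,
                                      build_host_datasets,
                                      classify_specificity,
                                      likelihood_ratio_stage,
                                      specificity_character)


def _record(name, hosts, sporadic=False, eco=False):
    return SpeciesHostRecord(name, frozenset(hosts), sporadic, eco)


class TestClassification:
    def test_two_genera_sporadic_eco_similar(self):
        """Sporadic ecologically similar second genus: specialist under I
        and II but generalist under the single-genus rule III."""
        rec = _record("cristatus", {"LO", "S"}, sporadic=True, eco=True)
        assert classify_specificity(rec, "I") == "S"
        assert classify_specificity(rec, "II") == "S"
        assert classify_specificity(rec, "III") == "G"

    def test_broad_host_range_generalist_everywhere(self):
        rec = _record("ephippius", {"LS", "LO", "H", "S", "A"})
        assert rec.n_genera == 3
        for d in ("I", "II", "III"):
            assert classify_specificity(rec, d) == "G"

    def test_single_genus_two_lineages(self):
        """Two host lineages of one genus still count as a single genus."""
        rec = _record("olivieri", {"LS", "LO"}, eco=True)
        assert rec.n_genera == 1
        for d in ("I", "II", "III"):
            assert classify_specificity(rec, d) == "S"

    def test_no_hosts_is_unknown(self):
        rec = _record("mystery", set())
        for d in ("I", "II", "III"):
            assert classify_specificity(rec, d) == "unknown"

    def test_sporadic_flag_with_single_genus_is_contradiction(self):
        with pytest.raises(ValueError, match="sporadic"):
            _record("bad", {"LO"}, sporadic=True)

    def test_reference_counts(self, host_table):
        """2, 8 and 9 generalists under rules I, II, III; 30 species with
        known hosts out of 37."""
        for dist, n_gen in (("I", 2), ("II", 8), ("III", 9)):
            n_s, n_g, n_u = ha.count_specificity(host_table, dist)
            assert n_g == n_gen
            assert n_s + n_g == 30
            assert n_u == 7

    def test_reference_full_agreement(self, host_table):
        """The rule logic reproduces every published per-species call of the
        packaged table under all three rule sets (37/37 rows)."""
        raw = pd.read_csv(files("hostarrow.data") / "sphecodes_hosts.csv")
        published = raw.set_index("species")
        for rec in host_table:
            for dist, col in (("I", "spec_I"), ("II", "spec_II"),
                              ("III", "spec_III")):
                want = published.loc[rec.species, col]
                got = classify_specificity(rec, dist)
                assert got == ("unknown" if want == "?" else want), \
                    f"{rec.species} under {dist}"

    def test_specificity_character_coding(self, host_table):
        char = specificity_character(host_table, "II")
        assert char.state_labels == ("G", "S")
        assert char.is_missing("S. dusmeti")
        assert char.state_index("S. ephippius") == 0  # G
        assert char.state_index("S. majalis") == 1    # S


class TestHostDatasets:
    def test_presence_rows(self, host_table):
        mats = build_host_datasets(host_table)
        assert set(mats) == set(HOST_LINEAGES)
        present = [h for h in HOST_LINEAGES
                   if mats[h].state_index("S. ephippius") == 1]
        assert present == ["LS", "LO", "H", "S", "A"]

    def test_unknown_species_missing_everywhere(self, host_table):
        mats = build_host_datasets(host_table)
        for h in HOST_LINEAGES:
            assert mats[h].is_missing("S. dusmeti")
            assert not mats[h].is_missing("S. majalis")

    def test_empty_table(self):
        mats = build_host_datasets(ha.HostTable([]))
        assert set(mats) == set(HOST_LINEAGES)
        assert all(len(m) == 0 for m in mats.values())


class TestAncestralCallsAndSwitches:
    def test_threshold_is_strict(self):
        from hostarrow.bayes_mapping import PosteriorSummary
        node = frozenset({"a", "b"})

        def summary(pp):
            return PosteriorSummary({node: np.array([1 - pp, pp])}, {node: 1},
                                    0.3, {}, 0.0, 0.0, 1)
        calls = ha.call_ancestral_hosts(
            {"LS": summary(0.71), "LO": summary(0.70), "A": summary(0.69)}, 0.7)
        assert calls.calls[node] == frozenset({"LS"})

    def test_threshold_application(self):
        from hostarrow.bayes_mapping import PosteriorSummary
        node = frozenset({"a"})
        posts = {h: PosteriorSummary({node: np.array([1 - p, p])}, {node: 1},
                                     0.3, {}, 0.0, 0.0, 1)
                 for h, p in (("A", 0.9), ("C", 0.8), ("M", 0.6))}
        calls = ha.call_ancestral_hosts(posts, 0.7)
        assert calls.calls[node] == frozenset({"A", "C"})

    def test_gain_counting(self, cherry):
        tree = ha.parse_newick("((A:1,B:1):1,C:1);")
        node_ab = tree.mrca(["A", "B"])
        a, b, c = (tree.mrca([x]) for x in "ABC")
        sets = {tree.root: {"LO"}, node_ab: {"LO"},
                a: {"LO", "A"},               # one gain
                b: {"C", "M", "LO"},          # two gains on one branch
                c: {"LO"}}
        switches, total = ha.detect_host_switches(tree, sets)
        assert total == 3
        assert (a, "A") in switches
        assert {(b, "C"), (b, "M")} <= set(switches)

    def test_empty_parent_sets_are_skipped(self):
        tree = ha.parse_newick("((A:1,B:1):1,C:1);")
        sets = {tree.root: set(), tree.mrca(["A", "B"]): {"LS"},
                tree.mrca(["A"]): {"LS", "A"}, tree.mrca(["B"]): set(),
                tree.mrca(["C"]): {"C"}}
        switches, total = ha.detect_host_switches(tree, sets)
        assert total == 1  # only the A-tip gain has a non-empty parent
        assert switches == [(tree.mrca(["A"]), "A")]

    def test_identical_sets_no_switches(self, quartet):
        sets = {v: {"LO"} for v in range(quartet.n_nodes)}
        assert ha.detect_host_switches(quartet, sets)[1] == 0

    def test_relabeling_invariance(self, quartet):
        rng = np.random.default_rng(3)
        sets = {v: set(rng.choice(HOST_LINEAGES, rng.integers(1, 4),
                                  replace=False))
                for v in range(quartet.n_nodes)}
        perm = dict(zip(HOST_LINEAGES, np.roll(HOST_LINEAGES, 3)))
        relabeled = {v: {perm[h] for h in s} for v, s in sets.items()}
        assert ha.detect_host_switches(quartet, sets)[1] == \
            ha.detect_host_switches(quartet, relabeled)[1]


class TestChiSquareTail:
    def test_zero_gives_one(self):
        assert ha.chi2_upper_tail_df1(0.0) == 1.0

    @pytest.mark.parametrize("x,expected", [(4.372, 0.0365), (2.610, 0.1062)])
    def test_reference_values_via_numerical_integration(self, x, expected):
        dens = lambda u: chi2_dist.pdf(u, 1)
        oracle, _ = quad(dens, x, np.inf)
        got = ha.chi2_upper_tail_df1(x)
        assert got == pytest.approx(oracle, abs=1e-8)
        assert got == pytest.approx(expected, abs=5e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ha.chi2_upper_tail_df1(-0.5)


class TestLikelihoodRatioStage:
    def test_published_mean_likelihoods(self):
        """From mean lnLs (-6.545, -8.731, -7.850): LR 4.37 / 2.610 and
        p 0.0365 / 0.1061."""
        res = likelihood_ratio_stage(-6.545, -8.731, -7.850)
        assert res.lr_g_to_s_only == pytest.approx(4.372, abs=1e-9)
        assert res.lr_s_to_g_only == pytest.approx(2.610, abs=1e-9)
        assert res.p_g_to_s_only == pytest.approx(0.0365, abs=5e-4)
        assert res.p_s_to_g_only == pytest.approx(0.1061, abs=5e-4)
        assert res.reject_g_to_s_only and not res.reject_s_to_g_only

    def test_identical_means_give_null(self):
        res = likelihood_ratio_stage(-5.0, -5.0, -5.0)
        assert res.lr_g_to_s_only == 0.0
        assert res.p_g_to_s_only == 1.0

    def test_small_negative_lr_clamped(self):
        with pytest.warns(UserWarning, match="clamped"):
            res = likelihood_ratio_stage(-5.00001, -5.0, -5.0)
        assert res.lr_g_to_s_only == 0.0

    def test_large_negative_lr_raises(self):
        with pytest.raises(RuntimeError):
            likelihood_ratio_stage(-6.0, -5.0, -5.0)


class TestIrreversibilityEndToEnd:
    def test_runs_on_synthetic_sample(self):
        base = ha.simulate_yule_tree(15, 1.0, seed=31)
        sample = ha.emulate_tree_sample(base, 5, 0.2, seed=32)
        from hostarrow.mk_model import RateModel
        char, _ = ha.simulate_mk_character(base, ha.RateModel.free(
            2, rates=(0.8, 0.8)), seed=33, state_labels=("G", "S"))
        res = ha.run_irreversibility_test(sample, char)
        assert res.mean_lnl_bidirectional >= res.mean_lnl_g_to_s_only - 1e-6
        assert res.mean_lnl_bidirectional >= res.mean_lnl_s_to_g_only - 1e-6
        assert 0 <= res.p_g_to_s_only <= 1

    def test_boundary_mixture_halves_tail(self):
        base = ha.simulate_yule_tree(10, 1.0, seed=41)
        sample = ha.TreeSample.from_trees([base])
        char, _ = ha.simulate_mk_character(base, ha.RateModel.free(
            2, rates=(1.0, 0.4)), seed=42, state_labels=("G", "S"))
        plain = ha.run_irreversibility_test(sample, char)
        mixed = ha.run_irreversibility_test(sample, char, boundary_mixture=True)
        if plain.lr_g_to_s_only > 0:
            assert mixed.p_g_to_s_only == pytest.approx(
                plain.p_g_to_s_only / 2, abs=1e-12)
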