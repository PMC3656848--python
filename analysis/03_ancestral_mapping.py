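#!/usr/bin/env python
"""Ancestral host mapping on the synthetic inputs, both ways.

Runs (a) one RJ-MCMC analysis per host lineage over the posterior-like tree
sample, thresholds the mean node posteriors at PP > 0.7 into ancestral host
sets and counts host switches; and (b) Fitch parsimony per host on the
consensus tree with MPR-set change counting.  Requires 01_simulate_inputs.py
to have been run first.
"""

import json
from pathlib import Path

import pandas as pd

import hostarrow as ha
from hostarrow.bayes_mapping import McmcConfig
from hostarrow.mk_model import RateModel
from hostarrow.specialization import HOST_LINEAGES

ROOT = Path(__file__).resolve().parent.parent / "results"
SRC = ROOT / "synthetic"


def main() -> None:
    base = ha.parse_newick((SRC / "consensus.nwk").read_text())
    sample = ha.parse_nexus_trees((SRC / "tree_sample.nex").read_text())
    table = ha.HostTable.from_csv(SRC / "host_table.csv")
    host_chars = ha.build_host_datasets(table)

    # --- Bayesian route -------------------------------------------------
    cfg = McmcConfig(iterations=12_000, burnin_iterations=3_000, ratedev=1.0,
                     hyper_interval=(0, 2), seed=11, thin=50)
    posteriors = {}
    for host in HOST_LINEAGES:
        posteriors[host] = ha.run_mcmc(sample, host_chars[host],
                                       RateModel.free(2), cfg)
    calls = ha.call_ancestral_hosts(posteriors, threshold=0.7)

    node_sets = {}
    for key, hosts in calls.calls.items():
        node = base.find_clade(key)
        if node is not None:
            node_sets[node] = set(hosts)
    for v in base.tips():  # tip host sets come from the table itself
        rec = next(r for r in table if r.species == base.labels[v])
        node_sets[v] = set(rec.hosts)
    b_switches, b_total = ha.detect_host_switches(base, node_sets)

    # --- Parsimony route ------------------------------------------------
    p_sets: dict[int, set[str]] = {v: set() for v in range(base.n_nodes)}
    p_changes = {}
    for host in HOST_LINEAGES:
        rec = ha.fitch_state_sets(base, host_chars[host])
        for v in range(base.n_nodes):
            if rec.state_sets[v] == frozenset({1}):  # unambiguously present
                p_sets[v].add(host)
        p_changes[host] = ha.count_parsimony_changes(rec)
    p_switches, p_total = ha.detect_host_switches(base, p_sets)

    pd.DataFrame(
        [{"node_tips": ";".join(sorted(k)), "host": h,
          "mean_pp_present": float(s.node_posteriors[k][1])}
         for h, s in posteriors.items() for k in s.node_posteriors]
    ).to_csv(ROOT / "host_node_posteriors.csv", index=False)

    summary = {
        "bayesian_switches": b_total,
        "bayesian_switch_nodes": len({v for v, _ in b_switches}),
        "parsimony_switches": p_total,
        "parsimony_switch_nodes": len({v for v, _ in p_switches}),
        "parsimony_changes_per_host": {h: list(c) for h, c in p_changes.items()},
    }
    (ROOT / "ancestral_mapping.json").write_text(
        json.dumps(summary, indent=2) + "\n")
    print(f"Bayesian mapping: {b_total} switches at "
          f"{summary['bayesian_switch_nodes']} nodes (PP > 0.7 rule)")
    print(f"Parsimony mapping: {p_total} switches at "
          f"{summary['parsimony_switch_nodes']} nodes (unambiguous MPR sets)")


if __name__ == "__main__":
    main()
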