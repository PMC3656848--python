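#!/usr/bin/env python
"""Generate the synthetic study inputs.

Builds a 37-tip Yule 'consensus' tree, a posterior-like sample of 100
jittered trees, a binary specialist/generalist character evolved under a
bidirectional model, and a full host-association table with eight
independently evolved host-lineage presence characters.  Everything is
written under results/synthetic/ in the same formats the pipeline reads,
alongside the simulation truth.
"""

import json
from pathlib import Path

import hostarrow as ha
from hostarrow.mk_model import RateModel

OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"
SEED = 20130517  # study publication date, used as a fixed scenario seed


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    base = ha.simulate_yule_tree(37, birth_rate=1.0, seed=SEED)
    (OUT / "consensus.nwk").write_text(base.newick() + "\n")

    sample = ha.emulate_tree_sample(base, n_trees=100, length_jitter_sd=0.2,
                                    seed=SEED + 1)
    ha.write_nexus_trees(sample, str(OUT / "tree_sample.nex"))

    spec_model = RateModel.free(2, rates=(0.4, 0.8))
    spec_char, spec_truth = ha.simulate_mk_character(
        base, spec_model, seed=SEED + 2, state_labels=("G", "S"))
    ha.write_character_matrix(spec_char, str(OUT / "specificity.csv"))

    table, host_truth = ha.simulate_host_table(base, seed=SEED + 3)
    table.to_frame().to_csv(OUT / "host_table.csv", index=False)

    truth = {
        "specificity_rates": list(spec_truth.rates),
        "specificity_root_state": spec_truth.node_states[base.root],
        "n_specificity_events": len(spec_truth.events),
        "n_host_events": len(host_truth.events),
        "true_host_switches": ha.detect_host_switches(
            base, ha.true_node_host_sets(host_truth))[1],
    }
    (OUT / "truth.json").write_text(json.dumps(truth, indent=2) + "\n")

    print(f"wrote synthetic inputs to {OUT}")
    print(f"  tree sample: {len(sample)} trees over {len(base.tips())} tips")
    print(f"  specificity character: {len(spec_truth.events)} true events")
    print(f"  host table: {truth['n_host_events']} events, "
          f"{truth['true_host_switches']} true switches (gains with a "
          "non-empty ancestral host set)")


if __name__ == "__main__":
    main()
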