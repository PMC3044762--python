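"""Closed-loop training: associative plasticity + reward-trained decisions.

Trains the associative layer (LTPi) and the winner-take-all decision
layer simultaneously on the XOR task at desk scale, and contrasts it with
the untrained ('initial') network where only the reward rule operates on
the decision afferents.  Performance is reported in 40-trial bins with
the reliable (>= 85%) / borderline (76-84%) / unreliable (<= 75%)
classification.

Writes results/decision_training.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

import pairnet as pn
from pairnet.dynamics import IntegrationConfig
from pairnet.metrics import performance_bins
from pairnet.protocol import ConditionSpec, train_network

OUT = Path(__file__).resolve().parent.parent / "results"
INTEG = IntegrationConfig(dt=0.05, cue_ms=1000.0, relax_ms=300.0)


def main(master_seed: int = 0) -> None:
    rows = []
    for condition in ("ltpi", "initial"):
        cfg = pn.NetworkConfig(n_associative=200, input_probability=1 / 3,
                               groups_per_stimulus=6, master_seed=master_seed)
        net = pn.build_associative_network(cfg)
        dec = pn.build_decision_network(cfg, trained=(condition != "initial"))
        n_trials = 400 if condition == "ltpi" else 160
        spec = ConditionSpec(condition=condition, n_trials=n_trials)
        log = train_network(net, dec, spec, integ=INTEG, probe_every=None,
                            probe_trials_per_pair=2)
        flags = [o["correct"] for o in log.outcomes]
        perf = performance_bins(flags)
        for b, frac in enumerate(perf.bin_fractions):
            rows.append({"condition": condition, "bin": b,
                         "fraction_correct": frac})
        print(f"{condition:>8s}: selectivity {log.initial_selectivity:.2f} -> "
              f"{log.final_selectivity:.2f}; performance by 40-trial bin "
              f"{np.round(perf.bin_fractions, 2).tolist()} "
              f"-> {perf.classification}")
    OUT.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(OUT / "decision_training.csv", index=False)


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 0)
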