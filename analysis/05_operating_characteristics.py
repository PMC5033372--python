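#!/usr/bin/env python
"""Monte-Carlo operating characteristics of the two-phase design.

Measures, under the generator's noise model (0.3-cycle CT noise),
(a) the type-I behaviour of the per-phase t-test and of the
repeatability-gated pooled analysis on null strata, and (b) the bias of
the recovered percent change for two planted reference effects. Writes
results/operating/rates.json.
"""
import json
from pathlib import Path

import selenoqpcr as sq

OUT = Path(__file__).resolve().parents[1] / "results" / "operating"
SEED = 2016


def main() -> None:
    rates = sq.null_operating_rates(n_strata=20000, sd=0.3, seed=SEED)
    th = sq.recover_percent_discovery(fold=0.575, n_reps=200, sd=0.3,
                                      n=4, seed=SEED)
    g4 = sq.recover_percent_combined(fold=0.718, n_reps=200, sd=0.3,
                                     seed=SEED)
    out = {
        "null": rates,
        "recovery": {
            "planted_-42.5_discovery_mean": round(float(th.mean()), 3),
            "planted_-28.2_combined_mean": round(float(g4.mean()), 3),
        },
    }
    OUT.mkdir(parents=True, exist_ok=True)
    (OUT / "rates.json").write_text(json.dumps(out, indent=2) + "\n")
    print(json.dumps(out, indent=2))
    print("\nthe gated pooled analysis makes a significant null call "
          f"{rates['repeatable_and_combined_significant_rate']:.1%} of the "
          f"time, below the per-phase "
          f"{rates['discovery_significant_rate']:.1%} — the "
          "discovery/replication gate buys specificity.")


if __name__ == "__main__":
    main()
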