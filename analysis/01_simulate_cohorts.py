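#!/usr/bin/env python
"""Simulate the two-phase study's CT tables.

Generates two cohort tables from the transcribed study outcomes — one
noise-free (every planted effect recoverable exactly) and one with
realistic 0.3-cycle CT noise — and writes them under results/simulated/.
"""
from pathlib import Path

import selenoqpcr as sq

OUT = Path(__file__).resolve().parents[1] / "results" / "simulated"
SEED = 2016


def main() -> None:
    panel = sq.default_panel()
    fixture = sq.load_results_fixture(panel=panel)
    abundance = sq.load_abundance_fixture(panel=panel)
    OUT.mkdir(parents=True, exist_ok=True)
    for name, sd in (("ct_noise_free.csv", 0.0), ("ct_sd03.csv", 0.3)):
        sc = sq.scenario_from_fixture(fixture, abundance, panel,
                                      mode="combined", ct_noise_sd=sd,
                                      seed=SEED)
        table = sq.simulate_ct(sc)
        sq.write_ct_table(table, OUT / name)
        nd = int(table["ct"].isna().sum())
        print(f"{name}: {len(table)} wells "
              f"({table['animal_id'].nunique()} animals x "
              f"{table['region'].nunique()} regions x "
              f"{table['gene'].nunique()} genes), {nd} ND wells, sd={sd}")


if __name__ == "__main__":
    main()
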