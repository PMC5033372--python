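#!/usr/bin/env python
"""Region signatures, volcano/heat-map data products, abundance tiers.

Summarises the noise-free cohort (so the signature equals the planted
truth): per-region outcome counts, volcano coordinates, the genes x
regions fractional-change grid with its colour anchors, and the
reference-normalized abundance tiers with the cross-region most-abundant
set. Writes under results/signatures/.
"""
from pathlib import Path

import numpy as np

import selenoqpcr as sq

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "signatures"


def main() -> None:
    panel = sq.default_panel()
    fixture = sq.load_results_fixture(panel=panel)
    abundance = sq.load_abundance_fixture(panel=panel)
    sc = sq.scenario_from_fixture(fixture, abundance, panel, ct_noise_sd=0.0)
    ct = sq.simulate_ct(sc)
    results = sq.run_two_phase(ct, panel, sq.RunConfig(ct_noise_sd=0.0))
    frame = sq.results_to_frame(results)
    OUT.mkdir(parents=True, exist_ok=True)

    summary, _ = sq.region_summary(frame, panel)
    sq.write_table(summary, OUT / "region_summary.csv")
    print(summary[["region", "decreased", "increased", "no_change",
                   "not_detected"]].to_string(index=False))

    points = sq.volcano_points(frame)
    sq.write_table(points, OUT / "volcano_points.csv")
    mat = sq.heatmap_matrix(frame)
    mat.to_csv(OUT / "heatmap_matrix.csv")
    lo, hi = np.nanmin(mat.to_numpy()), np.nanmax(mat.to_numpy())
    print(f"heat-map colour anchors (fractional change): "
          f"min {lo:+.3f}, max {hi:+.3f}")
    sq.plot_volcano(points, OUT / "volcano.png")
    sq.plot_heatmap(mat, OUT / "heatmap.png")

    recs = sq.abundance_records(ct, panel)
    tab, most = sq.abundance_table(recs)
    sq.write_table(tab, OUT / "abundance.csv")
    print(f"most abundant in every region: {', '.join(most)}")


if __name__ == "__main__":
    main()
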