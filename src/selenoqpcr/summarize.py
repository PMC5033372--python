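"""Region signatures, volcano coordinates, heat-map grid and abundance
tables — the study's figure panels as plain data products."""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import COARSE_LABELS, GenePanel, REGIONS

P_FLOOR = 1e-16  # -log10 clip for p = 0 / underflow


def to_label_frame(results, panel: GenePanel) -> pd.DataFrame:
    """Normalize results to (gene, region, label) with coarse labels.

    Accepts a list of GeneRegionResult, a pipeline results frame
    (final_label column), or a reported-results fixture frame (label
    column). The reference gene is dropped; the marker gene is kept here
    and excluded by the per-region summaries."""
    if isinstance(results, list):
        df = pd.DataFrame([{"gene": r.gene, "region": r.region,
                            "label": r.final_label} for r in results])
    else:
        col = "final_label" if "final_label" in results.columns else "label"
        df = results[["gene", "region", col]].rename(columns={col: "label"})
    return df[df["gene"] != panel.reference_gene].reset_index(drop=True)


def region_summary(results, panel: GenePanel) -> tuple[pd.DataFrame, dict]:
    """Per-region counts of selenoprotein genes by outcome label.

    Returns (counts frame, members) where members maps
    (region, label) -> sorted gene list. Genes absent from the input are
    counted separately as not_assessed; decreased/increased convenience
    columns pool significant and trend calls.
    """
    labels = to_label_frame(results, panel)
    seleno = set(panel.selenoprotein_genes)
    labels = labels[labels["gene"].isin(seleno)]
    dup = labels.duplicated(subset=["gene", "region"])
    if dup.any():
        raise ValueError("multiple labels for one gene x region")
    members: dict[tuple[str, str], list[str]] = {}
    rows = []
    for region in REGIONS:
        sub = labels[labels["region"] == region]
        row = {"region": region}
        for lab in COARSE_LABELS:
            genes = sorted(sub.loc[sub["label"] == lab, "gene"])
            row[lab] = len(genes)
            members[(region, lab)] = genes
        assessed = set(sub["gene"])
        row["not_assessed"] = len(seleno - assessed)
        members[(region, "not_assessed")] = sorted(seleno - assessed)
        row["decreased"] = row["significant_down"] + row["trend_down"]
        row["increased"] = row["significant_up"] + row["trend_up"]
        rows.append(row)
    return pd.DataFrame(rows), members


def volcano_points(results_frame: pd.DataFrame,
                   selector: str = "auto") -> pd.DataFrame:
    """Volcano coordinates: x = log2 fold change of group means,
    y = -log10 p (p clipped at 1e-16).

    selector "auto" uses the combined analysis where the repeatability
    gate passed and the discovery phase otherwise; "discovery",
    "replication" or "combined" force one source. Trend-labelled genes
    carry a flag (the figure convention underlines them)."""
    if selector not in ("auto", "discovery", "replication", "combined"):
        raise ValueError(f"unknown selector {selector!r}")
    rows = []
    for r in results_frame.itertuples():
        if r.status != "ok":
            continue
        if selector == "auto":
            src = "combined" if r.repeatable else "discovery"
        else:
            src = selector
        pct = getattr(r, f"{src}_percent")
        p = getattr(r, f"{src}_p")
        label = getattr(r, f"{src}_label")
        if not np.isfinite(pct):
            continue
        y = -math.log10(max(p, P_FLOOR)) if np.isfinite(p) else math.nan
        rows.append({
            "gene": r.gene, "region": r.region, "source": src,
            "log2_fold_change": math.log2(1.0 + pct / 100.0),
            "neg_log10_p": y, "label": label,
            "trend": label.startswith("trend"),
            "significant": label.startswith("significant"),
        })
    return pd.DataFrame(rows)


def heatmap_matrix(results_frame: pd.DataFrame,
                   selector: str = "auto") -> pd.DataFrame:
    """Genes x regions grid of signed fractional change (PD/control - 1),
    i.e. percent/100; NaN for not-detected or not-assessable strata."""
    rows = []
    for r in results_frame.itertuples():
        if r.status != "ok":
            val = math.nan
        else:
            src = ("combined" if (selector == "auto" and r.repeatable)
                   else ("discovery" if selector == "auto" else selector))
            pct = getattr(r, f"{src}_percent")
            val = pct / 100.0 if np.isfinite(pct) else math.nan
        rows.append({"gene": r.gene, "region": r.region, "value": val})
    long = pd.DataFrame(rows)
    genes = list(dict.fromkeys(long["gene"]))
    mat = long.pivot(index="gene", columns="region", values="value")
    cols = [c for c in REGIONS if c in mat.columns]
    return mat.reindex(index=genes, columns=cols)


def abundance_table(abundance: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Per-region abundance listing plus the cross-region most-abundant
    set: genes binned "high" in every region present."""
    df = abundance.copy()
    regions = [r for r in REGIONS if r in set(df["region"])]
    per_gene = df.pivot(index="gene", columns="region", values="bin")
    most = sorted(g for g, row in per_gene.iterrows()
                  if all(row.get(r) == "high" for r in regions))
    order = {b: i for i, b in enumerate(
        ("high", "medium", "low", "barely_detectable"))}
    df = df.sort_values(["region", "bin", "gene"],
                        key=lambda s: s.map(order) if s.name == "bin" else s)
    return df.reset_index(drop=True), most


# ---------------------------------------------------------------------------
# Fixture agreement (the reproduce-fixture mode)
# ---------------------------------------------------------------------------

@dataclass
class FixtureComparison:
    n_compared: int
    n_matched: int
    n_skipped: int
    mismatches: pd.DataFrame
    headline: dict

    @property
    def ok(self) -> bool:
        return len(self.mismatches) == 0


def _direction_of(label: str) -> str:
    if label.endswith("_up"):
        return "up"
    if label.endswith("_down"):
        return "down"
    return "none"


def _changed(label: str) -> bool:
    return label.startswith(("significant", "trend"))


def compare_to_fixture(results_frame: pd.DataFrame, fixture: pd.DataFrame,
                       abundance_recomputed: pd.DataFrame,
                       abundance_fixture: pd.DataFrame,
                       panel: GenePanel,
                       percent_tol: float = 1e-6) -> FixtureComparison:
    """Per-stratum agreement between recomputed and transcribed outcomes.

    Percents are compared exactly (to percent_tol); labels at the
    direction + changed/unchanged level, since simulated noise-free data
    has no within-group variance and therefore no assessable p-value.
    Fixture rows with a change label but no printed percent cannot seed a
    planted fold and are skipped, not failed. Abundance bins are compared
    cell-for-cell.
    """
    res = results_frame.set_index(["gene", "region"])
    mism, n_cmp, n_skip, n_match = [], 0, 0, 0

    for row in fixture.itertuples():
        key = (row.gene, row.region)
        want_pct = row.combined_percent
        if row.label != "not_detected" and pd.isna(want_pct) and \
                _changed(row.label):
            n_skip += 1
            continue
        n_cmp += 1
        if key not in res.index:
            mism.append({"gene": row.gene, "region": row.region,
                         "field": "presence", "expected": row.label,
                         "got": "missing"})
            continue
        got = res.loc[key]
        problems = []
        if row.label == "not_detected":
            if got["final_label"] != "not_detected":
                problems.append(("label", row.label, got["final_label"]))
        else:
            gl = got["final_label"]
            if _direction_of(gl) != _direction_of(row.label) or \
                    _changed(gl) != _changed(row.label):
                problems.append(("label", row.label, gl))
            if pd.notna(want_pct):
                got_pct = got["combined_percent"]
                if not (np.isfinite(got_pct)
                        and abs(got_pct - want_pct) <= percent_tol):
                    problems.append(("combined_percent", want_pct, got_pct))
        if problems:
            for f, e, g in problems:
                mism.append({"gene": row.gene, "region": row.region,
                             "field": f, "expected": e, "got": g})
        else:
            n_match += 1

    ab = abundance_recomputed.set_index(["gene", "region"])["bin"]
    for row in abundance_fixture.itertuples():
        n_cmp += 1
        got_bin = ab.get((row.gene, row.region), "missing")
        if got_bin != row.bin:
            mism.append({"gene": row.gene, "region": row.region,
                         "field": "abundance_bin", "expected": row.bin,
                         "got": got_bin})
        else:
            n_match += 1

    summary, _ = region_summary(results_frame, panel)
    sn = summary.set_index("region").loc["substantia nigra"]
    _, most = abundance_table(abundance_recomputed)
    headline = {
        "panel_genes": len(panel.genes),
        "panel_selenoproteins": panel.selenoprotein_count,
        "substantia_nigra_decreased": int(sn["decreased"]),
        "substantia_nigra_increased": int(sn["increased"]),
        "most_abundant_genes": most,
    }
    return FixtureComparison(n_cmp, n_match, n_skip,
                             pd.DataFrame(mism), headline)


# ---------------------------------------------------------------------------
# Plots (matplotlib; data products above are the source of truth)
# ---------------------------------------------------------------------------

def plot_volcano(points: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    regions = [r for r in REGIONS if r in set(points["region"])]
    fig, axes = plt.subplots(1, max(len(regions), 1),
                             figsize=(3.2 * max(len(regions), 1), 3.2),
                             squeeze=False)
    for ax, region in zip(axes[0], regions):
        sub = points[points["region"] == region]
        colors = np.where(sub["significant"], "crimson",
                          np.where(sub["trend"], "darkorange", "grey"))
        ax.scatter(sub["log2_fold_change"], sub["neg_log10_p"],
                   c=colors, s=14)
        ax.axvline(0, lw=0.5, color="k")
        ax.set_title(region, fontsize=9)
        ax.set_xlabel("log2 fold change")
    axes[0][0].set_ylabel("-log10 p")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_heatmap(matrix: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import seaborn as sns

    lo = float(np.nanmin(matrix.to_numpy())) if matrix.size else -1.0
    hi = float(np.nanmax(matrix.to_numpy())) if matrix.size else 1.0
    fig, ax = plt.subplots(figsize=(4.5, 0.28 * len(matrix) + 1.5))
    sns.heatmap(matrix, cmap="RdBu_r", center=0.0, vmin=lo, vmax=hi,
                ax=ax, cbar_kws={"label": "fractional change"})
    ax.set_xlabel("")
    ax.set_ylabel("")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
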