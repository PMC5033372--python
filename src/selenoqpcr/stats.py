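"""Two-phase statistics: per-phase t-tests, tiered change labels, the
repeatability gate, and pooled combined-phase analysis.

The design mirrors a discovery/replication qPCR workflow on small cohorts:
each phase is tested on its own control-normalized folds with an
equal-variance two-tailed Student's t-test; a change is a "trend" when it
exceeds 10% without reaching significance (tiers 10-15%, 15-20%, >20%);
and a pooled analysis over all animals (n = n_discovery + n_replication
per group) is licensed only when both phases show a significance-or-trend
change in the same direction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import RunConfig
from .panel import GenePanel, PHASES, REGIONS
from .relquant import delta_ct, detectability, normalized_folds, percent_change

#: Label categories, finest first. Trend tier names follow the default
#: 10/15/20 brackets; custom tiers reuse the same three bracket slots.
CATEGORIES: tuple[str, ...] = (
    "significant", "trend_gt20", "trend_15_20", "trend_10_15",
    "no_change", "not_detected",
)
CHANGED_CATEGORIES = frozenset(
    {"significant", "trend_gt20", "trend_15_20", "trend_10_15"})


@dataclass(frozen=True)
class ChangeLabel:
    category: str
    direction: str  # "up" | "down" | "none"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.direction not in ("up", "down", "none"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if self.category in ("no_change", "not_detected") and self.direction != "none":
            raise ValueError(f"{self.category} must carry direction 'none'")
        if self.category in CHANGED_CATEGORIES and self.direction == "none":
            raise ValueError(f"{self.category} requires a direction")

    @property
    def changed(self) -> bool:
        return self.category in CHANGED_CATEGORIES

    def coarse(self) -> str:
        """Collapse to the fixture vocabulary (trend tiers merged)."""
        if self.category == "significant":
            return f"significant_{self.direction}"
        if self.changed:
            return f"trend_{self.direction}"
        return self.category


NO_CHANGE = ChangeLabel("no_change", "none")
NOT_DETECTED = ChangeLabel("not_detected", "none")


def phase_test(control_folds, pd_folds) -> float:
    """Two-tailed equal-variance Student's t p-value on fold values.

    Returns NaN (not assessable) with < 2 animals in either group or a
    degenerate pooled variance; the caller's label then falls back to
    trend logic.
    """
    a = np.asarray(control_folds, dtype=float)
    b = np.asarray(pd_folds, dtype=float)
    if a.size < 2 or b.size < 2:
        return math.nan
    ss = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
    # Degenerate pooled variance, allowing for last-ulp dust in data that
    # is constant within groups (e.g. noise-free simulations).
    scale = max(float(np.abs(a).max()), float(np.abs(b).max()), 1e-300)
    if ss <= (1e-12 * scale) ** 2 * (a.size + b.size):
        return math.nan
    return float(sps.ttest_ind(a, b, equal_var=True).pvalue)


def classify_change(percent: float, p: float | None,
                    alpha: float = 0.05, trend_floor: float = 10.0,
                    tiers: tuple[float, float] = (15.0, 20.0)) -> ChangeLabel:
    """Tiered label for a (percent change, p) pair.

    Significant when p < alpha (and the change has a direction); otherwise
    a trend tier by |percent| in (floor, tiers[0]], (tiers[0], tiers[1]],
    (tiers[1], inf); otherwise no change. Exactly the floor is no change:
    a trend requires the change to exceed it.
    """
    if not np.isfinite(percent):
        raise ValueError(f"percent change must be finite, got {percent}")
    direction = "up" if percent > 0 else ("down" if percent < 0 else "none")
    p_ok = p is not None and not (isinstance(p, float) and math.isnan(p))
    if p_ok and p < alpha and direction != "none":
        return ChangeLabel("significant", direction)
    a = abs(percent)
    if a > tiers[1]:
        return ChangeLabel("trend_gt20", direction)
    if a > tiers[0]:
        return ChangeLabel("trend_15_20", direction)
    if a > trend_floor:
        return ChangeLabel("trend_10_15", direction)
    return NO_CHANGE


def classify_from_annotation(percent: float, p_annotation: str | None,
                             alpha: float = 0.05, trend_floor: float = 10.0,
                             tiers: tuple[float, float] = (15.0, 20.0),
                             ) -> ChangeLabel:
    """Classify using a printed p annotation such as "<0.05" or "=0.17"."""
    from .panel import parse_p_annotation
    parsed = parse_p_annotation(p_annotation) if p_annotation else None
    if parsed is None:
        p = math.nan
    else:
        op, v = parsed
        # "<v" proves p < alpha only when v <= alpha; ">v" proves nothing.
        p = v - 1e-12 if op == "<" else (v if op == "=" else math.nan)
    return classify_change(percent, p, alpha, trend_floor, tiers)


def is_repeatable(discovery: ChangeLabel, replication: ChangeLabel) -> bool:
    """True when both phases show significance-or-trend in one direction."""
    return (discovery.changed and replication.changed
            and discovery.direction == replication.direction)


@dataclass(frozen=True)
class PhaseResult:
    gene: str
    region: str
    phase: str
    n_control: int
    n_pd: int
    percent_change: float
    p_value: float
    label: ChangeLabel


@dataclass(frozen=True)
class CombinedResult:
    n_control: int
    n_pd: int
    percent_change: float
    p_value: float
    label: ChangeLabel


@dataclass(frozen=True)
class GeneRegionResult:
    gene: str
    region: str
    detected: bool = True
    status: str = "ok"  # ok | not_detected | not_assessable
    discovery: Optional[PhaseResult] = None
    replication: Optional[PhaseResult] = None
    repeatable: bool = False
    combined: Optional[CombinedResult] = None
    note: str = ""

    @property
    def final_label(self) -> str:
        """Coarse per-stratum call: combined label when the repeatability
        gate passed, not_detected for undetectable strata, else no_change
        (an unreplicated change is not called)."""
        if not self.detected:
            return "not_detected"
        if self.repeatable and self.combined is not None:
            return self.combined.label.coarse()
        return "no_change"


def combined_analysis(disc_control, disc_pd, rep_control, rep_pd,
                      repeatable: bool,
                      config: RunConfig | None = None,
                      ) -> Optional[CombinedResult]:
    """Pooled two-phase analysis over per-animal folds, licensed by the
    repeatability gate; returns None when the gate failed (even if a
    pooled test would have been significant)."""
    if not repeatable:
        return None
    config = config or RunConfig()
    c = np.concatenate([np.asarray(disc_control, float),
                        np.asarray(rep_control, float)])
    p_ = np.concatenate([np.asarray(disc_pd, float),
                         np.asarray(rep_pd, float)])
    pct = percent_change(c, p_)
    pv = phase_test(c, p_)
    lab = classify_change(pct, pv, config.alpha, config.trend_floor, config.tiers)
    return CombinedResult(len(c), len(p_), pct, pv, lab)


def _group_folds(folds: pd.DataFrame):
    return {k: v["fold"].to_numpy()
            for k, v in folds.groupby(["gene", "region", "phase", "group"],
                                      sort=False)}


def run_two_phase(ct: pd.DataFrame, panel: GenePanel,
                  config: RunConfig | None = None) -> list[GeneRegionResult]:
    """Full two-phase pipeline over a validated CT table.

    One result per gene x region present in the table (reference gene
    excluded): detectability, per-phase folds/percent/t-test/label,
    repeatability verdict, and the pooled combined analysis where licensed.
    """
    config = config or RunConfig()
    if len(ct) == 0:
        raise ValueError("empty CT table")
    dct = delta_ct(ct, panel.reference_gene)

    results: list[GeneRegionResult] = []
    detected_keys = []
    strata = []
    regions_present = [r for r in REGIONS if (ct["region"] == r).any()]
    for gene in panel.target_genes:
        for region in regions_present:
            sub = ct[(ct["gene"] == gene) & (ct["region"] == region)]
            if len(sub) == 0:
                continue
            ok = detectability(sub, config.max_ct, config.max_nd_fraction)
            strata.append((gene, region, ok))
            if ok:
                detected_keys.append((gene, region))

    mask = pd.Series(list(zip(dct["gene"], dct["region"]))).isin(detected_keys)
    folds = normalized_folds(dct.loc[mask.to_numpy()])
    groups = _group_folds(folds)

    for gene, region, ok in strata:
        if not ok:
            results.append(GeneRegionResult(gene, region, detected=False,
                                            status="not_detected"))
            continue
        phase_res: dict[str, Optional[PhaseResult]] = {}
        arrays: dict[tuple[str, str], np.ndarray] = {}
        for phase in PHASES:
            c = groups.get((gene, region, phase, "control"))
            p_ = groups.get((gene, region, phase, "PD"))
            if c is None or p_ is None or len(c) == 0 or len(p_) == 0:
                phase_res[phase] = None
                continue
            arrays[(phase, "control")], arrays[(phase, "PD")] = c, p_
            pct = percent_change(c, p_)
            pv = phase_test(c, p_)
            lab = classify_change(pct, pv, config.alpha,
                                  config.trend_floor, config.tiers)
            phase_res[phase] = PhaseResult(gene, region, phase,
                                           len(c), len(p_), pct, pv, lab)
        disc, rep = phase_res["discovery"], phase_res["replication"]
        if disc is None or rep is None:
            results.append(GeneRegionResult(
                gene, region, status="not_assessable",
                discovery=disc, replication=rep,
                note="one or both phases missing"))
            continue
        repeat = is_repeatable(disc.label, rep.label)
        combined = combined_analysis(
            arrays[("discovery", "control")], arrays[("discovery", "PD")],
            arrays[("replication", "control")], arrays[("replication", "PD")],
            repeat, config)
        note = ""
        if not repeat:
            pooled = combined_analysis(
                arrays[("discovery", "control")], arrays[("discovery", "PD")],
                arrays[("replication", "control")], arrays[("replication", "PD")],
                True, config)
            if pooled.p_value < config.alpha:
                note = (f"pooled p = {pooled.p_value:.3g} would be significant "
                        "but the repeatability gate failed")
        results.append(GeneRegionResult(gene, region, discovery=disc,
                                        replication=rep, repeatable=repeat,
                                        combined=combined, note=note))
    return results


def _phase_cols(pr: Optional[PhaseResult], prefix: str) -> dict:
    if pr is None:
        return {f"{prefix}_n_control": 0, f"{prefix}_n_pd": 0,
                f"{prefix}_percent": math.nan, f"{prefix}_p": math.nan,
                f"{prefix}_label": ""}
    return {f"{prefix}_n_control": pr.n_control, f"{prefix}_n_pd": pr.n_pd,
            f"{prefix}_percent": pr.percent_change, f"{prefix}_p": pr.p_value,
            f"{prefix}_label": f"{pr.label.category}:{pr.label.direction}"}


def results_to_frame(results: list[GeneRegionResult],
                     config: RunConfig | None = None) -> pd.DataFrame:
    """Flatten pipeline results into a tidy table (one row per stratum)."""
    config = config or RunConfig()
    rows = []
    for r in results:
        row = {"gene": r.gene, "region": r.region, "detected": r.detected,
               "status": r.status}
        row.update(_phase_cols(r.discovery, "discovery"))
        row.update(_phase_cols(r.replication, "replication"))
        row["repeatable"] = r.repeatable
        if r.combined is not None:
            row.update(combined_n_control=r.combined.n_control,
                       combined_n_pd=r.combined.n_pd,
                       combined_percent=r.combined.percent_change,
                       combined_p=r.combined.p_value,
                       combined_label=(f"{r.combined.label.category}:"
                                       f"{r.combined.label.direction}"))
        else:
            row.update(combined_n_control=0, combined_n_pd=0,
                       combined_percent=math.nan, combined_p=math.nan,
                       combined_label="")
        row["final_label"] = r.final_label
        row["note"] = r.note
        rows.append(row)
    df = pd.DataFrame(rows)
    if config.qvalues and len(df):
        from statsmodels.stats.multitest import multipletests
        q = np.full(len(df), math.nan)
        have = df["combined_p"].notna().to_numpy()
        if have.any():
            q[have] = multipletests(df.loc[have, "combined_p"],
                                    method="fdr_bh")[1]
        df["combined_q"] = q
    return df
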