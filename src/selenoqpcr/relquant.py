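"""Relative quantification: dCT, control-normalized 2^-ddCT folds,
percent change, detectability, and the reference-normalized abundance index.

All quantities derive from the comparative-CT model under perfect
amplification efficiency: one cycle is a two-fold difference in template.
Folds are normalized so the control-group mean is exactly 1 within each
gene x region x phase stratum, so a group percent change reads directly
off the PD mean.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenePanel

#: Abundance tiers relative to the reference gene, lowest to highest.
ABUNDANCE_BINS: tuple[str, ...] = (
    "barely_detectable", "low", "medium", "high",
)

STRATUM = ["gene", "region", "phase"]


def delta_ct(ct: pd.DataFrame, reference_gene: str) -> pd.DataFrame:
    """Per-well dCT = CT(gene) - CT(reference) within the same animal x region.

    Not-detected target wells propagate NaN; a missing or not-detected
    reference well is an error naming the animals concerned.
    """
    key = ["animal_id", "phase", "group", "region"]
    ref = ct[ct["gene"] == reference_gene]
    if ref["ct"].isna().any():
        bad = ref.loc[ref["ct"].isna(), "animal_id"].unique()
        raise ValueError(
            f"reference gene {reference_gene!r} not detected for animals: "
            f"{sorted(bad)}")
    dup = ref.duplicated(subset=key)
    if dup.any():
        raise ValueError(
            f"multiple reference wells for animal x region: "
            f"{ref.loc[dup, key].to_dict('records')[:3]}")
    targets = ct[ct["gene"] != reference_gene].copy()
    ref_ct = ref.set_index(key)["ct"]
    mapped = ref_ct.reindex(pd.MultiIndex.from_frame(targets[key]))
    if mapped.isna().any():
        bad = targets.loc[mapped.isna().to_numpy(), "animal_id"].unique()
        raise ValueError(
            f"no reference-gene CT for animals: {sorted(bad)}")
    targets["delta_ct"] = targets["ct"].to_numpy() - mapped.to_numpy()
    return targets.reset_index(drop=True)


def normalized_folds(dct: pd.DataFrame) -> pd.DataFrame:
    """Control-mean-normalized 2^-ddCT fold per animal.

    Within each gene x region x phase stratum the ddCT baseline is the
    control-group mean dCT; the resulting 2^-ddCT values are then rescaled
    by their control mean so mean(control folds) == 1 exactly.
    """
    d = dct.dropna(subset=["delta_ct"]).copy()
    if len(d) == 0:
        return d.assign(fold=pd.Series(dtype=float))
    is_ctrl = d["group"] == "control"
    n_ctrl = is_ctrl.groupby([d[c] for c in STRATUM]).sum()
    empty = n_ctrl[n_ctrl == 0]
    if len(empty):
        raise ValueError(
            f"stratum with no control animals: {list(empty.index)[:3]}")
    b = d.loc[is_ctrl].groupby(STRATUM)["delta_ct"].mean()
    idx = pd.MultiIndex.from_frame(d[STRATUM])
    raw = np.exp2(-(d["delta_ct"].to_numpy() - b.reindex(idx).to_numpy()))
    d["fold"] = raw
    ctrl_mean = d.loc[is_ctrl].groupby(STRATUM)["fold"].mean()
    d["fold"] = raw / ctrl_mean.reindex(idx).to_numpy()
    return d.reset_index(drop=True)


def percent_change(control_folds, pd_folds) -> float:
    """Signed percent change of group means; negative means a decline."""
    c = np.asarray(control_folds, dtype=float)
    p = np.asarray(pd_folds, dtype=float)
    if c.size == 0 or p.size == 0:
        raise ValueError("both groups must be non-empty")
    mc = c.mean()
    if mc == 0:
        raise ValueError("control mean fold is zero")
    return float(100.0 * (p.mean() - mc) / mc)


def detectability(records: pd.DataFrame, max_ct: float = 35.0,
                  max_nd_fraction: float = 0.5) -> bool:
    """Whether a gene x region stratum counts as detected.

    Not detected when the fraction of ND wells exceeds ``max_nd_fraction``
    or the mean detected CT exceeds ``max_ct`` cycles.
    """
    if len(records) == 0:
        raise ValueError("detectability needs at least one record")
    ct = records["ct"]
    nd_fraction = float(ct.isna().mean())
    if nd_fraction > max_nd_fraction:
        return False
    detected = ct.dropna()
    if len(detected) == 0:
        return False
    return float(detected.mean()) <= max_ct


def assign_bin(exp_index: float) -> str:
    """Map an abundance index to its tier.

    Half-open brackets: [0, 0.1) barely detectable, [0.1, 0.5) low,
    [0.5, 1] medium, (1, inf) high — so "high" strictly means exceeding
    the reference gene.
    """
    if exp_index < 0:
        raise ValueError("abundance index must be >= 0")
    if exp_index < 0.1:
        return "barely_detectable"
    if exp_index < 0.5:
        return "low"
    if exp_index <= 1.0:
        return "medium"
    return "high"


@dataclass(frozen=True)
class AbundanceRecord:
    gene: str
    region: str
    exp_index: float
    bin: str


def abundance_index(control_records: pd.DataFrame, gene: str, region: str,
                    reference_gene: str) -> AbundanceRecord:
    """Reference-normalized expression Exp(g, r) = 2^(mean CT_ref - mean CT_g)
    from control-group wells of one brain region.

    A gene with no detected control well gets exp_index 0 and the
    barely-detectable bin.
    """
    sub = control_records[control_records["region"] == region]
    g_ct = sub.loc[sub["gene"] == gene, "ct"].dropna()
    r_ct = sub.loc[sub["gene"] == reference_gene, "ct"].dropna()
    if len(r_ct) == 0:
        raise ValueError(
            f"no detected reference CT for region {region!r}")
    if len(g_ct) == 0:
        return AbundanceRecord(gene, region, 0.0, "barely_detectable")
    exp = float(np.exp2(r_ct.mean() - g_ct.mean()))
    return AbundanceRecord(gene, region, exp, assign_bin(exp))


def abundance_records(ct: pd.DataFrame, panel: GenePanel,
                      max_ct: float = 35.0,
                      max_nd_fraction: float = 0.5) -> pd.DataFrame:
    """Abundance index and bin for every selenoprotein gene x region,
    computed from control-group wells (both phases pooled)."""
    ctrl = ct[ct["group"] == "control"]
    rows = []
    for region in sorted(ctrl["region"].unique(), key=list(ctrl["region"]).index):
        for gene in panel.selenoprotein_genes:
            sub = ctrl[(ctrl["region"] == region) & (ctrl["gene"] == gene)]
            if len(sub) == 0 or not detectability(sub, max_ct, max_nd_fraction):
                rows.append(AbundanceRecord(gene, region, 0.0, "barely_detectable"))
            else:
                rows.append(abundance_index(ctrl, gene, region,
                                            panel.reference_gene))
    return pd.DataFrame([r.__dict__ for r in rows])
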