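# Methods

## Data model

One row per well: animal, phase (`discovery`, `replication`), group
(`control`, `PD`), brain region (closed five-region vocabulary), gene, and a
CT value or the `ND` sentinel for wells that never crossed threshold. Empty
cells are errors: missingness must be explicit. Percent changes are signed
throughout (a decline is negative); p-values printed only as inequalities in
the transcription fixture are kept as annotation strings (`"<0.05"`), never
coerced to floats.

## Relative quantification

ΔCT is CT(gene) − CT(reference) within the same animal × region, under the
perfect-efficiency assumption (one cycle = one doubling); no
amplification-efficiency (Pfaffl-style) correction is applied. The ΔΔCT
baseline is the control-group mean ΔCT of the same gene × region × phase, and
the resulting 2^−ΔΔCT values are rescaled by their control mean so
mean(control folds) = 1 exactly. Each phase normalizes to its own controls;
this makes the PD mean fold equal 1 + percent/100 and makes all downstream
quantities invariant to adding a constant to every CT of an animal × region
(reference cancellation — verified as a property test).

Detectability: a gene × region stratum is treated as not detected when the
ND fraction exceeds 0.5 or the mean detected CT exceeds 35 cycles. Both
defaults are conventional qPCR practice; neither is derived from data, and
both are configurable.

Abundance: Exp(g, r) = 2^(mean CT_ref − mean CT_gene) over control wells
(both phases pooled, since the abundance atlas describes control animals),
binned with half-open brackets [0, 0.1) barely detectable, [0.1, 0.5) low,
[0.5, 1] medium, (1, ∞) high. The printed tier edges leave the boundary
assignment open; 1.0 is assigned to "medium" so that "high" strictly means
exceeding the reference gene. An undetected gene records index 0. The typeset
abundance equation is read as the ratio 2^−ΔCT_gene / 2^−ΔCT_reference with
ΔCT as raw CT — the alternative reading (ΔCT already reference-normalized)
would make the denominator identically 1.

## Two-phase statistics

Per phase, groups are compared on the normalized folds with a two-tailed
equal-variance Student's *t*-test ("Student's" is read literally; with
n = 3–4 per group Welch's correction is not the standard reading). When the
pooled within-group sum of squares is zero — to a relative tolerance of
1e−12, absorbing last-ulp dust in noise-free data — the p-value is *not
assessable* (NaN) and the label falls back to trend logic.

Labels: significant when p < 0.05; otherwise a trend by |percent| in
(10, 15], (15, 20], (20, ∞); otherwise no change. Exactly 10.0% is no
change — the floor must be exceeded. The repeatability gate passes when both
phases carry a significance-or-trend label in the same direction (mixed
significant/trend is allowed). Only gated strata get the combined analysis:
per-animal folds from both phases are pooled (so n = 4+3 = 7 per group is
literal), percent change and the *t*-test are recomputed, and the label is
reassigned. A non-gated stratum reports no combined result even when the
pooled test would have been significant; such cases carry an explanatory
note. No multiple-testing correction is applied across the 24 × 5 grid by
default, matching the two-phase design's own false-positive control;
`RunConfig(qvalues=True)` appends Benjamini–Hochberg q-values as an extra
column without gatekeeping.

A stratum's final call is the combined label when the gate passed,
`not_detected` for undetectable strata, and `no_change` otherwise — an
unreplicated change is not called.

## Summaries

Region summaries count selenoprotein genes (marker and reference excluded)
per coarse label; "decreased" pools significant and trend declines, which is
how the 17-gene substantia nigra signature is counted (one of the 17 is a
> 20% trend with p = 0.17). Volcano coordinates are x = log2(1 + percent/100)
and y = −log10 p with p floored at 1e−16; the combined result is used where
the gate passed, the discovery phase otherwise. The heat-map grid is the
signed fractional change percent/100, with colour anchors computed from the
data rather than fixed. The "most abundant" set comprises genes binned high
in *every* region.

## Synthetic data

The generator emulates the study design: per animal × region a reference CT
is drawn from Normal(20, sd) (the 20-cycle mean is arbitrary and cancels),
and each gene's CT is the reference CT plus a gene × region abundance offset,
minus log2(planted fold) in PD animals, plus independent Normal(0, sd) well
noise. Noise lives on the CT (log2) scale, so folds are log-normal —
matching qPCR physics. Default sd is 0.3 cycles, a typical well-to-well
spread for replicated SYBR assays; cohort sizes default to the study's 4/3
per group (the unprinted substantia nigra discovery n is taken as 4 and never
hard-coded in the analysis code, which always counts the table).

Fixture-driven scenarios plant 1 + combined-percent/100 in both phases
(per-phase percents where printed, in `per_phase` mode), put undetectable
genes in the ND set, and place abundance offsets at −log2 of a representative
index per tier (high 2, medium 0.75, low 0.3, barely 0.05). Strata whose
outcome has a label but no printed magnitude are planted at fold 1 and
skipped by round-trip comparisons.

What the generator does *not* model: within-animal correlation between gene
and reference wells, primer-efficiency differences, inter-animal biological
covariance across genes, plate/batch effects. Passing round trips therefore
demonstrate the pipeline's arithmetic and decision logic, not robustness to
those real-data features.

## Operating characteristics and numerical choices

On noise-free data every within-group fold is identical, so significance is
unattainable by construction and round-trip label agreement is assessed at
the direction + changed/unchanged level while percents are compared exactly.

Monte-Carlo checks (seeded, vectorized where strata are many): the percent
estimator is unbiased to within ~1 point at sd 0.3 (a small upward ratio-mean
bias is expected and observed); the per-phase type-I rate at n = 4 vs 4 sits
at the nominal 0.05 within ±0.01 over 20,000 null strata. Recovery means for
planted effects are measured by unconditional pooling across replicates —
conditioning on the repeatability gate would select toward large effects and
bias the estimate. One subtlety: pooling per-phase-normalized folds pins each
control half's mean at 1 while PD halves float, so the pooled equal-variance
test is mildly anti-conservative under the null (≈ 0.052 unconditionally);
combined with the gate the effective null call rate drops to ≈ 0.045, below
the per-phase rate — the gate is what buys specificity in this design.

## Known limitations

- Pure 2^−ΔΔCT model; no efficiency correction or melt-curve QC.
- The transcription fixture stores printed values only; strata whose
  magnitudes were never printed cannot be round-tripped and are reported as
  skipped.
- The classifier's three trend-tier names follow the default 10/15/20
  brackets; custom tiers reuse the same three slots.
- The equal-variance *t*-test inherits the small-n fragility of the original
  design; the package reports, it does not remedy.
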