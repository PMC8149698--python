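# Methods

This note documents the models, defaults and numerical choices behind
`mirsens`, and what the synthetic-data generators do and do not emulate.

## Screen model and simulation

Viability is measured as CellTiter-Glo luminescence, a ratio-scaled
quantity, so all effects are modeled additively on the log2 scale
(multiplicatively on the raw scale):

```
log2(signal) = baseline + drug_effect(arm) + surface(row, col)
             + spike_effect(reagent, cell line, arm) + ε,   ε ~ N(0, σ²)
```

* `baseline` defaults to 20 log2 units (~10⁶ counts, a typical plate-reader
  scale).
* `drug_effect` defaults to the single-agent viability reductions observed
  for these drugs in this cell system: 4% for trastuzumab, 17% for
  lapatinib, 33% for the combination (log2 0.96 / 0.83 / 0.67). The vehicle
  arm is the no-drug reference.
* `surface` is a linear row gradient plus a linear column gradient
  (amplitude `spatial_gradient_log2`, default 0.3) with an optional smooth
  radial bowl — the artifact classes that loess spatial correction removes
  (edge evaporation, dispensing and incubation gradients).
* `σ` (`noise_sd_log2`) defaults to 0.15 log2 units, i.e. a ~10% CV,
  typical for CellTiter-Glo at 2,000 cells/well.
* The library defaults to 810 mimics + 816 inhibitors on 384-well plates
  (16 × 24), with 8 negative-control and 8 positive (cell-death) control
  wells per plate. Death controls are forced 7 log2 units below baseline.
  Library wells are placed in a seed-determined shuffled order, since
  printed position is unrelated to reagent identity; control wells are
  clustered at the end of each plate, which is why the loess fit uses
  library wells only.
* Replicates: the screen design implies one well per reagent per arm;
  `n_replicates` exists (used for validation plates) but defaults to 1.

Spiked effects (`SpikeSpec`) encode the causal ground truth: which reagents
sensitize, in which cell lines and arms, at what magnitude, whether they are
also toxic without drug, and (for inhibitors) whether the targeted miRNA is
endogenously expressed. All of this is returned as a `GroundTruth` record
for recovery testing.

What the generator does **not** emulate: transfection-efficiency gradients,
cell-cycle or growth kinetics, batch effects between plate sets, realistic
miRNA sequence identities, or non-Gaussian heavy-tailed well noise. Passing
recovery tests therefore demonstrates correctness of the analysis chain
under its own assumptions, not robustness to every artifact of real screens.

## Loess spatial correction

The paper-style normalization is "loess then log2"; the covariate is not
further specified anywhere, so the package adopts the screen-standard
choice: a 2-D loess of log2(signal) over well (row, column), fitted per
plate. The smoother is a tricube-weighted local polynomial regression
(span 0.5, degree 1 by default, both configurable), solved for all wells in
one batched weighted-least-squares pass, with one bisquare robustifying
iteration by default so strong hits do not drag the surface toward
themselves. Normalized values are recentred so the fit-well median of the
normalized plate equals the fit-well median of log2(raw) exactly — plates
stay mutually comparable because the downstream outlier rule pools reagents
across plates within a treatment group.

Degenerate inputs: plates with fewer than 20 fit wells are skipped with a
warning (normalized value left missing); a spatially flat plate is returned
unchanged (to ≈1e-6), which also makes the operation idempotent on
already-flat data.

Validation plates deliberately use a different normalization — raw signal
divided by the plate-wise median of the scrambled negative-control wells,
linear scale — mirroring the separate convention of the validation phase.

## Hit calling

Group statistics are the median and classical sample SD (ddof 1) of all
library reagents (mimics and inhibitors pooled, matching "all miRNAs within
the same treatment group"; a per-class option exists) per cell line × arm,
controls excluded. The SD includes outliers, since the rule is stated as
"standard deviations from the median" without robustification; a scaled-MAD
option is provided but off by default. Boundary convention: a value exactly
at median − 3·SD is *not* a hit (strict inequality); only the low-viability
tail is called. Zero-SD groups are flagged degenerate and produce no hits.

The no-drug-toxicity exclusion is applied per cell line: a reagent toxic
on its own in one cell line can remain a hit in the other, consistent with
the cell-line-specific treatment of effects throughout the analysis.
"Endogenously expressed" is operationalized as detection-flag true (or
value above a configurable floor) in at least one untreated sample of that
cell line. Candidates require ≥ 2 distinct (cell line, arm) sensitizer
contexts after exclusions — equivalently both cell lines, or two treatment
settings within one.

## Lysate microarrays

Loading is corrected spot-wise by the total-protein (Sypro) stain:
`log2(raw/sypro)`. Z-scores use the sample SD within a stratum of all
conditions sharing a (protein, cell line); the stratum choice is open in
the source protocol — per (protein, cell line) keeps treatment effects,
the readout of interest, inside the stratum; a per-(protein, arm) option is
provided. The hit threshold |z| ≥ 2 is inclusive, per the "± 2 SD" wording.
Hit sets are invariant to affine rescaling of raw intensities within a
stratum.

## Differential miRNA expression

Preprocessing follows the one-color array convention: per sample, subtract
the median of *detected* probes (so the detected median is exactly 0
afterwards); probes detected in no sample are set to one common floor,
defaulting to one less than the minimum centred detected value. The
treatment comparison is one Kruskal–Wallis per probe across the four arms,
run within three cell-line sets (all four lines, responsive, poorly
responding). The wording "before vs after treatment in three groups" is
ambiguous between a 4-group test and per-drug 2-group tests; both are
implemented (`mode="arms"` default, `mode="pairwise"`), and no claim is
made about which the original analysis used. Significance is the nominal
p < 0.05, deliberately without multiple-testing correction. Tie correction
is always applied. For pooled n ≤ 12 the p-value comes from the exact
permutation distribution of H (cached per rank multiset and group sizes);
the chi-squared approximation is off by up to several hundredths at three
samples per arm.

## Clinical association

* Spearman correlations use average ranks and the t-approximation for the
  two-sided p (identical to `scipy.stats.spearmanr`); BH adjustment is
  applied within each miRNA's family of mRNA tests by default (a global
  all-pairs scope is available) at adjusted p < 0.05. Constant vectors give
  missing correlations, never significance.
* Stage comparisons exclude stages with fewer than `min_group` (default 5)
  patients — the convention used for sparsely populated extreme stages —
  then run all pairwise two-sided rank-sum tests, exact where sample sizes
  permit, reported unadjusted.
* Survival uses a median split with the high arm strictly above the cohort
  median (ties at the median go low), Kaplan–Meier product-limit estimates
  per arm, and the standard hypergeometric-variance log-rank test with
  1 df, unstratified. BCSS treats non-disease deaths as censored; OS counts
  all deaths. The cohort median is computed after removing patients with
  missing expression or follow-up.

The cohort generator draws expression from a one-factor Gaussian copula:
a requested Spearman ρ between a miRNA and an mRNA is achieved by latent
Pearson r = 2·sin(πρ/6), the exact inversion for bivariate normals.
Survival is exponential with proportional hazards
(rate = baseline·exp(Σ log-HR·expression)) — the simplest model under which
the log-rank test is exact in distribution — with optional constant
other-cause mortality and independent exponential censoring whose rate is
matched to the requested censored fraction under the average hazard
(approximate when covariate effects are strong). Default sizes mirror the
clinical materials the analyses are designed for: 377 patients for
correlation cohorts, stage probabilities concentrated on stages 1–3 with
rare stages 0 and 4.

## Enrichment

Over-representation is the one-sided hypergeometric upper tail on the
overlap between a query gene list and each GMT set, BH-adjusted across
sets at 0.05. This is a deliberate local stand-in for web-based enrichment
services whose combined ranking scores are not reproducible offline; raw
hypergeometric p-values equal one-sided Fisher exact tests on the 2×2
table. The universe defaults to the union of all set members and should be
overridden with the measured gene space (e.g. all mRNAs on the array) when
the query derives from expression data. miRNA→target maps are user input
(tab-separated with `experimentally_observed` / `high_prediction` evidence
tiers); no target prediction is performed.

## Orchestration and determinism

Both workflows (screen → hits → validation; cohort associations) write
every stage as tab-separated text with a fixed float format plus a JSON
manifest containing the configuration hash, seed, package version, per-stage
row counts (the selection funnel), and sha256 digests of all outputs.
Reruns with the same configuration and seed are byte-identical; no stage
mutates its inputs. Exit codes: 0 success, 2 configuration error, 3 data
error.

## Problem sizes used in tests and the acceptance script

Hit-caller equivalence is checked against a brute-force oracle on 200
random tables of up to 1,000 wells; null calibration on a screen with
10,000 library wells per arm; spike recovery at the full 1,626-reagent
library over 25 seeds; survival power/size over 100 simulated cohorts of
300 patients at 30% censoring; correlation recovery at the 377-patient
cohort size with 200 mRNAs. These sizes give stable Monte-Carlo estimates
while keeping a full run in the order of a minute on one CPU.

## Known limitations

* The loess surface is estimated per plate; systematic biases shared across
  plates (batch effects) are only removed through the per-plate median
  recentring.
* The screen hit rule is a marginal outlier test; no replicate-based error
  model (SSMD, B-score) is provided.
* The copula generator ties each mRNA to at most one miRNA; arbitrary
  correlation matrices are out of scope.
* Censoring calibration in the cohort generator is approximate under strong
  covariate effects.
* Exact Kruskal–Wallis p-values are limited to pooled n ≤ 12 (enumeration
  grows multinomially).
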