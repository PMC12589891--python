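# Methods

## Scope and data model

`cartprofiler` profiles CAR-T cell products along three axes — cytometric
phenotype, serial tumor-killing function, and post-treatment correlates —
and integrates them into per-product composite potency scores. The unit of
cytometry data is the `EventTable`: an events × channels matrix of
fluorescence intensities with sample metadata (donor, stimulation
condition, construct group, ordinal clinical outcome) and an explicit scale
state, `raw` or `arcsinh`, that every transform checks. Synthetic tables
additionally carry per-event ground truth (population label, transgene
positivity) in a side container that is not a channel, so clustering and
gating can never peek at it.

## Synthetic cohort generator

The generator emulates the study conditions: ten products (three CAR-only,
seven with the C7R co-stimulatory receptor), two conditions (unstimulated
and tumor-stimulated), a 33-marker T cell panel, a CAR⁺ transduction
fraction of 0.5671 and a CAR⁺C7R⁺ fraction of 0.2307 as cohort defaults.

* **Events.** Each sample is a mixture of latent populations; marker
  intensities are drawn log-normally (`exp(N(μ_m, σ_m))`) on the raw
  intensity scale, which reproduces the right-skewed, strictly positive
  shape of unmixed fluorescence data. Stimulation adds a per-marker shift
  to the log-mean (defaults on CD137, IFN-γ, TNF-α, HLA-DR). Transgene
  positivity (14g2a for the CAR, CD34 for the C7R) is sampled per event as
  an independent Bernoulli and expressed as a bimodal log-mean shift
  (log-means 2 vs 6) on the detection channel, so the configured fraction
  is recoverable by gating. Spillover/spread error and spectral unmixing
  are deliberately not simulated — inputs are modeled post-unmixing — and
  no negative intensities are generated. Population log-SD defaults to
  0.25 with centroids placed several SD apart: the defaults are chosen for
  separability and testability, not fidelity to any clinical product, so
  recovery results on synthetic data bound what the pipeline can do under
  favorable conditions rather than predict performance on real samples
  (which carry heavier tails, doublets, spread error and rare populations).
* **Killing series.** Within each re-challenge round the tumor GFP area
  resets to `area0` at the anchor frame and evolves as
  `area0·exp((g − k_eff)t)` with
  `k_eff = kill_rate · et_scaling(ratio) · round_decay^(round−1)`;
  E:T scaling defaults to the ratio value itself (2, 1, 0.5, 1/6) and
  `round_decay` models per-round potency loss. Cadence defaults: 11 rounds,
  frames every 7 h, 11 frames per round (anchor at 0 h through 70 h) — the
  assay's stated 3-day cycle and 7-h imaging interval fix the cadence but
  not the frame count, so 11 is this package's configurable choice.
  Optional multiplicative log-normal noise spares the anchor frame so
  normalization stays exact. An infinite effective kill rate is clamped to
  instant clearance.
* **Correlates.** Each patient carries a latent product factor in [0, 1],
  exposed in the metric table. Cytokines respond as
  `baseline + effect(group) · factor · profile(t) + noise` on the
  {pre, 3 h, wk1, wk2, wk4} grid (3 h = 0.125 days on the AUC axis);
  persistence follows peak-then-exponential decay scaled by the factor.
  Planted effects make recovery testable by construction.

Determinism: one seed makes every generator bit-reproducible; distinct
seeds give distinct draws.

## Preprocessing

Arcsinh scaling uses `asinh(x / cofactor)` with a per-channel cofactor
defaulting to 150, the conventional value for unmixed fluorescence
intensities (the upstream study relied on its analysis platform's
defaults, which are not printed; the cofactor is therefore config). The
transform is monotone, odd and order-preserving, and refuses to run twice.

The drift cleaner is a simplified segment-mean outlier remover, not a
reimplementation of the full flowCut heuristic set: events are ordered by
acquisition time and split into consecutive segments of 500; a segment is
removed when any channel's segment mean deviates from the distribution of
segment means by more than 3 robust z-units (median/MAD, falling back to
the sample SD when MAD is zero), with removal capped at 30% of events,
most aberrant segments first. A shift common to all segments is invisible
by construction. The published cleaner's full parameter set is echoed in
the QC report for provenance only; no equivalence with its removals is
claimed.

Subsampling draws a uniform, seeded sample without replacement down to a
100,000-event cap (tables at or under the cap pass through unchanged),
preserving acquisition order and marginal marker distributions.

## Clustering

The SOM is batch-trained on a rectangular grid (default 10×10, `rlen` = 10
epochs, seed 3421): each epoch assigns every event to its best-matching
unit and recomputes each node as the Gaussian-neighborhood-weighted mean of
the data, the neighborhood radius shrinking linearly from `max(xdim,ydim)/2`
to 0.5. Batch updates make training deterministic given the seeded
initialization (codebook sampled from the data without replacement) and
fast on a single CPU. The final assignment is the exact nearest-codebook
rule under the Euclidean metric — verified against exhaustive search in the
tests. Fewer events than nodes is a warning, not an error; empty nodes are
excluded from metaclustering and profiling.

Metaclustering cuts an average-linkage dendrogram of the codebook vectors
at a target `k`. The study refined its consolidation with spanning-tree
topology and manual judgment; this package fixes the automated
average-linkage rule (matching the heatmap's stated clustering method) with
`k` as configuration. Two presets reflect the study design: an
activation-marker run at k = 25 (optionally including the 2-D embedding
coordinates as features) and a full-marker run at k = 50 consolidated to
35. Clustering features exclude CD3, viability and the transgene detection
channels (14g2a, CD34) used for pre-filtering, and consume arcsinh-scaled,
unstandardized intensities by default (whether the original analysis
standardized per channel is unstated; both are supported).

Profiles are per-cluster mean intensities, min-max scaled per marker across
clusters; a marker constant across clusters scales to 0 by convention, and
presence is called at scaled ≥ 0.58. Abundance tables are per-sample
percentages (rows sum to 100); the group contrast is
`mean(C7R) − mean(CAR-only)` — the source figures state the subtraction in
both directions, so the convention is fixed here and written into the
output metadata — and deltas sum to zero across clusters by conservation.
Outcome association is Spearman rho of abundance against the ordinal
outcome PD = 0 < SD = 1 < PR = 2 (the original presentation of this trend
is visual; the rank correlation formalizes it). The 2-D embedding is
delegated to umap-learn (n_neighbors = 15, min_dist = 0.4, Euclidean,
spectral initialization, 200 epochs, seed 2553); its internals are out of
scope.

## Killing assay

% killing normalizes areas to the anchor (first) frame of each round —
the re-challenge reset makes the per-round anchor the meaningful baseline;
the alternative reading (one global t1) is rejected here because areas
reset by construction every round. The anchor frame scores 0; values are
not clamped, so net growth contributes negatively. The 3-day IV sums %
killing over a round's frames; the 33-day IV sums the 3-day IVs, giving a
score linear in per-frame killing and strictly increasing in kill rate at
equal growth. A zero anchor area makes that round's killing undefined
(NaN, flagged). Image quantification (Otsu or fixed threshold + pixel
count, optional pixel-size calibration) is provided for raw frames; the
pipeline equally accepts pre-tabulated area CSVs, the study's situation.
No attempt is made to reproduce the trial's printed clinical IVs: the raw
areas are not deposited.

## Scorecards

Metrics are z-scaled per column with the sample SD (ddof = 1) — the right
convention for a 10-product cohort; a zero-variance metric is an error
naming the metric. Z-scores are mapped to radii by per-axis min-max onto
[0.05, 1.0]: the floor keeps every vertex off the origin so a product
dominant on one axis still gains area, and the mapping preserves rank. How
the original analysis mapped negative z-values to radii is not recoverable,
so areas are arbitrary units and only ordering properties are asserted.
The polygon area is the shoelace formula at equal angular spacing,
`½·sin(2π/m)·Σ rᵢr₍ᵢ₊₁₎`; it is invariant to cyclic rotation of the axis
order but not arbitrary permutation, so the order (cytotoxicity,
activation, infiltration, resilience, serial killing) is fixed in config
and recorded in every output. The killing axis uses the 2:1 E:T 33-day IV.
Boolean-gate positivity thresholds are not printed in the source; the
pipeline derives defaults from pooled per-marker means and accepts
config/FMO-derived overrides.

## Correlates

Cytokine group scores are means of member cytokines per patient and
timepoint (raw concentrations by default, log1p optional — the original
choice is unstated); group membership is configuration, with synthetic
defaults {inflammatory, regulatory, homeostatic}. Deltas are later − earlier
for the pairs pre→wk1, pre→wk4, wk1→wk4 and telescope exactly. Spearman
uses midranks; constant vectors are flagged undefined. Persistence AUC is
the trapezoid rule on the day grid; unordered timepoints are an error, not
silently sorted. The area-vs-persistence relationship is Pearson r with a
t-based p-value and an OLS slope with a t-interval at 95%. Correlations
are exploratory: no multiplicity correction by default (a
Benjamini–Hochberg option exists) and outputs say so.

## Panel QC

Stain index `SI = (MFI⁺ − MFI⁻)/(2·SD⁻)` with MFI as the arithmetic mean
(median optional); SI is invariant under common multiplicative rescaling.
Titration picks the argmax SI, breaking exact ties toward the most dilute
preparation (the cheaper choice). FMO variability is the per-marker sample
SD of positive-cell frequencies across donors, passing below 8 percentage
points — the threshold is interpreted in percentage points, the natural
reading for frequency data. The instrument vendor's proprietary spectral
complexity metric is not implemented (it requires spectral signatures this
package never sees).

## Pipeline and reproducibility

`run_pipeline` executes simulate → preprocess → cluster → kill → score →
associate → qc from one config; a stage whose inputs were not produced
fails fast with an error naming the missing dependency, retaining partial
outputs. One global seed derives a named per-stage seed via
`SeedSequence([seed, crc32(stage)])` (kept below 2³¹); reruns are bit-exact
for all CSV/JSON outputs, recorded as SHA-256 checksums in the manifest.
The default configuration runs a 10-product cohort at 3,000 events per
sample with a 10×10 SOM cut at 10 metaclusters — sizes chosen so a full
run completes in seconds on one CPU while preserving every structural
property the tests assert; all sizes scale up by config. Tests exercise
the stated study scales where they are the point (100-node SOM
nearest-codebook equivalence at 1,000 events; 20,000-event, k = 5
metacluster recovery with centroids ≥ 3 SD apart, ARI ≥ 0.9).

## Known limitations

* The synthetic mixtures are cleaner than clinical cytometry: no doublets,
  debris, spectral spread or rare populations, so recovery metrics are
  upper bounds.
* The drift cleaner is intentionally simpler than the published cleaning
  tool and will not reproduce its removals.
* Radar areas are not comparable across cohorts (the z-scaling and radial
  map are cohort-relative by design).
* Printed clinical quantities (per-product IVs, the persistence
  correlation) derive from undeposited patient data and are context, not
  targets.
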