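# Methods

This note documents the models behind phenolink, the defaults and why they
were chosen, what the simulator does and does not emulate, and the design
choices made where the underlying assay description left the design open.

## Sensor model and OCR extraction

A sealed well of volume V (default 140 pL) traps an oxygen amount
A₀ = V·C₀·k_u fmol, with C₀ the dissolved-oxygen concentration at seal time
and k_u = 10⁻³ fmol·pL⁻¹·µM⁻¹ the unit conversion. C₀ defaults to 200 µM
(approximately air-saturated aqueous medium near 37 °C); at 140 pL this is
28 fmol of oxygen, giving drawdown times of tens of minutes for rates of
0.5–5 fmol/min, the experimentally relevant range. A cell consuming at a
constant rate r gives A(t) = max(0, A₀ − r·t): concentration falls linearly
at r/(V·k_u) µM/min until the depletion floor.

The sensor photophysics are modeled as ideal Stern–Volmer quenching of the
sensor/reference ratio, ρ(C) = I₀/(1 + K_SV·C), the simplest model
consistent with a self-referencing ratiometric intensity sensor. Defaults
K_SV = 0.005 µM⁻¹, I₀ = 2.0 place the dynamic range of ρ between 1 (at
200 µM) and 2 (anoxia). A two-point calibration (`two_point_calibrate`)
fits (K_SV, I₀) from an anoxic ratio and a ratio at one known
concentration, as produced by gas-purged media.

Extraction inverts this chain: ratio → optional centered 5-point sliding
average → Stern–Volmer inverse → OLS line fit of C(t) → OCR =
max(0, −slope)·V·k_u. Numerical choices:

- **Pre-floor truncation.** The regression stops at the first sample below
  2% of the initial concentration; fitting into the clamped region would
  bias slopes toward zero. At least 5 usable points are required.
- **Volume factor.** Converting a concentration slope (µM/min) to an
  absolute rate (fmol/min) dimensionally requires *multiplying* by the well
  volume (×k_u). Assay write-ups sometimes describe this step as a division
  by volume; we implement the dimensionally consistent multiplication.
- **Regression target.** The line is fitted to calibrated concentration
  (not raw intensity or ratio), matching how drawdown curves are reported;
  for Stern–Volmer kinetics the concentration is the linear-in-time
  quantity, so this is also the statistically natural scale.
- **Unweighted OLS**; the slope standard error is propagated to an OCR
  standard error by the same V·k_u factor. An exactly flat series is
  reported as slope 0 with R² = 1 (a zero-slope line fits it perfectly).
- **Detection floor.** Cells with OCR < 0.1 fmol/min are classed
  non-respiring. The assay reports such cells as "OCR = 0" without stating
  a measurement threshold; 0.1 fmol/min sits well below the typical
  respiring range (~0.5–5 fmol/min) and well above the noiseless numerical
  error of the fit.
- **Smoothing** defaults on (window 5) and is always applied before the
  regression when enabled.

**Seal QC.** `qc_seal` asserts stability of the normalized ratio over a QC
window, comparing short medians at the window ends against a relative
tolerance (default 2%). It is meant for a dedicated perturbation trace
(exterior oxygen changed, e.g. a nitrogen purge after the drawdown): an
intact hermetic seal leaves the interior unchanged while a leak lets the
interior track the exterior. The simulator reproduces a leak with a
first-order exchange term (`leak_per_min`) toward a configurable exterior
concentration.

## Expression normalization

Input is a genes × cells matrix of log-scale expression with non-detects.
Genes detected in fewer than 3 cells are dropped (reported). Non-detects
are imputed at the per-gene minimum detected value — a conservative
"at-or-below detection" placement — and flagged. The global mean of all
detected entries is subtracted, then each gene is Z-scored using the mean
and *sample* SD (ddof = 1) of its detected entries. Detected entries of
every retained gene therefore have mean 0 and SD 1 (to 10⁻⁹); imputed
entries sit at or below each gene's detected minimum. Genes with zero
variance across detected entries are set to 0 and recorded in the
metadata. The Z-scores are computed per gene; the global-mean subtraction
is retained for interpretability of the stored metadata even though
per-gene centering absorbs it.

## Clustering and the TES/RV statistics

Cells are pooled across all strains and clustered agglomeratively
(scipy linkage; default Ward on Euclidean distances of the normalized
matrix, cut to exactly k = 10 clusters; all configurable). Labels are
renumbered in order of first appearance, so permuting cell order permutes
labels but never the partition. The merge tree is exportable as Newick.

TES_g = Σ_i f²_{g,i}/p_i is the occupancy-weighted mean of the per-cluster
enrichment ratio f_{g,i}/p_i. By Cauchy–Schwarz (with Σf = Σp = 1),
TES ≥ 1 with equality iff the group's occupancy matches the pooled
occupancy, and TES ≤ N_total/n_g with equality iff the group exclusively
owns one cluster — so TES is a variability scale anchored at both ends.
For n_g ≈ 21 of N_total ≈ 170 the upper bound is ≈ 8.1, which brackets the
empirically reported TES range. RV = TES_control/TES_hypoxia is reported
raw and rounded to two decimals. The aggregation formula is a design
choice of this package: published analyses of this kind state p_i and the
enrichment-ratio idea but not the aggregation; the squared-occupancy form
is the occupancy-weighted mean of the stated ratio with the boundedness
properties above.

Group-mean OCR comparisons per cell type report both a Welch
(unequal-variance) t test and a two-sided Mann–Whitney test, each
Benjamini–Hochberg-adjusted across cell types; the underlying assay report
does not name its test, so both a location and a rank test are given.
Degenerate pairs (both strains constant and identical) get p = 1 and a
flag.

## Combined-phenotype analysis

PCA is column-centered with a deterministic sign convention (the largest
|loading| of each component is made positive). t-SNE (scikit-learn, PCA
initialization) is deterministic given its seed and requires perplexity
< (n−1)/3. The OCR-augmented coordinates keep PC1 and PC2 and replace the
third coordinate by a robust Z of OCR: (OCR − median)/(1.4826·MAD),
computed over respiring cells; non-respirers are pinned at the axis
minimum. Median/MAD is used instead of mean/SD because single-cell OCR
distributions are zero-inflated and right-skewed, so the axis has exactly
zero median and unit scaled-MAD over respiring cells (zero mean / unit SD
hold only approximately). If the MAD is zero the SD is used; a fully
constant OCR yields an all-zero axis with a warning.

Flags (thresholds are operational choices, all exposed in config):

- `high-OCR-outlier`: respiring, |robust OCR Z| > 2.5, and expression
  distance to the cell's own cluster centroid within the 0.75 quantile of
  that cluster's distances — extreme function inside an ordinary
  transcriptome. The Z threshold 2.5 corresponds to ~1% two-sided tail
  under normality, so in a noisy homogeneous population occasional flags
  are expected and correct.
- `non-respirer-cluster`: non-respiring, with mean pairwise expression
  correlation to the other non-respirers > 0.5. Skipped (with a note) when
  fewer than two non-respirers exist.

Flags are invariant to relabeling cell types and to any common positive
rescaling of OCR (the respirer class is taken from the OCR table, not
recomputed from the floor).

## The study simulator

`generate_study` emulates the study design end to end: 4 cell types ×
2 strains, 20–24 cells per strain (total within [160, 192]), each cell's
true OCR drawn from a per-strain zero-inflated lognormal (defaults:
median ≈ 1.5 fmol/min, log-SD 0.5; non-respirer fractions 0.18–0.35 for
seven strains and exactly 0 for the control CP-A analog), sensor traces
with 1% multiplicative channel noise, and a 96-gene panel (glycolysis,
angiogenesis/vessel development, chemotaxis, migration, phosphorylation,
apoptosis categories plus housekeeping genes with near-zero dropout;
default dropout 0.15 elsewhere). Expression is Gaussian around latent
cluster centroids; CP-B and CP-D analogs carry two latent sub-clusters
each (the bi-cluster pattern seen in dysplastic lines), the others one.
Between-cluster spread (1.2) is comparable to within-cluster noise (1.0),
producing a heterogeneous landscape with only slight cell-type clustering
rather than separable blobs. Control and hypoxia strains of a type share
centroids, encoding the observation that hypoxia-adapted cells
recapitulate the control molecular phenotype; correspondingly the default
selection heritability is 0. All randomness flows from one explicit seed;
same seed gives byte-identical output files.

**Bottleneck selection.** `simulate_hypoxia_selection` runs n_rounds = 6
episodes at survival_fraction = 0.10 with re-expansion to the original
size. Survivor slots split between strict trait-rank selection (weight h =
heritability) and uniform survival (weight 1−h). Offspring resample
survivors (inheriting phenotype columns such as latent cluster) and the
trait regresses as

    trait' = h·m_surv + (1−h)·m_base + h·(parent − m_surv) + √(1−h²)·s_base·ε

with m_base, s_base from the original base population. The anchoring to
the *base* statistics is deliberate: h = 0 means the trait is not
heritable, so each generation redraws it from the stable environmental
distribution and the trait distribution is preserved across any number of
bottlenecks (anchoring to the survivor mean instead would random-walk the
mean by ~σ/√(bottleneck size) per round and spuriously signal selection
under the null). h = 1 copies parent traits faithfully, so rank selection
shifts the mean directionally. Phenotype columns still drift by bottleneck
resampling — that is genetic drift and is intentionally retained.

## What the simulator does not emulate

No raw images, ROI extraction or shading correction (simulation starts at
per-well intensities); no qPCR chemistry (expression is generated directly
on the log scale); no cell-cycle, burst kinetics or gene–gene correlation
structure within a cluster (noise is iid across genes); dropout is
independent of expression level except through the housekeeping set; OCR
and expression are independent given the strain. Consequently, passing
tests demonstrate that the *pipeline* recovers what the generative model
puts in — rates, cluster structure, planted aberrant cells — not that real
instrument data are free of drift, focus loss or harvesting artifacts.

## Problem sizes and runtime choices

Tests and examples use the full study size (~170 cells, 96 genes) but
short traces (25–40 min at 1 min sampling) and population sizes of
1000–2000 for the selection simulations; these sizes give stable
statistics for every assertion while keeping the whole suite fast.
Distribution-level checks (zero-fraction bounds, KS null calibration,
type-I error) use 3-SD binomial bounds or medians over 10–25 seeds.

## Known limitations

- TES depends on k and the linkage/metric choice; comparisons are only
  meaningful within one pooled clustering.
- TES values from different studies are not comparable without matching
  n_g and N_total, since the upper bound depends on both.
- The aberrance thresholds are operational definitions of "well
  differentiated", not estimates of any underlying rate.
- The h = 0 trait redraw assumes the base trait distribution is the
  stationary environmental distribution; strongly non-Gaussian base
  distributions are preserved only up to their first two moments.
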