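# Methods

This note documents the models and procedures implemented in `miratlas`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic data does and does not emulate.

## Problem setting

Circulating microRNAs (serum, plasma, PBMC) are widely reported as
disease biomarkers. Interpreting such a report requires knowing where the
microRNA is expressed at the *cell* level: a biomarker should be
expressed in a cell type involved in the disease and should not be
expressed everywhere. The pipeline therefore (i) harmonizes heterogeneous
multi-platform array data into one cell-type × microRNA expression atlas,
(ii) makes binary expression calls per cell type, (iii) classifies each
reported biomarker against the atlas and a curated disease → cell-type
map, and (iv) audits a whole corpus of reports for replication and
disease specificity.

## Nomenclature

All microRNA identities are keyed by mature-form MIMAT accessions.
The key is built from a miRBase-`aliases.txt`-dialect table (accession,
semicolon-separated names, oldest first); the last name is taken as
current. Lookup is case-insensitive and tolerates a missing `hsa-`
prefix, because source studies print names inconsistently. Carrier
(minor) strand status is inferred from any `*`-suffixed alias, with an
optional per-accession annotation override; when no evidence exists the
strand is recorded as unknown and treated as a guide strand downstream.
Which miRBase release generated the key is deliberately *not* baked in:
the key is an input, not a constant.

## Array ingestion

Input tables follow the GEO series-matrix convention (probe rows ×
sample columns, log2 scale; a flag transposes or log-transforms).
Recognized missing tokens: empty cell, `NA`, `NaN`, `null`
(case-insensitive); any other non-numeric cell is an error naming its
coordinates. Arrays whose missing fraction strictly exceeds 0.5 are
dropped (the strict inequality follows the "greater than 50 %" rule; the
fraction is computed over all features present on the sample's
platform). Probes are collapsed to accessions by per-sample **median**
of non-missing values — robust to a single aberrant probe; unresolvable
probes are dropped and logged.

## Modified subset quantile normalization

Full quantile normalization assumes all samples share one value
distribution — wrong across platform versions that target different
microRNA sets. Subset quantile normalization enforces distributional
equality only on a chosen subset; here the subset is the features
**common to all platform versions**. The original formulation of subset
quantile normalization was built around a small set of negative-control
probes and a mixture model; with a common subset hundreds of features
wide, a nonparametric rank-interpolation construction is simpler and
more stable, and is this module's defining design decision:

* **Reference**: for each sample, the sorted non-missing subset values
  are interpolated onto the plotting-position grid p_k = (k − ½)/m
  (m = subset size); the reference is the across-sample mean at each
  grid point. All samples are pooled (not per-platform averages); this
  is a documented open choice.
* **Subset features**: rank r of n_s (average ranks for ties) receives
  the reference evaluated at (r − ½)/n_s.
* **Non-subset features**: value v receives the reference at F̂(v),
  where F̂ is the piecewise-linear empirical CDF through the sample's
  unique subset values at their (average-rank) plotting positions,
  clamped to [½/n_s, 1 − ½/n_s]. Clamping is flat: out-of-range values
  map to the reference extremes rather than being extrapolated.

Both paths go through one monotone value → probability → reference map,
so within-sample ordering is preserved exactly and subset/non-subset
features with equal values agree. The map is idempotent, and
post-normalization the sorted subset values of every sample equal the
reference on that sample's rank grid to float precision. A sample needs
at least 3 non-missing subset values; fewer is an error (or exclusion
from the reference, with a warning).

## Empirical Bayes batch correction

Chip-level effects remaining after normalization are removed with the
standard empirical Bayes location/scale model, implemented from scratch:

    Y_ijg = α_g + (Xβ_g)_j + γ_ig + δ_ig ε_ijg

for feature g, sample j in batch (chip) i, with optional categorical
covariates X (cell type by default when building the atlas, so biology
is protected from removal; covariate-free mode reproduces the plain
algorithm). Estimation:

1. Per-feature least squares on batch dummies + covariate dummies
   (first level dropped); the design must be full rank, otherwise a
   confounding error is raised. Each batch needs ≥ 2 samples.
2. α_g is the observation-count-weighted mean of per-batch means (the
   weighting matters for features unmeasured on some chips, e.g.
   platform-tail microRNAs in a nested design).
3. Pooled variance σ̂²_g = RSS/(N_obs − 1). The N − 1 denominator
   (rather than N) matches the ddof = 1 per-batch variances, making a
   single-batch fit exactly γ* = 0, δ*² = 1 and the adjustment the
   identity; the difference from the reference implementation is
   O(1/N) and is covered by a cross-check test against Bioconductor's
   implementation (max deviation < 0.15 log2 units on a 40 × 20
   fixture, mean < 0.03).
4. Per-batch per-feature location γ̂ and scale δ̂² of the standardized
   data; hyperparameters by method of moments — normal prior
   (γ̄_i, τ̄²_i), inverse-gamma prior (λ_i, θ_i).
5. Shrinkage by the standard fixed-point iteration, tolerance 1e-4
   relative change, max 500 iterations (non-convergence is an error).
   A degenerate scale prior (zero spread across features) disables
   scale shrinkage for that batch.

Missing data: all statistics use non-missing entries; a feature with
fewer than two observations in a batch gets the shrinkage-only estimate
(γ* = γ̄_i, δ*² = prior mean) and is logged as low-confidence. Adjusted
output is σ̂_g (Z − γ*)/δ* + α_g + Xβ_g; missing stays missing.

## Cell atlas and expression calls

After adjustment, samples are grouped by cell type. A microRNA is called
expressed in a cell type when **any one sample** of that cell type
reaches the threshold — default 8.0 on the log2 scale, inclusive
(observed values span roughly 4.8–12.8; everything below 7.0 is array
noise, and the 8.0 cutoff is a deliberately conservative convention).
The per-cell mean profile is kept for clustering and display but never
drives calls; a mean-based call rule exists as an experimental switch.
A microRNA absent from the matrix is absent from the atlas — queries
return a distinguished no-data result, never an empty set.
Contamination annotations (e.g. ductal/acinar preparations carrying
red-cell and endothelial signal) are surfaced as metadata and never
alter calls.

Cell-type clustering is deterministic agglomerative clustering on
1 − Pearson correlation of mean profiles with average linkage (the
conventional choice for expression heatmaps; config-overridable), on the
microRNAs complete across all cells. Zero-variance profiles are an
error because correlation is undefined.

## Plausibility classification

Decision order per report (exactly one rule fires):

1. name unresolvable, or microRNA absent from the atlas → **unknown**;
2. expressed in zero cell types → **questionable**;
3. compartment is PBMC → **likely** iff expressed in ≥ 1 leukocyte cell
   type, else **unlikely**;
4. expressed in ≥ 7 cell types → **ubiquitous**;
5. expressed in ≥ 1 disease-mapped cell type (or granted by a
   tissue-level override, below) → **likely**;
6. otherwise → **unlikely**.

The PBMC precedence (rule 3 before the ubiquity rule) is deliberate and
documents a real tension: a microRNA that is ubiquitous across cell
types can still be a fair PBMC biomarker because the assay measures the
cells directly rather than cell-free promiscuity. The leukocyte set
defaults to the atlas's hematopoietic labels but should exclude red
cells and platelets (not mononuclear cells); the bundled demonstration
data passes an explicit leukocyte set for this reason. Carrier-strand
microRNAs need no special casing: they fall into rule 2 when the atlas
has no signal for them.

Tissue-level override: when a disease maps to a tissue label (e.g.
placenta for pre-eclampsia) and the atlas metadata lists the microRNA as
expressed in that tissue, rule 5 grants likely even without cell-level
overlap — covering cell types the atlas lacks.

"Some level of cellular exclusivity" for likely is operationalized
purely as "not ubiquitous"; no additional exclusivity test is applied.
The ubiquity threshold (7), expression threshold (8.0) and leukocyte set
are configuration.

## Cross-study audit

* **De-duplication**: uniqueness is keyed by accession; the merged level
  keeps one record per (accession, canonical disease) pair. Disease
  merging is driven by an optional synonym table (curated input, not
  hard-coded medicine). When one pair received different categories
  across studies, the **most favorable** category is kept, in the order
  likely > ubiquitous > unlikely > questionable > unknown.
* **Replication**: only diseases with ≥ 2 distinct studies are scored
  (PBMC and cell-free studies of one disease are treated as comparable
  by default; a compartment-stratified mode exists). A microRNA is
  replicated when ≥ 2 studies agree in direction, opposite when they
  disagree; a "mixed" direction makes it discordant-eligible.
* **Promiscuity**: accessions claimed for ≥ 9 distinct diseases
  (threshold configurable).
* **Normalization quality**: *poor* = RNU6B evaluated in serum, plasma
  or blood NOS (U6 is unstable in cell-free fluids); no or unreported
  normalization; or miR-451a as normalizer (a red-cell microRNA
  confounded by hemolysis). *Acceptable* = anything else, including
  spike-ins, RNU6B in PBMC, and other human microRNAs.
* **Statistics**: Pearson χ² on 2×2 tables without continuity
  correction, df = 1; Welch unequal-variance t with Satterthwaite df
  (the safer default where variances differ; a pooled-variance switch
  would be trivial but is deliberately not offered). Both delegate to
  scipy behind this module's interface; tests verify them against hand
  computation and a seeded null calibration.
* Category tallies report counts plus integer-rounded percentages
  (display convention), so percentages sum to 100 ± 1.

## Synthetic data

The generator produces every input the pipeline consumes, with planted
ground truth. Defaults are the emulated study conditions: three nested
platform versions of 461/711/837 microRNAs (common subset = the 461),
18 cell types of which 8 are hematopoietic, 6 samples per cell type
dealt round-robin across platforms, chips of 8 samples as batches.
Per-(cell, microRNA) true means live on the observed log2 scale:
expressed in [9.0, 12.8], unexpressed in [4.8, 6.0] — a margin of ≥ 1.0
around the 8.0 threshold, so end-to-end call recovery is a sharp test
rather than a statistical one (an adversarial mode plants means inside
the margin for robustness testing). Archetypes: cell-specific (1–6
cells), ubiquitous (≥ 7), unexpressed, in a 45/25/30 mix; two paired
lineage signatures (30 microRNAs each, one per lineage group) make the
hematopoietic split recoverable by clustering while keeping per-cell
expressed-feature counts comparable, as they are in real cell types — a
one-sided signature would violate the distributional-similarity premise
of quantile-based normalization.

Measurements are true mean + chip shift + chip scale × noise, with
chip shift ~ N(0, 0.4), chip scale ~ lognormal(0, 0.15), noise
sd 0.25 (log2 units), 2 % missingness — moderate, realistic magnitudes.
Batch effects are applied per chip, not per platform, so normalization
(platform-level) and batch correction (chip-level) are exercised
separately. Optional corrupt samples with 60 % missing data exist to
trip the missing-array filter.

Report tables are drawn so every row's correct category is known under
the classifier's rules evaluated on the planted truth; per-disease
replication and direction-conflict rates are planted (defaults 0.12 and
0.04); compartments, normalization texts and impact factors are drawn
from configurable distributions echoing the published corpus (serum and
plasma dominate).

What the generator does **not** emulate: probe-sequence effects, dye and
background chemistry, hemolysis (direction-label noise stands in for
it), correlated missingness, and real biological covariance between
microRNAs. Passing end-to-end tests therefore demonstrates the
pipeline's correctness under its stated model, not performance on any
particular real dataset.

The bundled demonstration data (`miratlas.datasets`) is synthetic by
construction: the 18-cell demonstration atlas encodes documented
cell-specificity facts (miR-122 hepatocyte-only, miR-451a/miR-144
red-cell, miR-223 myeloid, miR-21-5p/miR-16-5p everywhere, miR-29a-3p in
16 of 18 cell types, carrier strands below the noise floor), and the
104-study × 192-microRNA grid is a deterministic constructor that
carries the corpus-level structure (416 reports; category tallies
139/93/139/37/8 at report level and 96/85/114/35/8 at merged level; 69
multi-manuscript and 6 promiscuous microRNAs; an 87-report/31-microRNA
cardiac subset; 21 of 180 biomarkers replicated and 8 opposite across
15 multiply-studied diseases). These are stand-ins for real exports,
which load through the same readers.

## Numerical choices and problem sizes

* Plotting positions (k − ½)/m throughout; linear interpolation; flat
  clamping outside observed ranges.
* Ties get average ranks, guaranteeing monotonicity.
* Reference is built after the 50 %-missing filter and before batch
  correction (pipeline order).
* Batch model: tolerance 1e-4, max 500 iterations; variance floors are
  not needed because δ*² is positive by construction.
* Tests and the acceptance script run the default-sized simulation
  (18 cells × 837 microRNAs × 108 samples, ~2 s) and reduced fixtures
  elsewhere; statistical calibrations use 1000 replicates and seeded
  generators everywhere.

## Known limitations

* The atlas covers only the cell types present in the input; missing
  cell types inflate the questionable category, and the unknown/
  questionable boundary depends on array coverage.
* The disease → cell-type map is curated input; classification quality
  cannot exceed its quality.
* The merged-level "most favorable category" conflict rule and the
  pooled (non-stratified) replication default are conventions; both are
  configurable, neither is derivable from first principles.
* Single-value-per-cell atlas tables (the serialized layout) collapse
  the any-sample call rule to a simple threshold on the stored summary;
  the values TSV therefore stores the per-cell max.
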