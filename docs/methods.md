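# Methods

## Scope and model of the analysis

`cwrgap` implements an ex situ conservation gap analysis for a crop
genepool: given occurrence records (genebank germplasm, G, and
herbarium/reference records, H) and gridded environmental layers, it
estimates each species' potential distribution, measures how completely
existing germplasm collections cover that distribution, and turns the
result into collecting priorities. The worked system is the sweetpotato
wild-relative genepool (*Ipomoea* series *Batatas*, 14 wild taxa), whose
published per-taxon summary ships with the package as a consistency
fixture; all spatial computation, however, runs on synthetic worlds with
known ground truth, because the underlying occurrence compilation is not
redistributable.

All grids are geographic WGS84, north-up, cell-center registered, with
square cells in decimal degrees (`GridSpec`). Distances are great circles
on a 6371-km sphere; at the 50–100 km scales that matter here (collection
buffers, coastal limits) the spherical error is far below a cell width.
Cell areas use the small-cell approximation
(πR/180 · res)² · cos(lat); a full-longitude zonal band reproduces the
exact spherical zone area within 0.5% at 1° resolution (tested).

## Distribution models

The learner is a presence–background suitability model: a ridge-penalized
logistic regression (λ = 10⁻³) on standardized linear + quadratic features,
with background points down-weighted so both classes carry equal total
weight. This is a deliberate, documented surrogate for the maximum-entropy
(Maxent) algorithm; its contract — suitability in [0, 1] over the grid,
ROC-comparable scores — is the only thing downstream stages rely on, and
the learner sits behind a narrow interface so it can be swapped.

* Background: 10,000 cells drawn uniformly once per run from the combined
  native land of all taxa and shared by every species and method. On worlds
  with fewer land cells the draw is capped (without replacement) with a
  warning.
* Replicates: presences are split into k = 5 random folds (fixed seed);
  each replicate trains on k−1 folds against the full background. Mean and
  per-cell SD over replicates form the model surface.
* Thresholding: the binary range keeps cells whose mean suitability is at
  or above the score minimizing the ROC distance to the (0,1) corner
  √((1−sens)² + (1−spec)²), computed on pooled out-of-fold presence scores
  against background scores, with ties broken toward the higher (more
  conservative) threshold.
* Native clipping: the thresholded range is intersected with the species'
  native countries and, when set, a maximum distance to the coast.

Three variable sets are compared per species: the 19 bioclimatic layers,
the full 27-layer stack (adding altitude and seven soil properties), and a
species-specific subset. The subset is chosen by NIPALS PCA on the
presence-cell matrix — NIPALS because presence matrices can have fewer rows
than variables and missing entries; components are extracted by the
iterative algorithm (tolerance 10⁻⁸, ≤ 500 iterations, deflation) and
variables correlated above |0.7| with either of the first two components
become candidates (correlation loadings, not unit-norm eigenvector entries:
only the former can plausibly exceed 0.7). Candidates are then pruned by
variance inflation factor, iteratively dropping the worst while any
VIF > 10. The |0.7| cut is the method's; the VIF cut of 10 is this
package's choice (the conventional collinearity rule of thumb). If fewer
than three candidates clear the loading rule, the top three by absolute
loading are taken.

Model quality is gated on four statistics: ATAUC (mean out-of-fold AUC,
rank/Mann–Whitney form) > 0.7; STAUC (SD of fold AUCs, ddof = 1) < 0.15;
ASD15 (share of cells inside the thresholded range with replicate
SD > 0.15) < 0.10; and cAUC > 0.40. The calibrated AUC is
cAUC = AUC + 0.5 − max(0.5, AUC_null), where the null model scores each
location by proximity to the nearest training presence — performance a
model could achieve from spatial aggregation alone is discounted. The
spatial-sorting-bias ratio (mean nearest-training-presence distance of test
presences over test background) is reported alongside but not gated.

Species with ≥ 20 distinct occupied cells use the subset model directly.
With 5–19 cells the range is the cell-wise **intersection** of the three
method models — "overlap" is read as intersection, the conservative choice,
and the per-method supports are retained on the result object so the
sensitivity of that choice can be inspected. Below 5 cells a species is
unmodelable and reported as such (the sparsest species modeled in the
source compilation had 8).

## Gap scores

With G and H the record counts (including non-georeferenced records — SRS
is sample-based) and CA50 the union of 50-km buffers around georeferenced
germplasm points:

* SRS = 10 · G/(G+H)
* GRS = 10 · min(1, area(CA50 ∩ range)/area(range)), spherical cell areas
* ERS = 10 · |ecosystem classes in CA50 ∩ range| / |classes in range|
* FPS = (SRS + GRS + ERS)/3

Buffers are intersected with the predicted range before any counting:
collections outside the modeled distribution cannot inflate coverage, and
GRS cannot exceed 10. The intersection is exposed as a switch
(`clip_to_distribution`) because the alternative reading is defensible.
Categories: HPS for FPS ≤ 2.5 **or** G = 0 (the override also covers the
FPS = 0 corner), MPS to 5, LPS to 7.5, NFCR above. All three scores are
monotone in added germplasm and invariant to duplicated points (buffer
union semantics); both properties are tested.

Spatial products: per-taxon gap = range ∧ ¬CA50; richness = count of
predicted ranges per cell; hotspots = gap count over HPS taxa only; country
tabulations are zonal sums of gap cells and km² over the country raster.

## Niche comparison

Geographic overlap is the Jaccard fraction of shared presence cells.
Niche overlap uses suitability surfaces normalized to unit mass over the
union of valid cells: Schoener's D = 1 − ½Σ|pA − pB| and the
Hellinger-based adjusted I = 1 − ½Σ(√pA − √pB)²; D ≤ I holds analytically
and is asserted on 1,000 random surface pairs. The analysis extent
(union of the two surfaces' valid cells) is this package's choice — the
method literature does not fix one.

The occurrence-level PCA is correlation-based, preceded by Bartlett's
sphericity test (χ² = −[(n−1) − (2p+5)/6]·ln det R, df = p(p−1)/2; a
singular R is clipped at det = 10⁻³⁰⁰ with a warning). Clustering is Ward
linkage on the leading PC scores — occurrences are clustered, not species
centroids, because species are observed to straddle clusters with split
memberships. When the cluster count is not given, the cut in 2–6 with the
largest relative inertia jump is used. A variable describes a cluster when
its cluster mean departs ≥ 15% of the |global mean| from the global mean
AND its cluster SD is ≤ 80% of the global SD; for variables whose global
mean is ≈ 0 the mean rule switches to an absolute criterion of 0.15 global
SD. A species gets a secondary cluster label when its second-largest
membership share is ≥ 0.25.

Niche summaries report median, quartiles, 5th/95th percentiles ("90% of
total variation" whiskers), min, and max per variable. The crop baseline
draws 1,000 cells with replacement, probability proportional to harvested
area.

## Expert concordance

Experts score each taxon 0–10 on the FPS scale (comparable and contextual
EPS). The report averages per taxon, maps the mean through the same FPS
category thresholds, and computes a linear agreement index
100·(1 − |meanEPS − FPS|/10). Published analyses of this kind have used a
multiple factor analysis over six per-expert evaluation variables; those
inputs are not available per expert, so the linear index is a clearly
labeled surrogate that preserves the 0 (disagreement) to 100 (agreement)
semantics. It is strictly decreasing in the absolute difference and
invariant to expert ordering (tested).

## Synthetic worlds

The generator emulates the study conditions rather than any particular
geography. Defaults: a 90 × 120 grid at 0.5° spanning 30°N–15°S (a
neotropical window at a desk-scale resolution; the method itself is
resolution-agnostic), ~70% land, 27 variables split 19 bioclim / 1
altitude / 7 edaphic, 10 countries, 8 ecosystem classes, 14 species slots,
and a germplasm share of 0.13 (the compiled real dataset held 749
germplasm of 5,614 records ≈ 13%).

* Layers are unit-variance Gaussian-filtered noise (σ = 8 cells);
  temperature-type bioclim variables add a −0.45 °C per degree |latitude|
  gradient, precipitation-type are lognormal, soil properties are built
  from five depth-slice fields (0–5, 5–15, 15–30, 30–60, 60–100 cm)
  combined by thickness weights (0.05, 0.10, 0.15, 0.30, 0.40) — the
  0–100 cm depth-weighted mean used for real soil data. Soil fields are
  generated directly at working resolution; the 30″ → 2.5′ resampling of
  real soil products is not emulated (its statistic is unspecified).
* Countries partition land by nearest seed cell; ecosystems are
  quantile-binned smooth fields (all classes present by construction);
  coast distance is a Euclidean distance transform in km; sea cells are
  nodata in every layer consistently.
* A virtual species has an explicit niche: suitability is the product of
  independent Gaussian responses over its niche variables, passed through
  a logistic occupancy curve centered on the (1 − prevalence) quantile of
  the raw response over native land (steepness 0.05 of the response
  spread). Exactly a `prevalence` share of native cells is suitable
  (≥ 0.5) by construction, and occupancy falls off sharply at range
  edges — the standard virtual-species design, and the property that
  makes thresholded-range recovery well-posed.
* Sampling draws presences proportional to suitability times a smooth
  multiplicative collection-bias field (roads/herbaria proxy; strength 0
  disables it), jitters coordinates within the cell, labels records G
  with probability `g_fraction`, then injects defects at configured
  per-record rates (defaults: exact duplicates 0.05, sea coordinates
  0.02, wrong country codes 0.02, missing coordinates 0.10). True
  injected counts are returned so the cleaning stage is checked against
  ground truth exactly.

What the generator does **not** emulate: the covariance structure of real
climate products, interspecific range coherence or phylogenetic
relatedness, georeferencing error gradients, and taxonomic misidentation.
Passing recovery tests therefore demonstrate that the pipeline's stages
compose correctly and recover known structure under realistic noise — not
that any real species' range or priority would be estimated with the
observed accuracy.

## Cleaning rules

Duplicates collapse on (taxon, record type, coordinates rounded to 10⁻⁴ °
≈ 11 m) — re-entered specimens merge, distinct nearby populations do not,
and G never collapses into H. Coordinate-free records collapse only on
identical provenance. Cross-checks remove records on sea cells, records
whose raster country contradicts the stated country (removal, not
correction — the manual re-evaluation loop of curated compilations is out
of scope), records outside the native country list, and records beyond a
species' coastal limit. Records without coordinates are kept (they count
toward SRS) but are unusable for modeling. Modeling points are unique
occupied cells snapped to cell centers, preventing pseudo-replication at
model resolution. The pipeline is idempotent and never invents records.

## Problem sizes and determinism

The analysis scripts and the reproduction script run 6 species × 200
records on the default 90 × 120 world — sizes chosen so the full chain
completes in well under a minute while every stage (including the ensemble
fallback and all four assessment statistics) is exercised; the package
itself has no built-in size limits. Every stochastic step takes an explicit
seed, and a fixed seed reproduces worlds, samples, folds, and draws
byte-identically (tested).

## Known limitations

* The logistic surrogate omits Maxent's hinge/threshold/product features;
  very sharp or interacting responses are smoothed.
* The subset selector inherits the loading-rule method's real weakness:
  when a species' niche variables do not align with the leading covariance
  axes of its presence environment, the subset model can miss them and
  inflate the range (the study context reports the same failure mode for
  its data-poor species; the ensemble fallback exists for exactly this
  reason).
* ERS counts distinct classes only; it ignores class areas and similarity
  between classes.
* The Bartlett test assumes approximate multivariate normality; on heavily
  skewed layers it is anticonservative, which is immaterial here since it
  gates nothing.
* Country zonal statistics attribute whole cells; border cells are not
  split by area.
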