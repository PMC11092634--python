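# Methods

This note documents the models, procedures and design choices behind
`paintbench`, in the spirit of the methods sections that accompany
statistical packages: what is computed, under what assumptions, with
which defaults, and what the synthetic validation does and does not
demonstrate.

## Scope and data model

The pipeline starts from CellProfiler-style single-cell feature tables
(one row per segmented cell; feature columns named
`Compartment_Group_Measurement_Channel` over the compartments Cells /
Cytoplasm / Nuclei and the Cell Painting stains DNA / RNA / ER / Mito /
AGP) plus a plate-metadata table assigning each well a chemical,
concentration (µM, 0 for vehicle), solvent (DMSO or water) and replicate
index. It ends with, per chemical: a per-feature benchmark-concentration
table, a signed morphological fingerprint, pairwise fingerprint-overlap
enrichment statistics, and optionally a comparison of benchmark
concentrations to population exposure-biomarker molarities.

## Preprocessing

Order of operations is fixed: feature QC → cytotoxicity flagging (on raw
cell counts) → robust normalization → variance-stabilizing transform →
per-well median aggregation → exclusion of cytotoxic doses.

* **Feature QC.** Features with no value in any cell are dropped first;
  Costes colocalization features are dropped wholesale (they are
  routinely missing in a majority of cells); only then are remaining
  incomplete cell rows removed. The order matters: a column that is
  mostly missing must not drag down its cells.
* **Cytotoxicity rule.** A (chemical, concentration) pair is cytotoxic
  when its mean well cell count is strictly below 25% of the mean of the
  matching vehicle wells on the same plate. The comparison uses raw,
  pre-normalization counts; chemicals spanning plates average plate-wise
  ratios with equal weights. Flagged doses are excluded from profiles and
  all downstream fingerprinting.
* **Robustize.** Per plate and per solvent, each feature is centered by
  the vehicle-well median and scaled by the vehicle-well MAD with the
  1.4826 normal-consistency factor (the R `mad()` convention). Features
  whose control MAD is zero on any plate are dropped globally with a
  warning — a per-plate drop would leave ragged feature sets across
  plates.
* **Generalized log.** `glog(x) = ln((x + sqrt(x² + c²))/2)` with offset
  `c = 1` on the normalized scale; monotone, defined for negative inputs,
  compressing large magnitudes of either sign. For large negative x the
  naive expression cancels catastrophically; the conjugate form
  `c²/(sqrt(x²+c²) − x)` is used there. The transform can be disabled
  (`glog_offset=None`).
* **Aggregation.** Per-well feature medians (median aggregation commutes
  with the monotone glog, which keeps the per-well profile insensitive to
  within-well outliers); the realized cell count is recorded per well.

## Dose-response modeling

For each chemical × feature, wells of the chemical plus the vehicle wells
of its solvent form a dose series (vehicle at dose 0).

* **Prefilter.** Classical one-way fixed-effects ANOVA across dose groups
  (unadjusted p < 0.05) combined with a mean-shift filter: the largest
  |dose-group mean − vehicle mean| on the normalized-transformed scale
  must reach 1.0, read as a 2-fold change on a log2-like scale. The rule
  is conjunctive. The fold-change reading is an interpretive choice
  surfaced in the configuration: morphological profiles are not
  expression ratios, so "2-fold" only has meaning through the transformed
  scale.
* **Mean families.** Hill `γ + ν dⁿ/(kⁿ + dⁿ)` (k > 0, 1 ≤ n ≤ 18),
  power `γ + β d^δ` (δ ≥ 1), and polynomials of degree 1 and 2 by default
  (degree 3 via configuration; degree is capped at distinct doses − 2).
* **Estimation.** Maximum likelihood under iid normal errors with
  constant variance; `AIC = 2(p+1) − 2 logL` with σ counted as a
  parameter. Linear-in-mean parameters are profiled out exactly by least
  squares, so the optimizer works in one (power: δ) or two (Hill: log k,
  n) nonlinear dimensions, multi-started from deterministic heuristics
  plus seeded jitter (8 starts, 250 iterations by default). Polynomial
  fits are closed-form. A grid-search oracle in
  `paintbench.experiments` verifies the optimizer reaches the global
  optimum on the screen's design. A modeled-variance option is left as a
  configuration stub; constant variance is the simplest defensible
  default for per-well profile data.
* **Benchmark concentration.** BMC is the smallest d > 0 with
  |μ(d) − μ(0)| = 1.349 σ̂, where σ̂ is the fitted residual SD of the
  selected model (the "standard deviation" benchmark-response
  convention; 1.349 SDs corresponds to a ~10% tail shift under
  normality). Hill and power invert in closed form; polynomials use
  safeguarded root-finding on [0, 10·d_max], taking the smallest positive
  crossing (the conservative choice for non-monotone quadratics). A Hill
  fit whose k falls below the lowest positive tested dose is flagged as
  an extrapolation risk but retained. Direction is the sign of
  μ(d_max) − μ(0), well-defined even for non-monotone fits.
* **BMCL.** One-sided 95% profile-likelihood lower bound: the smallest
  BMC′ ≤ BMC whose constrained maximum log-likelihood stays within
  χ²₁(0.90)/2 of the optimum. The BMR-defining parameter is substituted
  from the constraint (for Hill, ν; for power, β; for polynomials, β₁)
  so the constrained problem is unconstrained in the remaining mean
  parameters and log σ, solved by Nelder-Mead, with the bound located by
  bisection to 1e-3 relative tolerance. Because the BMR is σ-based, the
  profile in σ never degenerates for merely small noise — the
  BMCL-to-BMC gap reflects uncertainty in σ itself and collapses only
  for exactly interpolated data.
* **Model selection.** Within the polynomial family, ascending-degree
  likelihood-ratio tests (χ², df = parameter difference, cutoff 0.05)
  pick the lowest adequate degree; the surviving polynomial competes with
  Hill and power on lowest AIC. Ties (ΔAIC < 1e-6) break toward fewer
  parameters, then poly < power < Hill.

A finding worth recording: with the screen's four-point dose series plus
vehicle, Hill-vs-quadratic discrimination is weak even at 6 σ effect
sizes, because at most one dose group sits inside the sigmoid
transition — family selection there is roughly a coin flip weighted by
noise. With an eight-point half-log series the true family is selected
essentially always. BMC estimates are far less sensitive to the family
choice than the family label itself.

## Fingerprints, clustering, overlap

A chemical's fingerprint entry for a feature is +1/−1 (direction) when
the feature passed the prefilter, has a defined BMC, and the BMC does not
exceed the chemical's highest tested dose; otherwise 0. Rows null for
every chemical are pruned for display and clustering (agglomerative,
Euclidean distance on the signed entries, complete linkage by default;
Jaccard-on-support available). Accumulation curves sort in-range BMCs
ascending against their rank.

Overlap between two chemicals counts features significant in both (sign
ignored, per the convention that up- and down-regulated features are both
"significant"; a sign-aware mode exists) and scores enrichment by the
one-sided hypergeometric tail, overall and stratified by compartment
(a partition) and stain (overlapping strata: two-stain colocalization
features belong to both; stain-free shape features to none).

The enrichment universe deserves care. By default each stratum's universe
is its own row count. With very few chemicals, however, a pruned matrix
contains only features significant somewhere, which biases pairwise
overlap toward apparent depletion; `build_fingerprint(prune=False)`
keeps the full feature namespace and is what the validation experiments
use for two-chemical screens. With a large screened panel the two
universes nearly coincide. No multiplicity adjustment is applied by
default (raw p-values are reported); Benjamini-Hochberg is available.

## Exposure comparison and translocation scoring

Biomarker concentrations in µg/L (≡ ng/mL) or mg/L are converted to
mol/L with user-supplied molecular weights — no chemistry is embedded in
the package. Per chemical, the report gives the interval intersection of
the biomarker range with the within-range BMC range (BMCs converted from
µM) and the fraction of biomarker values at or above the minimum BMC.
Urinary creatinine adjustment and survey weighting are out of scope.

Nuclear translocation is scored as the per-well mean nuclear reporter
intensity; each dose group is compared to vehicle with a two-sided
Wilcoxon rank-sum test (exact enumeration for tie-free samples up to 12
per group, tie-corrected normal approximation otherwise). Wells, not
cells, are the statistical unit: cells within a well are correlated, and
a per-cell test (available behind a flag) is anti-conservative.

## Synthetic plate generator

The generator emulates the screen's design: 384-well plates, ~500 cells
seeded per well, 6 replicate wells per dose, four-point dose series
(0.025/0.25/2.5/25 µM for exposure-relevant "toxicant" chemicals,
0.01/0.1/1/10 µM for reference small molecules), DMSO or water vehicle
wells (24 per solvent per plate by default — imaging plates devote
generous real estate to controls, and at least 6 are required), and a
deterministic feature catalog spanning compartments × stains ×
measurement classes.

Per cell and feature:

    value = baseline(feature)            # log-uniform scale, 10^U(−1, 2)
          + plate_offset(plate, feature) # N(0, plate_shift_sd²), default 0.5
          + hill_shift(chemical, feature, dose)
          + well_effect(well, feature)   # N(0, noise_sd²), default 1
          + cell_scatter(cell, feature)  # N(0, cell_sd²), default 1

`noise_sd` is the replicate-level (well-to-well) residual SD: the scale
on which per-well profiles scatter around the dose-response curve, and
therefore the σ entering the planted true benchmark concentration
(closed form: the dose where the planted Hill shift equals
1.349 · noise_sd; undefined when the amplitude cannot reach it). The
replicate-level component is essential — with purely per-cell noise,
median aggregation over ~500 cells would shrink the well-level residual
SD by ~20×, and no benchmark concentration defined on the cell-level
noise scale could be recovered from well profiles. Real plates have
well-to-well variability from seeding, edge effects and handling, which
this component stands in for. `cell_sd` is within-well scatter that the
median absorbs; it inflates the control MAD, but since normalization
divides shift and noise by the same constant, BMC recovery is invariant
to it.

Realized well cell counts are Poisson around `cells_per_well ×
multiplier(chemical, dose)`; multipliers below 1 plant cytotoxicity
(truth flag at < 0.25, matching the downstream rule on expectation),
above 1 plant the low-dose proliferation some exposures show. An
optional missingness flag blanks a configurable fraction of
Costes-named features to exercise the QC path.

What the generator does **not** model: feature-feature correlation beyond
shared Hill shifts, heteroscedastic or heavy-tailed noise,
segmentation artifacts, spatial plate gradients (plate effects are
feature-wise constants), and dose-dependent changes in within-well
dispersion. Passing recovery tests therefore demonstrates correctness of
the estimation machinery under the stated noise model, not robustness to
every failure mode of real imaging data.

## Validation battery and problem sizes

`paintbench.experiments` (exercised by `tests/test_acceptance.py` and
`scripts/acceptance.py`) runs, with seeds:

* closed-form BMC identities and the polynomial root-finder vs the power
  closed form (30-observation series);
* Hill fits vs a 50³ grid-search likelihood oracle on 20 seeded series;
* the one-sided hypergeometric test vs exhaustive enumeration on all
  1819 valid tables with universe ≤ 12;
* parameter recovery at the screen's design (100 planted 3 σ Hill
  features with varying k and Hill power, 100 nulls, one plate);
* BMCL coverage over 200 power-model simulations;
* the 25% cytotoxicity boundary (24.75% excluded, 25.0% retained);
* end-to-end recovery of a 50-of-500 shared feature block between two
  chemicals plus null calibration over 1000 random fingerprint pairs;
* byte-identity of fixed-seed generation and 1e-12 round-trips of every
  writer/reader pair, including the three-header-row per-well matrix.

These sizes keep the full battery under ~2 minutes on one core while
leaving the statistical assertions comfortably powered.

## Known limitations

* The exponential model family of some benchmark-dose tools is not
  implemented; polynomial degree 3 is off by default.
* The fold-change prefilter on the glog scale is a convention, not a
  measurement of biological fold change.
* Stratified enrichment p-values are raw; the stratum-vs-global universe
  choice materially changes p-values for small screens (both modes are
  exposed).
* Whether urinary biomarker molarities should refer to metabolite or
  parent compound is left to the user-supplied table.
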