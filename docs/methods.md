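# Methods

## Problem and data model

The pipeline decides, per tumor, whether the immune profiles of its
sampled regions are mutually similar enough that any single region
represents the whole tumor. A tumor is sampled at five sites along its
long axis, T1 (centre) to T5 (periphery), under the working hypothesis
that a large tumor grows from the centre outward, so the largest
within-tumor contrast should lie on the centre–periphery axis. Each
region is described by nine features: the densities of CD4⁺, CD8⁺,
Foxp3⁺, CD20⁺, CD68⁺, LAMP3⁺, PD-1⁺ and PD-L1⁺ cells (IHC) and the TLS
count — or, on the RNA side, the matching marker-gene-set abundances at
T1/T3/T5.

## IHC quantification

Per section and marker, ten ×400 high-power fields (area 0.0788 mm²) each
report the positive cells among 100 assessed cells. Summaries:

* positive index = mean of 100·positives/assessed over fields (%);
* score: <1% → 0, 1–10% → 1, 10–50% → 2, >50% → 3. The verbal bins put
  10% and 50% in two bins at once; we adopt upper-inclusive boundaries
  ([0,1) → 0, [1,10] → 1, (10,50] → 2, (50,100] → 3), since ">50%" forces
  50 into score 2 and symmetry puts 10 into score 1. The edges are
  configurable.
* density = mean positives per field / field area (cells/mm²). Field
  counts for index and density are treated as the same observations; any
  number of fields ≥ 1 is accepted and the formulas use the actual count.

TLS are an input count per section; no image analysis is attempted.

## RNA abundance

Counts (featureCounts-style gene × sample) are normalized per sample to
CPM and transformed log2(x+1) by default (raw and linear-CPM modes
exist); each feature's abundance is the unweighted mean of its marker
genes' normalized values. The shipped gene map (CD4→CD4, CD8→CD8A/CD8B,
Foxp3→FOXP3, CD20→MS4A1, CD68→CD68, LAMP3→LAMP3, PD-1→PDCD1,
PD-L1→CD274, TLS→CCL19/CCL21/CXCL13) is a package default and fully
user-overridable; genes missing from a matrix are recorded in the result
provenance (strict mode errors instead). Pathway panels (antigen
presentation, adhesion, co-stimulation, …) reuse the same averaging.

## Similarity analysis

**Feature scale.** IHC densities enter as √density (TLS as √count).
Densities are scaled Poisson counts whose variance grows with the mean;
the square root is the classical variance-stabilizing transform, makes
counting noise approximately homoscedastic across markers that differ
50-fold in abundance, and — unlike log(x+c) — does not saturate at the
zero counts common for sparse markers (Foxp3, PD-L1). RNA abundances are
already log-scale and enter untransformed.

**Covariance.** One tumor (5 regions, 9 features) cannot support its own
covariance, so region-minus-centroid deviations are pooled across tumors:
Σ̂ = Σₜ DₜᵀDₜ / ν with ν = Σₜ(nₜ−1). Three refinements keep the estimate
honest:

1. *Diagonal shrinkage.* Σ̂_λ = (1−λ)Σ̂ + λ·diag(Σ̂), with λ the smallest
   value (bisection) whose condition number is below a bound (default
   10⁶); λ may be fixed. λ=1 is exactly diagonal.
2. *Jackknifed pooling.* A tumor's distances use the covariance pooled
   from the **other** tumors. A genuinely heterogeneous tumor otherwise
   inflates the very covariance it is judged against and masks itself —
   at the default 10-tumor scale its own deviations are 1/10 of the
   pooling weight at several times the variance, which in testing halved
   detection power.
3. *Reweighting.* Classification iterates (≤5 passes, fixed point):
   after each pass the pooling is restricted to tumors currently
   classified homogeneous, as in reweighted robust covariance estimation.
   Whenever a restriction would leave ν ≤ p degrees of freedom it is
   skipped.

**Distance and calibration.** d² = (x−x̄ₜ)ᵀ Σ̂_λ⁻¹ (x−x̄ₜ), solved by
Cholesky factorization (matches an explicit-inverse oracle to machine
precision). Two exact finite-sample corrections keep d² on the χ²(p)
scale that the critical value presumes:

* deviations from an estimated centroid of nₜ regions have covariance
  (1−1/nₜ)Σ, so d² is rescaled by nₜ/(nₜ−1) (not applied in oracle mode,
  when true centroids are supplied);
* with jackknifed pooling the deviation is independent of the Wishart
  covariance estimate, so d²(ν−p+1)/(νp) ~ F(p, ν−p+1) under
  homogeneity; distances are mapped through this F onto the χ²(p) scale
  (identity as ν→∞). Without it the χ² threshold is badly anti-
  conservative at 10-tumor covariance df (ν≈36).

**Classification.** Homogeneous ⇔ max regional distance ≤ critical value.
The default critical value is 22, the rounded upper-1% χ² quantile at
df=9 (21.67); `chi2:<alpha>` recomputes it for any feature count. The
"narrow distribution range" flag uses max−min ≤ critical/2 — an explicit
package convention, since no numeric definition of "narrow" exists in
the source analyses; it is configurable. The squared (not root) distance
is reported, because only the squared form is χ²-referenced.

**Driver attribution (LOMO).** For each feature, pooled covariance and
the tumor's distances are recomputed on the remaining features
(calibrated at df p−1). The attribution score is the reduction in the
tumor's maximum distance; drivers are the features whose removal flips
the tumor to homogeneous (or, for a homogeneous-but-wide tumor, narrows
its range), reported flips-first and ranked by score, ties broken by
panel order. If no single removal flips a heterogeneous tumor, a greedy
depth-2 search reports a flipping pair, and the tumor is flagged
irreducible ("highly heterogeneous").

## Cohort statistics

Mann–Whitney U: midrank ties; exact enumeration null when n₁+n₂ ≤ 12 and
tie-free, else normal approximation with tie and continuity correction;
two-sided. Spearman: Pearson correlation of midranks; exact permutation
p for n ≤ 8 (full enumeration), else t approximation with n−2 df. The
exact-test cutoffs are chosen for sub-second enumeration. The
association screen compares each feature across sex, multiplicity,
diagnosis, dedifferentiation type and an age median split (cutoff
configurable) and correlates against diameter and age; raw p-values are
reported unchanged with Benjamini–Hochberg q-values alongside.
TLS⁺/TLS⁻ and PD-L1⁺ (score ≥1) /PD-L1⁻ comparisons run at section level
by default (tumor level optional); an empty stratum yields a flagged
non-computable row. Modality concordance reports per-marker Spearman rho
across samples present in both feature matrices and a 2×2 tumor-level
agreement table of the homogeneity classifications; the two sources are
reported side by side, never merged.

## Synthetic cohort generator

The generator emulates the study conditions: 10 tumors × T1–T5 (defaults),
8 markers × 10 fields × 100 cells per section, field area 0.0788 mm²,
RNA at T1/T3/T5 plus one paratumor sample per tumor.

* **Densities.** log-normal hierarchy: per-marker baseline log densities
  (5–120 cells/mm², ordered CD4 > CD68 > PD-1 > CD20 > LAMP3 > CD8 >
  PD-L1 > Foxp3 to reflect a TIL-poor sarcoma with PD-1⁺ cells common and
  PD-L1⁺ cells rare), between-tumor SD 0.5, within-tumor (region)
  biological CV 15%, and signed clinical covariate effects on the log
  scale (diameter −0.03/cm, multiple −0.35, female +0.35, age +0.015/yr).
* **Heterogeneity.** A fraction of tumors (default 20%) receives, for 2
  randomly chosen driver markers (the reference tumors implicate 1–4; 2
  is a middle value), a mean-centred linear log-density ramp along
  T1→T5 whose extremes sit at ∓/± `driver_effect` pooled SDs from the
  tumor mean. The SD unit is the *total* within-tumor log SD, biological
  plus the delta-method Poisson counting contribution at the baseline
  density, so planted effects are calibrated against the noise the
  classifier actually sees.
* **Counts.** Field counts ~ Poisson(density × area), capped at assessed
  cells. TLS ~ Poisson with rate 1.1/section scaled by
  exp(0.8 × mean standardized CD4/CD8/CD68 deviation), coupling TLS to
  the infiltrate. Marker-gene counts are negative-binomial (dispersion
  0.1) around exp(3 + 1.0·log density + N(0, 0.25²)) times a log-normal
  library factor; paratumor samples sit at a −0.7 shifted baseline;
  filler genes are i.i.d.
* Identical configuration + seed ⇒ byte-identical outputs.

What the generator does **not** emulate: spatial structure beyond the
T1–T5 axis, inter-marker biological correlation beyond the shared
TLS/infiltrate factor, cellularity variation across fields, batch or
section-quality artifacts, and real marker-gene cross-talk. Passing
recovery tests therefore demonstrate internal consistency of the method
under its own noise model, not performance on real tissue.

## Operating characteristics (computed by the suite/script)

At the generator defaults, the default 10-tumor design classifies ~80% of
tumors homogeneous (averaged over seeds), consistent with the intended
~70–80% regime; detection at this small scale runs at roughly 0.7
recall / 0.95 specificity. On 100-tumor cohorts with 20% heterogeneous
tumors and 3-SD drivers, pooled recall and specificity are ≈0.9 and
top-1 driver identification ≈0.96. Oracle-mode calibration of the
distance is 1% ± Monte-Carlo error at the χ²₀.₉₉ point; the uncorrected
estimated-centroid variant is conservative (exceedance below nominal),
which is why the corrections above are on by default. RNA-side detection
at 3 regions/tumor is weaker than IHC (fewer within-tumor df and extra
sequencing noise); the two sources are reported side by side.

## Numerical and degenerate-input policy

Covariance must be positive definite after shrinkage (eigenvalue check);
a zero-variance feature is an error naming the feature. Singularity at
λ=0 raises with advice to shrink. Distances are never computed through an
explicit inverse. Empty field lists, empty groups, constant vectors for
correlation, unknown regions/markers/samples and unmatched ids raise
errors naming the offending item; an empty stratum in the TLS comparison
is flagged rather than raised. Problem sizes in the validation
experiments (3×100-tumor recovery cohorts, 10⁴ calibration regions, 10³
null tests, 10⁵ binning checks) were chosen as the package's own
desk-scale defaults and are parameters of the evaluation functions.
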