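# Methods

This note documents the models and procedures implemented in `toxprio`,
the choices made where the problem left the design open, and what the
synthetic-data experiments do and do not demonstrate.

## Problem setting

The quantity of interest is the acute fish toxicity of an organic
chemical, summarised as the 96 h LC50 (the concentration lethal to half
of test fathead minnows), worked with throughout on the log₁₀(mg/L)
scale. For prioritization and regulatory labelling the continuous LC50
is ultimately mapped to an ordered hazard category, so the package
treats two estimation strategies as first-class competitors:

1. **Two-step**: regress log₁₀ LC50 on molecular descriptors, then
   threshold the prediction into a category.
2. **Direct classification**: predict the category itself from the
   descriptors.

The two-step route inherits the regression error at the category
boundaries; the direct route learns only the boundary. Both use random
forests, which handle the nonlinearity and non-continuity typical of
descriptor–toxicity relationships and need little tuning beyond forest
size and leaf granularity.

## Descriptor curation

Descriptor-calculation software can fail to converge, producing values
that differ between repeated runs on identical structures, and produces
columns on wildly different scales. The curation cascade applies, in
order, with each removal attributed to the first filter that triggers:

1. **Missing-value screen** — columns with > 10% missing cells are
   dropped; remaining missing cells are imputed with the training-column
   median. (Median imputation is deterministic and conservative; the
   choice matters little because heavily missing columns are gone.)
2. **Replicate stability** — a descriptor is unstable if, for any
   chemical, its spread across the three replicate calculations exceeds
   `rel_tol` (default 1e−6) relative to the largest absolute replicate
   value (`abs_tol = 1e−9` where that value is 0). The tolerance is not
   standardised anywhere; 1e−6 separates numerical jitter from genuine
   non-convergence by about two orders of magnitude in practice.
3. **Scaling** — each column is divided by its **maximum absolute**
   training-set value, so negative-valued descriptors map into [−1, 1]
   rather than flipping sign under a plain-maximum convention; constant
   zero columns cannot be scaled and are removed here. Application-set
   columns are scaled with the *training* factors.
4. **Variance filter** — columns with scaled sample variance
   (n−1 denominator) strictly below 0.1 are kept. Keeping *low*-variance
   columns is the opposite of common low-variance pruning; because the
   convention is debatable, the direction is exposed as a configuration
   switch (`variance_direction = keep_below | keep_above`) with
   `keep_below` as the default behaviour.
5. **Ratio filter** — a descriptor is removed from both sets when its
   application-set maximum absolute value exceeds 100× the training
   factor (a zero training factor with any nonzero application value also
   removes it); such columns indicate instability of the calculation on
   the application chemicals, which ship no replicates.

The cascade is idempotent — curating an already-curated pair is a
no-op — and the curated training and application tables always share an
identical, identically ordered descriptor set. PCA (mean-centred, full
SVD) provides a two-component projection for chemical-space coverage
plots.

## Toxicity categories

**GHS schema.** Fixed thresholds for short-term aquatic hazard:
acute 1 for LC50 ≤ 1 mg/L, acute 2 for 1 < LC50 ≤ 10 mg/L, acute 3
above. Boundaries are inclusive on the more-toxic side.

**Bootstrapped k-means schema.** Chemicals are clustered on the pair
(log₁₀ LC50 in mg/L, monoisotopic mass in Da). Choices:

- LC50 enters on the log scale (raw mg/L spans six orders of magnitude
  and would collapse the axis); mass enters in Da.
- Both features are z-scored with the training split's mean and sample
  SD before clustering — Euclidean k-means is meaningless when one axis
  is in hundreds of Da and the other in log units.
- The data are split 90/10; k-means (k-means++ seeding, 25 restarts,
  tolerance 1e−6, max 300 iterations) is refit on 500 bootstrap
  resamples of the training split. Each iteration's centroids are
  aligned by sorting on the log-LC50 coordinate (ties by mass), rounded
  to 2 decimals in standardized units, and the most frequent rounded set
  wins (ties to the earliest iteration); the reported centroids are the
  mean of the winning class's unrounded members.
- `holdout_agreement` is the fraction of held-out points assigned
  identically by the modal centroids and by a single k-means fit on the
  full training split. It measures the stability of the bootstrap
  consensus, not agreement with any external labelling.
- Labels are ordered most-toxic-first: the centroid with the lowest
  log-LC50 coordinate is "high toxicity". Assignment ties go to the
  lower (more toxic) centroid index.

## Modeling

Random forests with √p candidate features per split and bootstrap
sampling. The tuning grid covers number of trees × minimum samples per
leaf: regression defaults to 10 log-spaced tree counts in 100–1000 and
leaf sizes 1–21 (step 2); classification to 20 linear steps over
200–2000 trees and 20 steps over leaf sizes 1–21. Model selection
maximises the mean 3-fold CV score (R² / accuracy; classification folds
are stratified), with ties broken toward fewer trees and then larger
leaves (parsimony). CV summaries report both the median and mean across
folds.

Variable importance is **out-of-bag permutation importance**: for every
tree, its out-of-bag rows are scored before and after permuting one
column, and the mean score drop (clipped at zero) is the column's
importance. Impurity-decrease importance is available by configuration
(`importance = impurity`); permutation is the default because impurity
importance inflates high-cardinality/continuous columns. Variables whose
importance exceeds 1% of the largest one (strict) are selected, and the
final model is refit on the **full** data set restricted to them. How
many survive the 1% rule is an outcome of the data, not a target.

Two-step categorization composes the regressor with a schema: GHS
thresholds applied to 10^(predicted log LC50), or nearest k-means
centroid for (predicted log LC50, monoisotopic mass). Monoisotopic mass
is never used as a predictor column unless it is itself among the
descriptors.

## Applicability domain

The leverage of a query vector x against the training matrix X
(restricted to a named descriptor subset, scaled with the training
factors) is h = xᵀ(XᵀX)⁻x. A chemical is in-domain when h ≤ h*, with
h* = 3p/n capped at 1 — the conventional warning leverage of Williams
plots; no alternative threshold presented itself, and it is
configurable. For p ≥ n (the full curated space) XᵀX is singular and a
Moore–Penrose generalized inverse with singular-value cutoff
(rcond = 1e−10) is used; reports carry a `rank_deficient` flag because
leverage in that regime measures distance within the training rows' span
only — components of a query orthogonal to that span contribute nothing,
so in/out decisions in the p ≫ n regime are optimistic and should be
read together with the model-subset ADs. Cross-subset comparison reports
in/out counts per subset and the pairwise fraction of chemicals with
identical flags.

## Synthetic-data generator

The generator emulates the *structure* of real descriptor/LC50 data,
not its chemistry:

- **Descriptors**: n_latent standard-normal latent factors; each of the
  p descriptors loads on one factor (loading magnitude 0.5–1.5, random
  sign) plus idiosyncratic noise, giving the correlated blocks that make
  variable selection meaningful. Eight designated "signal" descriptors
  are tight proxies (noise SD 0.05) of eight distinct latents.
- **Response weights** decay geometrically (1, ½, ¼, ⅛ per group):
  descriptor importance in real QSAR models is strongly skewed, and
  axis-aligned trees cannot learn a dense equal-weight linear score.
- **Smooth response**: a sum of ridge functions (linear + tanh) of the
  signal descriptors, affinely rescaled to span −3…+5 log(mg/L), plus
  Gaussian noise (default SD 0.3 log units, the order of interlaboratory
  LC50 variability).
- **Discontinuous response**: four signal descriptors form a latent
  score that is cut at configurable quantiles (default equal thirds)
  into categories with category-specific mean log LC50 (−1.5, 0.5, 2.5 —
  one per GHS bin); the other four drive a smooth within-category spread
  (default amplitude 1.2 log units, about one GHS bin width) so the
  generated LC50s fill the hazard bins continuously the way measured
  data do. Without the spread term the regression task degenerates to
  predicting three constants and the two-step route is artificially
  immune to thresholding error; with it, chemicals genuinely sit near
  the category boundaries.
- **Masses** uniform in 50–1000 Da; **replicates** 2 and 3 equal
  replicate 1 up to ~1e−8 relative jitter except a configurable fraction
  of deliberately unstable columns (rescaled ×1.5 / ×0.7); the
  **application set** is half in-distribution, half displaced by
  `shift_sd` latent SDs along a fixed random direction.

All outputs are pure functions of the configuration, including its seed
(loading structure and draws use separate child seeds, so the
application set is reproducible whether or not the training set was
generated first).

**What passing tests on this generator show — and what they do not.**
They show that the algorithms behave as specified under controlled
conditions: filters remove exactly the planted defects, the categorizer
recovers separated mixture components, direct classification beats
two-step categorization when the descriptor→toxicity map is
discontinuous, and shifted chemicals are flagged out-of-domain. They do
not validate predictive accuracy on real chemicals: the generator has no
descriptor semantics (no logP, no fingerprints), Gaussian rather than
heavy-tailed noise, and a far simpler correlation structure than a real
descriptor matrix.

## Problem sizes and numerical choices

The built-in experiments run at desk scale by design: the
direct-vs-two-step benchmark uses 800 chemicals × 100 descriptors over
20 seeds at matched forest budgets (400 trees, leaf 4); blob recovery
uses 400 points and 500 bootstrap refits; the pipeline-reproducibility
check uses 80 × 16 with single-cell grids. Degenerate inputs are handled
explicitly: bootstrap resamples with fewer distinct points than k are
skipped; zero-variance features standardize with SD 1; leverage values
are clipped at 0 against rounding; all tie-breaks (modal-set selection,
grid cells, centroid assignment) are deterministic and documented above.

## Known limitations

- The variance filter's printed direction (`keep_below`) is unusual;
  users with conventional low-variance pruning in mind must flip the
  switch.
- Leverage-based AD in the p ≫ n regime is optimistic (see above).
- `holdout_agreement` is an internal-stability metric, not a clustering
  accuracy against ground truth.
- No chronic-toxicity categories, M-factors, probability calibration, or
  learners beyond random forests.
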