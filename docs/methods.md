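# Methods

`vtcwm` re-implements, as a tested pipeline over synthetic cohorts, a family
of analyses of the white-matter connectivity of category-selective regions in
ventral temporal cortex (VTC): sub-bundle extraction from tractograms,
endpoint-density connectivity profiles over a cortical parcellation,
classification of cytoarchitecture / category / age from those profiles,
eccentricity-band connection counts in early visual cortex (EVC), and
developmental slope and slope-similarity analyses. This note records the
models, the synthetic data they are exercised on, the numerical choices, and
the known limitations.

## The synthetic cohort

Real infant/adult dMRI is not part of this package; every analysis runs on a
generator whose defaults emulate the study conditions the analyses assume.

**Sessions.** 88 sessions in four age groups — 23 newborn (ages drawn from
N(28.6, 10.2) days), 23 three-month (N(106.9, 19.3)), 21 six-month
(N(189.0, 15.8)), 21 adult (N(28.21, 5.51) **years**, converted to days at
365.25 d/y) — clipped into disjoint group bins (<60, 60–150, 150–250,
>6000 days) so longitudinal ages are strictly increasing. 21 infants are
longitudinal: a deterministic layout of 4 three-session and 17 two-session
subjects solves the group-count equations exactly while every group retains
at least one cross-sectional subject. Simulated outlier-volume fractions are
drawn from the post-QC distributions (infants 0.45% ± 0.43%, adults
0.29% ± 0.10%, clipped to [0, 0.05]), so the default cohort passes the >5%
session-exclusion filter intact; the filter itself retains
`outlier_fraction <= threshold` (strictly-greater excludes).

**Surface.** Two planar hemisphere "sheets", each tiled with 180 parcels
(3x3-vertex patches, 2 mm vertex spacing, 10 mm parcel pitch, unit normals).
Parcel ordinals 0–10 are flagged as seed-region exclusions (169 usable per
hemisphere); retained ordinals 11–13 carry the three EVC eccentricity-band
labels (0–5°, 5–10°, 10–20°); the ten fROIs (word-selective ones left-only)
each own one excluded parcel, so fROI vertex sets are pairwise disjoint and
parcels are farther apart (6 mm gaps) than the 3 mm search radius plus the
0.9 mm endpoint jitter — endpoint-to-parcel assignment is therefore exact.

**Planted structure.** For each (cytoarchitecture, category) pair the
generator draws a mean endpoint distribution over the 169 retained parcels:
a Dirichlet(0.5) base profile per cytoarchitectonic area mixed with a
category-specific Dirichlet perturbation at weight `category_scale = 0.10`;
a fixed `evc_mass = 0.2` of each profile sits on the three band parcels,
split by per-area band proportions (FG2 63.57 / 9.85 / 26.58%, FG3
26.58 / 29.42 / 44.00%, FG4 43.97 / 28.03 / 28.00% — central-5° means from
the adult/infant literature the generator emulates). Developmental change is
a per-fROI slope vector (density per log10-day): a shared within-area
direction (weight 0.85) plus an fROI-specific component, scaled per parcel
by the parcel's own mass (`age_scale = 0.06`), iteratively demeaned and
clipped so that the adjusted vector stays on the simplex **without clipping**
across the whole cohort age range — per-parcel densities are then exactly
linear in log10(age), which makes recovery tests exact. The default scales
were chosen once so that the generated means separate in the order
cytoarchitecture (~0.11 L2) > category (~0.015) > age (~0.008) and the
classifier reproduces the qualitative accuracy ordering; they are study
conditions, not tuning knobs.

**Tractograms.** Each streamline is a jittered 3-point polyline: one
terminal uniformly on the seed fROI patch, the other on a vertex of a
retained parcel drawn from the session-adjusted multinomial (2000
streamlines per fROI-session by default; the midpoint dips below the sheet
to mimic a white-matter arc, though only terminals matter downstream).
Because the seed terminal always lies in an excluded parcel, the retained
profile equals exactly one half of the planted target distribution — the
"looping-fiber" mass removed by parcel exclusion is exactly 0.5. Recovery
tests use this arithmetic (truth = planted/2) rather than a fitted constant,
and statistical recovery suites may draw parcel counts directly from the
same multinomial (`sample_parcel_counts`) — the identical sampling law
without the geometry, which keeps 100-replicate suites at desk scale.

**What the generator does not emulate:** folded cortical geometry, curved
streamline trajectories, partial-volume and registration error, spatially
correlated endpoint noise, subject-level profile idiosyncrasies, and
real-data class overlap. Passing recovery tests therefore show that the
*estimators* are correct and calibrated under the planted model, not that
the scientific findings would replicate on real tractography.

## Geometry and profiles

Track files use the standard MRtrix layout (text header terminated by `END`,
float32 triplets, NaN separators, Inf terminator); the reader validates the
header fields and the triplet stream and names the offending field on
failure. Sub-bundle extraction selects a streamline iff either **terminal**
point lies within `radius_mm` (default 3.0, inclusive) of any ROI point —
interior points never count, matching the endpoint-density goal. Endpoint
density assigns each terminal to its nearest mesh vertex (exact ties to the
lower index; endpoints farther than 3 mm from every vertex are dropped from
numerator and denominator) and normalizes to sum 1. Parcel aggregation sums
vertex densities into retained same-hemisphere parcels *after* whole-surface
normalization; by default the retained vector is not renormalized (a
`renormalize` flag exposes the alternative), so profile mass outside the
seed region is preserved as-is. Surface areas use the barycentric
one-third-of-adjacent-triangles vertex-area convention.

## Classification

PCA is column-mean-centered SVD without variance scaling; component count is
the elbow of the variance-explained curve (maximum perpendicular distance to
the line joining its first and last points, ties to the smaller index), or a
user-fixed K. PCA is fitted once on the full matrix before the
cross-validation loop — the procedure being replicated does the same — and a
leakage-free per-fold refit sits behind `refit_pca_per_fold`. The classifier
is multinomial logistic regression (scikit-learn L-BFGS) with a small ridge
(`1e-6`, i.e. C = 5e5) so that the optimum stays finite on separable
clusters; winner-take-all takes the argmax of the softmax, ties resolving to
the first class in the fixed canonical label orders. Cross-validation leaves
out **subjects** (all sessions of one subject together); correctness is
averaged into one accuracy per session — hence t-tests against chance have
df = sessions − 1 = 87 — and chance is 1/#classes (3 or 4). The balanced
variant resamples the training set with replacement to 200 rows per label.

On the default synthetic cohort the auto elbow lands at ~3 components
(the planted structure is low-rank and the multinomial noise floor is low),
which is enough for cytoarchitecture (100%) and category (~90%) but leaves
almost no age signal; age-group accuracy can then fall below chance through
leave-one-out's anti-correlated-error pathology. The qualitative ordering
cytoarchitecture > category > age is robust across seeds; the individual
age number is not a stable quantity of the synthetic conditions.

## Eccentricity bands

A streamline counts toward a band when one terminal is within 3 mm of the
fROI and the other within 3 mm of a band vertex; it is assigned to the band
of that endpoint's nearest band vertex (equidistant bands resolve to the
lowest band). Percentages are out of EVC-connected streamlines only. The
factorial model (central-5° percentage ~ cytoarchitecture x category x age
group) is OLS with treatment coding and sequential (type-I) sums of squares
in the listed order; aliased columns are dropped first-come-kept, which is
what fixes the df pattern (2, 2, 3, 1, 6, 6, 3; residual 504 on the
left-hemisphere 6 fROI x 88 session design): the place category is
confounded with FG3, so the category main effect keeps 2 df and the
two-way interaction 1. Post-hoc within-area comparisons are session-matched
paired t-tests, Bonferroni-multiplied by the number of pairs.

The development post-hoc is a random-intercept model
`value ~ log10(age_days) + (1 | subject)` fitted by REML with the variance
ratio profiled on a closed-form 1-D criterion (block-diagonal V = I + λJ per
subject); a boundary optimum collapses to OLS with a flag. The fixed-slope
df is a Satterthwaite approximation from the numeric curvature of the
restricted likelihood. Fitted slopes and SEs agree with statsmodels MixedLM
to ~3 decimals. Limitation: with 42 of 63 subjects contributing a single
session, the plug-in REML interval covers a planted slope ~93.5% of the
time rather than 95% — the familiar small-sample downward bias of plug-in
fixed-effect SEs; a delta-method (Kackar–Harville-type) correction was
evaluated and found numerically negligible for this design, so the plain
Satterthwaite interval is reported.

## Development

Per-parcel developmental slopes are independent simple regressions of
density on log10(age in days) (positive slope = increasing connectivity).
The global test regresses long-form density on parcel, age, and age x parcel
(no subject random intercept: normalized densities sum to a constant per
profile, which makes a shared intercept unidentifiable). Limitation: parcel
variances under multinomial noise span orders of magnitude, and the pooled
homoscedastic interaction F is anticonservative on such data (~12% rejection
at nominal 1% in zero-slope simulations); the per-parcel t-tests are
calibrated, and the null-calibration suite checks the pooled F on
homoscedastic reduced-scale nulls where its nominal level is exact.

Slope similarity: for each of 1000 iterations, 66 of 88 profiles (75%,
drawn **without** replacement — resampling with replacement is the balanced
classifier's procedure, not this one) are used to refit all 169 slopes per
fROI; iterations are paired across fROIs (the same session subsample for
every fROI) so that per-iteration correlations compare like with like, with
an unpaired mode behind a flag. Pearson correlations (the Fisher transform
presupposes them; Spearman behind a flag) are Fisher-z transformed (|r|
clipped at 1 − 1e-12) and regressed on same-category and
same-cytoarchitecture indicators. Limitation: the 15,000 pair-iteration
rows are not independent (each pair contributes 1000 correlated rows), so
the row-level t-statistics are anticonservative; the package reports the
row-level model for fidelity, and calibration claims are evaluated on
pair-level mean z (15 pairs).

## Numerical conventions

Single RNG per operation, seeded explicitly; per-stage seeds derive from one
run seed. All tie-breaks are deterministic (lowest index / first canonical
label). OLS is rank-revealing with first-come-kept aliasing (modified
Gram–Schmidt, relative tolerance 1e-9·sqrt(max(n, p))); numerically exact
fits are snapped so round-off cannot manufacture t-statistics. p-values are
two-sided; CIs are estimate ± t_crit(df)·SE; Cohen's d = (mean −
chance)/SD. Simulation suites use 300–1500 replicates where a 100-replicate
binomial would be too coarse to distinguish nominal from broken coverage.

## Problem sizes

Default end-to-end scale: 88 sessions x 10 fROIs x 2000 streamlines
(1.76 M streamlines per cohort, generated and consumed one session at a
time), 880 x 169 profile matrix, 1000 bootstrap iterations, 500-replicate
null-calibration batches. A full pipeline run completes in about 90 seconds
on one CPU.
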