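# Methods

`cortmorph` implements a multi-site analysis of parcellated cortical
morphometry for the contrast between Parkinson's patients with visual
hallucinations (VH) and without (noVH): empirical-Bayes site
harmonisation, covariate-adjusted group-difference mapping, receptor
binding-potential associations with spatial-permutation inference,
correlation-matrix PCA, and structural covariance graph analysis. Since
multi-site clinical scans cannot be redistributed, every stage is
validated on synthetic cohorts with planted ground truth; this note
records the models, the parameters that matter, and the choices made
where the design was open.

## Synthetic cohorts (`synthio`)

The generative model per subject *j*, region *r* is

    y_jr = b_r + x_j' beta_r + delta_r 1[VH_j] + (L_g f_j)_r
           + gamma_sr + lambda_s eps_jr,

with region baselines `b_r ~ U(2.2, 2.9)` mm (thickness-like), additive
site shifts `gamma_sr`, multiplicative site scales `lambda_s`,
standardised covariates (age ~ N(66, 8.5²) years truncated to [40, 90];
TIV ~ N(1.45·10⁶, (1.5·10⁵)²) mm³; gender Bernoulli(0.4 female)) with
region-specific slopes, group-specific latent-factor loadings `L_g`
inducing inter-regional covariance, and idiosyncratic noise `eps ~ N(0,
sigma_r²)`. The default study condition is 3 sites × 2 groups with 200
subjects in total, site shifts of 1 noise-SD, site scales lognormal(0,
0.2), and thinning of 0.3 × (total residual SD) planted in 20 regions
(negative `delta`, i.e. lower thickness in VH).

Latent structure is specified as a *target residual correlation matrix*
(community blocks at r = 0.22 across four modules, plus an optional hub)
and converted to loadings by an eigen square root, with each region's
variance split between the latent part and noise (noise share 0.5 by
default). This gives exact control of the implied covariance the
recovery tests compare against. The planted hub sits inside one
community (r = 0.22 to its members) and is the sole strong bridge
(r = 0.30–0.32) to one spoke per other community; a free-standing star
hub is impossible at useful strengths because a unit-variance region's
squared correlations must sum below its communality.

Clinical scores use plausible ranges (MMSE 24–30, UPDRS-III ~N(25, 11²),
LED ~N(550, 250²) mg, onset ~N(5, 3²) years). The NPI hallucination
subscale (frequency × severity) has no published distribution; the
generator uses a zero-inflated discrete distribution on
{0,1,2,3,4,6,8,9,12} for VH patients and 0 for noVH — an assumption, not
an estimate. Optional missingness is limited to UPDRS-III, mirroring the
analysis that imputes it.

Atlases are Fibonacci lattices per half-sphere, mirrored across the
midline, so mirror pairing is exact and spin permutations are always
defined. Real parcellations have irregular parcel sizes and a medial
wall; none of that is emulated, so passing tests demonstrate correctness
of the statistics, not robustness to anatomical irregularities.

Receptor-like maps are Gaussian-kernel mixtures of white noise on the
centroids (angular scale in degrees). When a target correlation rho is
requested, the component orthogonal to the target is rescaled in closed
form so the *sample* correlation equals rho exactly.

## Harmonisation (`harmonize`)

Parametric location–scale empirical-Bayes adjustment (the ComBat model):
standardise per region by the fitted grand mean + covariate effects and
pooled residual SD, estimate per-site location (`gamma`) and scale
(`delta²`) on the standardised residuals, shrink via a normal prior on
location and an inverse-gamma prior on scale (hyperparameters by method
of moments per site), and iterate the coupled posterior means to an
absolute tolerance of 1e-6 (max 200 iterations, warning on
non-convergence). Adjusted values restore the protected covariate
contribution. Default protected covariates: group, age, gender, TIV —
protecting the contrast of interest. There is no reference-batch mode;
the pooled mean is the target, matching the reference implementations'
default (the implementation agrees with Bioconductor `sva::ComBat` to
~1e-6 on a test cohort). `empirical_bayes=False` disables shrinkage,
which makes the two-site pure-shift case exactly mean-equalising. Each
morphometric kind (thickness, area, volume) is harmonised separately.
TIV is metadata and is never itself harmonised.

## Group statistics (`groupstats`)

Screening is a per-region ANCOVA F-test for group (covariates: age,
gender, TIV by default), vectorised over regions via shared QR
projections, with Benjamini–Hochberg FDR at q = 0.05 over all
non-degenerate regions of one morphometric kind (148/148/21 for
thickness/area/volumes; never pooled across kinds). Constant regions are
reported with p = NaN and excluded from the family. Flagged regions
enter a MANCOVA — Pillai's trace by default because it is the most
robust of the classical statistics to covariance heterogeneity (the
source analyses do not name their statistic); Wilks' lambda is available.
With one dependent variable the multivariate table is computed by
term-deletion F-tests and reduces exactly to the univariate ANCOVA.
Pairwise group contrasts are Bonferroni-corrected over the number of
regions entered. Effect sizes are partial eta²: reported covariate
effects (e.g. several eta² of 0.3–0.65 in one model) exceed what
non-partial eta² could jointly allow.

Difference maps are unadjusted VH − noVH means with pooled-variance SE;
planted thinning therefore yields negative values for thickness.
Sensitivity utilities: Tukey fences (1.5·IQR, quartiles by linear
interpolation of order statistics — the convention matters only in tiny
samples), pooled-sample mean imputation by default (per-group mode
available), residual-based partial correlations (t reference with
df = n − 2 − k), DerSimonian–Laird random-effects pooling
(cross-checked against `statsmodels.combine_effects`), leave-one-study-
out screening with Jaccard overlap against the full-sample flags, and
demographic comparisons (one-way ANOVA; chi-square without continuity
correction by default; Brown–Forsythe median-centred Levene test).

## Receptor associations (`receptormap`)

For each receptor map, three simple OLS fits of the difference map on
binding potential mirror the study design: significant regions, all
regions, non-significant regions. The standardized slope equals the
Pearson correlation in this simple regression. Cook's distance > 1 marks
influential regions; the headline fit excludes them (both fits are
reported). CIs are percentile bootstrap over regions, 10,000 resamples
by default, seeded. Slopes of two receptors are compared by a stacked
interaction test on per-map standardized predictors.

Spatial inference uses rotation permutations: per spin a Haar-uniform
rotation (QR of a Gaussian matrix, determinant +1) is applied to
left-hemisphere centroids and its x-mirrored counterpart to the right;
regions are reassigned to the nearest original centroid within each
hemisphere by greedy smallest-distance-first matching (ties to the
lowest index). The two-sided p is `(1 + #{|r_null| >= |r_obs|}) /
(1 + n_spins)`; the default is 10,000 spins, and the test suites use
1,000 for desk-scale runtime. A known property of this family of nulls
is that reassignment degrades map smoothness, making the test
anticonservative for very smooth fields: measured type-I error at
alpha = 0.05 is ~0.05–0.06 at a 5° angular scale but ~0.11 at 10–30°
(optimal Hungarian matching was evaluated and is no better, so the
greedy standard form is kept). The calibration suite therefore runs at a
5° scale; results on smoother maps should be read as approximate.

## PCA (`pcadim`)

PCA of the region-by-region *correlation* matrix (regions share a scale
but not a variance; standardisation also matches the common toolchain
default). Eigenvalues sum to the number of regions; the Kaiser rule
(eigenvalue > 1) selects retained dimensions; contributions are
100·v²_ik and squared cosines l²_ik (summing to 1 per region over all
components). The sign convention makes each component's largest-|loading|
entry positive so loadings are reproducible. Input defaults to
harmonised subject-level values of the flagged thickness regions;
a covariate-residualised mode is available since the source is silent on
which was used.

## Covariance networks (`covnet`)

Residuals from per-region OLS on age and gender (full sample, Levene
homogeneity check reported as a warning) are correlated within each
group (68-region parcellation by default). Edges are compared with the
Fisher z test for two independent correlations — the groups are
independent samples, and this is the standard default for that case —
two-sided, BH-FDR over all unordered pairs; |r| = 1 is clamped to
1 − 1e-12 with a warning. The |delta r²| > 0.3 rule is a display filter
only. Binary graphs keep the k = round(d·R(R−1)/2) most positive
correlations (round-half-even; ties by lexicographic pair order;
negative correlations never enter) over the sweep d = 0.05…0.20 in 0.01
steps (16 densities).

Node metrics: degree; betweenness centrality (unnormalised counts with
fractional attribution over equal-length shortest paths — the hub rule
depends only on within-density ranking, which is convention-invariant);
nodal efficiency (mean inverse shortest-path length, disconnected pairs
contributing 0); local efficiency (global efficiency of the
neighbour-induced subgraph — the classic definition; nodal and local
efficiency are computed and labelled separately because the prose term
"local efficiency" is ambiguous between them). Hubs: betweenness above
mean + 1 SD at a density, at ≥ ceil(n_densities/2) of the densities
(8 of 16 in the default sweep).

Communities are found by a Louvain implementation authored here
(two-phase local moves + aggregation, seeded restarts keeping the
maximum Newman–Girvan modularity, sweep count bounded so floating-point
gain oscillations terminate, deterministic tie-breaks, labels
canonicalised by descending community size). It matches exhaustive
partition search exactly on random graphs of ≤ 10 nodes. Default 100
restarts.

Inference: group-label permutation tests rebuild covariance → threshold
→ metric per shuffle (metrics are functionals of group-level matrices,
so nothing short of a full rebuild is valid); per-density mode with
BH-FDR over nodes × densities is the default, an averaged-over-densities
mode exists. 5,000 cycles is the reference setting; suites use 120–1,000.
Modularity is bootstrapped within group (resample subjects, rebuild,
threshold at d = 0.13, Louvain Q; percentile CI). Graph-metric
differences are related to morphometric difference maps by Pearson
correlation with BH correction across metric families and an OLS with a
percentile bootstrap CI.

## Pipeline (`pipeline`, CLI `cortmorph`)

One global seed fans out to named per-stage seeds through
`numpy.random.SeedSequence` in a fixed order, so each stage is
independently reproducible and two runs from the same config produce
byte-identical `report.json` files. Stage runtimes go to the log only —
embedding them would break report determinism — and the output directory
is likewise excluded from the embedded config. Configs are YAML with
explicit validation errors naming unknown keys, missing columns and
unknown regions. The synthetic default uses a 148-region atlas for the
group/receptor/PCA stages and a 68-region atlas for the covariance
stage, mirroring the two parcellation granularities of the study design.

## Problem sizes in the shipped suites

The test and acceptance suites run at desk scale, chosen as the package's
own study conditions: 10 harmonisation seeds (200 subjects each), 20
screening seeds (400/group), 500 spin null datasets × 1,000 spins and
100 power seeds, 2,000 edge-calibration simulations (n = 100/group,
8 regions), 200 brute-force oracle graphs (≤ 7 nodes) and 30–50
exhaustive-modularity graphs (≤ 10 nodes), 50 hub-recovery seeds
(200/group), 500 bootstrap-coverage regressions (200 points, 1,000
resamples), 50 PCA-recovery seeds, and a reduced end-to-end pipeline for
the determinism check.

## Known limitations

- The spin null's anticonservativeness at large smoothing scales (above).
- Synthetic atlases are geometrically idealised; parcel-size and
  medial-wall effects on the spin test are not modelled.
- Percentile bootstrap CIs undercover slightly in small samples
  (measured ~0.91 at 68 points, ~0.95 at 200); BCa intervals are not
  implemented.
- Harmonisation assumes the location–scale model; batch-by-covariate
  interactions and longitudinal structure are out of scope.
- Ordinal models for graded hallucination severity and hippocampal
  subfield analyses are out of scope.
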