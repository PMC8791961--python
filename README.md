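# cortmorph

Statistical tooling for multi-site cortical morphometry case–control
studies, built around the analysis of visual hallucinations (VH) in
Parkinson's disease: pooling parcellated FreeSurfer-style measures
(cortical thickness, surface area, subcortical volume) from many
scanners into one mega-analysis and asking which regions differ, how
those differences relate to neuroreceptor distributions, and how the
covariance structure of grey matter reorganises.

It is aimed at neuroimaging researchers who have subject × region
tables plus clinical metadata and want the full chain as reusable,
tested components rather than one-off scripts:

- **Harmonisation** — parametric empirical-Bayes location–scale
  adjustment (the ComBat model): per region *r*, site *s*,
  `y = α_r + x'β_r + γ_sr + δ_sr ε`, with normal/inverse-gamma priors
  shrinking the site effects `γ̂, δ̂²` and declared biological covariates
  (group, age, gender, TIV) protected.
- **Group differences** — per-region ANCOVA screen with
  Benjamini–Hochberg FDR, then a MANCOVA (Pillai's trace) on the
  surviving regions with Bonferroni pairwise contrasts and partial η²
  effect sizes; difference-of-means maps (VH − noVH) with pooled SEs.
- **Receptor associations** — OLS of the difference map on parcellated
  PET binding potential (e.g. D2/D3, 5-HT1A, 5-HT2A templates), with
  Cook's-distance influence screening, 10,000-cycle percentile bootstrap
  CIs, slope comparisons between receptors, and spatial inference by
  spin permutation: random mirrored rotations of the parcel centroids on
  the sphere, preserving spatial autocorrelation under the null.
- **Dimensionality** — correlation-matrix PCA of the group-different
  regions with Kaiser (eigenvalue > 1) retention, contributions and cos².
- **Structural covariance networks** — inter-regional correlation of
  GLM residuals per group; Fisher-z edge comparison with FDR; density
  thresholding (top positive correlations, d = 0.05…0.20 in 0.01 steps);
  degree, betweenness, nodal/local efficiency; betweenness hubs
  (mean + 1 SD at ≥ half the densities); Louvain communities and
  modularity with label-permutation and bootstrap inference.
- **Synthetic cohorts** — a first-class generator planting site effects,
  covariate effects, region-sparse group thinning, latent-factor
  covariance (communities and hubs) and receptor maps with controlled
  correlation to the planted difference map, so every stage is testable
  against known ground truth.

## Worked example

```python
import numpy as np
from cortmorph import synthio, harmonize, groupstats, receptormap, pcadim

atlas = synthio.generate_atlas(74, seed=7)               # 148 regions
truth = synthio.default_truth(atlas, effect_size=0.5, seed=42)
plan = {"siteA": (45, 120), "siteB": (45, 120), "siteC": (45, 120)}
table, meta = synthio.generate_cohort(atlas, truth, plan, seed=43)

adjusted, fit = harmonize.harmonize(table, meta)
screen = groupstats.screen_regions_anova(adjusted, meta, q=0.05)
flagged = screen.loc[screen.significant, "region_id"].tolist()
mv = groupstats.fit_mancova(adjusted, meta, flagged)

diff = groupstats.compute_difference_map(adjusted, meta)
rmap = synthio.generate_receptor_map(
    atlas, smoothness=30.0, seed=11, target=(truth.delta, -0.5),
    receptor_label="5HT2A",
)
spins = receptormap.generate_spin_permutations(atlas, 1000, seed=5)
d, bp, _ = receptormap.align_receptor_map(rmap, diff.diff, atlas)
r_obs, p_spin = receptormap.spin_correlation_test(d.to_numpy(), bp.to_numpy(), spins)
```

Output of the full script (a 495-subject, 3-site cohort with 0.5-SD
thinning planted in 20 regions and a receptor map correlated at −0.5
with the planted difference):

```
cohort: 495 subjects x 148 regions, 3 sites, 135 VH / 360 noVH
mean site eta^2: 0.063 -> 0.0015
regions flagged at q=0.05: 18 (18 of 20 planted)
MANCOVA group effect: Pillai=0.321, F(18,473)=12.44, p=5.41e-30
5HT2A vs thickness difference (flagged regions): beta_std=-0.13, t=-0.53, p=6.0e-01
all-region spatial correlation: r=-0.37, spin p=0.0010 (1000 spins)
PCA on flagged regions: 5 components with eigenvalue > 1 (leading eigenvalues [3.35, 1.65, 1.42])
```

Reading it: harmonisation cuts the between-site variance fraction from
6.3% to 0.15%; the FDR screen recovers 18 of the 20 planted regions with
no false positives; the MANCOVA confirms a multivariate group effect;
the negative all-region correlation with the receptor map (r = −0.37,
higher binding where thinning is greater) survives the
spatial-autocorrelation-aware spin test at p = 0.001 while the 18-region
subset alone is too small to show it; and the PCA summarises the flagged
regions into a few latent dimensions.

The same stages are available as a CLI (`cortmorph simulate | harmonise
| group-diff | receptor | pca | covnet | run-all`); `run-all` executes
the whole pipeline from a YAML config and writes a deterministic
`report.json` keyed by a single seed.

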