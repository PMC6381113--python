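# altimet

Longitudinal plasma metabolomics and lipidomics of humans ascending to
high altitude: preprocessing of binned ¹H-NMR and direct-infusion MS
(DIMS) feature data, a two-stage screen culminating in **robust Bayesian
hierarchical regression** of feature abundance on altitude, and the
downstream effect summaries and covariate correlations.

The package is aimed at metabolomics analysts who want a tested,
reusable implementation of this analysis — and a synthetic-data module
that reproduces the study's statistical structure (≈198 subjects × 5
altitude locations from 0.075 to 5.3 km, 965 samples, per-subject linear
altitude responses, heavy-tailed residuals, two-batch spectral bias,
missed visits), so every stage can be exercised and validated without
access to the original cohort.

## The model

For each feature (an NMR bin or a lipid), subject *s*'s repeated
measurements follow a line in standardized altitude with t-distributed
residuals:

```
y_si ~ t(ν)·σ + β0_s + β1_s · x_si
β0_s ~ N(μ₀, σ₀)        β1_s ~ N(μ₁, σ₁)
```

σ and ν are shared across subjects (one pair per feature); both data and
altitude are z-transformed before fitting. Priors are non-informative:
N(M=0, S=10) on μ's, Uniform(L=10⁻³, H=10³) on σ's, and a shifted
exponential (minimum 1, mean 30) on ν. Because the subject-level and
group-level regressions are estimated simultaneously, individual lines
are shrunk toward the group line, and the t residuals make the group
slope robust to outlying observations.

Screening is two-stage: (1) a cheap frequentist hierarchical estimate
(per-subject OLS slopes, averaged) keeps only features whose mean slope
lies > ±1.96 population SDs from the across-feature mean; (2) the full
Bayesian fit flags a feature as a *changer* when the 95% highest-density
interval (HDI) of the μ₁ posterior excludes zero. Changers are
summarized as median per-subject % change and back-transformed slopes in
arbitrary units per km (AU/km), and their per-subject deltas are
correlated with SpO₂ and body-weight deltas (Pearson or Spearman, gated
by the D'Agostino–Pearson normality test; significant correlations get a
follow-up OLS fit).

Posterior sampling is an in-package, chain-vectorized
Metropolis-within-Gibbs sampler (normal scale-mixture representation of
the t residual, conjugate updates for lines and means, adaptive
random-walk steps for scales and ν, plus ASIS/collapsed moves for
mixing), cross-checked in the test suite against JAGS.

## Worked example

```python
from altimet import (FeatureSpec, MCMCConfig, StudyDesign, decide_changers,
                     fit_feature, generate_cohort, generate_feature_matrix,
                     select_candidates, simple_hier_fit)

design = StudyDesign(locations=tuple((n, a, 40) for n, a, _ in
                                     StudyDesign().locations),
                     n_subjects=40, seed=9)
md = generate_cohort(design)
specs = [FeatureSpec(f"null_{i:02d}", mu1=0.0, sigma1=0.1, sigma=0.4, nu=5)
         for i in range(30)]
specs += [FeatureSpec("riser", mu1=0.35, sigma1=0.1, sigma=0.4, nu=5),
          FeatureSpec("faller", mu1=-0.35, sigma1=0.1, sigma=0.4, nu=5)]
data = generate_feature_matrix(md, specs, seed=10)

screen = select_candidates(simple_hier_fit(data), threshold=1.96)
summaries = [fit_feature(data, f, mcmc=MCMCConfig(n_chains=3, n_draws=3000,
                                                  n_burn=800, seed=11 + i))
             for i, f in enumerate(screen.selected)]
print(decide_changers(summaries).round(3).to_string(index=False))
```

prints

```
feature  mu1_median  hdi_low  hdi_high  changer  direction  slope_au_per_km  converged
  riser       0.516    0.397     0.616     True Increasing            0.189       True
 faller      -0.478   -0.590    -0.372     True Decreasing           -0.180       True
```

Of 32 features, stage 1 selects exactly the two planted effects; stage 2
confirms both as changers with the right direction. `mu1_median` is the
group slope on the z-scale, the HDI columns are its 95%
highest-density interval, and `slope_au_per_km` is the back-transformed
slope in original units per km of ascent.

The `examples/` directory has one short script per capability: cohort
simulation, the NMR chain (region exclusion → 10:1 binning → PQN →
Pareto → SVD batch-bias removal), the DIMS chain (scan averaging → 22 ppm
grouping → TIC normalization → exact-mass + Kendrick annotation), the
two-stage screen, and the covariate correlations. The full pipeline is
also runnable from the shell:

```sh
altimet all --outdir runs/demo --seed 1
```

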