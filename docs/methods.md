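# Methods

This document states the statistical models implemented in `germsoma`,
their assumptions, the meaning and defaults of every tunable parameter,
what the synthetic-data generator does and does not emulate, the
numerical choices, and the known limitations. No empirical claim here
goes beyond what the test suite or `scripts/acceptance.py` computes.

## 1. Expression normalization (`germsoma.normalize`)

**Model.** For a count matrix with library sizes Nⱼ, log expression is
yᵢⱼ = log₂((cᵢⱼ + 0.5) / (Nⱼ + 1) · 10⁶). Optionally the columns are
quantile-normalized (each column's sorted values replaced by the mean
sorted profile; ties receive the average-rank interpolated value).
Gene-wise residual standard deviations from an unweighted fit of the
design are paired with mean log counts, a lowess curve is fitted to
√sd versus mean log count, and each observation's precision weight is
the predicted sd⁻⁴ at its fitted log count. This is the voom recipe:
it converts the count mean–variance relationship into observation
weights so that ordinary linear-model machinery applies to log counts.

**Assumptions.** Library sizes are comparable up to scaling; the
mean–variance trend is smooth and shared across samples; counts are not
dominated by a few transcripts.

**Parameters.**
- `min_cpm = 1.0`, `min_samples = 2` (`cpm_filter`): a gene is kept when
  its CPM exceeds `min_cpm` in at least `min_samples` samples — the
  conventional low-expression filter; below this the log transform and
  trend fit are unstable.
- `quantile = True` (`voom_transform`): cross-sample quantile
  normalization, appropriate when the samples' expression distributions
  are believed to be exchangeable. **Set `quantile=False` when a large
  fraction of the transcriptome genuinely disappears in one condition**
  (the germline-collapse calibration scenario): forcing identical column
  distributions onto samples that lost a quarter of their transcriptome
  erases the compositional shift being measured.
- `span = 0.5`: lowess span; the default gives a smooth trend on a few
  thousand genes without chasing local noise.

**Numerics.** The predicted √sd is clamped at 10⁻⁶ before the ⁻⁴ power
to avoid infinite weights on a degenerate flat trend.

## 2. Moderated differential expression (`germsoma.linear`)

**Model.** Per gene g, weighted least squares of yg on a cell-means
design X (one column per genotype/RNAi condition) with the voom weights:
β̂g solves the weighted normal equations (computed in one batched einsum
across genes), σ̂²g = Σⱼ wgⱼ r²gⱼ / (n − p) with d = n − p residual df.
The gene variances are modeled as draws from a scaled inverse-χ² prior
(d₀, s₀²), estimated by moment matching on log σ̂² (digamma/trigamma
identities; trigamma inverted by Newton iteration). The posterior
variance is s̃²g = (d₀ s₀² + d σ̂²g)/(d₀ + d) and a contrast c is tested
with t = c′β̂g / (s̃g · se₀(c)) on d₀ + d degrees of freedom (normal
reference when d₀ = ∞). Limits: d₀ = 0 reproduces the ordinary t
exactly; d₀ = ∞ pins every variance to s₀². The test suite verifies the
whole chain — estimates, hyperparameters, t, p, posterior variances —
against R limma on a shared fixture.

**Assumptions.** Gaussian log expression given the weights; a common
variance prior across genes; the design has full column rank and at
least one residual degree of freedom.

**Parameters.** `ebayes(prior=None)` estimates (d₀, s₀²) from the data;
pass `EBayesParams(df_prior, var_prior)` to fix them. `bh_fdr` is the
standard Benjamini–Hochberg step-up.

**Numerics.** If the moment estimator's excess log-variance is ≤ 0, the
prior df is set to ∞ (no between-gene variance heterogeneity beyond
sampling noise). p-values are floored at the smallest positive float to
keep downstream −log₁₀ finite.

## 3. Dependency screen (`germsoma.screen`)

**Model.** For contrasts 1 (GSC(−) vs WT) and 2 (*skn-1* RNAi vs
GSC(−)), the statistic is T = min(|t₁|, |t₂|) if sign(t₁) = +1 and
sign(t₂) = −1, else T = 0. Significance is empirical:
p = (1 + #{T\*₍ₙᵤₗₗ₎ ≥ T}) / (1 + n_draws) against a simulated null,
followed by BH across genes.

**The null's correlation structure matters.** The two observed
t-statistics are not independent: the contrasts share the GSC(−)
condition mean — correlation exactly −½ between the numerators under a
balanced cell-means design — and both are scaled by the *same* moderated
variance estimate. `DependencyScreen` therefore defaults to
`correlation="auto"`: it recovers the between-contrast correlation from
the shared fit's coefficient covariances and draws the null as a
bivariate-normal numerator pair over a single shared χ²_df/df
denominator. Drawing the pair independently makes the null
stochastically too small and the screen anti-conservative (about an
order of magnitude more false calls at q < 0.05 on global-null data, as
measured in development). The bare `sample_null_distribution` function
defaults to independent draws — for which P(T > 0) = ¼ exactly — with
`correlation` and `shared_denominator` arguments to opt into the
structured null.

**Parameters.** `n_draws = 100 000` (Monte-Carlo resolution; the add-one
correction bounds the smallest p at ≈ 10⁻⁵), `seed`, `pattern`
(default +, −). `classify_gene_sets` applies the published fold-change
rules with strict inequalities: FC > 4 (and > 5) up after germline
loss, FC < 2/3 (a ≥ 33 % reduction) under *skn-1* RNAi.

## 4. Composition model (`germsoma.composition`)

**Model.** Two compartments with n_soma and n_germ nuclei; a germline
nucleus produces ρ times the transcript output of a somatic one; after
ablation a fraction `residual_germline` of germline output remains. A
soma-only transcript's pool share is multiplied by
E = (n_soma + ρ n_germ) / (n_soma + ρ n_germ · residual).
Defaults n_soma = 959, n_germ = 2000, ρ = 1, residual = 0 give
E = 2959/959 ≈ 3.086 — the "about threefold" enrichment expected from
composition alone, which motivates the fourfold cutoff:
`call_somatic_upregulated` uses max(4, E · margin).

**Assumptions.** Output proportional to nuclei within a compartment;
no global transcriptional compensation after ablation.

## 5. Phenotype statistics (`germsoma.phenotype`)

- Kaplan–Meier and the unweighted log-rank test are delegated to
  lifelines; the tests verify them against hand product-limit arithmetic
  and a 10⁴-draw label-permutation reference.
- `percent_extension` is 100 · (mean_treatment/mean_control − 1),
  rounded to 2 decimals, matching how published summary tables report
  lifespan extension. When recomputed from printed (already rounded)
  means, agreement is only guaranteed within the propagated ±0.005
  rounding of each input — the golden tests carry that bound explicitly.
- `anova2_from_summary` reconstructs a two-way factorial ANOVA with
  interaction from mean/SEM/n cells: the error mean square pools the
  within-cell variances (SEM²·n) over Σ(nᵢⱼ − 1) df; factor and
  interaction sums of squares use unweighted cell means with the
  harmonic mean of cell sizes. On balanced designs this equals the
  raw-data ANOVA exactly (verified against statsmodels); on unbalanced
  designs it is the unweighted-means approximation — the appropriate
  choice when only summary cells were published.
- Holm–Šídák adjustment and the Pearson χ² test (no continuity
  correction) wrap statsmodels/scipy and are checked against literal
  formula oracles.

## 6. Image quantification (`germsoma.imaging`)

Oil red O absorbs green light, so the per-pixel stain signal is
max(0, R − G); an animal's readout is the mean of max(0, signal − b)
over a region of interest, with background b defaulting to the median
signal outside the ROI. `isolate_color` mimics selective-color editing:
a pixel is kept when its Chebyshev (max-channel) distance to the target
RGB is within the fuzziness setting. The dataset constants record the
target colors and fuzziness used for SKN-1::GFP and DAF-16::GFP
isolation.

## 7. Synthetic-data generator (`germsoma.simulate`)

**What it emulates.** A three-condition (WT, GSC(−), GSC(−)+*skn-1*
RNAi) RNA-seq study over a soma/germline compartment structure. Genes
get lognormal baseline rates (`baseline_log_mean = 0`,
`baseline_log_sd = 1.5`, giving a realistic dynamic range) and a class:
`somatic_specific`, `germline_specific`, `ubiquitous` (rates in both
compartments), `gsc_induced` (up `induction_fc`-fold on germline loss),
or `skn1_dependent` (up `induction_fc = 6`-fold on loss, losing fraction
`knockdown_reduction = 0.6` of the induction under RNAi). Germline rates
are scaled so the germline contributes `germline_share` (default ⅔,
matching the nuclei ratio) of the intact pool; after ablation a fraction
`residual_germline = 0.05` persists (ablation is not perfectly clean).
Expected counts are library_size × the gene's renormalized pool share —
so compositional enrichment of somatic genes emerges mechanically, not
by construction — and observed counts are negative binomial with
var = μ + φμ², `nb_dispersion φ = 0.05` (typical biological-replicate
overdispersion; φ = 0 gives Poisson). Default
`class_fractions` (8 % somatic-specific, 25 % germline-specific, 56.2 %
ubiquitous, 10 % GSC-induced, 0.8 % dependent) make roughly a tenth of
genes exceed fourfold after germline loss, the order observed in the
modeled study.

Scenario constructors fix interpretable special cases:
- `calibration_config`: pure compartment collapse (γ = ⅔, zero residual,
  no induced classes) — every fold change is compositional, closed form
  1/(1 − γ) = 3; analyze with `quantile=False` (see §1).
- `global_null_config`: no compartment, no induced classes — both screen
  contrasts globally null.
- `planted_config`: global null plus `n_planted = 100` dependent genes —
  known truth for recall/FDP.

Survival cohorts are gamma-distributed lifetimes (shape 20, so CV ≈ 22 %,
worm-like) with independent uniform censoring; score tables are
multinomial; stain images are a rectangular ROI with the green channel
attenuated by `stain_level` plus Gaussian noise, clipped to [0, 255].

**What it does not emulate.** Gene length and mappability effects (no
length bias — counts are per-gene, not per-read-position), GC or batch
effects, correlated gene modules, isoform structure, partial-penetrance
ablation varying across replicates, competing-risks censoring, or
spatial structure in images beyond one rectangular stain region. The
generator's truth labels are per-gene classes, not effect-size continua.

## 8. Limitations

- The screen's error control is Monte-Carlo and depends on drawing the
  null with the observed statistics' correlation structure; using the
  independent null on data with shared conditions is anti-conservative.
- The empirical p-values are bounded below by 1/(1 + n_draws); genes far
  in the tail are tied at that floor and ranked only by T.
- The summary-cell ANOVA is exact only for balanced cells; with the
  published (unbalanced) cohort sizes it is the unweighted-means
  approximation.
- `expected_enrichment` treats transcript output as proportional to
  nuclei; polyploid or transcriptionally atypical tissues violate ρ = 1.
- The moderated model assumes one shared variance prior; strong
  variance strata (e.g., expression-dependent priors) are not modeled
  beyond the voom weights.
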