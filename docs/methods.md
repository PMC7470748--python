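# Methods

## Model

Let Y be a binary (logit link) or continuous (identity link) outcome, G an
n×P dosage matrix for one gene region, and M a K-vector of mediators
(typically gene expression) predicted from G by a linear model with weight
matrix W (P×K), so that M̂ = GW. The working model is

g{E(Y | X, M, G)} = Xᵀη + Σ_k M̂_k γ_k + Σ_p δ_p G_p,

with fixed mediator effects γ and per-variant direct effects δ_p treated as
random with mean 0 and variance τ². The null of no total effect is
H₀: γ = 0 and τ² = 0, and the two parts are tested separately:

1. a K-df chi-square test of γ (mediation / predicted-expression
   component), and
2. a score-type variance-component test of τ² computed *after conditioning
   on the fitted mediators*, which makes it independent of the first test.

All quantities are reconstructed from per-variant marginal summary
statistics plus a genotype covariance estimate; the algebra is in the
README and the module docstrings. Under the logit link the reconstruction
treats the GLM weight μ(1−μ) as approximately constant — exact under the
null, an approximation under the alternative; the validation suite
quantifies how little this costs at case-control scale.

### Summary-statistic dialects

* `wald` — marginal β̂ and se per variant.
* `score` — score statistic U and its variance V, with β̂ ≈ U/V,
  se ≈ V^(−1/2). Scores are computed under the null, so this dialect is the
  stable choice for rare or low-frequency variants and is preferred when
  both are available.
* `standardized` — only signed z statistics: β̂ is replaced by z, se by 1,
  and the LD panel is used on the correlation scale.

### Independence of the components

The conditioning row a_p is built so that any pure mediation signal
(marginal effects proportional to D⁻¹cov(G)Wγ) maps to α̂* = 0 exactly;
this is property-tested. Consequently U_γ and U_τ² are asymptotically
independent under the null, and the empirical correlation of the two
statistics over 1000 complete-null replicates is ~0.01.

## Chi-square mixture tail

The null law of U_τ² is Σ_j w_j χ²₁ with w_j the eigenvalues of
D_α R* D_α (eigenvalues below 1e-8 of the largest are discarded as
numerical rank noise). The survival function is evaluated by:

* exact closed forms when the weights are equal (scaled central
  chi-square);
* Imhof's characteristic-function inversion (adaptive quadrature, absolute
  tolerance 1e-12) in the central region;
* Kuonen's saddlepoint approximation when the tail probability falls below
  5e-4, where double-precision quadrature can no longer resolve the
  integral against its leading 1/2; its relative error there is O(10%),
  i.e. ≤ ~0.04 on the log10 scale — negligible against the agreement bands
  used anywhere in the package;
* the Liu–Tang–Zhang 4-moment match only if both of the above fail.

Results are clipped to [1e-300, 1] and the method actually used is reported
per gene (`method_vc` column).

## Ridge regularization of the LD panel

Reference panels estimated from modest samples can be near- or exactly
singular for genes whose variants sit in near-perfect LD; the conditioning
step then amplifies estimation noise and produces spuriously small
variance-component p-values. The correlation matrix is therefore shifted to
cor + λI (diagonal left at 1 + λ; the covariance is rebuilt as
diag(√d)·(cor + λI)·diag(√d)), applied to every gene. The default
λ = 1/√(n_ref·ln n_ref) (≈0.012 at n_ref = 1000) vanishes as the panel
grows, so the regularized test is consistent; λ is a configuration
parameter, not a constant. In the packaged near-singular stress experiment
(12 variants at pairwise dosage r ≈ 0.999, external panel of 1000) the
unregularized test deviates from the individual-level gold standard by up
to tens of orders of magnitude in the anti-conservative direction, while
the default ridge leaves no anti-conservative deviation beyond one order;
the residual deviations are conservative and confined to large p-values,
the expected cost of the ridge.

## Conditional analysis

A known risk locus is adjusted for by adding (i) its variant to the variant
set and joint LD panel and (ii) an indicator column to W — the locus is
treated as an extra "mediator" whose predicted value is its own dosage. The
adjusted mediation p-value is the joint chi-square test of the gene's
mediator columns from the (Q+K)-mediator fit; the variance-component test
conditions on all Q+K columns through the same code path. A known locus
that is itself a gene variant is represented once, carrying both the
indicator and its gene weight, which avoids exact collinearity. Sequential
selection iterates this: test, stop if both component p-values exceed the
stopping level (default 0.05), otherwise add the variant with the largest
conditioned |α̂*_p|/se(α̂*_p) (ties to the lower index) and repeat. The
"marginal significance" driving selection is conditioned on the predicted
expression as well as previously selected loci — it is the same conditioned
statistic the variance component already produces.

## p-value combination

Fisher (χ²₄ of −2Σln p) and Tippett/minP (1−(1−min p)²) are exact for two
independent components. The "weighted" method evaluates
T(ρ) = −2[ρ ln p_med + (1−ρ) ln p_vc] over a grid (default 0, 0.1, …, 1),
refers each T(ρ) to the exact law of ρχ²₂ + (1−ρ)χ²₂, and calibrates the
minimum per-ρ p-value by Monte Carlo under the joint null (default 10⁵
seeded draws, cached per grid/seed so a scan pays the cost once). The
reported p is floored at 1/(draws+1). This is a grid-search weighted Fisher
combination — a deliberate, transparently named stand-in for optimally
weighted combinations whose exact construction lives outside this package.

## Individual-level oracle

The gold standard fits the null GLMs by IRLS (statsmodels, tolerance 1e-8,
100 iterations): the mediation component is the K-df score test of M̂ under
the confounder-only null; the variance component is U = SᵀS with S the
genotype score vector under the (X, M̂) null fit, V its projected
information, and the p-value from the same mixture machinery with weights
eig(V). Non-converged or separated fits are flagged and excluded from
comparisons. The oracle exists for validation, not as a product.

## Synthetic data generator

The generator emulates a case-control study of a gene region:

* **Genotypes** — latent multivariate normal with block-exchangeable
  correlation, thresholded to dosages {0,1,2} at Hardy–Weinberg cutpoints
  for each variant's MAF. Defaults: P = 40 in four equal blocks at within-
  block correlation 0.95 / 0.6 / 0.3 / 0, MAFs uniform on (0.05, 0.5) —
  clusters of tightly linked variants next to effectively independent ones.
  A "near_singular" preset (12 variants, shared MAF 0.3, dosage r ≈ 0.999)
  reproduces the regime in which small reference panels go rank-deficient.
* **Mediator** — M = cB + ε with B = Σ w_p G_p, ε ~ N(0, σ²); c and σ² are
  solved so G explains R² ∈ {0.05, 0.2, 0.8} (default 0.05) of
  var(M) = 1.5. eQTL weights default to a sparse vector (half the variants,
  standard normal); only their direction matters since c rescales. A
  mis-specified-mediator option generates E(M|G) through an exponential
  (log-link) transform of B while the analysis keeps the linear weights.
* **Direct effects** — δ_p ~ N(0, 0.05) on a fraction prop_direct of
  variants (default all); the sum Σ δ_p G_p is residualized on B so the
  direct signal is orthogonal to the mediated one (empirical |r| ≤ 0.01).
  The inconsistent-mediator option flips δ signs against γ·w_p.
* **Outcome** — logit link with intercept −3 (baseline disease probability
  inverse-logit(−3) ≈ 4.7%, "about 5%"), mediator effect γ = log 2; 1000
  cases and 1000 controls collected by rejection sampling over fresh
  individuals. Generating parameters (c, σ, δ, residualization) are frozen
  on a 20 000-draw calibration sample so every batch comes from one
  population.
* **Confounder** — an anchor variant (the one most correlated with B)
  diluted with independent variants until corr(confounder, B) hits a target
  in [0.1, 0.4] (±0.02); it enters the linear predictor with coefficient
  β ∈ [0.3, 0.9] and is *included* in the null model of the per-variant
  summary statistics (standard GWAS covariate adjustment) and in the
  oracle, but the LD panel remains unadjusted — exactly the gap the
  validation probes.

What the generator does **not** emulate: real LD (no long-range structure,
no allele-frequency–dependent LD decay), imputation uncertainty, population
stratification, or weights estimated with error from a finite expression
panel. Passing tests therefore demonstrate the correctness of the summary
algebra and its robustness to the modeled perturbations, not performance on
any particular cohort.

## Problem sizes and determinism

The validation studies run at: 200 studies (8 conditions × 25) for the
oracle-agreement check; 1000 complete-null studies for calibration and
independence; 120 studies for the near-singular rescue; 300 replicates per
setting for the power orderings; 10⁶ draws per point for the mixture-tail
Monte Carlo. Every replicate stream is driven by a single master seed
(per-replicate seeds drawn below 2³¹), so replicate tables are bit-identical
across runs. Power orderings are asserted at α = 0.05 and at the gene-level
discovery threshold 0.04/8893 ≈ 4.5e-6, where the mediation test's power is
not yet saturated (noncentrality at R² = 0.05 is ~18, rising ~linearly
in R²).

## Known limitations

* cor(β̂*) ≈ cor(G) is exact only under the null; under strong alternatives
  with a strongly correlated confounder (r = 0.4, β = 0.9) the mediation
  p-values can be somewhat conservative.
* Reported standard errors are used verbatim; no correction is attempted
  when the GWAS and reference-panel sample sizes differ by orders of
  magnitude.
* The weighted combiner's resolution is bounded by its calibration draws;
  genome-wide-significant combined p-values should be read from the Fisher
  column when they fall below the floor.
* Strand-ambiguous (A/T, C/G) variants are dropped by default during
  harmonization; no liftover or dbSNP normalization is attempted.
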