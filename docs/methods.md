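# Methods

`germtherm` implements a quantitative-genetics pipeline for dissecting the
response of seed germination to elevated temperature in accession panels of
*Brassica rapa* and *B. oleracea* — wild populations and landraces phenotyped
for germination time (GT, hours to radicle emergence, right-censored at
168 h) and germination rate (GR, the 0/1 indicator of germination within
168 h) at a reference temperature (20 °C) and an elevated one (35 °C for
*B. rapa*, 30 °C for *B. oleracea*), genotyped by pooled resequencing, and
scored for field emergence. This note records the models, the numerical
choices, and what the synthetic validation does and does not establish.

## Variant filtering

Input is a multi-sample VCF with per-sample allele depths (AD), per-sample
total depth (DP) and site mapping quality (INFO/MQ). The chain applies, in
order:

1. **Accession depth** — drop accessions whose mean site depth is not
   strictly above 20×.
2. **Multiallelic sites** — drop sites with more than one ALT allele.
3. **Indel proximity** — drop SNPs less than 5 bp from an indel anchor
   position (the indel's POS; the span end is configurable). Indel records
   are still visible at this step.
4. **Indel records** — drop the indels themselves. Together with step 2
   this realises "retain only biallelic SNPs"; the accounting is split so
   each removal has exactly one attributable rule.
5. **Site depth percentiles** — keep sites whose mean depth lies inside the
   closed 5th–95th percentile band of the *current* site set (linear
   interpolation between order statistics; method configurable). This
   filter is rank-based and therefore one-shot: re-applying it would trim
   new tails. All threshold-based filters in the chain are idempotent.
6. **Mapping quality** — keep MQ strictly above 40; missing MQ fails.
7. **Chromosome scaffolds** — keep sites on the named chromosomes.
8. **Allele depth** — drop a site if any retained accession has both
   allelic depths below 10; this also removes sites with missing calls.
9. **LD pruning** — greedy left-to-right per chromosome: a site is kept
   unless its squared dosage correlation with a previously kept site inside
   the trailing window exceeds r² = 0.2. The window is 1000 *sites* by
   default (the literal reading of the pruning flag), switchable to base
   pairs; monomorphic sites define r² = 0 and are kept.

Every step reports (rule, sites before, removed, after), and the report
validates its own bookkeeping.

## Relationships and ordination

The genomic relationship matrix uses the GCTA-default estimator

    G_jk = (1/m) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)),

with allele frequencies from the current accession set. G* rescales G to
unit diagonal (cov2cor) and the dissimilarity is D = 1 − G*. Classical
(Torgerson) MDS double-centres B = −½ J D⁽²⁾ J, eigendecomposes, and keeps
positive eigenvalues only — both for the coordinates (√λ·v) and as the
denominator of the per-axis percentage of variance. Axes are oriented so
the first accession's coordinate is non-negative, purely for reproducible
plots and tests.

## The gBLUP mixed model

The engine fits y = Xβ + Zg + e with g ~ N(0, σ²_G·G), e ~ N(0, σ²_e·I) by
EM-REML on Henderson's mixed-model equations; one average-information step
at convergence supplies standard errors for the variance components, and
fixed-effect standard errors come from the inverse coefficient matrix.
Heritability is h² = σ²_G/(σ²_G + σ²_e). Conventions and safeguards:

* Convergence: |Δ REML log-likelihood| < 1e-6 (configurable), at most 500
  EM iterations; the trace is retained and is non-decreasing (asserted in
  tests). Near a flat optimum EM creeps; oracle tests that require 1e-6
  agreement in the components themselves use tol = 1e-14, which the
  balanced closed-form instance reaches in ~40 iterations.
* Variance components are floored at 1e-8; a fit that touches the floor is
  flagged `boundary` and reported without AI standard errors.
* G is "bent" before factorisation whenever its smallest eigenvalue is
  below 1e-8, by adding 1e-6 (doubling until positive definite) to the
  diagonal — small simulated panels are routinely rank-deficient. The same
  rule is used everywhere a Cholesky of G is taken.
* The design builder uses treatment coding against the first sorted level,
  standardises the conservation covariate (days of seed storage before
  phenotyping), drops within-subset constant columns with a log message,
  and removes aliased columns by pivoted-QR rank detection. Temperature is
  a two-level factor; per-degree effects are obtained afterwards by
  dividing the contrast by the species' temperature difference.
* gBLUPs are returned for every accession in G, including accessions
  without phenotype records (predicted through relationship).

Fixed effects are tested with Wald Z-tests (the panels are large enough
that the normal reference is a good approximation of the t). Factor-level
comparisons use Tukey's HSD: q = |difference|/(SE(difference)/√2) referred
to the studentized-range distribution with residual degrees of freedom.

Model suites mirror the analysis design: the full GT model
(temperature + type + batch + year + conservation + polygenic term), the
per-type split ("b"), the per-type-by-temperature split ("c", which
estimates the heritabilities and supplies the per-temperature gBLUPs), and
the per-country temperature-slope variant ("d"). Where a results
narrative attributes a GR test to a "1*" suite, the runner maps it to the
corresponding "3*" suite (the GR model family) and logs the redirection.

## Two-stage treatment of the binary outcome

A joint binary GLMM is deliberately avoided (reliable convergence is not
guaranteed by available one-step software); instead a GRAMMAR-style
two-stage scheme is used. Stage one regresses the 0/1 germination
indicator on the experimental nuisances — batch, multiplication year,
conservation length and its interaction with temperature — with a
binomial-logit GLM (IRLS, |Δdeviance| < 1e-8). Both main effects of the
interaction are included: printing only the interaction would make the
estimates depend on the coding. Stage two fits the gBLUP model to the
stage-one residuals on the latent (linear-predictor) scale, "GRA".

The residual type is the central unstated choice of this scheme. The
default is the working residual (y − μ̂)/(μ̂(1 − μ̂)) — the quantity IRLS
itself regresses, and the GRAMMAR-family convention; Pearson and deviance
residuals are selectable and the choice is recorded in the output
metadata. Fitted probabilities are clipped at 1e-8 from both ends with a
logged count. Constant responses raise a separation error; diverging
coefficients (|β| > 30 on the logit scale) are reported as
quasi-separation naming the term. The stage-one model is fitted per
species, as every downstream model is.

## Downstream regressions

From the per-temperature stage-two fits, each accession carries its cold
gBLUP C, warm gBLUP W, and heat tolerance H = W − C, joined with latitude
of the sampling site and field emergence rate E.

* **Cross-temperature (model 4)**: OLS of W on C with intercept, pooled
  per species, with per-type fits additionally reported. A slope near 1
  means ranking is maintained across temperatures; attenuation by gBLUP
  reliability keeps the slope slightly below 1 even without G×E.
* **Latitude (model 5)**: OLS of H on C (baseline control) and latitude,
  fitted separately for wild and landrace accessions — analogous to a
  Finlay–Wilkinson regression with latitude as the environmental index.
  Latitude is used in raw degrees; a pooled fit with a type covariate is
  available. Near-collinearity of C and latitude (|r| > 0.999) is an
  error.
* **Emergence (model 6)**: OLS of E on C with the cold stage-two intercept
  μ₃ entered as a fixed offset (subtracted from E, never re-estimated).
  The offset only shifts the estimated intercept; slope, Z-test and R² are
  invariant to it, so the pipeline's choice of μ₃ (the n-weighted mean of
  the per-type cold intercepts) is inconsequential for inference.
  Emergence is analysed on the raw proportion scale (configurable).

All fits report adjusted R² = 1 − (1 − R²)(n − 1)/(n − p − 1) and
per-coefficient Z-tests. Every OLS path is cross-checked in the tests
against explicit normal-equation solutions.

## Synthetic cohorts

The generator emulates the statistical structure the models assume, so
every stage is verifiable without external downloads.

* **Genotypes**: Balding–Nichols. Ancestral frequencies Uniform(0.05,
  0.95); population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) with F the
  divergence parameter (default 0.3, three ancestral populations —
  emulating the wild/landrace clustering of the real panels); accession
  frequencies are Dirichlet-admixed mixtures (equal-size blocks under
  `hard_split`); dosages Binomial(2, freq); monomorphic columns are
  redrawn. Accessions in the first ancestral cluster play the wild group;
  clusters map to countries.
* **Phenotypes**: cold genetic values a_C ~ N(0, σ²_G·G); warm values
  ρ·a_C + √(1−ρ²)·a⊥ + b_lat·(latitude − mean latitude), giving a
  cross-temperature genetic correlation ρ (default 0.8) and a latitude
  cline in heat tolerance. The latitude slope is applied to *centred
  degrees*, so its units match what the downstream regression on raw
  degrees estimates — making noise-free recovery an identity rather than
  a rescaling. GT per seed is Gaussian around intercept + fixed effects +
  genetic value (default intercept 60 h, σ²_G = 75, σ²_e = 175, i.e.
  h² = 0.3, wild slowdown 25.92 h, warm effect −16 h); a log-normal
  option provides a heavier right tail; times at or beyond 168 h are
  censored and flagged non-germinated. The binary outcome follows its own
  logistic liability with its own polygenic values (default liability
  variance 0.5) so that germination and GT selection are conditionally
  independent. Emergence is logistic(1.0 + 0.8·b_C + noise) on the cold
  liability genetic value.
* **Contaminated VCF**: clean sites carry a constant per-sample DP of 60×
  so the depth-percentile band is degenerate and removes exactly the
  planted outliers; planted records (multiallelic, indel + near-indel SNP
  pairs, low-MQ incl. the MQ = 40 boundary, depth outliers, low-AD cells,
  off-chromosome scaffolds, low-depth accessions) sit ≥ 37 bp from any
  clean site so no rule fires by accident. The manifest names the rule
  expected to remove each planted record, which the tests compare against
  the chain's counts exactly.

What the generator does **not** emulate: linkage maps and realistic LD
decay (LD arises only from population structure), pooled allele-depth
noise, dormancy dynamics, spatially structured field emergence, or any
dependence of censoring on the liability beyond independence — so passing
recovery tests demonstrate correctness of the estimators under the
models' assumptions, not robustness to their violation on real data.

## Validation experiment sizes

The validation battery (shared by the acceptance tests and
`scripts/acceptance.py`) uses: a ~2,000-site, 30-accession filter fixture;
50 cohorts of 100 accessions × 50 seeds (25 per temperature) at h² = 0.3
for heritability recovery; 20 cohorts of 80 accessions × 40 seeds per cell
for the no-G×E null (cross-temperature slope, latitude type-I behaviour);
and 20 low-noise cohorts (σ²_e = 4, 50 seeds per cell, latitudes spanning
20–70°) for recovery of a planted −0.02 h/degree cline. Recovery cohorts
are simulated with ρ = 1 where the fitted model estimates a single genetic
value per accession: recovery against a deliberately misspecified
generator would measure the misspecification, not the estimator. These
sizes keep the whole battery under a minute while holding Monte-Carlo
error well inside the asserted bands.

## Known limitations

* GT is modelled as Gaussian despite being positive and right-censored;
  censored seeds are excluded from GT fits (they still contribute zeros
  to GR), which is unbiased only while censoring is rare or independent
  of the genetic values.
* The two-stage GRA scheme estimates heritability on a residual scale; it
  is not the liability-scale h² and should be compared across subsets,
  not across scales.
* EM-REML is first-order; very flat likelihoods (tiny panels, h² near 0)
  converge slowly and may stop short of the optimum at the default
  tolerance. The non-decreasing likelihood trace is always available for
  diagnosis.
* The LD-pruning window dialect (sites vs bp) is a genuine ambiguity of
  the upstream flag; both are implemented and the choice is logged.
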