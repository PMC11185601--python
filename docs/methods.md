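# Methods

`polylife` implements a pipeline for polygenic modelling of blood-pressure
traits (systolic pressure SP, diastolic pressure DP and pulse pressure
PP = SP − DP) that combines genome-wide SNP data with a panel of c = 27
lifestyle variables, paying particular attention to the bias that
genotype–environment correlation (rGE) introduces when lifestyle variables
are themselves partly heritable.  Because the motivating data (a biobank
cohort of ~10⁵ genotyped individuals aged 40–70) is access-restricted, the
package ships a first-class synthetic-data generator that reproduces the
statistical structure the models assume, so every stage of the pipeline is
exercised and tested end to end on truth-known data.

## Phenotype derivation and grouping

Raw systolic/diastolic readings of individuals on blood-pressure medication
are corrected by adding 15 mmHg and 10 mmHg respectively; pulse pressure is
the difference of the corrected measures.  Sex crossed with four age groups
(break points after ages 51, 58 and 63, i.e. ranges 40–51, 52–58, 59–63,
64–70) defines 8 cohort classes (`0-1` … `1-4`) used as fixed effects
throughout.  Age groups 1–2 form the young (Y) group and 3–4 the old (O)
group for the across-age prediction design; a randomized grouping (RND)
with the same group-size multiset provides the easy-transfer control.
Responses are standardized to mean 100 / sd 10, so fitted variance
components read directly as percentages of phenotypic variance; predictors
(lifestyle columns, covariates) are standardized to mean 0 / sd 1.  All
standard deviations use the n−1 denominator.

Variant QC retains variants with MAF ≥ 0.01, minor allele count ≥ 5,
missing rate < 0.1 and Hardy–Weinberg p > 1e−10.  The HWE test is a 1-df
chi-square on observed genotype counts; at the extreme p < 1e−10 cut-off
it agrees with an exact test everywhere except at tiny counts, which the
MAC filter removes anyway.  Relatedness pruning is greedy on the GRM
violation graph: repeatedly remove the individual in the most
over-threshold pairs (ties → larger row index) until no retained pair
exceeds the threshold.  This rule is deterministic; only the end condition
(no pair above threshold) is intrinsic to the method.  The 0.025 threshold
is calibrated to GRMs built from several hundred thousand variants, whose
off-diagonal sampling noise is ~0.001; at desk-scale variant counts
(10²–10⁴) the noise floor alone exceeds 0.025, so the demo pipeline uses a
threshold matched to its variant count while tests of the pruning rule
itself plant near-duplicate pairs.

## Kernels

The genomic relationship matrix uses the centred-and-scaled estimator
G_ij = p⁻¹ Σ_k (x_ik − 2f_k)(x_jk − 2f_k) / (2f_k(1−f_k)) with sample
allele frequencies; missing dosages are mean-imputed (contributing zero
after centring), which keeps the estimator one matrix product — with
post-QC missingness below 10 % the difference from per-pair denominators
is negligible.  Lifestyle kernels are WW⊺/c for W ∈ {M (raw), L
(predicted), E (residual)}; genotype-by-lifestyle kernels are Hadamard
products G ∘ WW⊺/c (PSD by the Schur product theorem).  The
population-structure control kernel P is the spectral reconstruction of G
from its top r = 20 eigenpairs, keeping the eigenvalue scale (the model's
variance component absorbs any rescaling).  Kernel dimensionality is
summarized by cumulative trace-normalized eigenvalue proportions with
negative eigenvalues clipped to zero.

## Adjustment of lifestyle variables

Each lifestyle variable m_l (response-standardized) is decomposed as

    m_l = X b_l + N_l u_l + a_l + e_l

with X the intercept + cohort design, N_l the lifestyle matrix whose l-th
column is replaced by i.i.d. N(0,1) noise (so a variable cannot predict
itself; the noise coefficient shrinks toward zero and its share is
reported as a diagnostic), u_l ~ N(0, I σ²_u) ridge regression effects,
a_l ~ N(0, G σ²_a) a genomic effect and Gaussian residuals.  The model is
fitted on all individuals, because downstream prediction needs E and L
values for training and validation rows alike.  Posterior means (not
single draws) define the adjusted matrices: E holds the residuals
m_l − Xb̂ − N_l û_l − â_l and L the predictions N_l û_l.  By default both
are column-standardized before kernel construction so the three lifestyle
kernels live on a common scale and their variance components are
comparable; a flag disables this.

Two numerical notes.  First, the posterior of a truly null kernel variance
component does not collapse to zero: the per-iteration variance of the
sampled effect vector has a noise floor roughly proportional to the
kernel's effective dimension divided by n.  Tests of null recovery
therefore use n comfortably above the variant count.  Second, the
cross-lifestyle share recovered by N_l u_l is the *predictable* share; when
the shared structure is spread over many weak factors the predictable
share sits below the nominal simulated fraction, which is attenuation of
the estimand, not estimator bias.

## Multi-kernel Bayesian LMMs

All phenotype models have the form y = Xb + Σ_t u_t + ε with flat priors
on b, scaled-inverse-χ² priors (df 5) on all variances and
u_t ~ N(0, K_t σ²_t).  The model suite: M0 = {G}; M1/M2/M3 = one lifestyle
kernel (MM⊺/c, LL⊺/c, EE⊺/c); M11/M12/M13 add G; M21/M22/M23 add the
matching Hadamard interaction kernel; M01 = {P} (structure control);
M02 = cohort only.  Prior scales default to an equal split: each term's
prior mode is r²·Var(y)/T with r² = 0.5 over T random terms, the residual
mode (1−r²)·Var(y); S solves mode = df·S/(df+2).

The Gibbs sampler re-parameterizes each kernel term through its
eigendecomposition (u = Vδ, δ_j ~ N(0, d_j σ²_t); eigenvalues below 1e−8 of
the maximum dropped), computed once per kernel and cached, so conditional
updates are univariate Gaussians.  Three numerically identical update
paths are chosen by problem shape: a vectorized joint draw when the
eigenbasis is orthonormal on the observed rows (no masking — the diagonal
posterior makes the blocked conditional exact), a small-block Cholesky
draw for terms with ≤ 160 coordinates, and a compiled single-site scan
otherwise.  Variances are drawn from their scaled-inverse-χ² full
conditionals, the fixed block from its multivariate normal conditional,
and the residual variance from the observed-row sum of squares.  Masked
phenotypes are handled by likelihood exclusion (not data augmentation);
the linear predictor is stored at every row, and prediction is its
posterior mean at the masked rows.  The study-scale schedule is
60,000 iterations / 10,000 burn-in / thin 50; the package default for
desk-scale fits and tests is 3,000 / 500 / 5, which at n ≈ 2,000 already
yields stable posterior means for variance fractions.  Uniform bounds on
fixed effects would never be active at these scales, so the flat prior is
used directly.  Empirical credible intervals are shortest-window (HPD)
intervals over the stored draws, ties broken toward the lowest start for
determinism.

Variance decomposition follows the per-iteration rule: at each stored draw
the sample variance across individuals of each fitted effect vector (and
of Xb) is recorded and summarized by posterior mean and 95 % HPD interval.
Because fitted effect vectors are not mutually orthogonal, the component
means need not sum exactly to Var(y); a ±15 % relative slack is the
documented expectation.  Prediction quality is measured on the validation
rows by accuracy r = cor(y, ŷ) and the bias regression y = β0 + β1 ŷ + ε
(ideal 0 and 1).  In the Y-O design the old-cohort dummy columns have no
observations in the training set; their coefficients are inestimable, so
those columns are dropped and the affected validation rows take the
baseline cohort level — a deterministic stand-in for coefficients a
flat-prior sampler would otherwise leave unidentified.

## Genetic correlation between age groups

Treating Y-group and O-group phenotypes as two traits, the bivariate model
has covariance σ²_gY G_YY, σ²_gO G_OO, σ_gYO G_YO across blocks plus
group-specific residuals, with per-group intercepts and the top 10 GRM
eigenvectors as fixed covariates.  The five (co)variance parameters are
estimated by average-information REML with step halving, variances floored
at 1e−8·Var(y) and the covariance clamped so |rG| ≤ 0.99999 (boundary
solutions flagged).  rG = σ_gYO/√(σ²_gY σ²_gO); its standard error comes
from the delta method applied to the inverse average-information matrix at
the optimum — the AI matrix is the standard observed-information surrogate
in REML software — and the interval is rG ± 2·SE.  AI-REML was chosen over
generic quasi-Newton maximization because it converges in a handful of
iterations on dense desk-scale problems, each iteration costing one
Cholesky factorization; the estimand is identical.

## Synthetic data

The generator draws biallelic dosages in Hardy–Weinberg proportions with
per-variant frequencies uniform on a configurable range (default
0.05–0.5), independent across variants (no linkage disequilibrium and no
population structure, matching the analysis assumption of a homogeneous,
unrelated sample; the structure-control model M01 is a negative control by
design).  Optional near-duplicate pairs copy a row and re-draw 1 % of its
entries — guaranteeing GRM entries near 1 for pruning tests — and
missingness is i.i.d.  Demographics are uniform ages 40–70, balanced sex
and a Bernoulli medication flag (default 20 %).

Each lifestyle column is the exact sum of four parts, each rescaled
in-sample to its configured variance fraction (defaults: cohort 5 %,
additive-genetic 3 %, cross-lifestyle 18 %, residual 74 %, matching the
reported decomposition of real lifestyle panels): a per-class cohort
effect, a polygenic score, loadings on shared latent factors (default 4),
and Gaussian noise.  Exact in-sample rescaling makes the truth fractions
exact, which simplifies recovery tests.  By default the genetic pathway of
all lifestyle variables runs through a single shared polygenic score with
per-variable signs — emulating a dominant heritable behavioural/adiposity
axis.  This is deliberate: at desk-scale n, idiosyncratic per-variable
genetic components of a few percent heritability are statistically
invisible to any adjustment method, whereas a shared score is exactly the
structure the cross-lifestyle regression and genomic term can remove.  A
`genetic_common_frac` knob interpolates toward independent per-variable
scores.  Lifestyle variables are emitted as Gaussian columns; an optional
flag discretizes leading columns into 5 ordinal levels (the truth record
then describes the latent continuous variables, so the exact-sum
invariant applies to the default continuous mode).

Traits are built on a latent unit scale as the exact sum of cohort,
additive-genetic, lifestyle, genotype-by-lifestyle and residual parts
(defaults 12/10/5/2/71 %, blood-pressure-like).  The genetic part routes a
fraction `rge_overlap` (default 0.5) of its variance through the
lifestyle-shared score — this, not variant-set overlap alone, is what
creates genotype–environment correlation, since independent effect sizes
on shared variants would leave the components uncorrelated.  Young/old
effect heterogeneity mixes the young score with an in-sample
orthogonalized second score so the realized young–old correlation equals
`rg_young_old` exactly (default 0.9).  The lifestyle part of a trait is a
random linear combination of the non-genetic, non-cohort lifestyle
components; the interaction part is the standardized elementwise product
of the genetic value and the lifestyle composite, inducing exactly the
G ∘ K covariance the models assume.  SP and DP latents are drawn with
independent effect vectors and emitted as mmHg-like readings (means
137/82, sds 18/11) with 15/10 mmHg subtracted from medicated individuals,
so the preprocessing adjustment reverses it.

What the generator does *not* emulate: linkage disequilibrium, realistic
allele-frequency spectra, population stratification or relatedness beyond
planted duplicates, ordinal/binary measurement of most lifestyle
variables, and SP–DP correlation.  Passing tests therefore demonstrate
correctness of the estimators and of the adjustment mechanism under the
assumed covariance structure, not robustness to confounding by structure
or to measurement artefacts in real data.

## Problem sizes used in tests and scripts

Parameter-recovery tests run at n = 2,000 / p = 3,000 with the reduced
schedule across 10 seeds; rG recovery at n = 2,000 / p = 1,000 across 10
seeds per target value; the rGE-reduction check at n = 2,000 / p = 250
(the low-dimensional genome keeps the lifestyle genetic component
estimable at desk-scale n — with effective marker counts far above n·h²,
no method could remove it and the check would test nothing); the split
comparison at n = 2,000 / p = 1,000 over 5 seeds; the analysis drivers at
n = 800 / p = 1,500.  These sizes are the package's chosen desk-scale
study conditions; estimates at these sizes carry proportionally larger
Monte-Carlo error than the motivating study's n ≈ 10⁵.

## Known limitations

* The Gibbs sampler stores full effect-vector draws; memory grows as
  (stored draws) × n per term, which is fine at desk scale but would need
  thinning-on-write for n ≫ 10⁴.
* AI-REML standard errors understate uncertainty near the |rG| = 1
  boundary; boundary solutions are flagged rather than profiled.
* The per-variable adjustment fits are embarrassingly parallel but run
  serially.
* Null kernel variance components have a positive posterior floor (see
  above); comparisons across models are unaffected, absolute small
  fractions should be read with that floor in mind.
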