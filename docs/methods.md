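# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limits of what the test suite demonstrates.

## Transmission model and error estimation

At a biallelic site with minor-allele frequency *m*, a sire heterozygous
for the minor allele transmits it to a son with probability ½; under random
mating the dam independently contributes at least one copy with probability
1 − (1 − m)² ≈ 2m, folded into the linearized carrier probability

  p(carrier son | het sire) = 0.5(1 − m) + m = 0.5 + 0.5 m,

exact if the dam contributes a single gamete draw at frequency *m*. For an
unrelated pair scored the same way the "son" is just a population sample,
so the curve drops to the Hardy–Weinberg carrier probability 1 − (1 − m)²,
which is below 0.5 + 0.5m for m < 0.38 — this separation is what makes the
related/unrelated contrast informative.

**Error fraction.** If a fraction ε of sire-heterozygote calls at a site
class are false (the true genotype is homozygous reference), transmission
is observed only at the 1 − ε true calls, so the pooled observed proportion
is ≈ (1 − ε)·p_expected + ε·(≈2m), and clip(1 − observed/expected, 0, 1)
recovers ε up to a term of order m/p_expected (< 0.02 for rare sites).

**Reference frequencies.** MAF used for binning and for the expectation is
computed from animals *outside* the duos. Using the full sample would be
circular: a non-transmitted allele lowers the very frequency used to bin
the site, sorting non-transmitting sites into the lowest bins and biasing
observed transmission downward there (we measured a ~0.05 artefactual
deficit in the lowest bin before making this change).

**Loess.** Smoothed transmission curves use locally weighted regression
with tricube weights and local polynomials of degree 2; the span (default
0.2, i.e. one fifth of the points influence each fit) selects the nearest
span·n points per evaluation point. Implemented in-package because the
installed nonparametric smoother is degree-1 only; it is cross-checked
against that smoother on linear signal, where both are unbiased. The
control band across unrelated pairs is a pointwise min–max envelope of the
per-pair curves by default (a quantile option exists); the choice matters
little with ≥ 10 pairs.

**Saturation projections.** Validated-count resampling draws, for every
subset size N from 1 to the number of duos, 50 random duo subsets and
counts distinct validated rare variants. Two parametric summaries are
fitted: an OLS quadratic over all replicate points, projected at its vertex
(duos needed = ⌈−b/(2c)⌉, the minimum whole number of duos at which the
fitted curve stops growing), and a saturation curve y = T(1 − e^(−kN)) by
bounded nonlinear least squares (T₀ = 1.1·max count, k₀ from inverting the
model at the mean; tolerances 1e-8, cap 500 evaluations). The two families
agree only approximately on real saturating data and both are reported;
neither is forced onto the other.

**Validation rule.** A rare site is validated when both members of at
least one duo carry ≥ 1 copy of the minor allele (carries-allele mode); a
strict both-heterozygous mode is available behind a flag. Carries-allele is
the default because the het–het reading would silently discard the
informative (but rare) homozygous-carrier configurations.

## Variance-component model

The analysis model is y = 1μ + Σ_c u_c + e with u_c ~ N(0, σ²_c M_c) and
e ~ N(0, σ²_e D). M_c is either a genomic relationship matrix G built from
one MAF class of markers or the pedigree numerator matrix A. D = diag(1/wᵢ)
encodes phenotype precision: a daughter trait deviation backed by w
effective daughters has residual variance σ²_e/w. This is the standard
reading of residual weighting for progeny-derived phenotypes.

**G.** Off-diagonals average (x_ik − 2p_k)(x_jk − 2p_k)/(2p_k(1−p_k));
diagonals use the homozygosity-corrected estimator
1 + (x² − (1+2p)x + 2p²)/(2p(1−p)), whose expectation is 1 + F under HWE.
Allele frequencies default to those observed in the analyzed sample.
Missing genotypes are mean-imputed to 2p_k (zero contribution after
centering); the corrected diagonal averages over each animal's non-missing
sites. A plain cross-product diagonal is available behind a flag.

**Bending.** The corrected diagonal is not a cross-product, so G from few
or very rare markers can be indefinite — we measured a minimum eigenvalue
of −0.78 for a rare-class G built from ~550 markers. A Gaussian likelihood
over an indefinite kernel is undefined, and patching V with adaptive jitter
makes log-likelihoods non-comparable across optimizer iterations (we
observed alternative-model likelihoods below their nested null before this
fix). Each relationship matrix is therefore projected once onto the PSD
cone (negative eigenvalues clipped to zero) before fitting. Clipping
perturbs the kernel far less than the alternative diagonal shift of
|λ_min|·I, which in our experiments suppressed the rare component entirely;
with clipping, joint-share recovery is unbiased within measurement error.

**A.** Tabular method: A_ij = ½(A_{j,s(i)} + A_{j,d(i)}),
A_ii = 1 + ½A_{s(i),d(i)}, unknown parents contributing zero. Verified
against a gene-drop IBD oracle.

**REML.** Average-information updates with: projection of proposed steps
onto σ² ≥ 0, step halving until the log-likelihood does not decrease, an
exact EM step (σ² ← σ² + 2σ⁴·score/n) as fallback, and termination at a
stationary point if even EM cannot ascend. Components pushed to the
boundary with a negative gradient are pinned at zero. Convergence requires
relative log-likelihood change < 1e-8 and parameter change < 1e-6·var(y).
The residual variance is floored at 1e-12·var(y) because the REML
log-likelihood is unbounded as V → 0 when residuals vanish exactly.
Standard errors come from the inverse AI matrix at the optimum. On small
instances the estimator is verified to 4 decimals against direct
maximization of the explicitly coded likelihood.

**LRT.** Testing one extra variance component places the null on the
boundary, so the statistic is asymptotically a ½χ²₀ + ½χ²₁ mixture; the
α-level critical value solves ½P(χ²₁ ≥ c) = α, giving 6.635 at α = 0.005.
This is implemented as the default (a plain χ²₁ option exists) because it
is the only reading under which the conventional 6.635 threshold and the
stated α are mutually consistent. Type-I error of the rare-component test
is verified by simulation under a null in which the common-variant model is
exactly true — with any mis-specified extra variance source in the
generator, "type-I error" would not be well defined.

**Missing heritability** is (σ²ₐ − σ²g)/σ²ₐ from a pedigree-only and a
marker-only fit; negative values (markers capturing more than pedigree) are
reported as-is.

## Prediction

Variance components for prediction are re-estimated on the training set
only — never taken from a full-data fit — so validation phenotypes cannot
leak into the predictor. Merits for validation animals are
ĝ = Σ_c σ²_c K_c(val, train) P y, the joint-MME solution. The validation
set is the n latest-born phenotyped animals (ties broken by id). Metrics:
Pearson correlation; slope of observed on predicted (1 = unbiased); MSE
divided by σ²ₐ. The "additive-genetic-standard-deviation units" convention
is ambiguous between /σₐ and /σ²ₐ; we use /σ²ₐ, record the choice in the
output metadata, and provide a /σₐ flag. Metrics are unweighted; weights
enter only through the mixed-model equations.

## Synthetic-data generator

The generator emulates the study conditions rather than any particular
genome:

- **Pedigree**: 250 founders, 3 non-overlapping generations, 19 sires per
  generation with 2 sons and 2 daughters each; the final generation's
  sire–son pairs are the 38 sequenced duos. Founder pairs provide the
  unrelated control pairs.
- **Sites**: 8,000 unlinked biallelic sites; founder frequencies from a
  density ∝ 1/p on [1/(2N), 0.5] — a rare-heavy spectrum in which roughly
  15–35% of segregating sites fall below MAF 0.01 depending on founder
  count (a Beta option exists). Gene drop is exact Mendelian sampling.
- **Phenotypes**: per MAF class, 100 causal sites receive standard-normal
  effects, rescaled so each class's realized genetic variance equals its
  configured share of h²·σ²_P exactly (defaults: common 83%, rare 3%,
  uncommon 0%, untyped 14%; h² = 0.34; σ²_P = 100 trait units² — the
  production-trait configuration). The untyped share is carried by causal
  sites removed from the returned marker table, making "pedigree captures
  what markers miss" literally true in the generator. Residuals are
  N(0, σ²_e/wᵢ) with wᵢ = 1 + Gamma(2, 2).
- **Errors**: each homozygous-reference genotype at a rare or monomorphic
  site flips to a false heterozygote with probability 0.02 (within the
  0.5–2.5 % substitution-error range of short-read calling); 100 entirely
  spurious sites (error-only heterozygotes) are appended. Only the 0→1
  mode is modelled — it is the mechanism the duo test detects. A
  calibrated injector (`inject_false_heterozygotes`) can instead make an
  exact fraction of heterozygote calls false, for recovery experiments.
- All randomness derives from one integer seed via tagged substreams, so
  reruns are bit-identical.

What the generator does **not** emulate: linkage disequilibrium between
sites (sites are unlinked, so marker sets capture causal variance only
through co-segregation in families), imputation structure, selection, or
overlapping generations. Passing tests therefore demonstrate the
estimators' internal correctness and calibration under the assumed model,
not robustness to LD patterns or imputation artefacts of real sequence
data.

## Problem sizes used in the test suite

Simulation-based checks run at sizes chosen to keep the whole suite in a
few minutes on one core: transmission-law and error-recovery checks use a
480-animal population (38 duos, 20,000 sites; ≥ 500 sire-het observations
per tested bin); joint variance-share recovery uses 10 replicates of a
1,020-animal pedigree (shares pedigree 0.2 / common 0.7 / rare 0.1,
h² = 0.5, tolerance 0.07 on the mean); LRT type-I calibration uses 150
null replicates at 280 animals; the rare-exclusion prediction property
uses 12 replicates at 470 animals with the rare class carrying 15% of
genetic variance. Tolerances are 3 standard errors for sampling
comparisons and stated absolute bounds elsewhere.

## Known limitations

- Dense linear algebra throughout: practical to a few thousand animals.
- The quadratic projection is an extrapolation device; it degenerates
  (non-concave) when the observed range is far from saturation, and the
  pipeline then reports the projection as unavailable rather than a
  number.
- Single-run joint variance partitions at a few hundred animals carry
  large sampling error (the worked example in the README shows this);
  calibration claims are about replicate means.
- Single-trait analyses only; no dominance/epistatic components; no
  single-step blending of G and A.
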