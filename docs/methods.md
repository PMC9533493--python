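# Methods

This document states the statistical models, estimators and numerical
conventions implemented in `microbreed`, together with the assumptions behind
them and the places where a deliberate choice had to be made between
competing conventions.

## 1. Compositional data analysis (`microbreed.coda`)

Microbial gene abundances are relative: only ratios carry information.
All downstream analysis therefore works in log-ratio coordinates.

**Core filtering.** A feature belongs to the analysis core when it is present
(non-zero) in at least 70% of samples and its mean relative abundance is at
least the configured floor. Both thresholds are inclusive; the retained
sub-composition is re-closed to sum to one.

**Zero replacement.** Log-ratios require strictly positive parts. Zeros are
treated as sampling (count) zeros and replaced by the geometric
Bayesian-multiplicative (GBM) posterior estimate: for sample *i* with total
count *n<sub>i</sub>*, a zero in part *j* is replaced by
*s·t<sub>j</sub>/(n<sub>i</sub>+s)* and the non-zero parts are rescaled
multiplicatively so the row still sums to one. The prior composition *t* is
the closed column-wise geometric mean of the positive proportions and the
prior strength is *s* = 1/exp(mean log *t*). Ratios between non-zero parts
are exactly preserved. When the table has no zeros the operation is the
identity.

**Transforms.** alr<sub>ref</sub>(x)<sub>j</sub> = log(x<sub>j</sub>/x<sub>ref</sub>);
clr(x)<sub>j</sub> = log(x<sub>j</sub>) − mean(log x). clr rows sum to zero by
construction; alr is subcompositionally coherent for any sub-composition
containing the reference.

**Reference selection.** The alr reference is chosen so alr geometry
resembles the (isometric) clr geometry while the reference itself is stable
across samples: for every candidate reference we compute the Procrustes
correlation between the alr and clr sample configurations (sum of singular
values of the cross-product of the standardized configurations, equal to
√(1−disparity)) and the log-variance of the candidate. Candidates within
ε = 0.005 of the best Procrustes correlation compete on minimal log-variance.

**Fatty-acid indices.** N3 = ln((C18:3n-3 + C20:5n-3 + C22:5n-3 + C22:6n-3) /
(C12:0 + C14:0 + C16:0)) and CLA = ln((cis-9 trans-11 C18:2 + trans-11
C18:1) / (C12:0 + C14:0 + C16:0)): log ratios of beneficial acid groups to
the same hypercholesterolemic denominator, so both behave as unconstrained
quantitative traits.

## 2. Genomics (`microbreed.genomics`)

SNP QC removes SNPs with call rate < 0.95, Hardy–Weinberg equilibrium
χ²-test p < 10⁻⁸ (one degree of freedom, computed from genotype counts) or
minor-allele frequency < 0.05, and animals with call rate < 0.90. Remaining
missing dosages are mean-imputed per SNP.

The genomic relationship matrix follows VanRaden's method 2, with each SNP
centred by 2p̂ and standardized by its own heteroscedastic variance
2p̂(1−p̂), averaged over SNPs: G = Z Zᵀ/m with
z<sub>ij</sub> = (x<sub>ij</sub> − 2p̂<sub>j</sub>)/√(2p̂<sub>j</sub>(1−p̂<sub>j</sub>)).
Monomorphic SNPs and missing dosages are rejected (they must be handled by
QC/imputation first). A ridge of 10⁻⁶ is added to the diagonal only, so the
matrix is positive definite for the samplers; all comparisons that involve G
account for this diagonal-only perturbation.

Because p̂ is estimated from the sample itself, relationships are expressed
relative to the current population as base: the mean off-diagonal is near
−1/(n−1) regardless of family structure, and half-sib structure appears as
the within- minus across-family contrast (≈ 0.25), not as an absolute 0.25.

## 3. Bayesian GBLUP (`microbreed.gblup`)

For T traits on n animals,

y<sub>it</sub> = β<sub>l(i),t</sub> + g<sub>it</sub> + e<sub>it</sub>,

with one categorical fixed factor (diet × breed × experiment in the
motivating application), vec(g) ~ N(0, Σ<sub>g</sub> ⊗ G) and residual rows
e<sub>i</sub> ~ N(0, Σ<sub>e</sub>). Priors are bounded flat for all
unknowns, giving inverse-Wishart (scaled inverse-χ² for T = 1) full
conditionals for the covariance matrices, rejected at the bounds.

**Samplers.** The default sampler rotates the genetic block by the
eigenvectors of G, reducing the joint update to n independent T×T Gaussian
draws per iteration. A direct sampler that draws the whole genetic block
from the mixed-model-equation conditional (O(n³T³)) is kept for
cross-checking on small problems; the two agree within Monte Carlo error.

**Missing data.** Missing phenotypes are data-augmented from their Gaussian
conditionals each iteration. A trait recorded on no animal at all — the
prediction scenarios — is allowed only with fixed variance components; its
fixed effects are pinned at zero and its EBVs are borrowed entirely through
the genomic covariance with the observed traits.

**Chain settings.** Desk-scale default: 20 000 iterations, 4 000 burn-in,
thinning 4 (4 000 stored draws). `McmcConfig.paper_scale()` gives
1 000 000 / 200 000 / 100. Summaries report posterior mean, sd,
highest-posterior-density interval, the sign probability P₀ (posterior
probability that the parameter shares the sign of its posterior mean),
Geweke's Z and the Monte Carlo standard error.

**Model comparison.** DIC = D̄ + p_D with p_D = D̄ − D(ĝ, β̄, Σ̂ₑ), using the
conditional deviance of the observed records. The Bayes factor between the
genomic and non-genomic model is estimated from the posterior likelihood
draws. Two estimators are provided:

- `posterior-mean-likelihood` (default): ratio of the arithmetic means of
  the per-draw observed-data likelihoods, computed with log-sum-exp.
- `harmonic-mean`: the Newton–Raftery harmonic-mean estimator.

The default follows the convention this package standardizes on; note that
the arithmetic-mean-of-likelihoods estimator targets the posterior expected
likelihood, not the marginal likelihood, and is strongly favourable to the
better-fitting model (for clearly heritable features log BF can saturate;
values are clipped at exp(690) to avoid overflow). The screening decision
below therefore never rests on the Bayes factor alone.

**Conjugate oracle.** For the sub-model with no genomic effect and a flat
variance prior, σ²ₑ | y is inverse-gamma with shape (n−L)/2 − 1 and scale
SSR/2 (L factor levels, SSR the within-level sum of squares); the Gibbs
output is validated against this closed form.

## 4. Screening (`microbreed.screening`)

A feature belongs to the host-genomically influenced functional core (HGFC)
when both

1. DIC(genomic) − DIC(non-genomic) < −20, and
2. BF ≥ the FDR-controlled threshold.

The Bayes-factor threshold follows Wen's Bayesian-FDR construction: with
null fraction π₀ the posterior null probability of feature *i* is
π₀/(π₀ + (1−π₀)BF<sub>i</sub>); the threshold is the smallest observed BF
whose rejection set keeps the average posterior null probability ≤ α = 10⁻⁴.
π₀ is bounded above by min(1, 1/mean(BF)) (E[BF] = 1 under the null); the
fully conservative π₀ = 1 can be forced. With the default BF estimator the
BF condition is near-saturated for any genuinely heritable feature, so the
DIC cut carries the discrimination — measured operating characteristics on
simulated features (half h² = 0.5, half h² = 0) are TPR ≈ 0.96,
FPR ≈ 0.04.

Genomic correlations between a feature and a goal trait are declared
significant when P₀ ≥ 0.95 from the bivariate model; features carried
forward to selection must additionally have the same correlation sign for
all goal traits ("same-sign rule"), so that raising the feature raises (or
lowers) every goal together.

## 5. Network reduction (`microbreed.network`)

Phenotypes can be pre-corrected for the fixed factor by subtracting level
means; the factor's explained-variance share (one-way redundancy analysis,
equal to ANOVA R² per response) is reported.

The co-abundance graph connects features with |Pearson r| strictly above
0.30. Markov clustering (inflation 2.0) runs on absolute edge weights with
unit self-loops: alternate matrix squaring (expansion) and element-wise
powering with column renormalization (inflation) to convergence; attractor
rows define clusters, clusters below 2 members stay unclustered. The
implementation is validated against an independently coded dense MCL.

Candidate features for the selection index must have mean relative
abundance ≥ 10⁻⁴ (inclusive). Redundant candidates are pruned by
redundancy analysis: multivariate least squares of the column-centred goal
EBVs on the candidates, with each candidate's marginal F tested by
Freedman–Lane permutation (residuals of the model without the candidate are
permuted, added back to that model's fitted values, and the marginal F
recomputed; 999 permutations). Candidates with p > 0.05 are dropped.

## 6. Breeding (`microbreed.breeding`)

**Covariance assembly.** The T×T genomic and residual covariance matrices
are assembled from all T(T−1)/2 bivariate fits: off-diagonals from the
pair's covariance posterior means, each diagonal as the average of the
trait's variance estimates across its pairs. Because the blocks come from
different models the result need not be positive definite; **bending**
raises eigenvalues below 0.001 to 0.001 and reconstructs, reporting the
minimum eigenvalue before/after and the Frobenius and maximum element-wise
change so the perturbation can be compared with posterior uncertainty.
Bending is idempotent and leaves positive-definite matrices untouched.

**Microbiome-driven prediction.** Goal-trait EBVs are obtained from a
multivariate GBLUP in which the selected features are the observed traits,
the goal traits are set missing, and the bent covariance matrices are held
fixed. Accuracy per animal is √(1 − sd²ᵢ/(G<sub>ii</sub>σ²_g)), with ratios
above one (Monte Carlo noise) clamped to accuracy 0 with a warning.

**Selection.** Animals are ranked on the equal-weight sum of goal EBVs (ties
broken by animal id). The selection intensity for proportion p is
i = φ(z)/p with z the standard-normal upper-p quantile; p = 1 gives 0.
Response to selection is computed per stored draw as mean(EBV of selected) −
mean(EBV of all), standardized by the phenotypic sd, and summarized by its
posterior mean and sd. Correlated responses (e.g. methane yield) use the
same ranking with the correlated trait's EBV chain, the correlated trait
having been set missing so its EBVs flow through the estimated genomic
covariances.

## 7. Synthetic-data generator (`microbreed.simulate`)

The generator produces a complete study at configurable size: half-sib
genotypes (one sire gamete, one population gamete; allele frequencies
uniform on the MAF range; SNPs that come out monomorphic in the realized
sample are dropped before the GRM), goal traits built from correlated
N(0, G) factors with target heritabilities (defaults 0.76/0.57) and genomic
correlation (0.39), a 17-level fixed factor explaining 40% of phenotypic
variance, and a compositional microbiome: latent log-abundances with
per-feature heritabilities, a subset loading on the goal factors at target
genomic correlations, closed and sampled multinomially at a depth calibrated
to a 5% zero fraction. An optional methane trait (h² = 0.30, genomic
correlation −0.30 with the goals) supports correlated-response studies.
Ground truth (breeding values, per-feature h² and correlations) is returned
for validation.

The generator's scope is evaluation and documentation: it makes no attempt
to mimic taxonomic composition, phylogenetic structure, or real
linkage-disequilibrium patterns.

## 8. Pipeline determinism

Every stage derives its random seed as the first four bytes of
SHA-256("{seed}|{stage}|{item}"), so runs are reproducible per stage and
item regardless of execution order, and reruns are byte-identical (only
timing entries in the manifest differ). When no feature passes the joint
significance and same-sign rules (small studies), the selection stage falls
back to the HGFC set — thresholds are never relaxed — and records the mode
in `selection_meta.json`.

## 9. Known limitations

- The default Bayes-factor estimator is not a marginal-likelihood estimator
  (see §3); inference about the HGFC rests jointly on DIC and the
  FDR-threshold construction.
- The bounded-flat variance priors make posterior means of ratio parameters
  (h², genomic correlations) slightly skewed at small n; at n = 250 the h²
  posterior-mean bias is about +0.04 with a replicate sd of ~0.12.
- Accuracy uses posterior-sd shrinkage against G<sub>ii</sub>σ²_g; with short
  chains individual animals can exceed the bound and are clamped.
- Single categorical fixed factor only; no polygenic-plus-marker mixtures,
  no dominance or epistasis; single generation (no recurrent selection).
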