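# Methods

## The model

`qtsgwas` maps quantitative trait SNPs (QTSs) under a full genetic model.
For accession *k* grown in environment *h*, the phenotype is

    y_kh = mu
         + sum_i  a_i  x_Aik  + sum_i  d_i  x_Dik
         + sum_{i<j} aa_ij x_AAijk + ad_ij x_ADijk + da_ij x_DAijk + dd_ij x_DDijk
         + e_h
         + sum_i  ae_ih u_Aik + sum_i de_ih u_Dik
         + sum_{i<j} aae_ijh u_AAijk + ade_ijh u_ADijk + dae_ijh u_DAijk + dde_ijh u_DDijk
         + eps_khr

with coefficient coding x_A = 1/0/-1 and x_D = 0/1/0 for QQ/Qq/qq (Q is
the major allele by default), epistasis coefficients formed as products of
the single-locus columns (x_DA = x_D(i) * x_A(j), completed by symmetry
with the other three products), and u-coefficients equal to the matching
x-coefficients.  Genetic effects (a, d, aa, ad, da, dd) are fixed; the
environment main effect and every per-(effect, environment) interaction
(ae, de, aae, ade, dae, dde) are random with their own variance component;
eps is the residual over replicates.

## Mapping strategy

Because neither the number nor the position of QTSs is known, mapping is
staged:

1. **GMDR prescreen** (`gmdr`).  Candidate SNPs are ranked by a
   cross-validated testing statistic on multilocus genotype cells.  The
   score of a quantitative trait is its null-model residual — grand-mean
   centered, or centered within environment when the environment covariate
   is included.  A cell is labeled high when its mean training score is
   positive; the testing statistic is the balanced accuracy of sign(score)
   against the cell label on held-out folds (10-fold CV).  Two strategies
   run (with and without the covariate) and the union of the per-strategy
   top-k SNPs is retained.  Combinations up to three-way are enumerated
   exhaustively on small panels; on large panels a marginal beam (top
   single-SNP candidates seed the higher orders) replaces full enumeration,
   with the exhaustive path retained for oracle tests.  The cell threshold
   (0), the statistic (balanced testing accuracy) and 10 folds are the
   conventional GMDR choices; none is prescribed by the method's sources,
   so each is a documented package convention.

2. **1-D and 2-D scans** (`model.scan_1d*`, `scan_2d*`).  The scan stage
   uses a fast fixed-effects approximation: the environment enters as
   fixed blocks (absorbed by within-environment centering) and the joint
   hypothesis of interest — (a, d) for single loci, the four epistasis
   terms for pairs — is tested with a partial F statistic against the
   residual.  A joint test of the genotype-by-environment interaction
   columns is reported alongside when there are at least two environments.
   Degenerate columns (monomorphic dominance, empty two-locus cells) are
   dropped with the df adjusted.  Missing genotypes are mean-imputed per
   locus at this stage only.

3. **Permutation thresholds** (`model.permutation_threshold`).
   Experiment-wise control follows the max-statistic permutation scheme:
   the accession-to-phenotype assignment is permuted within environment
   (whole accession blocks when replication is balanced), the maximum scan
   statistic over the family is recorded per permutation, and the
   (1 - alpha) upper quantile (conservative "higher" rule, equivalent to
   rejecting when the permutation p-value (1 + #{max >= obs})/(B+1) is at
   most alpha) is the threshold.  Default B = 1000 permutations at
   alpha = 0.05.

4. **Full-model fit** (`model.fit_full_model`).  All significant loci and
   pairs enter one model estimated by a Gibbs sampler: flat priors on
   fixed effects, inverse-gamma priors on variance components, 20,000
   iterations with 2,000 burn-in by default, split-chain potential scale
   reduction reported as a convergence diagnostic.  Point estimates are
   posterior means; per-effect -log10 p values come from the posterior
   mean/sd Wald ratio against a standard normal, with the conventional
   "-log10 p > 7" reporting label attached in the effect tables.

### Identifiability of random interaction blocks

Each GxE block's H design columns sum exactly to its parent fixed-effect
column (the u-coefficients equal the x-coefficients), so the block mean is
confounded with the parent effect.  The sampler therefore works in an
orthonormal sum-to-zero contrast basis: the H-1 contrast coefficients are
data-identified, while the confounded mean component kappa ~ N(0, s2/H) is
drawn from its conditional prior each sweep and folded back into the
reported fixed effect.  This is an exact reparameterization of the
unconstrained model, and it makes the reported credible interval of a
fixed effect include the genuine uncertainty about the mean of its
interaction terms.  With a scale-free block prior the implied marginal
for kappa approaches an exactly pivotal t with H-1 degrees of freedom —
with only three environments a block variance is learned from two
contrasts, and the heavy t tails are what keeps interval coverage honest.
A fully scale-free inverse-gamma, however, has a near-absorbing state at
zero variance (the familiar InvGamma(eps, eps) pathology), which
truncates the upper tail of the sampled kappa and erodes coverage.  The
default block prior is therefore shape 0.01 with a small rate (3e-3 in
squared trait units), chosen by a calibration study of a stylized version
of the sampler: 2,000 frequentist replicates of kappa-interval coverage
against the rate parameter, balanced against the spurious variance a
truly null block absorbs (coverage ~98%, null-block mean square below
0.002 at the default).  The same treatment applies to the environment main
effect (confounded with mu).

Because the variance posterior for a 3-level block has very few degrees of
freedom, the reported variance component is the posterior **median** of
the realized mean square of the block effects (kappa^2 + ||contrasts||^2/H)
rather than a posterior mean, which the heavy upper tail would destabilize.
The residual variance, well identified by thousands of observations, is
reported as a posterior mean under a vague inverse-gamma prior
(shape = rate = 0.01).

## Heritability partition

The phenotypic variance V_P is the variance of environment-centered
observations: the environment main effect is excluded from the denominator
(total heritabilities above 90% are arithmetically impossible otherwise),
while GxE and residual variation remain in it.  Each fixed effect
contributes `estimate^2 * Var(column)` and each GxE component contributes
`variance * mean(column^2)` — the second moment enters because the
coefficient columns are not standardized, and without that factor the
per-class entries would not add up to the share of V_P the component
actually explains.  Class aggregates are sums of member effects and the
total h2_T is the sum of the aggregates, so the partition is additive by
construction.  Covariances between non-orthogonal coefficient columns
(substantial for x_A vs x_D at extreme allele frequencies) are ignored in
this marginal partition; `heritability.joint_genetic_variance` provides the
joint alternative.  The genotypic correlation r_g between two traits is the
Pearson correlation across accessions of their total predicted genetic
values (main + epistasis, no environment terms); the phenotypic r_p uses
accession means pooled over environments (switchable to per-environment).

## Superior-genotype design

Designs optimize the pure genetic value (mu and the environment main
effect excluded): GSL/GSH over main + epistatic effects only, SL/SH adding
the predicted GxE effects of one environment (epistasis-by-environment
terms included by default, switchable).  Line designs restrict loci to
homozygotes; hybrid designs allow heterozygotes per locus without
cross-locus parental feasibility constraints.  The optimum is exact: loci
are partitioned into connected components of the epistasis graph, isolated
loci are optimized independently, components are enumerated exhaustively
(refused above 20 loci), and ties break lexicographically (QQ < Qq < qq).
Both maximization and minimization are supported — for fatty acids such as
myristic and palmitic the breeding goal is a minimum.

## Synthetic data

The generator emulates the study design: 316 accessions in two
subpopulations, three environments with three replicates, MAF floor 0.01,
LD half-decay around 160 kb at ~5 kb SNP spacing.  Subpopulation allele
frequencies follow a Balding-Nichols draw around a shared ancestral
frequency (Uniform(0.1, 0.9)), with `divergence` the Fst-like parameter.
Haplotypes threshold a latent Gaussian AR(1) process at each SNP's
frequency quantile, so marginal frequencies are exact while allele
correlation decays with physical distance; the decay constant is
calibrated (factor 2.6 in the exponent, set by pilot simulation) so the
binned genotype r2 halves at `ld_block_bp`.  A configurable fraction of
accessions (default 0.5) are fully homozygous lines, reflecting a
germplasm collection under partial selfing; the remainder follow
Hardy-Weinberg within subpopulation.  This keeps per-SNP heterozygosity
compatible with the 30% QC cap while preserving the heterozygote classes
that dominance and dd effects need.  SNPs whose empirical MAF lands below
the floor are dropped, so a panel can hold slightly fewer SNPs than
requested.

Phenotypes are drawn exactly from the model above: environment effects
once per environment, GxE effects once per (planted effect, environment)
with a per-class standard deviation, residuals per observation.  The
companion `true_heritabilities` oracle reports the h2 values implied by
the architecture and the realized genotype frequencies with the same
variance formulas as the estimation side, so parameter-recovery
comparisons are internally consistent.

What the generator does **not** emulate: tetraploid subgenome homoeology,
ascertainment of the SNP discovery pipeline, non-exchangeable GxE
(genotype-environment correlation), linked selection, or realistic
missingness patterns (missingness and excess heterozygosity are injected
uniformly at random by `degrade_panel`).  Passing tests therefore certify
the statistical machinery under the model's own assumptions, not
robustness to the full complexity of field data.

## Verification experiments and problem sizes

`scripts/acceptance.py` re-runs, at sizes chosen to finish in minutes on
one CPU:

* the aggregation identities on the packaged per-trait tables (instant);
* the Bonferroni threshold 0.05 / 203,021;
* LD half-decay recovery at the 160 kb setting (316 accessions, 300 SNPs,
  one chromosome);
* a 20-seed parameter-recovery study at the study's design shape (316
  accessions x 1,000 SNPs, 3 environments x 3 replicates) with a planted
  architecture of a = 0.6, d = 0.5 at one locus, dd = 1.5 at a pair, and a
  weak additive-by-environment component (sd 0.2), residual and
  environment sd 1.  Effect sizes were chosen to sit in the per-effect h2
  range the study's tables report (single-effect shares of a few to ~20
  percent); the GxE component is kept weak because with three environments
  the additive share of a locus carrying strong GxE is only weakly
  identified (its estimate absorbs the interaction mean).  The study
  reports per-seed credible-interval coverage of each planted effect and
  the seed-averaged class-heritability error against the
  `true_heritabilities` oracle, with the sampler run at 4,000 iterations
  (800 burn-in) per seed — pilot runs showed estimates indistinguishable
  from the 20,000-iteration default on this problem size;
* the experiment-wise type-I error of permutation-thresholded scans, 600
  independent null replicates of a 200-SNP x 200-accession scan with
  1000-permutation thresholds at alpha 0.05 (600 rather than the minimal
  200 replicates, purely to tighten the binomial Monte-Carlo error of the
  reported rate).

## Known limitations

* The scan-stage F statistic is a fixed-effects approximation of the mixed
  submodel; its null calibration is verified by simulation, but it is not
  the REML/likelihood-ratio statistic a full mixed-model scan would use.
* Variance components of 3-level random blocks are intrinsically noisy;
  per-seed GxE heritabilities scatter widely even when the seed-averaged
  estimates are accurate.
* The marginal heritability partition can overstate (or understate) the
  joint variance explained when coefficient columns are strongly
  correlated, e.g. additive and dominance columns at extreme allele
  frequencies.
* GMDR screening power is reported for additive architectures; the beam
  heuristic can miss purely epistatic pairs whose members have no marginal
  signal unless the exhaustive path is used.
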