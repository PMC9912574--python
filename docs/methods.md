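# Methods

This package implements a complete two-trait genetic evaluation for a
family-structured aquaculture breeding program — fillet yield (FY, %) and
body weight (BW, g) in rainbow trout are the motivating trait pair — plus a
seeded simulator of such a program for testing and calibration.

## The model

For each trait `t`,

    y_t = X b_t + Z1 u_t + Z2 f_t + e_t

* `b_t` — fixed effects.  FY: harvest age (covariate), line (high/low),
  and the harvest-year x slaughter-group interaction.  BW: age (covariate),
  line, and hatch year.  The first factor of each trait is coded with one
  dummy per level (it absorbs the intercept); later factors drop their
  first level, which fixes the estimable functions reproducibly.
* `u_t` — additive genetic effects with covariance `Su (x) K`, where `K`
  is the pedigree numerator relationship matrix `A` (PBLUP) or the
  single-step matrix `H` (ssGBLUP).
* `f_t` — a common full-sib family effect, covariance `Sf (x) I`.  It
  captures the shared early-rearing environment of full-sib tanks.
* `e_t` — residuals with 2x2 covariance `Se` acting within animal; a fish
  recorded for one trait only contributes that trait's residual variance.

`Su`, `Sf`, `Se` are full symmetric 2x2 matrices by default; the family and
residual cross-trait covariances can be fixed at zero through
`estimate_vc_aireml(..., free_cov=...)`, and whole components can be held
fixed (`fix_components=`), which the test suite uses for closed-form
cross-checks.

## Relationship matrices

* `A` is built by the tabular method; inbreeding `F` by the Meuwissen–Luo
  recursion (results cached per full-sib family); the sparse `A^-1` by
  Henderson's rules with inbreeding-adjusted Mendelian-sampling variances.
  Unknown parents are unrelated, non-inbred base animals — the model
  carries no genetic groups.
* `G = Z D Z' / (2 Σ d_i p_i (1 - p_i))` (VanRaden), `Z` centered at twice
  the base-population allele frequencies, `D` the SNP weights (identity
  unless weighted ssGBLUP is running).  The weighted denominator keeps
  `trace(G)` stable as weights change across iterations, so the genetic
  variance attached to `G` remains comparable; `lambda = 1/(2 Σ d_i p_i
  (1-p_i))` is the matching shrinkage constant used when backsolving SNP
  effects (it makes the backsolve the exact inverse map of the `G` in use).
* Base allele frequencies come from gene-content GLS:
  `2 p_j = (1' A22^-1 m_j) / (1' A22^-1 1)`, the limiting form of gene-content
  BLUP as the gene-content variance ratio goes to zero; missing entries are
  excluded through the corresponding observed sub-block of `A22`.
  Frequencies are clamped to [0.01, 0.99] to protect the heterozygosity
  denominator.  Using base frequencies makes `G` and `A22` refer to the
  same base population, so no further compatibility tuning is applied;
  a small blend `G <- (1-tau) G + tau A22` (default `tau = 0.05`,
  `tau = 0` allowed) guards invertibility when near-duplicate genotypes
  (many sibs per family) make `G` ill-conditioned.
* `H^-1 = A^-1 + [[0,0],[0, G^-1 - A22^-1]]` on the genotyped block.
  `A22` is formed densely from the full-pedigree `A` and inverted directly;
  the genotyped subset at the scales this package targets (a few thousand
  animals) makes that the simplest exact route.

## Solving and REML

The mixed model equations are assembled sparse (residual weights per
record pattern, `Su^-1 (x) K^-1` and `Sf^-1 (x) I` priors) and solved by a
direct sparse LU factorization; the factor is retained so blocks of the
inverse coefficient matrix (needed for SNP-effect sampling variances) can
be extracted on demand.  A Jacobi-preconditioned conjugate-gradient solver
is available as an alternative and is cross-checked against the direct
solve in the tests.

Variance components are estimated by AI-REML in the phenotypic-covariance
(`V`) parameterisation: with a few thousand records, `V` is dense and one
Cholesky factorization per iteration yields the restricted likelihood, the
exact trace terms of the score, and the average-information matrix from
nine working variates.  This is numerically identical to the conventional
sparse-MME formulation with selected-inverse trace terms; it was chosen
because a supernodal sparse Cholesky with a selected inverse is not among
the available building blocks, and at desk scale the dense route is exact
and fast.  Numerical choices:

* traits are standardized internally to unit phenotypic variance (the two
  traits differ by four orders of magnitude in scale), and estimates,
  SEs and the parameter covariance are transformed back on exit;
* the AI step is Levenberg–Marquardt damped (`AI + lm * diag(AI)`), with
  `lm` adapted by success/failure.  The restricted likelihood is often
  non-concave along weakly identified directions (additive vs family
  variance in deep full-sib designs), where an undamped AI/Newton step
  overshoots;
* diagonal variances may not shrink more than ten-fold per iteration, and
  variances pinned at the boundary with an outward score are frozen
  (active set) so they cannot corrupt the step;
* candidate parameter vectors are repaired by clipping correlations to
  +-0.999 and eigen-projecting each 2x2 component onto the PSD cone;
* two EM warmup iterations absorb wild starting values, and an EM step is
  the fallback whenever no damped AI step improves the likelihood;
* the geometric tail of the iteration is accelerated by Aitken
  extrapolation (accepted only if it improves the likelihood);
* convergence: relative parameter change < 1e-8 (or likelihood
  stagnation below 1e-9 relative with parameter changes < 1e-6, which is
  reported as converged; hitting the iteration cap is flagged
  non-converged and the current estimates are returned).

Standard errors of the components come from the inverse AI matrix at the
optimum; SEs of heritabilities, family fractions and the genetic
correlation by a numerical delta method over that covariance.

Adjusted phenotypes are `y* = y - X b - Z2 f` — the family effect is
removed together with the fixed effects, so `y*` is an additive-genetic
plus residual quantity.

## Validation

* **Mid-parent**: full-sib families keyed by (sire, dam); families sharing
  a sire or dam with an earlier family are dropped (half-sib removal,
  first occurrence kept).  The family-mean progeny phenotype (raw or
  adjusted) is correlated with and regressed on the parent average
  `PA = (u_sire + u_dam)/2`.  The regression is of family mean **on** PA,
  so a slope below 1 reads as over-dispersed breeding values; the
  alternative direction (PA on phenotype) would invert that
  interpretation and is not used.
* **Adjusted-phenotype forward validation**: `accuracy = cor(y*, u_p) /
  sqrt(h2)`, with `y*` from the whole-data pedigree run and `u_p` from a
  partial run whose validation-cohort phenotypes (both traits) are
  removed; genotypes are retained.
* **LR method**: accuracy `sqrt(cov(u_w, u_p) / ((1 - Fbar) sigma2_u))`
  (whole-data REML `sigma2_u`, pedigree mean inbreeding of the validation
  animals), bias `mean(u_p) - mean(u_w)`, dispersion slope
  `cov(u_w, u_p)/var(u_p)`, consistency `cor(u_w, u_p)`.  A negative
  covariance makes the accuracy undefined; it is flagged rather than
  silently clipped.  All moments use the n-1 denominator, consistent with
  the regression slope.

## Single-step GWAS and weighted ssGBLUP

SNP effects are backsolved one trait at a time:
`a_hat = lambda D Z' G^-1 u_hat_g`.  Their sampling variances use
`Cov(u_hat_g) = sigma2_u G - C^uu`, with `C^uu` the genotyped block of the
inverse MME coefficient matrix extracted from the retained sparse factor —
the exact, small-scale version of the usual approximation.  P-values are
two-sided normal; the display threshold is Bonferroni,
`-log10(alpha/n_snp)`.

Window variances are computed over sliding windows (step 1) of 20 adjacent
SNPs within a chromosome: the variance across genotyped animals of the
summed window contribution `Σ z_i a_i`, as a percent of the additive
variance.  Sliding windows were chosen over disjoint ones as the common
ssGWAS practice; a chromosome shorter than the window yields one truncated
window with a warning.

Nonlinear-A weights are `d_i = CT^(min(|a_i|/sd(a), 5) - 2)` (the cap
prevents numerically explosive weights).  Weighted ssGBLUP iterates:
iteration 1 is the unweighted run; each later iteration backsolves
effects, renormalizes the weights to mean 1 (so the genetic variance scale
is stable across iterations), rebuilds `G` and `H^-1`, re-solves, and
records a validation statistic.  Variance components are held fixed
across iterations.

## The simulator

The generator emulates a divergent-selection fillet-yield program:
discrete generations of full-sib families (60 families x 15 offspring x 3
generations by default — the scale used throughout the acceptance
checks), a high line under truncation selection on family-mean EBVs from
an internal PBLUP, and a low line (20% of families) with one downward
selection followed by random mating over all of its families (keeping
the line's diversity, as the real program did).  Fillet-yield
phenotyping is lethal: FY-recorded fish never become parents.

Mate allocation is a greedy stand-in for the operational optimisation a
real program runs, engineered so the <=1%-per-generation inbreeding
constraint actually holds over five generations: pairs whose expected
progeny inbreeding `a(sire,dam)/2` exceeds the parental-generation mean
plus the limit are rejected; among feasible pairs the allocator first
spreads usage across parents (each individual breeds at most twice,
protecting the effective population size), then takes the least-related
pair, with *random* tie-breaking — a deterministic choice builds a
regular lattice pedigree whose families all become equally related at
the same moment and then violate the constraint at once.  When no
feasible pair exists inside the selected families, the pool is expanded
with the next-best families before any constraint-violating mating is
accepted (least-related fallback with a warning, realized inbreeding
logged).

Genetics: founder haplotypes are drawn from a finite-Ne coalescent with
recombination (msprime; Ne = 50 by default), so the founder population
carries ancestral LD of the magnitude a 57K-array livestock population
actually shows.  This matters: with founders in linkage equilibrium,
markers tag QTL only through within-pedigree cosegregation, and genomic
evaluation measurably *loses* to pedigree evaluation at this scale — the
opposite of what any real SNP-array population shows.  A linkage
equilibrium mode (`founder_ld=False`) is kept for algorithmic tests.
Alleles then drop through the pedigree with Haldane (Poisson)
recombination.  True breeding values come from 300 QTL excluded from the
marker panel.  Bivariate QTL effects are calibrated exactly: in the LE
mode the realized founder TBV covariance equals the target additive
covariance to machine precision; in the LD mode the effects are chosen
inside an isotropic subspace of the realized between-QTL disequilibrium
form, so that the genic covariance (`sum_q 2 p_q (1-p_q) beta_q beta_q'`,
which fixes the Mendelian-sampling variance a pedigree model expects at
`0.5 Su`) *and* the realized founder covariance both equal the target —
ancestral LD would otherwise leak a seed-dependent disequilibrium
contribution into the effect scale and distort heritability recovery
(the default targets are the FY/BW estimates the package is calibrated
against:
`Su = [[1.99, 45.0], [45.0, 17648]]` (r_g = 0.24), `Sf` diag `[0.24,
5679]`, `Se` diag `[2.60, 29913]`; family and residual cross-trait
correlations default to 0.3 — a realistic value for a part-whole trait
pair, freely re-estimated by REML and not part of any assertion).

Phenotypes: BW on every grown fish; FY on 5 fish per family chosen by the
rank-skipping rule (sort family by descending BW, exclude fish beyond 3 SD
of the family mean, keep every second fish), assigned to five weekly
harvest groups in descending BW order.  Fixed layers (year, line,
harvest-year x group, age covariate) are drawn once per simulation at
magnitudes small relative to the trait SDs.  The genotyped subset is the
FY-sampled fish (≈5/family) plus all parents, mimicking the real design's
within-family genotyping.

What the simulator does **not** emulate: genotyping error and missing
genotypes (QC paths are tested on constructed matrices instead), mutation,
sex-limited expression, overlapping generations, heterogeneous residual
variance across years, and the real population's admixture history.
Passing recovery tests therefore show correctness of the estimation
machinery under the stated generating model, not robustness to those
artefacts.

## Problem sizes and determinism

All stochastic checks run at desk scale: parameter recovery uses five
replicates of the 3x60x15 design (≈3,600 records, ≈6,000 mixed-model
equations); the genomic-vs-pedigree comparison uses ten replicates of a
30-family design with an 800-SNP panel; GWAS calibration uses twenty null
replicates in which breeding values are drawn from the pedigree so the
markers are truly unassociated.  Every random draw descends from a single
seed through named `SeedSequence` substreams, so each simulated dataset is
bit-reproducible.

## Known limitations

* Two traits maximum; no maternal effects; no genetic groups or
  metafounders.
* AI-REML near a variance boundary converges linearly despite the Aitken
  acceleration; boundary components are reported at the floor rather than
  exactly zero.
* `A22` and `G` are handled densely; populations with many tens of
  thousands of genotyped animals would need APY-type approximations that
  are deliberately out of scope.
* The greedy mate-allocation heuristic is a stand-in for the operational
  optimisation a real program uses; it enforces the same constraint but
  not optimal genetic contributions.
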