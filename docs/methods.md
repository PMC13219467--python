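# Methods

`forestgs` analyses two-site forest-tree progeny trials with genomic and
pedigree relationship matrices, and ships a synthetic-trial generator so
every estimator can be checked against known truth. This note documents the
models, the numerical choices, and what the synthetic data do and do not
emulate.

## The mixed model

A tree's phenotype is modeled as

    y = X b + Z_b b(s) [+ Z_p p(s)] + Z_a a(s) + Z_d d(s) + e

with fixed overall mean and site effect, and random terms

- `b(s)` — block within site, independent levels, per-site variances
  σ²b(s)1, σ²b(s)2;
- `p(s)` — plot within site (optional: present for row-plot designs,
  absent for post-block-only designs), same structure;
- `a(s)` — site-specific additive genetic effects, covariance
  `Va ⊗ K_a`;
- `d(s)` — site-specific dominance effects, covariance `Vd ⊗ K_d`;
- `e` — residual, per-site variances.

`Va` and `Vd` are 2×2 CORH matrices: unique variances per site plus one
between-site correlation each (the type-B genetic correlations r_a, r_d;
low values mean strong genotype-by-environment interaction). `K_a`/`K_d`
are either the pedigree matrices A and D, or blended genomic matrices
(GBLUP). Block and plot labels are nested-coded (`site:block`,
`site:block:plot`) so identical labels across sites never alias.

Negative across-site dominance variance is representable only through a
negative r_d — per-site variances stay non-negative — which is exactly how
negative dominance ratios arise.

## Relationship matrices

- `A`: tabular numerator-relationship recursion; founders unrelated and
  non-inbred.
- `D`: d_ij = f(s_i,s_j)·f(d_i,d_j) + f(s_i,d_j)·f(d_i,s_j), with f the
  pedigree coancestry (A/2); the standard non-inbred parametrization —
  inbred diagonals are not adjusted, adequate for the shallow pedigrees of
  progeny trials.
- `Ga` (VanRaden): dosages centered at 2p per SNP, divided by 2·Σ p_k q_k.
  Allele frequencies come from the analyzed sample; consequently realized
  full-sib values sit slightly below the pedigree 0.5 (the matrix is
  referenced to the sample mean). Missing calls are mean-imputed only
  inside the construction and counted in the matrix provenance.
- `Gd` (orthogonal/Vitezica parametrization): codes {0,1,2} →
  {−2p², 2pq, −2q²}, denominator Σ (2 p_k q_k)².
- Blending: `G_blended = (1−w)·G + w·P` with w = 0.02 by default (0.05 and
  0.01 are one argument away); the same weights apply to Gd/D. The inverse
  is a Cholesky solve with an enforced product check
  `max|B·B⁻¹ − I| < 1e−8`.

## AI-REML

The restricted log-likelihood −½(log|V| + log|XᵀV⁻¹X| + yᵀPy) is evaluated
on the dense observation covariance V. V is a linear combination of
precomputed constant structure matrices (block/plot incidence products,
site-masked kinship blocks, site-diagonal residuals), so each iteration
costs one Cholesky factorization plus O(n²) contractions for the score and
average-information matrix. At the scales this package targets (hundreds to
~1500 trees) this is faster and simpler than mixed-model-equation
evaluation with inverse kinship matrices; the inverses are still produced
and checked by `blend_and_invert` for interoperability.

Optimization runs on transformed parameters — log variances and
0.999·tanh-bounded correlations — with:

- AI (quasi-Newton) updates with step halving;
- an active set: a variance at the floor (1e−8 of the phenotypic variance)
  whose gradient points further down is frozen for that iteration, because
  its transformed AI row is numerically zero and corrupts the Newton
  direction;
- an L-BFGS-B polish with the analytic gradient when the AI loop stops
  short of the gradient tolerance (typically boundary solutions);
- targeted restarts: the restricted likelihood can be multimodal in the
  sign of a type-B correlation when the paired genetic variance is small,
  so a fit ending at |r| > 0.95 or with a pinned genetic variance is
  refit from flipped-correlation starting values and the best optimum
  kept. Warm-started refits (cross-validation folds, bootstrap) skip the
  restarts.

Convergence requires a log-likelihood change below 1e−6 and a gradient
norm below 1e−3 (free parameters only). Starting values: half the
phenotypic variance split equally between additive and dominance,
correlations at 0.5, small block/plot variances, remainder residual.
Components driven to the floor are flagged as pinned and reported as 0.00.
These tolerances are the package's defaults; they are not inherited from
any external software.

BLUPs solve û = Cov(u, y) V⁻¹(y − Xβ̂) through the same machinery; genetic
values are returned for every genotype at both sites with the home site
flagged, and EGV = EBV + EDV holds exactly by construction. Genotypes
without phenotype records are predicted through their kinship rows with the
observed genotypes.

## Genetic parameters

Across-site variances are recovered from the CORH fit as
σ²a = r_a(σ²aS1 + σ²aS2)/2 and σ²d = r_d(σ²dS1 + σ²dS2)/2 (negative when
the correlation is negative). The ratios share one denominator — the
site means of plot, additive, dominance and residual variances:

    h² = σ²a / denom,   d² = σ²d / denom,   H² = h² + d²

Note the denominator deliberately **excludes the block variance**: blocks
are treated as coarse environmental strata outside the individual-tree
phenotypic variance. The plot term drops out when not modeled.

Standard errors use the delta method with the inverse average-information
matrix (numerical central-difference gradients of each ratio with respect
to the raw components); pinned components get SE 0.00, and a singular AI
matrix yields NaN rather than fabricated values. A parametric bootstrap
(`parametric_bootstrap_se`, default 200 replicates refit from simulated
y* ~ N(Xβ̂, V̂)) is provided as a cross-check; on a 400-tree fixture the
two agree within ~10–15%.

## Cross-validation

Genotypes are split into k = 10 folds stratified by full-sib family (fold
sizes within a family differ by at most one). Each fold's phenotypes are
withheld **by deleting their records** — not by residualizing in place —
while the relationship matrices keep all genotypes, so predictions for
withheld trees flow purely through kinship; this matches standard GBLUP
validation and supports predicting non-phenotyped trees. Fold models are
refit by REML warm-started at the full-data components.

- PA_BV / PA_GV: Pearson correlation of cross-validated EBV / EGV with the
  raw observed phenotype, within site, using each genotype's home-site
  prediction. Phenotypes are deliberately not pre-adjusted for block or
  plot effects (an adjusted mode exists but is non-canonical); because the
  correlation is computed within site, the fixed site effect cancels.
- PACC_BV / PACC_GV: correlation of cross-validated values with the
  full-data-model values used as truth proxies.

All four are averaged over sites, then over repetitions. With clonal
ramets, one ramet per clone is redrawn per repetition and folding happens
at the genotype level, preventing genetically identical trees from sitting
on both sides of the split.

## Marker-density study

For each subset size in a grid (default arithmetic: 500, 1500, … plus the
full panel; explicit or logarithmic grids for large panels), SNPs are drawn
uniformly without replacement, Ga/Gd rebuilt and blended, the GBLUP-AD
model refit, heritabilities recomputed, and optionally cross-validation
rerun — five replicates per size by default, aggregated as means and
replicate SDs with the full-panel GBLUP-AD and the pedigree-only ABLUP-AD
fits as references. No formal plateau breakpoint is computed; an advisory
heuristic (smallest size from which the mean stays inside a band around
the full-panel value) is clearly labeled as an extension. Cells are
cached to disk keyed on (dataset hash, size, cell seed), so interrupted
runs resume.

## Synthetic trials

The generator emulates the structure of two-site conifer progeny trials:

- **Pedigree**: a partial diallel — distinct unordered parent pairs drawn
  at random from the possible crosses, each yielding one full-sib family.
  Family:parent ratios around 1–2 reproduce the half-sib network of real
  breeding designs; those half-sib links are what separates additive from
  dominance variance, so very sparse diallels make dominance poorly
  identified (a property of the design, not the estimator).
- **Genotypes**: founders at Hardy–Weinberg proportions in linkage
  equilibrium with per-SNP allele frequencies uniform on the MAF bounds;
  offspring by Mendelian gamete dropping. Unlinked segregation is the
  default for speed; linked mode places SNPs uniformly on 12 chromosomes
  totalling 2000 cM with Haldane recombination (Poisson crossovers, no
  interference). Linkage matters for marker-density questions — with
  unlinked markers every SNP contributes independent relatedness
  information and density curves stabilize only near the full panel,
  whereas on a 2000 cM genome a few thousand SNPs saturate the map —
  so density studies should use the genome map. LD arises only from
  family structure, as in the trial populations emulated.
- **Traits**: QTL subsets of the simulated SNPs; additive effects act on
  centered dosages, dominance effects on the orthogonal coding. Site
  specificity is built by recombining two QTL-effect images of the marker
  matrix so the realized between-site correlation equals the target
  exactly (the recombination stays a linear function of QTL effects, so
  marker–trait linkage is intact; calibrating on realized vectors is
  necessary because the family-structured genotype covariance has low
  effective rank and would otherwise push realized correlations toward
  ±1). Genetic values are rescaled so realized per-site sample variances
  among each site's trees hit the targets — realized (genic) scaling makes
  parameter-recovery tests well-posed at finite n.
- **Layout**: offspring of every family split evenly between the two
  sites; family row plots (default 4 trees) dealt into randomized complete
  blocks; block, plot and residual effects drawn at the per-site target
  variances; optional clonal ramets share genotype, genetic values and
  plot, and differ in residuals.
- All randomness flows from one seed through named substreams (pedigree,
  genotypes, effects, design, noise); identical configuration and seed
  reproduce every output bit-for-bit.

What the generator does **not** emulate: selection and multi-generation
structure, mutation, epistasis, spatially autocorrelated residuals,
genotyping-intensity artifacts, ascertainment bias of SNP panels.
Passing recovery tests therefore demonstrates estimator correctness under
the stated generating model, not robustness to these real-data features.

## Default study conditions used in tests

Parameter-recovery checks: 30 families from 15 parents, 20 offspring per
family (600 trees), 4000 unlinked SNPs, 200 QTLs; per-site additive 0.5,
dominance 0.1875, block 0.1, residual 0.3125 with r_a = r_d = 0.8, giving
h² = 0.4, d² = 0.15 against the shared denominator of 1.0. The
marker-density check uses the same architecture on 6000 SNPs over the
2000 cM map with grid {500, 1500, 2500, 3500, 4500, 6000} and five
replicates. These sizes keep the full suite to a few minutes on one core
while leaving Monte-Carlo error small enough for 3-SE recovery assertions.

## Known limitations

- Exactly two sites; the CORH machinery generalizes but is not exposed for
  more.
- Dense linear algebra bounds practical size to a few thousand trees.
- d² estimates on GBLUP fits carry a small positive bias near zero
  dominance (scale mismatch between sample-referenced genomic matrices and
  the generating covariance); visible in the boundary-behavior tests.
- The delta-method SEs rely on the asymptotic AI approximation and
  understate uncertainty in small samples — the bootstrap flag exists for
  exactly that case.
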