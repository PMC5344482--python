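# Methods

This note documents the models, the simulator's assumptions, the numerical
choices, and the limits of what the package's tests demonstrate.

## Population simulator

The generator produces a three-generation intercross. Two founder lines
represent a selected fast-growing broiler line and a slow-growing
indigenous breed. Per marker, a base allele frequency `p0 ~ U(0.1, 0.9)` is
drawn; each line's frequency is Beta-distributed around `p0` with
concentration `(1 − d)/d`, `d ∈ [0, 1)` the divergence parameter (default
0.3). `d = 0` collapses both lines onto `p0`; fixed line differences are
possible at large `d` or through explicit frequency overrides. Founder
genotypes are Binomial(2, p_line); line A supplies the 6 founder sires,
line B the 14 founder dams.

Offspring genotypes are produced by gene dropping: one allele sampled from
each parent per marker, markers independent. There is no linkage map — the
downstream methods never use map positions, and the linkage disequilibrium
that genomic prediction exploits in such a cross arises from family
structure and line divergence, which gene dropping creates. The F1
comprises 8 male and 43 female breeders from line-A × line-B matings; the
43 F1 dams are split into disjoint groups, one per F1 sire, giving 8
paternal half-sib families (full-sib nests inside) totalling 511 F2 birds
by default (family sizes near-equal unless configured).

### Traits

Five base traits are simulated directly — ADG, ADFI, EP, BMP, LMP — with
phenotypic means/SDs and heritabilities set to the analysis targets
(ADG 29.34 ± 5.82 g/d at h² 0.49; ADFI 102.36 ± 14.41 g/d at 0.53;
EP 66.60 ± 1.81 % at 0.39; BMP 17.40 ± 1.44 % at 0.34;
LMP 23.72 ± 2.58 % at 0.52). A random subset of markers (default 200 of
5000) acts as QTL. Per-QTL effect vectors are drawn multivariate normal
and then linearly transformed so that the realized genetic covariance of
the true breeding values **over the phenotyped F2 birds equals the target
exactly** (an empirical Cholesky standardization). The transform acts on
the effect matrix, so breeding values remain strictly linear in genotype
dosage and Mendelian-transmission consistency is preserved. Residuals are
multivariate normal with variance `(1 − h²)σ²_P`; only the ADG–ADFI
residual correlation is non-zero (0.6), reflecting shared appetite and
pen environment.

FCR and RFI are *not* simulated. They are derived downstream
(FCR = ADFI/ADG; RFI = feed-intake regression residual), so their
heritabilities and genetic correlations are emergent properties — reported,
never targeted. The base-trait genetic correlation matrix was chosen by
back-solving, through the linearized genetic values of the derived traits,
for entries that make the emergent efficiency × carcass correlations land
at moderate negative values (FCR × EP/BMP/LMP ≈ −0.43/−0.16/−0.34;
RFI × EP/BMP/LMP ≈ −0.32/−0.40/−0.35), verified on a 6000-bird simulation.
The resulting defaults are: r_g(ADG, ADFI) = 0.75; ADG × carcass =
0.24/−0.18/0.10; ADFI × carcass = −0.06/−0.39/−0.17; carcass × carcass =
0.30. A useful side effect mirrors field experience: the genetic value of
FCR is strongly related to ADG (r ≈ −0.68) while that of RFI is nearly
orthogonal to ADG (r ≈ 0.15), which is the whole argument for RFI.

Sex and hatch (3 levels) enter as additive fixed effects (defaults 0.4 and
0.25 phenotypic SD). Start-of-test body weight is 900 ± 60 g plus a
1.5 g per g/d loading on ADG; end weight is start + 42 d × ADG, so
metabolic body weight `MBW = ((BW_start + BW_end)/2)^0.75` is strongly
gain-related, as in a real growth test.

### Genotype quality metadata and planted failures

Missing calls are injected per SNP (default rate 1%, capped at 4% of birds
so a clean SNP can never fail the call-rate screen by chance), a per-SNP
quality score in [0.65, 1] emulates a chip clustering score, and a
configurable fraction of SNPs (default 5%) is planted to fail QC — half by
quality score in [0, 0.55], half by forcing ⌈8%⌉ missing calls. MAF
failures are not planted; rare alleles drift below 1% naturally in the
cross, and the panel's `expected_fail` column (computed from the realized
metrics) identifies the full expected exclusion set.

For the phenotype screen, the outlier-planting helper clips clean ADG/ADFI
deviations to 3.5 input SD and plants deviants at 12 SD. The contaminated
SD is then bounded near 1.7 input SD, so planted birds sit beyond 6
contaminated SD and clean birds within ~2.1 — the 3-SD rule recovers
exactly the planted set, deterministically, at any seed.

## Quality control

SNPs are retained when call rate > 0.95, quality score > 0.6 and
MAF > 0.01, all strict inequalities. Birds are removed whole when ADG or
ADFI deviates more than 3 SD from the mean, with mean and SD computed once
on the input table (a single deterministic pass; iterating the rule could
remove more birds, and the pipeline deliberately does not). A zero-SD
trait removes nobody. Missing genotypes surviving QC are mean-imputed to
`2pⱼ` only inside the G-matrix construction.

## Relationship matrices

**A** uses the tabular recursion (`a_jj = 1 + ½a_sd`,
`a_ij = ½(a_is + a_id)`), so diagonals are 1 + F. **G** uses VanRaden's
first method with allele frequencies computed from all genotyped
individuals (founders, F1 and F2 are all genotyped; an F2-only base is a
caller option). With sample frequencies G is exactly singular (the ones
vector is in its null space), so a `stabilize` step adds the minimal ridge
`ε·mean(diag)` (ε starting at 1e-6, escalating tenfold to at most 1e-2)
only when the Cholesky factorization fails, and records having done so.
No A–G blending is done: the pedigree and genomic analyses are fitted
separately, as the comparison requires.

## Mixed models and REML

Henderson's equations are assembled densely (n ≈ 600 needs no sparse
machinery); the coefficient matrix is inverted by Cholesky (LU fallback
when a strongly ridged K⁻¹ leaves it numerically semi-definite), giving
solutions, prediction error variances `PEV_i = (C⁻¹)_{u_i u_i} σ²ₑ`
(clamped to [0, σ²ₐ] with a counter) and theoretical accuracies
`√(1 − PEV/σ²ₐ)`. Aliased fixed-effect columns are dropped by pivoted QR
before assembly.

Univariate AIREML maximizes the restricted likelihood over (σ²ₐ, σ²ₑ),
starting from half the phenotypic variance each. An AI update is accepted
only if it stays positive and does not decrease the likelihood; otherwise
the update falls back to the EM-REML step (P-form), which guarantees both.
A negative AI proposal is first truncated to a tenth of the current value,
which reaches a zero-variance boundary geometrically; a component at the
floor with a downhill gradient is pinned there. Convergence is declared at
a maximum relative parameter change below 1e-8 (200 iterations cap;
non-convergence returns the best iterate, flagged). The standard error of
h² comes from the delta method on the inverse AI matrix.

Bivariate AIREML estimates (V_g, V_e) under `u ~ N(0, V_g ⊗ K)` with
per-trait fixed effects and residual covariance confined to shared
individuals. Updates are AI steps with a trust region (relative step capped
at 5) and step halving against positive-definiteness and likelihood
decrease; when a joint step stalls at a covariance boundary, genetic-only
and residual-only block steps are tried before declaring convergence. The
genetic correlation's standard error again comes from the delta method,
and its significance is reported as a Wald z-test — the conventional
"t-test of r_g" is underspecified without a degrees-of-freedom convention,
so the output is labelled as Wald.

RFI is modelled with an intercept only (its fixed effects are removed by
construction); all other traits carry sex + hatch.

## Cross-validation

Variance components are estimated once on the full data and held fixed
across folds (a per-fold re-estimation flag exists for sensitivity
analysis, default off). Test birds are masked, not excluded: all
individuals stay in the random effect, and only training records form y,
X and Z, so a test bird's GEBV flows entirely through the relationship
matrix. Per repeat, folds partition the birds; accuracies are averaged
with equal fold weights within repeat, then across repeats (the per-fold
detail table is also written). The r_cor denominator uses one heritability
per trait — the genomic-relationship AIREML estimate — for both GBLUP and
PBLUP, so the two models' accuracies are on the same scale; scaling each
model by its own estimate would flatter the pedigree model, whose
A-based h² estimates are systematically lower. All fold randomization
derives from the single run seed through deterministic child streams.

## Selection analysis

Birds are ranked on full-data GBLUP GEBVs for FCR and RFI (lowest = most
efficient; ties broken by id for determinism); the top and bottom k = 50
form the comparison groups, tested per trait with a pooled-variance
two-sample Student's t-test. No power analysis is attached to the genetic
correlations: the procedure such a claim would require is not specified
anywhere the package could follow, and the report says so rather than
inventing one.

## Problem sizes and runtime

The default conditions are the study scale: 5000 markers (configurable up
to chip scale), 200 QTL, 511 → 504 birds, 10 CVF and 50 CVR repeats. The
full pipeline runs in roughly a minute on one CPU; the parameter-recovery
test batteries (20 replicates each) use 1000-marker panels, which the
recovery experiments showed to be unbiased at this family structure.

## What the tests do and do not show

Passing tests demonstrate estimator correctness *under the simulator's
assumptions*: additive gene action, independent markers, Gaussian
residuals, exact variance standardization, no genotyping error beyond
missingness, no selection or pedigree errors. Real chip data add LD decay
along chromosomes, genotyping artefacts correlated with quality scores,
non-additive variance and pedigree mistakes — none of which are emulated,
so accuracy levels here do not transfer to real populations; the
*contrasts* (CVR > CVF, GBLUP > PBLUP, r_theo inflation when markers tag
QTL imperfectly) are the robust findings. Known limitations: the
theoretical accuracy is systematically optimistic in the CVR design when
causal loci are a sparse subset of the panel (the realized-vs-theoretical
gap closes when the panel is exactly the causal set, as the calibration
test shows); bivariate REML at n ≈ 500 yields genetic-correlation
estimates with large sampling spread, and boundary estimates (|r_g| → 1)
occur at unfavourable seeds; Monte Carlo noise in the 10-repeat CVF design
is substantial, as the small number of family permutations limits
averaging.
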