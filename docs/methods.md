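# Methods

## Liability-threshold recurrence model

Disease liability is standard normal; an individual is affected when
liability exceeds T = Φ⁻¹(1 − K) for prevalence K. The polygenic score is
modelled as the component x ~ N(0, r²) of liability, with r² the variance
explained on the liability scale and ρ the proband–relative score
correlation (0.5 for full siblings under additive inheritance; exposed as
a parameter for other relative types). All non-score liability variance is
assumed independent between the pair, so the relative's liability given
the proband's score is N(ρx, 1 − ρ²r²). The recurrence risk for relatives
of probands whose score exceeds the population percentile q is the
expectation of Φ((ρx − T)/√(1 − ρ²r²)) over the truncated proband score
distribution, taken as a true expectation (not a plug-in of the truncated
mean — the difference is below two-decimal precision at these parameters
but is not in general negligible). The integral is evaluated with
`scipy.integrate.quad` at absolute tolerance 1e-9; the truncated mass is
1 − q exactly, so only the numerator is computed numerically. The r²
supplied by the user is consumed as-is on the liability scale; no
observed-scale/liability-scale transformation is applied, so a regression
R² is interpreted directly as a liability fraction. Limits are exact:
r² = 0 or ρ = 0 returns K.

A Monte-Carlo oracle (bivariate draws of proband score and relative
liability) cross-checks the quadrature in the test suite at 3 MC standard
errors on a parameter grid, and monotonicity in each of K, r², q, ρ is
asserted numerically.

## Synthetic cohort generator

The generator produces the conditions the analyses assume; its defaults
are the study conditions and are not tuned per test.

**Family structure.** Sibship sizes are drawn from a distribution over
{2,…,6} (default mean ≈ 3.2); unrelated singletons emulate clinically
ascertained cases without genotyped relatives. Parent rows are optional
(off by default); parental haplotypes always exist internally for
transmission.

**Genotypes ("snp" mode).** SNPs lie in LD blocks (default 10 SNPs per
block, blocks tiled over chromosomes 1–22 at 50 kb spacing). Haplotype
alleles come from a shared latent Gaussian factor per block (latent
correlation 0.7) thresholded at Φ⁻¹(MAF), giving exchangeable within-block
LD and zero cross-block LD — enough structure to exercise clumping and
simple enough to verify. Children receive one parental haplotype per block
from each parent (recombination between blocks only), so per-SNP sibling
dosage correlation is 0.5 in expectation. The APOE-like locus is a
separate biallelic major locus with ε2/ε3/ε4 alleles (default frequencies
0.08/0.77/0.15) transmitted Mendelianly; two dedicated panel entries at
the GRCh38 positions of rs429358 and rs7412 carry its allele dosages so
that PRS.AD can add them back while the region exclusion removes them from
the PRS.

**Liability.** L = g_prs + g_apoe + g_fam + e with configured variances
(defaults r²_prs = 0.068, r²_apoe = 0.052, r²_fam = 0, residual making the
total 1). g_prs is a weighted sum of causal-SNP dosages (30% of SNPs
causal, Gaussian effects) rescaled empirically to its target variance; in
"infinitesimal" mode it is instead drawn by exact Gaussian mid-parent
segregation (marginal N(0, r²), sibling correlation exactly 0.5), which is
the fast, analytically exact configuration used for large-n oracle tests.
The ε4/ε2 per-allele effects are in ratio +1 : −0.45 and scaled to the
APOE variance. The shared familial residual defaults to zero because the
recurrence model attributes all sibling liability covariance to the score;
setting r²_fam > 0 (transmitted as a mid-parent Gaussian) deliberately
violates that assumption for sensitivity work.

**Onset and observation.** Onset is deterministic given liability through
an age-declining threshold T(band) = Φ⁻¹(1 − K(band)) over the cumulative
prevalence schedule (default 3%/17%/32% by 75/85/95 years), with onset age
uniform within the first band whose threshold the liability exceeds; this
makes the population cumulative incidence available in closed form as a
test oracle. Unaffected individuals are censored at an exam age drawn
uniform on [65, 95] — a stand-in choice, since real last-exam
distributions are cohort-specific. An individual whose lifetime onset
postdates the exam age is recorded unaffected, so observed prevalence at a
given exam age matches the schedule.

**Ascertainment.** Families are retained when at least one member is
affected with onset after 60 and a second sibling is affected; affected
singletons are kept and flagged, unaffected singletons dropped. About 5%
of unselected families qualify under the defaults, so the analysis drivers
simulate a larger base population (4000 families) to obtain a multiplex
cohort of realistic size (~230 families); problem sizes in tests are
chosen the same way, as the package's own trade-off between Monte-Carlo
error and turnaround.

**Summary statistics.** Emitted effect sizes are true liability-scale
betas plus N(0, se²) noise with se = 1/√(2·N·MAF·(1−MAF)) at a base-study
size of N = 100,000, and two-sided normal p-values; null SNPs therefore
give uniform p-values.

**What the generator does not emulate.** Realistic genome-wide LD maps,
imputation error, population admixture (PCs are independent noise
covariates by default, i.e. the no-confounding case), competing mortality,
secular diagnostic drift, and shared environment. Passing tests therefore
show that the estimators recover the generating model's truth under its
assumptions — not that the published cohort-dependent values (penetrance
tables, discordant-pair proportions, empirical recurrence) are recoverable
from any synthetic data. The analytic recurrence grid is the only
desk-reproducible quantity, and it is checked at printed precision.

## Scoring

Clumping is greedy on ascending p (ties broken by SNP id): the best
remaining SNP is retained and removes all same-chromosome SNPs within the
window with dosage r² at or above the bound; candidates require
p ≤ threshold and MAF ≥ 0.01. LD is computed from the analysis panel
itself. Scores are Σβ·dosage over retained SNPs outside the 2 Mb APOE
region, with mean-dosage imputation for missing genotypes and sign-flips
for swapped allele orientation (unresolvable pairs are dropped with a
warning and counted). Adjusted scores are least-squares residuals on
covariates; standardized scores have mean 0, SD 1, so association odds
ratios are per SD. PRS.AD adds β₄·d(rs429358) + β₂·d(rs7412) to the
standardized adjusted PRS. Quantile bins are rank-based on the pooled
analysis cohort (cases and controls together — the choice under which a
top-quintile penetrance above 50% is possible), with exact ties broken by
individual id so bin sizes differ by at most one and assignment is
deterministic.

## Sibling pairs and pair statistics

Pair eligibility requires role "sibling", a non-missing PRS and affection
status, and sibship size ≥ 2. The one-per-family strategy draws one
uniform pair per family; the maximal strategy pairs a uniform permutation
of each sibship, leaving one sibling out of odd sibships. Every replicate
is asserted individual-disjoint. Replicated statistics report mean and
sample SD (n−1) over 100 independently seeded replicates by default;
undefined replicates (empty strata) are counted, not silently dropped.

The discordant-pair statistic is the fraction of affection-discordant
pairs whose affected member has the strictly higher PRS; exact ties are
excluded from numerator and denominator. A pair belongs to a score-bin
stratum when its higher-PRS member is in the stated bin, and to an
APOE-stratified row only when both siblings share carrier status — the
interpretation under which low-bin strata can fall well below 0.5. Age
ordering for the empirical recurrence statistic breaks exact age ties by
individual id.

## Cumulative penetrance and permutation test

The group-specific curve is a product-limit cumulative incidence
1 − Ŝ(age) with unaffected individuals censored at last exam. Covariate
adjustment uses stabilized inverse-probability weights from a logistic
model of group membership on the supplied covariates — a nonparametric,
covariate-allowing reconstruction, not a transcription of any particular
published estimator. Confidence bands are percentile bootstrap over
families (200 resamples by default), respecting within-family dependence.
The in-house vectorised product-limit routine is cross-checked against
lifelines' Kaplan–Meier fit (weighted and unweighted) in the tests and is
the fast path inside the permutation loop.

The permutation test shuffles each individual's (affection, age) outcome
pair across the pooled two-group sample — diagnosis and age move together,
preserving the pooled age distribution under the null of no group–risk
association (permuting diagnosis alone is the obvious alternative; the
joint scheme is the implemented and documented choice). Two-sided
p-values use the add-one correction (1 + #{|null| ≥ |obs|})/(1 + n_perm),
so p ∈ (0, 1]; the default is 1000 permutations, and type-I error at
α = 0.05 is verified over 500 null simulations.

## Association models

Affection is regressed on the standardized score plus age, sex and PCs by
maximum-likelihood logit; the variance explained is reported as Nagelkerke
pseudo-R² of the full versus covariate-only model (the scale choice is a
convention; the recurrence model deliberately consumes whatever R² the
caller supplies, decoupling the two decisions). Perfect separation falls
back to an L2-penalised fit and is flagged. Age-at-onset models are OLS of
onset on standardized score plus PCs in cases only, refusing fewer than
10 cases. Covariate handling is complete-case.

## Numerical and design notes

- One master seed drives everything; all substreams are spawned
  deterministically (`numpy` SeedSequence), so reruns of the pipeline are
  byte-identical, which the manifest's SHA-256 checksums make checkable.
- Quadrature tolerance 1e-9 absolute; KM tie handling processes
  individuals in age order with stable sorts (ages are continuous here, so
  ties have measure zero); bootstrap bands are clipped to contain the
  point estimate.
- Degenerate inputs: constant scores refuse standardisation and
  correlation; empty strata yield NaN with n = 0; groups with fewer than
  two events refuse the permutation test; empty cohorts round-trip as
  headered files.
- The MAF inclusion criterion is implemented as MAF ≥ 0.01 (a "≤" form
  occasionally seen in pipeline descriptions is internally inconsistent
  with genome-wide common-SNP scoring and is treated as a transcription
  slip).
- Known limitations: no left truncation beyond censoring at last exam, no
  competing risk of death, no cross-ancestry weight transfer, no Bayesian
  shrinkage scores; the IPW estimator assumes the membership model is
  correctly specified when covariates matter.
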