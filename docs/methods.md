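# Methods

## Model and assumptions

`triolinear` analyzes case-parent trios genotyped at a biallelic locus
(locus 1: mother *M*, father *F*, child *C*, coded as risk-allele
counts, by convention the minor allele) with the mother additionally
genotyped at a second biallelic locus (*M*₂).  The two loci are assumed
unlinked and in linkage equilibrium — both M×M and M×O interactions
cannot be tested simultaneously without that assumption.  Under
parental mating symmetry at locus 1, the 15 Mendelian-consistent
(M, F, C) configurations span six mating types; crossing them with the
three *M*₂ genotypes gives the 45-cell space on which everything
operates.

Ascertainment on an affected child makes the expected count in a cell
proportional to population frequency × penetrance:

    mult · μ_m · S_i · R_j · ϑ_ik · Φ_jk · τ_k · p_k

with `mult = 2` for the double-heterozygote configuration (two equally
likely transmission paths), μ_m the mating-type scaling factor treated
per ordered parental pair (each ordered pair of a type carries the same
factor; under HWE with allele frequency q, μ_m = q^{a_m}(1-q)^{4-a_m}
where a_m is the parents' total risk-allele count), and relative risks
as in the README.  Index 0 of every effect is the reference (risk 1);
interaction entries with any index 0 are 1.

On the log scale this is a Poisson log-linear model.  The ln p_k and
ln 2 terms are fixed offsets; the Poisson likelihood conditional on the
total is the multinomial likelihood, so LRT statistics agree with the
conditional (multinomial) analysis — verified in the tests against a
directly optimized multinomial oracle.

### Variants

- **eq1** — offsets carry ln p_k with user-specified (p₀, p₁, p₂); the
  locus-2 main effect δ_k = ln τ_k is estimable, but its test is valid
  only when the specified frequencies are correct.  The interaction
  tests are provably invariant to the specified frequencies as long as
  δ is in the model: a change of ln p_k is a linear shift absorbed by
  the free δ columns.
- **eq2** — frequencies estimated through free nuisance columns
  λ_k = ln(p_k/p₀), which constrains the implied frequencies to sum to
  one; δ is then confounded with λ and not estimable.  Interaction
  LRTs from eq1 (any strictly positive specified p) and eq2 are
  identical to numerical tolerance.
- **eq1_hwe** — replaces the six μ_m parameters by {intercept,
  θ·a_m} with θ = logit(q₁).  The heterozygous-parent pair
  multiplicities 2^h cancel exactly against the Mendelian transmission
  constants 2^{-h}, so no extra offset is needed beyond eq1's; the
  fitted θ recovers logit(q₁) exactly on HWE data.
- **eq3** — the single-locus model on the 15 locus-1 cells with a
  same-locus maternal-by-child interaction ρ_ij.  With codominant main
  effects, only two of the four ρ indicator columns are identifiable
  (rank 12 of 14); the fit raises an identifiability error naming the
  aliased parameters.  Dominant ρ (the coding used in all shipped
  analyses) is fully identified.

### Genetic codings

Per effect: `dominant` (index-1 = index-2 parameter), `multiplicative`
(index-2 log-coefficient = 2 × index-1), `codominant`/`unconstrained`
(both free).  Degrees of freedom for every LRT are derived from the
actual column count, never hard-coded.  The locus-2 main effect δ (and
eq2's λ) is always fitted with two free parameters.

## Fitting

Newton–Raphson with step halving on the Poisson kernel log-likelihood
Σ y·η − exp(η), started at 0; convergence when max |score| <
1e-8·max(1, Σy) or the relative deviance change falls below 1e-10;
100 iterations maximum, non-convergence flagged, never silent.  The
45-cell problem is concave and typically converges in < 10 iterations.

Zero cells are retained (the Poisson likelihood handles them; no
continuity correction).  A column whose nonzero entries all fall on
zero-count cells has its MLE at −∞ (all design columns are
nonnegative): the implementation realizes that limit exactly by
removing the column *and excluding the cells it supports* from the
likelihood, which keeps the eq1/eq2 identity and the
frequency-invariance exact even in sparse replicates — fixing the
coefficient at zero instead would leave offset-dependent fitted mass
in empty strata.  Tests whose parameters were all removed report a
not-estimable result rather than a zero statistic.  Remaining rank
deficiency raises an identifiability error naming the aliased columns.

p-values are upper chi-square tail probabilities at the effect's df;
no small-sample correction (all reference analyses are asymptotic at
α = 0.05).  Wald-style CIs on single coefficients are reported in the
effects table for orientation; LRTs are the inference.

## EM for incomplete trios

Families with a missing father (mother-and-child pairs) or a missing
mother are handled by EM over each family's compatible cells — every
cell consistent with the observed genotypes under Mendelian rules.  A
missing mother is assumed missing at both loci.  The E-step distributes
each incomplete family over its compatible cells proportionally to the
current fitted means (offsets included, so locus-2 frequency
information enters for families missing *M*₂); the M-step refits to
full convergence (full M-steps are cheap on 45 cells).  The iteration
maximizes the observed-data log-likelihood
Σ_fam ln(Σ_compat μ) − Σ μ, which is checked to be nondecreasing at
every iteration; convergence at |Δ| < 1e-8, 500 iterations maximum.

Families with a missing mother are excluded by default (they carry
almost no locus-2 information and can distort calibration); an
explicit flag retains them.  Exclusions are counted and reported.
Standard errors after EM are available from the observed-data
information computed by central differences; observed-data LRTs are
the primary inference, with both nested models maximized by their own
EM runs (eq2's λ are re-estimated freely in each).

Missingness is assumed completely at random.  Missing child genotypes
and informative missingness are out of scope.

## Simulator

Scenarios fix the risk model, population structure, sample size, and
missingness rates.  Presets `model1`–`model14` (and asymmetric-mating
`model11a`–`model14a`) encode the reference simulation conditions:
baseline incidence 0.1, HWE, risk-allele frequency 0.3 at both loci
(so p = (0.49, 0.42, 0.09)), dominant or multiplicative-laddered
codominant effects of 1.3–2.744, and for the asymmetric variants a
male population that is an equal mixture of HWE strata with allele
frequencies 0.1 and 0.5 (marginal 0.3, but e.g. P(F=1) = 0.34 against
0.42 in females).  Scenarios whose maximum cell penetrance exceeds 1
are rejected at validation rather than silently capped.

The primary sampler draws cell counts multinomially from the ordered
cell probabilities P(M)·P(F)·P(C|M,F)·p_k·risk; an individual-level
rejection sampler (prospective families accepted with the child's
disease probability) is retained as a cross-validation oracle and is
checked against the multinomial sampler by two-sample chi-square.
Missingness blanks the father, or the mother at both loci, using one
uniform draw per family over successive intervals (the events are
mutually exclusive; reference scenarios vary one rate at a time).

What the generator does *not* emulate: linkage or LD between the loci,
genotyping error, population stratification beyond the stated male
mixture, imprinting, and informative missingness.  Passing tests
therefore validate the estimator under its stated model, not
robustness to those violations.

## Replicate engine

A study pairs a scenario with an analysis spec: each replicate
simulates, fits (EM when missingness is present), and records LRT
rejections at α (strictly below; a p-value exactly at α counts as
non-rejection, fixed for determinism).  Replicate r uses seed
base_seed + r, making studies exactly reproducible and allowing
replicate-by-replicate comparisons across analysis variants.
Non-estimable tests in sparse replicates count as non-rejections and
are tallied; replicates that fail outright are counted and excluded
with a warning above 1%.  Rejection fractions carry the binomial
Monte-Carlo standard error sqrt(f(1−f)/R).

Default replicate count is 1,000 (the reference study size), used by
`scripts/acceptance.py`; the test suite reruns the same studies at
250–400 replicates and compares within three Monte-Carlo standard
errors.

## Design choices that were genuinely open

- **Ordered-pair μ convention.** The mating-type factor multiplies each
  ordered parental pair (types 2, 3, 5 cover two ordered pairs).  This
  affects only the interpretation of fitted μ̂, not any test.
- **Mating-type collapse.** Replacing the six μ columns by one
  intercept leaves the interaction *decisions and power* essentially
  unchanged (≈98% identical decisions in simulation) but not the
  bitwise statistics: the likelihood only factorizes free of the row
  margins when the row-margin model is saturated, which 6μ + main
  effects is not.  The package therefore always fits the full
  mating-type stratification (or the HWE reduction).
- **Restricted models.** A reduced analysis containing only the effects
  of interest is supported; when it contains a locus-2 interaction it
  must retain the δ nuisance terms, enforced at run time.  Under these
  conditions the two-sided LRT of a dominant interaction RR of 1.5 in
  the reduced model (interaction + δ + μ) has asymptotic power ≈ 60%
  at 300 trios (noncentral chi-square, ncp ≈ 4.9–5.1), roughly double
  the full-model power at the same size.
- **Seed discipline.** All randomness flows from user-supplied seeds;
  samplers take one generator per dataset.

## Known limitations

- Two alleles per locus, autosomal; no imprinting/parent-of-origin
  terms; no augmentation with unrelated controls.
- The locus-2 main-effect test (eq1 with specified p) is exquisitely
  sensitive to frequency misspecification and is flagged with a warning
  whenever run; it should only be used with frequencies estimated from
  reliable reference data.
- EM assumes MCAR missingness; with ≥30% missing mothers interaction
  power visibly declines and estimates degrade.
- Very sparse datasets (rare alleles, small samples, codominant
  codings) can leave interaction parameters non-estimable; these are
  reported as such, never as null results.
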