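# Methods

## Cohort model

A cohort is a validated pedigree forest. Each member carries a clinical
phenotype subtype (`myxedematous_severe/_moderate/_unknown_grade`, `mixed`,
`neurological`, `deaf_mute`, `ech_unspecified`, `unaffected`, `unknown`),
vital status, sex, approximate age (years, often missing in field data) and
WHO goitre grade. Three analysis categories map subtypes to case status:
*myxedematous* (the myxedematous subtypes plus the mixed form),
*neurological* (neurological, deaf-mute) and *combined* (their union).
Under every category the denominator is the full phenotyped cohort — the
living members with a known phenotype — so a subject affected under one
category is a control under the other. Deceased members stay in the
pedigree (they contribute kinship paths) but are never cases, controls or
members of the resampling pool; the same holds for phenotype-unknown
members. Sex is recorded and reported descriptively but enters no test.

Family structure exists at two levels: the recorded *family unit* (the
62 survey families; polygamous households are one unit) and the *nuclear
family* (one father-mother pair with their common offspring; a father with
w wives contributes w nuclear families). Counting tests (binomial,
clustering, BH multiplicity) operate on family units with parents included
in the unit size; the sibship table operates on nuclear families, with
sibship size counting living offspring only.

## Kinship

Malécot kinship coefficients are computed by the standard recursion on an
acyclic pedigree (φ(i,i) = (1 + φ(father, mother))/2; φ(i,j) expands the
member that cannot be an ancestor of the other, chosen by generation depth;
distinct founders are unrelated). The matrix is assembled per connected
component of the parent graph — members of different components are exactly
0 — which keeps the 478-member reconstruction fast. Correctness is checked
two ways: closed forms for canonical relationships (parent-offspring and
full sibs 0.25, half sibs 0.125, first cousins 0.0625, inbred self-kinship
0.5625 for a child of half sibs) and a gene-dropping simulation (founder
alleles uniquely labelled, transmitted with fair coin flips; 10⁵ drops;
agreement required within 3 Monte-Carlo standard errors on every pair).

## Aggregation tests and Monte-Carlo conventions

The null throughout is uniformly random allocation of the observed number
of case labels over the phenotyped pool. Conventions, chosen once:

- p-estimator (k + 1)/(B + 1) with k the exceedance count; ties (null
  statistic equal to the observed) count as exceedances — the conservative
  choice. Zero exceedances set `p_is_bound`, read as "p < 1/B".
- Kinship-sum per-individual p-values use a **pooled** null by default:
  each of B draws samples n_affected labels, and every sampled member's
  kinship sum enters one pooled distribution of B·n_affected values, so
  p_i = (1 + #{pooled ≥ s_i})/(1 + B·n_affected). The stricter per-draw
  maximum null is available via `null="max"`. The two conventions differ
  by roughly the factor n_affected in the tail; which one the original
  survey analysis used is not recoverable, so per-individual kinship-sum
  p-values should be compared across conventions with care.
- The clustering test is Monte-Carlo, not an exact recursion: per draw the
  per-family case counts are tabulated and their log multivariate
  hypergeometric mass compared with the observed one (tolerance 1e-9 on the
  log scale so that equal configurations summed in different orders still
  count as ties). Probabilities far below 1/B are therefore reported as
  bounds, not as point values.
- BH adjustment is the standard step-up, applied per test type and category
  across all tested units (62 families for family-wise tests; affected
  individuals for the kinship sum). Degenerate family-GIF results carry no
  p-value and are excluded from the adjustment.
- Reproducibility: every Monte-Carlo routine takes an explicit seed;
  `FamilialAggregation.fit` derives one child seed per test from its single
  seed argument, so any subset of tests re-runs identically.

The binomial family test uses scipy's exact binomial tail; the recessive
transmission probabilities P(X ≥ k | n, 1/4) are computed in exact rational
arithmetic and returned as floats. The sibship χ² uses the sizes actually
present as cells, df = cells − 1 (no reduction for the estimated
prevalence, and no pooling of small expected counts — both deliberate, to
match how such field tables are conventionally assessed), and
E_s = F_s · s · π with π defaulting to the cohort's observed
affected/phenotyped ratio. Two-tailed Fisher tests use the mass-summation
convention; the age comparison uses the two-sided Mann-Whitney test (exact
when sample sizes and ties allow). Age strata are <5, [5, 18), ≥18 with the
boundary in the upper stratum.

## The survey-cohort reconstruction

`reference_cohort()` deterministically rebuilds the 62-family cohort from
its published summary constraints: per-sibship-size nuclear-family counts
(19, 15, 19, 11, 10, 4, 6, 3, 2 for sizes 1–9; 89 nuclear families, 308
living offspring), affected-family and case counts per size, 45 monogamous
/ 12 bigamous / 5 four-wife polygamous units, 468 phenotyped members (151
parents, 308 offspring, 9 additional founder relatives), 46 cases (44
myxedematous — 20 severe, 17 moderate, 3 unknown grade, 4 mixed — and 2
neurological), 4 phenotype-unknown subjects excluded from every statistic,
and the published case/control sex margins (24/22 and 185/237).

Families A and B are built to their published pedigrees: eight offspring
each, five living and affected (A: five myxedematous, with three deceased
siblings reported affected, stored as `ech_unspecified` and dead; B: four
myxedematous — two mixed, one severe, one moderate — plus one neurological
woman, with three deceased siblings of unknown status). Ages are populated
only where the published pedigrees bound them (A: 5–25, B: 6–30); all other
ages, and all goitre grades, are missing. Conflicting prose about family
B's sex composition is resolved in favour of its pedigree figure.

Two reconstruction choices are not pinned by any published number and are
therefore explicit, documented rules:

- **Case allocation.** Within each sibship size the affected-family case
  counts follow a fixed split (size 3: 2,2,2,1,1,1; size 5: 5,5,2,1;
  size 7: 4,3,1; size 6: 3; size 8: 2; all other sizes singletons),
  consistent with every published total and with the reported third
  4-affected/3-healthy family. The `allocation` argument accepts
  alternatives; the headline result (exactly families A and B significant
  at the observed prevalence) is verified to be stable across consistent
  alternatives.
- **Unit grouping.** Which sibships shared a father was never published, so
  every half-sib pair in the reconstruction is an invented relationship.
  The rebuild follows a minimal-relatedness rule: all 26 affected sibships
  are monogamous units (their binomial counts are then exactly
  sibship + 2), and the multi-wife units take the smallest unaffected
  sibships. Grouping only affects zero-case units for the counting tests,
  but it shapes the kinship null pool: the minimal-relatedness pool has
  mean pair kinship 2.9 × 10⁻³, and under it the cohort GIF null tail at
  the observed statistic is ~2 × 10⁻⁶.

The nine extra founder relatives ("multigeneration" members) are stored
without parent links: linking them as literal grandparents would create
additional nuclear families and change the published sibship table, whereas
their only documented role is enlarging the phenotyped pool. A test
verifies the significant-family set is insensitive to their presence.

Prevalence-scenario counts at the observed prevalence (2 significant
families), 7% (3) and 5% (3) match the published sweep; at 2% the
reconstruction yields 8 significant families against a published 9 — the
ninth family there is a 2-case size-5 sibship whose p (7.9 × 10⁻³) sits
just above the BH threshold at rank 9 (7.3 × 10⁻³), a margin inside the
uncertainty of the unpublished case allocation. The myxedematous-category
binomial p for family A likewise depends on an unrecoverable convention in
the original analysis and is not asserted.

## Synthetic cohorts

`generate_cohort` emulates the study conditions: 62 family units with the
structure fractions above, sibship sizes drawn from the survey's empirical
distribution (or fixed to its exact counts), parents alive, unaffected and
phenotyped with no recorded age, prevalence 46/468 by default. Offspring
affection follows one of three mechanisms:

- `null_iid` — independent Bernoulli(π); the calibration condition.
- `beta_binomial` — a per-sibship risk drawn from a Beta with mean π and
  intra-class correlation ρ (default 0.2, a moderate familial effect),
  offspring conditionally independent.
- `recessive` — parental genotypes in Hardy-Weinberg proportions at allele
  frequency q (default 0.076, putting the carrier-couple frequency near
  2%), offspring affected iff homozygous; parental phenotypes never
  expressed, matching the survey's universally unaffected parents.

Generated cohorts capture sibship-size structure, family grouping and the
affection mechanism; they do not model mortality, age structure, goitre, or
ascertainment bias, so tests passing on them demonstrate calibration and
power of the statistics under the stated mechanisms, not robustness to
survey artefacts of real field data.

Calibration and problem sizes used by the test suite (chosen as desk-scale
defaults): type-I error of the BH-adjusted binomial family test over 300
null cohorts at the survey profile (any-family rejection rate required
≤ 0.05 + 3 MC SE); recessive-vs-null power direction over 40 replicates
each; Monte-Carlo-vs-enumeration agreement at B = 10⁵ within 99% binomial
confidence intervals on cohorts small enough for exhaustive enumeration;
mechanism recovery (prevalence, carrier-couple 1/4 risk, ICC) at 2×10⁴ to
9×10⁴ offspring. The bundled pipeline defaults to B = 10⁵ (`--full` raises
it to 10⁶); per-test runtime on the 468-member cohort is a few seconds at
B = 10⁵.

## Known limitations

- Per-individual kinship-sum p-values are convention-dependent (pooled vs
  per-draw maximum); only the pooled default is calibrated against
  enumeration here.
- Clustering probabilities below Monte-Carlo resolution are reported as
  bounds; no exact recursion is implemented.
- The reconstruction is one member of the family of cohorts consistent
  with the published tables; quantities sensitive to the unpublished case
  allocation or half-sib structure (the 2% scenario count, per-individual
  Monte-Carlo p-values) vary across that family, and are documented rather
  than asserted.
- Heavily inbred pedigrees are handled by the recursion but not optimized
  for; pedigree drawing is out of scope.
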