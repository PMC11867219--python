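# Methods

## Background and model

Gene-based burden tests compare the frequency of rare-variant carriers
between cases and controls.  In a population cohort, unaffected participants
with an affected first-degree relative carry partial information about
genotype–disease association: a first-degree relative shares half of a
proband's alleles, so an affected relative raises the expected carrier
frequency in the proband by roughly half the case–control effect.

The package's central device is a *reversed* logistic regression: carrier
status G (0/1, collapsed over a gene's qualifying variants) is the outcome
and the phenotype is the covariate.  For a 2×2 table the odds ratio is
symmetric in which margin is the outcome (Breslow–Day), so exp(β₁) still
estimates the disease odds ratio, and the reversal makes family history (FH,
the indicator of ≥1 affected first-degree relative) trivially easy to add:

    null :  logit P(G=1) = α + β₃·Sex (+ covariates)
    M1   :  … + β₁·Case
    M2   :  … + β₁·Case + β₂·FH
    M3   :  … + β₁·(Case + k·FH)

M1 is the ordinary case–control burden test (k = 0); M2 estimates the FH
effect freely and yields k_T = β₂/β₁, the empirical relative information in
family history; M3 constrains β₂ = k·β₁ and yields a 1-df test against the
null (vs 2 df for M2).  k = 1/2 is the locally optimal weight for small
effects; for a rare allele with relative risk e^β the allele frequency in
FH-positive subjects is approximately the mean of the case and control
frequencies, giving the exact relation e^β₂ = (e^β₁+1)/2, i.e.
k = log((e^β₁+1)/2)/β₁, which increases from 1/2 with effect size
(`optimal_k`).  Model 3 with fixed k = 1/2 therefore tends to overestimate
β₁ for large effects; the package reports k_T from M2 alongside so that this
is visible.  For 0/1/2 genotypes (common variants) the same three models are
fitted as adjacent-categories logit models with free transition intercepts
and slopes shared across the two transitions, making β₁ a per-allele log
odds ratio.

The composite Case + ½·FH is the rare-disease reduction of a kinship-weighted
pedigree score test (module `pedscore`): with untyped relatives the locally
most powerful score statistic is

    U = Σᵢ Σⱼ (D_ij − Λ₀(t_ij)) · 2φ_ij0 · (g_i0 − 2p),
    V = 2p(1−p) · N · var(Σⱼ (D_ij − Λ₀(t_ij)) · 2φ_ij0),

with Λ₀ the population cumulative hazard, φ the kinship coefficient to the
proband (2φ = 1, ½, ¼ for self, first- and second-degree) and p the allele
frequency.  When the disease is rare (Λ₀ ≈ 0) and only first-degree
relatives are summarised, the weighted phenotype collapses to d + ½f.

## Effective sample sizes

For planning, three strategies are put on the common scale of a balanced
case-control study with the same expected score-test Z (module `effsize`):
Neff1 = 2N₀N₁/N for the plain case–control test, the quadratic form
Neff2 = [N₀₀N₀₁ + N₀₁N₁₀ + N₁₀N₁₁ + 4(N₀₀N₁₀ + N₀₁N₁₁) + 9N₀₀N₁₁]/(2N) for
the d + f/2 test, and Neff3 = N₀₀(N₀₁ + 2N₁₀ + 3N₁₁)²/(2N(N₀₁+N₁₀+N₁₁)) for
the proxy-case test on max(d, f).  The Neff3 denominator is written here in
the form that satisfies the required consistency check — all three formulas
reduce to 2N₀N₁/N when N₀₁ = N₁₁ = 0 — and every expected-Z expression is
E(Z|β) = β·√(2p(1−p))·√(Neff/2), so E(Z|0) = 0 identically.

A caution established while testing: Neff2 ≥ Neff1 is *not* an algebraic
identity.  quad − 4N₀N₁ = N₀₀N₀₁ + N₁₀N₁₁ + 5N₀₀N₁₁ − 3N₀₁N₁₀ can go
negative when FH-positive controls dominate or cases outnumber controls; the
fixed ½ weight then loses efficiency.  For population-cohort compositions
(cases a minority, FH rates ≲ 30%) the inequality holds, and the property
test asserts it on that domain only.

## Variant inclusion rules

`rare_variant_filter` keeps variants whose stored reference-panel frequency
AND in-sample frequency (computed over non-missing calls) are strictly below
the threshold (default 0.001); a variant at exactly the threshold is
excluded.  `nmd_escape_excluded` removes PTVs expected to escape
nonsense-mediated decay: any position in the last coding exon, or within the
final 50 bp of the penultimate exon measured along the coding strand and
inclusive of the exon's 3′-most base (for a penultimate exon [101, 200] on
the + strand, 151 is the first excluded base).  Intervals are 1-based
inclusive.  Single-exon genes cannot trigger NMD, so all their exonic PTVs
are excluded.  Missing dosages count as non-carrier evidence by default
(with a per-gene tally); a flag switches to dropping incomplete samples.

## Fitting

All binary-covariate models are fitted by iteratively reweighted least
squares on the grouped 2×2×2×2 sex × case × FH × carrier cell counts, which
are sufficient, so a 450,000-sample fit costs the same as an 8-row one;
arbitrary numeric covariates switch to the (grouped-by-pattern) per-record
path.  Convergence is max |score| < 1e-8 with at most 100 iterations and
step-halving; log-likelihoods omit the binomial coefficient, which cancels
in every likelihood ratio.  Separation is flagged when any |coefficient|
exceeds 15 (odds ratio > 3×10⁶); flagged fits are reported with a warning,
never silently dropped, and no penalized fallback is applied — plain ML is
what every downstream number assumes.  The adjacent-categories models are
fitted by direct Newton iteration on the equivalent constrained multinomial
likelihood (category scores 0, a₀+s·x, a₀+a₁+2s·x); when a boundary genotype
level is absent the model degenerates to the single observed transition and
is fitted as ordinary logistic regression.

Wald tests are two-sided normal with fixed 95% CIs; LRTs are χ² with df
equal to the parameter-count difference and the statistic clamped at zero.
Gene scans apply strict `<` at the exome-wide (2.5×10⁻⁶) and suggestive
(10⁻³) thresholds with no further multiplicity adjustment.

## Monte-Carlo engine and the shipped cohort compositions

The simulator draws each replicate by sequential binomial sampling — sex,
case | sex, FH | (sex, case) — from packaged conditional proportions
(`data/cohort_proportions.tsv`) that describe a 419,307-sample European-
ancestry exome cohort for breast, prostate, bowel and lung cancer; realized
case/control counts by sex ship alongside (`data/cohort_counts.tsv`).
Carrier status is then drawn per phenotype cell from
logit P(G=1) = α + β₁·Case + β₂·FH + β₃·Sex with defaults α = log(0.001)
(baseline aggregate carrier frequency ~0.001), β₁ = log(OR),
β₂ = k_generate·β₁ with k_generate = 0.5, and β₃ = log(1.15).

The sex covariate codes male = 1 by default and receives β₃.  This direction
matters and is deliberate: for a female cancer, female *controls* are
depleted of risk-variant carriers (carriers have disproportionately become
cases), so in the carrier-status regression male sex predicts carrier status
positively — which is what a CHEK2-style breast-cohort fit estimates, and
what the closed-form noncentralities of the power study require.  The coding
is configurable (`female_coded_one`); model fits themselves are invariant to
it, only the generator's β₃ placement changes.

Default study sizes are n = 450,000 and 5000 replicates, the scale of the
reference simulation study; the grouped fitting path completes a full
5000-replicate, four-model run in well under a minute.  Per model the LRT
against the null (1 df for M1/M3, 2 df for M2) is computed and power is the
proportion of p-values strictly below each level (0.05 and 2.5×10⁻⁶ by
default).  Replicates with a non-converged or separated fit are excluded
from the rejection denominator and tallied (at these settings they are
essentially absent).  Randomness is counter-based —
`SeedSequence(master_seed, spawn_key=(OR index, replicate))` — so replicates
are reproducible in any order.  `power_curve` shares each replicate's data
across the model-3 k grid, making k comparisons paired.

Monte-Carlo SE is √(p(1−p)/reps) (reported as NA when fewer than two usable
replicates), CIs are exact (Clopper–Pearson); the type-I runner adds a flag
for whether the nominal level lies inside the 99% exact CI.

What the generator does *not* emulate: linkage disequilibrium and multi-gene
structure, relatives' genotypes (FH is drawn marginally given sex and case),
covariate structure such as genetic principal components, and
genotype-calling error.  Passing power checks therefore validate the model
machinery under the stated sampling scheme, not robustness to those
real-data features.

## Numerical and design notes

- k sensitivity: at the nominal 0.05 level, model-3 power is essentially
  flat across k_fit ∈ [0.4, 0.7] (spread < 0.01 at any OR).  At the extreme
  2.5×10⁻⁶ tail near the steepest point of the power curve (OR ≈ 2 for the
  breast composition) the closed-form noncentralities give a true spread of
  ≈ 0.026 between k = 0.5 and k = 0.7 — "insensitive to k" is a
  nominal-level statement, not a tail statement.
- Expected-count cell tables (real-valued) are accepted everywhere counts
  are, enabling closed-form noncentrality/power checks without simulation.
- `counts_from_proportions` returns real-valued expected counts and
  collapses sex.
- The pedigree score variance uses the population (1/N) divisor to match
  V = N·var(·).
- Incidence input is a piecewise-constant age-band cumulative hazard with
  half-open bands; no interpolation by default.
- Only probands are genotyped in `pedscore`; using relatives' genotypes
  would add power but is out of scope, and such input is rejected loudly.
- Ties and degenerate inputs: empty included-variant sets, all-carrier or
  no-carrier responses, constant covariate columns, single-level genotypes
  and zero score variance all raise errors naming the offending gene/column
  rather than returning NaN.

## Limitations

- No Firth or other penalized fallback for separated fits; results for
  genes with a handful of carriers should be treated with caution (very low
  carrier counts also inflate small-p type-I error in any plain-ML burden
  framework).
- The adjacent-categories fitter assumes independent samples; no
  relatedness/mixed-model adjustment anywhere.
- k = 1/2 is motivated for first-degree family history; summaries mixing
  relative degrees need the pedigree score test instead.
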