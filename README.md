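# fhburden

Family-history-weighted rare-variant burden association testing, effective
sample sizes, pedigree score tests and Monte-Carlo power simulation.

## The problem

Gene-based burden tests in population cohorts compare rare-variant carrier
frequency between cases and controls, discarding a quietly informative
group: unaffected participants who report an affected first-degree relative.
Since first-degree relatives share half their alleles, a positive family
history (FH) shifts the expected carrier frequency by about half the
case–control effect.  `fhburden` implements an association framework that
uses this: carrier status G is regressed on the phenotype (the odds ratio is
invariant to which margin is the outcome), and family history enters either
freely or through the composite phenotype **Case + k·FH** with k = ½:

    null :  logit P(G=1) = α + β₃ Sex          (+ covariates)
    M1   :  … + β₁ Case                        (standard burden test, k = 0)
    M2   :  … + β₁ Case + β₂ FH                (free FH effect, 2-df LRT; k_T = β₂/β₁)
    M3   :  … + β₁ (Case + k·FH)               (1-df LRT; k = ½ default)

The composite is the rare-disease reduction of a kinship-weighted pedigree
score test (`pedscore`), the locally most powerful test when relatives are
untyped.  Closed-form effective sample sizes (`effsize`) and a Monte-Carlo
power engine with packaged UK-Biobank-derived cohort compositions for
breast, prostate, bowel and lung cancer (`simulate`) quantify the gain:
roughly a 1.3–2× effective-sample-size increase over the plain case–control
test, larger than treating FH-positive controls as full proxy cases.

Intended users: statistical geneticists running gene-based rare-variant
scans on biobank cohorts, and study designers sizing such analyses.

## Worked example

Effective sample sizes for a cohort of 1100 with 100 FH-positive controls
and 100 cases (10 FH-positive):

```sh
$ fhburden neff --counts 900 100 90 10
{
  "counts": {"n00": 900.0, "n01": 100.0, "n10": 90.0, "n11": 10.0},
  "neff_case_control": 181.8181818181818,
  "neff_weighted_fh": 231.3181818181818,
  "neff_proxy": 196.5681818181818,
  "ratio_weighted_vs_cc": 1.27225,
  "ratio_proxy_vs_cc": 1.081125
}
```

The ½-weighted FH test is worth 231 balanced samples against 182 for the
plain case–control test (a 27% gain); pooling FH-positive controls with
cases as proxy cases recovers only 197.

Power of the three models for a breast-cancer-composition cohort of 450,000
at odds ratio 2 (carrier model: α = log 0.001, β₁ = log 2, β₂ = ½ log 2,
β₃ = log 1.15), 5000 replicates:

```sh
$ fhburden simulate-power --cancer breast --or-grid 2 --reps 5000 --seed 1 \
      --out power.tsv
$ cat power.tsv            # comment header (version/seed/config) trimmed
cancer  or   k    model  level    power   se        reps_used
breast  2.0  NA   m1     0.05     0.9644  0.00262   5000
breast  2.0  NA   m1     2.5e-06  0.2286  0.00594   5000
breast  2.0  NA   m2     0.05     0.9866  0.00163   5000
breast  2.0  NA   m2     2.5e-06  0.4256  0.00699   5000
breast  2.0  0.5  m3     0.05     0.9954  0.00096   5000
breast  2.0  0.5  m3     2.5e-06  0.5212  0.00706   5000
```

At exome-wide significance (2.5×10⁻⁶), adding family history freely (M2)
raises power from 0.23 to 0.43, and the 1-df composite test (M3) to 0.52.

The same models run on real data from TSV phenotype/carrier tables (or a
VCF plus variant map, with rarity and NMD-escape filters applied during
collapsing):

```sh
fhburden collapse --vcf cohort.vcf --variant-map variants.tsv \
    --exons exons.tsv --af-threshold 0.001 --out carriers.tsv
fhburden fit --phenotypes pheno.tsv --carriers carriers.tsv \
    --model 3 --k 0.5 --out results.tsv
```

`results.tsv` has one row per gene: odds ratio exp(β₁) with 95% CI, Wald and
LRT p-values, carrier count, convergence/separation flags.

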