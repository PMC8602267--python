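# strlink

Analysis pipeline for **multiallelic (STR) markers around a functional
SNP**, built around the *OCA2–HERC2* eye-colour region: microsatellites
flanking rs12913832, whose C allele is strongly associated with blue eye
colour as a recessive trait.

The package answers the questions population and forensic geneticists ask
of such a panel:

* How do STR allele frequencies differ between groups of individuals with
  predicted blue vs brown eyes (or between chromosomes carrying the C vs
  T allele of the functional SNP)?
* Are those differences significant, given sparse multiallelic tables?
* Which SNP–STR haplotypes exist, at what frequencies, and how strong is
  allele-level linkage disequilibrium with the functional allele?
* Can a core STR haplotype act as a *proxy* for the functional SNP
  genotype?

## Methods at a glance

* **Gene counting** — allele frequencies over 2N chromosomes per group;
  observed homozygosity; per-allele frequency differences Δ.
* **Monte-Carlo association tests** for 2×K allele tables (the CLUMP
  scheme): T1 is the Pearson χ² of the full table, T2 the χ² after
  pooling columns with small expected counts; significance by simulating
  null tables with fixed row totals and pooled column probabilities,
  with p = (r+1)/(n+1).
* **EM haplotype estimation** — maximum-likelihood multilocus haplotype
  frequencies from unphased genotypes (gene-counting EM under HWE), plus
  most-probable diplotype calls.
* **Allele-level LD** — for allele *i* at one locus and *j* at another,
  D = h\_ij − p\_i q\_j, Lewontin's D′, and
  r² = D² / (p\_i(1−p\_i) q\_j(1−q\_j)), from pairwise EM haplotype
  frequencies; reporting keeps r² ≥ 0.1 with ≥ 5 counts per allele.
* **Allelic odds ratios** — 2×2 (positive allele vs rest × group1 vs
  group2), OR = ad/bc with Wald 95% CI on ln OR and Haldane–Anscombe
  correction for empty cells.
* **Eye-colour prediction** — the standard two-logit multinomial over a
  6-SNP panel (blue/intermediate vs brown on effect-allele counts);
  individuals with p(blue) ≥ 0.8 or p(brown) ≥ 0.8 form the two groups.
  Coefficients are supplied via YAML; the packaged set is synthetic.
* **Core-haplotype proxy evaluation** — copies (0/1/2) of a required
  haplotype (e.g. RRRR at STR6–8–9–10) cross-tabulated against predicted
  phenotype, with predictive values for the homozygous and zero-copy
  rows.
* **Synthetic populations** — diploid cohorts drawn from explicit
  haplotype pools (European-like, East-Asian-like, African-like) under
  Hardy–Weinberg random mating, giving closed-form ground truth for
  every estimator.

## Worked example

Simulate a European-like cohort, assign predicted eye-colour groups, and
run the statistics:

```bash
strlink simulate --n 300 --seed 1 --out genotypes.tsv
strlink predict --genotypes genotypes.tsv --out grouped.tsv
# -> group assignment at threshold 0.80: {'blue': 99, 'brown': 199, 'unassigned': 2}

strlink clump --genotypes grouped.tsv --marker STR9 --nsim 5000 --seed 1
# -> STR9  T1  chi2=201.0704  K=4  p_mc=0.0002
# -> STR9  T2  chi2=201.0704  K=4  p_mc=0.0002

strlink haplotypes --genotypes grouped.tsv \
    --loci STR6,STR8,rs12913832,STR9,STR10 --out haps.tsv
# -> 12 haplotypes, loglik=-801.601, iterations=9, converged=True
# top of haps.tsv:
#   R-R-C-R-R      0.5167   (the C core haplotype)
#   -4--1-T--1--1  0.1367

strlink proxy-eval --genotypes grouped.tsv --out proxy.tsv
# ->           blue  brown
#    2_copies    76      9
#    1_copy      22    132
#    0_copies     1     58
#    ppv homozygous=0.894, ppv zero-copy=0.983
```

The simulated cohort reproduces the qualitative structure the panel is
known for: the blue-eyed group is essentially the rs12913832 C/C
genotype class, the reference-allele core haplotype RRRR rides on the C
background (≈0.5 frequency), homozygosity is elevated in the blue group,
and RRRR homozygotes are predicted blue ~90% of the time while
individuals lacking RRRR are almost always predicted brown.

A full config-driven run (`strlink run --config run.yaml`) executes
predict → group → allele stats → Monte-Carlo tests → EM/LD → proxy
evaluation and writes per-stage TSVs plus `report.txt`.

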