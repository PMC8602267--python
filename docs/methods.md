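# Methods

This note documents the statistical procedures, the synthetic-data
model, and the numerical and design choices behind `strlink`.

## Data model and allele conventions

Markers are either STRs or SNPs.  STR alleles are named by their repeat
offset from the reference genome: `R` for the reference count, `+n`/`-n`
for n repeats more/fewer.  Bare integers on input (as printed in summary
tables) are accepted and normalised to the signed form, and Unicode
minus variants are normalised to ASCII.  SNP alleles are bases.  STR
alleles order by offset, SNP alleles lexicographically; unphased calls
are stored as unordered pairs in this canonical order, which makes
diplotype enumeration and hashing deterministic.

Genotypes travel as TSV (`<marker>_A1`/`<marker>_A2` columns, `.` for
missing) rather than VCF: STR alleles here are repeat-offset symbols,
not sequences, so a VCF encoding would be artificial.  A call is either
complete or missing; half-calls are rejected at parse time.  Multi-locus
analyses use complete cases at their locus subset only — EM with partial
missingness is deliberately out of scope, mirroring the per-marker
variation in usable sample size that real panels show.

An optional per-marker allele-merge map can relabel alleles before
analysis (e.g. merging an STR allele that a particular calling pipeline
cannot distinguish from the reference allele).  No merge is applied by
default.

## Synthetic populations

`simulate` draws diploid individuals from an explicit multilocus
haplotype pool: two independent haplotype draws per individual
(Hardy–Weinberg random mating), phase discarded.  There is no mutation,
inbreeding or population structure within a pool — exactly the
conditions the downstream gene-counting statistics assume.  Because the
pool is explicit, allele frequencies, haplotype frequencies and
allele-level LD all have closed forms (`expected_allele_ld`,
`HaplotypePool.marginal`), which the test suite uses as oracles.

Three packaged scenario pools over 9 polymorphic STRs plus rs1800407 and
rs12913832 are hand-authored fixtures, shaped after the qualitative
population patterns reported for this region but not estimates of any
real population:

* `european_like` — the rs12913832-C allele (0.55) rides almost
  exclusively on a reference-allele core at STR6–8–9–10 (C∧RRRR = 0.50),
  with one RRRR-on-T haplotype (0.03) so the proxy is imperfect; the T
  background carries the alternative −4/−1 STR motifs.
* `east_asian_like` — one dominant T-linked STR motif (−4/−1 at
  STR6/STR8 with T totals 0.87); C is rare (0.01) and sits on the
  *common* background, so no allele pair anchored at the SNP can clear
  the r² ≥ 0.1 reporting filter.
* `african_like` — ten haplotypes, none above 0.14, alleles spread
  widely: per-STR expected heterozygosity exceeds the European-like
  pool's at every STR, and LD is weak.

Four additional unlinked biallelic SNPs (the rest of the 6-SNP
prediction panel, which lies on other chromosomes) are simulated
independently under HWE at typical European frequencies.

What the simulator does **not** emulate: genotyping error, missing data,
population admixture, mutation on the sampled haplotypes, and linkage
between the four unlinked SNPs and the chr15 panel.  Tests passing on
these cohorts therefore validate the estimators under their model
assumptions, not robustness to real-data artefacts.

## Eye-colour prediction and grouping

The prediction model is the standard two-logit multinomial of the 6-SNP
eye-colour panels: with brown as reference, η_blue and η_int are linear
in effect-allele counts (0/1/2), and class probabilities are the softmax
of (η_blue, η_int, 0).  Coefficient values are not part of the package's
claims: they load from YAML, and the packaged `irisplex_demo.yaml` is a
synthetic set (dominated by rs12913832, as the real model is) used by
demos and tests.  Individuals reach the `blue` or `brown` group only
with class probability ≥ the threshold (default 0.8, configurable in
(0.5, 1]); confident intermediate predictions are `unassigned`, never a
group, matching the analysis design the threshold comes from.

## Monte-Carlo association tests

For a 2×K table of allele counts in two groups, the asymptotic χ²
reference is unreliable when many cells are sparse, so significance is
simulated: null tables keep the two row totals fixed and draw each row
from Multinomial(row total, pooled column probabilities).  Conditioning
on both margins was considered and rejected — it changes the reference
distribution relative to the published scheme this follows.  Two
statistics:

* **T1**: Pearson χ² of the full table (zero-total columns dropped).
* **T2**: χ² after *clumping*: columns whose smaller expected cell is
  below `min_expected` (default 5) are pooled into one rare column, in
  ascending order of column total (ties by label), stopping once the
  pooled column itself reaches the threshold.  The rule is re-derived on
  every simulated table so the reference distribution accounts for the
  data-dependent pooling.  A simulated table that collapses to a single
  column scores χ² = 0 (the null-concordant limit).

p = (r+1)/(n+1), never exactly zero — small p-values are honest bounds.
The max-single-column and max-subset statistics of the original CLUMP
program are not implemented; this pipeline uses only T1/T2.  Asymptotic
p-values are available only as a diagnostic, never the primary output.

## EM haplotype estimation

Gene-counting EM for unphased multiallelic genotypes under HWE.  A
genotype with h heterozygous loci has max(1, 2^(h−1)) compatible
unordered haplotype pairs (capped at h = 20; beyond that the caller is
told to use a locus subset).  E-step: each genotype's mass splits over
compatible pairs ∝ 2·h_a·h_b (h_a² for homozygous pairs); M-step: h_k =
expected haplotype count / 2N.  The haplotype universe is the union of
haplotypes compatible with at least one observed genotype — not the full
Cartesian product, which 17-allele STRs would make intractable.

Numerical choices: initialisation at linkage equilibrium
(product-of-allele-frequency start) — a uniform start and random
Dirichlet restarts (`restarts`) are available, but EM for this model at
these scales is well-behaved and single-run deterministic by default;
convergence on max |Δh_k| < 1e−8 (scale-free, unlike a log-likelihood
criterion); haplotypes below 1e−10 pruned at the end with
renormalisation.  The log-likelihood is asserted non-decreasing at every
iteration in the test suite, and EM's fixed point reproduces
gene-counting allele frequencies at each locus — both used as
correctness checks, alongside a brute-force grid-search ML oracle on a
two-locus problem and parameter recovery from simulated cohorts.

Most-probable diplotype calls take the argmax pair probability; exact
ties break on the lexicographically smallest (sorted) pair, so calls are
deterministic.

## Allele-level linkage disequilibrium

LD is computed per allele pair by collapsing each multiallelic locus to
"allele i vs rest" — the form in which multiallelic LD figures are
reported — rather than as a single aggregate multiallelic r² (a
frequency-weighted aggregate is exposed separately).  Pairwise haplotype
frequencies come from EM on the locus pair (not composite genotypic LD);
pre-phased haplotype input can be analysed by constructing the pairwise
frequency table directly.  D′ uses Lewontin's normalisation with
Dmax = min(p(1−q), (1−p)q) for D > 0 and min(pq, (1−p)(1−q)) for D < 0.

Reporting filters follow the figure convention for this kind of panel:
keep r² ≥ 0.1 (inclusive) and both allele counts ≥ 5, where counts are
round(p·2N) on the analysed complete-case sample — the filter counts
alleles, not frequencies.  The anchored view restricts to pairs
involving one named allele (the "associations around the C allele"
presentation).

## Homozygosity and odds ratios

"% homozygosity" is the *observed* fraction of homozygous individuals —
the natural per-individual statistic for a recessive-trait argument;
HWE-expected Σp² is exposed separately under its own name.  The allelic
odds ratio dichotomises a marker at its positive allele, defined for new
data as the allele with the largest frequency excess in group 1
(documented in the output).  From frequencies, the point estimate uses
the odds formula on the exact frequencies (no count rounding); CI and
P come from the implied counts via the Wald interval on ln OR, with a
0.5 continuity correction on all cells when one is empty (flagged
`corrected`).  This is the method family of the common clinical-stats
tools and keeps CIs defined on sparse tables; exact (mid-p/Fisher)
intervals are out of scope.  No multiple-testing correction is applied —
P values are reported raw, and the output metadata says so.

## Core-haplotype proxy evaluation

Dosage of a core haplotype (required allele at each core locus) is
forced to 2 (homozygous match at every locus) or 0 (some locus carries
no required allele) independently of phasing; only the remaining
heterozygous cases consult the EM diplotype call.  Integer dosage via
the most-probable diplotype is the default because the published
cross-tabulations report integer classes; a posterior-weighted
fractional dosage is available as a sensitivity analysis.  The 3×2
dosage-by-phenotype table reports column-conserving counts and two
predictive values: fraction blue among 2-copy individuals and fraction
brown among 0-copy individuals (undefined rows reported as
not-available).  Only `blue`/`brown` individuals enter; unassigned
predictions are excluded.

## Pipeline and reproducibility

A single YAML config drives the full run; every reporting default (0.8
threshold, r² ≥ 0.1, ≥ 5 counts, clumping threshold 5) is a config
default, never hard-coded in computation.  Unknown config keys are
rejected.  All stochastic stages derive seeds from the config seed and
log them; two runs from the same config are byte-identical.

## Problem sizes

The packaged analyses and checks run at desk scale, chosen to give the
estimators comfortable statistical margins: cohorts of 300–2000
simulated individuals (20000 for the HWE calibration check), 5-locus EM
(n = 2000 bounds the recovery error at 0.02), Monte-Carlo tests at
200000 simulations against exact enumeration and 500-replicate null
calibration at 199 simulations each.  Published per-group summary
tables (frequencies, group sizes, 3×2 counts) are treated as inputs for
the worked-example checks; population-scale quantities that would
require the original raw genotypes are covered instead by the
property-based checks on the scenario pools.

## Known limitations

* EM assumes HWE within the analysed sample; strong substructure biases
  haplotype frequencies.
* Complete-case analysis can shrink the sample at wide locus subsets.
* The clumping rule pools rare columns ascending until the pooled column
  clears the threshold; leftover small columns (possible when pooling
  stops early) remain unpooled by design.
* The allele-level r² of a rare allele is bounded well below 1 whenever
  its partner allele is common; filtered views should be read together
  with allele counts.
* Synthetic scenario pools are fixtures: they demonstrate estimator
  correctness and qualitative population signatures, not real allele
  frequencies.
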