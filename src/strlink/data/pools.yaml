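# Hand-authored multilocus haplotype pools for the three simulation
# scenarios.  These are synthetic test populations, loosely shaped after
# the published frequency patterns of the OCA2-HERC2 STR panel; they are
# fixtures with known ground truth, not estimates of real populations.
#
# Loci are ordered by genomic position (chr15, GRCh38).  STR alleles are
# repeat offsets from the reference ("R" = reference count); SNP alleles
# are bases.
loci: [STR1, STR2, STRA, STRB, rs1800407, STR5, STR6, STR8, rs12913832, STR9, STR10]
populations:
  european_like:
    # rs12913832-C rides almost exclusively on the R-R-(C)-R-R core at
    # STR6-STR8-STR9-STR10 (core+C total 0.50); the T background carries
    # the alternative -4/-1 STR motifs plus one RRRR-on-T haplotype so
    # the core haplotype is an imperfect proxy for the SNP.
    haplotypes:
      - {alleles: [R, -6, -2, -4, G, +2, R, R, C, R, R], freq: 0.22}
      - {alleles: [-2, -6, -2, -4, G, -8, R, R, C, R, R], freq: 0.18}
      - {alleles: [R, +2, R, R, G, +2, R, R, C, R, R], freq: 0.10}
      - {alleles: [-4, -6, -2, R, G, -8, -2, R, C, -8, R], freq: 0.05}
      - {alleles: [R, R, R, R, G, R, -4, -1, T, -1, -1], freq: 0.16}
      - {alleles: [-2, R, R, +2, G, R, -4, -1, T, -6, -4], freq: 0.06}
      - {alleles: [R, +2, R, R, A, R, R, -1, T, -1, R], freq: 0.08}
      - {alleles: [-4, R, -2, R, G, +2, R, R, T, R, R], freq: 0.03}
      - {alleles: [+2, -2, R, -4, G, -8, -2, -1, T, -1, -1], freq: 0.06}
      - {alleles: [R, -6, R, R, G, R, -4, -1, T, -1, R], freq: 0.06}
  east_asian_like:
    # One dominant STR motif: -4/-1 at STR6/STR8 paired with rs12913832-T
    # totals 0.87.  The C allele is rare (0.01) and sits on the common
    # background, so no allele-level r^2 anchored at the SNP survives the
    # reporting filters.
    haplotypes:
      - {alleles: [R, R, R, -2, A, R, -4, -1, T, -1, -1], freq: 0.28}
      - {alleles: [R, R, R, -2, G, R, -4, -1, T, -1, R], freq: 0.25}
      - {alleles: [-2, R, -2, -2, G, -8, -4, -1, T, R, -4], freq: 0.20}
      - {alleles: [R, +2, R, R, G, R, -4, -1, T, -6, -4], freq: 0.14}
      - {alleles: [R, R, R, -2, G, +2, R, R, T, R, R], freq: 0.07}
      - {alleles: [-2, -6, -2, -4, G, -8, R, R, T, R, R], freq: 0.05}
      - {alleles: [R, R, R, -2, G, R, -4, -1, C, -1, -1], freq: 0.01}
  african_like:
    # Many haplotypes, none above 0.14, alleles spread widely at every
    # STR: high allelic diversity and weak LD.
    haplotypes:
      - {alleles: [R, R, R, R, G, R, R, R, T, R, R], freq: 0.14}
      - {alleles: [-2, -6, -2, -4, G, -8, -4, -1, T, -1, -1], freq: 0.13}
      - {alleles: [-4, +2, -1, -2, A, +2, -2, -2, T, -8, -4], freq: 0.12}
      - {alleles: [+2, -2, +1, +1, G, -4, -1, +1, T, -6, -6], freq: 0.11}
      - {alleles: [+4, +4, R, -1, G, -2, +1, R, T, -4, +2], freq: 0.10}
      - {alleles: [-6, R, -2, R, A, +4, R, -1, T, +2, R], freq: 0.10}
      - {alleles: [R, -6, -1, -4, G, R, -4, -2, T, R, -1], freq: 0.09}
      - {alleles: [-2, +2, R, -2, G, -8, -2, +1, T, -1, -4], freq: 0.08}
      - {alleles: [-4, -2, +1, +1, A, +2, -1, R, C, -8, -6], freq: 0.07}
      - {alleles: [+2, R, -2, -1, G, -4, +1, -1, C, -6, +2], freq: 0.06}
# Additional biallelic SNPs simulated independently of the haplotype pool
# (they lie on other chromosomes); used to complete the 6-SNP prediction
# panel.  freq is the frequency of the first listed allele.
unlinked_snps:
  - {name: rs16891982, alleles: [G, C], freq: 0.97}
  - {name: rs12203592, alleles: [T, C], freq: 0.15}
  - {name: rs1393350, alleles: [A, G], freq: 0.25}
  - {name: rs12896399, alleles: [T, G], freq: 0.45}
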