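"""Published summary statistics used as worked-example inputs.

These are the printed per-group summaries from the population survey of
this STR panel around rs12913832 (HGDP-CEPH genotypes plus gnomAD v3.1.1
European extracts): positive-allele frequencies with group sizes for the
odds-ratio rows, and the 3x2 core-haplotype / SNP-genotype counts.  They
are *inputs* — small printed tables, not raw genotypes — and the package
recomputes odds ratios and proxy predictive values from them.

``OR_ROWS`` carries the printed odds ratio alongside, so recomputation
can be compared at printed precision.  The STR9 row is a known anomaly:
the odds formula on its printed frequencies gives about 11.8 while the
printed OR is 8; it is flagged ``discrepant`` and excluded from
equivalence checks.
"""

from __future__ import annotations

from dataclasses import dataclass

N_BLUE = 361  # predicted blue-eyed Europeans
N_BROWN = 312  # predicted brown-eyed Europeans


@dataclass(frozen=True)
class ORRow:
    marker: str
    positive_allele: str
    freq_blue: float
    freq_brown: float
    printed_or: float
    discrepant: bool = False


OR_ROWS = [
    ORRow("STR1", "R", 0.409, 0.263, 1.9),
    ORRow("STRA", "-2", 0.740, 0.553, 2.3),
    ORRow("STR5", "+2", 0.490, 0.283, 2.4),
    ORRow("STR6", "R", 0.907, 0.697, 4.25),
    ORRow("STR8", "R", 0.848, 0.573, 4.2),
    ORRow("STR9", "R", 0.936, 0.553, 8.0, discrepant=True),
    ORRow("STR10", "R", 0.935, 0.581, 10.4),
    ORRow("STR6-8-9-10", "RRRR", 0.756, 0.305, 7.1),
]

# Core-haplotype (RRRR at STR6-8-9-10) dosage x predicted phenotype:
# rows (2 copies, 1 copy, 0 copies), columns (blue, brown).
CORE_PROXY_COUNTS = [
    [167, 18],
    [109, 138],
    [17, 136],
]

# rs12913832 genotype x predicted phenotype in the same individuals:
# rows (C/C, C/T, T/T), columns (blue, brown).
SNP_GENOTYPE_COUNTS = [
    [361, 0],
    [0, 139],
    [0, 173],
]
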