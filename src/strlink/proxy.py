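"""Core-haplotype dosage classification and proxy evaluation.

A "core haplotype" is a required allele at each of a set of linked STRs
(e.g. the reference allele R at the four markers flanking the functional
SNP).  Each individual carries 0, 1 or 2 copies; cross-tabulating dosage
against predicted phenotype measures how well the core haplotype proxies
the functional SNP:

* dosage 2 is forced when the individual is homozygous for the required
  allele at every core locus, and dosage 0 when some locus carries
  neither required allele — both independent of phasing;
* otherwise the copy number comes from the most probable EM diplotype
  (or, under the fractional mode, the posterior-weighted expected copy
  number, for sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data_model import GenotypeTable, StrlinkError
from .haplotype_em import (
    HaplotypeFrequencyTable,
    enumerate_compatible_pairs,
    most_probable_diplotype,
)

CoreDef = list[tuple[str, str]]  # (locus, required allele) in locus order


class DataError(StrlinkError):
    pass


def _hap_matches(hap: Sequence[str], required: Sequence[str]) -> bool:
    return all(a == r for a, r in zip(hap, required))


def core_haplotype_dosage(
    genotype: Sequence[tuple[str, str]],
    core_def: CoreDef,
    hft: Optional[HaplotypeFrequencyTable] = None,
    fractional: bool = False,
) -> float:
    """Copies (0/1/2) of the core haplotype carried by one individual.

    ``genotype`` holds the unordered allele pairs at the core loci, in
    core-definition order.  ``hft`` is only needed for the
    phase-ambiguous middle cases.
    """
    required = [r for _, r in core_def]
    if len(genotype) != len(required):
        raise ValueError("genotype/core definition length mismatch")
    if all(a == r and b == r for (a, b), r in zip(genotype, required)):
        return 2
    if any(a != r and b != r for (a, b), r in zip(genotype, required)):
        return 0
    # exactly-heterozygous-at-some-core-locus case: phase decides
    if hft is None:
        raise ValueError("phase-ambiguous dosage requires a haplotype frequency table")
    if fractional:
        pairs = enumerate_compatible_pairs(genotype)
        num = 0.0
        den = 0.0
        for ha, hb in pairs:
            mult = 2.0 if ha != hb else 1.0
            prob = mult * hft.freq.get(ha, 0.0) * hft.freq.get(hb, 0.0)
            copies = int(_hap_matches(ha, required)) + int(_hap_matches(hb, required))
            num += prob * copies
            den += prob
        if den <= 0:
            raise StrlinkError("zero-support genotype under haplotype table")
        return num / den
    dip = most_probable_diplotype(genotype, hft)
    return int(_hap_matches(dip.hap1, required)) + int(_hap_matches(dip.hap2, required))


@dataclass
class ProxyTable:
    """3x2 dosage-by-phenotype counts with proxy predictive values."""

    core_def: CoreDef
    counts: np.ndarray  # rows: 2/1/0 copies; cols: (blue, brown)
    ppv_homozygous: Optional[float]
    ppv_null: Optional[float]

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (3, 2):
            raise StrlinkError("proxy table must be 3x2")
        for v in (self.ppv_homozygous, self.ppv_null):
            if v is not None and not 0 <= v <= 1:
                raise StrlinkError(f"predictive value {v} outside [0, 1]")


def proxy_table_from_counts(counts, core_def: Optional[CoreDef] = None) -> ProxyTable:
    """Build a ProxyTable (with predictive values) from 3x2 counts whose
    rows are (2 copies, 1 copy, 0 copies) and columns (blue, brown)."""
    counts = np.asarray(counts, dtype=np.int64)
    row2, row0 = counts[0], counts[2]
    ppv_hom = float(row2[0] / row2.sum()) if row2.sum() else None
    ppv_null = float(row0[1] / row0.sum()) if row0.sum() else None
    return ProxyTable(
        core_def=core_def or [],
        counts=counts,
        ppv_homozygous=ppv_hom,
        ppv_null=ppv_null,
    )


def cross_tabulate(
    dosages: Sequence[float],
    groups: Sequence[str],
    core_def: Optional[CoreDef] = None,
) -> ProxyTable:
    """Cross-tabulate integer core-haplotype dosages against blue/brown
    group labels; rows ordered (2, 1, 0) copies."""
    if len(dosages) != len(groups):
        raise ValueError("dosages and groups differ in length")
    counts = np.zeros((3, 2), dtype=np.int64)
    col = {"blue": 0, "brown": 1}
    for dose, g in zip(dosages, groups):
        if g not in col:
            raise DataError(f"group {g!r} not in (blue, brown)")
        d = int(round(dose))
        if d not in (0, 1, 2):
            raise DataError(f"dosage {dose} not in (0, 1, 2)")
        counts[2 - d, col[g]] += 1
    return proxy_table_from_counts(counts, core_def)


def classify_cohort(
    gt: GenotypeTable,
    core_def: CoreDef,
    hft: HaplotypeFrequencyTable,
    groups: tuple[str, str] = ("blue", "brown"),
    fractional: bool = False,
) -> ProxyTable:
    """Dosage-classify all grouped, complete-case samples and tabulate."""
    loci = [l for l, _ in core_def]
    dosages = []
    labels = []
    for i in range(gt.n_samples):
        g = gt.samples["group"].iloc[i]
        if g not in groups:
            continue
        genotype = [gt.calls[l][i] for l in loci]
        if any(c is None for c in genotype):
            continue
        dosages.append(core_haplotype_dosage(genotype, core_def, hft, fractional))
        labels.append(g)
    return cross_tabulate(dosages, labels, core_def)


def snp_genotype_crosstab(
    gt: GenotypeTable,
    snp: str,
    groups: tuple[str, str] = ("blue", "brown"),
    derived_allele: Optional[str] = None,
) -> "pd.DataFrame":
    """3x2 genotype-class counts for a biallelic SNP per phenotype group.

    Rows ordered (derived hom, het, ancestral hom); ``derived_allele``
    defaults to the alphabetically first observed allele.
    """
    import pandas as pd

    m = gt.marker(snp)
    observed = sorted(
        {a for call in gt.calls[snp] if call is not None for a in call}
    )
    if len(observed) > 2:
        raise DataError(f"{snp}: more than two alleles observed ({observed})")
    if derived_allele is None:
        derived_allele = observed[0]
    others = [a for a in observed if a != derived_allele]
    anc = others[0] if others else None
    rows = [
        f"{derived_allele}/{derived_allele}",
        f"{derived_allele}/{anc}" if anc else f"{derived_allele}/-",
        f"{anc}/{anc}" if anc else "-/-",
    ]
    counts = np.zeros((3, 2), dtype=np.int64)
    col = {groups[0]: 0, groups[1]: 1}
    for i in range(gt.n_samples):
        g = gt.samples["group"].iloc[i]
        if g not in col:
            continue
        call = gt.calls[snp][i]
        if call is None:
            continue
        n_derived = sum(1 for a in call if a == derived_allele)
        counts[2 - n_derived, col[g]] += 1
    return pd.DataFrame(counts, index=rows, columns=list(groups))
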