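"""Per-group allele frequencies, deltas, homozygosity and odds ratios.

All frequencies are gene-counting estimates: each non-missing diploid
sample contributes two chromosomes.  The allelic odds ratio treats one
"positive" allele against all others in a 2x2 table of two groups, with a
Wald confidence interval on log OR and a Haldane-Anscombe 0.5 continuity
correction when a cell is empty.  No multiple-testing correction is
applied; P values are reported raw.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

from scipy import stats

from .data_model import (
    EmptyGroupError,
    GenotypeTable,
    StrlinkError,
    sort_alleles,
)


class MismatchError(StrlinkError):
    pass


class UndefinedORError(StrlinkError):
    pass


@dataclass
class AlleleFrequencyTable:
    marker: str
    group: str
    two_N: int
    freq: dict[str, float]
    counts: dict[str, int]

    def __post_init__(self):
        total = sum(self.freq.values())
        if self.freq and abs(total - 1.0) > 1e-9:
            raise StrlinkError(f"frequencies sum to {total}, not 1")


def allele_frequencies(
    gt: GenotypeTable,
    marker: str,
    group: str,
    allele_universe: Optional[list[str]] = None,
) -> AlleleFrequencyTable:
    """Gene-counting allele frequencies for one marker in one group.

    ``allele_universe``, when given, forces zero-frequency entries for
    alleles not observed in the group.
    """
    m = gt.marker(marker)
    col = gt.calls[marker]
    idx = gt.samples.index[gt.group_mask(group)]
    tally: dict[str, int] = {}
    for i in idx:
        call = col[i]
        if call is None:
            continue
        for a in call:
            tally[a] = tally.get(a, 0) + 1
    if not tally:
        raise EmptyGroupError(f"group {group!r} empty at marker {marker}")
    two_N = sum(tally.values())
    alleles = set(tally)
    if allele_universe is not None:
        alleles |= set(allele_universe)
    ordered = sort_alleles(alleles, m.kind)
    counts = {a: tally.get(a, 0) for a in ordered}
    freq = {a: c / two_N for a, c in counts.items()}
    return AlleleFrequencyTable(marker=marker, group=group, two_N=two_N, freq=freq, counts=counts)


def frequency_delta(
    fa: AlleleFrequencyTable, fb: AlleleFrequencyTable
) -> list[tuple[str, float]]:
    """Per-allele frequency difference p_a - p_b over the allele union,
    sorted by |delta| descending (ties broken by allele label)."""
    if fa.marker != fb.marker:
        raise MismatchError(f"marker mismatch: {fa.marker} vs {fb.marker}")
    alleles = set(fa.freq) | set(fb.freq)
    deltas = [(a, fa.freq.get(a, 0.0) - fb.freq.get(a, 0.0)) for a in alleles]
    return sorted(deltas, key=lambda t: (-abs(t[1]), t[0]))


def observed_homozygosity(gt: GenotypeTable, marker: str, group: str) -> float:
    """Fraction of non-missing samples in ``group`` carrying two identical
    alleles at ``marker``."""
    col = gt.calls[marker]
    idx = gt.samples.index[gt.group_mask(group)]
    calls = [col[i] for i in idx if col[i] is not None]
    if not calls:
        raise EmptyGroupError(f"group {group!r} empty at marker {marker}")
    return sum(1 for c in calls if c[0] == c[1]) / len(calls)


def expected_homozygosity(gt: GenotypeTable, marker: str, group: str) -> float:
    """HWE-expected homozygosity sum p_i^2 from gene-counting frequencies."""
    ft = allele_frequencies(gt, marker, group)
    return sum(p * p for p in ft.freq.values())


@dataclass
class ORResult:
    """Allelic odds ratio from a 2x2 (positive allele vs rest) table."""

    a: float  # group1, positive allele
    b: float  # group1, other alleles
    c: float  # group2, positive allele
    d: float  # group2, other alleles
    or_point: float
    ci_low: float
    ci_high: float
    p: float
    corrected: bool

    def __post_init__(self):
        if not (self.ci_low <= self.or_point <= self.ci_high):
            raise StrlinkError("CI does not bracket the odds ratio")


def _wald_or(a: float, b: float, c: float, d: float) -> ORResult:
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ln_or = math.log(or_point)
    z = ln_or / se
    return ORResult(
        a=a,
        b=b,
        c=c,
        d=d,
        or_point=or_point,
        ci_low=math.exp(ln_or - 1.959963984540054 * se),
        ci_high=math.exp(ln_or + 1.959963984540054 * se),
        p=float(2 * stats.norm.sf(abs(z))),
        corrected=corrected,
    )


def allelic_odds_ratio_counts(a: float, b: float, c: float, d: float) -> ORResult:
    """OR = (a*d)/(b*c) with Wald 95% CI on ln OR and a two-sided z P value.

    Rows are groups, columns (positive allele, all other alleles); if any
    cell is zero all cells get +0.5 and the result is flagged corrected.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell count")
    if a + b == 0 or c + d == 0:
        raise UndefinedORError("a group has zero total chromosomes")
    return _wald_or(a, b, c, d)


def allelic_odds_ratio_freqs(p1: float, n1: int, p2: float, n2: int) -> ORResult:
    """OR from per-group positive-allele frequencies and sample sizes.

    Uses the odds formula on the exact frequencies (no count rounding):
    OR = [p1/(1-p1)] / [p2/(1-p2)]; the CI/P use implied cell counts
    p*2n on 2n chromosomes per group.
    """
    for p in (p1, p2):
        if not 0 <= p <= 1:
            raise ValueError(f"frequency {p} outside [0, 1]")
    if n1 <= 0 or n2 <= 0:
        raise UndefinedORError("group sample size must be positive")
    a, b = p1 * 2 * n1, (1 - p1) * 2 * n1
    c, d = p2 * 2 * n2, (1 - p2) * 2 * n2
    res = _wald_or(a, b, c, d)
    if not res.corrected:
        # point estimate from exact frequencies, CI/P from implied counts
        res.or_point = (p1 / (1 - p1)) / (p2 / (1 - p2))
    return res


def swap_groups(res: ORResult) -> ORResult:
    """The same comparison with groups exchanged: OR -> 1/OR, CI inverted."""
    return ORResult(
        a=res.c,
        b=res.d,
        c=res.a,
        d=res.b,
        or_point=1 / res.or_point,
        ci_low=1 / res.ci_high,
        ci_high=1 / res.ci_low,
        p=res.p,
        corrected=res.corrected,
    )


def positive_allele(
    gt: GenotypeTable, marker: str, group1: str, group2: str
) -> str:
    """The allele with the largest frequency excess in group1 over group2."""
    f1 = allele_frequencies(gt, marker, group1)
    f2 = allele_frequencies(gt, marker, group2)
    deltas = frequency_delta(f1, f2)
    return max(deltas, key=lambda t: (t[1], t[0]))[0]


def marker_or_summary(
    gt: GenotypeTable, marker: str, group1: str, group2: str
) -> dict:
    """Per-marker summary row: homozygosity per group, positive allele,
    its frequencies, and the allelic OR with CI and P."""
    f1 = allele_frequencies(gt, marker, group1)
    f2 = allele_frequencies(gt, marker, group2)
    # positive allele = largest frequency excess in group1
    pos = max(frequency_delta(f1, f2), key=lambda t: (t[1], t[0]))[0]
    a = f1.counts.get(pos, 0)
    b = f1.two_N - a
    c = f2.counts.get(pos, 0)
    d = f2.two_N - c
    res = allelic_odds_ratio_counts(a, b, c, d)
    return {
        "marker": marker,
        "pct_hom_group1": 100 * observed_homozygosity(gt, marker, group1),
        "pct_hom_group2": 100 * observed_homozygosity(gt, marker, group2),
        "positive_allele": pos,
        "freq_group1": f1.freq.get(pos, 0.0),
        "freq_group2": f2.freq.get(pos, 0.0),
        "or": res.or_point,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "p": res.p,
        "corrected": res.corrected,
    }
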