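"""Allele-level linkage disequilibrium between multiallelic loci.

For a pair of loci, pairwise haplotype frequencies h_ij are estimated by
EM on the locus pair; each allele pair (i, j) is then collapsed to a 2x2
problem (allele i vs rest, allele j vs rest):

    D      = h_ij - p_i q_j
    D'     = D / Dmax            (Lewontin's signed normalisation)
    r^2    = D^2 / (p_i (1-p_i) q_j (1-q_j))

Reporting follows the convention for multiallelic LD figures: records are
kept when r^2 >= 0.1 and both alleles are supported by at least five
counted chromosomes (both thresholds configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .data_model import GenotypeTable, StrlinkError
from .haplotype_em import HaplotypeFrequencyTable, em_haplotype_frequencies

logger = logging.getLogger("strlink")

DEFAULT_MIN_R2 = 0.1
DEFAULT_MIN_COUNT = 5

_TOL = 1e-9


class LookupError_(StrlinkError):
    pass


@dataclass
class LDRecord:
    locusA: str
    locusB: str
    alleleA: str
    alleleB: str
    p_i: float
    q_j: float
    h_ij: float
    D: float
    D_prime: float
    r2: float
    count_i: int
    count_j: int

    def __post_init__(self):
        if not -_TOL <= self.r2 <= 1 + _TOL:
            raise StrlinkError(f"r2 {self.r2} outside [0, 1]")
        if not -1 - _TOL <= self.D_prime <= 1 + _TOL:
            raise StrlinkError(f"D' {self.D_prime} outside [-1, 1]")


def _d_prime(D: float, p: float, q: float) -> float:
    if D > 0:
        dmax = min(p * (1 - q), (1 - p) * q)
    elif D < 0:
        dmax = min(p * q, (1 - p) * (1 - q))
    else:
        return 0.0
    return D / dmax if dmax > 0 else 0.0


def ld_records_from_pairwise(
    hft: HaplotypeFrequencyTable, two_N: int
) -> list[LDRecord]:
    """Allele-pair LD records from a two-locus haplotype frequency table."""
    if len(hft.loci) != 2:
        raise ValueError("pairwise haplotype table required")
    locusA, locusB = hft.loci
    p = hft.marginal_allele_frequencies(locusA)
    q = hft.marginal_allele_frequencies(locusB)
    if len(p) < 2 or len(q) < 2:
        logger.warning("monomorphic locus in pair (%s, %s); no LD records", locusA, locusB)
        return []
    joint: dict[tuple[str, str], float] = {}
    for hap, f in hft.freq.items():
        joint[(hap[0], hap[1])] = joint.get((hap[0], hap[1]), 0.0) + f
    records = []
    for ai in sorted(p):
        for bj in sorted(q):
            pi, qj = p[ai], q[bj]
            denom = pi * (1 - pi) * qj * (1 - qj)
            if denom <= 0:
                continue  # monomorphic allele: r2 undefined, not reported
            h = joint.get((ai, bj), 0.0)
            D = h - pi * qj
            records.append(
                LDRecord(
                    locusA=locusA,
                    locusB=locusB,
                    alleleA=ai,
                    alleleB=bj,
                    p_i=pi,
                    q_j=qj,
                    h_ij=h,
                    D=D,
                    D_prime=_d_prime(D, pi, qj),
                    r2=min(D * D / denom, 1.0),
                    count_i=round(pi * two_N),
                    count_j=round(qj * two_N),
                )
            )
    return records


def pairwise_allele_ld(
    gt: GenotypeTable,
    locusA: str,
    locusB: str,
    **em_kwargs,
) -> list[LDRecord]:
    """Allele-pair D, D', r^2 between two loci via pairwise EM.

    Complete cases at the locus pair only; returns one record per allele
    pair with both alleles segregating.  Monomorphic loci yield an empty
    list with a warning.
    """
    idx = gt.complete_case_index([locusA, locusB])
    if not idx:
        raise StrlinkError(f"no complete cases at ({locusA}, {locusB})")
    sub = gt.subset(idx)
    hft = em_haplotype_frequencies(sub, [locusA, locusB], **em_kwargs)
    return ld_records_from_pairwise(hft, two_N=2 * len(idx))


def filter_ld(
    records: Sequence[LDRecord],
    min_r2: float = DEFAULT_MIN_R2,
    min_count: int = DEFAULT_MIN_COUNT,
) -> list[LDRecord]:
    """Reporting filter: keep r^2 >= min_r2 (inclusive) with both allele
    counts >= min_count; input order preserved."""
    return [
        r
        for r in records
        if r.r2 >= min_r2 - _TOL and r.count_i >= min_count and r.count_j >= min_count
    ]


def ld_matrix(
    gt: GenotypeTable,
    loci: Sequence[str],
    anchor_allele: Optional[tuple[str, str]] = None,
    min_r2: float = DEFAULT_MIN_R2,
    min_count: int = DEFAULT_MIN_COUNT,
    **em_kwargs,
) -> pd.DataFrame:
    """Filtered allele-pair r^2 across locus pairs, as a long-format table.

    With ``anchor_allele = (locus, allele)``, only pairs involving that
    allele are reported — the "associations around one allele" view.
    """
    loci = list(loci)
    if len(loci) < 2:
        raise ValueError("need at least two loci")
    rows = []
    if anchor_allele is not None:
        anchor_locus, anchor = anchor_allele
        if anchor_locus not in loci:
            raise LookupError_(f"anchor locus {anchor_locus!r} not among loci")
        observed = {
            a
            for call in gt.calls[anchor_locus]
            if call is not None
            for a in call
        }
        if anchor not in observed:
            raise LookupError_(
                f"anchor allele {anchor!r} not observed at {anchor_locus}"
            )
        pairs = [(anchor_locus, other) for other in loci if other != anchor_locus]
    else:
        pairs = [(a, b) for i, a in enumerate(loci) for b in loci[i + 1 :]]

    for locusA, locusB in pairs:
        records = pairwise_allele_ld(gt, locusA, locusB, **em_kwargs)
        if anchor_allele is not None:
            records = [r for r in records if r.alleleA == anchor_allele[1]]
        for r in filter_ld(records, min_r2=min_r2, min_count=min_count):
            rows.append(
                {
                    "locusA": r.locusA,
                    "alleleA": r.alleleA,
                    "locusB": r.locusB,
                    "alleleB": r.alleleB,
                    "r2": r.r2,
                    "D": r.D,
                    "D_prime": r.D_prime,
                    "count_i": r.count_i,
                    "count_j": r.count_j,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "locusA",
            "alleleA",
            "locusB",
            "alleleB",
            "r2",
            "D",
            "D_prime",
            "count_i",
            "count_j",
        ],
    )


def aggregate_r2(records: Sequence[LDRecord]) -> float:
    """Frequency-weighted average allele-pair r^2 (a single multiallelic
    summary; the per-allele records remain the primary output)."""
    if not records:
        return 0.0
    weights = [r.p_i * r.q_j for r in records]
    total = sum(weights)
    return sum(w * r.r2 for w, r in zip(weights, records)) / total


def plot_ld_heatmap(matrix: pd.DataFrame, path) -> None:
    """Simple r^2 heat-map rendering of an ld_matrix output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if matrix.empty:
        fig, ax = plt.subplots(figsize=(4, 2))
        ax.text(0.5, 0.5, "no LD records pass filters", ha="center", va="center")
        ax.axis("off")
        fig.savefig(path)
        plt.close(fig)
        return
    matrix = matrix.assign(
        pairA=matrix["locusA"] + ":" + matrix["alleleA"],
        pairB=matrix["locusB"] + ":" + matrix["alleleB"],
    )
    pivot = matrix.pivot_table(index="pairA", columns="pairB", values="r2")
    fig, ax = plt.subplots(figsize=(1 + 0.5 * len(pivot.columns), 1 + 0.4 * len(pivot)))
    im = ax.imshow(pivot.to_numpy(), vmin=0, vmax=1, cmap="Reds")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns, rotation=90)
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    fig.colorbar(im, ax=ax, label="$r^2$")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
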