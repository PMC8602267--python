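"""EM estimation of multilocus haplotype frequencies from unphased data.

The classical gene-counting EM for unphased multiallelic genotypes:
under HWE an individual's genotype probability is the sum over compatible
ordered haplotype pairs of h_a * h_b.  The E-step splits each genotype's
mass over its compatible unordered pairs in proportion to 2*h_a*h_b
(h_a^2 for homozygous pairs); the M-step re-estimates h_k as the expected
haplotype count over 2N chromosomes.  The log-likelihood is non-
decreasing at every iteration — asserted in the test suite.

Only complete cases at the chosen loci enter the estimation; the
haplotype universe is the union of haplotypes compatible with at least
one observed genotype (not the full Cartesian product), which keeps the
problem tractable with 17-allele STRs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data_model import GenotypeTable, StrlinkError

logger = logging.getLogger("strlink")

DEFAULT_TOL = 1e-8
DEFAULT_MAX_ITER = 1000
DEFAULT_PRUNE = 1e-10
DEFAULT_HET_CAP = 20

Hap = tuple[str, ...]


class CombinatorialLimitError(StrlinkError):
    pass


class EmptyInputError(StrlinkError):
    pass


class ZeroSupportError(StrlinkError):
    pass


def enumerate_compatible_pairs(
    genotype: Sequence[tuple[str, str]], het_cap: int = DEFAULT_HET_CAP
) -> list[tuple[Hap, Hap]]:
    """All unordered haplotype pairs consistent with an unphased genotype.

    With h heterozygous loci there are max(1, 2^(h-1)) distinct unordered
    pairs: the first heterozygous locus can be fixed to one orientation.
    """
    het_idx = [i for i, (a, b) in enumerate(genotype) if a != b]
    if len(het_idx) > het_cap:
        raise CombinatorialLimitError(
            f"{len(het_idx)} heterozygous loci exceeds cap {het_cap}; "
            "run on a smaller locus subset"
        )
    if not het_idx:
        hap = tuple(a for a, _ in genotype)
        return [(hap, hap)]
    pairs = []
    # fix orientation at the first heterozygous locus to avoid mirror-image
    # duplicates
    free = het_idx[1:]
    for flips in itertools.product((False, True), repeat=len(free)):
        h1 = list(a for a, _ in genotype)
        h2 = list(b for _, b in genotype)
        for idx, flip in zip(free, flips):
            if flip:
                h1[idx], h2[idx] = h2[idx], h1[idx]
        pairs.append((tuple(h1), tuple(h2)))
    return pairs


@dataclass
class HaplotypeFrequencyTable:
    loci: list[str]
    freq: dict[Hap, float]
    loglik: float
    n_iter: int
    converged: bool

    def __post_init__(self):
        total = sum(self.freq.values())
        if abs(total - 1.0) > 1e-9:
            raise StrlinkError(f"haplotype frequencies sum to {total}, not 1")

    def sorted_items(self) -> list[tuple[Hap, float]]:
        return sorted(self.freq.items(), key=lambda kv: (-kv[1], kv[0]))

    def marginal_allele_frequencies(self, locus: str) -> dict[str, float]:
        j = self.loci.index(locus)
        out: dict[str, float] = {}
        for hap, f in self.freq.items():
            out[hap[j]] = out.get(hap[j], 0.0) + f
        return out


@dataclass
class Diplotype:
    hap1: Hap
    hap2: Hap
    posterior: float

    def __post_init__(self):
        if not 0 <= self.posterior <= 1 + 1e-12:
            raise StrlinkError(f"posterior {self.posterior} outside [0, 1]")


def _complete_genotypes(
    gt: GenotypeTable, loci: Sequence[str]
) -> list[tuple[tuple[tuple[str, str], ...], int]]:
    """Distinct complete-case multilocus genotypes with their multiplicities."""
    for l in loci:
        gt.marker(l)
        if l not in gt.calls:
            raise StrlinkError(f"no calls for locus {l!r}")
    counts: dict[tuple, int] = {}
    for i in range(gt.n_samples):
        calls = tuple(gt.calls[l][i] for l in loci)
        if any(c is None for c in calls):
            continue
        counts[calls] = counts.get(calls, 0) + 1
    return sorted(counts.items())


def em_haplotype_frequencies(
    gt: GenotypeTable,
    loci: Sequence[str],
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    prune: float = DEFAULT_PRUNE,
    init: str = "allele_product",
    het_cap: int = DEFAULT_HET_CAP,
    restarts: int = 0,
    restart_seed: int = 0,
    _trace: Optional[list] = None,
    _dirichlet_rng: Optional[np.random.Generator] = None,
) -> HaplotypeFrequencyTable:
    """Maximum-likelihood haplotype frequencies at ``loci`` by EM.

    Convergence on max absolute frequency change < ``tol`` (scale-free);
    haplotypes below ``prune`` are removed at the end and the remainder
    renormalised.  ``init`` is ``"allele_product"`` (linkage-equilibrium
    start from gene-counting allele frequencies) or ``"uniform"`` over
    the observed-compatible haplotype universe.  ``restarts`` adds that
    many extra runs from random (Dirichlet) starting points, keeping the
    highest log-likelihood — EM is well-behaved at these scales, so the
    default is a single deterministic run.  ``_trace``, if a list,
    collects the per-iteration log-likelihood (test hook).
    """
    if restarts:
        best = em_haplotype_frequencies(
            gt, loci, tol=tol, max_iter=max_iter, prune=prune, init=init,
            het_cap=het_cap, _trace=_trace,
        )
        rng = np.random.default_rng(restart_seed)
        for _ in range(restarts):
            cand = em_haplotype_frequencies(
                gt, loci, tol=tol, max_iter=max_iter, prune=prune,
                init="uniform", het_cap=het_cap, _dirichlet_rng=rng,
            )
            if cand.loglik > best.loglik:
                best = cand
        return best
    loci = list(loci)
    genotypes = _complete_genotypes(gt, loci)
    if not genotypes:
        raise EmptyInputError(f"no complete-case samples at loci {loci}")

    pair_lists = [enumerate_compatible_pairs(g, het_cap) for g, _ in genotypes]
    universe: list[Hap] = sorted({h for pairs in pair_lists for p in pairs for h in p})
    hap_index = {h: i for i, h in enumerate(universe)}
    H = len(universe)
    weights = np.array([w for _, w in genotypes], dtype=float)
    two_N = 2 * weights.sum()

    if _dirichlet_rng is not None:
        h_freq = _dirichlet_rng.dirichlet(np.ones(H))
    elif init == "uniform":
        h_freq = np.full(H, 1.0 / H)
    elif init == "allele_product":
        allele_freqs: list[dict[str, float]] = []
        for j, locus in enumerate(loci):
            tally: dict[str, float] = {}
            for (g, w) in genotypes:
                for a in g[j]:
                    tally[a] = tally.get(a, 0.0) + w
            total = sum(tally.values())
            allele_freqs.append({a: c / total for a, c in tally.items()})
        h_freq = np.array(
            [
                math.prod(allele_freqs[j][h[j]] for j in range(len(loci)))
                for h in universe
            ]
        )
        h_freq /= h_freq.sum()
    else:
        raise ValueError(f"unknown init {init!r}")

    # pair structure flattened for vectorised E-steps
    pair_a = []
    pair_b = []
    pair_geno = []
    pair_het = []
    for gi, pairs in enumerate(pair_lists):
        for (ha, hb) in pairs:
            pair_a.append(hap_index[ha])
            pair_b.append(hap_index[hb])
            pair_geno.append(gi)
            pair_het.append(ha != hb)
    pair_a = np.array(pair_a)
    pair_b = np.array(pair_b)
    pair_geno = np.array(pair_geno)
    pair_mult = np.where(np.array(pair_het), 2.0, 1.0)

    n_geno = len(genotypes)
    loglik = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        pair_prob = pair_mult * h_freq[pair_a] * h_freq[pair_b]
        geno_prob = np.bincount(pair_geno, weights=pair_prob, minlength=n_geno)
        if (geno_prob <= 0).any():
            raise ZeroSupportError("a genotype has zero probability under current estimate")
        loglik = float(weights @ np.log(geno_prob))
        if _trace is not None:
            _trace.append(loglik)
        # E-step: expected pair counts; M-step: haplotype dosage / 2N
        resp = pair_prob / geno_prob[pair_geno] * weights[pair_geno]
        new = (
            np.bincount(pair_a, weights=resp, minlength=H)
            + np.bincount(pair_b, weights=resp, minlength=H)
        ) / two_N
        delta = float(np.max(np.abs(new - h_freq)))
        h_freq = new
        if delta < tol:
            converged = True
            break
    if not converged:
        logger.warning(
            "EM did not converge in %d iterations (last max change %.3g)",
            max_iter,
            delta,
        )

    keep = h_freq >= prune
    h_freq = h_freq[keep] / h_freq[keep].sum()
    freq = {universe[i]: float(f) for i, f in zip(np.flatnonzero(keep), h_freq)}
    return HaplotypeFrequencyTable(
        loci=loci, freq=freq, loglik=loglik, n_iter=n_iter, converged=converged
    )


def most_probable_diplotype(
    genotype: Sequence[tuple[str, str]],
    hft: HaplotypeFrequencyTable,
    het_cap: int = DEFAULT_HET_CAP,
) -> Diplotype:
    """Argmax compatible haplotype pair under ``hft``; ties broken by
    lexicographic order of the (sorted) pair."""
    pairs = enumerate_compatible_pairs(genotype, het_cap)
    scored = []
    for ha, hb in pairs:
        key = tuple(sorted((ha, hb)))
        mult = 2.0 if ha != hb else 1.0
        prob = mult * hft.freq.get(ha, 0.0) * hft.freq.get(hb, 0.0)
        scored.append((prob, key))
    total = sum(p for p, _ in scored)
    if total <= 0:
        raise ZeroSupportError(
            "no compatible pair has positive probability (pruning too aggressive?)"
        )
    best_prob = max(p for p, _ in scored)
    # deterministic tie-break: smallest lexicographic pair among maxima
    maxima = [key for p, key in scored if p >= best_prob - 1e-15 * max(best_prob, 1.0)]
    best_key = min(maxima)
    return Diplotype(hap1=best_key[0], hap2=best_key[1], posterior=best_prob / total)
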