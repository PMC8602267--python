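"""Synthetic diploid populations from explicit haplotype pools.

Individuals are formed by drawing two haplotypes independently from a
population's haplotype frequency distribution (Hardy-Weinberg random
mating, no mutation, no inbreeding), then discarding phase.  Because the
pool is explicit, every downstream statistic — allele frequencies,
haplotype frequencies, allele-level LD — has a closed-form ground truth
that the estimators can be checked against.

Three packaged scenarios emulate the qualitative structure of the study
populations: ``european_like`` (a frequent rs12913832-C core haplotype
with reference STR alleles and strong LD), ``east_asian_like`` (one
dominant T-background STR motif, C nearly absent), and ``african_like``
(many haplotypes, high allelic diversity, weak LD).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .data_model import (
    GenotypeTable,
    MarkerDef,
    MarkerKind,
    StrlinkError,
    canonical_pair,
    read_marker_panel,
    validate_panel,
)

SCENARIOS = ("european_like", "east_asian_like", "african_like")

_FREQ_TOL = 1e-12


class ConfigurationError(StrlinkError):
    pass


@dataclass(frozen=True)
class UnlinkedSnp:
    """A biallelic SNP simulated independently of the haplotype pool."""

    name: str
    alleles: tuple[str, str]
    freq: float  # frequency of alleles[0]


@dataclass
class HaplotypePool:
    """Ground-truth multilocus haplotypes with frequencies."""

    loci: list[str]
    haplotypes: list[tuple[str, ...]]
    freqs: np.ndarray

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.haplotypes) != len(self.freqs):
            raise ConfigurationError("haplotype/frequency length mismatch")
        for h in self.haplotypes:
            if len(h) != len(self.loci):
                raise ConfigurationError(
                    f"haplotype {h} has {len(h)} alleles for {len(self.loci)} loci"
                )
        if (self.freqs < 0).any():
            raise ConfigurationError("negative haplotype frequency")
        if abs(self.freqs.sum() - 1.0) > _FREQ_TOL:
            raise ConfigurationError(
                f"haplotype frequencies sum to {self.freqs.sum()!r}, not 1"
            )

    def locus_index(self, locus: str) -> int:
        try:
            return self.loci.index(locus)
        except ValueError:
            raise ConfigurationError(f"locus {locus!r} not in pool")

    def allele_frequencies(self, locus: str) -> dict[str, float]:
        """Marginal allele frequencies at one locus, implied by the pool."""
        j = self.locus_index(locus)
        out: dict[str, float] = {}
        for hap, f in zip(self.haplotypes, self.freqs):
            out[hap[j]] = out.get(hap[j], 0.0) + f
        return out

    def expected_heterozygosity(self, locus: str) -> float:
        p = np.array(list(self.allele_frequencies(locus).values()))
        return float(1.0 - (p**2).sum())

    def marginal(self, loci: Sequence[str]) -> "HaplotypePool":
        """Pool marginalised onto a locus subset (summing frequencies)."""
        idx = [self.locus_index(l) for l in loci]
        agg: dict[tuple[str, ...], float] = {}
        for hap, f in zip(self.haplotypes, self.freqs):
            key = tuple(hap[i] for i in idx)
            agg[key] = agg.get(key, 0.0) + f
        haps = sorted(agg)
        return HaplotypePool(
            loci=list(loci), haplotypes=haps, freqs=np.array([agg[h] for h in haps])
        )


@dataclass
class SimTruth:
    """Ground-truth phase for a simulated cohort."""

    pool: HaplotypePool
    diplotypes: list[tuple[int, int]]  # ordered haplotype indices per sample
    seed: int


def _package_yaml(name: str) -> dict:
    ref = importlib.resources.files("strlink").joinpath("data", name)
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


def default_panel() -> list[MarkerDef]:
    """The packaged demo marker panel (chr15 STR/SNP loci + unlinked SNPs)."""
    ref = importlib.resources.files("strlink").joinpath("data", "panel.tsv")
    with importlib.resources.as_file(ref) as path:
        return read_marker_panel(path)


def load_pool(doc: dict, population: str) -> HaplotypePool:
    """Build a HaplotypePool from a parsed pool.yaml document."""
    loci = list(doc["loci"])
    pops = doc["populations"]
    if population not in pops:
        raise ConfigurationError(
            f"unknown population {population!r}; available: {sorted(pops)}"
        )
    entries = pops[population]["haplotypes"]
    haps = [tuple(str(a) for a in e["alleles"]) for e in entries]
    freqs = np.array([float(e["freq"]) for e in entries])
    return HaplotypePool(loci=loci, haplotypes=haps, freqs=freqs)


def load_pool_file(path, population: str) -> HaplotypePool:
    with open(path) as fh:
        return load_pool(yaml.safe_load(fh), population)


def default_unlinked_snps() -> list[UnlinkedSnp]:
    doc = _package_yaml("pools.yaml")
    return [
        UnlinkedSnp(name=e["name"], alleles=tuple(e["alleles"]), freq=float(e["freq"]))
        for e in doc.get("unlinked_snps", [])
    ]


def build_default_pool(scenario: str) -> HaplotypePool:
    """Load one of the packaged scenario pools.

    ``scenario`` is one of ``european_like``, ``east_asian_like``,
    ``african_like``.
    """
    if scenario not in SCENARIOS:
        raise ConfigurationError(
            f"unknown scenario {scenario!r}; expected one of {SCENARIOS}"
        )
    return load_pool(_package_yaml("pools.yaml"), scenario)


def simulate_population(
    pool: HaplotypePool,
    n: int,
    seed: int,
    panel: Optional[Sequence[MarkerDef]] = None,
    unlinked_snps: Optional[Sequence[UnlinkedSnp]] = None,
    population: str = "sim",
) -> tuple[GenotypeTable, SimTruth]:
    """Draw ``n`` diploid individuals from a haplotype pool under HWE.

    Each individual is two independent draws from the pool's haplotype
    distribution; the returned GenotypeTable carries unordered (unphased)
    allele pairs, while SimTruth records the ordered haplotype indices.
    Optional ``unlinked_snps`` are drawn independently per chromosome.
    Deterministic given ``seed``.
    """
    if n < 1:
        raise ValueError(f"sample count must be >= 1, got {n}")
    rng = np.random.default_rng(seed)
    k = len(pool.haplotypes)
    draws = rng.choice(k, size=(n, 2), p=pool.freqs)

    if panel is None:
        panel = default_panel()
    panel = validate_panel(list(panel))
    marker_map = {m.name: m for m in panel}
    for locus in pool.loci:
        if locus not in marker_map:
            raise ConfigurationError(f"pool locus {locus!r} missing from panel")

    samples = pd.DataFrame(
        {
            "sample_id": [f"{population}_{i:05d}" for i in range(n)],
            "population": population,
            "group": [None] * n,
        }
    )
    calls: dict[str, list] = {}
    for j, locus in enumerate(pool.loci):
        kind = marker_map[locus].kind
        col = []
        for h1, h2 in draws:
            a = pool.haplotypes[h1][j]
            b = pool.haplotypes[h2][j]
            col.append(canonical_pair(a, b, kind))
        calls[locus] = col

    for snp in unlinked_snps or []:
        if snp.name not in marker_map:
            raise ConfigurationError(f"unlinked SNP {snp.name!r} missing from panel")
        kind = marker_map[snp.name].kind
        if kind is not MarkerKind.SNP:
            raise ConfigurationError(f"unlinked SNP {snp.name!r} is not a SNP marker")
        g = rng.random((n, 2)) < snp.freq
        calls[snp.name] = [
            canonical_pair(
                snp.alleles[0] if g[i, 0] else snp.alleles[1],
                snp.alleles[0] if g[i, 1] else snp.alleles[1],
                kind,
            )
            for i in range(n)
        ]

    gt = GenotypeTable(panel=list(panel), samples=samples, calls=calls)
    truth = SimTruth(pool=pool, diplotypes=[tuple(d) for d in draws], seed=seed)
    return gt, truth


def expected_allele_ld(
    pool: HaplotypePool, locusA: str, locusB: str
) -> list[dict]:
    """Closed-form allele-pair LD implied by a pool (the estimator oracle).

    For each allele pair (i at locusA, j at locusB):
    ``D = h_ij - p_i q_j`` and ``r2 = D^2 / (p_i(1-p_i) q_j(1-q_j))``,
    computed exactly from pool frequencies.  Monomorphic alleles
    (p in {0, 1}) yield records flagged ``defined=False`` with r2 None.
    """
    ia, ib = pool.locus_index(locusA), pool.locus_index(locusB)
    p = pool.allele_frequencies(locusA)
    q = pool.allele_frequencies(locusB)
    joint: dict[tuple[str, str], float] = {}
    for hap, f in zip(pool.haplotypes, pool.freqs):
        key = (hap[ia], hap[ib])
        joint[key] = joint.get(key, 0.0) + f
    records = []
    for ai, pi in sorted(p.items()):
        for bj, qj in sorted(q.items()):
            h = joint.get((ai, bj), 0.0)
            D = h - pi * qj
            denom = pi * (1 - pi) * qj * (1 - qj)
            defined = denom > 0
            records.append(
                {
                    "locusA": locusA,
                    "locusB": locusB,
                    "alleleA": ai,
                    "alleleB": bj,
                    "p_i": pi,
                    "q_j": qj,
                    "h_ij": h,
                    "D": D,
                    "r2": (D * D / denom) if defined else None,
                    "defined": defined,
                }
            )
    return records
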