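"""Run configuration: YAML loading, defaulting and range checks.

A single YAML file drives the end-to-end pipeline; every reporting
default (group-probability threshold 0.8, LD filters r^2 >= 0.1 with
>= 5 allele counts, clumping threshold 5) lives here, never hard-coded
in the computation modules.  Unknown keys are rejected to catch typos.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .data_model import StrlinkError


class ConfigError(StrlinkError):
    pass


_KNOWN_KEYS = {
    "genotypes",
    "panel",
    "model",
    "pool",
    "pool_population",
    "simulate_n",
    "seed",
    "group_threshold",
    "clump",
    "em",
    "ld",
    "core_haplotype",
    "functional_snp",
    "derived_allele",
    "allele_merge",
    "output_dir",
}
_CLUMP_KEYS = {"n_sim", "min_expected"}
_EM_KEYS = {"tol", "max_iter", "prune", "restarts", "loci"}
_LD_KEYS = {"min_r2", "min_count", "anchor"}


@dataclass
class RunConfig:
    genotypes: Optional[str] = None
    panel: Optional[str] = None
    model: Optional[str] = None
    pool: Optional[str] = None
    pool_population: str = "european_like"
    simulate_n: int = 500
    seed: int = 1
    group_threshold: float = 0.8
    clump_n_sim: int = 100_000
    clump_min_expected: float = 5.0
    em_tol: float = 1e-8
    em_max_iter: int = 1000
    em_prune: float = 1e-10
    em_restarts: int = 0
    em_loci: list = field(
        default_factory=lambda: ["STR6", "STR8", "rs12913832", "STR9", "STR10"]
    )
    ld_min_r2: float = 0.1
    ld_min_count: int = 5
    ld_anchor: Optional[str] = "rs12913832:C"
    core_haplotype: list = field(
        default_factory=lambda: [
            ["STR6", "R"],
            ["STR8", "R"],
            ["STR9", "R"],
            ["STR10", "R"],
        ]
    )
    functional_snp: str = "rs12913832"
    derived_allele: str = "C"
    allele_merge: dict = field(default_factory=dict)
    output_dir: str = "strlink_out"

    def __post_init__(self):
        if not 0.5 < self.group_threshold <= 1.0:
            raise ConfigError(
                f"group_threshold must be in (0.5, 1], got {self.group_threshold}"
            )
        if self.clump_n_sim < 1:
            raise ConfigError("clump.n_sim must be >= 1")
        if self.clump_min_expected <= 0:
            raise ConfigError("clump.min_expected must be positive")
        if not 0 <= self.ld_min_r2 <= 1:
            raise ConfigError("ld.min_r2 must be in [0, 1]")
        if self.ld_min_count < 0:
            raise ConfigError("ld.min_count must be non-negative")
        if self.em_tol <= 0 or self.em_prune < 0 or self.em_max_iter < 1 or self.em_restarts < 0:
            raise ConfigError("invalid EM settings")
        if self.simulate_n < 1:
            raise ConfigError("simulate_n must be >= 1")

    @property
    def anchor_tuple(self) -> Optional[tuple[str, str]]:
        if not self.ld_anchor:
            return None
        locus, _, allele = self.ld_anchor.partition(":")
        if not allele:
            raise ConfigError(f"anchor must be 'locus:allele', got {self.ld_anchor!r}")
        return locus, allele


def _check_keys(section: dict, allowed: set, where: str) -> None:
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown {where} keys: {sorted(unknown)}")


def config_from_dict(doc: dict) -> RunConfig:
    doc = doc or {}
    _check_keys(doc, _KNOWN_KEYS, "config")
    clump = doc.get("clump") or {}
    em = doc.get("em") or {}
    ld = doc.get("ld") or {}
    _check_keys(clump, _CLUMP_KEYS, "clump")
    _check_keys(em, _EM_KEYS, "em")
    _check_keys(ld, _LD_KEYS, "ld")
    kwargs = dict(
        genotypes=doc.get("genotypes"),
        panel=doc.get("panel"),
        model=doc.get("model"),
        pool=doc.get("pool"),
        pool_population=doc.get("pool_population", "european_like"),
        simulate_n=int(doc.get("simulate_n", 500)),
        seed=int(doc.get("seed", 1)),
        group_threshold=float(doc.get("group_threshold", 0.8)),
        clump_n_sim=int(clump.get("n_sim", 100_000)),
        clump_min_expected=float(clump.get("min_expected", 5.0)),
        em_tol=float(em.get("tol", 1e-8)),
        em_max_iter=int(em.get("max_iter", 1000)),
        em_prune=float(em.get("prune", 1e-10)),
        em_restarts=int(em.get("restarts", 0)),
        ld_min_r2=float(ld.get("min_r2", 0.1)),
        ld_min_count=int(ld.get("min_count", 5)),
        ld_anchor=ld.get("anchor", "rs12913832:C"),
        functional_snp=doc.get("functional_snp", "rs12913832"),
        derived_allele=doc.get("derived_allele", "C"),
        allele_merge=doc.get("allele_merge") or {},
        output_dir=doc.get("output_dir", "strlink_out"),
    )
    if "em" in doc and "loci" in em:
        kwargs["em_loci"] = list(em["loci"])
    if "core_haplotype" in doc:
        kwargs["core_haplotype"] = [list(x) for x in doc["core_haplotype"]]
    return RunConfig(**kwargs)


def validate_config(path) -> RunConfig:
    """Load, type, default and range-check a YAML run config.

    Referenced input paths must exist at validation time (fail fast,
    before any computation).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    cfg = config_from_dict(doc)
    for attr in ("genotypes", "panel", "model", "pool"):
        p = getattr(cfg, attr)
        if p is not None and not os.path.exists(p):
            raise ConfigError(f"{attr} path does not exist: {p}")
    return cfg
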