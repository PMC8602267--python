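"""End-to-end orchestration: simulate/load -> predict -> statistics.

``run_pipeline`` executes the full analysis a config describes and
writes one TSV per stage plus a human-readable report.  Every stochastic
stage derives its seed from the config seed and logs it; re-running the
same config reproduces byte-identical outputs.
"""

from __future__ import annotations

import logging
import os
import time
from typing import Optional

import pandas as pd

from . import allele_stats, clump, ld, phenotype, proxy, simulate
from .config import RunConfig
from .data_model import (
    GenotypeTable,
    count_alleles,
    read_genotypes,
    read_marker_panel,
    write_genotypes,
)
from .haplotype_em import em_haplotype_frequencies

logger = logging.getLogger("strlink")


def setup_logging(log_path: Optional[str] = None, level: int = logging.INFO) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if log_path:
        handlers.append(logging.FileHandler(log_path, mode="w"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def _load_or_simulate(cfg: RunConfig) -> GenotypeTable:
    panel = read_marker_panel(cfg.panel) if cfg.panel else simulate.default_panel()
    if cfg.genotypes:
        logger.info("stage load: reading genotypes from %s", cfg.genotypes)
        return read_genotypes(cfg.genotypes, panel)
    pool = (
        simulate.load_pool_file(cfg.pool, cfg.pool_population)
        if cfg.pool
        else simulate.build_default_pool(cfg.pool_population)
    )
    logger.info(
        "stage simulate: n=%d population=%s seed=%d",
        cfg.simulate_n,
        cfg.pool_population,
        cfg.seed,
    )
    gt, _ = simulate.simulate_population(
        pool,
        cfg.simulate_n,
        seed=cfg.seed,
        panel=panel,
        unlinked_snps=simulate.default_unlinked_snps(),
        population=cfg.pool_population,
    )
    return gt


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute predict -> group -> allele stats -> clump -> EM/LD -> proxy.

    Returns a dict of the stage outputs; side effect: TSVs and report.txt
    under ``cfg.output_dir``.
    """
    t0 = time.time()
    os.makedirs(cfg.output_dir, exist_ok=True)
    out = lambda name: os.path.join(cfg.output_dir, name)

    gt = _load_or_simulate(cfg)
    if cfg.allele_merge:
        logger.info("applying allele merge map: %s", cfg.allele_merge)
        gt = gt.merge_alleles(cfg.allele_merge)

    model = phenotype.load_model(cfg.model) if cfg.model else phenotype.load_demo_model()
    preds = phenotype.predict(gt, model)
    labels = phenotype.assign_groups(preds, cfg.group_threshold)
    gt = gt.with_groups(
        [l if l in (phenotype.GROUP_BLUE, phenotype.GROUP_BROWN) else None for l in labels]
    )
    write_genotypes(gt, out("genotypes_grouped.tsv"))
    pd.DataFrame(
        [
            {
                "sample_id": p.sample_id,
                "p_blue": p.p_blue,
                "p_intermediate": p.p_intermediate,
                "p_brown": p.p_brown,
                "group": l,
            }
            for p, l in zip(preds, labels)
            if p is not None
        ]
    ).to_csv(out("predictions.tsv"), sep="\t", index=False)

    groups = (phenotype.GROUP_BLUE, phenotype.GROUP_BROWN)
    str_markers = [
        m.name
        for m in gt.panel
        if m.name in gt.calls and m.kind.value == "STR"
    ]

    # Table-3-style per-marker summary
    stats_rows = [
        allele_stats.marker_or_summary(gt, m, *groups) for m in str_markers
    ]
    stats_df = pd.DataFrame(stats_rows)
    stats_df.to_csv(out("allele_stats.tsv"), sep="\t", index=False)

    # Table-2-style Monte-Carlo association tests
    clump_rows = []
    for i, m in enumerate(str_markers):
        table = count_alleles(gt, m, groups)
        row = {"marker": m}
        for stat in (clump.T1, clump.T2):
            res = clump.clump_test(
                table,
                statistic=stat,
                n_sim=cfg.clump_n_sim,
                seed=cfg.seed + 1000 + i,
                min_expected=cfg.clump_min_expected,
            )
            row[f"p_{stat}"] = res.p_mc
            row[f"chi2_{stat}"] = res.chi2_obs
        logger.info("stage clump: %s p_T1=%.3g p_T2=%.3g", m, row["p_T1"], row["p_T2"])
        clump_rows.append(row)
    clump_df = pd.DataFrame(clump_rows)
    clump_df.to_csv(out("clump.tsv"), sep="\t", index=False)

    # EM haplotype frequencies over the configured locus subset
    em_idx = gt.complete_case_index(cfg.em_loci)
    hft = em_haplotype_frequencies(
        gt.subset(em_idx),
        cfg.em_loci,
        tol=cfg.em_tol,
        max_iter=cfg.em_max_iter,
        prune=cfg.em_prune,
        restarts=cfg.em_restarts,
        restart_seed=cfg.seed,
    )
    hap_rows = []
    cum = 0.0
    for hap, f in hft.sorted_items():
        cum += f
        hap_rows.append({"haplotype": "-".join(hap), "frequency": f, "cumulative": cum})
    hap_df = pd.DataFrame(hap_rows)
    hap_df.to_csv(out("haplotypes.tsv"), sep="\t", index=False)
    logger.info(
        "stage EM: %d haplotypes, loglik=%.3f, %d iterations, converged=%s",
        len(hft.freq),
        hft.loglik,
        hft.n_iter,
        hft.converged,
    )

    # Filtered LD around the anchor allele
    ld_df = ld.ld_matrix(
        gt,
        cfg.em_loci,
        anchor_allele=cfg.anchor_tuple,
        min_r2=cfg.ld_min_r2,
        min_count=cfg.ld_min_count,
        tol=cfg.em_tol,
        max_iter=cfg.em_max_iter,
        prune=cfg.em_prune,
    )
    ld_df.to_csv(out("ld.tsv"), sep="\t", index=False)

    # Core-haplotype proxy classification
    core_def = [(l, a) for l, a in cfg.core_haplotype]
    core_loci = [l for l, _ in core_def]
    core_hft = em_haplotype_frequencies(
        gt.subset(gt.complete_case_index(core_loci)),
        core_loci,
        tol=cfg.em_tol,
        max_iter=cfg.em_max_iter,
        prune=cfg.em_prune,
    )
    proxy_table = proxy.classify_cohort(gt, core_def, core_hft, groups)
    snp_tab = proxy.snp_genotype_crosstab(
        gt, cfg.functional_snp, groups, derived_allele=cfg.derived_allele
    )
    proxy_df = pd.DataFrame(
        proxy_table.counts,
        index=["2_copies", "1_copy", "0_copies"],
        columns=list(groups),
    )
    proxy_df.to_csv(out("proxy.tsv"), sep="\t")
    snp_tab.to_csv(out("snp_crosstab.tsv"), sep="\t")

    report = _render_report(cfg, gt, stats_df, clump_df, hap_df, ld_df, proxy_table, snp_tab)
    with open(out("report.txt"), "w") as fh:
        fh.write(report)
    logger.info("pipeline finished in %.1f s; outputs in %s", time.time() - t0, cfg.output_dir)
    return {
        "genotypes": gt,
        "allele_stats": stats_df,
        "clump": clump_df,
        "haplotypes": hft,
        "ld": ld_df,
        "proxy": proxy_table,
        "snp_crosstab": snp_tab,
    }


def _render_report(cfg, gt, stats_df, clump_df, hap_df, ld_df, proxy_table, snp_tab) -> str:
    n_blue = int((gt.samples["group"] == "blue").sum())
    n_brown = int((gt.samples["group"] == "brown").sum())
    lines = [
        "strlink run report",
        "==================",
        f"seed: {cfg.seed}",
        f"samples: {gt.n_samples} (blue {n_blue}, brown {n_brown}, "
        f"unassigned {gt.n_samples - n_blue - n_brown})",
        f"group threshold: {cfg.group_threshold}",
        "",
        "Per-marker allele statistics (blue vs brown)",
        stats_df.to_string(index=False),
        "",
        f"Monte-Carlo association tests (n_sim={cfg.clump_n_sim})",
        clump_df.to_string(index=False),
        "",
        f"EM haplotype frequencies over {cfg.em_loci}",
        hap_df.head(15).to_string(index=False),
        "",
        f"Filtered LD (r2 >= {cfg.ld_min_r2}, counts >= {cfg.ld_min_count}, "
        f"anchor {cfg.ld_anchor})",
        ld_df.to_string(index=False) if not ld_df.empty else "(no records pass filters)",
        "",
        "Core-haplotype proxy classification (rows 2/1/0 copies)",
        pd.DataFrame(
            proxy_table.counts,
            index=["2_copies", "1_copy", "0_copies"],
            columns=["blue", "brown"],
        ).to_string(),
        f"predictive value, homozygous row: {proxy_table.ppv_homozygous}",
        f"predictive value, zero-copy row:  {proxy_table.ppv_null}",
        "",
        f"{cfg.functional_snp} genotype cross-tabulation",
        snp_tab.to_string(),
        "",
    ]
    return "\n".join(lines)
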