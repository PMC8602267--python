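"""EM haplotype estimation: pair enumeration, likelihood, oracles."""

import itertools

import numpy as np
import pytest

from strlink.haplotype_em import (
    CombinatorialLimitError,
    em_haplotype_frequencies,
    enumerate_compatible_pairs,
    most_probable_diplotype,
)
from strlink.simulate import build_default_pool, simulate_population

from conftest import make_gt, make_panel


class TestEnumerateCompatiblePairs:
    def test_fully_homozygous_single_pair(self):
        pairs = enumerate_compatible_pairs([("R", "R"), ("C", "C")])
        assert pairs == [(("R", "C"), ("R", "C"))]

    def test_two_heterozygous_loci_cis_trans(self):
        pairs = enumerate_compatible_pairs([("R", "-4"), ("C", "T")])
        assert len(pairs) == 2
        as_sets = {frozenset(p) for p in pairs}
        assert frozenset({("R", "C"), ("-4", "T")}) in as_sets
        assert frozenset({("R", "T"), ("-4", "C")}) in as_sets

    @pytest.mark.parametrize("h", [1, 2, 3, 4])
    def test_pair_count_and_compatibility(self, h):
        genotype = [("a", "b")] * h + [("x", "x")]
        pairs = enumerate_compatible_pairs(genotype)
        assert len(pairs) == max(1, 2 ** (h - 1))
        assert len({tuple(sorted(p)) for p in pairs}) == len(pairs)
        for h1, h2 in pairs:
            for (ga, gb), a1, a2 in zip(genotype, h1, h2):
                assert {a1, a2} == {ga, gb} or (ga == gb and a1 == a2 == ga)

    def test_heterozygosity_cap(self):
        genotype = [("a", "b")] * 25
        with pytest.raises(CombinatorialLimitError):
            enumerate_compatible_pairs(genotype)


def em_on(calls, loci=None, panel=None, **kw):
    panel = panel or make_panel(("L1", "STR", 1), ("L2", "STR", 2))
    gt = make_gt(panel, calls)
    return em_haplotype_frequencies(gt, loci or list(calls), **kw)


class TestEMHaplotypeFrequencies:
    def test_homozygous_data_equals_direct_counting(self):
        hft = em_on({"L1": ["R/R", "R/R", "-4/-4"], "L2": ["R/R", "-1/-1", "-1/-1"]})
        assert hft.freq[("R", "R")] == pytest.approx(1 / 3)
        assert hft.freq[("R", "-1")] == pytest.approx(1 / 3)
        assert hft.freq[("-4", "-1")] == pytest.approx(1 / 3)
        assert hft.converged

    def test_loglik_monotone_nondecreasing(self):
        trace = []
        em_on(
            {
                "L1": ["R/-4", "R/-4", "R/R", "-4/-4", "R/-4", "R/R"],
                "L2": ["R/-1", "R/-1", "R/R", "-1/-1", "R/R", "R/-1"],
            },
            _trace=trace,
        )
        assert len(trace) > 1
        assert all(b >= a - 1e-10 for a, b in zip(trace, trace[1:]))

    def test_matches_grid_search_ml_oracle(self):
        """2-locus biallelic mixture of double heterozygotes and phase-known
        genotypes: EM equals brute-force ML over the haplotype simplex."""
        calls = {
            "L1": ["R/-4"] * 4 + ["R/R"] * 3 + ["-4/-4"] * 2 + ["R/R"],
            "L2": ["R/-1"] * 4 + ["R/R"] * 3 + ["-1/-1"] * 2 + ["-1/-1"],
        }
        hft = em_on(calls, tol=1e-12)

        haps = [("R", "R"), ("R", "-1"), ("-4", "R"), ("-4", "-1")]

        def loglik(h):
            freq = dict(zip(haps, h))
            ll = 0.0
            for g1, g2 in zip(calls["L1"], calls["L2"]):
                pair1 = tuple(g1.split("/"))
                pair2 = tuple(g2.split("/"))
                prob = 0.0
                seen = set()
                for a1, b1 in (pair1, pair1[::-1]):
                    ha = (a1, pair2[0])
                    hb = (b1, pair2[1])
                    key = tuple(sorted((ha, hb)))
                    if key in seen:
                        continue
                    seen.add(key)
                    mult = 2.0 if ha != hb else 1.0
                    prob += mult * freq.get(ha, 0.0) * freq.get(hb, 0.0)
                ll += np.log(max(prob, 1e-300))
            return ll

        # coarse-to-fine grid over the 3-simplex
        best, step = None, 0.05
        grid = [
            (a, b, c, 1 - a - b - c)
            for a in np.arange(0, 1.0001, step)
            for b in np.arange(0, 1.0001 - a, step)
            for c in np.arange(0, 1.0001 - a - b, step)
        ]
        best = max(grid, key=loglik)
        for step in (0.01, 0.002, 0.0004, 0.0001, 0.00002):
            a0, b0, c0, _ = best
            local = []
            for da in np.arange(-5 * step, 5.0001 * step, step):
                for db in np.arange(-5 * step, 5.0001 * step, step):
                    for dc in np.arange(-5 * step, 5.0001 * step, step):
                        a, b, c = a0 + da, b0 + db, c0 + dc
                        if a < 0 or b < 0 or c < 0 or a + b + c > 1:
                            continue
                        local.append((a, b, c, 1 - a - b - c))
            best = max(local, key=loglik)

        for hap, f_oracle in zip(haps, best):
            assert hft.freq.get(hap, 0.0) == pytest.approx(f_oracle, abs=1e-4)
        assert hft.loglik >= loglik(best) - 1e-6

    def test_recovers_pool_frequencies_from_simulation(self):
        pool = build_default_pool("european_like")
        loci = ["STR6", "STR8", "rs12913832", "STR9", "STR10"]
        gt, _ = simulate_population(pool, 2000, seed=13)
        hft = em_haplotype_frequencies(gt, loci)
        truth = pool.marginal(loci)
        truth_map = dict(zip(truth.haplotypes, truth.freqs))
        all_haps = set(truth_map) | set(hft.freq)
        errs = [abs(hft.freq.get(h, 0.0) - truth_map.get(h, 0.0)) for h in all_haps]
        assert max(errs) < 0.02

    def test_random_restarts_reach_same_optimum(self):
        calls = {
            "L1": ["R/-4"] * 4 + ["R/R"] * 3 + ["-4/-4"] * 2 + ["R/R"],
            "L2": ["R/-1"] * 4 + ["R/R"] * 3 + ["-1/-1"] * 2 + ["-1/-1"],
        }
        single = em_on(calls, tol=1e-12)
        multi = em_on(calls, tol=1e-12, restarts=3, restart_seed=5)
        assert multi.loglik == pytest.approx(single.loglik, abs=1e-6)

    def test_marginal_consistency_with_gene_counting(self):
        calls = {
            "L1": ["R/-4", "R/R", "R/-4", "-4/-4", "R/R"],
            "L2": ["R/-1", "R/-1", "-1/-1", "R/R", "R/-1"],
        }
        hft = em_on(calls, tol=1e-12)
        for locus, col in calls.items():
            tally = {}
            for c in col:
                for a in c.split("/"):
                    tally[a] = tally.get(a, 0) + 1
            total = sum(tally.values())
            implied = hft.marginal_allele_frequencies(locus)
            for a, n in tally.items():
                assert implied[a] == pytest.approx(n / total, abs=1e-6)

    def test_pairwise_marginalisation_consistency(self):
        pool = build_default_pool("european_like")
        gt, _ = simulate_population(pool, 400, seed=21)
        hft = em_haplotype_frequencies(gt, ["STR6", "rs12913832"])
        from strlink.allele_stats import allele_frequencies

        gtg = gt.with_groups(["g"] * gt.n_samples)
        direct = allele_frequencies(gtg, "STR6", "g").freq
        implied = hft.marginal_allele_frequencies("STR6")
        for a, p in direct.items():
            assert implied[a] == pytest.approx(p, abs=1e-6)


class TestMostProbableDiplotype:
    def test_homozygous_posterior_one(self):
        hft = em_on({"L1": ["R/R"], "L2": ["R/R"]})
        dip = most_probable_diplotype([("R", "R"), ("R", "R")], hft)
        assert dip.posterior == pytest.approx(1.0)
        assert dip.hap1 == dip.hap2 == ("R", "R")

    def test_tie_broken_lexicographically_at_half(self):
        from strlink.haplotype_em import HaplotypeFrequencyTable

        hft = HaplotypeFrequencyTable(
            loci=["L1", "L2"],
            freq={
                ("R", "R"): 0.25,
                ("R", "-1"): 0.25,
                ("-4", "R"): 0.25,
                ("-4", "-1"): 0.25,
            },
            loglik=0.0,
            n_iter=1,
            converged=True,
        )
        dip = most_probable_diplotype([("R", "-4"), ("R", "-1")], hft)
        assert dip.posterior == pytest.approx(0.5)
        assert (dip.hap1, dip.hap2) == (("-4", "-1"), ("R", "R"))

    def test_high_ld_pool_calls_match_truth(self):
        pool = build_default_pool("european_like")
        loci = ["STR6", "STR8", "rs12913832", "STR9", "STR10"]
        gt, truth = simulate_population(pool, 1000, seed=29)
        hft = em_haplotype_frequencies(gt, loci)
        idx = [pool.locus_index(l) for l in loci]
        hits = 0
        for i in range(gt.n_samples):
            genotype = [gt.calls[l][i] for l in loci]
            dip = most_probable_diplotype(genotype, hft)
            h1, h2 = truth.diplotypes[i]
            true_pair = tuple(
                sorted(
                    (
                        tuple(pool.haplotypes[h1][j] for j in idx),
                        tuple(pool.haplotypes[h2][j] for j in idx),
                    )
                )
            )
            if (dip.hap1, dip.hap2) == true_pair:
                hits += 1
        assert hits / gt.n_samples > 0.95
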