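"""The directional rank-based running Fisher statistic."""

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from sigscreen.core_io import Annotation, Bioset, BiosetEntry
from sigscreen.running_fisher import (
    RfParams,
    directional_pair_p,
    hypergeom_upper_tail,
    rank_target,
    running_fisher,
)
from sigscreen.synthetic import gene_universe, simulate_bioset, simulate_null_bioset


def bioset_from(entries, bioset_id="t"):
    return Bioset(bioset_id, tuple(BiosetEntry(g, fc) for g, fc in entries))


class TestHypergeomTail:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_upper_tail(0, 5, 5, 100) == 1.0

    def test_single_outcome_tail(self):
        # all 3 marked drawn in 3 draws from 10: 1 / C(10,3)
        assert hypergeom_upper_tail(3, 3, 3, 10) == pytest.approx(1 / 120, rel=1e-12)

    def test_two_of_two_in_three_draws(self):
        # C(2,2) * C(98,1) / C(100,3)
        expected = 98 / math.comb(100, 3)
        assert hypergeom_upper_tail(2, 2, 3, 100) == pytest.approx(expected, rel=1e-12)

    def test_bounds_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(4, 3, 3, 10)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 3, 11, 10)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pmf_summation_and_monotone_in_k(self, seed):
        rng = np.random.default_rng(seed)
        N = int(rng.integers(10, 500))
        K = int(rng.integers(1, N // 2 + 1))
        c = int(rng.integers(1, N // 2 + 1))
        previous = 1.0
        for k in range(0, min(K, c) + 1):
            ours = hypergeom_upper_tail(k, K, c, N)
            oracle = float(hypergeom.pmf(np.arange(k, min(K, c) + 1), N, K, c).sum())
            assert ours == pytest.approx(oracle, rel=1e-10, abs=1e-300)
            assert ours <= previous + 1e-15
            previous = ours


class TestRankTarget:
    def test_orders_by_abs_fc_descending(self):
        bs = bioset_from([("a", 3.0), ("b", -5.0), ("c", 2.0)])
        assert rank_target(bs) == [("b", -1), ("a", 1), ("c", 1)]

    def test_tie_broken_by_gene_id(self):
        bs = bioset_from([("gB", 2.0), ("gA", -2.0)])
        assert [g for g, _ in rank_target(bs)] == ["gA", "gB"]

    def test_singleton(self):
        bs = bioset_from([("only", 1.5)])
        assert rank_target(bs) == [("only", 1)]


def brute_force_min_tail(query, ranked, target_sign, N):
    """Independent oracle: evaluate the tail at every rank cutoff."""
    sub = [g for g, s in ranked if s == target_sign]
    K = len(query)
    best = 1.0
    for c in range(1, len(sub) + 1):
        k = sum(1 for g in sub[:c] if g in query)
        best = min(best, hypergeom_upper_tail(k, K, c, N))
    return best


class TestDirectionalScan:
    def test_zero_overlap(self):
        ranked = [("x", 1), ("y", 1)]
        assert directional_pair_p({"q"}, ranked, 1, RfParams(100)) == (1.0, 0)

    def test_scan_cutoffs_and_bonferroni_factor(self):
        # query genes at ranks 1 and 3 of a 3-gene sign-matched target:
        # scan cutoffs {1, 3}, Bonferroni factor 2
        ranked = [("g1", 1), ("x", 1), ("g2", 1)]
        params = RfParams(100)
        p, k = directional_pair_p({"g1", "g2"}, ranked, 1, params)
        t1 = hypergeom_upper_tail(1, 2, 1, 100)
        t3 = hypergeom_upper_tail(2, 2, 3, 100)
        assert p == pytest.approx(min(1.0, 2 * min(t1, t3)))
        assert k == 2

    @pytest.mark.parametrize("seed", range(20))
    def test_overlap_position_scan_equals_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n_target = int(rng.integers(5, 60))
        genes = [f"g{i}" for i in range(200)]
        ranked = [(g, 1) for g in rng.choice(genes, n_target, replace=False)]
        query = set(rng.choice(genes, int(rng.integers(1, 30)), replace=False))
        params = RfParams(200)
        p, _ = directional_pair_p(query, ranked, 1, params)
        oracle = brute_force_min_tail(query, ranked, 1, 200)
        sub = [g for g, s in ranked if s == 1]
        positions = [i + 1 for i, g in enumerate(sub) if g in query]
        if not positions:
            assert p == 1.0
        else:
            m = len(set(positions) | {len(sub)})
            assert p == pytest.approx(min(1.0, m * oracle), rel=1e-12)

    def test_query_filling_top_ranks_is_extreme(self):
        genes = [f"q{i}" for i in range(20)]
        ranked = [(g, 1) for g in genes] + [(f"x{i}", 1) for i in range(30)]
        p, k = directional_pair_p(set(genes), ranked, 1, RfParams(23238))
        assert p < 1e-4 and k == 20


class TestRunningFisher:
    def test_self_comparison_is_extreme_positive(self, nrf2, rf20k):
        entries = {}
        for e in nrf2.entries:
            entries.setdefault(e.gene_id, e.avg_fold_change)
        bs = bioset_from(sorted(entries.items()), "self")
        res = running_fisher(nrf2, bs, rf20k)
        assert res.direction == 1
        assert res.p_value <= 1e-10
        assert res.signed_score == pytest.approx(-math.log10(res.p_value))

    def test_no_shared_genes(self, nrf2, rf20k):
        bs = bioset_from([("zzz1", 2.0), ("zzz2", -1.5)])
        res = running_fisher(nrf2, bs, rf20k)
        assert (res.direction, res.p_value, res.signed_score) == (0, 1.0, 0.0)
        assert res.overlap_concordant == res.overlap_discordant == 0

    @pytest.mark.parametrize("seed", range(5))
    def test_global_target_sign_flip_negates_direction(self, nrf2, rf20k, universe20k, seed):
        bs = simulate_bioset(nrf2, 0.5, 300, universe20k, seed=seed)
        flipped = Bioset(
            "flip", tuple(BiosetEntry(e.gene_id, -e.fold_change) for e in bs.entries)
        )
        a = running_fisher(nrf2, bs, rf20k)
        b = running_fisher(nrf2, flipped, rf20k)
        assert b.direction == -a.direction
        assert b.p_value == a.p_value
        assert b.signed_score == -a.signed_score

    def test_query_sign_flip_is_antisymmetric(self, nrf2, rf20k, universe20k):
        bs = simulate_bioset(nrf2, 0.6, 300, universe20k, seed=3)
        a = running_fisher(nrf2, bs, rf20k)
        b = running_fisher(nrf2.flipped(), bs, rf20k)
        assert b.direction == -a.direction
        assert b.p_value == a.p_value

    def test_invariant_under_permuting_genes_below_last_overlap(self, nrf2, rf20k, universe20k):
        bs = simulate_bioset(nrf2, 0.5, 200, universe20k, seed=9)
        # swap fold-changes of the two weakest non-biomarker entries
        order = sorted(bs.entries, key=lambda e: abs(e.fold_change))
        tail = [e for e in order if e.gene_id not in nrf2.genes][:2]
        swapped = {tail[0].gene_id: tail[1].fold_change, tail[1].gene_id: tail[0].fold_change}
        bs2 = Bioset(
            "perm",
            tuple(
                BiosetEntry(e.gene_id, swapped.get(e.gene_id, e.fold_change))
                for e in bs.entries
            ),
        )
        assert running_fisher(nrf2, bs2, rf20k).p_value == pytest.approx(
            running_fisher(nrf2, bs, rf20k).p_value
        )

    def test_null_bioset_rarely_significant(self, nrf2, rf20k, universe20k):
        hits = 0
        for seed in range(200):
            bs = simulate_null_bioset(universe20k, 300, seed=seed)
            res = running_fisher(nrf2, bs, rf20k)
            hits += res.p_value <= 1e-2
        assert hits <= 8  # conservative at alpha = 1e-2 (2x safety factor)

    def test_platform_restriction_reduces_query(self, nrf2, universe20k):
        bs = simulate_bioset(nrf2, 0.5, 300, universe20k, seed=4)
        platform = frozenset(universe20k[:10000]) | nrf2.genes
        res = running_fisher(nrf2, bs, RfParams(20000, platform_genes=platform))
        assert res.direction == 1
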