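"""Determinism and statistical structure of the synthetic generators."""

import numpy as np
import pytest

from sigscreen.coupling import regress_signed_scores
from sigscreen.running_fisher import RfParams, running_fisher
from sigscreen.synthetic import (
    SimulationConfig,
    gene_universe,
    make_biomarker,
    simulate_bioset,
    simulate_compendium,
    simulate_gene_annotation,
    simulate_genotype_experiment,
    simulate_null_bioset,
    simulate_peaks,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            {"noise_sd": 0.0},
            {"concordance": 1.2},
            {"latent_correlation": -1.5},
            {"n_per_group": 1},
        ],
    )
    def test_out_of_bounds_rejected(self, kw):
        with pytest.raises(ValueError):
            SimulationConfig(**kw)


class TestGenotypeExperiment:
    def test_fixed_seed_is_bit_identical(self):
        cfg = SimulationConfig(seed=5, n_genes=200)
        m1 = simulate_genotype_experiment(cfg, [("g00010", 1)])
        m2 = simulate_genotype_experiment(cfg, [("g00010", 1)])
        assert np.array_equal(np.asarray(m1.values), np.asarray(m2.values))

    def test_four_groups_with_replicates(self):
        cfg = SimulationConfig(seed=0, n_genes=100, n_per_group=3)
        m = simulate_genotype_experiment(cfg, [])
        assert sorted(set(m.groups.values())) == ["KO-ctl", "KO-trt", "WT-ctl", "WT-trt"]
        assert len(m.sample_ids) == 12

    def test_shift_applied_only_in_treated_wild_type(self):
        cfg = SimulationConfig(seed=1, n_genes=100, responder_effect=4.0, noise_sd=0.05)
        m = simulate_genotype_experiment(cfg, [("g00001", 1)])
        v = np.log2(np.asarray(m.values))[0]
        cols = {g: m.group_columns(g) for g in ("WT-ctl", "WT-trt", "KO-ctl", "KO-trt")}
        assert v[cols["WT-trt"]].mean() - v[cols["WT-ctl"]].mean() == pytest.approx(4.0, abs=0.5)
        assert abs(v[cols["KO-trt"]].mean() - v[cols["KO-ctl"]].mean()) < 0.5

    def test_unknown_responder_rejected(self):
        with pytest.raises(ValueError, match="not in the simulated universe"):
            simulate_genotype_experiment(SimulationConfig(n_genes=10), [("nope", 1)])


class TestSimulateBioset:
    def test_full_concordance_is_extreme_positive(self, nrf2, universe20k, rf20k):
        bs = simulate_bioset(nrf2, 1.0, 500, universe20k, seed=0)
        res = running_fisher(nrf2, bs, rf20k)
        assert res.direction == 1 and res.p_value <= 1e-10

    def test_zero_concordance_excludes_biomarker(self, nrf2, universe20k, rf20k):
        bs = simulate_bioset(nrf2, 0.0, 300, universe20k, seed=1)
        assert not set(bs.gene_signs) & nrf2.genes
        res = running_fisher(nrf2, bs, rf20k)
        assert (res.direction, res.p_value) == (0, 1.0)
        assert res.overlap_concordant == res.overlap_discordant == 0

    def test_flipped_biomarker_gives_mirror_direction(self, nrf2, universe20k, rf20k):
        mirror = simulate_bioset(nrf2.flipped(), 0.8, 300, universe20k, seed=2)
        res = running_fisher(nrf2, mirror, rf20k)
        assert res.direction == -1 and res.p_value <= 1e-10
        # same draw, same |FC| layout: only the biomarker-gene signs differ
        straight = simulate_bioset(nrf2, 0.8, 300, universe20k, seed=2)
        assert {g: abs(f) for g, f in straight.gene_fold_changes.items()} == pytest.approx(
            {g: abs(f) for g, f in mirror.gene_fold_changes.items()}
        )

    def test_concordant_genes_land_in_top_quartile(self, nrf2, universe20k):
        bs = simulate_bioset(nrf2, 1.0, 400, universe20k, seed=3)
        ranked = sorted(bs.entries, key=lambda e: -abs(e.fold_change))
        top = {e.gene_id for e in ranked[:100]}
        assert nrf2.genes <= top

    def test_determinism_and_validation(self, nrf2, universe20k):
        a = simulate_bioset(nrf2, 0.5, 200, universe20k, seed=9)
        b = simulate_bioset(nrf2, 0.5, 200, universe20k, seed=9)
        assert a == b
        with pytest.raises(ValueError, match="concordance"):
            simulate_bioset(nrf2, 1.1, 200, universe20k, seed=0)


class TestNullBioset:
    def test_uniform_sampling_and_determinism(self, universe20k):
        a = simulate_null_bioset(universe20k, 300, seed=4)
        assert a == simulate_null_bioset(universe20k, 300, seed=4)
        assert len(a) == 300

    def test_oversized_request_rejected(self):
        with pytest.raises(ValueError):
            simulate_null_bioset(["a", "b"], 3, seed=0)


class TestCompendium:
    def test_disjointness_enforced(self):
        bm = make_biomarker("A", 5, 5, seed=0)
        with pytest.raises(ValueError, match="disjoint"):
            simulate_compendium(SimulationConfig(), bm, bm, 10)

    def test_returns_truth_latents(self):
        bm_a = make_biomarker("A", 10, 5, seed=1)
        bm_b = make_biomarker("B", 8, 6, seed=2)
        cfg = SimulationConfig(seed=0, n_genes=3000, latent_correlation=0.5)
        triples = simulate_compendium(cfg, bm_a, bm_b, 5, n_entries=150)
        assert len(triples) == 5
        la = [t[1] for t in triples]
        assert len(set(la)) == 5

    def test_single_bioset_regression_refused_downstream(self):
        bm_a = make_biomarker("A", 10, 5, seed=1)
        bm_b = make_biomarker("B", 8, 6, seed=2)
        cfg = SimulationConfig(seed=0, n_genes=2000)
        [(bs, la, lb)] = simulate_compendium(cfg, bm_a, bm_b, 1, n_entries=100)
        with pytest.raises(ValueError, match="at least 3"):
            regress_signed_scores([la], [lb])

    def test_correlated_latents_couple_signed_scores(self):
        bm_a = make_biomarker("A", 20, 10, seed=1)
        bm_b = make_biomarker("B", 15, 10, seed=2)
        cfg = SimulationConfig(seed=7, n_genes=5000, latent_correlation=0.9)
        triples = simulate_compendium(cfg, bm_a, bm_b, 100, n_entries=250)
        params = RfParams(universe_size=5000)
        xs = [running_fisher(bm_a, bs, params).signed_score for bs, _, _ in triples]
        ys = [running_fisher(bm_b, bs, params).signed_score for bs, _, _ in triples]
        r = regress_signed_scores(xs, ys)
        assert r.f_p_value < 0.01 and r.slope > 0

    def test_uncorrelated_latents_give_flat_regression(self):
        bm_a = make_biomarker("A", 20, 10, seed=1)
        bm_b = make_biomarker("B", 15, 10, seed=2)
        r2s = []
        for seed in range(10):
            cfg = SimulationConfig(seed=seed, n_genes=5000, latent_correlation=0.0)
            triples = simulate_compendium(cfg, bm_a, bm_b, 40, n_entries=200)
            params = RfParams(universe_size=5000)
            xs = [running_fisher(bm_a, bs, params).signed_score for bs, _, _ in triples]
            ys = [running_fisher(bm_b, bs, params).signed_score for bs, _, _ in triples]
            r2s.append(regress_signed_scores(xs, ys).r_squared)
        assert np.mean(r2s) < 0.1


class TestPeaks:
    def test_frac_bounds_and_determinism(self):
        ann = simulate_gene_annotation(30)
        targets = [g.gene_id for g in ann.genes[:10]]
        with pytest.raises(ValueError, match="frac_near"):
            simulate_peaks(ann, targets, 1.5, seed=0)
        a = simulate_peaks(ann, targets, 0.5, seed=3)
        assert a == simulate_peaks(ann, targets, 0.5, seed=3)

    def test_one_peak_per_target(self):
        ann = simulate_gene_annotation(30)
        targets = [g.gene_id for g in ann.genes[:10]]
        assert len(simulate_peaks(ann, targets, 0.3, seed=1)) == 10

    def test_unknown_target_rejected(self):
        ann = simulate_gene_annotation(10)
        with pytest.raises(ValueError, match="not in annotation"):
            simulate_peaks(ann, ["nope"], 0.5, seed=0)


def test_gene_universe_contains_requested_genes():
    u = gene_universe(100, include=["Nqo1", "Gclc"])
    assert len(u) == 100 and "Nqo1" in u and u == sorted(u)
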