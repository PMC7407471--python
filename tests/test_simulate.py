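"""Polysomic population simulator: segregation, linkage, reads, phenotypes."""

import numpy as np
import pytest
from scipy import stats

from polyassoc.simulate import (
    SimConfig,
    gamete_dosage_distribution,
    genetic_effect,
    offspring_dosage_distribution,
    simulate_background_markers,
    simulate_dosages,
    simulate_linked_pair,
    simulate_phenotype,
    simulate_population,
    simulate_read_counts,
)


class TestSegregationDistributions:
    def test_simplex_gametes_are_half_half(self):
        assert np.allclose(gamete_dosage_distribution(6, 1), [0.5, 0.5, 0, 0])

    def test_triplex_gametes_1_9_9_1(self):
        assert np.allclose(gamete_dosage_distribution(6, 3), np.array([1, 9, 9, 1]) / 20)

    @pytest.mark.parametrize("ld,expect", [(0, [1, 0, 0, 0]), (6, [0, 0, 0, 1])])
    def test_fixed_parents_give_fixed_gametes(self, ld, expect):
        assert np.allclose(gamete_dosage_distribution(6, ld), expect)

    def test_odd_ploidy_rejected(self):
        with pytest.raises(ValueError):
            gamete_dosage_distribution(5, 1)

    def test_s1_simplex_offspring_1_2_1(self):
        d = offspring_dosage_distribution(6, 1)
        assert np.allclose(d[:3], [0.25, 0.5, 0.25])
        assert np.allclose(d[3:], 0)

    def test_s1_triplex_offspring_matches_brute_convolution(self):
        d = offspring_dosage_distribution(6, 3)
        g = np.array([1, 9, 9, 1]) / 20
        brute = np.zeros(7)
        for i, a in enumerate(g):
            for j, b in enumerate(g):
                brute[i + j] += a * b
        assert np.allclose(d, brute)
        assert d[0] == pytest.approx(1 / 400)
        assert d[3] == pytest.approx(164 / 400)

    def test_nulliplex_cross_is_degenerate(self):
        assert np.allclose(offspring_dosage_distribution(6, 0, 0), [1, 0, 0, 0, 0, 0, 0])


class TestLinkedPair:
    def test_complete_linkage_identity(self, rng):
        cfg = SimConfig(n_individuals=500, marker_type="DD", distance_cM=0.0)
        gene, marker, xov = simulate_linked_pair(cfg, rng)
        assert np.array_equal(gene, marker)
        assert (xov == 0).all()

    def test_marginals_match_offspring_distribution_under_recombination(self, rng):
        cfg = SimConfig(n_individuals=10_000, marker_type="DD", distance_cM=2.0)
        gene, marker, _ = simulate_linked_pair(cfg, rng)
        expected = offspring_dosage_distribution(6, 2)
        for vec in (gene, marker):
            obs = np.bincount(vec, minlength=7)
            keep = expected > 0
            chi = stats.chisquare(obs[keep], expected[keep] * vec.size)
            assert chi.pvalue > 0.001

    def test_large_distance_decouples_marker_and_gene(self, rng):
        cfg = SimConfig(n_individuals=5000, marker_type="SS", distance_cM=20.0)
        gene, marker, _ = simulate_linked_pair(cfg, rng)
        assert abs(np.corrcoef(gene, marker)[0, 1]) < 0.05

    def test_intermediate_distance_partially_correlated(self, rng):
        cfg = SimConfig(n_individuals=5000, marker_type="SS", distance_cM=1.0)
        gene, marker, _ = simulate_linked_pair(cfg, rng)
        r = np.corrcoef(gene, marker)[0, 1]
        assert 0.4 < r < 0.95

    def test_morgan_mode_is_near_complete_linkage_at_5cM(self, rng):
        cfg = SimConfig(n_individuals=5000, marker_type="SS", distance_cM=5.0,
                        crossover_mode="morgan")
        gene, marker, _ = simulate_linked_pair(cfg, rng)
        assert np.corrcoef(gene, marker)[0, 1] > 0.95

    def test_f1_population_runs_and_segregates(self, rng):
        cfg = SimConfig(population="F1", n_individuals=2000, marker_type="SS")
        gene, marker, _ = simulate_linked_pair(cfg, rng)
        obs = np.bincount(marker, minlength=7)
        chi = stats.chisquare(obs[:3], offspring_dosage_distribution(6, 1)[:3] * 2000)
        assert chi.pvalue > 0.001


class TestReadCounts:
    def test_homozygote_without_error_gives_all_reference(self, rng):
        cfg = SimConfig(depth=40, seq_error=0.0)
        dp, rd = simulate_read_counts(np.full(200, 6), cfg, rng)
        assert (dp == 40).all() and (rd == 40).all()

    def test_heterozygote_mean_half(self, rng):
        cfg = SimConfig(depth=40, seq_error=0.0, n_individuals=100_000)
        dp, rd = simulate_read_counts(np.full(100_000, 3), cfg, rng)
        assert np.mean(rd / dp) == pytest.approx(0.5, abs=0.003)

    def test_bias_half_shifts_mean_to_two_thirds(self, rng):
        cfg = SimConfig(depth=40, bias=0.5, seq_error=0.0)
        dp, rd = simulate_read_counts(np.full(100_000, 3), cfg, rng)
        assert np.mean(rd / dp) == pytest.approx(2 / 3, abs=0.003)

    def test_empirical_depth_mode_resamples_supplied_depths(self, rng):
        cfg = SimConfig(depth_empirical=(20, 37, 44))
        dp, _ = simulate_read_counts(np.full(500, 2), cfg, rng)
        assert set(np.unique(dp)) <= {20, 37, 44}


class TestGeneticEffects:
    @pytest.mark.parametrize(
        "d,model,expect",
        [
            (3, "Add", 0.5),
            (6, "Add", 1.0),
            (0, "SimDom", 0.0),
            (1, "SimDom", 1.0),
            (3, "SimDom", 1.0),
            (0, "DipAdd", 0.0),
            (5, "DipAdd", 0.5),
            (6, "DipAdd", 1.0),
        ],
    )
    def test_effect_models(self, d, model, expect):
        assert genetic_effect(d, model) == expect

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            genetic_effect(3, "Dominant")


class TestPhenotype:
    def test_high_pve_limit_approaches_genetic_values(self, rng):
        cfg = SimConfig(pve=0.999, n_individuals=200)
        d = simulate_dosages(cfg, rng)
        y, g, s2 = simulate_phenotype(d, cfg, rng)
        assert np.max(np.abs(y - g)) < 0.05

    def test_realized_variance_ratio_matches_pve(self, rng):
        cfg = SimConfig(pve=0.2, n_individuals=5000)
        d = simulate_dosages(cfg, rng)
        y, g, s2 = simulate_phenotype(d, cfg, rng)
        assert np.var(g) / np.var(y) == pytest.approx(0.2, abs=0.02)

    def test_noise_variance_algebra(self, rng):
        # sigma2 = Var(g) (1-PVE)/PVE; at PVE = 0.2 that is 4 Var(g)
        cfg = SimConfig(pve=0.2, n_individuals=400)
        d = simulate_dosages(cfg, rng)
        _, g, s2 = simulate_phenotype(d, cfg, rng)
        assert s2 == pytest.approx(4 * np.var(g), rel=1e-12)

    def test_constant_genetic_values_rejected(self, rng):
        cfg = SimConfig(pve=0.2)
        with pytest.raises(ValueError, match="PVE undefined"):
            simulate_phenotype(np.full(100, 3), cfg, rng)

    def test_binary_trait_values_and_signal(self, rng):
        cfg = SimConfig(pve=0.3, trait_type="binary", n_individuals=4000)
        d = simulate_dosages(cfg, rng)
        y, g, s2 = simulate_phenotype(d, cfg, rng)
        assert set(np.unique(y)) <= {0.0, 1.0}
        assert np.isnan(s2)
        assert y[g > 0.1].mean() > y[g <= 0.1].mean() + 0.1


class TestBackgroundMarkers:
    def test_reproducible_and_mixture_frequencies(self):
        cfg = SimConfig(n_individuals=100, n_background_markers=300, seed=8)
        a = simulate_background_markers(cfg, np.random.default_rng(8))
        b = simulate_background_markers(cfg, np.random.default_rng(8))
        assert all(np.array_equal(x.RD, y.RD) for x, y in zip(a, b))
        freqs = np.array([sum(m.marker_type == t for m in a) for t in ("SS", "DD", "TT")]) / 300
        expect = np.array([0.6, 0.3, 0.1])
        assert np.all(np.abs(freqs - expect) < 3 * np.sqrt(expect * (1 - expect) / 300))

    def test_segregating_types_pass_mgf_filter(self):
        from polyassoc.dosage import filter_mgf
        from polyassoc.experiments import _one_hot_matrix

        cfg = SimConfig(n_individuals=100, n_background_markers=100, seed=21)
        markers = simulate_background_markers(cfg, np.random.default_rng(21))
        mats = [_one_hot_matrix(m.dosages, 6) for m in markers]
        assert len(filter_mgf(mats)) == len(mats)


class TestEndToEnd:
    def test_high_depth_simplex_calls_recover_truth(self, rng):
        from polyassoc.dosage import call_dosage
        from polyassoc.experiments import estimate_focal_matrix

        cfg = SimConfig(n_individuals=1000, depth=100)
        d = simulate_dosages(cfg, rng)
        dp, rd = simulate_read_counts(d, cfg, rng)
        M = estimate_focal_matrix(dp, rd, "SS", "naive", cfg)
        assert np.mean(call_dosage(M) == d) >= 0.95

    def test_population_draw_reproducible(self):
        cfg = SimConfig(n_individuals=50, seed=33, distance_cM=1.0)
        a = simulate_population(cfg)
        b = simulate_population(cfg)
        assert np.array_equal(a.RD, b.RD)
        assert np.allclose(a.phenotype, b.phenotype)
        assert np.array_equal(a.crossovers, b.crossovers)
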