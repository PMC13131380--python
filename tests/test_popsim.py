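"""Simulator behaviour: drift, selection response, bookkeeping, files."""

import numpy as np
import pytest
from scipy import stats

from ipsim import io as ipio
from ipsim.genome import GenomeMap
from ipsim.popsim import (HaplotypePool, SimConfig, TraitModel, assign_qtl_effects,
                          expand_and_found, simulate_historical, simulate_population,
                          simulate_selection)

from conftest import small_sim_config

ONE_LOCUS = GenomeMap([50.0], [np.array([25.0])], [np.array([False])],
                      mutation_rate=0.0)


class TestHistorical:
    def test_allele_frequency_preserved_in_expectation(self):
        """Random union of two opposite homozygotes over many seeds keeps
        the frequency near 0.5 (binomial sampling oracle)."""
        cfg = SimConfig(historical_schedule=((2, 2, 1),), mutation_rate=0.0)
        init = np.array([[0], [0], [1], [1]], dtype=np.uint8)
        freqs = []
        for seed in range(1000):
            pool = simulate_historical(cfg, np.random.default_rng(seed),
                                       genome=ONE_LOCUS, initial_haplotypes=init)
            freqs.append(pool.allele_freqs[0])
        assert 0.45 < np.mean(freqs) < 0.55

    def test_fixed_loci_stay_fixed_without_mutation(self):
        g = GenomeMap([50.0], [np.array([10.0, 40.0])],
                      [np.array([False, False])], mutation_rate=0.0)
        cfg = SimConfig(historical_schedule=((10, 10, 5),), mutation_rate=0.0)
        init = np.ones((20, 2), dtype=np.uint8)
        pool = simulate_historical(cfg, np.random.default_rng(0), genome=g,
                                   initial_haplotypes=init)
        assert np.all(pool.haplotypes == 1)

    def test_heterozygosity_decays_like_wright_fisher(self):
        """Mean heterozygosity after t generations ≈ H0 (1 - 1/2N)^t."""
        N, t, n_loci = 30, 60, 400
        g = GenomeMap([100.0], [np.linspace(1, 99, n_loci)],
                      [np.zeros(n_loci, bool)], mutation_rate=0.0)
        cfg = SimConfig(historical_schedule=((N, N, t),), mutation_rate=0.0,
                        founder_freq=0.5)
        hets = []
        for seed in range(6):
            pool = simulate_historical(cfg, np.random.default_rng(seed), genome=g)
            p = pool.allele_freqs
            hets.append(np.mean(2 * p * (1 - p)))
            seg = np.mean((p > 0) & (p < 1))
            assert 0 < seg < 1
        expected = 0.5 * (1 - 1 / (2 * N)) ** t
        se = np.std(hets, ddof=1) / np.sqrt(len(hets))
        assert abs(np.mean(hets) - expected) < 3 * se

    def test_degenerate_schedule_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            simulate_historical(SimConfig(historical_schedule=((0, 5, 3),)),
                                np.random.default_rng(0), genome=ONE_LOCUS)

    def test_panel_selection_returns_configured_counts(self):
        cfg = small_sim_config()
        pool = simulate_historical(cfg, np.random.default_rng(3))
        assert pool.genome.n_snps == cfg.n_snps
        assert pool.genome.n_qtl == cfg.n_qtl
        maf = np.minimum(pool.allele_freqs, 1 - pool.allele_freqs)
        assert (maf > 0).all()  # no fixed locus makes it onto the panel


class TestExpandAndFound:
    def _pool(self, n=40, n_loci=60, seed=0):
        rng = np.random.default_rng(seed)
        g = GenomeMap.random(n_loci - 6, 6, rng, n_chromosomes=3, total_cM=300)
        haps = rng.integers(0, 2, size=(2 * n, n_loci)).astype(np.uint8)
        return g, HaplotypePool(genome=g, haplotypes=haps)

    def test_founder_counts(self):
        g, pool = self._pool()
        cfg = small_sim_config(n_sires=5, n_dams=100, expansion_generations=6)
        pop = expand_and_found(cfg, pool, TraitModel(), np.random.default_rng(1))
        assert pop.n_animals == 105
        assert (pop.generation == 0).all()
        assert (pop.sex[:5] == 0).all() and (pop.sex[5:] == 1).all()
        assert (pop.sire == 0).all() and (pop.dam == 0).all()

    def test_same_seed_reproduces_founders(self):
        g, pool = self._pool()
        cfg = small_sim_config(n_sires=4, n_dams=20)
        a = expand_and_found(cfg, pool, TraitModel(), np.random.default_rng(5))
        b = expand_and_found(cfg, pool, TraitModel(), np.random.default_rng(5))
        assert np.array_equal(a.haplotypes, b.haplotypes)
        np.testing.assert_allclose(a.tbv, b.tbv)

    def test_pool_too_small_rejected(self):
        g, pool = self._pool(n=3)
        cfg = small_sim_config(n_sires=500, n_dams=5000, expansion_generations=0)
        with pytest.raises(ValueError, match="too small"):
            expand_and_found(cfg, pool, TraitModel(), np.random.default_rng(0))


class TestQtlEffects:
    def test_single_qtl_closed_form(self):
        """Va = 2p(1-p)a² → |a| = sqrt(0.20 / 0.5) at p = 0.5."""
        trait = TraitModel(h2=0.25, rpg_fraction=0.05)
        codes = np.array([[0], [1], [1], [2]])  # p = 0.5, HWE proportions
        out = assign_qtl_effects(trait, codes, np.random.default_rng(0))
        assert abs(out.qtl_effects[0]) == pytest.approx(np.sqrt(0.20 / 0.5), rel=1e-12)

    def test_zero_target_variance_gives_zero_effects(self):
        trait = TraitModel(h2=0.25, rpg_fraction=0.25)  # fully polygenic
        codes = np.random.default_rng(0).integers(0, 3, size=(10, 2))
        out = assign_qtl_effects(trait, codes, np.random.default_rng(0))
        np.testing.assert_allclose(out.qtl_effects, 0.0, atol=1e-6)

    def test_scaled_effects_hit_target_variance_exactly(self):
        rng = np.random.default_rng(5)
        codes = rng.integers(0, 3, size=(80, 30))
        out = assign_qtl_effects(TraitModel(), codes, rng)
        assert np.var(codes @ out.qtl_effects) == pytest.approx(0.20, rel=1e-10)

    def test_rescaling_is_idempotent(self):
        rng = np.random.default_rng(2)
        codes = rng.integers(0, 3, size=(50, 30))
        once = assign_qtl_effects(TraitModel(), codes, rng)
        twice = assign_qtl_effects(once, codes, rng)
        np.testing.assert_allclose(once.qtl_effects, twice.qtl_effects, atol=1e-13)

    def test_monomorphic_qtl_zeroed_and_all_monomorphic_rejected(self):
        rng = np.random.default_rng(3)
        codes = np.column_stack([np.zeros(6), rng.integers(0, 3, size=6),
                                 np.full(6, 2)])
        out = assign_qtl_effects(TraitModel(), codes, rng)
        assert out.qtl_effects[0] == 0.0 and out.qtl_effects[2] == 0.0
        with pytest.raises(ValueError, match="monomorphic"):
            assign_qtl_effects(TraitModel(),
                               np.column_stack([np.zeros(4), np.full(4, 2)]), rng)


class TestSelection:
    def test_selection_response_is_monotone(self, small_population):
        """Directional selection: cohort mean TBV rises over generations."""
        cfg, pop = small_population
        gens = np.arange(1, cfg.n_generations + 1)
        means = [pop.tbv[pop.generation == g].mean() for g in gens]
        rho = stats.spearmanr(gens, means).statistic
        assert rho > 0.9
        assert means[-1] > means[0]

    def test_no_turnover_keeps_breeding_set(self):
        cfg = small_sim_config(sire_replacement=0.0, dam_replacement=0.0,
                               growth_rate=0.0, max_dams=None, n_generations=3,
                               selection_on="phenotype")
        pop = simulate_population(cfg, TraitModel(), seed=11)
        first = pop.breeding_log[0]
        for entry in pop.breeding_log[1:]:
            assert set(entry["sires"]) == set(first["sires"])
            assert set(entry["dams"]) == set(first["dams"])

    def test_cohort_sizes_follow_growth_arithmetic(self, small_population):
        cfg, pop = small_population
        planned = cfg.cohort_sizes()
        for g, size in zip(range(1, cfg.n_generations + 1), planned):
            assert (pop.generation == g).sum() == size

    def test_genotype_is_sum_of_gametes(self, small_population):
        _, pop = small_population
        ids = pop.id[:: max(1, pop.n_animals // 50)]
        rows = ids - 1
        expected = pop.haplotypes[2 * rows] + pop.haplotypes[2 * rows + 1]
        np.testing.assert_array_equal(pop.genotypes(ids), expected)

    def test_parents_precede_offspring_and_sexes_consistent(self, small_population):
        _, pop = small_population
        has_sire = pop.sire > 0
        assert np.all(pop.sire[has_sire] < pop.id[has_sire])
        assert np.all(pop.sex[pop.sire[has_sire] - 1] == 0)
        has_dam = pop.dam > 0
        assert np.all(pop.sex[pop.dam[has_dam] - 1] == 1)

    def test_drift_without_selection_has_zero_trend(self):
        """Random (zero-intensity) selection: no systematic TBV change."""
        cfg = small_sim_config(selection_on="random", mutation_rate=0.0,
                               n_generations=4, n_snps=150, n_qtl=30,
                               pool_multiplier=8.0)
        slopes = []
        for seed in range(20):
            pop = simulate_population(cfg, TraitModel(), seed=seed)
            gens = np.arange(0, cfg.n_generations + 1)
            means = [pop.tbv[pop.generation == g].mean() for g in gens]
            slopes.append(np.polyfit(gens, means, 1)[0])
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert abs(np.mean(slopes)) < 3 * se

    def test_insufficient_candidates_rejected(self):
        cfg = small_sim_config(litter_size=1, sire_replacement=1.0,
                               n_generations=2, selection_on="phenotype")
        with pytest.raises(ValueError, match="insufficient candidates"):
            simulate_population(cfg, TraitModel(), seed=0)

    def test_founder_tbv_variance_near_additive_variance(self):
        cfg = small_sim_config(n_sires=30, n_dams=170, n_generations=0,
                               selection_on="phenotype")
        trait = TraitModel(h2=0.25, rpg_fraction=0.05, sigma2_p=1.0)
        pop = simulate_population(cfg, trait, seed=5)
        v = pop.tbv.var(ddof=1)
        assert 0.5 * 0.25 < v < 2.0 * 0.25


class TestScaledConfig:
    def test_scale_factor_shrinks_counts_proportionally(self):
        full = SimConfig()
        small = full.scaled(0.1)
        assert small.n_dams == 250 and small.n_sires == 2
        assert small.n_snps == 7000 and small.n_qtl == 100
        assert small.historical_schedule[0][2] == 102

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            SimConfig().scaled(0.0)


class TestExport:
    def test_roundtrip_and_formats(self, small_population, tmp_path):
        cfg, pop = small_population
        train = pop.ids_of_generation(list(cfg.training_generations))
        val = pop.ids_of_generation(cfg.validation_generation)
        paths = ipio.export_population(pop, tmp_path, training_ids=train,
                                       validation_ids=val)
        ids, codes = ipio.read_snp_file(paths["geno_train"])
        np.testing.assert_array_equal(ids, train)
        np.testing.assert_array_equal(
            codes, pop.genotypes(train)[:, pop.genome.snp_mask])
        ped = ipio.read_pedigree(paths["pedigree"])
        assert (ped.loc[ped.generation == 0, ["sire", "dam"]] == 0).all().all()
        # BLUPF90 dialect: id, single space run, unbroken 0/1/2 string
        line = open(paths["geno_val"]).readline().rstrip("\n")
        animal, geno = line.split(" ", 1)
        assert animal == str(val[0])
        assert set(geno) <= {"0", "1", "2"} and len(geno) == pop.genome.n_snps
        phen = ipio.read_phenotypes(paths["phenotypes"])
        np.testing.assert_allclose(phen.to_numpy(), pop.phenotype)
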