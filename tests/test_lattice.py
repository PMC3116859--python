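"""Lattice engine: metabolism, lottery, placement, death, diffusion and
whole-generation dynamics."""

import numpy as np
import pytest
from scipy import stats

from metarep import (
    Conformation,
    Lattice,
    Params,
    Phenotype,
    death_update,
    diffusion_step,
    fitness,
    initialize,
    is_feasible,
    local_metabolism,
    place_offspring,
    replication_lottery,
    run_generation,
    sample_mutant,
)
from metarep.core import sample_mutants
from metarep.lattice import claim_weights


def spec_e1(e1, k=2.0):
    return Phenotype(e1, 0.0, k, Conformation.EXPRESS_E1)


def spec_e2(e2, k=2.0):
    return Phenotype(0.0, e2, k, Conformation.EXPRESS_E2)


class TestLocalMetabolism:
    def test_empty_neighbourhood(self, params):
        lat = Lattice.empty(9)
        assert local_metabolism((4, 4), lat, params) == 0.0

    def test_single_activity_starves(self, params):
        # assumption (v): a missing activity shuts local metabolism down
        lat = Lattice.empty(9)
        for j in range(9):
            lat.set((4, j), spec_e1(5.0))
        assert local_metabolism((4, 4), lat, params) == 0.0

    def test_geometric_mean_of_summed_activities(self, params):
        # one neighbour expresses e1 = 9, another e2 = 4: M = sqrt(9*4) = 6
        lat = Lattice.empty(9)
        lat.set((4, 3), spec_e1(9.0))
        lat.set((4, 5), spec_e2(4.0))
        assert local_metabolism((4, 4), lat, params) == pytest.approx(6.0)

    def test_focal_site_belongs_to_its_own_neighbourhood(self, params):
        lat = Lattice.empty(9)
        lat.set((4, 4), spec_e1(9.0))
        lat.set((4, 5), spec_e2(4.0))
        assert local_metabolism((4, 4), lat, params) == pytest.approx(6.0)

    def test_unexpressed_activity_does_not_count(self, params):
        # a generalist expressing e1 contributes nothing to the e2 pool
        lat = Lattice.empty(9)
        lat.set((4, 3), Phenotype(4.0, 4.0, 2.0, Conformation.EXPRESS_E1))
        lat.set((4, 5), spec_e1(9.0))
        assert local_metabolism((4, 4), lat, params) == 0.0

    def test_torus_wraparound(self, params):
        lat = Lattice.empty(5)
        lat.set((0, 0), spec_e1(9.0))
        lat.set((4, 4), spec_e2(4.0))  # diagonal neighbour across the seam
        assert local_metabolism((0, 0), lat, params) == pytest.approx(6.0)


class TestFitness:
    def test_starvation_and_product(self):
        p = Phenotype(0.0, 0.0, 2.0)
        assert fitness(p, 0.0) == 0.0
        assert fitness(p, 3.0) == pytest.approx(6.0)
        assert fitness(Phenotype(0.0, 0.0, 2.5), 6.0) == pytest.approx(15.0)

    def test_negative_supply_rejected(self):
        with pytest.raises(ValueError):
            fitness(Phenotype(0.0, 0.0, 2.0), -1.0)


class TestReplicationLottery:
    def test_occupied_site_is_a_scheduler_bug(self, params, rng):
        lat = Lattice.empty(9)
        lat.set((4, 4), spec_e1(5.0))
        with pytest.raises(RuntimeError, match="scheduler bug"):
            replication_lottery((4, 4), lat, params, rng)

    def test_no_claimants_stays_empty(self, params, rng):
        lat = Lattice.empty(9)
        for _ in range(300):
            assert replication_lottery((4, 4), lat, params, rng) is None

    def test_zero_fitness_claimants_never_win(self, params, rng):
        # neighbours present but starved (one activity missing locally)
        lat = Lattice.empty(9)
        lat.set((4, 3), spec_e1(5.0))
        lat.set((4, 5), spec_e1(7.0))
        for _ in range(300):
            assert replication_lottery((4, 4), lat, params, rng) is None

    @staticmethod
    def _single_claimant_w20(params):
        # claimant at (4,5): k = 2.5, expressing e1 = 7.5; helper at (4,6)
        # expresses e2 = 64/7.5, so M = sqrt(7.5 * 64/7.5) = 8, W = 20
        lat = Lattice.empty(9)
        p = params.replace(k_max=4.0)
        lat.set((4, 5), Phenotype(7.5, 0.0, 2.5, Conformation.EXPRESS_E1))
        lat.set((4, 6), spec_e2(64.0 / 7.5))
        return lat, p

    def test_single_claimant_weights(self, params):
        lat, p = self._single_claimant_w20(params)
        coords, w = claim_weights((4, 4), lat, p)
        assert coords == [(4, 5)]
        assert w[0] == pytest.approx(20.0)

    def test_even_odds_against_the_empty_state(self, params, rng):
        # W = W_e = 20: the claimant wins the site half of the time
        lat, p = self._single_claimant_w20(params)
        n = 50_000
        wins = sum(
            replication_lottery((4, 4), lat, p, rng) is not None for _ in range(n)
        )
        assert wins / n == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))

    def test_win_frequencies_match_lottery_probabilities(self, params, rng):
        # two unequal claimants: empirical win rates vs W_i/(W_e + sum W)
        lat = Lattice.empty(9)
        lat.set((4, 3), Phenotype(6.0, 0.0, 2.2, Conformation.EXPRESS_E1))
        lat.set((3, 4), Phenotype(0.0, 3.0, 2.8, Conformation.EXPRESS_E2))
        p = params.replace(k_max=4.0)
        coords, w = claim_weights((4, 4), lat, p)
        probs = np.append(w, p.W_e) / (w.sum() + p.W_e)
        n = 30_000
        counts = {c: 0 for c in coords}
        empties = 0
        for _ in range(n):
            winner = replication_lottery((4, 4), lat, p, rng)
            if winner is None:
                empties += 1
            else:
                counts[winner] += 1
        freqs = np.array([counts[c] for c in coords] + [empties]) / n
        assert np.allclose(freqs, probs, atol=3 * np.sqrt(0.25 / n))
        assert probs.sum() == pytest.approx(1.0)


class TestPlaceOffspring:
    def test_faithful_copy(self, params, rng):
        lat = Lattice.empty(9)
        parent = Phenotype(4.0, 4.0, 2.1, Conformation.EXPRESS_E2)
        lat.set((4, 5), parent)
        place_offspring((4, 5), (4, 4), lat, params.replace(p_m=0.0), rng)
        child = lat.get((4, 4))
        assert child == parent  # traits and conformation inherited

    def test_both_sites_occupied_and_feasible_after(self, params, rng):
        lat = Lattice.empty(9)
        lat.set((4, 5), spec_e1(5.0))
        place_offspring((4, 5), (4, 4), lat, params.replace(p_m=1.0), rng)
        assert lat.get((4, 4)) is not None and lat.get((4, 5)) is not None
        assert is_feasible(lat.get((4, 4)), params)

    def test_mutants_distributed_as_sampler(self, params, rng):
        # p_m = 1: offspring traits follow the uniform feasible draw,
        # independent of the parent (KS on e1 against direct sampler draws)
        lat = Lattice.empty(9)
        n = 3000
        child_e1 = np.empty(n)
        for t in range(n):
            lat.set((4, 4), None)
            lat.set((4, 5), spec_e1(9.99))
            place_offspring((4, 5), (4, 4), lat, params.replace(p_m=1.0), rng)
            child_e1[t] = lat.get((4, 4)).e1
        ref = np.array([q.e1 for q in sample_mutants(n, params, rng)])
        assert stats.ks_2samp(child_e1, ref).pvalue > 0.01


class TestDeath:
    def test_empty_site_unchanged(self, params, rng):
        lat = Lattice.empty(5)
        death_update((2, 2), lat, params.replace(p_d=1.0), rng)
        assert lat.n_occupied == 0

    def test_certain_death(self, params, rng):
        lat = Lattice.empty(5)
        lat.set((2, 2), spec_e1(5.0))
        death_update((2, 2), lat, params.replace(p_d=1.0), rng)
        assert lat.get((2, 2)) is None

    def test_empirical_rate(self, params, rng):
        # p_d = 0.1 vacates about a tenth of occupied-site trials
        p = params.replace(p_d=0.1)
        lat = Lattice.empty(5)
        n = 100_000
        deaths = 0
        for _ in range(n):
            lat.set((2, 2), spec_e1(5.0))
            death_update((2, 2), lat, p, rng)
            deaths += lat.get((2, 2)) is None
        assert deaths / n == pytest.approx(0.1, abs=3 * np.sqrt(0.09 / n))

    def test_death_is_class_neutral(self, params):
        # death ignores traits: per-class death counts in one sweep over a
        # random lattice are consistent with a single shared rate
        from metarep.observables import classify_arrays

        p = params.replace(L=150, p_d=0.1, seed=3)
        rng = np.random.default_rng(3)
        lat = initialize(p, rng)
        occ = np.argwhere(lat.occupied)
        codes = classify_arrays(lat.e1[lat.occupied], lat.e2[lat.occupied])
        died = np.zeros(len(occ), dtype=bool)
        for t, (i, j) in enumerate(occ):
            death_update((i, j), lat, p, rng)
            died[t] = lat.get((i, j)) is None
        table = np.array(
            [[(died & (codes == c)).sum(), (~died & (codes == c)).sum()] for c in range(4)]
        )
        table = table[table.sum(axis=1) > 0]
        assert stats.chi2_contingency(table).pvalue > 0.01


class TestDiffusion:
    def test_conserves_occupancy_and_multiset(self, params, rng):
        p = params.replace(L=20, seed=11)
        lat = initialize(p, rng)
        before = np.sort(lat.e1[lat.occupied])
        n_before = lat.n_occupied
        for _ in range(2000):
            diffusion_step(lat, p, rng)
        assert lat.n_occupied == n_before
        assert np.allclose(np.sort(lat.e1[lat.occupied]), before)

    def test_all_empty_lattice_unchanged(self, params, rng):
        lat = Lattice.empty(6)
        for _ in range(100):
            diffusion_step(lat, params, rng)
        assert lat.n_occupied == 0

    def test_occupied_only_mode_pins_a_lone_replicator(self, params, rng):
        p = params.replace(diffusion_occupied_only=True)
        lat = Lattice.empty(6)
        lat.set((3, 3), spec_e1(5.0))
        for _ in range(500):
            diffusion_step(lat, p, rng)
        assert lat.get((3, 3)) is not None

    def test_moves_content_by_default(self, params, rng):
        lat = Lattice.empty(6)
        lat.set((3, 3), spec_e1(5.0))
        for _ in range(500):
            diffusion_step(lat, params, rng)
        assert lat.n_occupied == 1  # moved somewhere, never duplicated


class TestInitialize:
    def test_exact_occupancy_count(self, rng):
        p = Params(L=30, init_occupancy=0.8, seed=1)
        lat = initialize(p, rng)
        assert lat.n_occupied == round(0.8 * 30 * 30) == 720

    def test_all_initial_phenotypes_feasible(self, params, rng):
        lat = initialize(params, rng)
        for i, j in np.argwhere(lat.occupied):
            assert is_feasible(lat.get((i, j)), params)

    def test_same_seed_bit_identical(self, params):
        a = initialize(params)
        b = initialize(params)
        assert np.array_equal(a.conf, b.conf)
        assert np.array_equal(a.e1, b.e1)
        assert np.array_equal(a.k, b.k)


class TestRunGeneration:
    def test_empty_lattice_is_absorbing(self, params, rng):
        p = params.replace(L=10, D=0.0, p_d=0.0, p_m=0.0)
        lat = Lattice.empty(10)
        for _ in range(5):
            run_generation(lat, p, rng)
        assert lat.n_occupied == 0
        assert lat.generation == 5

    def test_feasibility_invariant_over_generations(self, rng):
        p = Params(L=24, b=0.8, g=1.2, k_max=3.0, D=1.0, p_m=0.05, seed=5)
        lat = initialize(p, rng)
        for _ in range(10):
            run_generation(lat, p, rng)
        for i, j in np.argwhere(lat.occupied):
            assert is_feasible(lat.get((i, j)), p)

    def test_degenerate_k_stays_at_floor(self, rng):
        p = Params(L=20, k_max=2.0, k_min=2.0, D=2.0, p_m=0.1, seed=6)
        lat = initialize(p, rng)
        for _ in range(8):
            run_generation(lat, p, rng)
        assert np.all(lat.k[lat.occupied] == 2.0)

    def test_specialist_monoculture_dies_without_diffusion(self):
        # a clonal patch of one specialist type cannot run metabolism:
        # no complementary activity anywhere, so no replication, only death
        p = Params(L=30, D=0.0, p_d=0.1, p_m=0.01, k_max=2.5, seed=0)
        for seed in range(5):
            rng = np.random.default_rng(seed)
            lat = Lattice.empty(30)
            for i in range(30):
                for j in range(30):
                    if rng.random() < 0.8:
                        lat.set((i, j), spec_e1(8.0))
            gens = 0
            while lat.n_occupied and gens < 200:
                run_generation(lat, p, rng)
                gens += 1
            assert lat.n_occupied == 0

    def test_pure_parasite_lattice_dies_at_any_diffusion(self, rng):
        for D in (0.0, 5.0):
            p = Params(L=20, D=D, p_d=0.1, p_m=0.01, k_max=4.0, seed=2)
            lat = Lattice.empty(20)
            for i in range(20):
                for j in range(20):
                    lat.set((i, j), Phenotype(0.0, 0.0, 4.0, Conformation.NONE))
            gens = 0
            while lat.n_occupied and gens < 200:
                run_generation(lat, p, rng)
                gens += 1
            assert lat.n_occupied == 0
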