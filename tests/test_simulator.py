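import numpy as np
import pytest

from riscape.fixtures import make_mini_config, make_toy_landscape
from riscape.genetics import build_fitness_table
from riscape.simulator import (
    OffspringPool,
    SimConfig,
    SiteSet,
    disperse_and_settle,
    generate_sites,
    init_population,
    movement_kernel,
    reproduce,
    run_simulation,
    select_mates,
)

INCOMPATIBLE_CODES = (1, 2, 4, 5)  # aaBb, aaBB, AaBb, AaBB


class TestMovementKernel:
    def test_inverse_square_two_candidates(self):
        p = movement_kernel((0, 0), [(1, 0), (2, 0)], max_dist=5)
        assert p == pytest.approx([0.8, 0.2])

    def test_single_in_range_candidate(self):
        p = movement_kernel((0, 0), [(3, 4), (100, 0)], max_dist=10)
        assert p == pytest.approx([1.0, 0.0])

    def test_matches_brute_force_table(self, rng):
        src = rng.uniform(0, 100, size=2)
        cand = rng.uniform(0, 100, size=(20, 2))
        max_dist = 60.0
        p = movement_kernel(src, cand, max_dist)
        d = np.sqrt(((cand - src) ** 2).sum(axis=1))
        w = np.where(d <= max_dist, 1.0 / d**2, 0.0)
        assert p == pytest.approx(w / w.sum())
        assert p.sum() == pytest.approx(1.0)

    def test_all_beyond_max_returns_empty_signal(self):
        assert movement_kernel((0, 0), [(50, 0), (0, 80)], max_dist=10) is None

    def test_rejects_nonpositive_max_dist(self):
        with pytest.raises(ValueError):
            movement_kernel((0, 0), [(1, 0)], max_dist=0)


class TestMating:
    def _tiny_state(self, coords, sexes, rng, n_loci=4, max_move_frac=0.5):
        sites = SiteSet(np.asarray(coords, dtype=float))
        config = SimConfig(n_sites=len(coords), n_loci=n_loci, burn_in=0,
                           total_gens=1, max_move_frac=max_move_frac)
        state = init_population(config, sites, rng)
        state.sexes = np.asarray(sexes)
        return state, config

    def test_pair_distances_within_truncation(self, rng):
        coords = rng.uniform(0, 6400, size=(60, 2))
        state, config = self._tiny_state(coords, rng.integers(0, 2, 60), rng)
        landscape = make_toy_landscape("half_split", dims=(64, 64))
        pairs = select_mates(state, landscape, config, rng)
        max_dist = config.max_move_frac * max(landscape.extent)
        for f, m in pairs:
            d = np.hypot(*(state.coords[f] - state.coords[m]))
            assert 0 < d <= max_dist

    def test_female_without_reachable_male_is_skipped(self, rng):
        # one female far in a corner, male cluster elsewhere
        coords = [(0.0, 0.0), (6000.0, 6000.0), (6000.0, 5900.0)]
        state, config = self._tiny_state(coords, [0, 0, 1], rng,
                                         max_move_frac=0.05)  # max_dist 320
        landscape = make_toy_landscape("half_split", dims=(64, 64))  # extent 6400
        pairs = select_mates(state, landscape, config, rng)
        assert [tuple(p) for p in pairs] == [(1, 2)]

    def test_missing_sex_gives_no_pairs(self, rng):
        coords = [(0.0, 0.0), (10.0, 10.0)]
        state, config = self._tiny_state(coords, [0, 0], rng)
        landscape = make_toy_landscape("half_split", dims=(64, 64))
        assert len(select_mates(state, landscape, config, rng)) == 0


class TestSettlement:
    def _pool_of(self, genotype_row, n, natal_site, n_loci=4):
        g = np.tile(genotype_row, (n, 1, 1)).astype(np.uint8)
        natal = np.broadcast_to(np.asarray(natal_site, dtype=np.int64), n)
        return OffspringPool(
            genotypes=g,
            sexes=np.zeros(n, dtype=np.int64),
            natal_site=natal.copy(),
        )

    def test_capacity_reached_with_excess_viable_pool(self, rng):
        landscape = make_toy_landscape("half_split", dims=(64, 64))
        sites = generate_sites(300, landscape.extent, rng)
        config = SimConfig(n_sites=300, n_loci=4, burn_in=10, total_gens=20,
                           max_move_frac=1.0,
                           incompatibility_during_burn_in=False)
        aabb = np.zeros((4, 2), dtype=np.uint8)
        # natal sites spread over the map so every site is reachable
        pool = self._pool_of(aabb, 10_000, natal_site=np.arange(10_000) % 300)
        site_idx, sexes, genos = disperse_and_settle(
            pool, sites, landscape, build_fitness_table(0.5), config, rng,
            selection_on=False,
        )
        assert len(site_idx) == 300
        assert len(np.unique(site_idx)) == 300

    def test_incompatible_offspring_never_settle(self, rng):
        landscape = make_toy_landscape("half_split", dims=(64, 64))
        sites = generate_sites(50, landscape.extent, rng)
        config = SimConfig(n_sites=50, n_loci=4, burn_in=0, total_gens=1,
                           max_move_frac=1.0)
        aabb_het = np.zeros((4, 2), dtype=np.uint8)
        aabb_het[0, 0] = 1  # Aa
        aabb_het[1, :] = 1  # BB -> AaBB, zero viability
        pool = self._pool_of(aabb_het, 2000, natal_site=0)
        site_idx, _, _ = disperse_and_settle(
            pool, sites, landscape, build_fitness_table(0.5), config, rng,
            selection_on=True,
        )
        assert len(site_idx) == 0

    def test_empty_pool_gives_empty_population(self, rng):
        landscape = make_toy_landscape("half_split", dims=(64, 64))
        sites = generate_sites(20, landscape.extent, rng)
        config = SimConfig(n_sites=20, n_loci=4, burn_in=0, total_gens=1)
        pool = OffspringPool(
            genotypes=np.empty((0, 4, 2), dtype=np.uint8),
            sexes=np.empty(0, dtype=np.int64),
            natal_site=np.empty(0, dtype=np.int64),
        )
        site_idx, _, _ = disperse_and_settle(
            pool, sites, landscape, build_fitness_table(0.5), config, rng,
            selection_on=True,
        )
        assert len(site_idx) == 0

    def test_out_of_reach_offspring_die(self, rng):
        landscape = make_toy_landscape("half_split", dims=(64, 64))
        # natal site in one corner, all other sites out of reach
        coords = np.array([[0.0, 0.0], [6000.0, 6000.0], [6000.0, 5990.0]])
        sites = SiteSet(coords)
        config = SimConfig(n_sites=3, n_loci=4, burn_in=0, total_gens=1,
                           max_move_frac=0.01)  # max_dist 64
        pool = self._pool_of(np.zeros((4, 2), dtype=np.uint8), 100, natal_site=0)
        site_idx, _, _ = disperse_and_settle(
            pool, sites, landscape, build_fitness_table(0.0), config, rng,
            selection_on=False,
        )
        assert len(site_idx) == 0


class TestReproduction:
    def test_offspring_counts_poisson_mean(self, rng):
        landscape = make_toy_landscape("half_split", dims=(64, 64))
        sites = generate_sites(400, landscape.extent, rng)
        config = SimConfig(n_sites=400, n_loci=4, burn_in=1, total_gens=2,
                           offspring_mean=4.0, max_move_frac=1.0)
        state = init_population(config, sites, rng)
        pairs = select_mates(state, landscape, config, rng)
        pool = reproduce(state, pairs, config, rng)
        mean = len(pool) / len(pairs)
        assert abs(mean - 4.0) < 4 * np.sqrt(4.0 / len(pairs))
        # natal coordinates are the mothers' sites
        assert set(pool.natal_site) <= set(state.site_idx[pairs[:, 0]])


class TestRunInvariants:
    def test_population_never_exceeds_capacity(self, mini_state):
        config, _, state = mini_state
        assert all(r.pop_size <= config.n_sites for r in state.records)

    def test_no_incompatible_class_survives_settlement(self, mini_state):
        """a/B carriers are purged in every generation after the initial
        standing population."""
        _, _, state = mini_state
        for r in state.records[1:]:
            assert sum(int(r.class_counts[c]) for c in INCOMPATIBLE_CODES) == 0

    def test_deterministic_given_seed(self):
        config = make_mini_config(total_gens=8, burn_in=2)
        landscape = make_toy_landscape("checkerboard", dims=(64, 64), block=16)
        a = run_simulation(config, landscape)
        b = run_simulation(config, landscape)
        assert a.size == b.size
        assert np.array_equal(a.site_idx, b.site_idx)
        assert np.array_equal(a.genotypes, b.genotypes)
        for ra, rb in zip(a.records, b.records):
            assert np.array_equal(ra.class_counts, rb.class_counts)

    def test_neutral_run_holds_capacity(self, rng):
        """With selection fully off and an excess offspring pool the
        population sits at exactly n_sites every generation."""
        config = SimConfig(n_sites=150, n_loci=4, burn_in=12, total_gens=12,
                           max_move_frac=1.0, s=0.0,
                           incompatibility_during_burn_in=False, seed=5)
        landscape = make_toy_landscape("half_split", dims=(64, 64))
        state = run_simulation(config, landscape)
        assert [r.pop_size for r in state.records] == [150] * 13

    def test_unique_site_occupancy(self, mini_state):
        _, _, state = mini_state
        assert len(np.unique(state.site_idx)) == state.size
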