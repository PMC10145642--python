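import numpy as np
import pytest

from conftest import random_bimodal_image
from mmpso_s.exceptions import DegenerateImageError, InvalidInputError
from mmpso_s.mopso import (
    ParetoArchive,
    SwarmConfig,
    apply_thresholds,
    best_particle,
    dominates,
    initialize_swarm,
    mutate,
    mutation_probability,
    run_mmpso,
    update_archive,
    update_particle,
)
from mmpso_s.objectives import ObjectiveTables, histogram

SMALL = SwarmConfig(n_particles=40, n_iterations=40, seed=0)


def archive_is_mutually_nondominated(F):
    """O(n^2) dominance scan."""
    for i in range(len(F)):
        for j in range(len(F)):
            if i != j and dominates(F[i], F[j]):
                return False
    return True


class TestDominance:
    def test_strictly_better(self):
        assert dominates((2, 2, 2), (1, 1, 1))

    def test_mutual_nondominance(self):
        assert not dominates((2, 1, 1), (1, 2, 1))
        assert not dominates((1, 2, 1), (2, 1, 1))

    def test_equal_vectors_do_not_dominate(self):
        assert not dominates((1, 1), (1, 1))

    def test_weak_improvement_dominates(self):
        assert dominates((1, 2), (1, 1))


class TestInitialization:
    def test_deterministic_under_seed(self, nuclei_fixture):
        img = nuclei_fixture[0][:, :, 0]
        counts = histogram(img)
        s1 = initialize_swarm(SMALL, counts)
        s2 = initialize_swarm(SMALL, counts)
        assert np.array_equal(s1.X, s2.X)
        assert np.array_equal(s1.F, s2.F)

    def test_velocities_start_at_zero(self):
        counts = histogram(random_bimodal_image(0))
        state = initialize_swarm(SMALL, counts)
        assert np.all(state.V == 0)

    def test_positions_sorted_within_bounds(self):
        counts = histogram(random_bimodal_image(1))
        state = initialize_swarm(SMALL, counts)
        assert np.all(state.X >= 0) and np.all(state.X <= 255)
        assert np.all(np.diff(state.X, axis=1) >= 0)

    def test_archive_seeded_nondominated(self):
        counts = histogram(random_bimodal_image(2))
        state = initialize_swarm(SMALL, counts)
        assert len(state.archive) >= 1
        assert archive_is_mutually_nondominated(state.archive.fitness_array)


class TestArchiveRules:
    def test_empty_archive_accepts(self):
        a = ParetoArchive(capacity=5, grid_size=7)
        update_archive(a, [10.0, 20.0], [1.0, 1.0])
        assert len(a) == 1

    def test_dominated_candidate_discarded(self):
        a = ParetoArchive(capacity=5, grid_size=7)
        a.add([10.0, 20.0], [2.0, 2.0])
        a.add([30.0, 40.0], [1.0, 1.0])
        assert len(a) == 1
        assert np.allclose(a.fitnesses[0], [2.0, 2.0])

    def test_candidate_evicts_dominated_members(self):
        a = ParetoArchive(capacity=5, grid_size=7)
        a.add([1.0, 2.0], [1.0, 3.0])
        a.add([3.0, 4.0], [3.0, 1.0])
        a.add([5.0, 6.0], [4.0, 4.0])  # dominates both
        assert len(a) == 1
        assert np.allclose(a.fitnesses[0], [4.0, 4.0])

    def test_full_archive_evicts_from_most_crowded_cube(self):
        a = ParetoArchive(capacity=4, grid_size=7)
        # three members crowd one corner; one sits alone at the other end
        for i in range(3):
            a.add([float(i), 0.0], [0.01 * (i + 1), 10.0 - 0.001 * (i + 1)])
        a.add([9.0, 0.0], [10.0, 0.0])
        assert len(a) == 4
        a.add([5.0, 5.0], [5.0, 4.0])  # non-dominated, archive full
        assert len(a) == 4
        # the lone member must survive; the crowded corner lost one
        fits = a.fitness_array
        assert any(np.allclose(f, [10.0, 0.0]) for f in fits)
        crowded = sum(1 for f in fits if f[1] > 9.0)
        assert crowded == 2

    def test_capacity_never_exceeded(self, rng):
        a = ParetoArchive(capacity=6, grid_size=5)
        for _ in range(200):
            f = rng.random(3) * 10
            a.add(rng.random(2) * 255, f)
            assert len(a) <= 6
            assert archive_is_mutually_nondominated(a.fitness_array)


class TestLeaderSelection:
    def test_single_member_always_selected(self, rng):
        a = ParetoArchive(capacity=5, grid_size=7)
        a.add([42.0, 99.0], [1.0, 2.0])
        for _ in range(10):
            pos, _ = a.select_leader(rng)
            assert np.allclose(pos, [42.0, 99.0])

    def test_roulette_prefers_sparse_cubes(self, rng):
        """Cube weight is x/occupancy: a lone member in its own cube is
        drawn ~x times more often than each member of a 9-member cube."""
        a = ParetoArchive(capacity=30, grid_size=7, grid_fitness_numerator=10.0)
        a.add([0.0, 0.0], [10.0, 0.0])  # lone cube
        for i in range(1, 10):  # anti-chain crowded near (0, 10)
            a.add([float(i), 0.0], [0.01 * i, 10.0 - 0.001 * i])
        assert len(a) == 10
        draws = a.select_leader_indices(20000, rng)
        freq_lone = np.mean(draws == 0)
        # weights 10/1 vs 10/9 -> P(lone cube) = 0.9
        assert freq_lone == pytest.approx(0.9, abs=0.02)

    def test_reproducible_under_seed(self):
        a = ParetoArchive(capacity=30, grid_size=7)
        for i in range(5):
            a.add([float(i), 0.0], [float(i), 5.0 - i])
        d1 = a.select_leader_indices(50, np.random.default_rng(3))
        d2 = a.select_leader_indices(50, np.random.default_rng(3))
        assert np.array_equal(d1, d2)

    def test_empty_archive_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            ParetoArchive(capacity=5, grid_size=7).select_leader(rng)


class TestParticleUpdate:
    def test_stationary_fixed_point(self):
        cfg = SwarmConfig()
        X = np.array([100.0, 150.0])
        Xn, Vn = update_particle(X, np.zeros(2), X, X, cfg, r1=0.7, r2=0.3)
        assert np.allclose(Xn, X) and np.allclose(Vn, 0)

    def test_hand_computed_step(self):
        # w=1.3, c1=c2=0.5, r1=r2=1:
        # V' = 1.3*(1,-1) + 0.5*(10,-10) + 0.5*(20,10) = (16.3, -1.3)
        # clamped to (5, -1.3); X' = (105, 148.7)
        cfg = SwarmConfig()
        X = np.array([100.0, 150.0])
        V = np.array([1.0, -1.0])
        pbest = np.array([110.0, 140.0])
        leader = np.array([120.0, 160.0])
        Xn, Vn = update_particle(X, V, pbest, leader, cfg, r1=1.0, r2=1.0)
        assert np.allclose(Vn, [5.0, -1.3])
        assert np.allclose(Xn, [105.0, 148.7])

    def test_bounds_always_respected(self, rng):
        cfg = SwarmConfig()
        for _ in range(200):
            X = rng.uniform(0, 255, 2)
            V = rng.uniform(-20, 20, 2)
            Xn, Vn = update_particle(
                X, V, rng.uniform(0, 255, 2), rng.uniform(0, 255, 2), cfg,
                r1=rng.random(), r2=rng.random(),
            )
            assert np.all(Vn >= -5) and np.all(Vn <= 5)
            assert np.all(Xn >= 0) and np.all(Xn <= 255)
            assert Xn[0] <= Xn[1]


class TestMutation:
    def test_schedule_endpoints(self):
        cfg = SwarmConfig(n_iterations=150)
        assert mutation_probability(1, cfg) == 1.0
        assert mutation_probability(150, cfg) == 0.0

    def test_schedule_monotone_nonincreasing(self):
        cfg = SwarmConfig(n_iterations=100)
        pm = [mutation_probability(t, cfg) for t in range(1, 101)]
        assert all(a >= b for a, b in zip(pm, pm[1:]))

    def test_last_iteration_leaves_swarm_unchanged(self):
        counts = histogram(random_bimodal_image(3))
        cfg = SwarmConfig(n_particles=20, n_iterations=50, seed=1)
        state = initialize_swarm(cfg, counts)
        X_before = state.X.copy()
        mutate(state, cfg.n_iterations, cfg, np.random.default_rng(0))
        assert np.array_equal(state.X, X_before)

    def test_first_iteration_mutates_particles(self):
        counts = histogram(random_bimodal_image(4))
        cfg = SwarmConfig(n_particles=20, n_iterations=50, seed=1)
        state = initialize_swarm(cfg, counts)
        X_before = state.X.copy()
        mutate(state, 1, cfg, np.random.default_rng(0))
        assert not np.array_equal(state.X, X_before)
        assert np.all(state.X >= 0) and np.all(state.X <= 255)


class TestBestParticle:
    def test_hand_distance(self):
        a = ParetoArchive(capacity=5, grid_size=7)
        a.add([1.0, 2.0], [3.0, 0.0, 0.0])
        a.add([3.0, 4.0], [0.0, 4.0, 0.0])
        pos, fit = best_particle(a)
        assert np.allclose(fit, [0.0, 4.0, 0.0])

    def test_single_member(self):
        a = ParetoArchive(capacity=5, grid_size=7)
        a.add([7.0, 8.0], [1.0, 1.0])
        pos, _ = best_particle(a)
        assert np.allclose(pos, [7.0, 8.0])

    def test_matches_brute_force_scan(self, rng):
        a = ParetoArchive(capacity=30, grid_size=7)
        for i in range(8):
            a.add([float(i), 0.0], [8.0 - i, float(i), 1.0])
        _, fit = best_particle(a)
        d = [np.linalg.norm(f) for f in a.fitnesses]
        assert np.linalg.norm(fit) == max(d)

    def test_empty_archive_rejected(self):
        with pytest.raises(InvalidInputError):
            best_particle(ParetoArchive(capacity=5, grid_size=7))


class TestRunMMPSO:
    def test_deterministic_under_seed(self):
        img = random_bimodal_image(5)
        cfg = SwarmConfig(n_particles=30, n_iterations=30, seed=9)
        assert run_mmpso(img, cfg) == run_mmpso(img, cfg)

    def test_degenerate_image_rejected(self):
        img = np.full((10, 10), 77, dtype=np.uint8)
        with pytest.raises(DegenerateImageError):
            run_mmpso(img, SMALL)

    def test_thresholds_strictly_increasing(self):
        img = random_bimodal_image(6)
        t1, t2 = run_mmpso(img, SwarmConfig(n_particles=30, n_iterations=30, seed=2))
        assert 1 <= t1 < t2 <= 255

    @pytest.mark.parametrize("seed", range(3))
    def test_single_objective_matches_exhaustive_otsu(self, seed):
        """With only f1 active and k=1 the engine must find the exact
        exhaustive-scan Otsu threshold."""
        img = random_bimodal_image(600 + seed)
        cfg = SwarmConfig(n_particles=60, n_iterations=60, n_thresholds=1,
                          objectives=("otsu",), seed=seed)
        (t,) = run_mmpso(img, cfg)
        tab = ObjectiveTables(histogram(img), 2.0)
        f = tab.evaluate_batch(np.arange(1, 256)[:, None], ("otsu",))[:, 0]
        assert t == int(np.argmax(f)) + 1


class TestApplyThresholds:
    def test_partition(self, rng):
        img = rng.integers(0, 256, size=(20, 20), dtype=np.uint8)
        i1, i2, i3 = apply_thresholds(img, 80, 170)
        assert np.array_equal(i1 | i2 | i3, np.ones_like(img, dtype=bool))
        assert not np.any(i1 & i2) and not np.any(i1 & i3) and not np.any(i2 & i3)

    def test_exactly_three_maps(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        maps = apply_thresholds(img, 10, 20)
        assert len(maps) == 3

    def test_constant_zero_image(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        i1, i2, i3 = apply_thresholds(img, 10, 20)
        assert np.all(i1) and not np.any(i2) and not np.any(i3)

    def test_boundary_semantics(self):
        img = np.array([[9, 10], [19, 20]], dtype=np.uint8)
        i1, i2, i3 = apply_thresholds(img, 10, 20)
        assert i1[0, 0] and not i1[0, 1]  # I1 = [0, t1-1]
        assert i2[0, 1] and i2[1, 0]  # I2 = [t1, t2-1]
        assert i3[1, 1]  # I3 = [t2, 255]

    def test_invalid_order_rejected(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        with pytest.raises(InvalidInputError):
            apply_thresholds(img, 20, 20)
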