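"""Fuzzy salp swarm algorithm: update rules, invariants and refinement hook."""

import numpy as np
import pytest

from foamidl.fssa import (
    FSSAConfig,
    adapt_population,
    adaptive_c1,
    c1_decay,
    exploration_update,
    follower_update,
    fuzzy_perturbation,
    gfm,
    greedy_select,
    initialize_population,
    leader_update,
    optimize,
    refine_classifier,
)
from foamidl.volio import ValidationError


class ScriptedRng:
    """Deterministic stand-in for a Generator: returns queued uniform draws."""

    def __init__(self, draws):
        self.draws = [np.atleast_1d(np.asarray(d, dtype=float)) for d in draws]

    def uniform(self, size=None):
        out = self.draws.pop(0)
        if size is not None and np.prod(np.atleast_1d(size)) != out.size:
            raise AssertionError("scripted draw size mismatch")
        return out if size is not None else float(out)


def sphere(x):
    return float(np.sum(x**2))


class TestInitialization:
    def test_bounds_contract(self):
        pop = initialize_population(3, (np.array([0.0]), np.array([1.0])), seed=0)
        assert pop.positions.shape == (3, 1)
        assert np.all((pop.positions >= 0) & (pop.positions <= 1))

    def test_determinism(self):
        p1 = initialize_population(5, (np.zeros(3), np.ones(3)), seed=11)
        p2 = initialize_population(5, (np.zeros(3), np.ones(3)), seed=11)
        assert np.array_equal(p1.positions, p2.positions)

    def test_uniform_law(self):
        pop = initialize_population(1000, (np.array([0.0]), np.array([1.0])), seed=2)
        assert pop.positions.mean() == pytest.approx(0.5, abs=0.05)

    def test_invalid_bounds(self):
        with pytest.raises(ValidationError):
            initialize_population(3, (np.array([1.0]), np.array([1.0])), seed=0)


class TestSchedules:
    def test_classic_decay_endpoints(self):
        assert c1_decay(0, 100) == 2.0
        assert c1_decay(100, 100) == pytest.approx(2 * np.exp(-16), rel=1e-12)

    def test_classic_decay_strictly_decreasing(self):
        vals = [c1_decay(t, 50) for t in range(51)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_adaptive_endpoints_and_monotone(self):
        cfg = FSSAConfig(t_max=100)
        assert adaptive_c1(0, cfg) == 0.95
        assert adaptive_c1(100, cfg) == pytest.approx(0.05)
        vals = [adaptive_c1(t, cfg) for t in range(101)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize("t, expected", [(0, 30), (50, 20), (100, 10)])
    def test_population_schedule(self, t, expected):
        assert adapt_population(t, FSSAConfig(n_max=30, n_min=10, t_max=100)) == expected


class TestLeaderUpdate:
    def _pop(self, rng_draws, lb=0.0, ub=1.0, food=0.5):
        pop = initialize_population(3, (np.array([lb]), np.array([ub])), seed=0)
        pop.food = np.array([food])
        pop.food_fitness = 0.0
        pop.rng = ScriptedRng(rng_draws)
        return pop

    def test_zero_coefficient_returns_food(self):
        pop = self._pop([[0.7], [0.9]])
        assert leader_update(pop, 0.0) == pytest.approx([0.5])

    def test_clamped_within_bounds(self):
        pop = self._pop([[1.0], [0.9]])
        x = leader_update(pop, 2.0)
        assert 0.0 <= x[0] <= 1.0

    def test_positive_branch_direction(self):
        """With C3 >= 0.5 and bounds [0, 1], the step adds (ub-lb)*C2 >= 0."""
        for c2 in (0.0, 0.3, 0.9):
            pop = self._pop([[c2], [0.75]])  # second draw = C3 >= 0.5
            assert leader_update(pop, 0.1)[0] >= 0.5 - 1e-12

    def test_negative_branch_direction(self):
        pop = self._pop([[0.3], [0.25]])  # C3 < 0.5
        assert leader_update(pop, 0.1)[0] <= 0.5 + 1e-12


class TestFollowerUpdate:
    def test_midpoint(self):
        out = follower_update(np.array([[4.0], [2.0]]), -10, 10)
        assert out[1, 0] == 3.0

    def test_fixed_point(self):
        pos = np.full((4, 2), 1.25)
        assert np.array_equal(follower_update(pos, 0, 2), pos)

    def test_sequential_chain(self):
        out = follower_update(np.array([[0.0], [8.0], [8.0]]), -10, 10)
        assert out[:, 0].tolist() == [0.0, 4.0, 6.0]


class TestExplorationUpdate:
    def test_end_of_schedule_collapses_to_best(self):
        pop = initialize_population(2, (np.array([-5.0]), np.array([5.0])), seed=0)
        pop.food = np.array([1.0])
        pop.rng = ScriptedRng([[0.5], [0.5]] * 3)
        cand = exploration_update(pop, np.array([3.0]), t=10, t_max=10)  # a = 0
        assert cand == pytest.approx([1.0])

    def test_fixed_point_at_best_with_unit_C(self):
        pop = initialize_population(2, (np.array([-5.0]), np.array([5.0])), seed=0)
        pop.food = np.array([2.0])
        pop.rng = ScriptedRng([[0.5], [0.5]] * 3)  # C = 2*0.5 = 1
        cand = exploration_update(pop, np.array([2.0]), t=2, t_max=10)
        assert cand == pytest.approx([2.0])

    def test_hand_trace_d1(self):
        pop = initialize_population(2, (np.array([-10.0]), np.array([10.0])), seed=0)
        pop.food = np.array([1.0])
        draws = [[0.25], [0.4], [0.75], [0.1], [0.5], [0.9]]
        pop.rng = ScriptedRng(draws)
        t, t_max = 2, 10
        a = 2 * (1 - t / t_max)
        x_i = np.array([4.0])
        expected = []
        for r1, r2 in [(0.25, 0.4), (0.75, 0.1), (0.5, 0.9)]:
            A = 2 * a * r1 - a
            C = 2 * r2
            expected.append(1.0 - A * abs(C * 1.0 - 4.0))
        expected = np.clip(np.mean(expected), -10, 10)
        cand = exploration_update(pop, x_i, t, t_max)
        assert cand[0] == pytest.approx(expected, rel=1e-12)


class TestFuzzyPerturbationAndGFM:
    def test_alpha_zero_noop(self):
        x = np.array([1.0, 2.0])
        assert np.array_equal(fuzzy_perturbation(x, np.array([9.0, 9.0]), 0.0), x)

    def test_alpha_one_absorbs(self):
        out = fuzzy_perturbation(np.zeros(2), np.array([3.0, -1.0]), 1.0)
        assert np.array_equal(out, [3.0, -1.0])

    def test_quarter_step(self):
        assert fuzzy_perturbation(np.array([0.0]), np.array([4.0]), 0.25)[0] == 1.0

    def test_alpha_out_of_range(self):
        with pytest.raises(ValidationError):
            fuzzy_perturbation(np.zeros(1), np.ones(1), 1.5)

    def test_gfm_peak_and_value(self):
        assert gfm(2.0, 2.0, 1.0) == 1.0
        assert gfm(3.0, 2.0, 1.0, m=2.0) == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_gfm_symmetric_and_bounded(self):
        for d in (0.1, 1.0, 7.0):
            assert gfm(2 + d, 2, 1.3) == pytest.approx(gfm(2 - d, 2, 1.3), rel=1e-12)
            assert 0 < gfm(2 + d, 2, 1.3) <= 1

    def test_gfm_invalid_spread(self):
        with pytest.raises(ValidationError):
            gfm(0.0, 0.0, 0.0)


class TestGreedySelect:
    def test_strict_improvement(self):
        x, f = greedy_select(np.zeros(1), 2.0, np.ones(1), 1.0)
        assert f == 1.0 and x[0] == 1.0

    def test_tie_keeps_old(self):
        x, f = greedy_select(np.zeros(1), 1.0, np.ones(1), 1.0)
        assert x[0] == 0.0

    def test_best_so_far_non_increasing(self, rng):
        x, f = np.zeros(1), 10.0
        best = [f]
        for _ in range(50):
            x, f = greedy_select(x, f, rng.standard_normal(1), float(rng.uniform(0, 20)))
            best.append(f)
        assert all(a >= b for a, b in zip(best, best[1:]))


class TestOptimize:
    def test_sphere_convergence_small(self):
        cfg = FSSAConfig(n_max=20, n_min=8, t_max=80, seed=0)
        bounds = (np.full(2, -5.0), np.full(2, 5.0))
        _, best_f, _ = optimize(sphere, bounds, cfg)
        assert best_f < 1e-4

    def test_1d_convex(self):
        cfg = FSSAConfig(n_max=30, n_min=10, t_max=100, seed=0)
        best, _, _ = optimize(lambda x: float((x[0] - 2.0) ** 2),
                              (np.array([-5.0]), np.array([5.0])), cfg)
        assert abs(best[0] - 2.0) < 0.01

    def test_trace_monotone_and_sizes(self):
        cfg = FSSAConfig(n_max=12, n_min=5, t_max=40, seed=3)
        _, _, trace = optimize(sphere, (np.full(3, -2.0), np.full(3, 2.0)), cfg)
        best = [r["best_fitness"] for r in trace]
        sizes = [r["pop_size"] for r in trace]
        assert all(a >= b for a, b in zip(best, best[1:]))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert sizes[0] <= 12 and sizes[-1] == 5

    def test_positions_within_bounds_random_configs(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            d = int(rng.integers(1, 4))
            lb = rng.uniform(-3, 0, size=d)
            ub = lb + rng.uniform(0.5, 3, size=d)
            cfg = FSSAConfig(n_max=8, n_min=4, t_max=20, seed=seed)
            best, _, _ = optimize(sphere, (lb, ub), cfg)
            assert np.all(best >= lb - 1e-12) and np.all(best <= ub + 1e-12)

    def test_x0_seeds_first_salp(self):
        cfg = FSSAConfig(n_max=5, n_min=5, t_max=4, seed=0)
        x0 = np.array([0.123, -0.456])
        bounds = (np.full(2, -1.0), np.full(2, 1.0))
        _, best_f, _ = optimize(sphere, bounds, cfg, x0=x0)
        assert best_f <= sphere(x0) + 1e-12

    def test_nan_fitness_aborts(self):
        cfg = FSSAConfig(n_max=4, n_min=4, t_max=4, seed=0)
        with pytest.raises(ValidationError, match="NaN"):
            optimize(lambda x: float("nan"), (np.zeros(1), np.ones(1)), cfg)

    def test_exploitation_matches_hand_rolled_ssa(self):
        """Exploration disabled, fixed n: the loop is the classical salp swarm
        (leader Eq. around food, follower midpoints, greedy keep)."""
        cfg = FSSAConfig(n_max=6, n_min=6, t_max=12, seed=5, exploration=False)
        lb, ub = np.full(2, -4.0), np.full(2, 4.0)

        def f(x):
            return float((x[0] - 1) ** 2 + 2 * (x[1] + 0.5) ** 2)

        best, best_f, _ = optimize(f, (lb, ub), cfg)

        # independent replica with the same seeded draw sequence
        rng = np.random.default_rng(5)
        pos = lb + rng.uniform(size=(6, 2)) * (ub - lb)
        fit = np.array([f(x) for x in pos])
        i = int(np.argmin(fit))
        food, food_f = pos[i].copy(), float(fit[i])
        for t in range(1, 13):
            c1 = 0.95 - 0.9 * t / 12
            c2, c3 = rng.uniform(size=2), rng.uniform(size=2)
            step = c1 * ((ub - lb) * c2 + lb)
            work = pos.copy()
            work[0] = np.clip(np.where(c3 >= 0.5, food + step, food - step), lb, ub)
            for j in range(1, 6):
                work[j] = np.clip(0.5 * (work[j] + work[j - 1]), lb, ub)
            for j in range(6):
                fj = f(work[j])
                if fj < fit[j]:
                    pos[j], fit[j] = work[j], fj
            i = int(np.argmin(fit))
            if fit[i] < food_f:
                food_f, food = float(fit[i]), pos[i].copy()
        assert best_f == pytest.approx(food_f, rel=1e-12)
        np.testing.assert_allclose(best, food, rtol=1e-12)


class TestRefineClassifier:
    def _toy(self, seed, n_val=12):
        from foamidl.classifier import BagModel
        from foamidl.patch_proposal import PatchBag
        from foamidl.volio import Patch, PatchCoord

        rng = np.random.default_rng(seed)
        model = BagModel.build(k=2, patch_width=4, patchnet_channels=(2, 2, 2, 2),
                               attention_hidden=2, classifier_channels=(2, 2),
                               seed=seed)
        bags = []
        for i in range(n_val):
            label = i % 2
            data = rng.standard_normal((2, 4, 4, 4)) + (2.0 if label else 0.0)
            patches = [Patch(PatchCoord((0, 0, 0), 4), data[0]),
                       Patch(PatchCoord((4, 0, 0), 4), data[1])]
            b = PatchBag(patches=patches)
            b.label = label
            bags.append(b)
        return model, bags

    def _val_acc(self, model, bags):
        from foamidl.classifier import bag_forward

        calls = [bag_forward(b, model).hard_call for b in bags]
        return float(np.mean([c == b.label for c, b in zip(calls, bags)]))

    def test_zero_radius_noop(self):
        model, bags = self._toy(0)
        before = [a.copy() for a in model.state_arrays()]
        refined, trace = refine_classifier(model, bags, radius=0.0)
        assert trace == []
        for a, b in zip(before, refined.state_arrays()):
            assert np.array_equal(a, b)

    def test_never_decreases_validation_accuracy(self):
        cfg = FSSAConfig(n_max=8, n_min=4, t_max=16, seed=0)
        for seed in range(5):
            model, bags = self._toy(seed)
            acc_before = self._val_acc(model, bags)
            model, _ = refine_classifier(model, bags, cfg)
            assert self._val_acc(model, bags) >= acc_before - 1e-12

    def test_recovers_separable_linear_classifier(self):
        """Mis-set 2-feature linear classifier: the FSSA restores >= 95%
        accuracy on a linearly separable validation set."""
        rng = np.random.default_rng(0)
        n = 40
        X = rng.standard_normal((n, 2))
        y = (X[:, 0] + X[:, 1] > 0).astype(int)
        X[y == 1] += 0.8  # margin
        y = (X[:, 0] + X[:, 1] > 0.8).astype(int)  # relabel with clear margin

        def accuracy(params):
            calls = (X @ params[:2] + params[2] > 0).astype(int)
            return float(np.mean(calls == y))

        x0 = np.array([-1.0, 0.3, 2.0])  # badly mis-set weights and bias
        assert accuracy(x0) < 0.7
        cfg = FSSAConfig(n_max=14, n_min=8, t_max=60, seed=1)
        bounds = (np.full(3, -3.0), np.full(3, 3.0))
        best, best_f, _ = optimize(lambda p: -accuracy(p), bounds, cfg, x0=x0)
        assert accuracy(best) >= 0.95

    def test_empty_validation_rejected(self):
        model, _ = self._toy(0)
        with pytest.raises(ValidationError):
            refine_classifier(model, [], FSSAConfig(n_max=4, n_min=4, t_max=4))
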