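"""Differential evolution on mixed complex/real parameter vectors."""

import numpy as np
import pytest

from tdgrn.cvde import (
    ComponentSpec,
    DEConfig,
    ParameterVector,
    cvde_optimize,
    de_crossover,
    de_mutate,
    init_population,
)
from tdgrn.errors import ConfigError

TEMPLATE = ("complex", "complex", "real")
BOUNDS = (
    ComponentSpec("complex", -5, 5),
    ComponentSpec("complex", -5, 5),
    ComponentSpec("real", -3, 3),
)


class TestConfigAndInit:
    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ConfigError):
            ComponentSpec("real", 2.0, -2.0)

    @pytest.mark.parametrize(
        "kwargs", [dict(np_pop=3), dict(f_weight=0.0), dict(cr=1.5)]
    )
    def test_invalid_de_config(self, kwargs):
        with pytest.raises(ConfigError):
            DEConfig(**kwargs)

    def test_seeded_determinism(self):
        cfg = DEConfig(np_pop=6)
        a = init_population(TEMPLATE, BOUNDS, cfg, np.random.default_rng(5))
        b = init_population(TEMPLATE, BOUNDS, cfg, np.random.default_rng(5))
        assert a == b

    def test_population_size_and_bounds(self, rng):
        cfg = DEConfig(np_pop=4)
        for _ in range(250):  # 1000 members in total
            pop = init_population(TEMPLATE, BOUNDS, cfg, rng)
            assert len(pop) == 4
            for v in pop:
                for c, spec in zip(v.components, BOUNDS):
                    if spec.kind == "complex":
                        assert spec.lo <= c.real <= spec.hi
                        assert spec.lo <= c.imag <= spec.hi
                    else:
                        assert spec.lo <= c <= spec.hi


class TestMutate:
    def test_direct_arithmetic(self):
        # population engineered so the three non-target members are known
        kinds = ("complex",)
        pop = [
            ParameterVector([0j], kinds),        # target (excluded)
            ParameterVector([1 + 1j], kinds),
            ParameterVector([2 + 0j], kinds),
            ParameterVector([0 + 1j], kinds),
        ]
        # try seeds until r1,r2,r3 = members 1,2,3 in that order
        for seed in range(200):
            rng = np.random.default_rng(seed)
            probe = rng.choice(3, size=3, replace=False)
            if list(probe) == [0, 1, 2]:
                donor = de_mutate(pop, 0, 0.5, np.random.default_rng(seed))
                assert donor[0] == pytest.approx(2 + 0.5j)
                return
        pytest.fail("no seed ordered the donors as required")

    def test_f_zero_copies_r1(self, rng):
        kinds = ("real", "complex")
        pop = [
            ParameterVector([float(i), complex(i, -i)], kinds) for i in range(5)
        ]
        donor = de_mutate(pop, 2, 0.0, rng)
        assert donor in [pop[i] for i in (0, 1, 3, 4)]

    def test_indices_distinct_and_not_target(self, rng):
        kinds = ("real",)
        pop = [ParameterVector([float(i)], kinds) for i in range(6)]
        values = {float(i) for i in range(6)}
        for _ in range(10_000):
            donor = de_mutate(pop, 3, 0.0, rng)  # F=0 -> donor = x_r1
            assert donor[0] in values - {3.0}


class TestCrossover:
    def test_cr_one_copies_donor(self, rng):
        t = ParameterVector([1 + 1j, 2 + 2j, 0.5], TEMPLATE)
        d = ParameterVector([3 + 3j, 4 + 4j, -0.5], TEMPLATE)
        assert de_crossover(t, d, 1.0, rng) == d

    def test_cr_zero_single_donor_component(self, rng):
        t = ParameterVector([1 + 1j, 2 + 2j, 0.5], TEMPLATE)
        d = ParameterVector([3 + 3j, 4 + 4j, -0.5], TEMPLATE)
        for _ in range(50):
            trial = de_crossover(t, d, 0.0, rng)
            diff = sum(a != b for a, b in zip(trial.components, t.components))
            assert diff == 1

    def test_complex_components_move_as_units(self, rng):
        t = ParameterVector([1 + 1j, 2 + 2j, 0.5], TEMPLATE)
        d = ParameterVector([3 + 3j, 4 + 4j, -0.5], TEMPLATE)
        for _ in range(200):
            trial = de_crossover(t, d, 0.5, rng)
            for c, tc, dc in zip(trial.components[:2], t.components[:2], d.components[:2]):
                assert c == tc or c == dc

    def test_seeded_determinism(self):
        t = ParameterVector([1 + 1j, 2 + 2j, 0.5], TEMPLATE)
        d = ParameterVector([3 + 3j, 4 + 4j, -0.5], TEMPLATE)
        a = de_crossover(t, d, 0.5, np.random.default_rng(9))
        b = de_crossover(t, d, 0.5, np.random.default_rng(9))
        assert a == b


class TestOptimize:
    @staticmethod
    def sphere(center):
        def f(v):
            return sum(abs(c - z) ** 2 for c, z in zip(v.components, center))
        return f

    def test_sphere_two_complex_dims(self):
        """np=30, 200 generations reaches the optimum to < 1e-6."""
        kinds = ("complex", "complex")
        bounds = (ComponentSpec("complex", -5, 5),) * 2
        center = (1.5 - 2.5j, -3.0 + 0.5j)
        cfg = DEConfig(np_pop=30, generations=200, early_stop_patience=1000)
        best, best_f, _ = cvde_optimize(
            self.sphere(center), kinds, bounds, cfg, np.random.default_rng(0)
        )
        assert best_f < 1e-6

    def test_zero_generations_returns_initial_best(self, rng):
        kinds = ("real",)
        bounds = (ComponentSpec("real", -2, 2),)
        cfg = DEConfig(np_pop=10, generations=0)
        f = self.sphere((0.0,))
        best, best_f, history = cvde_optimize(f, kinds, bounds, cfg, rng)
        assert len(history) == 1
        assert best_f == pytest.approx(f(best))

    def test_history_monotone_nonincreasing(self, rng):
        kinds = ("complex", "real")
        bounds = (ComponentSpec("complex", -5, 5), ComponentSpec("real", -5, 5))
        cfg = DEConfig(np_pop=8, generations=40, early_stop_patience=1000)
        _, _, history = cvde_optimize(
            self.sphere((1 + 1j, 0.5)), kinds, bounds, cfg, rng
        )
        assert all(a >= b for a, b in zip(history, history[1:]))

    def test_separable_quadratic_median_error(self):
        """Median final error over 20 seeds beats 1e-4 at default budget."""
        kinds = ("real", "real", "real")
        bounds = (ComponentSpec("real", -4, 4),) * 3
        center = (0.7, -1.3, 2.1)
        cfg = DEConfig()  # defaults: np=40, 150 generations
        finals = []
        for seed in range(20):
            _, best_f, _ = cvde_optimize(
                self.sphere(center), kinds, bounds, cfg,
                np.random.default_rng(seed),
            )
            finals.append(best_f)
        assert np.median(finals) < 1e-4

    def test_initial_seed_vector_is_used(self, rng):
        kinds = ("real",)
        bounds = (ComponentSpec("real", -5, 5),)
        cfg = DEConfig(np_pop=5, generations=0)
        seed_vec = ParameterVector([1.234], kinds)
        best, best_f, _ = cvde_optimize(
            self.sphere((1.234,)), kinds, bounds, cfg, rng, initial=[seed_vec]
        )
        assert best_f == pytest.approx(0.0)
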