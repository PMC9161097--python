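"""TDCVSS evaluation: powers, slopes, fitness, simulation, rendering."""

import cmath

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tdgrn.data import ExpressionTimeSeries
from tdgrn.errors import DivergenceError, DomainError
from tdgrn.model import (
    DOMAIN_PENALTY,
    GeneModel,
    NetworkModel,
    TermFactor,
    complex_power,
    decoupled_sse,
    estimate_slopes,
    evaluate_rhs,
    parse_equation,
    render_equation,
    simulate_network,
)

IRMA_GENES = ("CBF1", "GAL4", "SWI5", "GAL80", "ASH1")

# the CBF1 equation printed for the IRMA "on" dataset
CBF1_MODEL = GeneModel(
    target_index=0,
    alpha=complex(14.3404, -4.3662),
    beta=complex(18.5262, 0.3632),
    production_term=(TermFactor(2, -0.4442, 0),),   # SWI5
    degradation_term=(TermFactor(4, 2.3205, 0),),   # ASH1
)


class TestComplexPower:
    @pytest.mark.parametrize(
        "z, g, expected",
        [
            (2 + 0j, 3.0, 8 + 0j),
            (1j, 2.0, -1 + 0j),
            (4 + 0j, 0.5, 2 + 0j),
        ],
    )
    def test_known_values(self, z, g, expected):
        assert complex_power(z, g) == pytest.approx(expected)

    def test_zero_base_positive_order(self):
        assert complex_power(0j, 1.5) == 0j

    def test_zero_base_nonpositive_order_raises(self):
        with pytest.raises(DomainError):
            complex_power(0j, -1.0)
        with pytest.raises(DomainError):
            complex_power(0j, 0.0)

    @settings(deadline=None, max_examples=200)
    @given(
        re=st.floats(-5, 5),
        im=st.floats(-5, 5),
        g=st.floats(-3, 3),
    )
    def test_modulus_identity(self, re, im, g):
        z = complex(re, im)
        if abs(z) < 1e-6:
            return
        assert abs(complex_power(z, g)) == pytest.approx(
            abs(z) ** g, rel=1e-9
        )


class TestEvaluateRhs:
    def test_identity_power_zero_degradation(self):
        m = GeneModel(0, 1 + 0j, 0j, (TermFactor(1, 1.0, 0),), (TermFactor(1, 0.0, 0),))
        assert evaluate_rhs(m, {(1, 0): 5 + 0j}) == pytest.approx(5 + 0j)

    def test_printed_equation_at_unit_expression(self):
        """With every gene at 1, each power is 1, so the RHS is alpha - beta."""
        values = {(2, 0): 1 + 0j, (4, 0): 1 + 0j}
        rhs = evaluate_rhs(CBF1_MODEL, values)
        assert rhs == pytest.approx(complex(-4.1858, -4.7294))

    def test_unit_bases_give_alpha_minus_beta(self):
        m = GeneModel(
            0, 2 + 1j, 1 + 0j, (TermFactor(1, 0.7, 0),), (TermFactor(2, -1.3, 1),)
        )
        vals = {(1, 0): 1 + 0j, (2, 1): 1 + 0j}
        assert evaluate_rhs(m, vals) == pytest.approx(1 + 1j)

    def test_real_inputs_match_real_ssystem(self, rng):
        """On real data with real constants it is the classic S-system RHS."""
        for _ in range(20):
            g1, g2, h1 = rng.uniform(-2, 2, size=3)
            a, b = rng.uniform(0.5, 3, size=2)
            x, y = rng.uniform(0.5, 2, size=2)
            m = GeneModel(
                0,
                complex(a, 0),
                complex(b, 0),
                (TermFactor(0, g1, 0), TermFactor(1, g2, 1)),
                (TermFactor(0, h1, 0),),
            )
            vals = {(0, 0): complex(x), (1, 1): complex(y)}
            expected = a * x**g1 * y**g2 - b * x**h1
            got = evaluate_rhs(m, vals)
            assert got.imag == pytest.approx(0.0, abs=1e-9)
            assert got.real == pytest.approx(expected, rel=1e-9)


class TestEstimateSlopes:
    def test_linear_series(self):
        data = ExpressionTimeSeries(
            ("a", "b"), np.arange(4.0), np.column_stack([np.arange(4.0), np.ones(4)])
        )
        assert np.allclose(estimate_slopes(data, 0), 1.0)

    def test_constant_series_zero(self):
        data = ExpressionTimeSeries(
            ("a", "b"), np.arange(5.0), np.column_stack([np.full(5, 2.0), np.arange(5.0)])
        )
        assert np.allclose(estimate_slopes(data, 0), 0.0)

    def test_quadratic_interior_exact(self):
        t = np.arange(5.0)
        data = ExpressionTimeSeries(
            ("a", "b"), t, np.column_stack([t**2, np.ones(5)])
        )
        slopes = estimate_slopes(data, 0)
        assert np.allclose(slopes[1:-1], 2 * t[1:-1])

    def test_nonuniform_grid_honored(self):
        t = np.array([0.0, 0.5, 1.5, 3.0, 5.0])
        data = ExpressionTimeSeries(
            ("a", "b"), t, np.column_stack([3.0 * t + 1.0, np.ones(5)])
        )
        assert np.allclose(estimate_slopes(data, 0), 3.0)


class TestDecoupledSse:
    @staticmethod
    def _naive_sse(model, data, slopes):
        """Per-time-point loop oracle re-evaluating the RHS term by term."""
        total = 0.0
        for t in range(model.max_lag, data.n_times):
            vals = {}
            for f in model.production_term + model.degradation_term:
                v = complex(data.values[t - f.lag, f.regulator])
                if abs(v) < 1e-6:
                    v = 1e-6 + 0j if v == 0 else v / abs(v) * 1e-6
                vals[(f.regulator, f.lag)] = v
            r = evaluate_rhs(model, vals) - slopes[t]
            total += abs(r) ** 2
        return total

    def test_matches_naive_loop(self, small_data, rng):
        slopes = estimate_slopes(small_data, 0)
        for _ in range(20):
            m = GeneModel(
                0,
                complex(*rng.uniform(-5, 5, 2)),
                complex(*rng.uniform(-5, 5, 2)),
                (TermFactor(1, rng.uniform(-2, 2), int(rng.integers(3))),),
                (
                    TermFactor(0, rng.uniform(-2, 2), 0),
                    TermFactor(2, rng.uniform(-2, 2), int(rng.integers(3))),
                ),
            )
            expected = self._naive_sse(m, small_data, slopes)
            assert decoupled_sse(m, small_data, slopes) == pytest.approx(
                expected, rel=1e-10
            )

    def test_zero_model_gives_slope_energy(self, small_data):
        slopes = estimate_slopes(small_data, 1)
        m = GeneModel(1, 0j, 0j, (TermFactor(0, 1.0, 1),), (TermFactor(2, 1.0, 0),))
        expected = float(np.sum(slopes[1:] ** 2))
        assert decoupled_sse(m, small_data, slopes) == pytest.approx(expected)

    def test_perfect_model_gives_zero(self):
        # dB/dt = A exactly, by construction of the slopes vector
        t = np.arange(8.0)
        a = 1.0 + 0.5 * np.sin(t)
        data = ExpressionTimeSeries(("A", "B"), t, np.column_stack([a, np.ones(8)]))
        m = GeneModel(1, 1 + 0j, 0j, (TermFactor(0, 1.0, 0),), (TermFactor(0, 0.0, 0),))
        assert decoupled_sse(m, data, a) == pytest.approx(0.0, abs=1e-18)

    def test_nonnegative(self, small_data, rng):
        slopes = estimate_slopes(small_data, 2)
        for _ in range(50):
            m = GeneModel(
                2,
                complex(*rng.uniform(-20, 20, 2)),
                complex(*rng.uniform(-20, 20, 2)),
                (TermFactor(int(rng.integers(3)), rng.uniform(-3, 3), 0),),
                (TermFactor(int(rng.integers(3)), rng.uniform(-3, 3), 1),),
            )
            assert decoupled_sse(m, small_data, slopes) >= 0.0


class TestSimulateNetwork:
    def test_zero_rates_constant(self):
        m0 = GeneModel(0, 0j, 0j, (TermFactor(1, 1.0, 0),), (TermFactor(1, 1.0, 0),))
        m1 = GeneModel(1, 0j, 0j, (TermFactor(0, 1.0, 0),), (TermFactor(0, 1.0, 0),))
        nm = NetworkModel(("a", "b"), (m0, m1))
        hist = np.array([[2.0, 3.0]])
        traj = simulate_network(nm, hist, 5, 0.1, substeps=4)
        assert traj.shape == (6, 2)
        assert np.allclose(traj, hist[0])

    def test_exponential_decay_converges_with_dt(self):
        """dX = -X integrates to e^{-t}; the Euler error halves with dt."""
        m = GeneModel(0, 0j, 1 + 0j, (TermFactor(0, 0.0, 0),), (TermFactor(0, 1.0, 0),))
        m2 = GeneModel(1, 0j, 0j, (TermFactor(0, 1.0, 0),), (TermFactor(0, 1.0, 0),))
        nm = NetworkModel(("x", "pad"), (m, m2))
        hist = np.array([[1.0, 1.0]])
        errors = []
        for substeps in (4, 8, 16, 32):
            traj = simulate_network(nm, hist, 10, 0.2, substeps=substeps)
            t = 0.2 * np.arange(11)
            errors.append(np.max(np.abs(traj[:, 0].real - np.exp(-t))))
        ratios = [errors[i] / errors[i + 1] for i in range(3)]
        assert all(r > 1.7 for r in ratios)  # first-order convergence

    def test_delayed_system_matches_independent_euler(self, rng):
        """Cross-check against a straightforward history-buffer integrator."""
        m0 = GeneModel(
            0, complex(0.8, 0.1), complex(0.9, 0.1),
            (TermFactor(1, 0.7, 1),), (TermFactor(0, 1.1, 0),),
        )
        m1 = GeneModel(
            1, complex(0.6, -0.1), complex(0.7, -0.1),
            (TermFactor(0, -0.5, 1),), (TermFactor(1, 0.9, 0),),
        )
        nm = NetworkModel(("a", "b"), (m0, m1))
        hist = np.array([[1.0, 1.2], [1.1, 1.0]])
        substeps = 5
        dt = 0.3
        traj = simulate_network(nm, hist, 8, dt, substeps=substeps)

        # independent re-implementation: flat list of fine-grid states
        def power(z, g):
            z = complex(z)
            if abs(z) < 1e-6:
                z = 1e-6 if z == 0 else z / abs(z) * 1e-6
            return cmath.exp(g * cmath.log(z))

        fine = [
            np.array([1.0 + (1.1 - 1.0) * k / substeps,
                      1.2 + (1.0 - 1.2) * k / substeps])
            for k in range(substeps + 1)
        ]
        fine = [v.astype(complex) for v in fine]
        h = dt / substeps
        for step in range(8 * substeps):
            cur = fine[-1]
            d0 = m0.alpha * power(fine[-1 - substeps][1], 0.7) - m0.beta * power(cur[0], 1.1)
            d1 = m1.alpha * power(fine[-1 - substeps][0], -0.5) - m1.beta * power(cur[1], 0.9)
            fine.append(cur + h * np.array([d0, d1]))
        expected = np.stack(fine[substeps::substeps])
        assert np.allclose(traj[1:], expected[1:], rtol=1e-12, atol=1e-12)

    def test_no_lag_equals_undelayed_euler(self, rng):
        """tau = 0 everywhere reduces to a plain Euler integrator."""
        m0 = GeneModel(0, 0.5 + 0j, 0.6 + 0j, (TermFactor(1, 0.8, 0),), (TermFactor(0, 1.0, 0),))
        m1 = GeneModel(1, 0.4 + 0j, 0.5 + 0j, (TermFactor(0, -0.6, 0),), (TermFactor(1, 1.2, 0),))
        nm = NetworkModel(("a", "b"), (m0, m1))
        hist = np.array([[1.0, 1.3]])
        substeps = 3
        dt = 0.25
        traj = simulate_network(nm, hist, 6, dt, substeps=substeps)

        state = np.array([1.0 + 0j, 1.3 + 0j])
        expected = [state.copy()]
        h = dt / substeps
        for step in range(6 * substeps):
            d0 = 0.5 * state[1] ** 0.8 - 0.6 * state[0] ** 1.0
            d1 = 0.4 * state[0] ** -0.6 - 0.5 * state[1] ** 1.2
            state = state + h * np.array([d0, d1])
            if (step + 1) % substeps == 0:
                expected.append(state.copy())
        assert np.allclose(traj, np.stack(expected), rtol=1e-12)

    def test_divergence_reports_step(self):
        m = GeneModel(0, 50 + 0j, 0j, (TermFactor(0, 2.0, 0),), (TermFactor(0, 0.0, 0),))
        pad = GeneModel(1, 0j, 0j, (TermFactor(0, 1.0, 0),), (TermFactor(0, 1.0, 0),))
        nm = NetworkModel(("x", "pad"), (m, pad))
        with pytest.raises(DivergenceError) as err:
            simulate_network(nm, np.array([[10.0, 1.0]]), 200, 1.0, substeps=1)
        assert err.value.step >= 1


class TestRendering:
    def test_printed_equation_format(self):
        text = render_equation(CBF1_MODEL, IRMA_GENES)
        assert "(14.3404-4.3662i)" in text
        assert "SWI5" in text and "ASH1" in text
        assert text.startswith("dCBF1/dt = ")
        assert "^-0.4442" in text  # explicit minus on negative orders
        assert "^2.3205" in text

    def test_lag_suffix_only_for_positive_lags(self):
        m = GeneModel(
            1, 1 + 1j, 2 - 1j, (TermFactor(0, 0.5, 2),), (TermFactor(2, 1.5, 0),)
        )
        text = render_equation(m, IRMA_GENES)
        assert "CBF1[t-2]" in text
        assert "SWI5[t-" not in text

    @pytest.mark.parametrize("lag", [0, 1, 3])
    def test_round_trip(self, lag, rng):
        for _ in range(10):
            m = GeneModel(
                int(rng.integers(5)),
                complex(*np.round(rng.uniform(-20, 20, 2), 4)),
                complex(*np.round(rng.uniform(-20, 20, 2), 4)),
                (
                    TermFactor(0, float(np.round(rng.uniform(-3, 3), 4)), lag),
                    TermFactor(3, float(np.round(rng.uniform(-3, 3), 4)), 1),
                ),
                (TermFactor(2, float(np.round(rng.uniform(-3, 3), 4)), 0),),
            )
            back = parse_equation(render_equation(m, IRMA_GENES), IRMA_GENES)
            assert back == m


class TestSerialization:
    def test_network_model_json_round_trip(self, tmp_path):
        nm = NetworkModel(
            ("a", "b"),
            (
                GeneModel(0, 1 + 2j, 3 - 4j, (TermFactor(1, 0.5, 1),), (TermFactor(0, 1.0, 0),)),
                GeneModel(1, 0.5 + 0j, 2 + 0j, (TermFactor(0, -0.7, 2),), (TermFactor(1, 1.2, 0),)),
            ),
        )
        path = tmp_path / "nm.json"
        nm.to_json(path)
        assert NetworkModel.from_json(path) == nm
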