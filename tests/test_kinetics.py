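"""Three-state model: rate matrices, eigen-solutions, closed forms, regimes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import siteexposure as se
from siteexposure.presets import KINETIC_PARAMS

P26_RATES = se.RateSet(k12=2.5, k21=100.0, k23=4.4, k32=0.66)


class TestRateSet:
    def test_kon_eff_identity(self):
        assert P26_RATES.kon_eff == pytest.approx(2.5 * 4.4 / 100.0, rel=1e-12)

    def test_regime_flag(self):
        assert P26_RATES.regime_valid
        assert not se.RateSet(k12=200.0, k21=100.0, k23=1.0, k32=1.0).regime_valid

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            se.RateSet(k12=-1.0, k21=100.0, k23=4.4, k32=0.66)

    def test_effective_roundtrip(self):
        eff = P26_RATES.effective()
        back = eff.to_rateset(k21=100.0)
        assert back.k23 == pytest.approx(P26_RATES.k23, rel=1e-12)


class TestRateMatrix:
    def test_full_columns_sum_to_zero(self):
        m = se.build_rate_matrix(P26_RATES, 10.0, "full")
        assert np.allclose(m.sum(axis=0), 0.0, atol=1e-12)

    def test_zero_concentration_has_no_binding(self):
        m = se.build_rate_matrix(P26_RATES, 0.0, "full")
        assert m[2, 1] == 0.0

    def test_binding_variant_third_column_zero(self):
        m = se.build_rate_matrix(P26_RATES, 10.0, "binding")
        assert np.all(m[:, 2] == 0.0)

    def test_release_variant_first_column_zero(self):
        m = se.build_rate_matrix(P26_RATES, 10.0, "release")
        assert np.all(m[:, 0] == 0.0)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            se.build_rate_matrix(P26_RATES, -1.0, "full")


class TestClosedForms:
    def test_high_to_low_derived_value(self):
        # frozen: 2.5 / (1 + 2.5/(0.11*10))
        assert se.k_high_to_low(2.5, 0.11, 10.0) == pytest.approx(0.7639, abs=1e-4)

    def test_high_to_low_matches_binding_eigenvalue(self):
        # oracle: slowest nonzero eigenvalue of the binding-variant matrix
        k12, kon_eff, conc, k21 = 2.5, 0.11, 10.0, 100.0
        rates = se.RateSet(k12=k12, k21=k21, k23=kon_eff * k21 / k12, k32=0.66)
        lam = np.linalg.eigvals(se.build_rate_matrix(rates, conc, "binding"))
        slowest = -sorted(lam.real, key=abs)[1]
        assert se.k_high_to_low(k12, kon_eff, conc) == pytest.approx(slowest, rel=0.02)

    def test_low_to_high_derived_value(self):
        assert se.k_low_to_high(1.03, 0.004, 0.9, 500.0) == pytest.approx(0.3197, abs=1e-4)

    def test_low_to_high_matches_release_eigenvalue(self):
        k32, kon_eff, k12, conc, k21 = 1.03, 0.004, 0.9, 500.0, 100.0
        rates = se.RateSet(k12=k12, k21=k21, k23=kon_eff * k21 / k12, k32=k32)
        lam = np.linalg.eigvals(se.build_rate_matrix(rates, conc, "release"))
        slowest = -sorted(lam.real, key=abs)[1]
        assert se.k_low_to_high(k32, kon_eff, k12, conc) == pytest.approx(slowest, rel=0.02)

    def test_saturation_and_linear_limits(self):
        assert se.k_high_to_low(2.5, 0.11, 1e9) == pytest.approx(2.5, rel=1e-6)
        c = 1e-6
        assert se.k_high_to_low(2.5, 0.11, c) == pytest.approx(0.11 * c, rel=1e-4)
        assert se.k_high_to_low(2.5, 0.11, 0.0) == 0.0

    def test_low_to_high_limits(self):
        assert se.k_low_to_high(0.66, 0.11, 2.5, 0.0) == 0.66
        # hyperbolic tail: ~ k32 * k12 / (kon_eff * c)
        c = 1e6
        assert se.k_low_to_high(0.66, 0.11, 2.5, c) == pytest.approx(
            0.66 * 2.5 / (0.11 * c), rel=1e-3
        )

    @given(
        k12=st.floats(0.01, 10.0),
        kon=st.floats(1e-4, 1.0),
        c1=st.floats(0.1, 1e4),
        factor=st.floats(1.01, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, k12, kon, c1, factor):
        c2 = c1 * factor
        assert se.k_high_to_low(k12, kon, c2) > se.k_high_to_low(k12, kon, c1)
        assert se.k_low_to_high(1.0, kon, k12, c2) < se.k_low_to_high(1.0, kon, k12, c1)


class TestPropagation:
    def test_identity_at_t0(self):
        m = se.build_rate_matrix(P26_RATES, 10.0, "full")
        x0 = se.StateDistribution(0.2, 0.3, 0.5)
        assert se.propagate_master_equation(m, x0, 0.0) == x0

    def test_binding_variant_absorbs_into_state3(self):
        m = se.build_rate_matrix(P26_RATES, 10.0, "binding")
        out = se.propagate_master_equation(m, se.StateDistribution(1, 0, 0), 1000.0)
        assert out.p3 == pytest.approx(1.0, abs=1e-6)

    def test_probability_conserved_at_all_times(self):
        m = se.build_rate_matrix(P26_RATES, 5.0, "full")
        x0 = se.StateDistribution(1, 0, 0)
        for t in [1e-4, 0.01, 0.5, 3.0, 100.0]:
            out = se.propagate_master_equation(m, x0, t)
            assert out.p1 + out.p2 + out.p3 == pytest.approx(1.0, abs=1e-9)

    def test_invalid_matrix_rejected(self):
        bad = np.ones((3, 3))
        with pytest.raises(ValueError):
            se.propagate_master_equation(bad, se.StateDistribution(1, 0, 0), 1.0)

    def test_matches_gillespie_occupancy(self):
        """Master-equation occupancy agrees with Monte-Carlo state fractions."""
        m = se.build_rate_matrix(P26_RATES, 10.0, "full")
        t = 1.0
        exact = se.propagate_master_equation(m, se.StateDistribution(1, 0, 0), t)
        rng = np.random.default_rng(7)
        n = 10_000
        counts = np.zeros(3)
        for _ in range(n):
            path = se.simulate_state_path(P26_RATES, 10.0, t + 1e-9, seed=rng)
            counts[path.states[np.searchsorted(path.entry_times, t, "right") - 1] - 1] += 1
        frac = counts / n
        for p_exact, p_mc in zip(exact.as_array(), frac):
            se_mc = np.sqrt(max(p_exact * (1 - p_exact), 1e-12) / n)
            assert abs(p_mc - p_exact) < 3 * se_mc + 1e-9


class TestSpectralSolution:
    def test_zero_eigenvalue_exact(self):
        m = se.build_rate_matrix(P26_RATES, 10.0, "binding")
        sol = se.spectral_solution(m)
        assert sol.eigenvalues[0] == 0.0

    def test_fast_eigenvalue_close_to_k21_plus_binding(self):
        conc = 10.0
        m = se.build_rate_matrix(P26_RATES, conc, "binding")
        sol = se.spectral_solution(m)
        expected = -(P26_RATES.k21 + P26_RATES.k23 * conc)
        assert sol.eigenvalues[1] == pytest.approx(expected, rel=0.03)

    def test_reconstruction_matches_propagation(self):
        m = se.build_rate_matrix(P26_RATES, 5.0, "full")
        x0 = se.StateDistribution(1, 0, 0)
        sol = se.spectral_solution(m, x0)
        for t in [0.0, 0.05, 1.0, 10.0]:
            direct = se.propagate_master_equation(m, x0, t).as_array()
            assert np.allclose(sol.evaluate(t), direct, atol=1e-8)

    def test_slow_eigenvalue_matches_closed_form_deep_in_regime(self):
        k12, k21, b = 0.01, 100.0, 50.0
        rates = se.RateSet(k12=k12, k21=k21, k23=1.0, k32=0.0)
        m = se.build_rate_matrix(rates, b, "binding")
        sol = se.spectral_solution(m)
        closed = k12 / (1 + k21 / b)
        assert -sol.eigenvalues[2] == pytest.approx(closed, rel=1e-3)

    def test_closed_form_oracle_equivalence_in_regime(self):
        """|lambda_+| matches k_high_to_low within 2% when k12 << k21, k23*c."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            k21 = rng.uniform(50, 500)
            b = rng.uniform(50, 500)  # k23 * conc
            k12 = rng.uniform(1e-3, min(k21, b) / 50)
            rates = se.RateSet(k12=k12, k21=k21, k23=1.0, k32=0.0)
            sol = se.spectral_solution(se.build_rate_matrix(rates, b, "binding"))
            kon_eff = k12 * 1.0 / k21
            closed = se.k_high_to_low(k12, kon_eff, b)
            assert -sol.eigenvalues[2] == pytest.approx(closed, rel=0.02)


class TestRegimeMetrics:
    def test_p26_printed_values(self):
        m = se.regime_metrics(KINETIC_PARAMS["P26"])
        assert m["KD_eff"] == pytest.approx(6.0, abs=0.01)
        assert m["c_cross"] == pytest.approx(22.7, abs=0.1)
        assert m["regime_ratio"] == pytest.approx(0.264, abs=0.001)

    def test_p31_printed_values(self):
        m = se.regime_metrics(KINETIC_PARAMS["P31"])
        assert m["KD_eff"] == pytest.approx(1037.0, rel=0.001)
        assert m["c_cross"] == pytest.approx(1125.0, rel=0.001)
        assert m["regime_ratio"] == pytest.approx(0.92, abs=0.01)

    def test_equal_rates_give_unit_ratio(self):
        m = se.regime_metrics(se.EffectiveParams(k12=0.5, k32=0.5, kon_eff=0.01))
        assert m["regime_ratio"] == 1.0

    def test_zero_kon_rejected(self):
        with pytest.raises(ValueError):
            se.regime_metrics(se.EffectiveParams(k12=1.0, k32=1.0, kon_eff=0.0))


def _stationary(m: np.ndarray) -> np.ndarray:
    w, v = np.linalg.eig(m)
    p = np.real(v[:, np.argmin(np.abs(w))])
    return p / p.sum()


def test_stationary_exposed_fraction_is_small():
    """Stationary occupancy of the exposed-unbound intermediate stays below
    k12/k21 at any concentration; at the inner-region construct parameters
    over their concentration grids the site is exposed < 1% of the time."""
    for conc in [1.0, 10.0, 100.0]:
        p = _stationary(se.build_rate_matrix(P26_RATES, conc, "full"))
        assert p[1] < P26_RATES.k12 / P26_RATES.k21
    for label in ("P31", "P36"):
        rates = KINETIC_PARAMS[label].to_rateset(100.0)
        for conc in [50.0, 500.0]:
            p = _stationary(se.build_rate_matrix(rates, conc, "full"))
            assert p[1] < 0.01
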