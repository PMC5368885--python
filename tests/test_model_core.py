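"""Core biochemistry: temperature responses, light response, FvCB rates."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leafphys.model_core import (
    BiochemParams,
    KineticConstants,
    NitrogenRelations,
    arrhenius,
    an_cc,
    gamma_star,
    j_from_light,
    nrh_a_ci,
    params_from_nitrogen,
    peaked_arrhenius,
    rates_at_t,
    R_GAS,
)


class TestTemperatureResponses:
    def test_arrhenius_reference_temperature(self):
        assert arrhenius(1.0, 46390.0, 25.0) == 1.0

    def test_arrhenius_zero_activation_energy(self):
        assert arrhenius(2.0, 0.0, 40.0) == 2.0

    def test_arrhenius_known_value(self):
        # independent evaluation: exp(10*46390 / (298*8.314*308)) = 1.83661
        expected = np.exp(10 * 46390 / (298 * R_GAS * 308))
        assert arrhenius(1.0, 46390.0, 35.0) == pytest.approx(expected)
        assert arrhenius(1.0, 46390.0, 35.0) == pytest.approx(1.837, abs=5e-4)

    def test_peaked_arrhenius_known_value(self):
        # direct evaluation of the peaked response for mesophyll conductance
        assert peaked_arrhenius(1.0, 49600, 1400, 437400, 30.0) == pytest.approx(
            1.385, abs=5e-4)

    @settings(derandomize=True, max_examples=50)
    @given(x25=st.floats(0.01, 1e3), e=st.floats(0, 2e5),
           s=st.floats(100, 2000), d=st.floats(1e4, 6e5))
    def test_identity_at_25C_for_all_parameters(self, x25, e, s, d):
        assert arrhenius(x25, e, 25.0) == pytest.approx(x25, rel=1e-12)
        assert peaked_arrhenius(x25, e, s, d, 25.0) == pytest.approx(x25, rel=1e-12)

    def test_large_deactivation_reduces_to_plain_arrhenius(self):
        plain = arrhenius(1.0, 49600.0, 38.0)
        peaked = peaked_arrhenius(1.0, 49600.0, 1400.0, 5e6, 38.0)
        assert peaked == pytest.approx(plain, rel=1e-9)

    def test_peaked_log_space_no_overflow(self):
        # entropy/deactivation combinations that overflow a naive exp
        value = peaked_arrhenius(1.0, 5e4, 3e4, 5e5, 45.0)
        assert np.isfinite(value) and value > 0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            arrhenius(np.nan, 46390.0, 25.0)


class TestGammaStar:
    def test_reference_conditions(self, kinetics):
        assert gamma_star(25.0, 210.0, kinetics) == pytest.approx(
            kinetics.gamma_star25)

    def test_proportional_to_oxygen(self, kinetics):
        assert gamma_star(25.0, 105.0, kinetics) == pytest.approx(
            kinetics.gamma_star25 / 2)

    def test_strictly_increasing_in_temperature(self, kinetics):
        t = np.linspace(5, 40, 50)
        g = gamma_star(t, 210.0, kinetics)
        assert np.all(np.diff(g) > 0)


class TestLightResponse:
    def test_dark(self):
        assert j_from_light(0.0, 0.3, 140.0) == 0.0

    def test_saturation(self):
        assert j_from_light(1e9, 0.3, 140.0) == pytest.approx(140.0, rel=1e-3)

    def test_known_value_quadratic_root(self):
        # lower root of 0.8 J^2 - (0.309*200 + 141) J + 0.309*200*141 = 0
        b, c = 0.309 * 200 + 141, 0.309 * 200 * 141
        expected = (b - np.sqrt(b * b - 4 * 0.8 * c)) / (2 * 0.8)
        assert j_from_light(200, 0.309, 141, 0.8) == pytest.approx(expected)
        assert j_from_light(200, 0.309, 141, 0.8) == pytest.approx(54.8, abs=0.05)

    def test_theta_to_zero_gives_rectangular_hyperbola(self):
        iinc, k, jmax = 600.0, 0.25, 150.0
        expected = k * iinc * jmax / (k * iinc + jmax)
        assert j_from_light(iinc, k, jmax, theta=1e-7) == pytest.approx(
            expected, rel=1e-6)

    @settings(derandomize=True, max_examples=50)
    @given(k=st.floats(0.1, 0.4), jmax=st.floats(50, 300),
           theta=st.floats(0.05, 0.95))
    def test_concave_nondecreasing_bounded(self, k, jmax, theta):
        iinc = np.linspace(0, 3000, 200)
        j = j_from_light(iinc, k, jmax, theta)
        assert np.all(j >= 0) and np.all(j < jmax + 1e-9)
        dj = np.diff(j)
        assert np.all(dj >= -1e-9)          # nondecreasing
        assert np.all(np.diff(dj) <= 1e-9)  # concave


class TestAnCc:
    def test_compensation_point(self, n85_biochem, kinetics):
        rates = rates_at_t(n85_biochem, 25.0, kinetics)
        ac, aj, an, _ = an_cc(rates.gamma_star, rates, j=120.0)
        assert ac == pytest.approx(-rates.rd)
        assert aj == pytest.approx(-rates.rd)
        assert an == pytest.approx(-rates.rd)

    def test_asymptotes(self, n85_biochem, kinetics):
        rates = rates_at_t(n85_biochem, 25.0, kinetics)
        ac, aj, _, _ = an_cc(1e9, rates, j=120.0)
        assert ac == pytest.approx(rates.vcmax - rates.rd, rel=1e-6)
        assert aj == pytest.approx(120.0 / 4 - rates.rd, rel=1e-6)

    def test_reference_parameter_evaluation(self, n85_biochem, kinetics):
        # hand evaluation of both branches at Cc = 250 with the well-watered
        # high-N parameter values at 25 °C
        rates = rates_at_t(n85_biochem, 25.0, kinetics)
        cc, j = 250.0, 120.0
        ac_hand = (cc - 37.43) * 109.0 / (cc + 272.4 * (1 + 210 / 165.8)) - 0.867
        aj_hand = (cc - 37.43) * j / (4 * cc + 8 * 37.43) - 0.867
        ac, aj, an, lim = an_cc(cc, rates, j=j)
        assert ac == pytest.approx(ac_hand, rel=1e-12)
        assert aj == pytest.approx(aj_hand, rel=1e-12)
        assert an == pytest.approx(min(ac_hand, aj_hand))
        assert lim == ("Rubisco" if ac_hand < aj_hand else "electron-transport")

    def test_aj_limited_at_low_light_all_reference_treatments(self):
        """At limiting light every reference leaf is electron-transport-limited."""
        from leafphys import reference, solve_leaf
        from leafphys.model_core import Environment

        for water in reference.WATERS:
            for nitrogen in reference.NITROGENS:
                sol = solve_leaf(
                    Environment(iinc=150, ca=370, t=20, vpd=1.0),
                    reference.reference_biochem(water, nitrogen),
                    reference.reference_stomatal(water, nitrogen))
                assert sol.limitation == "electron-transport"


class TestNrhACi:
    def test_ci_star_forces_minus_rd(self):
        gstar, rd, gm = 37.43, 0.7, 0.2
        ci = gstar - rd / gm
        assert nrh_a_ci(ci, 30.0, 2 * gstar, rd, gm, gstar) == pytest.approx(
            -rd, abs=1e-10)

    def test_infinite_gm_reduces_to_ci_based_hyperbola(self):
        ci, x1, x2, rd, gstar = 300.0, 30.0, 2 * 37.43, 0.7, 37.43
        expected = (ci - gstar) * x1 / (ci + x2) - rd
        assert nrh_a_ci(ci, x1, x2, rd, 1e9, gstar) == pytest.approx(
            expected, rel=1e-6)

    @staticmethod
    def _bisection_oracle(ci, x1, x2, rd, gm, gstar, iters=100):
        """Bisection on Cc for the implicit system A=f(Cc), A=gm(Ci-Cc)."""
        def h(cc):
            return (cc - gstar) * x1 / (cc + x2) - rd - gm * (ci - cc)
        lo, hi = 0.0, max(ci + rd / gm, gstar) + 1.0
        for _ in range(iters):
            mid = 0.5 * (lo + hi)
            if h(mid) < 0:
                lo = mid
            else:
                hi = mid
        cc = 0.5 * (lo + hi)
        return gm * (ci - cc)

    def test_example_against_bisection_oracle(self):
        a = nrh_a_ci(300.0, 30.0, 2 * 37.43, 0.7, 0.2, 37.43)
        oracle = self._bisection_oracle(300.0, 30.0, 2 * 37.43, 0.7, 0.2, 37.43)
        assert a == pytest.approx(oracle, abs=1e-9)

    def test_oracle_equivalence_random_draws(self, rng):
        """Closed-form lower root equals the implicit-system bisection."""
        for _ in range(1000):
            ci = rng.uniform(40, 1200)
            x1 = rng.uniform(5, 150)
            gstar = rng.uniform(20, 60)
            x2 = rng.uniform(0.5, 700)
            rd = rng.uniform(0.1, 2.0)
            gm = rng.uniform(0.02, 0.5)
            a = nrh_a_ci(ci, x1, x2, rd, gm, gstar)
            oracle = self._bisection_oracle(ci, x1, x2, rd, gm, gstar)
            assert abs(a - oracle) < 1e-8


class TestNitrogenRelations:
    def test_base_nitrogen_gives_zero_capacity(self):
        rel = NitrogenRelations()
        with pytest.warns(UserWarning):
            biochem, _ = params_from_nitrogen(rel.nb, rel)
        assert biochem.vcmax25 == 0.0
        assert biochem.jmax25 == 0.0

    def test_published_capacity_slopes(self):
        # one g N m^-2 above the base content gives the published slopes
        rel = NitrogenRelations(chi_v=62.0, chi_j=93.0, nb=0.35)
        biochem, _ = params_from_nitrogen(1.35, rel)
        assert biochem.vcmax25 == pytest.approx(62.0)
        assert biochem.jmax25 == pytest.approx(93.0)

    def test_invalid_nitrogen_rejected(self):
        with pytest.raises(ValueError):
            params_from_nitrogen(-0.1, NitrogenRelations())
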