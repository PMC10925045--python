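"""Plume-model tests: worked constants, oracle equivalence, analytic limits."""

import math
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aeroplume import (
    AirportRecord,
    MIXING_LAYER_COASTAL_M,
    MIXING_LAYER_INLAND_M,
    PlumeParams,
    average_concentration,
    concentration_at,
    run_concentration_table,
    select_mixing_layer,
    vertical_term,
)
from _oracles import concentration_oracle, mean_concentration_oracle, vertical_term_oracle


class TestVerticalTerm:
    def test_default_value_matches_oracle(self, default_params):
        p = vertical_term(default_params)
        assert p == pytest.approx(vertical_term_oracle(2.0, 1.0, 900.0, 2), rel=1e-14)
        # reflections underflow at l=900, delta_z=1: only 2 exp(-h^2/2) remains
        assert p == pytest.approx(2.0 * math.exp(-2.0), rel=1e-12)

    def test_ground_level_source_far_lid_gives_two(self):
        p = vertical_term(PlumeParams(h=0.0, mixing_layer=1e9))
        assert p == pytest.approx(2.0, abs=1e-15)

    def test_wide_vertical_diffusion_limit(self):
        # exponents scale as 1/delta_z^2, so P approaches 2 + 2N from below
        p6 = vertical_term(PlumeParams(delta_z=1e6, h=2.0, mixing_layer=900.0))
        p7 = vertical_term(PlumeParams(delta_z=1e7, h=2.0, mixing_layer=900.0))
        assert p6 < p7 <= 2.0 + 2 * 2
        assert p7 == pytest.approx(2.0 + 2 * 2, abs=1e-6)

    def test_reflection_convergence_beyond_two(self, default_params):
        p2 = vertical_term(default_params)
        for n in (3, 5, 10):
            pn = vertical_term(replace(default_params, n_reflections=n))
            assert abs(pn - p2) < 1e-15

    def test_bounded_by_two_plus_two_n(self):
        for n in (0, 1, 2, 5):
            p = vertical_term(PlumeParams(h=0.0, mixing_layer=1e-6, n_reflections=n))
            assert 0.0 < p <= 2.0 + 2 * n + 1e-12

    def test_literal_exp_of_sum_mode_differs_when_reflections_matter(self):
        base = PlumeParams(h=2.0, delta_z=10.0, mixing_layer=30.0)
        literal = replace(base, literal_exp_of_sum=True)
        assert vertical_term(base) != pytest.approx(vertical_term(literal), rel=1e-6)


class TestConcentration:
    def test_prefactor_cancellation(self, default_params):
        # E chosen as 2 pi mu dy dz so C(y=0) equals the vertical term itself
        E = 2.0 * math.pi * 3.7 * 1.33 * 1.0
        c = concentration_at(E, 0.0, default_params)
        assert c == pytest.approx(vertical_term(default_params), rel=1e-12)

    def test_zero_emission_gives_zero(self, default_params):
        assert concentration_at(0.0, 1.0, default_params) == 0.0
        assert average_concentration(0.0, default_params) == 0.0

    def test_unit_flow_offset_one(self, default_params):
        c = concentration_at(1.0, 1.0, default_params)
        assert c == pytest.approx(
            concentration_oracle(1.0, 1.0, 3.7, 1.33, 1.0, 2.0, 900.0, 2), rel=1e-13
        )
        assert c == pytest.approx(6.5989e-3, rel=1e-4)

    def test_negative_emission_rejected(self, default_params):
        with pytest.raises(ValueError, match="non-negative"):
            concentration_at(-1.0, 0.0, default_params)

    def test_mean_over_receptors_default_constant(self, default_params):
        k = average_concentration(1.0, default_params)
        oracle = mean_concentration_oracle(1.0, (1.0, 2.0, 3.0), 3.7, 1.33, 1.0, 2.0, 900.0, 2)
        assert k == pytest.approx(oracle, rel=1e-13)
        assert k == pytest.approx(3.3709e-3, rel=1e-4)

    def test_linearity_exact_for_power_of_two(self, default_params):
        c1 = average_concentration(7.3, default_params)
        c2 = average_concentration(2.0 * 7.3, default_params)
        assert c2 == 2.0 * c1

    def test_monotone_decreasing_in_offset_wind_and_height(self):
        p = PlumeParams()
        cs = [concentration_at(1.0, y, p) for y in (0.0, 1.0, 2.0, 3.0, 5.0)]
        assert all(a > b for a, b in zip(cs, cs[1:]))
        winds = [concentration_at(1.0, 1.0, replace(p, mu=m)) for m in (1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(winds, winds[1:]))
        heights = [concentration_at(1.0, 1.0, replace(p, h=h)) for h in (0.0, 2.0, 10.0)]
        assert all(a > b for a, b in zip(heights, heights[1:]))

    def test_upper_bound(self, default_params):
        E = 13.7
        bound = E * (2 + 2 * 2) / (2 * math.pi * 3.7 * 1.33 * 1.0)
        assert average_concentration(E, default_params) <= bound

    def test_unit_scale_multiplies_output(self, default_params):
        base = average_concentration(1.0, default_params)
        scaled = average_concentration(1.0, replace(default_params, unit_scale=1e6))
        assert scaled == pytest.approx(1e6 * base, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.0, 100.0), st.floats(0.0, 50.0))
    def test_linearity_property(self, E, a):
        p = PlumeParams()
        assert average_concentration(a * E, p) == pytest.approx(
            a * average_concentration(E, p), rel=1e-12, abs=1e-300
        )


def test_oracle_equivalence_random_draws():
    """Implementation matches an independently coded direct evaluation
    within 1e-12 relative over 1,000 random parameter draws."""
    rng = np.random.default_rng(20240309)
    worst = 0.0
    for _ in range(1000):
        mu = rng.uniform(0.5, 10.0)
        dy = rng.uniform(0.3, 3.0)
        dz = rng.uniform(0.3, 3.0)
        h = rng.uniform(0.0, 10.0)
        l = rng.uniform(20.0, 2000.0)
        n = int(rng.integers(0, 5))
        E = rng.uniform(0.0, 100.0)
        y = rng.uniform(-5.0, 5.0)
        params = PlumeParams(mu=mu, delta_y=dy, delta_z=dz, h=h, mixing_layer=l,
                             n_reflections=n)
        ours = concentration_at(E, y, params)
        ref = concentration_oracle(E, y, mu, dy, dz, h, l, n)
        if ref != 0.0:
            worst = max(worst, abs(ours - ref) / abs(ref))
        else:
            assert ours == 0.0
    assert worst < 1e-12


class TestMixingLayer:
    def test_coastal_and_inland_defaults(self):
        assert select_mixing_layer(AirportRecord("CAN", coastal=True)) == 900.0
        assert select_mixing_layer(AirportRecord("SIA", coastal=False)) == 1100.0
        assert MIXING_LAYER_COASTAL_M == 900.0 and MIXING_LAYER_INLAND_M == 1100.0

    def test_override_wins(self):
        rec = AirportRecord("PEK", coastal=False, mixing_layer_override=1000.0)
        assert select_mixing_layer(rec) == 1000.0


class TestConcentrationTable:
    def _emissions(self, airports, flows):
        return pd.DataFrame(
            {
                "year": [2020] * len(airports),
                "month": [6] * len(airports),
                "airport": airports,
                "flow_g_per_s": flows,
            }
        )

    def test_empty_input_empty_output(self):
        table = run_concentration_table(self._emissions([], []), [])
        assert len(table) == 0

    def test_inland_uses_1100_and_nearly_equals_coastal(self):
        em = self._emissions(["III"], [1.0])
        inland = run_concentration_table(em, [AirportRecord("III", coastal=False)])
        expected = average_concentration(1.0, PlumeParams(mixing_layer=1100.0))
        assert inland["concentration_ugm3"].iloc[0] == expected
        coastal_val = average_concentration(1.0, PlumeParams(mixing_layer=900.0))
        # reflections underflow at either lid height: values agree to > 6 sig figs
        assert inland["concentration_ugm3"].iloc[0] == pytest.approx(coastal_val, rel=1e-6)

    def test_two_regimes_positive_finite(self):
        em = self._emissions(["AAA", "BBB"], [2.5, 2.5])
        table = run_concentration_table(
            em, [AirportRecord("AAA", coastal=True), AirportRecord("BBB", coastal=False)]
        )
        assert (table["concentration_ugm3"] > 0).all()
        assert np.isfinite(table["concentration_ugm3"]).all()

    def test_unknown_airport_named_in_error(self):
        em = self._emissions(["ZZZ"], [1.0])
        with pytest.raises(KeyError, match="ZZZ"):
            run_concentration_table(em, [AirportRecord("AAA", coastal=True)])
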