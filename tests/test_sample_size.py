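"""Required-events / required-n calculations and binary power."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from multiarm.sample_size import (binary_power, event_probability,
                                  required_events, required_n,
                                  size_time_to_event)


class TestRequiredEvents:
    def test_schoenfeld_reproduces_the_original_design(self):
        # hr 0.75, two-sided 5%, 80% power: 379.3 events unrounded
        assert required_events(0.75, 0.05, 0.80, "schoenfeld") in (379, 380)

    def test_schoenfeld_unrounded_value(self):
        z = 1.9599639845400545 + 0.8416212335729143
        d = 4 * z**2 / math.log(0.75) ** 2
        assert d == pytest.approx(379.35, abs=0.01)

    def test_amended_design_event_count_bracket(self):
        # the 232-event target of the added comparison sits between the
        # schoenfeld and freedman counts at hr ~ 0.69
        assert required_events(0.69, method="schoenfeld") == 229
        assert required_events(0.69, method="freedman") == 234
        # at the exact median ratio 4.5/6.5 schoenfeld gives 232.2
        assert required_events(4.5 / 6.5, method="schoenfeld") == 233

    def test_null_effect_raises(self):
        with pytest.raises(ValueError, match="superiority"):
            required_events(1.0)
        with pytest.raises(ValueError):
            required_events(-0.2)

    def test_vanishing_effect_hits_cap(self):
        with pytest.raises(ValueError, match="cap"):
            required_events(0.99999)

    def test_gsd_inflation_scales_events(self):
        base = required_events(0.75)
        assert required_events(0.75, gsd_inflation=1.1) == math.ceil(base / 1 * 1.1) or \
            required_events(0.75, gsd_inflation=1.1) >= base

    @given(hr=st.floats(0.5, 0.9))
    def test_freedman_dominates_schoenfeld_below_one(self, hr):
        assert (required_events(hr, method="freedman")
                >= required_events(hr, method="schoenfeld"))

    @given(hr1=st.floats(0.4, 0.95), hr2=st.floats(0.4, 0.95))
    def test_events_decrease_with_stronger_effect(self, hr1, hr2):
        lo, hi = sorted((hr1, hr2))
        assert required_events(lo) <= required_events(hi)


class TestEventProbability:
    def test_original_design_value(self):
        assert event_probability(4.5, 4, 4) == pytest.approx(0.597, abs=5e-4)

    def test_monte_carlo_oracle(self, rng):
        # 1e6 exponential event times with uniform entry over the accrual window
        median, a, f = 4.5, 4.0, 4.0
        lam = math.log(2) / median
        t = rng.exponential(1 / lam, size=1_000_000)
        entry = rng.uniform(0, a, size=1_000_000)
        observed = t <= (a + f - entry)
        est = observed.mean()
        se = math.sqrt(est * (1 - est) / 1_000_000)
        assert event_probability(median, a, f) == pytest.approx(est, abs=3 * se)

    def test_infinite_median_limit(self):
        assert event_probability(1e12, 4, 4) == pytest.approx(0.0, abs=1e-9)

    def test_zero_accrual_limit_is_fixed_followup(self):
        m, f = 4.5, 4.0
        closed = 1 - 2 ** (-f / m)
        assert event_probability(m, 1e-9, f) == pytest.approx(closed, rel=1e-6)

    def test_domain_errors(self):
        for bad in ((0, 4, 4), (4.5, 0, 4), (4.5, 4, -1)):
            with pytest.raises(ValueError):
                event_probability(*bad)


class TestRequiredN:
    def test_original_design_total_within_five_percent(self):
        res = size_time_to_event(hr=0.75, control_median=4.5, experimental_median=6.0,
                                 accrual_years=4, min_followup_years=4,
                                 dropout_prob=0.05)
        assert 700 <= res.required_n_total <= 760
        assert abs(res.required_n_total - 754) / 754 < 0.05
        assert res.required_n_total >= res.required_events

    def test_amended_design_per_arm_within_five_percent(self):
        res = size_time_to_event(control_median=4.5, experimental_median=6.5,
                                 accrual_years=2.5, min_followup_years=3.5,
                                 dropout_prob=0.05)
        per_arm = res.required_n_per_arm[0]
        assert abs(per_arm - 274) / 274 < 0.05

    def test_no_dropout_certain_events_gives_n_equal_events(self):
        res = required_n(100, 1.0, 1.0, dropout_prob=0.0)
        assert res.required_n_total == 100
        assert res.dropout_inflation == 1.0

    def test_zero_event_probability_rejected(self):
        with pytest.raises(ValueError):
            required_n(100, 0.0, 0.5)

    def test_itemised_inflations_reported(self):
        res = size_time_to_event(hr=0.75, control_median=4.5, experimental_median=6.0,
                                 accrual_years=4, min_followup_years=4,
                                 dropout_prob=0.05, gsd_inflation=1.0078)
        assert res.dropout_inflation == pytest.approx(1 / 0.95)
        assert res.gsd_inflation == pytest.approx(1.0078)


class TestBinaryPower:
    def test_design_scenarios_give_ninety_percent(self):
        assert 0.885 <= binary_power(260, 0.10, 0.20).power <= 0.905
        assert 0.885 <= binary_power(260, 0.20, 0.325).power <= 0.905

    def test_null_case_returns_test_size(self):
        res = binary_power(260, 0.2, 0.2)
        assert res.null_case
        assert res.power == pytest.approx(0.05, abs=0.005)

    def test_exact_enumeration_matches_simulation_within_two_mc_se(self):
        for p0, p1 in ((0.10, 0.20), (0.20, 0.325)):
            enum = binary_power(260, p0, p1, test="exact_enum").power
            sim = binary_power(260, p0, p1, test="exact_sim", reps=100_000, seed=99)
            assert abs(enum - sim.power) <= 2 * sim.mc_se

    def test_normal_approximation_close_to_exact_power(self):
        # the pooled normal approximation understates the exact power of the
        # pooled z-test by a few parts per thousand at design-sized n
        for p0, p1 in ((0.10, 0.20), (0.20, 0.325)):
            ana = binary_power(260, p0, p1, test="pooled_z").power
            enum = binary_power(260, p0, p1, test="exact_enum").power
            assert abs(ana - enum) < 0.01

    @given(n=st.sampled_from([50, 150, 300, 600]))
    def test_power_increases_with_n(self, n):
        assert (binary_power(2 * n, 0.1, 0.2).power
                >= binary_power(n, 0.1, 0.2).power - 1e-12)

    @given(p1=st.floats(0.21, 0.5))
    def test_power_increases_with_effect(self, p1):
        assert (binary_power(200, 0.1, p1).power
                >= binary_power(200, 0.1, 0.2).power - 1e-12)

    def test_unpooled_variant_close_to_pooled(self):
        a = binary_power(260, 0.1, 0.2, test="pooled_z").power
        b = binary_power(260, 0.1, 0.2, test="unpooled_z").power
        assert abs(a - b) < 0.03
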