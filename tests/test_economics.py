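import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from divempa import economics as econ
from divempa.economics import (
    EconomicsError,
    WTPParams,
    attribute_components,
    baseline_surplus_and_revenue,
    choke_price,
    delta_consumer_surplus,
    delta_dive_revenue,
    delta_dives,
    demand_from_equilibrium,
    estimate_global_dives,
    fee_revenue,
    split_surplus_by_origin,
    wtp_shift,
)


def triangle_cs_oracle(Q_star, P_star, C, sum_wtp, fee):
    """Geometric consumer-surplus change of the shifted linear demand system.

    CS is the area of the triangle between the (shifted) inverse demand line
    and the horizontal price paid, built explicitly as a polygon.
    """
    b = Q_star / (C - P_star)
    choke_shifted = C + sum_wtp
    paid = P_star + fee
    q_new = max(b * (choke_shifted - paid), 0.0)
    tri_new = (Polygon([(0, paid), (0, choke_shifted), (q_new, paid)]).area
               if q_new > 0 else 0.0)
    tri_base = Polygon([(0, P_star), (0, C), (Q_star, P_star)]).area
    return tri_new - tri_base


class TestChokePrice:
    def test_nearest_rank_oracle(self):
        assert choke_price(np.arange(1, 101), 99) == 99.0
        assert choke_price(np.arange(1, 101), 100) == 100.0

    def test_degenerate_equal_prices_rejected_downstream(self):
        c = choke_price([60.0, 60.0, 60.0])
        with pytest.raises(EconomicsError):
            demand_from_equilibrium(100.0, 60.0, c)

    def test_needs_two_observations(self):
        with pytest.raises(EconomicsError):
            choke_price([60.0])


class TestDemand:
    def test_anchored_at_equilibrium_and_choke(self):
        a, b = demand_from_equilibrium(1000.0, 58.75, 220.0)
        assert b == pytest.approx(6.2016, abs=1e-4)
        assert a == pytest.approx(1364.3, abs=0.1)
        assert a - b * 58.75 == pytest.approx(1000.0)   # Q(P*) = Q*
        assert a - b * 220.0 == pytest.approx(0.0, abs=1e-9)  # Q(C) = 0

    def test_degenerate_market(self):
        assert demand_from_equilibrium(0.0, 50.0, 40.0) == (0.0, 0.0)

    def test_choke_must_exceed_price(self):
        with pytest.raises(EconomicsError):
            demand_from_equilibrium(10.0, 60.0, 60.0)


class TestWTP:
    def test_name_effect_only(self):
        assert wtp_shift(0.0, 0.0, True, WTPParams(), 58.75) == \
            pytest.approx(0.04 * 58.75)

    def test_all_zero_outside_mpa(self):
        assert wtp_shift(0.0, 0.0, False, WTPParams(), 58.75) == 0.0

    def test_biomass_response_saturates_at_cap(self):
        p = WTPParams()
        huge = wtp_shift(1e9, 0.0, False, p, 100.0)
        assert huge == pytest.approx(p.biomass_cap * 100.0, rel=1e-6)
        assert wtp_shift(2.0, 0.0, False, p, 100.0) < p.biomass_cap * 100.0

    def test_monotone_in_both_gains(self):
        p = WTPParams()
        lo = wtp_shift(0.5, 0.01, True, p, 100.0)
        hi = wtp_shift(1.5, 0.05, True, p, 100.0)
        assert hi > lo

    def test_invalid_inputs_rejected(self):
        with pytest.raises(EconomicsError):
            wtp_shift(-1.5, 0.0, True, WTPParams(), 100.0)
        with pytest.raises(EconomicsError):
            WTPParams(name_effect=-0.1).validate()


class TestDeltaDives:
    def test_neutral_fee_zeroes_change(self):
        assert delta_dives(1000.0, 58.75, 220.0, 53.0, 53.0) == 0.0

    def test_wtp_shift_hand_value(self):
        assert delta_dives(1000.0, 58.75, 220.0, 53.0, 0.0) == \
            pytest.approx(328.68, abs=0.01)

    def test_pure_fee_hand_value(self):
        assert delta_dives(1000.0, 58.75, 220.0, 0.0, 10.0) == \
            pytest.approx(-62.02, abs=0.01)

    def test_clamped_at_zero_dives(self):
        dQ = delta_dives(1000.0, 58.75, 220.0, 0.0, 1e6)
        assert dQ == -1000.0


class TestRevenueAndSurplus:
    def test_industry_revenue(self):
        assert delta_dive_revenue(58.75, 0.0) == 0.0
        assert delta_dive_revenue(58.75, 328.68) == pytest.approx(19310, abs=1)
        assert np.sign(delta_dive_revenue(58.75, -5.0)) == -1

    def test_fee_revenue(self):
        assert fee_revenue(0.0, 1000.0, 10.0) == 0.0
        assert fee_revenue(53.0, 1000.0, 0.0) == 53000.0

    def test_fee_revenue_concave_with_closed_form_argmax(self):
        """Grid search matches F = (C - P* + SumWTP) / 2 for the quadratic."""
        Q, P, C, wtp = 1000.0, 58.75, 220.0, 53.0
        fine = np.linspace(0, (C - P) + wtp, 100001)
        rev = fee_revenue(fine, Q, delta_dives(Q, P, C, wtp, fine))
        argmax = fine[np.argmax(rev)]
        assert argmax == pytest.approx((C - P + wtp) / 2, abs=0.01)
        coarse = np.linspace(0, (C - P) + wtp, 2001)
        rev_c = fee_revenue(coarse, Q, delta_dives(Q, P, C, wtp, coarse))
        assert (np.diff(rev_c, 2) < 1e-9).all()

    def test_consumer_surplus_hand_values(self):
        assert delta_consumer_surplus(1000.0, 58.75, 220.0, 0.0) == pytest.approx(0.0)
        assert delta_consumer_surplus(1000.0, 58.75, 220.0, 328.68) == \
            pytest.approx(61710, abs=2)
        assert delta_consumer_surplus(1000.0, 58.75, 220.0, -1000.0) == \
            pytest.approx(-0.5 * 1000 * 161.25)
        assert delta_consumer_surplus(0.0, 58.75, 220.0, 0.0) == 0.0

    def test_cs_matches_triangle_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(300):
            P = rng.uniform(20, 120)
            C = P + rng.uniform(5, 300)
            Q = rng.uniform(1, 1e5)
            wtp = rng.uniform(0, 80)
            fee = rng.uniform(0, wtp + (C - P))
            dQ = delta_dives(Q, P, C, wtp, fee)
            got = delta_consumer_surplus(Q, P, C, dQ)
            want = triangle_cs_oracle(Q, P, C, wtp, fee)
            assert got == pytest.approx(want, rel=1e-9, abs=1e-9)

    def test_neutral_fee_triple_zero(self):
        """F = SumWTP leaves dives, industry revenue, and CS unchanged."""
        Q, P, C, wtp = 5000.0, 60.0, 200.0, 47.0
        dQ = delta_dives(Q, P, C, wtp, wtp)
        assert dQ == 0.0
        assert delta_dive_revenue(P, dQ) == 0.0
        assert delta_consumer_surplus(Q, P, C, dQ) == 0.0
        assert fee_revenue(wtp, Q, dQ) == wtp * Q


class TestBaselinesAndGlobalDives:
    def test_two_pixel_toy(self):
        df = pd.DataFrame({"Q_star": [10.0, 20.0], "P_star": [50.0, 60.0],
                           "C": [100.0, 100.0]})
        rev, cs = baseline_surplus_and_revenue(df)
        assert rev == pytest.approx(1700.0)
        assert cs == pytest.approx(0.5 * 10 * 50 + 0.5 * 20 * 40)

    def test_global_arithmetic_reproduced(self):
        total, marine = estimate_global_dives()
        assert total == pytest.approx(50.7e6, rel=1e-3)
        assert marine == pytest.approx(33.1e6, rel=1e-2)
        assert econ.DEFAULT_CASUAL_SHARE == pytest.approx(0.728, abs=0.001)

    def test_all_casual(self):
        total, _ = estimate_global_dives(9e6, casual_share=1.0)
        assert total == 36e6

    def test_revenue_at_printed_inputs(self):
        df = pd.DataFrame({"Q_star": [33.1e6], "P_star": [58.75], "C": [200.0]})
        rev, _ = baseline_surplus_and_revenue(df)
        assert rev == pytest.approx(1.94e9, rel=5e-3)


class TestAttribution:
    def test_name_effect_only(self):
        shares, ok = attribute_components(0.0, 0.0, True, WTPParams(), 100.0)
        assert ok and shares == {"biodiversity": 0.0, "biomass": 0.0,
                                 "name_effect": 1.0}

    def test_zero_total_flagged(self):
        shares, ok = attribute_components(0.0, 0.0, False, WTPParams(), 100.0)
        assert not ok and sum(shares.values()) == 0.0

    def test_shares_proportional_to_components(self):
        """Components sized 0.49/0.47/0.04 of P* attribute in those shares."""
        p = WTPParams(name_effect=0.04, k_biomass=0.0, k_biodiversity=0.0,
                      biomass_cap=0.47, biodiversity_cap=0.49)
        shares, ok = attribute_components(1.0, 1.0, True, p, 100.0)
        assert ok
        assert shares["biodiversity"] == pytest.approx(0.49)
        assert shares["biomass"] == pytest.approx(0.47)
        assert shares["name_effect"] == pytest.approx(0.04)

    def test_central_effects_reproduce_printed_split(self):
        """At a 113% biomass gain and 0.03 score gain the default response
        curves split ~49/47/4 and total ~US$53 at the median price."""
        p = WTPParams()
        shares, _ = attribute_components(1.13, 0.03, True, p, 58.75)
        assert shares["biodiversity"] == pytest.approx(0.49, abs=0.02)
        assert shares["biomass"] == pytest.approx(0.47, abs=0.02)
        assert shares["name_effect"] == pytest.approx(0.04, abs=0.01)
        assert wtp_shift(1.13, 0.03, True, p, 58.75) == pytest.approx(53.0, abs=1.5)


class TestOriginSplit:
    def _surplus(self):
        s = pd.Series([100.0, 200.0, 50.0], index=[0, 1, 2])
        regions = pd.Series(["R1", "R1", "R2"], index=[0, 1, 2])
        return s, regions

    def test_zero_fraction_all_local(self):
        s, r = self._surplus()
        out = split_surplus_by_origin(s, r, {"R1": 0.0, "R2": 0.0})
        assert (out["foreign"] == 0.0).all()
        assert out["local"].sum() == pytest.approx(350.0)

    def test_global_61_percent(self):
        s, r = self._surplus()
        out = split_surplus_by_origin(s, r, {"R1": 0.61, "R2": 0.61})
        assert out["foreign"].sum() == pytest.approx(0.61 * 350.0)

    def test_conservation_and_missing_region(self):
        s, r = self._surplus()
        out = split_surplus_by_origin(s, r, {"R1": 0.3, "R2": 0.9})
        assert (out["foreign"] + out["local"]).sum() == pytest.approx(350.0, abs=1e-9)
        with pytest.raises(EconomicsError):
            split_surplus_by_origin(s, r, {"R1": 0.3})
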