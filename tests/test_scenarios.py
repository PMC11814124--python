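import numpy as np
import pandas as pd
import pytest

from divempa import ScenarioConfig, scenarios
from divempa.world import WorldBundle, WorldError
from conftest import small_bundle


class TestRunScenario:
    def test_bau_zero_fee_is_noop(self, small_prepared):
        res = scenarios.run_scenario(small_prepared.bundle,
                                     ScenarioConfig(policy="bau", fee=0.0),
                                     prepared=small_prepared)
        for col in ("delta_dives", "delta_revenue", "fee_revenue", "delta_cs"):
            assert res.aggregates[col] == 0.0
        assert res.d_score == 0.0 and res.biomass_mean_pct == 0.0

    def test_protect_all_increases_dives_everywhere(self, small_prepared):
        """With a positive WTP shift and no fee, demand rises in every pixel."""
        res = scenarios.run_scenario(small_prepared.bundle,
                                     ScenarioConfig(policy="protect_all", fee=0.0),
                                     prepared=small_prepared)
        assert (res.per_pixel["sum_wtp"] > 0).all()
        assert (res.per_pixel["delta_dives"] > 0).all()
        assert res.aggregates["delta_cs"] > 0

    def test_deterministic_given_seed(self):
        r1 = scenarios.run_scenario(small_bundle(seed=31), ScenarioConfig(seed=31))
        r2 = scenarios.run_scenario(small_bundle(seed=31), ScenarioConfig(seed=31))
        assert r1.summary() == r2.summary()
        pd.testing.assert_frame_equal(r1.per_pixel, r2.per_pixel)

    def test_aggregates_equal_pixel_and_region_sums(self, small_prepared):
        res = scenarios.run_scenario(small_prepared.bundle, ScenarioConfig(),
                                     prepared=small_prepared)
        assert res.aggregates["delta_cs"] == pytest.approx(
            res.per_pixel["delta_cs"].sum(), rel=1e-9)
        assert res.origin_split["total"].sum() == pytest.approx(
            res.aggregates["delta_cs"], rel=1e-6)

    def test_incomplete_bundle_rejected(self, small_prepared):
        bad = WorldBundle(world=small_prepared.bundle.world,
                          coverage=small_prepared.bundle.coverage,
                          prices=pd.DataFrame(columns=["operator_id", "pixel_id",
                                                       "price_per_dive"]))
        with pytest.raises(WorldError, match="prices"):
            scenarios.prepare_world(bad)


class TestFeeSweep:
    def test_zero_fee_zero_fee_revenue(self, small_prepared):
        sweep = scenarios.fee_sweep(small_prepared, fees=[0.0, 10.0])
        at0 = sweep[sweep["fee"] == 0.0]
        assert (at0["fee_revenue"] == 0.0).all()

    def test_mpa_branch_dominates_at_every_fee(self, small_prepared):
        sweep = scenarios.fee_sweep(small_prepared)
        mpa = sweep[sweep["policy"] == "protect_all"].set_index("fee")
        bau = sweep[sweep["policy"] == "bau"].set_index("fee")
        assert (mpa["fee_revenue"] >= bau["fee_revenue"] - 1e-9).all()

    def test_no_mpa_optimum_matches_closed_form(self, small_prepared):
        econ = small_prepared.econ
        margin = float((econ["C"] - econ["P_star"]).iloc[0])
        fees = np.linspace(0.0, 2 * margin, 2001)
        sweep = scenarios.fee_sweep(small_prepared, fees=fees)
        bau = sweep[sweep["policy"] == "bau"].reset_index(drop=True)
        best = bau.loc[bau["fee_revenue"].idxmax()]
        step = fees[1] - fees[0]
        assert best["fee"] == pytest.approx(margin / 2, abs=step)
        assert best["fee_revenue"] == pytest.approx(
            0.25 * econ["Q_star"].sum() * margin, rel=1e-3)

    def test_fee_without_mpa_strictly_hurts(self, small_prepared):
        """Direction of the no-MPA branch: fees cut dives, revenue, and CS."""
        sweep = scenarios.fee_sweep(small_prepared, fees=[0.0, 5.0, 25.0])
        bau = sweep[sweep["policy"] == "bau"].sort_values("fee")
        assert (bau["delta_dives"].to_numpy()[1:] < 0).all()
        assert (bau["delta_revenue"].to_numpy()[1:] < 0).all()
        assert (bau["delta_cs"].to_numpy()[1:] < 0).all()
        assert bau["delta_dives"].is_monotonic_decreasing

    def test_mpa_optimum_exceeds_bau_by_half_wtp(self, small_prepared):
        """Uniform economics: argmax fee differs by SumWTP/2 between branches."""
        import copy
        prep = copy.copy(small_prepared)
        wtp_u = float(small_prepared.sum_wtp.mean())
        prep.sum_wtp = small_prepared.sum_wtp * 0.0 + wtp_u  # uniform WTP
        econ = prep.econ
        margin = float((econ["C"] - econ["P_star"]).iloc[0])
        fees = np.linspace(0.0, margin + wtp_u, 4001)
        sweep = scenarios.fee_sweep(prep, fees=fees)
        step = fees[1] - fees[0]
        opt = {p: g.loc[g["fee_revenue"].idxmax(), "fee"]
               for p, g in sweep.groupby("policy")}
        assert opt["protect_all"] - opt["bau"] == pytest.approx(wtp_u / 2, abs=2 * step)


class TestNeutralFee:
    def test_neutral_fee_equals_wtp_and_holds_everything(self, small_prepared):
        fees, mean = scenarios.neutral_fee(small_prepared)
        np.testing.assert_allclose(fees.to_numpy(),
                                   small_prepared.sum_wtp.to_numpy(), rtol=1e-12)
        pp = scenarios.evaluate(small_prepared, "protect_all", "neutral")
        assert (pp["delta_cs"].abs() < 1e-6).all()
        assert mean > 0

    def test_zero_wtp_gives_zero_fee(self, small_prepared):
        import copy
        prep = copy.copy(small_prepared)
        prep.sum_wtp = small_prepared.sum_wtp * 0.0
        fees, mean = scenarios.neutral_fee(prep)
        assert (fees == 0.0).all() and mean == 0.0


class TestMonteCarlo:
    def test_collapsed_bounds_equal_single_run(self, small_prepared):
        base = float(small_prepared.econ["Q_star"].sum())
        mc = scenarios.monte_carlo(small_prepared, n_runs=1,
                                   dive_bounds=(base, base), seed=0)
        sweep = scenarios.fee_sweep(small_prepared)
        mpa = sweep[sweep["policy"] == "protect_all"]
        assert mc.loc[0, "max_fee_revenue_mpa"] == pytest.approx(
            float(mpa["fee_revenue"].max()), rel=1e-9)

    def test_mpa_advantage_in_every_run(self, small_prepared):
        mc = scenarios.monte_carlo(small_prepared, n_runs=20, seed=1)
        assert (mc["fee_revenue_advantage"] > 0).all()

    def test_ensemble_mean_stabilizes(self, small_prepared):
        m1 = scenarios.monte_carlo(small_prepared, n_runs=40, seed=2)
        m2 = scenarios.monte_carlo(small_prepared, n_runs=80, seed=2)
        se = m2["max_fee_revenue_mpa"].std() / np.sqrt(len(m2))
        assert abs(m1["max_fee_revenue_mpa"].mean()
                   - m2["max_fee_revenue_mpa"].mean()) < 2 * se


@pytest.fixture(scope="module")
def table():
    return scenarios.sensitivity_suite(
        small_bundle(seed=17, n_stocks=5, n_species=25),
        base_config=ScenarioConfig(seed=17),
        price_schemes=("global_median", "interpolated"),
    )


class TestSensitivity:
    def test_higher_dive_totals_weakly_raise_fee_revenue(self, table):
        for (_, _), grp in table.groupby(["price_scheme", "weights"]):
            g = grp.set_index("dive_total_case")
            assert g.loc["upper", "max_fee_revenue"] >= g.loc["central", "max_fee_revenue"]
            assert g.loc["central", "max_fee_revenue"] >= g.loc["lower", "max_fee_revenue"]

    def test_price_scheme_isolated_from_biodiversity(self, table):
        """Swapping the price scheme must not move the biodiversity score."""
        per_scheme = table.groupby("price_scheme")["d_score"].unique()
        flat = {tuple(np.round(v, 12)) for v in per_scheme}
        assert len(flat) == 1

    def test_grid_is_complete(self, table):
        assert len(table) == 2 * 2 * 3
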