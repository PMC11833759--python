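import datetime as dt

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from rxsmoke.fuels import (
    CATEGORIES,
    ConsumptionFractions,
    EmissionFactors,
    FuelBed,
    PlumeParams,
    allocate_hourly,
    calibrate_fractions,
    consume,
    default_emission_factors,
    emissions_total,
    gatlinburg_fractions,
    gatlinburg_loads,
    plume_extent,
    residual_fuel,
    scenario_emissions,
)
from rxsmoke.units import BurnPlan, BurnUnit


def simple_bed(value=100.0):
    return FuelBed({c: value for c in CATEGORIES})


def uniform_fractions(value):
    f = {c: value for c in CATEGORIES}
    return ConsumptionFractions({"WF": dict(f), "Rx": {**f, "canopy": 0.0}, "postRxWF": dict(f)})


class TestConsume:
    def test_zero_fractions_zero_consumption(self):
        res = consume(simple_bed(), "WF", uniform_fractions(0.0))
        assert res.total_tons == 0.0

    def test_full_fractions_consume_everything(self):
        bed = simple_bed(50.0)
        res = consume(bed, "WF", uniform_fractions(1.0))
        assert res.total_tons == pytest.approx(bed.total())
        assert all(res.consumed[c] == bed.loads[c] for c in CATEGORIES)

    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError):
            uniform_fractions(1.2)
        with pytest.raises(ValueError):
            uniform_fractions(-0.1)

    def test_rx_never_consumes_canopy(self):
        with pytest.raises(ValueError, match="canopy"):
            ConsumptionFractions({"Rx": {c: 0.5 for c in CATEGORIES}})
        res = consume(simple_bed(), "Rx", uniform_fractions(0.7))
        assert res.consumed["canopy"] == 0.0

    def test_case_study_totals(self):
        """Calibrated fractions reproduce the published regional totals."""
        loads = gatlinburg_loads()
        fr = gatlinburg_fractions()
        assert loads.total() == pytest.approx(794638.1, abs=0.05)
        wf = consume(loads, "WF", fr)
        assert wf.total_tons == pytest.approx(356483.3, abs=0.05)
        rx = consume(loads, "Rx", fr)
        assert rx.total_tons == pytest.approx(179779.2, abs=0.05)
        post = consume(residual_fuel(loads, rx), "postRxWF", fr)
        assert post.total_tons == pytest.approx(147476.2, abs=0.05)


class TestResidual:
    def test_ground_fuel_case_study_value(self):
        loads = gatlinburg_loads()
        rx = consume(loads, "Rx", gatlinburg_fractions())
        res = residual_fuel(loads, rx)
        assert res.loads["ground_fuel"] == pytest.approx(94784.2 - 8116.2, abs=1e-6)

    def test_zero_consumption_identity(self):
        bed = simple_bed(42.0)
        res = residual_fuel(bed, consume(bed, "WF", uniform_fractions(0.0)))
        assert res.loads == bed.loads

    def test_full_consumption_empties_bed(self):
        bed = simple_bed(42.0)
        res = residual_fuel(bed, consume(bed, "WF", uniform_fractions(1.0)))
        assert res.total() == 0.0

    def test_no_fuel_created(self):
        """Rx consumption + post-treatment wildfire consumption never
        exceeds the original load, category by category."""
        bed = simple_bed(10.0)
        fr = gatlinburg_fractions()
        rx = consume(bed, "Rx", fr)
        post = consume(residual_fuel(bed, rx), "postRxWF", fr)
        for c in CATEGORIES:
            assert rx.consumed[c] + post.consumed[c] <= bed.loads[c] + 1e-9


class TestEmissions:
    def test_zero_factor_zero_emission(self):
        res = consume(simple_bed(), "WF", uniform_fractions(0.5))
        out = emissions_total(res, EmissionFactors({"WF": {"PM25": 0.0}}))
        assert out["PM25"] == 0.0

    def test_kg_per_ton_arithmetic(self):
        # 100 t consumed at 10 kg/ton -> 1 t emitted
        bed = FuelBed({c: (100.0 if c == "woody" else 0.0) for c in CATEGORIES})
        res = consume(bed, "WF", uniform_fractions(1.0))
        out = emissions_total(res, EmissionFactors({"WF": {"PM25": 10.0}}))
        assert out["PM25"] == pytest.approx(1.0)

    def test_linearity_in_consumption(self):
        factors = default_emission_factors()
        e1 = emissions_total(consume(simple_bed(10.0), "WF", uniform_fractions(0.5)), factors)
        e2 = emissions_total(consume(simple_bed(20.0), "WF", uniform_fractions(0.5)), factors)
        for sp in e1:
            assert e2[sp] == pytest.approx(2 * e1[sp])

    def test_unknown_species_rejected(self):
        res = consume(simple_bed(), "WF", uniform_fractions(0.5))
        with pytest.raises(ValueError, match="XYZ"):
            default_emission_factors().factor("XYZ", "WF")
        assert "PM25" in emissions_total(res, default_emission_factors())


class TestAllocateHourly:
    def test_rx_mass_confined_to_burn_window(self):
        series = allocate_hourly({"PM25": 10.0}, 100.0, "Rx", [dt.date(2016, 10, 5)])
        hours = series.times.hour
        outside = (hours < 10) | (hours >= 17)
        assert np.all(series.species["PM25"][outside] == 0.0)
        assert series.species["PM25"].sum() == pytest.approx(10.0, rel=1e-9)

    def test_wf_equal_daily_split(self):
        dates = [dt.date(2016, 11, 25) + dt.timedelta(days=i) for i in range(5)]
        series = allocate_hourly({"PM25": 50.0}, 500.0, "WF", dates)
        daily = series.species["PM25"].reshape(5, 24).sum(axis=1)
        assert np.allclose(daily, 10.0)
        assert series.fuel_tons.sum() == pytest.approx(500.0, rel=1e-9)

    def test_rx_requires_single_date(self):
        with pytest.raises(ValueError):
            allocate_hourly({"PM25": 1.0}, 1.0, "Rx", [dt.date(2016, 1, 1), dt.date(2016, 1, 2)])

    def test_wf_requires_contiguous_range(self):
        with pytest.raises(ValueError):
            allocate_hourly({"PM25": 1.0}, 1.0, "WF", [dt.date(2016, 1, 1), dt.date(2016, 1, 3)])
        with pytest.raises(ValueError):
            allocate_hourly({"PM25": 1.0}, 1.0, "WF", [])


class TestPlumeExtent:
    def test_zero_heat_zero_plume(self):
        bottom, top = plume_extent(np.array([0.0]), np.array([5.0]))
        assert bottom[0] == 0.0 and top[0] == 0.0

    def test_cube_root_scaling(self):
        _, top1 = plume_extent(np.array([100.0]), np.array([5.0]))
        _, top2 = plume_extent(np.array([200.0]), np.array([5.0]))
        assert top2[0] == pytest.approx(2 ** (1 / 3) * top1[0])

    def test_hand_computed_fixture(self):
        # rise = 140 * (8.8 * 1 MW)^(1/3) / 2 m/s = 140 * 2.06457... / 2
        params = PlumeParams(rise_coeff=140.0, buoyancy_per_mw=8.8, bottom_fraction=0.5)
        bottom, top = plume_extent(np.array([1.0]), np.array([2.0]), params)
        assert top[0] == pytest.approx(144.5203, abs=0.01)
        assert bottom[0] == pytest.approx(top[0] / 2)

    def test_nonpositive_wind_rejected(self):
        with pytest.raises(ValueError):
            plume_extent(np.array([1.0]), np.array([0.0]))

    @given(
        st.floats(0.1, 1e5),
        st.floats(0.1, 1e5),
        st.floats(0.5, 30.0),
        st.floats(0.5, 30.0),
    )
    def test_monotone_in_heat_antitone_in_wind(self, h1, h2, w1, w2):
        lo_h, hi_h = sorted([h1, h2])
        lo_w, hi_w = sorted([w1, w2])
        _, top_low = plume_extent(np.array([lo_h]), np.array([lo_w]))
        _, top_high = plume_extent(np.array([hi_h]), np.array([lo_w]))
        assert top_high >= top_low
        _, top_windy = plume_extent(np.array([hi_h]), np.array([hi_w]))
        assert top_windy <= top_high


def plan_of(n_units, area=500.0):
    units = []
    for i in range(n_units):
        u = BurnUnit(i, np.array([[i, 0]]), area)
        u.burn_date = dt.date(2016, 9, 1) + dt.timedelta(days=3 * i)
        units.append(u)
    return BurnPlan(units)


class TestScenarioEmissions:
    WF_DATES = [dt.date(2016, 11, 25) + dt.timedelta(days=i) for i in range(5)]

    def test_full_treatment_reproduces_case_study_totals(self):
        plan = plan_of(4)
        shares = [0.4, 0.3, 0.2, 0.1]
        loads = gatlinburg_loads()
        beds = [FuelBed({c: loads.loads[c] * s for c in CATEGORIES}) for s in shares]
        emis = scenario_emissions(
            plan, beds, gatlinburg_fractions(), default_emission_factors(),
            self.WF_DATES, treatment_fraction=1.0,
        )
        assert emis.consumption["WF"].total_tons == pytest.approx(356483.3, abs=0.05)
        assert emis.consumption["Rx"].total_tons == pytest.approx(179779.2, abs=0.05)
        assert emis.consumption["postRxWF"].total_tons == pytest.approx(147476.2, abs=0.05)
        reduction = 100 * (1 - emis.consumption["postRxWF"].total_tons
                           / emis.consumption["WF"].total_tons)
        assert reduction == pytest.approx(58.6, abs=0.05)

    def test_zero_treatment_collapses_onto_wildfire(self):
        plan = plan_of(3)
        beds = [simple_bed(100.0)] * 3
        emis = scenario_emissions(
            plan, beds, gatlinburg_fractions(), default_emission_factors(),
            self.WF_DATES, treatment_fraction=0.0,
        )
        assert emis.rx == []
        for sp in emis.wf.species:
            assert np.array_equal(emis.wf.species[sp], emis.post_rx.species[sp])
        assert np.array_equal(emis.wf.fuel_tons, emis.post_rx.fuel_tons)

    def test_partial_treatment_is_strictly_between(self):
        plan = plan_of(4)
        beds = [simple_bed(100.0)] * 4
        totals = {}
        for tf in (0.0, 0.5, 1.0):
            emis = scenario_emissions(
                plan, beds, gatlinburg_fractions(), default_emission_factors(),
                self.WF_DATES, treatment_fraction=tf,
            )
            totals[tf] = emis.consumption["postRxWF"].total_tons
        assert totals[1.0] < totals[0.5] < totals[0.0]

    def test_hourly_sums_conserve_species_totals(self):
        plan = plan_of(2)
        beds = [simple_bed(100.0)] * 2
        emis = scenario_emissions(
            plan, beds, gatlinburg_fractions(), default_emission_factors(),
            self.WF_DATES, treatment_fraction=1.0,
        )
        factors = default_emission_factors()
        expected = emissions_total(emis.consumption["WF"], factors)
        for sp, tot in expected.items():
            assert emis.wf.total(sp) == pytest.approx(tot, rel=1e-9)

    def test_invalid_fraction_rejected(self):
        plan = plan_of(1)
        with pytest.raises(ValueError):
            scenario_emissions(
                plan, [simple_bed()], gatlinburg_fractions(), default_emission_factors(),
                self.WF_DATES, treatment_fraction=1.5,
            )


def test_calibration_round_trip():
    """calibrate_fractions inverts consume for an arbitrary accounting table."""
    rng = np.random.default_rng(8)
    loads = FuelBed({c: float(rng.uniform(10, 100)) for c in CATEGORIES})
    consumption = {
        "WF": {c: loads.loads[c] * float(rng.uniform(0, 1)) for c in CATEGORIES},
        "Rx": {c: (0.0 if c == "canopy" else loads.loads[c] * float(rng.uniform(0, 0.9)))
               for c in CATEGORIES},
    }
    resid = {c: loads.loads[c] - consumption["Rx"][c] for c in CATEGORIES}
    consumption["postRxWF"] = {c: resid[c] * float(rng.uniform(0, 1)) for c in CATEGORIES}
    fr = calibrate_fractions(loads, consumption)
    wf = consume(loads, "WF", fr)
    rx = consume(loads, "Rx", fr)
    post = consume(residual_fuel(loads, rx), "postRxWF", fr)
    for c in CATEGORIES:
        assert wf.consumed[c] == pytest.approx(consumption["WF"][c])
        assert rx.consumed[c] == pytest.approx(consumption["Rx"][c])
        assert post.consumed[c] == pytest.approx(consumption["postRxWF"][c])
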