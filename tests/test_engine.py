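import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoclimex import (
    SoilMoistureConfig,
    ValidationError,
    annual_growth_index,
    classify,
    cold_stress,
    degree_days,
    dry_stress,
    ecoclimatic_index,
    heat_stress,
    moisture_index,
    run_grid,
    soil_moisture_series,
    temperature_index,
)
from ecoclimex.engine import evaluate, prepare_weekly

from conftest import constant_cell_grid


class TestTrapezoids:
    @pytest.mark.parametrize(
        "t, expected",
        [
            (4.0, 0.0),     # limiting low
            (25.0, 1.0),    # lower optimal
            (35.0, 1.0),    # upper optimal
            (45.0, 0.0),    # limiting high
            (14.5, 0.5),    # rising ramp midpoint: (14.5-4)/(25-4)
            (40.0, 0.5),    # falling ramp midpoint: (45-40)/(45-35)
            (-10.0, 0.0),
            (60.0, 0.0),
        ],
    )
    def test_temperature_index_values(self, params, t, expected):
        assert temperature_index(t, params) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "sm, expected",
        [
            (0.1, 0.0),
            (0.2, 1.0),
            (8.0, 1.0),
            (10.0, 0.0),
            (0.15, 0.5),    # (0.15-0.1)/(0.2-0.1)
            (9.0, 0.5),     # (10-9)/(10-8)
            (0.0, 0.0),
            (12.0, 0.0),
        ],
    )
    def test_moisture_index_values(self, params, sm, expected):
        assert moisture_index(sm, params) == pytest.approx(expected, abs=1e-12)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(min_value=-20, max_value=60, allow_nan=False))
    def test_temperature_index_bounded_and_piecewise_linear(self, params, t):
        v = float(temperature_index(t, params))
        assert 0.0 <= v <= 1.0
        # continuity: small steps change the index by at most step/min-ramp-width
        eps = 1e-6
        assert abs(float(temperature_index(t + eps, params)) - v) <= eps / 10.0 + 1e-12


class TestSoilMoisture:
    def test_zero_net_flux_keeps_initial_sm(self):
        cfg = SoilMoistureConfig(capacity=100.0, et_coefficient=2.0, initial_sm=0.5)
        tmean = np.full(52, 20.0)
        rh = np.full(52, 0.8)
        precip = 2.0 * 20.0 * (1.05 - 0.8) * np.ones(52)  # exactly the weekly demand
        sm = soil_moisture_series(precip, tmean, rh, cfg)
        np.testing.assert_allclose(sm, 0.5, atol=1e-12)

    def test_zero_precip_drains_to_zero(self):
        """Matches the step-by-step bucket recurrence and ends dry."""
        cfg = SoilMoistureConfig(capacity=50.0, et_coefficient=2.0, initial_sm=0.8, spinup_years=1)
        tmean = np.full(52, 25.0)
        rh = np.full(52, 0.6)
        sm = soil_moisture_series(np.zeros(52), tmean, rh, cfg)
        # recurrence oracle
        expected = []
        s = 0.8
        for _ in range(52):
            s = max(0.0, s - 2.0 * 25.0 * (1.05 - 0.6) / 50.0)
            expected.append(s)
        np.testing.assert_allclose(sm, expected, atol=1e-12)
        assert np.all(np.diff(sm) <= 1e-12)
        assert sm[-1] == 0.0

    def test_huge_precip_caps_at_ceiling(self):
        cfg = SoilMoistureConfig(ceiling=1.0)
        sm = soil_moisture_series(np.full(52, 1e4), np.full(52, 20.0), np.full(52, 0.5), cfg)
        np.testing.assert_allclose(sm, 1.0)

    def test_non_convergence_warns(self):
        # spinup_years=2 with a state that needs ~4 years to drain
        cfg = SoilMoistureConfig(capacity=5000.0, et_coefficient=2.0, initial_sm=1.0, spinup_years=2)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            soil_moisture_series(np.zeros(52), np.full(52, 10.0), np.full(52, 0.5), cfg)


class TestStressAndGrowth:
    def test_annual_growth_index_arithmetic(self):
        assert annual_growth_index(np.ones(52), np.ones(52)) == pytest.approx(100.0)
        assert annual_growth_index(np.zeros(52), np.ones(52)) == pytest.approx(0.0)
        ti = np.concatenate([np.ones(26), np.zeros(26)])
        assert annual_growth_index(ti, np.ones(52)) == pytest.approx(50.0)

    def test_annual_growth_index_length_mismatch(self):
        with pytest.raises(ValidationError):
            annual_growth_index(np.ones(52), np.ones(51))

    def test_cold_stress_accumulation(self, params):
        tmin = np.full(52, 10.0)
        assert cold_stress(tmin, params) == 0.0
        tmin[:10] = -6.0  # deficit 10 °C for 10 weeks at |THCS|=0.002
        assert cold_stress(tmin, params) == pytest.approx(20.0)
        assert cold_stress(np.full(52, -50.0), params) == 100.0

    def test_heat_stress_accumulation(self, params):
        tmax = np.full(52, 40.0)
        assert heat_stress(tmax, params) == 0.0
        tmax[:5] = 50.0  # excess 5 °C for 5 weeks at THHS=0.02
        assert heat_stress(tmax, params) == pytest.approx(50.0)
        assert heat_stress(np.full(52, 120.0), params) == 100.0

    def test_dry_stress_occupancy(self, params):
        sm = np.full(52, 0.5)
        assert dry_stress(sm, params) == 0.0
        sm[:30] = 0.05  # 30 weeks below SMDS at |HDS|=0.01
        assert dry_stress(sm, params) == pytest.approx(30.0)
        assert dry_stress(np.full(52, 0.0), params) == pytest.approx(52.0)

    def test_degree_days(self, params):
        assert degree_days(np.full(52, 4.0), params) == 0.0
        assert degree_days(np.full(52, 25.0), params) == pytest.approx(52 * 7 * 21)  # 7644 >= PPD
        assert degree_days(np.full(52, 8.0), params) == pytest.approx(52 * 7 * 4)    # 1456 < PPD

    def test_ecoclimatic_index_combination(self, params):
        assert ecoclimatic_index(80.0, 50.0, 0.0, 0.0, 2000.0, params) == pytest.approx(40.0)
        # persistence gate: 1456 degree-days < PPD=1517 forces EI to 0
        assert ecoclimatic_index(80.0, 0.0, 0.0, 0.0, 1456.0, params) == 0.0
        assert ecoclimatic_index(100.0, 0.0, 0.0, 0.0, 9000.0, params) == pytest.approx(100.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        gi=st.floats(0, 100),
        cs=st.floats(0, 100),
        hs=st.floats(0, 100),
        ds=st.floats(0, 100),
        dd=st.floats(0, 9000),
    )
    def test_ei_bounded(self, params, gi, cs, hs, ds, dd):
        ei = float(ecoclimatic_index(gi, cs, hs, ds, dd, params))
        assert 0.0 <= ei <= 100.0

    def test_more_stress_never_raises_ei(self, params, small_grid):
        """EI is non-increasing in each stress-rate magnitude, climate held fixed."""
        prepared = prepare_weekly(small_grid, SoilMoistureConfig())
        base = evaluate(prepared, params)[0].EI
        for code, value in (("THCS", -0.004), ("THHS", 0.04), ("HDS", -0.02)):
            harsher = evaluate(prepared, params.with_overrides(**{code: value}))[0].EI
            assert np.all(harsher <= base + 1e-12)


class TestClassify:
    @pytest.mark.parametrize(
        "ei, expected",
        [(0.0, "unsuitable"), (1e-9, "low"), (15.0, "low"), (29.999, "low"), (30.0, "high"), (100.0, "high")],
    )
    def test_class_boundaries(self, ei, expected):
        assert classify(ei) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify(101.0)
        with pytest.raises(ValidationError):
            classify(-0.5)


class TestGridEngine:
    def test_all_cold_cell_gets_zero_ei(self, params):
        smap = run_grid(constant_cell_grid(-5.0, 60.0))
        assert smap.EI[0] == 0.0
        assert smap.classes[0] == "unsuitable"
        assert smap.DD[0] == 0.0

    def test_single_cell_equals_scalar_pipeline(self, params, soil_cfg):
        from reference import cell_result

        grid = constant_cell_grid(22.0, 40.0, rh=0.6, diurnal=12.0)
        smap = run_grid(grid, params, soil_cfg)
        ref = cell_result(
            grid.tmin[0], grid.tmax[0], grid.precip[0], grid.rh09[0], grid.rh15[0], params, soil_cfg
        )
        for key in ("GI_A", "CS", "HS", "DS", "DD", "EI"):
            assert getattr(smap, key)[0] == pytest.approx(ref[key], rel=1e-10, abs=1e-10)
        assert smap.classes[0] == ref["class"]

    def test_permuting_cells_permutes_results(self, small_grid, params, soil_cfg):
        from ecoclimex import ClimateGrid

        smap = run_grid(small_grid, params, soil_cfg)
        rng = np.random.default_rng(0)
        perm = rng.permutation(small_grid.n_cells)
        shuffled = ClimateGrid(
            lat=small_grid.lat[perm], lon=small_grid.lon[perm],
            tmin=small_grid.tmin[perm], tmax=small_grid.tmax[perm],
            precip=small_grid.precip[perm], rh09=small_grid.rh09[perm], rh15=small_grid.rh15[perm],
        )
        smap2 = run_grid(shuffled, params, soil_cfg)
        np.testing.assert_allclose(smap2.EI, smap.EI[perm], atol=1e-12)

    def test_indices_bounded_on_synthetic_grid(self, small_grid, params, soil_cfg):
        prepared = prepare_weekly(small_grid, soil_cfg)
        smap, res = evaluate(prepared, params)
        for arr, hi in ((res.TI_w, 1), (res.MI_w, 1), (res.GI_w, 1), (res.SI, 1),
                        (smap.GI_A, 100), (smap.CS, 100), (smap.HS, 100), (smap.DS, 100), (smap.EI, 100)):
            assert np.all(arr >= 0.0) and np.all(arr <= hi)
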