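"""Lake upscaling: per-lake arithmetic, CO2-eq, ensemble Monte Carlo."""

import numpy as np
import pandas as pd
import pytest

from sedch4 import SynthConfig, gen_lakes
from sedch4.upscale import (
    UpscaleModel,
    UpscaleParams,
    lake_production,
    to_co2eq,
)


def _lake_table(areas, p_cur, p_fut_cols):
    df = pd.DataFrame(
        {
            "lake_id": [f"L{i}" for i in range(len(areas))],
            "area_km2": areas,
            "p_current": p_cur,
        }
    )
    for name, vals in p_fut_cols.items():
        df[name] = vals
    return df


class TestLakeProduction:
    def test_zero_probability_zero_production(self):
        assert lake_production(10.0, 0.0, UpscaleParams()) == 0.0

    def test_hand_arithmetic_example(self):
        # 1 km^2, p 0.5, rate 7.22e3 mg/m2, habitat 0.28, surficial 0.70
        params = UpscaleParams(rate_mean_mg_m2=7.22e3)
        prod = lake_production(1.0, 0.5, params)
        assert prod == pytest.approx(1444.0, rel=1e-3)

    def test_full_occurrence_covers_28_pct(self):
        params = UpscaleParams(surficial_fraction=1.0, rate_mean_mg_m2=1.0)
        # with unit rate and no profile scaling, production kg = coverage m2 * 1e-6
        prod = lake_production(1.0, 1.0, params)
        assert prod == pytest.approx(0.28)

    def test_probability_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="probabilities"):
            lake_production(1.0, 1.5, UpscaleParams())

    def test_linear_in_area_and_probability(self):
        params = UpscaleParams()
        assert lake_production(2.0, 0.3, params) == pytest.approx(
            2 * lake_production(1.0, 0.3, params)
        )
        assert lake_production(1.0, 0.6, params) == pytest.approx(
            2 * lake_production(1.0, 0.3, params)
        )


class TestCo2Eq:
    def test_printed_gwp(self):
        assert to_co2eq(1.0) == 25.0
        assert to_co2eq(0.0) == 0.0
        assert to_co2eq(1444.0) == pytest.approx(36100.0)

    def test_bad_gwp_rejected(self):
        with pytest.raises(ValueError):
            to_co2eq(1.0, gwp=0.0)


class TestEnsemble:
    def test_future_equal_to_current_gives_zero_change(self):
        table = _lake_table([5.0], [0.4], {"p_gcm_rcp4.5": [0.4]})
        res = UpscaleModel(table).simulate(n_mc=200, seed=0)
        np.testing.assert_allclose(res.pct_change_draws, 0.0, atol=1e-10)

    def test_doubled_probability_gives_exactly_100pct_in_every_draw(self):
        rng = np.random.default_rng(0)
        p = rng.uniform(0.05, 0.45, 20)
        table = _lake_table(
            rng.uniform(0.5, 50, 20), p,
            {"p_a_rcp2.6": 2 * p, "p_b_rcp8.5": 2 * p},
        )
        res = UpscaleModel(table).simulate(n_mc=300, seed=1)
        np.testing.assert_allclose(res.pct_change_draws, 100.0, rtol=1e-10)

    def test_change_is_rate_free_per_draw(self):
        # the drawn rate cancels: each draw's change equals the deterministic
        # change of its drawn scenario
        lakes = gen_lakes(SynthConfig(seed=9, n_lakes=100))
        model = UpscaleModel(lakes)
        res = model.simulate(n_mc=500, seed=3)
        per_scenario = set(np.round(res.per_scenario["pct_change_vs_current"], 6))
        draws = set(np.round(res.pct_change_draws, 6))
        assert draws.issubset(per_scenario)

    def test_doubling_all_areas_doubles_totals(self):
        lakes = gen_lakes(SynthConfig(seed=10, n_lakes=50))
        lakes = lakes[lakes["area_km2"] <= 500.0].reset_index(drop=True)
        doubled = lakes.copy()
        doubled["area_km2"] *= 2
        r1 = UpscaleModel(lakes).simulate(n_mc=100, seed=4)
        r2 = UpscaleModel(doubled).simulate(n_mc=100, seed=4)
        assert r2.current_total_ch4_kg == pytest.approx(
            2 * r1.current_total_ch4_kg, rel=1e-12
        )
        np.testing.assert_allclose(
            r2.future_draws_ch4_kg, 2 * r1.future_draws_ch4_kg, rtol=1e-12
        )

    def test_calibrated_uplift_recovers_73pct_increase(self):
        # probabilities low enough that a 1.73x uplift never clips at 1
        rng = np.random.default_rng(5)
        p = rng.uniform(0.01, 0.5, 200)
        table = _lake_table(
            rng.uniform(0.2, 100, 200), p, {"p_comp_rcp4.5": 1.73 * p}
        )
        res = UpscaleModel(table).simulate(n_mc=400, seed=6)
        assert res.min_ensemble_pct_change == pytest.approx(73.0, abs=1e-8)
        assert np.all(res.pct_change_draws >= 73.0 - 1e-8)

    def test_zero_current_total_flagged_not_infinite(self):
        table = _lake_table([1.0], [0.0], {"p_x_rcp4.5": [0.5]})
        res = UpscaleModel(table).simulate(n_mc=50, seed=7)
        assert res.undefined_change
        assert np.all(np.isnan(res.pct_change_draws))

    def test_quantiles_ordered_and_stabilize(self):
        lakes = gen_lakes(SynthConfig(seed=11, n_lakes=100))
        res = UpscaleModel(lakes).simulate(n_mc=2000, seed=8)
        lo, md, hi = res.pct_change_quantiles
        assert lo <= md <= hi
        # median is stable across independent halves of the draws
        a = np.nanmedian(res.pct_change_draws[:1000])
        b = np.nanmedian(res.pct_change_draws[1000:])
        assert a == pytest.approx(b, rel=0.15)

    def test_colonization_modes(self):
        table = _lake_table([1.0, 1.0, 1.0], [0.2, 0.6, 0.9], {"p_x_rcp4.5": [0.4, 0.8, 1.0]})
        expected = UpscaleModel(table, UpscaleParams(colonization_mode="expected"))
        assert expected.colonized_counts().set_index("scenario").loc[
            "current", "colonized_lakes"
        ] == pytest.approx(1.7)
        thresh = UpscaleModel(
            table, UpscaleParams(colonization_mode="threshold", colonization_p=0.5)
        )
        counts = thresh.colonized_counts().set_index("scenario")
        assert counts.loc["current", "colonized_lakes"] == 2
        assert counts.loc["x_rcp4.5", "colonized_lakes"] == 2

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError, match="scenario"):
            UpscaleModel(_lake_table([1.0], [0.1], {}))
        with pytest.raises(ValueError, match="areas"):
            UpscaleModel(_lake_table([0.01], [0.1], {"p_x_rcp4.5": [0.2]}))
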