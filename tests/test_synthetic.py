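"""Synthetic bay generator: determinism, structure, statistical faithfulness."""

import numpy as np
import pandas as pd
import pytest

from sedigrass import (
    BayConfig,
    SecchiLinearModel,
    fit_secchi_model,
    generate_bay,
    generate_seagrass_map,
    generate_secchi_obs,
    generate_sediment_series,
    reference,
)


def test_config_validation():
    with pytest.raises(ValueError, match="wet_season_share"):
        BayConfig(wet_season_share=1.2)
    with pytest.raises(ValueError, match="cell_size"):
        BayConfig(cell_size=0.0)
    with pytest.raises(ValueError, match="counts"):
        BayConfig(n_rows=0)


class TestBay:
    def test_seeded_determinism(self, small_config):
        a = generate_bay(small_config)
        b = generate_bay(small_config)
        np.testing.assert_array_equal(a.depth, b.depth)
        np.testing.assert_array_equal(a.hs, b.hs)
        np.testing.assert_array_equal(a.water_mask, b.water_mask)
        np.testing.assert_array_equal(a.d_river, b.d_river)
        assert a.river_mouths == b.river_mouths

    def test_open_ocean_exists(self, small_grid):
        assert np.nanmax(small_grid.depth) >= 30.0

    def test_depth_cutoff_unreachable_errors(self, small_config):
        from dataclasses import replace

        with pytest.raises(ValueError, match="open-ocean"):
            generate_bay(replace(small_config, depth_max=10.0))

    def test_mouths_on_water_adjacent_to_land(self, small_grid):
        mask = small_grid.water_mask
        for r, c in small_grid.river_mouths:
            assert mask[r, c]
            neighbours = mask[max(0, r - 1) : r + 2, max(0, c - 1) : c + 2]
            assert not neighbours.all()  # touches the shoreline

    def test_wave_field_nonnegative(self, small_grid):
        hs = small_grid.hs[small_grid.water_mask]
        assert (hs >= 0).all() and np.isfinite(hs).all()


class TestSediment:
    def test_non_negative_and_three_rivers(self, small_config):
        series = generate_sediment_series(small_config)
        assert (series.daily["tss_tonnes"] >= 0).all()
        assert series.daily["river"].nunique() == small_config.n_rivers

    def test_determinism(self, small_config):
        a = generate_sediment_series(small_config).daily
        b = generate_sediment_series(small_config).daily
        pd.testing.assert_frame_equal(a, b)

    def test_wet_season_share_converges(self):
        # 10 simulated years, no flood multipliers: realised Nov-Mar share
        # within +/-0.05 of the configured 0.76
        cfg = BayConfig(n_months=126, flood_months=[], seed=17)
        series = generate_sediment_series(cfg)
        assert series.wet_season_fraction() == pytest.approx(0.76, abs=0.05)

    def test_flood_multiplier_scales_month(self):
        months = pd.period_range("2000-07", periods=126, freq="M")
        january = [i for i, p in enumerate(months) if p.month == 1]
        cfg = BayConfig(n_months=126, flood_months=[(january[3], 10.0)], seed=17)
        series = generate_sediment_series(cfg)
        monthly = series.monthly_totals()
        jan_totals = monthly[monthly.index.month == 1]
        flooded = jan_totals.iloc[3]
        assert flooded >= 5.0 * jan_totals.drop(jan_totals.index[3]).median()

    def test_needs_a_year_of_forcing(self):
        with pytest.raises(ValueError, match="12 months"):
            generate_sediment_series(BayConfig(n_months=6))

    def test_default_pattern_spans_flood_and_drought(self):
        series = generate_sediment_series(BayConfig(seed=17))
        annual = series.annual_totals("water")
        assert annual.max() / annual.min() > 8.0  # flood-to-drought span


class TestSecchiObservations:
    def test_zero_noise_equals_predictor_and_positive(self, small_config):
        from dataclasses import replace

        cfg = replace(small_config, secchi_noise_sd=0.0)
        grid = generate_bay(cfg)
        series = generate_sediment_series(cfg)
        obs = generate_secchi_obs(grid, series, cfg.secchi_truth, cfg)
        assert (obs["secchi_m"] > 0).all()
        truth = SecchiLinearModel.from_coefficients(cfg.secchi_truth)
        monthly = series.monthly_totals()
        r, c = obs["row"].to_numpy(), obs["col"].to_numpy()
        X = np.column_stack(
            [
                monthly.reindex(pd.PeriodIndex(obs["month"])).to_numpy(),
                grid.depth[r, c],
                grid.d_ocean[r, c],
                grid.d_river[r, c],
            ]
        )
        np.testing.assert_allclose(obs["secchi_m"], truth.predict(X), rtol=1e-12)

    def test_station_locations_fixed_across_months(self, small_config):
        grid = generate_bay(small_config)
        series = generate_sediment_series(small_config)
        obs = generate_secchi_obs(grid, series, small_config.secchi_truth, small_config)
        per_station = obs.groupby("station_id")[["row", "col"]].nunique()
        assert (per_station == 1).all().all()

    def test_zero_noise_refit_recovers_truth(self):
        # no floods keeps observations above the reporting floor, so OLS
        # recovery of the generating coefficients is exact
        cfg = BayConfig(n_rows=48, n_cols=120, n_months=36, n_stations=50,
                        secchi_noise_sd=0.0, flood_months=[], seed=5)
        grid = generate_bay(cfg)
        series = generate_sediment_series(cfg)
        obs = generate_secchi_obs(grid, series, cfg.secchi_truth, cfg)
        model = fit_secchi_model(obs, grid, series)
        ref = reference.SECCHI_REFERENCE
        assert model.intercept_ == pytest.approx(ref["intercept"], rel=1e-6)
        for got, key in zip(model.coef_, ("sediment", "depth", "d_ocean", "d_river")):
            assert got == pytest.approx(ref[key], rel=1e-6)


class TestSeagrassMap:
    def test_degenerate_probabilities(self):
        L = np.zeros((10, 10))
        hs = np.zeros((10, 10))
        sure = {"intercept": 50.0, "light": 0.0, "waves": 0.0, "waves_x_light": 0.0}
        out = generate_seagrass_map(L, hs, sure, seed=1)
        assert (out == 1.0).all()

    def test_half_probability_sampling(self):
        shape = (120, 120)
        fair = {"intercept": 0.0, "light": 0.0, "waves": 0.0, "waves_x_light": 0.0}
        out = generate_seagrass_map(np.zeros(shape), np.zeros(shape), fair, seed=2)
        frac = out.mean()
        se = 0.5 / np.sqrt(out.size)
        assert abs(frac - 0.5) < 3 * se

    def test_land_propagates_as_nan(self):
        L = np.array([[np.nan, 1.0]])
        out = generate_seagrass_map(L, np.zeros((1, 2)), reference.HABITAT_REFERENCE,
                                    seed=3)
        assert np.isnan(out[0, 0]) and out[0, 1] in (0.0, 1.0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="shape"):
            generate_seagrass_map(np.zeros((2, 2)), np.zeros((3, 2)),
                                  reference.HABITAT_REFERENCE, seed=0)
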