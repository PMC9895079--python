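import numpy as np
import pandas as pd
import pytest

from grazegrid import (
    PartitionSpec,
    RasterField,
    fit,
    partition_samples,
    predict,
    residual_correct,
    spatial_metrics,
    theoretical_capacity_threshold,
)
from grazegrid.model import GriddedGrazing


class TestCapacityThreshold:
    def test_standard_formula(self):
        # 1000 kg/hm2 yield, half usable, 1.8 kg/SU/day over a full year
        out = theoretical_capacity_threshold(1000, 0.5, 1.8, 365)
        assert out == pytest.approx(0.761, abs=5e-4)

    def test_linear_in_yield(self):
        a = theoretical_capacity_threshold(500, 1.0, 2.0, 300)
        b = theoretical_capacity_threshold(1000, 1.0, 2.0, 300)
        assert b == pytest.approx(2 * a)

    @pytest.mark.parametrize("kwargs", [
        dict(forage_yield=-1, utilization=0.5, intake=1.8, grazing_days=365),
        dict(forage_yield=100, utilization=1.5, intake=1.8, grazing_days=365),
        dict(forage_yield=100, utilization=0.5, intake=0, grazing_days=365),
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            theoretical_capacity_threshold(**kwargs)

    def test_printed_defaults_used_verbatim(self):
        spec = PartitionSpec()
        assert spec.thresholds_by_type == {
            "alpine_meadow": 0.43, "alpine_steppe": 0.35, "alpine_desert_steppe": 0.21}


class TestPartitionSamples:
    def _table(self, rows):
        return pd.DataFrame(rows, columns=["grassland_type", "response", "x"])

    def test_boundary_goes_low(self):
        spec = PartitionSpec(pixel_area=1.0)
        table = self._table([("alpine_meadow", 0.43, 1.0)])
        parts = partition_samples(table, spec)
        assert len(parts["low"]) == 1 and len(parts["high"]) == 0

    def test_type_specific_thresholds(self):
        spec = PartitionSpec(pixel_area=1.0)
        table = self._table([("alpine_meadow", 0.50, 1.0), ("alpine_steppe", 0.30, 2.0)])
        parts = partition_samples(table, spec)
        assert list(parts["high"]["x"]) == [1.0]
        assert list(parts["low"]["x"]) == [2.0]

    def test_pixel_area_converts_to_density(self):
        spec = PartitionSpec(pixel_area=100.0)  # 50 SU/pixel -> 0.5 SU/hm2
        table = self._table([("alpine_meadow", 50.0, 0.0)])
        assert len(partition_samples(table, spec)["high"]) == 1

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="grassland type"):
            partition_samples(self._table([("swamp", 1.0, 0.0)]), PartitionSpec())


def _loglinear_table(n, seed, noise=0.0):
    """Rows whose response is exactly expm1(linear(features)): with the
    log1p transform the forest fits a smooth linear surface."""
    rng = np.random.default_rng(seed)
    x1 = rng.uniform(-1, 1, n)
    x2 = rng.uniform(-1, 1, n)
    y = np.expm1(2.0 + 0.8 * x1 + 0.5 * x2)  # exponent stays positive
    if noise:
        y = np.clip(y + rng.normal(0, noise, n), 0, None)
    return pd.DataFrame({"response": y, "x1": x1, "x2": x2})


class TestFit:
    def test_recovers_noise_free_loglinear_response(self):
        model = fit(_loglinear_table(3000, seed=0), variant="M1",
                    split_seed=7, model_seed=7)
        r2 = model.test_metrics["pooled"][0]
        assert r2 >= 0.99

    def test_seeded_refit_is_identical(self):
        table = _loglinear_table(300, seed=1, noise=0.3)
        a = fit(table, variant="M1", split_seed=3, model_seed=5, n_estimators=50)
        b = fit(table, variant="M1", split_seed=3, model_seed=5, n_estimators=50)
        assert a.importances == b.importances
        assert a.test_metrics == b.test_metrics

    def test_informative_features_dominate_importance(self):
        table = _loglinear_table(500, seed=2)
        table["noise_feature"] = np.random.default_rng(3).normal(size=500)
        model = fit(table, variant="M1", n_estimators=100)
        imp = model.importances["pooled"]
        assert imp["x1"] > imp["noise_feature"]
        assert imp["x2"] > imp["noise_feature"]

    def test_empty_partition_falls_back_to_single_model(self):
        table = _loglinear_table(100, seed=4)
        table["grassland_type"] = "alpine_meadow"
        table["response"] = 0.1  # all far below the 0.43 threshold
        model = fit(table, variant="M4", partition=PartitionSpec(pixel_area=1.0),
                    n_estimators=20)
        assert model.fallback_single_model
        assert set(model.submodels) == {"pooled"}

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError, match="rows"):
            fit(_loglinear_table(5, seed=5), variant="M1")


class TestPredict:
    def test_all_nodata_mask_gives_all_nodata(self):
        model = fit(_loglinear_table(100, seed=6), variant="M1", n_estimators=20)
        grid = predict(model, {"x1": np.zeros((4, 4)), "x2": np.zeros((4, 4))},
                       mask=np.zeros((4, 4), bool))
        assert np.isnan(grid.su_raw.values).all()

    def test_constant_covariates_give_constant_prediction(self):
        model = fit(_loglinear_table(100, seed=6), variant="M1", n_estimators=20)
        grid = predict(model, {"x1": np.full((3, 3), 0.2), "x2": np.full((3, 3), -0.1)})
        vals = grid.su_raw.values
        assert np.allclose(vals, vals[0, 0])

    def test_missing_covariate_listed(self):
        model = fit(_loglinear_table(100, seed=6), variant="M1", n_estimators=20)
        with pytest.raises(ValueError, match="x2"):
            predict(model, {"x1": np.zeros((2, 2))})

    def test_pixel_predictions_near_truth_on_dense_fixture(self):
        rng = np.random.default_rng(11)
        x1 = rng.uniform(-1, 1, (40, 40))
        x2 = rng.uniform(-1, 1, (40, 40))
        truth = np.expm1(2.0 + 0.8 * x1 + 0.5 * x2)
        table = pd.DataFrame({"response": truth.ravel(), "x1": x1.ravel(), "x2": x2.ravel()})
        model = fit(table, variant="M1", split_seed=1, model_seed=1)
        grid = predict(model, {"x1": x1, "x2": x2})
        rel_err = np.abs(grid.su_raw.values - truth) / truth
        assert np.mean(rel_err <= 0.05) >= 0.95


class TestResidualCorrect:
    def _grid(self, raw, year=0):
        return GriddedGrazing(RasterField(np.asarray(raw, dtype=float)), year=year)

    def test_additive_shift(self):
        zones = RasterField(np.zeros((1, 4), dtype=int))
        grid = residual_correct(self._grid([[5.0, 5, 5, 5]]), {0: 28.0}, zones)
        assert np.allclose(grid.su_corrected.values, 7.0)

    def test_zero_residual_is_identity(self):
        zones = RasterField(np.zeros((1, 3), dtype=int))
        grid = residual_correct(self._grid([[1.0, 2.0, 3.0]]), {0: 6.0}, zones)
        assert np.allclose(grid.su_corrected.values, [[1.0, 2.0, 3.0]])

    def test_negative_clip_respreads_mass(self):
        # shift of -1.8 drives four pixels negative; the iterative clip +
        # proportional respread must land on [5, 0, 0, 0, 0] (hand oracle)
        zones = RasterField(np.zeros((1, 5), dtype=int))
        grid = residual_correct(self._grid([[10.0, 1, 1, 1, 1]]), {0: 5.0}, zones)
        out = grid.su_corrected.values
        assert (out >= 0).all()
        assert out.mean() == pytest.approx(1.0, abs=1e-6)
        assert out[0, 0] == pytest.approx(5.0, abs=1e-6)

    def test_missing_county_left_uncorrected_and_reported(self):
        zones = RasterField(np.array([[0, 0, 1, 1]]))
        grid = residual_correct(self._grid([[2.0, 2, 3, 3]]), {0: 8.0}, zones)
        assert grid.uncorrected_counties == [1]
        assert np.allclose(grid.su_corrected.values[0, 2:], 3.0)
        assert np.allclose(grid.su_corrected.values[0, :2], 4.0)

    def test_county_means_match_census_on_landscape(self, small_truth):
        rng = np.random.default_rng(0)
        zones = small_truth.county_zones
        year = small_truth.years[0]
        totals = small_truth.census.totals_for_year(year)
        raw = np.clip(small_truth.truth_density[0] + rng.normal(0, 5, zones.shape), 0, None)
        grid = residual_correct(self._grid(raw, year), totals, zones)
        for county, total in totals.items():
            sel = zones.values == county
            assert grid.su_corrected.values[sel].mean() == pytest.approx(
                total / sel.sum(), rel=1e-6)
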