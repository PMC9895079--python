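import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import davies_bouldin_score

from grazegrid import RasterField, davies_bouldin, extract_csf, select_group_count
from grazegrid.disturbance import DistributedDensity

from conftest import dbi_oracle


class TestDaviesBouldin:
    def test_zero_within_group_spread(self):
        assert davies_bouldin([0, 0, 10, 10], [0, 0, 1, 1]) == 0.0

    def test_coincident_centroids_flagged_infinite(self):
        assert np.isinf(davies_bouldin([0, 2, 1, 1], [0, 0, 1, 1]))

    def test_nine_point_three_group_toy(self):
        values = [0, 1, 2, 10, 11, 12, 25, 27, 29]
        labels = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        out = davies_bouldin(values, labels)
        # hand computation: spreads (2/3, 2/3, 4/3), centroids (1, 11, 27)
        # worst ratios (2/15, 2/15, 1/8), mean = 47/360
        assert out == pytest.approx(47 / 360)
        assert out == pytest.approx(dbi_oracle(values, labels))

    def test_agrees_with_sklearn_on_random_grouping(self):
        rng = np.random.default_rng(4)
        values = rng.normal(size=50)
        labels = rng.integers(0, 3, size=50)
        ours = davies_bouldin(values, labels)
        theirs = davies_bouldin_score(values.reshape(-1, 1), labels)
        assert ours == pytest.approx(theirs, rel=1e-10)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            davies_bouldin([1, 2, 3], [0, 0, 0])


class TestSelectGroupCount:
    def test_recovers_three_separated_clumps(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(c, 0.1, 20) for c in (0, 10, 20)])
        sel = select_group_count(values, k_range=tuple(range(2, 7)))
        assert sel.k_selected == 3
        # brute-force check: DBI really is minimal at the selected k
        assert sel.dbi_values[sel.k_candidates.index(3)] == min(sel.dbi_values)

    def test_identical_values_take_degenerate_path(self):
        sel = select_group_count(np.full(10, 3.14))
        assert sel.k_selected == 1
        assert sel.dbi_values == []

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=40)
        a = select_group_count(values)
        b = select_group_count(values)
        assert a.k_selected == b.k_selected
        assert a.dbi_values == b.dbi_values
        assert np.array_equal(a.labels, b.labels)

    def test_tiny_sample_returns_single_group(self):
        assert select_group_count(np.array([1.0])).k_selected == 1


def _dist(su, zones):
    su = np.asarray(su, dtype=float)
    return DistributedDensity(RasterField(su, "su"), RasterField(np.asarray(zones)))


class TestExtractCsf:
    def test_homogeneous_county_collapses_to_county_mean(self):
        dist = _dist([[5.0, 5.0, 5.0, 5.0]], [[0, 0, 0, 0]])
        cov = {"x": np.array([[1.0, 2.0, 3.0, 4.0]])}
        table = extract_csf(dist, cov)
        assert len(table) == 1
        assert table.iloc[0]["response"] == 5.0
        assert table.iloc[0]["x"] == pytest.approx(2.5)

    def test_four_pixel_two_group_toy(self):
        dist = _dist([[1.0, 1.0, 9.0, 9.0]], [[0, 0, 0, 0]])
        cov = {"x": np.array([[2.0, 2.0, 4.0, 4.0]])}
        table = extract_csf(dist, cov).sort_values("response").reset_index(drop=True)
        assert len(table) == 2
        assert list(table["response"]) == [1.0, 9.0]
        assert list(table["x"]) == [2.0, 4.0]

    def test_partition_and_aggregation_consistency(self, small_truth):
        from grazegrid import ad_index, dasymetric_distribute
        year = small_truth.years[0]
        ad = ad_index(small_truth.ndvi)
        dist = dasymetric_distribute(small_truth.census.totals_for_year(year), ad,
                                     small_truth.county_zones,
                                     np.ones(small_truth.county_zones.shape, bool))
        table = extract_csf(dist, small_truth.covariates,
                            grassland_type=RasterField(small_truth.grassland_type_labels()))
        zones = small_truth.county_zones.values
        for county, sub in table.groupby("county_id"):
            sel = zones == county
            # groups partition the county's pixels
            assert sub["n_pixels"].sum() == sel.sum()
            # pixel-count-weighted group response reproduces the county total
            assert (sub["n_pixels"] * sub["response"]).sum() == pytest.approx(
                dist.su.values[sel].sum(), rel=1e-9)

    def test_group_table_enlarges_training_sample(self, small_truth):
        from grazegrid import ad_index, dasymetric_distribute
        year = small_truth.years[0]
        ad = ad_index(small_truth.ndvi)
        dist = dasymetric_distribute(small_truth.census.totals_for_year(year), ad,
                                     small_truth.county_zones,
                                     np.ones(small_truth.county_zones.shape, bool))
        group = extract_csf(dist, small_truth.covariates)
        county = extract_csf(dist, small_truth.covariates, k_range=())
        assert len(group) > len(county)
        assert len(county) == small_truth.config.n_counties
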