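"""Plot-map rasterization, skewness and per-plot trait extraction."""

import numpy as np
import pytest
import shapely
from scipy import stats as sps

from aeropheno.errors import ConfigurationError, UndefinedSkewnessError
from aeropheno.plot_traits import (
    BACKGROUND,
    PlotDefinition,
    PlotMap,
    extract_plot_traits,
    rasterize_plot_map,
    records_to_frame,
    seasonal_table,
    skewness,
)
from aeropheno.segmentation import SegmentationMask


def rect_plot(plot_id, r0, c0, r1, c1, genotype="g00", rows=2, block="b1"):
    return PlotDefinition(
        plot_id=plot_id,
        genotype=genotype,
        rows=rows,
        block=block,
        polygon=((r0, c0), (r0, c1), (r1, c1), (r1, c0)),
    )


class TestRasterize:
    def test_rectangle_matches_brute_force_point_in_polygon(self):
        plot = rect_plot("p1", 2.5, 3.5, 8.2, 11.7)
        labels = rasterize_plot_map(PlotMap([plot]), (16, 16))
        poly = plot.shapely_polygon()
        expected = sum(
            poly.contains(shapely.Point(c, r))
            for r in range(16)
            for c in range(16)
        )
        assert (labels == 0).sum() == expected

    def test_empty_plot_list_is_all_background(self):
        labels = rasterize_plot_map(PlotMap([]), (8, 8))
        assert (labels == BACKGROUND).all()

    def test_overlapping_rectangles_rejected(self):
        a = rect_plot("a", 0, 0, 5, 5)
        b = rect_plot("b", 3, 3, 8, 8)
        with pytest.raises(ConfigurationError, match="overlap"):
            rasterize_plot_map(PlotMap([a, b]), (10, 10))

    def test_touching_rectangles_allowed(self):
        a = rect_plot("a", 0, 0, 5, 5)
        b = rect_plot("b", 0, 5, 5, 10)
        labels = rasterize_plot_map(PlotMap([a, b]), (12, 12))
        assert set(np.unique(labels)) == {BACKGROUND, 0, 1}

    def test_duplicate_plot_ids_rejected(self):
        with pytest.raises(ConfigurationError, match="duplicate"):
            PlotMap([rect_plot("a", 0, 0, 2, 2), rect_plot("a", 5, 5, 7, 7)])


class TestSkewness:
    def test_symmetric_sample_is_zero(self):
        assert skewness([1.0, 2.0, 3.0]) == pytest.approx(0.0, abs=1e-15)

    def test_hand_evaluated_right_tail(self):
        assert skewness([0.0, 0.0, 1.0]) == pytest.approx(1 / np.sqrt(2))

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedSkewnessError):
            skewness([5.0, 5.0, 5.0])

    def test_single_value_undefined(self):
        with pytest.raises(UndefinedSkewnessError):
            skewness([5.0])

    def test_matches_population_moment_reference(self, rng):
        # population (biased) skewness, cross-checked against scipy
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(3, 200)))
            assert skewness(x) == pytest.approx(
                float(sps.skew(x, bias=True)), abs=1e-12
            )

    def test_sign_convention(self, rng):
        right = np.concatenate([np.zeros(90), np.full(10, 5.0)])
        assert skewness(right) > 0
        assert skewness(-right) < 0


def full_valid_mask(plant):
    return SegmentationMask(plant=plant, valid=np.ones_like(plant, dtype=bool))


class TestExtractPlotTraits:
    def setup_method(self):
        # half-pixel inset so all 100 pixel centres fall strictly inside
        self.plot = rect_plot("p1", -0.5, -0.5, 9.5, 9.5)
        self.pm = PlotMap([self.plot])
        self.labels = rasterize_plot_map(self.pm, (10, 10))

    def test_canopy_cover_is_plant_fraction(self):
        plant = np.zeros((10, 10), dtype=bool)
        plant.ravel()[:60] = True
        recs = extract_plot_traits(
            np.full((10, 10), 0.5), full_valid_mask(plant), self.labels, self.pm
        )
        assert recs[0].cc == pytest.approx(0.60)
        assert recs[0].n_pixels == 100
        assert recs[0].n_plant_pixels == 60

    def test_balanced_mixture_median_is_tie_midpoint(self):
        ndvi = np.zeros((10, 10))
        plant = np.zeros((10, 10), dtype=bool)
        plant[:5] = True
        ndvi[:5] = 0.8
        recs = extract_plot_traits(ndvi, full_valid_mask(plant), self.labels, self.pm)
        assert recs[0].ndvi_plot == pytest.approx(0.4)  # midpoint of 0.0 / 0.8
        assert recs[0].ndvi_plant == pytest.approx(0.8)

    def test_dt_sign_convention(self):
        # canopy cooler than ambient air gives negative dT
        thermal = np.full((10, 10), 22.6)
        recs = extract_plot_traits(
            np.full((10, 10), 0.5),
            full_valid_mask(np.ones((10, 10), dtype=bool)),
            self.labels,
            self.pm,
            thermal=thermal,
            air_temp=24.4,
        )
        assert recs[0].t_c == pytest.approx(22.6)
        assert recs[0].dt == pytest.approx(-1.8)

    def test_empty_plot_yields_error_record_and_run_continues(self):
        ndvi = np.full((10, 10), np.nan)
        mask = SegmentationMask(
            plant=np.zeros((10, 10), dtype=bool),
            valid=np.zeros((10, 10), dtype=bool),
        )
        with pytest.warns(UserWarning, match="no valid pixels"):
            recs = extract_plot_traits(ndvi, mask, self.labels, self.pm)
        assert recs[0].error
        assert np.isnan(recs[0].cc)

    def test_pixel_conservation_over_plots(self):
        plots = [rect_plot("a", 0, 0, 5, 5), rect_plot("b", 0, 5, 5, 10)]
        pm = PlotMap(plots)
        labels = rasterize_plot_map(pm, (10, 10))
        recs = extract_plot_traits(
            np.full((10, 10), 0.3),
            full_valid_mask(np.zeros((10, 10), dtype=bool)),
            labels,
            pm,
        )
        assert sum(r.n_pixels for r in recs) == (labels != BACKGROUND).sum()

    def test_plant_median_at_least_plot_median_when_soil_darker(self, rng):
        ndvi = rng.uniform(-0.4, 0.0, (10, 10))
        plant = rng.random((10, 10)) < 0.4
        ndvi[plant] = rng.uniform(0.3, 0.9, int(plant.sum()))
        recs = extract_plot_traits(ndvi, full_valid_mask(plant), self.labels, self.pm)
        assert recs[0].ndvi_plant >= recs[0].ndvi_plot
        # equality at full cover
        recs2 = extract_plot_traits(
            ndvi, full_valid_mask(np.ones((10, 10), dtype=bool)), self.labels, self.pm
        )
        assert recs2[0].ndvi_plant == pytest.approx(recs2[0].ndvi_plot, abs=1e-12)

    def test_plot_skewness_sign_tracks_canopy_cover(self, rng):
        # sparse canopy: soil bulk + bright plant tail -> positive skewness
        for cc, predicate in ((0.3, lambda s: s > 0), (1.0, lambda s: abs(s) < 0.5)):
            plant = rng.random((10, 10)) < cc
            ndvi = np.where(
                plant,
                rng.normal(0.6, 0.05, (10, 10)),
                rng.normal(-0.05, 0.03, (10, 10)),
            )
            recs = extract_plot_traits(
                ndvi, full_valid_mask(plant), self.labels, self.pm
            )
            assert predicate(recs[0].skew_plot), f"cc={cc}"


class TestSeasonalTable:
    def make_records(self, n_campaigns=2):
        plots = [
            rect_plot(f"p{i}", 0, 10 * i, 5, 10 * i + 5, rows=1 + i % 4)
            for i in range(4)
        ]
        pm = PlotMap(plots)
        labels = rasterize_plot_map(pm, (10, 45))
        records = []
        for c in range(n_campaigns):
            records += extract_plot_traits(
                np.full((10, 45), 0.4),
                full_valid_mask(np.ones((10, 45), dtype=bool)),
                labels,
                pm,
                campaign_id=f"c{c + 1}",
            )
        return pm, records

    def test_row_count(self):
        pm, records = self.make_records()
        table = seasonal_table(records, pm, {"c1": 371.0, "c2": 540.0})
        assert len(table) == 4 * 2 * 6

    def test_empty_records_give_empty_table_with_header(self):
        pm, _ = self.make_records()
        table = seasonal_table([], pm, {})
        assert table.empty
        assert "degree_days" in table.columns

    def test_unknown_campaign_rejected(self):
        pm, records = self.make_records()
        with pytest.raises(ConfigurationError, match="unknown campaign"):
            seasonal_table(records, pm, {"c1": 371.0})

    def test_records_frame_shape(self):
        _, records = self.make_records()
        df = records_to_frame(records)
        assert len(df) == 8
        assert {"cc", "ndvi_plot", "ndvi_plant"} <= set(df.columns)
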