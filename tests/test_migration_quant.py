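import math

import numpy as np
import pytest

from chemotaxgel import geometry, imaging, migration_quant as mq, synthetic_data as sd
from chemotaxgel.geometry import GeometryError
from chemotaxgel.migration_quant import (
    crop_centered,
    crop_to_well,
    directional_bias_index,
    facing_quadrants,
    migration_time_series,
    permutation_null,
    quadrant_migration_areas,
    spider_chart_export,
)


def _areas(mask, excl=0.0):
    return quadrant_migration_areas(np.asarray(mask, bool), excl)


class TestCropping:
    def test_well_center_lands_on_crop_center(self, paper_layout):
        frame = np.zeros((940, 1065))
        side = 301
        rc = paper_layout.well_center_px("outer0")
        crop = crop_to_well(frame, paper_layout, "outer0", side)
        assert crop.shape == (side, side)
        # recompute where the center ended up inside the crop
        r0 = round(rc[0] - (side - 1) / 2)
        c0 = round(rc[1] - (side - 1) / 2)
        assert abs((rc[0] - r0) - (side - 1) / 2) <= 0.5
        assert abs((rc[1] - c0) - (side - 1) / 2) <= 0.5

    def test_idempotent_when_centered(self):
        rng = np.random.default_rng(0)
        frame = rng.uniform(size=(101, 101))
        once = crop_centered(frame, (50.0, 50.0), 101)
        twice = crop_centered(once, (50.0, 50.0), 101)
        assert np.array_equal(once, twice)

    def test_crop_exceeding_frame_rejected(self, paper_layout):
        with pytest.raises(GeometryError, match="crop"):
            crop_to_well(np.zeros((100, 100)), paper_layout, "center", 301)


class TestQuadrantAreas:
    def test_full_mask_gives_equal_quarters_summing_to_one(self):
        qa = _areas(np.ones((64, 64)), excl=10.0)
        assert qa.total_fraction == pytest.approx(1.0)
        for f in qa.fractions.values():
            assert f == pytest.approx(0.25)

    def test_empty_mask_gives_zeros(self):
        qa = _areas(np.zeros((64, 64)), excl=10.0)
        assert qa.total_fraction == 0.0

    def test_half_plane_matches_half_annulus_area(self):
        side, excl = 200, 40.0
        mask = np.zeros((side, side), bool)
        mask[:, : side // 2] = True  # left half
        qa = _areas(mask, excl)
        assert qa.fractions["NE"] == 0.0 and qa.fractions["SE"] == 0.0
        left = qa.fractions["NW"] + qa.fractions["SW"]
        assert left == pytest.approx(0.5, abs=1e-12)  # symmetry: exactly half
        # closed form: (side^2/2 - pi R^2 / 2) / (side^2 - pi R^2) = 0.5
        expected = (side**2 / 2 - math.pi * excl**2 / 2) / (side**2 - math.pi * excl**2)
        assert left == pytest.approx(expected, rel=0.01)

    def test_fractions_sum_to_total_every_frame(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            qa = _areas(rng.uniform(size=(50, 50)) > 0.6, excl=8.0)
            assert sum(qa.fractions.values()) == pytest.approx(
                qa.total_fraction, abs=1e-12
            )


class TestFacingQuadrants:
    def test_north_well_faces_south_quadrants(self, paper_layout):
        assert facing_quadrants(paper_layout, "outer0") == frozenset({"SW", "SE"})

    def test_east_well_faces_west_quadrants(self):
        layout = geometry.build_layout(
            1630.0, 1460.0, (10650.0, 9400.0), orientation_deg=90.0
        )
        assert facing_quadrants(layout, "outer0") == frozenset({"NW", "SW"})

    def test_center_well_has_no_facing(self, paper_layout):
        with pytest.raises(GeometryError):
            facing_quadrants(paper_layout, "center")


class TestBiasIndex:
    def test_uniform_spread_scores_zero(self):
        qa = _areas(np.ones((64, 64)), excl=10.0)
        assert directional_bias_index(qa, {"SW", "SE"}) == pytest.approx(0.0)

    def test_all_area_in_facing_scores_plus_one(self):
        mask = np.zeros((64, 64), bool)
        mask[40:60, 5:25] = True  # SW only
        qa = _areas(mask, excl=10.0)
        assert directional_bias_index(qa, {"SW", "SE"}) == pytest.approx(1.0)

    def test_no_area_in_facing_scores_minus_one(self):
        mask = np.zeros((64, 64), bool)
        mask[2:20, 2:20] = True  # NW only
        qa = _areas(mask, excl=10.0)
        assert directional_bias_index(qa, {"SW", "SE"}) == pytest.approx(-1.0)

    def test_empty_mask_flagged_undefined(self):
        qa = _areas(np.zeros((64, 64)), excl=10.0)
        assert math.isnan(directional_bias_index(qa, {"SW", "SE"}))

    def test_facing_must_be_proper_subset(self):
        qa = _areas(np.ones((64, 64)), excl=10.0)
        with pytest.raises(ValueError):
            directional_bias_index(qa, {"NW", "NE", "SW", "SE"})


@pytest.fixture(scope="module")
def small_layout():
    return sd.pixel_aligned_layout(
        geometry.build_layout(400.0, 400.0, (4000.0, 4000.0), pixel_size=10.0)
    )


class TestMigrationTimeSeries:
    def _params(self):
        return imaging.SegmentationParams(
            threshold_method="fixed",
            classifier=imaging.RuleBasedClassifier(200.0, 60.0),
        )

    def test_empty_stack_gives_all_zero_series(self, small_layout):
        frames = np.full((4, 400, 400), 200.0)
        stack = imaging.ImageStack(frames, np.arange(4) * 1800.0, 10.0)
        res = migration_time_series(
            stack, small_layout, "outer0", self._params(), side=100
        )
        assert len(res.series) == 4
        assert all(qa.total_fraction == 0.0 for qa in res.series)
        assert all(math.isnan(b) for b in res.bias_index)

    def test_cells_in_one_quadrant_stay_there(self, small_layout):
        # render agents held in the NE quadrant of the outer0 crop
        rc = small_layout.well_center_px("outer0")
        side = 150
        wx, wy = small_layout.well_position("outer0")
        ps = small_layout.pixel_size
        # physical positions well inside the crop's NE quadrant, outside exclusion
        pos = np.array(
            [[wx + 450.0, wy - 450.0], [wx + 550.0, wy - 350.0], [wx + 350.0, wy - 550.0]]
        )
        traj = np.repeat(pos[None], 3, axis=0)  # static over 3 frames
        origin = (
            round(rc[0] - (side - 1) / 2),
            round(rc[1] - (side - 1) / 2),
        )
        stack, _ = sd.render_migration_frames(
            traj, small_layout, (side, side), origin_px=origin, blob_radius_um=30.0
        )
        # embed crop back into a full frame for the end-to-end path
        full = np.full((3, 400, 400), 200.0)
        full[:, origin[0] : origin[0] + side, origin[1] : origin[1] + side] = stack.frames
        res = migration_time_series(
            imaging.ImageStack(full, stack.timestamps, ps),
            small_layout,
            "outer0",
            self._params(),
            side=side,
        )
        last = res.series[-1]
        assert last.fractions["NE"] > 0
        leakage = last.total_fraction - last.fractions["NE"]
        assert leakage <= 0.01 * last.total_fraction

    def test_series_length_matches_frame_count(self, small_layout):
        frames = np.full((6, 400, 400), 200.0)
        stack = imaging.ImageStack(frames, np.arange(6) * 1800.0, 10.0)
        res = migration_time_series(
            stack, small_layout, "outer1", self._params(), side=100
        )
        assert len(res.series) == len(res.bias_index) == 6


class TestPermutationNull:
    def test_identical_groups_give_p_one(self):
        p = permutation_null([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]).p_value
        assert p >= 0.9

    def test_exact_enumeration_for_small_groups(self):
        res = permutation_null([0.9, 0.8, 0.7, 0.95], [0.1, 0.0, 0.2, 0.05])
        assert res.exact and res.n_arrangements == 70
        assert res.p_value == pytest.approx(2.0 / 70.0)

    def test_seeded_monte_carlo_is_deterministic(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0.5, 0.2, 10), rng.normal(0.3, 0.2, 10)
        r1 = permutation_null(a, b, n_perm=500, seed=3)
        r2 = permutation_null(a, b, n_perm=500, seed=3)
        assert not r1.exact
        assert r1.p_value == r2.p_value

    def test_small_n_perm_warns(self):
        with pytest.warns(UserWarning, match="coarse"):
            permutation_null([1.0, 0.9], [0.1, 0.0], n_perm=50)

    def test_one_sided_alternative_orders_correctly(self):
        hi, lo = [0.9, 0.95, 0.85, 0.9], [0.1, 0.05, 0.0, 0.15]
        p_greater = permutation_null(hi, lo, alternative="greater").p_value
        p_less = permutation_null(hi, lo, alternative="less").p_value
        assert p_greater < 0.05 < p_less


class TestConfluency:
    def test_blank_fixture_reported_empty(self, seg_params):
        img, _ = sd.generate_confluency_image((256, 256), 0.0, seed=31)
        assert mq.confluency(img, seg_params) < 0.02

    def test_fully_covered_fixture_saturates(self, seg_params):
        rng = np.random.default_rng(5)
        full = np.clip(120 + 25 * rng.standard_normal((256, 256)), 0, 255).astype(
            np.uint8
        )
        assert mq.confluency(full, seg_params) > 0.98

    def test_area_recovery_within_five_points(self, seg_params):
        img, truth = sd.generate_confluency_image((512, 512), 0.6, seed=60)
        frac = mq.confluency(img, seg_params)
        assert abs(frac - truth.mean()) < 0.05


class TestQuadrantInvariants:
    """Property checks over arbitrary masks, exclusion radii and facing sets."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        seed=st.integers(0, 10_000),
        side=st.sampled_from([16, 17, 40, 63]),
        excl_frac=st.floats(0.0, 0.9),
        density=st.floats(0.0, 1.0),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_fractions_partition_and_bias_is_bounded(self, seed, side, excl_frac, density):
        rng = np.random.default_rng(seed)
        mask = rng.uniform(size=(side, side)) < density
        excl = excl_frac * (side / 2 - 1)
        qa = quadrant_migration_areas(mask, excl)
        assert all(0.0 <= f <= 1.0 for f in qa.fractions.values())
        assert sum(qa.fractions.values()) == pytest.approx(qa.total_fraction, abs=1e-12)
        bias = directional_bias_index(qa, {"SW", "SE"})
        if qa.total_fraction == 0:
            assert math.isnan(bias)
        else:
            assert -1.0 <= bias <= 1.0


class TestSpiderExport:
    def _result(self):
        mask = np.zeros((64, 64), bool)
        mask[40:60, 5:25] = True
        qa = _areas(mask, excl=10.0)
        return mq.MigrationResult(
            series=[qa], condition="with-tumor", well="outer0",
            facing=frozenset({"SW", "SE"}), bias_index=[1.0],
        )

    def test_one_condition_exports_four_rows(self):
        df = spider_chart_export(self._result())
        assert len(df) == 4
        assert set(df["quadrant"]) == set(geometry.QUADRANTS)

    def test_values_equal_terminal_frame(self):
        res = self._result()
        df = spider_chart_export(res)
        for q in geometry.QUADRANTS:
            row = df[df["quadrant"] == q]["terminal_area_fraction"].iloc[0]
            assert row == res.series[-1].fractions[q]

    def test_csv_round_trip(self, tmp_path):
        import pandas as pd

        path = tmp_path / "spider.csv"
        df = spider_chart_export(self._result(), path)
        again = pd.read_csv(path)
        assert np.allclose(
            again["terminal_area_fraction"], df["terminal_area_fraction"]
        )
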