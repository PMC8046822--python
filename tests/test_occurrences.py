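"""Occurrence cleaning, thinning, balancing, zone assignment, background."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from shapely.geometry import box

from zonesdm import (
    OccurrenceSet,
    ZoneSet,
    area_weighted_balance,
    assign_zone,
    clean_occurrences,
    generate_env_stack,
    sample_background,
    thin_by_distance,
)
from zonesdm.occurrences import pairwise_distance_km
from zonesdm.synth import SyntheticConfig


def occ_frame(rows):
    return pd.DataFrame(rows, columns=["lon", "lat", "year", "uncertainty_km", "source", "zone"])


class TestClean:
    def toy(self):
        return occ_frame(
            [
                (10.0, 200.0, 2010, 5.0, "a", ""),   # bad latitude
                (10.0, 10.0, 1995, 5.0, "a", ""),    # too old
                (10.0, 11.0, 2010, 80.0, "a", ""),   # too uncertain
                (10.0, 12.0, 2005, 5.0, "a", ""),
                (11.0, 12.0, 2010, np.nan, "a", ""),
                (12.0, 12.0, 2020, 1.0, "a", ""),
            ]
        )

    def test_rules_and_rejection_log(self):
        out, log = clean_occurrences(self.toy(), metric="spherical")
        assert len(out) == 3
        assert log.counts == {"coordinates": 1, "year": 1, "uncertainty": 1}

    def test_all_valid_is_identity(self):
        df = self.toy().iloc[3:]
        out, log = clean_occurrences(df, metric="spherical")
        assert len(out) == 3
        assert sum(log.counts.values()) == 0

    def test_missing_year_dropped_under_year_rule(self):
        df = occ_frame([(10.0, 10.0, np.nan, 5.0, "a", "")])
        with pytest.warns(UserWarning):  # everything rejected
            out, log = clean_occurrences(df, metric="spherical")
        assert len(out) == 0
        assert log.counts["year"] == 1

    def test_missing_uncertainty_kept(self):
        df = occ_frame([(10.0, 10.0, 2015, np.nan, "a", "")])
        out, _ = clean_occurrences(df, metric="spherical")
        assert len(out) == 1

    def test_empty_survivors_warns_not_raises(self):
        df = occ_frame([(10.0, 10.0, 1990, 5.0, "a", "")])
        with pytest.warns(UserWarning, match="every record"):
            out, _ = clean_occurrences(df, metric="spherical")
        assert len(out) == 0

    @given(st.permutations(list(range(6))))
    @settings(max_examples=30, deadline=None)
    def test_order_independent(self, perm):
        base = self.toy()
        out_a, _ = clean_occurrences(base, metric="spherical")
        out_b, _ = clean_occurrences(base.iloc[perm].reset_index(drop=True), metric="spherical")
        key = ["lon", "lat", "year"]
        a = out_a.records[key].sort_values(key).reset_index(drop=True)
        b = out_b.records[key].sort_values(key).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestThin:
    def planar(self, pts):
        return OccurrenceSet(
            records=occ_frame([(x, y, 2010, 1.0, "a", "") for x, y in pts]),
            metric="planar",
        )

    def test_close_pair_keeps_first(self):
        out = thin_by_distance(self.planar([(0, 0), (3, 0)]), radius_km=5)
        assert out.records.lon.tolist() == [0]

    def test_sparse_grid_all_kept(self):
        pts = [(10 * i, 10 * j) for i in range(3) for j in range(3)]
        out = thin_by_distance(self.planar(pts), radius_km=5)
        assert len(out) == 9

    def test_collinear_greedy_keeps_alternate(self):
        pts = [(3 * i, 0) for i in range(5)]
        out = thin_by_distance(self.planar(pts), radius_km=5)
        assert out.records.lon.tolist() == [0, 6, 12]

    @given(
        st.lists(
            st.tuples(st.floats(0, 100), st.floats(0, 100)),
            min_size=1,
            max_size=25,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_greedy_output_is_maximal(self, pts):
        """Kept points are >= r apart, and every dropped point is < r from
        some kept point (brute-force re-check of the greedy rule)."""
        occ = self.planar(pts)
        out = thin_by_distance(occ, radius_km=5)
        kept = out.records[["lon", "lat"]].to_numpy()
        if len(kept) > 1:
            d = pairwise_distance_km(kept, kept, "planar")
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 5
        all_pts = occ.records[["lon", "lat"]].to_numpy()
        kept_set = {tuple(p) for p in kept}
        for p in all_pts:
            if tuple(p) not in kept_set:
                d = pairwise_distance_km(p[None, :], kept, "planar")
                assert d.min() < 5

    def test_haversine_metric_used_for_spherical(self):
        # ~0.05 deg latitude is ~5.5 km: kept at radius 5, dropped at radius 6
        occ = OccurrenceSet(
            records=occ_frame([(10.0, 0.0, 2010, 1, "a", ""), (10.0, 0.05, 2010, 1, "a", "")]),
            metric="spherical",
        )
        assert len(thin_by_distance(occ, radius_km=5)) == 2
        assert len(thin_by_distance(occ, radius_km=6)) == 1


def square_zones(n, side=10.0):
    zones = [
        (f"z{i}", box(i * side, 0.0, (i + 1) * side, side))
        for i in range(n)
    ]
    return ZoneSet(zones=zones, domain=box(0, 0, n * side, side))


class TestBalance:
    def labelled(self, counts, side=10.0):
        rows = []
        rng = np.random.default_rng(0)
        for i, n in enumerate(counts):
            for _ in range(n):
                rows.append(
                    (i * side + rng.uniform(0.1, side - 0.1), rng.uniform(0.1, side - 0.1),
                     2010, 1.0, "a", f"z{i}")
                )
        return OccurrenceSet(records=occ_frame(rows), metric="planar")

    def test_equal_density_is_identity(self):
        occ = self.labelled([10, 10, 10])
        out = area_weighted_balance(occ, square_zones(3), seed=1)
        assert len(out) == 30

    def test_dense_zone_capped_at_median(self):
        occ = self.labelled([10, 10, 40])
        out = area_weighted_balance(occ, square_zones(3), seed=1)
        counts = out.records.zone.value_counts()
        assert counts["z0"] == 10 and counts["z1"] == 10 and counts["z2"] == 10

    def test_single_zone_identity_with_warning(self):
        occ = self.labelled([12])
        with pytest.warns(UserWarning, match="fewer than 2"):
            out = area_weighted_balance(occ, square_zones(1), seed=1)
        assert len(out) == 12

    def test_deterministic_given_seed(self):
        occ = self.labelled([10, 10, 40])
        a = area_weighted_balance(occ, square_zones(3), seed=7)
        b = area_weighted_balance(occ, square_zones(3), seed=7)
        assert a.records.equals(b.records)


class TestAssignZone:
    def test_centroid_and_outside(self):
        zones = square_zones(2)
        occ = OccurrenceSet(
            records=occ_frame([(5.0, 5.0, 2010, 1, "a", ""), (15.0, 5.0, 2010, 1, "a", ""),
                               (50.0, 50.0, 2010, 1, "a", "")]),
            metric="planar",
        )
        out = assign_zone(occ, zones)
        assert out.records.zone.tolist() == ["z0", "z1", "other"]

    def test_boundary_goes_to_lexicographically_first(self):
        zones = square_zones(2)  # shared edge at x=10
        occ = OccurrenceSet(
            records=occ_frame([(10.0, 5.0, 2010, 1, "a", "")]), metric="planar"
        )
        out = assign_zone(occ, zones)
        assert out.records.zone.tolist() == ["z0"]


@pytest.fixture(scope="module")
def stack():
    return generate_env_stack(
        SyntheticConfig(grid_rows=32, grid_cols=32, cell_km=10.0, rng_seed=5)
    )


class TestBackground:
    def presences(self, pts):
        return OccurrenceSet(
            records=occ_frame([(x, y, 2010, 1.0, "a", "") for x, y in pts]),
            metric="planar",
        )

    def test_count_is_ratio_times_presences(self, stack):
        occ = self.presences([(55.0, 55.0), (155.0, 155.0)])
        bg = sample_background(occ, stack, ratio=10, buffer_km=10, seed=1)
        assert len(bg) == 20

    def test_every_point_outside_buffer(self, stack):
        occ = self.presences([(55.0, 55.0), (155.0, 155.0), (250.0, 90.0)])
        bg = sample_background(occ, stack, ratio=10, buffer_km=10, seed=1)
        d = pairwise_distance_km(bg.points, occ.xy, "planar")
        assert d.min(axis=1).min() >= 10.0

    def test_points_are_distinct_cells(self, stack):
        occ = self.presences([(55.0, 55.0)])
        bg = sample_background(occ, stack, ratio=10, buffer_km=10, seed=1)
        assert len(np.unique(bg.points, axis=0)) == len(bg)

    def test_infeasible_buffer_reports_deficit(self, stack):
        occ = self.presences([(160.0, 160.0)])
        with pytest.raises(ValueError, match="deficit"):
            sample_background(occ, stack, ratio=10, buffer_km=10_000, seed=1)

    def test_prevalence_contract(self, stack):
        """1:10 design keeps presences at 1/11 of the model table."""
        occ = self.presences([(55.0, 55.0), (155.0, 155.0)])
        bg = sample_background(occ, stack, ratio=10, buffer_km=10, seed=1)
        prevalence = len(occ) / (len(occ) + len(bg))
        assert prevalence == pytest.approx(1 / 11)
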