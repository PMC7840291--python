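"""Unit and property tests for the daily life-space feature extractor."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lifespace as ls
from lifespace.features import FEATURE_COLUMNS

HOME = (29.65, -82.35)


def _stamps(n, start="2020-01-06 08:00", minutes=15):
    tz = "-05:00"
    base = pd.Timestamp(f"{start}{tz}")
    return [base + pd.Timedelta(minutes=minutes * k) for k in range(n)]


def _day_at(distances_km, bearings=None):
    """Fixes placed at given distances from home (km)."""
    distances_km = np.asarray(distances_km, dtype=float)
    if bearings is None:
        bearings = np.zeros_like(distances_km)
    lat, lon = ls.destination_point(*HOME, np.asarray(bearings), distances_km)
    return np.atleast_1d(lat), np.atleast_1d(lon)


class TestMotionClassification:
    def test_identical_fixes_all_stationary(self):
        lat = np.full(5, HOME[0])
        lon = np.full(5, HOME[1])
        speeds, stationary = ls.classify_motion(_stamps(5), lat, lon)
        assert np.all(speeds == 0.0)
        assert stationary.all()

    def test_two_fixes_one_km_in_30_min_is_moving(self):
        lat, lon = _day_at([0.0, 1.0])
        speeds, stationary = ls.classify_motion(_stamps(2, minutes=30), lat, lon)
        assert speeds[1] == pytest.approx(2.0, rel=1e-6)
        assert not stationary[1]

    def test_first_fix_inherits_second_speed(self):
        lat, lon = _day_at([0.0, 1.0, 1.0])
        speeds, _ = ls.classify_motion(_stamps(3, minutes=30), lat, lon)
        assert speeds[0] == speeds[1]

    def test_single_fix_day_is_stationary(self):
        speeds, stationary = ls.classify_motion(_stamps(1), [HOME[0]], [HOME[1]])
        assert speeds[0] == 0.0 and stationary[0]

    def test_nonincreasing_timestamps_rejected(self):
        lat, lon = _day_at([0.0, 1.0])
        stamps = _stamps(2)
        with pytest.raises(ValueError, match="strictly increasing"):
            ls.classify_motion([stamps[1], stamps[0]], lat, lon)


class TestHomeAwayAndTrips:
    def test_boundary_inclusive_at_radius(self):
        lat, lon = _day_at([0.0, 0.099, 0.101])
        at_home = ls.home_away_labels(lat, lon, *HOME, home_radius_m=100)
        assert at_home.tolist() == [True, True, False]

    def test_labels_invariant_to_order(self, rng):
        lat, lon = _day_at(rng.uniform(0, 2, 20))
        labels = ls.home_away_labels(lat, lon, *HOME)
        perm = rng.permutation(20)
        assert np.array_equal(ls.home_away_labels(lat[perm], lon[perm], *HOME), labels[perm])

    @pytest.mark.parametrize(
        "pattern, expected",
        [
            ("HAAH", 1),
            ("HHHH", 0),
            ("HAHAAH", 2),
            ("AAH", 0),
            ("HAA", 0),
            ("AHAH", 1),
            ("A", 0),
            ("H", 0),
        ],
    )
    def test_trip_counting(self, pattern, expected):
        labels = np.array([c == "H" for c in pattern])
        assert ls.count_trips(labels) == expected

    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.text(alphabet="HA", min_size=1, max_size=40))
    def test_trip_count_matches_regex_oracle(self, pattern):
        labels = np.array([c == "H" for c in pattern])
        oracle = len(re.findall(r"H(A+)(?=H)", pattern))
        assert ls.count_trips(labels) == oracle

    def test_homestay_fractions(self):
        assert ls.homestay([True, True]) == 1.0
        assert ls.homestay([False, False]) == 0.0
        assert ls.homestay([True, False, True, False]) == 0.5


class TestExcursion:
    def test_out_and_back_path(self):
        """home -> 5 km east -> home: size 5, total 10, span 0 (one away fix)."""
        lat, lon = _day_at([0.0, 5.0, 0.0], bearings=[0, np.pi / 2, 0])
        size, span, total = ls.excursion_features(lat, lon, *HOME)
        assert size == pytest.approx(5.0, abs=1e-6)
        assert span == 0.0
        assert total == pytest.approx(10.0, abs=1e-6)

    def test_homebound_day_near_zero(self, rng):
        lat, lon = _day_at(rng.uniform(0, 0.05, 30), bearings=rng.uniform(0, 2 * np.pi, 30))
        size, span, total = ls.excursion_features(lat, lon, *HOME)
        assert size < 0.05 + 1e-9
        assert span == 0.0

    def test_span_at_most_twice_size(self, rng):
        for _ in range(50):
            n = rng.integers(2, 40)
            lat, lon = _day_at(
                rng.uniform(0, 30, n), bearings=rng.uniform(0, 2 * np.pi, n)
            )
            size, span, _ = ls.excursion_features(lat, lon, *HOME)
            assert span <= 2.0 * size + 1e-9


class TestEntropy:
    def test_closed_forms(self):
        assert ls.dwell_entropy([1.0]) == 0.0
        assert ls.dwell_entropy([0.5, 0.5]) == pytest.approx(np.log(2), rel=1e-12)
        assert ls.dwell_entropy([0.25] * 4) == pytest.approx(np.log(4), rel=1e-12)
        assert ls.dwell_entropy([0.5, 0.5], base=2) == pytest.approx(1.0, rel=1e-12)

    def test_invalid_shares_rejected(self):
        with pytest.raises(ValueError):
            ls.dwell_entropy([0.5, 0.0, 0.5])
        with pytest.raises(ValueError):
            ls.dwell_entropy([0.4, 0.4])

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=10))
    def test_bounds(self, raw):
        p = np.asarray(raw) / np.sum(raw)
        p = p / p.sum()
        h = ls.dwell_entropy(p)
        assert -1e-12 <= h <= np.log(len(p)) + 1e-9


class TestClustering:
    def test_single_tight_blob_is_one_cluster(self, rng):
        lat, lon = _day_at(rng.uniform(0, 0.1, 25), bearings=rng.uniform(0, 2 * np.pi, 25))
        cs = ls.adaptive_kmeans(lat, lon)
        assert cs.n_clusters == 1
        assert cs.dwell_share.tolist() == [1.0]

    def test_two_groups_five_km_apart(self, rng):
        d1 = rng.uniform(0, 0.1, 6)
        d2 = 5.0 + rng.uniform(0, 0.1, 4)
        lat, lon = _day_at(
            np.concatenate([d1, d2]), bearings=np.zeros(10)
        )
        cs = ls.adaptive_kmeans(lat, lon)
        assert cs.n_clusters == 2
        # assignment must match group identity exactly
        assert len(set(cs.labels[:6])) == 1
        assert len(set(cs.labels[6:])) == 1
        assert cs.labels[0] != cs.labels[6]
        np.testing.assert_allclose(sorted(cs.dwell_share), [0.4, 0.6])

    def test_inclusion_radius_always_satisfied(self, rng):
        for _ in range(20):
            n = rng.integers(1, 60)
            lat, lon = _day_at(
                rng.uniform(0, 20, n), bearings=rng.uniform(0, 2 * np.pi, n)
            )
            cs = ls.adaptive_kmeans(lat, lon, cluster_radius_m=500)
            cen = cs.centroids[cs.labels]
            d_m = np.asarray(ls.geodesic_km(lat, lon, cen[:, 0], cen[:, 1])) * 1000
            assert d_m.max() <= 500.0 + 1e-6
            assert cs.dwell_share.sum() == pytest.approx(1.0, abs=1e-12)

    def test_deterministic_under_seed(self, rng):
        lat, lon = _day_at(rng.uniform(0, 10, 30), bearings=rng.uniform(0, 2 * np.pi, 30))
        a = ls.adaptive_kmeans(lat, lon, seed=3)
        b = ls.adaptive_kmeans(lat, lon, seed=3)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_allclose(a.centroids, b.centroids)


class TestEllipseFeatures:
    def test_area_identity(self, rng):
        n = 20
        lat, lon = _day_at(rng.uniform(0, 15, n), bearings=rng.uniform(0, 2 * np.pi, n))
        area, minor, major = ls.ellipse_features(lat, lon)
        assert area == pytest.approx(np.pi / 4.0 * major * minor, rel=1e-9)

    def test_major_bounds_diameter(self, rng):
        for _ in range(20):
            n = rng.integers(3, 40)
            lat, lon = _day_at(
                rng.uniform(0, 25, n), bearings=rng.uniform(0, 2 * np.pi, n)
            )
            _, _, major = ls.ellipse_features(lat, lon)
            diameter = ls.pairwise_geodesic_km(lat, lon).max()
            assert major >= diameter - 1e-3

    def test_monotone_under_radial_scaling(self, rng):
        """Scaling all displacements from home by c > 1 cannot shrink the
        extent features."""
        n = 25
        d = rng.uniform(0.2, 20, n)
        b = rng.uniform(0, 2 * np.pi, n)
        for c in (1.5, 3.0):
            lat1, lon1 = _day_at(d, bearings=b)
            lat2, lon2 = _day_at(c * d, bearings=b)
            s1 = ls.excursion_features(lat1, lon1, *HOME)
            s2 = ls.excursion_features(lat2, lon2, *HOME)
            assert s2[0] >= s1[0] - 1e-9      # excursion size
            assert s2[1] >= s1[1] - 1e-9      # excursion span
            assert s2[2] >= s1[2] - 1e-9      # total distance
            _, _, maj1 = ls.ellipse_features(lat1, lon1)
            _, _, maj2 = ls.ellipse_features(lat2, lon2)
            assert maj2 >= maj1 - 1e-6


class TestDailyComposition:
    def test_homebound_day_limit_values(self, rng):
        n = 48
        lat, lon = _day_at(
            rng.uniform(0, 0.03, n), bearings=rng.uniform(0, 2 * np.pi, n)
        )
        rec = ls.extract_daily_features(_stamps(n), lat, lon, *HOME)
        assert rec["homestay"] == 1.0
        assert rec["n_trips"] == 0
        assert rec["n_clusters"] == 1
        assert rec["entropy"] == 0.0
        assert rec["excursion_span"] == 0.0
        assert rec["excursion_size"] < 0.05
        assert rec["ellipse_area"] < 0.01
        assert rec["valid"]

    def test_short_day_flagged_invalid(self):
        lat, lon = _day_at([0.0, 0.01])
        rec = ls.extract_daily_features(_stamps(2), lat, lon, *HOME)
        assert not rec["valid"]
        assert rec["n_fixes"] == 2

    def test_cohort_table_schema(self, small_cohort):
        feats = ls.extract_cohort(
            small_cohort.fixes.head(96 * 3), small_cohort.demographics
        )
        assert list(feats.columns) == [
            "participant_id",
            "local_date",
            *FEATURE_COLUMNS,
            "n_fixes",
            "valid",
        ]

    def test_home_estimated_from_night_fixes(self, small_cohort):
        pid = small_cohort.demographics.participant_id.iloc[0]
        part = small_cohort.fixes[small_cohort.fixes.participant_id == pid]
        est = ls.estimate_home(part)
        truth = small_cohort.demographics.iloc[0]
        err_km = ls.geodesic_km(est[0], est[1], truth.home_lat, truth.home_lon)
        assert float(err_km) < 0.1
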