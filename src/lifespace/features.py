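"""Daily life-space mobility features from one participant-day of GPS fixes.

Ten features per day, in four families:

* excursion — excursion size (farthest distance from home, km), excursion
  span (farthest pairwise distance among away-from-home fixes, km), and
  total distance travelled (sum of consecutive fix distances, km);
* ellipsoid — area (km^2), minor-axis and major-axis diameters (km) of the
  minimum-area ellipse enclosing all of the day's fixes;
* clustering — number of dwell clusters of the stationary fixes (adaptive
  k-means with a 500 m inclusion radius) and the Shannon entropy of the
  time shares spent in each cluster;
* trips / homestay — number of chronological home -> away -> home trips and
  the fraction of fixes within the 100 m home radius.

Fixes are classified stationary when the time-derivative speed at the fix
is below 1 km/h; only stationary fixes enter the dwell clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon_entropy
from sklearn.cluster import KMeans

from .ellipse import Ellipse, min_enclosing_ellipse
from .geodesy import (
    geodesic_km,
    pairwise_geodesic_km,
    project_local,
    unproject_local,
)

#: the ten daily life-space features, in reporting order
FEATURE_COLUMNS = [
    "excursion_size",
    "excursion_span",
    "total_distance",
    "ellipse_area",
    "ellipse_minor",
    "ellipse_major",
    "n_trips",
    "homestay",
    "n_clusters",
    "entropy",
]

#: human-readable names used in reports
FEATURE_DISPLAY_NAMES = {
    "excursion_size": "Excursion size (km)",
    "excursion_span": "Excursion span (km)",
    "total_distance": "Total distance (km)",
    "ellipse_area": "Ellipse area (km^2)",
    "ellipse_minor": "Ellipse minor axis (km)",
    "ellipse_major": "Ellipse major axis (km)",
    "n_trips": "Frequency of trips",
    "homestay": "Homestay percentage",
    "n_clusters": "Number of clusters",
    "entropy": "Entropy",
}


@dataclass(frozen=True)
class FeatureParams:
    """Tunable thresholds of the feature extractor.

    home_radius_m
        A fix within this great-circle distance of home (inclusive) counts
        as at home.
    cluster_radius_m
        Inclusion criterion of the adaptive k-means: every stationary fix
        must lie within this distance of its cluster centroid.
    speed_threshold_kmh
        Fixes whose time-derivative speed is below this are stationary.
    entropy_base
        Logarithm base for dwell entropy; ``None`` means natural log.
    min_fixes_per_day
        Days with fewer fixes are still summarised but flagged invalid.
    """

    home_radius_m: float = 100.0
    cluster_radius_m: float = 500.0
    speed_threshold_kmh: float = 1.0
    entropy_base: float | None = None
    min_fixes_per_day: int = 10
    seed: int = 0


@dataclass(frozen=True)
class ClusterSet:
    """Dwell clusters of a day's stationary fixes."""

    centroids: np.ndarray  # (k, 2) lat/lon
    labels: np.ndarray     # per stationary fix, cluster index
    dwell_share: np.ndarray  # per cluster, fraction of stationary time

    @property
    def n_clusters(self) -> int:
        return len(self.centroids)


def _elapsed_hours(timestamps) -> np.ndarray:
    ts = pd.to_datetime(pd.Series(list(timestamps)))
    ns = ts.astype("int64").to_numpy()
    dt = np.diff(ns) / 3.6e12
    if np.any(dt <= 0):
        raise ValueError("timestamps must be strictly increasing within a day")
    return dt


def fix_speeds_kmh(timestamps, lats, lons) -> np.ndarray:
    """Time-derivative speed at each fix, km/h.

    The speed at fix k is the distance from fix k-1 divided by the elapsed
    time; the first fix of the day inherits the second fix's speed (a
    single-fix day has speed 0).
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    n = len(lats)
    if n == 0:
        raise ValueError("at least one fix required")
    if n == 1:
        return np.zeros(1)
    dt = _elapsed_hours(timestamps)
    seg = geodesic_km(lats[:-1], lons[:-1], lats[1:], lons[1:])
    speeds = np.empty(n)
    speeds[1:] = seg / dt
    speeds[0] = speeds[1]
    return speeds


def classify_motion(timestamps, lats, lons, speed_threshold_kmh: float = 1.0):
    """Label each fix stationary (True) or moving (False).

    Returns ``(speeds_kmh, stationary)``; a fix is stationary iff its speed
    is strictly below the threshold.
    """
    speeds = fix_speeds_kmh(timestamps, lats, lons)
    return speeds, speeds < speed_threshold_kmh


def home_away_labels(lats, lons, home_lat, home_lon, home_radius_m: float = 100.0):
    """True where a fix is within ``home_radius_m`` (inclusive) of home."""
    d_km = geodesic_km(home_lat, home_lon, np.asarray(lats, float), np.asarray(lons, float))
    return np.asarray(d_km) * 1000.0 <= home_radius_m


def homestay(home_labels) -> float:
    """Fraction of the day's fixes that are at home, in [0, 1]."""
    labels = np.asarray(home_labels, dtype=bool)
    if labels.size == 0:
        raise ValueError("at least one label required")
    return float(labels.mean())


def count_trips(home_labels) -> int:
    """Number of chronological home -> away -> home excursions.

    A trip is a maximal run of away labels immediately preceded and
    followed by a home label; away runs truncated by the start or end of
    the day are not counted.
    """
    labels = np.asarray(home_labels, dtype=bool)
    if labels.size == 0:
        raise ValueError("at least one label required")
    away = ~labels
    if away.sum() == 0:
        return 0
    run_start_idx = np.flatnonzero(away & ~np.concatenate([[False], away[:-1]]))
    run_end_idx = np.flatnonzero(away & ~np.concatenate([away[1:], [False]]))
    trips = 0
    for s, e in zip(run_start_idx, run_end_idx):
        bounded_left = s > 0 and labels[s - 1]
        bounded_right = e < len(labels) - 1 and labels[e + 1]
        if bounded_left and bounded_right:
            trips += 1
    return trips


def excursion_features(
    lats, lons, home_lat, home_lon, home_radius_m: float = 100.0
):
    """(excursion_size, excursion_span, total_distance), all in km."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    if len(lats) == 0:
        raise ValueError("at least one fix required")
    d_home = np.asarray(geodesic_km(home_lat, home_lon, lats, lons))
    size = float(d_home.max())
    away = d_home * 1000.0 > home_radius_m
    if away.sum() >= 2:
        span = float(pairwise_geodesic_km(lats[away], lons[away]).max())
    else:
        span = 0.0
    if len(lats) >= 2:
        total = float(
            np.sum(geodesic_km(lats[:-1], lons[:-1], lats[1:], lons[1:]))
        )
    else:
        total = 0.0
    return size, span, total


def dwell_entropy(dwell_share, base: float | None = None) -> float:
    """Shannon entropy of cluster time shares, H = -sum p_i log p_i.

    Shares must be strictly positive and sum to 1 (tolerance 1e-9); zero
    shares are rejected because an empty cluster carries no dwell time.
    """
    p = np.asarray(dwell_share, dtype=float)
    if p.size == 0:
        raise ValueError("at least one share required")
    if np.any(p <= 0.0):
        raise ValueError("dwell shares must be in (0, 1]")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("dwell shares must sum to 1")
    return float(_shannon_entropy(p, base=base))


def _farthest_point_seeds(points: np.ndarray, k: int) -> np.ndarray:
    """Deterministic farthest-point initialisation for k-means.

    The first seed is the point farthest from the cloud centroid (lowest
    index on ties); each subsequent seed maximises the distance to its
    nearest already-chosen seed.
    """
    center = points.mean(axis=0)
    d0 = np.linalg.norm(points - center, axis=1)
    seeds = [int(np.argmax(d0))]
    min_dist = np.linalg.norm(points - points[seeds[0]], axis=1)
    while len(seeds) < k:
        nxt = int(np.argmax(min_dist))
        seeds.append(nxt)
        min_dist = np.minimum(min_dist, np.linalg.norm(points - points[nxt], axis=1))
    return points[seeds]


def adaptive_kmeans(
    lats,
    lons,
    cluster_radius_m: float = 500.0,
    max_k: int | None = None,
    seed: int = 0,
) -> ClusterSet:
    """Cluster stationary fixes with an adaptively chosen number of clusters.

    Starting from k = 1, k-means (deterministic farthest-point seeding,
    at most 300 Lloyd iterations per k) is re-run with increasing k until
    every fix lies within ``cluster_radius_m`` of its assigned centroid,
    measured geodesically.  Empty clusters are dropped, and dwell shares
    are the fraction of stationary fixes per cluster.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    n = len(lats)
    if n == 0:
        raise ValueError("at least one stationary fix required")
    origin = (float(lats.mean()), float(lons.mean()))
    x, y = project_local(lats, lons, *origin)
    points = np.column_stack([x, y])
    n_distinct = len(np.unique(points, axis=0))
    if max_k is None:
        max_k = n_distinct
    for k in range(1, min(max_k, n_distinct) + 1):
        if k == 1:
            centers = points.mean(axis=0, keepdims=True)
            labels = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k,
                init=_farthest_point_seeds(points, k),
                n_init=1,
                max_iter=300,
                random_state=seed,
            ).fit(points)
            labels = km.labels_.astype(int)
            centers = km.cluster_centers_
        # drop empty clusters and relabel contiguously
        occupied = np.unique(labels)
        remap = {old: new for new, old in enumerate(occupied)}
        labels = np.array([remap[v] for v in labels])
        centers = centers[occupied]
        cen_lat, cen_lon = unproject_local(centers[:, 0], centers[:, 1], *origin)
        d_m = (
            np.asarray(geodesic_km(lats, lons, cen_lat[labels], cen_lon[labels]))
            * 1000.0
        )
        if d_m.max() <= cluster_radius_m:
            counts = np.bincount(labels, minlength=len(centers))
            return ClusterSet(
                centroids=np.column_stack([cen_lat, cen_lon]),
                labels=labels,
                dwell_share=counts / counts.sum(),
            )
    # unreachable in principle: k = number of distinct points always satisfies
    raise RuntimeError("adaptive k-means failed to satisfy the inclusion radius")


def day_ellipse(lats, lons) -> Ellipse:
    """Minimum-area ellipse of all the day's fixes, in a local plane about
    their centroid."""
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    origin = (float(lats.mean()), float(lons.mean()))
    x, y = project_local(lats, lons, *origin)
    return min_enclosing_ellipse(np.column_stack([x, y]))


def ellipse_features(lats, lons):
    """(area km^2, minor-axis diameter km, major-axis diameter km)."""
    ell = day_ellipse(lats, lons)
    return ell.area, 2.0 * ell.semi_minor, 2.0 * ell.semi_major


def extract_daily_features(
    timestamps,
    lats,
    lons,
    home_lat: float,
    home_lon: float,
    params: FeatureParams | None = None,
) -> dict:
    """All ten life-space features for one participant-day.

    Returns a plain dict with the :data:`FEATURE_COLUMNS` keys plus
    ``n_fixes`` and ``valid``.  Days with fewer than
    ``params.min_fixes_per_day`` fixes are summarised anyway but flagged
    ``valid=False``.  A day with no stationary fix yields ``n_clusters=0``
    and entropy 0.
    """
    params = params or FeatureParams()
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    n = len(lats)
    speeds, stationary = classify_motion(
        timestamps, lats, lons, params.speed_threshold_kmh
    )
    at_home = home_away_labels(lats, lons, home_lat, home_lon, params.home_radius_m)
    size, span, total = excursion_features(
        lats, lons, home_lat, home_lon, params.home_radius_m
    )
    area, minor, major = ellipse_features(lats, lons)
    if stationary.any():
        clusters = adaptive_kmeans(
            lats[stationary],
            lons[stationary],
            cluster_radius_m=params.cluster_radius_m,
            seed=params.seed,
        )
        n_clusters = clusters.n_clusters
        ent = dwell_entropy(clusters.dwell_share, base=params.entropy_base)
    else:
        n_clusters = 0
        ent = 0.0
    return {
        "excursion_size": size,
        "excursion_span": span,
        "total_distance": total,
        "ellipse_area": area,
        "ellipse_minor": minor,
        "ellipse_major": major,
        "n_trips": count_trips(at_home),
        "homestay": homestay(at_home),
        "n_clusters": n_clusters,
        "entropy": ent,
        "n_fixes": n,
        "valid": bool(n >= params.min_fixes_per_day),
    }


def estimate_home(fixes: pd.DataFrame, params: FeatureParams | None = None):
    """Estimate a participant's home as the centroid of the modal
    night-time (midnight to 6 AM local) dwell cluster.

    Falls back to all fixes when no night-time fixes exist.
    """
    params = params or FeatureParams()
    hours = fixes["timestamp"].dt.hour
    night = fixes[(hours >= 0) & (hours < 6)]
    if len(night) == 0:
        night = fixes
    clusters = adaptive_kmeans(
        night["lat"].to_numpy(),
        night["lon"].to_numpy(),
        cluster_radius_m=params.cluster_radius_m,
        seed=params.seed,
    )
    modal = int(np.argmax(clusters.dwell_share))
    return float(clusters.centroids[modal, 0]), float(clusters.centroids[modal, 1])


def extract_cohort(
    fixes: pd.DataFrame,
    homes: pd.DataFrame | None = None,
    params: FeatureParams | None = None,
) -> pd.DataFrame:
    """Daily feature table for a whole cohort.

    Parameters
    ----------
    fixes
        Columns ``participant_id, timestamp, lat, lon``; timestamps
        timezone-aware.  Days are bucketed by the local civil date carried
        in the timestamp offset.
    homes
        Optional frame with ``participant_id, home_lat, home_lon``; when
        absent each participant's home is estimated from night-time fixes.
    """
    params = params or FeatureParams()
    if homes is not None:
        home_map = {
            row.participant_id: (row.home_lat, row.home_lon)
            for row in homes.itertuples()
        }
    else:
        home_map = {}
    rows = []
    for pid, part in fixes.groupby("participant_id", sort=True):
        if pid not in home_map:
            home_map[pid] = estimate_home(part, params)
        hlat, hlon = home_map[pid]
        for date, day in part.groupby(part["timestamp"].dt.date, sort=True):
            day = day.sort_values("timestamp")
            rec = extract_daily_features(
                day["timestamp"],
                day["lat"].to_numpy(),
                day["lon"].to_numpy(),
                hlat,
                hlon,
                params,
            )
            rec["participant_id"] = pid
            rec["local_date"] = date
            rows.append(rec)
    cols = ["participant_id", "local_date", *FEATURE_COLUMNS, "n_fixes", "valid"]
    return pd.DataFrame(rows, columns=cols)
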