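"""Synthetic smartwatch cohort with known pain -> mobility effects.

Real GPS/EMA data from older adults are identifiable and rarely shared, so
every downstream stage of the pipeline is exercised against a simulated
cohort whose ground truth is known.  The generator emulates the study
conditions of a small knee-osteoarthritis smartwatch deployment:

* participants wear the device for Normal(13.16, 2.94) days (rounded,
  floored at 1), with one GPS fix every 15 minutes;
* three pain prompts per day at random times in the morning (8-12),
  afternoon (12-16) and evening (16-20) windows, each answered with
  probability 0.82;
* a latent day-level pain score p_id = clamp(round(mu_i + eps_id), 0, 10)
  with person means mu_i ~ Normal(grand_mean, between_sd) and day
  deviations eps_id ~ Normal(0, within_sd);
* home-anchored travel: each day consists of 0-3 out-and-back trips from
  home whose farthest-point distance equals
  max(0, base_i + beta_between * (mu_i - grand_mean)
         + beta_within * (p_id - mu_i) + noise),
  so the within- and between-person effects of pain on excursion size are
  known exactly;
* overnight (8 PM - 8 AM) fixes sit at home plus isotropic GPS noise.

The day-level stage (pain, prompts, intended excursion size) is exposed on
its own through :func:`generate_day_panel` for fast statistical
simulation; :func:`generate_cohort` additionally synthesises the GPS fix
streams realising those intended excursions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from datetime import date, datetime, timedelta, timezone
from typing import NamedTuple

import numpy as np
import pandas as pd

from .geodesy import destination_point, unproject_local

PROMPT_WINDOWS = ("morning", "afternoon", "evening")
_WINDOW_START_H = {"morning": 8.0, "afternoon": 12.0, "evening": 16.0}

#: local civil time boundaries of the waking day, hours
WAKING_START_H = 8.0
WAKING_END_H = 20.0


@dataclass
class CohortConfig:
    """All knobs of the synthetic cohort.

    Defaults reproduce the study conditions described in the module
    docstring; distances in km, GPS noise in metres, pain in 0-10 points.
    ``beta_within`` / ``beta_between`` are per-feature maps (km per pain
    point); only the ``"excursion_size"`` entry drives trip geometry, the
    other features responding through the induced geometry.
    """

    n_participants: int = 19
    mean_days: float = 13.16
    sd_days: float = 2.94
    fix_interval: float = 15.0           # minutes
    prompt_response_rate: float = 0.82
    pain_grand_mean: float = 1.0
    pain_between_sd: float = 1.2
    pain_within_sd: float = 1.5
    beta_within: dict = field(default_factory=lambda: {"excursion_size": -3.06})
    beta_between: dict = field(default_factory=lambda: {"excursion_size": -3.79})
    gps_noise_sd: float = 10.0           # metres, isotropic
    base_excursion_mean: float = 25.0    # km, participant mobility intercept
    base_excursion_sd: float = 5.0
    base_excursion_min: float = 10.0
    excursion_noise_sd: float = 4.0      # km, day-level noise
    prompt_jitter_prob: float = 0.0      # chance a prompt rating moves +/-1
    age_mean: float = 73.1
    age_sd: float = 4.8
    prop_female: float = 0.68
    prop_live_alone: float = 0.21
    region_lat: float = 29.65
    region_lon: float = -82.35
    region_extent_km: float = 30.0
    start_date: str = "2020-01-06"
    utc_offset_hours: float = -5.0
    seed: int = 0

    def __post_init__(self):
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not math.isfinite(v):
                raise ValueError(f"non-finite config value for {f.name}")
        if self.n_participants < 2:
            raise ValueError(
                "n_participants must be >= 2 (between-person effect undefined)"
            )
        for name in (
            "prompt_response_rate",
            "prompt_jitter_prob",
            "prop_female",
            "prop_live_alone",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "sd_days",
            "pain_between_sd",
            "pain_within_sd",
            "gps_noise_sd",
            "base_excursion_sd",
            "excursion_noise_sd",
            "age_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.fix_interval <= 0:
            raise ValueError("fix_interval must be > 0")
        for m in (self.beta_within, self.beta_between):
            if any(not math.isfinite(v) for v in m.values()):
                raise ValueError("non-finite effect coefficient")

    @property
    def tzinfo(self) -> timezone:
        return timezone(timedelta(hours=self.utc_offset_hours))


class Cohort(NamedTuple):
    """Output bundle of :func:`generate_cohort` (all pandas DataFrames)."""

    fixes: pd.DataFrame
    prompts: pd.DataFrame
    demographics: pd.DataFrame
    ground_truth: pd.DataFrame


def _rng_streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _simulate_participants(config: CohortConfig, rng: np.random.Generator):
    n = config.n_participants
    pid = np.array([f"P{i + 1:03d}" for i in range(n)])
    half = config.region_extent_km / 2.0
    hx = rng.uniform(-half, half, n)
    hy = rng.uniform(-half, half, n)
    home_lat, home_lon = unproject_local(hx, hy, config.region_lat, config.region_lon)
    n_days = np.maximum(
        1, np.rint(rng.normal(config.mean_days, config.sd_days, n)).astype(int)
    )
    mu_pain = rng.normal(config.pain_grand_mean, config.pain_between_sd, n)
    base = np.maximum(
        config.base_excursion_min,
        rng.normal(config.base_excursion_mean, config.base_excursion_sd, n),
    )
    age = np.rint(rng.normal(config.age_mean, config.age_sd, n)).astype(int)
    female = (rng.uniform(size=n) < config.prop_female).astype(int)
    alone = (rng.uniform(size=n) < config.prop_live_alone).astype(int)
    return pd.DataFrame(
        {
            "participant_id": pid,
            "home_lat": home_lat,
            "home_lon": home_lon,
            "n_days": n_days,
            "mu_pain": mu_pain,
            "base_km": base,
            "age": age,
            "female": female,
            "lives_alone": alone,
        }
    )


def _simulate_days(config: CohortConfig, participants: pd.DataFrame, rng):
    """Per participant-day latent pain, prompts and intended excursion."""
    bw = config.beta_within.get("excursion_size", 0.0)
    bb = config.beta_between.get("excursion_size", 0.0)
    start = date.fromisoformat(config.start_date)
    recs = []
    for p in participants.itertuples():
        for d in range(int(p.n_days)):
            eps = rng.normal(0.0, config.pain_within_sd)
            pain = float(np.clip(np.rint(p.mu_pain + eps), 0, 10))
            intended = max(
                0.0,
                p.base_km
                + bb * (p.mu_pain - config.pain_grand_mean)
                + bw * (pain - p.mu_pain)
                + rng.normal(0.0, config.excursion_noise_sd),
            )
            answered = rng.uniform(size=3) < config.prompt_response_rate
            ratings = np.full(3, pain)
            jitter_mask = rng.uniform(size=3) < config.prompt_jitter_prob
            jitter = rng.choice([-1.0, 1.0], size=3)
            ratings = np.clip(ratings + jitter_mask * jitter, 0, 10)
            recs.append(
                {
                    "participant_id": p.participant_id,
                    "local_date": start + timedelta(days=d),
                    "mu_pain": p.mu_pain,
                    "pain_latent": pain,
                    "intended_excursion_km": intended,
                    "base_km": p.base_km,
                    "answered_1": bool(answered[0]),
                    "answered_2": bool(answered[1]),
                    "answered_3": bool(answered[2]),
                    "rating_1": ratings[0],
                    "rating_2": ratings[1],
                    "rating_3": ratings[2],
                }
            )
    return pd.DataFrame(recs)


def generate_day_panel(config: CohortConfig) -> pd.DataFrame:
    """Day-level panel of the generative model without GPS synthesis.

    One row per participant-day with the latent pain, the intended (true)
    excursion size, the observed day-mean pain after prompt non-response,
    and the person-level covariates.  Deterministic under ``config.seed``
    and identical to the day-level truth underlying
    :func:`generate_cohort` with the same config.
    """
    rng_part, rng_days = _rng_streams(config.seed, 4)[:2]
    participants = _simulate_participants(config, rng_part)
    days = _simulate_days(config, participants, rng_days)
    answered = days[["answered_1", "answered_2", "answered_3"]].to_numpy()
    ratings = days[["rating_1", "rating_2", "rating_3"]].to_numpy()
    n_answered = answered.sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean_obs = np.where(
            n_answered > 0,
            (ratings * answered).sum(axis=1) / np.maximum(n_answered, 1),
            np.nan,
        )
    panel = days[
        [
            "participant_id",
            "local_date",
            "mu_pain",
            "pain_latent",
            "base_km",
            "intended_excursion_km",
        ]
    ].copy()
    panel["n_answered"] = n_answered
    panel["mean_pain"] = mean_obs
    panel = panel.merge(
        participants[["participant_id", "age", "female", "lives_alone"]],
        on="participant_id",
    )
    return panel


def _plan_trips(intended_km: float, rng) -> list[dict]:
    """Out-and-back trip plan realising the intended farthest distance.

    Each trip: departure hour, one-way distance, bearing, speed and dwell
    at the endpoint; the main trip reaches exactly ``intended_km``.
    """
    if intended_km < 0.3:
        return []
    dists = [intended_km]
    for extra_d in intended_km * rng.uniform(0.15, 0.8, rng.integers(0, 3)):
        dists.append(float(extra_d))
    trips = []
    for dist in dists:
        dwell = rng.uniform(0.5, 2.0)
        speed = max(rng.uniform(5.0, 40.0), 2.0 * dist / 3.5)
        trips.append(
            {
                "dist": dist,
                "speed": speed,
                "dwell": dwell,
                "bearing": rng.uniform(0.0, 2.0 * np.pi),
                "duration": 2.0 * dist / speed + dwell,
            }
        )
    while len(trips) > 1 and sum(t["duration"] for t in trips) > 11.0:
        trips.pop()
    slack = (WAKING_END_H - WAKING_START_H) - sum(t["duration"] for t in trips)
    gaps = rng.dirichlet(np.ones(len(trips) + 1)) * max(slack, 0.0)
    t = WAKING_START_H
    for gap, trip in zip(gaps, trips):
        t += gap
        trip["start"] = t
        t += trip["duration"]
    return trips


def _day_positions(trips: list[dict], t_hours: np.ndarray):
    """Distance-from-home (km) and bearing at each fix time."""
    r = np.zeros_like(t_hours)
    bearing = np.zeros_like(t_hours)
    for trip in trips:
        out_t = trip["dist"] / trip["speed"]
        rel = t_hours - trip["start"]
        on_trip = (rel >= 0) & (rel < trip["duration"])
        seg = np.clip(rel, 0.0, None)
        dist = np.where(
            seg < out_t,
            seg * trip["speed"],
            np.where(
                seg < out_t + trip["dwell"],
                trip["dist"],
                np.clip(trip["dist"] - (seg - out_t - trip["dwell"]) * trip["speed"], 0.0, None),
            ),
        )
        r = np.where(on_trip, dist, r)
        bearing = np.where(on_trip, trip["bearing"], bearing)
    return r, bearing


def generate_cohort(config: CohortConfig) -> Cohort:
    """Full synthetic cohort: GPS fixes, EMA prompts, demographics, truth.

    Deterministic under ``config.seed``: identical configs give identical
    tables.
    """
    rng_part, rng_days, rng_traj, rng_prompt = _rng_streams(config.seed, 4)
    participants = _simulate_participants(config, rng_part)
    days = _simulate_days(config, participants, rng_days)
    tz = config.tzinfo
    minute_grid = np.arange(0.0, 24.0 * 60.0, config.fix_interval)
    t_hours = minute_grid / 60.0
    waking = (t_hours >= WAKING_START_H) & (t_hours < WAKING_END_H)
    noise_km = config.gps_noise_sd / 1000.0

    home_by_pid = participants.set_index("participant_id")
    fix_frames = []
    prompt_recs = []
    for day in days.itertuples():
        home = home_by_pid.loc[day.participant_id]
        trips = _plan_trips(day.intended_excursion_km, rng_traj)
        r, bearing = _day_positions(trips, t_hours)
        r = np.where(waking, r, 0.0)  # overnight at home
        lat, lon = destination_point(home.home_lat, home.home_lon, bearing, r)
        nx = rng_traj.normal(0.0, noise_km, len(r))
        ny = rng_traj.normal(0.0, noise_km, len(r))
        lat, lon = unproject_local(nx, ny, lat, lon)
        midnight = datetime.combine(day.local_date, datetime.min.time(), tz)
        stamps = pd.Timestamp(midnight) + pd.to_timedelta(minute_grid, unit="m")
        fix_frames.append(
            pd.DataFrame(
                {
                    "participant_id": day.participant_id,
                    "timestamp": stamps,
                    "lat": lat,
                    "lon": lon,
                }
            )
        )
        for k, window in enumerate(PROMPT_WINDOWS):
            # whole minutes, truncated so the prompt stays inside its window
            offset_min = int(_WINDOW_START_H[window] * 60.0) + int(
                rng_prompt.uniform(0.0, 4.0) * 60.0
            )
            ts = pd.Timestamp(midnight) + pd.to_timedelta(offset_min, unit="m")
            answered = getattr(day, f"answered_{k + 1}")
            rating = getattr(day, f"rating_{k + 1}") if answered else np.nan
            prompt_recs.append(
                {
                    "participant_id": day.participant_id,
                    "timestamp": ts,
                    "window": window,
                    "rating": rating,
                }
            )

    fixes = pd.concat(fix_frames, ignore_index=True)
    fixes = fixes.sort_values(["participant_id", "timestamp"], ignore_index=True)
    prompts = pd.DataFrame(prompt_recs).sort_values(
        ["participant_id", "timestamp"], ignore_index=True
    )
    demographics = participants[
        ["participant_id", "age", "female", "lives_alone", "home_lat", "home_lon"]
    ].copy()
    bw = config.beta_within.get("excursion_size", 0.0)
    bb = config.beta_between.get("excursion_size", 0.0)
    truth = days[
        [
            "participant_id",
            "local_date",
            "mu_pain",
            "pain_latent",
            "base_km",
            "intended_excursion_km",
        ]
    ].copy()
    truth["beta_within_used"] = bw
    truth["beta_between_used"] = bb
    truth = truth.merge(
        participants[["participant_id", "home_lat", "home_lon"]], on="participant_id"
    )
    return Cohort(fixes, prompts, demographics, truth)


def drop_gps_days(
    fixes: pd.DataFrame, missing_participant_fraction: float, seed: int
) -> pd.DataFrame:
    """Remove all fixes of a random subset of participants.

    Emulates missing-at-random device failures that render a participant's
    GPS stream unusable.  Deterministic under ``seed``.
    """
    if not 0.0 <= missing_participant_fraction < 1.0:
        raise ValueError("missing_participant_fraction must be in [0, 1)")
    ids = np.array(sorted(fixes["participant_id"].unique()))
    n_drop = int(round(missing_participant_fraction * len(ids)))
    if n_drop == 0:
        return fixes.copy()
    dropped = np.random.default_rng(seed).choice(ids, size=n_drop, replace=False)
    return fixes[~fixes["participant_id"].isin(dropped)].reset_index(drop=True)
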