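"""CSV formats, configuration and the simulate -> analyze pipeline.

All tables are plain CSV.  GPS fixes carry ISO-8601 timestamps with a UTC
offset; day bucketing uses the local civil date implied by that offset.
Every pipeline run writes the fully resolved configuration next to its
outputs so any result can be regenerated from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import (
    FEATURE_COLUMNS,
    FEATURE_DISPLAY_NAMES,
    FeatureParams,
    extract_cohort,
)
from .model import build_panel, fit_all_features
from .pain import aggregate_daily_pain
from .synthetic import CohortConfig, generate_cohort

log = logging.getLogger("lifespace")

FIX_COLUMNS = ["participant_id", "timestamp", "lat", "lon"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    """Resolved configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    features: FeatureParams = field(default_factory=FeatureParams)
    min_prompts: int = 1
    grand: str = "person_mean"
    reml: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d or {})
        cohort = CohortConfig(**d.pop("cohort", {}))
        feats = FeatureParams(**d.pop("features", {}))
        return cls(cohort=cohort, features=feats, **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def read_fixes(path) -> pd.DataFrame:
    """Read and validate a GPS fix table.

    Rows are sorted by participant then time; malformed coordinates,
    unparseable timestamps and duplicate (participant, timestamp) pairs
    are rejected with their (1-based, header-exclusive) row numbers.
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: empty fix table")
    missing = [c for c in FIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    ts = pd.to_datetime(df["timestamp"], format="ISO8601", errors="coerce", utc=False)
    bad = np.flatnonzero(ts.isna())
    if len(bad):
        raise ValueError(f"{path}: unparseable timestamps at rows {(bad + 1).tolist()[:10]}")
    df = df.assign(timestamp=ts)
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    out_of_range = (
        lat.isna() | lon.isna() | (lat.abs() > 90.0) | (lon <= -180.0) | (lon > 180.0)
    )
    bad = np.flatnonzero(out_of_range)
    if len(bad):
        raise ValueError(f"{path}: invalid coordinates at rows {(bad + 1).tolist()[:10]}")
    df = df.assign(lat=lat, lon=lon)
    dup = df.duplicated(subset=["participant_id", "timestamp"])
    if dup.any():
        rows = (np.flatnonzero(dup) + 1).tolist()[:10]
        raise ValueError(f"{path}: duplicate (participant, timestamp) at rows {rows}")
    return df.sort_values(["participant_id", "timestamp"], ignore_index=True)


def read_prompts(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValueError(f"{path}: empty prompt table")
    df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    df["rating"] = pd.to_numeric(df["rating"], errors="coerce")
    return df.sort_values(["participant_id", "timestamp"], ignore_index=True)


def read_demographics(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["participant_id", "age", "female", "lives_alone"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def _read_dated(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["local_date"] = pd.to_datetime(df["local_date"]).dt.date
    return df


def read_features(path) -> pd.DataFrame:
    return _read_dated(path)


def read_pain_days(path) -> pd.DataFrame:
    return _read_dated(path)


def render_report(results: pd.DataFrame, n_obs: int | None = None) -> str:
    """Human-readable markdown table of the pain coefficients per feature."""
    lines = [
        "# Mixed-effect association between pain and life-space features",
        "",
        "Adjusted for age, living alone and gender; participant random",
        "intercept with independent within-person residuals; z inference.",
        "",
        "| GPS feature | Effect | Coefficient | SE | P>\\|z\\| | 95% CI |",
        "|---|---|---|---|---|---|",
    ]
    for feature in FEATURE_COLUMNS:
        sub = results[results["feature"] == feature]
        display = FEATURE_DISPLAY_NAMES.get(feature, feature)
        for term, label in (("pain_between", "Between"), ("pain_within", "Within")):
            row = sub[sub["term"] == term]
            if len(row) == 0 or not np.isfinite(row.iloc[0].get("coef", np.nan)):
                status = sub["status"].iloc[0] if len(sub) else "missing"
                lines.append(f"| {display} | {label} | — | — | — | {status} |")
                continue
            r = row.iloc[0]
            lines.append(
                f"| {display} | {label} | {r['coef']:.2f} | {r['se']:.2f} "
                f"| {r['p_value']:.2f} | {r['ci_low']:.2f}, {r['ci_high']:.2f} |"
            )
    if n_obs is not None:
        lines += ["", f"Participant-days modelled: {n_obs}."]
    lines.append("")
    return "\n".join(lines)


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """simulate -> extract -> aggregate pain -> join -> model -> report.

    Writes fixes.csv, prompts.csv, demographics.csv, ground_truth.csv,
    features.csv, pain_days.csv, panel.csv, model_results.csv, report.md
    and config.yaml into ``outdir`` and returns its path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "simulate"
    try:
        cohort = generate_cohort(config.cohort)
        log.info(
            "simulate: %d fixes, %d prompts, %d participants",
            len(cohort.fixes),
            len(cohort.prompts),
            len(cohort.demographics),
        )
        cohort.fixes.to_csv(outdir / "fixes.csv", index=False)
        cohort.prompts.to_csv(outdir / "prompts.csv", index=False)
        cohort.demographics.to_csv(outdir / "demographics.csv", index=False)
        cohort.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)

        stage = "extract"
        features = extract_cohort(cohort.fixes, cohort.demographics, config.features)
        log.info("extract: %d participant-days", len(features))
        features.to_csv(outdir / "features.csv", index=False)

        stage = "pain"
        pain_days = aggregate_daily_pain(cohort.prompts, min_prompts=config.min_prompts)
        answered = pain_days["n_answered"].sum()
        log.info(
            "pain: %d pain-days, %d answered prompts (rate %.3f)",
            len(pain_days),
            answered,
            answered / (3 * len(pain_days)),
        )
        pain_days.to_csv(outdir / "pain_days.csv", index=False)

        stage = "panel"
        panel = build_panel(features, pain_days, cohort.demographics)
        log.info("panel: %d modellable participant-days", len(panel))
        panel.to_csv(outdir / "panel.csv", index=False)

        stage = "analyze"
        results = fit_all_features(
            panel, grand=config.grand, reml=config.reml
        )
        results.to_csv(outdir / "model_results.csv", index=False)

        stage = "report"
        report = render_report(results, n_obs=len(panel))
        (outdir / "report.md").write_text(report)
        config.to_yaml(outdir / "config.yaml")
        (outdir / "VERSION").write_text(f"lifespace {__version__}\n")
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(stage, exc) from exc
    return outdir
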