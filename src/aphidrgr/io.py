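"""CSV / JSON / YAML plumbing for the survey-analysis pipeline.

Conventions: comma-separated UTF-8 CSV with a mandatory header row and '.'
decimal separator; dates are ISO-8601 calendar dates; metadata (config hash
and seed) travels in '#'-prefixed comment lines at the top of every output
file so any artifact can be traced to the run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .surface import RGRParams
from .smoothing import RGRSeries
from .synthetic import (
    FieldSurvey,
    NoiseParams,
    SeasonalParams,
    SimulationConfig,
    TemperatureSeries,
)

__all__ = [
    "PipelineConfig",
    "config_hash",
    "load_config",
    "read_survey_csv",
    "write_survey_csv",
    "read_weather_csv",
    "write_weather_csv",
    "write_rgr_csv",
    "read_rgr_csv",
    "write_json",
]

logger = logging.getLogger(__name__)

SURVEY_COLUMNS = ["field_id", "region", "date", "tillers", "aphids", "stage"]
ENEMY_COLUMNS = ["e_kills", "mummies"]
WEATHER_COLUMNS = ["date", "t_min", "t_mean", "t_max"]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Run configuration: fixed constants, fit options, simulation set-up."""

    seed: int = 0
    theta_max: float = 30.0
    s_max: float = 92.0
    with_enemies: bool = False
    max_iter: int = 200
    tol: float = 1e-8
    n_fields_fit: int = 17
    n_fields_test: int = 9
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"]["true_params"] = self.simulation.true_params.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = dict(d.pop("simulation", {}))
        if "true_params" in sim:
            sim["true_params"] = RGRParams.from_dict(sim["true_params"])
        if "seasonal" in sim:
            sim["seasonal"] = SeasonalParams(**sim["seasonal"])
        if "noise" in sim:
            sim["noise"] = NoiseParams(**sim["noise"])
        if "enemy_rates" in sim:
            sim["enemy_rates"] = tuple(sim["enemy_rates"])
        d["simulation"] = SimulationConfig(**sim)
        return cls(**d)


def config_hash(config: PipelineConfig) -> str:
    """Short stable digest of the resolved configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    """Read a pipeline configuration from a YAML or JSON file."""
    text = Path(path).read_text(encoding="utf-8")
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} did not parse to a mapping")
    return PipelineConfig.from_dict(data)


def _metadata_header(meta: Optional[dict]) -> str:
    if not meta:
        return ""
    parts = " ".join(f"{k}={v}" for k, v in meta.items())
    return f"# aphidrgr {parts}\n"


# ---------------------------------------------------------------------------
# survey CSV
# ---------------------------------------------------------------------------

def write_survey_csv(survey: FieldSurvey, path, meta: Optional[dict] = None) -> None:
    df = survey.to_frame()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_metadata_header(meta))
        df.to_csv(fh, index=False)


def _reject(path, row: int, message: str):
    raise ValueError(f"{path}, data row {row}: {message}")


def read_survey_csv(path) -> list[FieldSurvey]:
    """Read one or more field surveys from CSV, validating every invariant.

    Returns a list of FieldSurvey (the file may pool several field-years);
    violations are rejected with the offending data-row number (1-based,
    excluding header and comment lines).
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in SURVEY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    has_enemies = all(c in df.columns for c in ENEMY_COLUMNS)
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    for i in np.flatnonzero(dates.isna().to_numpy()):
        _reject(path, i + 1, f"unparseable date {df['date'].iloc[i]!r} (need YYYY-MM-DD)")
    df = df.assign(date=dates)
    for col in ("tillers", "aphids") + (tuple(ENEMY_COLUMNS) if has_enemies else ()):
        vals = pd.to_numeric(df[col], errors="coerce")
        for i in np.flatnonzero(vals.isna().to_numpy()):
            _reject(path, i + 1, f"non-numeric {col} {df[col].iloc[i]!r}")
        for i in np.flatnonzero((vals < 0).to_numpy()):
            _reject(path, i + 1, f"negative {col} ({vals.iloc[i]})")
    for i in np.flatnonzero(((df["tillers"] < 50) | (df["tillers"] > 1000)).to_numpy()):
        _reject(path, i + 1, f"tillers={df['tillers'].iloc[i]} outside [50, 1000]")

    surveys = []
    for field_id, sub in df.groupby("field_id", sort=True):
        sub = sub.reset_index()  # keep original row numbers in 'index'
        dec = np.flatnonzero(np.diff(sub["stage"].to_numpy(float)) < -1e-9)
        if dec.size:
            _reject(path, int(sub["index"].iloc[dec[0] + 1]) + 1,
                    f"growth stage decreases within field {field_id!r}")
        try:
            surveys.append(
                FieldSurvey(
                    field_id=str(field_id),
                    region=str(sub["region"].iloc[0]),
                    dates=pd.DatetimeIndex(sub["date"]),
                    tillers=sub["tillers"].to_numpy(int),
                    aphids=sub["aphids"].to_numpy(int),
                    stage=sub["stage"].to_numpy(float),
                    e_kills=sub["e_kills"].to_numpy(int) if has_enemies else None,
                    mummies=sub["mummies"].to_numpy(int) if has_enemies else None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}, field {field_id!r}: {exc}") from exc
    return surveys


# ---------------------------------------------------------------------------
# weather CSV
# ---------------------------------------------------------------------------

def write_weather_csv(temps: TemperatureSeries, path, meta: Optional[dict] = None) -> None:
    df = temps.to_frame()
    df["date"] = df["date"].dt.strftime("%Y-%m-%d")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_metadata_header(meta))
        df.to_csv(fh, index=False)


def read_weather_csv(path) -> TemperatureSeries:
    """Read a daily temperature series; interior gaps are filled by linear
    interpolation with a logged warning, ordering violations are rejected."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in WEATHER_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing mandatory columns {missing}")
    dates = pd.to_datetime(df["date"], format="%Y-%m-%d", errors="coerce")
    for i in np.flatnonzero(dates.isna().to_numpy()):
        _reject(path, i + 1, f"unparseable date {df['date'].iloc[i]!r}")
    bad = np.flatnonzero((df["t_min"] > df["t_max"]).to_numpy())
    if bad.size:
        _reject(path, int(bad[0]) + 1,
                f"t_min={df['t_min'].iloc[bad[0]]} > t_max={df['t_max'].iloc[bad[0]]}")
    df = df.assign(date=dates).set_index("date").sort_index()
    full = pd.date_range(df.index[0], df.index[-1], freq="D")
    if len(full) != len(df):
        n_gap = len(full) - len(df)
        logger.warning("%s: %d missing day(s) interpolated linearly", path, n_gap)
        df = df.reindex(full).interpolate(method="linear")
    return TemperatureSeries(
        dates=pd.DatetimeIndex(df.index),
        t_min=df["t_min"].to_numpy(float),
        t_mean=df["t_mean"].to_numpy(float),
        t_max=df["t_max"].to_numpy(float),
    )


# ---------------------------------------------------------------------------
# RGR series CSV and JSON artifacts
# ---------------------------------------------------------------------------

def write_rgr_csv(series_by_field: dict[str, RGRSeries], path, meta: Optional[dict] = None) -> None:
    frames = []
    for field_id, s in series_by_field.items():
        frames.append(
            pd.DataFrame(
                {
                    "field_id": field_id,
                    "date": pd.DatetimeIndex(s.dates).strftime("%Y-%m-%d"),
                    "rgr": s.rgr,
                    "log_count": s.log_counts,
                    "smoothing_parameter": s.smoothing_parameter,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(_metadata_header(meta))
        df.to_csv(fh, index=False)


def read_rgr_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", parse_dates=["date"])


def write_json(obj: dict, path, meta: Optional[dict] = None) -> None:
    """Deterministic JSON serialization (sorted keys, fixed separators)."""
    payload = {"_meta": meta or {}, **obj}
    Path(path).write_text(
        json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Timestamp):
        return o.strftime("%Y-%m-%d")
    raise TypeError(f"cannot serialize {type(o)}")
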