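"""File formats, pipeline configuration and run manifests.

All tabular interchange is CSV (UTF-8, comma separated, "." decimal,
ISO-8601 timestamps); geometry interchange is GeoJSON in WGS84; configs,
manifests and ground truth are JSON.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from datetime import date, datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape

from .gps import GpsPointStream, LocalFrame

__all__ = [
    "PipelineConfig",
    "read_gps_csv",
    "write_gps_csv",
    "read_trip_table",
    "write_trip_table",
    "write_geojson",
    "read_geojson",
    "write_manifest",
    "read_sessions_csv",
    "write_sessions_csv",
]

MANDATORY_TRIP_COLUMNS = ("participant_id", "trip_id")


@dataclass
class PipelineConfig:
    """The pipeline's fixed thresholds plus the knobs of every stage."""

    buffer_radius_m: float = 25.0
    hex_diameter_m: float = 25.0
    gap_exclusion_m: float = 500.0
    qc_min_duration_s: float = 120.0
    qc_temp_contact_c: float = 30.0
    qc_eda_contact_us: float = 0.05
    stop_speed_mps: float = 0.5
    stop_dwell_s: float = 120.0
    min_trip_duration_s: float = 120.0
    max_walk_speed_mps: float = 3.0
    hrv_window_s: float = 10.0
    sg_window_s: float = 1.0
    sg_polyorder: int = 3
    hp_cutoff_hz: float = 0.015
    hp_order: int = 4
    scr_amp_threshold_us: float = 0.01
    lf_band: tuple = (0.04, 0.15)
    hf_band: tuple = (0.15, 0.40)
    alpha: float = 0.05
    beta_gate: float = 0.1
    k_range: tuple = (2, 8)
    seed: int = 0

    def __post_init__(self):
        for name in ("buffer_radius_m", "hex_diameter_m", "gap_exclusion_m",
                     "qc_min_duration_s", "alpha", "beta_gate"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self, path):
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))

    @classmethod
    def from_json(cls, path):
        raw = json.loads(Path(path).read_text())
        for key in ("lf_band", "hf_band", "k_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# --------------------------------------------------------------------------
# GPS streams

def write_gps_csv(streams, path):
    """GPS fixes as CSV: trip_id, participant_id, ISO-8601 timestamp, lat, lon."""
    frames = []
    for s in streams:
        ts = pd.to_datetime(s.t, unit="s", utc=True)
        frames.append(
            pd.DataFrame(
                {"trip_id": s.trip_id, "participant_id": s.participant_id,
                 "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S.%f"),
                 "lat": s.lat, "lon": s.lon}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_gps_csv(path) -> list[GpsPointStream]:
    df = pd.read_csv(path)
    missing = [c for c in ("trip_id", "participant_id", "timestamp", "lat", "lon")
               if c not in df.columns]
    if missing:
        raise ValueError(f"GPS CSV missing columns: {missing}")
    t = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    df = df.assign(_t=t.astype("int64") / 1e9)
    out = []
    for tid, g in df.groupby("trip_id", sort=True):
        out.append(
            GpsPointStream(str(tid), str(g["participant_id"].iloc[0]),
                           g["_t"].to_numpy(), g["lat"].to_numpy(), g["lon"].to_numpy())
        )
    return out


# --------------------------------------------------------------------------
# physiological sessions (long CSV, one file for all trips)

def write_sessions_csv(sessions, outdir):
    """Per-signal long CSVs: ibi.csv, eda.csv, temp.csv under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ibi, eda, temp = [], [], []
    for s in sessions:
        ibi.append(pd.DataFrame({"trip_id": s.trip_id, "t_s": s.ibi_t,
                                 "ibi_ms": s.ibi_ms}))
        te = np.arange(len(s.eda_raw)) / s.fs_eda
        eda.append(pd.DataFrame({"trip_id": s.trip_id, "t_s": te,
                                 "eda_uS": s.eda_raw}))
        tt = np.arange(len(s.skin_temp)) / s.fs_temp
        temp.append(pd.DataFrame({"trip_id": s.trip_id, "t_s": tt,
                                  "temp_c": s.skin_temp}))
    pd.concat(ibi, ignore_index=True).to_csv(outdir / "ibi.csv", index=False,
                                             float_format="%.4f")
    pd.concat(eda, ignore_index=True).to_csv(outdir / "eda.csv", index=False,
                                             float_format="%.5f")
    pd.concat(temp, ignore_index=True).to_csv(outdir / "temp.csv", index=False,
                                              float_format="%.3f")


def read_sessions_csv(indir, fs_eda: float = 4.0, fs_temp: float = 4.0):
    """Rebuild PhysioSession objects from the per-signal long CSVs."""
    from .physio import PhysioSession

    indir = Path(indir)
    ibi = pd.read_csv(indir / "ibi.csv")
    eda = pd.read_csv(indir / "eda.csv")
    temp = pd.read_csv(indir / "temp.csv")
    sessions = {}
    eda_g = dict(tuple(eda.groupby("trip_id")))
    temp_g = dict(tuple(temp.groupby("trip_id")))
    for tid, g in ibi.groupby("trip_id"):
        ge = eda_g.get(tid)
        gt = temp_g.get(tid)
        sessions[tid] = PhysioSession(
            trip_id=str(tid),
            ibi_t=g["t_s"].to_numpy(), ibi_ms=g["ibi_ms"].to_numpy(),
            eda_raw=ge["eda_uS"].to_numpy() if ge is not None else np.array([]),
            skin_temp=gt["temp_c"].to_numpy() if gt is not None else np.array([]),
            fs_eda=fs_eda, fs_temp=fs_temp,
        )
    return sessions


# --------------------------------------------------------------------------
# trip table

def write_trip_table(table: pd.DataFrame, path):
    missing = [c for c in MANDATORY_TRIP_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trip table missing mandatory columns: {missing}")
    table.to_csv(path, index=False)


def read_trip_table(path, canonical_columns=None) -> pd.DataFrame:
    """Read the trip-level analysis table.

    Mandatory columns participant_id and trip_id must be present;
    unknown columns pass through untouched. When ``canonical_columns``
    is given, names outside it (plus the mandatory ones) draw a
    warning but are kept.
    """
    df = pd.read_csv(path)
    missing = [c for c in MANDATORY_TRIP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trip table missing mandatory columns: {missing}")
    if canonical_columns is not None:
        extra = set(df.columns) - set(canonical_columns) - set(MANDATORY_TRIP_COLUMNS)
        if extra:
            warnings.warn(f"non-canonical columns kept as passthrough: {sorted(extra)}",
                          stacklevel=2)
    if "date" in df.columns:
        df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


# --------------------------------------------------------------------------
# GeoJSON

def write_geojson(geometries, properties, path, frame: LocalFrame = None):
    """FeatureCollection of shapely geometries with per-feature properties.

    Geometries given in a local metric frame are exported to WGS84 when
    ``frame`` is supplied (equirectangular inverse), else written as-is.
    """
    feats = []
    for geom, props in zip(geometries, properties):
        if frame is not None:
            geom = _frame_to_wgs84(geom, frame)
        feats.append({"type": "Feature", "geometry": mapping(geom),
                      "properties": props})
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": feats})
    )


def _frame_to_wgs84(geom, frame: LocalFrame):
    from shapely.ops import transform

    def tx(x, y):
        lat, lon = frame.to_latlon(np.asarray(x), np.asarray(y))
        return lon, lat

    return transform(tx, geom)


def read_geojson(path, frame: LocalFrame = None):
    """Read a FeatureCollection; returns (geometries, properties) lists.

    With ``frame``, coordinates are projected from WGS84 into the local
    metric frame.
    """
    from shapely.ops import transform

    raw = json.loads(Path(path).read_text())
    geoms, props = [], []
    for feat in raw["features"]:
        g = shape(feat["geometry"])
        if frame is not None:
            def tx(lon, lat):
                x, y = frame.to_xy(np.asarray(lat), np.asarray(lon))
                return x, y

            g = transform(tx, g)
        geoms.append(g)
        props.append(feat.get("properties", {}))
    return geoms, props


def write_manifest(path, seed, stage, counts: dict, extra: dict = None):
    """JSON run manifest: seed, stage, counts in/out per filter, timestamp."""
    payload = {
        "stage": stage,
        "seed": seed,
        "created": datetime.now(tz=timezone.utc).isoformat(),
        "counts": counts,
    }
    if extra:
        payload.update(extra)
    path = Path(path)
    existing = {}
    if path.exists():
        existing = json.loads(path.read_text())
    existing[stage] = payload
    path.write_text(json.dumps(existing, indent=2, default=str))
    return payload
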