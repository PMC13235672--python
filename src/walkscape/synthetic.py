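"""Synthetic study generator with known ground truth.

Emulates the structure of a naturalistic urban-walking study: 90
participants contribute ~25 GPS-tracked walking trips each inside a
synthetic city laid out as contiguous environmental archetype zones
(distinct NDVI / noise / POI / streetscape profiles on a 25-m hexagonal
grid). Each trip carries a wearable session (interbeat intervals, 4-Hz
electrodermal activity, skin temperature) and four post-trip ratings.

Ground-truth effect sizes are injected exactly where the downstream
estimators look for them:

* rating betas enter the linear predictor of the ratings (standardized
  exposures, participant random intercept, residual noise, clip+round
  to the discrete scales);
* physio betas shift per-trip SCR pulse amplitudes by beta µS per 1 SD
  of the exposure;
* the interbeat series is lag-1 autoregressive with its innovation
  variance solved analytically from the target RMSSD;
* SCR pulses are linear-rise / exponential-decay, so amplitude, rise
  time and 63%-recovery are analytically known.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import date, datetime, timedelta, timezone

import numpy as np
import pandas as pd

from . import gps as gps_mod
from .exposure import (
    IMAGE_CLASSES,
    POI_CATEGORIES,
    compute_trip_exposures,
)
from .gps import GpsPointStream, LocalFrame, WalkingTrip, build_hex_grid, buffer_route
from .physio import PhysioSession, extract_trip_indicators

__all__ = [
    "GroundTruthConfig",
    "EnvironmentScene",
    "SyntheticDataset",
    "generate_scene",
    "generate_trips",
    "generate_weather",
    "generate_physio",
    "generate_ratings",
    "generate_dataset",
    "cell_features",
]

#: Rating scale bounds: (low, high), integers.
RATING_SCALES = {
    "trip_feeling_env": (0, 5),
    "unwell_well": (1, 6),
    "agitated_calm": (1, 6),
    "tired_awake": (1, 6),
}

DEFAULT_RATING_MEANS = {
    "trip_feeling_env": 3.0,
    "unwell_well": 3.5,
    "agitated_calm": 3.5,
    "tired_awake": 3.5,
}

#: Default injected rating effects (standardized beta per outcome),
#: magnitudes in the 0.05-0.2 band typical of trip-level studies.
DEFAULT_RATING_BETAS = {
    "trip_feeling_env": {"poi_tourism": 0.12, "ndvi_mean": 0.10},
    "unwell_well": {"img_curbs": 0.078, "poi_water": -0.073},
    "agitated_calm": {"img_curbs": 0.092, "ndvi_mean": 0.126,
                      "ndvi_max": -0.094, "img_sky": -0.115},
    "tired_awake": {"img_curbs": 0.099, "ndvi_mean": 0.129, "poi_tourism": 0.127},
}

#: Default injected physiological effects: µS shift of SCR amplitude per
#: 1 SD of the exposure.
DEFAULT_PHYSIO_BETAS = {"t_max": 0.16, "noise_lden_mean": 0.18}

STUDY_START = date(2024, 8, 1)
STUDY_DAYS = 150


@dataclass
class GroundTruthConfig:
    """Tunable ground truth for the synthetic study."""

    n_participants: int = 90
    trips_per_participant: int = 25
    rating_betas: dict = field(default_factory=lambda: dict(DEFAULT_RATING_BETAS))
    physio_betas: dict = field(default_factory=lambda: dict(DEFAULT_PHYSIO_BETAS))
    random_intercept_sd: float = 0.5   # rating units
    residual_sd: float = 1.0           # rating units
    rating_means: dict = field(default_factory=lambda: dict(DEFAULT_RATING_MEANS))
    # SCR pulse ground truth
    scr_rate: float = 4.0              # events/min
    scr_amp_range: tuple = (0.5, 1.1)  # µS; lower bound exceeds the largest
                                       # configured additive shift (|beta|*|z|)
                                       # so effect injection never hits the
                                       # positivity floor and stays linear
    scr_rise_s: float = 2.0
    scr_tau_s: float = 3.0             # exponential decay constant
    scr_trip_noise_sd: float = 0.08    # per-trip amplitude offset, µS
    # IBI ground truth
    target_rmssd_ms: float = 50.0
    mean_ibi_ms: float = 800.0
    ibi_phi: float = 0.9               # lag-1 autocorrelation
    # scene
    n_archetypes: int = 4
    archetype_separation: float = 1.0  # 0 -> identical profiles
    ndvi_noise_sd: float = 0.04
    noise_noise_sd: float = 2.0
    image_rate: float = 0.25           # images per cell
    # trips
    trip_duration_range_s: tuple = (240.0, 600.0)
    walk_speed_range_mps: tuple = (0.8, 1.8)
    teleport_rate: float = 0.0
    dwell_rate: float = 0.0
    dwell_duration_s: float = 180.0
    seed: int = 0

    def __post_init__(self):
        for name in ("random_intercept_sd", "residual_sd", "scr_trip_noise_sd",
                     "ndvi_noise_sd", "noise_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.trips_per_participant < 1:
            raise ValueError("trips_per_participant must be >= 1")
        if self.n_archetypes < 1:
            raise ValueError("n_archetypes must be >= 1")
        if not 0 <= self.ibi_phi < 1:
            raise ValueError("ibi_phi must be in [0, 1)")


# --------------------------------------------------------------------------
# scene

#: Base archetype profiles: (ndvi, lden dB(A), poi rates per cell,
#: streetscape class mix). Four urban types: low-density quiet, green
#: open, mixed-use, dense noisy commercial.
_BASE_PROFILES = [
    {
        "ndvi": 0.12, "noise": 44.0,
        "poi": {"leisure": 0.02, "tourism": 0.01, "arts": 0.005, "greenery": 0.02,
                "water": 0.005, "services": 0.05, "commerce": 0.05, "public": 0.02},
        "img": {"vegetation": 0.10, "sky": 0.25, "road": 0.28, "sidewalk": 0.12,
                "cars": 0.05, "poles": 0.02, "curbs": 0.04, "pedestrians": 0.02,
                "other": 0.12},
    },
    {
        "ndvi": 0.60, "noise": 50.0,
        "poi": {"leisure": 0.15, "tourism": 0.05, "arts": 0.02, "greenery": 0.25,
                "water": 0.06, "services": 0.03, "commerce": 0.02, "public": 0.03},
        "img": {"vegetation": 0.35, "sky": 0.28, "road": 0.10, "sidewalk": 0.08,
                "cars": 0.02, "poles": 0.01, "curbs": 0.03, "pedestrians": 0.02,
                "other": 0.11},
    },
    {
        "ndvi": 0.35, "noise": 60.0,
        "poi": {"leisure": 0.10, "tourism": 0.08, "arts": 0.06, "greenery": 0.08,
                "water": 0.02, "services": 0.15, "commerce": 0.15, "public": 0.06},
        "img": {"vegetation": 0.18, "sky": 0.15, "road": 0.22, "sidewalk": 0.14,
                "cars": 0.07, "poles": 0.03, "curbs": 0.06, "pedestrians": 0.05,
                "other": 0.10},
    },
    {
        "ndvi": 0.06, "noise": 73.0,
        "poi": {"leisure": 0.08, "tourism": 0.15, "arts": 0.08, "greenery": 0.01,
                "water": 0.005, "services": 0.30, "commerce": 0.35, "public": 0.12},
        "img": {"vegetation": 0.04, "sky": 0.06, "road": 0.26, "sidewalk": 0.16,
                "cars": 0.14, "poles": 0.05, "curbs": 0.08, "pedestrians": 0.10,
                "other": 0.11},
    },
]


def _archetype_profiles(n: int, separation: float):
    """n profiles, blended toward their common mean as separation -> 0."""
    base = [_BASE_PROFILES[k % len(_BASE_PROFILES)] for k in range(n)]
    mean_ndvi = float(np.mean([p["ndvi"] for p in base]))
    mean_noise = float(np.mean([p["noise"] for p in base]))
    mean_poi = {c: float(np.mean([p["poi"][c] for p in base])) for c in POI_CATEGORIES}
    mean_img = {c: float(np.mean([p["img"][c] for p in base])) for c in IMAGE_CLASSES}
    out = []
    for p in base:
        out.append(
            {
                "ndvi": mean_ndvi + separation * (p["ndvi"] - mean_ndvi),
                "noise": mean_noise + separation * (p["noise"] - mean_noise),
                "poi": {c: max(0.0, mean_poi[c] + separation * (p["poi"][c] - mean_poi[c]))
                        for c in POI_CATEGORIES},
                "img": {c: max(1e-6, mean_img[c] + separation * (p["img"][c] - mean_img[c]))
                        for c in IMAGE_CLASSES},
            }
        )
    return out


def _smooth_field(centers: np.ndarray, extent, rng, scale_m: float = 200.0):
    """Unit-variance spatially smooth Gaussian field at the cell centres.

    White noise on a coarse lattice (``scale_m`` spacing), bilinearly
    interpolated; gives each environmental layer continuous within-zone
    variation on top of its archetype profile, the way real cities vary
    block by block.
    """
    xmin, ymin, xmax, ymax = extent
    nx = int(np.ceil((xmax - xmin) / scale_m)) + 3
    ny = int(np.ceil((ymax - ymin) / scale_m)) + 3
    lattice = rng.normal(0.0, 1.0, (nx, ny))
    fx = (centers[:, 0] - xmin) / scale_m + 1.0
    fy = (centers[:, 1] - ymin) / scale_m + 1.0
    i0 = np.clip(np.floor(fx).astype(int), 0, nx - 2)
    j0 = np.clip(np.floor(fy).astype(int), 0, ny - 2)
    tx, ty = fx - i0, fy - j0
    v = (lattice[i0, j0] * (1 - tx) * (1 - ty)
         + lattice[i0 + 1, j0] * tx * (1 - ty)
         + lattice[i0, j0 + 1] * (1 - tx) * ty
         + lattice[i0 + 1, j0 + 1] * tx * ty)
    sd = v.std()
    return v / sd if sd > 0 else v


@dataclass
class EnvironmentScene:
    """Synthetic environmental layers on a hexagonal grid."""

    grid: gps_mod.HexGrid
    frame: LocalFrame
    extent: tuple
    archetype: np.ndarray      # cell -> zone label
    ndvi: np.ndarray           # cell -> value in [-1, 1]
    noise_lden: np.ndarray     # cell -> dB(A)
    slope: np.ndarray          # cell -> %
    poi_points: list           # (x, y, category)
    images: list               # (image_id, x, y, {class: proportion})
    zones: list                # per-archetype (xmin, xmax) strip bounds
    profiles: list

    @property
    def layers(self) -> dict:
        return {
            "ndvi": self.ndvi,
            "noise_lden": self.noise_lden,
            "slope": self.slope,
            "poi_points": self.poi_points,
            "images": self.images,
        }


def generate_scene(config: GroundTruthConfig, extent=(0.0, 0.0, 2000.0, 1200.0),
                   ref_latlon=(38.72, -9.14)) -> EnvironmentScene:
    """Lay out the synthetic city: archetype strips over a hexagonal grid.

    ``extent`` is (xmin, ymin, xmax, ymax) in metres and must cover at
    least 1 km². Cells are partitioned into ``n_archetypes`` contiguous
    vertical strips with distinct NDVI / noise / POI / streetscape
    profiles; per-cell values add small Gaussian noise to the profile.
    """
    xmin, ymin, xmax, ymax = map(float, extent)
    area = (xmax - xmin) * (ymax - ymin)
    if area < 1e6:
        raise ValueError(f"extent area {area:.0f} m² below the 1 km² minimum")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    grid = build_hex_grid(extent, diameter_m=25.0)
    n = len(grid)
    profiles = _archetype_profiles(config.n_archetypes, config.archetype_separation)
    strip_w = (xmax - xmin) / config.n_archetypes
    zones = [(xmin + k * strip_w, xmin + (k + 1) * strip_w)
             for k in range(config.n_archetypes)]
    cx = grid.centers[:, 0]
    arche = np.clip(((cx - xmin) // strip_w).astype(int), 0, config.n_archetypes - 1)

    # within-zone spatial structure: a weakly shared urban-fabric field
    # plus a mostly independent field per layer, so exposures co-vary
    # realistically block-by-block without becoming collinear
    ext = (xmin, ymin, xmax, ymax)
    common = _smooth_field(grid.centers, ext, rng)

    def layer_field():
        own = _smooth_field(grid.centers, ext, rng)
        return 0.3 * common + np.sqrt(1.0 - 0.09) * own

    f_ndvi = layer_field()
    f_noise = layer_field()
    f_veg = layer_field()
    f_sky = layer_field()
    f_curbs = layer_field()
    f_side = layer_field()
    f_street = layer_field()       # poles, cars, pedestrians
    f_poi_green = layer_field()    # greenery, water, leisure
    f_poi_dense = layer_field()    # the remaining categories

    ndvi = np.empty(n)
    noise = np.empty(n)
    for k, prof in enumerate(profiles):
        m = arche == k
        ndvi[m] = prof["ndvi"] + rng.normal(0, config.ndvi_noise_sd, m.sum())
        noise[m] = prof["noise"] + rng.normal(0, config.noise_noise_sd, m.sum())
    sep = config.archetype_separation
    ndvi = np.clip(ndvi + sep * 0.10 * f_ndvi, -1.0, 1.0)
    noise = noise + sep * 2.5 * f_noise
    slope = np.abs(rng.normal(4.0, 2.0, n))

    img_log_boost = {
        "vegetation": (f_veg, 0.35), "sky": (f_sky, 0.3),
        "curbs": (f_curbs, 0.5), "sidewalk": (f_side, 0.3),
        "poles": (f_street, 0.4), "cars": (f_street, 0.4),
        "pedestrians": (f_street, 0.4),
    }
    poi_points = []
    images = []
    half = grid.diameter_m / 2.0
    img_id = 0
    green_cats = {"greenery", "water", "leisure"}
    for i in range(n):
        prof = profiles[arche[i]]
        x0, y0 = grid.centers[i]
        for cat in POI_CATEGORIES:
            boost = f_poi_green[i] if cat in green_cats else f_poi_dense[i]
            rate = prof["poi"][cat] * math.exp(sep * 0.10 * boost)
            for _ in range(rng.poisson(rate)):
                poi_points.append(
                    (x0 + rng.uniform(-half, half) * 0.8,
                     y0 + rng.uniform(-half, half) * 0.8, cat)
                )
        if rng.random() < config.image_rate:
            conc = 300.0
            w = {c: prof["img"][c] for c in IMAGE_CLASSES}
            for c, (field, amp) in img_log_boost.items():
                w[c] *= math.exp(sep * amp * field[i])
            total = sum(w.values())
            alpha = np.array([w[c] / total for c in IMAGE_CLASSES]) * conc
            props = rng.dirichlet(alpha)
            props = props / props.sum()
            images.append(
                (f"img{img_id:06d}",
                 x0 + rng.uniform(-half, half) * 0.5,
                 y0 + rng.uniform(-half, half) * 0.5,
                 dict(zip(IMAGE_CLASSES, props.tolist())))
            )
            img_id += 1
    return EnvironmentScene(
        grid=grid,
        frame=LocalFrame(*ref_latlon),
        extent=(xmin, ymin, xmax, ymax),
        archetype=arche,
        ndvi=ndvi,
        noise_lden=noise,
        slope=slope,
        poi_points=poi_points,
        images=images,
        zones=zones,
        profiles=profiles,
    )


def cell_features(scene: EnvironmentScene) -> np.ndarray:
    """Standardized per-cell (NDVI, Lden) feature matrix for clustering checks."""
    X = np.column_stack([scene.ndvi, scene.noise_lden])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


# --------------------------------------------------------------------------
# trips

def _fold(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Reflect an unbounded coordinate series into [lo, hi] (billiard walk)."""
    L = hi - lo
    v = np.mod(u - lo, 2 * L)
    return lo + np.where(v <= L, v, 2 * L - v)


def generate_trips(scene: EnvironmentScene, config: GroundTruthConfig):
    """Simulate GPS point streams, one per intended walking trip.

    Walks are constant-cadence (1 fix/s) heading-jitter random walks at
    0.8-1.8 m/s, reflected at the boundary of the archetype strip they
    start in, so each trip's exposure stays within one archetype.
    Defects are injected at configurable rates: a single teleport fix
    displaced > 500 m (``teleport_rate``) and a stationary dwell long
    enough to split the trip (``dwell_rate``). Returns ``(streams,
    truth)`` where truth stores, per trip, the archetype label, the
    expected post-cleaning/segmentation outcome and the defect
    positions.
    """
    if len(scene.grid) == 0:
        raise ValueError("scene is empty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    xmin, ymin, xmax, ymax = scene.extent
    margin = 30.0
    streams, truth = [], {}
    for p in range(config.n_participants):
        pid = f"P{p:03d}"
        window_start = int(rng.integers(0, STUDY_DAYS - 14))
        for j in range(config.trips_per_participant):
            tid = f"{pid}-T{j:03d}"
            day = window_start + int(rng.integers(0, 14))
            trip_date = STUDY_START + timedelta(days=day)
            t0 = datetime(trip_date.year, trip_date.month, trip_date.day,
                          tzinfo=timezone.utc).timestamp() + 8 * 3600 + j * 120.0
            k = int(rng.integers(0, config.n_archetypes))
            zx0, zx1 = scene.zones[k]
            dur = rng.uniform(*config.trip_duration_range_s)
            nfix = int(dur) + 1
            speeds = rng.uniform(*config.walk_speed_range_mps, nfix - 1)
            heading = np.cumsum(
                np.concatenate([[rng.uniform(0, 2 * np.pi)],
                                rng.normal(0, 0.15, nfix - 2)])
            )
            dx = np.concatenate([[0.0], speeds * np.cos(heading)])
            dy = np.concatenate([[0.0], speeds * np.sin(heading)])
            x = _fold(rng.uniform(zx0 + margin, zx1 - margin) + np.cumsum(dx),
                      zx0 + 5.0, zx1 - 5.0)
            y = _fold(rng.uniform(ymin + margin, ymax - margin) + np.cumsum(dy),
                      ymin + 5.0, ymax - 5.0)
            t = t0 + np.arange(nfix, dtype=float)

            teleport_idx = None
            if rng.random() < config.teleport_rate and nfix > 20:
                teleport_idx = int(rng.integers(5, nfix - 5))
                ang = rng.uniform(0, 2 * np.pi)
                x = x.copy(); y = y.copy()
                x[teleport_idx] += 700.0 * np.cos(ang)
                y[teleport_idx] += 700.0 * np.sin(ang)

            segments = [(t[0], t[-1])]
            dwell_at = None
            if rng.random() < config.dwell_rate and dur >= 2 * 150.0 + 10:
                split = int(rng.uniform(150.0, dur - 150.0))
                ndwell = int(config.dwell_duration_s)
                xd = np.concatenate([x[: split + 1],
                                     np.full(ndwell, x[split]) + rng.normal(0, 0.02, ndwell),
                                     x[split + 1 :]])
                yd = np.concatenate([y[: split + 1],
                                     np.full(ndwell, y[split]) + rng.normal(0, 0.02, ndwell),
                                     y[split + 1 :]])
                t = t0 + np.arange(len(xd), dtype=float)
                dwell_at = (t0 + split, t0 + split + ndwell)
                segments = [(t[0], t0 + split), (t0 + split + ndwell, t[-1])]
                x, y = xd, yd

            lat, lon = scene.frame.to_latlon(x, y)
            streams.append(GpsPointStream(tid, pid, t, lat, lon))
            truth[tid] = {
                "participant_id": pid,
                "archetype": k,
                "date": trip_date.isoformat(),
                "segments": segments,
                "teleport_idx": teleport_idx,
                "dwell": dwell_at,
            }
    return streams, truth


def generate_weather(config: GroundTruthConfig) -> pd.DataFrame:
    """Daily weather table over the study window (late-summer to winter ramp)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    days = [STUDY_START + timedelta(days=d) for d in range(STUDY_DAYS)]
    frac = np.arange(STUDY_DAYS) / STUDY_DAYS
    t_max = 30.0 - 16.0 * frac + rng.normal(0, 2.5, STUDY_DAYS)
    t_mean = t_max - 6.0 + rng.normal(0, 1.0, STUDY_DAYS)
    t_min = t_mean - 5.0 + rng.normal(0, 1.0, STUDY_DAYS)
    precip = np.where(rng.random(STUDY_DAYS) < 0.30,
                      rng.exponential(5.0, STUDY_DAYS), 0.0)
    return pd.DataFrame(
        {"date": days, "t_max": t_max, "t_mean": t_mean, "t_min": t_min,
         "precipitation": precip}
    )


# --------------------------------------------------------------------------
# physiology

def generate_physio(
    trip: WalkingTrip,
    config: GroundTruthConfig,
    rng: np.random.Generator,
    amp_shift_uS: float = 0.0,
    target_rmssd_ms: float = None,
) -> PhysioSession:
    """Simulate one wearable session matched to a trip.

    IBI: stationary lag-1 autoregressive series around ``mean_ibi_ms``
    with innovation SD solved from the target RMSSD
    (``rmssd = sqrt(2) * sigma_eps / sqrt(1 + phi)``). EDA: slow
    sinusoidal tonic drift plus Poisson-timed SCR pulses with linear
    rise over ``scr_rise_s`` and exponential decay ``scr_tau_s``; every
    pulse amplitude in this trip is shifted by ``amp_shift_uS`` (how
    exposure effects are injected). Skin temperature ~33 ± 1 °C.
    """
    if trip.duration_s < 120.0:
        raise ValueError("trip shorter than 2 min cannot carry a valid session")
    dur = trip.duration_s
    rmssd = config.target_rmssd_ms if target_rmssd_ms is None else target_rmssd_ms
    phi = config.ibi_phi
    sig_eps = rmssd * math.sqrt((1.0 + phi) / 2.0)
    sig_x = sig_eps / math.sqrt(1.0 - phi**2) if phi > 0 else sig_eps
    n_beats = int(dur / (config.mean_ibi_ms / 1000.0)) + 8
    eps = rng.normal(0.0, sig_eps, n_beats)
    ibi = np.empty(n_beats)
    ibi[0] = config.mean_ibi_ms + rng.normal(0.0, sig_x)
    for i in range(1, n_beats):
        ibi[i] = config.mean_ibi_ms + phi * (ibi[i - 1] - config.mean_ibi_ms) + eps[i]
    ibi = np.clip(ibi, 300.0, 2000.0)
    beat_t = np.cumsum(ibi) / 1000.0
    keep = beat_t <= dur
    ibi_t, ibi_ms = beat_t[keep], ibi[keep]

    fs = 4.0
    t = np.arange(0.0, dur, 1.0 / fs)
    tonic = (2.0 + rng.uniform(-0.4, 0.4)
             + 0.3 * np.sin(2 * np.pi * t / 600.0 + rng.uniform(0, 2 * np.pi)))
    eda = tonic.copy()
    rate_s = config.scr_rate / 60.0
    trip_offset = rng.normal(0.0, config.scr_trip_noise_sd)
    if rate_s > 0:
        t_ev = 5.0 + rng.exponential(1.0 / rate_s)
        while t_ev < dur - 5.0:
            amp = rng.uniform(*config.scr_amp_range) + amp_shift_uS + trip_offset
            amp = max(amp, 0.02)
            m_rise = (t >= t_ev) & (t < t_ev + config.scr_rise_s)
            eda[m_rise] += amp * (t[m_rise] - t_ev) / config.scr_rise_s
            m_dec = t >= t_ev + config.scr_rise_s
            eda[m_dec] += amp * np.exp(-(t[m_dec] - t_ev - config.scr_rise_s)
                                       / config.scr_tau_s)
            # refractory interval of 4 tau keeps pulses analytically
            # separable (trough-to-peak amplitude stays unbiased)
            t_ev += (rng.exponential(1.0 / rate_s) + config.scr_rise_s
                     + 4.0 * config.scr_tau_s)
    eda = np.maximum(eda + rng.normal(0, 0.003, len(t)), 0.0)

    temp = (33.0 + rng.normal(0, 0.5)
            + 0.3 * np.sin(2 * np.pi * t / 300.0 + rng.uniform(0, 2 * np.pi))
            + rng.normal(0, 0.03, len(t)))
    return PhysioSession(
        trip_id=trip.trip_id, ibi_t=ibi_t, ibi_ms=ibi_ms,
        eda_raw=eda, skin_temp=temp, fs_eda=fs, fs_temp=fs, duration_s=dur,
    )


# --------------------------------------------------------------------------
# ratings

def _normalize_betas(betas: dict, outcomes=RATING_SCALES) -> dict:
    """Accept flat {predictor: beta} (applied to every outcome) or nested."""
    if not betas:
        return {o: {} for o in outcomes}
    if all(isinstance(v, dict) for v in betas.values()):
        unknown = set(betas) - set(outcomes)
        if unknown:
            raise ValueError(f"unknown rating outcomes: {sorted(unknown)}")
        return {o: dict(betas.get(o, {})) for o in outcomes}
    return {o: dict(betas) for o in outcomes}


def generate_ratings(
    trip_table: pd.DataFrame,
    config: GroundTruthConfig,
    rng: np.random.Generator = None,
    participant_intercepts: dict = None,
):
    """Post-trip ratings from exposures, intercepts and residual noise.

    rating = clip-and-round(grand mean + sum(beta * z(exposure))
    + participant intercept + residual). Returns ``(ratings_df,
    participant_intercepts)``. Predictors named in the betas must be
    columns of ``trip_table``.
    """
    rng = np.random.default_rng(config.seed + 404) if rng is None else rng
    betas = _normalize_betas(config.rating_betas)
    preds = sorted({p for m in betas.values() for p in m})
    missing = [p for p in preds if p not in trip_table.columns]
    if missing:
        raise ValueError(f"rating_betas reference unknown predictors: {missing}")
    z = {}
    for p in preds:
        x = pd.to_numeric(trip_table[p], errors="coerce")
        if p.startswith("poi_"):
            x = x.fillna(0.0)
        sd = x.std(ddof=0)
        z[p] = ((x - x.mean()) / sd if sd > 0 else x * 0.0).to_numpy()
    pids = trip_table["participant_id"].to_numpy()
    if participant_intercepts is None:
        uniq = pd.unique(pids)
        participant_intercepts = {
            pid: rng.normal(0.0, config.random_intercept_sd) for pid in uniq
        }
    b = np.array([participant_intercepts[pid] for pid in pids])
    out = {}
    for outcome, (lo, hi) in RATING_SCALES.items():
        eta = np.full(len(trip_table), config.rating_means[outcome], dtype=float)
        for p, beta in betas[outcome].items():
            eta = eta + beta * z[p]
        eta = eta + b + rng.normal(0.0, config.residual_sd, len(eta))
        out[outcome] = np.clip(np.rint(eta), lo, hi).astype(int)
    return pd.DataFrame(out, index=trip_table.index), participant_intercepts


# --------------------------------------------------------------------------
# full dataset

@dataclass
class SyntheticDataset:
    config: GroundTruthConfig
    scene: EnvironmentScene
    weather: pd.DataFrame
    streams: list
    truth: dict
    trips: list
    trip_table: pd.DataFrame
    sessions: list = None  # populated when keep_sessions=True


def generate_dataset(
    config: GroundTruthConfig = None,
    extent=(0.0, 0.0, 2000.0, 1200.0),
    compute_physio: bool = True,
    keep_sessions: bool = False,
) -> SyntheticDataset:
    """End-to-end synthetic study: scene, trips, signals, ratings, trip table.

    The GPS streams are passed through the real cleaning/segmentation
    pipeline; exposures are aggregated with the real spatial operators;
    injected effects use the pooled z-scores of the realized exposures,
    so the downstream estimators see exactly the configured betas.
    """
    config = GroundTruthConfig() if config is None else config
    scene = generate_scene(config, extent=extent)
    weather = generate_weather(config)
    streams, truth = generate_trips(scene, config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 505]))

    trips = []
    for stream in streams:
        cleaned, _ = gps_mod.clean_stream(stream)
        trips.extend(gps_mod.segment_trips(cleaned))

    from shapely.geometry import LineString

    rows = []
    weather_idx = weather.set_index("date")
    for trip in trips:
        # route buffer in the scene frame, where the layers live
        x, y = scene.frame.to_xy(trip.lat, trip.lon)
        buf = buffer_route(LineString(np.column_stack([x, y])))
        row = {"participant_id": trip.participant_id, "trip_id": trip.trip_id,
               "date": trip.date, "duration_s": trip.duration_s,
               "length_m": trip.length_m}
        base_tid = trip.trip_id.split("-")[0] + "-" + trip.trip_id.split("-")[1]
        row["archetype_true"] = truth.get(base_tid, {}).get("archetype", -1)
        row.update(
            compute_trip_exposures(scene.grid, buf, scene.layers,
                                   trip_date=trip.date, weather_table=weather_idx)
        )
        rows.append(row)
    table = pd.DataFrame(rows)

    sessions = [] if keep_sessions else None
    if compute_physio and len(table):
        shifts = np.zeros(len(table))
        for pred, beta in (config.physio_betas or {}).items():
            x = pd.to_numeric(table[pred], errors="coerce").fillna(0.0)
            sd = x.std(ddof=0)
            if sd > 0:
                shifts = shifts + beta * ((x - x.mean()) / sd).to_numpy()
        indicator_rows = []
        for i, trip in enumerate(trips):
            session = generate_physio(trip, config, rng, amp_shift_uS=float(shifts[i]))
            indicator_rows.append(extract_trip_indicators(session))
            if keep_sessions:
                sessions.append(session)
        table = pd.concat(
            [table.reset_index(drop=True), pd.DataFrame(indicator_rows)], axis=1
        )

    ratings, intercepts = generate_ratings(table, config, rng)
    table = pd.concat([table, ratings], axis=1)
    for tid, info in truth.items():
        info.setdefault("participant_intercept", intercepts.get(info["participant_id"]))
    truth["_betas"] = {
        "rating_betas": _normalize_betas(config.rating_betas),
        "physio_betas": dict(config.physio_betas or {}),
        "random_intercept_sd": config.random_intercept_sd,
        "residual_sd": config.residual_sd,
    }
    return SyntheticDataset(
        config=config, scene=scene, weather=weather, streams=streams,
        truth=truth, trips=trips, trip_table=table, sessions=sessions,
    )
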