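"""Trip-level environmental exposure aggregation.

Environmental layers live on a 25-m hexagonal grid (NDVI, Lden noise,
slope), as point sets (POIs by category, geolocated streetscape images
with per-class pixel proportions) and as a daily weather table. Each
layer is aggregated over the 25-m buffer around a walking route:
cell-value statistics (mean/min/max/SD, unweighted over intersecting
cells), POI counts per category with absent categories reported as 0,
unweighted per-class means over images inside the buffer, and an exact
date join for weather.
"""

from __future__ import annotations

import warnings

import numpy as np
from shapely.geometry import Point

from .gps import HexGrid, cells_for_route

__all__ = [
    "POI_CATEGORIES",
    "IMAGE_CLASSES",
    "WEATHER_FIELDS",
    "EXPOSURE_COLUMNS",
    "raster_stats",
    "poi_counts",
    "image_class_means",
    "weather_join",
    "compute_trip_exposures",
]

#: Canonical POI categories (functional-diversity indicators).
POI_CATEGORIES = (
    "leisure", "tourism", "arts", "greenery", "water",
    "services", "commerce", "public",
)

#: Canonical streetscape segmentation classes (per-image pixel proportions).
IMAGE_CLASSES = (
    "vegetation", "sky", "road", "sidewalk", "cars",
    "poles", "curbs", "pedestrians", "other",
)

WEATHER_FIELDS = ("t_max", "t_mean", "t_min", "precipitation")

EXPOSURE_COLUMNS = (
    tuple(f"ndvi_{s}" for s in ("mean", "min", "max", "sd"))
    + tuple(f"noise_lden_{s}" for s in ("mean", "min", "max", "sd"))
    + ("slope_mean",)
    + tuple(f"img_{c}" for c in IMAGE_CLASSES)
    + tuple(f"poi_{c}" for c in POI_CATEGORIES)
    + WEATHER_FIELDS
)


def raster_stats(grid: HexGrid, buffer, layer, sd: str = "population"):
    """(mean, min, max, sd) of a cell-indexed layer over a buffered route.

    ``layer`` maps cell_id -> value (dict or array indexed by cell id).
    Statistics are unweighted over all grid cells intersecting the
    buffer; SD uses the population (n) convention by default
    (``sd="sample"`` switches to n-1). A single cell yields SD 0. No
    intersecting cells yields all-NaN with a warning.
    """
    cells = cells_for_route(grid, buffer)
    if len(cells) == 0:
        warnings.warn("no grid cells intersect the buffer; exposure missing", stacklevel=2)
        nan = float("nan")
        return nan, nan, nan, nan
    if isinstance(layer, dict):
        vals = np.array([layer[c] for c in cells], dtype=float)
    else:
        vals = np.asarray(layer, dtype=float)[cells]
    ddof = 0 if sd == "population" else 1
    sd_val = float(np.std(vals, ddof=ddof)) if len(vals) > ddof else 0.0
    return float(np.mean(vals)), float(np.min(vals)), float(np.max(vals)), sd_val


def poi_counts(buffer, poi_points, categories=POI_CATEGORIES):
    """Count POI points inside (or on the boundary of) the buffer, per category.

    ``poi_points`` is an iterable of (x, y, category) in the buffer's
    metric frame. Every canonical category is present in the result,
    absent ones as 0 (the missing-POI -> zero rule). Unknown category
    labels are tallied under ``"other"`` with a warning.
    """
    import shapely

    counts = {c: 0 for c in categories}
    unknown = 0
    pts = list(poi_points)
    if not pts:
        return counts
    xs = np.array([p[0] for p in pts], dtype=float)
    ys = np.array([p[1] for p in pts], dtype=float)
    # intersects == covers for points: boundary counts (closed region)
    inside = shapely.intersects_xy(buffer, xs, ys)
    for keep, (x, y, cat) in zip(inside, pts):
        if not keep:
            continue
        if cat not in counts:
            unknown += 1
            counts.setdefault("other", 0)
            counts["other"] += 1
        else:
            counts[cat] += 1
    if unknown:
        warnings.warn(f"{unknown} POIs with unknown category counted under 'other'",
                      stacklevel=2)
    return counts


def image_class_means(buffer, images, classes=IMAGE_CLASSES, tol: float = 1e-9):
    """Unweighted mean class proportion over images located within the buffer.

    ``images`` is an iterable of (image_id, x, y, {class: proportion}).
    Per-image proportions must sum to 1 within ``tol``. With no image
    inside the buffer every class is NaN (trip flagged missing).
    """
    import shapely

    sums = {c: 0.0 for c in classes}
    n = 0
    imgs = list(images)
    if imgs:
        xs = np.array([im[1] for im in imgs], dtype=float)
        ys = np.array([im[2] for im in imgs], dtype=float)
        inside = shapely.intersects_xy(buffer, xs, ys)
    else:
        inside = []
    for keep, (image_id, x, y, props) in zip(inside, imgs):
        total = sum(props.values())
        if abs(total - 1.0) > tol:
            raise ValueError(
                f"image {image_id}: class proportions sum to {total}, expected 1"
            )
        if not keep:
            continue
        n += 1
        for c in classes:
            sums[c] += props.get(c, 0.0)
    if n == 0:
        return {c: float("nan") for c in classes}
    return {c: sums[c] / n for c in classes}


def weather_join(trip_date, weather_table):
    """Weather fields for the trip's calendar day (exact match, no interpolation).

    ``weather_table`` is a pandas DataFrame indexed by ``datetime.date``
    (or with a ``date`` column) holding t_max, t_mean, t_min,
    precipitation. A missing date yields NaNs with a warning.
    """
    table = weather_table
    if "date" in getattr(table, "columns", ()):
        table = table.set_index("date")
    if trip_date not in table.index:
        warnings.warn(f"no weather record for {trip_date}", stacklevel=2)
        return {f: float("nan") for f in WEATHER_FIELDS}
    row = table.loc[trip_date]
    return {f: float(row[f]) for f in WEATHER_FIELDS}


def compute_trip_exposures(grid, buffer, scene_layers, trip_date=None, weather_table=None):
    """Assemble the full exposure block for one buffered route.

    ``scene_layers`` carries cell-indexed layers ``ndvi``, ``noise_lden``
    and ``slope``, plus ``poi_points`` and ``images`` as accepted by
    :func:`poi_counts` / :func:`image_class_means`. Returns a flat dict
    matching :data:`EXPOSURE_COLUMNS` (weather fields NaN when no table
    is given).
    """
    out = {}
    for name, key in (("ndvi", "ndvi"), ("noise_lden", "noise_lden")):
        m, lo, hi, sd = raster_stats(grid, buffer, scene_layers[key])
        out[f"{name}_mean"], out[f"{name}_min"] = m, lo
        out[f"{name}_max"], out[f"{name}_sd"] = hi, sd
    out["slope_mean"] = raster_stats(grid, buffer, scene_layers["slope"])[0]
    for c, v in image_class_means(buffer, scene_layers["images"]).items():
        out[f"img_{c}"] = v
    for c, v in poi_counts(buffer, scene_layers["poi_points"]).items():
        out[f"poi_{c}"] = v
    if weather_table is not None and trip_date is not None:
        out.update(weather_join(trip_date, weather_table))
    else:
        out.update({f: float("nan") for f in WEATHER_FIELDS})
    return out
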