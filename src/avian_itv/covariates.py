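"""Geographic and environmental covariates for the regression stages.

Within-species covariates, one value per station x species:

* ``Lat`` — station latitude in decimal degrees;
* ``DistEdge`` — shortest distance (km) of the station to the species'
  breeding-range edge.  Small gaps in the range polygon (lakes, rivers) are
  ignored by dilating the polygon by a buffer, measuring the distance to the
  dilated boundary, and subtracting the buffer; stations outside the range
  get distance 0;
* ``SpatVar`` — spatial CV of a productivity raster around the station: the
  SD across cells of the per-cell cross-year average, divided by the mean of
  those averages, over all cells whose centers lie within the buffer radius;
* ``TempVar`` — temporal CV: per-cell CV across years, averaged over the
  cells in the buffer.

``DistEdge``, ``SpatVar`` and ``TempVar`` are right-skewed and enter the
model log-transformed; all four covariates are then centered within species.
Species-level covariates (generation time, hand-wing index, range size, each
log-transformed, plus 0/1 migratory status) are centered and scaled across
species.

Geometry is planar in kilometres.  Longitude/latitude inputs are projected
with a local equirectangular approximation about each query point, which is
accurate to well under a percent at the 10-km scales involved.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "distance_to_edge",
    "spatial_cv",
    "temporal_cv",
    "assemble_within_design",
    "build_species_profiles",
    "vif",
]

KM_PER_DEGREE = 111.32

WITHIN_COVARIATES = ["Lat", "DistEdge", "SpatVar", "TempVar"]
AMONG_COVARIATES = ["GenTime", "HWI", "RangeSize", "MigStatus"]


def _project_equirect(geom: BaseGeometry, lon0: float, lat0: float) -> BaseGeometry:
    """Project lon/lat geometry to local planar km about (lon0, lat0)."""
    import shapely.ops

    cos0 = np.cos(np.radians(lat0))

    def tx(x, y):
        return (
            (np.asarray(x) - lon0) * KM_PER_DEGREE * cos0,
            (np.asarray(y) - lat0) * KM_PER_DEGREE,
        )

    return shapely.ops.transform(tx, geom)


def distance_to_edge(
    point: tuple[float, float],
    range_polygon,
    buffer_km: float = 10.0,
    crs: str = "planar_km",
) -> float:
    """Distance (km) from a station to the range edge, with small-gap closing.

    Implements the buffer trick: the polygon is dilated by ``buffer_km``
    (which erases interior holes of radius below the buffer), the distance
    from the point to the dilated boundary is measured, and ``buffer_km`` is
    subtracted.  Points outside the original polygon are assigned 0.

    ``point`` is (x_km, y_km) for ``crs="planar_km"`` or (lon, lat) for
    ``crs="lonlat"``; GeoJSON-style dicts are accepted for the polygon.
    """
    if isinstance(range_polygon, dict):
        range_polygon = shape(range_polygon)
    if not range_polygon.is_valid:
        raise ValueError("invalid range polygon")
    if crs == "lonlat":
        lon0, lat0 = point
        range_polygon = _project_equirect(range_polygon, lon0, lat0)
        pt = Point(0.0, 0.0)
    elif crs == "planar_km":
        pt = Point(*point)
    else:
        raise ValueError(f"unknown crs {crs!r}")
    if not range_polygon.covers(pt):
        return 0.0
    dilated = range_polygon.buffer(buffer_km)
    return max(0.0, pt.distance(dilated.boundary) - buffer_km)


def _cells_in_buffer(
    raster: pd.DataFrame,
    center: tuple[float, float],
    radius_km: float,
    crs: str,
) -> pd.DataFrame:
    x = raster["x"].to_numpy(dtype=float)
    y = raster["y"].to_numpy(dtype=float)
    if crs == "planar_km":
        d2 = (x - center[0]) ** 2 + (y - center[1]) ** 2
    elif crs == "lonlat":
        lon0, lat0 = center
        cos0 = np.cos(np.radians(lat0))
        d2 = ((x - lon0) * KM_PER_DEGREE * cos0) ** 2 + ((y - lat0) * KM_PER_DEGREE) ** 2
    else:
        raise ValueError(f"unknown crs {crs!r}")
    return raster.loc[d2 <= radius_km**2]


def spatial_cv(
    raster: pd.DataFrame,
    center: tuple[float, float],
    radius_km: float = 10.0,
    crs: str = "planar_km",
) -> float:
    """Spatial CV of productivity around a station.

    Per cell, average the value across years; then divide the SD (n-1
    denominator) across cells by the mean across cells.  ``raster`` has
    columns x, y, year, value with (x, y) cell centers.
    """
    cells = _cells_in_buffer(raster, center, radius_km, crs)
    means = cells.groupby(["x", "y"], sort=True)["value"].mean()
    if len(means) < 2:
        raise ValueError("spatial_cv: fewer than 2 cells within the buffer")
    m = means.mean()
    if m == 0:
        raise ValueError("spatial_cv: zero mean productivity")
    return float(means.std(ddof=1) / m)


def temporal_cv(
    raster: pd.DataFrame,
    center: tuple[float, float],
    radius_km: float = 10.0,
    crs: str = "planar_km",
) -> float:
    """Temporal CV: per-cell across-year CV, averaged over cells in the buffer."""
    cells = _cells_in_buffer(raster, center, radius_km, crs)
    g = cells.groupby(["x", "y"], sort=True)["value"]
    if (g.size() < 2).any():
        raise ValueError("temporal_cv: a cell has fewer than 2 years")
    means = g.mean()
    if (means == 0).any():
        raise ValueError("temporal_cv: a cell has zero across-year mean")
    cvs = g.std(ddof=1) / means
    if len(cvs) == 0:
        raise ValueError("temporal_cv: no cells within the buffer")
    return float(cvs.mean())


def assemble_within_design(
    group_cvs: pd.DataFrame,
    stations: pd.DataFrame,
    raster: pd.DataFrame,
    polygons: dict[str, object],
    buffer_km: float = 10.0,
    radius_km: float = 10.0,
    crs: str = "planar_km",
    dist_edge_offset_km: float = 1.0,
) -> pd.DataFrame:
    """Build the within-species design table from group CV estimates.

    ``group_cvs`` needs columns (species, location_id, cv_hat, tau_hat, n);
    ``stations`` maps location_id to latitude plus planar x/y (or lon/lat).
    Output columns: species, location_id, cv_hat (x1000), tau_hat (x1000),
    Lat, DistEdge, SpatVar, TempVar — covariates log-transformed where
    applicable and centered within species — plus the uncentered raw
    covariates (suffix ``_raw``).  DistEdge enters as
    log(distance + offset) because stations outside the range have exact 0.
    """
    st = stations.set_index("location_id")
    rows = []
    for rec in group_cvs.itertuples(index=False):
        if rec.location_id not in st.index:
            raise ValueError(f"no station metadata for {rec.location_id!r}")
        srow = st.loc[rec.location_id]
        if crs == "planar_km":
            pt = (float(srow["x_km"]), float(srow["y_km"]))
        else:
            pt = (float(srow["longitude"]), float(srow["latitude"]))
        if rec.species not in polygons:
            raise ValueError(f"no range polygon for species {rec.species!r}")
        dist = distance_to_edge(pt, polygons[rec.species], buffer_km, crs)
        svar = spatial_cv(raster, pt, radius_km, crs)
        tvar = temporal_cv(raster, pt, radius_km, crs)
        rows.append(
            {
                "species": rec.species,
                "location_id": rec.location_id,
                "cv_hat": rec.cv_hat * 1000.0,
                "tau_hat": rec.tau_hat * 1000.0,
                "n": rec.n,
                "Lat_raw": float(srow["latitude"]),
                "DistEdge_raw": dist,
                "SpatVar_raw": svar,
                "TempVar_raw": tvar,
            }
        )
    out = pd.DataFrame(rows)
    out["Lat"] = out["Lat_raw"]
    out["DistEdge"] = np.log(out["DistEdge_raw"] + dist_edge_offset_km)
    with np.errstate(divide="raise"):
        out["SpatVar"] = np.log(out["SpatVar_raw"])
        out["TempVar"] = np.log(out["TempVar_raw"])
    for col in WITHIN_COVARIATES:
        out[col] -= out.groupby("species")[col].transform("mean")
    return out


def build_species_profiles(
    species_cvs: pd.DataFrame, traits: pd.DataFrame
) -> pd.DataFrame:
    """Species-level design: log-transform, then center and scale covariates.

    ``species_cvs`` has columns (species, cvsp_hat, tausp_hat); ``traits``
    has (species, gen_time_yr, hwi, range_size_km2, mig_status).  Output
    keeps the raw 0/1 ``mig_status`` alongside the centered-scaled design
    columns GenTime, HWI, RangeSize, MigStatus; CVs are put on the x1000
    scale used by the regressions.
    """
    df = species_cvs.merge(traits, on="species", how="left", validate="1:1")
    if df[["gen_time_yr", "hwi", "range_size_km2", "mig_status"]].isna().any().any():
        missing = df.loc[df["gen_time_yr"].isna(), "species"].tolist()
        raise ValueError(f"missing trait data for species: {missing}")
    if not set(df["mig_status"]) <= {0, 1}:
        raise ValueError("mig_status must be 0/1")
    df["cvsp_hat"] = df["cvsp_hat"] * 1000.0
    df["tausp_hat"] = df["tausp_hat"] * 1000.0
    df["GenTime"] = np.log(df["gen_time_yr"])
    df["HWI"] = np.log(df["hwi"])
    df["RangeSize"] = np.log(df["range_size_km2"])
    df["MigStatus"] = df["mig_status"].astype(float)
    for col in AMONG_COVARIATES:
        v = df[col]
        sd = v.std(ddof=1)
        if sd == 0:
            raise ValueError(f"species covariate {col} is constant")
        df[col] = (v - v.mean()) / sd
    return df


def vif(design: np.ndarray | pd.DataFrame) -> np.ndarray:
    """Variance inflation factor per column: 1 / (1 - R^2) from an OLS of the
    column on the remaining columns plus an intercept.

    Perfect collinearity is reported as ``inf``.
    """
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("vif needs more rows than columns")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("vif: constant column")
    out = np.empty(p)
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        yj = X[:, j]
        beta, *_ = np.linalg.lstsq(others, yj, rcond=None)
        resid = yj - others @ beta
        ss_res = float(resid @ resid)
        ss_tot = float(((yj - yj.mean()) ** 2).sum())
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out
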