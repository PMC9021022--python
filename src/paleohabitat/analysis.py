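"""Downstream habitat diagnostics: maps, regional series, overlap, site NPP.

These operations turn per-species habitat-suitability fields H(x, y, t)
and the resolved fossil record into the summary products used to reason
about species ranges, contact zones and successions: time-averaged
suitability maps, 4-degree regional series, zonal-mean overlap Hovmoeller
diagrams, per-cell suitability covariance, NPP sampled in a 6-degree
vicinity of each site, and fossil-presence probability curves built from
dating uncertainties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .grids import haversine_km, nearest_time_index
from .species_db import FossilRecord

logger = logging.getLogger(__name__)

#: reference point in central-eastern Africa for site-distance diagnostics
EAST_AFRICA_REFERENCE = (36.0, 4.0)  # (lon, lat)


@dataclass
class RegionalBox:
    """A width x width degree averaging box around a centre point."""

    center_lon: float
    center_lat: float
    width: float = 4.0

    def mask(self, field: xr.DataArray) -> xr.DataArray:
        """Cell-centre membership, half-open on the east/north edges."""
        half = self.width / 2
        lon = field["lon"]
        lat = field["lat"]
        return (
            (lon >= self.center_lon - half)
            & (lon < self.center_lon + half)
            & (lat >= self.center_lat - half)
            & (lat < self.center_lat + half)
        )


@dataclass
class SiteNPPPoint:
    record_index: int
    site_name: str
    species: str
    age_ka: float
    vicinity_npp: float  # mean NPP in a 6x6 degree box at the site's age slice
    distance_km: float  # haversine distance to the reference point


def _window_slice(field: xr.DataArray, window: tuple[float, float]) -> xr.DataArray:
    lo, hi = min(window), max(window)
    sel = field.sel(time=(field["time"] >= lo) & (field["time"] <= hi))
    if sel.sizes["time"] == 0:
        raise ValueError(f"time window {window} ka selects no slices")
    return sel


def time_mean_map(H: xr.DataArray, window: tuple[float, float] | None = None) -> xr.DataArray:
    """Per-cell mean suitability over an age window (ka)."""
    sel = H if window is None else _window_slice(H, window)
    return sel.mean("time")


def regional_series(H: xr.DataArray, box: RegionalBox) -> xr.DataArray:
    """Per-slice mean of H over land cells inside the box.

    Ocean cells are already NaN in H, so the mean runs over land only.
    """
    sub = H.where(box.mask(H))
    if bool(sub.isnull().all()):
        raise ValueError(
            f"no land cells inside the {box.width} deg box at "
            f"({box.center_lat} N, {box.center_lon} E)"
        )
    return sub.mean(("lat", "lon"))


def overlap_product(H1: xr.DataArray, H2: xr.DataArray) -> xr.DataArray:
    """Pointwise product of two suitability fields ('spatial scalar product')."""
    _check_registered(H1, H2)
    return H1 * H2


def zonal_mean(field: xr.DataArray) -> xr.DataArray:
    """Mean over longitudes (land cells) per latitude/slice: a Hovmoeller."""
    return field.mean("lon")


def overlap_covariance(
    H1: xr.DataArray, H2: xr.DataArray, window: tuple[float, float] | None = None
) -> xr.DataArray:
    """Per-cell temporal covariance of two suitability fields.

    A positive value marks cells where the two species' habitats breathe
    in phase over the window — candidate succession/contact regions.
    """
    _check_registered(H1, H2)
    a = H1 if window is None else _window_slice(H1, window)
    b = H2 if window is None else _window_slice(H2, window)
    if a.sizes["time"] < 2:
        raise ValueError("covariance needs at least 2 time slices")
    da = a - a.mean("time")
    db = b - b.mean("time")
    return (da * db).sum("time") / (a.sizes["time"] - 1)


def npp_at_sites(
    records: list[FossilRecord],
    npp_field: xr.DataArray,
    reference: tuple[float, float] = EAST_AFRICA_REFERENCE,
    vicinity_deg: float = 6.0,
) -> list[SiteNPPPoint]:
    """Vicinity-mean NPP and reference distance for each record.

    NPP is averaged over land cells of a ``vicinity_deg`` box centred on
    the site, at the time slice nearest the record's mean age.  Records
    outside the field's time axis are skipped with a log message.
    """
    time_ka = np.asarray(npp_field["time"].values, dtype=float)
    half_step = 0.5 * float(np.abs(np.diff(time_ka)).max()) if time_ka.size > 1 else 0.0
    out: list[SiteNPPPoint] = []
    ref_lon, ref_lat = reference
    for i, rec in enumerate(records):
        if not (time_ka.min() - half_step <= rec.age_ka <= time_ka.max() + half_step):
            logger.info("record %s outside NPP time axis; skipped", rec.site_name)
            continue
        ti = nearest_time_index(time_ka, rec.age_ka)
        box = RegionalBox(rec.lon, rec.lat, width=vicinity_deg)
        slab = npp_field.isel(time=ti)
        vic = slab.where(box.mask(slab))
        if bool(vic.isnull().all()):
            logger.info("record %s has no land in its vicinity box; skipped", rec.site_name)
            continue
        out.append(
            SiteNPPPoint(
                record_index=i,
                site_name=rec.site_name,
                species=rec.attributions[0],
                age_ka=rec.age_ka,
                vicinity_npp=float(vic.mean()),
                distance_km=float(haversine_km(rec.lon, rec.lat, ref_lon, ref_lat)),
            )
        )
    return out


def site_npp_frame(points: list[SiteNPPPoint]) -> pd.DataFrame:
    return pd.DataFrame([p.__dict__ for p in points])


def presence_probability(
    records: list[FossilRecord],
    time_ka: np.ndarray,
    kernel: str = "uniform",
) -> xr.DataArray:
    """Fossil-presence probability curve from ages and age uncertainties.

    Each record contributes a uniform kernel over [t - Δt, t + Δt]
    (matching the Monte-Carlo age-sampling distribution); a record with
    Δt = 0 contributes a spike at its nearest slice.  The superposition
    is normalised to peak 1.
    """
    if kernel != "uniform":
        raise NotImplementedError("only the uniform kernel is implemented")
    if len(records) == 0:
        raise ValueError("need at least one record")
    time_ka = np.asarray(time_ka, dtype=float)
    dt = float(np.abs(np.diff(time_ka)).max()) if time_ka.size > 1 else 1.0
    dens = np.zeros_like(time_ka)
    for rec in records:
        if rec.age_uncertainty_ka == 0:
            dens[nearest_time_index(time_ka, rec.age_ka)] += 1.0 / dt
        else:
            lo = rec.age_ka - rec.age_uncertainty_ka
            hi = rec.age_ka + rec.age_uncertainty_ka
            inside = (time_ka >= lo - dt / 2) & (time_ka <= hi + dt / 2)
            dens[inside] += 1.0 / (hi - lo)
    peak = dens.max()
    if peak > 0:
        dens = dens / peak
    return xr.DataArray(
        dens, dims=("time",), coords={"time": time_ka}, name="presence_probability"
    )


def _check_registered(a: xr.DataArray, b: xr.DataArray) -> None:
    for dim in ("time", "lat", "lon"):
        if dim in a.dims or dim in b.dims:
            if a.sizes.get(dim) != b.sizes.get(dim) or not np.allclose(
                np.asarray(a[dim].values, dtype=float),
                np.asarray(b[dim].values, dtype=float),
            ):
                raise ValueError(f"fields are not co-registered along {dim!r}")
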