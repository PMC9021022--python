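"""Grid definitions shared by the climate, downscaling and habitat modules.

A grid is a regular longitude/latitude raster with an associated boolean
land mask.  Climate fields live on :class:`xarray.Dataset` objects whose
``lat``/``lon`` coordinates come from a :class:`GridSpec`; the time axis is
expressed as age in thousands of years before present (ka), oldest first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

EARTH_RADIUS_KM = 6371.0


@dataclass
class GridSpec:
    """A regular lon/lat grid with a land mask.

    Parameters
    ----------
    lon_centers : array of cell-centre longitudes, degrees east, monotone.
    lat_centers : array of cell-centre latitudes, degrees north, monotone.
    land_mask : boolean array of shape ``(nlat, nlon)``; ``True`` = land.
        Defaults to all-land.
    """

    lon_centers: np.ndarray
    lat_centers: np.ndarray
    land_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.lon_centers = np.asarray(self.lon_centers, dtype=float)
        self.lat_centers = np.asarray(self.lat_centers, dtype=float)
        if self.lon_centers.ndim != 1 or self.lat_centers.ndim != 1:
            raise ValueError("lon_centers and lat_centers must be 1-D")
        for name, arr in (("lon_centers", self.lon_centers), ("lat_centers", self.lat_centers)):
            d = np.diff(arr)
            if arr.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{name} must be strictly monotone")
        if np.any(np.abs(self.lat_centers) > 90):
            raise ValueError("lat_centers must lie in [-90, 90]")
        if self.lon_centers.min() < -180 or self.lon_centers.max() >= 360:
            raise ValueError("lon_centers must lie in [-180, 180) or [0, 360)")
        if self.land_mask is None:
            self.land_mask = np.ones(self.shape, dtype=bool)
        self.land_mask = np.asarray(self.land_mask, dtype=bool)
        if self.land_mask.shape != self.shape:
            raise ValueError(
                f"land_mask shape {self.land_mask.shape} does not match grid {self.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.lat_centers.size, self.lon_centers.size)

    @property
    def n_cells(self) -> int:
        return self.lat_centers.size * self.lon_centers.size

    @classmethod
    def regular(
        cls,
        lon_min: float,
        lon_max: float,
        lat_min: float,
        lat_max: float,
        dlon: float,
        dlat: float | None = None,
        land_mask: np.ndarray | None = None,
    ) -> "GridSpec":
        """Build a grid of cell centres covering the given bounds."""
        if dlat is None:
            dlat = dlon
        lon = np.arange(lon_min + dlon / 2, lon_max, dlon)
        lat = np.arange(lat_min + dlat / 2, lat_max, dlat)
        return cls(lon, lat, land_mask)

    def coords(self) -> dict[str, np.ndarray]:
        return {"lat": self.lat_centers, "lon": self.lon_centers}

    def land_da(self) -> xr.DataArray:
        return xr.DataArray(
            self.land_mask, dims=("lat", "lon"), coords=self.coords(), name="land"
        )

    def nearest_cell(self, lon: float, lat: float) -> tuple[int, int]:
        """Index of the grid cell whose centre is nearest in lon/lat."""
        return (
            int(np.argmin(np.abs(self.lat_centers - lat))),
            int(np.argmin(np.abs(self.lon_centers - lon))),
        )

    def nearest_land_cell(self, lon: float, lat: float) -> tuple[tuple[int, int], float]:
        """Nearest *land* cell by great-circle distance.

        Returns ``((ilat, ilon), distance_km)`` from the query point to the
        chosen cell centre.  Raises if the grid has no land at all.
        """
        if not self.land_mask.any():
            raise ValueError("grid has no land cells")
        ilat, ilon = np.nonzero(self.land_mask)
        d = haversine_km(lon, lat, self.lon_centers[ilon], self.lat_centers[ilat])
        k = int(np.argmin(d))
        return (int(ilat[k]), int(ilon[k])), float(d[k])


def haversine_km(lon1, lat1, lon2, lat2, radius_km: float = EARTH_RADIUS_KM):
    """Great-circle (haversine) distance in km; broadcasts over arrays."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * radius_km * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def nearest_time_index(time_ka: np.ndarray, age_ka) -> np.ndarray:
    """Index of the time slice nearest to each requested age.

    Works for ascending or descending (oldest-first) age axes.
    """
    time_ka = np.asarray(time_ka, dtype=float)
    ages = np.atleast_1d(np.asarray(age_ka, dtype=float))
    idx = np.abs(ages[:, None] - time_ka[None, :]).argmin(axis=1)
    return int(idx[0]) if np.ndim(age_ka) == 0 else idx
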