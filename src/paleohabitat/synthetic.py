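"""Synthetic palaeoclimate trajectories, topography, CO2 and fossil databases.

This module generates inputs with *known* statistical structure so the
downscaling, productivity, envelope and null-model stages can be tested
end to end without any external climate-server download.  A trajectory is
a stack of 1,000-year climate slices over as much as 2 Myr; each of the
four envelope variables (annual mean temperature ``t_am``, annual mean
precipitation ``p_am``, annual minimum monthly precipitation ``p_min`` and
net primary productivity ``npp``) is built per grid cell as

    mean map  +  sum of orbital-period sinusoids  +  cross-correlated AR(1) noise.

Orbital periods default to the Milankovitch set (precession ~21 ka,
obliquity 41 ka, eccentricity 100/405 ka).  Noise innovations are coupled
across the four variables through the Cholesky factor of a 4x4 correlation
matrix, mirroring the co-varying components that the climate envelope
model assumes.  Fossil databases are drawn by rejection sampling against a
known ("true") climate envelope, which makes parameter-recovery tests of
the envelope fit self-consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage, stats

from .grids import GridSpec, nearest_time_index

VARIABLES = ("t_am", "p_am", "p_min", "npp")
#: variables that are physically non-negative and get clipped at zero
NONNEGATIVE = ("p_am", "p_min", "npp")

UNITS = {
    "t_am": "degC",
    "p_am": "mm/year",
    "p_min": "mm/month",
    "npp": "gC/m2/year",
    "co2": "ppm",
}


@dataclass
class OrbitalComponent:
    """One sinusoidal forcing component: ``amplitude * sin(2*pi*age/period + phase)``."""

    period_ka: float
    amplitude: float
    phase: float = 0.0

    def __post_init__(self) -> None:
        if self.period_ka <= 0:
            raise ValueError("orbital period must be positive")
        if self.amplitude < 0:
            raise ValueError("orbital amplitude must be non-negative")


@dataclass
class VariableSpec:
    """Spatial mean map, orbital forcing and noise level for one variable."""

    base: float
    lat_gradient: float = 0.0  # units per degree latitude
    spatial_sd: float = 0.0  # sd of the smooth random part of the mean map
    spatial_scale: float = 2.0  # gaussian smoothing length, in grid cells
    orbital: list[OrbitalComponent] = field(default_factory=list)
    noise_sd: float = 0.0  # stationary sd of the AR(1) noise

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.spatial_sd < 0:
            raise ValueError("standard deviations must be non-negative")


@dataclass
class SyntheticClimateSpec:
    """Full recipe for a synthetic four-variable climate trajectory."""

    variables: dict[str, VariableSpec]
    ar1_coef: float = 0.7
    cross_correlation: np.ndarray = field(
        default_factory=lambda: np.eye(len(VARIABLES))
    )
    n_time: int = 400
    dt_ka: float = 1.0
    age_oldest_ka: float | None = None  # default: n_time * dt_ka
    seed: int = 0

    def __post_init__(self) -> None:
        missing = [v for v in VARIABLES if v not in self.variables]
        if missing:
            raise ValueError(f"variable specs missing for {missing}")
        if self.n_time < 2:
            raise ValueError("n_time must be >= 2")
        if not -1 < self.ar1_coef < 1:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")
        R = np.asarray(self.cross_correlation, dtype=float)
        if R.shape != (4, 4) or not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("cross_correlation must be a symmetric 4x4 matrix")
        try:
            np.linalg.cholesky(R)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "cross_correlation must be positive-definite "
                f"(eigenvalues {np.linalg.eigvalsh(R)})"
            ) from exc
        self.cross_correlation = R

    def time_axis(self) -> np.ndarray:
        """Ages (ka before present) oldest-first."""
        oldest = self.age_oldest_ka if self.age_oldest_ka is not None else self.n_time * self.dt_ka
        return oldest - self.dt_ka * np.arange(self.n_time)


def default_climate_spec(n_time: int = 2000, seed: int = 0) -> SyntheticClimateSpec:
    """Study-scale default: 2,000 one-ka slices with Milankovitch forcing.

    Amplitudes and noise levels are set to glacial–interglacial magnitudes
    (a few degC in temperature, ~10% of mean in precipitation and NPP).
    """
    return SyntheticClimateSpec(
        variables={
            "t_am": VariableSpec(
                base=18.0, lat_gradient=-0.35, spatial_sd=2.0,
                orbital=[
                    OrbitalComponent(21, 1.2), OrbitalComponent(41, 1.8),
                    OrbitalComponent(100, 2.2, phase=0.7), OrbitalComponent(405, 0.8, phase=1.9),
                ],
                noise_sd=0.9,
            ),
            "p_am": VariableSpec(
                base=900.0, lat_gradient=-4.0, spatial_sd=150.0,
                orbital=[OrbitalComponent(21, 110.0, phase=0.3), OrbitalComponent(100, 60.0, phase=2.1)],
                noise_sd=80.0,
            ),
            "p_min": VariableSpec(
                base=25.0, lat_gradient=-0.15, spatial_sd=6.0,
                orbital=[OrbitalComponent(21, 6.0, phase=1.1), OrbitalComponent(41, 3.0)],
                noise_sd=4.0,
            ),
            "npp": VariableSpec(
                base=550.0, lat_gradient=-3.0, spatial_sd=90.0,
                orbital=[OrbitalComponent(21, 55.0, phase=0.5), OrbitalComponent(100, 35.0, phase=1.4)],
                noise_sd=45.0,
            ),
        },
        ar1_coef=0.7,
        cross_correlation=np.array(
            [
                [1.0, 0.5, 0.4, 0.55],
                [0.5, 1.0, 0.6, 0.5],
                [0.4, 0.6, 1.0, 0.45],
                [0.55, 0.5, 0.45, 1.0],
            ]
        ),
        n_time=n_time,
        dt_ka=1.0,
        seed=seed,
    )


def _mean_map(grid: GridSpec, vs: VariableSpec, rng: np.random.Generator) -> np.ndarray:
    lat2d = np.broadcast_to(grid.lat_centers[:, None], grid.shape)
    m = vs.base + vs.lat_gradient * (lat2d - lat2d.mean())
    if vs.spatial_sd > 0:
        noise = rng.standard_normal(grid.shape)
        smooth = ndimage.gaussian_filter(noise, vs.spatial_scale, mode="wrap")
        smooth = smooth - smooth.mean()  # smoothing leaves a nonzero mean on small grids
        sd = smooth.std()
        if sd > 1e-12:
            m = m + vs.spatial_sd * smooth / sd
    return m


def gen_climate_fields(grid: GridSpec, spec: SyntheticClimateSpec) -> xr.Dataset:
    """Generate the four co-registered envelope fields on ``(time, lat, lon)``.

    Per cell: mean map + orbital sinusoids + AR(1) noise whose innovations
    are correlated across the four variables (Cholesky coupling).  The
    stationary noise sd equals ``VariableSpec.noise_sd``.  Precipitation
    and NPP are clipped at zero.  Bit-reproducible for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx = grid.shape
    nt = spec.n_time
    ages = spec.time_axis()

    means = np.stack([_mean_map(grid, spec.variables[v], rng) for v in VARIABLES])

    # orbital forcing, spatially uniform per variable
    forcing = np.zeros((4, nt))
    for k, v in enumerate(VARIABLES):
        for comp in spec.variables[v].orbital:
            forcing[k] += comp.amplitude * np.sin(
                2 * np.pi * ages / comp.period_ka + comp.phase
            )

    sds = np.array([spec.variables[v].noise_sd for v in VARIABLES])
    rho = spec.ar1_coef
    L = np.linalg.cholesky(spec.cross_correlation)
    ncell = ny * nx
    noise = np.zeros((nt, 4, ncell))
    if np.any(sds > 0):
        z = rng.standard_normal((nt, 4, ncell))
        # stationary start, then AR recursion with innovation sd scaled so the
        # stationary sd equals the requested per-variable sd
        innov_scale = sds[:, None] * np.sqrt(1.0 - rho**2)
        noise[0] = sds[:, None] * (L @ z[0])
        for t in range(1, nt):
            noise[t] = rho * noise[t - 1] + innov_scale * (L @ z[t])

    data_vars = {}
    for k, v in enumerate(VARIABLES):
        cube = (
            means[k][None, :, :]
            + forcing[k][:, None, None]
            + noise[:, k, :].reshape(nt, ny, nx)
        )
        if v in NONNEGATIVE:
            cube = np.clip(cube, 0.0, None)
        data_vars[v] = xr.DataArray(
            cube, dims=("time", "lat", "lon"), attrs={"units": UNITS[v]}
        )
    ds = xr.Dataset(
        data_vars,
        coords={"time": ("time", ages, {"units": "ka BP"}), **grid.coords()},
    )
    ds["land"] = grid.land_da()
    return ds


def gen_topography_pair(
    grid_coarse: GridSpec,
    grid_fine: GridSpec,
    seed: int = 0,
    relief_m: float = 1500.0,
    fine_relief_m: float = 400.0,
) -> tuple[xr.DataArray, xr.DataArray]:
    """Smooth random orography on the coarse grid plus a refined surface.

    The fine surface is the coarse one bilinearly interpolated onto the
    fine grid plus smooth sub-grid relief, so the height difference used
    by the lapse-rate correction is non-trivial but fully known.
    """
    rng = np.random.default_rng(seed)

    def _surface(grid: GridSpec, amp: float, scale: float) -> np.ndarray:
        z = ndimage.gaussian_filter(rng.standard_normal(grid.shape), scale, mode="wrap")
        z = z - z.mean()
        sd = z.std()
        out = amp * z / sd if sd > 1e-12 else np.zeros(grid.shape)
        return np.clip(out + amp, 0.0, None)  # keep orography non-negative

    coarse = xr.DataArray(
        _surface(grid_coarse, relief_m, 1.5),
        dims=("lat", "lon"),
        coords=grid_coarse.coords(),
        name="orography",
        attrs={"units": "m"},
    )
    on_fine = coarse.interp(
        lat=grid_fine.lat_centers, lon=grid_fine.lon_centers,
        method="linear", kwargs={"fill_value": None},
    )
    sub = ndimage.gaussian_filter(rng.standard_normal(grid_fine.shape), 2.0, mode="wrap")
    sub = sub - sub.mean()
    sd = sub.std()
    sub = fine_relief_m * sub / sd if sd > 1e-12 else np.zeros(grid_fine.shape)
    fine = (on_fine + sub).clip(min=0.0).rename("orography")
    fine.attrs["units"] = "m"
    return coarse, fine


def gen_co2_series(
    n_time: int,
    base_ppm: float = 230.0,
    amplitude_ppm: float = 50.0,
    period_ka: float = 100.0,
    seed: int = 0,
    noise_sd_ppm: float = 0.0,
    time_ka: np.ndarray | None = None,
) -> xr.DataArray:
    """Sinusoidal glacial–interglacial CO2 series (ppm), strictly positive."""
    if base_ppm <= 0:
        raise ValueError("base_ppm must be positive")
    if amplitude_ppm < 0:
        raise ValueError("amplitude_ppm must be non-negative")
    if amplitude_ppm + max(noise_sd_ppm, 0) * 5 >= base_ppm:
        raise ValueError(
            "amplitude (plus 5 sd of noise) must stay below base_ppm; "
            "the series would reach non-positive concentrations"
        )
    if time_ka is None:
        time_ka = float(n_time) - np.arange(n_time, dtype=float)
    time_ka = np.asarray(time_ka, dtype=float)
    if time_ka.size != n_time:
        raise ValueError("time_ka length must equal n_time")
    series = base_ppm + amplitude_ppm * np.sin(2 * np.pi * time_ka / period_ka)
    if noise_sd_ppm > 0:
        rng = np.random.default_rng(seed)
        series = series + np.clip(
            noise_sd_ppm * rng.standard_normal(n_time), -5 * noise_sd_ppm, 5 * noise_sd_ppm
        )
    return xr.DataArray(
        series,
        dims=("time",),
        coords={"time": ("time", time_ka, {"units": "ka BP"})},
        name="co2",
        attrs={"units": "ppm"},
    )


@dataclass
class TrueEnvelopeSpec:
    """Ground-truth climate envelope used to place synthetic fossils."""

    centroid: np.ndarray  # (t_am degC, p_am mm/yr, p_min mm/month, npp gC/m2/yr)
    covariance: np.ndarray  # 4x4
    n_records: int = 200
    age_range_ka: tuple[float, float] = (30.0, 400.0)
    age_uncertainty_ka: tuple[float, float] = (1.0, 10.0)  # Δt drawn uniformly here
    species: str = "synthetica"
    seed: int = 0

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float)
        self.covariance = np.asarray(self.covariance, dtype=float)
        if self.centroid.shape != (4,) or self.covariance.shape != (4, 4):
            raise ValueError("centroid must be length-4, covariance 4x4")
        try:
            np.linalg.cholesky(self.covariance)
        except np.linalg.LinAlgError as exc:
            raise ValueError("true envelope covariance must be positive-definite") from exc
        if self.n_records < 1:
            raise ValueError("n_records must be >= 1")
        lo, hi = self.age_range_ka
        if lo > hi:
            raise ValueError("age_range_ka must be (min, max)")


def _true_suitability(spec: TrueEnvelopeSpec, quadruplets: np.ndarray) -> np.ndarray:
    """H = 1 - chi2_cdf(zeta^2; 4) under the true envelope (same transform
    as the analysis modules, so recovery tests are self-consistent)."""
    d = quadruplets - spec.centroid
    z2 = np.einsum("...i,ij,...j->...", d, np.linalg.inv(spec.covariance), d)
    return stats.chi2.sf(z2, df=4)


def gen_fossil_records(
    fields: xr.Dataset,
    truth: TrueEnvelopeSpec,
    max_attempt_factor: int = 2000,
) -> pd.DataFrame:
    """Draw a synthetic fossil/archaeological record table.

    Sites and ages are proposed uniformly over land cells and the allowed
    age range, then accepted with probability equal to the habitat
    suitability the *true* envelope assigns to the local climate at the
    nearest time slice — i.e. presence probability proportional to H.

    Returns a DataFrame with the species-database column schema
    (site_name, layer_id, lon, lat, age_ka, age_uncertainty_ka, species,
    dating_method, region).
    """
    rng = np.random.default_rng(truth.seed)
    time_ka = np.asarray(fields["time"].values, dtype=float)
    lo, hi = truth.age_range_ka
    if lo < time_ka.min() - 0.5 or hi > time_ka.max() + 0.5:
        raise ValueError(
            f"age_range_ka {truth.age_range_ka} outside climate time axis "
            f"[{time_ka.min()}, {time_ka.max()}]"
        )
    land = np.asarray(fields["land"].values, dtype=bool)
    ilat, ilon = np.nonzero(land)
    if ilat.size == 0:
        raise ValueError("fieldset has no land cells")
    cube = np.stack([fields[v].values for v in VARIABLES], axis=-1)  # (t, y, x, 4)

    rows: list[dict] = []
    max_attempts = max_attempt_factor * truth.n_records
    attempts = 0
    batch = max(256, truth.n_records)
    while len(rows) < truth.n_records and attempts < max_attempts:
        cells = rng.integers(0, ilat.size, size=batch)
        ages = rng.uniform(lo, hi, size=batch)
        tidx = nearest_time_index(time_ka, ages)
        quads = cube[tidx, ilat[cells], ilon[cells], :]
        accept = rng.uniform(size=batch) < _true_suitability(truth, quads)
        attempts += batch
        for j in np.nonzero(accept)[0]:
            if len(rows) >= truth.n_records:
                break
            k = len(rows)
            rows.append(
                {
                    "site_name": f"syn_site_{k:04d}",
                    "layer_id": "",
                    "lon": float(fields["lon"].values[ilon[cells[j]]]),
                    "lat": float(fields["lat"].values[ilat[cells[j]]]),
                    "age_ka": float(ages[j]),
                    "age_uncertainty_ka": float(
                        rng.uniform(*truth.age_uncertainty_ka)
                    ),
                    "species": truth.species,
                    "dating_method": "synthetic",
                    "region": "synthetic",
                }
            )
    if len(rows) < truth.n_records:
        raise RuntimeError(
            f"rejection sampling accepted only {len(rows)}/{truth.n_records} records "
            f"after {attempts} proposals; the true centroid likely lies outside the "
            "range of the simulated climate"
        )
    return pd.DataFrame(rows)


def envelope_spec_from_fields(
    fields: xr.Dataset,
    n_records: int = 200,
    age_range_ka: tuple[float, float] | None = None,
    scale: float = 1.0,
    seed: int = 0,
    species: str = "synthetica",
) -> TrueEnvelopeSpec:
    """Convenience: a true envelope centred on the fieldset's land-mean
    climate with covariance ``scale`` times the land climate covariance —
    guaranteed to be reachable by rejection sampling."""
    land = np.asarray(fields["land"].values, dtype=bool)
    X = np.stack(
        [fields[v].values[:, land].ravel() for v in VARIABLES], axis=1
    )
    time_ka = np.asarray(fields["time"].values, dtype=float)
    if age_range_ka is None:
        age_range_ka = (float(time_ka.min()), float(time_ka.max()))
    return TrueEnvelopeSpec(
        centroid=X.mean(axis=0),
        covariance=scale * np.cov(X, rowvar=False),
        n_records=n_records,
        age_range_ka=age_range_ka,
        seed=seed,
        species=species,
    )
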