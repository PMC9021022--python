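"""Mahalanobis climate-envelope model and habitat suitability.

For each hominin group the climate quadruplets (annual mean temperature,
annual mean precipitation, minimum monthly precipitation, NPP) are
extracted at the occurrence sites and ages, with dating uncertainty
propagated by Monte-Carlo age draws.  The envelope is the sample mean
``m`` and (unbiased) covariance ``S`` of those rows; distance from the
envelope centre is the Mahalanobis squared distance

    zeta^2(c) = (c - m)^T S^{-1} (c - m),

and habitat suitability is its upper chi-squared tail with one degree of
freedom per climate variable (4 by default):

    H(c) = 1 - chi2_cdf(zeta^2; d)    in [0, 1].

H is interpreted as the probability of finding fossil or archaeological
evidence of the group under climate ``c``; for d = 4 it has the closed
form exp(-z/2) * (1 + z/2).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .grids import GridSpec, nearest_time_index
from .species_db import FossilRecord, sample_ages
from .synthetic import VARIABLES

logger = logging.getLogger(__name__)

CONDITION_LIMIT = 1e10
DEFAULT_RIDGE = 1e-8


@dataclass
class ClimateMatrix:
    """Occurrence-climate rows (N x d) with per-row provenance."""

    data: np.ndarray
    variables: tuple[str, ...] = VARIABLES
    provenance: pd.DataFrame | None = None  # record index, sampled age, cell

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.variables):
            raise ValueError("climate matrix must be N x d")
        if np.isnan(self.data).any():
            raise ValueError("climate matrix contains missing values")

    @property
    def n(self) -> int:
        return self.data.shape[0]


@dataclass
class EnvelopeModel:
    """Fitted climate envelope: mean, covariance and its inverse."""

    mean: np.ndarray
    covariance: np.ndarray
    inverse: np.ndarray
    n_samples: int
    variables: tuple[str, ...] = VARIABLES
    species: str = ""
    ridge_applied: float = 0.0

    @property
    def dof(self) -> int:
        """Degrees of freedom of the chi-squared transform = dimensionality."""
        return len(self.variables)

    def to_json(self, path) -> None:
        payload = {
            "species": self.species,
            "variables": list(self.variables),
            "mean": self.mean.tolist(),
            "covariance": self.covariance.tolist(),
            "n_samples": self.n_samples,
            "ridge_applied": self.ridge_applied,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "EnvelopeModel":
        with open(path) as fh:
            payload = json.load(fh)
        cov = np.asarray(payload["covariance"], dtype=float)
        return cls(
            mean=np.asarray(payload["mean"], dtype=float),
            covariance=cov,
            inverse=np.linalg.inv(cov),
            n_samples=int(payload["n_samples"]),
            variables=tuple(payload["variables"]),
            species=payload.get("species", ""),
            ridge_applied=float(payload.get("ridge_applied", 0.0)),
        )


def extract_climate(
    records: list[FossilRecord],
    fields: xr.Dataset,
    n_draws: int = 10,
    rng: np.random.Generator | None = None,
    variables: tuple[str, ...] = VARIABLES,
    age_distribution: str = "uniform",
    min_records: int = 5,
) -> ClimateMatrix:
    """Extract climate quadruplets at occurrence sites and sampled ages.

    Each record contributes ``n_draws`` rows (Monte-Carlo propagation of
    its age uncertainty).  Sites snap to the nearest *land* grid cell
    (snapping distance logged); each sampled age maps to the nearest
    1,000-year slice.  Records whose mean age falls outside the fieldset's
    time axis are skipped with a log message.  Fewer than ``min_records``
    usable records is an error: the covariance would be unidentifiable.
    """
    if rng is None:
        rng = np.random.default_rng()
    time_ka = np.asarray(fields["time"].values, dtype=float)
    t_lo, t_hi = time_ka.min(), time_ka.max()
    half_step = 0.5 * float(np.abs(np.diff(time_ka)).max()) if time_ka.size > 1 else 0.0
    grid = GridSpec(
        fields["lon"].values, fields["lat"].values, np.asarray(fields["land"].values, dtype=bool)
    )
    cube = np.stack([fields[v].values for v in variables], axis=-1)

    rows: list[np.ndarray] = []
    prov: list[dict] = []
    n_used = 0
    for i, rec in enumerate(records):
        if not (t_lo - half_step <= rec.age_ka <= t_hi + half_step):
            logger.info(
                "record %s (age %.1f ka) outside the climate time axis; skipped",
                rec.site_name, rec.age_ka,
            )
            continue
        (ilat, ilon), dist = grid.nearest_land_cell(rec.lon, rec.lat)
        if dist > 0:
            logger.debug("record %s snapped %.1f km to nearest land cell", rec.site_name, dist)
        ages = np.clip(sample_ages(rec, n_draws, rng, age_distribution), min(t_lo, t_hi), max(t_lo, t_hi))
        tidx = nearest_time_index(time_ka, ages)
        for a, ti in zip(ages, np.atleast_1d(tidx)):
            rows.append(cube[ti, ilat, ilon, :])
            prov.append(
                {"record": i, "site_name": rec.site_name, "sampled_age_ka": float(a),
                 "time_index": int(ti), "ilat": ilat, "ilon": ilon, "snap_km": dist}
            )
        n_used += 1
    if n_used < min_records:
        raise ValueError(
            f"only {n_used} usable records (< {min_records}); "
            "covariance of the climate envelope is unidentifiable"
        )
    return ClimateMatrix(
        data=np.asarray(rows), variables=variables, provenance=pd.DataFrame(prov)
    )


def fit_envelope(
    D: ClimateMatrix | np.ndarray,
    species: str = "",
    ridge: float | None = DEFAULT_RIDGE,
) -> EnvelopeModel:
    """Fit the envelope: sample mean and unbiased covariance with inverse.

    Near-singular covariances (condition number above 1e10) receive a
    diagonal ridge ``ridge * diag(S)`` (logged); pass ``ridge=None`` to
    make ill-conditioning a hard error instead.
    """
    if isinstance(D, ClimateMatrix):
        X, variables = D.data, D.variables
    else:
        X = np.asarray(D, dtype=float)
        variables = VARIABLES[: X.shape[1]] if X.shape[1] <= 4 else tuple(
            f"v{i}" for i in range(X.shape[1])
        )
    n, d = X.shape
    if n < d + 1:
        raise ValueError(f"need at least {d + 1} rows to fit a {d}-D envelope, got {n}")
    mean = X.mean(axis=0)
    cov = np.cov(X, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    ridge_applied = 0.0
    if np.linalg.cond(cov) > CONDITION_LIMIT:
        if ridge is None:
            raise np.linalg.LinAlgError(
                f"envelope covariance is ill-conditioned (cond > {CONDITION_LIMIT:.0e}); "
                "enable the diagonal ridge fallback (ridge=1e-8) or drop degenerate variables"
            )
        dvar = np.diag(cov).copy()
        floor = dvar[dvar > 0].mean() if (dvar > 0).any() else 1.0
        cov = cov + ridge * np.diag(np.where(dvar > 0, dvar, floor))
        ridge_applied = ridge
        logger.warning("ill-conditioned covariance; applied ridge %.1e * diag(S)", ridge)
    inv = np.linalg.inv(cov)
    resid = np.max(np.abs(inv @ cov - np.eye(d)))
    if resid > 1e-8:
        logger.warning("S^-1 S deviates from identity by %.2e", resid)
    return EnvelopeModel(
        mean=mean, covariance=cov, inverse=inv, n_samples=n,
        variables=tuple(variables), species=species, ridge_applied=ridge_applied,
    )


def mahalanobis_sq(env: EnvelopeModel, c) -> np.ndarray:
    """zeta^2 = (c - m)^T S^-1 (c - m); broadcasts over leading axes of c."""
    diff = np.asarray(c, dtype=float) - env.mean
    return np.einsum("...i,ij,...j->...", diff, env.inverse, diff)


def suitability(env: EnvelopeModel, c=None, zeta_sq=None):
    """Habitat suitability H = 1 - chi2_cdf(zeta^2; dof), in [0, 1].

    Provide either a climate vector/array ``c`` or precomputed ``zeta_sq``.
    """
    if (c is None) == (zeta_sq is None):
        raise ValueError("provide exactly one of c or zeta_sq")
    z2 = mahalanobis_sq(env, c) if zeta_sq is None else np.asarray(zeta_sq, dtype=float)
    return stats.chi2.sf(z2, df=env.dof)


def suitability_field(env: EnvelopeModel, fields: xr.Dataset) -> xr.DataArray:
    """Evaluate H at every land cell and time slice of a fieldset."""
    missing = [v for v in env.variables if v not in fields]
    if missing:
        raise ValueError(f"fieldset lacks envelope variables {missing}")
    cube = np.stack(
        [fields[v].transpose("time", "lat", "lon").values for v in env.variables], axis=-1
    )
    H = suitability(env, c=cube)
    out = xr.DataArray(
        H,
        dims=("time", "lat", "lon"),
        coords={"time": fields["time"], "lat": fields["lat"], "lon": fields["lon"]},
        name="habitat_suitability",
        attrs={"long_name": "habitat suitability", "species": env.species},
    )
    if "land" in fields:
        out = out.where(fields["land"])
    return out
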