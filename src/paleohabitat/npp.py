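"""Empirical tree-fraction and net-primary-productivity diagnostic.

NPP (gC m-2 yr-1) is computed a posteriori from downscaled annual mean
temperature T* (degC) and annual precipitation p* (mm yr-1):

    tree fraction   tau = 0.95 * {1 - exp[-beta (T* - T_m)]} * p*^alpha / (p*^alpha + f)
                    f   = b * exp[gamma (T* - T_m)]
    grass term      G   = 6116 * [1 - exp(-0.0000605 p*)]
    forest terms    FP  = 0.551 * p*^1.055 / exp(0.000306 p*)
                    FT  = 2540 / [1 + exp(1.584 - 0.0622 T*)]
    productivity    N*  = [G (1 - tau) + tau min(FP, FT)] * fCO2
    fertilization   fCO2 = 1 + 0.4 * ln(CO2 / 280) / ln 2

with beta = 0.45, alpha = 3, b = 2.6e6, gamma = 0.155, T_m = -15 degC.
tau is capped to [0, 1].  The precipitation constants presuppose
mm yr-1; a units check guards field evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import xarray as xr

from .synthetic import UNITS


@dataclass
class NPPParams:
    beta: float = 0.45  # 1/degC
    alpha: float = 3.0
    b: float = 2.6e6
    gamma: float = 0.155  # 1/degC
    t_m: float = -15.0  # degC
    grass_max: float = 6116.0  # gC/m2/yr
    grass_rate: float = 0.0000605  # 1/mm
    fp_coef: float = 0.551
    fp_exp: float = 1.055
    fp_rate: float = 0.000306  # 1/mm
    ft_max: float = 2540.0  # gC/m2/yr
    ft_a: float = 1.584
    ft_b: float = 0.0622  # 1/degC
    co2_ref: float = 280.0  # ppm
    co2_coef: float = 0.4


def tree_fraction(t_s, p_ann, params: NPPParams | None = None):
    """Tree-covered fraction tau in [0, 1]; tau = 0 at p* = 0 (limit)."""
    params = params or NPPParams()
    t_s = np.asarray(t_s) if not isinstance(t_s, xr.DataArray) else t_s
    p = np.asarray(p_ann) if not isinstance(p_ann, xr.DataArray) else p_ann
    if np.any(np.asarray(p) < 0):
        raise ValueError("annual precipitation must be non-negative")
    f = params.b * np.exp(params.gamma * (t_s - params.t_m))
    p_a = p**params.alpha
    tau = 0.95 * (1.0 - np.exp(-params.beta * (t_s - params.t_m))) * p_a / (p_a + f)
    return np.clip(tau, 0.0, 1.0)


def co2_fertilization(co2_ppm, params: NPPParams | None = None):
    """Logarithmic CO2 fertilization factor, 1 at the 280 ppm reference."""
    params = params or NPPParams()
    if np.any(np.asarray(co2_ppm) <= 0):
        raise ValueError("CO2 concentration must be positive")
    return 1.0 + params.co2_coef * np.log(co2_ppm / params.co2_ref) / np.log(2.0)


def npp(t_s, p_ann, tau, co2_ppm, params: NPPParams | None = None):
    """Net primary productivity (gC m-2 yr-1), elementwise and non-negative."""
    params = params or NPPParams()
    p = np.asarray(p_ann) if not isinstance(p_ann, xr.DataArray) else p_ann
    grass = params.grass_max * (1.0 - np.exp(-params.grass_rate * p))
    with np.errstate(divide="ignore", invalid="ignore"):
        fp = params.fp_coef * p**params.fp_exp / np.exp(params.fp_rate * p)
    fp = xr.where(p == 0, 0.0, fp) if isinstance(fp, xr.DataArray) else np.where(np.asarray(p) == 0, 0.0, fp)
    ft = params.ft_max / (1.0 + np.exp(params.ft_a - params.ft_b * t_s))
    forest = np.minimum(fp, ft)  # pointwise, per cell
    return (grass * (1.0 - tau) + tau * forest) * co2_fertilization(co2_ppm, params)


def npp_field(
    fine_fields: xr.Dataset,
    co2: xr.DataArray,
    params: NPPParams | None = None,
) -> xr.DataArray:
    """Evaluate NPP per time slice over land cells of a downscaled fieldset.

    ``fine_fields`` must carry ``t_am`` (degC) and ``p_am`` (mm/year);
    ``co2`` (ppm) must share the fieldset's time axis exactly.  Ocean
    cells are masked (NaN).
    """
    params = params or NPPParams()
    for var in ("t_am", "p_am"):
        if var not in fine_fields:
            raise ValueError(f"fieldset lacks variable {var!r}")
    p_units = fine_fields["p_am"].attrs.get("units")
    if p_units not in (None, "mm/year"):
        raise ValueError(
            f"p_am units {p_units!r} are not mm/year; the NPP constants presuppose mm/year"
        )
    if co2.sizes.get("time") != fine_fields.sizes["time"] or not np.allclose(
        np.asarray(co2["time"].values, dtype=float),
        np.asarray(fine_fields["time"].values, dtype=float),
    ):
        raise ValueError("CO2 series time axis does not match the climate fieldset")
    t = fine_fields["t_am"]
    p = fine_fields["p_am"]
    tau = tree_fraction(t, p, params)
    out = npp(t, p, tau, co2, params).transpose("time", "lat", "lon")
    if "land" in fine_fields:
        out = out.where(fine_fields["land"])
    out.name = "npp"
    out.attrs["units"] = UNITS["npp"]
    return out
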