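"""NetCDF/CSV persistence helpers.

Gridded products are written as classic NetCDF through xarray's scipy
backend with CF-style units attributes; tabular products go to CSV via
pandas.
"""

from __future__ import annotations

import pandas as pd
import xarray as xr


def write_netcdf(obj: xr.Dataset | xr.DataArray, path) -> None:
    """Write a dataset/array as classic NetCDF (scipy backend)."""
    ds = obj.to_dataset() if isinstance(obj, xr.DataArray) else obj
    enc = {}
    for name, var in ds.data_vars.items():
        if var.dtype == bool:  # classic NetCDF has no bool type
            ds[name] = var.astype("i1")
            enc[name] = {}
    ds.to_netcdf(path, engine="scipy")


def read_netcdf(path) -> xr.Dataset:
    ds = xr.load_dataset(path, engine="scipy")
    if "land" in ds:
        ds["land"] = ds["land"].astype(bool)
    return ds


def write_records_csv(records, path) -> None:
    from .species_db import records_to_frame

    records_to_frame(records).to_csv(path, index=False)


def read_records_csv(path):
    from .species_db import frame_to_records

    return frame_to_records(pd.read_csv(path, keep_default_na=False))
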