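"""Serialization of epoch arrays and information series (HDF5), tables (CSV)
and fits/cluster statistics (JSON)."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import xarray as xr

from .dynamics import InfoSeries
from .stats import Cluster, ClusterResult

__all__ = [
    "save_epochs",
    "load_epochs",
    "save_info_series",
    "load_info_series",
    "cluster_result_to_dict",
    "save_json",
]

_STR = h5py.string_dtype(encoding="utf-8")


def save_epochs(path: str | Path, epochs: xr.DataArray) -> None:
    """Write a (contact, trial, time) epoch array with its metadata."""
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=epochs.values)
        f.create_dataset("time", data=epochs["time"].values)
        f.attrs["sfreq"] = float(epochs.attrs.get("sfreq", 0.0))
        for aux in ("subject", "roi", "role"):
            if aux in epochs.coords:
                vals = epochs[aux].values
                dt = _STR if vals.dtype.kind in "OU" else vals.dtype
                f.create_dataset(aux, data=vals.astype(dt))


def load_epochs(path: str | Path) -> xr.DataArray:
    with h5py.File(path, "r") as f:
        data = f["power"][()]
        times = f["time"][()]
        da = xr.DataArray(
            data,
            dims=("contact", "trial", "time"),
            coords={
                "contact": np.arange(data.shape[0]),
                "trial": np.arange(data.shape[1]),
                "time": times,
            },
        )
        for aux in ("subject", "roi", "role"):
            if aux in f:
                v = f[aux][()]
                if v.dtype.kind == "O" or v.dtype.kind == "S":
                    v = np.array([s.decode() if isinstance(s, bytes) else s for s in v])
                da = da.assign_coords({aux: ("contact", v)})
        da.attrs["sfreq"] = float(f.attrs["sfreq"])
    return da


def save_info_series(path: str | Path, series: InfoSeries) -> None:
    """Write an information series (and its permutation null, if present)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=series.values.values)
        f.create_dataset("time", data=series.values["time"].values)
        f.create_dataset(
            "unit", data=np.asarray(series.values["unit"].values, dtype=str).astype(_STR)
        )
        f.attrs["measure"] = series.measure
        f.attrs["target"] = series.target
        if series.seed is not None:
            f.attrs["seed"] = int(series.seed)
        if series.null is not None:
            f.create_dataset("null", data=series.null.values)
        for aux in ("subject", "roi"):
            if aux in series.values.coords:
                vals = series.values[aux].values
                dt = _STR if vals.dtype.kind in "OU" else vals.dtype
                f.create_dataset(aux, data=vals.astype(dt))


def load_info_series(path: str | Path) -> InfoSeries:
    with h5py.File(path, "r") as f:
        units = np.array([u.decode() if isinstance(u, bytes) else u for u in f["unit"][()]])
        coords = {"unit": units, "time": f["time"][()]}
        values = xr.DataArray(f["values"][()], dims=("unit", "time"), coords=coords)
        for aux in ("subject", "roi"):
            if aux in f:
                v = f[aux][()]
                if v.dtype.kind in "OS":
                    v = np.array([s.decode() if isinstance(s, bytes) else s for s in v])
                values = values.assign_coords({aux: ("unit", v)})
        null = None
        if "null" in f:
            null = xr.DataArray(
                f["null"][()],
                dims=("unit", "time", "perm"),
                coords=coords | {"perm": np.arange(f["null"].shape[-1])},
            )
        return InfoSeries(
            values=values,
            measure=str(f.attrs["measure"]),
            target=str(f.attrs["target"]),
            null=null,
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )


def cluster_result_to_dict(res: ClusterResult) -> dict:
    def window(c: Cluster) -> dict:
        d = {"start": c.start, "stop": c.stop, "mass": c.mass, "p": c.p}
        if res.times is not None:
            d["t_start"] = float(res.times[c.start])
            d["t_stop"] = float(res.times[min(c.stop, len(res.times)) - 1])
        return d

    return {
        "threshold": res.threshold,
        "n_perm": res.n_perm,
        "clusters": [window(c) for c in res.clusters],
    }


def save_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_default))


def _default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
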