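"""Serialization of complex spectra, sinograms and crossbar arrays.

Complex matrices/vectors go to HDF5 as two real planes named ``re`` and
``im``, or to CSV with columns ``index,re,im`` (vectors only).  Sinograms
are stored as an HDF5 dataset ``sinogram`` with ``n_bins`` and
``angles_deg`` attributes.  Crossbar arrays keep their target/programmed
conductances, fault mask and configuration attributes.
"""

from __future__ import annotations

import dataclasses

import h5py
import numpy as np
import pandas as pd

from .crossbar import CrossbarArray, CrossbarConfig
from .ct import Sinogram

__all__ = [
    "save_complex_h5",
    "load_complex_h5",
    "save_complex_csv",
    "load_complex_csv",
    "save_sinogram_h5",
    "load_sinogram_h5",
    "save_crossbar_h5",
    "load_crossbar_h5",
]


def save_complex_h5(path, z: np.ndarray, name: str = "data") -> None:
    z = np.asarray(z, dtype=complex)
    with h5py.File(path, "w") as f:
        grp = f.create_group(name)
        grp.create_dataset("re", data=z.real)
        grp.create_dataset("im", data=z.imag)


def load_complex_h5(path, name: str = "data") -> np.ndarray:
    with h5py.File(path, "r") as f:
        grp = f[name]
        return grp["re"][()] + 1j * grp["im"][()]


def save_complex_csv(path, z: np.ndarray) -> None:
    z = np.asarray(z, dtype=complex)
    if z.ndim != 1:
        raise ValueError("CSV serialization is defined for vectors")
    pd.DataFrame(
        {"index": np.arange(z.size), "re": z.real, "im": z.imag}
    ).to_csv(path, index=False)


def load_complex_csv(path) -> np.ndarray:
    df = pd.read_csv(path).sort_values("index")
    return df["re"].to_numpy() + 1j * df["im"].to_numpy()


def save_sinogram_h5(path, sino: Sinogram) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("sinogram", data=sino.values)
        d.attrs["n_bins"] = sino.n_bins
        d.attrs["angles_deg"] = sino.angles_deg
        if sino.patch_shape is not None:
            d.attrs["patch_shape"] = sino.patch_shape


def load_sinogram_h5(path) -> Sinogram:
    with h5py.File(path, "r") as f:
        d = f["sinogram"]
        patch_shape = (
            tuple(int(v) for v in d.attrs["patch_shape"])
            if "patch_shape" in d.attrs
            else None
        )
        return Sinogram(
            values=d[()],
            angles_deg=np.asarray(d.attrs["angles_deg"]),
            patch_shape=patch_shape,
        )


def save_crossbar_h5(path, arr: CrossbarArray) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("g_target", data=arr.g_target)
        f.create_dataset("g_programmed", data=arr.g_programmed)
        f.create_dataset("fault_mask", data=arr.fault_mask)
        f.attrs["scale_factor"] = arr.scale_factor
        if arr.n_points is not None:
            f.attrs["n_points"] = arr.n_points
        if arr.direction is not None:
            f.attrs["direction"] = arr.direction
        for k, v in dataclasses.asdict(arr.config).items():
            if v is not None:
                f.attrs[f"config_{k}"] = v


def load_crossbar_h5(path) -> CrossbarArray:
    with h5py.File(path, "r") as f:
        cfg_kwargs = {}
        for k in ("g_full_scale", "mapping_margin", "n_levels", "read_voltage", "scheme"):
            key = f"config_{k}"
            if key in f.attrs:
                v = f.attrs[key]
                cfg_kwargs[k] = v.item() if hasattr(v, "item") else v
        if "scheme" in cfg_kwargs and isinstance(cfg_kwargs["scheme"], bytes):
            cfg_kwargs["scheme"] = cfg_kwargs["scheme"].decode()
        if "n_levels" in cfg_kwargs:
            cfg_kwargs["n_levels"] = int(cfg_kwargs["n_levels"])
        return CrossbarArray(
            g_target=f["g_target"][()],
            g_programmed=f["g_programmed"][()],
            fault_mask=f["fault_mask"][()].astype(bool),
            scale_factor=float(f.attrs["scale_factor"]),
            config=CrossbarConfig(**cfg_kwargs),
            n_points=int(f.attrs["n_points"]) if "n_points" in f.attrs else None,
            direction=str(f.attrs["direction"]) if "direction" in f.attrs else None,
        )
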