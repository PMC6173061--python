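"""Reading and writing measurement stacks and parameter maps.

On-disk conventions: angles are degrees (direction in [0, 180),
inclination in [-90, 90]); internally everything is radians.  Stacks live
in HDF5 under ``/intensities`` with shape (n_tilts, n_p, H, W) and the
acquisition geometry as attributes, or — for legacy pipelines — as a
directory of per-position multi-page TIFFs plus a ``meta.json``.  Output
maps are 32-bit float TIFFs plus an HDF5 bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import tifffile

from .geometry import TiltState

__all__ = ["Stack", "read_stack", "write_stack", "write_maps", "read_maps"]

_STACK_ATTRS = ("tilt_labels", "tilt_psi_deg", "tilt_tau_deg", "rho_deg", "n_tissue")
#: map name -> (file name, stored unit)
_MAP_FILES = {
    "direction": ("direction.tif", "deg"),
    "inclination": ("inclination.tif", "deg"),
    "thickness": ("thickness.tif", ""),
    "chi2": ("chi2.tif", ""),
    "r_squared": ("r_squared.tif", ""),
}


@dataclass
class Stack:
    """An image stack of tilting measurements.

    ``tilt_states`` carry the *internal* tilt angles; conversion from the
    stage angle happens when reading experimental data.
    """

    intensities: np.ndarray  # (n_tilts, n_p, H, W)
    tilt_states: list[TiltState]
    rho: np.ndarray
    n_tissue: float = 1.45

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 4:
            raise ValueError("stack must have shape (n_tilts, n_p, H, W)")
        n_t, n_p = self.intensities.shape[:2]
        if n_t != len(self.tilt_states) or n_p != len(self.rho):
            raise ValueError("stack axes inconsistent with tilt states / rho")


def write_stack(path, stack: Stack) -> None:
    """Write a stack to HDF5 (dataset /intensities + geometry attributes)."""
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("intensities", data=stack.intensities)
        ds.attrs["tilt_labels"] = [t.label for t in stack.tilt_states]
        ds.attrs["tilt_psi_deg"] = [np.rad2deg(t.psi) for t in stack.tilt_states]
        ds.attrs["tilt_tau_deg"] = [np.rad2deg(t.tau) for t in stack.tilt_states]
        ds.attrs["rho_deg"] = np.rad2deg(stack.rho)
        ds.attrs["n_tissue"] = stack.n_tissue


def _states_from_meta(labels, psi_deg, tau_deg) -> list[TiltState]:
    return [
        TiltState(j, float(np.deg2rad(p)), float(np.deg2rad(t)), str(lab))
        for j, (lab, p, t) in enumerate(zip(labels, psi_deg, tau_deg))
    ]


def read_stack(path) -> Stack:
    """Read a stack from an HDF5 file or a legacy TIFF directory."""
    path = Path(path)
    if path.is_dir():
        return _read_tiff_dir(path)
    with h5py.File(path, "r") as f:
        if "intensities" not in f:
            raise ValueError(f"{path}: missing dataset 'intensities'")
        ds = f["intensities"]
        for a in _STACK_ATTRS:
            if a not in ds.attrs:
                raise ValueError(f"{path}: missing stack attribute '{a}'")
        states = _states_from_meta(
            ds.attrs["tilt_labels"], ds.attrs["tilt_psi_deg"], ds.attrs["tilt_tau_deg"]
        )
        return Stack(ds[()], states, np.deg2rad(ds.attrs["rho_deg"]),
                     float(ds.attrs["n_tissue"]))


def write_tiff_dir(path, stack: Stack) -> None:
    """Legacy layout: one multi-page TIFF per stage position + meta.json."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for j, t in enumerate(stack.tilt_states):
        tifffile.imwrite(
            path / f"{j:02d}_{t.label}.tif",
            stack.intensities[j].astype(np.float32),
            photometric="minisblack",
        )
    meta = {
        "tilt_labels": [t.label for t in stack.tilt_states],
        "tilt_psi_deg": [float(np.rad2deg(t.psi)) for t in stack.tilt_states],
        "tilt_tau_deg": [float(np.rad2deg(t.tau)) for t in stack.tilt_states],
        "rho_deg": [float(r) for r in np.rad2deg(stack.rho)],
        "n_tissue": stack.n_tissue,
    }
    (path / "meta.json").write_text(json.dumps(meta, indent=1))


def _read_tiff_dir(path: Path) -> Stack:
    meta_path = path / "meta.json"
    if not meta_path.exists():
        raise ValueError(f"{path}: missing stack attribute file 'meta.json'")
    meta = json.loads(meta_path.read_text())
    for a in _STACK_ATTRS:
        if a not in meta:
            raise ValueError(f"{path}: missing stack attribute '{a}'")
    states = _states_from_meta(
        meta["tilt_labels"], meta["tilt_psi_deg"], meta["tilt_tau_deg"]
    )
    pages = [
        tifffile.imread(sorted(path.glob(f"{j:02d}_*.tif"))[0])
        for j in range(len(states))
    ]
    return Stack(np.stack(pages), states, np.deg2rad(np.asarray(meta["rho_deg"])),
                 float(meta["n_tissue"]))


def write_maps(maps: dict, out_dir) -> None:
    """Write parameter maps as 32-bit float TIFFs plus an HDF5 bundle.

    Angle maps are converted to degrees on disk: direction in [0, 180),
    inclination in [-90, 90].
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with h5py.File(out_dir / "maps.h5", "w") as bundle:
        for name, arr in maps.items():
            fname, unit = _MAP_FILES.get(name, (f"{name}.tif", ""))
            data = np.rad2deg(arr) if unit == "deg" else np.asarray(arr)
            data = data.astype(np.float32)
            tifffile.imwrite(out_dir / fname, data, photometric="minisblack")
            bundle.create_dataset(name, data=data).attrs["unit"] = unit


def read_maps(out_dir) -> dict:
    """Read back a map directory written by :func:`write_maps` (radians)."""
    out = {}
    with h5py.File(Path(out_dir) / "maps.h5", "r") as bundle:
        for name in bundle:
            data = bundle[name][()].astype(float)
            if bundle[name].attrs.get("unit") == "deg":
                data = np.deg2rad(data)
            out[name] = data
    return out
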