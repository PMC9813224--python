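"""Reading and writing the package's on-disk formats.

Spectra travel as delimited text (first column = wavenumber, one column per
spectrum, header row of spectrum ids) with a separate metadata table; a
hyperspectral map is a single HDF5 container holding the cube, axis, pixel
size and any ground truth, optionally exported as per-band TIFF stacks.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import HyperspectralMap, SpectralAxis, SpectralDataset

__all__ = [
    "write_spectra",
    "read_spectra",
    "write_dataset_h5",
    "read_dataset_h5",
    "write_map",
    "read_map",
    "export_map_tiff",
]


def write_spectra(dataset: SpectralDataset, spectra_path, meta_path=None, sep: str = "\t") -> None:
    """Write spectra and (optionally) metadata as delimited text."""
    ids = [f"s{i:05d}" for i in range(len(dataset))]
    frame = pd.DataFrame(dataset.X.T, columns=ids)
    frame.insert(0, "wavenumber", dataset.axis.grid)
    frame.to_csv(spectra_path, sep=sep, index=False)
    if meta_path is not None:
        meta = dataset.meta.copy()
        meta.insert(0, "spectrum_id", ids)
        meta.to_csv(meta_path, sep=sep, index=False)


def read_spectra(spectra_path, meta_path=None, sep: str = "\t") -> SpectralDataset:
    """Read spectra written by :func:`write_spectra` (or user tables in the
    same layout: wavenumber column + one intensity column per spectrum)."""
    frame = pd.read_csv(spectra_path, sep=sep)
    wn = frame.iloc[:, 0].to_numpy(dtype=float)
    spacing = np.diff(wn)
    if len(wn) < 2 or np.any(spacing <= 0) or not np.allclose(spacing, spacing[0], rtol=1e-6):
        raise ValueError("wavenumber column must be strictly increasing and uniform")
    axis = SpectralAxis(float(wn[0]), float(wn[-1]), len(wn))
    X = frame.iloc[:, 1:].to_numpy(dtype=float).T
    if meta_path is not None:
        meta = pd.read_csv(meta_path, sep=sep).drop(columns=["spectrum_id"], errors="ignore")
    else:
        meta = pd.DataFrame(index=range(X.shape[0]))
    return SpectralDataset(axis, X, meta)


def write_dataset_h5(dataset: SpectralDataset, path) -> None:
    """Compact binary round-trip of a dataset (pipeline intermediate state)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=dataset.X, compression="gzip")
        f.attrs["axis_start"] = dataset.axis.start
        f.attrs["axis_stop"] = dataset.axis.stop
        f.attrs["axis_n_points"] = dataset.axis.n_points
        f.attrs["meta_json"] = dataset.meta.to_json(orient="split")


def read_dataset_h5(path) -> SpectralDataset:
    import io as _io

    with h5py.File(path, "r") as f:
        axis = SpectralAxis(
            float(f.attrs["axis_start"]),
            float(f.attrs["axis_stop"]),
            int(f.attrs["axis_n_points"]),
        )
        meta = pd.read_json(_io.StringIO(f.attrs["meta_json"]), orient="split")
        return SpectralDataset(axis, np.asarray(f["X"]), meta)


def write_map(hsmap: HyperspectralMap, path) -> None:
    """Write a hyperspectral map to a single HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("cube", data=hsmap.cube, compression="gzip")
        f.attrs["axis_start"] = hsmap.axis.start
        f.attrs["axis_stop"] = hsmap.axis.stop
        f.attrs["axis_n_points"] = hsmap.axis.n_points
        f.attrs["pixel_size_um"] = hsmap.pixel_size
        if hsmap.z_spacing is not None:
            f.attrs["z_spacing_um"] = hsmap.z_spacing
        if hsmap.surface_height is not None:
            f.create_dataset("surface_height", data=hsmap.surface_height)
        if hsmap.ground_truth is not None:
            g = f.create_group("ground_truth")
            for key, value in hsmap.ground_truth.items():
                g.create_dataset(key, data=np.asarray(value))


def read_map(path) -> HyperspectralMap:
    with h5py.File(path, "r") as f:
        axis = SpectralAxis(
            float(f.attrs["axis_start"]),
            float(f.attrs["axis_stop"]),
            int(f.attrs["axis_n_points"]),
        )
        gt = None
        if "ground_truth" in f:
            gt = {k: np.asarray(v) for k, v in f["ground_truth"].items()}
        return HyperspectralMap(
            axis=axis,
            cube=np.asarray(f["cube"]),
            pixel_size=float(f.attrs["pixel_size_um"]),
            z_spacing=float(f.attrs["z_spacing_um"]) if "z_spacing_um" in f.attrs else None,
            surface_height=np.asarray(f["surface_height"]) if "surface_height" in f else None,
            ground_truth=gt,
        )


def export_map_tiff(hsmap: HyperspectralMap, path) -> None:
    """Export the cube as a per-band TIFF stack (bands as pages)."""
    import tifffile

    cube = hsmap.cube
    if hsmap.has_z:
        raise ValueError("export planes individually")
    tifffile.imwrite(Path(path), cube.transpose(2, 0, 1).astype(np.float32))
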