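"""Core containers for Raman spectral data.

The package represents a spectrum as an intensity vector aligned to a shared
uniform wavenumber grid (:class:`SpectralAxis`). Collections of spectra with
patient/sample metadata live in :class:`SpectralDataset`; raster-scanned
images in which every pixel carries a full spectrum live in
:class:`HyperspectralMap`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any

import numpy as np
import pandas as pd

__all__ = [
    "SpectralAxis",
    "RamanSpectrum",
    "SpectralDataset",
    "HyperspectralMap",
    "make_axis",
    "FINGERPRINT_AXIS",
    "HIGHWAVENUMBER_AXIS",
]


@dataclass(frozen=True)
class SpectralAxis:
    """Uniform wavenumber grid in cm^-1, shared by all spectra of a dataset.

    Parameters
    ----------
    start, stop
        First and last wavenumber (cm^-1), both included in the grid.
    n_points
        Number of grid points (>= 2).
    """

    start: float
    stop: float
    n_points: int

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError(
                f"axis span must be positive, got [{self.start}, {self.stop}]"
            )
        if self.n_points < 2:
            raise ValueError(f"axis needs at least 2 points, got {self.n_points}")

    @property
    def grid(self) -> np.ndarray:
        """Wavenumber values, strictly increasing, uniformly spaced."""
        return np.linspace(self.start, self.stop, self.n_points)

    @property
    def spacing(self) -> float:
        return (self.stop - self.start) / (self.n_points - 1)

    def __len__(self) -> int:
        return self.n_points

    def contains(self, wavenumber: float) -> bool:
        return self.start <= wavenumber <= self.stop

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point closest to ``wavenumber``."""
        if not self.contains(wavenumber):
            raise ValueError(f"{wavenumber} cm^-1 outside axis [{self.start}, {self.stop}]")
        return int(round((wavenumber - self.start) / self.spacing))


def make_axis(start: float, stop: float, n_points: int) -> SpectralAxis:
    """Build a uniform wavenumber axis including both endpoints."""
    return SpectralAxis(start=start, stop=stop, n_points=int(n_points))


#: Fingerprint region used for the diagnostic classifier: 500-2000 cm^-1,
#: 889 channels (spacing ~1.689 cm^-1).
FINGERPRINT_AXIS = SpectralAxis(500.0, 2000.0, 889)

#: High-wavenumber (C-H stretch) region used for protein/lipid imaging.
HIGHWAVENUMBER_AXIS = SpectralAxis(2000.0, 3400.0, 701)


@dataclass
class RamanSpectrum:
    """A single spectrum: intensities aligned to an axis, plus metadata."""

    axis: SpectralAxis
    intensities: np.ndarray
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (self.axis.n_points,):
            raise ValueError(
                f"intensity vector length {self.intensities.shape} does not match "
                f"axis with {self.axis.n_points} points"
            )

    def with_intensities(self, intensities: np.ndarray) -> "RamanSpectrum":
        return RamanSpectrum(self.axis, intensities, dict(self.metadata))


class SpectralDataset:
    """A stack of spectra on a common axis with per-spectrum metadata.

    Attributes
    ----------
    axis : SpectralAxis
    X : ndarray of shape (n_spectra, n_points)
    meta : pandas.DataFrame with one row per spectrum. The generator fills
        ``patient_id``, ``sample_id``, ``tissue`` (cancer/paracancer),
        ``subtype`` (HCC/ICC), ``stage`` and ``differentiation``.
    """

    def __init__(self, axis: SpectralAxis, X: np.ndarray, meta: pd.DataFrame):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != axis.n_points:
            raise ValueError(
                f"X must be (n_spectra, {axis.n_points}), got {X.shape}"
            )
        if len(meta) != X.shape[0]:
            raise ValueError("metadata rows must match number of spectra")
        self.axis = axis
        self.X = X
        self.meta = meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.X.shape[0]

    def subset(self, mask) -> "SpectralDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectralDataset(self.axis, self.X[idx], self.meta.iloc[idx])

    def with_X(self, X: np.ndarray) -> "SpectralDataset":
        return SpectralDataset(self.axis, X, self.meta)

    def spectra(self):
        for i in range(len(self)):
            yield RamanSpectrum(self.axis, self.X[i], self.meta.iloc[i].to_dict())

    def decimate(self, factor: int) -> "SpectralDataset":
        """Keep every ``factor``-th wavenumber channel (desk-scale profile).

        Requires the last grid point to survive, so both axis endpoints stay
        exact; band positions are unchanged and band shapes keep >= 3 points
        at the default 12 cm^-1 width for factor 2 on the fingerprint axis.
        """
        if factor < 1 or (self.axis.n_points - 1) % factor != 0:
            raise ValueError("factor must divide the number of grid intervals")
        axis = SpectralAxis(
            self.axis.start, self.axis.stop, (self.axis.n_points - 1) // factor + 1
        )
        return SpectralDataset(axis, self.X[:, ::factor], self.meta)


@dataclass
class HyperspectralMap:
    """Pixel grid x wavenumber cube from raster Raman scanning.

    The cube is row-major with origin at the top-left pixel; pixel centres sit
    at ``(i + 0.5) * pixel_size``. An optional z-dimension holds successive
    focal planes; an optional surface-height map (um) records the focus-tracked
    sample topography. ``ground_truth`` is populated by the synthetic generator
    (mixing fractions, pure spectra, segment labels) so unmixing and
    segmentation can be scored against a known answer.
    """

    axis: SpectralAxis
    cube: np.ndarray  # (rows, cols, n_points) or (z, rows, cols, n_points)
    pixel_size: float  # um
    z_spacing: float | None = None  # um, set when cube has a z dimension
    surface_height: np.ndarray | None = None  # (rows, cols), um
    ground_truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube, dtype=float)
        if self.cube.ndim not in (3, 4):
            raise ValueError("cube must be (rows, cols, wn) or (z, rows, cols, wn)")
        if self.cube.shape[-1] != self.axis.n_points:
            raise ValueError("cube wavenumber dimension does not match axis")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def has_z(self) -> bool:
        return self.cube.ndim == 4

    @property
    def n_planes(self) -> int:
        return self.cube.shape[0] if self.has_z else 1

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the pixel grid."""
        return self.cube.shape[-3], self.cube.shape[-2]

    def plane(self, z: int) -> "HyperspectralMap":
        """Extract a single focal plane as a 2-D map."""
        if not self.has_z:
            if z != 0:
                raise IndexError("map has a single plane")
            return self
        gt = None
        if self.ground_truth is not None:
            gt = dict(self.ground_truth)
        return replace(self, cube=self.cube[z], z_spacing=None, ground_truth=gt)

    def as_matrix(self) -> np.ndarray:
        """Flatten the (single-plane) cube to (n_pixels, n_points), row-major."""
        if self.has_z:
            raise ValueError("flatten a single plane, not a z-stack")
        r, c = self.shape
        return self.cube.reshape(r * c, self.axis.n_points)
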