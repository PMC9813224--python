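"""Spectral preprocessing and descriptive statistics.

The chain applied before classification is baseline subtraction followed by
Savitzky-Golay smoothing; the imaging chain adds cosmic-ray removal and an
optional spatial noise filter. Baseline estimation uses the asymmetric
least-squares (Whittaker) smoother, the standard choice for the broad
fluorescence background that dominates 532 nm tissue spectra: a smooth curve
is fit under the spectrum by iteratively down-weighting points that lie above
it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.linalg import solveh_banded
from scipy.ndimage import gaussian_filter, median_filter
from scipy.signal import find_peaks, savgol_filter
from scipy.stats import ttest_ind

from .core import HyperspectralMap, SpectralAxis, SpectralDataset
from .peaks import PeakDefinition

__all__ = [
    "PreprocessConfig",
    "PeakTable",
    "als_baseline",
    "baseline_correct",
    "sg_smooth",
    "remove_cosmic_rays",
    "preprocess_dataset",
    "preprocess_map",
    "group_mean_sd",
    "extract_peak_table",
    "peak_group_ttest",
    "peak_correlation",
    "detect_peaks",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Parameters of the preprocessing chain.

    ``baseline_lam`` controls the stiffness of the asymmetric-least-squares
    baseline (larger = smoother); ``baseline_p`` is the asymmetry (weight of
    points above the baseline). The Savitzky-Golay window must be odd and
    larger than the polynomial order. ``cosmic_z`` is the robust z-score
    threshold for single-band spike replacement.
    """

    baseline_method: str = "als"  # "als", "poly" or "none"
    baseline_lam: float = 1e5
    baseline_p: float = 0.01
    baseline_niter: int = 10
    poly_order: int = 3
    sg_window: int = 11
    sg_order: int = 3
    cosmic_z: float = 8.0
    spatial_noise_filter: bool = False
    spatial_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.sg_window % 2 == 0:
            raise ValueError("Savitzky-Golay window must be odd")
        if self.sg_window <= self.sg_order:
            raise ValueError("Savitzky-Golay window must exceed the polynomial order")
        if self.cosmic_z <= 0:
            raise ValueError("cosmic-ray z-threshold must be positive")


def _check_spectra(Y: np.ndarray) -> np.ndarray:
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if not np.all(np.isfinite(Y)):
        raise ValueError("spectra contain non-finite values")
    if np.all(Y == 0):
        raise ValueError("spectra are identically zero")
    return Y


def als_baseline(
    y: np.ndarray, lam: float = 1e5, p: float = 0.01, niter: int = 10
) -> np.ndarray:
    """Asymmetric-least-squares baseline estimate (Whittaker smoother).

    Minimizes ``sum_i w_i (y_i - z_i)^2 + lam * sum_i (d2 z)_i^2`` with
    asymmetric weights ``w_i = p`` above the baseline and ``1 - p`` below,
    re-estimated for ``niter`` iterations. Accepts a single spectrum or a
    (n_spectra, n_points) stack; returns the baseline(s) with the same shape.
    """
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    Y = np.atleast_2d(y)
    n = Y.shape[1]
    d2 = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    penalty = (lam * (d2.T @ d2)).todia()
    # symmetric pentadiagonal system in upper banded form for solveh_banded
    bands = np.zeros((3, n))
    for off in (0, 1, 2):
        diag = penalty.data[list(penalty.offsets).index(off)]
        bands[2 - off, off:] = diag[off:] if off else diag
    Z = np.empty_like(Y)
    for i, yi in enumerate(Y):
        w = np.ones(n)
        z = yi
        for _ in range(niter):
            ab = bands.copy()
            ab[2] += w
            z = solveh_banded(ab, w * yi, lower=False)
            w = np.where(yi > z, p, 1.0 - p)
        Z[i] = z
    return Z[0] if single else Z


def _poly_baseline(Y: np.ndarray, axis: SpectralAxis, order: int) -> np.ndarray:
    t = np.linspace(-1.0, 1.0, axis.n_points)
    V = np.polynomial.polynomial.polyvander(t, order)
    coef, *_ = np.linalg.lstsq(V, Y.T, rcond=None)
    return (V @ coef).T


def baseline_correct(
    Y: np.ndarray, axis: SpectralAxis, config: PreprocessConfig | None = None
) -> np.ndarray:
    """Subtract the estimated smooth background from spectra.

    After subtraction the minimum of each spectrum sits near zero. The axis
    is unchanged; input shape is preserved ((n_points,) or (n, n_points)).
    """
    config = config or PreprocessConfig()
    arr = np.asarray(Y, dtype=float)
    single = arr.ndim == 1
    X = _check_spectra(arr)
    if config.baseline_method == "als":
        base = als_baseline(X, config.baseline_lam, config.baseline_p, config.baseline_niter)
    elif config.baseline_method == "poly":
        base = _poly_baseline(X, axis, config.poly_order)
    elif config.baseline_method == "none":
        base = np.zeros_like(X)
    else:
        raise ValueError(f"unknown baseline method {config.baseline_method!r}")
    out = X - base
    return out[0] if single else out


def sg_smooth(Y: np.ndarray, window: int = 11, order: int = 3) -> np.ndarray:
    """Savitzky-Golay least-squares local-polynomial smoothing."""
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= order:
        raise ValueError("window must exceed polynomial order")
    return savgol_filter(np.asarray(Y, dtype=float), window, order, axis=-1)


def remove_cosmic_rays(
    hsmap: HyperspectralMap, z_threshold: float = 8.0
) -> tuple[HyperspectralMap, int]:
    """Replace single-band spatial spikes by the local median.

    For every band, each pixel is compared with the median over its 3x3
    spatial neighbourhood; deviations whose robust z-score (median absolute
    deviation across the band) exceeds ``z_threshold`` are treated as cosmic
    rays and replaced by that median. Returns the cleaned map and the number
    of replaced entries.
    """
    cube = hsmap.cube
    if hsmap.has_z:
        raise ValueError("remove cosmic rays plane by plane")
    if cube.shape[0] * cube.shape[1] < 2:
        raise ValueError("map needs at least two pixels")
    if not np.isfinite(z_threshold):
        return hsmap, 0
    med = median_filter(cube, size=(3, 3, 1), mode="nearest")
    resid = cube - med
    # per-band MAD floored by a cube-wide upper-quantile estimate: flat bands
    # (signal clipped at zero) leave many exactly-zero residuals, which would
    # drive a pure median scale to zero and flag plain noise as spikes
    mad = np.median(np.abs(resid), axis=(0, 1), keepdims=True) / 0.6745
    global_scale = np.quantile(np.abs(resid), 0.9) / 1.645
    scale = np.maximum(mad, global_scale) + 1e-12
    z = np.abs(resid) / scale
    spikes = z > z_threshold
    cleaned = np.where(spikes, med, cube)
    out = HyperspectralMap(
        axis=hsmap.axis,
        cube=cleaned,
        pixel_size=hsmap.pixel_size,
        z_spacing=hsmap.z_spacing,
        surface_height=hsmap.surface_height,
        ground_truth=hsmap.ground_truth,
    )
    return out, int(spikes.sum())


def preprocess_dataset(
    dataset: SpectralDataset, config: PreprocessConfig | None = None
) -> SpectralDataset:
    """Baseline-correct then Savitzky-Golay smooth every spectrum."""
    config = config or PreprocessConfig()
    X = baseline_correct(dataset.X, dataset.axis, config)
    X = sg_smooth(X, config.sg_window, config.sg_order)
    return dataset.with_X(X)


def preprocess_map(
    hsmap: HyperspectralMap, config: PreprocessConfig | None = None
) -> tuple[HyperspectralMap, int]:
    """Imaging chain: baseline, smoothing, cosmic-ray removal, noise filter.

    Applied pixel-wise per plane; returns the cleaned map and the cosmic-ray
    replacement count.
    """
    config = config or PreprocessConfig()

    def _plane(cube: np.ndarray) -> tuple[np.ndarray, int]:
        r, c, w = cube.shape
        X = baseline_correct(cube.reshape(r * c, w), hsmap.axis, config)
        X = sg_smooth(X, config.sg_window, config.sg_order).reshape(r, c, w)
        plane = HyperspectralMap(axis=hsmap.axis, cube=X, pixel_size=hsmap.pixel_size)
        plane, n = remove_cosmic_rays(plane, config.cosmic_z)
        X = plane.cube
        if config.spatial_noise_filter:
            X = gaussian_filter(X, sigma=(config.spatial_sigma, config.spatial_sigma, 0))
        return X, n

    if hsmap.has_z:
        cleaned, counts = zip(*(_plane(hsmap.cube[z]) for z in range(hsmap.n_planes)))
        cube, n_replaced = np.stack(cleaned), sum(counts)
    else:
        cube, n_replaced = _plane(hsmap.cube)
    out = HyperspectralMap(
        axis=hsmap.axis,
        cube=cube,
        pixel_size=hsmap.pixel_size,
        z_spacing=hsmap.z_spacing,
        surface_height=hsmap.surface_height,
        ground_truth=hsmap.ground_truth,
    )
    return out, n_replaced


def group_mean_sd(
    dataset: SpectralDataset, grouping: str
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Pointwise mean and SD spectrum per group (for mean +/- SD bands)."""
    if grouping not in dataset.meta.columns:
        raise ValueError(f"unknown grouping column {grouping!r}")
    out = {}
    for label, idx in dataset.meta.groupby(grouping, sort=True).groups.items():
        if len(idx) == 0:
            raise ValueError(f"group {label!r} is empty")
        block = dataset.X[np.asarray(idx)]
        out[str(label)] = (block.mean(axis=0), block.std(axis=0))
    return out


@dataclass
class PeakTable:
    """Per-spectrum intensities at the characteristic bands."""

    values: pd.DataFrame  # columns = peak centers (floats as str), one row per spectrum
    meta: pd.DataFrame
    centers: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.values) != len(self.meta):
            raise ValueError("values and metadata must align row-wise")


def extract_peak_table(
    dataset: SpectralDataset,
    peaks: list[PeakDefinition],
    half_window: float = 8.0,
    mode: str = "max",
) -> PeakTable:
    """Intensity of each characteristic band for every spectrum.

    ``mode='max'`` takes the maximum within +/- ``half_window`` cm^-1 of the
    band centre (tolerant of small peak shifts); ``mode='area'`` integrates
    over the same window.
    """
    axis = dataset.axis
    cols = {}
    for p in peaks:
        if not p.on_axis(axis):
            raise ValueError(f"peak at {p.center} cm^-1 off axis")
        lo = axis.index_of(max(p.center - half_window, axis.start))
        hi = axis.index_of(min(p.center + half_window, axis.stop)) + 1
        window = dataset.X[:, lo:hi]
        if mode == "max":
            cols[f"{p.center:g}"] = window.max(axis=1)
        elif mode == "area":
            cols[f"{p.center:g}"] = np.trapezoid(window, dx=axis.spacing, axis=1)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return PeakTable(pd.DataFrame(cols), dataset.meta.copy(), [p.center for p in peaks])


def peak_group_ttest(
    table: PeakTable, grouping: str, welch: bool = False, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sided Student's t-test per band between two groups.

    Returns a frame indexed by band with t statistic, p value and a
    significance flag at ``alpha``. Degenerate bands (zero variance in both
    groups and equal means) get p = 1 by convention.
    """
    labels = table.meta[grouping]
    groups = [g for g in labels.unique() if g != ""]
    if len(groups) != 2:
        raise ValueError(f"t-test needs exactly two groups, found {groups}")
    a = table.values[labels == groups[0]].to_numpy()
    b = table.values[labels == groups[1]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two spectra")
    t, p = ttest_ind(a, b, axis=0, equal_var=not welch)
    t, p = np.asarray(t, dtype=float), np.asarray(p, dtype=float)
    degenerate = np.isnan(t)
    equal_means = np.isclose(a.mean(axis=0), b.mean(axis=0))
    t[degenerate] = 0.0
    p[degenerate & equal_means] = 1.0
    p[degenerate & ~equal_means] = 0.0
    return pd.DataFrame(
        {"t": t, "p": p, "significant": p < alpha},
        index=table.values.columns,
    )


def peak_correlation(table: PeakTable) -> tuple[pd.DataFrame, list[int]]:
    """Pairwise Pearson correlation of band intensities + dendrogram order.

    Bands constant across spectra have undefined correlation and are reported
    as missing (NaN) and placed after the ordered bands.
    """
    from scipy.cluster.hierarchy import leaves_list, linkage

    V = table.values.to_numpy()
    if V.shape[0] < 3:
        raise ValueError("correlation needs at least three spectra")
    sd = V.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(V, rowvar=False)
    corr[sd == 0, :] = np.nan
    corr[:, sd == 0] = np.nan
    np.fill_diagonal(corr, np.where(sd == 0, np.nan, 1.0))
    valid = np.flatnonzero(sd > 0)
    order: list[int] = []
    if len(valid) >= 2:
        sub = corr[np.ix_(valid, valid)]
        dist = 1.0 - sub[np.triu_indices(len(valid), k=1)]
        z = linkage(np.clip(dist, 0.0, None), method="average")
        order = [int(valid[i]) for i in leaves_list(z)]
    elif len(valid) == 1:
        order = [int(valid[0])]
    order += [int(i) for i in np.flatnonzero(sd == 0)]
    frame = pd.DataFrame(corr, index=table.values.columns, columns=table.values.columns)
    return frame, order


def detect_peaks(
    spectrum: np.ndarray,
    axis: SpectralAxis,
    prominence_frac: float = 0.02,
    min_separation: float = 10.0,
) -> np.ndarray:
    """Locate characteristic bands in a (preprocessed) spectrum.

    Peaks must exceed a prominence of ``prominence_frac`` times the intensity
    range and be at least ``min_separation`` cm^-1 apart. Returns band centre
    wavenumbers.
    """
    y = np.asarray(spectrum, dtype=float)
    rng_ = y.max() - y.min()
    idx, _ = find_peaks(
        y,
        prominence=prominence_frac * rng_,
        distance=max(int(min_separation / axis.spacing), 1),
    )
    return axis.grid[idx]
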