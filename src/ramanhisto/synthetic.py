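"""Synthetic Raman cohorts and hyperspectral phantoms with known ground truth.

No raw spectra are publicly deposited for the liver-tissue study this package
models, so every downstream stage (preprocessing, classification, unmixing,
segmentation) is exercised on synthetic data whose generating parameters are
retained. Spectra are sums of Gaussian bands (class-profile scaled), times a
per-patient intensity factor, plus a smooth fluorescence-like baseline and
additive Gaussian noise, clipped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import norm

from .core import FINGERPRINT_AXIS, HyperspectralMap, RamanSpectrum, SpectralAxis, SpectralDataset
from .peaks import PeakDefinition, default_peak_table
from .profiles import TissueClassProfile, combine_profiles, default_profiles

__all__ = [
    "BaselineParams",
    "CohortConfig",
    "generate_spectrum",
    "generate_cohort",
    "generate_map",
    "generate_zstack",
    "generate_afp",
    "pure_spectrum",
]

_SIGMA_PER_FWHM = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _peak_basis(peaks: list[PeakDefinition], axis: SpectralAxis) -> np.ndarray:
    """Unit-amplitude Gaussian line shapes, one row per peak."""
    grid = axis.grid
    basis = np.empty((len(peaks), axis.n_points))
    for i, p in enumerate(peaks):
        if not p.on_axis(axis):
            raise ValueError(f"peak at {p.center} cm^-1 lies outside the axis")
        sigma = p.width * _SIGMA_PER_FWHM
        basis[i] = np.exp(-0.5 * ((grid - p.center) / sigma) ** 2)
    return basis


def _amplitudes(profile: TissueClassProfile, peaks: list[PeakDefinition]) -> np.ndarray:
    return np.array(
        [p.base_amplitude * profile.multiplier(p.center) for p in peaks]
    ) * profile.global_scale


def pure_spectrum(
    profile: TissueClassProfile, peaks: list[PeakDefinition], axis: SpectralAxis
) -> np.ndarray:
    """Noiseless, baseline-free class spectrum (used as ground truth)."""
    return _amplitudes(profile, peaks) @ _peak_basis(peaks, axis)


@dataclass(frozen=True)
class BaselineParams:
    """Fluorescence-like background: cubic polynomial plus one broad hump.

    Each coefficient is drawn uniformly from its ``(low, high)`` range per
    spectrum, so the background varies from spot to spot as it does between
    measurement points on real tissue.
    """

    offset: tuple[float, float] = (100.0, 300.0)
    slope: tuple[float, float] = (-80.0, 80.0)
    quad: tuple[float, float] = (-50.0, 50.0)
    cubic: tuple[float, float] = (-30.0, 30.0)
    hump_amplitude: tuple[float, float] = (100.0, 400.0)
    hump_center: tuple[float, float] = (800.0, 1600.0)
    hump_width: tuple[float, float] = (150.0, 400.0)

    def sample(self, axis: SpectralAxis, rng: np.random.Generator, n: int = 1) -> np.ndarray:
        """Draw ``n`` baselines, shape (n, n_points)."""
        t = (axis.grid - axis.start) / (axis.stop - axis.start)  # in [0, 1]
        u = rng.uniform
        c0 = u(*self.offset, size=(n, 1))
        c1 = u(*self.slope, size=(n, 1))
        c2 = u(*self.quad, size=(n, 1))
        c3 = u(*self.cubic, size=(n, 1))
        amp = u(*self.hump_amplitude, size=(n, 1))
        mu = u(*self.hump_center, size=(n, 1))
        width = u(*self.hump_width, size=(n, 1))
        poly = c0 + c1 * t + c2 * t**2 + c3 * t**3
        hump = amp * np.exp(-0.5 * ((axis.grid - mu) / width) ** 2)
        return poly + hump


ZERO_BASELINE = BaselineParams(
    offset=(0, 0), slope=(0, 0), quad=(0, 0), cubic=(0, 0),
    hump_amplitude=(0, 0), hump_center=(1000, 1000), hump_width=(200, 200),
)


def _generate_batch(
    profile: TissueClassProfile,
    peaks: list[PeakDefinition],
    axis: SpectralAxis,
    n: int,
    patient_effect: float,
    rng: np.random.Generator,
    noise_sd: float,
    baseline: BaselineParams | np.ndarray | None,
) -> np.ndarray:
    clean = patient_effect * pure_spectrum(profile, peaks, axis)
    X = np.tile(clean, (n, 1))
    if isinstance(baseline, BaselineParams):
        X += baseline.sample(axis, rng, n)
    elif baseline is not None:
        X += np.asarray(baseline, dtype=float)
    if noise_sd > 0:
        X += rng.normal(0.0, noise_sd, size=X.shape)
    return np.clip(X, 0.0, None)


def generate_spectrum(
    profile: TissueClassProfile,
    peaks: list[PeakDefinition],
    axis: SpectralAxis,
    patient_effect: float = 1.0,
    rng: np.random.Generator | int | None = None,
    noise_sd: float = 0.0,
    baseline: BaselineParams | np.ndarray | None = None,
) -> RamanSpectrum:
    """Generate one spectrum for a tissue class.

    intensities = patient_effect * sum of class-scaled Gaussian bands
    + fluorescence baseline + additive Gaussian noise, clipped at zero.
    Deterministic given the random generator state.
    """
    rng = np.random.default_rng(rng)
    X = _generate_batch(profile, peaks, axis, 1, patient_effect, rng, noise_sd, baseline)
    return RamanSpectrum(axis, X[0], {"class_label": profile.class_label})


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of a synthetic matched-pair cohort.

    Defaults mirror the modelled study: 120 patients (98 HCC, 22 ICC), one
    carcinoma and one matched paracancer sample each, 50 spectra per sample
    (12,000 spectra total) on the 889-point fingerprint axis. Stage and
    differentiation-grade labels apply to HCC patients and default to uniform
    proportions. The per-patient intensity factor is log-normal and shared by
    both of a patient's samples.
    """

    n_patients: int = 120
    n_hcc: int = 98
    n_icc: int = 22
    spectra_per_sample: int = 50
    stage_probs: dict[str, float] = field(
        default_factory=lambda: {"early_stage": 0.5, "advanced_stage": 0.5}
    )
    diff_probs: dict[str, float] = field(
        default_factory=lambda: {"well_diff": 1 / 3, "moderate_diff": 1 / 3, "poor_diff": 1 / 3}
    )
    patient_effect_sd: float = 0.15
    noise_sd: float = 12.0
    baseline_params: BaselineParams | None = field(default_factory=BaselineParams)
    seed: int = 0

    def validate(self) -> None:
        if self.n_hcc + self.n_icc != self.n_patients:
            raise ValueError(
                f"n_hcc + n_icc = {self.n_hcc + self.n_icc} must equal n_patients = {self.n_patients}"
            )
        if self.n_patients < 1 or self.spectra_per_sample < 1:
            raise ValueError("cohort must have at least one patient and one spectrum per sample")
        for name, probs in (("stage_probs", self.stage_probs), ("diff_probs", self.diff_probs)):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} must sum to 1")


def generate_cohort(
    config: CohortConfig | None = None,
    peaks: list[PeakDefinition] | None = None,
    axis: SpectralAxis = FINGERPRINT_AXIS,
    profiles: dict[str, TissueClassProfile] | None = None,
) -> SpectralDataset:
    """Generate a matched-pair spectral cohort, reproducible from its seed.

    Each patient contributes one carcinoma and one paracancer sample, each
    with ``spectra_per_sample`` spectra. HCC patients additionally carry a
    tumour stage and a differentiation grade drawn from the configured
    proportions; the carcinoma profile composes subtype x stage x grade.
    """
    config = config or CohortConfig()
    config.validate()
    peaks = peaks or default_peak_table()
    profiles = profiles or default_profiles()
    rng = np.random.default_rng(config.seed)

    stages = list(config.stage_probs)
    diffs = list(config.diff_probs)
    rows = []
    blocks = []
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        subtype = "HCC" if i < config.n_hcc else "ICC"
        stage = grade = ""
        cancer_profile = profiles[subtype]
        if subtype == "HCC":
            stage = stages[rng.choice(len(stages), p=list(config.stage_probs.values()))]
            grade = diffs[rng.choice(len(diffs), p=list(config.diff_probs.values()))]
            cancer_profile = combine_profiles(
                profiles[subtype], profiles[stage], profiles[grade], label=subtype
            )
        patient_effect = float(np.exp(rng.normal(0.0, config.patient_effect_sd)))
        for tissue, profile in (("cancer", cancer_profile), ("paracancer", profiles["paracancer"])):
            sid = f"{pid}-{'C' if tissue == 'cancer' else 'N'}"
            X = _generate_batch(
                profile, peaks, axis, config.spectra_per_sample, patient_effect,
                rng, config.noise_sd, config.baseline_params,
            )
            blocks.append(X)
            rows.extend(
                {
                    "patient_id": pid,
                    "sample_id": sid,
                    "tissue": tissue,
                    "subtype": subtype,
                    "stage": stage,
                    "differentiation": grade,
                    "patient_effect": patient_effect,
                }
                for _ in range(config.spectra_per_sample)
            )
    return SpectralDataset(axis, np.vstack(blocks), pd.DataFrame(rows))


def _as_fractions(layout: np.ndarray, n_components: int) -> np.ndarray:
    layout = np.asarray(layout)
    if layout.ndim == 2:  # hard labels
        if layout.min() < 0 or layout.max() >= n_components:
            raise ValueError("layout labels must index the provided components")
        frac = np.zeros(layout.shape + (n_components,))
        for k in range(n_components):
            frac[..., k] = layout == k
        return frac
    if layout.ndim == 3:
        if layout.shape[2] != n_components:
            raise ValueError("soft layout last dimension must match component count")
        if np.any(layout < 0) or np.any(np.abs(layout.sum(axis=2) - 1.0) > 1e-8):
            raise ValueError("soft-layout fractions must be >= 0 and sum to 1 per pixel")
        return layout.astype(float)
    raise ValueError("layout must be a 2-D label image or a 3-D fraction stack")


def _surface_field(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Smooth random height field with max - min equal to ``amplitude`` um."""
    raw = gaussian_filter(rng.normal(size=shape), sigma=max(min(shape) / 6.0, 1.0), mode="nearest")
    span = raw.max() - raw.min()
    if span == 0:
        return np.zeros(shape)
    return (raw - raw.min()) / span * amplitude


def generate_map(
    pure_profiles,
    layout: np.ndarray,
    axis: SpectralAxis,
    pixel_size: float = 2.0,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    peaks: list[PeakDefinition] | None = None,
    surface_amplitude: float = 0.0,
) -> HyperspectralMap:
    """Generate a hyperspectral phantom with ground truth retained.

    ``pure_profiles`` is either a list of :class:`TissueClassProfile` or an
    array of pure spectra (K, n_points). ``layout`` is a hard label image
    (rows, cols) or soft per-pixel mixing fractions (rows, cols, K) -- soft
    layouts emulate carcinoma infiltrating parenchyma without a sharp border.
    Each pixel spectrum is the fraction-weighted mixture of the pure spectra
    plus additive Gaussian noise.
    """
    rng = np.random.default_rng(rng)
    if isinstance(pure_profiles, np.ndarray):
        S = np.asarray(pure_profiles, dtype=float)
    else:
        peaks = peaks or default_peak_table()
        S = np.vstack([pure_spectrum(p, peaks, axis) for p in pure_profiles])
    if S.shape[1] != axis.n_points:
        raise ValueError("pure spectra do not match the axis")
    frac = _as_fractions(layout, S.shape[0])
    cube = frac @ S
    if noise_sd > 0:
        cube = np.clip(cube + rng.normal(0.0, noise_sd, size=cube.shape), 0.0, None)
    height = None
    if surface_amplitude > 0:
        height = _surface_field(frac.shape[:2], surface_amplitude, rng)
    return HyperspectralMap(
        axis=axis,
        cube=cube,
        pixel_size=pixel_size,
        surface_height=height,
        ground_truth={
            "fractions": frac,
            "pure_spectra": S,
            "labels": frac.argmax(axis=2),
        },
    )


def generate_zstack(
    template: HyperspectralMap,
    n_planes: int = 6,
    z_spacing: float = 5.0,
    depth_attenuation: float = 0.8,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> HyperspectralMap:
    """Stack attenuated copies of a planar map into a z-stack.

    Plane ``p`` is the template cube scaled by ``depth_attenuation ** p``
    (confocal signal loss with depth) plus fresh noise. Defaults: six planes
    at 5 um spacing.
    """
    if n_planes < 1:
        raise ValueError("need at least one plane")
    if template.has_z:
        raise ValueError("template must be a single-plane map")
    rng = np.random.default_rng(rng)
    planes = []
    for p in range(n_planes):
        plane = template.cube * depth_attenuation**p
        if noise_sd > 0:
            plane = np.clip(plane + rng.normal(0.0, noise_sd, size=plane.shape), 0.0, None)
        planes.append(plane)
    return replace(
        template,
        cube=np.stack(planes),
        z_spacing=z_spacing,
        ground_truth=None if template.ground_truth is None else dict(template.ground_truth),
    )


def generate_afp(
    cohort: SpectralDataset,
    positive_rate_hcc: float = 25 / 92,
    threshold: float = 200.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Per-patient serum alpha-fetoprotein (AFP) values, in ng/ml.

    AFP is drawn from a two-component log-normal mixture truncated at the
    positivity threshold: each HCC patient is AFP-positive (> threshold) with
    probability ``positive_rate_hcc``; ICC patients and negatives draw from
    the sub-threshold component. The expected positive fraction among HCC
    patients therefore equals the configured rate exactly.
    """
    rng = np.random.default_rng(rng)
    patients = cohort.meta.drop_duplicates("patient_id")[["patient_id", "subtype"]]
    if not (patients["subtype"] == "HCC").any():
        raise ValueError("cohort has no HCC patients")

    def _truncated_lognormal(mu: float, sd: float, n: int, above: bool) -> np.ndarray:
        # inverse-CDF sampling of LogNormal(mu, sd) truncated at `threshold`
        f_thr = norm.cdf((np.log(threshold) - mu) / sd)
        u = rng.uniform(0.0, 1.0, size=n)
        u = f_thr + u * (1.0 - f_thr) if above else u * f_thr
        return np.exp(mu + sd * norm.ppf(u))

    values = np.empty(len(patients))
    is_hcc = (patients["subtype"] == "HCC").to_numpy()
    positive = np.zeros(len(patients), dtype=bool)
    positive[is_hcc] = rng.uniform(size=is_hcc.sum()) < positive_rate_hcc
    n_pos, n_neg = int(positive.sum()), int((~positive).sum())
    if n_pos:
        values[positive] = _truncated_lognormal(np.log(600.0), 1.2, n_pos, above=True)
    if n_neg:
        values[~positive] = _truncated_lognormal(np.log(8.0), 1.5, n_neg, above=False)
    out = patients.reset_index(drop=True).copy()
    out["afp_ng_ml"] = values
    out.attrs["threshold_ng_ml"] = threshold
    return out
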