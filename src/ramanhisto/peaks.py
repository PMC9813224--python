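"""Characteristic Raman bands of liver tissue.

Nineteen fingerprint-region bands recur across most liver tissue samples:
aromatic amino acids (tryptophan, tyrosine, phenylalanine), resonance-enhanced
carotenoids, lipids/fatty acids, nucleic acids, the amide I band and a
saccharide band. The high-wavenumber region adds the C-H stretch bands that
separate proteins (2930 cm^-1) from lipids (2855, 2885, 3007 cm^-1).
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import SpectralAxis

__all__ = ["PeakDefinition", "default_peak_table", "highwavenumber_peak_table"]

#: Default full-width-half-maximum of a condensed-phase tissue Raman band.
DEFAULT_FWHM = 12.0


@dataclass(frozen=True)
class PeakDefinition:
    """One Raman band: position, width, reference amplitude, assignment."""

    center: float  # cm^-1
    width: float = DEFAULT_FWHM  # FWHM, cm^-1
    base_amplitude: float = 1.0  # arbitrary intensity units
    assignment: str = ""

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width must be positive")
        if self.base_amplitude < 0:
            raise ValueError("base amplitude must be non-negative")

    def on_axis(self, axis: SpectralAxis) -> bool:
        return axis.contains(self.center)


# (center, base amplitude, assignment). Amplitudes are relative intensities of
# a healthy-parenchyma reference spectrum; carotenoid bands dominate because
# 532 nm excitation resonantly enhances them.
_FINGERPRINT_PEAKS = [
    (674.0, 220.0, "nucleic acids"),
    (749.0, 420.0, "tryptophan (aromatic amino acid)"),
    (835.0, 200.0, "saccharides"),
    (974.0, 240.0, "nucleic acids"),
    (1003.0, 900.0, "carotenoid C-C/C-N stretch; phenylalanine ring breathing"),
    (1081.0, 300.0, "lipids / fatty acids"),
    (1130.0, 380.0, "fatty acids (C-C skeletal)"),
    (1156.0, 850.0, "carotenoid C-C/C-N stretch"),
    (1212.0, 320.0, "tyrosine / phenylalanine"),
    (1304.0, 420.0, "lipids / fatty acids (CH2 twist)"),
    (1336.0, 380.0, "nucleic acids"),
    (1356.0, 300.0, "nucleic acids"),
    (1393.0, 260.0, "tryptophan"),
    (1448.0, 450.0, "CH2 deformation (proteins and lipids)"),
    (1519.0, 950.0, "carotenoid C=C stretch"),
    (1547.0, 400.0, "tryptophan"),
    (1586.0, 420.0, "phenylalanine"),
    (1602.0, 380.0, "phenylalanine / tyrosine"),
    (1637.0, 500.0, "amide I (C=O stretch)"),
]

_HIGHWAVENUMBER_PEAKS = [
    (2855.0, 700.0, "lipid: symmetric CH2 stretch"),
    (2885.0, 600.0, "lipid: CH2 Fermi resonance / asymmetric stretch"),
    (2930.0, 1000.0, "protein: CH3 stretch"),
    (3007.0, 300.0, "lipid: unsaturated =CH stretch"),
]


def default_peak_table(extra_center: float = 1448.0) -> list[PeakDefinition]:
    """The 19 characteristic fingerprint-region bands (500-2000 cm^-1).

    Eighteen positions are fixed; the remaining band defaults to the
    ubiquitous 1448 cm^-1 CH2 deformation and can be repositioned via
    ``extra_center`` (amplitude and assignment are kept).
    """
    peaks = []
    for center, amp, label in _FINGERPRINT_PEAKS:
        if center == 1448.0 and extra_center != 1448.0:
            center = float(extra_center)
        peaks.append(PeakDefinition(center=center, base_amplitude=amp, assignment=label))
    return peaks


def highwavenumber_peak_table() -> list[PeakDefinition]:
    """C-H stretch bands (2000-3400 cm^-1): 3 lipid bands and 1 protein band."""
    return [
        PeakDefinition(center=c, base_amplitude=a, assignment=s)
        for c, a, s in _HIGHWAVENUMBER_PEAKS
    ]
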