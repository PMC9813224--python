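"""Per-class peak-amplitude models driving the synthetic generator.

A :class:`TissueClassProfile` rescales the reference peak amplitudes of
:mod:`ramanhisto.peaks`: a global intensity factor plus per-band multipliers.
Profiles compose multiplicatively, so a hepatocellular-carcinoma spectrum at a
given stage and differentiation grade is the product of the subtype, stage and
grade profiles.

The default profiles encode the qualitative contrasts seen in matched liver
tissue pairs: every characteristic band is weaker in carcinoma than in the
adjacent parenchyma (carotenoid bands most strongly, consistent with their
loss during carcinogenesis); intrahepatic cholangiocarcinoma (ICC) retains
more carotenoid signal than hepatocellular carcinoma (HCC) but less amino
acid / lipid / nucleic acid signal; early-stage tumours keep more carotenoid,
fatty-acid and tryptophan intensity than advanced ones, which gain nucleic
acid and saccharide signal; better-differentiated tumours are brighter
overall, especially in the carotenoid bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["TissueClassProfile", "default_profiles", "combine_profiles", "CLASS_LABELS"]

CLASS_LABELS = (
    "paracancer",
    "HCC",
    "ICC",
    "early_stage",
    "advanced_stage",
    "well_diff",
    "moderate_diff",
    "poor_diff",
)

CAROTENOID_BANDS = (1003.0, 1156.0, 1519.0)


@dataclass(frozen=True)
class TissueClassProfile:
    """Relative peak-amplitude model for one tissue class (or class factor)."""

    class_label: str
    peak_multipliers: dict[float, float] = field(default_factory=dict)
    global_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.global_scale <= 0:
            raise ValueError("global_scale must be positive")
        for center, m in self.peak_multipliers.items():
            if m <= 0:
                raise ValueError(f"multiplier for {center} cm^-1 must be positive")

    def multiplier(self, center: float) -> float:
        return self.peak_multipliers.get(center, 1.0)


def combine_profiles(*profiles: TissueClassProfile, label: str | None = None) -> TissueClassProfile:
    """Multiply profiles (global scales and per-band multipliers) together."""
    if not profiles:
        raise ValueError("need at least one profile")
    scale = 1.0
    mult: dict[float, float] = {}
    for p in profiles:
        scale *= p.global_scale
        for c, m in p.peak_multipliers.items():
            mult[c] = mult.get(c, 1.0) * m
    if label is None:
        label = "+".join(p.class_label for p in profiles)
    return TissueClassProfile(label, mult, scale)


def _mult(centers, value) -> dict[float, float]:
    return {float(c): float(value) for c in centers}


def default_profiles() -> dict[str, TissueClassProfile]:
    """Default profiles for all eight tissue classes / class factors.

    ``paracancer``, ``HCC`` and ``ICC`` are absolute profiles relative to the
    reference amplitudes; the stage and differentiation entries are modifiers
    composed onto the HCC profile.
    """
    carot = CAROTENOID_BANDS
    return {
        "paracancer": TissueClassProfile("paracancer"),
        # carcinoma loses carotenoid and lipid signal disproportionately, so
        # cancer spectra differ from parenchyma in shape, not just brightness
        "HCC": TissueClassProfile(
            "HCC",
            {**_mult(carot, 0.60), **_mult((1081.0, 1130.0, 1304.0), 0.82)},
            global_scale=0.72,
        ),
        # ICC sits between HCC and parenchyma in carotenoid signal, inside
        # the spread the stage/grade modifiers give HCC, so the subtype task
        # is genuinely harder than carcinoma-vs-parenchyma
        "ICC": TissueClassProfile(
            "ICC",
            {
                **_mult(carot, 0.62),
                **_mult((1081.0, 1130.0), 0.82),
                **_mult((749, 974, 1304, 1356, 1393, 1586), 0.80),
            },
            global_scale=0.72,
        ),
        # stage and grade modifiers only suppress bands (all factors <= 1), so
        # composing them onto a carcinoma profile can never push a band back
        # up towards the parenchyma level
        "early_stage": TissueClassProfile(
            "early_stage", _mult((674.0, 974.0, 835.0), 0.85)
        ),
        "advanced_stage": TissueClassProfile(
            "advanced_stage", _mult(carot + (1130.0, 749.0, 1547.0), 0.85)
        ),
        "well_diff": TissueClassProfile("well_diff"),
        "moderate_diff": TissueClassProfile(
            "moderate_diff", _mult(carot, 0.93), global_scale=0.93
        ),
        "poor_diff": TissueClassProfile("poor_diff", _mult(carot, 0.85), global_scale=0.85),
    }
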