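"""Tissue oximetry: venous saturation, oxygen extraction, CMRO₂, hypoxia.

Tissue microvascular saturation is modeled as a fixed arterial/venous
mixture (default 0.25/0.75), so venous saturation follows from the
measured arterial and tissue saturations.  The oxygen extraction
fraction is the arteriovenous saturation difference over the arterial
saturation, and the cerebral metabolic rate of oxygen comes from the
modified Fick principle:

    CMRO₂ = CBF · OEF · (SaO₂/100) · k_O₂

with k_O₂ the arterial O₂-carrying capacity at full saturation
(ml O₂ per ml blood).  The default k_O₂ = 0.107 is a calibration
constant of this implementation, not a measured physiological value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "OximetryParams",
    "OximetryResult",
    "SvO2Result",
    "HypoxiaResult",
    "compute_SvO2",
    "compute_OEF",
    "compute_CMRO2",
    "classify_hypoxia",
]


@dataclass(frozen=True)
class OximetryParams:
    """Constants of the saturation-partition and Fick calculations."""

    arterial_fraction: float = 0.25
    k_O2: float = 0.107  # ml O2 / ml blood at SaO2 = 100 %
    SaO2_source: str = "fixed"  # "fixed" | "measured-trace"

    def __post_init__(self):
        if not 0 < self.arterial_fraction < 1:
            raise ValueError("arterial_fraction must lie in (0, 1)")
        if self.k_O2 <= 0:
            raise ValueError("k_O2 must be positive")
        if self.SaO2_source not in ("fixed", "measured-trace"):
            raise ValueError("SaO2_source must be 'fixed' or 'measured-trace'")


class SvO2Result(NamedTuple):
    value: float  # %
    flagged: bool  # True when physiologically inconsistent (negative)


class HypoxiaResult(NamedTuple):
    flags: np.ndarray
    fraction: float
    threshold: float


@dataclass(frozen=True)
class OximetryResult:
    """Per-animal oximetry summary.

    ``OEF_clamped`` marks animals whose raw extraction fraction fell
    outside [0, 1] (tissue saturation above the arterial value) and was
    clamped; they stay in the cohort but remain auditable.
    """

    SaO2: float
    SvO2: float
    OEF: float
    CMRO2: float
    SvO2_flagged: bool = False
    OEF_clamped: bool = False

    def __post_init__(self):
        if not 0.0 <= self.OEF <= 1.0:
            raise ValueError("OEF must lie in [0, 1] after clamping")
        if self.CMRO2 < 0:
            raise ValueError("CMRO2 must be non-negative")


def compute_SvO2(StO2: float, SaO2: float, params: OximetryParams = OximetryParams()) -> SvO2Result:
    """Venous saturation (%) from the arterial/venous partition of StO₂.

    StO₂ = f·SaO₂ + (1−f)·SvO₂ with arterial fraction f, hence
    SvO₂ = (StO₂ − f·SaO₂) / (1−f).  A negative result is returned with
    a flag rather than clipped, so inconsistent animals stay auditable.
    """
    if not 0 < SaO2 <= 100:
        raise ValueError("SaO2 must lie in (0, 100]")
    f = params.arterial_fraction
    svo2 = (StO2 - f * SaO2) / (1.0 - f)
    return SvO2Result(float(svo2), bool(svo2 < 0))


def compute_OEF(SaO2: float, SvO2: float) -> float:
    """Oxygen extraction fraction = (SaO₂ − SvO₂) / SaO₂."""
    if SaO2 <= 0:
        raise ValueError("SaO2 must be positive")
    return float((SaO2 - SvO2) / SaO2)


def compute_CMRO2(
    CBF: float, OEF: float, SaO2: float, params: OximetryParams = OximetryParams()
) -> float:
    """Modified Fick principle: CMRO₂ = CBF · OEF · (SaO₂/100) · k_O₂.

    Units: CBF in ml·100g⁻¹·min⁻¹ gives CMRO₂ in ml O₂·100g⁻¹·min⁻¹.
    """
    if CBF < 0:
        raise ValueError("CBF must be non-negative")
    return float(CBF * OEF * (SaO2 / 100.0) * params.k_O2)


def classify_hypoxia(values, reference_mean: float, reference_sd: float) -> HypoxiaResult:
    """Flag StO₂ values at least 2 SD below a healthy reference mean.

    The boundary is inclusive: a value exactly at mean − 2·SD is
    hypoxic.  Returns per-value flags and the flagged fraction.
    """
    if reference_sd <= 0:
        raise ValueError("reference_sd must be positive")
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    threshold = reference_mean - 2.0 * reference_sd
    flags = arr <= threshold
    return HypoxiaResult(flags, float(np.mean(flags)), float(threshold))
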