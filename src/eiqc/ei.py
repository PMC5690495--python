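"""Exposure-index arithmetic for digital radiography dose QC.

The Carestream-style exposure index (EI) maps the exposure ``X`` incident on a
digital detector onto a logarithmic scale::

    EI = 1000 * log10(X / X0) + 2000,      X0 = 1.0 mR  (8.7 uGy air kerma)

so a detector exposure of exactly 1.0 mR reads EI 2000, every +1000 EI is a
tenfold increase in exposure, and every +300 EI is very nearly a doubling.
This module is the pure computational core the rest of the package builds on:
the EI formula and its inverse, the dose-ratio interpretation of EI
differences, the mR <-> air-kerma conversion, and the inverse-square geometric
correction used to refer a chamber reading at the field periphery to the
detector plane during acceptance testing.

All functions here are scalar, deterministic and side-effect free.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EI_REFERENCE_MR",
    "UGY_PER_MR",
    "EI_SUSPECT_RANGE",
    "GeometrySpec",
    "round_ei",
    "ei_from_exposure",
    "exposure_from_ei",
    "exposure_change_from_delta",
    "exposure_change_percent",
    "airkerma_from_exposure",
    "exposure_from_airkerma",
    "detector_exposure_from_chamber",
    "is_suspect_ei",
]

#: Reference exposure X0 at which the EI scale reads 2000.
EI_REFERENCE_MR: float = 1.0

#: Air kerma per unit exposure for the reference beam (uGy per mR).
UGY_PER_MR: float = 8.7

#: Clinical EI values outside this closed interval are flagged suspect rather
#: than rejected; the scale has no formal bound but nothing plausible lies
#: outside it.
EI_SUSPECT_RANGE: tuple[float, float] = (0.0, 3500.0)


@dataclass(frozen=True)
class GeometrySpec:
    """Acceptance-test beam geometry.

    Parameters
    ----------
    sid_cm
        Source-to-image (detector) distance in cm.
    scd_cm
        Source-to-chamber distance in cm; the ion chamber sits closer to the
        focal spot than the detector, at the periphery of the field.
    center_periphery_ratio
        Ratio of the exposure measured at the center of the beam to that at
        the periphery, used to convert the peripheral chamber reading to a
        central value.
    """

    sid_cm: float
    scd_cm: float
    center_periphery_ratio: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sid_cm", "scd_cm", "center_periphery_ratio"):
            value = getattr(self, name)
            if not (math.isfinite(value) and value > 0):
                raise ValueError(f"GeometrySpec.{name} must be finite and > 0, got {value!r}")


def round_ei(ei: float) -> int:
    """Round an EI value to the nearest integer, halves away from zero.

    This is the presentation rounding used for all displayed EI values;
    Python's built-in banker's rounding is deliberately not used.
    """
    if not math.isfinite(ei):
        raise ValueError(f"cannot round non-finite EI {ei!r}")
    return int(math.copysign(math.floor(abs(ei) + 0.5), ei))


def ei_from_exposure(mr: float) -> float:
    """Exposure index for a detector exposure of ``mr`` milliroentgen.

    Returns the unrounded EI ``1000*log10(mr/1.0) + 2000``; use
    :func:`round_ei` for the integer presentation value.

    Raises
    ------
    ValueError
        If ``mr`` is not strictly positive (the logarithm is undefined).
    """
    if not (math.isfinite(mr) and mr > 0):
        raise ValueError(f"exposure must be finite and > 0 mR for an EI, got {mr!r}")
    return 1000.0 * math.log10(mr / EI_REFERENCE_MR) + 2000.0


def exposure_from_ei(ei: float) -> float:
    """Detector exposure in mR implied by an exposure index.

    Algebraic inverse of :func:`ei_from_exposure`:
    ``10 ** ((ei - 2000) / 1000)`` mR.
    """
    if not math.isfinite(ei):
        raise ValueError(f"EI must be finite, got {ei!r}")
    return EI_REFERENCE_MR * 10.0 ** ((ei - 2000.0) / 1000.0)


def exposure_change_from_delta(delta_ei: float) -> float:
    """Relative exposure change implied by an EI difference.

    A difference of ``delta_ei`` points corresponds to multiplying the
    detector exposure by ``10 ** (delta_ei / 1000)``; the signed fractional
    change is that factor minus one. A drop of 400 EI is a 60% reduction in
    radiation level; a drop of 200 is roughly 40%.
    """
    if not math.isfinite(delta_ei):
        raise ValueError(f"EI difference must be finite, got {delta_ei!r}")
    return 10.0 ** (delta_ei / 1000.0) - 1.0


def exposure_change_percent(delta_ei: float) -> int:
    """Exposure change for an EI difference, as a rounded integer percent."""
    return round_ei(100.0 * exposure_change_from_delta(delta_ei))


def airkerma_from_exposure(mr: float) -> float:
    """Air kerma (uGy) for an exposure in mR, at 8.7 uGy/mR."""
    if not (math.isfinite(mr) and mr >= 0):
        raise ValueError(f"exposure must be finite and >= 0 mR, got {mr!r}")
    return UGY_PER_MR * mr

def exposure_from_airkerma(ugy: float) -> float:
    """Exposure (mR) for an air kerma in uGy; inverse of :func:`airkerma_from_exposure`."""
    if not (math.isfinite(ugy) and ugy >= 0):
        raise ValueError(f"air kerma must be finite and >= 0 uGy, got {ugy!r}")
    return ugy / UGY_PER_MR


def detector_exposure_from_chamber(chamber_mr: float, geom: GeometrySpec) -> float:
    """Refer a peripheral chamber reading to the detector plane.

    Applies the inverse-square falloff from the chamber plane at ``scd_cm``
    to the detector plane at ``sid_cm`` and then the periphery-to-center
    conversion::

        X_detector = X_chamber * (scd_cm / sid_cm)**2 * center_periphery_ratio

    With the chamber at the detector plane and a flat beam profile this is
    the identity.
    """
    if not (math.isfinite(chamber_mr) and chamber_mr >= 0):
        raise ValueError(f"chamber exposure must be finite and >= 0 mR, got {chamber_mr!r}")
    return chamber_mr * (geom.scd_cm / geom.sid_cm) ** 2 * geom.center_periphery_ratio


def is_suspect_ei(ei: float) -> bool:
    """True when an EI value lies outside the plausible clinical range."""
    lo, hi = EI_SUSPECT_RANGE
    return not (math.isfinite(ei) and lo <= ei <= hi)
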