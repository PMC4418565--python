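"""Steady-state GFR and clearance estimators, and body surface area.

These closed-form equations serve two roles: as comparator predictors in
their own right (single-sample "unadjusted" eGFR, valid only at steady
state), and as the source of the anchor filtration estimate inside the
kinetic GFR computation in :mod:`kegfr.kinetic`.

Units follow clinical reporting conventions: serum creatinine in μmol/L,
plasma cystatin C in mg/L. The CKD-EPI and Cockcroft-Gault equations are
defined on creatinine in mg/dL; conversion happens internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

__all__ = [
    "Subject",
    "SteadyStateEstimate",
    "convert_creatinine",
    "ckd_epi_creatinine",
    "ckd_epi_cystatin",
    "cockcroft_gault",
    "dubois_bsa",
]

#: μmol/L of creatinine per mg/dL (molar mass of creatinine = 113.12 g/mol).
CREATININE_UMOL_PER_MGDL = 88.4

Sex = Literal["male", "female"]


@dataclass(frozen=True)
class Subject:
    """Demographics and anthropometrics of one transplant recipient.

    Parameters
    ----------
    id : str
        Opaque identifier.
    age : float
        Age in years. Must be positive.
    sex : {"male", "female"}
    race_black : bool, default False
        Applies the CKD-EPI 2009 race coefficient (1.159) when True.
    weight : float, optional
        Body weight in kg; required for Cockcroft-Gault, volume of
        distribution and BSA.
    height : float, optional
        Height in cm; required only for BSA-dependent computations.
    """

    id: str
    age: float
    sex: Sex
    race_black: bool = False
    weight: float | None = None
    height: float | None = None

    def __post_init__(self) -> None:
        if self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.weight is not None and self.weight <= 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        if self.height is not None and self.height <= 0:
            raise ValueError(f"height must be positive, got {self.height}")

    @property
    def is_female(self) -> bool:
        return self.sex == "female"

    def require_weight(self) -> float:
        if self.weight is None:
            raise ValueError(f"subject {self.id}: weight is required but missing")
        return self.weight

    def require_height(self) -> float:
        if self.height is None:
            raise ValueError(f"subject {self.id}: height is required but missing")
        return self.height

    def bsa(self) -> float:
        """DuBois body surface area (m²); raises if weight/height missing."""
        return dubois_bsa(self.require_weight(), self.require_height())


@dataclass(frozen=True)
class SteadyStateEstimate:
    """A single-sample GFR/clearance estimate.

    ``value`` is in mL/min/1.73m² for the CKD-EPI equations and in
    absolute mL/min for Cockcroft-Gault. ``marker_concentration`` echoes
    the input concentration in its native unit (μmol/L or mg/L).
    """

    value: float
    equation: Literal["ckd_epi_cr", "ckd_epi_cysc", "cockcroft_gault"]
    marker_concentration: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError(f"estimate cannot be negative, got {self.value}")


def convert_creatinine(
    value: float,
    from_unit: Literal["umol_L", "mg_dL"],
    to_unit: Literal["umol_L", "mg_dL"],
) -> float:
    """Convert a creatinine concentration between μmol/L and mg/dL.

    Uses the molar factor 88.4 μmol/L per mg/dL; identity when units are
    equal. Round-trips are lossless to floating precision.
    """
    if value < 0:
        raise ValueError(f"concentration cannot be negative, got {value}")
    for unit in (from_unit, to_unit):
        if unit not in ("umol_L", "mg_dL"):
            raise ValueError(f"unknown creatinine unit {unit!r}")
    if from_unit == to_unit:
        return value
    if from_unit == "umol_L":
        return value / CREATININE_UMOL_PER_MGDL
    return value * CREATININE_UMOL_PER_MGDL


def ckd_epi_creatinine(scr: float, subject: Subject) -> SteadyStateEstimate:
    """CKD-EPI 2009 creatinine eGFR (mL/min/1.73m²).

    eGFR = 141 × min(Scr/κ, 1)^α × max(Scr/κ, 1)^−1.209 × 0.993^age
    × 1.018 [female] × 1.159 [black], with Scr in mg/dL,
    κ = 0.7 (female) / 0.9 (male), α = −0.329 (female) / −0.411 (male).

    Parameters
    ----------
    scr : float
        Serum creatinine in μmol/L (converted internally).
    """
    if scr <= 0:
        raise ValueError(f"serum creatinine must be positive, got {scr}")
    scr_mgdl = convert_creatinine(scr, "umol_L", "mg_dL")
    if subject.is_female:
        kappa, alpha = 0.7, -0.329
    else:
        kappa, alpha = 0.9, -0.411
    ratio = scr_mgdl / kappa
    egfr = (
        141.0
        * min(ratio, 1.0) ** alpha
        * max(ratio, 1.0) ** -1.209
        * 0.993 ** subject.age
    )
    if subject.is_female:
        egfr *= 1.018
    if subject.race_black:
        egfr *= 1.159
    return SteadyStateEstimate(egfr, "ckd_epi_cr", scr)


def ckd_epi_cystatin(cysc: float, subject: Subject) -> SteadyStateEstimate:
    """CKD-EPI 2012 cystatin-C-only eGFR (mL/min/1.73m²).

    eGFR = 133 × min(Scys/0.8, 1)^−0.499 × max(Scys/0.8, 1)^−1.328
    × 0.996^age × 0.932 [female]. No race term.

    Parameters
    ----------
    cysc : float
        Plasma cystatin C in mg/L.
    """
    if cysc <= 0:
        raise ValueError(f"cystatin C must be positive, got {cysc}")
    ratio = cysc / 0.8
    egfr = (
        133.0
        * min(ratio, 1.0) ** -0.499
        * max(ratio, 1.0) ** -1.328
        * 0.996 ** subject.age
    )
    if subject.is_female:
        egfr *= 0.932
    return SteadyStateEstimate(egfr, "ckd_epi_cysc", cysc)


def cockcroft_gault(scr: float, subject: Subject) -> SteadyStateEstimate:
    """Cockcroft-Gault creatinine clearance in absolute mL/min.

    CrCl = (140 − age) × weight / (72 × Scr[mg/dL]), × 0.85 if female.
    Clamped at 0 for age ≥ 140 (a clearance cannot be negative).
    """
    if scr <= 0:
        raise ValueError(f"serum creatinine must be positive, got {scr}")
    weight = subject.require_weight()
    scr_mgdl = convert_creatinine(scr, "umol_L", "mg_dL")
    crcl = max(140.0 - subject.age, 0.0) * weight / (72.0 * scr_mgdl)
    if subject.is_female:
        crcl *= 0.85
    return SteadyStateEstimate(crcl, "cockcroft_gault", scr)


def dubois_bsa(weight: float, height: float) -> float:
    """DuBois & DuBois body surface area (m²).

    BSA = 0.007184 × weight[kg]^0.425 × height[cm]^0.725.
    """
    if weight <= 0:
        raise ValueError(f"weight must be positive, got {weight}")
    if height <= 0:
        raise ValueError(f"height must be positive, got {height}")
    return 0.007184 * weight**0.425 * height**0.725
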