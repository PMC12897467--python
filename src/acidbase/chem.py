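"""Derived acid-base quantities for arterial blood gas interpretation.

Implements the three bedside frameworks used to screen for unmeasured ions
(UIs) in critically ill patients:

* the traditional anion gap with albumin correction (AG, AGc),
* Stewart's physicochemical approach (SIDa, SIDe, ATOT, SIG),
* the partitioned standard base excess (BECl, BEAlb, BELac, BEGap).

All concentrations are mmol/L, PaCO2 is mmHg and albumin is g/L throughout.
Scalar formulas are written so they also broadcast over numpy arrays, which
is how the cohort-level panel table is built.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "MG_MGDL_TO_MMOL",
    "PO4_MGDL_TO_MMOL",
    "PH_MIN",
    "PH_MAX",
    "PatientChemistry",
    "TraditionalPanel",
    "StewartPanel",
    "PartitionedBEPanel",
    "SideMode",
    "convert_units",
    "albumin_charge",
    "phosphate_charge",
    "co2_bicarbonate",
    "compute_traditional",
    "compute_stewart",
    "compute_partitioned_be",
    "compute_sbe_van_slyke",
    "round_half_away",
]

#: mg/dL -> mmol/L conversion factors for magnesium and inorganic phosphate.
MG_MGDL_TO_MMOL = 0.41152
PO4_MGDL_TO_MMOL = 0.323

#: Physiologically admissible arterial pH range used for validation and for
#: bracketing the charge-balance root (values outside are treated as
#: unphysiological rather than extrapolated).
PH_MIN = 6.5
PH_MAX = 7.9

# Van Slyke-type standard base excess constants (buffer slope, reference
# bicarbonate, pH weighting). SBE is analyzer-reported in clinical data; this
# form exists so synthetic records carry a self-consistent SBE.
SBE_SLOPE = 0.9287
SBE_HCO3_REF = 24.4
SBE_PH_WEIGHT = 14.83

ALBUMIN_REFERENCE_G_L = 42.0


class SideMode(str, Enum):
    """How the bicarbonate term of the effective SID is obtained.

    ``formula`` evaluates 0.0301*PaCO2*10^(pH-6.1) (Henderson-Hasselbalch
    plasma CO2 term); ``measured_hco3`` substitutes the analyzer-reported
    bicarbonate. The worked clinical cases shipped with the package are only
    reproducible in ``measured_hco3`` mode, while the formula mode is exactly
    invertible and therefore used by the synthetic-data engine.
    """

    FORMULA = "formula"
    MEASURED_HCO3 = "measured_hco3"


def convert_units(mg_mgdl: float, po4_mgdl: float) -> tuple[float, float]:
    """Convert magnesium and phosphate from mg/dL to mmol/L.

    Returns ``(mg_mmol_l, pi_mmol_l)`` using the fixed factors 0.41152 and
    0.323. Negative inputs are rejected.
    """
    if np.any(np.asarray(mg_mgdl) < 0) or np.any(np.asarray(po4_mgdl) < 0):
        raise ValueError("mg/dL concentrations must be non-negative")
    return mg_mgdl * MG_MGDL_TO_MMOL, po4_mgdl * PO4_MGDL_TO_MMOL


def albumin_charge(ph, albumin_g_l):
    """Negative charge carried by albumin, [Alb-] = (0.123*pH - 0.631)*albumin."""
    return (0.123 * ph - 0.631) * albumin_g_l


def phosphate_charge(ph, pi_mmol_l):
    """Negative charge carried by phosphate, [Pi-] = Pi*(0.309*pH - 0.469)."""
    return pi_mmol_l * (0.309 * ph - 0.469)


def co2_bicarbonate(ph, paco2_mmhg):
    """Plasma bicarbonate implied by pH and PaCO2: 0.0301*PaCO2*10^(pH-6.1)."""
    return 0.0301 * paco2_mmhg * 10.0 ** (ph - 6.1)


def compute_sbe_van_slyke(ph, hco3):
    """Standard base excess from pH and bicarbonate (Van Slyke form).

    SBE = 0.9287 * (HCO3 - 24.4 + 14.83 * (pH - 7.4)); zero at the
    physiological reference point (pH 7.40, HCO3 24.4 mmol/L).
    """
    ph = np.asarray(ph, dtype=float) if not np.isscalar(ph) else ph
    if np.any(np.asarray(ph) < PH_MIN) or np.any(np.asarray(ph) > PH_MAX):
        raise ValueError(f"pH outside [{PH_MIN}, {PH_MAX}]")
    if np.any(np.asarray(hco3) <= 0):
        raise ValueError("hco3 must be positive")
    return SBE_SLOPE * (hco3 - SBE_HCO3_REF + SBE_PH_WEIGHT * (ph - 7.4))


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero, the convention of printed clinical tables.

    numpy/python banker's rounding would turn 20.85 into 20.8; bedside tables
    round 0.5 upward in magnitude.
    """
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class PatientChemistry:
    """One patient's measured blood-gas and biochemistry values.

    Electrolytes, lactate and phosphate are mmol/L, albumin g/L, PaCO2 mmHg.
    ``raw_mg_mgdl``/``raw_po4_mgdl`` optionally carry the pre-conversion
    laboratory values and are checked against the mmol/L fields.
    """

    ph: float
    paco2: float
    hco3: float
    sbe: float
    na: float
    k: float
    cl: float
    ca: float
    mg: float
    lactate: float
    albumin: float
    pi: float
    raw_mg_mgdl: Optional[float] = None
    raw_po4_mgdl: Optional[float] = None

    def __post_init__(self) -> None:
        if not (PH_MIN <= self.ph <= PH_MAX):
            raise ValueError(f"pH {self.ph} outside [{PH_MIN}, {PH_MAX}]")
        if self.paco2 <= 0:
            raise ValueError("paco2 must be positive")
        for name in ("hco3", "na", "k", "cl", "ca", "mg", "lactate", "albumin", "pi"):
            value = getattr(self, name)
            if value is None or not np.isfinite(value):
                raise ValueError(f"missing or non-finite field: {name}")
            if value < 0:
                raise ValueError(f"{name} must be non-negative, got {value}")
        if not np.isfinite(self.sbe):
            raise ValueError("missing or non-finite field: sbe")
        if self.raw_mg_mgdl is not None:
            if abs(self.mg - self.raw_mg_mgdl * MG_MGDL_TO_MMOL) > 1e-9:
                raise ValueError("mg inconsistent with raw_mg_mgdl conversion")
        if self.raw_po4_mgdl is not None:
            if abs(self.pi - self.raw_po4_mgdl * PO4_MGDL_TO_MMOL) > 1e-9:
                raise ValueError("pi inconsistent with raw_po4_mgdl conversion")


@dataclass(frozen=True)
class TraditionalPanel:
    """Anion gap and its albumin-corrected form, mmol/L."""

    ag: float
    agc: float


@dataclass(frozen=True)
class StewartPanel:
    """Stewart physicochemical parameters, mmol/L."""

    sida: float
    side: float
    alb_charge: float
    pi_charge: float
    atot: float
    sig: float
    side_mode: SideMode


@dataclass(frozen=True)
class PartitionedBEPanel:
    """Standard base excess partitioned into chloride, albumin, lactate and gap."""

    becl: float
    bealb: float
    belac: float
    begap: float


def compute_traditional(p: PatientChemistry) -> TraditionalPanel:
    """AG = (Na+K) - (Cl+HCO3); AGc = AG + 0.25*(42 - albumin g/L)."""
    ag = (p.na + p.k) - (p.cl + p.hco3)
    agc = ag + 0.25 * (ALBUMIN_REFERENCE_G_L - p.albumin)
    return TraditionalPanel(ag=ag, agc=agc)


def compute_stewart(
    p: PatientChemistry, mode: SideMode = SideMode.FORMULA
) -> StewartPanel:
    """Apparent/effective strong ion difference and the strong ion gap.

    SIDa = (Na+K+Ca+Mg) - (Cl+lactate), with calcium and magnesium entering
    at their reported mmol/L concentrations. SIDe sums the bicarbonate term
    (per ``mode``) with the albumin and phosphate charges at the patient's
    pH; SIG = SIDa - SIDe.
    """
    mode = SideMode(mode)
    sida = (p.na + p.k + p.ca + p.mg) - (p.cl + p.lactate)
    alb = albumin_charge(p.ph, p.albumin)
    phos = phosphate_charge(p.ph, p.pi)
    if mode is SideMode.FORMULA:
        bicarb = co2_bicarbonate(p.ph, p.paco2)
    else:
        if p.hco3 is None or not np.isfinite(p.hco3):
            raise ValueError("measured_hco3 mode requires hco3")
        bicarb = p.hco3
    side = bicarb + alb + phos
    return StewartPanel(
        sida=sida,
        side=side,
        alb_charge=alb,
        pi_charge=phos,
        atot=alb + phos,
        sig=sida - side,
        side_mode=mode,
    )


def panel_table(records, side_mode: SideMode = SideMode.FORMULA):
    """Vectorized framework panels for a cohort table.

    ``records`` is a DataFrame with the canonical cohort columns (see
    :mod:`acidbase.io`). Returns a DataFrame with one column per derived
    parameter (ag, agc, sida, side, alb_charge, pi_charge, atot, sig, becl,
    bealb, belac, begap) aligned with the input index. ``side_mode`` selects
    the bicarbonate term of the effective SID used for SIG.
    """
    import pandas as pd

    r = records
    ph, paco2, hco3 = r["ph"], r["paco2_mmhg"], r["hco3_mmol_l"]
    alb, pi, lac = r["albumin_g_l"], r["pi_mmol_l"], r["lactate"]
    ag = (r["na"] + r["k"]) - (r["cl"] + hco3)
    agc = ag + 0.25 * (ALBUMIN_REFERENCE_G_L - alb)
    sida = (r["na"] + r["k"] + r["ca"] + r["mg"]) - (r["cl"] + lac)
    alb_q = albumin_charge(ph, alb)
    pi_q = phosphate_charge(ph, pi)
    if SideMode(side_mode) is SideMode.FORMULA:
        bicarb = co2_bicarbonate(ph, paco2)
    else:
        bicarb = hco3
    side = bicarb + alb_q + pi_q
    becl = r["na"] - r["cl"] - 35.0
    bealb = 0.25 * (ALBUMIN_REFERENCE_G_L - alb)
    belac = 1.0 - lac
    return pd.DataFrame(
        {
            "ag": ag,
            "agc": agc,
            "sida": sida,
            "side": side,
            "alb_charge": alb_q,
            "pi_charge": pi_q,
            "atot": alb_q + pi_q,
            "sig": sida - side,
            "becl": becl,
            "bealb": bealb,
            "belac": belac,
            "begap": r["sbe_mmol_l"] - becl - bealb - belac,
        },
        index=r.index,
    )


def compute_partitioned_be(p: PatientChemistry) -> PartitionedBEPanel:
    """Partition SBE into BECl, BEAlb, BELac and the base excess gap.

    BECl = Na - Cl - 35; BEAlb = 0.25*(42 - albumin); BELac = 1 - lactate;
    BEGap = SBE - BECl - BEAlb - BELac, so the four parts sum to SBE exactly.
    A negative BEGap indicates unmeasured anions.
    """
    if p.sbe is None or not np.isfinite(p.sbe):
        raise ValueError("partitioned base excess requires sbe")
    becl = p.na - p.cl - 35.0
    bealb = 0.25 * (ALBUMIN_REFERENCE_G_L - p.albumin)
    belac = 1.0 - p.lactate
    begap = p.sbe - becl - bealb - belac
    return PartitionedBEPanel(becl=becl, bealb=bealb, belac=belac, begap=begap)
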