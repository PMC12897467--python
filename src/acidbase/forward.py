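"""Forward physicochemical solver: pH from the independent Stewart variables.

The clinical frameworks in :mod:`acidbase.chem` all run "backwards", from
measurements to gap indices. To *generate* data with a known unmeasured-ion
burden we need the causal direction: given the strong ion difference left
after unmeasured anions, the weak acids (albumin, phosphate) and PaCO2, find
the pH at which plasma is electroneutral. The balance solved here is exactly
the effective-SID equation of the Stewart panel,

    sid_effective = 0.0301*PaCO2*10^(pH-6.1) + [Alb-](pH) + [Pi-](pH),

whose right side is strictly increasing in pH, so the root is unique when it
exists in the physiological bracket.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .chem import (
    PH_MAX,
    PH_MIN,
    albumin_charge,
    co2_bicarbonate,
    compute_sbe_van_slyke,
    phosphate_charge,
)

__all__ = [
    "StewartState",
    "UnphysiologicalStateError",
    "charge_balance_residual",
    "solve_ph",
    "implied_chemistry",
]


class UnphysiologicalStateError(ValueError):
    """The charge balance has no root in the physiological pH bracket."""


@dataclass(frozen=True)
class StewartState:
    """Independent variables of the charge balance.

    ``sid_effective`` is the apparent strong ion difference minus the latent
    net unmeasured anion load ``xa`` (SIDa - XA): the charge that bicarbonate
    and the weak acids must balance at equilibrium. ``xa`` may be negative
    (net unmeasured cations).
    """

    sid_effective: float
    albumin: float
    pi: float
    paco2: float
    xa: float = 0.0

    def __post_init__(self) -> None:
        if self.paco2 <= 0:
            raise ValueError("paco2 must be positive")
        if self.albumin < 0 or self.pi < 0:
            raise ValueError("albumin and pi must be non-negative")


def charge_balance_residual(ph: float, s: StewartState) -> float:
    """sid_effective minus the pH-dependent buffer charge; decreasing in pH."""
    if not (PH_MIN <= ph <= PH_MAX):
        raise ValueError(f"pH {ph} outside [{PH_MIN}, {PH_MAX}]")
    buffered = (
        co2_bicarbonate(ph, s.paco2)
        + albumin_charge(ph, s.albumin)
        + phosphate_charge(ph, s.pi)
    )
    return s.sid_effective - buffered


def solve_ph(s: StewartState, tol: float = 1e-10) -> float:
    """Unique pH at which the charge balance closes, by bracketed root finding.

    Uses Brent's method (safeguarded, unconditionally convergent on a sign
    change) on [6.5, 7.9]. States whose residual does not change sign on the
    bracket are rejected rather than extrapolated.
    """
    lo = charge_balance_residual(PH_MIN, s)
    hi = charge_balance_residual(PH_MAX, s)
    if lo < 0.0 or hi > 0.0:
        raise UnphysiologicalStateError(
            "charge balance has no root in "
            f"[{PH_MIN}, {PH_MAX}] for sid_effective={s.sid_effective:.3f}, "
            f"albumin={s.albumin:.2f} g/L, pi={s.pi:.3f}, paco2={s.paco2:.2f} mmHg"
        )
    return float(brentq(charge_balance_residual, PH_MIN, PH_MAX, args=(s,), xtol=tol))


def implied_chemistry(s: StewartState, ph: float) -> dict[str, float]:
    """Analyzer-style derived values at the solved pH.

    Returns the bicarbonate implied by (pH, PaCO2) and the Van Slyke standard
    base excess computed from it, for assembly into full synthetic records.
    """
    hco3 = co2_bicarbonate(ph, s.paco2)
    return {"hco3": float(hco3), "sbe": float(compute_sbe_van_slyke(ph, hco3))}
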