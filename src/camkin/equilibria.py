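"""Acid-base speciation, Henry's-law CO2 solubility and rate-constant conversions.

A metal-bound water ligand LM-OH2 deprotonates to the catalytically active
hydroxo form LM-OH- with acid-dissociation exponent pKa.  At a working pH the
two forms are in fast equilibrium, so an observed second-order rate constant
``k_obs`` (per total complex) maps onto a pH-independent constant ``k_ind``
(per hydroxo complex) through the deprotonated fraction.  This module houses
that speciation arithmetic plus the shared proton/charge-balance solver used
by the titration and stopped-flow simulators.

Concentrations are treated as activities throughout (no ionic-strength
correction): the constants being reproduced are mixed, concentration-scale
constants measured at fixed ionic strength.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

__all__ = [
    "AquaComplex",
    "SpeciationState",
    "RateConstantResult",
    "fraction_hydroxide",
    "k_ind_from_kobs",
    "delta_k_stats",
    "co2_saturation",
    "solve_proton_balance",
    "load_presets",
    "HENRY_KH_25C",
    "PKW_25C",
]

#: Henry's-law constant for CO2 at 25 degC, M atm^-1, fixed so that water
#: saturated under 1 atm CO2 holds 33.8 mM.
HENRY_KH_25C = 3.38e-2

#: Water autoionization exponent at 25 degC.
PKW_25C = 14.00


@dataclass(frozen=True)
class AquaComplex:
    """A metal-TPA aqua complex characterised by the pKa of its bound water."""

    id: str
    metal: str
    pKa: float

    def __post_init__(self) -> None:
        if self.metal not in {"Zn", "Cu", "Ni"}:
            raise ValueError(f"unsupported metal {self.metal!r}")
        if not math.isfinite(self.pKa) or not (0.0 < self.pKa < 14.0):
            raise ValueError(f"pKa must be finite and in (0, 14), got {self.pKa}")


@dataclass(frozen=True)
class SpeciationState:
    """Fraction of complex present as the hydroxo form at a given pH."""

    pH: float
    fraction_hydroxide: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_hydroxide <= 1.0:
            raise ValueError("fraction_hydroxide outside [0, 1]")


@dataclass(frozen=True)
class RateConstantResult:
    """One row of a rate-constant report for a single complex.

    All rate constants in M^-1 s^-1; ``percent_increase`` is
    ``100 * delta_k / k_obs``.
    """

    complex_id: str
    metal: str
    pKa: float
    k_obs: float
    sigma_obs: float
    k_ind: float
    delta_k: float
    percent_increase: float

    def __post_init__(self) -> None:
        if self.sigma_obs < 0:
            raise ValueError("sigma_obs must be non-negative")


def fraction_hydroxide(pKa: float, pH: float) -> float:
    """Fraction of the complex present as LM-OH- at ``pH``.

    Henderson-Hasselbalch speciation of a monoprotic acid:
    ``1 / (1 + 10**(pKa - pH))``.  Strictly increasing in pH and equal to
    0.5 at pH == pKa.
    """
    if not (math.isfinite(pKa) and math.isfinite(pH)):
        raise ValueError("pKa and pH must be finite")
    return 1.0 / (1.0 + 10.0 ** (pKa - pH))


def k_ind_from_kobs(k_obs: float, pKa: float, pH: float) -> float:
    """Convert an observed rate constant to its pH-independent form.

    ``k_obs`` is defined per total complex; only the hydroxo fraction is
    reactive, so the constant attributable to LM-OH- alone is
    ``k_obs * (1 + 10**(pKa - pH))``.
    """
    if k_obs < 0:
        raise ValueError("k_obs must be non-negative")
    return k_obs / fraction_hydroxide(pKa, pH)


def delta_k_stats(k_obs: float, k_ind: float) -> tuple[float, float]:
    """Return ``(delta_k, percent_increase)`` for a k_obs/k_ind pair.

    ``delta_k = k_ind - k_obs``; the percent increase is relative to k_obs.
    """
    if k_obs <= 0:
        raise ValueError("k_obs must be positive for a percent increase")
    delta_k = k_ind - k_obs
    return delta_k, 100.0 * delta_k / k_obs


def co2_saturation(
    temperature_c: float, partial_pressure_atm: float, k_h: float | None = None
) -> float:
    """Dissolved CO2 concentration (M) at equilibrium with a gas phase.

    Only 25 degC is supported unless an explicit Henry constant ``k_h``
    (M atm^-1) is supplied.
    """
    if partial_pressure_atm < 0:
        raise ValueError("partial pressure must be non-negative")
    if k_h is None:
        if temperature_c != 25:
            raise ValueError(
                "only 25 degC supported without an explicit Henry constant"
            )
        k_h = HENRY_KH_25C
    return k_h * partial_pressure_atm


def _charge_residual(
    pH: float,
    strong_acid: float,
    strong_base: float,
    weak_acids: Sequence[tuple[float, float]],
    pKw: float,
) -> float:
    """Charge-balance residual (M), positive when the trial pH is too low.

    [Na+] + [H+] - [OH-] - [X-] - sum of deprotonated weak-acid forms.
    """
    h = 10.0 ** (-pH)
    oh = 10.0 ** (pH - pKw)
    res = strong_base + h - oh - strong_acid
    for total, pKa in weak_acids:
        res -= total / (1.0 + 10.0 ** (pKa - pH))
    return res


def solve_proton_balance(
    strong_acid: float,
    strong_base: float,
    weak_acids: Sequence[tuple[float, float]] = (),
    pKw: float = PKW_25C,
    *,
    residual_tol: float = 1e-12,
    bracket: tuple[float, float] = (0.5, 13.5),
) -> float:
    """Solve the charge balance for pH by bracketing bisection.

    Parameters
    ----------
    strong_acid, strong_base
        Total concentrations (M) of fully dissociated acid (e.g. HNO3, HCl)
        and base (e.g. NaOH).
    weak_acids
        Sequence of ``(total_concentration, pKa)`` pairs, each treated as a
        monoprotic acid.
    pKw
        Water autoionization exponent.

    The residual is strictly decreasing in pH, so bisection on a bracketing
    interval converges unconditionally; iteration stops when the residual
    magnitude falls below ``residual_tol`` (M) or the interval reaches
    floating-point resolution.
    """
    for total, _ in weak_acids:
        if total < 0:
            raise ValueError("weak-acid totals must be non-negative")
    if strong_acid < 0 or strong_base < 0:
        raise ValueError("strong acid/base totals must be non-negative")

    lo, hi = bracket
    f_lo = _charge_residual(lo, strong_acid, strong_base, weak_acids, pKw)
    f_hi = _charge_residual(hi, strong_acid, strong_base, weak_acids, pKw)
    if f_lo < 0 or f_hi > 0:
        raise ValueError(
            "charge balance has no root in the pH bracket; totals inconsistent"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = _charge_residual(mid, strong_acid, strong_base, weak_acids, pKw)
        if abs(f_mid) < residual_tol or (hi - lo) < 1e-15:
            return mid
        if f_mid > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def load_presets(mapping: str = "table3_consistent") -> list[AquaComplex]:
    """Load the shipped three-complex preset registry.

    Two pKa-to-complex assignments are shipped because the source data are
    internally inconsistent: ``table2_printed`` is the titration table as
    printed (1->8.0, 2->7.6, 3->6.0) and ``table3_consistent`` is the
    assignment under which the printed k_obs -> k_ind conversions are
    arithmetically exact (1->8.0, 2->6.0, 3->7.6).
    """
    text = resources.files("camkin.data").joinpath("complexes.json").read_text()
    registry = json.loads(text)
    if mapping not in registry:
        raise KeyError(f"unknown preset mapping {mapping!r}; have {sorted(registry)}")
    return [AquaComplex(**row) for row in registry[mapping]]
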