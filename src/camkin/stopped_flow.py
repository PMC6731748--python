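"""Stopped-flow changing-pH-indicator traces for catalysed CO2 hydration.

A CO2-saturated solution is mixed 1:1 with a buffered (AMPSO, pH 9) solution
carrying thymol blue and, optionally, a metal-TPA catalyst.  Each hydration
event CO2 + H2O -> HCO3- + H+ injects one proton into the buffer/indicator
pool; the indicator's basic form absorbs at 596 nm, so the absorbance decays
as the reaction proceeds.  Proton partitioning among buffer, indicator and
water is treated as instantaneous (protonation steps are diffusion-limited
relative to hydration), so the pool pH is an algebraic function of the
cumulative acid released.

Two simulation modes are provided:

* phenomenological - a single effective second-order constant ``k_cat``
  (referenced to the initial pH) multiplies catalyst and CO2; the pH drift
  during the run modulates the catalytic term through the hydroxo fraction
  of the catalyst and the hydroxide pathway of the background.
* mechanistic - explicit mass-action kinetics of the three-step catalytic
  cycle (water deprotonation, CO2 addition to LM-OH-, bicarbonate release),
  integrated with an implicit stiff solver because the protonation steps
  sit near the diffusion limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .equilibria import PKW_25C, AquaComplex, fraction_hydroxide, solve_proton_balance

__all__ = [
    "AssayConditions",
    "MechanismParams",
    "AbsorbanceTrace",
    "ProtonPool",
    "simulate_trace_phenomenological",
    "simulate_trace_mechanistic",
    "generate_assay_set",
    "DEFAULT_CATALYST_SERIES",
]

LN10 = math.log(10.0)

#: Default post-mixing catalyst concentration series (M) for a rate assay.
DEFAULT_CATALYST_SERIES = (0.0, 1.0e-4, 2.5e-4, 5.0e-4)


@dataclass(frozen=True)
class AssayConditions:
    """Post-mixing composition of one stopped-flow shot.

    All concentrations are AFTER the 1:1 mix: 33.8 mM saturated CO2 becomes
    16.9 mM, the 0.1 M AMPSO buffer becomes 0.05 M and the 5e-5 M thymol
    blue indicator becomes 2.5e-5 M.  ``epsilon_basic``/``epsilon_acidic``
    are the 596 nm molar absorptivities of the basic and acidic indicator
    forms; the defaults are calibrated so a full-conversion run changes the
    absorbance by about 0.41.  ``k_uncat`` and ``k_oh`` are the uncatalysed
    CO2 + H2O and CO2 + OH- background rate constants at 25 degC.
    """

    co2_initial: float = 0.0169
    catalyst_conc: float = 0.0
    catalyst_pKa: float | None = None
    buffer_total: float = 0.05
    buffer_pKa: float = 9.0
    indicator_total: float = 2.5e-5
    indicator_pKa: float = 8.9
    epsilon_basic: float = 4.6e4
    epsilon_acidic: float = 1.0e3
    path_length: float = 1.0
    initial_pH: float = 9.0
    temperature: float = 25.0
    k_uncat: float = 0.037
    k_oh: float = 8.5e3
    pKw: float = PKW_25C

    def __post_init__(self) -> None:
        for name in (
            "co2_initial",
            "catalyst_conc",
            "buffer_total",
            "indicator_total",
            "epsilon_basic",
            "epsilon_acidic",
            "path_length",
            "k_uncat",
            "k_oh",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class MechanismParams:
    """Rate constants of the catalytic-cycle steps.

    ``k_deprot`` (s^-1) and ``k_reprot`` (M^-1 s^-1) are the forward and
    reverse constants of LM-OH2 <-> LM-OH- + H+ and are tied by detailed
    balance: k_deprot / k_reprot = Ka of the complex.  ``k_co2`` (M^-1 s^-1)
    is the CO2-addition step LM-OH- + CO2 -> LM-HCO3-, ``k_release`` (s^-1)
    the bicarbonate release LM-HCO3- + H2O -> LM-OH2 + HCO3-.
    """

    k_deprot: float
    k_reprot: float
    k_co2: float
    k_release: float

    def __post_init__(self) -> None:
        if min(self.k_deprot, self.k_reprot, self.k_co2, self.k_release) < 0:
            raise ValueError("rate constants must be non-negative")

    @classmethod
    def from_equilibrium(
        cls, pKa: float, k_deprot: float, k_co2: float, k_release: float
    ) -> "MechanismParams":
        """Build parameters with k_reprot fixed by detailed balance."""
        return cls(k_deprot, k_deprot / 10.0 ** (-pKa), k_co2, k_release)

    def equilibrium_pKa(self) -> float:
        if self.k_reprot == 0:
            raise ValueError("k_reprot = 0 has no finite equilibrium pKa")
        return -math.log10(self.k_deprot / self.k_reprot)


@dataclass(frozen=True)
class AbsorbanceTrace:
    """One simulated stopped-flow shot: time (s) vs absorbance at 596 nm."""

    times: np.ndarray
    absorbance: np.ndarray
    conditions: AssayConditions = field(default_factory=AssayConditions)
    seed: int | None = None
    pH: np.ndarray | None = None
    species: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        a = np.asarray(self.absorbance, dtype=float)
        if t.shape != a.shape or t.ndim != 1:
            raise ValueError("times and absorbance must be 1-D of equal length")
        if t.size and (t[0] < 0 or np.any(np.diff(t) <= 0)):
            raise ValueError("times must ascend from 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "absorbance", a)


class ProtonPool:
    """pH of the buffer/indicator pool as a function of cumulative acid.

    The pool is calibrated so that with zero added acid the pH equals the
    stated initial pH (the background sodium level is solved in closed form
    from the charge balance).  Subsequent calls solve the same charge
    balance by safeguarded Newton iteration warm-started from the previous
    solution, falling back to bisection when the step leaves the bracket.
    """

    def __init__(self, cond: AssayConditions):
        self.cond = cond
        p0 = cond.initial_pH
        h0 = 10.0 ** (-p0)
        oh0 = 10.0 ** (p0 - cond.pKw)
        self._weak = [
            (cond.buffer_total, cond.buffer_pKa),
            (cond.indicator_total, cond.indicator_pKa),
        ]
        self.na_background = oh0 - h0 + sum(
            c / (1.0 + 10.0 ** (pk - p0)) for c, pk in self._weak
        )
        self._last_pH = p0

    def _residual(self, pH: float, h_cum: float) -> tuple[float, float]:
        h = 10.0 ** (-pH)
        oh = 10.0 ** (pH - self.cond.pKw)
        res = self.na_background + h - oh - h_cum
        dres = h + oh
        for c, pk in self._weak:
            f = 1.0 / (1.0 + 10.0 ** (pk - pH))
            res -= c * f
            dres += c * f * (1.0 - f)
        return res, -LN10 * dres

    def pH(self, h_cum: float) -> float:
        """pH after ``h_cum`` M of strong acid has entered the pool."""
        x = self._last_pH
        for _ in range(60):
            res, dres = self._residual(x, h_cum)
            if abs(res) < 1e-13:
                self._last_pH = x
                return x
            step = res / dres
            x_new = x - step
            if not (0.5 <= x_new <= 13.5):
                break
            if abs(x_new - x) < 1e-14:
                self._last_pH = x_new
                return x_new
            x = x_new
        x = solve_proton_balance(
            h_cum, self.na_background, self._weak, self.cond.pKw
        )
        self._last_pH = x
        return x

    def absorbance(self, pH: float | np.ndarray) -> float | np.ndarray:
        """596 nm absorbance of the indicator at the given pH."""
        c = self.cond
        f_basic = 1.0 / (1.0 + 10.0 ** (c.indicator_pKa - np.asarray(pH, float)))
        a = c.path_length * c.indicator_total * (
            c.epsilon_basic * f_basic + c.epsilon_acidic * (1.0 - f_basic)
        )
        return float(a) if np.isscalar(pH) else a


def _finish_trace(
    times: np.ndarray,
    pH: np.ndarray,
    pool: ProtonPool,
    cond: AssayConditions,
    noise_sd: float,
    seed: int | None,
) -> AbsorbanceTrace:
    absorbance = np.asarray(pool.absorbance(pH))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + rng.normal(0.0, noise_sd, size=absorbance.shape)
    return AbsorbanceTrace(times, absorbance, cond, seed, pH)


def simulate_trace_phenomenological(
    cond: AssayConditions,
    k_cat: float,
    duration: float = 150.0,
    dt: float = 0.01,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> AbsorbanceTrace:
    """Integrate a trace with a single effective catalytic rate constant.

    The CO2 pool obeys ``d[CO2]/dt = -k_tot(pH) [CO2]`` with

    ``k_tot = k_uncat + k_oh [OH-] + k_cat [cat] f(pKa, pH) / f(pKa, pH0)``

    where f is the hydroxo fraction of the catalyst; the normalisation by
    the initial-pH fraction makes ``k_cat`` the observed second-order
    constant at the nominal assay pH (the quantity the slope analysis
    recovers), while the ratio captures the loss of active catalyst as the
    pH falls.  Without a catalyst pKa the catalytic term is pH-independent.
    Fixed-step RK4; a step consuming more than 5% of the remaining CO2
    aborts the run (dt too coarse for the rate regime).
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("duration and dt must be positive")
    if k_cat < 0:
        raise ValueError("k_cat must be non-negative")
    pool = ProtonPool(cond)
    c0 = cond.co2_initial
    f0 = (
        fraction_hydroxide(cond.catalyst_pKa, cond.initial_pH)
        if cond.catalyst_pKa is not None
        else 1.0
    )
    cat = cond.catalyst_conc

    def k_tot(co2: float) -> float:
        ph = pool.pH(c0 - co2)
        oh = 10.0 ** (ph - cond.pKw)
        k = cond.k_uncat + cond.k_oh * oh
        if cat > 0 and k_cat > 0:
            frac = (
                fraction_hydroxide(cond.catalyst_pKa, ph) / f0
                if cond.catalyst_pKa is not None
                else 1.0
            )
            k += k_cat * cat * frac
        return k

    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    pH = np.empty(n_steps + 1)
    pH[0] = pool.pH(0.0)
    c = c0
    for i in range(1, n_steps + 1):
        k1 = -k_tot(c) * c
        k2 = -k_tot(c + 0.5 * dt * k1) * (c + 0.5 * dt * k1)
        k3 = -k_tot(c + 0.5 * dt * k2) * (c + 0.5 * dt * k2)
        k4 = -k_tot(c + dt * k3) * (c + dt * k3)
        dc = (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if c > 0 and abs(dc) > 0.05 * c:
            raise ValueError(
                f"step at t={times[i]:.3f}s consumes {abs(dc) / c:.1%} of CO2; "
                "decrease dt"
            )
        c = max(c + dc, 0.0)
        pH[i] = pool.pH(c0 - c)
    return _finish_trace(times, pH, pool, cond, noise_sd, seed)


def simulate_trace_mechanistic(
    cond: AssayConditions,
    mech: MechanismParams,
    complex_: AquaComplex,
    duration: float = 150.0,
    dt: float = 0.01,
    noise_sd: float = 0.0,
    seed: int | None = None,
    rtol: float = 1e-9,
    atol: float = 1e-14,
) -> AbsorbanceTrace:
    """Integrate the explicit three-step catalytic cycle.

    Species: LM-OH2 (E), LM-OH- (EOH), LM-HCO3- (EHCO3) and CO2, with the
    proton pool handled algebraically as in the phenomenological mode.
    E is reconstructed as total - EOH - EHCO3 and released bicarbonate as
    CO2_0 - CO2 - EHCO3, so catalyst and carbon are conserved exactly.
    The catalyst starts speciated at the initial pH (it is prepared in the
    same buffer); the proton ledger counts only post-mixing releases.
    Integration uses an implicit stiff solver (Radau) because near-diffusion-
    limited protonation makes the system stiff; ``dt`` sets the output grid.
    """
    from scipy.integrate import solve_ivp

    pka_db = mech.equilibrium_pKa()
    if abs(pka_db - complex_.pKa) > 1e-6:
        raise ValueError(
            f"detailed balance violated: k_deprot/k_reprot gives pKa {pka_db:.4f} "
            f"but the complex has pKa {complex_.pKa}"
        )
    pool = ProtonPool(cond)
    total = cond.catalyst_conc
    c0 = cond.co2_initial
    eoh0 = total * fraction_hydroxide(complex_.pKa, cond.initial_pH)

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        eoh, ehco3, co2, h_cum = y
        e = total - eoh - ehco3
        ph = pool.pH(h_cum)
        h = 10.0 ** (-ph)
        oh = 10.0 ** (ph - cond.pKw)
        v_deprot = mech.k_deprot * e
        v_reprot = mech.k_reprot * h * eoh
        v_add = mech.k_co2 * eoh * co2
        v_rel = mech.k_release * ehco3
        v_bg = (cond.k_uncat + cond.k_oh * oh) * co2
        return [
            v_deprot - v_reprot - v_add,
            v_add - v_rel,
            -v_add - v_bg,
            v_deprot - v_reprot + v_bg,
        ]

    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    sol = solve_ivp(
        rhs,
        (0.0, duration),
        [eoh0, 0.0, c0, 0.0],
        method="Radau",
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise RuntimeError(f"mechanistic integration failed: {sol.message}")
    h_cum = sol.y[3]
    pH = np.array([pool.pH(h) for h in h_cum])
    trace = _finish_trace(times, pH, pool, cond, noise_sd, seed)
    # attach species trajectories for conservation diagnostics
    object.__setattr__(
        trace,
        "species",
        {
            "LM-OH": sol.y[0],
            "LM-HCO3": sol.y[1],
            "CO2": sol.y[2],
            "H_cum": h_cum,
            "LM-OH2": total - sol.y[0] - sol.y[1],
            "HCO3_released": c0 - sol.y[2] - sol.y[1],
        },
    )
    return trace


def generate_assay_set(
    complex_: AquaComplex,
    k_cat_true: float,
    catalyst_concs: Sequence[float] = DEFAULT_CATALYST_SERIES,
    n_replicates: int = 4,
    noise_sd: float = 0.002,
    seed: int = 0,
    conditions: AssayConditions | None = None,
    duration: float = 150.0,
    dt: float = 0.01,
) -> list[tuple[float, int, AbsorbanceTrace]]:
    """Simulate a full rate assay: a catalyst series with replicates.

    Returns ``(catalyst_conc, replicate_index, trace)`` triples, reproducible
    from the seed (per-trace noise seeds are drawn from one generator).  A
    zero concentration is the uncatalysed control.
    """
    concs = list(catalyst_concs)
    if not concs:
        raise ValueError("catalyst concentration series is empty")
    if len(set(concs)) < 2:
        raise ValueError("need at least 2 distinct catalyst concentrations")
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    base = conditions or AssayConditions(catalyst_pKa=complex_.pKa)
    rng = np.random.default_rng(seed)
    out: list[tuple[float, int, AbsorbanceTrace]] = []
    for conc in concs:
        cond = replace(base, catalyst_conc=conc, catalyst_pKa=complex_.pKa)
        noiseless: AbsorbanceTrace | None = None
        for rep in range(n_replicates):
            sub = int(rng.integers(0, 2**31 - 1))
            if noiseless is None:
                noiseless = simulate_trace_phenomenological(
                    cond, k_cat_true, duration, dt, 0.0, None
                )
            trace = noiseless
            if noise_sd > 0:
                trace = _finish_trace(
                    noiseless.times, noiseless.pH, ProtonPool(cond), cond,
                    noise_sd, sub,
                )
            out.append((conc, rep, trace))
    return out
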