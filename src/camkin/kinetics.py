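"""Inference chain from absorbance traces to second-order rate constants.

The changing-pH-indicator method converts proton release into an absorbance
decay; the chain back to chemistry is

1. buffer factor Q (mol of H+ per absorbance unit), calibrated by adding
   known HCl to the buffer/indicator mix;
2. initial rate v_int = Q (A0 - Ae) [-d ln(A - Ae)/dt]_{t->0}, with the decay
   constant from a single-exponential fit to the first 10% of the absorbance
   change;
3. k_obs as the slope of v_int/[CO2] against catalyst concentration, with
   the uncatalysed rate appearing as the intercept.  The replicate spread of
   the slopes gives sigma_obs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .equilibria import AquaComplex, RateConstantResult, delta_k_stats, k_ind_from_kobs
from .stopped_flow import AbsorbanceTrace, AssayConditions, ProtonPool

__all__ = [
    "BufferFactor",
    "InitialRateResult",
    "KobsFit",
    "estimate_buffer_factor",
    "fit_initial_rate",
    "fit_kobs",
    "assemble_results",
    "DEFAULT_HCL_ADDITIONS",
]

#: Default HCl additions (M) for the buffer-factor calibration; they span
#: well under 20% of the buffer capacity so the response stays linear.
DEFAULT_HCL_ADDITIONS = (1.0e-4, 2.0e-4, 3.0e-4, 4.0e-4, 5.0e-4)


@dataclass(frozen=True)
class BufferFactor:
    """Buffer factor Q: mol L^-1 of protons per unit of absorbance drop."""

    Q: float
    fit_r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.Q <= 0:
            raise ValueError("Q must be positive for a functioning indicator")


@dataclass(frozen=True)
class InitialRateResult:
    """Initial hydration rate extracted from one trace."""

    v_int: float
    A0: float
    Ae: float
    decay_constant: float
    window_end: float
    fit_rms: float
    n_window_points: int


@dataclass(frozen=True)
class KobsFit:
    """Second-order rate constant from the rate-vs-catalyst regression."""

    k_obs: float
    intercept: float
    sigma_obs: float
    co2_conc_used: float
    points: tuple[tuple[float, float], ...]
    replicate_slopes: tuple[float, ...]


def estimate_buffer_factor(
    cond: AssayConditions,
    hcl_additions: Sequence[float] = DEFAULT_HCL_ADDITIONS,
) -> BufferFactor:
    """Calibrate Q by titrating the buffer/indicator mix with HCl.

    For each addition the equilibrium pH and hence the indicator absorbance
    are computed from the charge balance; Q is the least-squares slope of
    added [HCl] against the absorbance drop A0 - A (through the measured
    zero-addition point).
    """
    additions = np.asarray(sorted(hcl_additions), dtype=float)
    if additions.size < 3:
        raise ValueError("need at least 3 HCl additions")
    if np.any(additions <= 0):
        raise ValueError("HCl additions must be positive")
    if cond.indicator_total == 0:
        raise ValueError("no indicator present: absorbance does not respond to HCl")
    pool = ProtonPool(cond)
    a0 = pool.absorbance(pool.pH(0.0))
    drops = np.array([a0 - pool.absorbance(pool.pH(h)) for h in additions])
    if np.any(np.diff(drops) <= 0) or drops[0] <= 0:
        raise ValueError("absorbance response non-monotone: indicator saturated")
    x = np.concatenate([[0.0], drops])
    y = np.concatenate([[0.0], additions])
    slope, intercept = np.polyfit(x, y, 1)
    pred = slope * x + intercept
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return BufferFactor(float(slope), 1.0 - ss_res / ss_tot, int(x.size))


def fit_initial_rate(
    trace: AbsorbanceTrace,
    Q: BufferFactor | float,
    window_fraction: float = 0.10,
    a_e: float | None = None,
    window_seconds: float | None = None,
) -> InitialRateResult:
    """Extract the initial hydration rate from one absorbance trace.

    The plateau absorbance Ae is the mean of the final 5% of points unless
    supplied.  The fit window is the initial stretch covering the first
    ``window_fraction`` of the total absorbance change (or, if
    ``window_seconds`` is given, the first that many seconds); over it the
    decay constant is the negated least-squares slope of ln(A - Ae) vs t,
    and ``v_int = Q (A0 - Ae) * decay_constant``.
    """
    q = Q.Q if isinstance(Q, BufferFactor) else float(Q)
    t = trace.times
    a = trace.absorbance
    if a_e is None:
        n_tail = max(int(round(0.05 * a.size)), 1)
        a_e = float(a[-n_tail:].mean())
    a0 = float(a[0])
    amplitude = a0 - a_e
    if amplitude <= 0:
        raise ValueError("A0 <= Ae: no decay to fit")
    if window_seconds is not None:
        n_win = int(np.searchsorted(t, window_seconds, side="right"))
    else:
        consumed = (a0 - a) / amplitude
        crossing = np.nonzero(consumed > window_fraction)[0]
        n_win = int(crossing[0]) if crossing.size else a.size
    if n_win < 5:
        raise ValueError(f"only {n_win} points in the initial-rate window; need >= 5")
    resid = a[:n_win] - a_e
    if np.any(resid <= 0):
        raise ValueError("A - Ae non-positive inside the fit window")
    log_resid = np.log(resid)
    slope, intercept = np.polyfit(t[:n_win], log_resid, 1)
    if slope >= 0:
        raise ValueError("no decay detected (non-negative log-slope)")
    rms = float(np.sqrt(np.mean((log_resid - (slope * t[:n_win] + intercept)) ** 2)))
    b = float(-slope)
    return InitialRateResult(
        v_int=q * amplitude * b,
        A0=a0,
        Ae=a_e,
        decay_constant=b,
        window_end=float(t[n_win - 1]),
        fit_rms=rms,
        n_window_points=n_win,
    )


def fit_kobs(
    rates: Mapping[tuple[float, int], InitialRateResult],
    co2_conc: float,
) -> KobsFit:
    """Fit k_obs as the slope of v_int/[CO2] against catalyst concentration.

    ``rates`` maps (catalyst_conc, replicate_index) to initial-rate results.
    Each replicate contributes one ordinary-least-squares slope across the
    concentration series; k_obs is the mean of those slopes and sigma_obs
    their sample standard deviation (n-1 denominator, 0 for one replicate).
    The mean intercept is retained as the uncatalysed rate constant.
    """
    if co2_conc <= 0:
        raise ValueError("co2_conc must be positive")
    concs = sorted({c for c, _ in rates})
    if len(concs) < 2:
        raise ValueError("need at least 2 distinct catalyst concentrations")
    reps = sorted({r for _, r in rates})
    slopes, intercepts = [], []
    points: list[tuple[float, float]] = []
    for rep in reps:
        xs, ys = [], []
        for c in concs:
            res = rates.get((c, rep))
            if res is None:
                continue
            xs.append(c)
            ys.append(res.v_int / co2_conc)
        if len(xs) < 2:
            continue
        slope, intercept = np.polyfit(xs, ys, 1)
        slopes.append(float(slope))
        intercepts.append(float(intercept))
        points.extend(zip(xs, ys))
    if not slopes:
        raise ValueError("no replicate had >= 2 concentrations")
    sigma = float(np.std(slopes, ddof=1)) if len(slopes) > 1 else 0.0
    return KobsFit(
        k_obs=float(np.mean(slopes)),
        intercept=float(np.mean(intercepts)),
        sigma_obs=sigma,
        co2_conc_used=co2_conc,
        points=tuple(points),
        replicate_slopes=tuple(slopes),
    )


def assemble_results(
    complex_: AquaComplex, fit: KobsFit, pH: float = 9.0
) -> RateConstantResult:
    """Combine a k_obs fit with the speciation correction into one report row."""
    k_ind = k_ind_from_kobs(fit.k_obs, complex_.pKa, pH)
    delta_k, pct = delta_k_stats(fit.k_obs, k_ind)
    return RateConstantResult(
        complex_id=complex_.id,
        metal=complex_.metal,
        pKa=complex_.pKa,
        k_obs=fit.k_obs,
        sigma_obs=fit.sigma_obs,
        k_ind=k_ind,
        delta_k=delta_k,
        percent_increase=pct,
    )
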