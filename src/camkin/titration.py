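"""Potentiometric titration simulation and half-equivalence pKa recovery.

The experiment being emulated: a 1.0 mM solution of the aqua complex in
2.0 mM HNO3 (50 mL) is titrated with 0.1 M NaOH while the pH is monitored.
The strong acid is neutralised first (equivalence at 1.00 mL), then the
metal-bound water is titrated as a monoprotic weak acid (second equivalence
at 1.50 mL).  The pH at the midpoint of the second buffering region equals
the pKa of the bound water.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .equilibria import PKW_25C, solve_proton_balance

__all__ = [
    "TitrationConfig",
    "TitrationCurve",
    "simulate_titration",
    "find_equivalence_points",
    "pka_half_equivalence",
]


@dataclass(frozen=True)
class TitrationConfig:
    """Conditions of one simulated potentiometric titration.

    Defaults reproduce the study conditions: 1.0 mM complex + 2.0 mM HNO3
    in 50 mL, titrated with 0.1 M NaOH over 0-2.5 mL on a 300-point grid.
    """

    analyte_conc: float = 1.0e-3
    strong_acid_conc: float = 2.0e-3
    initial_volume: float = 0.050
    titrant_conc: float = 0.1
    max_titrant_volume: float = 2.5e-3
    n_points: int = 300
    noise_sd_pH: float = 0.0
    seed: int = 0
    pKw: float = PKW_25C

    def __post_init__(self) -> None:
        if min(self.strong_acid_conc, self.initial_volume, self.titrant_conc) <= 0:
            raise ValueError("concentrations and volumes must be positive")
        if self.analyte_conc < 0 or self.noise_sd_pH < 0:
            raise ValueError("analyte_conc and noise_sd_pH must be non-negative")
        if self.n_points < 10:
            raise ValueError("need at least 10 titration points")


@dataclass(frozen=True)
class TitrationCurve:
    """Titrant volume (L) vs pH series plus the generating config."""

    titrant_volumes: np.ndarray
    pH_values: np.ndarray
    config: TitrationConfig = field(default_factory=TitrationConfig)

    def __post_init__(self) -> None:
        v = np.asarray(self.titrant_volumes, dtype=float)
        p = np.asarray(self.pH_values, dtype=float)
        if v.shape != p.shape or v.ndim != 1:
            raise ValueError("volumes and pH must be 1-D arrays of equal length")
        if np.any(np.diff(v) <= 0):
            raise ValueError("titrant volumes must be strictly increasing")
        object.__setattr__(self, "titrant_volumes", v)
        object.__setattr__(self, "pH_values", p)


def simulate_titration(config: TitrationConfig, pKa: float) -> TitrationCurve:
    """Simulate the pH curve for a complex with the given bound-water pKa.

    At every titrant volume v the analytical totals are diluted into
    V0 + v and the charge balance is solved exactly; optional Gaussian
    pH-reading noise is applied afterwards.
    """
    n_acid = config.strong_acid_conc * config.initial_volume
    n_complex = config.analyte_conc * config.initial_volume
    volumes = np.linspace(0.0, config.max_titrant_volume, config.n_points)
    pH = np.empty_like(volumes)
    for i, v in enumerate(volumes):
        vtot = config.initial_volume + v
        weak = [(n_complex / vtot, pKa)] if n_complex > 0 else []
        pH[i] = solve_proton_balance(
            n_acid / vtot, config.titrant_conc * v / vtot, weak, config.pKw
        )
    if config.noise_sd_pH > 0:
        rng = np.random.default_rng(config.seed)
        pH = pH + rng.normal(0.0, config.noise_sd_pH, size=pH.shape)
    return TitrationCurve(volumes, pH, config)


def _smoothed_derivative(curve: TitrationCurve) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference dpH/dV smoothed by a 5-point running mean."""
    v = curve.titrant_volumes
    p = curve.pH_values
    dpdv = np.gradient(p, v)
    kernel = np.ones(5) / 5.0
    smooth = np.convolve(dpdv, kernel, mode="same")
    # running mean shortens effective support at the edges; renormalise there
    norm = np.convolve(np.ones_like(dpdv), kernel, mode="same")
    return v, smooth / norm


def find_equivalence_points(
    curve: TitrationCurve, min_prominence: float = 0.01
) -> list[float]:
    """Locate equivalence points as maxima of the smoothed first derivative.

    Peaks are kept if they rise above ``min_prominence`` times the tallest
    derivative value, refined by parabolic interpolation through the three
    samples around each maximum, and returned tallest-first.
    """
    from scipy.signal import find_peaks

    if len(curve.titrant_volumes) < 10:
        raise ValueError("need at least 10 points to locate equivalence points")
    v, d = _smoothed_derivative(curve)
    span = float(d.max() - d.min())
    if span <= 0 or not np.isfinite(span):
        raise ValueError("curve has no inflection; cannot locate equivalence point")
    idx, props = find_peaks(d, prominence=min_prominence * span)
    if len(idx) == 0:
        raise ValueError("no equivalence point detected in derivative curve")
    heights = d[idx]
    volumes = []
    for i in idx:
        if 0 < i < len(v) - 1:
            # parabola through (v[i-1..i+1], d[i-1..i+1]); vertex offset
            y0, y1, y2 = d[i - 1], d[i], d[i + 1]
            denom = y0 - 2 * y1 + y2
            off = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
            off = float(np.clip(off, -1.0, 1.0))
            volumes.append(float(v[i] + off * (v[min(i + 1, len(v) - 1)] - v[i])))
        else:
            volumes.append(float(v[i]))
    order = np.argsort(heights)[::-1]
    return [volumes[i] for i in order]


def pka_half_equivalence(curve: TitrationCurve) -> float:
    """Recover pKa as the pH at the half-equivalence point.

    The two tallest equivalence points v1 < v2 bracket the weak-acid
    buffering region; at v = (v1 + v2)/2 half of the complex is
    deprotonated, so the interpolated pH equals the pKa.
    """
    eq = find_equivalence_points(curve)
    if len(eq) < 2:
        raise ValueError(
            "expected two equivalence points (strong acid, then complex); "
            f"found {len(eq)} - curve unresolved"
        )
    v1, v2 = sorted(eq[:2])
    v_half = 0.5 * (v1 + v2)
    return float(np.interp(v_half, curve.titrant_volumes, curve.pH_values))
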