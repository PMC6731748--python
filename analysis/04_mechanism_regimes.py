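"""Demonstrate the rate-determining-step logic on the mechanistic simulator.

The catalytic cycle has three steps: deprotonation of the bound water,
CO2 addition to LM-OH-, and bicarbonate release.  Holding the CO2-addition
constant fixed while sweeping the bicarbonate-release constant shows how a
complex with a LOW pKa (plenty of active hydroxo form, like the Ni and Cu
complexes) can still hydrate CO2 slowly when bicarbonate release is
sluggish, while a HIGH-pKa complex with fast release (the Zn complex) wins:
the observed ordering of the three complexes.

Writes results/mechanism_sweep.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from camkin.equilibria import AquaComplex, fraction_hydroxide
from camkin.stopped_flow import AssayConditions, MechanismParams, \
    simulate_trace_mechanistic

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

K_CO2 = 600.0  # shared CO2-addition constant, M^-1 s^-1


def time_to_10pct(trace):
    a0, ae = trace.absorbance[0], trace.absorbance[-1]
    idx = np.nonzero(trace.absorbance <= a0 - 0.1 * (a0 - ae))[0]
    return float(trace.times[idx[0]]) if idx.size else float("inf")


rows = []
for pka, label in [(6.0, "low pKa (Ni/Cu-like)"), (8.0, "high pKa (Zn-like)")]:
    cpx = AquaComplex("1", "Zn", pka)
    cond = AssayConditions(catalyst_conc=5e-4, catalyst_pKa=pka)
    for k_release in (1e4, 1e2, 1e1, 1e0, 1e-1):
        mech = MechanismParams.from_equilibrium(pka, 1e4, K_CO2, k_release)
        trace = simulate_trace_mechanistic(cond, mech, cpx, 200.0, 0.05)
        t10 = time_to_10pct(trace)
        rows.append(
            {
                "pKa": pka,
                "fraction_hydroxide_pH9": round(fraction_hydroxide(pka, 9.0), 3),
                "k_release_per_s": k_release,
                "t_10pct_s": round(t10, 2),
            }
        )
        print(f"{label}: k_release {k_release:8.1f} s^-1 -> 10% conversion in "
              f"{t10:6.2f} s")

pd.DataFrame(rows).to_csv(OUT / "mechanism_sweep.csv", index=False)
print("\nSlowing bicarbonate release always slows conversion; once it is")
print("rate-limiting, a lower pKa no longer buys speed - fast release beats")
print(f"easy deprotonation.  wrote {OUT / 'mechanism_sweep.csv'}")
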