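# camkin

Simulation and kinetic analysis of CO2 hydration catalysed by
carbonic-anhydrase-mimicking metal complexes.

Carbonic anhydrase (CA) hydrates CO2 at ≥10⁶ M⁻¹s⁻¹ using a zinc-bound
hydroxide as the nucleophile. Small biomimetic complexes such as
[(TPA)M(OH₂)]²⁺ (TPA = tris(2-pyridylmethyl)amine; M = Zn²⁺, Cu²⁺, Ni²⁺)
probe which step of the catalytic cycle — deprotonation of the bound water,
CO2 addition to LM-OH⁻, or bicarbonate release — limits the rate. `camkin`
implements, on synthetic data, the complete measurement-and-inference chain
used to characterise such complexes:

* **Potentiometric titration** of the aqua complex (1.0 mM complex +
  2.0 mM HNO₃ vs 0.1 M NaOH) and pKa recovery at the half-equivalence
  point.
* **Stopped-flow changing-pH-indicator traces**: CO2-saturated water
  (33.8 mM by Henry's law) mixed 1:1 with AMPSO buffer (pH 9.0) + thymol
  blue; hydration releases protons and bleaches the indicator at 596 nm.
  A phenomenological mode (one effective rate constant) and a mechanistic
  mode (explicit mass-action catalytic cycle) are provided.
* **Rate inference**: buffer factor Q, initial rates via
  v_int = Q·(A₀−A_e)·[−d ln(A−A_e)/dt]₍t→0₎ over the first 10% of the
  decay, k_obs as the slope of v_int/[CO2] vs catalyst concentration, and
  the speciation correction

      k_ind = k_obs · (1 + 10^(pKa − pH))

  that re-expresses the observed constant per active hydroxo complex.

## Worked example

```python
from camkin import (AquaComplex, AssayConditions, generate_assay_set,
                    estimate_buffer_factor, fit_initial_rate, fit_kobs,
                    assemble_results)

zn = AquaComplex("1", "Zn", pKa=8.0)
cond = AssayConditions()                      # post-mix: 16.9 mM CO2, pH 9.0
q = estimate_buffer_factor(cond)              # Q = 0.0450 M per AU
traces = generate_assay_set(zn, 645.7, noise_sd=0.002, seed=17)
rates = {(c, r): fit_initial_rate(t, q) for c, r, t in traces}
fit = fit_kobs(rates, cond.co2_initial)
row = assemble_results(zn, fit, pH=9.0)
print(f"k_obs = {row.k_obs:.1f} ± {row.sigma_obs:.1f}, "
      f"k_ind = {row.k_ind:.1f}, Δk = {row.delta_k:.1f} "
      f"({row.percent_increase:.1f}%)")
```

prints

```
k_obs = 626.6 ± 37.9, k_ind = 689.2, Δk = 62.7 (10.0%)
```

i.e. the chain recovers the generating k_obs = 645.7 M⁻¹s⁻¹ within the
replicate scatter (−3% here; the noiseless chain is accurate to ~0.5%),
and the speciation correction at pH 9 adds 10% for a pKa-8.0 complex —
only 91% of it is present as the active hydroxo form. For the low-pKa
complexes the correction nearly vanishes (pKa 6.0 ⇒ Δk ≈ 0.1%), which is
how one can tell that their slower observed rates reflect a genuinely
slower catalytic cycle (rate-limiting bicarbonate release) rather than a
lack of active species.

The numbered scripts under `analysis/` run the same machinery as a
narrative: `01_simulate_titrations.py` (pKa recovery for all three
presets), `02_simulate_stopped_flow.py` (assay sets; full-conversion
ΔA ≈ 0.41), `03_fit_rate_constants.py` (the rate-constant table), and
`04_mechanism_regimes.py` (the rate-determining-step sweep on the
mechanistic simulator). Each writes its tables under `results/`.

A CLI wraps the same functions:

```bash
camkin titrate simulate --pka 8.0 --out curve.csv
camkin titrate analyze curve.csv
camkin stopflow simulate --kcat 645.7 --catalyst-conc 5e-4 \
    --catalyst-pka 8.0 --out trace.csv
camkin stopflow analyze trace0.csv trace1.csv ... --out rates.json
camkin run --seed 1 --outdir results/
```

## Layout

```
src/camkin/       equilibria, titration, stopped_flow, kinetics, io,
                  pipeline, cli
analysis/         numbered narrative drivers (write tables to results/)
tests/            pytest suite (unit, property, end-to-end recovery)
docs/methods.md   models, assumptions, parameter choices, limitations
```
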