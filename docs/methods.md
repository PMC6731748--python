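# Methods

`camkin` simulates and analyses the two measurements that characterise
carbonic-anhydrase-mimicking metal-TPA complexes — potentiometric pKa
titration and stopped-flow CO2-hydration kinetics by the changing-pH-
indicator method — and the arithmetic that turns raw signals into the
pH-independent rate constant k_ind. This note records the models, the
parameters that matter, and the design choices where the design was open.

## Acid–base model

All speciation is concentration-based (activity coefficients are ignored
even though the emulated experiments run at I = 0.1–0.2 M): the constants
being reproduced are mixed, concentration-scale constants measured at fixed
ionic strength, and no activity model for them is available. pKw = 14.00 at
25 °C.

The aqua complex is treated as a simple monoprotic weak acid
LM-OH₂ ⇌ LM-OH⁻ + H⁺; hydrolysis side-products and dimerisation are
excluded (the tetradentate N4 ligand leaves a single exchangeable site and
disfavours dimerisation). The hydroxo fraction is
f(pKa, pH) = 1/(1 + 10^(pKa−pH)), and the pH-independent rate constant is
k_ind = k_obs / f — the observed constant re-expressed per active hydroxo
complex.

The shared charge-balance solver finds the unique pH with
[Na⁺] + [H⁺] = [OH⁻] + [X⁻] + Σ[A⁻] by bisection on [0.5, 13.5]
(residual tolerance 10⁻¹² M). The residual is strictly decreasing in pH, so
bisection is unconditionally convergent; the stopped-flow simulator uses a
warm-started Newton iteration on the same residual (fallback: bisection)
because it solves the balance tens of thousands of times per trace.

Two pKa-to-complex assignments ship as presets because the reference data
are internally inconsistent (the titration table and the rate table imply
different Cu/Ni assignments); `table3_consistent` (Zn 8.0, Cu 6.0, Ni 7.6)
is the one under which the k_obs → k_ind arithmetic is exact and is the
default everywhere.

## Titration simulation and pKa recovery

Conditions: 1.0 mM complex + 2.0 mM HNO₃ in 50 mL, titrated with 0.1 M
NaOH; 300 points over 0–2.5 mL (the source protocol states no grid, so the
density is a package choice that puts ~60 points across each buffering
region). At each titrant volume the diluted totals enter the charge balance
exactly; optional Gaussian pH noise (default 0) models electrode read-out
scatter. Electrode calibration is assumed already applied.

Equivalence points are maxima of the 5-point-smoothed central-difference
derivative dpH/dV, refined by parabolic interpolation and accepted above a
prominence floor of 1% of the derivative span — low enough to keep the
genuine but small first-equivalence peak of a pKa-5 analyte, high enough to
reject smoothing ripple. The pKa is the pH interpolated at the midpoint of
the two equivalence volumes (half-equivalence identity).

Limitation: at 1 mM analyte the method resolves pKa ≈ 5.0–9.0 (noiseless
recovery within ±0.05 across that grid). For pKa ≥ 9.5 the buffering region
merges with the equivalence jump — dpH/dV becomes monotone through the
stoichiometric equivalence volume and no half-equivalence point exists; the
package raises an explicit "unresolved curve" error rather than guessing.

## Stopped-flow trace model

Post-mixing convention: every concentration in `AssayConditions` is after
the 1:1 mix (16.9 mM CO2, 0.05 M AMPSO, 2.5×10⁻⁵ M thymol blue, pH 9.0);
the CLI accepts pre-mix values behind an explicit `--premix` flag.

Proton bookkeeping. Each hydration event releases exactly one proton into
the buffer/indicator pool (bicarbonate is treated as a spectator at pH
8.3–9.0, where re-equilibration toward carbonate or carbonic acid is
negligible on the assay timescale). Protonation equilibria are treated as
instantaneous relative to hydration — the protonation steps are
diffusion-limited — so the pool pH is an algebraic function of the
cumulative acid, solved from the same charge balance at every integrator
evaluation. The pool's sodium background is calibrated in closed form so
that zero added acid reproduces the stated initial pH exactly.

Optics. Only the basic transition of thymol blue matters at pH 8–9:
indicator pKa 8.9, ε_basic = 4.6×10⁴ M⁻¹cm⁻¹, ε_acidic = 1×10³ M⁻¹cm⁻¹ at
596 nm, 1 cm path. The source gives the indicator identity and wavelength
but no optical constants; these values were calibrated once so that a
full-conversion run changes the absorbance by ≈ 0.41, the reported
amplitude, and are config-overridable.

Background kinetics. k_uncat = 0.037 s⁻¹ (CO2 + H2O) and
k_oh = 8.5×10³ M⁻¹s⁻¹ (CO2 + OH⁻) at 25 °C — literature-typical values,
overridable; the emulated study measures but never prints its uncatalysed
rate, which the analysis chain treats as a regression intercept anyway.

Phenomenological mode integrates d[CO2]/dt = −k_tot(pH)·[CO2] with

    k_tot = k_uncat + k_oh[OH⁻] + k_cat·[cat]·f(pKa, pH)/f(pKa, pH₀)

by fixed-step RK4 (dt = 0.01 s) with a guard that aborts if a step consumes
more than 5% of the remaining CO2. The normalisation of the speciation
factor by its initial-pH value makes k_cat exactly the observed second-order
constant at the nominal assay pH — the quantity the slope analysis defines
and recovers — while the ratio still throttles the catalysis as the pH
falls and the hydroxo pool shrinks. An unnormalised f would silently
redefine k_cat as the per-hydroxo constant and build a ~9% bias (for
pKa 8 at pH 9) into every recovery comparison.

Mechanistic mode integrates mass-action kinetics of the explicit cycle
(deprotonation k_a / reprotonation constrained by detailed balance
k_deprot/k_reprot = Ka, CO2 addition k_co2, bicarbonate release k_release)
plus the same background. Because realistic reprotonation sits near the
diffusion limit (k_reprot ≈ 10¹² M⁻¹s⁻¹ for pKa 8), the system is stiff and
is integrated with an implicit solver (Radau, rtol 10⁻⁹); fixed-step
explicit integration is not usable in exactly the fast-cycle regime the
cross-checks need. Catalyst and carbon conservation are enforced
structurally: LM-OH₂ and released bicarbonate are reconstructed from the
integrated states, so the ≤10⁻¹² M conservation checks hold by construction
of the mass-conserving formulation. The steady-state flux of the cycle,

    k_eff = k_co2 / ((k_reprot[H⁺] + k_co2[CO2])/k_deprot + 1 + k_co2[CO2]/k_release),

serves as an independent algebraic oracle: in the fast-cycle limit the
simulated trace matches it (and the phenomenological mode) within 2%.

Noise: i.i.d. Gaussian on the absorbance, added last, seeded. Replicates in
an assay set share the deterministic trajectory and differ only in their
noise draws, so a zero-noise set has bit-identical replicates. Defaults for
a rate assay: catalyst series {0, 0.1, 0.25, 0.5 mM} × 4 replicates,
noise 0.002 AU — series and noise level are package choices (the emulated
protocol states "measured four times" but not the series or the instrument
noise), picked as a realistic span of the linear regime and a typical
stopped-flow photometric scatter. Trace length 150 s at dt 0.01 s lets the
slowest (uncatalysed) run reach its plateau.

## Inference chain

Buffer factor. Q (mol H⁺ per absorbance unit) is the least-squares slope of
added [HCl] vs the absorbance drop of the buffer/indicator mix, through the
measured zero point; default additions 0.1–0.5 mM span well under 20% of
the buffer capacity so the secant tracks the derivative dH/dA at the
working pH (verified against a finite-difference oracle to 2%).

Initial rate. A_e is the mean of the final 5% of points (the analysis
treats A_e as known rather than free-floating, matching the v_int
equation); A₀ is the first point. The fit window is the initial stretch
covering the first 10% of the total absorbance change — the fractional
definition transfers across rate regimes, while a `window_seconds` override
reproduces a fixed-10 s reading. The decay constant is the OLS slope of
ln(A−A_e) vs t over the window, and v_int = Q·(A₀−A_e)·b.

k_obs. Per replicate, the OLS slope of v_int/[CO2] against catalyst
concentration; k_obs is the mean of the replicate slopes and σ_obs their
sample standard deviation (n−1). The uncatalysed rate is the intercept (no
pre-subtraction). v_int/[CO2] uses the post-mixing initial CO2 (16.9 mM)
throughout: the initial-rate window consumes under 10% of it. Replicate-wise
slopes, rather than pooled OLS, define σ_obs so that four replicate
measurements yield one standard deviation per complex.

## What the synthetic data do and do not show

The generator reproduces the arithmetic and signal shapes of the emulated
experiments: buffering and dilution during titration, the optical response
of a one-indicator system, pH-dependent background and catalyst speciation
during a trace, replicate noise. It does not model instrument dead time,
photobleaching, CO2 outgassing, temperature drift, electrode drift, or
activity effects. Passing recovery tests therefore demonstrates that the
inference chain is unbiased for the model's own signal class (within ~0.5%
noiseless, ~2% at 0.002 AU noise), not that real instruments are free of
systematic error. Reported σ_obs values from real replicates depend on
instrument noise that is not printed anywhere, and are not reproducible;
the package makes no attempt to match them.

## Numerical summary

| quantity | value | note |
|---|---|---|
| Henry constant (25 °C) | 3.38×10⁻² M atm⁻¹ | fixed so 1 atm ⇒ 33.8 mM |
| pKw | 14.00 | overridable |
| charge-balance tolerance | 10⁻¹² M residual | bisection, bracket [0.5, 13.5] |
| titration grid | 300 pts / 2.5 mL | ≈8.4 µL per step |
| RK4 step | 0.01 s | 5%-per-step CO2 guard |
| stiff solver | Radau, rtol 10⁻⁹, atol 10⁻¹⁴ | mechanistic mode |
| noiseless k_obs recovery bias | ≈ −0.5% | pH drift across the 10% window |
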