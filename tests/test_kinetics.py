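"""Buffer factor, initial-rate extraction and the k_obs slope fit."""

import numpy as np
import pytest

from camkin.equilibria import AquaComplex
from camkin.kinetics import (
    BufferFactor,
    InitialRateResult,
    assemble_results,
    estimate_buffer_factor,
    fit_initial_rate,
    fit_kobs,
)
from camkin.stopped_flow import AbsorbanceTrace, AssayConditions, ProtonPool


def exponential_trace(a0=0.65, ae=0.24, b=0.05, duration=150.0, dt=0.1):
    t = np.arange(0.0, duration + dt / 2, dt)
    return AbsorbanceTrace(t, ae + (a0 - ae) * np.exp(-b * t))


class TestBufferFactor:
    def test_matches_finite_difference_oracle(self, default_conditions):
        """Q must equal d[H+]_total/dA of the pool at the working pH."""
        pool = ProtonPool(default_conditions)
        eps = 1e-6
        dh = 2 * eps
        da = pool.absorbance(pool.pH(0.0)) - pool.absorbance(pool.pH(dh))
        oracle = dh / da
        q = estimate_buffer_factor(default_conditions)
        assert q.Q == pytest.approx(oracle, rel=0.02)
        assert q.fit_r_squared > 0.999

    def test_optical_scaling_halves_q(self, default_conditions):
        from dataclasses import replace

        doubled = replace(
            default_conditions,
            epsilon_basic=2 * default_conditions.epsilon_basic,
            epsilon_acidic=2 * default_conditions.epsilon_acidic,
        )
        q1 = estimate_buffer_factor(default_conditions)
        q2 = estimate_buffer_factor(doubled)
        assert q2.Q == pytest.approx(q1.Q / 2, rel=1e-6)

    def test_zero_indicator_is_an_error(self, default_conditions):
        from dataclasses import replace

        with pytest.raises(ValueError):
            estimate_buffer_factor(replace(default_conditions, indicator_total=0.0))

    def test_needs_three_additions(self, default_conditions):
        with pytest.raises(ValueError):
            estimate_buffer_factor(default_conditions, hcl_additions=[1e-4, 2e-4])


class TestInitialRate:
    def test_closed_form_exponential(self):
        """v_int = Q (A0 - Ae) b for an exact single exponential."""
        trace = exponential_trace(a0=0.65, ae=0.24, b=0.05)
        res = fit_initial_rate(trace, 2.0e-3)
        assert res.decay_constant == pytest.approx(0.05, rel=1e-3)
        assert res.v_int == pytest.approx(2.0e-3 * 0.41 * 0.05, rel=2e-3)
        assert res.A0 == pytest.approx(0.65)
        assert res.Ae == pytest.approx(0.24, abs=1e-3)

    def test_window_covers_first_ten_percent(self):
        trace = exponential_trace(b=0.05, dt=0.01)
        res = fit_initial_rate(trace, 1.0)
        # 10% conversion of an exponential happens at t = -ln(0.9)/b
        assert res.window_end == pytest.approx(-np.log(0.9) / 0.05, rel=0.05)

    def test_window_seconds_override(self):
        trace = exponential_trace(b=0.05, dt=0.01)
        res = fit_initial_rate(trace, 1.0, window_seconds=10.0)
        assert res.window_end == pytest.approx(10.0, abs=0.02)

    def test_flat_trace_is_an_error(self):
        t = np.arange(0.0, 100.0, 0.1)
        flat = AbsorbanceTrace(t, np.full_like(t, 0.5))
        with pytest.raises(ValueError):
            fit_initial_rate(flat, 1.0)

    def test_recovers_simulator_initial_log_slope(self, default_conditions):
        """Noiseless simulated trace: fitted decay within 3% of the analytic
        initial log-slope of A - Ae.

        -d ln(A - Ae)/dt at t=0 equals (dA/dH) k_tot [CO2]_0 / (A0 - Ae),
        with dA/dH the finite-difference optical response of the pool at the
        starting pH and k_tot the generating first-order constant.
        """
        from camkin.stopped_flow import simulate_trace_phenomenological

        cond = AssayConditions(catalyst_conc=2.5e-4, catalyst_pKa=8.0)
        trace = simulate_trace_phenomenological(cond, 645.7, 150.0, 0.01)
        oh = 10.0 ** (9.0 - 14.0)
        k_tot = cond.k_uncat + cond.k_oh * oh + 645.7 * 2.5e-4
        pool = ProtonPool(cond)
        eps = 1e-7
        dadh = (pool.absorbance(pool.pH(0.0)) - pool.absorbance(pool.pH(eps))) / eps
        n_tail = max(int(round(0.05 * trace.absorbance.size)), 1)
        a_e = trace.absorbance[-n_tail:].mean()
        b_true = dadh * k_tot * cond.co2_initial / (trace.absorbance[0] - a_e)
        res = fit_initial_rate(trace, 1.0)
        assert res.decay_constant == pytest.approx(b_true, rel=0.03)


class TestKobsFit:
    @staticmethod
    def rates_from_line(slope, intercept, concs, reps, co2, jitter=None):
        rates = {}
        for rep in range(reps):
            for c in concs:
                v = (intercept + slope * c) * co2
                if jitter is not None:
                    v *= 1 + jitter[(c, rep)]
                rates[(c, rep)] = InitialRateResult(
                    v_int=v, A0=0.65, Ae=0.24, decay_constant=0.1,
                    window_end=1.0, fit_rms=0.0, n_window_points=10,
                )
        return rates

    def test_exact_line_recovered(self):
        concs = [0.0, 1e-4, 2.5e-4, 5e-4]
        rates = self.rates_from_line(645.7, 0.03, concs, 1, 0.0169)
        fit = fit_kobs(rates, 0.0169)
        assert fit.k_obs == pytest.approx(645.7, rel=1e-10)
        assert fit.intercept == pytest.approx(0.03, rel=1e-8)

    def test_identical_replicates_zero_sigma(self):
        concs = [0.0, 1e-4, 2.5e-4, 5e-4]
        rates = self.rates_from_line(645.7, 0.03, concs, 4, 0.0169)
        fit = fit_kobs(rates, 0.0169)
        assert fit.sigma_obs == 0.0
        assert len(fit.replicate_slopes) == 4

    def test_single_concentration_rejected(self):
        rates = self.rates_from_line(645.7, 0.03, [1e-4], 4, 0.0169)
        with pytest.raises(ValueError):
            fit_kobs(rates, 0.0169)

    def test_order_invariance(self):
        concs = [0.0, 1e-4, 2.5e-4, 5e-4]
        jit = {(c, r): 0.01 * np.sin(i) for i, (c, r) in
               enumerate((c, r) for r in range(2) for c in concs)}
        rates = self.rates_from_line(600.0, 0.05, concs, 2, 0.0169, jitter=jit)
        shuffled = dict(reversed(list(rates.items())))
        a = fit_kobs(rates, 0.0169)
        b = fit_kobs(shuffled, 0.0169)
        assert a.k_obs == pytest.approx(b.k_obs, rel=1e-12)
        assert a.sigma_obs == pytest.approx(b.sigma_obs, rel=1e-9)


class TestAssembleResults:
    @pytest.mark.parametrize(
        "k_obs, pKa, k_ind_expected, dk_expected",
        [
            (645.7, 8.0, 710.3, 64.6),
            (526.4, 6.0, 527.0, 0.6),
            (542.3, 7.6, 563.9, 21.6),
        ],
    )
    def test_rate_table_rows(self, k_obs, pKa, k_ind_expected, dk_expected):
        cpx = AquaComplex("x", "Zn", pKa)
        from camkin.kinetics import KobsFit

        fit = KobsFit(k_obs, 0.0, 1.0, 0.0169, (), (k_obs,))
        row = assemble_results(cpx, fit, pH=9.0)
        # printed reference values carry one-decimal rounding
        assert row.k_ind == pytest.approx(k_ind_expected, abs=0.1)
        assert row.delta_k == pytest.approx(dk_expected, abs=0.1)

    def test_low_pKa_limit_no_correction(self):
        from camkin.kinetics import KobsFit

        cpx = AquaComplex("x", "Zn", 0.5)
        fit = KobsFit(500.0, 0.0, 0.0, 0.0169, (), (500.0,))
        row = assemble_results(cpx, fit, pH=9.0)
        assert row.k_ind == pytest.approx(500.0, rel=1e-6)
        assert row.delta_k == pytest.approx(0.0, abs=1e-3)


class TestEndToEndRecovery:
    """The full chain Q -> v_int -> slope on synthetic assay sets."""

    def _recover(self, noise_sd, seed=11):
        from camkin.stopped_flow import generate_assay_set

        cpx = AquaComplex("1", "Zn", 8.0)
        cond = AssayConditions()
        q = estimate_buffer_factor(cond)
        traces = generate_assay_set(cpx, 645.7, noise_sd=noise_sd, seed=seed,
                                    conditions=cond)
        rates = {(c, r): fit_initial_rate(tr, q) for c, r, tr in traces}
        return fit_kobs(rates, cond.co2_initial)

    def test_noiseless_recovery_within_one_percent(self):
        fit = self._recover(0.0)
        assert fit.k_obs == pytest.approx(645.7, rel=0.01)
        assert fit.sigma_obs == 0.0

    def test_noisy_recovery_within_five_percent(self):
        fit = self._recover(0.002)
        assert fit.k_obs == pytest.approx(645.7, rel=0.05)
        assert fit.sigma_obs > 0.0

    def test_sigma_shrinks_with_noise(self):
        hi = self._recover(0.004).sigma_obs
        lo = self._recover(0.001).sigma_obs
        assert lo < hi

    def test_vint_invariant_under_affine_absorbance_rescaling(self):
        """Rescaling A -> alpha A + beta rescales Q by 1/alpha, leaving
        v_int unchanged."""
        from dataclasses import replace
        from camkin.stopped_flow import simulate_trace_phenomenological

        cond = AssayConditions(catalyst_conc=2.5e-4, catalyst_pKa=8.0)
        trace = simulate_trace_phenomenological(cond, 645.7, 150.0, 0.01)
        q = estimate_buffer_factor(cond)
        res = fit_initial_rate(trace, q)

        alpha, beta = 2.5, 0.1
        scaled_cond = replace(
            cond,
            epsilon_basic=alpha * cond.epsilon_basic
            + beta / (cond.path_length * cond.indicator_total),
            epsilon_acidic=alpha * cond.epsilon_acidic
            + beta / (cond.path_length * cond.indicator_total),
        )
        scaled_trace = AbsorbanceTrace(
            trace.times, alpha * trace.absorbance + beta, scaled_cond
        )
        q_scaled = estimate_buffer_factor(scaled_cond)
        res_scaled = fit_initial_rate(scaled_trace, q_scaled)
        assert res_scaled.v_int == pytest.approx(res.v_int, rel=1e-6)
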