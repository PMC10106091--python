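"""Channel-model unit and property tests."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from navblock.channel import (
    ChannelState,
    analytic_block_time_course,
    equilibrium_state,
    evolve_constant_v,
    inactivation_drive,
    integrate_gating,
    messenger_level,
    mode_transition_rates,
    sodium_current,
    steady_state_gates,
)
from navblock.params import CouplingParams, GatingParams, ModifiedModeParams


@pytest.fixture
def p():
    return GatingParams()


@pytest.fixture
def mp():
    return ModifiedModeParams()


@pytest.fixture
def cp():
    return CouplingParams()


class TestSteadyStateGates:
    def test_availability_midpoint(self, p):
        g = steady_state_gates(p.h_V05, p, "normal")
        assert g.h_inf == pytest.approx(0.5, abs=1e-12)

    def test_modified_midpoint_shifted(self, p, mp):
        # -65 mV control midpoint moves to -98 mV in the modified mode
        g = steady_state_gates(p.h_V05 + mp.delta_V05, p, "modified", mp)
        assert g.h_inf == pytest.approx(0.5, abs=1e-12)
        assert p.h_V05 + mp.delta_V05 == -98.0

    def test_saturation_at_hyperpolarized(self, p):
        assert steady_state_gates(-140.0, p, "normal").h_inf == pytest.approx(1.0, abs=1e-6)

    def test_modified_recovery_slowed(self, p, mp):
        gn = steady_state_gates(-120.0, p, "normal")
        gm = steady_state_gates(-120.0, p, "modified", mp)
        assert gm.tau_h_recovery == pytest.approx(gn.tau_h_recovery * mp.rec_slow_factor)
        assert gm.tau_h_entry == pytest.approx(gn.tau_h_entry)

    def test_rejects_bad_input(self, p, mp):
        with pytest.raises(ValueError):
            steady_state_gates(float("nan"), p)
        with pytest.raises(ValueError):
            steady_state_gates(-80.0, p, "latched")
        with pytest.raises(ValueError):
            steady_state_gates(-80.0, p, "modified")  # missing mp

    @given(V=st.floats(-140, 40))
    def test_gate_ranges(self, V):
        p, mp = GatingParams(), ModifiedModeParams()
        gn = steady_state_gates(V, p, "normal")
        gm = steady_state_gates(V, p, "modified", mp)
        for g in (gn, gm):
            assert 0.0 <= g.m_inf <= 1.0 and 0.0 <= g.h_inf <= 1.0
            assert g.tau_m > 0 and g.tau_h_entry > 0 and g.tau_s > 0
        # stabilized inactivation: modified mode is never more available
        assert gm.h_inf <= gn.h_inf + 1e-12


class TestIntegration:
    def test_matches_closed_form_relaxation(self, p, mp, cp):
        init = equilibrium_state(-120.0, p, mp)
        traj = integrate_gating([(-60.0, 50.0)], p, mp, cp, init, dt=0.01)
        g = steady_state_gates(-60.0, p, "normal")
        expected = g.h_inf + (init.h_n - g.h_inf) * np.exp(-traj["t_ms"] / g.tau_h_entry)
        assert np.max(np.abs(traj["h_n"] - expected)) < 1e-6

    def test_frozen_modes_when_rates_zero(self, p, mp):
        cp0 = CouplingParams(k_mod=0.0)
        mp0 = mp.model_copy(update=dict(unlatch_rate_max=0.0))
        init = ChannelState(x_mod=0.37)
        traj = integrate_gating([(-80.0, 10.0), (-10.0, 10.0)], p, mp0, cp0,
                                init, dt=0.02, drug_onset_s=0.0, conc=10.0)
        assert np.allclose(traj["x_mod"], 0.37)

    def test_step_inactivates_within_30ms(self, p, mp, cp):
        init = equilibrium_state(-80.0, p, mp)
        traj = integrate_gating([(-10.0, 30.0)], p, mp, cp, init, dt=0.02)
        i = traj["i_pA"]
        peak_idx = np.argmin(i)
        assert i[peak_idx] < 0  # inward
        assert abs(i[-1]) < 0.05 * abs(i[peak_idx])  # decayed by end of step

    def test_refuses_coarse_dt(self, p, mp, cp):
        with pytest.raises(ValueError, match="dt"):
            integrate_gating([(-10.0, 5.0)], p, mp, cp, ChannelState(), dt=5.0)

    def test_occupancy_conservation(self, p, mp, cp):
        st_ = equilibrium_state(-80.0, p, mp, x_mod=0.2)
        for k in range(40):  # 1000 s of holding with drug
            st_ = evolve_constant_v(st_, -80.0, 25_000.0, k * 25.0, p, mp, cp,
                                    drug_onset_s=0.0, conc=10.0)
            f_n, f_m = st_.mode_fractions(cp)
            assert abs(f_n + f_m - 1.0) < 1e-9
            assert 0.0 <= st_.x_mod <= 1.0


class TestCurrent:
    def test_reversal(self, p, cp):
        st_ = ChannelState(m_n=0.7, h_n=0.6, s_n=1.0)
        assert sodium_current(st_, p.E_Na, p, cp) == 0.0

    def test_linearity_in_gmax(self, p, mp, cp):
        st_ = equilibrium_state(-80.0, p, mp)
        st_.m_n = 0.8
        p2 = p.model_copy(update=dict(g_max=2 * p.g_max))
        assert sodium_current(st_, -10.0, p2, cp) == pytest.approx(
            2 * sodium_current(st_, -10.0, p, cp))

    def test_modified_mode_residual_below_5pct(self, p, mp, cp):
        # after a long hold at -80 mV the fully modified ensemble passes
        # <= 5% of the control current at -10 mV
        ctl = equilibrium_state(-80.0, p, mp, x_mod=0.0)
        mod = equilibrium_state(-80.0, p, mp, x_mod=1.0)
        drive = np.linspace(0, 1.0, 11)
        # compare at matched activation
        for m in (0.5, 1.0):
            ctl.m_n = ctl.m_m = m
            mod.m_n = mod.m_m = m
            i_ctl = sodium_current(ctl, -10.0, p, cp)
            i_mod = sodium_current(mod, -10.0, p, cp)
            assert abs(i_mod) <= 0.05 * abs(i_ctl)


class TestMessengerAndRates:
    def test_zero_concentration(self, cp):
        assert messenger_level(100.0, 0.0, 0.0, cp) == 0.0

    def test_hill_midpoint(self, cp):
        assert cp.eta(cp.K_half) == pytest.approx(0.5)

    def test_negative_concentration_rejected(self, cp):
        with pytest.raises(ValueError):
            messenger_level(1.0, 0.0, -1.0, cp)

    def test_no_messenger_no_modification(self, p, mp, cp):
        lam, _ = mode_transition_rates(ChannelState(), -80.0, 0.0, cp, mp)
        assert lam == 0.0

    def test_drive_increases_with_depolarized_holding(self, p, cp):
        drives = []
        for vh in (-60.0, -80.0, -100.0):
            g = steady_state_gates(vh, p, "normal")
            drives.append(inactivation_drive(g.h_inf, g.s_inf, cp))
        assert drives[0] > drives[1] > drives[2]

    def test_unlatch_voltage_dependence(self, mp, cp):
        st_ = ChannelState()
        _, mu120 = mode_transition_rates(st_, -120.0, 0.0, cp, mp)
        _, mu80 = mode_transition_rates(st_, -80.0, 0.0, cp, mp)
        assert mu120 >= 50 * mu80

    def test_gaussian_decay_closed_form(self, p, mp):
        # with a constant drive the modified fraction follows
        # 1 - exp(-(t/tau)^2) with tau = sqrt(2/(k*r*eta*D))
        cp = CouplingParams(w_fast=0.0, w_slow=0.0, d0=0.3, k_mod=0.1)
        st_ = equilibrium_state(-80.0, p, mp)
        mp0 = mp.model_copy(update=dict(unlatch_rate_max=0.0))
        eta = cp.eta(10.0)
        tau = math.sqrt(2.0 / (cp.k_mod * cp.ramp_rate * eta * 0.3))
        t = 0.0
        for _ in range(20):
            st_ = evolve_constant_v(st_, -80.0, 25_000.0, t, p, mp0, cp,
                                    drug_onset_s=0.0, conc=10.0,
                                    max_substep_ms=250.0)
            t += 25.0
            expected = 1.0 - math.exp(-((t / tau) ** 2))
            assert st_.x_mod == pytest.approx(expected, abs=1e-4)


class TestAnalyticEnvelope:
    def test_no_drug_limit(self, p, mp, cp):
        A, B, tau = analytic_block_time_course(cp, -80.0, p, mp, conc=0.0)
        assert (A, B) == (0.0, 1.0)

    def test_zero_drive_flagged_infinite(self, p, mp):
        cp = CouplingParams(k_mod=0.0)
        _, _, tau = analytic_block_time_course(cp, -80.0, p, mp)
        assert math.isinf(tau) and not math.isnan(tau)

    def test_tau_scales_inverse_sqrt_drive(self, p, mp):
        cp1 = CouplingParams(w_fast=0.0, w_slow=0.0, d0=0.1)
        cp4 = CouplingParams(w_fast=0.0, w_slow=0.0, d0=0.4)
        _, _, t1 = analytic_block_time_course(cp1, -80.0, p, mp)
        _, _, t4 = analytic_block_time_course(cp4, -80.0, p, mp)
        assert t1 == pytest.approx(2 * t4, rel=1e-12)

    def test_amplitudes_sum_to_baseline(self, p, mp, cp):
        A, B, _ = analytic_block_time_course(cp, -80.0, p, mp)
        assert A + B == pytest.approx(1.0)
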