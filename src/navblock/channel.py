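"""Two-mode sodium-channel forward model.

The ensemble is split into a *normal* gating mode and a drug-*modified*
mode in which fast inactivation is stabilized (availability shifted
negative, recovery from inactivation slowed).  A fraction ``p_resistant``
of channels can never be modified.  Mode occupancy evolves by

    d f_mod/dt = lambda * (1 - f_mod) - mu * f_mod

on the modifiable pool, with ``lambda = k_mod * M * D`` driven by the
messenger level M and the inactivated-state drive D, and a voltage-gated
unlatch rate ``mu``.  Because M ramps linearly after drug onset, the
surviving normal fraction decays as exp(-(t/tau)^2) whenever D is
constant — the Gaussian-in-time envelope the diary analysis fits.

Within a constant-voltage segment every gate relaxes exponentially, so
integration uses exact exponential updates for the gates and short
sub-steps (trapezoidal accumulation of lambda) for the mode fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .params import (
    CouplingParams,
    GatingParams,
    ModifiedModeParams,
    require_finite,
)

__all__ = [
    "ChannelState",
    "GateSteadyState",
    "steady_state_gates",
    "sodium_current",
    "messenger_level",
    "mode_transition_rates",
    "analytic_block_time_course",
    "integrate_gating",
    "equilibrium_state",
]


@dataclass
class ChannelState:
    """Instantaneous state of the channel ensemble.

    Gates are kept per mode; ``x_mod`` is the fraction of the *modifiable*
    pool in the modified mode, so total mode occupancies are
    ``f_modified = (1 - p_resistant) * x_mod`` and
    ``f_normal = 1 - f_modified`` (resistant channels gate normally).
    """

    m_n: float = 0.0
    h_n: float = 1.0
    s_n: float = 1.0
    m_m: float = 0.0
    h_m: float = 1.0
    s_m: float = 1.0
    x_mod: float = 0.0
    M: float = 0.0  # messenger level (Mu), informational

    def mode_fractions(self, cp: CouplingParams) -> tuple[float, float]:
        f_mod = (1.0 - cp.p_resistant) * self.x_mod
        return 1.0 - f_mod, f_mod

    def copy(self) -> "ChannelState":
        return replace(self)


@dataclass(frozen=True)
class GateSteadyState:
    m_inf: float
    tau_m: float
    h_inf: float
    tau_h_entry: float
    tau_h_recovery: float
    s_inf: float
    tau_s: float


def steady_state_gates(V: float, p: GatingParams, mode: str = "normal",
                       mp: ModifiedModeParams | None = None) -> GateSteadyState:
    """Steady states and time constants of every gate at voltage ``V``.

    ``mode`` is ``"normal"`` or ``"modified"``.  In the modified mode the
    availability curve is shifted by ``delta_V05`` and the recovery
    branch of the fast-inactivation time constant (h rising) is slowed by
    ``rec_slow_factor``; entry into inactivation is unchanged.
    """
    V = require_finite("V", V)
    if mode not in ("normal", "modified"):
        raise ValueError(f"unknown gating mode {mode!r}")
    if mode == "modified" and mp is None:
        raise ValueError("modified mode requires ModifiedModeParams")
    h_V05 = p.h_V05 + (mp.delta_V05 if mode == "modified" else 0.0)
    h_inf = 1.0 / (1.0 + math.exp((V - h_V05) / p.h_k))
    tau_h = float(p.tau_h(V))
    rec = tau_h * (mp.rec_slow_factor if mode == "modified" else 1.0)
    return GateSteadyState(
        m_inf=float(p.m_inf(V)),
        tau_m=float(p.tau_m(V)),
        h_inf=h_inf,
        tau_h_entry=tau_h,
        tau_h_recovery=rec,
        s_inf=float(p.s_inf(V)),
        tau_s=float(p.tau_s(V)),
    )


def sodium_current(state: ChannelState, V: float, p: GatingParams,
                   cp: CouplingParams | None = None) -> float:
    """Instantaneous sodium current (pA); inward is negative below E_Na."""
    cp = cp or CouplingParams()
    f_norm, f_mod = state.mode_fractions(cp)
    g_open = p.g_max * (
        f_norm * state.m_n ** 3 * state.h_n * state.s_n
        + f_mod * state.m_m ** 3 * state.h_m * state.s_m
    )
    return g_open * (V - p.E_Na)


def messenger_level(t: float, drug_onset: float, conc: float, cp: CouplingParams) -> float:
    """Messenger level at absolute time ``t`` (s): linear ramp after onset."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if conc < 0:
        raise ValueError("negative concentration")
    return cp.ramp_rate * cp.eta(conc) * max(0.0, t - drug_onset)


def inactivation_drive(h: float, s: float, cp: CouplingParams) -> float:
    """Drive D = d0 + w_fast*(1-h) + w_slow*(1-s), clipped to [0, 1]."""
    D = cp.d0 + cp.w_fast * (1.0 - h) + cp.w_slow * (1.0 - s)
    return min(1.0, max(0.0, D))


def mode_transition_rates(state: ChannelState, V: float, M: float,
                          cp: CouplingParams, mp: ModifiedModeParams) -> tuple[float, float]:
    """(lambda, mu): normal->modified and modified->normal rates (1/s)."""
    D = inactivation_drive(state.h_n, state.s_n, cp)
    lam = cp.k_mod * M * D
    mu = mp.unlatch_rate_max / (1.0 + math.exp((V - mp.unlatch_V05) / mp.unlatch_k))
    return lam, mu


def analytic_block_time_course(cp: CouplingParams, Vh: float, p: GatingParams,
                               mp: ModifiedModeParams, conc: float = 10.0,
                               residual_conductance: float | None = None,
                               D: float | None = None) -> tuple[float, float, float]:
    """Predicted (A, B, tau) of the Gaussian-time diary envelope.

    With a constant drive D at the holding potential and a linear
    messenger ramp, the normal-mode survivor fraction is
    exp(-(t/tau)^2) with ``tau = sqrt(2 / (k_mod*ramp_rate*eta*D))``.
    The plateau B collects the resistant fraction plus the residual
    availability of modified channels at the holding potential; A + B
    equals the pre-drug normalized amplitude (1).
    """
    gn = steady_state_gates(Vh, p, "normal")
    gm = steady_state_gates(Vh, p, "modified", mp)
    if D is None:
        D = inactivation_drive(gn.h_inf, gn.s_inf, cp)
    if residual_conductance is None:
        residual_conductance = gm.h_inf / gn.h_inf if gn.h_inf > 0 else 0.0
    rate = cp.k_mod * cp.ramp_rate * cp.eta(conc) * D
    tau = math.inf if rate <= 0 else math.sqrt(2.0 / rate)
    B = cp.p_resistant + (1.0 - cp.p_resistant) * residual_conductance
    A = 1.0 - B
    if cp.eta(conc) == 0.0:
        A, B = 0.0, 1.0
    return A, B, tau


# ---------------------------------------------------------------------------
# integration


def _relax(x0: float, x_inf: float, tau_ms: float, dt_ms: float) -> float:
    return x_inf + (x0 - x_inf) * math.exp(-dt_ms / tau_ms)


def _h_tau(g: GateSteadyState, h0: float) -> float:
    """Pick entry vs recovery branch of the h time constant."""
    return g.tau_h_recovery if h0 < g.h_inf else g.tau_h_entry


def evolve_constant_v(state: ChannelState, V: float, duration_ms: float,
                      t_abs_s: float, p: GatingParams, mp: ModifiedModeParams,
                      cp: CouplingParams, drug_onset_s: float | None, conc: float,
                      freeze_modes: bool = False,
                      max_substep_ms: float | None = None) -> ChannelState:
    """Advance the state through ``duration_ms`` at constant voltage.

    Gates use exact exponential relaxation; the mode fraction integrates
    lambda by trapezoid over sub-steps short enough to track the gate
    transients (and the messenger ramp on long holds).
    """
    if duration_ms <= 0:
        return state.copy()
    gn = steady_state_gates(V, p, "normal")
    gm = steady_state_gates(V, p, "modified", mp)
    if max_substep_ms is None:
        # resolve gate transients; on long holds the messenger ramp is the
        # only slow driver, 250-ms slices are ample for a per-mille Δf
        max_substep_ms = min(250.0, max(1.0, duration_ms / 8.0))
    n_sub = max(1, int(math.ceil(duration_ms / max_substep_ms)))
    dt = duration_ms / n_sub
    st = state.copy()
    onset = math.inf if drug_onset_s is None else drug_onset_s
    lam_prev, _ = _rates_at(st, V, t_abs_s, onset, conc, cp, mp)
    t_ms = 0.0
    for _ in range(n_sub):
        st.m_n = _relax(st.m_n, gn.m_inf, gn.tau_m, dt)
        st.h_n = _relax(st.h_n, gn.h_inf, _h_tau(gn, st.h_n), dt)
        st.s_n = _relax(st.s_n, gn.s_inf, gn.tau_s, dt)
        st.m_m = _relax(st.m_m, gm.m_inf, gm.tau_m, dt)
        st.h_m = _relax(st.h_m, gm.h_inf, _h_tau(gm, st.h_m), dt)
        st.s_m = _relax(st.s_m, gm.s_inf, gm.tau_s, dt)
        t_ms += dt
        lam, mu = _rates_at(st, V, t_abs_s + t_ms * 1e-3, onset, conc, cp, mp)
        if not freeze_modes:
            lam_eff = 0.5 * (lam_prev + lam)
            k = lam_eff + mu
            if k > 0:
                x_inf = lam_eff / k
                st.x_mod = x_inf + (st.x_mod - x_inf) * math.exp(-k * dt * 1e-3)
        lam_prev = lam
    st.M = messenger_level(max(t_abs_s + duration_ms * 1e-3, 0.0), onset, conc, cp) \
        if math.isfinite(onset) else 0.0
    return st


def _rates_at(st: ChannelState, V: float, t_s: float, onset: float, conc: float,
              cp: CouplingParams, mp: ModifiedModeParams) -> tuple[float, float]:
    M = 0.0 if not math.isfinite(onset) else messenger_level(max(t_s, 0.0), onset, conc, cp)
    return mode_transition_rates(st, V, M, cp, mp)


def sample_segment(state: ChannelState, V: float, t_grid_ms: np.ndarray,
                   p: GatingParams, mp: ModifiedModeParams, cp: CouplingParams) -> np.ndarray:
    """Closed-form sodium current on ``t_grid_ms`` (offsets from segment
    start) at constant V, *without* advancing mode occupancy.

    Used by the protocol engine to render densely sampled sweeps: mode
    occupancy changes negligibly within a millisecond-scale segment and is
    advanced separately by :func:`evolve_constant_v`.
    """
    gn = steady_state_gates(V, p, "normal")
    gm = steady_state_gates(V, p, "modified", mp)
    t = np.asarray(t_grid_ms, float)
    m_n = gn.m_inf + (state.m_n - gn.m_inf) * np.exp(-t / gn.tau_m)
    h_n = gn.h_inf + (state.h_n - gn.h_inf) * np.exp(-t / _h_tau(gn, state.h_n))
    s_n = gn.s_inf + (state.s_n - gn.s_inf) * np.exp(-t / gn.tau_s)
    m_m = gm.m_inf + (state.m_m - gm.m_inf) * np.exp(-t / gm.tau_m)
    h_m = gm.h_inf + (state.h_m - gm.h_inf) * np.exp(-t / _h_tau(gm, state.h_m))
    s_m = gm.s_inf + (state.s_m - gm.s_inf) * np.exp(-t / gm.tau_s)
    f_norm, f_mod = state.mode_fractions(cp)
    g_open = p.g_max * (f_norm * m_n ** 3 * h_n * s_n + f_mod * m_m ** 3 * h_m * s_m)
    return g_open * (V - p.E_Na)


def equilibrium_state(V: float, p: GatingParams, mp: ModifiedModeParams,
                      x_mod: float = 0.0) -> ChannelState:
    """Gate steady state at ``V`` with a prescribed mode mixture."""
    gn = steady_state_gates(V, p, "normal")
    gm = steady_state_gates(V, p, "modified", mp)
    return ChannelState(m_n=gn.m_inf, h_n=gn.h_inf, s_n=gn.s_inf,
                       m_m=gm.m_inf, h_m=gm.h_inf, s_m=gm.s_inf,
                       x_mod=x_mod)


def integrate_gating(waveform: Sequence[tuple[float, float]], p: GatingParams,
                     mp: ModifiedModeParams, cp: CouplingParams,
                     init: ChannelState, dt: float,
                     t0_s: float = 0.0, drug_onset_s: float | None = None,
                     conc: float = 0.0, freeze_modes: bool = False) -> dict:
    """Integrate the gating ODEs over a piecewise-constant voltage command.

    ``waveform`` is a list of ``(level_mV, duration_ms)`` segments; ``dt``
    is the reporting/integration step in ms.  Returns a dict of arrays
    ``t_ms, v_mV, m_n, h_n, s_n, h_m, x_mod, i_pA`` sampled every ``dt``.

    Raises ``ValueError`` when ``dt`` is too coarse to resolve the fastest
    activation time constant encountered (accuracy guard).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for lv, dur in waveform:
        require_finite("segment level", lv)
        if dur <= 0:
            raise ValueError("segment durations must be positive")
        tau_fast = float(p.tau_m(lv))
        if dt > 2.0 * tau_fast:
            raise ValueError(
                f"dt={dt} ms too large for tau_m={tau_fast:.3g} ms at {lv} mV; "
                "reduce dt for a stable/accurate integration"
            )
    st = init.copy()
    rows = {k: [] for k in ("t_ms", "v_mV", "m_n", "h_n", "s_n", "h_m", "x_mod", "i_pA")}
    t_ms = 0.0
    for lv, dur in waveform:
        n = int(round(dur / dt))
        n = max(n, 1)
        for _ in range(n):
            st = evolve_constant_v(st, lv, dt, t0_s + t_ms * 1e-3, p, mp, cp,
                                   drug_onset_s, conc, freeze_modes,
                                   max_substep_ms=dt)
            t_ms += dt
            rows["t_ms"].append(t_ms)
            rows["v_mV"].append(lv)
            rows["m_n"].append(st.m_n)
            rows["h_n"].append(st.h_n)
            rows["s_n"].append(st.s_n)
            rows["h_m"].append(st.h_m)
            rows["x_mod"].append(st.x_mod)
            rows["i_pA"].append(sodium_current(st, lv, p, cp))
    return {k: np.asarray(v) for k, v in rows.items()}
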