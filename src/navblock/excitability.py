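"""Current-clamp simulation and spike analysis.

A single-compartment neuron (capacitance, leak, delayed-rectifier
potassium, and the two-mode sodium channel) is driven with 1-s current
injections from a -80 mV holding potential.  Receptor-mediated block
enters only through the sodium mode mixture computed by the channel
model — there is no separate excitability parameter.  Spikes are
detected from the dV/dt threshold crossing, the standard convention when
counting evoked action potentials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .channel import equilibrium_state, evolve_constant_v
from .params import NeuronParams, ScenarioConfig

__all__ = [
    "SpikeTrain",
    "simulate_current_clamp",
    "detect_spikes",
    "block_state_after_exposure",
    "concentration_response",
]


@dataclass
class SpikeTrain:
    times_ms: np.ndarray
    thresholds_mV: np.ndarray
    peaks_mV: np.ndarray
    injection_pA: float = math.nan

    def __len__(self) -> int:
        return len(self.times_ms)

    @property
    def amplitudes_mV(self) -> np.ndarray:
        """Threshold-to-peak spike amplitudes."""
        return self.peaks_mV - self.thresholds_mV


def simulate_current_clamp(npar: NeuronParams, sc: ScenarioConfig,
                           injections_pA: Sequence[float],
                           duration_ms: float = 1000.0,
                           x_mod: float = 0.0,
                           dt_ms: float = 0.02,
                           pre_ms: float = 50.0,
                           post_ms: float = 50.0) -> tuple[np.ndarray, np.ndarray]:
    """Membrane voltage for a family of square current injections.

    All injections are integrated in parallel (exponential-Euler gates,
    forward-Euler voltage).  ``x_mod`` is the fraction of the modifiable
    sodium-channel pool in the drug-modified mode, held fixed for the
    second-scale injection.  Returns ``(t_ms, V)`` with V of shape
    ``(n_injections, n_samples)``.

    Raises on numerical instability after one step-halving retry.
    """
    inj = np.asarray(injections_pA, float)
    if np.any(np.abs(inj) > 500):
        raise ValueError("injections limited to ±500 pA")
    if not (0.0 <= x_mod <= 1.0):
        raise ValueError("x_mod must lie in [0, 1]")
    p, mp, cp = sc.gating, sc.modified, sc.coupling
    for attempt in range(2):
        dt = dt_ms / (2 ** attempt)
        n_steps = int(round((pre_ms + duration_ms + post_ms) / dt))
        t = np.arange(1, n_steps + 1) * dt
        drive = np.where((t[None, :] > pre_ms) & (t[None, :] <= pre_ms + duration_ms),
                         inj[:, None], 0.0)
        V = np.full(inj.shape, npar.V_rest)
        st0 = equilibrium_state(npar.V_rest, p, mp, x_mod=x_mod)
        m_n = np.full_like(V, st0.m_n); h_n = np.full_like(V, st0.h_n)
        s_n = np.full_like(V, st0.s_n)
        m_m = np.full_like(V, st0.m_m); h_m = np.full_like(V, st0.h_m)
        s_m = np.full_like(V, st0.s_m)
        ng = np.asarray(npar.n_inf(npar.V_rest), float) * np.ones_like(V)
        f_mod = (1.0 - cp.p_resistant) * x_mod
        f_norm = 1.0 - f_mod
        out = np.empty((len(inj), n_steps))
        ok = True
        for k in range(n_steps):
            m_inf = p.m_inf(V); tau_m = p.tau_m(V)
            h_inf_n = p.h_inf(V); tau_h = p.tau_h(V)
            s_inf = p.s_inf(V); tau_s = p.tau_s(V)
            h_inf_m = 1.0 / (1.0 + np.exp((V - p.h_V05 - mp.delta_V05) / p.h_k))
            tau_h_m = np.where(h_m < h_inf_m, tau_h * mp.rec_slow_factor, tau_h)
            m_n = m_inf + (m_n - m_inf) * np.exp(-dt / tau_m)
            h_n = h_inf_n + (h_n - h_inf_n) * np.exp(
                -dt / np.where(h_n < h_inf_n, tau_h, tau_h))
            s_n = s_inf + (s_n - s_inf) * np.exp(-dt / tau_s)
            m_m = m_inf + (m_m - m_inf) * np.exp(-dt / tau_m)
            h_m = h_inf_m + (h_m - h_inf_m) * np.exp(-dt / tau_h_m)
            s_m = s_inf + (s_m - s_inf) * np.exp(-dt / tau_s)
            n_inf = npar.n_inf(V); tau_n = npar.tau_n(V)
            ng = n_inf + (ng - n_inf) * np.exp(-dt / tau_n)
            i_na = npar.g_Na * (f_norm * m_n ** 3 * h_n * s_n
                                + f_mod * m_m ** 3 * h_m * s_m) * (V - p.E_Na)
            i_k = npar.g_K * ng ** 4 * (V - npar.E_K)
            i_leak = npar.g_leak * (V - npar.E_leak)
            V = V + dt * (-(i_na + i_k + i_leak) + drive[:, k]) / npar.C_m
            out[:, k] = V
            if not np.all(np.isfinite(V)) or np.any(np.abs(V) > 500):
                ok = False
                break
        if ok:
            return t, out
    raise RuntimeError("current-clamp integration unstable even after step halving")


def detect_spikes(t_ms: np.ndarray, v_mV: np.ndarray,
                  dvdt_threshold: float = 10.0,
                  min_interval_ms: float = 2.0,
                  injection_pA: float = math.nan) -> SpikeTrain:
    """Threshold-crossing spike detector.

    Threshold is the first sample at which dV/dt exceeds
    ``dvdt_threshold`` (mV/ms) from below; the spike peak is the voltage
    maximum before dV/dt next returns below zero.  A refractory
    ``min_interval_ms`` suppresses double counting.  Invariant to uniform
    voltage offsets and to resampling.
    """
    t = np.asarray(t_ms, float)
    v = np.asarray(v_mV, float)
    if len(t) < 3:
        return SpikeTrain(np.array([]), np.array([]), np.array([]), injection_pA)
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError("spike detection requires uniform sampling")
    dvdt = np.gradient(v, t)
    above = dvdt >= dvdt_threshold
    onsets = np.nonzero(above & ~np.roll(above, 1))[0]
    onsets = onsets[onsets > 0]
    times, thr, peaks = [], [], []
    last = -math.inf
    for i0 in onsets:
        if t[i0] - last < min_interval_ms:
            continue
        # peak: maximum until dV/dt falls below zero (end of upstroke + apex)
        j = i0
        while j + 1 < len(v) and dvdt[j] > 0:
            j += 1
        pk = float(np.max(v[i0:j + 1]))
        if pk - v[i0] < 5.0:       # reject sub-threshold blips
            continue
        times.append(t[i0])
        thr.append(float(v[i0]))
        peaks.append(pk)
        last = t[i0]
    return SpikeTrain(np.asarray(times), np.asarray(thr), np.asarray(peaks),
                      injection_pA)


def block_state_after_exposure(sc: ScenarioConfig, conc_uM: float,
                               exposure_s: float = 500.0) -> float:
    """Modified-mode fraction after a silent agonist exposure at rest.

    Evolves the channel model at the scenario holding potential with the
    drug applied at t=0 and no test pulses, mirroring the current-clamp
    exposure condition, and returns the resulting ``x_mod``.
    """
    st = equilibrium_state(sc.holding_mV, sc.gating, sc.modified)
    if conc_uM == 0:
        return 0.0
    st = evolve_constant_v(st, sc.holding_mV, exposure_s * 1e3, 0.0,
                           sc.gating, sc.modified, sc.coupling,
                           drug_onset_s=0.0, conc=conc_uM,
                           max_substep_ms=250.0)
    return st.x_mod


def concentration_response(npar: NeuronParams, sc: ScenarioConfig,
                           injections_pA: Sequence[float],
                           concentrations_uM: Sequence[float],
                           exposure_s: float = 500.0,
                           dt_ms: float = 0.02) -> pd.DataFrame:
    """Spike counts per (concentration, injection) with in-cell normalization.

    For every concentration the sodium mode mixture after ``exposure_s``
    of agonist at rest is computed first, then the full injection family
    is simulated and spikes are counted.  ``normalized`` divides each
    count by the same-injection count at zero concentration.
    """
    rows = []
    for c in concentrations_uM:
        if c < 0:
            raise ValueError("negative concentration")
        x_mod = block_state_after_exposure(sc, c, exposure_s)
        t, V = simulate_current_clamp(npar, sc, injections_pA, x_mod=x_mod,
                                      dt_ms=dt_ms)
        for inj, v in zip(injections_pA, V):
            st = detect_spikes(t, v, injection_pA=inj)
            rows.append(dict(conc_uM=c, injection_pA=inj, x_mod=x_mod,
                             n_spikes=len(st)))
    df = pd.DataFrame(rows)
    base = df[df.conc_uM == 0].set_index("injection_pA").n_spikes
    df["normalized"] = [
        r.n_spikes / base[r.injection_pA] if base.get(r.injection_pA, 0) else math.nan
        for r in df.itertuples()
    ]
    return df
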