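"""Parameter containers for the sodium-channel block model.

All voltages are in mV, times in ms unless a field name says otherwise
(rates in 1/s, experiment-scale times in s), conductances in nS, currents
in pA, concentrations in µM.  Containers are pydantic models so that
scenario files (JSON) are validated on load and invalid physiology is
rejected early.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "GatingParams",
    "ModifiedModeParams",
    "CouplingParams",
    "NoiseLeakParams",
    "NeuronParams",
    "ScenarioConfig",
]


class _Frozenish(BaseModel):
    model_config = ConfigDict(validate_assignment=True, extra="forbid")


class GatingParams(_Frozenish):
    """Hodgkin-Huxley style gating of the unmodified (control) channel.

    The channel opens with ``m**3``, fast-inactivates with ``h`` and
    slow-inactivates with ``s``.  Steady states are Boltzmann functions of
    voltage; time constants are skewed bell curves (for m and h) or a
    logistic interpolation (for s).
    """

    g_max: float = Field(400.0, gt=0, description="maximal conductance (nS)")
    E_Na: float = Field(60.0, description="sodium reversal potential (mV)")

    # activation (m)
    m_V05: float = Field(-40.0, description="activation half-voltage (mV)")
    m_k: float = Field(6.0, gt=0, description="activation slope (mV)")
    m_tau_min: float = Field(0.05, gt=0, description="floor of tau_m (ms)")
    m_tau_amp: float = Field(0.4, gt=0, description="amplitude of tau_m bell (ms)")
    m_tau_V05: float = Field(-35.0, description="centre of tau_m bell (mV)")
    m_tau_k: float = Field(18.0, gt=0, description="width of tau_m bell (mV)")

    # fast inactivation (h)
    h_V05: float = Field(-65.0, description="availability half-voltage (mV)")
    h_k: float = Field(4.5, gt=0, description="availability slope (mV)")
    h_tau_min: float = Field(0.3, gt=0, description="floor of tau_h (ms)")
    h_tau_amp: float = Field(18.0, gt=0, description="amplitude of tau_h bell (ms)")
    h_tau_V05: float = Field(-65.0, description="centre of tau_h bell (mV)")
    h_tau_kf: float = Field(16.0, gt=0, description="depolarized-side width (mV)")
    h_tau_kr: float = Field(12.0, gt=0, description="hyperpolarized-side width (mV)")

    # slow inactivation (s); only partial (floor) so that duty-cycle
    # driven accumulation saturates above ~0.2 Hz
    s_V05: float = Field(-45.0, description="slow-availability half-voltage (mV)")
    s_k: float = Field(6.0, gt=0, description="slow-availability slope (mV)")
    s_floor: float = Field(0.85, ge=0, le=1, description="depolarized limit of s_inf")
    s_tau_min: float = Field(100.0, gt=0, description="tau_s at depolarized V (ms)")
    s_tau_max: float = Field(100000.0, gt=0, description="tau_s at hyperpolarized V (ms)")
    s_tau_V05: float = Field(-35.0, description="centre of tau_s transition (mV)")
    s_tau_k: float = Field(3.0, gt=0, description="width of tau_s transition (mV)")

    @model_validator(mode="after")
    def _check_taus(self) -> "GatingParams":
        # time constants must stay positive over the physiological range
        for v in np.linspace(-140.0, 40.0, 37):
            if self.tau_m(float(v)) <= 0 or self.tau_h(float(v)) <= 0 or self.tau_s(float(v)) <= 0:
                raise ValueError("non-positive time constant in [-140, +40] mV")
        return self

    # -- closed forms ------------------------------------------------------
    def m_inf(self, V):
        return 1.0 / (1.0 + np.exp(-(np.asarray(V, float) - self.m_V05) / self.m_k))

    def h_inf(self, V):
        return 1.0 / (1.0 + np.exp((np.asarray(V, float) - self.h_V05) / self.h_k))

    def s_inf(self, V):
        core = 1.0 / (1.0 + np.exp((np.asarray(V, float) - self.s_V05) / self.s_k))
        return self.s_floor + (1.0 - self.s_floor) * core

    def tau_m(self, V):
        x = (np.asarray(V, float) - self.m_tau_V05) / self.m_tau_k
        return self.m_tau_min + self.m_tau_amp / (np.exp(x) + np.exp(-x))

    def tau_h(self, V):
        V = np.asarray(V, float)
        return self.h_tau_min + self.h_tau_amp / (
            np.exp((V - self.h_tau_V05) / self.h_tau_kf)
            + np.exp(-(V - self.h_tau_V05) / self.h_tau_kr)
        )

    def tau_s(self, V):
        V = np.asarray(V, float)
        return self.s_tau_min + (self.s_tau_max - self.s_tau_min) / (
            1.0 + np.exp((V - self.s_tau_V05) / self.s_tau_k)
        )


class ModifiedModeParams(_Frozenish):
    """Drug-modified gating mode: the inactivated state is stabilized.

    The modified mode keeps the control activation machinery but its
    fast-inactivation availability curve is shifted by ``delta_V05``
    (negative: less available at any voltage) and escape from
    inactivation (h rising) is slowed ``rec_slow_factor``-fold.  Channels
    leave the modified mode ("unlatch") at a voltage-dependent rate that
    falls steeply with depolarization, so only prolonged hyperpolarization
    reverses the modification itself.
    """

    delta_V05: float = Field(-33.0, le=0, description="availability shift (mV)")
    rec_slow_factor: float = Field(403.0, ge=1, description="fold slowing of h recovery")
    unlatch_rate_max: float = Field(1.0e-3, ge=0, description="max modified->normal rate (1/s)")
    unlatch_V05: float = Field(-100.0, description="half-voltage of unlatch rate (mV)")
    unlatch_k: float = Field(5.0, gt=0, description="slope of unlatch rate (mV)")


class CouplingParams(_Frozenish):
    """Phenomenological receptor-to-channel coupling.

    After drug onset an intracellular messenger M accrues linearly in time
    (rate ``ramp_rate`` scaled by Hill occupancy of the agonist).  The
    normal->modified rate is ``k_mod * M * D`` where the inactivation
    drive ``D = d0 + w_fast*(1-h) + w_slow*(1-s)`` reflects occupancy of
    the inactivated states the drug stabilizes.  A linearly growing rate
    produces the Gaussian-in-time decay of the diary amplitude.
    """

    k_mod: float = Field(0.0807, ge=0, description="modification efficacy (1/(s*Mu))")
    ramp_rate: float = Field(1.0e-3, ge=0, description="messenger accrual (Mu/s)")
    K_half: float = Field(2.0, gt=0, description="agonist conc. of half-maximal ramp (µM)")
    hill_n: float = Field(1.0, gt=0, description="coupling Hill coefficient")
    p_resistant: float = Field(0.0, ge=0, le=1, description="never-modifiable channel fraction")
    w_fast: float = Field(1.0, ge=0, description="weight of fast-inactivated occupancy in D")
    w_slow: float = Field(0.6, ge=0, description="weight of slow-inactivated occupancy in D")
    d0: float = Field(0.0245, ge=0, description="baseline inactivation drive")

    def eta(self, conc: float) -> float:
        """Hill occupancy of the agonist; ``conc`` in µM."""
        if conc < 0:
            raise ValueError("negative concentration")
        if conc == 0:
            return 0.0
        cn = conc ** self.hill_n
        return cn / (cn + self.K_half ** self.hill_n)


class NoiseLeakParams(_Frozenish):
    """Recording imperfections added to synthetic sweeps."""

    leak_g: float = Field(2.0, ge=0, description="linear leak conductance (nS)")
    leak_E: float = Field(-5.0, description="leak reversal (mV)")
    noise_sd: float = Field(0.0, ge=0, description="white current noise SD (pA)")
    pn_divisor: int = Field(4, ge=1, description="p/n leak subtraction divisor")


class NeuronParams(_Frozenish):
    """Single-compartment neuron for current-clamp simulation."""

    C_m: float = Field(100.0, gt=0, description="membrane capacitance (pF)")
    g_leak: float = Field(5.0, ge=0, description="leak conductance (nS)")
    E_leak: float = Field(-80.0, description="leak reversal (mV)")
    g_K: float = Field(700.0, ge=0, description="delayed-rectifier conductance (nS)")
    E_K: float = Field(-90.0, description="potassium reversal (mV)")
    n_V05: float = Field(-30.0, description="K activation half-voltage (mV)")
    n_k: float = Field(9.0, gt=0, description="K activation slope (mV)")
    n_tau_min: float = Field(1.0, gt=0, description="floor of tau_n (ms)")
    n_tau_amp: float = Field(4.0, gt=0, description="amplitude of tau_n bell (ms)")
    n_tau_V05: float = Field(-30.0, description="centre of tau_n bell (mV)")
    n_tau_k: float = Field(25.0, gt=0, description="width of tau_n bell (mV)")
    V_rest: float = Field(-80.0, description="pre-step holding potential (mV)")
    g_Na: float = Field(1600.0, gt=0, description="sodium conductance in the neuron (nS)")

    def n_inf(self, V):
        return 1.0 / (1.0 + np.exp(-(np.asarray(V, float) - self.n_V05) / self.n_k))

    def tau_n(self, V):
        x = (np.asarray(V, float) - self.n_tau_V05) / self.n_tau_k
        return self.n_tau_min + self.n_tau_amp / (np.exp(x) + np.exp(-x))


class ScenarioConfig(_Frozenish):
    """Everything needed to generate one experimental condition."""

    label: str = "somatic_wt"
    gating: GatingParams = Field(default_factory=GatingParams)
    modified: ModifiedModeParams = Field(default_factory=ModifiedModeParams)
    coupling: CouplingParams = Field(default_factory=CouplingParams)
    noise: NoiseLeakParams = Field(default_factory=NoiseLeakParams)
    holding_mV: float = Field(-80.0, description="inter-sweep holding potential (mV)")
    drug_onset_s: Optional[float] = Field(300.0, description="absolute drug onset (s); None = no drug")
    drug_conc_uM: float = Field(10.0, ge=0, description="agonist concentration (µM)")
    drug_label: str = "agonist"
    freeze_modes: bool = Field(
        False,
        description="clamp mode occupancies (no modification / unlatching); used "
        "for gating measurements of a fixed mode mixture",
    )
    init_modified_fraction: float = Field(
        0.0, ge=0, le=1, description="fraction of the modifiable pool starting in the modified mode"
    )

    def to_json(self) -> str:
        return self.model_dump_json(indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ScenarioConfig":
        return cls.model_validate_json(text)


def require_finite(name: str, value: float) -> float:
    v = float(value)
    if not math.isfinite(v):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return v
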