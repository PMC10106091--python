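"""Voltage-clamp protocol definitions and the synthetic-recording engine.

Every protocol is a list of ``(level_mV, duration_ms)`` segments repeated
at a fixed sweep period, with an optional per-sweep varying segment
(prepulse level, recovery interval).  The engine carries the channel
state continuously across sweeps and the unrecorded inter-sweep holding
periods, applies drug events at absolute experiment times, and adds
linear leak and Gaussian current noise, yielding a :class:`SweepBundle`
analogous to one whole-cell recording digitized at 50 kHz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .channel import ChannelState, equilibrium_state, evolve_constant_v, sample_segment
from .params import ScenarioConfig

__all__ = [
    "VoltageProtocol",
    "Sweep",
    "DrugEvent",
    "SweepBundle",
    "make_protocol",
    "simulate_experiment",
    "pn_subtract",
    "peak_current",
]

PROTOCOL_KINDS = (
    "diary_step",
    "inactivation_prepulse",
    "two_pulse_recovery",
    "double_pulse",
    "use_dependence",
    "concentration_series",
)


@dataclass
class VoltageProtocol:
    kind: str
    segments: list[tuple[float, float]]          # (level mV, duration ms)
    sweep_period_s: float
    n_sweeps: int
    sample_rate_hz: float = 50_000.0
    variable_index: Optional[int] = None         # segment whose level/duration varies
    variable_field: str = "level"                # "level" or "duration"
    variable_values: Optional[list[float]] = None
    test_index: Optional[int] = None             # segment holding the test pulse
    sweep_start_times_s: Optional[list[float]] = None  # overrides uniform schedule

    def __post_init__(self):
        if self.sample_rate_hz < 10_000:
            raise ValueError("sample_rate must be >= 10 kHz")
        for lv, dur in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be positive")
        if self.variable_index is not None:
            if not (0 <= self.variable_index < len(self.segments)):
                raise ValueError("variable segment index out of range")
            if self.variable_values is not None and len(self.variable_values) != self.n_sweeps:
                raise ValueError("need one variable value per sweep")

    def start_times(self) -> np.ndarray:
        if self.sweep_start_times_s is not None:
            t = np.asarray(self.sweep_start_times_s, float)
            if np.any(np.diff(t) <= 0):
                raise ValueError("sweep start times must be strictly increasing")
            return t
        return np.arange(self.n_sweeps) * self.sweep_period_s

    def segments_for_sweep(self, i: int) -> list[tuple[float, float]]:
        segs = list(self.segments)
        if self.variable_index is not None and self.variable_values is not None:
            lv, dur = segs[self.variable_index]
            v = self.variable_values[i]
            segs[self.variable_index] = (v, dur) if self.variable_field == "level" else (lv, v)
        return segs


@dataclass
class Sweep:
    t_s: np.ndarray      # time within sweep (s)
    v_mV: np.ndarray
    i_pA: np.ndarray


@dataclass
class DrugEvent:
    onset_s: float
    conc_uM: float
    label: str = "agonist"


@dataclass
class SweepBundle:
    sweeps: list[Sweep]
    start_times_s: np.ndarray
    protocol: VoltageProtocol
    scenario: ScenarioConfig
    seed: int
    drug_events: list[DrugEvent] = field(default_factory=list)
    pn_templates: Optional[list[np.ndarray]] = None   # averaged, baseline-referenced
    pn_n: int = 4
    units: dict = field(default_factory=lambda: {"t": "s", "v": "mV", "i": "pA"})

    @property
    def drug_onset_s(self) -> Optional[float]:
        return self.drug_events[0].onset_s if self.drug_events else None


# ---------------------------------------------------------------------------
# protocol factory — defaults follow the published step protocols


def make_protocol(kind: str, **overrides) -> VoltageProtocol:
    """Build one of the named voltage protocols.

    diary_step           hold -80, step to -10 mV for 30 ms every 5 s
    inactivation_prepulse 100-ms conditioning prepulse (-130..-30 mV), test -10 mV
    two_pulse_recovery   two 10-ms steps to -10 mV separated by a variable
                         interval at -120 mV
    double_pulse         two steps to -10 mV separated by 1 s at -120 mV
    use_dependence       diary schedule silenced between drug onset and a
                         resumption time
    concentration_series diary schedule used per agonist concentration
    """
    if kind not in PROTOCOL_KINDS:
        raise ValueError(f"unknown protocol kind {kind!r}")
    known = dict(overrides)

    def pop(name, default):
        return known.pop(name, default)

    if kind in ("diary_step", "concentration_series"):
        hold = pop("holding_mV", -80.0)
        step = pop("step_mV", -10.0)
        step_ms = pop("step_ms", 30.0)
        period = pop("sweep_period_s", 5.0)
        n = pop("n_sweeps", 220)
        proto = VoltageProtocol(
            kind=kind,
            segments=[(hold, 5.0), (step, step_ms), (hold, 10.0)],
            sweep_period_s=period, n_sweeps=n, test_index=1,
            sample_rate_hz=pop("sample_rate_hz", 50_000.0),
        )
    elif kind == "inactivation_prepulse":
        hold = pop("holding_mV", -130.0)
        prepulses = pop("prepulse_mV", list(np.arange(-130.0, -29.9, 5.0)))
        proto = VoltageProtocol(
            kind=kind,
            segments=[(hold, 20.0), (hold, 100.0), (-10.0, 20.0), (hold, 10.0)],
            sweep_period_s=pop("sweep_period_s", 3.0),
            n_sweeps=len(prepulses),
            variable_index=1, variable_field="level",
            variable_values=[float(v) for v in prepulses],
            test_index=2,
            sample_rate_hz=pop("sample_rate_hz", 50_000.0),
        )
    elif kind == "two_pulse_recovery":
        hold = pop("holding_mV", -80.0)
        intervals = pop("intervals_ms",
                        list(np.geomspace(0.1, 3000.0, 25)))
        proto = VoltageProtocol(
            kind=kind,
            segments=[(hold, 5.0), (-10.0, 10.0), (-120.0, 1.0), (-10.0, 10.0), (hold, 5.0)],
            sweep_period_s=pop("sweep_period_s", 10.0),
            n_sweeps=len(intervals),
            variable_index=2, variable_field="duration",
            variable_values=[float(x) for x in intervals],
            test_index=3,
            sample_rate_hz=pop("sample_rate_hz", 50_000.0),
        )
    elif kind == "double_pulse":
        hold = pop("holding_mV", -80.0)
        proto = VoltageProtocol(
            kind=kind,
            segments=[(hold, 5.0), (-10.0, 10.0), (-120.0, pop("gap_ms", 1000.0)),
                      (-10.0, 10.0), (hold, 5.0)],
            sweep_period_s=pop("sweep_period_s", 10.0),
            n_sweeps=pop("n_sweeps", 1), test_index=3,
            sample_rate_hz=pop("sample_rate_hz", 50_000.0),
        )
    else:  # use_dependence
        hold = pop("holding_mV", -80.0)
        period = pop("sweep_period_s", 5.0)
        onset = pop("drug_onset_s", 300.0)
        silent_s = pop("silent_s", 0.0)       # 0 = continuously cycled
        total_post = pop("post_onset_s", 600.0)
        base = list(np.arange(0.0, onset, period))
        if silent_s > 0:
            post = list(np.arange(onset + silent_s, onset + total_post, period))
        else:
            post = list(np.arange(onset, onset + total_post, period))
        times = base + post
        proto = VoltageProtocol(
            kind=kind,
            segments=[(hold, 5.0), (pop("step_mV", -10.0), pop("step_ms", 30.0)), (hold, 10.0)],
            sweep_period_s=period, n_sweeps=len(times), test_index=1,
            sweep_start_times_s=times,
            sample_rate_hz=pop("sample_rate_hz", 50_000.0),
        )
    if known:
        raise ValueError(f"unknown override(s) for {kind}: {sorted(known)}")
    return proto


# ---------------------------------------------------------------------------
# simulation


_GATES = ("m_n", "h_n", "s_n", "m_m", "h_m", "s_m")


def _burn_in(state: ChannelState, sc: ScenarioConfig, proto: VoltageProtocol,
             max_rounds: int = 25, tol: float = 1e-13) -> ChannelState:
    """Advance to the drug-free periodic steady state of the cycling schedule.

    Each gate's one-cycle map is affine (linear relaxations under a
    piecewise-constant command), so after a few warm-up cycles the fixed
    point is obtained by secant extrapolation of the map rather than by
    cycling until the slowest gate (tau_s, minutes) has relaxed.
    """
    p, mp, cp = sc.gating, sc.modified, sc.coupling
    segs = proto.segments_for_sweep(0)
    sweep_ms = sum(d for _, d in segs)
    hold_ms = max(0.0, proto.sweep_period_s * 1e3 - sweep_ms)

    def cycle(st: ChannelState) -> ChannelState:
        for lv, dur in segs:
            st = evolve_constant_v(st, lv, dur, 0.0, p, mp, cp, None, 0.0,
                                   freeze_modes=True)
        if hold_ms > 0:
            st = evolve_constant_v(st, sc.holding_mV, hold_ms, 0.0, p, mp, cp,
                                   None, 0.0, freeze_modes=True)
        return st

    for _ in range(3):
        state = cycle(state)
    for _ in range(max_rounds):
        s0 = state
        s1 = cycle(s0)
        s2 = cycle(s1)
        drift = max(abs(getattr(s2, g) - getattr(s1, g)) for g in _GATES)
        if drift < tol:
            return s2
        state = s2.copy()
        for g in _GATES:
            g0, g1, g2 = (getattr(s, g) for s in (s0, s1, s2))
            denom = g1 - g0
            if abs(denom) < 1e-15:
                continue
            b = (g2 - g1) / denom
            if abs(1.0 - b) > 1e-9:
                fixed = g1 + (g2 - g1) / (1.0 - b)
                setattr(state, g, min(1.0, max(0.0, fixed)))
    return state


def simulate_experiment(scenario: ScenarioConfig, protocol: VoltageProtocol,
                        seed: int = 0, include_pn: bool = True) -> SweepBundle:
    """Run a protocol against the channel model and return a sweep bundle.

    The channel state is carried continuously across sweeps and holding
    periods (no resets); the drug event from the scenario is applied at
    its absolute onset time.  Reproducible bit-for-bit under a fixed seed.
    """
    sc = scenario
    p, mp, cp = sc.gating, sc.modified, sc.coupling
    rng = np.random.default_rng(seed)
    starts = protocol.start_times()
    onset = sc.drug_onset_s
    conc = sc.drug_conc_uM if onset is not None else 0.0

    state = equilibrium_state(sc.holding_mV, p, mp, x_mod=sc.init_modified_fraction)
    state = _burn_in(state, sc, protocol)

    fs = protocol.sample_rate_hz
    dt_ms = 1e3 / fs
    g_leak, E_leak = sc.noise.leak_g, sc.noise.leak_E
    sd = sc.noise.noise_sd
    n_pn = sc.noise.pn_divisor

    sweeps: list[Sweep] = []
    pn_templates: list[np.ndarray] = []
    # burn-in leaves the state exactly at a sweep boundary, so the first
    # sweep starts with no extra holding; when the drug comes on before
    # the first sweep (incubation protocols) the holding evolution starts
    # at the onset so the exposure is fully simulated
    t_cursor = starts[0] if onset is None else min(starts[0], onset)
    for i, t0 in enumerate(starts):
        gap_ms = (t0 - t_cursor) * 1e3
        if gap_ms > 1e-9:
            state = evolve_constant_v(state, sc.holding_mV, gap_ms,
                                      t_cursor, p, mp, cp, onset, conc,
                                      freeze_modes=sc.freeze_modes)
        segs = protocol.segments_for_sweep(i)
        t_parts, v_parts, i_parts = [], [], []
        seg_t0_ms = 0.0
        for lv, dur in segs:
            n_samp = max(1, int(round(dur * fs / 1e3)))
            grid = (np.arange(n_samp) + 1.0) * dt_ms
            grid = grid[grid <= dur + 1e-9]
            ina = sample_segment(state, lv, grid, p, mp, cp)
            state = evolve_constant_v(state, lv, dur, t0 + seg_t0_ms * 1e-3,
                                      p, mp, cp, onset, conc,
                                      freeze_modes=sc.freeze_modes,
                                      max_substep_ms=min(1.0, dur))
            t_parts.append((seg_t0_ms + grid) * 1e-3)
            v_parts.append(np.full(grid.shape, lv))
            i_parts.append(ina + g_leak * (lv - E_leak))
            seg_t0_ms += dur
        t_s = np.concatenate(t_parts)
        v = np.concatenate(v_parts)
        cur = np.concatenate(i_parts)
        if sd > 0:
            cur = cur + rng.normal(0.0, sd, cur.shape)
        sweeps.append(Sweep(t_s=t_s, v_mV=v, i_pA=cur))
        if include_pn:
            dv = (v - sc.holding_mV) / n_pn
            tmpl = g_leak * (-dv)            # hyperpolarizing direction
            if sd > 0:
                tmpl = tmpl + rng.normal(0.0, sd / math.sqrt(n_pn), tmpl.shape)
            pn_templates.append(tmpl)
        t_cursor = t0 + seg_t0_ms * 1e-3

    events = [] if onset is None else [DrugEvent(onset, conc, sc.drug_label)]
    return SweepBundle(
        sweeps=sweeps, start_times_s=np.asarray(starts, float), protocol=protocol,
        scenario=sc, seed=seed, drug_events=events,
        pn_templates=pn_templates if include_pn else None, pn_n=n_pn,
    )


# ---------------------------------------------------------------------------
# sweep-level operations


def pn_subtract(main: np.ndarray, leak_sweeps: Sequence[np.ndarray], n: int,
                polarity: int = -1) -> np.ndarray:
    """Remove linear leak using p/n sub-sweep responses.

    ``leak_sweeps`` are baseline-referenced responses to the command
    scaled by 1/n; ``polarity`` is -1 when the sub-pulses were delivered
    in the hyperpolarizing direction (the default convention here) and
    +1 when scaled in the same direction as the main command.  A purely
    ohmic main trace maps to zero up to the noise floor.
    """
    main = np.asarray(main, float)
    if n < 1:
        raise ValueError("n must be >= 1")
    tmpl = np.mean([np.asarray(s, float) for s in leak_sweeps], axis=0)
    if tmpl.shape != main.shape:
        raise ValueError("sampling mismatch between main and leak sweeps")
    return main - polarity * n * tmpl


def subtract_leak(bundle: SweepBundle, i: int) -> np.ndarray:
    """p/n-corrected current of sweep ``i`` (falls back to raw if no templates)."""
    sw = bundle.sweeps[i]
    if bundle.pn_templates is None:
        return sw.i_pA
    corrected = pn_subtract(sw.i_pA, [bundle.pn_templates[i]], bundle.pn_n, polarity=-1)
    # remove the standing (holding-potential) leak using the pre-step samples
    hold = bundle.scenario.holding_mV
    base = sw.v_mV == sw.v_mV[0]
    return corrected - np.mean(corrected[base][: max(3, int(base.sum() // 2))])


def peak_current(sweep: Sweep, window_s: tuple[float, float] | None = None,
                 i_pA: np.ndarray | None = None) -> float:
    """Most-negative sample (inward peak, pA) inside a time window.

    ``window_s`` is an interval in within-sweep seconds; by default the
    whole sweep is searched.  ``i_pA`` may supply a corrected current
    trace sharing the sweep's time base.
    """
    cur = sweep.i_pA if i_pA is None else np.asarray(i_pA, float)
    t = sweep.t_s
    if window_s is None:
        sel = np.ones(t.shape, bool)
    else:
        lo, hi = window_s
        sel = (t >= lo) & (t <= hi)
    if not np.any(sel):
        raise ValueError("empty peak-measurement window")
    return float(np.min(cur[sel]))


def sweep_test_window(bundle: SweepBundle, i: int = 0, pad_ms: float = 0.0) -> tuple[float, float]:
    """Within-sweep window (s) covering the test segment of sweep ``i``."""
    proto = bundle.protocol
    idx = proto.test_index
    if idx is None:
        raise ValueError("protocol has no designated test segment")
    segs = proto.segments_for_sweep(i)
    t0 = sum(d for _, d in segs[:idx])
    t1 = t0 + segs[idx][1]
    return ((t0 - pad_ms) * 1e-3, (t1 + pad_ms) * 1e-3)
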