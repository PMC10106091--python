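"""Protocol-specific block metrics derived from sweep bundles.

A diary series (per-sweep inward peak amplitude against absolute
experiment time) is the common currency: it is normalized to the mean
amplitude 50-100 s before drug onset, after which fractional block is
1 minus the normalized residual current.  The other metrics map the
prepulse, two-pulse-recovery, double-pulse and use-dependence bundles to
the summary quantities reported for those protocols.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .fits import fit_eq1, time_to_fraction
from .protocols import SweepBundle, peak_current, subtract_leak, sweep_test_window

__all__ = [
    "DiarySeries",
    "DoublePulseResult",
    "RecoveryCurve",
    "diary_from_bundle",
    "normalize_baseline",
    "fractional_block_at",
    "i1_i2_ratio",
    "availability_curve",
    "recovery_curve",
    "use_dependence_contrast",
]


@dataclass
class DiarySeries:
    t_s: np.ndarray            # absolute sweep times (s)
    amp_pA: np.ndarray         # signed inward peaks
    drug_onset_s: Optional[float]
    norm_window_s: tuple[float, float] = (50.0, 100.0)  # s before onset
    normalized: bool = False

    def post_onset(self) -> tuple[np.ndarray, np.ndarray]:
        if self.drug_onset_s is None:
            raise ValueError("diary has no drug onset")
        sel = self.t_s >= self.drug_onset_s
        return self.t_s[sel] - self.drug_onset_s, self.amp_pA[sel]


def diary_from_bundle(bundle: SweepBundle, pad_ms: float = 0.0) -> DiarySeries:
    """Leak-corrected inward test-pulse peaks of every sweep."""
    peaks = []
    for i, sw in enumerate(bundle.sweeps):
        cur = subtract_leak(bundle, i)
        peaks.append(peak_current(sw, sweep_test_window(bundle, i, pad_ms), i_pA=cur))
    return DiarySeries(
        t_s=np.asarray(bundle.start_times_s, float),
        amp_pA=np.asarray(peaks, float),
        drug_onset_s=bundle.drug_onset_s,
    )


def normalize_baseline(diary: DiarySeries) -> DiarySeries:
    """Divide amplitudes by the mean over the 50-100 s pre-onset window.

    Idempotent: normalizing an already-normalized diary re-divides by a
    baseline mean of one.
    """
    if diary.drug_onset_s is None:
        raise ValueError("cannot normalize a diary without a drug onset")
    lo = diary.drug_onset_s - diary.norm_window_s[1]
    hi = diary.drug_onset_s - diary.norm_window_s[0]
    sel = (diary.t_s >= lo) & (diary.t_s <= hi)
    if sel.sum() < 3:
        raise ValueError("fewer than 3 sweeps in the baseline window")
    ref = float(np.mean(diary.amp_pA[sel]))
    if abs(ref) < 1e-12:
        raise ValueError("zero baseline amplitude; cannot normalize")
    return replace(diary, amp_pA=diary.amp_pA / ref, normalized=True)


def fractional_block_at(diary: DiarySeries, t_after_onset_s: float,
                        n_sweeps: int = 1) -> float:
    """1 - normalized residual current at the sweep(s) nearest ``t``.

    ``n_sweeps`` > 1 averages that many consecutive sweeps starting at
    the nearest one (used for the first resumed sweeps of a silent run).
    """
    if not diary.normalized:
        diary = normalize_baseline(diary)
    if t_after_onset_s < 0:
        raise ValueError("t must be at or after drug onset")
    t_rel, y = diary.post_onset()
    if len(t_rel) == 0:
        raise ValueError("no post-onset sweeps")
    j = int(np.argmin(np.abs(t_rel - t_after_onset_s)))
    return 1.0 - float(np.mean(y[j:j + n_sweeps]))


def plateau_block(diary: DiarySeries) -> float:
    """Plateau fractional block, 1 - B/(A+B) from the Gaussian-time fit."""
    if not diary.normalized:
        diary = normalize_baseline(diary)
    t_rel, y = diary.post_onset()
    f = fit_eq1(t_rel, y)
    return 1.0 - f.B / (f.A + f.B)


@dataclass
class DoublePulseResult:
    I1: float
    I2: float

    @property
    def ratio(self) -> float:
        return self.I1 / self.I2


def _pulse_windows(bundle: SweepBundle, i: int, level: float = -10.0):
    segs = bundle.protocol.segments_for_sweep(i)
    wins, t0 = [], 0.0
    for lv, dur in segs:
        if lv == level:
            wins.append((t0 * 1e-3, (t0 + dur) * 1e-3))
        t0 += dur
    return wins


def i1_i2_ratio(bundle: SweepBundle, sweep: int = 0) -> DoublePulseResult:
    """I1/I2 from a double-pulse bundle: the drug-insensitive fraction.

    I1 is the first test-pulse peak (channels still blocked), I2 the peak
    after the 1-s hyperpolarization to -120 mV has reversed the majority
    of the inhibition; no correction is applied for incomplete reversal.
    """
    wins = _pulse_windows(bundle, sweep)
    if len(wins) < 2:
        raise ValueError("bundle does not contain two test steps")
    cur = subtract_leak(bundle, sweep)
    sw = bundle.sweeps[sweep]
    I1 = peak_current(sw, wins[0], i_pA=cur)
    I2 = peak_current(sw, wins[1], i_pA=cur)
    if abs(I2) < 1e-9:
        raise ValueError("reference peak is zero")
    return DoublePulseResult(I1=I1, I2=I2)


def availability_curve(bundle: SweepBundle) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state availability from an inactivation-prepulse bundle.

    Test-pulse peaks normalized to the largest; because the test step is
    fixed at -10 mV, normalized current equals normalized conductance.
    """
    proto = bundle.protocol
    if proto.variable_values is None:
        raise ValueError("bundle has no prepulse levels")
    V = np.asarray(proto.variable_values, float)
    if len(V) < 5:
        raise ValueError("fewer than 5 prepulse levels")
    if V.max() - V.min() < 60:
        raise ValueError("prepulse range must span at least 60 mV")
    peaks = np.array([
        peak_current(bundle.sweeps[i], sweep_test_window(bundle, i),
                     i_pA=subtract_leak(bundle, i))
        for i in range(len(bundle.sweeps))
    ])
    avail = peaks / peaks.min()     # inward peaks are negative
    order = np.argsort(V)
    return V[order], avail[order]


@dataclass
class RecoveryCurve:
    intervals_ms: np.ndarray
    fraction: np.ndarray
    reference: str = "I1"          # "I1" or "Icon"

    def t50_ms(self, target: float = 0.5) -> float:
        return time_to_fraction(self.intervals_ms, self.fraction, target)


def recovery_curve(bundle: SweepBundle, reference: str = "I1",
                   I_con_pA: float | None = None) -> RecoveryCurve:
    """I2 recovery against the -120 mV interval from a two-pulse bundle.

    ``reference="I1"`` normalizes each sweep's second peak to its own
    first peak; ``reference="Icon"`` normalizes to a pre-drug control
    amplitude supplied in ``I_con_pA``.
    """
    proto = bundle.protocol
    if proto.variable_values is None:
        raise ValueError("bundle has no recovery intervals")
    iv = np.asarray(proto.variable_values, float)
    order = np.argsort(iv)
    fracs = []
    for i in range(len(bundle.sweeps)):
        wins = _pulse_windows(bundle, i)
        cur = subtract_leak(bundle, i)
        sw = bundle.sweeps[i]
        I1 = peak_current(sw, wins[0], i_pA=cur)
        I2 = peak_current(sw, wins[1], i_pA=cur)
        if reference == "I1":
            ref = I1
        elif reference == "Icon":
            if I_con_pA is None:
                raise ValueError("Icon reference requires I_con_pA")
            ref = I_con_pA
        else:
            raise ValueError(f"unknown reference {reference!r}")
        if abs(ref) < 1e-9:
            raise ValueError("reference peak is zero")
        fracs.append(I2 / ref)
    return RecoveryCurve(intervals_ms=iv[order],
                         fraction=np.asarray(fracs)[order],
                         reference=reference)


def use_dependence_contrast(cycled: SweepBundle, silent: SweepBundle,
                            at_s: float, n_resumed: int = 2) -> tuple[float, float]:
    """(block_cycled, block_silent) at ``at_s`` after drug onset.

    The cycled run is read at the sweep nearest ``at_s``; the silent run
    at the mean of its first ``n_resumed`` resumed sweeps.  Both bundles
    must share gating/coupling parameters (same cell, different duty
    cycle).
    """
    if cycled.scenario.gating != silent.scenario.gating or \
            cycled.scenario.coupling != silent.scenario.coupling:
        raise ValueError("cycled and silent runs use different scenarios")
    d_c = normalize_baseline(diary_from_bundle(cycled))
    d_s = normalize_baseline(diary_from_bundle(silent))
    block_c = fractional_block_at(d_c, at_s)
    t_rel, _ = d_s.post_onset()
    first_resumed = float(t_rel[t_rel >= at_s - 1e-6][0])
    block_s = fractional_block_at(d_s, first_resumed, n_sweeps=n_resumed)
    return block_c, block_s
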