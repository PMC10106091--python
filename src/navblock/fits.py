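"""Nonlinear fits used by the analysis chain.

Time-course models for the diary amplitude after drug onset:

    Gaussian-time decay   I(t) = A * exp(-(t/tau)**2) + B
    single exponential    I(t) = A * exp(-t/tau) + B

plus the Boltzmann availability curve, the Hill concentration-effect
curve, and log-time interpolation of recovery half-times.  All fitters
are plain least squares (scipy) with documented initialization and
bounds, and return small records carrying diagnostics so downstream code
never has to guess whether a fit is trustworthy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "Eq1Fit", "ExpFit", "BoltzmannFit", "HillFit",
    "fit_eq1", "fit_single_exp", "select_time_course_model",
    "fit_boltzmann", "fit_hill", "time_to_fraction",
]


@dataclass
class _TimeCourseFit:
    A: float
    B: float
    tau: float
    rss: float
    converged: bool
    identifiable: bool
    se: dict = field(default_factory=dict)
    n: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


class Eq1Fit(_TimeCourseFit):
    """Parameters of the Gaussian-time decay I(t) = A exp(-(t/tau)^2) + B."""


class ExpFit(_TimeCourseFit):
    """Parameters of the single exponential I(t) = A exp(-t/tau) + B."""


def _gauss_time(t, A, B, tau):
    return A * np.exp(-((t / tau) ** 2)) + B


def _single_exp(t, A, B, tau):
    return A * np.exp(-t / tau) + B


def _init_time_course(t, y):
    """B from the last-decile mean, A = 1 - B, tau from the 1/e crossing."""
    n = len(t)
    B0 = float(np.mean(y[max(0, n - max(1, n // 10)):]))
    A0 = max(1e-6, float(y[0]) - B0)
    target = B0 + A0 * math.exp(-1.0)
    below = np.nonzero(y <= target)[0]
    tau0 = float(t[below[0]]) if len(below) else float(t[-1])
    tau0 = min(max(tau0, 1.0), 1e5)
    return max(A0, 1e-6), max(B0, 1e-9), tau0


def _fit_time_course(cls, model, t, y, se_names=("A", "B", "tau")):
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    if len(t) < 6:
        raise ValueError("need at least 6 post-onset points")
    if np.any(t < 0):
        raise ValueError("time must be measured from drug onset (t >= 0)")
    A0, B0, tau0 = _init_time_course(t, y)
    t_max = float(np.max(t))
    tau_lo, tau_hi = 1e-3 * t_max, 1e3 * t_max
    tau0 = min(max(tau0, tau_lo), tau_hi)
    span = float(np.max(y) - np.min(y))
    if span < 5e-3:  # flat series: tau unconstrained
        return cls(A=0.0, B=float(np.mean(y)), tau=math.nan,
                   rss=float(np.sum((y - np.mean(y)) ** 2)),
                   converged=True, identifiable=False, n=len(t))
    try:
        popt, pcov = optimize.curve_fit(
            model, t, y, p0=[A0, B0, tau0],
            bounds=([0.0, 0.0, tau_lo], [1.5, 1.5, tau_hi]),
            maxfev=20000, xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
        converged = True
    except RuntimeError:
        return cls(A=math.nan, B=math.nan, tau=math.nan, rss=math.inf,
                   converged=False, identifiable=False, n=len(t))
    resid = y - model(t, *popt)
    rss = float(resid @ resid)
    se = {}
    if pcov is not None and np.all(np.isfinite(pcov)):
        se = {k: float(v) for k, v in zip(se_names, np.sqrt(np.diag(pcov)))}
    A, B, tau = (float(v) for v in popt)
    block = A / max(A + B, 1e-12)
    return cls(A=A, B=B, tau=tau, rss=rss, converged=True,
               identifiable=block >= 0.05, se=se, n=len(t))


def fit_eq1(t_s: Sequence[float], y: Sequence[float]) -> Eq1Fit:
    """Fit the Gaussian-time decay to a normalized post-onset diary series.

    ``t_s`` is time from drug onset in seconds.  The identifiability flag
    is lowered when total block is under 5% (tau then means little).
    """
    return _fit_time_course(Eq1Fit, _gauss_time, t_s, y)


def fit_single_exp(t_s: Sequence[float], y: Sequence[float]) -> ExpFit:
    """Fit the competing single-exponential time course."""
    return _fit_time_course(ExpFit, _single_exp, t_s, y)


def select_time_course_model(t_s: Sequence[float], y: Sequence[float]) -> dict:
    """Compare the Gaussian-time and exponential kernels on one series.

    Both models carry three parameters, so the small-sample information
    criterion reduces to an RSS comparison; both criteria are reported.
    Returns ``{"selected": "eq1"|"exponential"|None, "aicc_eq1":..,
    "aicc_exp":.., "eq1":.., "exp":..}``; ``selected`` is None (abstain)
    when either fit failed or the series is flat.
    """
    f1 = fit_eq1(t_s, y)
    f2 = fit_single_exp(t_s, y)
    out = {"eq1": f1, "exp": f2, "selected": None,
           "aicc_eq1": math.nan, "aicc_exp": math.nan,
           "reason": None}
    if not (f1.converged and f2.converged):
        out["reason"] = "fit failure"
        return out
    if not (f1.identifiable and f2.identifiable):
        out["reason"] = "flat series"
        return out
    n, k = f1.n, 3
    for key, f in (("aicc_eq1", f1), ("aicc_exp", f2)):
        out[key] = n * math.log(max(f.rss, 1e-300) / n) + 2 * k \
            + (2 * k * (k + 1)) / max(n - k - 1, 1)
    out["selected"] = "eq1" if out["aicc_eq1"] < out["aicc_exp"] else "exponential"
    return out


# ---------------------------------------------------------------------------


@dataclass
class BoltzmannFit:
    V05: float
    slope_k: float
    floor: float
    ceiling: float
    rss: float
    converged: bool
    spans_transition: bool
    se: dict = field(default_factory=dict)

    def predict(self, V):
        V = np.asarray(V, float)
        return self.floor + (self.ceiling - self.floor) / (
            1.0 + np.exp((V - self.V05) / self.slope_k))


def fit_boltzmann(prepulse_mV: Sequence[float], availability: Sequence[float]) -> BoltzmannFit:
    """Fit a falling Boltzmann to an availability curve.

    y = floor + (ceiling - floor) / (1 + exp((V - V05)/k)).  Requires at
    least five voltages; flags (does not reject) fits whose midpoint
    falls outside the sampled span.
    """
    V = np.asarray(prepulse_mV, float)
    y = np.asarray(availability, float)
    if len(V) < 5:
        raise ValueError("need at least 5 prepulse voltages")
    order = np.argsort(V)
    V, y = V[order], y[order]

    def model(V, V05, k, lo, hi):
        return lo + (hi - lo) / (1.0 + np.exp((V - V05) / k))

    v05_0 = float(V[np.argmin(np.abs(y - 0.5 * (y.max() + y.min())))])
    popt, pcov = optimize.curve_fit(
        model, V, y, p0=[v05_0, 6.0, float(y.min()), float(y.max())],
        bounds=([-140, 0.5, -0.5, 0.5], [0, 40, 0.5, 1.5]), maxfev=20000,
        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    resid = y - model(V, *popt)
    se = {}
    if np.all(np.isfinite(pcov)):
        se = dict(zip(("V05", "slope_k", "floor", "ceiling"), np.sqrt(np.diag(pcov))))
    V05, k, lo, hi = (float(v) for v in popt)
    return BoltzmannFit(V05=V05, slope_k=k, floor=lo, ceiling=hi,
                        rss=float(resid @ resid), converged=True,
                        spans_transition=bool(V.min() <= V05 <= V.max()),
                        se={k2: float(v) for k2, v in se.items()})


@dataclass
class HillFit:
    ec50: float
    hill_n: float
    floor: float
    rss: float
    converged: bool
    monotone: bool
    se: dict = field(default_factory=dict)

    def predict(self, c):
        c = np.asarray(c, float)
        return self.floor + (1.0 - self.floor) / (1.0 + (c / self.ec50) ** self.hill_n)


def fit_hill(conc_uM: Sequence[float], response: Sequence[float]) -> HillFit:
    """Fit a descending Hill curve to normalized responses.

    y = floor + (1 - floor) / (1 + (c/EC50)^n); the zero-concentration
    anchor (response 1) must be present.  Non-monotone data beyond a 5%
    ripple only lower the ``monotone`` flag.
    """
    c = np.asarray(conc_uM, float)
    y = np.asarray(response, float)
    if not np.any(c == 0):
        raise ValueError("concentration series must include the 0 anchor")
    order = np.argsort(c)
    c, y = c[order], y[order]
    monotone = bool(np.all(np.diff(y) <= 0.05))

    def model(c, ec50, n, lo):
        return lo + (1.0 - lo) / (1.0 + (c / ec50) ** n)

    pos = c[c > 0]
    ec0 = float(np.median(pos)) if len(pos) else 1.0
    popt, pcov = optimize.curve_fit(
        model, c, y, p0=[ec0, 1.0, max(float(y.min()), 0.0)],
        bounds=([1e-3, 0.3, 0.0], [1e3, 6.0, 0.9]), maxfev=20000,
        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    resid = y - model(c, *popt)
    se = {}
    if np.all(np.isfinite(pcov)):
        se = dict(zip(("ec50", "hill_n", "floor"), np.sqrt(np.diag(pcov))))
    ec50, n, lo = (float(v) for v in popt)
    return HillFit(ec50=ec50, hill_n=n, floor=lo, rss=float(resid @ resid),
                   converged=True, monotone=monotone,
                   se={k: float(v) for k, v in se.items()})


def time_to_fraction(times: Sequence[float], fractions: Sequence[float],
                     target: float) -> float:
    """Interpolated time at which a monotone recovery curve hits ``target``.

    Interpolation is linear in log-time between the bracketing samples
    (recovery intervals span four decades).  An exact sample hit returns
    that sample's time; a target outside the observed range raises.
    """
    t = np.asarray(times, float)
    f = np.asarray(fractions, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    hits = np.nonzero(np.isclose(f, target, rtol=0, atol=1e-12))[0]
    if len(hits):
        return float(t[hits[0]])
    if target < f[0] or target > f.max():
        raise ValueError("target fraction outside the observed recovery range")
    above = np.nonzero(f >= target)[0][0]
    lo, hi = above - 1, above
    lt = np.log10(t[lo]), np.log10(t[hi])
    w = (target - f[lo]) / (f[hi] - f[lo])
    return float(10 ** (lt[0] + w * (lt[1] - lt[0])))
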