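"""Thermal stability: melting midpoint T_m from absorbance-vs-temperature
traces and the stabilization shift between free and drug-bound protein.

The unfolding transition is modelled as two-state with flat baselines::

    A(T) = A_pre + (A_post - A_pre) / (1 + exp((T_m - T) / w))

T_m is the midpoint (half the protein unfolded) and ``w`` the transition
width.  A model-free midpoint — the temperature where the smoothed signal
crosses halfway between the fitted baselines — is returned alongside as a
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core import _as_float_tuple


class NoTransitionError(RuntimeError):
    """The trace shows no resolvable unfolding transition in its range."""


@dataclass(frozen=True)
class MeltTrace:
    """Temperature-indexed signal, stored in kelvin.

    Use :meth:`from_celsius` at the I/O boundary; at least 8 strictly
    increasing temperatures are required.
    """

    temperature: tuple  # K
    signal: tuple  # AU
    label: str = ""
    heating_rate_C_per_min: float = None  # provenance only; not used in fits

    def __post_init__(self):
        object.__setattr__(self, "temperature", _as_float_tuple(self.temperature))
        object.__setattr__(self, "signal", _as_float_tuple(self.signal))
        temp = np.asarray(self.temperature)
        sig = np.asarray(self.signal)
        if temp.size != sig.size:
            raise ValueError("temperature and signal must have equal length")
        if temp.size < 8:
            raise ValueError("a melt trace needs at least 8 points")
        if np.any(np.diff(temp) <= 0):
            raise ValueError("temperature must be strictly increasing")
        if np.any(temp <= 0):
            raise ValueError("temperatures must be positive kelvin")

    @classmethod
    def from_celsius(cls, temperature_C, signal, label: str = "", **kw) -> "MeltTrace":
        return cls(
            temperature=tuple(t + 273.15 for t in temperature_C),
            signal=tuple(signal),
            label=label,
            **kw,
        )


@dataclass(frozen=True)
class MeltFit:
    """Two-state fit of one melting trace (temperatures in kelvin)."""

    T_m: float
    width: float
    baseline_pre: float
    baseline_post: float
    fit_quality: float  # R^2 of the sigmoid fit
    midpoint_model_free: float

    @property
    def T_m_celsius(self) -> float:
        return self.T_m - 273.15


@dataclass(frozen=True)
class TmShift:
    """ΔT_m = T_m(bound) − T_m(free), kelvin; positive is stabilizing."""

    delta: float
    verdict: str  # "stabilizing" | "destabilizing" | "neutral"


def _sigmoid(T, A_pre, A_post, T_m, w):
    return A_pre + (A_post - A_pre) / (1.0 + np.exp((T_m - T) / w))


def _model_free_midpoint(temp: np.ndarray, sig: np.ndarray, midline: float) -> float:
    # light smoothing (moving average, window 5) before locating the crossing
    if sig.size >= 5:
        kernel = np.ones(5) / 5.0
        smooth = np.convolve(sig, kernel, mode="same")
        smooth[:2], smooth[-2:] = sig[:2], sig[-2:]
    else:
        smooth = sig
    rising = smooth[-1] >= smooth[0]
    crossed = smooth >= midline if rising else smooth <= midline
    if not crossed.any() or crossed.all():
        return float("nan")
    idx = int(np.argmax(crossed))
    s0, s1 = smooth[idx - 1], smooth[idx]
    if s1 == s0:
        return float(temp[idx])
    frac = (midline - s0) / (s1 - s0)
    return float(temp[idx - 1] + frac * (temp[idx] - temp[idx - 1]))


def fit_two_state_melt(trace: MeltTrace) -> MeltFit:
    """Fit the two-state sigmoid to a melting trace.

    The sigmoid must beat a straight line by AIC, otherwise the trace is
    declared to contain no transition in its temperature window (e.g. a
    scan truncated before the unfolding step).

    Raises
    ------
    NoTransitionError
        If no sigmoidal transition is resolvable within the trace.
    """
    temp = np.asarray(trace.temperature)
    sig = np.asarray(trace.signal)
    n = temp.size
    span = temp[-1] - temp[0]

    a_pre0 = sig[:3].mean()
    a_post0 = sig[-3:].mean()
    midline0 = 0.5 * (a_pre0 + a_post0)
    T_m0 = float(temp[int(np.argmin(np.abs(sig - midline0)))])
    p0 = [a_pre0, a_post0, T_m0, max(span / 10.0, 0.5)]
    lo = [-np.inf, -np.inf, temp[0], 1e-3]
    hi = [np.inf, np.inf, temp[-1], span]
    try:
        popt, _ = curve_fit(_sigmoid, temp, sig, p0=p0, bounds=(lo, hi), maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise NoTransitionError(f"no transition in range: sigmoid fit failed ({exc})")
    resid = sig - _sigmoid(temp, *popt)
    rss_sig = float(resid @ resid)

    # straight-line null model
    coeffs = np.polyfit(temp, sig, 1)
    resid_line = sig - np.polyval(coeffs, temp)
    rss_line = float(resid_line @ resid_line)

    eps = 1e-30
    aic_sig = n * np.log((rss_sig + eps) / n) + 2 * 4
    aic_line = n * np.log((rss_line + eps) / n) + 2 * 2
    if aic_sig >= aic_line:
        raise NoTransitionError(
            "no transition in range: a straight line describes the trace at "
            "least as well as the two-state sigmoid (by AIC)"
        )

    a_pre, a_post, T_m, w = (float(v) for v in popt)
    ss_tot = float(((sig - sig.mean()) ** 2).sum())
    r2 = 1.0 - rss_sig / ss_tot if ss_tot > 0 else 1.0
    midpoint_mf = _model_free_midpoint(temp, sig, 0.5 * (a_pre + a_post))
    return MeltFit(
        T_m=T_m,
        width=w,
        baseline_pre=a_pre,
        baseline_post=a_post,
        fit_quality=max(min(r2, 1.0), 0.0),
        midpoint_model_free=midpoint_mf,
    )


def tm_shift(free: MeltTrace, bound: MeltTrace) -> TmShift:
    """Stabilization shift ΔT_m = T_m(bound) − T_m(free), in kelvin."""
    fit_free = fit_two_state_melt(free)
    fit_bound = fit_two_state_melt(bound)
    delta = fit_bound.T_m - fit_free.T_m
    if delta > 0:
        verdict = "stabilizing"
    elif delta < 0:
        verdict = "destabilizing"
    else:
        verdict = "neutral"
    return TmShift(delta=float(delta), verdict=verdict)
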