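"""Kinetic order discrimination from absorbance–time traces.

Two integrated rate laws for an approach-to-equilibrium signal are
linearized and compared by regression quality:

* first order:   ln(A_inf − A) = −a k t + ln(A_inf − A0)
* second order:  1/(A_inf − A) =  a k t + 1/(A_inf − A0)

``a`` is a stoichiometric factor, by default 1 (the composite a·k is
reported as-is; separating it would need concentration information the
trace does not carry).  The order whose linearization has the larger R²
is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .core import ExclusionWarning, LineFit, _as_float_tuple, fit_line

#: R² margins below this are flagged indeterminate.
TIE_MARGIN = 1e-3


class Order(str, Enum):
    FIRST = "first"
    SECOND = "second"


@dataclass(frozen=True)
class KineticTrace:
    """Time-indexed signal with endpoint anchors A0 (initial) and A_inf (final)."""

    time: tuple  # s, strictly increasing, t0 >= 0
    signal: tuple  # AU
    A0: float
    A_inf: float

    def __post_init__(self):
        object.__setattr__(self, "time", _as_float_tuple(self.time))
        object.__setattr__(self, "signal", _as_float_tuple(self.signal))
        t = np.asarray(self.time)
        s = np.asarray(self.signal)
        if t.size != s.size:
            raise ValueError("time and signal must have equal length")
        if t.size < 5:
            raise ValueError("a kinetic trace needs at least 5 points")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing with t0 >= 0")
        if self.A_inf == self.A0:
            raise ValueError("endpoint anchors A0 and A_inf must differ")

    @classmethod
    def with_estimated_endpoint(
        cls, time, signal, A0: float = None, tail_fraction: float = 0.05
    ) -> "KineticTrace":
        """Build a trace taking A0 from the first sample and A_inf from the
        mean of the trailing ``tail_fraction`` of the trace."""
        signal = list(signal)
        n_tail = max(1, int(np.ceil(tail_fraction * len(signal))))
        A_inf = float(np.mean(signal[-n_tail:]))
        if A0 is None:
            A0 = float(signal[0])
        return cls(time=tuple(time), signal=tuple(signal), A0=A0, A_inf=A_inf)


@dataclass(frozen=True)
class RateFit:
    """A rate constant (k, s^-1 for first order; a·k, AU^-1 s^-1 for second)
    together with the linearized regression it came from."""

    k: float
    fit: LineFit


@dataclass(frozen=True)
class OrderSelection:
    """Outcome of the first- vs second-order comparison."""

    first: RateFit
    second: RateFit
    chosen: Order
    margin: float  # ΔR² between the two linearizations
    indeterminate: bool


def _admissible(trace: KineticTrace) -> np.ndarray:
    """Points still strictly on the A0 side of A_inf (transforms defined)."""
    s = np.asarray(trace.signal)
    direction = np.sign(trace.A_inf - trace.A0)
    mask = (trace.A_inf - s) * direction > 0
    n_dropped = int(np.sum(~mask))
    if n_dropped:
        warnings.warn(
            f"excluded {n_dropped} point(s) at or past the A_inf anchor "
            "(rate-law transforms undefined there)",
            ExclusionWarning,
            stacklevel=3,
        )
    if mask.sum() < 3:
        raise ValueError("fewer than 3 points approach A_inf: no usable decay")
    return mask


def _require_decay(d: np.ndarray, trace: KineticTrace) -> None:
    """A flat trace never moves toward A_inf; the transforms are then vacuous."""
    if np.ptp(d) <= 1e-12 * abs(trace.A_inf - trace.A0):
        raise ValueError("no approach to A_inf: signal does not decay toward the anchor")


def first_order_fit(trace: KineticTrace, a: float = 1.0, _mask=None) -> RateFit:
    """Fit the first-order linearization ln|A_inf − A| vs t; k = −slope/a.

    The flat-trace degenerate case (no approach to A_inf) gives a
    non-positive rate and raises.
    """
    mask = _admissible(trace) if _mask is None else _mask
    t = np.asarray(trace.time)[mask]
    d = np.abs(trace.A_inf - np.asarray(trace.signal))[mask]
    _require_decay(d, trace)
    fit = fit_line(t, np.log(d))
    k = -fit.slope / a
    if not k > 0:
        raise ValueError(f"no approach to A_inf: first-order rate k = {k:.4g} s^-1")
    return RateFit(k=float(k), fit=fit)


def second_order_fit(trace: KineticTrace, a: float = 1.0, _mask=None) -> RateFit:
    """Fit the second-order linearization 1/|A_inf − A| vs t; a·k = slope."""
    mask = _admissible(trace) if _mask is None else _mask
    t = np.asarray(trace.time)[mask]
    d = np.abs(trace.A_inf - np.asarray(trace.signal))[mask]
    _require_decay(d, trace)
    fit = fit_line(t, 1.0 / d)
    if not fit.slope > 0:
        raise ValueError(
            f"no approach to A_inf: second-order slope {fit.slope:.4g} not positive"
        )
    return RateFit(k=float(fit.slope / a), fit=fit)


def select_order(trace: KineticTrace, a: float = 1.0) -> OrderSelection:
    """Choose the rate law whose linearization is straighter (larger R²).

    Both transforms are fitted on the same admissible points so the R²
    values are directly comparable; margins below ``TIE_MARGIN`` are
    flagged indeterminate.
    """
    mask = _admissible(trace)
    first = first_order_fit(trace, a=a, _mask=mask)
    second = second_order_fit(trace, a=a, _mask=mask)
    margin = abs(first.fit.r_squared - second.fit.r_squared)
    chosen = Order.FIRST if first.fit.r_squared >= second.fit.r_squared else Order.SECOND
    return OrderSelection(
        first=first,
        second=second,
        chosen=chosen,
        margin=float(margin),
        indeterminate=margin < TIE_MARGIN,
    )
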