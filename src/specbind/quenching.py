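"""Fluorescence quenching analysis: Stern–Volmer fit, bimolecular quenching
constant with the static/dynamic verdict, and the double-log binding fit.

Stern–Volmer: F0/F = 1 + K_sv [Q], with K_sv = k_q τ0.  A bimolecular
quenching constant k_q above the diffusion-controlled limit (~2e10
M^-1 s^-1) cannot arise from collisional quenching alone and indicates
static, ground-state complex formation.

Double-log binding fit: log10((F0 − F)/F) = log10 K_b + n log10 [Q], giving
the association constant and the apparent number of binding sites.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .core import AnalysisWarning, CurvatureWarning, LineFit, _as_float_tuple, fit_line

logger = logging.getLogger(__name__)

#: Diffusion-controlled limit for collisional quenching of a biopolymer,
#: M^-1 s^-1; k_q strictly above it is classified static.
DIFFUSION_LIMIT = 2e10

#: Default unquenched fluorophore lifetime, s.
DEFAULT_TAU0 = 1e-8


class Mechanism(str, Enum):
    STATIC = "static"
    DYNAMIC = "dynamic"


@dataclass(frozen=True)
class QuenchSeries:
    """Quencher-concentration vs fluorescence-intensity titration.

    ``F0`` is the unquenched intensity; if the series starts at Q = 0 the
    first reading normally supplies it.  ``tau0`` is the fluorophore
    lifetime used to convert K_sv into k_q.
    """

    Q: tuple  # M, strictly increasing, Q0 = 0 permitted
    F: tuple  # AU, positive
    F0: float
    tau0: float = DEFAULT_TAU0

    def __post_init__(self):
        object.__setattr__(self, "Q", _as_float_tuple(self.Q))
        object.__setattr__(self, "F", _as_float_tuple(self.F))
        Q = np.asarray(self.Q)
        F = np.asarray(self.F)
        if Q.size != F.size:
            raise ValueError("Q and F must have equal length")
        if Q.size < 3:
            raise ValueError("a quenching series needs at least 3 points")
        if Q[0] < 0 or np.any(np.diff(Q) <= 0):
            raise ValueError("Q must be strictly increasing and non-negative")
        if np.any(F <= 0) or not self.F0 > 0:
            raise ValueError("intensities must be positive")
        if not self.tau0 > 0:
            raise ValueError("tau0 must be positive")
        if F.max() > self.F0 * (1 + 1e-9):
            warnings.warn(
                "some intensities exceed F0; treating as noise",
                AnalysisWarning,
                stacklevel=2,
            )

    @classmethod
    def from_arrays(cls, Q, F, F0: float = None, tau0: float = DEFAULT_TAU0):
        Q = list(Q)
        F = list(F)
        if F0 is None:
            if Q[0] != 0:
                raise ValueError("F0 not supplied and the series has no Q = 0 point")
            F0 = F[0]
        return cls(Q=tuple(Q), F=tuple(F), F0=float(F0), tau0=float(tau0))


@dataclass(frozen=True)
class QuenchResult:
    """Full quenching analysis of one titration."""

    K_sv: float  # M^-1
    k_q: float  # M^-1 s^-1
    mechanism: Mechanism
    K_b_doublelog: float  # M^-1 (apparent, from the double-log plot)
    n_sites: float
    sv_fit: LineFit
    dl_fit: LineFit


def stern_volmer_fit(
    series: QuenchSeries,
    linear_region: Optional[slice] = None,
    r2_min: float = 0.99,
) -> tuple:
    """Stern–Volmer regression of F0/F on [Q]; returns ``(K_sv, LineFit)``.

    Unless ``linear_region`` pins the fitted points, the fit is restricted
    to the longest low-concentration prefix whose regression keeps
    R² >= ``r2_min`` (upward curvature from combined static + dynamic
    quenching makes the full-range plot super-linear).  A
    :class:`CurvatureWarning` is raised when points had to be dropped or the
    intercept strays more than 0.1 from 1.
    """
    Q = np.asarray(series.Q)
    y = series.F0 / np.asarray(series.F)
    if np.ptp(y) == 0:  # F identical to F0 everywhere: no quenching at all
        return 0.0, fit_line(Q, y)
    overall = fit_line(Q, y)
    if overall.slope * np.ptp(Q) < -0.01:  # F0/F falling beyond noise
        raise ValueError(
            "fluorescence increases with quencher concentration: "
            "not a quenching series"
        )
    if linear_region is not None:
        Q_fit, y_fit = Q[linear_region], y[linear_region]
        if Q_fit.size < 3:
            raise ValueError("linear_region must contain at least 3 points")
        fit = fit_line(Q_fit, y_fit)
        n_used = Q_fit.size
    else:
        n_used = 3
        fit = fit_line(Q[:3], y[:3])
        for end in range(4, Q.size + 1):
            candidate = fit_line(Q[:end], y[:end])
            if candidate.r_squared >= r2_min:
                fit, n_used = candidate, end
            else:
                break
        if n_used < Q.size:
            warnings.warn(
                f"Stern-Volmer plot curved: fit restricted to the {n_used} "
                f"lowest concentrations of {Q.size}",
                CurvatureWarning,
                stacklevel=2,
            )
    if abs(fit.intercept - 1.0) > 0.1:
        warnings.warn(
            f"Stern-Volmer intercept {fit.intercept:.3f} deviates from 1: "
            "curvature or endpoint problems suspected",
            CurvatureWarning,
            stacklevel=2,
        )
    return float(fit.slope), fit


def quenching_mechanism(K_sv: float, tau0: float = DEFAULT_TAU0) -> tuple:
    """k_q = K_sv/τ0 and the static/dynamic verdict.

    Static quenching is declared for k_q strictly above the diffusion
    limit (2e10 M^-1 s^-1); at or below it the collisional (dynamic)
    mechanism suffices.
    """
    if not tau0 > 0:
        raise ValueError("tau0 must be positive")
    k_q = K_sv / tau0
    mechanism = Mechanism.STATIC if k_q > DIFFUSION_LIMIT else Mechanism.DYNAMIC
    return float(k_q), mechanism


def temperature_trend_flag(
    K_sv_low_T: float, T_low: float, K_sv_high_T: float, T_high: float
) -> Mechanism:
    """Secondary mechanism flag from the temperature dependence of K_sv.

    A Stern–Volmer constant that falls as temperature rises points to
    static quenching (heating destabilizes the ground-state complex); a
    rising K_sv points to dynamic quenching (diffusion accelerates).
    """
    if not T_high > T_low:
        raise ValueError("temperatures must satisfy T_high > T_low")
    return Mechanism.STATIC if K_sv_high_T < K_sv_low_T else Mechanism.DYNAMIC


def double_log_fit(series: QuenchSeries) -> tuple:
    """Double-log binding fit; returns ``(K_b, n, LineFit)``.

    Regresses log10((F0 − F)/F) on log10 [Q] over points with F < F0 and
    Q > 0 (others are excluded and logged); the intercept gives log10 K_b
    and the slope the apparent site number n.
    """
    Q = np.asarray(series.Q)
    F = np.asarray(series.F)
    mask = (Q > 0) & (F < series.F0)
    n_excluded = int(np.sum(~mask))
    if n_excluded:
        logger.info("double_log_fit: excluded %d point(s) with Q = 0 or F >= F0", n_excluded)
    if mask.sum() < 3:
        raise ValueError("fewer than 3 admissible points for the double-log fit")
    x = np.log10(Q[mask])
    y = np.log10((series.F0 - F[mask]) / F[mask])
    fit = fit_line(x, y)
    return float(10.0 ** fit.intercept), float(fit.slope), fit


def analyze_quench(
    series: QuenchSeries, linear_region: Optional[slice] = None
) -> QuenchResult:
    """Run the complete quenching chain on one titration."""
    K_sv, sv_fit = stern_volmer_fit(series, linear_region=linear_region)
    k_q, mechanism = quenching_mechanism(K_sv, series.tau0)
    K_b, n_sites, dl_fit = double_log_fit(series)
    return QuenchResult(
        K_sv=K_sv,
        k_q=k_q,
        mechanism=mechanism,
        K_b_doublelog=K_b,
        n_sites=n_sites,
        sv_fit=sv_fit,
        dl_fit=dl_fit,
    )
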