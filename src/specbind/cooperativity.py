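"""Cooperativity analysis: binding capacity, the single-set linear
diagnostic, Hill fit, Scatchard classification and per-site Gibbs energy.

All operations work on ``(nu, L_free)`` binding points, i.e. moles of ligand
bound per mole of protein against free-ligand concentration, typically
produced by combining an isotherm's saturation curve with the mass balance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np

from .core import R, BindingParameters, LineFit, fit_line

logger = logging.getLogger(__name__)

#: |n_H - 1| at or below this is reported as non-cooperative.
TIE_TOLERANCE = 0.05


class Cooperativity(str, Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NON_COOPERATIVE = "non_cooperative"


@dataclass(frozen=True)
class BindingPoint:
    """One point of the binding isotherm in (nu, free ligand) coordinates."""

    nu: float
    L_free: float

    def __post_init__(self):
        if self.nu < 0:
            raise ValueError("nu must be non-negative")
        if self.L_free < 0:
            raise ValueError("L_free must be non-negative")


@dataclass(frozen=True)
class HillResult:
    """Hill analysis: ln(nu/(g-nu)) regressed on ln L_free.

    ``K_H`` carries units M^-n_H.  Cooperativity is positive when
    ``n_H > 1 + TIE_TOLERANCE``, negative when ``n_H < 1 - TIE_TOLERANCE``.
    """

    K_H: float
    n_H: float
    g: float
    fit: LineFit
    cooperativity: Cooperativity


@dataclass(frozen=True)
class CapacityDiagnostic:
    """Linear single-set diagnostic: RTθ/nu regressed on nu.

    For one set of g identical sites the plot is a straight line with
    intercept n_H and slope −n_H/g; linearity (high R²) is the classical
    operational evidence for a single binding set.
    """

    fit: LineFit
    n_H: float
    g: float
    single_set: bool


def binding_capacity(nu: float, params: BindingParameters, T: float) -> float:
    """Binding capacity θ = n_H ν (g − ν) / (g R T), in mol/J.

    θ vanishes at ν = 0 and ν = g and peaks at half-occupancy ν = g/2.
    """
    if not 0 <= nu <= params.g:
        raise ValueError(f"nu must lie in [0, g={params.g}]")
    if not T > 0:
        raise ValueError("T must be positive")
    return params.n_H * nu * (params.g - nu) / (params.g * R * T)


def capacity_diagnostic(
    points: Sequence[BindingPoint],
    params: BindingParameters,
    T: float,
    r2_threshold: float = 0.95,
) -> CapacityDiagnostic:
    """Regress RTθ/ν on ν and read (n_H, g) off the line.

    A straight plot (R² at or above ``r2_threshold``) is declared consistent
    with a single set of binding sites; low R² is a finding, not an error.
    """
    nus = np.array([p.nu for p in points if p.nu > 0])
    if nus.size < 3:
        raise ValueError("need at least 3 points with nu > 0")
    theta = np.array([binding_capacity(nu, params, T) for nu in nus])
    y = R * T * theta / nus
    fit = fit_line(nus, y)
    n_H = fit.intercept
    g = -fit.intercept / fit.slope if fit.slope != 0 else float("inf")
    return CapacityDiagnostic(
        fit=fit, n_H=float(n_H), g=float(g), single_set=fit.r_squared >= r2_threshold
    )


def hill_fit(
    points: Sequence[BindingPoint],
    g: float,
    occupancy_window: tuple = (0.05, 0.95),
    tie_tolerance: float = TIE_TOLERANCE,
) -> HillResult:
    """Hill analysis: slope n_H and intercept ln K_H of ln(ν/(g−ν)) vs ln L_free.

    Points with ν outside ``occupancy_window`` (as a fraction of g), with
    ν ≥ g, or with zero free ligand are excluded (the log transform has
    unbounded leverage there); exclusions are logged.
    """
    lo, hi = occupancy_window
    admissible = [
        p
        for p in points
        if p.L_free > 0 and 0 < p.nu < g and lo <= p.nu / g <= hi
    ]
    n_excluded = len(points) - len(admissible)
    if n_excluded:
        logger.info("hill_fit: excluded %d point(s) outside the occupancy window", n_excluded)
    if len(admissible) < 3:
        raise ValueError("fewer than 3 admissible points for the Hill fit")
    x = np.log([p.L_free for p in admissible])
    y = np.log([p.nu / (g - p.nu) for p in admissible])
    fit = fit_line(x, y)
    n_H = fit.slope
    if not n_H > 0:
        raise ValueError(f"non-positive Hill coefficient estimate n_H = {n_H:.4g}")
    K_H = float(np.exp(fit.intercept))
    if n_H > 1 + tie_tolerance:
        verdict = Cooperativity.POSITIVE
    elif n_H < 1 - tie_tolerance:
        verdict = Cooperativity.NEGATIVE
    else:
        verdict = Cooperativity.NON_COOPERATIVE
    return HillResult(K_H=K_H, n_H=float(n_H), g=float(g), fit=fit, cooperativity=verdict)


def scatchard(
    points: Sequence[BindingPoint], curvature_tolerance: float = 0.02
) -> tuple:
    """Scatchard transform ν/L_free vs ν with an algorithmic shape call.

    Returns ``(curve, classification)`` where ``curve`` is the list of
    ``(nu, nu/L_free)`` pairs.  Classification mirrors the visual rule:
    a straight line (classically slope −K, intercept gK) is
    non-cooperative; a concave-down rise-then-fall is positive
    cooperativity; a convex, everywhere-falling curve is negative.  The
    shape test fits a quadratic in ν and compares the curvature term's
    contribution over the ν span with the overall ν/L range
    (``curvature_tolerance`` as the fraction below which the plot counts
    as straight).
    """
    if any(p.L_free <= 0 for p in points):
        raise ValueError("Scatchard transform requires L_free > 0 for every point")
    nus = np.array([p.nu for p in points])
    y = np.array([p.nu / p.L_free for p in points])
    curve = [(float(n), float(v)) for n, v in zip(nus, y)]
    if nus.size < 3 or np.ptp(nus) == 0:
        raise ValueError("need at least 3 points spanning a range of nu")
    c2, c1, _ = np.polyfit(nus, y, 2)
    y_span = np.ptp(y) if np.ptp(y) > 0 else max(abs(y).max(), 1.0)
    curvature = abs(c2) * np.ptp(nus) ** 2 / 4.0
    if curvature <= curvature_tolerance * y_span:
        classification = Cooperativity.NON_COOPERATIVE
    elif c2 < 0 and c1 > 0:
        classification = Cooperativity.POSITIVE
    else:
        classification = Cooperativity.NEGATIVE
    return curve, classification


def gibbs_per_site(
    points: Sequence[BindingPoint], hill: HillResult, T: float
) -> list:
    """Per-site molar binding Gibbs energy along the titration, in J/mol.

    ΔG°(ν) = −RT n_H ln K_H + RT (1 − n_H) ln L_free evaluated at each
    point; the slope against ln L_free is analytically RT(1 − n_H), so a
    negative slope corroborates positive cooperativity (n_H > 1).
    Returns ``(ln L_free, ΔG)`` pairs.
    """
    if not T > 0:
        raise ValueError("T must be positive")
    out = []
    base = -R * T * hill.n_H * np.log(hill.K_H)
    for p in points:
        if p.L_free <= 0:
            continue
        lnL = float(np.log(p.L_free))
        out.append((lnL, float(base + R * T * (1.0 - hill.n_H) * lnL)))
    return out
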