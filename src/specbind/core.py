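"""Shared domain types, the one-set-of-sites binding model, and binding thermodynamics.

Internal unit convention (everything outside the I/O layer):

* concentrations in mol/L (M)
* temperatures in kelvin
* Gibbs energies and enthalpies in kJ/mol, entropies in J/(mol K)
* signals (absorbance or fluorescence intensity) in arbitrary units (AU)

Celsius/kelvin and any other conversions happen only when reading or
writing files, never inside the analysis chain.

The forward model throughout is a single set of ``g`` identical binding
sites on the protein with an empirical Hill exponent ``n_H``::

    nu(L_free) = g * K_H * L_free**n_H / (1 + K_H * L_free**n_H)

where ``nu`` is moles of ligand bound per mole of total protein and
``L_free`` the free-ligand concentration.  Totals and free concentrations
are linked by the conservation law ``L_total = L_free + nu * P_total``,
solved here by bracketed root finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

#: Gas constant, J mol^-1 K^-1.
R = 8.314


class AnalysisWarning(UserWarning):
    """Base class for non-fatal findings raised during an analysis."""


class ExclusionWarning(AnalysisWarning):
    """Data points were excluded from a fit (logged in the message)."""


class ExtrapolationWarning(AnalysisWarning):
    """A reported quantity lies outside the measured range."""


class CurvatureWarning(AnalysisWarning):
    """A plot expected to be linear shows systematic curvature."""


class SignalKind(str, Enum):
    ABSORBANCE = "absorbance"
    FLUORESCENCE = "fluorescence"


class DrivingForce(str, Enum):
    """Dominant intermolecular force inferred from the signs of ΔH° and ΔS°."""

    VDW_OR_HBOND = "vdW_or_Hbond"
    HYDROPHOBIC = "hydrophobic"
    ELECTROSTATIC = "electrostatic"
    MIXED = "mixed"


def _as_float_tuple(values: Sequence[float]) -> tuple:
    return tuple(float(v) for v in values)


@dataclass(frozen=True)
class TitrationSeries:
    """A titration at fixed temperature: total ligand concentration vs. signal.

    Parameters
    ----------
    protein_total
        Total protein concentration, M (> 0).
    ligand_total
        Strictly increasing total (added) ligand concentrations, M.  A leading
        zero point is permitted and serves as the free-protein signal anchor.
    signal
        Non-negative absorbance or fluorescence readings, AU, one per ligand
        concentration.
    temperature
        Kelvin.
    """

    protein_total: float
    ligand_total: tuple
    signal: tuple
    temperature: float
    signal_kind: SignalKind = SignalKind.ABSORBANCE

    def __post_init__(self):
        object.__setattr__(self, "ligand_total", _as_float_tuple(self.ligand_total))
        object.__setattr__(self, "signal", _as_float_tuple(self.signal))
        lig = np.asarray(self.ligand_total)
        sig = np.asarray(self.signal)
        if lig.size != sig.size:
            raise ValueError("ligand_total and signal must have equal length")
        if lig.size < 3:
            raise ValueError("a titration needs at least 3 points")
        if np.any(np.diff(lig) <= 0):
            raise ValueError("ligand_total must be strictly increasing")
        if np.any(sig < 0):
            raise ValueError("signal readings must be non-negative")
        if not self.protein_total > 0:
            raise ValueError("protein_total must be positive")
        if not self.temperature > 0:
            raise ValueError("temperature must be positive (kelvin)")


@dataclass(frozen=True)
class EndpointPair:
    """Signal of fully free (A0) and fully bound (A_inf) protein, AU."""

    A0: float
    A_inf: float

    def __post_init__(self):
        if self.A0 == self.A_inf:
            raise ValueError("endpoint signals A0 and A_inf must differ")

    @property
    def amplitude(self) -> float:
        return self.A_inf - self.A0


@dataclass(frozen=True)
class BindingParameters:
    """Parameters of one set of identical binding sites.

    ``K_b`` is the association constant (M^-1), ``g`` the number of sites in
    the set, ``n_H`` the Hill coefficient and ``K_H`` the Hill constant
    (units M^-n_H).  For a non-cooperative single site ``n_H = 1`` and
    ``K_H = K_b``.
    """

    K_b: float
    g: float
    n_H: float
    K_H: float

    def __post_init__(self):
        for name in ("K_b", "g", "n_H", "K_H"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def single_site(cls, K: float, g: float = 1.0) -> "BindingParameters":
        """Non-cooperative parameters with ``n_H = 1`` and ``K_H = K_b = K``."""
        return cls(K_b=K, g=g, n_H=1.0, K_H=K)


@dataclass(frozen=True)
class ThermoResult:
    """ΔG°, ΔH°, ΔS° of binding at one temperature.

    ΔG and ΔH in kJ/mol, ΔS in J/(mol K).  When all three are set jointly
    they must satisfy ΔG = ΔH − TΔS to within 0.1 kJ/mol.
    """

    delta_G: float
    T: float
    delta_H: Optional[float] = None
    delta_S: Optional[float] = None
    source_Kb: Optional[float] = None

    def __post_init__(self):
        if not self.T > 0:
            raise ValueError("temperature must be positive (kelvin)")
        if self.delta_H is not None and self.delta_S is not None:
            gap = abs(self.delta_G - (self.delta_H - self.T * self.delta_S / 1000.0))
            if gap > 0.1:
                raise ValueError(
                    f"inconsistent thermodynamic cycle: |dG - (dH - T dS)| = {gap:.3g} kJ/mol"
                )


@dataclass(frozen=True)
class LineFit:
    """Slope/intercept/R² of an ordinary least-squares line."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int

    def predict(self, x):
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def fit_line(x: Sequence[float], y: Sequence[float]) -> LineFit:
    """Ordinary least-squares straight line through ``(x, y)``.

    ``r_squared = 1 - SS_res / SS_tot``; when the response is constant
    (``SS_tot = 0``) R² is defined as 1 for a perfect fit and 0 otherwise.

    Raises
    ------
    ValueError
        If fewer than two points are given or all ``x`` coincide (the slope
        is then not identifiable).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 2:
        raise ValueError("need at least two points to fit a line")
    if np.ptp(x) == 0:
        raise ValueError("all x values are equal: slope is not identifiable")
    design = np.column_stack([x, np.ones_like(x)])
    (slope, intercept), *_ = np.linalg.lstsq(design, y, rcond=None)
    residuals = y - (slope * x + intercept)
    ss_res = float(residuals @ residuals)
    centred = y - y.mean()
    ss_tot = float(centred @ centred)
    if ss_tot == 0.0:
        scale = max(1.0, float(np.abs(y).max()) ** 2) * y.size
        r2 = 1.0 if ss_res <= 1e-24 * scale else 0.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    r2 = min(max(r2, 0.0), 1.0)
    return LineFit(float(slope), float(intercept), r2, int(x.size))


def nu_forward(L_free: float, params: BindingParameters) -> float:
    """Bound ligand per protein, ``nu``, at a given free-ligand concentration.

    ``nu = g K_H L^n_H / (1 + K_H L^n_H)``; monotone non-decreasing in
    ``L_free`` and bounded by ``g``.
    """
    if L_free < 0:
        raise ValueError("L_free must be non-negative")
    if L_free == 0:
        return 0.0
    x = params.K_H * L_free ** params.n_H
    if math.isinf(x):
        return params.g
    return params.g * x / (1.0 + x)


def solve_mass_balance(
    L_total: float, P_total: float, params: BindingParameters
) -> tuple:
    """Split total ligand into free and bound given the binding model.

    Solves ``L_free + nu(L_free) * P_total = L_total`` for ``L_free`` by
    bracketed root finding on ``[0, L_total]`` (the residual is monotone, so
    the bracket is guaranteed).  Returns ``(L_free, nu)``.

    Raises
    ------
    RuntimeError
        If the residual after solving exceeds 1e-12 relative to ``L_total``.
    """
    if L_total < 0:
        raise ValueError("L_total must be non-negative")
    if not P_total > 0:
        raise ValueError("P_total must be positive")
    if L_total == 0:
        return 0.0, 0.0

    def residual(L_free: float) -> float:
        return L_free + nu_forward(L_free, params) * P_total - L_total

    if residual(L_total) == 0.0:  # no depletion at all
        return L_total, nu_forward(L_total, params)
    # Bisection to float (ulp) convergence.  The residual is strictly
    # increasing in L_free, negative at 0 and positive at L_total, so the
    # bracket is guaranteed; running until the interval contains no interior
    # float keeps the residual at machine level even where the residual's
    # slope is enormous (strong binding, near-total depletion).
    lo, hi = 0.0, L_total
    L_free = None
    for _ in range(1200):
        mid = 0.5 * (lo + hi)
        if mid <= lo or mid >= hi:
            L_free = lo if abs(residual(lo)) <= abs(residual(hi)) else hi
            break
        r = residual(mid)
        if r == 0.0:
            L_free = mid
            break
        if r < 0.0:
            lo = mid
        else:
            hi = mid
    if L_free is None:  # pragma: no cover - 1200 halvings exhaust any double
        L_free = 0.5 * (lo + hi)
    rel = abs(residual(L_free)) / L_total
    if rel > 1e-12:
        raise RuntimeError(f"mass balance did not converge: relative residual {rel:.3g}")
    return float(L_free), nu_forward(float(L_free), params)


def gibbs_from_kb(K_b: float, T: float) -> float:
    """Standard binding Gibbs energy ΔG° = −RT ln K_b, in kJ/mol."""
    if not K_b > 0:
        raise ValueError("K_b must be positive")
    if not T > 0:
        raise ValueError("T must be positive")
    return -R * T * math.log(K_b) / 1000.0


def vant_hoff_two_point(K1: float, T1: float, K2: float, T2: float) -> float:
    """Two-point van't Hoff enthalpy, kJ/mol.

    ΔH° = (ΔG°(T1)/T1 − ΔG°(T2)/T2) / (1/T1 − 1/T2), with ΔG° from
    :func:`gibbs_from_kb`; algebraically identical to
    R ln(K2/K1) / (1/T1 − 1/T2).
    """
    if T1 == T2:
        raise ValueError("the two temperatures must differ")
    dG1 = gibbs_from_kb(K1, T1)
    dG2 = gibbs_from_kb(K2, T2)
    return (dG1 / T1 - dG2 / T2) / (1.0 / T1 - 1.0 / T2)


def entropy_from_gh(delta_G: float, delta_H: float, T: float) -> float:
    """Binding entropy ΔS° = (ΔH° − ΔG°)/T, in J/(mol K)."""
    if not T > 0:
        raise ValueError("T must be positive")
    return (delta_H - delta_G) * 1000.0 / T


def gibbs_from_enthalpy_entropy(delta_H: float, delta_S: float, T: float) -> float:
    """Gibbs–Helmholtz: ΔG° = ΔH° − TΔS°, in kJ/mol (ΔS in J/(mol K))."""
    if not T > 0:
        raise ValueError("T must be positive")
    return delta_H - T * delta_S / 1000.0


def classify_driving_force(delta_H: float, delta_S: float) -> DrivingForce:
    """Standard sign rules relating (ΔH°, ΔS°) to the dominant binding force.

    ΔH<0 and ΔS<0: van der Waals / hydrogen bonding; ΔH>0 and ΔS>0:
    hydrophobic; ΔH<0 and ΔS>0: electrostatic.  Zeros and the remaining
    quadrant are reported as mixed.
    """
    if not (math.isfinite(delta_H) and math.isfinite(delta_S)):
        raise ValueError("delta_H and delta_S must be finite")
    if delta_H < 0 and delta_S < 0:
        return DrivingForce.VDW_OR_HBOND
    if delta_H > 0 and delta_S > 0:
        return DrivingForce.HYDROPHOBIC
    if delta_H < 0 and delta_S > 0:
        return DrivingForce.ELECTROSTATIC
    return DrivingForce.MIXED
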