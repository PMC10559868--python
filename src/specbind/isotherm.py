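"""Binding isotherm from a UV titration: K_b by the double-reciprocal
(Benesi–Hildebrand) linearization, half-saturation concentration, and the
two-temperature thermodynamic table.

The linearization regresses 1/(A − A0) on 1/[ligand]_total::

    1/(A - A0) = 1/(A_inf - A0) + 1/(K_b (A_inf - A0)) * 1/[L]

so K_b = intercept/slope and A_inf = A0 + 1/intercept.  Because the
regressor is the *total* ligand concentration, the estimator is consistent
only when ligand depletion by the protein is small; a direct nonlinear fit
of the saturation hyperbola is provided as a cross-check.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core import (
    EndpointPair,
    ExtrapolationWarning,
    LineFit,
    ThermoResult,
    TitrationSeries,
    entropy_from_gh,
    fit_line,
    gibbs_from_kb,
    vant_hoff_two_point,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IsothermResult:
    """Outcome of a double-reciprocal isotherm analysis at one temperature."""

    K_b: float
    endpoints: EndpointPair
    L_half: float
    fit: LineFit
    temperature: float
    L_half_extrapolated: bool = False


def _resolve_A0(series: TitrationSeries, A0):
    if A0 is not None:
        return float(A0)
    if series.ligand_total[0] == 0.0:
        return series.signal[0]
    raise ValueError(
        "A0 not supplied and the series has no zero-ligand point to take it from"
    )


def double_reciprocal_fit(
    series: TitrationSeries, A0: float = None, noise_floor: float = 0.0
) -> IsothermResult:
    """Estimate K_b from the double-reciprocal plot of a titration.

    Parameters
    ----------
    series
        The titration.  If ``A0`` is not given the zero-ligand point of the
        series supplies the free-protein signal.
    noise_floor
        Estimated 1-sigma signal noise, AU.  Points with
        ``|A - A0| < 3 * noise_floor`` are excluded before taking
        reciprocals (the transform amplifies noise without bound as
        ``A -> A0``); exclusions are logged.

    Raises
    ------
    ValueError
        On fewer than 3 admissible points, or when the fitted K_b or
        intercept has the wrong sign (non-saturating data).
    """
    A0 = _resolve_A0(series, A0)
    lig = np.asarray(series.ligand_total)
    sig = np.asarray(series.signal)
    delta = sig - A0
    mask = (lig > 0) & (np.abs(delta) > 3.0 * noise_floor) & (delta != 0)
    n_excluded = int(np.sum(~mask))
    if n_excluded:
        logger.info(
            "double_reciprocal_fit: excluded %d point(s) (zero ligand or |A-A0| "
            "below 3x noise floor %.3g AU)",
            n_excluded,
            noise_floor,
        )
    if mask.sum() < 3:
        raise ValueError("fewer than 3 admissible points for the reciprocal fit")
    fit = fit_line(1.0 / lig[mask], 1.0 / delta[mask])
    # The direction of the signal change fixes the sign of A_inf - A0 and
    # hence of the intercept; K_b must come out positive either way.
    direction = np.sign(np.median(delta[mask]))
    if fit.intercept == 0 or np.sign(fit.intercept) != direction:
        raise ValueError(
            f"double-reciprocal intercept {fit.intercept:.4g} has the wrong sign "
            "for the observed signal change: data do not approach saturation"
        )
    K_b = fit.intercept / fit.slope
    if not K_b > 0:
        raise ValueError(
            f"non-positive binding constant estimate K_b = {K_b:.4g} M^-1: "
            "data do not approach saturation"
        )
    A_inf = A0 + 1.0 / fit.intercept
    endpoints = EndpointPair(A0=A0, A_inf=A_inf)
    L_half, extrapolated = _half_saturation(series, endpoints)
    return IsothermResult(
        K_b=float(K_b),
        endpoints=endpoints,
        L_half=L_half,
        fit=fit,
        temperature=series.temperature,
        L_half_extrapolated=extrapolated,
    )


def hyperbola_fit(series: TitrationSeries, A0: float = None) -> tuple:
    """Direct nonlinear fit of ``A = A0 + (A_inf - A0) K L / (1 + K L)``.

    Cross-check for :func:`double_reciprocal_fit`; returns ``(K_b, A_inf)``.
    """
    A0 = _resolve_A0(series, A0)
    lig = np.asarray(series.ligand_total)
    sig = np.asarray(series.signal)

    def model(L, K, A_inf):
        return A0 + (A_inf - A0) * K * L / (1.0 + K * L)

    span = sig[-1] - A0
    K0 = 1.0 / max(lig[-1] / 2.0, np.finfo(float).tiny)
    popt, _ = curve_fit(model, lig, sig, p0=[K0, A0 + 2.0 * span], maxfev=20000)
    K_b, A_inf = popt
    if not K_b > 0:
        raise ValueError(f"non-positive binding constant estimate K_b = {K_b:.4g}")
    return float(K_b), float(A_inf)


def fractional_saturation(series: TitrationSeries, endpoints: EndpointPair) -> np.ndarray:
    """Per-point fractional saturation α = (A − A0)/(A_inf − A0), clipped to [0, 1]."""
    sig = np.asarray(series.signal)
    alpha = (sig - endpoints.A0) / endpoints.amplitude
    return np.clip(alpha, 0.0, 1.0)


def saturation_curve(
    series: TitrationSeries, endpoints: EndpointPair, g: float = 1.0
) -> list:
    """Binding isotherm points ``(nu, signal)`` with ``nu = α g``."""
    alpha = fractional_saturation(series, endpoints)
    sig = np.asarray(series.signal)
    return [(float(a * g), float(s)) for a, s in zip(alpha, sig)]


def _half_saturation(series: TitrationSeries, endpoints: EndpointPair) -> tuple:
    lig = np.asarray(series.ligand_total)
    alpha = fractional_saturation(series, endpoints)
    # tolerate small noise-induced non-monotonicity; beyond 2% of the range,
    # smooth with isotonic regression before interpolating
    drops = np.diff(alpha)
    if np.any(drops < -0.02):
        warnings.warn(
            "saturation profile is non-monotone beyond noise tolerance; "
            "interpolating on an isotonic-regression smoothing",
            ExtrapolationWarning,
            stacklevel=3,
        )
        from sklearn.isotonic import IsotonicRegression

        alpha = IsotonicRegression(increasing=True).fit_transform(lig, alpha)
    if alpha.max() >= 0.5 and alpha.min() <= 0.5:
        # interpolate on the first crossing segment
        idx = int(np.argmax(alpha >= 0.5))
        if alpha[idx] == 0.5:
            return float(lig[idx]), False
        a_lo, a_hi = alpha[idx - 1], alpha[idx]
        frac = (0.5 - a_lo) / (a_hi - a_lo)
        return float(lig[idx - 1] + frac * (lig[idx] - lig[idx - 1])), False
    # extrapolate linearly from the end segment
    if alpha.max() < 0.5:
        i0, i1 = -2, -1
    else:
        i0, i1 = 0, 1
    slope = (alpha[i1] - alpha[i0]) / (lig[i1] - lig[i0])
    L_half = lig[i1] + (0.5 - alpha[i1]) / slope if slope != 0 else float("nan")
    return float(L_half), True


def half_saturation(series: TitrationSeries, endpoints: EndpointPair) -> float:
    """Total ligand concentration at half-saturation (α = 0.5), M.

    Obtained by monotone piecewise-linear interpolation of α against total
    ligand; warns and extrapolates from the end segment when the titration
    does not span α = 0.5.
    """
    L_half, extrapolated = _half_saturation(series, endpoints)
    if extrapolated:
        warnings.warn(
            "titration does not span half-saturation; L_half extrapolated",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return L_half


def thermo_table(result_T1: IsothermResult, result_T2: IsothermResult) -> tuple:
    """Full thermodynamic table from isotherms at two temperatures.

    ΔG° at each temperature from its binding constant, a shared two-point
    van't Hoff ΔH°, and ΔS° at each temperature from ΔS = (ΔH − ΔG)/T.
    """
    if result_T1.temperature == result_T2.temperature:
        raise ValueError("the two isotherms must be at distinct temperatures")
    out = []
    dH = vant_hoff_two_point(
        result_T1.K_b, result_T1.temperature, result_T2.K_b, result_T2.temperature
    )
    for res in (result_T1, result_T2):
        dG = gibbs_from_kb(res.K_b, res.temperature)
        dS = entropy_from_gh(dG, dH, res.temperature)
        out.append(
            ThermoResult(
                delta_G=dG,
                T=res.temperature,
                delta_H=dH,
                delta_S=dS,
                source_Kb=res.K_b,
            )
        )
    return tuple(out)
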