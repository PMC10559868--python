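"""Double-reciprocal isotherm analysis, half-saturation and the
two-temperature thermodynamic table."""

import warnings

import numpy as np
import pytest

from specbind import (
    EndpointPair,
    NoiseSpec,
    TitrationSeries,
    default_config,
    double_reciprocal_fit,
    gen_uv_titration,
    gibbs_from_enthalpy_entropy,
    half_saturation,
    hyperbola_fit,
    saturation_curve,
    thermo_table,
)
from specbind.core import ExtrapolationWarning
from specbind.isotherm import IsothermResult, _half_saturation
from specbind.core import LineFit


def make_isotherm_result(K_b, T):
    fit = LineFit(1.0, 1.0, 1.0, 5)
    return IsothermResult(
        K_b=K_b,
        endpoints=EndpointPair(0.9, 0.6),
        L_half=1.0 / K_b,
        fit=fit,
        temperature=T,
    )


class TestDoubleReciprocal:
    def test_exact_points_on_the_line(self):
        # 1/(A-A0) = 2 + 1e-3 * (1/L)  ->  K_b = 2000, A_inf = A0 + 0.5
        A0 = 0.1
        L = np.array([2e-4, 5e-4, 1e-3])
        A = A0 + 1.0 / (2.0 + 1e-3 / L)
        series = TitrationSeries(1e-9, tuple(L), tuple(A), 300.0)
        res = double_reciprocal_fit(series, A0=A0)
        assert res.K_b == pytest.approx(2000.0, rel=1e-9)
        assert res.endpoints.A_inf == pytest.approx(A0 + 0.5, rel=1e-9)

    def test_noiseless_round_trip(self):
        cfg = default_config(
            "uv_titration",
            seed=0,
            protein_total=1e-9,  # negligible depletion
            truth={"K_b": 5000.0, "K_H": 5000.0, "n_H": 1.0, "g": 1.0},
            noise=NoiseSpec("multiplicative", 0.0),
        )
        series, truth = gen_uv_titration(cfg)
        res = double_reciprocal_fit(series)
        assert res.K_b == pytest.approx(truth["truth"]["K_b"], rel=1e-3)
        assert res.fit.r_squared > 0.9999

    def test_recovery_under_noise_median_over_seeds(self):
        """Median K_b over 50 noisy titrations lands within 5% of the truth.

        The titration spans fractional saturation ~0.3-0.9 (the reciprocal
        transform amplifies noise without bound below that) and uses 1 uM
        protein so ligand depletion stays below 1%.
        """
        grid = (0.0,) + tuple(np.linspace(63e-6, 1.33e-3, 12))
        vals = []
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            for seed in range(50):
                cfg = default_config(
                    "uv_titration", seed=seed, protein_total=1e-6, grid=grid
                )
                series, _ = gen_uv_titration(cfg)
                vals.append(double_reciprocal_fit(series, noise_floor=0.0045).K_b)
        assert np.median(vals) == pytest.approx(6778.0, rel=0.05)

    def test_non_saturating_data_raise(self):
        # supra-linear signal change (no saturation): the reciprocal plot's
        # intercept lands on the wrong side of zero
        L = np.array([1e-6, 2e-6, 3e-6, 4e-6])
        A = 0.5 - 1e-3 * (L / 1e-6) ** 1.5
        series = TitrationSeries(1e-9, tuple(L), tuple(A), 300.0)
        with pytest.raises(ValueError):
            double_reciprocal_fit(series, A0=0.5)

    def test_missing_A0_raises_without_zero_point(self):
        series = TitrationSeries(1e-9, (1e-6, 2e-6, 3e-6), (0.8, 0.7, 0.6), 300.0)
        with pytest.raises(ValueError, match="A0"):
            double_reciprocal_fit(series)

    def test_agrees_with_direct_hyperbola_fit_noiseless(self):
        cfg = default_config(
            "uv_titration",
            seed=0,
            protein_total=1e-9,
            noise=NoiseSpec("multiplicative", 0.0),
        )
        series, truth = gen_uv_titration(cfg)
        res = double_reciprocal_fit(series)
        K_direct, A_inf_direct = hyperbola_fit(series)
        assert res.K_b == pytest.approx(K_direct, rel=1e-4)
        assert res.endpoints.A_inf == pytest.approx(A_inf_direct, rel=1e-4)


class TestSaturationCurve:
    def test_endpoint_identities(self):
        ep = EndpointPair(A0=0.9, A_inf=0.6)
        series = TitrationSeries(1e-6, (0.0, 1e-5, 2e-5), (0.9, 0.75, 0.6), 300.0)
        curve = saturation_curve(series, ep, g=2.0)
        assert curve[0][0] == 0.0  # A == A0 -> nu = 0
        assert curve[-1][0] == pytest.approx(2.0)  # A == A_inf -> nu = g

    def test_half_occupancy_scales_with_g(self):
        ep = EndpointPair(A0=0.0, A_inf=1.0)
        series = TitrationSeries(1e-6, (0.0, 1e-5, 2e-5), (0.0, 0.5, 1.0), 300.0)
        curve = saturation_curve(series, ep, g=3.8)
        assert curve[1][0] == pytest.approx(1.9)


class TestHalfSaturation:
    def test_exact_grid_point(self):
        ep = EndpointPair(A0=0.0, A_inf=1.0)
        series = TitrationSeries(1e-9, (0.0, 10e-6, 20e-6), (0.0, 0.5, 1.0), 300.0)
        assert half_saturation(series, ep) == pytest.approx(10e-6)

    def test_linear_interpolation(self):
        ep = EndpointPair(A0=0.0, A_inf=1.0)
        series = TitrationSeries(1e-9, (0.0, 10e-6, 20e-6), (0.0, 0.4, 0.8), 300.0)
        assert half_saturation(series, ep) == pytest.approx(12.5e-6)

    def test_strong_binder_half_saturation_at_reciprocal_K(self):
        grid = (0.0,) + tuple(np.linspace(0.1e-6, 5e-6, 30))
        cfg = default_config(
            "uv_titration",
            seed=0,
            protein_total=1e-12,
            grid=grid,
            truth={"K_b": 1e6, "K_H": 1e6, "n_H": 1.0, "g": 1.0},
            noise=NoiseSpec("multiplicative", 0.0),
        )
        series, _ = gen_uv_titration(cfg)
        L_half = half_saturation(series, cfg.endpoints)
        assert L_half == pytest.approx(1e-6, rel=0.01)

    def test_extrapolation_flagged(self):
        ep = EndpointPair(A0=0.0, A_inf=1.0)
        series = TitrationSeries(1e-9, (0.0, 10e-6, 20e-6), (0.0, 0.1, 0.2), 300.0)
        with pytest.warns(ExtrapolationWarning):
            L_half = half_saturation(series, ep)
        assert L_half > 20e-6

    def test_invariant_under_signal_rescaling(self):
        grid = (0.0,) + tuple(np.linspace(20e-6, 600e-6, 15))
        cfg = default_config(
            "uv_titration", seed=3, protein_total=1e-9, grid=grid,
            noise=NoiseSpec("multiplicative", 0.0),
        )
        series, _ = gen_uv_titration(cfg)
        ep = cfg.endpoints
        base = half_saturation(series, ep)
        scaled = TitrationSeries(
            series.protein_total,
            series.ligand_total,
            tuple(5.0 * s for s in series.signal),
            series.temperature,
        )
        ep_scaled = EndpointPair(5.0 * ep.A0, 5.0 * ep.A_inf)
        assert half_saturation(scaled, ep_scaled) == pytest.approx(base, rel=1e-12)

    def test_nonmonotone_profile_smoothed_with_warning(self):
        ep = EndpointPair(A0=0.0, A_inf=1.0)
        series = TitrationSeries(
            1e-9,
            (0.0, 5e-6, 10e-6, 15e-6, 20e-6),
            (0.0, 0.45, 0.30, 0.70, 1.0),  # dip beyond the 2% tolerance
            300.0,
        )
        with pytest.warns(ExtrapolationWarning, match="non-monotone"):
            L_half, extrap = _half_saturation(series, ep)
        assert 0 < L_half < 20e-6


class TestThermoTable:
    def test_worked_example_pair(self):
        r300 = make_isotherm_result(6778.0, 300.0)
        r310 = make_isotherm_result(3038.0, 310.0)
        t1, t2 = thermo_table(r300, r310)
        assert t1.delta_H == pytest.approx(-62.1, abs=0.5)
        assert t1.delta_S == pytest.approx(-133.6, abs=0.5)
        assert t1.delta_G == pytest.approx(-22.0, abs=0.3)

    def test_equal_constants_give_zero_enthalpy(self):
        t1, t2 = thermo_table(
            make_isotherm_result(500.0, 300.0), make_isotherm_result(500.0, 310.0)
        )
        assert t1.delta_H == pytest.approx(0.0, abs=1e-9)
        assert t1.delta_S == pytest.approx(-t1.delta_G * 1000.0 / t1.T, rel=1e-9)

    def test_chained_identity_random_inputs(self, rng):
        for _ in range(20):
            K1, K2 = rng.uniform(10, 1e6, 2)
            T1 = rng.uniform(270, 320)
            T2 = T1 + rng.uniform(5, 30)
            t1, t2 = thermo_table(
                make_isotherm_result(K1, T1), make_isotherm_result(K2, T2)
            )
            for t in (t1, t2):
                assert gibbs_from_enthalpy_entropy(
                    t.delta_H, t.delta_S, t.T
                ) == pytest.approx(t.delta_G, rel=1e-9, abs=1e-9)

    def test_decreasing_K_with_T_implies_exothermic(self):
        t1, _ = thermo_table(
            make_isotherm_result(6778.0, 300.0), make_isotherm_result(3038.0, 310.0)
        )
        assert t1.delta_H < 0

    def test_equal_temperatures_rejected(self):
        with pytest.raises(ValueError):
            thermo_table(
                make_isotherm_result(100.0, 300.0), make_isotherm_result(200.0, 300.0)
            )
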