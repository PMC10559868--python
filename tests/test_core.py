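"""Unit and property tests for the shared binding model and thermodynamics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specbind import (
    R,
    BindingParameters,
    DrivingForce,
    EndpointPair,
    ThermoResult,
    TitrationSeries,
    classify_driving_force,
    entropy_from_gh,
    fit_line,
    gibbs_from_enthalpy_entropy,
    gibbs_from_kb,
    nu_forward,
    solve_mass_balance,
    vant_hoff_two_point,
)

params_strategy = st.builds(
    BindingParameters,
    K_b=st.floats(1.0, 1e8),
    g=st.floats(0.2, 5.0),
    n_H=st.floats(0.3, 3.0),
    K_H=st.floats(1.0, 1e8),
)


class TestFitLine:
    @pytest.mark.parametrize(
        "x, y, slope, intercept, r2",
        [
            ([0, 1, 2], [1, 3, 5], 2.0, 1.0, 1.0),  # exact line
            ([0, 1], [0, 0], 0.0, 0.0, 1.0),  # flat, zero-variance response
            # normal-equation oracle: slope = (n Sxy - Sx Sy)/(n Sxx - Sx^2)
            # = (4*35 - 6*13)/(4*14 - 36) = 3.1; intercept = (13 - 3.1*6)/4 = -1.4
            ([0, 1, 2, 3], [0, 1, 2, 10], 3.1, -1.4, None),
        ],
    )
    def test_against_closed_form_ols(self, x, y, slope, intercept, r2):
        fit = fit_line(x, y)
        assert fit.slope == pytest.approx(slope, abs=1e-12)
        assert fit.intercept == pytest.approx(intercept, abs=1e-12)
        if r2 is not None:
            assert fit.r_squared == pytest.approx(r2, abs=1e-12)
        assert fit.n_points == len(x)

    def test_degenerate_x_raises(self):
        with pytest.raises(ValueError, match="slope is not identifiable"):
            fit_line([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            fit_line([1.0], [1.0])


class TestForwardModel:
    def test_zero_ligand_gives_zero_occupancy(self, single_site_params):
        assert nu_forward(0.0, single_site_params) == 0.0

    def test_half_saturation_by_symmetry(self):
        # K_H * L^n_H = 1 puts the site set at half occupancy
        p = BindingParameters(K_b=1e4, g=3.0, n_H=1.7, K_H=1e4)
        L = (1.0 / p.K_H) ** (1.0 / p.n_H)
        assert nu_forward(L, p) == pytest.approx(p.g / 2, rel=1e-12)

    def test_direct_evaluation(self):
        p = BindingParameters(K_b=1e4, g=2.0, n_H=1.0, K_H=1e4)
        assert nu_forward(1e-4, p) == pytest.approx(1.0, rel=1e-12)

    @settings(derandomize=True, max_examples=50)
    @given(params=params_strategy, data=st.data())
    def test_monotone_and_bounded(self, params, data):
        Ls = sorted(
            data.draw(st.lists(st.floats(0.0, 1e-2), min_size=3, max_size=10))
        )
        nus = [nu_forward(L, params) for L in Ls]
        assert all(0.0 <= nu < params.g or nu == params.g for nu in nus)
        assert all(b >= a - 1e-15 for a, b in zip(nus, nus[1:]))


class TestMassBalance:
    def test_zero_total(self, single_site_params):
        assert solve_mass_balance(0.0, 1e-5, single_site_params) == (0.0, 0.0)

    def test_no_depletion_limit(self, single_site_params):
        L_free, _ = solve_mass_balance(1e-5, 1e-15, single_site_params)
        assert L_free == pytest.approx(1e-5, rel=1e-9)

    def test_matches_quadratic_closed_form(self):
        # for n_H = g = 1 the free ligand is the positive root of
        # K L^2 + (1 + K (P - Lt)) L - Lt = 0
        K, P, Lt = 1e6, 1e-5, 1e-5
        p = BindingParameters.single_site(K)
        roots = np.roots([K, 1.0 + K * (P - Lt), -Lt])
        expected = float(max(roots))
        L_free, nu = solve_mass_balance(Lt, P, p)
        assert L_free == pytest.approx(expected, rel=1e-9)
        assert 0.0 <= L_free <= Lt

    @settings(derandomize=True, max_examples=100)
    @given(
        params=params_strategy,
        L_total=st.floats(1e-9, 1e-2),
        P_total=st.floats(1e-9, 1e-3),
    )
    def test_mass_conservation(self, params, L_total, P_total):
        L_free, nu = solve_mass_balance(L_total, P_total, params)
        assert L_free + nu * P_total == pytest.approx(L_total, rel=1e-10)


class TestThermodynamics:
    def test_gibbs_worked_example_cisplatin(self):
        # K_b = 1183 1/M at 298 K for the clinical-drug control row
        assert gibbs_from_kb(1183.0, 298.0) == pytest.approx(-17.6, abs=0.2)

    def test_gibbs_unit_and_identity_cases(self):
        assert gibbs_from_kb(1.0, 310.0) == 0.0
        assert gibbs_from_kb(math.e, 300.0) == pytest.approx(-R * 300.0 / 1000.0, rel=1e-12)

    def test_gibbs_rejects_nonpositive_kb(self):
        with pytest.raises(ValueError):
            gibbs_from_kb(0.0, 300.0)

    def test_vant_hoff_equal_constants(self):
        assert vant_hoff_two_point(500.0, 300.0, 500.0, 310.0) == pytest.approx(0.0, abs=1e-12)

    def test_vant_hoff_worked_example(self):
        # Pt-complex pair: 6778 1/M at 300 K, 3038 1/M at 310 K
        dH = vant_hoff_two_point(6778.0, 300.0, 3038.0, 310.0)
        assert dH == pytest.approx(-62.1, abs=0.5)

    def test_vant_hoff_closed_form(self):
        expected = R * math.log(2.0) / (1.0 / 290.0 - 1.0 / 300.0) / 1000.0
        assert vant_hoff_two_point(100.0, 290.0, 200.0, 300.0) == pytest.approx(
            expected, rel=1e-12
        )

    def test_vant_hoff_equal_temperatures_raise(self):
        with pytest.raises(ValueError):
            vant_hoff_two_point(100.0, 300.0, 200.0, 300.0)

    @settings(derandomize=True, max_examples=100)
    @given(
        K1=st.floats(1e-3, 1e9),
        K2=st.floats(1e-3, 1e9),
        T1=st.floats(250.0, 350.0),
        T2=st.floats(250.0, 350.0),
    )
    def test_vant_hoff_two_algebraic_forms_agree(self, K1, K2, T1, T2):
        if abs(T1 - T2) < 1.0:
            T2 = T1 + 5.0
        via_gibbs = vant_hoff_two_point(K1, T1, K2, T2)
        direct = R * math.log(K2 / K1) / (1.0 / T1 - 1.0 / T2) / 1000.0
        assert via_gibbs == pytest.approx(direct, rel=1e-9, abs=1e-12)

    @pytest.mark.parametrize(
        "dG, dH, T, expected, tol",
        [
            (-22.0, -62.1, 300.0, -133.6, 0.5),  # printed 300 K row
            (-22.7, -62.1, 310.0, -126.9, 0.5),  # printed 310 K row
            (-40.0, -40.0, 300.0, 0.0, 1e-12),
        ],
    )
    def test_entropy_from_gibbs_helmholtz(self, dG, dH, T, expected, tol):
        assert entropy_from_gh(dG, dH, T) == pytest.approx(expected, abs=tol)

    @settings(derandomize=True, max_examples=100)
    @given(
        K1=st.floats(1.0, 1e8),
        K2=st.floats(1.0, 1e8),
        T1=st.floats(260.0, 340.0),
    )
    def test_chained_cycle_closes(self, K1, K2, T1):
        """gibbs + van't Hoff + entropy chained satisfy dG = dH - T dS."""
        T2 = T1 + 10.0
        dH = vant_hoff_two_point(K1, T1, K2, T2)
        for K, T in ((K1, T1), (K2, T2)):
            dG = gibbs_from_kb(K, T)
            dS = entropy_from_gh(dG, dH, T)
            assert gibbs_from_enthalpy_entropy(dH, dS, T) == pytest.approx(
                dG, rel=1e-9, abs=1e-9
            )


class TestDrivingForce:
    @pytest.mark.parametrize(
        "dH, dS, expected",
        [
            (-62.1, -133.6, DrivingForce.VDW_OR_HBOND),
            (10.0, 50.0, DrivingForce.HYDROPHOBIC),
            (-5.0, 20.0, DrivingForce.ELECTROSTATIC),
            (5.0, -20.0, DrivingForce.MIXED),
            (0.0, -20.0, DrivingForce.MIXED),  # zero treated as mixed
        ],
    )
    def test_sign_rules(self, dH, dS, expected):
        assert classify_driving_force(dH, dS) is expected


class TestDomainTypes:
    def test_titration_series_invariants(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TitrationSeries(1e-5, (0.0, 2e-6, 1e-6), (1.0, 0.9, 0.8), 300.0)
        with pytest.raises(ValueError, match="at least 3"):
            TitrationSeries(1e-5, (0.0, 1e-6), (1.0, 0.9), 300.0)

    def test_endpoints_must_differ(self):
        with pytest.raises(ValueError):
            EndpointPair(A0=0.5, A_inf=0.5)

    def test_thermo_result_consistency_guard(self):
        ThermoResult(delta_G=-22.0, T=300.0, delta_H=-62.1, delta_S=-133.67)
        with pytest.raises(ValueError, match="inconsistent"):
            ThermoResult(delta_G=-22.0, T=300.0, delta_H=-62.1, delta_S=-100.0)

    def test_binding_parameters_positive(self):
        with pytest.raises(ValueError):
            BindingParameters(K_b=0.0, g=1.0, n_H=1.0, K_H=1.0)
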