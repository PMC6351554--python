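"""Competitive-binding chemistry: calibration, equilibrium, mass action."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import solve_ivp

from pbutkin.binding import (
    BOUND_IDX,
    FREE_IDX,
    P_IDX,
    SoluteDefinition,
    SpeciesVector,
    calibrate_binding,
    free_fraction,
    mass_action_rates,
    rate_constants,
    solve_competitive_equilibrium,
)

IS_DEF = SoluteDefinition("IS", 100e-6, 0.07, 213.21)
PCS_DEF = SoluteDefinition("pCS", 150e-6, 0.05, 188.20)
P_TOT = 600e-6


class TestFreeFraction:
    def test_matches_seven_percent_at_baseline_free_protein(self):
        # free albumin at the joint baseline equilibrium is 600 - 93 - 142.5 uM
        assert free_fraction(3.64e4, 364.5e-6) == pytest.approx(0.070, rel=5e-3)

    @pytest.mark.parametrize("K_A,P", [(0.0, 1e-3), (3.64e4, 0.0), (0.0, 0.0)])
    def test_unbinding_limits_give_unity(self, K_A, P):
        assert free_fraction(K_A, P) == 1.0

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            free_fraction(-1.0, 1e-4)
        with pytest.raises(ValueError):
            free_fraction(1e4, -1e-4)

    @given(st.floats(1e2, 1e7), st.floats(1e-7, 1e-3), st.floats(1.01, 10.0))
    @settings(derandomize=True, max_examples=50)
    def test_strictly_decreasing_in_free_protein(self, K_A, P, factor):
        assert free_fraction(K_A, P * factor) < free_fraction(K_A, P)


class TestCalibration:
    def test_reproduces_toxin_association_constants(self):
        IS, pCS = calibrate_binding([IS_DEF, PCS_DEF], P_TOT)
        assert IS.K_A == pytest.approx(3.64e4, rel=5e-3)
        assert pCS.K_A == pytest.approx(5.21e4, rel=5e-3)

    def test_dissociation_rate_from_fixed_association_rate(self):
        IS, _ = calibrate_binding([IS_DEF, PCS_DEF], P_TOT, k_assoc=1e8)
        assert IS.k_dissoc == pytest.approx(1e8 / IS.K_A)
        assert IS.k_dissoc == pytest.approx(2.75e3, rel=2e-2)

    def test_fully_free_solute_has_zero_affinity(self):
        (s,) = calibrate_binding([SoluteDefinition("x", 1e-4, 1.0, 100.0)], P_TOT)
        assert s.K_A == 0.0 and s.k_dissoc == 0.0

    def test_oversaturated_protein_is_infeasible(self):
        big = SoluteDefinition("big", 1e-3, 0.05, 100.0)  # 950 uM bound > albumin
        with pytest.raises(ValueError, match="saturat"):
            calibrate_binding([big], P_TOT)


def _quadratic_single_solute(K, tot, P_tot):
    """Closed-form single-solute equilibrium: PT from the binding quadratic."""
    a, b, c = K, -(K * tot + K * P_tot + 1.0), K * tot * P_tot
    PT = (-b - np.sqrt(b * b - 4 * a * c)) / (2 * a)
    return tot - PT, PT, P_tot - PT


class TestEquilibriumSolver:
    def test_round_trip_recovers_free_fractions(self):
        cal = calibrate_binding([IS_DEF, PCS_DEF], P_TOT)
        eq = solve_competitive_equilibrium(
            [s.K_A for s in cal], [s.total_conc_init for s in cal], P_TOT)
        assert eq[FREE_IDX[0]] == pytest.approx(7e-6, rel=1e-8)
        assert eq[FREE_IDX[1]] == pytest.approx(7.5e-6, rel=1e-8)

    def test_matches_single_solute_quadratic(self):
        K, tot = 5e4, 2e-4
        T, PT, P = _quadratic_single_solute(K, tot, P_TOT)
        eq = solve_competitive_equilibrium([K], [tot], P_TOT)
        assert eq[0] == pytest.approx(T, rel=1e-10)
        assert eq[1] == pytest.approx(PT, rel=1e-10)
        assert eq[P_IDX] == pytest.approx(P, rel=1e-10)

    def test_empty_system_keeps_protein_free(self):
        eq = solve_competitive_equilibrium([1e4, 2e4], [0.0, 0.0], P_TOT)
        assert eq[P_IDX] == P_TOT
        assert np.all(eq[:6] == 0.0)

    def test_kinetic_relaxation_converges_to_equilibrium_root(self):
        cal = calibrate_binding([IS_DEF, PCS_DEF], P_TOT)
        k1, k2 = rate_constants(cal)
        y0 = np.zeros(7)
        y0[FREE_IDX[:2]] = [100e-6, 150e-6]  # start fully unbound
        y0[P_IDX] = P_TOT
        sol = solve_ivp(lambda t, y: mass_action_rates(y, k1, k2),
                        (0.0, 1.0), y0, method="BDF", rtol=1e-10, atol=1e-16)
        eq = solve_competitive_equilibrium(
            [s.K_A for s in cal], [s.total_conc_init for s in cal], P_TOT)
        np.testing.assert_allclose(sol.y[:, -1], eq, rtol=1e-6)

    @given(st.floats(1e-6, 5e-4), st.floats(1e-6, 5e-4))
    @settings(derandomize=True, max_examples=30)
    def test_displacer_dose_raises_both_toxin_free_fractions(self, d_lo, d_hi):
        # a binding competitor lowers free protein, so more displacer means a
        # higher equilibrium free fraction for every co-resident toxin
        if d_lo > d_hi:
            d_lo, d_hi = d_hi, d_lo
        if np.isclose(d_lo, d_hi):
            return
        K = [3.64e4, 5.21e4, 1.73e4]
        for i in range(2):
            lo = solve_competitive_equilibrium(K, [100e-6, 150e-6, d_lo], P_TOT)
            hi = solve_competitive_equilibrium(K, [100e-6, 150e-6, d_hi], P_TOT)
            tot = [100e-6, 150e-6][i]
            assert hi[FREE_IDX[i]] / tot > lo[FREE_IDX[i]] / tot


class TestMassActionRates:
    def test_zero_at_equilibrium(self):
        cal = calibrate_binding([IS_DEF, PCS_DEF], P_TOT)
        k1, k2 = rate_constants(cal)
        eq = solve_competitive_equilibrium(
            [s.K_A for s in cal], [s.total_conc_init for s in cal], P_TOT)
        rates = mass_action_rates(eq, k1, k2)
        assert np.all(np.abs(rates) < 1e-12)

    def test_fully_unbound_start_binds(self):
        k1 = np.array([1e8, 0, 0])
        k2 = np.array([1e4, 0, 0])
        C = np.zeros(7)
        C[0], C[P_IDX] = 1e-4, P_TOT
        r = mass_action_rates(C, k1, k2)
        assert r[0] == pytest.approx(-1e8 * 1e-4 * P_TOT)
        assert r[1] == -r[0] and r[P_IDX] == r[0]

    @given(st.lists(st.floats(0, 1e-3), min_size=7, max_size=7))
    @settings(derandomize=True, max_examples=50)
    def test_conservation_per_solute_for_any_state(self, vals):
        k1 = np.array([1e8, 1e8, 1e8])
        k2 = np.array([2.7e3, 1.9e3, 5.8e3])
        r = mass_action_rates(np.array(vals), k1, k2)
        for i in range(3):
            assert r[FREE_IDX[i]] + r[BOUND_IDX[i]] == pytest.approx(0.0, abs=1e-18)
        assert r[P_IDX] == pytest.approx(r[FREE_IDX].sum(), rel=1e-12)

    def test_nodewise_rates_on_spatial_grid(self):
        k1 = np.array([1e8, 0, 0])
        k2 = np.array([1e4, 0, 0])
        C = np.zeros((7, 5))
        C[0] = np.linspace(0, 1e-4, 5)
        C[P_IDX] = P_TOT
        r = mass_action_rates(C, k1, k2)
        assert r.shape == (7, 5)
        np.testing.assert_allclose(r[0], -1e8 * C[0] * P_TOT)


def test_species_vector_round_trip_and_totals():
    v = SpeciesVector(T1=7e-6, PT1=93e-6, T2=7.5e-6, PT2=142.5e-6, P=364.5e-6)
    assert SpeciesVector.from_array(v.as_array()) == v
    assert v.total(0) == pytest.approx(100e-6)
    assert v.total(1) == pytest.approx(150e-6)
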