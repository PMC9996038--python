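"""Closed-form model functions: frozen examples and invariants."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hergfit.model_core import (
    BoltzmannParams,
    DoubleBoltzmannParams,
    ExpMixture,
    GatingParams,
    HillParams,
    boltzmann_gv,
    double_boltzmann_gv,
    equilibrium_constants,
    exp_mixture_value,
    hill_response,
    po_equilibrium,
    reduced_potential,
    state_occupancies,
)


class TestReducedPotential:
    def test_zero_voltage(self, ctx):
        assert reduced_potential(0.0, ctx) == 0.0

    def test_unit_value_near_25mV(self, ctx):
        # 96485 * 0.02542 / (8.314 * 295.15) = 0.99950 (hand-checked)
        assert reduced_potential(25.42, ctx) == pytest.approx(0.99950, abs=1e-4)

    def test_antisymmetry(self, ctx):
        assert reduced_potential(-25.42, ctx) == -reduced_potential(25.42, ctx)

    def test_nonfinite_voltage_rejected(self, ctx):
        with pytest.raises(ValueError):
            reduced_potential(float("nan"), ctx)


class TestEquilibriumConstants:
    def test_zero_voltage_returns_zero_voltage_constants(self, control_gating, ctx):
        K, Ko = equilibrium_constants(control_gating, 0.0, ctx)
        assert (K, Ko) == (0.155, 0.32)

    def test_hyperpolarized_value(self, control_gating, ctx):
        # independent oracle: direct evaluation of the two exponentials at
        # -100 mV, T = 295.15 K (u = -3.931941): K = 0.155*e^(1.71*u),
        # Ko = 0.32*e^(0.73*u), computed with math.exp
        u = 0.1 * 96485.0 / (8.314 * 295.15)
        K, Ko = equilibrium_constants(control_gating, -100.0, ctx)
        assert K == pytest.approx(0.155 * math.exp(1.71 * u), rel=1e-12)
        assert Ko == pytest.approx(0.32 * math.exp(0.73 * u), rel=1e-12)

    def test_monotone_decreasing_with_depolarization(self, control_gating, ctx):
        V = np.arange(-140.0, 61.0, 10.0)
        K, Ko = equilibrium_constants(control_gating, V, ctx)
        assert np.all(np.diff(K) < 0) and np.all(np.diff(Ko) < 0)


class TestStateOccupancies:
    def test_depolarized_limit_fully_open(self, control_gating, ctx):
        sv = state_occupancies(control_gating, 1500.0, ctx)
        assert sv.open_probability == pytest.approx(1.0, abs=1e-9)

    def test_hyperpolarized_limit_fully_resting(self, control_gating, ctx):
        sv = state_occupancies(control_gating, -1500.0, ctx)
        assert sv["C0"] == pytest.approx(1.0, abs=1e-9)

    def test_open_occupancy_at_zero_voltage(self, control_gating, ctx):
        # independent hand calculation: Po = 1/(1 + 0.32 * 1.155^4) = 0.637154
        sv = state_occupancies(control_gating, 0.0, ctx)
        assert sv.open_probability == pytest.approx(0.637154, abs=1e-6)

    @pytest.mark.parametrize("V", np.arange(-200.0, 201.0, 25.0).tolist())
    def test_sums_to_one_over_wide_range(self, control_gating, ctx, V):
        sv = state_occupancies(control_gating, V, ctx)
        assert abs(sv.occupancies.sum() - 1.0) < 1e-9
        assert np.all(sv.occupancies >= 0)


class TestPoEquilibrium:
    def test_matches_state_occupancies_entry(self, control_gating, rpr_gating, ctx):
        """Two independent code paths (binomial sum vs log1p form) agree to 1e-12."""
        for p in (control_gating, rpr_gating):
            for V in np.arange(-150.0, 151.0, 10.0):
                assert po_equilibrium(p, V, ctx) == pytest.approx(
                    state_occupancies(p, V, ctx).open_probability, abs=1e-12
                )

    def test_rpr_params_closed_form_value(self, rpr_gating, ctx):
        # brute-force evaluation of 1/(1 + Ko*(1+K)^4) at 0 mV:
        # 1/(1 + 0.513 * 1.023^4) = 0.640525 (hand-checked)
        assert po_equilibrium(rpr_gating, 0.0, ctx) == pytest.approx(
            1.0 / (1.0 + 0.513 * 1.023**4), rel=1e-12
        )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        K0=st.floats(1e-4, 10.0),
        z1=st.floats(0.1, 5.0),
        Ko0=st.floats(1e-4, 10.0),
        z2=st.floats(0.1, 5.0),
    )
    def test_monotone_nondecreasing_in_voltage(self, K0, z1, Ko0, z2):
        p = GatingParams(K0=K0, z1=z1, Ko0=Ko0, z2=z2)
        po = po_equilibrium(p, np.arange(-140.0, 61.0, 5.0))
        assert np.all(np.diff(po) >= -1e-15)
        assert 0.0 <= po[0] and po[-1] <= 1.0


class TestBoltzmann:
    def test_midpoint_is_half(self):
        p = BoltzmannParams(V05=-20.0, k=8.0)
        assert boltzmann_gv(-20.0, p) == 0.5

    def test_one_slope_factor_above_midpoint(self):
        p = BoltzmannParams(V05=-20.0, k=8.0)
        assert boltzmann_gv(-12.0, p) == pytest.approx(1 / (1 + math.e**-1), rel=1e-12)

    def test_saturation(self):
        p = BoltzmannParams(V05=-20.0, k=8.0)
        assert boltzmann_gv(500.0, p) == pytest.approx(1.0, abs=1e-12)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError):
            BoltzmannParams(V05=0.0, k=0.0)


class TestDoubleBoltzmann:
    def test_reduces_to_single_boltzmann(self):
        dp = DoubleBoltzmannParams(
            V05_hyp=-120.0, k_hyp=10.0, A_hyp=0.0,
            V05_dep=-25.0, k_dep=7.0, A_dep=1.0, offset=0.0,
        )
        V = np.arange(-140.0, 41.0, 10.0)
        assert double_boltzmann_gv(V, dp) == pytest.approx(
            boltzmann_gv(V, BoltzmannParams(-25.0, 7.0)), abs=1e-12
        )

    def test_symmetric_construction_at_shared_midpoint(self):
        # both branches sigma(0) = 0.5 scaled by 0.5 -> total 0.5 at -70 mV
        dp = DoubleBoltzmannParams(
            V05_hyp=-70.0, k_hyp=10.0, A_hyp=0.5,
            V05_dep=-70.0, k_dep=10.0, A_dep=0.5, offset=0.0,
        )
        assert double_boltzmann_gv(-70.0, dp) == pytest.approx(0.5, abs=1e-12)

    def test_biphasic_shape_rises_toward_hyperpolarization(self):
        # D540K-style control branch midpoints: conductance at -140 mV
        # exceeds the trough near -70 mV
        dp = DoubleBoltzmannParams(
            V05_hyp=-118.0, k_hyp=10.6, A_hyp=1.0,
            V05_dep=-24.7, k_dep=7.2, A_dep=1.0, offset=0.0,
        )
        assert double_boltzmann_gv(-140.0, dp) > double_boltzmann_gv(-70.0, dp)
        assert double_boltzmann_gv(40.0, dp) > double_boltzmann_gv(-70.0, dp)


class TestHill:
    P = HillParams(Amax=1.0, Amin=2.5, EC50=15.0, nH=1.3)

    def test_zero_dose_gives_Amax(self):
        assert hill_response(0.0, self.P) == self.P.Amax

    def test_half_effect_at_EC50(self):
        assert hill_response(15.0, self.P) == pytest.approx(1.75, rel=1e-12)

    def test_saturation_gives_Amin(self):
        assert hill_response(1e9, self.P) == pytest.approx(self.P.Amin, rel=1e-6)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            hill_response(-1.0, self.P)


class TestExpMixture:
    def test_initial_value_is_amplitude_sum(self):
        m = ExpMixture((10.0, 100.0), (0.7, 0.3), offset=0.1)
        assert exp_mixture_value(0.0, m) == pytest.approx(1.1, rel=1e-12)

    def test_mono_decay_one_tau(self):
        # control split-channel deactivation at -40 mV: tau = 67 ms
        m = ExpMixture((67.0,), (1.0,))
        assert exp_mixture_value(67.0, m) == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_long_time_limit_is_offset(self):
        m = ExpMixture((10.0,), (1.0,), offset=0.25)
        assert exp_mixture_value(1e6, m) == pytest.approx(0.25, abs=1e-12)

    def test_permutation_invariance_via_canonical_form(self):
        a = ExpMixture.from_unsorted((100.0, 10.0), (0.3, 0.7))
        b = ExpMixture.from_unsorted((10.0, 100.0), (0.7, 0.3))
        t = np.linspace(0, 400, 50)
        assert exp_mixture_value(t, a) == pytest.approx(exp_mixture_value(t, b), abs=1e-15)
        assert a.taus == b.taus == (10.0, 100.0)

    def test_unsorted_taus_rejected(self):
        with pytest.raises(ValueError):
            ExpMixture((100.0, 10.0), (0.3, 0.7))
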