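"""Least-squares fitters: exact recovery, misfit detection, degeneracy flags."""

import numpy as np
import pandas as pd
import pytest

from hergfit.conditions import solve_double_boltzmann
from hergfit.fitting import (
    DoseResponseDataset,
    GVDataset,
    fit_boltzmann,
    fit_double_boltzmann,
    fit_exp_decay,
    fit_gating_gv,
    fit_hill,
    select_exp_order,
)
from hergfit.model_core import (
    BoltzmannParams,
    ExpMixture,
    HillParams,
    exp_mixture_value,
)
from hergfit.synth import NoiseSpec, gen_dose_response, gen_gv, gen_tail_trace

NOISELESS = NoiseSpec(0.0, 0)
CONCS = [1.0, 3.0, 5.0, 10.0, 20.0, 30.0]


class TestHillFit:
    @pytest.mark.parametrize(
        "truth",
        [
            HillParams(Amax=1.0, Amin=2.5, EC50=15.0, nH=1.3),
            HillParams(Amax=1.0, Amin=4.0, EC50=7.9, nH=1.9),
            HillParams(Amax=10.0, Amin=2.0, EC50=5.0, nH=0.8),  # inhibition
        ],
    )
    def test_noiseless_exact_recovery(self, truth):
        ds = gen_dose_response(truth, CONCS, NOISELESS, n=1)
        hp, fr = fit_hill(ds)
        for name in ("Amax", "Amin", "EC50", "nH"):
            assert getattr(hp, name) == pytest.approx(getattr(truth, name), rel=1e-6)
        assert fr.converged and fr.rss < 1e-12

    def test_noisy_recovery_of_deactivation_EC50(self):
        """tau_deact concentration-response at -60 mV: EC50 near 7.9 uM."""
        truth = HillParams(Amax=1.0, Amin=4.0, EC50=7.9, nH=1.9)
        ds = gen_dose_response(
            truth, CONCS, NoiseSpec(0.03, seed=5, mode="fraction_of_span"), n=5
        )
        hp, fr = fit_hill(ds)
        assert fr.converged
        assert hp.EC50 == pytest.approx(7.9, rel=0.10)

    def test_flat_response_flagged(self):
        df = pd.DataFrame({"conc": CONCS, "response": np.ones(len(CONCS))})
        hp, fr = fit_hill(DoseResponseDataset(df))
        assert not fr.converged
        assert fr.flags

    def test_too_few_concentrations_rejected(self):
        df = pd.DataFrame({"conc": [1.0, 10.0, 30.0], "response": [1.0, 2.0, 2.5]})
        with pytest.raises(ValueError):
            fit_hill(DoseResponseDataset(df))


class TestBoltzmannFit:
    def test_noiseless_exact_recovery(self, voltage_grid):
        truth = BoltzmannParams(V05=-15.0, k=9.0)
        ds = gen_gv("boltzmann", truth, voltage_grid, NOISELESS, n=1)
        bp, fr = fit_boltzmann(ds)
        assert bp.V05 == pytest.approx(truth.V05, rel=1e-6)
        assert bp.k == pytest.approx(truth.k, rel=1e-6)

    def test_row_shuffle_invariance(self, voltage_grid):
        truth = BoltzmannParams(V05=-15.0, k=9.0)
        ds = gen_gv(
            "boltzmann", truth, voltage_grid, NoiseSpec(0.02, 3, "fraction_of_span"), n=2
        )
        shuffled = GVDataset(
            ds.data.sample(frac=1.0, random_state=9).reset_index(drop=True)
        )
        a, _ = fit_boltzmann(ds)
        b, _ = fit_boltzmann(shuffled)
        assert a.V05 == pytest.approx(b.V05, abs=1e-5)
        assert a.k == pytest.approx(b.k, abs=1e-5)

    def test_systematic_lack_of_fit_against_gating_model(self, control_gating, voltage_grid, ctx):
        """A Boltzmann cannot reproduce 6-state G-V data as well as the
        generating model: nested rss comparison on noiseless data."""
        ds = gen_gv("gating6", control_gating, voltage_grid, NOISELESS, n=1, ctx=ctx)
        _, fr_b = fit_boltzmann(ds)
        _, fr_g = fit_gating_gv(ds, ctx, n_starts=3, seed=0)
        assert fr_g.rss < fr_b.rss
        assert fr_b.rss > 1e-6  # visible lack of fit

    def test_underdetermined_dataset_rejected(self):
        df = pd.DataFrame({"V": [-40.0, 0.0], "g_norm": [0.1, 0.9]})
        with pytest.raises(ValueError):
            fit_boltzmann(GVDataset(df))


class TestDoubleBoltzmannFit:
    GRID = np.arange(-140.0, 41.0, 10.0)

    def test_noiseless_midpoints_recovered_within_1mV(self):
        truth = solve_double_boltzmann(
            {"V05_hyp": -118.0, "k_hyp": 10.6, "V05_dep": -24.7, "k_dep": 7.2}, 0.02
        )
        ds = gen_gv("double_boltzmann", truth, self.GRID, NOISELESS, n=1)
        dp, fr = fit_double_boltzmann(ds)
        assert dp.V05_hyp == pytest.approx(-118.0, abs=1.0)
        assert dp.V05_dep == pytest.approx(-24.7, abs=1.0)
        assert fr.converged

    def test_curve_minimum_matches_generator(self):
        truth = solve_double_boltzmann(
            {"V05_hyp": -114.0, "k_hyp": 9.2, "V05_dep": -23.9, "k_dep": 14.2}, 0.17
        )
        ds = gen_gv(
            "double_boltzmann", truth, self.GRID, NoiseSpec(0.02, 4), n=10
        )
        dp, fr = fit_double_boltzmann(ds)
        assert fr.extras["curve_min"] == pytest.approx(0.17, abs=0.02)

    def test_single_branch_data_degenerates_gracefully(self):
        bp = BoltzmannParams(V05=-25.0, k=7.0)
        ds = gen_gv("boltzmann", bp, self.GRID, NOISELESS, n=1)
        dp, fr = fit_double_boltzmann(ds)
        # depolarized branch carries the curve; fit reproduces the data
        assert fr.rss < 1e-6
        assert dp.V05_dep == pytest.approx(-25.0, abs=1.0) or dp.A_hyp < 1e-3


class TestGatingFit:
    def test_noiseless_exact_recovery(self, control_gating, voltage_grid, ctx):
        ds = gen_gv("gating6", control_gating, voltage_grid, NOISELESS, n=1, ctx=ctx)
        gp, fr = fit_gating_gv(ds, ctx, n_starts=5, seed=0)
        for name in ("K0", "z1", "Ko0", "z2"):
            assert getattr(gp, name) == pytest.approx(
                getattr(control_gating, name), rel=1e-4
            )
        assert fr.converged

    def test_row_shuffle_invariance(self, control_gating, voltage_grid, ctx):
        ds = gen_gv(
            "gating6", control_gating, voltage_grid,
            NoiseSpec(0.02, 8, "fraction_of_span"), n=3, ctx=ctx,
        )
        shuffled = GVDataset(ds.data.sample(frac=1.0, random_state=2).reset_index(drop=True))
        a, _ = fit_gating_gv(ds, ctx, n_starts=3, seed=1)
        b, _ = fit_gating_gv(shuffled, ctx, n_starts=3, seed=1)
        assert a.K0 == pytest.approx(b.K0, rel=1e-6)

    def test_flexible_enough_for_boltzmann_data(self, voltage_grid, ctx):
        bp = BoltzmannParams(V05=-10.0, k=10.0)
        ds = gen_gv("boltzmann", bp, voltage_grid, NOISELESS, n=1)
        _, fr_g = fit_gating_gv(ds, ctx, n_starts=5, seed=0)
        _, fr_b = fit_boltzmann(ds)
        assert fr_g.converged
        assert fr_g.rss < max(10 * fr_b.rss, 1e-4)

    def test_too_few_voltages_rejected(self, ctx):
        df = pd.DataFrame({"V": [-40, -20, 0, 20, 40.0], "g_norm": [0.1, 0.3, 0.6, 0.8, 1.0]})
        with pytest.raises(ValueError):
            fit_gating_gv(GVDataset(df), ctx)


class TestExpDecayFit:
    def test_noiseless_biexponential_exact_recovery(self):
        """N-del + RPR values at -60 mV: tau_f = 44 ms, tau_s = 1451 ms."""
        truth = ExpMixture((44.0, 1451.0), (0.6, 0.4))
        t = np.arange(0.0, 6000.0, 2.0)
        mix, fr = fit_exp_decay(t, exp_mixture_value(t, truth), 2)
        assert mix.taus == pytest.approx(truth.taus, rel=1e-6)
        assert mix.amps == pytest.approx(truth.amps, rel=1e-6)
        assert fr.converged

    def test_relative_slow_amplitude_recovered(self):
        truth = ExpMixture((44.0, 1451.0), (0.6, 0.4))
        tr = gen_tail_trace(truth, dt=2.0, duration=6000.0, noise=NoiseSpec(0.02, 17))
        mix, fr = fit_exp_decay(tr.time, tr.current, 2)
        rel_slow = abs(mix.amps[1]) / (abs(mix.amps[0]) + abs(mix.amps[1]))
        assert rel_slow == pytest.approx(0.4, abs=0.05)

    def test_overfitting_mono_data_is_flagged(self):
        truth = ExpMixture((67.0,), (1.0,))
        t = np.arange(0.0, 500.0, 1.0)
        mix, fr = fit_exp_decay(t, exp_mixture_value(t, truth), 2)
        assert fr.flags  # tau collapse or negligible amplitude
        assert not fr.converged

    def test_too_short_segment_rejected(self):
        with pytest.raises(ValueError):
            fit_exp_decay(np.arange(15.0), np.ones(15), 2)


class TestOrderSelection:
    def test_selects_printed_orders(self):
        """Mono, bi and tri archetypes at SNR 50 select their true order."""
        cases = [
            (1, ExpMixture((67.0,), (1.0,)), 500.0, 1.0),
            (2, ExpMixture((44.0, 1451.0), (0.6, 0.4)), 6000.0, 2.0),
            (3, ExpMixture((35.0, 442.0, 1970.0), (0.4, 0.3, 0.3)), 8000.0, 4.0),
        ]
        for true_order, mix, duration, dt in cases:
            peak = sum(mix.amps)
            tr = gen_tail_trace(mix, dt=dt, duration=duration, noise=NoiseSpec(peak / 50, 99))
            order, fits = select_exp_order(tr.time, tr.current)
            assert order == true_order

    def test_noiseless_mono_does_not_escalate(self):
        t = np.arange(0.0, 500.0, 1.0)
        y = exp_mixture_value(t, ExpMixture((67.0,), (1.0,)))
        order, _ = select_exp_order(t, y)
        assert order == 1
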