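"""Reference parameter sets for hERG1a channel variants with and without RPR260243.

These are the fitted values reported for two-electrode voltage-clamp
recordings from *Xenopus* oocytes expressing split hERG1a channels
(severed at the S4-S5 linker), N- and C-terminal truncated channels and
the D540K mutant, before and after treatment with the activator
RPR260243 (RPR).  They serve as ground-truth generating parameters for
the synthetic-data module and as initial values for refitting.

Units: voltages mV, time constants ms, concentrations uM.
"""

from __future__ import annotations

from .model_core import DoubleBoltzmannParams, GatingParams, HillParams

__all__ = [
    "SPLIT_GATING_CONTROL",
    "SPLIT_GATING_RPR",
    "HILL_SPLIT_ITAIL",
    "HILL_SPLIT_IPEAK",
    "HILL_SPLIT_TAU_DEACT",
    "SPLIT_TAU_CONTROL",
    "SPLIT_TAU_RPR",
    "NDEL_TAU_CONTROL",
    "NDEL_TAU_RPR",
    "NDEL_SLOW_FRACTION",
    "CDEL_TAU",
    "D540K_GV_CONTROL",
    "D540K_GV_RPR",
    "D540K_TROUGH_CONTROL",
    "D540K_TROUGH_RPR",
    "D540K_TAIL_TAUS_CONTROL",
    "D540K_TAIL_TAUS_RPR",
]

# 6-state gating model for split hERG1a channels (high-K bath)
SPLIT_GATING_CONTROL = GatingParams(K0=0.155, z1=1.71, Ko0=0.32, z2=0.73)
SPLIT_GATING_RPR = GatingParams(K0=0.023, z1=2.98, Ko0=0.513, z2=0.81)

# Cumulative concentration-response of RPR on split hERG1a channels.
# EC50 (uM) and Hill coefficients are reported values; the response
# endpoints encode the observed effect sizes relative to control = 1
# (I_tail-peak increased ~2.5-fold; I_peak modestly; tau_deact at -60 mV
# slowed ~4-fold).
HILL_SPLIT_ITAIL = HillParams(Amax=1.0, Amin=2.5, EC50=15.0, nH=1.3)
HILL_SPLIT_IPEAK = HillParams(Amax=1.0, Amin=1.6, EC50=8.2, nH=1.2)
HILL_SPLIT_TAU_DEACT = HillParams(Amax=1.0, Amin=4.0, EC50=7.9, nH=1.9)

# Mono-exponential deactivation time constants (ms) of split hERG1a
# channels at the extremes of the V_ret range; intermediate voltages are
# generated by log-linear interpolation in V.
SPLIT_TAU_CONTROL = {-40.0: 67.0, -140.0: 3.4}
SPLIT_TAU_RPR = {-40.0: 272.0, -140.0: 16.6}

# N-terminal truncated channels: mono-exponential under control,
# bi-exponential (tau_f, tau_s) with RPR.
NDEL_TAU_CONTROL = {-60.0: 17.4, -140.0: 3.6}
NDEL_TAU_RPR = {-60.0: (44.0, 1451.0), -140.0: (9.3, 62.0)}
NDEL_SLOW_FRACTION = 0.4  # relative amplitude of the slow component (range 0.32-0.47)

# C-terminal truncated channels: RPR does not alter deactivation, so the
# same time constants are used for both conditions.
CDEL_TAU = {-60.0: 15.0, -140.0: 3.0}

# D540K mutant biphasic G-V: (V05, k) for the hyperpolarization- and
# depolarization-activated branches, with the minimum g/gmax near -70 mV
# ("trough").  Amplitudes/offset are solved at generation time so the
# curve spans [trough, 1] over the protocol voltage range.
D540K_GV_CONTROL = {"V05_hyp": -118.0, "k_hyp": 10.6, "V05_dep": -24.7, "k_dep": 7.2}
D540K_GV_RPR = {"V05_hyp": -114.0, "k_hyp": 9.2, "V05_dep": -23.9, "k_dep": 14.2}
D540K_TROUGH_CONTROL = 0.02
D540K_TROUGH_RPR = 0.17

# D540K tail decay at -70 mV after a depolarizing prepulse:
# bi-exponential under control, tri-exponential with RPR.
D540K_TAIL_TAUS_CONTROL = (24.0, 79.0)
D540K_TAIL_TAUS_RPR = (35.0, 442.0, 1970.0)


def solve_double_boltzmann(
    branch: dict, trough: float, v_lo: float = -140.0, v_hi: float = 40.0
) -> DoubleBoltzmannParams:
    """Construct a biphasic G-V with a prescribed trough and unit maximum.

    Given the two (V05, k) pairs of ``branch``, solves for a shared branch
    amplitude ``A`` and constant ``offset`` such that over [v_lo, v_hi]
    the curve minimum equals ``trough`` and the maximum equals 1.
    """
    import numpy as np

    from .model_core import double_boltzmann_gv

    grid = np.linspace(v_lo, v_hi, 721)

    def span_stats(A: float, offset: float):
        p = DoubleBoltzmannParams(
            V05_hyp=branch["V05_hyp"], k_hyp=branch["k_hyp"], A_hyp=A,
            V05_dep=branch["V05_dep"], k_dep=branch["k_dep"], A_dep=A,
            offset=offset,
        )
        y = double_boltzmann_gv(grid, p)
        return float(y.min()), float(y.max()), p

    # fixed-point iteration: offset follows from the trough once A is known,
    # A from the unit-maximum condition; converges in a few rounds because
    # the branch contributions at the trough are small.
    A, offset = 1.0 - trough, trough
    for _ in range(50):
        lo, hi, _ = span_stats(A, offset)
        new_offset = max(0.0, offset + (trough - lo))
        new_A = A + (1.0 - hi)
        if abs(new_offset - offset) < 1e-12 and abs(new_A - A) < 1e-12:
            break
        A, offset = new_A, new_offset
    lo, hi, p = span_stats(A, offset)
    if abs(lo - trough) > 1e-6 or abs(hi - 1.0) > 1e-6:
        raise RuntimeError("double-Boltzmann construction did not converge")
    return p
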