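"""Time-domain Markov simulation of the 6-state gating scheme.

The equilibrium model (``model_core``) constrains only the ratios of
forward and backward rates.  To simulate voltage-clamp protocols the
equilibria are lifted to a kinetic scheme by choosing base rates and an
Eyring-style charge split: for the per-subunit step

    alpha(V) = base_rate_closed * exp(+charge_split * z1 * FV/RT)
    beta(V)  = alpha(V) * K(V)

and analogously for the concerted opening step with ``z2`` and ``Ko``.
Any such lift leaves the steady-state G-V identical to the closed-form
model; changing the base rates or the charge split only rescales the
kinetics.  State occupancies are propagated exactly per constant-voltage
epoch with the matrix exponential of the generator (Q-matrix).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm

from .model_core import (
    GatingParams,
    StateVector,
    ThermoContext,
    equilibrium_constants,
    reduced_potential,
    state_occupancies,
)

__all__ = [
    "RateParams",
    "VoltageProtocol",
    "SimConfig",
    "CurrentTrace",
    "build_rate_matrix",
    "stationary_distribution",
    "propagate",
    "simulate_protocol",
    "slowest_relaxation_tau",
]

_MAX_RATE = 1e9  # 1/ms; beyond this the matrix exponential loses accuracy


@dataclass(frozen=True)
class RateParams:
    """Kinetic lift of :class:`GatingParams`.

    ``base_rate_closed`` is the per-subunit activation rate at 0 mV and
    ``base_rate_open`` the concerted opening rate at 0 mV (both 1/ms);
    ``charge_split`` is the fraction of each effective charge assigned to
    the forward (activating) rate.  Defaults put control-channel
    deactivation at strongly negative voltages on the millisecond scale.
    """

    gating: GatingParams
    base_rate_closed: float = 0.2
    base_rate_open: float = 0.05
    charge_split: float = 0.5

    def __post_init__(self) -> None:
        if self.base_rate_closed <= 0 or self.base_rate_open <= 0:
            raise ValueError("base rates must be positive")
        if not 0.0 <= self.charge_split <= 1.0:
            raise ValueError("charge_split must lie in [0, 1]")


@dataclass(frozen=True)
class VoltageProtocol:
    """Step voltage-clamp protocol.

    ``epochs`` is an ordered list of (duration_ms, voltage_mV) pairs,
    preceded by an implicit holding epoch at ``holding_potential`` of
    ``holding_duration`` ms.  The state is initialized at equilibrium at
    the holding potential.
    """

    epochs: tuple
    sample_interval: float = 1.0
    holding_potential: float = -70.0
    holding_duration: float = 100.0

    def __post_init__(self) -> None:
        epochs = tuple((float(d), float(v)) for d, v in self.epochs)
        if len(epochs) == 0:
            raise ValueError("protocol must contain at least one epoch")
        if any(d <= 0 for d, _ in epochs):
            raise ValueError("epoch durations must be positive")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.holding_duration < 0:
            raise ValueError("holding_duration must be non-negative")
        object.__setattr__(self, "epochs", epochs)

    @property
    def all_epochs(self) -> tuple:
        """(duration, voltage) pairs including the holding epoch at index 0."""
        if self.holding_duration > 0:
            return ((self.holding_duration, self.holding_potential),) + self.epochs
        return self.epochs

    def with_epoch_voltage(self, index: int, voltage: float) -> "VoltageProtocol":
        """Copy of the protocol with the voltage of one epoch (0-based over
        ``epochs``, holding excluded) replaced."""
        epochs = list(self.epochs)
        epochs[index] = (epochs[index][0], float(voltage))
        return VoltageProtocol(
            tuple(epochs), self.sample_interval, self.holding_potential, self.holding_duration
        )

    @classmethod
    def from_dict(cls, d: dict) -> "VoltageProtocol":
        return cls(
            epochs=tuple((e[0], e[1]) for e in d["epochs"]),
            sample_interval=d.get("sample_interval_ms", 1.0),
            holding_potential=d.get("holding_mV", -70.0),
            holding_duration=d.get("holding_ms", 100.0),
        )

    def to_dict(self) -> dict:
        return {
            "holding_mV": self.holding_potential,
            "holding_ms": self.holding_duration,
            "epochs": [[d, v] for d, v in self.epochs],
            "sample_interval_ms": self.sample_interval,
        }


@dataclass(frozen=True)
class SimConfig:
    """Current-scaling and noise configuration for simulated sweeps.

    Defaults give a macroscopic conductance of 50 uS (5e6 channels at
    10 pS), i.e. whole-oocyte currents of a few microamperes at typical
    driving forces.  ``reversal_potential`` defaults to the K+ reversal in
    a high-K bath.
    """

    n_channels: int = 5_000_000
    unitary_conductance: float = 0.01  # nS
    reversal_potential: float = -10.0  # mV
    noise_sd: float = 0.0  # uA
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.unitary_conductance <= 0:
            raise ValueError("unitary_conductance must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def macro_conductance_nS(self) -> float:
        return self.n_channels * self.unitary_conductance


@dataclass
class CurrentTrace:
    """A sampled voltage-clamp sweep: time (ms), command voltage (mV), current (uA)."""

    time: np.ndarray
    command_voltage: np.ndarray
    current: np.ndarray
    metadata: dict = field(default_factory=dict)
    protocol: VoltageProtocol | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.command_voltage = np.asarray(self.command_voltage, dtype=float)
        self.current = np.asarray(self.current, dtype=float)
        n = len(self.time)
        if len(self.command_voltage) != n or len(self.current) != n:
            raise ValueError("time, voltage and current vectors must have equal length")
        if n >= 2:
            dt = np.diff(self.time)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
                raise ValueError("time must be uniformly sampled")

    @property
    def sample_interval(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else math.nan

    def epoch_bounds(self, epoch_index: int) -> tuple:
        """Start/end times (ms) of an epoch of ``protocol.all_epochs``."""
        if self.protocol is None:
            raise ValueError("trace carries no protocol metadata")
        eps = self.protocol.all_epochs
        if not 0 <= epoch_index < len(eps):
            raise IndexError(f"epoch {epoch_index} out of range (protocol has {len(eps)})")
        start = sum(d for d, _ in eps[:epoch_index])
        return start, start + eps[epoch_index][0]

    def epoch_slice(self, epoch_index: int) -> slice:
        t0, t1 = self.epoch_bounds(epoch_index)
        i0 = int(np.searchsorted(self.time, t0 - 1e-9))
        i1 = int(np.searchsorted(self.time, t1 - 1e-9))
        return slice(i0, i1)


def build_rate_matrix(
    r: RateParams, V: float, ctx: ThermoContext = ThermoContext()
) -> np.ndarray:
    """Generator (Q-matrix) of the 6-state chain at voltage V (mV).

    States are ordered (C0, C1, C2, C3, C4, O).  Forward (activating)
    rates carry the subunit multiplicities 4a, 3a, 2a, a then the
    concerted opening rate; backward rates b, 2b, 3b, 4b then closing,
    with b = a*K(V) and closing = opening*Ko(V), which makes the stationary
    distribution the binomial equilibrium of the closed-form model.
    Rows sum to zero.
    """
    u = reduced_potential(V, ctx)
    K, Ko = equilibrium_constants(r.gating, V, ctx)
    alpha = r.base_rate_closed * math.exp(r.charge_split * r.gating.z1 * u)
    beta = alpha * K
    gamma = r.base_rate_open * math.exp(r.charge_split * r.gating.z2 * u)
    delta = gamma * Ko
    rates = [alpha, beta, gamma, delta]
    if any(not math.isfinite(x) or x > _MAX_RATE for x in rates):
        raise OverflowError(
            f"transition rates overflow at V = {V} mV; clip the protocol voltage range"
        )
    Q = np.zeros((6, 6))
    fwd = [4 * alpha, 3 * alpha, 2 * alpha, alpha, gamma]
    bwd = [beta, 2 * beta, 3 * beta, 4 * beta, delta]
    for i in range(5):
        Q[i, i + 1] = fwd[i]
        Q[i + 1, i] = bwd[i]
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return Q


def stationary_distribution(Q: np.ndarray) -> np.ndarray:
    """Stationary distribution of a generator via the null space of Q^T."""
    n = Q.shape[0]
    A = np.vstack([Q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(A, b, rcond=None)
    pi = np.clip(pi, 0.0, None)
    return pi / pi.sum()


def propagate(Q: np.ndarray, s: StateVector | np.ndarray, dt: float) -> StateVector:
    """Advance occupancies by dt (ms): s_new = s . exp(Q dt)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    s0 = s.occupancies if isinstance(s, StateVector) else np.asarray(s, dtype=float)
    s1 = s0 @ expm(Q * dt)
    s1 = np.clip(s1, 0.0, None)
    return StateVector(s1 / s1.sum())


def simulate_protocol(
    r: RateParams,
    prot: VoltageProtocol,
    cfg: SimConfig = SimConfig(),
    ctx: ThermoContext = ThermoContext(),
    return_states: bool = False,
):
    """Simulate a step protocol; returns a :class:`CurrentTrace`.

    The state starts at the equilibrium distribution for the holding
    potential and is propagated sample-by-sample with the per-epoch
    matrix exponential.  The deterministic mean-field current is

        I(t) = G * P_O(t) * (V(t) - E_rev) * 1e-6   [uA]

    with G = n_channels * unitary_conductance in nS, plus additive
    Gaussian noise of SD ``cfg.noise_sd`` (seeded, reproducible).
    With ``return_states=True`` also returns the (n_samples, 6) state
    trajectory.
    """
    dt = prot.sample_interval
    s = state_occupancies(r.gating, prot.holding_potential, ctx).occupancies

    times, volts, popen, states = [], [], [], []
    t0 = 0.0
    for duration, V in prot.all_epochs:
        Q = build_rate_matrix(r, V, ctx)
        P = expm(Q * dt)
        n_samp = int(round(duration / dt))
        for i in range(n_samp):
            times.append(t0 + i * dt)
            volts.append(V)
            popen.append(s[-1])
            if return_states:
                states.append(s.copy())
            s = np.clip(s @ P, 0.0, None)
            s = s / s.sum()
        t0 += n_samp * dt

    times = np.asarray(times)
    volts = np.asarray(volts)
    popen = np.asarray(popen)
    current = cfg.macro_conductance_nS * popen * (volts - cfg.reversal_potential) * 1e-6
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        current = current + rng.normal(0.0, cfg.noise_sd, size=current.shape)
    trace = CurrentTrace(
        time=times,
        command_voltage=volts,
        current=current,
        metadata={"seed": cfg.seed, "noise_sd": cfg.noise_sd},
        protocol=prot,
    )
    if return_states:
        return trace, np.asarray(states)
    return trace


def slowest_relaxation_tau(Q: np.ndarray) -> float:
    """Slowest relaxation time constant (ms): -1/Re(lambda_1).

    lambda_1 is the nonzero eigenvalue of the generator with the largest
    (least negative) real part; for a reversible birth-death chain all
    eigenvalues are real.
    """
    ev = np.linalg.eigvals(Q)
    ev = np.sort(ev.real)
    nonzero = ev[ev < -1e-12]
    if len(nonzero) == 0:
        raise ValueError("generator has no relaxing mode")
    return float(-1.0 / nonzero[-1])
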