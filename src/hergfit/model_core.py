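"""Closed-form gating and concentration-response models for hERG1 channels.

This module collects the pure, stateless model functions that the rest of
the package fits, simulates and generates data from:

* a 6-state sequential activation scheme
  ``C0 <-> C1 <-> C2 <-> C3 <-> C4 <-> O`` in which four identical voltage
  sensors activate independently (per-subunit equilibrium constant ``K``)
  followed by a concerted pore-opening step (constant ``Ko``),
* single and double Boltzmann conductance-voltage (G-V) curves,
* the logistic (Hill) concentration-response equation, and
* sums of 1-3 decaying exponentials for tail-current deactivation.

Conventions
-----------
Voltages are in millivolts, times in milliseconds, concentrations in
micromolar.  ``K`` and ``Ko`` are *closing-direction* equilibrium constants
(ratio of the deactivated to the activated state at each step), so with
positive effective charges ``z1``/``z2`` the channel activates on
depolarization:

    K(V)  = K(0)  * exp(-z1 * F V / R T)
    Ko(V) = Ko(0) * exp(-z2 * F V / R T)

With four independent subunits, the closed-state occupancies relative to
the open state follow binomial weights, giving the normalized equilibrium
open probability

    Po(V) = [1 + Ko + 4 Ko K + 6 Ko K^2 + 4 Ko K^3 + Ko K^4]^-1
          = [1 + Ko (1 + K)^4]^-1

The successive pairwise equilibrium constants toward the resting state are
K/4, 2K/3, 3K/2 and 4K; this statistical-factor assignment is the unique
one consistent with independent subunits and reproduces the binomial
denominator above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logsumexp

__all__ = [
    "FARADAY",
    "GAS_CONSTANT",
    "ThermoContext",
    "GatingParams",
    "StateVector",
    "BoltzmannParams",
    "DoubleBoltzmannParams",
    "HillParams",
    "ExpMixture",
    "STATE_NAMES",
    "BINOMIAL_WEIGHTS",
    "reduced_potential",
    "equilibrium_constants",
    "state_occupancies",
    "po_equilibrium",
    "boltzmann_gv",
    "double_boltzmann_gv",
    "hill_response",
    "exp_mixture_value",
]

FARADAY = 96485.0  # C/mol
GAS_CONSTANT = 8.314  # J/(mol K)

#: state ordering used throughout the package (resting -> open)
STATE_NAMES = ("C0", "C1", "C2", "C3", "C4", "O")

#: binomial coefficients C(4, j) weighting the closed states C4..C0
BINOMIAL_WEIGHTS = (1.0, 4.0, 6.0, 4.0, 1.0)


@dataclass(frozen=True)
class ThermoContext:
    """Thermodynamic context: temperature and the reduced-potential scale.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.  Defaults to 295.15 K (22 degC,
        a typical room temperature for two-electrode voltage clamp).
    """

    temperature: float = 295.15

    def __post_init__(self) -> None:
        if not (math.isfinite(self.temperature) and self.temperature > 0):
            raise ValueError(f"temperature must be positive and finite, got {self.temperature}")

    @property
    def vt_factor(self) -> float:
        """F/(R*T) in 1/volt."""
        return FARADAY / (GAS_CONSTANT * self.temperature)


@dataclass(frozen=True)
class GatingParams:
    """Equilibrium parameters of the 6-state activation scheme.

    Attributes
    ----------
    K0 : float
        Zero-voltage per-subunit equilibrium constant (closing direction).
    z1 : float
        Effective charge of each subunit transition, in elementary charges.
    Ko0 : float
        Zero-voltage equilibrium constant of the concerted C4 <-> O step
        (closing direction).
    z2 : float
        Effective charge of the concerted step.
    """

    K0: float
    z1: float
    Ko0: float
    z2: float

    def __post_init__(self) -> None:
        for name in ("K0", "z1", "Ko0", "z2"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")

    @classmethod
    def from_dict(cls, d: dict) -> "GatingParams":
        return cls(K0=d["K0"], z1=d["z1"], Ko0=d["Ko0"], z2=d["z2"])

    def to_dict(self) -> dict:
        return {"K0": self.K0, "z1": self.z1, "Ko0": self.Ko0, "z2": self.z2}


@dataclass(frozen=True)
class StateVector:
    """Occupancy distribution over (C0, C1, C2, C3, C4, O)."""

    occupancies: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancies, dtype=float)
        if occ.shape != (6,):
            raise ValueError(f"expected 6 occupancies, got shape {occ.shape}")
        if np.any(occ < -1e-12) or np.any(occ > 1 + 1e-12):
            raise ValueError("occupancies must lie in [0, 1]")
        if abs(occ.sum() - 1.0) > 1e-9:
            raise ValueError(f"occupancies must sum to 1, got {occ.sum()!r}")
        object.__setattr__(self, "occupancies", occ)

    @property
    def open_probability(self) -> float:
        return float(self.occupancies[-1])

    def __getitem__(self, state: str) -> float:
        return float(self.occupancies[STATE_NAMES.index(state)])


@dataclass(frozen=True)
class BoltzmannParams:
    """Half-activation voltage V05 (mV) and slope factor k (mV) of a Boltzmann G-V."""

    V05: float
    k: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.k) and self.k > 0):
            raise ValueError(f"slope factor k must be positive, got {self.k}")
        if not math.isfinite(self.V05):
            raise ValueError("V05 must be finite")


@dataclass(frozen=True)
class DoubleBoltzmannParams:
    """Sum of two opposed Boltzmann branches plus a constant offset.

    Describes biphasic G-V curves (e.g. the D540K hERG1a mutant, which
    opens on both depolarization and hyperpolarization): one branch rises
    toward hyperpolarized potentials with midpoint ``V05_hyp`` and slope
    ``k_hyp``, the other toward depolarized potentials with ``V05_dep`` and
    ``k_dep``.  Amplitudes and offset are dimensionless fractions of the
    normalized conductance.
    """

    V05_hyp: float
    k_hyp: float
    A_hyp: float
    V05_dep: float
    k_dep: float
    A_dep: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.k_hyp <= 0 or self.k_dep <= 0:
            raise ValueError("slope factors must be positive")
        if self.A_hyp < 0 or self.A_dep < 0 or self.offset < 0:
            raise ValueError("amplitudes and offset must be non-negative")
        if self.A_hyp + self.A_dep + self.offset <= 0:
            raise ValueError("curve must have positive total amplitude")


@dataclass(frozen=True)
class HillParams:
    """Logistic (Hill) concentration-response parameters.

    The curve runs from ``Amax`` at zero dose to ``Amin`` at saturating
    dose; for a potentiating drug ``Amin > Amax`` is perfectly legal, the
    names merely follow the conventional writing of the equation.
    """

    Amax: float
    Amin: float
    EC50: float
    nH: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.EC50) and self.EC50 > 0):
            raise ValueError(f"EC50 must be positive, got {self.EC50}")
        if not (math.isfinite(self.nH) and self.nH > 0):
            raise ValueError(f"Hill coefficient must be positive, got {self.nH}")


@dataclass(frozen=True)
class ExpMixture:
    """Parameters of a 1-3 component exponential decay.

    ``taus`` (ms) are stored strictly increasing; ``amps`` are the matched
    signed amplitudes (current units) and ``offset`` the steady-state
    asymptote.
    """

    taus: tuple
    amps: tuple
    offset: float = 0.0

    def __post_init__(self) -> None:
        taus = tuple(float(t) for t in self.taus)
        amps = tuple(float(a) for a in self.amps)
        if len(taus) != len(amps):
            raise ValueError("taus and amps must have equal length")
        if not 1 <= len(taus) <= 3:
            raise ValueError(f"order must be 1, 2 or 3, got {len(taus)}")
        if any(t <= 0 for t in taus):
            raise ValueError("time constants must be positive")
        if any(b <= a for a, b in zip(taus, taus[1:])):
            raise ValueError("taus must be strictly increasing")
        object.__setattr__(self, "taus", taus)
        object.__setattr__(self, "amps", amps)

    @property
    def order(self) -> int:
        return len(self.taus)

    @classmethod
    def from_unsorted(cls, taus, amps, offset=0.0) -> "ExpMixture":
        """Build a canonical (tau-ascending) mixture from unsorted components."""
        pairs = sorted(zip(taus, amps), key=lambda p: p[0])
        return cls(tuple(p[0] for p in pairs), tuple(p[1] for p in pairs), offset)


# ---------------------------------------------------------------------------
# model functions


def reduced_potential(V, ctx: ThermoContext = ThermoContext()):
    """Dimensionless reduced potential F*V/(R*T) for V in millivolts."""
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("voltage must be finite")
    u = V * 1e-3 * ctx.vt_factor
    return float(u) if u.ndim == 0 else u


def equilibrium_constants(p: GatingParams, V, ctx: ThermoContext = ThermoContext()):
    """Voltage-dependent equilibrium constants (K, Ko) of the 6-state scheme.

    Both constants are in the closing direction and decrease with
    depolarization for positive effective charges.
    """
    u = reduced_potential(V, ctx)
    K = p.K0 * np.exp(-p.z1 * np.asarray(u))
    Ko = p.Ko0 * np.exp(-p.z2 * np.asarray(u))
    if np.ndim(u) == 0:
        return float(K), float(Ko)
    return K, Ko


def _log_state_weights(p: GatingParams, V, ctx: ThermoContext):
    """Log relative weights of (C0..C4, O) with the open state at 0.

    Working in logs keeps extreme voltages (|V| of hundreds of mV) from
    overflowing: C_{4-j} has weight Ko * C(4,j) * K^j relative to O.
    """
    u = reduced_potential(V, ctx)
    with np.errstate(divide="ignore"):
        logK = np.log(p.K0) - p.z1 * u
        logKo = np.log(p.Ko0) - p.z2 * u
    j = np.arange(4, -1, -1)  # exponent of K for C0..C4
    log_closed = logKo + np.log([1.0, 4.0, 6.0, 4.0, 1.0]) + j * logK
    return np.append(log_closed, 0.0)


def state_occupancies(
    p: GatingParams, V: float, ctx: ThermoContext = ThermoContext()
) -> StateVector:
    """Equilibrium occupancy of each state at voltage V (mV)."""
    logw = _log_state_weights(p, float(V), ctx)
    occ = np.exp(logw - logsumexp(logw))
    occ = occ / occ.sum()
    return StateVector(occ)


def po_equilibrium(p: GatingParams, V, ctx: ThermoContext = ThermoContext()):
    """Equilibrium open probability Po(V) = 1 / (1 + Ko (1 + K)^4).

    Evaluated on a log scale so extreme hyperpolarizations underflow to 0
    rather than overflowing.  Accepts scalar or array V.
    """
    u = np.asarray(reduced_potential(V, ctx), dtype=float)
    with np.errstate(divide="ignore"):
        logK = np.log(p.K0) - p.z1 * u
        logKo = np.log(p.Ko0) - p.z2 * u
    # log denominator = log(1 + exp(logKo + 4*log(1+K)))
    log_closed = logKo + 4.0 * np.logaddexp(0.0, logK)
    po = np.exp(-np.logaddexp(0.0, log_closed))
    return float(po) if po.ndim == 0 else po


def boltzmann_gv(V, p: BoltzmannParams):
    """Single Boltzmann activation curve 1 / (1 + exp((V05 - V)/k))."""
    V = np.asarray(V, dtype=float)
    g = expit((V - p.V05) / p.k)
    return float(g) if g.ndim == 0 else g


def double_boltzmann_gv(V, p: DoubleBoltzmannParams):
    """Biphasic G-V: offset + A_hyp*sigma((V05_hyp - V)/k_hyp) + A_dep*sigma((V - V05_dep)/k_dep)."""
    V = np.asarray(V, dtype=float)
    g = (
        p.offset
        + p.A_hyp * expit((p.V05_hyp - V) / p.k_hyp)
        + p.A_dep * expit((V - p.V05_dep) / p.k_dep)
    )
    return float(g) if g.ndim == 0 else g


def hill_response(c, p: HillParams):
    """Logistic concentration-response: Amax + (Amin - Amax)/(1 + (c/EC50)^-nH)...

    Written in the conventional form

        y(c) = Amax + (Amin - Amax) / (1 + (EC50/c)^nH)

    so y(0) = Amax, y(EC50) = (Amax + Amin)/2 and y(inf) = Amin.
    Concentrations are in micromolar and must be non-negative.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    with np.errstate(divide="ignore"):
        frac = 1.0 / (1.0 + (p.EC50 / np.where(c > 0, c, np.nan)) ** p.nH)
    frac = np.where(c > 0, frac, 0.0)
    y = p.Amax + (p.Amin - p.Amax) * frac
    return float(y) if y.ndim == 0 else y


def exp_mixture_value(t, m: ExpMixture):
    """Evaluate the exponential mixture sum_i amps[i]*exp(-t/taus[i]) + offset."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    y = np.full(t.shape, m.offset, dtype=float)
    for tau, amp in zip(m.taus, m.amps):
        y = y + amp * np.exp(-t / tau)
    return float(y) if y.ndim == 0 else y
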