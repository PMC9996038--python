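"""Nonlinear least-squares fitting of the gating and response models.

Every fitter follows the same contract: it consumes a tidy dataset (or
raw time/current vectors for tail fits), runs a bounded
Levenberg-Marquardt minimization (via lmfit), and returns the fitted
parameter record together with a :class:`FitResult` carrying the residual
sum of squares, convergence status, Jacobian-based standard errors and
any degeneracy flags.  Non-convergence and unidentifiable data are
flagged, never silently defaulted.

EC50 and the gating equilibrium constants are searched on a log scale;
the 4-parameter 6-state gating fit uses seeded multi-start to avoid the
local minima of its correlated parameter surface.  Exponential model
order is chosen by the extra-sum-of-squares F-test, the convention in
electrophysiology; small-sample corrected AIC is reported alongside but
does not decide.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .model_core import (
    BoltzmannParams,
    DoubleBoltzmannParams,
    ExpMixture,
    GatingParams,
    HillParams,
    ThermoContext,
    boltzmann_gv,
    double_boltzmann_gv,
    hill_response,
    po_equilibrium,
)

__all__ = [
    "GVDataset",
    "DoseResponseDataset",
    "FitResult",
    "fit_hill",
    "fit_boltzmann",
    "fit_double_boltzmann",
    "fit_gating_gv",
    "fit_exp_decay",
    "select_exp_order",
]

_FIT_KWS = dict(xtol=1e-14, ftol=1e-14, gtol=1e-14)


@dataclass
class GVDataset:
    """Normalized conductance-voltage table: columns ``V`` (mV) and ``g_norm``."""

    data: pd.DataFrame
    label: str = ""

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = {"V", "g_norm"} - set(df.columns)
        if missing:
            raise ValueError(f"GVDataset missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("GVDataset is empty")
        if not np.all(np.isfinite(df["V"])) or not np.all(np.isfinite(df["g_norm"])):
            raise ValueError("GVDataset contains non-finite values")
        self.data = df.reset_index(drop=True)

    @property
    def n_voltages(self) -> int:
        return int(self.data["V"].nunique())


@dataclass
class DoseResponseDataset:
    """Concentration-response table: columns ``conc`` (uM) and ``response``."""

    data: pd.DataFrame
    label: str = ""
    quantity: str = ""  # e.g. I_peak, I_tail-peak, tau_deact

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = {"conc", "response"} - set(df.columns)
        if missing:
            raise ValueError(f"DoseResponseDataset missing columns: {sorted(missing)}")
        if len(df) == 0:
            raise ValueError("DoseResponseDataset is empty")
        if np.any(df["conc"] < 0):
            raise ValueError("concentrations must be non-negative")
        self.data = df.reset_index(drop=True)

    @property
    def n_concentrations(self) -> int:
        return int(self.data["conc"].nunique())


@dataclass
class FitResult:
    """Outcome of a least-squares fit."""

    model_tag: str
    rss: float
    n_points: int
    n_params: int
    converged: bool
    param_se: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    extras: dict = field(default_factory=dict)

    @property
    def aicc(self) -> float:
        """Small-sample corrected Akaike information criterion (Gaussian errors)."""
        n, k = self.n_points, self.n_params + 1  # +1 for the noise variance
        if n <= k + 1:
            return math.inf
        aic = n * math.log(max(self.rss, 1e-300) / n) + 2 * k
        return aic + 2 * k * (k + 1) / (n - k - 1)

    def to_dict(self, params: dict | None = None) -> dict:
        out = {
            "model_tag": self.model_tag,
            "rss": self.rss,
            "n_points": self.n_points,
            "converged": self.converged,
            "param_se": self.param_se,
            "flags": list(self.flags),
            "aicc": self.aicc,
        }
        if params is not None:
            out["params"] = params
        return out


def _run(params: lmfit.Parameters, residual, *args) -> lmfit.minimizer.MinimizerResult:
    return lmfit.minimize(residual, params, args=args, method="leastsq", **_FIT_KWS)


def _stderr(res: lmfit.minimizer.MinimizerResult) -> dict:
    return {
        name: (float(p.stderr) if p.stderr is not None else math.nan)
        for name, p in res.params.items()
        if p.vary
    }


# ---------------------------------------------------------------------------
# Hill concentration-response


def fit_hill(d: DoseResponseDataset, init: HillParams | None = None):
    """Fit the logistic (Hill) equation; EC50 searched on a log scale."""
    if d.n_concentrations < 4:
        raise ValueError("need >= 4 distinct concentrations for a Hill fit")
    conc = d.data["conc"].to_numpy(float)
    y = d.data["response"].to_numpy(float)

    span = float(np.ptp(y))
    flags: list = []
    pos = conc[conc > 0]
    if init is None:
        c_lo = y[conc == conc.min()].mean()
        c_hi = y[conc == conc.max()].mean()
        ec50_0 = float(np.exp(np.mean(np.log(pos)))) if len(pos) else 1.0
        init = HillParams(Amax=float(c_lo), Amin=float(c_hi), EC50=ec50_0, nH=1.0)

    params = lmfit.Parameters()
    params.add("Amax", value=init.Amax)
    params.add("Amin", value=init.Amin)
    params.add("logEC50", value=math.log(init.EC50), min=math.log(1e-6), max=math.log(1e6))
    params.add("nH", value=init.nH, min=1e-3, max=10.0)

    def residual(p, c, obs):
        hp = HillParams(p["Amax"].value, p["Amin"].value, math.exp(p["logEC50"].value), p["nH"].value)
        return hill_response(c, hp) - obs

    res = _run(params, residual, conc, y)
    hp = HillParams(
        res.params["Amax"].value,
        res.params["Amin"].value,
        math.exp(res.params["logEC50"].value),
        res.params["nH"].value,
    )
    converged = bool(res.success)
    if span == 0 or abs(hp.Amax - hp.Amin) < 1e-9 * max(1.0, abs(hp.Amax)):
        flags.append("unidentifiable-flat-response")
        converged = False
    if len(pos) and not (pos.min() / 100 < hp.EC50 < pos.max() * 100):
        flags.append("ec50-outside-data-range")
        converged = False
    # delta-method SE for EC50 from the log-scale parameter
    se = _stderr(res)
    if "logEC50" in se and math.isfinite(se["logEC50"]):
        se["EC50"] = hp.EC50 * se.pop("logEC50")
    fr = FitResult(
        model_tag="hill",
        rss=float(np.sum(res.residual**2)),
        n_points=len(y),
        n_params=4,
        converged=converged,
        param_se=se,
        flags=flags,
    )
    return hp, fr


# ---------------------------------------------------------------------------
# Boltzmann G-V


def _boltzmann_init(V: np.ndarray, g: np.ndarray) -> BoltzmannParams:
    """Initial (V05, k) from the half-max crossing and the 10-90% spread."""
    order = np.argsort(V)
    Vs, gs = V[order], g[order]
    lo, hi = gs.min(), gs.max()
    if hi - lo <= 0:
        return BoltzmannParams(V05=float(np.median(Vs)), k=10.0)
    gn = (gs - lo) / (hi - lo)
    v05 = float(np.interp(0.5, gn, Vs))
    v10 = float(np.interp(0.1, gn, Vs))
    v90 = float(np.interp(0.9, gn, Vs))
    k = max((v90 - v10) / (2 * math.log(9.0)), 0.5)
    return BoltzmannParams(V05=v05, k=k)


def fit_boltzmann(
    d: GVDataset, init: BoltzmannParams | None = None, free_amplitude: bool = False
):
    """Fit a single Boltzmann to a G-V (or ratio-voltage) relationship.

    With ``free_amplitude=True`` the curve is ``offset + amp * sigma``,
    used for tail-ratio curves that need not run from 0 to 1; the
    amplitude may be negative (curves falling with depolarization).
    """
    if d.n_voltages < 4:
        raise ValueError("need >= 4 distinct voltages for a Boltzmann fit")
    V = d.data["V"].to_numpy(float)
    g = d.data["g_norm"].to_numpy(float)
    if init is None:
        init = _boltzmann_init(V, g)

    params = lmfit.Parameters()
    params.add("V05", value=init.V05)
    params.add("k", value=init.k, min=1e-2, max=1e3)
    params.add("amp", value=float(np.ptp(g)) or 1.0, vary=free_amplitude)
    params.add("offset", value=float(g.min()), vary=free_amplitude)
    if not free_amplitude:
        params["amp"].value = 1.0
        params["offset"].value = 0.0

    # falling curves (g decreasing with V) need a negative amplitude start
    if free_amplitude and np.corrcoef(V, g)[0, 1] < 0:
        params["amp"].value = -params["amp"].value
        params["offset"].value = float(g.max())

    def residual(p, v, obs):
        bp = BoltzmannParams(p["V05"].value, p["k"].value)
        return p["offset"].value + p["amp"].value * boltzmann_gv(v, bp) - obs

    res = _run(params, residual, V, g)
    bp = BoltzmannParams(res.params["V05"].value, res.params["k"].value)
    fr = FitResult(
        model_tag="boltzmann",
        rss=float(np.sum(res.residual**2)),
        n_points=len(g),
        n_params=2 + (2 if free_amplitude else 0),
        converged=bool(res.success),
        param_se=_stderr(res),
        extras={
            "amp": float(res.params["amp"].value),
            "offset": float(res.params["offset"].value),
        },
    )
    return bp, fr


# ---------------------------------------------------------------------------
# Double Boltzmann (biphasic G-V)


def fit_double_boltzmann(d: GVDataset, init: DoubleBoltzmannParams | None = None):
    """Fit the sum of two opposed Boltzmann branches to a biphasic G-V.

    After the least-squares step the amplitudes and offset are rescaled so
    the fitted curve's maximum over the data voltage range equals 1 (the
    data are normalized conductances).  The curve minimum over that range
    — the trough of the biphasic relationship — is reported in
    ``extras["curve_min"]`` together with its voltage.
    """
    if d.n_voltages < 6:
        raise ValueError("need >= 6 distinct voltages for a double-Boltzmann fit")
    V = d.data["V"].to_numpy(float)
    g = d.data["g_norm"].to_numpy(float)
    v_lo, v_hi = float(V.min()), float(V.max())
    if init is None:
        span = float(np.ptp(g)) or 1.0
        init = DoubleBoltzmannParams(
            V05_hyp=v_lo + 0.25 * (v_hi - v_lo), k_hyp=10.0, A_hyp=span,
            V05_dep=v_lo + 0.75 * (v_hi - v_lo), k_dep=10.0, A_dep=span,
            offset=max(float(g.min()), 0.0),
        )

    params = lmfit.Parameters()
    params.add("V05_hyp", value=init.V05_hyp, min=v_lo - 100, max=v_hi + 100)
    params.add("k_hyp", value=init.k_hyp, min=0.1, max=100.0)
    params.add("A_hyp", value=init.A_hyp, min=0.0)
    params.add("V05_dep", value=init.V05_dep, min=v_lo - 100, max=v_hi + 100)
    params.add("k_dep", value=init.k_dep, min=0.1, max=100.0)
    params.add("A_dep", value=init.A_dep, min=0.0)
    params.add("offset", value=init.offset, min=0.0)

    def make(p) -> DoubleBoltzmannParams:
        return DoubleBoltzmannParams(
            V05_hyp=p["V05_hyp"].value, k_hyp=p["k_hyp"].value, A_hyp=p["A_hyp"].value,
            V05_dep=p["V05_dep"].value, k_dep=p["k_dep"].value, A_dep=p["A_dep"].value,
            offset=p["offset"].value,
        )

    def residual(p, v, obs):
        return double_boltzmann_gv(v, make(p)) - obs

    res = _run(params, residual, V, g)
    fitted = make(res.params)

    grid = np.linspace(v_lo, v_hi, 1001)
    curve = double_boltzmann_gv(grid, fitted)
    scale = float(curve.max())
    if scale > 0:
        fitted = DoubleBoltzmannParams(
            V05_hyp=fitted.V05_hyp, k_hyp=fitted.k_hyp, A_hyp=fitted.A_hyp / scale,
            V05_dep=fitted.V05_dep, k_dep=fitted.k_dep, A_dep=fitted.A_dep / scale,
            offset=fitted.offset / scale,
        )
        curve = curve / scale

    flags: list = []
    if abs(fitted.V05_hyp - fitted.V05_dep) < 5.0:
        flags.append("branch-collapse")
    rss = float(np.sum((double_boltzmann_gv(V, fitted) - g) ** 2))
    fr = FitResult(
        model_tag="double_boltzmann",
        rss=rss,
        n_points=len(g),
        n_params=7,
        converged=bool(res.success) and "branch-collapse" not in flags,
        param_se=_stderr(res),
        flags=flags,
        extras={
            "curve_min": float(curve.min()),
            "curve_min_V": float(grid[int(np.argmin(curve))]),
            "normalization_scale": scale,
        },
    )
    return fitted, fr


# ---------------------------------------------------------------------------
# 6-state gating model G-V


def fit_gating_gv(
    d: GVDataset,
    ctx: ThermoContext = ThermoContext(),
    init: GatingParams | None = None,
    n_starts: int = 5,
    seed: int = 0,
):
    """Fit the 6-state gating model to a normalized G-V relationship.

    The model curve is the equilibrium open probability renormalized to
    its maximum over the dataset's voltages (matching how tail-current
    G-V data are normalized to their own maximum).  K(0) and Ko(0) are
    searched on a log10 scale with multi-start (>= ``n_starts`` seeded
    jittered starts) and the lowest-rss converged solution wins.
    """
    if d.n_voltages < 6:
        raise ValueError("need >= 6 distinct voltages for a 6-state gating fit")
    V = d.data["V"].to_numpy(float)
    g = d.data["g_norm"].to_numpy(float)
    v_unique = np.unique(V)
    if init is None:
        init = GatingParams(K0=0.1, z1=1.5, Ko0=0.3, z2=0.8)

    def model(gp: GatingParams, v):
        po = po_equilibrium(gp, v, ctx)
        norm = float(np.max(po_equilibrium(gp, v_unique, ctx)))
        return po / norm if norm > 0 else po

    def residual(p, v, obs):
        gp = GatingParams(
            K0=10 ** p["log10_K0"].value, z1=p["z1"].value,
            Ko0=10 ** p["log10_Ko0"].value, z2=p["z2"].value,
        )
        return model(gp, v) - obs

    rng = np.random.default_rng(seed)
    starts = [(math.log10(init.K0), init.z1, math.log10(init.Ko0), init.z2)]
    while len(starts) < max(n_starts, 1):
        starts.append(
            (
                starts[0][0] + rng.uniform(-1.5, 1.5),
                np.clip(starts[0][1] * rng.uniform(0.3, 3.0), 0.05, 6.0),
                starts[0][2] + rng.uniform(-1.5, 1.5),
                np.clip(starts[0][3] * rng.uniform(0.3, 3.0), 0.05, 6.0),
            )
        )

    best = None
    for lk0, z1, lko0, z2 in starts:
        params = lmfit.Parameters()
        params.add("log10_K0", value=lk0, min=-5.0, max=3.0)
        params.add("z1", value=z1, min=1e-3, max=8.0)
        params.add("log10_Ko0", value=lko0, min=-5.0, max=3.0)
        params.add("z2", value=z2, min=1e-3, max=8.0)
        try:
            res = _run(params, residual, V, g)
        except Exception:
            continue
        rss = float(np.sum(res.residual**2))
        if res.success and (best is None or rss < best[0]):
            best = (rss, res)

    if best is None:
        fr = FitResult(
            model_tag="gating6", rss=math.inf, n_points=len(g), n_params=4,
            converged=False, flags=["no-start-converged"],
        )
        return init, fr

    rss, res = best
    gp = GatingParams(
        K0=10 ** res.params["log10_K0"].value,
        z1=res.params["z1"].value,
        Ko0=10 ** res.params["log10_Ko0"].value,
        z2=res.params["z2"].value,
    )
    se = _stderr(res)
    # delta method back to the natural scale
    ln10 = math.log(10.0)
    if math.isfinite(se.get("log10_K0", math.nan)):
        se["K0"] = gp.K0 * ln10 * se.pop("log10_K0")
    if math.isfinite(se.get("log10_Ko0", math.nan)):
        se["Ko0"] = gp.Ko0 * ln10 * se.pop("log10_Ko0")
    fr = FitResult(
        model_tag="gating6", rss=rss, n_points=len(g), n_params=4,
        converged=True, param_se=se,
    )
    return gp, fr


# ---------------------------------------------------------------------------
# Exponential tail fits


def _peel_init(t: np.ndarray, y: np.ndarray, order: int):
    """Initial mixture by exponential peeling.

    Estimate the offset from the final samples, then repeatedly fit a
    log-linear slope to the late phase of the remaining signal (which is
    dominated by the slowest surviving component), subtract, and recurse
    toward faster components.
    """
    n = len(y)
    offset = float(np.mean(y[-max(3, n // 20):]))
    sign = 1.0 if float(np.mean(y[: max(3, n // 10)]) - offset) >= 0 else -1.0
    resid = sign * (y - offset)
    span = float(t[-1] - t[0]) or 1.0
    taus, amps = [], []
    for k in range(order):
        good = np.where(resid > max(float(resid.max()) * 1e-3, 1e-12))[0]
        tau = amp = None
        if len(good) >= 4:
            late = good[len(good) // 2 :]
            try:
                slope, intercept = np.polyfit(t[late], np.log(resid[late]), 1)
                if slope < 0:
                    tau = -1.0 / slope
                    amp = math.exp(intercept)
            except Exception:
                pass
        if tau is None or not math.isfinite(tau) or tau <= 0:
            tau = span / (2.0 * 3.0**k)
            amp = float(resid.max()) if len(resid) else 1.0
        while any(1.0 / 1.6 < tau / t0 < 1.6 for t0 in taus):
            tau /= 3.0
        taus.append(float(tau))
        amps.append(float(amp))
        resid = resid - amp * np.exp(-t / tau)
    return [sign * a for a in amps], taus, offset


def fit_exp_decay(t, I, order: int, init: ExpMixture | None = None):
    """Fit a sum of ``order`` decaying exponentials plus offset to a tail segment.

    The time axis is re-zeroed at the first sample (assumed to be the
    tail peak).  Time constants are searched on a log scale, returned
    sorted ascending with their matched amplitudes.  Fits whose adjacent
    time constants differ by less than a factor of 1.5, or whose
    components carry negligible amplitude, are flagged as
    over-parameterized.
    """
    t = np.asarray(t, dtype=float)
    I = np.asarray(I, dtype=float)
    if t.shape != I.shape or t.ndim != 1:
        raise ValueError("t and I must be equal-length 1-D vectors")
    if len(t) < 10 * order:
        raise ValueError(f"need >= {10 * order} samples for an order-{order} fit")
    if order not in (1, 2, 3):
        raise ValueError("order must be 1, 2 or 3")
    t = t - t[0]
    dt = float(np.median(np.diff(t)))
    span = float(t[-1]) or 1.0

    if init is not None:
        amps0, taus0, offset0 = list(init.amps), list(init.taus), init.offset
    else:
        amps0, taus0, offset0 = _peel_init(t, I, order)

    lo, hi = math.log10(max(dt / 2, 1e-6)), math.log10(span * 10)
    params = lmfit.Parameters()
    for i in range(order):
        params.add(f"log10_tau{i}", value=float(np.clip(math.log10(taus0[i]), lo, hi)), min=lo, max=hi)
        params.add(f"amp{i}", value=amps0[i])
    params.add("offset", value=offset0)

    def residual(p, tt, obs):
        y = np.full_like(tt, p["offset"].value)
        for i in range(order):
            y = y + p[f"amp{i}"].value * np.exp(-tt / 10 ** p[f"log10_tau{i}"].value)
        return y - obs

    res = _run(params, residual, t, I)
    taus = [10 ** res.params[f"log10_tau{i}"].value for i in range(order)]
    amps = [res.params[f"amp{i}"].value for i in range(order)]
    mix = ExpMixture.from_unsorted(taus, amps, float(res.params["offset"].value))

    flags: list = []
    for a, b in zip(mix.taus, mix.taus[1:]):
        if b / a < 1.5:
            flags.append("tau-collapse")
            break
    amp_scale = sum(abs(a) for a in mix.amps) + abs(mix.offset)
    if amp_scale > 0 and any(abs(a) < 1e-2 * amp_scale for a in mix.amps):
        flags.append("negligible-amplitude")
    fr = FitResult(
        model_tag=f"exp{order}",
        rss=float(np.sum(res.residual**2)),
        n_points=len(I),
        n_params=2 * order + 1,
        converged=bool(res.success) and not flags,
        param_se=_stderr(res),
        flags=flags,
    )
    return mix, fr


def select_exp_order(t, I, max_order: int = 3, alpha: float = 0.05):
    """Choose the exponential model order by the extra-sum-of-squares F-test.

    Starting from a mono-exponential, the order is incremented while the
    richer model significantly reduces the residual sum of squares
    (F-test at ``alpha``) and is not degenerate (collapsed or
    negligible-amplitude components).  Returns ``(order, fits)`` with the
    per-order ``(ExpMixture, FitResult)`` pairs.
    """
    t = np.asarray(t, dtype=float)
    I = np.asarray(I, dtype=float)
    fits = {}
    chosen = 1
    fits[1] = fit_exp_decay(t, I, 1)
    for order in range(2, max_order + 1):
        if len(t) < 10 * order:
            break
        fits[order] = fit_exp_decay(t, I, order)
        _, lo_fr = fits[chosen]
        mix, hi_fr = fits[order]
        if hi_fr.flags or not hi_fr.converged:
            continue
        df_lo = lo_fr.n_points - lo_fr.n_params
        df_hi = hi_fr.n_points - hi_fr.n_params
        if hi_fr.rss <= 0 or df_hi <= 0:
            p_value = 0.0
        elif hi_fr.rss >= lo_fr.rss:
            p_value = 1.0
        else:
            F = ((lo_fr.rss - hi_fr.rss) / (df_lo - df_hi)) / (hi_fr.rss / df_hi)
            p_value = float(f_dist.sf(F, df_lo - df_hi, df_hi))
        hi_fr.extras["f_test_p"] = p_value
        if p_value < alpha:
            chosen = order
    return chosen, fits
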