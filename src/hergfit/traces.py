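"""Measurement operators on voltage-clamp current traces.

Peak and tail-current extraction, normalized G-V construction from tail
peaks, the model-free tail-ratio statistic I_tail-end / I_tail-peak, and
per-voltage multi-exponential deactivation fitting across sweep
families.

Sign convention is outward-positive; measurements on inward currents
(e.g. hyperpolarization-activated D540K sweeps) take the negative
extremum via ``sign="inward"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import GVDataset, fit_boltzmann, fit_exp_decay, select_exp_order
from .kinetics import CurrentTrace

__all__ = [
    "SweepFamily",
    "RatioCurve",
    "measure_peak_current",
    "measure_tail_peak",
    "tail_ratio",
    "ratio_curve_midpoint",
    "build_gv_from_tails",
    "deactivation_tau_curve",
]


@dataclass
class SweepFamily:
    """Sweeps sharing a protocol template with one varied epoch voltage."""

    traces: list
    varied_voltages: np.ndarray
    varied_epoch: int  # index into protocol.all_epochs
    label: str = ""

    def __post_init__(self) -> None:
        self.varied_voltages = np.asarray(self.varied_voltages, dtype=float)
        if len(self.traces) != len(self.varied_voltages):
            raise ValueError("one trace per varied voltage required")
        if len(self.traces) == 0:
            raise ValueError("empty sweep family")
        dts = {round(tr.sample_interval, 9) for tr in self.traces}
        if len(dts) > 1:
            raise ValueError("all sweeps must share one sample interval")


@dataclass
class RatioCurve:
    """Tail-ratio statistic vs return potential."""

    data: pd.DataFrame  # columns V_ret, ratio
    t_end: float  # ms after the tail peak
    label: str = ""

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        df = pd.DataFrame(self.data)
        missing = {"V_ret", "ratio"} - set(df.columns)
        if missing:
            raise ValueError(f"RatioCurve missing columns: {sorted(missing)}")
        self.data = df.reset_index(drop=True)


def _epoch_segment(tr: CurrentTrace, epoch_index: int, blank_ms: float):
    sl = tr.epoch_slice(epoch_index)
    t = tr.time[sl]
    i = tr.current[sl]
    if len(t) == 0:
        raise ValueError(f"epoch {epoch_index} contains no samples")
    t0, t1 = tr.epoch_bounds(epoch_index)
    if blank_ms < 0 or blank_ms >= (t1 - t0):
        raise ValueError(f"blank_ms = {blank_ms} must lie within the {t1 - t0} ms epoch")
    keep = t - t0 >= blank_ms - 1e-9
    return t[keep], i[keep]


def measure_peak_current(
    tr: CurrentTrace, epoch_index: int, blank_ms: float = 0.0, sign: str = "outward"
) -> float:
    """Extremum current (uA) within an epoch, after a capacitance blanking window."""
    _, i = _epoch_segment(tr, epoch_index, blank_ms)
    return float(i.max()) if sign == "outward" else float(i.min())


def measure_tail_peak(
    tr: CurrentTrace, return_epoch: int, blank_ms: float = 2.0, sign: str = "outward"
):
    """Peak tail current and its time: (I_tail_peak in uA, t_peak in ms)."""
    t, i = _epoch_segment(tr, return_epoch, blank_ms)
    idx = int(np.argmax(i)) if sign == "outward" else int(np.argmin(i))
    return float(i[idx]), float(t[idx])


def tail_ratio(
    tr: CurrentTrace,
    return_epoch: int,
    t_end: float,
    blank_ms: float = 2.0,
    sign: str = "outward",
) -> float:
    """I_tail-end / I_tail-peak, with I_tail-end read t_end ms after the tail peak.

    A model-free summary of how far the tail has decayed by ``t_end``: 1
    means no deactivation, exp(-t_end/tau) for an offset-free
    mono-exponential tail.
    """
    i_peak, t_peak = measure_tail_peak(tr, return_epoch, blank_ms, sign)
    if abs(i_peak) < 1e-12:
        raise ValueError("tail peak is ~0; ratio undefined")
    _, t1 = tr.epoch_bounds(return_epoch)
    t_read = t_peak + t_end
    if t_read > t1 + 1e-9:
        raise ValueError(f"t_end = {t_end} ms reads past the end of the return epoch")
    idx = int(np.argmin(np.abs(tr.time - t_read)))
    return float(tr.current[idx] / i_peak)


def ratio_curve_midpoint(rc: RatioCurve):
    """Midpoint voltage of a tail-ratio curve from a free-amplitude Boltzmann fit.

    Returns ``(V_mid in mV, FitResult)``.  Requires the ratios to span
    more than half of their own range across the sampled voltages
    (otherwise the midpoint is extrapolated and the fit is refused).
    """
    V = rc.data["V_ret"].to_numpy(float)
    r = rc.data["ratio"].to_numpy(float)
    span = float(np.ptp(r))
    if span < 1e-6:
        raise ValueError("flat ratio curve; midpoint undefined")
    # the curve must actually cross its own midpoint within the data
    mid = r.min() + span / 2
    if not (r.min() < mid < r.max()):
        raise ValueError("ratio curve does not span its midpoint")
    ds = GVDataset(pd.DataFrame({"V": V, "g_norm": r}), label=rc.label)
    bp, fr = fit_boltzmann(ds, free_amplitude=True)
    return float(bp.V05), fr


def build_gv_from_tails(
    fam: SweepFamily,
    return_epoch: int,
    normalization: str = "per_condition_max",
    control_max: float | None = None,
    blank_ms: float = 2.0,
    sign: str = "outward",
) -> GVDataset:
    """Normalized G-V from the tail peaks of a varied-V_t sweep family.

    ``per_condition_max`` divides by this family's own maximum tail peak
    (so the maximum point is exactly 1); ``control_max`` divides by a
    supplied reference value, letting treated-condition conductances
    exceed 1.
    """
    peaks = np.array(
        [measure_tail_peak(tr, return_epoch, blank_ms, sign)[0] for tr in fam.traces]
    )
    if normalization == "per_condition_max":
        denom = float(np.max(np.abs(peaks)))
    elif normalization == "control_max":
        if control_max is None:
            raise ValueError("control_max normalization requires a reference value")
        denom = float(abs(control_max))
    else:
        raise ValueError(f"unknown normalization mode: {normalization!r}")
    if denom == 0:
        raise ValueError("zero maximal tail current; cannot normalize")
    df = pd.DataFrame({"V": fam.varied_voltages, "g_norm": np.abs(peaks) / denom})
    return GVDataset(df.sort_values("V").reset_index(drop=True), label=fam.label)


def deactivation_tau_curve(
    fam: SweepFamily,
    return_epoch: int,
    order: str | int = "auto",
    blank_ms: float = 2.0,
    sign: str = "outward",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tail-decay time constants as a function of the return potential.

    For each sweep, the tail segment from its (post-blank) peak to the
    end of the return epoch is fit with ``order`` exponentials
    (``"auto"`` selects the order per sweep by the F-test).  Returns a
    tidy table with one row per (V_ret, component): columns ``V_ret``,
    ``order``, ``component``, ``tau_ms``, ``amp``, ``rel_amp``,
    ``offset``, ``converged``, ``flags``.
    """
    rows = []
    for tr, v in zip(fam.traces, fam.varied_voltages):
        _, t_peak = measure_tail_peak(tr, return_epoch, blank_ms, sign)
        _, t1 = tr.epoch_bounds(return_epoch)
        seg = (tr.time >= t_peak - 1e-9) & (tr.time < t1 - 1e-9)
        t_seg, i_seg = tr.time[seg], tr.current[seg]
        if order == "auto":
            chosen, fits = select_exp_order(t_seg, i_seg, alpha=alpha)
            mix, fr = fits[chosen]
        else:
            mix, fr = fit_exp_decay(t_seg, i_seg, int(order))
        total = sum(abs(a) for a in mix.amps)
        for comp, (tau, amp) in enumerate(zip(mix.taus, mix.amps), start=1):
            rows.append(
                {
                    "V_ret": float(v),
                    "order": mix.order,
                    "component": comp,
                    "tau_ms": tau,
                    "amp": amp,
                    "rel_amp": abs(amp) / total if total > 0 else np.nan,
                    "offset": mix.offset,
                    "converged": fr.converged,
                    "flags": ";".join(fr.flags),
                }
            )
    return pd.DataFrame(rows)
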