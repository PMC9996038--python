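"""Seeded synthetic-data generators for every dataset shape the pipeline fits.

The generators emulate the experimental designs of two-electrode
voltage-clamp studies of hERG1 channel gating: cumulative
concentration-response runs, normalized G-V relationships, tail-current
decays with prescribed time constants, and full step-protocol sweep
families driven by the kinetic simulator.  Noise is additive Gaussian
(specified either in absolute units or as a fraction of the signal
span); every generator is deterministic given its seed, and a study
bundle derives one child seed per file from a single master seed via
``numpy.random.SeedSequence``.

Noiseless output is exactly the corresponding closed-form model — the
oracle identity the test suite leans on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import conditions as cond
from .fitting import DoseResponseDataset, GVDataset
from .kinetics import CurrentTrace, RateParams, SimConfig, VoltageProtocol, simulate_protocol
from .model_core import (
    ExpMixture,
    GatingParams,
    HillParams,
    ThermoContext,
    boltzmann_gv,
    double_boltzmann_gv,
    exp_mixture_value,
    hill_response,
    po_equilibrium,
)

__all__ = [
    "NoiseSpec",
    "ConditionSpec",
    "gen_dose_response",
    "gen_gv",
    "gen_tail_trace",
    "gen_protocol_family",
    "gen_study_bundle",
    "tau_log_interp",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Additive Gaussian noise: ``sd`` in data units, or as a fraction of the
    signal span with ``mode="fraction_of_span"``."""

    sd: float = 0.0
    seed: int = 0
    mode: str = "absolute"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.mode not in ("absolute", "fraction_of_span"):
            raise ValueError(f"unknown noise mode: {self.mode!r}")

    def resolve_sd(self, signal: np.ndarray) -> float:
        if self.mode == "absolute":
            return self.sd
        span = float(np.ptp(signal))
        return self.sd * (span if span > 0 else 1.0)


@dataclass
class ConditionSpec:
    """A labelled model + parameter record with a replicate count."""

    label: str
    model: str  # hill | boltzmann | double_boltzmann | gating6 | exp_mixture
    params: object
    n: int = 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("replicate count must be >= 1")


def _noisy(signal: np.ndarray, noise: NoiseSpec, rng: np.random.Generator) -> np.ndarray:
    sd = noise.resolve_sd(signal)
    if sd == 0:
        return signal.copy()
    return signal + rng.normal(0.0, sd, size=signal.shape)


def gen_dose_response(
    p: HillParams, concs, noise: NoiseSpec = NoiseSpec(), n: int = 1, label: str = ""
) -> DoseResponseDataset:
    """Synthetic cumulative concentration-response dataset, ``n`` replicates."""
    concs = np.asarray(concs, dtype=float)
    if len(concs) < 4:
        raise ValueError("need >= 4 concentrations")
    if np.any(concs < 0):
        raise ValueError("concentrations must be non-negative")
    clean = hill_response(concs, p)
    rng = np.random.default_rng(noise.seed)
    frames = []
    for rep in range(n):
        frames.append(
            pd.DataFrame(
                {"conc": concs, "response": _noisy(clean, noise, rng), "replicate": rep}
            )
        )
    return DoseResponseDataset(pd.concat(frames, ignore_index=True), label=label)


def _gv_clean(model: str, params, V: np.ndarray, ctx: ThermoContext) -> np.ndarray:
    if model == "boltzmann":
        return boltzmann_gv(V, params)
    if model == "double_boltzmann":
        return double_boltzmann_gv(V, params)
    if model == "gating6":
        po = po_equilibrium(params, V, ctx)
        return po / float(np.max(po))  # renormalized to the grid maximum
    raise ValueError(f"unknown G-V model kind: {model!r}")


def gen_gv(
    model: str,
    params,
    V_grid,
    noise: NoiseSpec = NoiseSpec(),
    n: int = 1,
    ctx: ThermoContext = ThermoContext(),
    label: str = "",
) -> GVDataset:
    """Synthetic normalized G-V dataset from a Boltzmann, double-Boltzmann or
    6-state gating model (the latter renormalized to its grid maximum)."""
    V = np.asarray(V_grid, dtype=float)
    if len(V) == 0:
        raise ValueError("empty voltage grid")
    clean = _gv_clean(model, params, V, ctx)
    rng = np.random.default_rng(noise.seed)
    frames = []
    for rep in range(n):
        frames.append(pd.DataFrame({"V": V, "g_norm": _noisy(clean, noise, rng), "replicate": rep}))
    return GVDataset(pd.concat(frames, ignore_index=True), label=label)


def gen_tail_trace(
    m: ExpMixture,
    dt: float = 1.0,
    duration: float = 500.0,
    noise: NoiseSpec = NoiseSpec(),
    voltage: float = 0.0,
    label: str = "",
) -> CurrentTrace:
    """Synthetic tail-current segment sampled from an exponential mixture.

    A duration shorter than ~5x the slowest time constant leaves the
    slow component poorly determined; kept legal but the caller is
    expected to know what they are doing.
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    t = np.arange(0.0, duration, dt)
    clean = exp_mixture_value(t, m)
    rng = np.random.default_rng(noise.seed)
    current = _noisy(clean, noise, rng)
    return CurrentTrace(
        time=t,
        command_voltage=np.full_like(t, voltage),
        current=current,
        metadata={"label": label, "seed": noise.seed, "model": "exp_mixture"},
    )


def gen_protocol_family(
    r: RateParams,
    template: VoltageProtocol,
    varied_epoch: int,
    voltages,
    cfg: SimConfig = SimConfig(),
    ctx: ThermoContext = ThermoContext(),
    label: str = "",
):
    """Simulate one sweep per voltage of a varied-epoch protocol family.

    ``varied_epoch`` indexes ``template.epochs`` (holding excluded).
    Per-sweep noise seeds are spawned deterministically from
    ``cfg.seed``.
    """
    from .traces import SweepFamily

    voltages = np.asarray(voltages, dtype=float)
    if len(voltages) == 0:
        raise ValueError("no varied voltages given")
    child_seeds = np.random.SeedSequence(cfg.seed).generate_state(len(voltages))
    traces = []
    for v, child in zip(voltages, child_seeds):
        prot = template.with_epoch_voltage(varied_epoch, v)
        cfg_v = SimConfig(
            n_channels=cfg.n_channels,
            unitary_conductance=cfg.unitary_conductance,
            reversal_potential=cfg.reversal_potential,
            noise_sd=cfg.noise_sd,
            seed=int(child),
        )
        traces.append(simulate_protocol(r, prot, cfg_v, ctx))
    # +1: epoch indices over all_epochs include the holding epoch at 0
    holding_offset = 1 if template.holding_duration > 0 else 0
    return SweepFamily(
        traces=traces,
        varied_voltages=voltages,
        varied_epoch=varied_epoch + holding_offset,
        label=label,
    )


# ---------------------------------------------------------------------------
# whole-study bundle


def tau_log_interp(anchors: dict, V: float) -> float:
    """Log-linear interpolation of a time constant between voltage anchors."""
    vs = sorted(anchors)
    taus = [anchors[v] for v in vs]
    return float(np.exp(np.interp(V, vs, np.log(taus))))


def _default_conditions() -> list:
    """Condition archetypes for split, N-del, C-del and D540K channels,
    control vs 30 uM RPR260243, using the reference parameter sets."""
    specs = [
        ConditionSpec("split-control-gv", "gating6", cond.SPLIT_GATING_CONTROL, n=7),
        ConditionSpec("split-rpr-gv", "gating6", cond.SPLIT_GATING_RPR, n=7),
        ConditionSpec("split-dose-itail", "hill", cond.HILL_SPLIT_ITAIL, n=7),
        ConditionSpec("split-dose-ipeak", "hill", cond.HILL_SPLIT_IPEAK, n=7),
        ConditionSpec("split-dose-tau", "hill", cond.HILL_SPLIT_TAU_DEACT, n=5),
        ConditionSpec(
            "d540k-control-gv",
            "double_boltzmann",
            cond.solve_double_boltzmann(cond.D540K_GV_CONTROL, cond.D540K_TROUGH_CONTROL),
            n=10,
        ),
        ConditionSpec(
            "d540k-rpr-gv",
            "double_boltzmann",
            cond.solve_double_boltzmann(cond.D540K_GV_RPR, cond.D540K_TROUGH_RPR),
            n=10,
        ),
    ]
    # tail archetypes: (label, tau anchors or fixed mixtures)
    tails = {
        "split-control-tail": {v: ExpMixture((tau,), (1.0,)) for v, tau in cond.SPLIT_TAU_CONTROL.items()},
        "split-rpr-tail": {v: ExpMixture((tau,), (1.0,)) for v, tau in cond.SPLIT_TAU_RPR.items()},
        "ndel-control-tail": {v: ExpMixture((tau,), (1.0,)) for v, tau in cond.NDEL_TAU_CONTROL.items()},
        "ndel-rpr-tail": {
            v: ExpMixture.from_unsorted(
                taus, (1.0 - cond.NDEL_SLOW_FRACTION, cond.NDEL_SLOW_FRACTION)
            )
            for v, taus in cond.NDEL_TAU_RPR.items()
        },
        # RPR does not alter C-del deactivation: identical mixtures per condition
        "cdel-control-tail": {v: ExpMixture((tau,), (1.0,)) for v, tau in cond.CDEL_TAU.items()},
        "cdel-rpr-tail": {v: ExpMixture((tau,), (1.0,)) for v, tau in cond.CDEL_TAU.items()},
        "d540k-control-tail": {
            -70.0: ExpMixture(cond.D540K_TAIL_TAUS_CONTROL, (0.5, 0.5))
        },
        "d540k-rpr-tail": {
            -70.0: ExpMixture(cond.D540K_TAIL_TAUS_RPR, (0.4, 0.3, 0.3))
        },
    }
    for label, mixtures in tails.items():
        specs.append(ConditionSpec(label, "exp_mixture", mixtures, n=1))
    return specs


def gen_study_bundle(
    out_dir,
    conditions: list | None = None,
    master_seed: int = 0,
    noise_fraction: float = 0.03,
    ctx: ThermoContext = ThermoContext(),
) -> dict:
    """Write a complete synthetic study to ``out_dir`` and return its manifest.

    One file per condition (CSV), plus ``manifest.json`` recording the
    generating model, parameters, per-file seed and noise settings.
    Per-file seeds are drawn deterministically from ``master_seed``.
    """
    from .io import write_trace_csv

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if conditions is None:
        conditions = _default_conditions()

    seeds = np.random.SeedSequence(master_seed).generate_state(len(conditions) * 8)
    seed_iter = iter(int(s) for s in seeds)
    dose_concs = np.array([1.0, 3.0, 5.0, 10.0, 20.0, 30.0])
    gv_grid_act = np.arange(-60.0, 61.0, 10.0)
    gv_grid_biphasic = np.arange(-140.0, 41.0, 10.0)

    manifest = {"master_seed": master_seed, "noise_fraction": noise_fraction, "files": []}
    for spec in conditions:
        seed = next(seed_iter)
        noise = NoiseSpec(sd=noise_fraction, seed=seed, mode="fraction_of_span")
        entry = {"label": spec.label, "model": spec.model, "seed": seed, "n": spec.n}
        if spec.model == "hill":
            ds = gen_dose_response(spec.params, dose_concs, noise, n=spec.n, label=spec.label)
            fname = f"{spec.label}.csv"
            ds.data.to_csv(out / fname, index=False)
            entry["params"] = vars(spec.params)
            entry["kind"] = "dose_response"
        elif spec.model in ("boltzmann", "double_boltzmann", "gating6"):
            grid = gv_grid_biphasic if spec.model == "double_boltzmann" else gv_grid_act
            ds = gen_gv(spec.model, spec.params, grid, noise, n=spec.n, ctx=ctx, label=spec.label)
            fname = f"{spec.label}.csv"
            ds.data.to_csv(out / fname, index=False)
            entry["params"] = (
                spec.params.to_dict() if isinstance(spec.params, GatingParams) else vars(spec.params)
            )
            entry["kind"] = "gv"
        elif spec.model == "exp_mixture":
            traces = []
            sweep_meta = []
            for v, mix in sorted(spec.params.items()):
                duration = max(500.0, 4.0 * max(mix.taus))
                dt = max(duration / 2500.0, 0.5)
                tr_noise = NoiseSpec(sd=noise_fraction, seed=next(seed_iter), mode="fraction_of_span")
                tr = gen_tail_trace(mix, dt=dt, duration=duration, noise=tr_noise, voltage=v)
                tr.metadata["sweep_id"] = f"{spec.label}_V{v:+.0f}"
                traces.append(tr)
                sweep_meta.append(
                    {"V_ret": v, "taus_ms": list(mix.taus), "amps": list(mix.amps), "seed": tr_noise.seed}
                )
            fname = f"{spec.label}.csv"
            write_trace_csv(traces, out / fname)
            entry["sweeps"] = sweep_meta
            entry["kind"] = "tail_traces"
        else:
            raise ValueError(f"unknown condition model: {spec.model!r}")
        entry["file"] = fname
        manifest["files"].append(entry)

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
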