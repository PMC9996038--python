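# hergfit

Kinetic modelling and curve fitting for voltage-clamp studies of hERG1
(Kv11.1) potassium channel gating, built around the analyses used to
characterize how the activator RPR260243 slows channel deactivation in
split, N-/C-terminal truncated and D540K hERG1a channels expressed in
*Xenopus* oocytes.

It is written for electrophysiologists and modellers who need a tested,
scriptable version of the standard two-electrode voltage-clamp analysis
stack:

* **6-state sequential gating model.**  Four independent voltage-sensor
  transitions (per-subunit equilibrium constant
  `K(V) = K(0)·exp(−z₁FV/RT)`) followed by a concerted pore opening
  (`Ko(V) = Ko(0)·exp(−z₂FV/RT)`), giving the closed-form normalized
  conductance

  `g/gmax = [1 + Ko + 4KoK + 6KoK² + 4KoK³ + KoK⁴]⁻¹`

* **Q-matrix simulator.**  A detailed-balance kinetic lift of the
  equilibrium model, propagated exactly per constant-voltage epoch with
  matrix exponentials, producing current sweeps for arbitrary step
  protocols.

* **Fitters.**  Hill (logistic) concentration–response with log-scale
  EC50, single and double (biphasic) Boltzmann G-V, the 4-parameter
  6-state G-V fit with seeded multi-start, and 1–3 component exponential
  tail-decay fits with extra-sum-of-squares F-test order selection.

* **Trace analysis.**  Peak/tail-current extraction, G-V construction
  from tail peaks, the model-free tail-ratio statistic
  `I_tail-end/I_tail-peak`, and τ–V deactivation curves across sweep
  families.

* **Synthetic data.**  Seeded generators that emulate every experiment
  shape above, with reference parameter sets for the split, N-del,
  C-del and D540K channel archetypes under control and RPR conditions
  (`hergfit.conditions`).

## Worked example

Fit the concentration dependence of deactivation slowing (τ_deact at
−60 mV) and a bi-exponential tail, from synthetic data generated at the
reference parameters:

```python
import numpy as np
from hergfit import fit_hill, fit_exp_decay, select_exp_order
from hergfit.synth import gen_dose_response, gen_tail_trace, NoiseSpec
from hergfit.conditions import HILL_SPLIT_TAU_DEACT
from hergfit.model_core import ExpMixture

ds = gen_dose_response(HILL_SPLIT_TAU_DEACT, [1, 3, 5, 10, 20, 30],
                       NoiseSpec(0.03, seed=5, mode="fraction_of_span"), n=5)
hp, fr = fit_hill(ds)
print(f"EC50 = {hp.EC50:.2f} uM, nH = {hp.nH:.2f}")

tr = gen_tail_trace(ExpMixture((44.0, 1451.0), (0.6, 0.4)), dt=2.0,
                    duration=6000.0, noise=NoiseSpec(0.02, seed=5))
order, fits = select_exp_order(tr.time, tr.current)
mix, _ = fits[order]
print(f"selected order = {order}")
print(f"tau_f = {mix.taus[0]:.1f} ms, tau_s = {mix.taus[1]:.0f} ms")
```

prints

```
EC50 = 7.59 uM, nH = 1.96
selected order = 2
tau_f = 42.8 ms, tau_s = 1456 ms
```

i.e. the half-maximal slowing concentration (generated at 7.9 µM with a
Hill coefficient of 1.9) and the fast/slow deactivation time constants
(generated at 44 and 1451 ms, a 0.4 slow fraction) are recovered from
noisy data, and the F-test correctly identifies a bi-exponential decay.

The same analyses are available from the shell:

```bash
hergfit synth --seed 1 --out study/            # synthetic study bundle
hergfit fit-dose --out hill.json study/split-dose-tau.csv
hergfit fit-gating --seed 1 --out gating.json study/split-control-gv.csv
hergfit fit-tails --order auto --out tails.json study/ndel-rpr-tail.csv
hergfit pipeline --seed 1 --out run1/          # everything, summarized
```

`pipeline` writes `summary.csv` with one row per recovered parameter
per condition; runs are deterministic given `--seed`.

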