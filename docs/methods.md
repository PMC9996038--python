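# Methods

## The gating model

hERG1 activation is modelled as a sequential 6-state scheme

    C0 <-> C1 <-> C2 <-> C3 <-> C4 <-> O

in which four identical, independent voltage sensors activate with a
per-subunit equilibrium constant and pore opening is a final concerted
step.  Both constants are written in the closing direction,

    K(V)  = K(0)  exp(−z1 F V / R T)
    Ko(V) = Ko(0) exp(−z2 F V / R T)

with `z1`, `z2` the effective charges (elementary charges), `F = 96485
C/mol`, `R = 8.314 J/(mol·K)`.  Because the subunits are independent,
the closed states carry binomial statistical factors: relative to the
open state, state C(4−j) has weight `Ko·C(4,j)·K^j`, so successive
pairwise equilibrium constants toward rest are K/4, 2K/3, 3K/2 and 4K —
the unique statistical-factor assignment consistent with independent
subunits — and the equilibrium open probability is

    Po(V) = [1 + Ko (1 + K)^4]^(−1)
          = [1 + Ko + 4KoK + 6KoK² + 4KoK³ + KoK⁴]^(−1).

Occupancies are evaluated on a log scale (`logsumexp`), so voltages of
hundreds of millivolts saturate to the limiting distribution instead of
overflowing.  `po_equilibrium` and `state_occupancies` are two
independent code paths (log1p closed form vs binomial weight
normalization) and are cross-checked to 1e−12 in the tests.

The model deliberately omits inactivation: it describes activation
G-V relationships built from peak tail currents, where inactivation has
been relieved at the return potential.  Temperature defaults to
295.15 K (22 °C, typical for two-electrode voltage clamp of oocytes)
and is configurable; the recordings it emulates did not state a
temperature.

## Kinetic lift and simulation

The equilibrium model constrains only rate *ratios*.  The simulator
lifts it to a Markov generator with an Eyring-style charge split
`delta` (default 0.5):

    alpha(V) = base_rate_closed · exp(+delta·z1·FV/RT),   beta(V)  = alpha·K(V)
    gamma(V) = base_rate_open   · exp(+delta·z2·FV/RT),   closing  = gamma·Ko(V)

with subunit multiplicities 4α,3α,2α,α forward and β,2β,3β,4β backward.
Any such lift leaves the stationary distribution — hence every
steady-state G-V — identical to the closed form; changing base rates or
the split rescales kinetics only (both properties are tested).  Default
base rates (0.2 and 0.05 ms⁻¹ at 0 mV) put control deactivation at
strongly negative potentials on the tens-of-milliseconds scale, in the
range of fast-deactivating hERG1 variants; absolute simulated time
constants are otherwise arbitrary, since no experimental rates
constrain them.

States are propagated exactly per constant-voltage epoch with the
matrix exponential of the generator; a fine-step RK4 integrator exists
only as a test oracle.  Current is deterministic mean-field,

    I(t) = N·g·P_O(t)·(V(t) − E_rev)·1e−6   [µA],

(defaults N·g = 50 µS, whole-oocyte scale) plus seeded additive
Gaussian noise.  Stochastic single-channel gating, capacitance
transients, leak and series-resistance artifacts are not modelled; a
blanking window in the trace measurements stands in for the absent
capacitance transient.

## Fitting

All fitters are bounded Levenberg–Marquardt least squares (lmfit),
unweighted by default (data are normalized before fitting), with
standard errors from the Jacobian-based covariance — comparable in
spirit but not identical in meaning to between-oocyte S.E.M. values.

* **Hill:** `y = Amax + (Amin − Amax)/(1 + (EC50/c)^nH)`; EC50 searched
  in log space, nH bounded to (0, 10].  Amax/Amin are free endpoints —
  for a potentiating drug the curve rises (Amin > Amax).  Flat data and
  EC50 estimates far outside the dosed range are flagged, not silently
  returned.
* **Boltzmann:** `g = 1/(1 + exp((V0.5 − V)/k))`; initialized from the
  half-max crossing and 10–90% spread.  An optional free
  amplitude/offset variant serves tail-ratio curves (which need not run
  0→1 and may fall with depolarization).
* **Double Boltzmann:** two opposed branches plus offset for biphasic
  (D540K-like) G-V curves.  After fitting, amplitudes and offset are
  rescaled so the curve maximum over the data's voltage range is
  exactly 1 (the data are normalized conductances); the curve minimum —
  the trough near −70 mV — is reported with its voltage.  Branch
  midpoints within 5 mV are flagged as collapsed.
* **6-state G-V:** least squares over (K(0), z1, Ko(0), z2), the
  equilibrium constants in log10 space, the model curve renormalized to
  its maximum over the dataset voltages (matching how tail-peak G-V
  data are normalized).  The parameter surface has a long flat valley
  (see Limitations), so the fit multi-starts (default 5 seeded jittered
  starts) and keeps the lowest-rss converged solution.
* **Exponential tails:** 1–3 decaying exponentials plus offset, time
  constants in log10 space, initialized by peeling (repeated log-linear
  fits of the late phase).  Taus are returned sorted ascending.
  Adjacent taus within a factor 1.5, or components carrying < 1% of the
  total amplitude, flag the fit as over-parameterized.
* **Order selection:** the order is increased while the
  extra-sum-of-squares F-test rejects the simpler model at α = 0.05
  (the convention in electrophysiology) and the richer fit is not
  degenerate.  AICc is computed and reported but does not decide.

Noiseless identifiable data are recovered to optimizer tolerance
(≤ 1e−6 relative; tested for every fitter).

## Synthetic data

Generators produce every dataset shape the fitters consume, with the
reference parameter sets of `hergfit.conditions` as default truths:
gating parameters for split channels ± RPR260243, Hill parameters for
the three concentration–response measures, deactivation time constants
for split/N-del/C-del channels at the ends of the V_ret range
(log-linear interpolation in between), and the D540K biphasic G-V
branch parameters with troughs of 0.02 (control) and 0.17 (RPR).

Where the underlying reports give only some parameters, the remainder
are fixed once here: Hill endpoints encode the observed effect sizes
(I_tail-peak 1→2.5, I_peak 1→1.6, τ_deact 1→4 relative to control);
the N-del slow-component fraction is 0.4 (middle of the reported
0.32–0.47); D540K tail amplitudes are 0.5/0.5 (bi) and 0.4/0.3/0.3
(tri); D540K double-Boltzmann amplitudes/offset are solved so the curve
spans [trough, 1] over −140…+40 mV with equal branch amplitudes.  The
C-del archetype uses identical time constants for control and RPR,
encoding the drug's lack of effect on that variant.

Noise is additive Gaussian only, specified in absolute units or as a
fraction of the signal span (default 3%), seeded and byte-reproducible;
study bundles derive one child seed per file from a master seed via
`numpy.random.SeedSequence`.  The generators do **not** emulate
oocyte-to-oocyte hierarchical variance, leak/capacitance artifacts,
rundown, or drug-binding kinetics (drug conditions are simply
alternative parameter sets).  Passing recovery tests therefore
demonstrates estimator correctness under the assumed noise model, not
robustness to every pathology of real recordings.

## Numerical choices

* Overflow-proof log-space evaluation of occupancies and Po; rate
  matrices refuse voltages whose rates exceed 1e9 ms⁻¹ with advice to
  clip the protocol.
* Optimizer tolerances 1e−14 (xtol/ftol/gtol) so "exact recovery"
  tests are meaningful; EC50/K(0)/Ko(0)/taus positive by log-scale
  parametrization rather than penalty.
* Tail fits re-zero time at the tail-peak sample (post-blank, default
  blank 2 ms); the tail-ratio read time `t_end` is anchored to the
  tail-peak time, which is invariant to where the epoch begins.
* Ratio-curve midpoints come from a free-amplitude Boltzmann fit, not
  linear interpolation (robust to noise); curves that do not span their
  own midpoint are refused.
* Degenerate inputs error early and specifically: < 4 distinct
  concentrations or voltages (6 for the two 4+-parameter G-V models),
  empty grids, flat curves, zero tail peaks.

## Problem sizes

Recovery experiments run at the reported design sizes: 6 concentrations
× 5–7 replicates, 13–19 voltages × 7–10 replicates, tail segments of
500–3000 samples.  The order-selection accuracy check uses 100 seeds at
signal-to-noise 20.  Everything, including the full test suite, runs in
a few minutes on one CPU.

## Known limitations

* **K(0) identifiability.**  On a −60…+60 mV grid the four gating
  parameters are strongly correlated (|r| > 0.95 pairwise); the
  linearized standard error of K(0) under a typical noisy design
  (2%-of-span noise, 7 replicates) is ≈50% of its value.  Recovered
  K(0) from any single noisy dataset should be read with that
  uncertainty in mind — this is a property of the model/protocol
  combination, not of the optimizer (which recovers noiseless data to
  1e−6 and sits at the Cramér–Rao floor).
* EC50 estimates whose dose range stops near 2×EC50 (as for the
  I_tail-peak measure, dosed to 30 µM against an EC50 of 15 µM) carry
  sampling SD comparable to the reported between-oocyte S.E.M. (~13%),
  because the saturation endpoint is extrapolated.
* The simulator's absolute kinetics are a modelling convention (see
  above); only equilibrium quantities are comparable across rate
  choices.
* Mean-field current only; no stochastic gating, so simulated noise is
  purely the additive Gaussian term.
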