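# Methods

## The regulation model

The package implements a homeostatic model of L-type calcium-channel
expression in spontaneously beating cardiomyocytes. The premise: the cell
senses its cytosolic calcium concentration `c` (mM) against a target `c*`
and adjusts channel expression to close the gap. Two variants are
implemented.

**Two-ODE model.** Relative mRNA count `m` and relative channel count `n`
(both 1 at default expression) evolve as

    tau_m dm/dt = c* - c        tau_m in mM·ms (default 400)
    tau_n dn/dt = m - n         tau_n in ms    (default 1000)

`c` is the *instantaneous* cytosolic calcium of the coupled cell model;
`c*` alone is defined as a cycle average (see below). Because `m` relaxes
to `n` within seconds while the drive integrates over hours, `|m - n|`
stays small; Gronwall's inequality gives the envelope

    |m - n|(t) <= e^(-t/tau_n) (|m - n|(0) - (tau_n/tau_m) sup|c* - c|)
                  + (tau_n/tau_m) sup|c* - c|,

implemented as `gronwall_bound` and verified numerically along coupled
trajectories in the test suite.

**Bounded scalar model.** Since `m ≈ n`, the system collapses to one
equation, and physiological limits on expression are imposed through a
smooth gate:

    tau dn/dt = (c* - c) H(c, n)          tau in mM·ms (default 400)
    H(c, n)   = h(n, n-, eps_n) h(c, c*, eps_c)
              + h(n+, n, eps_n) h(c*, c, eps_c)
    h(a, b, eps) = (1 + tanh((a - b)/eps)) / 2

with `n- = 0.1`, `n+ = 3`, `eps_n = 0.01`, `eps_c = 1e-7 mM` by default.
`H` is 1 everywhere except the two corner regimes — `n > n+` with `c < c*`
(growth would exceed the ceiling) and `n < n-` with `c > c*` — where it
vanishes. Equilibria are therefore `c = c*`, `n ≈ n+`, or `n ≈ n-`.

The two appearances of the protein time constant carry different units
(ms in the two-ODE model, mM·ms in the scalar model); `RegulationParams`
keeps them as separate fields (`tau_n_traffic_ms`, `tau_scalar_mM_ms`) so
the collision cannot cause a unit error. An "unbounded" run is the bounded
model with `n+` far above `1/b` — not a separate code path.

**Drug block.** A calcium channel blocker scales the single-channel
current by `b(D) ∈ (0, 1]` (`b = 0.45` for 0.1 uM nifedipine, `b = 0.12`
for 1 uM). The whole-cell L-type current depends on `(n, b)` only through
the product `n·b`, so full compensation (`n = 1/b`) reproduces the control
model exactly — an identity tested at both the derivative and the trace
level. Predicted equilibria are `n_eq = min(1/b, n+)`.

## The reference cell model

The cell model is a pluggable contract (`CellModel`): any spontaneously
beating ODE system exposing voltage, cytosolic calcium and per-protein
density scale factors can drive the regulation. The shipped reference,
`MinimalHiPSCCM`, is a compact purpose-built pacemaking model (9 states)
in the Hodgkin–Huxley tradition, with the current families that dominate
the spontaneous hiPSC-CM action potential:

* fast sodium `I_Na` (instantaneous activation `m_inf^3`, gated
  inactivation `h`) — upstroke;
* late/persistent sodium `I_NaL` (slowly inactivating gate `hL`) —
  sustains the plateau; its slow inactivation also removes any spurious
  depolarised rest point under strong calcium block;
* L-type calcium `I_CaL` (`d`/`f` gates) — plateau and calcium influx,
  scaled by `n·b(D)` times a per-protein density factor;
* rapid delayed rectifier `I_Kr` (`xr` gate) — repolarisation;
* inward rectifier `I_K1` — maximum diastolic potential;
* funny current `I_f` (`y` gate) — diastolic depolarisation.

Calcium handling comprises L-type influx (`j_cal`, proportional to the
inward `I_CaL`), graded sarcoplasmic-reticulum release proportional to the
instantaneous influx and saturating in SR load (`j_rel ∝ j_cal ·
c_sr/(1 + c_sr/K_sr)`), SERCA uptake with Hill-type saturation, a small SR
leak, and lumped sarcolemmal extrusion with Hill-2 cooperativity
(`j_out = v_out · c²/(c² + K_out²)`, standing for NCX/PMCA). The release
trigger is the influx itself, which yields graded release by construction:
reducing `I_CaL` reduces the whole transient. The extrusion cooperativity
matters structurally: with a linear pump the periodic steady state would
pin the cycle-averaged calcium to `mean(j_cal)/k_out` regardless of SR
handling, and SERCA density would have no steady-state effect on the
average; with a convex pump a more peaked transient (the consequence of
stronger SERCA uptake and release) lowers the mean for the same influx.

The default parameters produce a limit cycle at ~96 beats/min with APD50
≈ 176 ms, APD80 ≈ 231 ms, a calcium transient of roughly 3×10⁻⁵ to
1.7×10⁻⁴ mM, and a cycle-averaged calcium `c*` ≈ 8.7×10⁻⁵ mM. The model
keeps beating down to an effective L-type scale of ~0.08, so both drug
arms remain spontaneously active. Like any strongly reduced formulation,
it is calibrated for qualitative fidelity — AP shape, pacemaking, the
monotone dependence of average calcium on L-type density, and the sign
pattern of density perturbations — not to reproduce any published model's
numerical traces.

Density scale factors exist for CaL, Na (fast and late together), f, Kr,
K1, SERCA and NCX. Scaling checks in the test suite pin the qualitative
structure: average calcium increases monotonically with the CaL scale
near baseline, and a 20 % density increase raises average calcium for
CaL/Na/f but lowers it for Kr/K1/SERCA.

**Target calcium.** `c*` is the time average of `c` over complete
upstroke-delimited cycles of the equilibrated default model (all scales 1,
no drug), computed by trapezoidal quadrature on a densely sampled window.
Equilibration runs 480 s of model time: SR content relaxes with a
~20–30 s time constant and is stationary well before that; the averaged
calcium is then stable to <0.1 % between consecutive windows.

## Coupled integration

The regulation variables move over hours; an AP lasts a few hundred ms.
Two strategies:

**Direct.** The full augmented system (cell states plus `m, n` or `n`) is
integrated with LSODA (automatic stiff/non-stiff switching; the stiff side
is a BDF-type multistep method) at `rtol 1e-6`, `atol 1e-8` on
voltage-scale states and `1e-10` on concentrations. Practical when the
mRNA time constant is compressed; used for validating the accelerator.

**Averaged (quasi-static).** Alternates two phases: (i) the cell is
integrated at frozen `n` in 8 s windows until the cycle-averaged calcium
changes by less than `5e-4` (relative) between consecutive windows — this
inner relaxation prevents slow SR loading from biasing the average after a
slow-variable jump; (ii) the slow variables advance over an adaptive step
`dt` chosen so `|Δn| ≤ 0.05`, capped at 30 min, holding the measured
average in place of `c`. The two-ODE slow update is closed-form (the
system is affine at frozen calcium); the bounded update integrates the 1-D
ODE with RK45. The cell's relaxation time does not advance the slow clock.
A guard refuses the method when the per-cycle change in `n` exceeds 0.01
(no time-scale separation) and points the caller to direct integration;
with the default parameters this guard also means the accelerator cannot
be validated at extreme time compression, so the validation test compresses
`tau_m` 25-fold, where both methods are applicable and agree within 2 %.

With `stop_at_plateau`, a run ends after `n` moves less than `1e-3` over
three consecutive maximal steps. Quiescent cells (no beats in a window)
are legal: the window mean replaces the cycle average and the regulation
proceeds.

**Snapshots** at requested wall times span two upstroke-delimited AP
cycles (one cycle is the display unit; the second lets the biomarker
pipeline measure a rate from the snapshot itself).

**Drug assay.** `block_experiment` applies the dose as a step at t = 0
from the equilibrated default cycle (no pharmacokinetics), runs the
bounded coupled model to 16 h with snapshots at 2, 4, 6, 8, 13 and 16 h,
and tabulates APD50, APD80 and beat rate per snapshot next to a pre-drug
control cycle (reported at 0 h).

## Biomarkers

Upstrokes are the times of maximal positive finite-difference slope within
excursions above 50 % of the per-trace amplitude, with a 200 ms refractory
guard. Slopes are measured on the raw trace (smoothing would smear the
one-frame upstroke), while excursion gating, extrema and the slow falling
crossing use the optionally smoothed trace (3-sample moving average by
default for 50 frame/s optical recordings, none for dense model traces).
APD at fraction `f` is the time between the rising and falling crossings
of `peak - f·(peak - baseline)`, located by linear interpolation. The
baseline is the 10th percentile of the post-peak segment rather than its
minimum: the minimum of ~10² noisy samples sits ~2σ below the true
diastolic level and would bias APD80 late by tens of ms at 5 % noise.
Beat rate is `60000 / mean inter-upstroke interval`. Summaries are medians
across beats (robust to clipped first/last beats). All quantities are
invariant to affine transforms of the voltage channel, and polarity is
auto-corrected using slope asymmetry (depolarisation is much faster than
repolarisation). Quiescent traces — amplitude below `min_snr` (8) times a
robust MAD noise estimate, or below an explicit `min_amplitude` — yield
empty beat lists and a `quiescent` flag, never an exception.

These definitions are standard for optical voltage recordings but are not
guaranteed to be byte-identical to any particular lab pipeline; absolute
APD values should be compared within one pipeline only.

## Synthetic optical data

The generator emulates plate-based optical recordings: 8 s at 50
frames/s, arbitrary units, additive Gaussian noise (as a fraction of
amplitude), linear baseline drift, optional polarity inversion, and a
study layout of 3 arms (control, 0.1 uM, 1 uM) × wells × 7 timepoints
(baseline, 2, 4, 6, 8, 13, 16 h) with well-level multiplicative
variability and per-recording jitter.

The single-beat template is piecewise half-cosine — rise `t_r` (default
20 ms), plateau `t_p`, fall `t_f` — whose level crossings are analytically
invertible: `APD(f) = t_p + w(f)(t_r + t_f)` with `w(f) = arccos(1-2f)/π`.
Given target APD50/APD80 the segment durations follow in closed form, so
ground-truth biomarkers are exact by construction. Arm effect curves are
parametric exponential recoveries (initial and residual fractional effects
with a time constant in hours) by default and can be replaced by callables
built from coupled-simulation output, so the synthetic study can embody
the mechanistic model. Everything is reproducible from a single seed.

What the generator does *not* emulate: dye kinetics, photobleaching,
motion artefacts, tissue-geometry effects, or non-stationary beat-to-beat
variability. Passing the recovery tests therefore demonstrates the
pipeline's correctness on idealised optical waveforms with realistic
sampling, noise and drift — not robustness to every failure mode of real
recordings.

## Sensitivity panel

`perturb_and_measure` scales one protein type's density (default ×1.2) at
t = 0 from the default limit cycle, integrates 1000 s at fixed `n`
(regulation off), and averages calcium over the following 10 s against the
default model's matching average. The unperturbed comparator is computed
once per panel and cached. Quiescent outcomes are flagged, and per-protein
failures are reported in the result rows without aborting the panel.

## Numerical choices and degenerate inputs

* Solver: LSODA everywhere (`rtol 1e-6`, per-state `atol`); deterministic
  for fixed inputs, so simulations need no seeds. Only the synthetic-data
  generator consumes randomness.
* Quadrature: trapezoidal on the solver's dense output grid (1–2 ms).
* Cycle averages span first-to-last detected upstroke; fewer than two
  upstrokes → plain window mean plus a quiescent flag.
* Gate saturation: "equals 1" is asserted at 1e-9, from tanh saturating
  beyond argument 10.
* Equilibration defaults: 480 s for limit-cycle initialisation and target
  calcium (SR loading is the slowest transient); 1000 s + 10 s windows for
  the sensitivity protocol.
* Ties and guards: upstroke refractory 200 ms; beats whose falling
  crossing leaves the trace are dropped and flagged; `n` is floored at
  1e-12 inside solvers to survive transient negative excursions.

## Known limitations

* The reference cell model is a minimal formulation built for this
  package; quantitative biomarker values (APD, rate, calcium levels) are
  plausible for hiPSC-CMs but not fitted to any dataset. All structural
  results (equilibria at `1/b` and `n+`, compensation identity, sign
  patterns) are contract-level and hold for any compliant cell model.
* The wet-lab arm of a drug study is emulated synthetically; agreement
  between the coupled model and the synthetic "measurements" demonstrates
  pipeline consistency, not biological validation.
* Model biomarkers are computed from membrane voltage directly; an optical
  transform (dye response) between voltage and fluorescence is not
  modelled.
* The averaged integrator assumes the cell relaxes to a (quasi-)periodic
  attractor at frozen `n`; strongly arrhythmic regimes would need direct
  integration.
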