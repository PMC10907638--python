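# calreg

Homeostatic regulation of L-type calcium-channel expression in
spontaneously beating cardiomyocytes — simulation, drug-block assays, and
optical-trace biomarkers.

## The problem

Cardiomyocytes keep their electrical phenotype stable even though every
membrane protein turns over continuously. One proposed mechanism is a
calcium setpoint: the cell senses its cytosolic calcium concentration `c`
against a target `c*` and adjusts the expression of calcium-carrying
channels to close the gap. This has a pharmacological consequence: an
L-type calcium channel blocker (CCB, e.g. nifedipine) lowers calcium
influx, which — under such a feedback — triggers *upregulation* of the
blocked channel, progressively eroding the drug's whole-cell efficacy over
the hours after dosing, even though each individual channel stays equally
blocked.

`calreg` implements this feedback loop coupled to a beating
human-iPSC-derived-cardiomyocyte (hiPSC-CM) style action-potential model,
and the analysis pipeline around it: action-potential biomarkers (APD50,
APD80, beat rate) from voltage traces, an in-silico drug assay over 16 h,
a protein-type sensitivity panel, and a synthetic generator for
plate-based optical voltage recordings that serves as ground truth for
pipeline validation.

## The model

Relative mRNA count `m` and relative channel count `n` (1 = default
expression) follow

    τ_m dm/dt = c* − c          τ_m in mM·ms
    τ_n dn/dt = m − n           τ_n in ms

with `c` the instantaneous cytosolic calcium of the coupled cell model and
`c*` its cycle average on the default limit cycle. Because `m ≈ n`
(a Gronwall argument bounds `|m − n|` by `(τ_n/τ_m)·sup|c* − c|`), the
system reduces to a single equation with smooth expression bounds
`n₋ ≤ n ≤ n₊`:

    τ dn/dt = (c* − c) · H(c, n)
    H(c, n) = h(n, n₋, ε_n) h(c, c*, ε_c) + h(n₊, n, ε_n) h(c*, c, ε_c)
    h(a, b, ε) = (1 + tanh((a − b)/ε)) / 2

A CCB dose scales the single-channel current by `b(D)` (0.45 at 0.1 µM
nifedipine, 0.12 at 1 µM); the whole-cell L-type current depends on `n`
and `b` only through `n·b`, so the unbounded model equilibrates at
`n = 1/b` (full compensation) while the bounded model halts at
`n ≈ n₊ = 3` and a residual drug effect persists. See `docs/methods.md`
for the cell model, the slow–fast averaged integrator, and all numerical
choices.

## Worked example

The 0.1 µM nifedipine assay: block applied at t = 0 from the equilibrated
default cycle, bounded regulation compensating over 16 h, one biomarker
row per recording timepoint (0 h is the pre-drug control):

```python
from calreg import MinimalHiPSCCM, RegulationParams, block_experiment
from calreg.cell_model import compute_target_calcium

model = MinimalHiPSCCM()
c_star = compute_target_calcium(model)       # 8.672e-05 mM
params = RegulationParams(c_target_mM=c_star)
table, result = block_experiment(model, params, "0.1uM")
print(table)
```

```
   timepoint_h    apd50_ms    apd80_ms  beat_rate_bpm         n
0          0.0  175.639886  230.525945      96.308186  1.000000
1          2.0  121.604696  180.000164     111.627907  1.390053
2          4.0  139.673519  196.234502     105.913504  1.643256
3          6.0  151.000993  206.841262     102.651839  1.815244
4          8.0  158.420981  213.920661     100.671141  1.933369
5         13.0  168.412997  223.403268      98.119379  2.096396
6         16.0  171.127824  226.158555      97.402597  2.144768
```

Reading the table: immediately after dosing the action potential shortens
sharply (APD50 drops from 176 to 122 ms) and beating accelerates (96 →
112 bpm) — the classical acute CCB signature. As the channel count `n`
climbs from 1 toward ~2.1, both biomarkers creep back toward control; by
16 h the residual APD50 deficit is ~4 ms against an initial ~54 ms, i.e.
the drug has lost most of its whole-cell effect. At 1 µM (`b = 0.12`),
`n` saturates at the bound `n₊ = 3` within ~6 h and a large residual
effect remains — the compensation is capped.

The same experiment from a shell:

```bash
calreg block --dose 0.1uM --out out/block
calreg synth --wells 4 --out study/          # synthetic optical study
calreg biomarkers --in study --fps-mode optical --out out/table.csv
calreg sensitivity --proteins all --scale 1.2 --out out/panel.csv
```

## Layout

| module | contents |
| --- | --- |
| `calreg.regulation` | regulation ODEs, expression gate, Gronwall envelope, equilibrium prediction |
| `calreg.cell_model` | cell-model contract, `MinimalHiPSCCM` reference model, drug block, traces |
| `calreg.coupled` | direct and slow–fast averaged coupled integration, drug assay |
| `calreg.biomarkers` | beat detection, APD50/APD80, beat rate, biomarker tables |
| `calreg.sensitivity` | per-protein-type calcium sensitivity panel |
| `calreg.synthetic` | synthetic optical traces and drug-study datasets with exact ground truth |
| `calreg.config` / `calreg.traceio` / `calreg.cli` | YAML config, trace CSV I/O, command-line interface |
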