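# mnephys

Measurement pipeline for the intrinsic electrical properties that govern
**motoneuron recruitment**, plus a conductance-based motoneuron simulator
that generates protocol-faithful patch-clamp sweeps with known ground
truth.

Spinal motoneurons come in two electrophysiological flavours: *delayed
firing* cells (late-onset, accelerating repetitive firing at rheobase;
putative fast motoneurons) and *immediate firing* cells (early-onset,
steady or adapting firing; putative slow motoneurons). Their orderly
recruitment depends not only on size (capacitance, input resistance) but
on subthreshold active currents: persistent inward currents (PICs, carried
by persistent Na and L-type Ca channels) and the hyperpolarization-
activated mixed-cation current I<sub>h</sub> (HCN channels). `mnephys`
implements the full measurement battery used to characterise these cells:

- **passive properties** from small hyperpolarizing steps:
  R<sub>in</sub> from the early voltage trough, τ<sub>m</sub> from the
  2/3-of-peak crossing, C = τ/R;
- **rheobase** from slow (100 pA/s) depolarizing ramps and from 5 s step
  families (first step with ≥ 3 spikes), with spike threshold at the first
  dV/dt ≥ 10 mV/ms sample;
- **ePIC**, the current-clamp PIC estimate: a line is fitted to the
  passive phase of the ramp trajectory, the acceleration onset is the
  sustained > 1 mV deviation from it, and
  ePIC = I<sub>passive rheobase</sub> − I<sub>rheobase</sub>;
- **ΔI hysteresis** on triangular ramps (derecruitment minus recruitment
  current; negative ΔI indicates a PIC) with the four-way hysteresis
  classification (linear / adapting / sustained / counterclockwise);
- **voltage-clamp PICs** from slow (10 mV/s, −90 → −10 mV) ramps after
  5 Hz zero-phase Bessel filtering and leak-line subtraction;
- **sag / gSag** from hyperpolarizing step families
  (gSag = 1/R<sub>ss</sub> − 1/R<sub>init</sub>) and **I<sub>h</sub>**
  from 1 s voltage steps (−60 → −110 mV), including the resting
  I<sub>h</sub> measured by stepping from −50 mV to the cell's resting
  potential;
- **single-spike and mAHP waveform** measures, FI curves with the
  sub-primary-range gain, and a **cohort stage** (feature table →
  correlation-matrix PCA, recruitment-gain summaries, Pearson
  correlations with between-group slope comparison).

The simulator (`mnephys.sim`) is a single-compartment Hodgkin–Huxley-style
model with leak, transient Na/delayed-rectifier K spike currents, a
spike-triggered mAHP conductance, a slowly inactivating low-threshold K
current (Kv1-like, produces the delayed firing onset), persistent Na and
L-type Ca currents, and an HCN current. Six presets encode the
delayed/immediate dichotomy across three postnatal weeks and a
pharmacology layer emulates selective blockers (4,9-AH-TTX → g<sub>NaP</sub>,
nifedipine → g<sub>CaL</sub>, ZD7288/ivabradine → g<sub>H</sub>).

## Worked example

```python
from mnephys.sim import make_preset, resting_potential
from mnephys.pipeline import simulate_and_extract

cell = make_preset("delayed", 3)          # week-3 delayed (fast-type) preset
row = simulate_and_extract(cell, seed=1)
print(f"RMP        {row['RMP']:8.1f} mV")
print(f"R_in       {row['R_in_initial']:8.1f} MOhm")
print(f"rheobase   {row['rheobase_ramp']:8.1f} pA (ramp)")
print(f"ePIC       {row['ePIC']:8.1f} pA")
print(f"delta I    {row['delta_I']:8.1f} pA")
print(f"Ih(-70)    {row['ih_amp_-70']:8.1f} pA")
print(f"resting Ih {row['resting_ih']:8.1f} pA")
print(f"type       {row['firing_type']:>8s}")
```

prints

```
RMP           -66.8 mV
R_in           41.3 MOhm
rheobase      310.2 pA (ramp)
ePIC          350.5 pA
delta I       -54.6 pA
Ih(-70)      -100.5 pA
resting Ih    -82.4 pA
type        delayed
```

— a large, low-resistance cell resting near −67 mV whose recruitment is
delayed by a high rheobase, with a prominent persistent inward current
(positive ePIC, negative ΔI) and an h-current active at rest near
−100 pA, the signature of a week-3 delayed-firing motoneuron.

The same pipeline is scriptable from the shell:

```bash
mnephys simulate --subtype delayed --week 3 --seed 7 --out d3.h5
mnephys extract d3.h5 --out d3_features.csv
mnephys report d3_features.csv
```

## Layout

| module | contents |
| --- | --- |
| `mnephys.sim` | model parameters, presets, integrator, analytic steady-state I–V, pharmacology |
| `mnephys.ccfeat` | current-clamp feature extraction |
| `mnephys.vcfeat` | voltage-clamp leak subtraction, PIC and I<sub>h</sub> measures |
| `mnephys.cohort` | feature table, PCA, recruitment gain, correlations |
| `mnephys.pipeline` | per-cell protocol battery and synthetic cohort studies |
| `mnephys.io` / `mnephys.cli` | HDF5/CSV sweep containers and the `mnephys` command |

See `docs/methods.md` for the model equations, measurement conventions
and design decisions.
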