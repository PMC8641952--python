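# Methods

## The model

`mnephys.sim` integrates a single-compartment current-balance equation

    C_m dV/dt = I_inj − I_L − I_NaT − I_KDR − I_mAHP − I_NaP − I_CaL − I_H − I_Kslow + ξ(t)

with every steady-state activation a Boltzmann function of voltage. Units
are fixed throughout the package: mV, pA, nS, pF, ms (so pA/pF integrates
directly to mV/ms, and MΩ = 1000/nS).

| current | gating | role |
| --- | --- | --- |
| I_L = g_L (V − E_L) | — | leak; sets R_in = 1000/g_L and τ_m = C_m/g_L |
| I_NaT = g_Na m∞³ h (V − E_Na) | m instantaneous, h first-order (τ_h 1–2 ms) | spike upstroke |
| I_KDR = g_K n⁴ (V − E_K) | n first-order (τ_n 1–3 ms) | spike repolarization |
| I_mAHP = g_mAHP z (V − E_K) | z charges while V > ~0 mV (1 ms), decays with τ_mAHP | medium afterhyperpolarization, rate adaptation |
| I_NaP = g_NaP p∞ (V − E_Na) | instantaneous | persistent Na PIC |
| I_CaL = g_CaL c∞ (V − E_Ca) | instantaneous | L-type Ca PIC |
| I_H = g_H r (V − E_H) | r first-order, inverted slope, constant τ_H | HCN current; sag, resting depolarization |
| I_Kslow = g_Kslow a∞ b (V − E_K) | a instantaneous, b slow inactivation (τ_b ≈ 2 s) | delayed firing onset |

Two modelling choices deserve note. First, τ_H is voltage-independent;
this keeps the Ih step response a single exponential, which is what the
2/3-of-peak activation-time read-out assumes, and is a reasonable
flattening of the bell-shaped HCN kinetics over the −60…−110 mV range
probed. Second, the slow-K inactivation gate `b` carries an extra
inactivation pathway that is only open while V is above ~0 mV
(`tau_b_spike`): each action potential inactivates a little more of the
conductance. This cumulative, spike-driven inactivation — the classic
Kv1 mechanism — is what makes the firing rate of delayed cells accelerate
through a rheobase step rather than only before the first spike.

The treatment of fast activations (m, p, c, a) as instantaneous removes
stiff sub-millisecond gating without changing any quantity the pipeline
measures: the protocols are 2–4 orders of magnitude slower.

### Integration

A fixed 10 µs internal step with exponential (exact-relaxation) updates
for the membrane potential and every gate, resampled to the protocol
sample rate (20 kHz by default, the standard digitiser rate for this
preparation). The scheme is unconditionally stable for the stiff spike
currents, bit-reproducible, and exact in the passive limit: with all
gated conductances zero the step response matches the RC exponential to
better than 0.2% at every sample (tested at 1%). Divergence beyond
±200 mV raises a simulation error naming the parameter set. Noise is
additive Gaussian current, drawn per output sample and held across
internal substeps; the default is 0 pA (oracle conditions) and cohort
studies use 5 pA SD. All randomness flows from explicit seeds.

Voltage clamp is ideal by default (recorded current = total ionic current
plus the capacitive current of the command); an optional series-resistance
mode models a pipette resistor instead. A 1 ms guard keeps analysis
windows clear of the capacitive transients at step edges.

### Analytic steady-state I–V

`steady_state_currents` evaluates every component in closed form on a
voltage grid; the total is exactly the component sum. It serves three
roles: the oracle for PIC/Ih recovery tests, the closed-form solve of the
holding bias current (at equilibrium the injected current equals the total
ionic current), and the zero-bias resting potential (most hyperpolarized
stable zero of the total).

## Presets

Six parameter sets span delayed/immediate firing across postnatal weeks
1–3. They are calibration targets for the phenotype, not literature
constants; each preset is its own ground-truth manifest. The encoded
programme:

- delayed presets carry g_Kslow (14–28 nS) → onset latency 2–4 s at the
  step rheobase with an accelerating rate; immediate presets lack it and
  fire within ~200 ms with a flat-to-adapting rate (mAHP: 80 nS/130 ms
  versus 30 nS/50 ms in delayed, giving immediate cells longer mAHPs and,
  with slower delayed-rectifier kinetics, broader spikes);
- V_half of the persistent Na current is more depolarized in delayed
  (−33 mV) than immediate (−40 mV) cells from week 2; activation is steep
  (k = 3 mV) so the current is large above threshold (the voltage-clamp
  PIC) while its subthreshold foot leaves rheobase realistic;
- delayed cells grow between weeks 1 and 2 (C_m 150 → 370 pF, g_L
  8 → 16 nS) but not between 2 and 3; immediate cells stay ~140–150 pF;
- delayed g_H rises from 2.5/4 nS (weeks 1–2) to 21.5 nS at week 3
  (V_half −80 mV, k 8 mV, τ_H 250 ms), which yields a resting potential
  near −67 mV, an Ih at −70 mV near −120 pA and a resting h-current
  (−50 mV → RMP step) near −100 pA; immediate presets keep 0.8 nS.

The leak reversal of every preset (and every cohort-sampled cell) is
solved in closed form so the zero-bias resting potential lands exactly on
the preset's target.

Synthetic cohorts draw cells around the presets with lognormal
variability (CV 15%): one shared size factor scales C_m, g_L and the
spike conductances together — preserving the size-principle correlation
between rheobase and passive properties — while each gated conductance
receives an additional independent factor.

Pharmacology is conductance scaling: each supported blocker multiplies
exactly one maximal conductance by (1 − block_fraction).

## Measurement conventions

- **Spike threshold**: first sample at which the boxcar-smoothed
  (0.2 ms, odd window, edge-padded) derivative reaches 10 mV/ms on the
  upstroke; the search for each spike starts at the preceding inter-spike
  voltage minimum so one spike's upstroke cannot shadow the next.
- **τ_m**: the time to 2/3 of the trough deflection, calibrated to an
  exponential (τ = t_f /(−ln(1−f))) so an ideal RC trace returns its true
  time constant; C = τ/R then recovers the true capacitance. The Ih
  activation time, by contrast, is reported raw as the time to 2/3 of
  peak Ih (τ·ln 3 for a single exponential), matching how that number is
  usually quoted.
- **Passive-phase fit** on ramps: iteratively grown line (start at the
  first 25% of the pre-spike segment, extend while residuals stay below
  the 1 mV criterion), then one refinement pass that refits away from the
  detected onset so early acceleration cannot tilt the line. Acceleration
  onset requires the deviation to stay above 1 mV for ≥ 10 ms.
- **Sag windows**: trough searched within the first 200 ms of the step;
  steady state is the mean of the final 100 ms. The same windows are
  mirrored in the voltage-clamp Ih measurement (initial window 5–20 ms
  after the transient, steady state the last 100 ms).
- **Delayed/immediate rule**: delayed iff onset latency > 500 ms with a
  positive rate slope; immediate iff latency ≤ 500 ms with slope below
  2 Hz/s; anything else is flagged unclassified rather than forced.
- **Sub-primary FI gain**: slope over the first four suprathreshold
  points, truncated where the local slope drops by more than 50%.
- **Leak subtraction**: 5 Hz 4-pole Bessel, applied forward–backward
  (zero phase) so onset voltages are read against the command without
  lag; default fit window −90 to −75 mV. `fit_window="auto"` instead
  picks the most linear 15 mV stretch ending below −55 mV — the
  programmatic analogue of fitting the visually linear region. The
  pipeline uses the auto window because cells with a large resting HCN
  conductance bend the trace over the fixed window (their h-current
  deactivates along the ramp), which would fold Ih deactivation into the
  PIC estimate.
- **PIC onset/peak**: peak is the most negative subtracted current before
  the terminal outward rectification; onset is the start of the
  contiguous below-criterion (−10 pA, ≥ 1 mV of command) run containing
  the peak. Additional deep local minima are flagged as multimodal.
- **Brief-pulse intensity**: the single-spike/mAHP pulse is 10 ms at 25%
  above the cell's measured brief-pulse threshold. In a single
  compartment the somatic charge needed to fire within 10 ms exceeds
  1.25× the slow-ramp rheobase (there is no axon initial segment to
  ignite the spike), so the intensity is referenced to the pulse
  threshold to preserve the measurement's intent.
- All voltages are nominal recorded values; no junction-potential
  correction is applied anywhere in the pipeline.

## Cohort stage

PCA operates on z-scored columns (correlation-matrix decomposition) since
the properties span wildly different units; constant columns are dropped
with a warning, incomplete rows per analysis (complete-case). Cells whose
spike amplitude from threshold is below 60 mV are excluded from the table
with a log message. Recruitment-gain summaries report, per group of
rheobase values, the range and the empirical cumulative-proportion curve,
and between groups both the range ratio (100·range_A/range_B) and the
range reduction (100·(range_B−range_A)/range_B) — both conventions appear
in practice and the package names which one it computes. Slope
comparisons use an OLS interaction model with HC3 robust covariance,
which keeps the test calibrated when the two groups have different
residual scales.

## What the synthetic data does and does not emulate

The generator reproduces protocol structure (holding via bias current,
step/ramp/triangle/pulse waveforms, 20 kHz sampling), the qualitative
subtype phenotypes, current noise, and optional series resistance. It
does not emulate dendritic PIC compartmentalization, space-clamp error,
electrode drift, channel stochasticity, or neuromodulation — so passing
recovery tests demonstrates that the measurement code is faithful to its
definitions on clean, well-clamped data, not that it is robust to every
pathology of real recordings. Absolute preset magnitudes (rheobase in the
tens-to-hundreds of pA, PIC amplitudes of 0.2–4 nA) are in the
physiological range but deliberately scaled-down in spread compared with
a real cohort of hundreds of cells.

## Problem sizes

Recovery checks use 20 passive cells, a 3×3 PIC grid and 6-step Ih
families; the synthetic cohort studies use 10 cells per subtype × week
(60 cells) in the test suite and 4 per group in the acceptance script,
with 5-cell-per-subtype week-3 samples for the HCN-block range
comparison. These sizes make every stage's behaviour visible while a full
study remains a few minutes of compute.

## Known limitations

- The quasi-static escape of the persistent Na current means ramp
  rheobase is governed by the saddle of the steady-state I–V, several mV
  below the detected spike threshold; ePIC fractions are accordingly at
  the high end of what is seen in real cells.
- The leak-subtracted voltage-clamp trace of a week-3 delayed cell
  genuinely contains Ih deactivation; the auto leak window confines, but
  cannot eliminate, that contamination.
- A single compartment cannot reproduce AIS-initiated spikes; brief-pulse
  excitability is therefore low relative to ramp rheobase (see above).
- The mAHP gate is voltage-triggered, not calcium-dependent; mAHP
  summation is mono-exponential.
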