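# Methods

`shuntsyn` is a behavioral simulator of a mixed-signal neuromorphic system
built around a conductance-based synapse circuit whose output stage emulates
a (non-linear) resistor between the postsynaptic membrane and a configurable
reversal potential. This note documents the models, the calibration
constants and why they have the values they do, the numerical choices, and
what the synthetic stimulus does and does not capture.

## Sign conventions and units

The simulator uses conventional neuroscience polarity: depolarization is an
increase of the membrane potential and positive synaptic current
depolarizes, `C dV/dt = -g_leak (V - V_rest) + I_syn`. The physical chip is
built mostly from PMOS devices and runs "upside down" (its soma rests near
the upper rail and depolarizes downward; excitatory circuits *sink* current),
and its current conveyor's inverting branch undoes that inversion for the
soma. Rather than carry the double inversion through the code, membrane
potentials are expressed in millivolts relative to rest = 0 and all
inversions are dropped; the conveyor still offers both polarities
(`conveyor_sum(..., "reversed")`). Units throughout: mV, pA, nS, pF
(1 pA = 1 nS·mV), seconds for time; gate voltages of the synapse circuit in
volts.

## Subthreshold inverter timing and the ring oscillator

The transconductance stage is clocked by a ring of current-starved
inverters. In weak inversion the pull-down NMOS (source at the floating
lower rail `Vin_osc`) sinks

    I = I0_n · exp((κ_n·Vg − Vin_osc)/U_T) · (1 − exp(−(Vout − Vin_osc)/U_T)),

and the PMOS mirror (source at `Vdd_osc`) sources the analogous current; the
body effect is ignored. Separating variables gives closed forms for the
time to the halfway point between the starting voltage and the destination
rail (`discharge_time`, `charge_time`), each a prefactor
`C_out·U_T/(I0·exp(drive/U_T))` times a logarithmic headroom factor.
`ode_transition_oracle` integrates the same device equation numerically
(adaptive LSODA, rtol 1e-8, halfway-crossing event, doubling horizon) and is
the ground truth the closed forms are tested against (<1% relative error
over random parameter grids).

`propagation_time` is the per-stage delay in the symmetric-device
approximation. The logarithmic factor is replaced by its large-headroom
limit `(Vdd_osc − Vin_osc)/(2 U_T)` — valid above ~4 U_T of rail
separation — while both branch exponentials are retained:

    t_P = C_out (Vdd_osc − Vin_osc) / (4 I0) · [e^{−(κ·Vdd_osc − Vin_osc)/U_T} + e^{−κ(Vdd_osc − Vin_osc)/U_T}].

Keeping both terms matters because the NMOS exponent carries the lower rail
unscaled; dropping either branch misestimates the mean of the exact
transition times by up to ~2x when `Vin_osc` is well above ground, whereas
this form tracks it to a few percent. Devices that differ are averaged
(geometric mean of I0, arithmetic mean of κ). The ring frequency uses the
standard relation `f = 1/(2·n_stages·t_P)` (each stage toggles once per
traversal; two traversals per period for an odd ring), making `ln f` affine
in `Vin_osc`. Default inverter constants (I0 = 1 pA, κ = 0.7,
C_out = 5 fF, U_T = 25.8 mV, Vdd_osc = 0.6 V, 3 stages) are calibration
constants chosen so the attainable band covers 2–25 kHz — the fabricated
stage's operating band — for `Vin_osc` in roughly 0.30–0.40 V; the real
device constants are not published.

During a synaptic event the oscillator's lower rail tracks the synapse gate
approximately linearly, so the frequency is exponential in the gate:
`GateFrequencyMap` maps gate voltage V to `f_scale · exp(V/V_f)` while the
gate exceeds `gate_floor` (the behavioral analogue of the integrator
transistor leaving saturation below ~4 U_T; below it the oscillator lacks
headroom and is off). Its two constants are anchored to the reported peak
frequencies of 2.4 kHz at efficacy 1 and 17.7 kHz at efficacy 15, evaluated
at the single-pulse gate peaks of those efficacies. A linearly discharging
gate then yields an exponentially decaying frequency, the behavior seen in
the hardware transient.

## Synapse model

Each synapse has a 4-bit efficacy w ∈ [0, 15] and a gate node:

* **Charging.** An input pulse (2 ms) charges the gate at
  `charge_rate · w` — exactly binary-weighted, as an ideal DAC; the
  discharge path is negligible against the DAC current during the pulse.
  Overlapping pulses extend the charging interval rather than stacking
  (one input transistor). The gate saturates at `gate_max`, the single
  maximal-efficacy pulse peak: the integrator's linear range is sized for
  one full-scale pulse, so closely spaced inputs saturate instead of piling
  up. Without this ceiling the exponential conversion below would turn
  occasional afferent bursts into currents orders of magnitude above the
  single-event scale.
* **Discharge.** Between pulses the gate discharges linearly at
  `discharge_rate`, clamping at 0.
* **Conversion.** The conductance is exponential in the gate,
  `g = g_unit · exp((V_gate − V_ref)/U_T_eff)` for a positive gate and
  exactly 0 at rest (the ~fA standing leakage of the physical circuit is
  not modeled). Linear discharge therefore gives exponential decay with
  `τ_syn = U_T_eff/discharge_rate = 3 ms`, at the fast end of the 3–5 ms
  AMPA-like range the hardware was configured for. `V_ref` defaults to the
  full-efficacy pulse peak, so `g_unit` is the peak conductance at w = 15.

With `charge_rate = 2.8 V/s` per efficacy step and `U_T_eff = 40 mV`, one
efficacy step scales the peak current by `e^{0.14} ≈ 1.15`, i.e. a
w15 : w1 peak-current ratio of ≈ 7.1 — close to the 68 pA : 10 pA ≈ 6.8
measured on the chip. (An exactly current-linear DAC would give 15:1; the
hardware is sublinear, and the exponential-conversion model with a
moderate `U_T_eff` reproduces that compression.)

Output modes:

* `excitatory_current` / `inhibitory_current`: stereotyped current
  `±g·s` independent of the membrane potential.
* `conductance`: `I = g · Φ(E_syn − V_mem)` with the asymmetric driving
  force

      Φ(x) = V_alpha (e^{x/V_alpha} − 1)        x ≥ 0
      Φ(x) = −V_beta (1 − e^{x/V_beta})          x < 0

  Φ is continuous, zero at the reversal potential, has unit slope there,
  and grows exponentially on the `E_syn > V_mem` side (scale
  `V_alpha = 35 mV`) while saturating on the other (scale
  `V_beta = 700 mV`): the emulated resistance is exponentially larger for
  `E_syn < V_mem`, as measured on the chip. At ±100 mV the magnitude ratio
  exceeds 6. Only the shape of this curve is known from measurement, not
  an equation; the piecewise form is the package's choice.
* **Oscillatory packets.** The switched-capacitor stage delivers the
  conductance-mode current in rectangular packets gated by the oscillator
  phase (duty 0.5, the shape itself being unpublished). The implementation
  integrates the exact on-phase measure of each time step, so the packet
  train conserves the smooth model's charge to first order regardless of
  the ratio of oscillator period to step, and its 5 ms moving average
  reproduces the smooth current within a few percent whenever the
  oscillator runs at its ≥2 kHz band.

## Neuron configurations

The soma is a leaky integrate-and-fire stand-in (the silicon soma is a
qualitative model outside this package's scope) with Class 1 behavior: a
continuous f–I curve and no spike-frequency adaptation. Threshold crossings
are located by linear interpolation inside the step; the membrane holds at
reset through the refractory period.

* **Single compartment.** A current conveyor clamps the shared postsynaptic
  node (`V_post_clamp`, default 0 mV, standing in for the 600 mV clamp),
  so conductance-mode synapse currents depend only on synapse parameters;
  `conveyor_sum` replicates the sum into the soma with either polarity.
* **Unidirectional two-compartment.** Synapses integrate on a dendritic RC
  node (C_den = 8.5 pF as in the hardware; the leak is one synapse circuit
  in conductance mode with a frozen gate, default 1 nS toward
  E_leak = 0 mV). The dendrite drives the soma through a one-way resistor,
  `I = (V_den − V_mem)/R_c`, with exactly zero back-action: the dendritic
  trajectory is bit-identical under any soma manipulation.

### Shunting-inhibition protocol

The demonstration uses the two-compartment neuron, all efficacies maximal,
learning off: (1) one current-based excitatory synapse alone — a clear
EPSP; (2) the shunting synapse alone (conductance mode, reversal +1 mV,
essentially at rest) — a deflection below 10% of the EPSP; (3) both — the
EPSP attenuated by the conductance divider. Under the calibrated defaults
the attenuation is ≈29%, in the same one-third regime as the hardware's
34.6% ± 1.65% (the exact figure is calibration-dependent). The volley runs
reproduce the hardware counts exactly: four synchronous excitatory synapses
are the minimal volley that spikes the soma, four plus the shunting synapse
do not spike it, five plus the shunting synapse do.

Calibration notes: the chip's shunting synapse sits on the strong
(exponential) side of its I–V because chip depolarization is downward;
mirrored into conventional polarity a depolarized dendrite sees the
shunt's near-linear side, so the shunting synapse uses a larger conductance
scale (3 nS) than a single excitatory circuit to reach the same one-third
attenuation. R_c = 1 GΩ, soma C = 5 pF, g_leak = 1 nS, threshold 10.6 mV
above rest (mirroring the 25 mV order of the chip's two-compartment
threshold gap) were fixed by the volley counts; they are reported by
`shuntsyn demo-shunting`.

## Adaptive STDP

Rectangular STDP with ±1-bit updates on the 4-bit counter and
nearest-spike memory (one remembered pre spike per synapse, one post spike —
matching the single-capacitor timing memory of the hardware learning
circuit): a post spike at `t_i` potentiates every synapse whose last pre
spike satisfies `0 ≤ t_i − t_j < t_pre`; a pre spike at `t_j` depresses its
synapse if the last post satisfies `0 < t_j − t_i < t_post`. Simultaneous
spikes potentiate. `t_pre` is fixed; `t_post` follows a non-decreasing
schedule of elapsed time — the adaptive element, driven externally on the
chip.

With Poisson pre spikes at rate r, each post spike potentiates a given
synapse with probability `1 − e^{−r·t_pre}` and is followed by
`r·t_post` expected depressing pre spikes, so uncorrelated drift cancels at
`t_post* = (1 − e^{−r·t_pre})/r` (≈3.6 ms at r = 54 Hz, t_pre = 4 ms).
The default schedule starts at that neutral point, ramps linearly to 8 ms
at 125 s (pruning synapses whose spikes do not predict output spikes while
pattern-locked synapses, whose LTP probability per in-pattern post
approaches 1, keep growing), then consolidates to 13.5 ms by 150 s so that
the scored final 75 s runs with maximal selectivity. The window durations
are declared calibration: the paper specifies the control voltages, fixes
`t_pre` constant and `t_post` rising, but publishes no millisecond values.

## Stimulus generator

256 independent afferents, 225 s. Instantaneous rates follow a
slew-limited random walk on [0, 90] Hz at 1 ms resolution (uniform
increments within ±1800 Hz/s · Δ, reflected at the bounds — stationary
distribution uniform, full-range slew no faster than 50 ms). Spikes are
drawn by thinning a 90 Hz homogeneous Poisson process with linearly
interpolated rates. Every empty disjoint 50 ms window then receives one
spike at a uniform position, enforcing the one-spike-per-50 ms floor
(20 Hz minimum windowed rate). Finally one 50 ms section is chosen as the
target pattern and copied over `round(repeat_fraction · n_sections)`
randomly chosen sections with no two adjacent (the source section counts as
an occurrence; it already equals the pattern). All afferents are replaced
within a chosen section, so only precise spike timing marks the pattern.

Under this construction the expected population rate in 10 ms bins is
`45 + 20·E[e^{−r/20}] ≈ 49.4 Hz`, identical inside and outside pattern
windows; the inside estimate fluctuates ±2 Hz across seeds because every
occurrence repeats a single 50 ms draw. What the generator does *not*
emulate: correlated afferents, jittered or partial patterns, multiple
patterns, rate nonstationarities beyond the walk. Passing the detection
experiment on this stimulus therefore demonstrates timing-based (not
rate-based) detection under idealized independence, no more.

## Detection experiment

Single-compartment configuration, 256 conductance-mode synapses
(E_syn 120 mV above the clamp, mirroring the 720/600 mV setting), initial
efficacy 8, soma C = 1.5 pF (a 1.5 ms membrane time constant — the soma
must act as a coincidence detector on the 4 ms volley for the
zero-false-alarm criterion to be attainable), g_leak = 1 nS, threshold
162 mV above rest, refractory 8 ms, dt = 0.1 ms. `g_unit` is set so that
the initial output rate lands in the 40–200 Hz band the study prescribes
(~65–85 Hz). A run
is successful when the hit rate in the last 75 s exceeds 98% with zero
false alarms; hits use the bare occurrence interval (a configurable latency
extension exists, default 0: occurrences truncated by the window edge are
excluded from scoring entirely).

The fixed-step engine tracks each synapse's exponential conductance
multiplicatively (per-regime constant factors), evaluating exponentials
only at gate-state changes; a 225 s run costs a few seconds. A pure-Python
reference built from the public module operations, and a dt-convergence
check at 0.01 ms, validate the kernel in the test suite. Batches run 50
independent seeds per condition; paired smooth-vs-oscillatory runs on
identical trains are compared with McNemar's exact test, mirroring the
study's claim that the packetized current does not change task performance.

## Known limitations

* The soma is LIF; the silicon soma's subthreshold nonlinearity, noise and
  Class-1 bifurcation structure are not modeled, so batch success rates
  are comparable only within the stochastic tolerance of the study's
  figures, not reproductions of the chip's exact percentages.  Under the
  default calibration the per-run success probability measured across seed
  sets is roughly 0.8–0.9 at both repetition fractions (the studied system
  reported 96% and 88%); the shortfall is dominated by runs with one or
  two residual background spikes in the 75 s zero-false-alarm window, with
  occasional failures of assembly formation.
* Success is sensitive to the learning-schedule calibration near the
  criterion's zero-false-alarm edge; the defaults are one calibrated
  operating point, not a robust region.
* The oscillator model is behavioral: no per-stage phase noise, no supply
  coupling, no explicit switched-capacitor charge injection.
* Chip bias voltages (sVw, sVt, VLTP, VLTD, ...) are represented only by
  named behavioral parameters; no voltage-to-parameter transduction is
  provided.
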