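# shuntsyn

Behavioral simulation of a conductance-based neuromorphic synapse and the
system around it: shunting inhibition on a two-compartment silicon neuron,
and unsupervised spike-pattern detection with 4-bit adaptive STDP.

Most low-power analog synapse circuits are *current-based*: they inject a
stereotyped exponential current and ignore the postsynaptic potential. A
*conductance-based* circuit instead emulates the phenomenological law

    I_syn(t) = g_syn(t) · (V_mem(t) − E_syn)

so the current reverses sign at the synaptic reversal potential E_syn. That
dependence is what makes **shunting inhibition** possible: a synapse with
E_syn near rest barely moves the membrane on its own but raises the local
conductance and divides down concurrent EPSPs. The hardware this package
models realizes the resistor-like element with a ring oscillator driving a
switched-capacitor stage, so its synaptic current arrives as kilohertz
charge packets whose envelope is the usual exponentially decaying synaptic
current, and its I–V is asymmetric (exponentially larger conductance for
E_syn > V_mem).

`shuntsyn` implements, in conventional units (mV, pA, nS, pF):

* closed-form subthreshold inverter transition times and the ring-oscillator
  frequency model, validated against an independent ODE oracle
  (`shuntsyn.oscillator`);
* the synapse: binary-weighted 4-bit DAC pulse, linear-charge /
  linear-discharge gate, exponential conductance conversion (τ ≈ 3 ms),
  asymmetric driving force, smooth or oscillatory charge-packet output
  (`shuntsyn.synapse`);
* leaky integrate-and-fire soma (Class 1, no adaptation), dendritic RC
  compartment with one-way coupling, current-conveyor clamp
  (`shuntsyn.neuron`), and the calibrated shunting-inhibition protocol
  (`shuntsyn.shunting`);
* adaptive rectangular STDP on 4-bit efficacies with a rising LTD window
  (`shuntsyn.plasticity`);
* the stimulus generator — 256 inhomogeneous-Poisson afferents, rates
  slew-limited in [0, 90] Hz, one spike per 50 ms guaranteed, a repeated
  50 ms pattern pasted into 25% or 10% of the sections, never adjacent
  (`shuntsyn.taskgen`);
* the end-to-end detection experiment and batch scoring
  (`shuntsyn.experiment`), with a fast numba kernel.

See `docs/methods.md` for the models, calibration constants and their
rationale, numerical choices, and limitations.

## Worked example

Shunting inhibition on the two-compartment neuron:

```bash
$ shuntsyn demo-shunting
run 1  EPSP peak (1 excitatory)               7.637 mV
run 2  deflection (shunting alone)            0.498 mV  (6.5% of EPSP)
run 3  EPSP peak (excitatory + shunting)      5.459 mV  (attenuation 28.5%)
volley 4 excitatory              -> 1 soma spike(s)
volley 4 excitatory + shunting   -> 0 soma spike(s)
volley 5 excitatory + shunting   -> 1 soma spike(s)
```

One excitatory synapse produces a ~7.6 mV dendritic EPSP; the shunting
synapse alone (reversal 1 mV above rest) deflects the dendrite by only 6.5%
of that, yet co-activated it attenuates the EPSP by ~29% — the conductance
divider at work. Four synchronous excitatory inputs are the minimal volley
that fires the soma; adding the single shunting synapse blocks the spike,
and a fifth excitatory input overpowers it.

Pattern detection, one run:

```bash
$ shuntsyn generate --repeat-fraction 0.25 --seed 7 --out trains.tsv
wrote 2849729 events to trains.tsv; 1125 pattern occurrences to trains.occurrences.txt
$ shuntsyn simulate --trains trains.tsv \
      --occurrences trains.occurrences.txt --out result.json
initial rate 76.2 Hz; hit rate 100.0%, 0 false alarms -> success
```

The neuron starts firing unselectively at ~76 Hz; as the LTD window widens
the efficacies turn bimodal and in a successful run the final 75 s show a
spike inside every 50 ms pattern occurrence and none elsewhere.

Python API:

```python
from shuntsyn import TaskConfig, generate, run_detection

ts = generate(TaskConfig(repeat_fraction=0.25, seed=7))
result = run_detection(ts)
print(result.hit_rate, result.false_alarms, result.success)
```

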