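# tctsim

A spiking-network model of the thalamo-cortico-thalamic (TCT) loop, built to
ask a simple question: can a ~1000-neuron circuit of thalamus and cortex,
driven by nothing but resting-state Poisson "retinal" input, produce
EEG-like rhythms that switch between a wake-like and a sleep-like regime
when one anatomical pathway is cut?

The package is aimed at computational neuroscientists studying sleep/wake
rhythm generation and at anyone who wants a small, fully deterministic,
pure-Python/NumPy testbed for thalamocortical circuit experiments.

## The model

* **Neurons.** Every cell is an Izhikevich two-variable neuron,

  dv/dt = 0.04 v² + 5v + 140 − u + I,  du/dt = a(bv − u),
  with reset v ← c, u ← u + d at the 30 mV cutoff,

  integrated by forward Euler (two dt/2 half-steps for v, one step for u)
  at dt = 1 ms.  Four parameter sets cover all cell classes: regular
  spiking (relay, pyramidal, spiny-stellate cells), fast spiking (basket
  cells, thalamic interneurons), low-threshold spiking (non-basket cells)
  and tonic bursting (reticular cells).
* **Circuit.** 1090 neurons in 16 populations: thalamic relay (TCR),
  interneuron (IN) and reticular (TRN) populations, plus pyramidal, basket
  and non-basket populations in cortical layers 2/3, 4, 5 and 6 and
  spiny-stellate cells in layer 4.  Each projection is wired by independent
  Bernoulli draws with probability P (0.25 for every thalamic and
  thalamus–cortex pathway) and carries a weight C routed through
  current-based exponential synapses; inter-module conduction delays are
  uniform on 1–10 ms.
* **Drive.** Homogeneous 25 Hz Poisson sources (one per target neuron)
  project all-to-all onto TCR and IN.
* **Readout.** The per-population mean membrane potential is treated as an
  EEG proxy: 30 s runs, three seeded repetitions averaged, downsampled to
  200 Hz, band-passed 1–16 Hz (order-10 zero-phase Butterworth), then a
  Welch periodogram (800 FFT points, 100-sample Hamming window, 50%
  overlap, 0.25 Hz grid).  Band powers over delta (1–4 Hz), theta
  (4–8 Hz), alpha (8–12 Hz) and sigma (12–16 Hz) classify the state:
  alpha-dominant → wake-like, delta/theta-dominant → sleep-like.
* **The experiment.** At basal parameters the TCR–TRN loop paces the relay
  population in the alpha band.  Disconnecting the TRN (disabling every
  projection into or out of it) hands control to the excitatory
  cortico-thalamo-cortical loop, whose spike-frequency adaptation produces
  a slower, larger-amplitude theta rhythm — a caricature of EEG "slowing"
  at sleep onset.

## Worked example

```python
from tctsim import SimulationSettings, experiment_baseline, experiment_trn_lesion

settings = SimulationSettings(master_seed=0)        # 3 x 30 s at 1 ms
baseline = experiment_baseline(settings=settings)
lesioned = experiment_trn_lesion(settings=settings)

for rep in (baseline, lesioned):
    tcr = rep.spectra["TCR"]
    print(rep.condition, rep.dominant_frequency["TCR"], tcr.dominant_band,
          round(rep.amplitude_sd["TCR"], 2), rep.classification["TCR"])
```

prints (about a minute of compute):

```
baseline 9.75 alpha 6.64 wake_like
trn_lesioned 6.25 theta 9.46 sleep_like
```

Read: with the circuit intact the averaged TCR trace peaks at 9.75 Hz —
inside the 8–12 Hz alpha band, the spectral signature of quiet
wakefulness — with a trace standard deviation of 6.6 mV.  Cutting the TRN
drops the peak to 6.25 Hz (theta) and raises the amplitude to 9.5 mV:
slower and larger, the sleep-like direction.  The layer-4 pyramidal
population follows its thalamic driver in both conditions (9.5 Hz alpha
baseline, 6 Hz theta lesioned).

The same runs from a shell:

```bash
tctsim experiment --which both --seed 0 --outdir out/
tctsim dump-config          # the full editable circuit configuration
tctsim calibrate            # re-run the weight-scale search
```

## Layout

| module | contents |
|---|---|
| `tctsim.neuron` | Izhikevich dynamics, synapse kinetics, step-current protocol, spike-train metrics |
| `tctsim.circuit` | population roster, projections, Bernoulli realization, TRN lesion |
| `tctsim.stimulus` | Poisson source bank and all-to-all wiring |
| `tctsim.engine` | vectorized clock-driven simulator, multi-run averaging |
| `tctsim.spectra` | downsample → Butterworth → Welch → band classification |
| `tctsim.experiments` | baseline/lesion experiments, reports, weight calibration |
| `tctsim.cli` | `tctsim` command-line entry point |

See `docs/methods.md` for modeling assumptions, parameter provenance and
known limitations.
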