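"""Izhikevich point neurons with current-based exponential synapses.

The network uses the two-variable Izhikevich model

    dv/dt = 0.04 v^2 + 5 v + 140 - u + I
    du/dt = a (b v - u)

with the reset rule ``v >= 30 mV  ->  v <- c, u <- u + d``.  Four parameter
sets (regular spiking, fast spiking, low-threshold spiking, tonic bursting)
cover every cell class in the circuit; they ship as a human-readable YAML
table (``data/neuron_modes.yaml``).

Integration is forward Euler with two half-steps of dt/2 for the voltage
equation and one full step for the recovery equation, the scheme of the
original reference implementation of the model.  Synapses are current-based
single-exponential: each presynaptic spike increments a decaying drive
variable (``g_E`` or ``g_I``); the total input current of a neuron is
``i_ext + g_E - g_I``.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace

import numpy as np
import yaml

#: Spike cutoff (mV).  A membrane potential at or above this value triggers
#: the reset rule; recorded traces are clamped here on spike samples.
SPIKE_CUTOFF = 30.0

MODE_LABELS = ("RS", "FS", "LTS", "TB")


@dataclass(frozen=True)
class NeuronParameters:
    """Parameter set for one Izhikevich firing mode.

    Parameters
    ----------
    a, b, c, d
        Izhikevich recovery time scale, recovery sensitivity, post-spike
        reset potential (mV) and post-spike recovery increment.
    v_init, u_init
        Initial conditions of the membrane potential (mV) and recovery
        variable.
    tau_syn_E, tau_syn_I
        Decay constants (ms) of the excitatory and inhibitory synaptic
        current variables.
    i_step
        Step-current amplitude used by the characterization protocol.
    mode_label
        One of ``RS``, ``FS``, ``LTS``, ``TB``.
    """

    a: float
    b: float
    c: float
    d: float
    v_init: float
    u_init: float
    tau_syn_E: float = 5.0
    tau_syn_I: float = 6.0
    i_step: float = 0.0
    mode_label: str = "RS"

    def __post_init__(self) -> None:
        if self.tau_syn_E <= 0 or self.tau_syn_I <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.c >= SPIKE_CUTOFF:
            raise ValueError(f"reset potential c must lie below the {SPIKE_CUTOFF} mV cutoff")
        for name in ("a", "b", "c", "d", "v_init", "u_init"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite neuron parameter {name!r}")


@dataclass
class NeuronState:
    """Dynamical state of one neuron: (v, u) plus the two synaptic drives."""

    v: float
    u: float
    g_E: float = 0.0
    g_I: float = 0.0

    def is_finite(self) -> bool:
        return all(map(math.isfinite, (self.v, self.u, self.g_E, self.g_I)))


def _load_mode_table() -> dict[str, NeuronParameters]:
    text = (
        importlib.resources.files("tctsim").joinpath("data/neuron_modes.yaml").read_text()
    )
    raw = yaml.safe_load(text)
    table = {}
    for label, rec in raw.items():
        table[label] = NeuronParameters(
            a=rec["a"],
            b=rec["b"],
            c=rec["c"],
            d=rec["d"],
            v_init=rec["v_init"],
            u_init=rec["u_init"],
            tau_syn_E=rec["tau_syn_E"],
            tau_syn_I=rec["tau_syn_I"],
            i_step=rec["i_step"],
            mode_label=label,
        )
    return table


#: The packaged firing-mode parameter table, keyed by mode label.
MODE_TABLE: dict[str, NeuronParameters] = _load_mode_table()


def initial_state(params: NeuronParameters) -> NeuronState:
    """Fresh state at the mode's documented initial conditions."""
    return NeuronState(v=params.v_init, u=params.u_init)


def step_neuron(
    state: NeuronState,
    params: NeuronParameters,
    i_ext: float = 0.0,
    dt: float = 1.0,
) -> tuple[NeuronState, bool]:
    """Advance one neuron by ``dt`` ms; return the new state and a spike flag.

    If the membrane potential is already at or above the 30 mV cutoff on
    entry the reset rule is applied immediately (``v <- c``, ``u <- u + d``)
    and no integration is performed for this step.  Otherwise the neuron is
    integrated with total current ``i_ext + g_E - g_I``; a post-step value
    at or above the cutoff applies the reset before returning.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not state.is_finite():
        raise FloatingPointError(
            "non-finite neuron state (numerical blow-up; reduce weights or dt)"
        )
    if not math.isfinite(i_ext):
        raise FloatingPointError("non-finite external current")

    if state.v >= SPIKE_CUTOFF:
        return replace(state, v=params.c, u=state.u + params.d), True

    v, u = state.v, state.u
    current = i_ext + state.g_E - state.g_I
    half = 0.5 * dt
    v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
    v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
    u += dt * params.a * (params.b * v - u)

    if not (math.isfinite(v) and math.isfinite(u)):
        raise FloatingPointError(
            "neuron state became non-finite during integration (numerical blow-up)"
        )

    spiked = v >= SPIKE_CUTOFF
    if spiked:
        v = params.c
        u += params.d
    return replace(state, v=v, u=u), spiked


def decay_and_inject(
    state: NeuronState,
    params: NeuronParameters,
    dt: float = 1.0,
    exc_input: float = 0.0,
    inh_input: float = 0.0,
) -> NeuronState:
    """Exponentially decay the synaptic drives over ``dt`` and add new input.

    ``g <- g * exp(-dt / tau) + input`` for each polarity.  ``exc_input`` and
    ``inh_input`` are the summed weight magnitudes of spikes arriving this
    step; inhibition is stored as a non-negative drive and enters the
    membrane equation with a negative sign.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (math.isfinite(exc_input) and math.isfinite(inh_input)):
        raise ValueError("non-finite synaptic input")
    g_E = state.g_E * math.exp(-dt / params.tau_syn_E) + exc_input
    g_I = state.g_I * math.exp(-dt / params.tau_syn_I) + inh_input
    return replace(state, g_E=g_E, g_I=g_I)


def run_step_protocol(
    params: NeuronParameters,
    amplitude: float | None = None,
    t_on: float = 250.0,
    t_off: float = 750.0,
    duration: float = 1000.0,
    dt: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Step-current characterization of a single neuron.

    A constant current ``amplitude`` (default: the mode's ``i_step``) is
    applied between ``t_on`` and ``t_off`` ms of a ``duration`` ms run from
    the mode's initial conditions.  Returns ``(t, v, spike_times)`` where
    ``v`` is clamped to the 30 mV cutoff on spike samples (recording only;
    the dynamics use the reset value).
    """
    if not (0 <= t_on < t_off <= duration):
        raise ValueError("require 0 <= t_on < t_off <= duration")
    if amplitude is None:
        amplitude = params.i_step
    n = int(round(duration / dt))
    t = np.arange(n) * dt
    v_trace = np.empty(n)
    spike_times = []
    state = initial_state(params)
    for k in range(n):
        i_ext = amplitude if t_on <= t[k] < t_off else 0.0
        state, spiked = step_neuron(state, params, i_ext=i_ext, dt=dt)
        if spiked:
            v_trace[k] = SPIKE_CUTOFF
            spike_times.append(t[k])
        else:
            v_trace[k] = state.v
    return t, v_trace, np.asarray(spike_times)


def save_protocol_trace(path, t: np.ndarray, v: np.ndarray) -> None:
    """Write a protocol trace as delimited text: time_ms, v_mV, spike_flag."""
    flags = (v >= SPIKE_CUTOFF).astype(int)
    data = np.column_stack([t, v, flags])
    np.savetxt(path, data, fmt=("%.3f", "%.6f", "%d"),
               header="time_ms\tv_mV\tspike_flag", delimiter="\t", comments="")


@dataclass
class SpikeTrainMetrics:
    """Summary statistics of a spike train used to verify firing modes.

    ``adaptation_index`` is the ratio of the mean of the late third of the
    inter-spike intervals to the mean of the early third (> 1 indicates
    spike-frequency adaptation).  Bursts are maximal groups of consecutive
    spikes whose inter-spike intervals stay at or below
    ``intra_burst_isi_max``.  Ratio metrics that need at least two (or
    several) spikes are ``nan`` when undefined.
    """

    spike_count: int
    mean_rate: float
    isi_list: list[float] = field(default_factory=list)
    isi_cv: float = float("nan")
    adaptation_index: float = float("nan")
    burst_count: int = 0
    intra_burst_isi_max: float = 10.0


def characterize_train(
    spike_times,
    duration: float | None = None,
    intra_burst_isi_max: float = 10.0,
    min_spikes_per_burst: int = 2,
) -> SpikeTrainMetrics:
    """Compute :class:`SpikeTrainMetrics` from a strictly increasing train.

    ``duration`` (ms) sets the denominator of ``mean_rate``; when omitted it
    defaults to the last spike time (rate undefined for empty trains).
    """
    times = np.asarray(spike_times, dtype=float)
    if times.ndim != 1:
        raise ValueError("spike_times must be one-dimensional")
    if times.size >= 2 and not np.all(np.diff(times) > 0):
        raise ValueError("spike times must be strictly increasing")

    n = int(times.size)
    if n == 0:
        return SpikeTrainMetrics(spike_count=0, mean_rate=0.0,
                                 intra_burst_isi_max=intra_burst_isi_max)
    span = duration if duration is not None else float(times[-1])
    rate = 1000.0 * n / span if span > 0 else float("nan")
    isis = np.diff(times)

    cv = float("nan")
    if isis.size >= 2 and isis.mean() > 0:
        cv = float(isis.std() / isis.mean())

    adaptation = float("nan")
    third = isis.size // 3
    if third >= 1:
        early = float(isis[:third].mean())
        late = float(isis[-third:].mean())
        if early > 0:
            adaptation = late / early

    # burst grouping: split the train where the ISI exceeds the ceiling
    groups = np.split(times, np.nonzero(isis > intra_burst_isi_max)[0] + 1)
    bursts = sum(1 for g in groups if len(g) >= min_spikes_per_burst)

    return SpikeTrainMetrics(
        spike_count=n,
        mean_rate=rate,
        isi_list=[float(x) for x in isis],
        isi_cv=cv,
        adaptation_index=adaptation,
        burst_count=bursts,
        intra_burst_isi_max=intra_burst_isi_max,
    )
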