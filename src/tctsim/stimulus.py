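"""Synthetic retinal drive: homogeneous Poisson spike sources.

The thalamic relay (TCR) and interneuron (IN) populations are driven by a
bank of independent Poisson spike trains — a stand-in for resting-state
retinal input, whose discharge rate in quiet rest is about 25 Hz.  Every
source connects to every neuron of every target population (all-to-all
fan-out) through an excitatory synapse with a uniformly distributed
conduction delay.

Trains are generated by Bernoulli thinning on the simulation clock: a bin
of width ``dt`` contains a spike with probability ``rate * dt``.  At
25 Hz and 1 ms bins the approximation error relative to an exact Poisson
process is of order ``rate * dt`` (~2.5%), negligible for the band
analysis downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class StimulusSpec:
    """Poisson source bank.

    Parameters
    ----------
    rate
        Source firing rate in Hz (homogeneous).
    n_sources
        Number of independent source trains.  ``None`` (default) means one
        source per target neuron, resolved when wiring against a circuit.
    targets
        Names of the populations that receive the drive.
    fan_out
        Only ``"all_to_all"`` is supported: every source reaches every
        neuron of every target population.
    weight
        Synaptic increment per source spike, in current units (excitatory).
    delay_law
        ``("uniform", lo_ms, hi_ms)`` or ``("fixed", value_ms)``.
    """

    rate: float = 25.0
    n_sources: int | None = None
    targets: list[str] = field(default_factory=lambda: ["TCR", "IN"])
    fan_out: str = "all_to_all"
    weight: float = 1.0
    delay_law: tuple = ("uniform", 1.0, 10.0)

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("stimulus rate must be non-negative")
        if not self.targets:
            raise ValueError("stimulus must have at least one target population")
        if self.weight < 0:
            raise ValueError("stimulus weight must be non-negative (source is excitatory)")
        if self.fan_out != "all_to_all":
            raise ValueError(f"unsupported fan_out {self.fan_out!r}")

    def resolve_n_sources(self, config) -> int:
        if self.n_sources is not None:
            return int(self.n_sources)
        offsets = config.offsets()
        return sum(offsets[t][1] for t in self.targets)


def generate_poisson_trains(
    spec: StimulusSpec,
    duration: float,
    dt: float = 1.0,
    seed=None,
    n_sources: int | None = None,
) -> np.ndarray:
    """Boolean spike raster of shape ``(n_sources, n_steps)``.

    Each bin spikes independently with probability ``rate * dt / 1000``
    (thinned-Bernoulli approximation of a Poisson process); reproducible
    per seed.  ``n_sources`` must be given here when the spec defers it to
    the circuit.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if n_sources is None:
        if spec.n_sources is None:
            raise ValueError("n_sources unresolved; pass n_sources or set spec.n_sources")
        n_sources = spec.n_sources
    p = spec.rate * dt / 1000.0
    if p >= 1.0:
        raise ValueError(
            f"rate*dt = {p:.3g} >= 1: the per-bin Bernoulli approximation is invalid"
        )
    n_steps = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    return rng.random((n_sources, n_steps)) < p


def spike_table(trains: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Two-column (source_id, time_ms) array from a boolean raster."""
    src, step = np.nonzero(trains)
    return np.column_stack([src.astype(float), step * dt])


def save_spike_table(path, trains: np.ndarray, dt: float = 1.0) -> None:
    np.savetxt(path, spike_table(trains, dt), fmt=("%d", "%.3f"),
               header="source_id\ttime_ms", delimiter="\t", comments="")


def wire_stimulus(spec: StimulusSpec, config, seed, dt: float = 1.0):
    """All-to-all stimulus edge list against a circuit configuration.

    Returns a :class:`tctsim.circuit.ProjectionEdges` whose ``pre`` indices
    refer to source trains (0..n_sources-1) and whose ``post`` indices are
    global neuron indices of the target populations.  Each edge gets an
    independent delay from the spec's delay law (integer steps >= 1).
    """
    from .circuit import ConfigurationError, ProjectionEdges, draw_delays

    offsets = config.offsets()
    for t in spec.targets:
        if t not in offsets:
            raise ConfigurationError(f"stimulus targets unknown population {t!r}")
    n_sources = spec.resolve_n_sources(config)
    post = np.concatenate([
        np.arange(offsets[t][0], offsets[t][0] + offsets[t][1]) for t in spec.targets
    ]).astype(np.int32)
    # all-to-all: every source to every target neuron
    pre_idx = np.repeat(np.arange(n_sources, dtype=np.int32), post.size)
    post_idx = np.tile(post, n_sources)
    rng = np.random.default_rng(seed)
    delays = draw_delays(spec.delay_law, pre_idx.size, dt, rng)
    return ProjectionEdges(
        name="stimulus",
        pre=pre_idx,
        post=post_idx,
        weight=np.full(pre_idx.size, spec.weight, dtype=float),
        delay_steps=delays,
        inhibitory=False,
    )
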