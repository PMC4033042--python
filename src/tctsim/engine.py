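"""Discrete-time network simulation on a 1 ms clock.

The engine advances all ~1090 neurons synchronously: at each step, spikes
whose conduction delay matures are delivered into the targets' synaptic
drive variables (exponential decay + increment), every neuron is advanced
one forward-Euler step of the Izhikevich equations, new spikes are placed
in a circular delay buffer, and the per-population mean membrane potential
(clamped at the 30 mV cutoff on spike samples) is recorded.  A spike
emitted at step ``t`` with delay ``k`` affects its target at step
``t + k``, before that step's neuron update.

Everything is deterministic given the realized connectivity, the stimulus
raster and the configuration; multi-run experiments derive per-run seeds
from a single master seed with separate streams for wiring and stimulus,
so disabling projections (a lesion) never perturbs the stimulus draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuit import CircuitConfig, ProjectionEdges, RealizedConnectivity, realize
from .neuron import MODE_TABLE, SPIKE_CUTOFF
from .stimulus import generate_poisson_trains, wire_stimulus


@dataclass
class SimulationSettings:
    """Protocol parameters: 30 s runs at 1 ms resolution, averaged over 3."""

    dt: float = 1.0
    duration: float = 30000.0
    n_runs: int = 3
    master_seed: int = 0
    record: list[str] | None = None      # population names; None = all
    redraw_connectivity: bool = True     # redraw wiring each run

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        n = self.duration / self.dt
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be an integer multiple of dt")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class PopulationTrace:
    """Mean membrane potential of one population, one value per step."""

    population: str
    dt: float
    values: np.ndarray
    run_id: int = 0

    def save(self, path) -> None:
        t = np.arange(self.values.size) * self.dt
        np.savetxt(path, np.column_stack([t, self.values]), fmt="%.6f",
                   header="time_ms\tmean_v_mV", delimiter="\t", comments="")


@dataclass
class SpikeRecord:
    """All spikes of one run: global neuron index and time (ms)."""

    neuron: np.ndarray                   # int32 global indices
    time_ms: np.ndarray                  # float64, non-decreasing
    offsets: dict[str, tuple[int, int]]  # population -> (start, size)

    @property
    def n_spikes(self) -> int:
        return int(self.neuron.size)

    def population_of(self, global_index: int) -> str:
        for name, (start, size) in self.offsets.items():
            if start <= global_index < start + size:
                return name
        raise IndexError(global_index)

    def times_for(self, population: str) -> np.ndarray:
        start, size = self.offsets[population]
        mask = (self.neuron >= start) & (self.neuron < start + size)
        return self.time_ms[mask]

    def to_table(self, path) -> None:
        """Delimited text: population, neuron_id (local), t_ms."""
        with open(path, "w") as fh:
            fh.write("population\tneuron_id\tt_ms\n")
            for idx, t in zip(self.neuron, self.time_ms):
                pop = self.population_of(int(idx))
                fh.write(f"{pop}\t{int(idx) - self.offsets[pop][0]}\t{t:.3f}\n")


class _Csr:
    """Edges grouped by source index for fast per-spike scatter."""

    __slots__ = ("indptr", "post", "weight", "delay")

    def __init__(self, edge_lists: list[ProjectionEdges], n_sources: int):
        if edge_lists:
            pre = np.concatenate([e.pre for e in edge_lists])
            post = np.concatenate([e.post for e in edge_lists])
            weight = np.concatenate([e.weight for e in edge_lists])
            delay = np.concatenate([e.delay_steps for e in edge_lists])
        else:
            pre = np.empty(0, np.int32)
            post = np.empty(0, np.int32)
            weight = np.empty(0, float)
            delay = np.empty(0, np.int32)
        order = np.argsort(pre, kind="stable")
        self.post = post[order]
        self.weight = weight[order]
        self.delay = delay[order].astype(np.int64)
        counts = np.bincount(pre, minlength=n_sources)
        self.indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    def edges_of(self, sources: np.ndarray) -> np.ndarray:
        """Flat edge indices of all listed source indices."""
        starts = self.indptr[sources]
        counts = self.indptr[sources + 1] - starts
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, np.int64)
        offs = np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
        return np.repeat(starts, counts) + offs

    @property
    def max_delay(self) -> int:
        return int(self.delay.max()) if self.delay.size else 1


def _neuron_arrays(config: CircuitConfig):
    """Per-neuron parameter vectors in population order."""
    n = config.total_size
    arr = {k: np.empty(n) for k in ("a", "b", "c", "d", "v", "u", "dec_E", "dec_I")}
    for pop in config.populations:
        start, size = config.offsets()[pop.name]
        p = MODE_TABLE[pop.mode_label]
        sl = slice(start, start + size)
        arr["a"][sl] = p.a
        arr["b"][sl] = p.b
        arr["c"][sl] = p.c
        arr["d"][sl] = p.d
        arr["v"][sl] = p.v_init
        arr["u"][sl] = p.u_init
        arr["dec_E"][sl] = p.tau_syn_E
        arr["dec_I"][sl] = p.tau_syn_I
    return arr


def simulate(
    config: CircuitConfig,
    connectivity: RealizedConnectivity,
    stimulus_trains: np.ndarray,
    stimulus_edges: ProjectionEdges,
    settings: SimulationSettings,
    i_ext: dict[str, float] | None = None,
) -> tuple[dict[str, PopulationTrace], SpikeRecord]:
    """Run one realization for ``settings.duration`` ms.

    Returns the per-population mean-voltage traces (clamped at the spike
    cutoff on spike samples) and the full spike record.  ``i_ext`` maps
    population names to a constant externally injected current (used by
    characterization tests; zero by default).
    """
    config.validate()
    dt = settings.dt
    n_steps = settings.n_steps
    n = config.total_size
    offsets = config.offsets()
    record_names = settings.record or config.population_names()
    for name in record_names:
        if name not in offsets:
            raise KeyError(f"cannot record unknown population {name!r}")

    arr = _neuron_arrays(config)
    v, u = arr["v"], arr["u"]
    a_, b_, c_, d_ = arr["a"], arr["b"], arr["c"], arr["d"]
    dec_E = np.exp(-dt / arr["dec_E"])
    dec_I = np.exp(-dt / arr["dec_I"])
    g_E = np.zeros(n)
    g_I = np.zeros(n)

    i_const = np.zeros(n)
    if i_ext:
        for name, amp in i_ext.items():
            start, size = offsets[name]
            i_const[start:start + size] = amp

    inhibitory = np.zeros(n, bool)
    for pop in config.populations:
        if pop.polarity == "inhibitory":
            start, size = offsets[pop.name]
            inhibitory[start:start + size] = True

    rec = _Csr(connectivity.projections, n)
    n_sources = stimulus_trains.shape[0] if stimulus_trains.size else 0
    stim = _Csr([stimulus_edges] if stimulus_edges is not None else [], max(n_sources, 1))
    if stimulus_trains.size and stimulus_trains.shape[1] != n_steps:
        raise ValueError("stimulus raster length does not match the simulation duration")

    depth = max(rec.max_delay, stim.max_delay) + 1
    buf_E = np.zeros((depth, n))
    buf_I = np.zeros((depth, n))
    flat_E = buf_E.ravel()
    flat_I = buf_I.ravel()

    pop_starts = np.array([offsets[nm][0] for nm in config.population_names()])
    pop_sizes = np.array([offsets[nm][1] for nm in config.population_names()], float)
    traces = np.empty((len(config.populations), n_steps))

    spk_neuron: list[np.ndarray] = []
    spk_step: list[np.ndarray] = []

    half = 0.5 * dt
    for t in range(n_steps):
        slot = t % depth
        # deliver matured spikes: decay + inject
        g_E *= dec_E
        g_E += buf_E[slot]
        g_I *= dec_I
        g_I += buf_I[slot]
        buf_E[slot] = 0.0
        buf_I[slot] = 0.0

        # stimulus spikes this step are queued for t + delay (delay >= 1)
        if n_sources:
            src = np.nonzero(stimulus_trains[:, t])[0]
            if src.size:
                eidx = stim.edges_of(src)
                if eidx.size:
                    slots = (t + stim.delay[eidx]) % depth
                    np.add.at(flat_E, slots * n + stim.post[eidx], stim.weight[eidx])

        # advance neurons (overflow surfaces as the finiteness check below)
        with np.errstate(over="ignore", invalid="ignore"):
            current = i_const + g_E - g_I
            v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
            v += half * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
            u += dt * a_ * (b_ * v - u)

        if not np.all(np.isfinite(v)):
            bad = int(np.nonzero(~np.isfinite(v))[0][0])
            pop = next(nm for nm, (s0, sz) in offsets.items() if s0 <= bad < s0 + sz)
            raise FloatingPointError(
                f"membrane potential diverged in population {pop} at step {t} "
                f"(mis-calibrated weights?)"
            )

        fired = v >= SPIKE_CUTOFF
        v_rec = np.where(fired, SPIKE_CUTOFF, v)
        np.add.reduceat(v_rec, pop_starts, out=traces[:, t])
        traces[:, t] /= pop_sizes

        fidx = np.nonzero(fired)[0]
        if fidx.size:
            spk_neuron.append(fidx.astype(np.int32))
            spk_step.append(np.full(fidx.size, t, np.int32))
            # queue efferent spikes
            eidx = rec.edges_of(fidx)
            if eidx.size:
                slots = (t + rec.delay[eidx]) % depth
                posts = rec.post[eidx]
                wts = rec.weight[eidx]
                # polarity is a property of the presynaptic neuron
                inh = inhibitory[np.repeat(fidx, rec.indptr[fidx + 1] - rec.indptr[fidx])]
                np.add.at(flat_E, slots[~inh] * n + posts[~inh], wts[~inh])
                np.add.at(flat_I, slots[inh] * n + posts[inh], wts[inh])
            # reset
            v[fidx] = c_[fidx]
            u[fidx] += d_[fidx]

    neuron_arr = (np.concatenate(spk_neuron) if spk_neuron else np.empty(0, np.int32))
    step_arr = (np.concatenate(spk_step) if spk_step else np.empty(0, np.int32))
    record = SpikeRecord(neuron=neuron_arr, time_ms=step_arr * dt, offsets=offsets)

    out = {
        name: PopulationTrace(name, dt, traces[k].copy())
        for k, name in enumerate(config.population_names())
        if name in record_names
    }
    return out, record


@dataclass
class MultiRunResult:
    """Averaged and per-run traces of a seeded multi-run experiment."""

    averaged: dict[str, PopulationTrace]
    per_run: list[dict[str, PopulationTrace]]
    spike_records: list[SpikeRecord]
    settings: SimulationSettings
    run_seeds: list[int] = field(default_factory=list)


def derive_streams(master_seed: int, n_runs: int):
    """Per-run (connectivity, stimulus) seed pairs from one master seed."""
    root = np.random.SeedSequence(master_seed)
    pairs = []
    for run_seq in root.spawn(n_runs):
        conn_seq, stim_seq = run_seq.spawn(2)
        pairs.append((conn_seq, stim_seq))
    return pairs


def run_experiment(config: CircuitConfig, settings: SimulationSettings) -> MultiRunResult:
    """``n_runs`` independent realizations + simulations, pointwise-averaged.

    Per-run seeds derive deterministically from ``settings.master_seed``;
    connectivity is redrawn each run unless
    ``settings.redraw_connectivity`` is False (then run 0's wiring is
    reused).  The returned average is the pointwise mean of the per-run
    mean-voltage traces.
    """
    config.validate()
    streams = derive_streams(settings.master_seed, settings.n_runs)
    per_run: list[dict[str, PopulationTrace]] = []
    records: list[SpikeRecord] = []
    fixed_conn = None
    n_src = config.stimulus.resolve_n_sources(config)
    for run_id, (conn_seq, stim_seq) in enumerate(streams):
        if settings.redraw_connectivity or fixed_conn is None:
            conn = realize(config, conn_seq, dt=settings.dt)
            if not settings.redraw_connectivity:
                fixed_conn = conn
        else:
            conn = fixed_conn
        stim_train_seq, stim_wire_seq = stim_seq.spawn(2)
        trains = generate_poisson_trains(
            config.stimulus, settings.duration, settings.dt,
            seed=stim_train_seq, n_sources=n_src,
        )
        stim_edges = wire_stimulus(config.stimulus, config, stim_wire_seq, dt=settings.dt)
        traces, record = simulate(config, conn, trains, stim_edges, settings)
        for tr in traces.values():
            tr.run_id = run_id
        per_run.append(traces)
        records.append(record)

    averaged = {}
    for name in per_run[0]:
        stack = np.stack([runs[name].values for runs in per_run])
        averaged[name] = PopulationTrace(name, settings.dt, stack.mean(axis=0), run_id=-1)
    return MultiRunResult(
        averaged=averaged,
        per_run=per_run,
        spike_records=records,
        settings=settings,
    )


def population_rate(
    record: SpikeRecord,
    window: float,
    duration: float,
    dt: float = 1.0,
    normalize: bool = True,
) -> dict[str, np.ndarray]:
    """Windowed spike counts per population, optionally in Hz per neuron.

    ``window`` must be a multiple of ``dt``.  With ``normalize=False`` the
    raw per-window spike counts are returned.
    """
    ratio = window / dt
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("window must be an integer multiple of dt")
    n_windows = int(np.ceil(duration / window))
    edges = np.arange(n_windows + 1) * window
    out = {}
    for name, (start, size) in record.offsets.items():
        times = record.times_for(name)
        counts, _ = np.histogram(times, bins=edges)
        if normalize:
            out[name] = counts / (size * window / 1000.0)
        else:
            out[name] = counts.astype(float)
    return out
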