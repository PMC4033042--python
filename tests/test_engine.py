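"""Network engine: quiescence, oracle equivalence, determinism, rates."""

import numpy as np
import pytest

from tctsim import (CircuitConfig, SimulationSettings, SpikeRecord,
                    build_default_circuit, population_rate, realize,
                    run_experiment, simulate, wire_stimulus,
                    generate_poisson_trains)
from tctsim.circuit import PopulationSpec, ProjectionSpec
from tctsim.engine import derive_streams
from tctsim.stimulus import StimulusSpec
from reference import reference_network

RS_KW = dict(a=0.02, b=0.2, c=-65.0, d=6.0, v=-60.0, u=0.0,
             tau_E=5.0, tau_I=6.0, inhibitory=False)
FS_KW = dict(a=0.1, b=0.2, c=-65.0, d=6.0, v=-70.0, u=0.0,
             tau_E=5.0, tau_I=6.0, inhibitory=True)


def _silent_stimulus(targets):
    return StimulusSpec(rate=0.0, n_sources=1, targets=targets, weight=0.0)


def _run(config, settings, seed=0, i_ext=None):
    conn = realize(config, seed=seed, dt=settings.dt)
    trains = generate_poisson_trains(
        config.stimulus, settings.duration, settings.dt, seed=seed + 1,
        n_sources=config.stimulus.resolve_n_sources(config))
    edges = wire_stimulus(config.stimulus, config, seed=seed + 2, dt=settings.dt)
    return simulate(config, conn, trains, edges, settings, i_ext=i_ext)


class TestQuiescence:
    def test_no_input_no_spikes(self):
        pops = [PopulationSpec("A", "thalamic", "none", "TCR", 5)]
        cfg = CircuitConfig(pops, [], _silent_stimulus(["A"]), weight_scale=0.0)
        settings = SimulationSettings(duration=1000.0, n_runs=1)
        traces, record = _run(cfg, settings)
        assert record.n_spikes == 0
        # subthreshold relaxation toward the stable fixed point near -70 mV
        values = traces["A"].values
        assert values.max() < 30.0
        assert abs(values[-1] - values[-2]) < 1e-3


class TestOracleEquivalence:
    def test_single_neuron_population_equals_step_protocol(self):
        from tctsim import MODE_TABLE, run_step_protocol
        pops = [PopulationSpec("A", "thalamic", "none", "TCR", 1)]
        cfg = CircuitConfig(pops, [], _silent_stimulus(["A"]), weight_scale=0.0)
        settings = SimulationSettings(duration=1000.0, n_runs=1)
        traces, record = _run(cfg, settings, i_ext={"A": 9.0})
        _, v_ref, spikes_ref = run_step_protocol(
            MODE_TABLE["RS"], amplitude=9.0, t_on=0.0, t_off=1000.0)
        np.testing.assert_array_equal(traces["A"].values, v_ref)
        np.testing.assert_array_equal(record.time_ms, spikes_ref)

    def test_three_neuron_circuit_matches_scalar_reference(self):
        # E0 -(w=4, d=3)-> E1 -(w=6, d=2)-> I2 -(w=3, d=1)-> E0
        pops = [PopulationSpec("E0", "cortical", "L4", "PY", 1),
                PopulationSpec("E1", "cortical", "L4", "PY", 1),
                PopulationSpec("I2", "cortical", "L4", "B", 1)]
        projs = [ProjectionSpec("E0", "E1", 1.0, 4.0, ("fixed", 3.0)),
                 ProjectionSpec("E1", "I2", 1.0, 6.0, ("fixed", 2.0)),
                 ProjectionSpec("I2", "E0", 1.0, 3.0, ("fixed", 1.0))]
        cfg = CircuitConfig(pops, projs, _silent_stimulus(["E0"]), weight_scale=1.0)
        settings = SimulationSettings(duration=500.0, n_runs=1)
        traces, record = _run(cfg, settings, i_ext={"E0": 9.0, "E1": 4.0})

        neurons = [dict(RS_KW), dict(RS_KW), dict(FS_KW)]
        edges = [(0, 1, 4.0, 3), (1, 2, 6.0, 2), (2, 0, 3.0, 1)]
        ref_traces, ref_spikes = reference_network(
            neurons, edges, i_ext=[9.0, 4.0, 0.0], n_steps=500)

        for k, name in enumerate(("E0", "E1", "I2")):
            np.testing.assert_array_equal(traces[name].values, ref_traces[k])
            start, _ = record.offsets[name]
            got = record.time_ms[record.neuron == start]
            np.testing.assert_array_equal(got, ref_spikes[k])
        assert record.n_spikes > 0


class TestDeterminismAndAveraging:
    def test_bit_level_determinism_per_seed(self):
        cfg = build_default_circuit()
        settings = SimulationSettings(duration=2000.0, n_runs=1, master_seed=5)
        a = run_experiment(cfg, settings)
        b = run_experiment(cfg, settings)
        for name in a.averaged:
            np.testing.assert_array_equal(a.averaged[name].values,
                                          b.averaged[name].values)
        ra, rb = a.spike_records[0], b.spike_records[0]
        np.testing.assert_array_equal(ra.neuron, rb.neuron)
        np.testing.assert_array_equal(ra.time_ms, rb.time_ms)

    def test_different_master_seeds_differ(self):
        cfg = build_default_circuit()
        a = run_experiment(cfg, SimulationSettings(duration=2000.0, n_runs=1,
                                                   master_seed=1))
        b = run_experiment(cfg, SimulationSettings(duration=2000.0, n_runs=1,
                                                   master_seed=2))
        assert not np.array_equal(a.averaged["TCR"].values,
                                  b.averaged["TCR"].values)

    def test_average_is_pointwise_mean_of_runs(self):
        cfg = build_default_circuit()
        res = run_experiment(cfg, SimulationSettings(duration=1000.0, n_runs=3,
                                                     master_seed=3))
        for name, avg in res.averaged.items():
            stack = np.stack([r[name].values for r in res.per_run])
            np.testing.assert_allclose(avg.values, stack.mean(axis=0), rtol=1e-12)

    def test_single_run_average_is_identity(self):
        cfg = build_default_circuit()
        res = run_experiment(cfg, SimulationSettings(duration=1000.0, n_runs=1,
                                                     master_seed=4))
        np.testing.assert_array_equal(res.averaged["TCR"].values,
                                      res.per_run[0]["TCR"].values)

    def test_lesion_shares_stimulus_stream_with_baseline(self):
        # wiring and stimulus use separate derived streams
        pairs_a = derive_streams(9, 3)
        pairs_b = derive_streams(9, 3)
        for (ca, sa), (cb, sb) in zip(pairs_a, pairs_b):
            assert ca.entropy == cb.entropy and sa.entropy == sb.entropy


class TestPopulationRate:
    def _record(self, times, offsets):
        times = np.asarray(times, float)
        return SpikeRecord(neuron=np.zeros(times.size, np.int32),
                           time_ms=times, offsets=offsets)

    def test_empty_record_all_zero(self):
        rec = self._record([], {"A": (0, 1)})
        rates = population_rate(rec, window=25.0, duration=100.0)
        assert np.all(rates["A"] == 0)

    def test_constructed_counts(self):
        rec = self._record([10.0, 20.0, 30.0], {"A": (0, 1)})
        counts = population_rate(rec, window=25.0, duration=50.0, normalize=False)
        np.testing.assert_array_equal(counts["A"], [2.0, 1.0])

    def test_total_count_conserved(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 1000.0, size=200))
        rec = self._record(times, {"A": (0, 4)})
        counts = population_rate(rec, window=50.0, duration=1000.0, normalize=False)
        assert counts["A"].sum() == 200

    def test_default_network_is_active_in_25ms_windows(self):
        cfg = build_default_circuit()
        settings = SimulationSettings(duration=3000.0, n_runs=1, master_seed=0)
        res = run_experiment(cfg, settings)
        rates = population_rate(res.spike_records[0], window=25.0,
                                duration=3000.0)
        # both EEG-proxy populations fire at sustained nonzero rates
        for name in ("TCR", "PY4"):
            assert rates[name].mean() > 1.0
            assert (rates[name] > 0).mean() > 0.3

    def test_window_must_divide_dt(self):
        rec = self._record([], {"A": (0, 1)})
        with pytest.raises(ValueError):
            population_rate(rec, window=12.3, duration=100.0)
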