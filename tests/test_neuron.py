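"""Single-neuron dynamics: integration, reset rule, synapse kinetics and
the step-current characterization of the four firing modes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tctsim import (MODE_TABLE, SPIKE_CUTOFF, NeuronParameters, NeuronState,
                    characterize_train, decay_and_inject, initial_state,
                    run_step_protocol, step_neuron)
from reference import reference_single_neuron

RS = MODE_TABLE["RS"]
FS = MODE_TABLE["FS"]
LTS = MODE_TABLE["LTS"]
TB = MODE_TABLE["TB"]


class TestModeTable:
    def test_four_modes_packaged(self):
        assert set(MODE_TABLE) == {"RS", "FS", "LTS", "TB"}

    @pytest.mark.parametrize("label,expected", [
        ("RS", (0.02, 0.2, -65.0, 6.0, -60.0, 0.0, 5.0, 6.0, 9.0)),
        ("FS", (0.1, 0.2, -65.0, 6.0, -70.0, 0.0, 5.0, 6.0, 9.0)),
        ("LTS", (0.01, 0.2, -65.0, 6.0, -70.0, 0.0, 5.0, 6.0, 25.0)),
        ("TB", (0.02, 0.25, -50.0, 2.0, -70.0, 0.0, 5.0, 6.0, 10.0)),
    ])
    def test_parameter_rows(self, label, expected):
        p = MODE_TABLE[label]
        got = (p.a, p.b, p.c, p.d, p.v_init, p.u_init,
               p.tau_syn_E, p.tau_syn_I, p.i_step)
        assert got == expected

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            NeuronParameters(a=0.02, b=0.2, c=-65, d=6, v_init=-60, u_init=0,
                             tau_syn_E=-1.0)
        with pytest.raises(ValueError):
            NeuronParameters(a=0.02, b=0.2, c=40.0, d=6, v_init=-60, u_init=0)


class TestStepNeuron:
    def test_subthreshold_rest_never_spikes(self):
        state = NeuronState(v=-65.0, u=-13.0)
        for _ in range(1000):
            state, spiked = step_neuron(state, RS, i_ext=0.0, dt=1.0)
            assert not spiked
            assert state.v < SPIKE_CUTOFF

    def test_reset_rule_applied_at_cutoff(self):
        state = NeuronState(v=35.0, u=-10.0)
        new, spiked = step_neuron(state, RS)
        assert spiked
        assert new.v == RS.c == -65.0
        assert new.u == state.u + RS.d == -4.0

    def test_matches_reference_integrator_under_constant_drive(self):
        ref_trace, ref_spikes = reference_single_neuron(
            RS.a, RS.b, RS.c, RS.d, RS.v_init, RS.u_init,
            lambda k: 9.0, n_steps=1000)
        state = initial_state(RS)
        spikes = []
        trace = []
        for k in range(1000):
            state, spiked = step_neuron(state, RS, i_ext=9.0)
            trace.append(SPIKE_CUTOFF if spiked else state.v)
            if spiked:
                spikes.append(float(k))
        assert spikes == ref_spikes
        np.testing.assert_array_equal(trace, ref_trace)

    def test_nonfinite_state_rejected(self):
        with pytest.raises(FloatingPointError):
            step_neuron(NeuronState(v=float("nan"), u=0.0), RS)
        with pytest.raises(FloatingPointError):
            step_neuron(NeuronState(v=-65.0, u=0.0), RS, i_ext=float("inf"))


class TestSynapseKinetics:
    def test_closed_form_decay(self):
        state = NeuronState(v=-65, u=0, g_E=10.0)
        out = decay_and_inject(state, RS, dt=5.0)
        assert out.g_E == pytest.approx(10.0 * math.exp(-1.0), rel=1e-12)

    def test_injection_identity(self):
        out = decay_and_inject(NeuronState(v=-65, u=0), RS, dt=1.0, exc_input=2.0)
        assert out.g_E == 2.0
        assert out.g_I == 0.0

    @given(g0=st.floats(0.01, 100.0), steps=st.integers(2, 50))
    @settings(max_examples=30, deadline=None)
    def test_unforced_decay_is_strictly_monotone(self, g0, steps):
        state = NeuronState(v=-65, u=0, g_E=g0, g_I=g0)
        values = [g0]
        for _ in range(steps):
            state = decay_and_inject(state, RS, dt=1.0)
            values.append(state.g_E)
            assert state.g_E >= 0 and state.g_I >= 0
        assert all(b < a for a, b in zip(values, values[1:]))


class TestStepProtocol:
    @pytest.mark.parametrize("label", list(MODE_TABLE))
    def test_zero_amplitude_never_spikes(self, label):
        _, _, spikes = run_step_protocol(MODE_TABLE[label], amplitude=0.0)
        assert spikes.size == 0

    def test_rs_firing_is_stimulus_locked(self):
        _, _, spikes = run_step_protocol(RS, amplitude=9.0)
        assert spikes.size > 0
        assert spikes.min() >= 250.0
        # at most one refractory-scale overshoot past stimulus offset
        assert spikes.max() <= 750.0 + 50.0

    def test_recorded_trace_clamped_and_reset(self):
        _, v, spikes = run_step_protocol(RS)
        assert v.max() <= SPIKE_CUTOFF
        spike_idx = np.nonzero(v == SPIKE_CUTOFF)[0]
        assert spike_idx.size == spikes.size

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            run_step_protocol(RS, t_on=800.0, t_off=700.0)


class TestCharacterizeTrain:
    def test_empty_train(self):
        m = characterize_train([])
        assert m.spike_count == 0
        assert math.isnan(m.isi_cv) and math.isnan(m.adaptation_index)

    def test_constructed_two_burst_train(self):
        m = characterize_train([100, 110, 120, 300, 310, 320],
                               intra_burst_isi_max=10.0)
        assert m.burst_count == 2
        assert m.spike_count == len(m.isi_list) + 1

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            characterize_train([10.0, 5.0, 20.0])

    @given(st.lists(st.floats(0.1, 5000.0), min_size=2, max_size=60, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_count_and_cv_invariants(self, times):
        times = sorted(times)
        m = characterize_train(times, duration=6000.0)
        assert m.spike_count == len(m.isi_list) + 1
        if not math.isnan(m.isi_cv):
            assert m.isi_cv >= 0


class TestModeVerification:
    """The four packaged parameter sets behave as their mode labels claim."""

    @staticmethod
    def _late_metrics(label):
        p = MODE_TABLE[label]
        _, _, spikes = run_step_protocol(p)
        late = spikes[(spikes >= 450.0) & (spikes < 750.0)]
        return characterize_train(late) if late.size >= 3 else None

    def test_tonic_modes_fire_regularly(self):
        for label in ("RS", "FS"):
            m = self._late_metrics(label)
            assert m is not None, f"{label} silent in late window"
            assert m.isi_cv < 0.2, f"{label} irregular: cv={m.isi_cv:.3f}"

    def test_fast_spiking_outpaces_regular_spiking(self):
        drive = RS.i_step  # identical drive for both modes
        _, _, rs_spikes = run_step_protocol(RS, amplitude=drive)
        _, _, fs_spikes = run_step_protocol(FS, amplitude=drive)
        assert fs_spikes.size > rs_spikes.size

    def test_lts_adapts(self):
        _, _, spikes = run_step_protocol(LTS)
        m = characterize_train(spikes)
        assert m.adaptation_index > 1.0

    def test_tonic_bursting_bursts_and_rs_does_not(self):
        _, _, tb_spikes = run_step_protocol(TB, amplitude=10.0)
        tb = characterize_train(tb_spikes, intra_burst_isi_max=10.0)
        assert tb.burst_count >= 2
        _, _, rs_spikes = run_step_protocol(RS)
        rs = characterize_train(rs_spikes, intra_burst_isi_max=10.0)
        assert rs.burst_count <= 1

    @pytest.mark.parametrize("label", list(MODE_TABLE))
    def test_engine_scheme_matches_reference_on_100_steps(self, label):
        p = MODE_TABLE[label]
        ref_trace, _ = reference_single_neuron(
            p.a, p.b, p.c, p.d, p.v_init, p.u_init, lambda k: p.i_step, 100)
        state = initial_state(p)
        trace = []
        for _ in range(100):
            state, spiked = step_neuron(state, p, i_ext=p.i_step)
            trace.append(SPIKE_CUTOFF if spiked else state.v)
        np.testing.assert_array_equal(trace, ref_trace)

    def test_reset_conservation(self):
        # any step that reports a spike leaves the state exactly at (c, u+d)
        state = initial_state(TB)
        for _ in range(500):
            prev_u = state.u
            state, spiked = step_neuron(state, TB, i_ext=TB.i_step)
            if spiked:
                assert state.v == TB.c
                assert state.u >= prev_u + TB.d
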