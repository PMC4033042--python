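"""Independent scalar reference implementations used as test oracles.

Everything here is written naively (plain Python floats, explicit loops,
per-neuron dictionaries) and deliberately shares no code with the package:
it exists so the vectorized engine can be checked against a second,
independently coded integrator.
"""

import math


def reference_single_neuron(a, b, c, d, v0, u0, i_of_t, n_steps, dt=1.0):
    """Naive Izhikevich integrator: two dt/2 half-steps for v, one full step
    for u, reset at the 30 mV cutoff after the update.

    ``i_of_t`` maps a step index to the input current.  Returns the recorded
    trace (30 on spike samples) and the spike times in ms.
    """
    v, u = v0, u0
    trace = []
    spikes = []
    for k in range(n_steps):
        current = i_of_t(k)
        v = v + 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
        v = v + 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
        u = u + dt * a * (b * v - u)
        if v >= 30.0:
            trace.append(30.0)
            spikes.append(k * dt)
            v = c
            u = u + d
        else:
            trace.append(v)
    return trace, spikes


def reference_network(neurons, edges, i_ext, n_steps, dt=1.0):
    """Event-by-event scalar simulation of a tiny hand-wired circuit.

    ``neurons`` is a list of dicts with keys a, b, c, d, v, u, tau_E, tau_I,
    inhibitory.  ``edges`` is a list of (pre, post, weight, delay_steps)
    with non-negative weight magnitudes routed by the presynaptic neuron's
    polarity.  ``i_ext`` is a per-neuron constant current.

    Per step: deliver spikes whose delay matures into the synaptic drives
    (after exponential decay), advance every neuron, then queue new spikes.
    Returns (traces, spike_times) per neuron; traces clamp spike samples at
    the cutoff.
    """
    n = len(neurons)
    state = [dict(v=nr["v"], u=nr["u"], gE=0.0, gI=0.0) for nr in neurons]
    pending = {}  # step -> list of (post, weight, inhibitory)
    traces = [[] for _ in range(n)]
    spikes = [[] for _ in range(n)]
    for k in range(n_steps):
        arrivals = pending.pop(k, [])
        for j, nr in enumerate(neurons):
            st = state[j]
            st["gE"] = st["gE"] * math.exp(-dt / nr["tau_E"])
            st["gI"] = st["gI"] * math.exp(-dt / nr["tau_I"])
        for (post, w, inh) in arrivals:
            if inh:
                state[post]["gI"] += w
            else:
                state[post]["gE"] += w
        fired = []
        for j, nr in enumerate(neurons):
            st = state[j]
            current = i_ext[j] + st["gE"] - st["gI"]
            v, u = st["v"], st["u"]
            v = v + 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
            v = v + 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
            u = u + dt * nr["a"] * (nr["b"] * v - u)
            if v >= 30.0:
                traces[j].append(30.0)
                spikes[j].append(k * dt)
                fired.append(j)
                v = nr["c"]
                u = u + nr["d"]
            else:
                traces[j].append(v)
            st["v"], st["u"] = v, u
        for j in fired:
            for (pre, post, w, delay) in edges:
                if pre == j:
                    pending.setdefault(k + delay, []).append(
                        (post, w, neurons[j]["inhibitory"])
                    )
    return traces, spikes
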