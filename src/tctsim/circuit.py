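"""Declarative thalamo-cortico-thalamic circuit and its stochastic realization.

The network has a thalamic module (relay cells TCR, local interneurons IN,
reticular nucleus TRN) and a cortical module of four layers (2/3 merged, 4,
5, 6), each with pyramidal (PY), basket (B) and non-basket (NB) populations
plus spiny-stellate (SS) cells in layer 4 — 16 populations, 1090 neurons in
total.  Every projection between two populations carries two attributes: a
connection probability ``P`` (independent Bernoulli wiring per ordered
cell pair) and a weight ``C`` expressed as a percentage of synapses, mapped
to current units by the global ``weight_scale``.

Population sizes and weights
----------------------------
The per-population counts follow the model's stated construction — cortical
proportions from a prior laminar cortical implementation scaled by 10,
thalamic proportions from a prior thalamocortical model scaled by 100 — but
the literal table values are not recoverable from the available text, so
the numbers packaged here are documented reconstructions that honour the
construction rule and the 1090 total.  The same applies to the weight
percentages ``C``; the global ``weight_scale`` and the stimulus weight are
set by the packaged calibration (see :mod:`tctsim.experiments`).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .stimulus import StimulusSpec

THALAMIC_CLASSES = {"TCR", "IN", "TRN"}
CORTICAL_CLASSES = {"PY", "B", "NB", "SS"}
INHIBITORY_CLASSES = {"IN", "TRN", "B", "NB"}
#: firing mode per cell class (excitatory relay/pyramidal/stellate cells are
#: regular spiking; basket and thalamic interneurons fast spiking; non-basket
#: low-threshold spiking; reticular cells tonic bursting)
CLASS_MODE = {
    "TCR": "RS", "PY": "RS", "SS": "RS",
    "B": "FS", "IN": "FS",
    "NB": "LTS",
    "TRN": "TB",
}


class ConfigurationError(ValueError):
    """A circuit configuration violates one of its structural invariants."""


@dataclass
class PopulationSpec:
    """One homogeneous cell population."""

    name: str
    module: str            # "thalamic" | "cortical"
    layer: str             # "L23" | "L4" | "L5" | "L6" | "none"
    cell_class: str        # TCR | IN | TRN | PY | B | NB | SS
    size: int

    @property
    def polarity(self) -> str:
        return "inhibitory" if self.cell_class in INHIBITORY_CLASSES else "excitatory"

    @property
    def mode_label(self) -> str:
        return CLASS_MODE[self.cell_class]

    def validate(self) -> None:
        if self.module not in ("thalamic", "cortical"):
            raise ConfigurationError(f"{self.name}: unknown module {self.module!r}")
        if self.size < 1:
            raise ConfigurationError(f"{self.name}: size must be >= 1")
        if self.cell_class not in THALAMIC_CLASSES | CORTICAL_CLASSES:
            raise ConfigurationError(f"{self.name}: unknown cell class {self.cell_class!r}")
        if self.module == "thalamic":
            if self.cell_class not in THALAMIC_CLASSES or self.layer != "none":
                raise ConfigurationError(
                    f"{self.name}: thalamic populations must be TCR/IN/TRN with layer 'none'"
                )
        else:
            if self.cell_class not in CORTICAL_CLASSES:
                raise ConfigurationError(f"{self.name}: {self.cell_class} is not cortical")
            if self.layer not in ("L23", "L4", "L5", "L6"):
                raise ConfigurationError(f"{self.name}: bad cortical layer {self.layer!r}")
            if self.cell_class == "SS" and self.layer != "L4":
                raise ConfigurationError(f"{self.name}: SS cells exist only in L4")


@dataclass
class ProjectionSpec:
    """A population-to-population pathway with Bernoulli wiring.

    ``delay_law`` is either ``("fixed", value_ms)`` or
    ``("uniform", lo_ms, hi_ms)``; realized delays are rounded to integer
    simulation steps and floored at one step.
    """

    pre: str
    post: str
    probability: float
    weight: float          # C, percent-of-synapses units (non-negative magnitude)
    delay_law: tuple = ("fixed", 1.0)
    enabled: bool = True

    def validate(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ConfigurationError(
                f"{self.pre}->{self.post}: probability {self.probability} outside [0, 1]"
            )
        if self.weight < 0:
            raise ConfigurationError(
                f"{self.pre}->{self.post}: weight magnitude must be non-negative"
            )
        kind = self.delay_law[0]
        if kind == "fixed":
            if self.delay_law[1] <= 0:
                raise ConfigurationError(f"{self.pre}->{self.post}: delay must be positive")
        elif kind == "uniform":
            lo, hi = self.delay_law[1], self.delay_law[2]
            if not 0 < lo <= hi:
                raise ConfigurationError(
                    f"{self.pre}->{self.post}: bad uniform delay range [{lo}, {hi}]"
                )
        else:
            raise ConfigurationError(f"{self.pre}->{self.post}: unknown delay law {kind!r}")


@dataclass
class CircuitConfig:
    """The full declarative circuit: roster, projections, stimulus, scaling."""

    populations: list[PopulationSpec]
    projections: list[ProjectionSpec]
    stimulus: StimulusSpec
    weight_scale: float = 1.0

    # -- structure helpers ------------------------------------------------
    def population(self, name: str) -> PopulationSpec:
        for p in self.populations:
            if p.name == name:
                return p
        raise ConfigurationError(f"unknown population {name!r}")

    def population_names(self) -> list[str]:
        return [p.name for p in self.populations]

    def offsets(self) -> dict[str, tuple[int, int]]:
        """Global index layout: name -> (start, size), populations contiguous."""
        out, start = {}, 0
        for p in self.populations:
            out[p.name] = (start, p.size)
            start += p.size
        return out

    @property
    def total_size(self) -> int:
        return sum(p.size for p in self.populations)

    def validate(self) -> None:
        names = self.population_names()
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate population names")
        for p in self.populations:
            p.validate()
        for proj in self.projections:
            proj.validate()
            for end in (proj.pre, proj.post):
                if end not in names:
                    raise ConfigurationError(
                        f"projection {proj.pre}->{proj.post} references unknown population {end!r}"
                    )
        for target in self.stimulus.targets:
            if target not in names:
                raise ConfigurationError(f"stimulus targets unknown population {target!r}")
        if self.weight_scale < 0:
            raise ConfigurationError("weight_scale must be non-negative")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "weight_scale": self.weight_scale,
            "populations": [asdict(p) for p in self.populations],
            "projections": [
                {**asdict(pr), "delay_law": list(pr.delay_law)} for pr in self.projections
            ],
            "stimulus": asdict(self.stimulus),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CircuitConfig":
        cfg = cls(
            populations=[PopulationSpec(**p) for p in d["populations"]],
            projections=[
                ProjectionSpec(**{**pr, "delay_law": tuple(pr["delay_law"])})
                for pr in d["projections"]
            ],
            stimulus=StimulusSpec(**{
                **d["stimulus"],
                "targets": list(d["stimulus"]["targets"]),
                "delay_law": tuple(d["stimulus"]["delay_law"]),
            }),
            weight_scale=d["weight_scale"],
        )
        cfg.validate()
        return cfg

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "CircuitConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Default circuit
# ---------------------------------------------------------------------------

# Per-population sizes (reconstructed; sum = 1090).  Thalamic counts keep the
# relay : interneuron : reticular proportion of the source thalamocortical
# model scaled by 100; cortical counts keep laminar proportions of the source
# cortical implementation scaled by 10, ~80/20 excitatory/inhibitory.
_DEFAULT_SIZES = {
    "TCR": 100, "IN": 20, "TRN": 40,                      # thalamus: 160
    "PY23": 200, "B23": 30, "NB23": 30,                   # layer 2/3: 260
    "PY4": 80, "SS4": 100, "B4": 25, "NB4": 25,           # layer 4:   230
    "PY5": 120, "B5": 20, "NB5": 20,                      # layer 5:   160
    "PY6": 240, "B6": 20, "NB6": 20,                      # layer 6:   280
}

_LAYER_OF = {"23": "L23", "4": "L4", "5": "L5", "6": "L6"}

#: Connection probability for all intra-thalamic, thalamocortical and
#: corticothalamic pathways.
P_THALAMIC = 0.25
#: Intra-cortical connection probability (reconstructed from the source
#: cortical implementation).
P_CORTICAL = 0.1

_INTER_MODULE_DELAY = ("uniform", 1.0, 10.0)
_INTRA_MODULE_DELAY = ("fixed", 1.0)

# Weight percentages C (reconstructed and then calibrated as a set, see
# module docstring and docs/methods.md).  Keys are (pre, post); values are
# percent-of-synapses magnitudes mapped to current units by weight_scale.
_DEFAULT_WEIGHTS: dict[tuple[str, str], float] = {
    # intra-thalamic: relay->reticular drive and the two inhibitory
    # return paths onto the relay cells
    ("TCR", "TRN"): 35.0,
    ("TRN", "TCR"): 45.0,
    ("IN", "TCR"): 15.0,
    # thalamocortical efferents to layer 4 (spiny stellate and basket)
    ("TCR", "SS4"): 75.0,
    ("TCR", "B4"): 30.0,
    # corticothalamic feedback (layer 6)
    ("PY6", "TCR"): 25.0,
    ("PY6", "IN"): 15.0,
    ("PY6", "TRN"): 30.0,
}

# interlaminar chain: L4 -> L2/3 -> L5 -> L6, closed weakly back onto L4.
# The L4-internal route (SS4 -> PY4) is strong so that layer 4 follows its
# thalamic drive rather than the slower intracortical rhythm.
_FEEDFORWARD_CORTICAL: dict[tuple[str, str], float] = {
    ("SS4", "PY23"): 28.0,
    ("SS4", "PY4"): 65.0,
    ("PY23", "PY5"): 40.0,
    ("PY5", "PY6"): 40.0,
    ("PY6", "SS4"): 5.0,
}

# within-layer weights per (pre-class, post-class)
_WITHIN_LAYER_WEIGHTS: dict[tuple[str, str], float] = {
    ("PY", "PY"): 25.0,
    ("PY", "B"): 30.0,
    ("PY", "NB"): 30.0,
    ("B", "PY"): 40.0,
    ("NB", "PY"): 30.0,
    ("B", "B"): 15.0,
}

# per-projection exceptions to the within-layer template; L4 pyramidal
# recurrence is kept weak for the same reason SS4 -> PY4 is strong
_WITHIN_LAYER_OVERRIDES: dict[tuple[str, str], float] = {
    ("PY4", "PY4"): 5.0,
}


def _default_populations() -> list[PopulationSpec]:
    pops = [
        PopulationSpec("TCR", "thalamic", "none", "TCR", _DEFAULT_SIZES["TCR"]),
        PopulationSpec("IN", "thalamic", "none", "IN", _DEFAULT_SIZES["IN"]),
        PopulationSpec("TRN", "thalamic", "none", "TRN", _DEFAULT_SIZES["TRN"]),
    ]
    for lay in ("23", "4", "5", "6"):
        classes = ["PY", "SS", "B", "NB"] if lay == "4" else ["PY", "B", "NB"]
        for cls_ in classes:
            name = f"{cls_}{lay}"
            pops.append(
                PopulationSpec(name, "cortical", _LAYER_OF[lay], cls_, _DEFAULT_SIZES[name])
            )
    return pops


def _default_projections() -> list[ProjectionSpec]:
    projs: list[ProjectionSpec] = []

    def add(pre, post, weight, probability, delay):
        projs.append(ProjectionSpec(pre, post, probability, weight, delay))

    # intra-thalamic pathways
    for pre, post in (("TCR", "TRN"), ("TRN", "TCR"), ("IN", "TCR")):
        add(pre, post, _DEFAULT_WEIGHTS[(pre, post)], P_THALAMIC, _INTRA_MODULE_DELAY)
    # thalamocortical efferents to L4
    for pre, post in (("TCR", "SS4"), ("TCR", "B4")):
        add(pre, post, _DEFAULT_WEIGHTS[(pre, post)], P_THALAMIC, _INTER_MODULE_DELAY)
    # corticothalamic feedback from L6
    for pre, post in (("PY6", "TCR"), ("PY6", "IN"), ("PY6", "TRN")):
        add(pre, post, _DEFAULT_WEIGHTS[(pre, post)], P_THALAMIC, _INTER_MODULE_DELAY)
    # interlaminar feedforward/feedback chain
    for (pre, post), w in _FEEDFORWARD_CORTICAL.items():
        add(pre, post, w, P_CORTICAL, _INTRA_MODULE_DELAY)
    # within-layer microcircuit
    for lay in ("23", "4", "5", "6"):
        for (pc, qc), w in _WITHIN_LAYER_WEIGHTS.items():
            pre, post = f"{pc}{lay}", f"{qc}{lay}"
            if lay != "4" and ("SS" in (pc, qc)):
                continue
            w = _WITHIN_LAYER_OVERRIDES.get((pre, post), w)
            add(pre, post, w, P_CORTICAL, _INTRA_MODULE_DELAY)
        if lay == "4":
            add("SS4", "B4", 25.0, P_CORTICAL, _INTRA_MODULE_DELAY)
            add("SS4", "NB4", 25.0, P_CORTICAL, _INTRA_MODULE_DELAY)
            add("B4", "SS4", 40.0, P_CORTICAL, _INTRA_MODULE_DELAY)
            add("NB4", "SS4", 30.0, P_CORTICAL, _INTRA_MODULE_DELAY)
    return projs


#: Calibrated global scale mapping weight percentages to current units, and
#: the calibrated stimulus weight (current units per source spike).  Set by
#: the packaged calibration run (tctsim.experiments.calibrate_weight_scale).
DEFAULT_WEIGHT_SCALE = 0.028
DEFAULT_STIMULUS_WEIGHT = 0.4


def build_default_circuit(overrides: dict | None = None) -> CircuitConfig:
    """The packaged default TCT configuration (1090 neurons, 16 populations).

    ``overrides`` is an optional nested dict merged over the default config
    dictionary (same schema as :meth:`CircuitConfig.to_dict`), e.g.
    ``{"weight_scale": 0.05}`` or ``{"stimulus": {"rate": 11.0}}``.
    """
    stim = StimulusSpec(
        rate=25.0,
        n_sources=None,  # one independent source per target neuron
        targets=["TCR", "IN"],
        fan_out="all_to_all",
        weight=DEFAULT_STIMULUS_WEIGHT,
        delay_law=("uniform", 1.0, 10.0),
    )
    cfg = CircuitConfig(
        populations=_default_populations(),
        projections=_default_projections(),
        stimulus=stim,
        weight_scale=DEFAULT_WEIGHT_SCALE,
    )
    if overrides:
        base = cfg.to_dict()
        cfg = CircuitConfig.from_dict(_deep_merge(base, overrides))
    cfg.validate()
    return cfg


def _deep_merge(base: dict, extra: dict) -> dict:
    out = copy.deepcopy(base)
    for key, val in extra.items():
        if key not in out:
            raise ConfigurationError(f"unknown configuration key {key!r}")
        if isinstance(val, dict) and isinstance(out[key], dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


# ---------------------------------------------------------------------------
# Lesion operator
# ---------------------------------------------------------------------------

def lesion_trn(config: CircuitConfig) -> CircuitConfig:
    """Disconnect the reticular nucleus: disable every projection whose
    source or target is TRN.  Populations (and the 1090 total) are kept;
    idempotent."""
    if not any(p.cell_class == "TRN" for p in config.populations):
        raise ConfigurationError("configuration has no TRN population to lesion")
    trn_names = {p.name for p in config.populations if p.cell_class == "TRN"}
    out = copy.deepcopy(config)
    for proj in out.projections:
        if proj.pre in trn_names or proj.post in trn_names:
            proj.enabled = False
    return out


# ---------------------------------------------------------------------------
# Stochastic realization
# ---------------------------------------------------------------------------

@dataclass
class ProjectionEdges:
    """Realized edges of one projection, in global neuron indices."""

    name: str
    pre: np.ndarray          # int32, global presynaptic indices
    post: np.ndarray         # int32, global postsynaptic indices
    weight: np.ndarray       # float64, magnitude in current units
    delay_steps: np.ndarray  # int32, >= 1
    inhibitory: bool

    @property
    def n_edges(self) -> int:
        return int(self.pre.size)


@dataclass
class RealizedConnectivity:
    """All realized recurrent edges of one circuit draw."""

    projections: list[ProjectionEdges] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return sum(p.n_edges for p in self.projections)

    def to_table(self, path) -> None:
        """Export as delimited text: projection, pre, post, weight, delay_steps."""
        with open(path, "w") as fh:
            fh.write("projection\tpre_index\tpost_index\tweight\tdelay_steps\n")
            for proj in self.projections:
                sign = -1.0 if proj.inhibitory else 1.0
                for i in range(proj.n_edges):
                    fh.write(
                        f"{proj.name}\t{proj.pre[i]}\t{proj.post[i]}\t"
                        f"{sign * proj.weight[i]:.6g}\t{proj.delay_steps[i]}\n"
                    )


def draw_delays(delay_law: tuple, n: int, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Realize ``n`` delays (integer steps, floored at one step)."""
    if delay_law[0] == "fixed":
        steps = np.full(n, int(round(delay_law[1] / dt)))
    else:
        lo, hi = delay_law[1], delay_law[2]
        steps = np.rint(rng.uniform(lo, hi, size=n) / dt).astype(int)
    return np.maximum(steps, 1).astype(np.int32)


def realize(config: CircuitConfig, seed, dt: float = 1.0) -> RealizedConnectivity:
    """Draw one Bernoulli realization of every enabled projection.

    Each ordered (pre, post) cell pair connects independently with the
    projection's probability; self-connections are excluded for
    within-population projections.  Weights are ``C * weight_scale`` with
    polarity taken from the presynaptic population; delays are drawn from
    the projection's delay law.  Deterministic per (config, seed).
    """
    config.validate()
    offsets = config.offsets()
    rng = np.random.default_rng(seed)
    realized = RealizedConnectivity()
    for proj in config.projections:
        if not proj.enabled:
            continue
        pre_pop = config.population(proj.pre)
        (pre0, n_pre) = offsets[proj.pre]
        (post0, n_post) = offsets[proj.post]
        mask = rng.random((n_pre, n_post)) < proj.probability
        if proj.pre == proj.post:
            np.fill_diagonal(mask, False)
        pre_loc, post_loc = np.nonzero(mask)
        n = pre_loc.size
        edges = ProjectionEdges(
            name=f"{proj.pre}->{proj.post}",
            pre=(pre_loc + pre0).astype(np.int32),
            post=(post_loc + post0).astype(np.int32),
            weight=np.full(n, proj.weight * config.weight_scale, dtype=float),
            delay_steps=draw_delays(proj.delay_law, n, dt, rng),
            inhibitory=(pre_pop.polarity == "inhibitory"),
        )
        realized.projections.append(edges)
    return realized
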