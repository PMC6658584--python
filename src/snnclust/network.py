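"""Network architecture: layers, connectivity, weights, inhibition, teaching.

The architecture is a three-layer spiking classifier with a self-organizing
middle layer:

* ``IN``    — Poisson input groups, one group of ``K_I`` neurons per pixel,
  firing at ``lambda_max * pixel`` Hz (row-major pixel order).
* ``CN``    — cluster neurons: ``K`` groups of ``K_C`` neurons.  Plastic
  excitatory IN->CN synapses (p=0.75) self-organize into prototype
  detectors; fixed inhibitory CN<->CN synapses between different groups
  implement winner-take-all competition (0.025 uS during the unsupervised
  phase, reduced to 0.015 uS for the supervised phase).
* ``AN``    — association (readout) neurons: one group of 40 per class,
  with plastic excitatory CN->AN synapses (p=0.5) and fixed AN<->AN lateral
  inhibition.
* ``TEACH`` — a 40-neuron Poisson population at ``lambda_teach`` Hz whose
  excitatory/inhibitory routes onto the AN groups are switched between 0
  and 0.5 uS to steer supervised learning toward the correct class.

Inhibitory connections run directly between subpopulations (no interneuron
relays).  All random structure (connectivity masks, initial weights) is
drawn from the generator passed in, so a network is a pure function of
(config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Literal, Optional

import numpy as np

from .models import (
    LIFParams,
    LIFState,
    MapNeuronParams,
    MapNeuronState,
)
from .plasticity import PairingBuffer, STDPRule

__all__ = [
    "GroupSpec",
    "ConnectivitySpec",
    "NetworkConfig",
    "SynapsePopulation",
    "Layer",
    "Network",
    "build_network",
    "init_plastic_weights",
    "set_lateral_inhibition",
    "set_teaching",
    "reset_output_weights",
]

V_SYN_EXC = 0.0     # mV, conductance backend
V_SYN_INH = -92.0


@dataclass(frozen=True)
class GroupSpec:
    layer: Literal["IN", "CN", "AN", "TEACH"]
    group_index: int
    size: int

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError("group size must be positive")


@dataclass(frozen=True)
class ConnectivitySpec:
    src: str
    dst: str
    p_connect: float
    sign: Literal["excitatory", "inhibitory"]
    plastic: bool = False
    fixed_weight: float = 0.0
    exclude_same_group: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_connect <= 1.0:
            raise ValueError("p_connect must lie in [0, 1]")


@dataclass
class NetworkConfig:
    """All architecture and protocol parameters with their defaults.

    ``r_cn`` / ``r_an`` are the LIF-backend input resistances (mV/nA) of the
    cluster and association layers.  Their defaults place the mean synaptic
    drive of a naive cluster neuron under the default stimulus statistics at
    its rheobase, which is the regime the spike-limit / WTA dynamics need
    (see docs/methods.md); they are plain config values and can be
    recalibrated for other image sizes with
    :func:`calibrate_input_resistance`.
    """

    n_classes: int = 5
    image_shape: tuple[int, int] = (16, 16)     # (rows, cols), row-major
    n_cn_groups: int = 10                        # K
    cn_group_size: int = 30                      # K_C (useful range 10-60)
    in_group_size: int = 10                      # K_I
    an_group_size: int = 40
    teach_size: int = 40
    backend: Literal["lif", "map"] = "lif"
    dt: Optional[float] = None                   # ms; 1.0 lif / 0.5 map
    lambda_max: float = 40.0                     # Hz
    lambda_teach: float = 60.0                   # Hz
    p_connect: float = 0.5
    p_connect_in_cn: float = 0.75
    inhibition_phase1: float = 0.025             # uS (nA on the LIF backend)
    inhibition_phase2: float = 0.015
    an_inhibition: float = 0.025
    teach_weight: float = 0.5
    spike_limit: int = 20
    silence_ms: float = 50.0
    test_duration_ms: float = 50.0
    presentation_timeout_ms: float = 2000.0
    tau_exc: Optional[float] = None              # ms; 2.0 both backends
    tau_inh: Optional[float] = None              # ms; 10.0 cond / 30.0 curr
    tau_inh_an: Optional[float] = None           # ms; 10.0 (readout WTA)
    r_cn: float = 0.15                           # mV/nA, LIF backend
    r_an: float = 30.0
    stdp: STDPRule = field(default_factory=STDPRule)
    plastic_in_cn: bool = True
    plastic_cn_an: bool = True
    # Plasticity is frozen during the test stage by default: with binary
    # flip noise, continued learning over a long stratified test run
    # potentiates noise pixels on every presentation and steadily converts
    # class specialists into generalists (measured ~3x accuracy loss).
    # Set True for the always-learning regime.
    plasticity_during_test: bool = False

    def __post_init__(self) -> None:
        if self.lambda_max < 0 or self.lambda_teach < 0:
            raise ValueError("rates must be non-negative")
        if self.n_classes < 1:
            raise ValueError("need at least one class")
        if len(self.image_shape) != 2 or min(self.image_shape) < 1:
            raise ValueError("image_shape must be a (rows, cols) pair")

    @property
    def dt_ms(self) -> float:
        if self.dt is not None:
            return self.dt
        return 1.0 if self.backend == "lif" else 0.5

    @property
    def n_pixels(self) -> int:
        return self.image_shape[0] * self.image_shape[1]

    @property
    def tau_exc_ms(self) -> float:
        return self.tau_exc if self.tau_exc is not None else 2.0

    @property
    def tau_inh_ms(self) -> float:
        if self.tau_inh is not None:
            return self.tau_inh
        return 30.0 if self.backend == "lif" else 10.0

    @property
    def tau_inh_an_ms(self) -> float:
        """Readout lateral inhibition decays fast: the AN competition must
        reset between 100 ms decision windows, or the previous winner's
        inhibitory tail locks the choice across presentations."""
        return self.tau_inh_an if self.tau_inh_an is not None else 15.0

    @property
    def total_neurons(self) -> int:
        return (
            self.n_pixels * self.in_group_size
            + self.n_cn_groups * self.cn_group_size
            + self.n_classes * self.an_group_size
            + self.teach_size
        )

    def to_file(self, path) -> None:
        d = asdict(self)
        d["stdp"] = asdict(self.stdp)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_file(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["stdp"] = STDPRule(**d.get("stdp", {}))
        d["image_shape"] = tuple(d["image_shape"])
        return cls(**d)


def calibrate_input_resistance(
    cfg: NetworkConfig, active_pixels: int, margin: float = 1.0
) -> float:
    """CN input resistance placing the mean naive drive at ``margin`` x rheobase.

    The steady synaptic current of a naive cluster neuron under a stimulus
    with ``active_pixels`` fully-on pixels is
    ``active_pixels * K_I * p_c * (lambda_max*dt) * mean_w * tau_exc / dt``;
    the rheobase drive is ``V_thresh - V_rest``.
    """
    mean_w = 0.75 * cfg.stdp.g_max          # mean of U[g_max/2, g_max]
    dt = cfg.dt_ms
    per_step = active_pixels * cfg.in_group_size * cfg.p_connect_in_cn * (
        cfg.lambda_max * dt * 1e-3
    ) * mean_w
    steady = per_step * cfg.tau_exc_ms / dt
    lif = LIFParams()
    return margin * (lif.V_thresh - lif.V_rest) / steady


class Layer:
    """One population of identical neurons, divided into groups by index."""

    def __init__(self, name, kind, n_groups, group_size, params=None):
        self.name = name
        self.kind = kind                    # "poisson" | "lif" | "map"
        self.n_groups = n_groups
        self.group_size = group_size
        self.n = n_groups * group_size
        self.params = params
        self.rates = np.zeros(self.n) if kind == "poisson" else None
        self.reset_state()

    def reset_state(self) -> None:
        if self.kind == "lif":
            self.state = LIFState.at_rest(self.n, self.params)
        elif self.kind == "map":
            self.state = MapNeuronState.zeros(self.n)
        else:
            self.state = None

    def group_slice(self, g: int) -> slice:
        if not 0 <= g < self.n_groups:
            raise IndexError(f"group {g} out of range for layer {self.name}")
        return slice(g * self.group_size, (g + 1) * self.group_size)

    def group_of(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(idx) // self.group_size


class SynapsePopulation:
    """Weight matrix + connectivity mask + synapse model between two layers."""

    def __init__(self, name, src: Layer, dst: Layer, spec: ConnectivitySpec,
                 backend: str, tau_syn: float, rule: STDPRule | None, dt: float):
        self.name = name
        self.src = src
        self.dst = dst
        self.spec = spec
        self.sign = +1 if spec.sign == "excitatory" else -1
        self.backend = backend
        self.tau_syn = tau_syn
        self.V_syn = V_SYN_EXC if self.sign > 0 else V_SYN_INH
        self.plastic = spec.plastic
        self.rule = rule if spec.plastic else None
        self.W = np.zeros((src.n, dst.n))
        self.mask = np.zeros((src.n, dst.n), dtype=bool)
        self.pairing = (
            PairingBuffer(src.n, dst.n, rule, dt) if spec.plastic else None
        )
        self.reset_state()

    def reset_state(self) -> None:
        if self.backend == "map":
            self.S = np.zeros(self.src.n)       # conductance-synapse activation
        else:
            self.I = np.zeros(self.dst.n)       # summed exponential current

    def build_mask(self, rng: np.random.Generator) -> None:
        m = rng.random((self.src.n, self.dst.n)) < self.spec.p_connect
        if self.spec.exclude_same_group:
            src_groups = np.repeat(np.arange(self.src.n_groups), self.src.group_size)
            dst_groups = np.repeat(np.arange(self.dst.n_groups), self.dst.group_size)
            m &= src_groups[:, None] != dst_groups[None, :]
        self.mask = m
        if not self.plastic:
            self.set_fixed_weight(self.spec.fixed_weight)

    def set_fixed_weight(self, w: float) -> None:
        self.W = np.where(self.mask, w, 0.0)


class Network:
    """Container for layers and synapse populations plus simulation config."""

    def __init__(self, cfg: NetworkConfig):
        self.cfg = cfg
        self.dt = cfg.dt_ms
        self.layers: dict[str, Layer] = {}
        self.pops: dict[str, SynapsePopulation] = {}
        self.teaching_class: Optional[int] = None
        self.plasticity_enabled = True

    @property
    def plastic_pops(self):
        return [p for p in self.pops.values() if p.plastic]

    def reset_dynamic_state(self) -> None:
        """Reset membranes, synapse currents and pairing buffers (not weights)."""
        for layer in self.layers.values():
            layer.reset_state()
        for pop in self.pops.values():
            pop.reset_state()
            if pop.pairing is not None:
                pop.pairing.reset()

    def save_weights(self, path) -> None:
        np.savez_compressed(
            path, **{name: pop.W for name, pop in self.pops.items()}
        )


def init_plastic_weights(pop: SynapsePopulation, rng: np.random.Generator) -> SynapsePopulation:
    """Draw connected weights from U[g_max/2, g_max]; masked-out entries stay 0."""
    if not pop.plastic:
        raise ValueError(f"population {pop.name} is not plastic")
    g_max = pop.rule.g_max
    w = rng.uniform(g_max / 2.0, g_max, size=pop.W.shape)
    pop.W = np.where(pop.mask, w, 0.0)
    return pop


def build_network(cfg: NetworkConfig, rng: np.random.Generator) -> Network:
    """Construct the full architecture from the config.

    Connectivity masks and initial plastic weights are drawn from ``rng``;
    teaching routes start switched off (weight 0) and both lateral
    inhibition populations start at their phase-1 values.
    """
    net = Network(cfg)
    dt = cfg.dt_ms
    backend = cfg.backend

    if backend == "lif":
        cn_params = LIFParams(R=cfg.r_cn, dt=dt)
        an_params = LIFParams(R=cfg.r_an, dt=dt)
        kind = "lif"
    elif backend == "map":
        cn_params = MapNeuronParams(dt=dt)
        an_params = MapNeuronParams(dt=dt)
        kind = "map"
    else:
        raise ValueError(f"unknown backend {backend!r}")

    net.layers["IN"] = Layer("IN", "poisson", cfg.n_pixels, cfg.in_group_size)
    cn = Layer("CN", kind, cfg.n_cn_groups, cfg.cn_group_size, cn_params)
    an = Layer("AN", kind, cfg.n_classes, cfg.an_group_size, an_params)
    net.layers["CN"] = cn
    net.layers["AN"] = an
    net.layers["TEACH"] = Layer("TEACH", "poisson", 1, cfg.teach_size)

    def add(name, src, dst, spec, tau, rule=None):
        pop = SynapsePopulation(name, net.layers[src], net.layers[dst], spec,
                                backend, tau, rule, dt)
        pop.build_mask(rng)
        net.pops[name] = pop
        return pop

    rule = cfg.stdp
    p_in_cn = add(
        "IN->CN", "IN", "CN",
        ConnectivitySpec("IN", "CN", cfg.p_connect_in_cn, "excitatory",
                         plastic=cfg.plastic_in_cn),
        cfg.tau_exc_ms, rule if cfg.plastic_in_cn else None,
    )
    if not cfg.plastic_in_cn:
        p_in_cn.set_fixed_weight(0.75 * rule.g_max)
    add(
        "CN->CN", "CN", "CN",
        ConnectivitySpec("CN", "CN", cfg.p_connect, "inhibitory",
                         fixed_weight=cfg.inhibition_phase1, exclude_same_group=True),
        cfg.tau_inh_ms,
    )
    p_cn_an = add(
        "CN->AN", "CN", "AN",
        ConnectivitySpec("CN", "AN", cfg.p_connect, "excitatory",
                         plastic=cfg.plastic_cn_an),
        cfg.tau_exc_ms, rule if cfg.plastic_cn_an else None,
    )
    if not cfg.plastic_cn_an:
        p_cn_an.set_fixed_weight(0.75 * rule.g_max)
    add(
        "AN->AN", "AN", "AN",
        ConnectivitySpec("AN", "AN", cfg.p_connect, "inhibitory",
                         fixed_weight=cfg.an_inhibition, exclude_same_group=True),
        cfg.tau_inh_an_ms,
    )
    add(
        "TEACH->AN:exc", "TEACH", "AN",
        ConnectivitySpec("TEACH", "AN", cfg.p_connect, "excitatory"),
        cfg.tau_exc_ms,
    )
    # The inhibitory teaching route uses the fast (excitatory) time constant:
    # teaching is switched per presentation, and a slow inhibitory tail would
    # suppress a group well into the next presentation it is supposed to learn.
    add(
        "TEACH->AN:inh", "TEACH", "AN",
        ConnectivitySpec("TEACH", "AN", cfg.p_connect, "inhibitory"),
        cfg.tau_exc_ms,
    )
    # Teaching starts off.
    net.pops["TEACH->AN:exc"].set_fixed_weight(0.0)
    net.pops["TEACH->AN:inh"].set_fixed_weight(0.0)

    for pop in net.plastic_pops:
        init_plastic_weights(pop, rng)

    net.layers["TEACH"].rates[:] = cfg.lambda_teach
    return net


def set_lateral_inhibition(net: Network, layer: str, weight: float) -> Network:
    """Set every existing lateral inhibitory weight in ``layer`` (mask unchanged)."""
    name = f"{layer}->{layer}"
    if name not in net.pops:
        raise ValueError(f"layer {layer!r} has no lateral inhibition")
    net.pops[name].set_fixed_weight(weight)
    return net


def set_teaching(net: Network, class_label: Optional[int]) -> Network:
    """Route the teaching population: excite AN(class), inhibit the others.

    ``class_label=None`` switches all teaching weights off.  The same
    switching magnitude (``teach_weight``) is used for the excitatory and
    inhibitory routes.
    """
    exc = net.pops["TEACH->AN:exc"]
    inh = net.pops["TEACH->AN:inh"]
    if class_label is None:
        exc.set_fixed_weight(0.0)
        inh.set_fixed_weight(0.0)
        net.teaching_class = None
        return net
    an = net.layers["AN"]
    if not 0 <= class_label < an.n_groups:
        raise ValueError(f"unknown class {class_label}")
    w = net.cfg.teach_weight
    sl = an.group_slice(class_label)
    exc.W[:] = 0.0
    exc.W[:, sl] = np.where(exc.mask[:, sl], w, 0.0)
    inh.W = np.where(inh.mask, w, 0.0)
    inh.W[:, sl] = 0.0
    net.teaching_class = class_label
    return net


def reset_output_weights(net: Network, rng: np.random.Generator) -> Network:
    """Re-draw the CN->AN weights (mask unchanged); used at the epoch-2 start."""
    pop = net.pops["CN->AN"]
    if not pop.plastic:
        raise ValueError("CN->AN population is not plastic")
    init_plastic_weights(pop, rng)
    if pop.pairing is not None:
        pop.pairing.reset()
    return net
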