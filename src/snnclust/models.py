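"""Pointwise neuron and synapse dynamics.

Two backends are supported:

* ``map``  — Rulkov-style two-dimensional map neurons with conductance-based
  synapses, stepped at 0.5 ms.  The map is its own discrete-time update; no
  integration scheme is involved.
* ``lif``  — leaky integrate-and-fire neurons with exponential current-based
  synapses, Euler-integrated at 1 ms.

All state-transition functions are pure: they take state arrays plus a
parameter object and return the new state.  Vectorised over neurons.

Sign convention
---------------
Synaptic current ``I_syn`` is *positive when depolarizing* everywhere in this
package.  For conductance synapses the per-afferent contribution is
``-g * S * (V_post - V_syn)`` (so an excitatory synapse, V_syn = 0 mV,
depolarizes a neuron resting below 0 mV), and the map-neuron update uses
``+beta * I_syn * (1 - m)`` in the denominator, which composes to the same
dynamics as feeding the raw ``g S (V - V_syn)`` into the textbook form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MapNeuronParams",
    "MapNeuronState",
    "LIFParams",
    "LIFState",
    "PoissonSourceParams",
    "CondSynapseParams",
    "CondSynapseState",
    "CurrSynapseParams",
    "CurrSynapseState",
    "map_step",
    "lif_step",
    "poisson_spikes",
    "cond_synapse_step",
    "cond_current",
    "curr_synapse_step",
]


@dataclass(frozen=True)
class MapNeuronParams:
    """Parameters of the discrete-time map neuron.

    ``V_spike`` scales the spike amplitude: the spike peak is
    ``V_spike * (alpha + y)`` and the post-spike trough is ``-V_spike``,
    giving a peak-to-trough amplitude of ``V_spike * (1 + alpha + y)``
    (91.92 mV with the defaults).  ``m`` implements spike-rate adaptation.
    """

    V_spike: float = 60.0       # mV
    alpha: float = 3.0
    y: float = -2.468
    beta: float = 0.0165        # mV/nA
    a: float = 1e-4             # 1/ms
    b: float = 0.02
    dt: float = 0.5             # ms

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.V_spike <= 0:
            raise ValueError("V_spike must be positive")
        if not 0.0 <= self.b <= 1.0:
            raise ValueError("b must lie in [0, 1]")
        if self.a * self.dt >= 1.0:
            raise ValueError("a*dt must be < 1 for the adaptation decay")

    @property
    def V_peak(self) -> float:
        """Spike peak, ``V_spike * (alpha + y)``."""
        return self.V_spike * (self.alpha + self.y)

    @property
    def amplitude(self) -> float:
        """Peak-to-trough spike amplitude, ``V_peak - (-V_spike)``."""
        return self.V_peak + self.V_spike


@dataclass
class MapNeuronState:
    """Membrane potential, its previous value, and adaptation ``m`` in [0,1]."""

    V: np.ndarray
    V_prev: np.ndarray
    m: np.ndarray

    @classmethod
    def zeros(cls, n: int, V0: float = -60.0) -> "MapNeuronState":
        V = np.full(n, float(V0))
        # V_prev is initialised to V at t=0 (needed by the rebound branch).
        return cls(V=V.copy(), V_prev=V.copy(), m=np.zeros(n))


def map_step(
    state: MapNeuronState, I_syn: np.ndarray | float, p: MapNeuronParams
) -> tuple[MapNeuronState, np.ndarray]:
    """Advance map neurons by one timestep.

    Exactly one of three branches applies per neuron:

    1. ``V(t) <= 0``: fast subsystem update
       ``V' = V_spike^2 * alpha / (V_spike*(1+y) - V + beta*I_syn*(1-m))``.
    2. ``0 < V(t) <= V_peak`` and ``V(t-dt) <= 0``: the upswing is capped at
       the peak ``V_peak`` — this is the spike.
    3. otherwise: reset to the trough ``-V_spike``.

    Adaptation decays every step (``m' = (1 - a*dt) m``) and jumps by
    ``b*(1-m)`` on the spiking neurons.  Returns ``(new_state, spiked)``.
    """
    V = state.V
    I = np.broadcast_to(np.asarray(I_syn, dtype=float), V.shape)
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(I))):
        raise FloatingPointError("non-finite membrane potential or synaptic current")

    peak = p.V_peak
    b1 = V <= 0.0
    b2 = (~b1) & (V <= peak) & (state.V_prev <= 0.0)

    denom = p.V_spike * (1.0 + p.y) - V + p.beta * I * (1.0 - state.m)
    with np.errstate(divide="ignore"):
        fast = p.V_spike ** 2 * p.alpha / denom
    V_new = np.where(b1, fast, np.where(b2, peak, -p.V_spike))

    m_new = (1.0 - p.a * p.dt) * state.m
    spiked = b2
    m_new = np.where(spiked, m_new + p.b * (1.0 - m_new), m_new)
    return MapNeuronState(V=V_new, V_prev=V.copy(), m=m_new), spiked


@dataclass(frozen=True)
class LIFParams:
    """Leaky integrate-and-fire parameters.

    Only the product ``I_syn * R`` enters the membrane equation; ``R``
    (mV/nA) is therefore the free gain of the backend and is configured
    per layer by :class:`snnclust.network.NetworkConfig`.
    """

    tau_m: float = 20.0         # ms
    V_rest: float = -66.0       # mV
    V_thresh: float = -65.0     # mV
    V_reset: float = -70.0      # mV
    t_ref: float = 2.0          # ms
    R: float = 1.0              # mV/nA
    dt: float = 1.0             # ms

    def __post_init__(self) -> None:
        if self.V_reset >= self.V_thresh:
            raise ValueError("V_reset must be below V_thresh")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")
        if self.t_ref < 0:
            raise ValueError("t_ref must be non-negative")


@dataclass
class LIFState:
    V: np.ndarray
    ref_remaining: np.ndarray   # ms

    @classmethod
    def at_rest(cls, n: int, p: LIFParams) -> "LIFState":
        return cls(V=np.full(n, p.V_rest), ref_remaining=np.zeros(n))


def lif_step(
    state: LIFState, I_syn: np.ndarray | float, p: LIFParams
) -> tuple[LIFState, np.ndarray]:
    """Euler step of the LIF membrane equation.

    Refractory neurons are clamped at ``V_reset`` while their timer runs
    down; all others integrate ``dV/dt = (V_rest - V + I_syn R)/tau_m``.
    A spike is emitted when ``V >= V_thresh`` (inclusive), after which the
    neuron is reset and held refractory for ``t_ref``.
    """
    V = state.V
    I = np.broadcast_to(np.asarray(I_syn, dtype=float), V.shape)
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(I))):
        raise FloatingPointError("non-finite membrane potential or synaptic current")

    refractory = state.ref_remaining > 0.0
    dV = (p.dt / p.tau_m) * (p.V_rest - V + I * p.R)
    V_new = np.where(refractory, p.V_reset, V + dV)
    ref_new = np.where(refractory, state.ref_remaining - p.dt, 0.0)
    ref_new = np.maximum(ref_new, 0.0)

    spiked = (~refractory) & (V_new >= p.V_thresh)
    V_new = np.where(spiked, p.V_reset, V_new)
    ref_new = np.where(spiked, p.t_ref, ref_new)
    return LIFState(V=V_new, ref_remaining=ref_new), spiked


def lif_rate_closed_form(IR: float, p: LIFParams) -> float:
    """Analytic steady firing rate (Hz) for constant suprathreshold drive.

    ``rate = 1000 / (t_ref + tau_m * ln((V_rest+IR-V_reset)/(V_rest+IR-V_thresh)))``.
    Used as an independent oracle in tests; returns 0 for subthreshold drive.
    """
    top = p.V_rest + IR - p.V_reset
    bot = p.V_rest + IR - p.V_thresh
    if bot <= 0:
        return 0.0
    return 1000.0 / (p.t_ref + p.tau_m * np.log(top / bot))


@dataclass(frozen=True)
class PoissonSourceParams:
    """Poisson source approximated as a Bernoulli process, ``p = rate * dt``."""

    rate: float                 # Hz
    dt: float                   # ms

    @property
    def p_spike(self) -> float:
        return self.rate * self.dt * 1e-3

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_spike <= 1.0:
            raise ValueError("rate*dt must lie in [0, 1]")


def poisson_spikes(
    rates: np.ndarray, dt: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw one step of Bernoulli spikes with ``p_i = rate_i * dt`` (dt in s).

    Raises if any rate is negative or any ``rate*dt`` exceeds 1 (the rate is
    then too high to be represented at this timestep).
    """
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    p = rates * dt * 1e-3
    if np.any(p > 1.0):
        raise ValueError("rate*dt > 1: rate too high for the timestep")
    return rng.random(rates.shape) < p


@dataclass(frozen=True)
class CondSynapseParams:
    """Conductance synapse: ``I = g S (V - V_syn)`` with decaying activation S.

    ``tau_syn`` is configurable (defaults: 2 ms excitatory, 10 ms inhibitory,
    set by the network builder); ``V_syn`` is 0 mV excitatory, -92 mV
    inhibitory.
    """

    g: float                    # uS, per-connection maximal conductance
    V_syn: float = 0.0          # mV
    tau_syn: float = 2.0        # ms

    def __post_init__(self) -> None:
        if self.g < 0:
            raise ValueError("g must be non-negative")
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")


@dataclass
class CondSynapseState:
    """Activation per presynaptic source (shared by all its efferents)."""

    S: np.ndarray

    @classmethod
    def zeros(cls, n_pre: int) -> "CondSynapseState":
        return cls(S=np.zeros(n_pre))


def cond_synapse_step(
    state: CondSynapseState, pre_spiked: np.ndarray, dt: float, tau_syn: float
) -> CondSynapseState:
    """``S <- S + 1`` for spiking sources, else geometric decay by 1 - dt/tau."""
    if dt >= tau_syn:
        raise ValueError("dt must be smaller than tau_syn")
    S = np.where(pre_spiked, state.S + 1.0, (1.0 - dt / tau_syn) * state.S)
    return CondSynapseState(S=S)


def cond_current(
    S: np.ndarray, g: np.ndarray | float, V_post: np.ndarray | float, V_syn: float
) -> np.ndarray:
    """Depolarizing-positive synaptic current, ``-g S (V_post - V_syn)``.

    ``g`` may be a scalar, a vector over afferents, or a weight matrix
    (n_pre, n_post); in the matrix case the afferents are summed.
    """
    g = np.asarray(g, dtype=float)
    S = np.asarray(S, dtype=float)
    if g.ndim == 2:
        drive = g.T @ S                       # (n_post,)
    else:
        drive = np.sum(g * S)
    return -(np.asarray(V_post, dtype=float) - V_syn) * drive


@dataclass(frozen=True)
class CurrSynapseParams:
    """Exponential current synapse: ``dI/dt = -I/tau + g_syn * delta(t_spk)``."""

    g_syn: float                # nA per presynaptic spike
    tau_syn: float              # ms

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")


@dataclass
class CurrSynapseState:
    """Summed synaptic current per postsynaptic neuron."""

    I: np.ndarray

    @classmethod
    def zeros(cls, n_post: int) -> "CurrSynapseState":
        return cls(I=np.zeros(n_post))


def curr_synapse_step(
    state: CurrSynapseState,
    spike_weights: np.ndarray | float,
    dt: float,
    tau_syn: float,
) -> CurrSynapseState:
    """Euler step: decay by ``1 - dt/tau`` then add this step's arriving weight sum."""
    if dt >= tau_syn:
        raise ValueError("dt must be smaller than tau_syn")
    I = state.I * (1.0 - dt / tau_syn) + spike_weights
    return CurrSynapseState(I=I)
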