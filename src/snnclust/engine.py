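"""Clocked simulation loop.

Per-step ordering (one global timestep):

1. draw Poisson input spikes (IN and TEACH layers);
2. decay synapse states and add arrivals from the *previous* step's spikes
   (synaptic transmission delay is one timestep);
3. update neuron states with the summed synaptic input;
4. detect spikes;
5. apply STDP to plastic populations (STDP sees the current step's spikes);
6. clip weights;
7. append to the spike raster.

The full state trajectory is a pure function of (config, seed): the engine
draws all randomness from the single generator it is given.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import lif_step, map_step, poisson_spikes
from .plasticity import on_spike_update
from .network import Network

__all__ = ["SimClock", "SpikeRaster", "Engine", "count_spikes"]

LAYER_ORDER = ("IN", "CN", "AN", "TEACH")


@dataclass
class SimClock:
    dt: float
    step_index: int = 0

    @property
    def t(self) -> float:
        return self.step_index * self.dt


class SpikeRaster:
    """Record of (time, neuron id, layer) spike events, append-only."""

    def __init__(self, layer_groups: dict[str, tuple[int, int]]):
        # layer -> (n_groups, group_size)
        self.layer_groups = dict(layer_groups)
        self._times: dict[str, list] = {k: [] for k in layer_groups}
        self._ids: dict[str, list] = {k: [] for k in layer_groups}

    def append(self, layer: str, t: float, ids: np.ndarray) -> None:
        if len(ids):
            self._times[layer].append((t, len(ids)))
            self._ids[layer].append(ids)

    def events(self, layer: str) -> tuple[np.ndarray, np.ndarray]:
        """All (times, neuron ids) for a layer, time-ordered."""
        if layer not in self._ids:
            raise KeyError(f"unknown layer {layer!r}")
        if not self._ids[layer]:
            return np.empty(0), np.empty(0, dtype=int)
        times = np.concatenate([np.full(n, t) for t, n in self._times[layer]])
        ids = np.concatenate(self._ids[layer])
        return times, ids

    def n_spikes(self, layer: str) -> int:
        return sum(n for _, n in self._times[layer])

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        offset = 0
        for layer in LAYER_ORDER:
            if layer not in self.layer_groups:
                continue
            n_groups, gsize = self.layer_groups[layer]
            t, ids = self.events(layer)
            frames.append(pd.DataFrame({
                "time_ms": t,
                "neuron_id": ids + offset,
                "layer": layer,
                "group": ids // gsize,
            }))
            offset += n_groups * gsize
        df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
            columns=["time_ms", "neuron_id", "layer", "group"])
        return df.sort_values(["time_ms", "neuron_id"], kind="stable").reset_index(drop=True)

    def save_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def save_npz(self, path) -> None:
        arrays = {}
        for layer in self._ids:
            t, ids = self.events(layer)
            arrays[f"{layer}_time_ms"] = t
            arrays[f"{layer}_id"] = ids
        np.savez_compressed(path, **arrays)


def count_spikes(
    raster: SpikeRaster,
    layer_tag: str,
    group_id: int | None = None,
    window: tuple[float, float] | None = None,
) -> int:
    """Count raster spikes for a layer/group in a half-open window [t0, t1)."""
    if layer_tag not in raster.layer_groups:
        raise KeyError(f"unknown layer {layer_tag!r}")
    t, ids = raster.events(layer_tag)
    keep = np.ones(len(t), dtype=bool)
    if window is not None:
        t0, t1 = window
        if t0 > t1:
            raise ValueError("window must have t0 <= t1")
        keep &= (t >= t0) & (t < t1)
    if group_id is not None:
        n_groups, gsize = raster.layer_groups[layer_tag]
        if not 0 <= group_id < n_groups:
            raise KeyError(f"unknown group {group_id} in layer {layer_tag}")
        keep &= (ids // gsize) == group_id
    return int(np.count_nonzero(keep))


class Engine:
    """Steps a built :class:`~snnclust.network.Network` through time."""

    def __init__(
        self,
        net: Network,
        rng: np.random.Generator,
        record_layers: tuple[str, ...] = ("IN", "CN", "AN"),
    ):
        self.net = net
        self.rng = rng
        self.clock = SimClock(dt=net.dt)
        self.record_layers = record_layers
        self.raster = SpikeRaster({
            name: (layer.n_groups, layer.group_size)
            for name, layer in net.layers.items() if name in record_layers
        })
        self._prev_spikes = {
            name: np.zeros(layer.n, dtype=bool) for name, layer in net.layers.items()
        }
        self.group_counts = {
            name: np.zeros(layer.n_groups, dtype=int) for name, layer in net.layers.items()
        }

    # ------------------------------------------------------------------

    def set_input_rates(self, rates: np.ndarray | float) -> None:
        layer = self.net.layers["IN"]
        layer.rates[:] = rates

    def reset_pairing_buffers(self) -> None:
        for pop in self.net.plastic_pops:
            if pop.pairing is not None:
                pop.pairing.reset()

    # ------------------------------------------------------------------

    def step(self) -> dict[str, np.ndarray]:
        net = self.net
        dt = net.dt
        t = self.clock.t
        spikes: dict[str, np.ndarray] = {}

        # (1) input draws
        for name, layer in net.layers.items():
            if layer.kind == "poisson":
                spikes[name] = poisson_spikes(layer.rates, dt, self.rng)

        # (2) synapse decay + arrivals from last step
        for pop in net.pops.values():
            prev = self._prev_spikes[pop.src.name]
            if pop.backend == "map":
                pop.S *= 1.0 - dt / pop.tau_syn
                pop.S[prev] += 1.0
            else:
                pop.I *= 1.0 - dt / pop.tau_syn
                if prev.any():
                    pop.I += pop.W[prev, :].sum(axis=0)

        # (3)-(4) neuron updates and spike detection
        try:
            for name, layer in net.layers.items():
                if layer.kind == "poisson":
                    continue
                I_syn = np.zeros(layer.n)
                for pop in net.pops.values():
                    if pop.dst is not layer:
                        continue
                    if pop.backend == "map":
                        drive = pop.W.T @ pop.S
                        I_syn += -(layer.state.V - pop.V_syn) * drive
                    else:
                        I_syn += pop.sign * pop.I
                if layer.kind == "lif":
                    layer.state, spk = lif_step(layer.state, I_syn, layer.params)
                else:
                    layer.state, spk = map_step(layer.state, I_syn, layer.params)
                spikes[name] = spk
        except FloatingPointError as err:
            raise RuntimeError(
                f"non-finite state at step {self.clock.step_index} (t={t} ms): {err}"
            ) from err

        # (5)-(6) plasticity (buffers advance every step regardless)
        for pop in net.plastic_pops:
            pre = spikes[pop.src.name]
            post = spikes[pop.dst.name]
            if net.plasticity_enabled:
                on_spike_update(pop, pre, post, pop.pairing)
            else:
                pop.pairing.advance(pre, post)
                if pop.rule.pairing == "nearest":
                    pop.pairing.commit_posts()

        # (7) record
        for name in self.record_layers:
            if name in spikes:
                ids = np.flatnonzero(spikes[name])
                self.raster.append(name, t, ids)
        for name, spk in spikes.items():
            layer = net.layers[name]
            if spk.any():
                np.add.at(
                    self.group_counts[name],
                    np.flatnonzero(spk) // layer.group_size, 1,
                )

        self._prev_spikes = spikes
        self.clock.step_index += 1
        return spikes

    # ------------------------------------------------------------------

    def run_for(
        self,
        duration: float | None = None,
        spike_limit: int | None = None,
        limit_layer: str = "CN",
        timeout_ms: float | None = None,
    ) -> dict:
        """Run until a fixed duration elapses or a layer's spike count hits a limit.

        Exactly one of ``duration`` / ``spike_limit`` must be given.  A
        spike-limited run that exceeds ``timeout_ms`` of simulated time ends
        with ``timed_out=True`` (a warning condition, not an error).  Returns
        presentation bookkeeping: start/stop times, per-group spike counts of
        the limit layer and the total.
        """
        if (duration is None) == (spike_limit is None):
            raise ValueError("specify exactly one of duration or spike_limit")
        t_start = self.clock.t
        start_counts = self.group_counts[limit_layer].copy()
        timed_out = False

        if duration is not None:
            n_steps = int(round(duration / self.net.dt))
            for _ in range(n_steps):
                self.step()
        else:
            if timeout_ms is None:
                timeout_ms = self.net.cfg.presentation_timeout_ms
            target = int(spike_limit)
            count = 0
            while count < target:
                spk = self.step()
                count += int(np.count_nonzero(spk[limit_layer]))
                if self.clock.t - t_start >= timeout_ms:
                    timed_out = count < target
                    break

        group_spikes = self.group_counts[limit_layer] - start_counts
        return {
            "t_start": t_start,
            "t_stop": self.clock.t,
            "duration_ms": self.clock.t - t_start,
            "timed_out": timed_out,
            "group_spikes": group_spikes,
            "n_spikes": int(group_spikes.sum()),
        }
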