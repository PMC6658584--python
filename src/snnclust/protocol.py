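"""Input encoding, the two-epoch training regime, and the test regime.

Training presents the stream twice.  Epoch 1 is unsupervised: strong CN
lateral inhibition (phase 1), teaching off; each input stays on until the
CN layer has emitted ``spike_limit`` spikes (novel inputs, which respond
slowly, are therefore presented longer), followed by a 50 ms silence during
which all input rates are zero.  Epoch 2 is supervised: CN inhibition is
reduced to its phase-2 value, the CN->AN weights are re-initialized, and
the teaching population is routed to the correct AN group for every sample.

Testing uses fixed 50 ms presentations plus 50 ms silence; the decision is
the AN group with the most spikes in the half-open 100 ms window from
presentation onset to the end of the silence (the window includes the
silence because of the IN->AN propagation delay).  Ties go to the lowest
group index and are flagged; a window with zero AN spikes is recorded as
``predicted = -1`` (no decision) and scored as incorrect.

Spike-pairing buffers are cleared at every presentation onset so that no
STDP pairing spans two input patterns.  Plasticity itself stays on
throughout training and testing unless configured off.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .engine import Engine
from .network import Network, reset_output_weights, set_lateral_inhibition, set_teaching

__all__ = [
    "StimulusStream",
    "VREncoderSpec",
    "TrainingPlan",
    "TrainingLog",
    "encode_pixels",
    "encode_vr",
    "train",
    "test",
    "n_train_per_class",
]

logger = logging.getLogger(__name__)


@dataclass
class StimulusStream:
    """Ordered labeled samples (flattened, values in [0, 1])."""

    samples: np.ndarray                 # (N, d)
    labels: np.ndarray                  # (N,)
    sample_ids: Optional[np.ndarray] = None
    image_shape: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.samples.ndim != 2:
            raise ValueError("samples must be (N, d)")
        if len(self.samples) != len(self.labels):
            raise ValueError("samples/labels length mismatch")
        if self.samples.size and (self.samples.min() < 0 or self.samples.max() > 1):
            raise ValueError("sample values must lie in [0, 1]")
        if self.sample_ids is None:
            self.sample_ids = np.arange(len(self.samples))

    def __len__(self) -> int:
        return len(self.samples)


@dataclass(frozen=True)
class VREncoderSpec:
    """Virtual-receptor (distance-based) rate encoder, the legacy front end.

    Channel ``i`` fires at ``lambda_max * (1 - (d(s,p_i) - d_min)/(d_max - d_min))``
    where ``d`` is the Manhattan distance to the receptor coordinate ``p_i``.
    """

    points: np.ndarray                  # (n_vr, d)
    d_min: float
    d_max: float
    lambda_max: float = 40.0

    def __post_init__(self) -> None:
        if self.d_min >= self.d_max:
            raise ValueError("degenerate VR spec: d_min must be below d_max")


@dataclass(frozen=True)
class TrainingPlan:
    """The two-epoch protocol with the paper-default presentation policy."""

    epochs: int = 2
    spike_limit: int = 20
    silence_ms: float = 50.0
    snapshot_fraction: float = 1.0 / 8.0    # snapshot every N/8 presentations


@dataclass
class TrainingLog:
    presentations: pd.DataFrame
    group_spikes: np.ndarray            # (n_presentations, K) CN spikes
    snapshots: list = field(default_factory=list)       # pseudo-pattern stacks
    snapshot_presentations: list = field(default_factory=list)


def n_train_per_class(K: int) -> int:
    """Training digits per class for K cluster groups: round(0.4*K), half-up."""
    if K < 1:
        raise ValueError("K must be >= 1")
    return int(np.floor(0.4 * K + 0.5))


def encode_pixels(s: np.ndarray, lambda_max: float, in_group_size: int = 10) -> np.ndarray:
    """Rate-code a sample: every neuron of IN group j fires at lambda_max * s_j.

    Pixels map to IN groups row-major (top-left to bottom-right).
    """
    s = np.asarray(s, dtype=float).ravel()
    if s.size and (s.min() < 0 or s.max() > 1):
        raise ValueError("pixel values must lie in [0, 1]")
    return np.repeat(lambda_max * s, in_group_size)


def encode_vr(s: np.ndarray, spec: VREncoderSpec) -> np.ndarray:
    """Distance-based rates for each virtual-receptor channel, clipped to
    [0, lambda_max]."""
    s = np.asarray(s, dtype=float).ravel()
    d = np.abs(spec.points - s[None, :]).sum(axis=1)
    lam = spec.lambda_max * (1.0 - (d - spec.d_min) / (spec.d_max - spec.d_min))
    return np.clip(lam, 0.0, spec.lambda_max)


def decide(counts: np.ndarray) -> tuple[int, bool]:
    """Classification decision from per-AN-group window spike counts.

    Returns ``(predicted, tie_flag)``: the group with the most spikes, ties
    going to the lowest group index (flagged); all-zero counts give
    ``predicted = -1`` (no decision).
    """
    counts = np.asarray(counts)
    if counts.sum() == 0:
        return -1, False
    top = counts.max()
    winners = np.flatnonzero(counts == top)
    return int(winners[0]), len(winners) > 1


def _render_all(net: Network) -> np.ndarray:
    from .evaluation import render_pseudo_pattern

    return np.stack([
        render_pseudo_pattern(net, g) for g in range(net.cfg.n_cn_groups)
    ])


def _present(engine: Engine, net: Network, sample: np.ndarray,
             spike_limit: int | None, duration: float | None) -> dict:
    engine.reset_pairing_buffers()
    engine.set_input_rates(
        encode_pixels(sample, net.cfg.lambda_max, net.cfg.in_group_size)
    )
    return engine.run_for(duration=duration, spike_limit=spike_limit)


def _silence(engine: Engine, net: Network, silence_ms: float) -> None:
    engine.set_input_rates(0.0)
    if silence_ms > 0:
        engine.run_for(duration=silence_ms)


def train(
    net: Network,
    stream: StimulusStream,
    plan: TrainingPlan,
    rng: np.random.Generator,
    engine: Optional[Engine] = None,
    record_layers: tuple[str, ...] = ("CN", "AN"),
) -> tuple[Network, TrainingLog, Engine]:
    """Run the two-epoch training protocol; returns the network, the
    per-presentation log and the engine (whose raster spans the whole run)."""
    if len(stream) == 0:
        raise ValueError("empty stimulus stream")
    if engine is None:
        engine = Engine(net, rng, record_layers=record_layers)

    rows = []
    group_rows = []
    snapshots: list[np.ndarray] = []
    snap_at: list[int] = []
    n = len(stream)
    snap_every = max(1, int(round(n * plan.snapshot_fraction)))
    presentation = 0

    for epoch in range(1, plan.epochs + 1):
        if epoch == 1:
            set_lateral_inhibition(net, "CN", net.cfg.inhibition_phase1)
            set_teaching(net, None)
            snapshots.append(_render_all(net))
            snap_at.append(presentation)
        else:
            set_lateral_inhibition(net, "CN", net.cfg.inhibition_phase2)
            reset_output_weights(net, rng)

        for sample, label in zip(stream.samples, stream.labels):
            if epoch >= 2:
                set_teaching(net, int(label))
            res = _present(engine, net, sample, plan.spike_limit, None)
            # Teaching is gated off for the silence: a teaching tail would
            # keep the readout firing 20-200 ms after the CN burst, where
            # the learning window depresses, undoing the association.
            if epoch >= 2:
                set_teaching(net, None)
            _silence(engine, net, plan.silence_ms)
            presentation += 1
            if res["timed_out"]:
                logger.warning(
                    "presentation %d (epoch %d) timed out after %.0f ms",
                    presentation, epoch, res["duration_ms"],
                )
            gs = res["group_spikes"]
            rows.append({
                "presentation": presentation,
                "epoch": epoch,
                "label": int(label),
                "duration_ms": res["duration_ms"],
                "timed_out": res["timed_out"],
                "cn_spikes": res["n_spikes"],
                "winner_group": int(np.argmax(gs)) if gs.sum() else -1,
            })
            group_rows.append(gs)
            logger.info(
                "epoch %d presentation %d label %d: %.0f ms, %d CN spikes, winner %s",
                epoch, presentation, label, res["duration_ms"], res["n_spikes"],
                rows[-1]["winner_group"],
            )
            if epoch == 1 and presentation % snap_every == 0:
                snapshots.append(_render_all(net))
                snap_at.append(presentation)

        if epoch == 1 and snap_at[-1] != presentation:
            snapshots.append(_render_all(net))
            snap_at.append(presentation)

    set_teaching(net, None)
    log = TrainingLog(
        presentations=pd.DataFrame(rows),
        group_spikes=np.array(group_rows),
        snapshots=snapshots,
        snapshot_presentations=snap_at,
    )
    return net, log, engine


def test(
    net: Network,
    stream: StimulusStream,
    rng: np.random.Generator,
    engine: Optional[Engine] = None,
) -> tuple[pd.DataFrame, Engine]:
    """Run the fixed-time test regime and return the predictions table.

    Columns: sample_id, true, predicted, tie_flag, and the per-AN-group
    window spike counts ``an0..an{n-1}``.
    """
    if engine is None:
        engine = Engine(net, rng, record_layers=("CN", "AN"))
    set_teaching(net, None)
    prev_plasticity = net.plasticity_enabled
    if not net.cfg.plasticity_during_test:
        net.plasticity_enabled = False

    cfg = net.cfg
    n_groups = net.layers["AN"].n_groups
    rows = []
    for sid, sample, label in zip(stream.sample_ids, stream.samples, stream.labels):
        before = engine.group_counts["AN"].copy()
        _present(engine, net, sample, None, cfg.test_duration_ms)
        _silence(engine, net, cfg.silence_ms)
        counts = engine.group_counts["AN"] - before
        pred, tie = decide(counts)
        row = {
            "sample_id": int(sid),
            "true": int(label),
            "predicted": pred,
            "tie_flag": tie,
        }
        row.update({f"an{g}": int(counts[g]) for g in range(n_groups)})
        rows.append(row)

    net.plasticity_enabled = prev_plasticity
    return pd.DataFrame(rows), engine
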