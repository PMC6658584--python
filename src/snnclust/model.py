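"""High-level modelling interface.

:class:`SpikingClusterModel` is built from labeled image data plus a
:class:`~snnclust.network.NetworkConfig`; :meth:`SpikingClusterModel.fit`
runs the full two-epoch spiking protocol and returns a
:class:`ClusteringResults` carrying the learned prototypes, the training
log, the clustering-quality trajectory, classical baselines and a summary
table.  All randomness is derived from the single ``seed`` passed to
``fit`` (sub-streams for connectivity, initial weights, simulation input
draws, stream order and baselines), so a fit is fully reproducible.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional

import numpy as np
import pandas as pd

from . import evaluation, protocol
from .data_io import Dataset, SynthSpec, stratified_stream, synth_generate
from .engine import Engine
from .evaluation import ClusterMap, MetricsReport
from .network import Network, NetworkConfig, build_network
from .protocol import StimulusStream, TrainingLog, TrainingPlan

__all__ = ["SpikingClusterModel", "ClusteringResults"]


def _spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


class SpikingClusterModel:
    """Self-organizing spiking clustering + readout model over image data.

    Parameters
    ----------
    data : Dataset or (images, labels)
        Training images with values in [0, 1] and integer class labels.
    config : NetworkConfig, optional
        Architecture/protocol parameters; image shape and class count are
        taken from the data.
    plan : TrainingPlan, optional
        Presentation policy (spike limit, silence, snapshot cadence).
    """

    def __init__(
        self,
        data: Dataset | tuple[np.ndarray, np.ndarray],
        config: Optional[NetworkConfig] = None,
        plan: Optional[TrainingPlan] = None,
    ):
        if not isinstance(data, Dataset):
            images, labels = data
            data = Dataset(images=np.asarray(images), labels=np.asarray(labels))
        self.data = data
        n_classes = int(data.labels.max()) + 1
        cfg = config or NetworkConfig()
        self.config = replace(cfg, n_classes=n_classes, image_shape=data.shape)
        self.plan = plan or TrainingPlan(
            spike_limit=self.config.spike_limit,
            silence_ms=self.config.silence_ms,
        )

    @classmethod
    def from_synthetic(
        cls,
        spec: SynthSpec | None = None,
        config: Optional[NetworkConfig] = None,
        seed: int = 0,
    ) -> tuple["SpikingClusterModel", np.ndarray]:
        """Build a model over a generated dataset; also returns the
        ground-truth class templates (n_classes, prototypes, rows, cols)."""
        spec = spec or SynthSpec()
        ds, templates = synth_generate(spec, np.random.default_rng(seed))
        return cls(ds, config=config), templates

    def fit(self, seed: int = 0, per_class: Optional[int] = None) -> "ClusteringResults":
        """Run the two-epoch protocol and return the fitted results.

        ``per_class`` defaults to the 0.4*K rule (training samples per class
        for K cluster groups), capped at the available data.
        """
        cfg = self.config
        rng_build, rng_sim, rng_stream, rng_base = _spawn_rngs(seed, 4)
        if per_class is None:
            per_class = protocol.n_train_per_class(cfg.n_cn_groups)
        counts = np.bincount(self.data.labels, minlength=cfg.n_classes)
        per_class = min(per_class, int(counts.min()))
        stream = stratified_stream(self.data, per_class, rng_stream)

        net = build_network(cfg, rng_build)
        net, log, engine = protocol.train(net, stream, self.plan, rng_sim)
        return ClusteringResults(
            model=self, network=net, training_log=log, stream=stream,
            engine=engine, seed=seed, rng_sim=rng_sim, rng_base=rng_base,
        )


class ClusteringResults:
    """Fitted state: learned prototypes, logs, metrics and prediction."""

    def __init__(self, model, network, training_log, stream, engine, seed,
                 rng_sim, rng_base):
        self.model = model
        self.network: Network = network
        self.training_log: TrainingLog = training_log
        self.train_stream: StimulusStream = stream
        self.engine: Engine = engine
        self.seed = seed
        self._rng_sim = rng_sim
        self._rng_base = rng_base
        self.active_mask = evaluation.active_pixel_mask(stream.samples)
        self._baselines: Optional[dict[str, float]] = None
        self.last_predictions: Optional[pd.DataFrame] = None

    # -- learned state --------------------------------------------------

    @property
    def cluster_map(self) -> ClusterMap:
        patterns = np.stack([
            evaluation.render_pseudo_pattern(self.network, g)
            for g in range(self.model.config.n_cn_groups)
        ])
        return ClusterMap(
            pseudo_patterns=patterns,
            active_mask=self.active_mask.reshape(self.model.config.image_shape),
        )

    def distance_trajectory(self) -> tuple[np.ndarray, np.ndarray]:
        """Mean nearest-cluster distance at each epoch-1 snapshot."""
        traj = np.array([
            evaluation.mean_nearest_cluster_distance(
                self.train_stream.samples, snap.reshape(len(snap), -1) / 255.0,
                mask=self.active_mask,
            )
            for snap in self.training_log.snapshots
        ])
        return np.asarray(self.training_log.snapshot_presentations), traj

    def baseline_distances(self) -> dict[str, float]:
        """d-bar of k-means and neural-gas centers fitted on the same samples."""
        if self._baselines is None:
            K = self.model.config.n_cn_groups
            data = self.train_stream.samples
            self._baselines = {
                "kmeans": evaluation.mean_nearest_cluster_distance(
                    data, evaluation.kmeans_centers(data, K, self._rng_base),
                    mask=self.active_mask),
                "neural_gas": evaluation.mean_nearest_cluster_distance(
                    data, evaluation.neural_gas_centers(data, K, self._rng_base),
                    mask=self.active_mask),
            }
        return self._baselines

    # -- prediction ------------------------------------------------------

    def predict(self, images: np.ndarray, labels=None) -> pd.DataFrame:
        """Run the spiking test regime on new images; returns the
        predictions table (continues the fitted network's state)."""
        images = np.asarray(images, dtype=float)
        flat = images.reshape(len(images), -1)
        if labels is None:
            labels = np.full(len(flat), -1)
        stream = StimulusStream(samples=flat, labels=np.asarray(labels, dtype=int))
        preds, _ = protocol.test(self.network, stream, self._rng_sim,
                                 engine=self.engine)
        self.last_predictions = preds
        return preds

    def evaluate(self, images: np.ndarray, labels: np.ndarray) -> MetricsReport:
        """Test-classify labeled images and bundle all quality metrics."""
        preds = self.predict(images, labels)
        pct, conf = evaluation.accuracy(preds)
        snaps, traj = self.distance_trajectory()
        return MetricsReport(
            distance_trajectory=traj,
            snapshot_presentations=snaps,
            final_distance=float(traj[-1]),
            baseline_distances=self.baseline_distances(),
            accuracy_pct=pct,
            confusion=conf,
        )

    # -- reporting -------------------------------------------------------

    def summary(self) -> str:
        cfg = self.model.config
        log = self.training_log.presentations
        snaps, traj = self.distance_trajectory()
        base = self.baseline_distances()
        e1 = log[log.epoch == 1]
        lines = [
            "Spiking self-organizing clustering results",
            "=" * 44,
            f"backend: {cfg.backend}   dt: {cfg.dt_ms} ms   seed: {self.seed}",
            f"image: {cfg.image_shape[0]}x{cfg.image_shape[1]}  classes: {cfg.n_classes}",
            f"CN groups (K): {cfg.n_cn_groups}  x {cfg.cn_group_size} neurons"
            f"   spike limit: {self.model.plan.spike_limit}",
            f"presentations: {len(log)} ({len(e1)} per epoch)",
            f"mean presentation [ms]: epoch1 {e1.duration_ms.mean():.1f}"
            f"  epoch2 {log[log.epoch == 2].duration_ms.mean():.1f}",
            f"timeouts: {int(log.timed_out.sum())}",
            "",
            "mean nearest-cluster distance (masked L1):",
            f"  start {traj[0]:.2f} -> final {traj[-1]:.2f}",
            f"  k-means baseline {base['kmeans']:.2f}"
            f"   neural gas baseline {base['neural_gas']:.2f}",
        ]
        return "\n".join(lines)

    def plot_prototypes(self, path=None):
        """Grid of learned pseudo-patterns (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        patterns = self.cluster_map.pseudo_patterns
        K = len(patterns)
        ncols = int(np.ceil(np.sqrt(K)))
        nrows = int(np.ceil(K / ncols))
        fig, axes = plt.subplots(nrows, ncols, figsize=(2 * ncols, 2 * nrows))
        for ax, pat in zip(np.atleast_1d(axes).ravel(), patterns):
            ax.imshow(pat, cmap="gray_r", vmin=0, vmax=255)
        for ax in np.atleast_1d(axes).ravel():
            ax.set_xticks([])
            ax.set_yticks([])
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return fig
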