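"""Cluster evaluation: pseudo-pattern rendering, pixel masking, the
mean-nearest-cluster distance metric, classical baselines, accuracy and a
2-D PCA overlay export.

A cluster group's *pseudo-pattern* is the image rendered from its average
afferent weight per pixel, scaled so that a fully-potentiated pixel is 255:
``Z_xy = mean(g over connected synapses from pixel (x,y)) * 255 / g_max``.
Pixels that are never stimulated keep their high initial weights (no spike
pairing ever touches them), so all feature-space comparisons first mask
out the least active 10% of pixels across the training set; pseudo-patterns
are rescaled to [0, 1] before distances so the centers share units with the
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .network import Network

__all__ = [
    "ClusterMap",
    "MetricsReport",
    "render_pseudo_pattern",
    "active_pixel_mask",
    "mean_nearest_cluster_distance",
    "kmeans_centers",
    "neural_gas_centers",
    "accuracy",
    "prototype_match_distances",
    "pca_overlay_export",
    "write_pgm",
]

Z_MAX = 255.0


@dataclass
class ClusterMap:
    """Learned pseudo-patterns plus the active-pixel mask used by metrics."""

    pseudo_patterns: np.ndarray         # (K, rows, cols), values in [0, Z_MAX]
    active_mask: np.ndarray             # (rows, cols) bool, True = kept
    epoch: Optional[int] = None
    presentation: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pseudo_patterns.min() < 0 or self.pseudo_patterns.max() > Z_MAX:
            raise ValueError("pseudo-pattern values must lie in [0, 255]")

    @property
    def centers(self) -> np.ndarray:
        """Flattened centers rescaled to [0, 1]."""
        return self.pseudo_patterns.reshape(len(self.pseudo_patterns), -1) / Z_MAX


@dataclass
class MetricsReport:
    distance_trajectory: np.ndarray
    snapshot_presentations: np.ndarray
    final_distance: float
    baseline_distances: dict[str, float]
    accuracy_pct: Optional[float] = None
    confusion: Optional[pd.DataFrame] = None

    def to_dict(self) -> dict:
        out = {
            "distance_trajectory": [float(v) for v in self.distance_trajectory],
            "snapshot_presentations": [int(v) for v in self.snapshot_presentations],
            "final_distance": float(self.final_distance),
            "baseline_distances": {k: float(v) for k, v in self.baseline_distances.items()},
        }
        if self.accuracy_pct is not None:
            out["accuracy_pct"] = float(self.accuracy_pct)
        if self.confusion is not None:
            out["confusion"] = self.confusion.to_dict()
        return out


def render_pseudo_pattern(
    net: Network, cn_group: int, mode: str = "connected"
) -> np.ndarray:
    """Render the pseudo-pattern of one CN group from the IN->CN weights.

    ``mode="connected"`` averages over the synapses that actually exist
    (unbiased at any connection probability); ``mode="strict"`` divides by
    the full K_I*K_C fan-in, which assumes complete connectivity.
    """
    cfg = net.cfg
    pop = net.pops["IN->CN"]
    cn = net.layers["CN"]
    sl = cn.group_slice(cn_group)
    W = pop.W[:, sl]
    mask = pop.mask[:, sl]
    K_I = cfg.in_group_size
    d = cfg.n_pixels
    w_sum = W.reshape(d, K_I, -1).sum(axis=(1, 2))
    if mode == "connected":
        counts = mask.reshape(d, K_I, -1).sum(axis=(1, 2))
        mean_g = np.divide(w_sum, counts, out=np.zeros(d), where=counts > 0)
    elif mode == "strict":
        mean_g = w_sum / (K_I * cn.group_size)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    g_max = cfg.stdp.g_max
    return (mean_g * Z_MAX / g_max).reshape(cfg.image_shape)


def active_pixel_mask(images: np.ndarray, fraction: float = 0.10) -> np.ndarray:
    """Boolean mask (True = active/kept) dropping the least active pixels.

    Pixels are ranked by summed intensity over the training set; the lowest
    ``floor(fraction * d)`` are marked inactive, ties broken by pixel index
    (lower index masked first).
    """
    images = np.asarray(images, dtype=float)
    if images.size == 0:
        raise ValueError("empty training set")
    flat = images.reshape(len(images), -1)
    sums = flat.sum(axis=0)
    d = flat.shape[1]
    n_mask = int(np.floor(fraction * d))
    order = np.argsort(sums, kind="stable")     # stable: ties by pixel index
    mask = np.ones(d, dtype=bool)
    mask[order[:n_mask]] = False
    return mask.reshape(images.shape[1:]) if images.ndim == 3 else mask


def mean_nearest_cluster_distance(
    data: np.ndarray, centers: np.ndarray, mask: Optional[np.ndarray] = None
) -> float:
    """Mean over data points of the Manhattan distance to the nearest center,
    computed over unmasked pixels."""
    data = np.asarray(data, dtype=float).reshape(len(data), -1)
    centers = np.asarray(centers, dtype=float).reshape(len(centers), -1)
    if len(centers) == 0 or len(data) == 0:
        raise ValueError("need at least one center and one data point")
    if data.shape[1] != centers.shape[1]:
        raise ValueError("data/centers dimension mismatch")
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        if m.size != data.shape[1]:
            raise ValueError("mask dimension mismatch")
        data = data[:, m]
        centers = centers[:, m]
    return float(cdist(data, centers, metric="cityblock").min(axis=1).mean())


def kmeans_centers(data: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """k-means cluster centers fitted on the given samples."""
    data = np.asarray(data, dtype=float).reshape(len(data), -1)
    if K > len(data):
        raise ValueError(f"K={K} exceeds the {len(data)} data points")
    km = KMeans(n_clusters=K, n_init=10, random_state=int(rng.integers(2**31)))
    km.fit(data)
    return km.cluster_centers_


def neural_gas_centers(
    data: np.ndarray,
    K: int,
    rng: np.random.Generator,
    n_passes: int = 2,
    lambda_schedule: tuple[float, float] = (10.0, 0.5),
    eps_schedule: tuple[float, float] = (0.5, 0.05),
) -> np.ndarray:
    """Neural-gas cluster centers (rank-based soft competitive learning).

    Every center moves toward each presented sample by
    ``eps(t) * exp(-rank / lambda(t))`` of the residual, where rank is the
    center's distance rank for that sample; ``eps`` and ``lambda`` decay
    exponentially from their initial to final values over ``n_passes``
    shuffled passes through the data.
    """
    data = np.asarray(data, dtype=float).reshape(len(data), -1)
    if K > len(data):
        raise ValueError(f"K={K} exceeds the {len(data)} data points")
    centers = data[rng.choice(len(data), size=K, replace=False)].copy()
    T = n_passes * len(data)
    l0, l1 = lambda_schedule
    e0, e1 = eps_schedule
    t = 0
    for _ in range(n_passes):
        for i in rng.permutation(len(data)):
            frac = t / max(T - 1, 1)
            lam = l0 * (l1 / l0) ** frac
            eps = e0 * (e1 / e0) ** frac
            dists = np.abs(centers - data[i]).sum(axis=1)
            ranks = np.argsort(np.argsort(dists))
            h = eps * np.exp(-ranks / lam)
            centers += h[:, None] * (data[i] - centers)
            t += 1
    return centers


def accuracy(predictions: pd.DataFrame) -> tuple[float, pd.DataFrame]:
    """Percent correct and the confusion matrix from a predictions table.

    ``predicted = -1`` (no decision) counts as incorrect and appears as its
    own confusion column when present.
    """
    true = predictions["true"].to_numpy()
    pred = predictions["predicted"].to_numpy()
    pct = 100.0 * float(np.mean(true == pred)) if len(true) else 0.0
    labels = sorted(set(true))
    pred_labels = sorted(set(labels) | set(pred))
    conf = pd.DataFrame(0, index=labels, columns=pred_labels)
    for t, p in zip(true, pred):
        conf.loc[t, p] += 1
    conf.index.name = "true"
    conf.columns.name = "predicted"
    return pct, conf


def prototype_match_distances(
    cluster_map: ClusterMap, templates: np.ndarray
) -> np.ndarray:
    """For each class template, the masked Manhattan distance to the best
    matching pseudo-pattern (centers and templates both in [0, 1])."""
    m = cluster_map.active_mask.ravel()
    centers = cluster_map.centers[:, m]
    tpl = np.asarray(templates, dtype=float).reshape(len(templates), -1)[:, m]
    return cdist(tpl, centers, metric="cityblock").min(axis=1)


def pca_overlay_export(
    data: np.ndarray,
    centers: np.ndarray,
    mask: Optional[np.ndarray] = None,
    labels: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Project data and cluster centers onto the first two PCs of the data.

    Returns a coordinates table (columns: pc1, pc2, kind, label) suitable
    for external plotting.
    """
    data = np.asarray(data, dtype=float).reshape(len(data), -1)
    centers = np.asarray(centers, dtype=float).reshape(len(centers), -1)
    if len(data) < 2:
        raise ValueError("need at least two samples for a PCA")
    if mask is not None:
        m = np.asarray(mask, dtype=bool).ravel()
        data = data[:, m]
        centers = centers[:, m]
    n_comp = min(2, data.shape[1])
    pca = PCA(n_components=n_comp)
    dp = pca.fit_transform(data)
    cp = pca.transform(centers)
    if dp.shape[1] < 2:
        dp = np.pad(dp, ((0, 0), (0, 2 - dp.shape[1])))
        cp = np.pad(cp, ((0, 0), (0, 2 - cp.shape[1])))
    frames = [
        pd.DataFrame({
            "pc1": dp[:, 0], "pc2": dp[:, 1], "kind": "data",
            "label": labels if labels is not None else -1,
        }),
        pd.DataFrame({
            "pc1": cp[:, 0], "pc2": cp[:, 1], "kind": "center",
            "label": np.arange(len(cp)),
        }),
    ]
    return pd.concat(frames, ignore_index=True)


def write_pgm(image: np.ndarray, path) -> None:
    """Write a 0-255 image as a plain-text (P2) PGM file."""
    img = np.asarray(np.round(image), dtype=int)
    rows, cols = img.shape
    with open(path, "w") as fh:
        fh.write(f"P2\n{cols} {rows}\n255\n")
        for r in range(rows):
            fh.write(" ".join(str(v) for v in img[r]) + "\n")
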