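"""Dataset readers, the synthetic prototype-image generator, and sampling.

The default experiment input is synthetic: each class has a fixed binary
prototype template (a compact "ink blob" anchored at a class-specific image
location), and samples are the template with independent per-pixel flip
noise.  Templates are constructed from noise-perturbed distance fields so
that (a) every class has exactly the same number of active pixels — the
rate-coded synaptic drive scales with stimulus ink, and unequal ink budgets
would make some classes systematically harder to detect — and (b) the
templates jointly cover nearly the whole image, so pixels outside every
class pattern (which keep their high initial synaptic weights, as no spike
pairings ever touch them) form a small set that the least-active-pixel mask
removes.

MNIST-format (IDX) files can be read optionally; nothing in the test suite
requires them.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import gaussian_filter

from .protocol import StimulusStream

__all__ = [
    "Dataset",
    "SynthSpec",
    "read_idx",
    "write_idx",
    "synth_generate",
    "stratified_stream",
]

IDX_IMAGES_MAGIC = 2051
IDX_LABELS_MAGIC = 2049


@dataclass
class Dataset:
    """Labeled grayscale images with values in [0, 1]."""

    images: np.ndarray          # (N, rows, cols)
    labels: np.ndarray          # (N,) integers
    split: str = "train"

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.images.ndim != 3:
            raise ValueError("images must be (N, rows, cols)")
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels length mismatch")
        if self.images.size and (self.images.min() < 0 or self.images.max() > 1):
            raise ValueError("image values must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def shape(self) -> tuple[int, int]:
        return self.images.shape[1:]

    @property
    def flat(self) -> np.ndarray:
        """Row-major flattened view, (N, rows*cols)."""
        return self.images.reshape(len(self.images), -1)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


# ----------------------------------------------------------------------
# IDX (MNIST) format


def _read_exact(fh, n: int, what: str) -> bytes:
    buf = fh.read(n)
    if len(buf) != n:
        raise ValueError(f"truncated IDX file while reading {what} at offset {fh.tell()}")
    return buf


def read_idx(images_path, labels_path, split: str = "train") -> Dataset:
    """Read an MNIST-style IDX image/label file pair.

    Big-endian headers; image magic 2051, label magic 2049; pixel bytes are
    scaled to [0, 1] by /255.
    """
    with open(images_path, "rb") as fh:
        magic, n, rows, cols = struct.unpack(">iiii", _read_exact(fh, 16, "image header"))
        if magic != IDX_IMAGES_MAGIC:
            raise ValueError(f"bad image magic {magic} (expected {IDX_IMAGES_MAGIC}) at offset 0")
        raw = _read_exact(fh, n * rows * cols, "pixel data")
    images = np.frombuffer(raw, dtype=np.uint8).reshape(n, rows, cols) / 255.0

    with open(labels_path, "rb") as fh:
        magic, n_lab = struct.unpack(">ii", _read_exact(fh, 8, "label header"))
        if magic != IDX_LABELS_MAGIC:
            raise ValueError(f"bad label magic {magic} (expected {IDX_LABELS_MAGIC}) at offset 0")
        labels = np.frombuffer(_read_exact(fh, n_lab, "labels"), dtype=np.uint8)

    if n != n_lab:
        raise ValueError(f"image file has {n} items but label file has {n_lab}")
    return Dataset(images=images, labels=labels.astype(int), split=split)


def write_idx(dataset: Dataset, images_path, labels_path) -> None:
    """Write a dataset as an IDX image/label pair (inverse of :func:`read_idx`)."""
    n, rows, cols = dataset.images.shape
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">iiii", IDX_IMAGES_MAGIC, n, rows, cols))
        fh.write(np.round(dataset.images * 255).astype(np.uint8).tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">ii", IDX_LABELS_MAGIC, n))
        fh.write(dataset.labels.astype(np.uint8).tobytes())


# ----------------------------------------------------------------------
# Synthetic generator


@dataclass(frozen=True)
class SynthSpec:
    """Specification of a synthetic class-prototype dataset.

    ``fill`` is the fraction of active pixels in every template (equal
    across classes by construction).  ``flip_prob`` is the per-pixel,
    per-sample flip probability; for binary templates the expected
    Manhattan distance of a sample to its template is ``flip_prob * d``.
    ``margin`` is the minimum pairwise Manhattan distance between
    templates; generation fails if it cannot be met.
    """

    n_classes: int = 5
    image_shape: tuple[int, int] = (16, 16)
    prototypes_per_class: int = 1
    fill: float = 0.20
    flip_prob: float = 0.05
    intensity_range: tuple[float, float] = (1.0, 1.0)
    samples_per_class: int = 20
    margin: float | None = None          # default 0.25 * fill * d

    def __post_init__(self) -> None:
        if not 0 < self.fill < 1:
            raise ValueError("fill must lie in (0, 1)")
        if not 0 <= self.flip_prob <= 1:
            raise ValueError("flip_prob must lie in [0, 1]")
        if self.n_classes < 1 or self.prototypes_per_class < 1:
            raise ValueError("need at least one class and one prototype")

    @property
    def d(self) -> int:
        return self.image_shape[0] * self.image_shape[1]

    @property
    def margin_value(self) -> float:
        return self.margin if self.margin is not None else 0.25 * self.fill * self.d


def _make_templates(spec: SynthSpec, rng: np.random.Generator) -> np.ndarray:
    """Equal-area, mutually disjoint binary templates anchored at distinct
    image locations.

    Each class scores every pixel by its noise-perturbed distance to a
    class-specific anchor (anchors spread on a ring around the image
    centre); the classes then draft pixels round-robin, each taking its
    best still-unclaimed pixel, until every template holds ``N_on`` pixels.
    Disjointness matters: overlapping prototypes give neurons already tuned
    to one class a head start on the overlapping class, which at small
    cluster counts lets early winners capture every class.  Equal area
    matters because the rate-coded synaptic drive scales with stimulus ink.
    """
    rows, cols = spec.image_shape
    n_tpl = spec.n_classes * spec.prototypes_per_class
    n_on = int(round(spec.fill * spec.d))
    if n_tpl * n_on > spec.d:
        raise ValueError(
            f"cannot fit {n_tpl} disjoint templates of {n_on} pixels in {spec.d}"
        )

    centre = np.array([(rows - 1) / 2.0, (cols - 1) / 2.0])
    radius = 0.30 * min(rows, cols)
    phase = rng.uniform(0, 2 * np.pi)
    yy, xx = np.mgrid[0:rows, 0:cols]

    scores = np.empty((n_tpl, spec.d))
    for k in range(n_tpl):
        ang = phase + 2 * np.pi * k / n_tpl
        anchor = centre + radius * np.array([np.sin(ang), np.cos(ang)])
        dist = np.hypot(yy - anchor[0], xx - anchor[1])
        noise = gaussian_filter(rng.standard_normal((rows, cols)), sigma=2.0)
        std = noise.std()
        if std > 0:
            noise = noise / std
        scores[k] = (dist + 1.5 * noise).ravel()

    order = np.argsort(scores, axis=1, kind="stable")
    claimed = np.zeros(spec.d, dtype=bool)
    picks = [[] for _ in range(n_tpl)]
    cursors = np.zeros(n_tpl, dtype=int)
    for _ in range(n_on):
        for k in range(n_tpl):            # snake draft, one pixel per round
            c = cursors[k]
            while claimed[order[k, c]]:
                c += 1
            claimed[order[k, c]] = True
            picks[k].append(order[k, c])
            cursors[k] = c + 1

    templates = np.zeros((n_tpl, rows, cols), dtype=float)
    for k in range(n_tpl):
        tpl = np.zeros(spec.d)
        tpl[picks[k]] = 1.0
        templates[k] = tpl.reshape(rows, cols)

    flat = templates.reshape(n_tpl, -1)
    dists = np.abs(flat[:, None, :] - flat[None, :, :]).sum(-1)
    off_diag = dists[~np.eye(n_tpl, dtype=bool)]
    if len(off_diag) and off_diag.min() < spec.margin_value:
        raise ValueError(
            f"template margin violation: min pairwise distance {off_diag.min():.1f} "
            f"< required {spec.margin_value:.1f}"
        )
    return templates


def synth_generate(
    spec: SynthSpec,
    rng: np.random.Generator,
    split: str = "train",
    templates: Optional[np.ndarray] = None,
) -> tuple[Dataset, np.ndarray]:
    """Generate a dataset and return it with its ground-truth templates.

    Each sample is a prototype template of its class with independent
    per-pixel flip noise (``v -> 1 - v`` with probability ``flip_prob``)
    and, if ``intensity_range`` is not degenerate, a per-sample uniform
    intensity applied to the active pixels.  ``templates`` has shape
    (n_classes, prototypes_per_class, rows, cols); pass the templates of a
    previous call to draw new samples (e.g. a held-out test split) from the
    same class prototypes.
    """
    if templates is None:
        templates = _make_templates(spec, rng)
        templates = templates.reshape(
            spec.n_classes, spec.prototypes_per_class, *spec.image_shape
        )
    else:
        templates = np.asarray(templates, dtype=float)
        expected = (spec.n_classes, spec.prototypes_per_class, *spec.image_shape)
        if templates.shape != expected:
            raise ValueError(f"templates shape {templates.shape} != {expected}")
    images = []
    labels = []
    lo, hi = spec.intensity_range
    for c in range(spec.n_classes):
        for _ in range(spec.samples_per_class):
            proto = templates[c, rng.integers(spec.prototypes_per_class)]
            flips = rng.random(spec.image_shape) < spec.flip_prob
            img = np.where(flips, 1.0 - proto, proto)
            if (lo, hi) != (1.0, 1.0):
                img = img * rng.uniform(lo, hi)
            images.append(img)
            labels.append(c)
    ds = Dataset(images=np.array(images), labels=np.array(labels), split=split)
    return ds, templates


def stratified_stream(
    dataset: Dataset, per_class: int, rng: np.random.Generator
) -> StimulusStream:
    """Draw ``per_class`` samples per class without replacement, interleaved
    in class order (0, 1, 2, ..., 0, 1, 2, ...)."""
    classes = dataset.classes
    picks = []
    for c in classes:
        idx = np.flatnonzero(dataset.labels == c)
        if len(idx) < per_class:
            raise ValueError(
                f"class {c} has only {len(idx)} samples, need {per_class}"
            )
        picks.append(rng.choice(idx, size=per_class, replace=False))
    order = np.stack(picks, axis=1).ravel()     # round-robin over classes
    return StimulusStream(
        samples=dataset.flat[order].copy(),
        labels=dataset.labels[order].copy(),
        sample_ids=order,
        image_shape=dataset.shape,
    )
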