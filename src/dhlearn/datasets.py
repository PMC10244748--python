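"""Synthetic supervised tasks and the IDX digit-image reader.

Two in-package generators define the study conditions: the two-input
single-neuron task (stimulus A must be mapped low, stimulus B high) and
a multi-class Gaussian-blob classification task standing in for digit
images at desk scale.  Blob features live in [0, 1] so inputs are
themselves valid firing rates (and per-bin spike probabilities for the
Poisson conversion).  Class targets
are one-hot vectors mapped into the sigmoid's reachable range
(0.95/0.05) because exact 0/1 is unattainable for a bounded rate.

Real digit images in the standard big-endian IDX format can be loaded
through :func:`read_idx_images` for scaled-up runs.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Dataset",
    "two_input_task",
    "gaussian_blobs",
    "one_hot_targets",
    "read_idx_images",
    "write_idx_images",
    "IDXFormatError",
]

TARGET_HIGH = 0.95
TARGET_LOW = 0.05


class IDXFormatError(ValueError):
    """Malformed IDX file (bad magic number or truncated payload)."""


@dataclass
class Dataset:
    """Supervised dataset: features, integer labels, continuous targets."""

    X: np.ndarray
    labels: np.ndarray
    targets: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.targets = np.asarray(self.targets, dtype=float)
        if not (len(self.X) == len(self.labels) == len(self.targets)):
            raise ValueError("X, labels and targets must have equal length")

    def __len__(self) -> int:
        return len(self.X)

    def subset(self, idx) -> "Dataset":
        return Dataset(self.X[idx], self.labels[idx], self.targets[idx])

    def with_targets(self, targets: np.ndarray) -> "Dataset":
        return Dataset(self.X, self.labels.copy(), targets)


def one_hot_targets(labels: np.ndarray, n_classes: int,
                    high: float = TARGET_HIGH, low: float = TARGET_LOW) -> np.ndarray:
    """One-hot labels mapped into the activation range [low, high]."""
    t = np.full((len(labels), n_classes), low)
    t[np.arange(len(labels)), labels] = high
    return t


def two_input_task(n_pairs: int = 1, seed: int | None = None) -> list[tuple[np.ndarray, np.ndarray]]:
    """Alternating single-neuron stimuli: A -> target low, B -> target high.

    Stimulus A drives input neuron A at rate 1 (B silent) and must map
    to output rate 0.05; stimulus B is the mirror image with target
    0.95.  The sequence is deterministic (seed accepted for interface
    symmetry).
    """
    a = (np.array([1.0, 0.0]), np.array([TARGET_LOW]))
    b = (np.array([0.0, 1.0]), np.array([TARGET_HIGH]))
    return [a, b] * n_pairs


def gaussian_blobs(
    n_classes: int = 4,
    n_per_class: int = 25,
    dim: int = 2,
    sep: float = 6.0,
    seed: int = 0,
) -> Dataset:
    """Isotropic Gaussian blobs with pairwise center distance >= sep * sigma.

    Centers are rejection-sampled uniformly inside [0.2, 0.8]^dim with a
    minimum pairwise spacing, and the within-class sigma is set to the
    realised minimum spacing divided by ``sep``.  Features therefore live
    directly in firing-rate space [0, 1] (valid per-bin spike
    probabilities) with the same relative class separation for every
    seed.
    """
    if sep <= 0:
        raise ValueError("sep must be positive")
    rng = np.random.default_rng(seed)
    spread = 0.3
    if n_classes > 1:
        target = min(spread, 1.0 / n_classes ** (1.0 / dim))
        for attempt in range(2000):
            centers = rng.uniform(0.2, 0.8, size=(n_classes, dim))
            d = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            if d.min() >= target:
                break
            if attempt % 200 == 199:  # infeasible spacing: relax
                target *= 0.8
        sigma = d.min() / sep
    else:
        centers = rng.uniform(0.2, 0.8, size=(1, dim))
        sigma = spread / sep
    labels = np.repeat(np.arange(n_classes), n_per_class)
    if len(labels):
        X = centers[labels] + rng.normal(0.0, sigma, size=(len(labels), dim))
        X = np.clip(X, 0.0, 1.0)
    else:
        X = np.empty((0, dim))
    return Dataset(X, labels, one_hot_targets(labels, n_classes))


# ---------------------------------------------------------------------------
# IDX (big-endian) image/label files


def _read_idx_array(path: Path, expected_magic: int) -> np.ndarray:
    data = Path(path).read_bytes()
    if len(data) < 4:
        raise IDXFormatError(f"{path}: truncated header")
    (magic,) = struct.unpack(">i", data[:4])
    if magic != expected_magic:
        raise IDXFormatError(f"{path}: bad magic {magic}, expected {expected_magic}")
    ndim = magic & 0xFF
    header = 4 + 4 * ndim
    if len(data) < header:
        raise IDXFormatError(f"{path}: truncated dimension header")
    dims = struct.unpack(f">{ndim}i", data[4:header])
    n_items = int(np.prod(dims))
    payload = np.frombuffer(data, dtype=np.uint8, offset=header)
    if payload.size != n_items:
        raise IDXFormatError(f"{path}: expected {n_items} bytes, found {payload.size}")
    return payload.reshape(dims)


def read_idx_images(images_path, labels_path) -> Dataset:
    """Load IDX images/labels: pixels scaled to [0, 1], flattened; one-hot targets."""
    images = _read_idx_array(Path(images_path), 2051)
    labels = _read_idx_array(Path(labels_path), 2049)
    if images.shape[0] != labels.shape[0]:
        raise IDXFormatError("image and label counts differ")
    X = images.reshape(images.shape[0], -1).astype(float) / 255.0
    labels = labels.astype(int)
    return Dataset(X, labels, one_hot_targets(labels, 10))


def write_idx_images(images_path, labels_path, images: np.ndarray, labels: np.ndarray) -> None:
    """Write uint8 images (n, h, w) and labels (n,) in IDX format."""
    images = np.ascontiguousarray(images, dtype=np.uint8)
    labels = np.ascontiguousarray(labels, dtype=np.uint8)
    with open(images_path, "wb") as fh:
        fh.write(struct.pack(">i", 2051))
        fh.write(struct.pack(">3i", *images.shape))
        fh.write(images.tobytes())
    with open(labels_path, "wb") as fh:
        fh.write(struct.pack(">i", 2049))
        fh.write(struct.pack(">i", labels.shape[0]))
        fh.write(labels.tobytes())
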