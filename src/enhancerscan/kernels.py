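"""Kernel construction and variance normalization.

Every feature family enters the classifier through a dot-product kernel:
the k-spectrum kernel is the dot product of k-mer count vectors, and the
functional-genomics and conservation kernels are linear kernels on their
(binary / scalar) feature vectors.  Each training kernel is divided by the
feature-space variance of the training points,

    v = mean(diag K) - mean(K),

so that differently scaled families contribute comparably; test-vs-train
blocks reuse the training normalizer and are never re-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import SpectrumCounts

__all__ = [
    "KernelMatrix",
    "spectrum_kernel",
    "linear_kernel",
    "gram_matrix",
    "variance_normalize",
    "cross_kernel",
]

KERNEL_FAMILIES = ("spectrum", "linear")


@dataclass
class KernelMatrix:
    """A symmetric similarity matrix with its recorded normalizer."""

    name: str
    values: np.ndarray
    normalizer: float = 1.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("kernel matrix must be square")
        if not np.allclose(values, values.T, atol=1e-9):
            raise ValueError(f"kernel {self.name!r} is not symmetric")
        self.values = values

    @property
    def n(self) -> int:
        return self.values.shape[0]


def spectrum_kernel(a: SpectrumCounts, b: SpectrumCounts) -> float:
    """Spectrum kernel: summed products of shared k-mer occurrence counts."""
    if a.k != b.k:
        raise ValueError(f"mismatched k: {a.k} vs {b.k}")
    return float(np.dot(a.counts.astype(float), b.counts.astype(float)))


def linear_kernel(x: np.ndarray, y: np.ndarray) -> float:
    """Plain dot product of two equal-length feature vectors."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    return float(np.dot(x, y))


def gram_matrix(X: np.ndarray, name: str = "kernel") -> KernelMatrix:
    """Dense dot-product Gram matrix of row-wise feature vectors."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    values = X @ X.T
    values = (values + values.T) / 2.0  # clean round-off asymmetry
    return KernelMatrix(name, values)


def feature_space_variance(values: np.ndarray) -> float:
    """Variance of the (implicit) feature vectors: mean(diag) - mean(all)."""
    values = np.asarray(values, dtype=float)
    return float(np.mean(np.diag(values)) - np.mean(values))


def variance_normalize(K: KernelMatrix) -> KernelMatrix:
    """Scale ``K`` by its feature-space variance; records the normalizer."""
    if K.n < 2:
        raise ValueError("variance normalization needs n >= 2")
    v = feature_space_variance(K.values)
    if v <= 0:
        raise ValueError(
            f"kernel {K.name!r} is degenerate (feature-space variance {v:g} <= 0)"
        )
    return KernelMatrix(K.name, K.values / v, normalizer=v * K.normalizer)


def cross_kernel(
    train_features: np.ndarray,
    test_features: np.ndarray,
    family: str = "linear",
    normalizer: float = 1.0,
) -> np.ndarray:
    """n_test x n_train block of normalized train-vs-test kernel values."""
    if family not in KERNEL_FAMILIES:
        raise ValueError(f"unknown kernel family {family!r}")
    if normalizer <= 0:
        raise ValueError("normalizer must be > 0")
    train = np.asarray(train_features, dtype=float)
    test = np.asarray(test_features, dtype=float)
    if train.ndim == 1:
        train = train[:, None]
    if test.ndim == 1:
        test = test[:, None]
    if train.shape[1] != test.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: train {train.shape[1]}, test {test.shape[1]}"
        )
    return (test @ train.T) / normalizer
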