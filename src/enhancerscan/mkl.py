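"""Single-kernel SVMs and 1-norm multiple kernel learning.

The classifier is a soft-margin SVM whose kernel is a convex combination
of per-data-type kernels.  The discrimination function for a new region x is

    f(x) = sum_i alpha_i * sum_j beta_j * k_j(x_i, x) + b

with N signed training-example weights alpha_i (alpha_i = y_i * lambda_i),
M kernel weights beta_j >= 0 constrained to sum to one (the 1-norm), and
bias b.  A positive score predicts the positive class.

Training alternates two convex steps (the SimpleMKL scheme): with beta
fixed, the combined kernel sum_j beta_j K_j is handed to a standard dual SVM
solve; with the example weights fixed, beta takes a projected-gradient step
on the probability simplex using the Danskin gradient
dJ/dbeta_j = -1/2 alpha' K_j alpha, with backtracking so the objective never
increases.  Misclassification costs are balanced by class size:
C_+ = C*N/(2*N_+), C_- = C*N/(2*N_-).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.svm import SVC

from .kernels import KernelMatrix, cross_kernel

__all__ = [
    "TrainConfig",
    "MKLModel",
    "class_costs",
    "train_svm",
    "train_mkl",
    "decision_scores",
    "linear_feature_weights",
    "kkt_residual",
    "save_model",
    "load_model",
]


@dataclass
class TrainConfig:
    C: float = 1.0
    class_balance: bool = True
    max_outer_iter: int = 100
    beta_tol: float = 1e-4
    qp_tol: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.beta_tol <= 0 or self.qp_tol <= 0:
            raise ValueError("tolerances must be > 0")


@dataclass
class MKLModel:
    """A trained (MKL-)SVM: example weights, kernel weights, bias.

    ``alphas`` are signed (they absorb the labels); ``train_features`` keeps
    the per-kernel training feature matrices so that new regions can be
    scored without re-touching the training data pipeline.
    """

    alphas: np.ndarray
    betas: np.ndarray
    bias: float
    labels: np.ndarray
    kernel_names: list[str]
    kernel_families: list[str]
    normalizers: list[float]
    train_refs: list[str]
    C: float
    converged: bool = True
    objective_path: list[float] = field(default_factory=list)
    train_features: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.alphas = np.asarray(self.alphas, dtype=float)
        self.betas = np.asarray(self.betas, dtype=float)
        self.labels = np.asarray(self.labels)
        if np.any(self.betas < -1e-9):
            raise ValueError("kernel weights must be non-negative")
        if abs(self.betas.sum() - 1.0) > 1e-6:
            raise ValueError("kernel weights must sum to 1")

    @property
    def n_kernels(self) -> int:
        return len(self.kernel_names)

    def score_features(self, features: Mapping[str, np.ndarray]) -> np.ndarray:
        """Score rows of per-kernel test feature matrices.

        Requires ``train_features`` to be populated (models built through
        :func:`train_mkl` with feature matrices, or loaded from disk).
        """
        if not self.train_features:
            raise ValueError("model carries no training features; score via decision_scores")
        blocks = []
        for name, family, norm in zip(
            self.kernel_names, self.kernel_families, self.normalizers
        ):
            if name not in features:
                raise KeyError(f"missing test features for kernel {name!r}")
            blocks.append(
                cross_kernel(self.train_features[name], features[name], family="linear", normalizer=norm)
            )
        return decision_scores(self, blocks)


def class_costs(labels: np.ndarray, C: float = 1.0, class_balance: bool = True) -> dict[int, float]:
    """Per-class misclassification costs, balanced by class size."""
    labels = np.asarray(labels)
    n = len(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    if not class_balance:
        return {1: C, -1: C}
    return {1: C * n / (2.0 * n_pos), -1: C * n / (2.0 * n_neg)}


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if not set(np.unique(labels)) <= {-1, 1}:
        raise ValueError("labels must be in {-1, +1}")
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return labels


def _solve_svm_dual(
    K: np.ndarray, labels: np.ndarray, config: TrainConfig
) -> tuple[np.ndarray, float, float]:
    """Dense dual SVM solve on a precomputed kernel.

    Returns (signed alphas over all examples, bias, dual objective value).
    """
    costs = class_costs(labels, C=1.0, class_balance=config.class_balance)
    clf = SVC(
        C=config.C,
        kernel="precomputed",
        class_weight={1: costs[1], -1: costs[-1]},
        tol=config.qp_tol,
        cache_size=200,
    )
    clf.fit(K, labels)
    alphas = np.zeros(len(labels))
    alphas[clf.support_] = clf.dual_coef_[0]
    bias = float(clf.intercept_[0])
    objective = float(np.sum(np.abs(alphas)) - 0.5 * alphas @ K @ alphas)
    return alphas, bias, objective


def train_svm(
    K: KernelMatrix,
    labels: np.ndarray,
    config: TrainConfig | None = None,
    train_refs: Sequence[str] | None = None,
    train_features: Mapping[str, np.ndarray] | None = None,
    family: str = "linear",
) -> MKLModel:
    """Train a single-kernel SVM (an MKL model with M=1, beta=[1])."""
    config = config or TrainConfig()
    labels = _check_labels(labels)
    alphas, bias, objective = _solve_svm_dual(K.values, labels, config)
    return MKLModel(
        alphas=alphas,
        betas=np.array([1.0]),
        bias=bias,
        labels=labels,
        kernel_names=[K.name],
        kernel_families=[family],
        normalizers=[K.normalizer],
        train_refs=list(train_refs) if train_refs is not None else [],
        C=config.C,
        converged=True,
        objective_path=[objective],
        train_features=dict(train_features or {}),
    )


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.nonzero(u * np.arange(1, len(v) + 1) > css)[0][-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


def train_mkl(
    Ks: Sequence[KernelMatrix],
    labels: np.ndarray,
    config: TrainConfig | None = None,
    families: Sequence[str] | None = None,
    train_refs: Sequence[str] | None = None,
    train_features: Mapping[str, np.ndarray] | None = None,
) -> MKLModel:
    """Train a 1-norm MKL classifier over ``Ks`` by alternating optimization."""
    config = config or TrainConfig()
    labels = _check_labels(labels)
    if not Ks:
        raise ValueError("need at least one kernel")
    n = Ks[0].n
    for K in Ks:
        if K.n != n:
            raise ValueError("all kernels must share the same example set")
    M = len(Ks)
    mats = [K.values for K in Ks]

    betas = np.full(M, 1.0 / M)
    alphas, bias, objective = _solve_svm_dual(_combine(mats, betas), labels, config)
    path = [objective]
    converged = M == 1

    for _ in range(config.max_outer_iter if M > 1 else 0):
        grad = np.array([-0.5 * alphas @ Km @ alphas for Km in mats])
        centered = grad - grad.mean()
        scale = np.max(np.abs(centered))
        if scale < 1e-15:  # objective flat in beta
            converged = True
            break
        step = 1.0 / scale
        accepted = False
        for _ in range(30):
            beta_try = _project_simplex(betas - step * grad)
            if np.max(np.abs(beta_try - betas)) < 1e-15:
                break
            a_t, b_t, o_t = _solve_svm_dual(_combine(mats, beta_try), labels, config)
            if o_t <= objective + 1e-12 * max(1.0, abs(objective)):
                delta = float(np.max(np.abs(beta_try - betas)))
                betas, alphas, bias, objective = beta_try, a_t, b_t, o_t
                path.append(objective)
                accepted = True
                break
            step *= 0.5
        if not accepted:  # no descent step exists: at a stationary point
            converged = True
            break
        if delta < config.beta_tol:
            converged = True
            break
        # objective stagnation: further beta movement is numerically idle
        if path[-2] - path[-1] <= 1e-7 * max(1.0, abs(path[-1])):
            converged = True
            break

    if not converged:
        warnings.warn(
            f"MKL did not converge within {config.max_outer_iter} outer iterations; "
            "returning best iterate",
            RuntimeWarning,
        )
    return MKLModel(
        alphas=alphas,
        betas=betas,
        bias=bias,
        labels=labels,
        kernel_names=[K.name for K in Ks],
        kernel_families=list(families) if families is not None else ["linear"] * M,
        normalizers=[K.normalizer for K in Ks],
        train_refs=list(train_refs) if train_refs is not None else [],
        C=config.C,
        converged=converged,
        objective_path=path,
        train_features=dict(train_features or {}),
    )


def _combine(mats: Sequence[np.ndarray], betas: np.ndarray) -> np.ndarray:
    out = np.zeros_like(mats[0])
    for b, Km in zip(betas, mats):
        if b > 0:
            out += b * Km
    return out


def decision_scores(model: MKLModel, cross_blocks: Sequence[np.ndarray]) -> np.ndarray:
    """Evaluate f on precomputed (normalized) test-vs-train kernel blocks."""
    if len(cross_blocks) != model.n_kernels:
        raise ValueError(
            f"expected {model.n_kernels} cross blocks, got {len(cross_blocks)}"
        )
    n_train = len(model.alphas)
    scores = None
    for beta, block in zip(model.betas, cross_blocks):
        block = np.asarray(block, dtype=float)
        if block.ndim != 2 or block.shape[1] != n_train:
            raise ValueError(
                f"cross block shape {block.shape} incompatible with {n_train} training examples"
            )
        contrib = beta * (block @ model.alphas)
        scores = contrib if scores is None else scores + contrib
    return scores + model.bias


def linear_feature_weights(
    model: MKLModel, linear_kernel_features: Mapping[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Explicit primal weight vector per linear kernel: w_j = beta_j X' alpha / v_j.

    The decision score decomposes as sum_j x_test . w_j (+ spectrum
    contributions) + b.  Requesting weights for a spectrum kernel raises;
    4-mer weights follow from the same formula applied to count vectors.
    """
    weights = {}
    for name, X in linear_kernel_features.items():
        if name not in model.kernel_names:
            raise KeyError(f"kernel {name!r} not in model")
        j = model.kernel_names.index(name)
        if model.kernel_families[j] == "spectrum":
            raise ValueError(
                f"kernel {name!r} is a spectrum kernel; apply the formula to "
                "k-mer count vectors instead"
            )
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        weights[name] = model.betas[j] * (X.T @ model.alphas) / model.normalizers[j]
    return weights


def kkt_residual(model: MKLModel, Ks: Sequence[KernelMatrix]) -> float:
    """Maximum violation of the dual optimality conditions on the training set.

    For each example with margin y_i f(x_i): lambda_i = 0 requires margin
    >= 1, lambda_i = C_i requires margin <= 1, interior lambda requires
    margin = 1.  Returns the largest one-sided violation.
    """
    blocks = [K.values for K in Ks]
    f = decision_scores(model, blocks)
    margins = model.labels * f
    lam = np.abs(model.alphas)
    costs = class_costs(model.labels, C=model.C)
    C_i = np.where(model.labels == 1, costs[1], costs[-1])
    tol_c = 1e-8 * max(1.0, float(C_i.max()))
    viol = np.zeros_like(margins)
    at_zero = lam <= tol_c
    at_cap = lam >= C_i - tol_c
    interior = ~(at_zero | at_cap)
    viol[at_zero] = np.maximum(0.0, 1.0 - margins[at_zero])
    viol[at_cap] = np.maximum(0.0, margins[at_cap] - 1.0)
    viol[interior] = np.abs(margins[interior] - 1.0)
    return float(viol.max()) if len(viol) else 0.0


# ---------------------------------------------------------------------------
# Serialization


def save_model(model: MKLModel, path: str | Path) -> None:
    """Write the model as self-describing JSON; loading is bit-faithful."""
    payload = {
        "format": "enhancerscan-mkl-model",
        "version": 1,
        "alphas": model.alphas.tolist(),
        "betas": model.betas.tolist(),
        "bias": model.bias,
        "labels": model.labels.tolist(),
        "kernel_names": model.kernel_names,
        "kernel_families": model.kernel_families,
        "normalizers": model.normalizers,
        "train_refs": model.train_refs,
        "C": model.C,
        "converged": model.converged,
        "objective_path": model.objective_path,
        "train_features": {
            name: X.tolist() for name, X in model.train_features.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> MKLModel:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format") != "enhancerscan-mkl-model":
        raise ValueError(f"{path} is not a saved model file")
    return MKLModel(
        alphas=np.array(payload["alphas"], dtype=float),
        betas=np.array(payload["betas"], dtype=float),
        bias=float(payload["bias"]),
        labels=np.array(payload["labels"], dtype=int),
        kernel_names=list(payload["kernel_names"]),
        kernel_families=list(payload["kernel_families"]),
        normalizers=[float(v) for v in payload["normalizers"]],
        train_refs=list(payload["train_refs"]),
        C=float(payload["C"]),
        converged=bool(payload["converged"]),
        objective_path=[float(v) for v in payload["objective_path"]],
        train_features={
            name: np.array(X, dtype=float)
            for name, X in payload["train_features"].items()
        },
    )
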