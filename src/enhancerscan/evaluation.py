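"""Cross-validation and performance metrics.

All classifiers are evaluated by stratified 10-fold cross-validation:
kernels and their variance normalizers are estimated on the training folds
only, the held-out fold is scored through train-vs-test kernel blocks, and
the pooled out-of-fold scores feed every metric (ROC AUC, precision-recall,
power at a fixed false positive rate, score thresholds at a target FPR).

The genome-wide false discovery rate is prior-dependent: with an assumed
fraction pi of windows truly harboring an enhancer,

    FDR = FPR*(1-pi) / (FPR*(1-pi) + TPR*pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.metrics import precision_recall_curve, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import FeatureBundle, bundles_to_matrices
from .kernels import cross_kernel, gram_matrix, variance_normalize
from .mkl import MKLModel, TrainConfig, decision_scores, train_mkl
from .trainsets import LabeledSet

__all__ = [
    "EvalResult",
    "KERNEL_SPECS",
    "stratified_kfold",
    "cross_validate",
    "roc_auc",
    "threshold_at_fpr",
    "power_at_fpr",
    "mcnemar_test",
    "estimate_fdr",
]

# kernel name -> (feature-matrix key, kernel family)
KERNEL_SPECS = {
    "spectrum": ("spectrum", "spectrum"),
    "functional": ("functional", "linear"),
    "conservation": ("conservation", "linear"),
}


@dataclass
class EvalResult:
    """Pooled out-of-fold scores and labels for one evaluated classifier."""

    scores: np.ndarray
    labels: np.ndarray
    fold_ids: np.ndarray
    ids: list[str] = field(default_factory=list)
    models: list[MKLModel] = field(default_factory=list)

    @property
    def auc(self) -> float:
        return roc_auc(self.scores, self.labels)

    @property
    def pr_points(self) -> list[tuple[float, float]]:
        precision, recall, _ = precision_recall_curve(self.labels, self.scores)
        return list(zip(recall.tolist(), precision.tolist()))

    def threshold_at_fpr(self, target_fpr: float) -> float:
        return threshold_at_fpr(self.scores[self.labels == -1], target_fpr)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {"score": self.scores, "label": self.labels, "fold": self.fold_ids}
        )
        if self.ids:
            frame.insert(0, "region_id", self.ids)
        return frame


def stratified_kfold(labels: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold assignment (0..k-1) with per-fold class ratios within 1 example."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class size ({counts.min()})"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_ids = np.empty(len(labels), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
        fold_ids[test_idx] = fold
    return fold_ids


def cross_validate(
    bundles: Mapping[str, FeatureBundle],
    labeled: LabeledSet,
    kernel_spec: Sequence[str] = ("spectrum", "functional", "conservation"),
    config: TrainConfig | None = None,
    k_folds: int = 10,
    keep_models: bool = False,
) -> EvalResult:
    """Stratified k-fold cross-validation of an MKL classifier.

    ``bundles`` maps region id -> features; ``kernel_spec`` selects the
    kernels (subset of spectrum / functional / conservation).  Kernel
    normalizers are estimated on training folds only.
    """
    config = config or TrainConfig()
    unknown = [name for name in kernel_spec if name not in KERNEL_SPECS]
    if unknown:
        raise ValueError(f"unknown kernels {unknown}; choose from {sorted(KERNEL_SPECS)}")
    ids = labeled.ids
    missing = [rid for rid in ids if rid not in bundles]
    if missing:
        raise ValueError(f"missing feature bundles for {missing[:5]}")
    labels = labeled.labels
    mats = bundles_to_matrices([bundles[rid] for rid in ids])
    fold_ids = stratified_kfold(labels, k=k_folds, seed=config.seed)

    scores = np.empty(len(ids))
    models = []
    for fold in range(k_folds):
        test_mask = fold_ids == fold
        train_mask = ~test_mask
        Ks, blocks, families = [], [], []
        for name in kernel_spec:
            key, family = KERNEL_SPECS[name]
            X_train, X_test = mats[key][train_mask], mats[key][test_mask]
            try:
                K = variance_normalize(gram_matrix(X_train, name=name))
            except ValueError as exc:
                raise ValueError(f"fold {fold}: {exc}") from exc
            Ks.append(K)
            families.append(family)
            blocks.append(
                cross_kernel(X_train, X_test, family="linear", normalizer=K.normalizer)
            )
        try:
            model = train_mkl(Ks, labels[train_mask], config, families=families)
        except ValueError as exc:
            raise ValueError(f"fold {fold}: {exc}") from exc
        scores[test_mask] = decision_scores(model, blocks)
        if keep_models:
            models.append(model)
    return EvalResult(scores=scores, labels=labels, fold_ids=fold_ids, ids=ids, models=models)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC = P(score_pos > score_neg) with ties counted 1/2."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, scores))


def threshold_at_fpr(neg_scores: np.ndarray, target_fpr: float) -> float:
    """Smallest observed score t with fraction(neg >= t) <= target_fpr.

    Returns +inf when no observed score satisfies the target (e.g. a target
    FPR of exactly 0 with finite scores).
    """
    neg_scores = np.asarray(neg_scores, dtype=float)
    if len(neg_scores) == 0:
        raise ValueError("need at least one negative score")
    if not 0.0 <= target_fpr <= 1.0:
        raise ValueError("target_fpr must be in [0, 1]")
    candidates = np.sort(np.unique(neg_scores))  # ascending
    n = len(neg_scores)
    for t in candidates:
        if np.count_nonzero(neg_scores >= t) / n <= target_fpr:
            return float(t)
    return float("inf")


def power_at_fpr(result: EvalResult, target_fpr: float) -> float:
    """Fraction of positives scoring at or above the target-FPR threshold."""
    t = result.threshold_at_fpr(target_fpr)
    pos = result.scores[result.labels == 1]
    return float(np.count_nonzero(pos >= t) / len(pos))


def mcnemar_test(
    correct_a: Sequence[bool], correct_b: Sequence[bool]
) -> tuple[float, float]:
    """Paired comparison of two classifiers on the same examples.

    Inputs are per-example correctness indicators.  Returns the
    continuity-corrected chi-square statistic and a p-value: chi-square
    (1 df) when the discordant count n01+n10 >= 25, otherwise an exact
    two-sided binomial test.
    """
    a = np.asarray(correct_a, dtype=bool)
    b = np.asarray(correct_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    n01 = int(np.count_nonzero(a & ~b))
    n10 = int(np.count_nonzero(~a & b))
    n_disc = n01 + n10
    if n_disc == 0:
        return 0.0, 1.0
    statistic = (abs(n01 - n10) - 1) ** 2 / n_disc
    if n_disc >= 25:
        p = float(scipy.stats.chi2.sf(statistic, df=1))
    else:
        p = float(
            scipy.stats.binomtest(min(n01, n10), n_disc, 0.5, alternative="two-sided").pvalue
        )
    return float(statistic), p


def estimate_fdr(fpr: float, tpr: float, prior: float) -> float:
    """Genome-wide FDR implied by an operating point and an assumed prior.

    ``prior`` is the assumed fraction of windows that truly harbor an
    enhancer.  At a 5% FPR and 50% TPR this gives 9% for a 50% prior and
    47% for a 10% prior.
    """
    for name, value in (("fpr", fpr), ("tpr", tpr), ("prior", prior)):
        if not 0.0 <= value <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {value}")
    false_pos = fpr * (1.0 - prior)
    true_pos = tpr * prior
    if false_pos + true_pos == 0:
        raise ValueError("FDR undefined: no predicted positives (fpr=tpr=0 or degenerate prior)")
    return false_pos / (false_pos + true_pos)
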