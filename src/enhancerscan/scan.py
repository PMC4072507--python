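"""Genome-wide two-step sliding-window prediction.

Chromosomes are tiled into 1500 bp windows every 500 bp.  Each window is
scored by the Step-1 classifier trained WITHOUT the conservation kernel —
conservation is excluded genome-wide because the tested training regions
are strongly ascertained for conservation, which would not generalize.
Windows passing a cross-validation-derived score threshold (5% FPR by
default) are merged into enhancer calls; tissue classifiers (Step 2) are
then applied to every window with a positive Step-1 score, thresholded per
tissue, and merged per tissue.  A window may be called in several tissues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .features import build_feature_bundles, bundles_to_matrices
from .intervals import FeatureTrack, GenomeAssembly, GenomicInterval
from .mkl import MKLModel

__all__ = [
    "ScanWindow",
    "ScanResult",
    "make_windows",
    "score_windows",
    "call_and_merge",
    "assign_tissues",
    "run_scan",
]

WINDOW_SIZE = 1500
WINDOW_STEP = 500


@dataclass
class ScanWindow:
    interval: GenomicInterval
    step1_score: float = float("nan")
    tissue_scores: dict[str, float] = field(default_factory=dict)


@dataclass
class ScanResult:
    """All scored windows plus merged calls per task (step1 and tissues)."""

    windows: list[ScanWindow]
    merged: dict[str, FeatureTrack] = field(default_factory=dict)


def make_windows(
    chrom_sizes: Mapping[str, int], size: int = WINDOW_SIZE, step: int = WINDOW_STEP
) -> list[GenomicInterval]:
    """Tile each chromosome from position 0; trailing partial windows dropped."""
    if not (size >= step > 0):
        raise ValueError("require size >= step > 0")
    windows = []
    for chrom, length in chrom_sizes.items():
        for start in range(0, length - size + 1, step):
            windows.append(GenomicInterval(chrom, start, start + size))
    return windows


def _check_no_conservation(model: MKLModel, allow_conservation: bool) -> None:
    if allow_conservation:
        return
    if any(name == "conservation" for name in model.kernel_names):
        raise ValueError(
            "model includes a conservation kernel; genome-wide scanning uses "
            "models trained without conservation (pass allow_conservation=True "
            "to override)"
        )


def score_windows(
    windows: Sequence[GenomicInterval],
    model: MKLModel,
    genome: GenomeAssembly,
    tracks: Sequence[FeatureTrack],
    k: int = 4,
    allow_conservation: bool = False,
) -> list[ScanWindow]:
    """Attach a Step-1 decision score to every window (deterministic)."""
    _check_no_conservation(model, allow_conservation)
    mats = _window_feature_matrices(windows, genome, tracks, k)
    scores = model.score_features(mats)
    return [
        ScanWindow(interval=w, step1_score=float(s)) for w, s in zip(windows, scores)
    ]


def _window_feature_matrices(
    windows: Sequence[GenomicInterval],
    genome: GenomeAssembly,
    tracks: Sequence[FeatureTrack],
    k: int,
) -> dict[str, np.ndarray]:
    empty_cons = FeatureTrack("conservation")
    bundles = build_feature_bundles(windows, genome, tracks, empty_cons, k=k)
    mats = bundles_to_matrices(bundles)
    return {"spectrum": mats["spectrum"], "functional": mats["functional"],
            "conservation": mats["conservation"]}


def call_and_merge(
    scored: Sequence[ScanWindow],
    threshold: float,
    score_of: str = "step1",
) -> FeatureTrack:
    """Keep windows scoring >= threshold; merge overlapping or book-ended
    survivors on the same chromosome.  Merged score = max member score."""

    def _score(w: ScanWindow) -> float:
        return w.step1_score if score_of == "step1" else w.tissue_scores[score_of]

    passing = sorted(
        (w for w in scored if _score(w) >= threshold),
        key=lambda w: (w.interval.chrom, w.interval.start),
    )
    merged: list[GenomicInterval] = []
    for w in passing:
        iv, s = w.interval, _score(w)
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            prev = merged[-1]
            merged[-1] = GenomicInterval(
                prev.chrom,
                prev.start,
                max(prev.end, iv.end),
                name=prev.name,
                score=max(prev.score, s),
            )
        else:
            merged.append(
                GenomicInterval(iv.chrom, iv.start, iv.end, name=score_of, score=s)
            )
    return FeatureTrack(score_of, merged)


def assign_tissues(
    scored: Sequence[ScanWindow],
    tissue_models: Mapping[str, MKLModel],
    tissue_thresholds: Mapping[str, float],
    genome: GenomeAssembly,
    tracks: Sequence[FeatureTrack],
    k: int = 4,
    allow_conservation: bool = False,
) -> dict[str, FeatureTrack]:
    """Step 2: score tissue classifiers on windows with positive Step-1 score.

    Each tissue is called independently (a window may pass several); calls
    are merged per tissue exactly as in Step 1.
    """
    missing = [t for t in tissue_models if t not in tissue_thresholds]
    if missing:
        raise ValueError(f"missing thresholds for tissues {missing}")
    gated = [w for w in scored if w.step1_score > 0]
    out: dict[str, FeatureTrack] = {}
    if gated:
        mats = _window_feature_matrices([w.interval for w in gated], genome, tracks, k)
    for tissue, model in tissue_models.items():
        _check_no_conservation(model, allow_conservation)
        if gated:
            scores = model.score_features(mats)
            for w, s in zip(gated, scores):
                w.tissue_scores[tissue] = float(s)
        out[tissue] = call_and_merge(gated, tissue_thresholds[tissue], score_of=tissue)
    return out


def run_scan(
    genome: GenomeAssembly,
    tracks: Sequence[FeatureTrack],
    step1_model: MKLModel,
    step1_threshold: float,
    tissue_models: Mapping[str, MKLModel] | None = None,
    tissue_thresholds: Mapping[str, float] | None = None,
    size: int = WINDOW_SIZE,
    step: int = WINDOW_STEP,
    k: int = 4,
) -> ScanResult:
    """Full two-step scan over an assembly; returns windows and merged calls."""
    windows = make_windows(genome.sizes, size=size, step=step)
    scored = score_windows(windows, step1_model, genome, tracks, k=k)
    result = ScanResult(windows=scored)
    result.merged["step1"] = call_and_merge(scored, step1_threshold)
    if tissue_models:
        result.merged.update(
            assign_tissues(
                scored, tissue_models, tissue_thresholds or {}, genome, tracks, k=k
            )
        )
    return result
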