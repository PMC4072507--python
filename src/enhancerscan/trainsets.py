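"""Training-set construction for the two classification steps.

Step 1 (enhancer vs background) uses every validated enhancer as a
positive and, per positive, one random genomic region of identical length
on the same chromosome as a negative — excluding every tested region and
assembly gaps.  Tested-negative regions are NOT used as Step-1 negatives.

Step 2 (tissue assignment) partitions the tested regions: positives are
regions active in the tissue of interest (activity in other tissues as
well is allowed), negatives are all remaining tested regions, including
inactive ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .intervals import FeatureTrack, GenomeAssembly, GenomicInterval, VistaRecord, write_bed

__all__ = [
    "LabeledSet",
    "BRAIN_SUBTISSUES",
    "sample_matched_random",
    "build_step1_set",
    "build_step2_set",
    "build_brain_set",
    "labeled_set_to_bed",
]

BRAIN_SUBTISSUES = ("forebrain", "midbrain", "hindbrain")


@dataclass
class LabeledSet:
    """Positive/negative region ids for one training task, plus coordinates."""

    positives: list[str]
    negatives: list[str]
    task: str
    regions: dict[str, GenomicInterval] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = set(self.positives) & set(self.negatives)
        if overlap:
            raise ValueError(f"ids labeled both positive and negative: {sorted(overlap)[:5]}")
        if not self.positives or not self.negatives:
            raise ValueError(f"task {self.task!r}: both classes must be non-empty")

    @property
    def ids(self) -> list[str]:
        return list(self.positives) + list(self.negatives)

    @property
    def labels(self) -> np.ndarray:
        return np.array([1] * len(self.positives) + [-1] * len(self.negatives))

    def intervals(self) -> list[GenomicInterval]:
        return [self.regions[rid] for rid in self.ids]


def sample_matched_random(
    positives: Sequence[GenomicInterval],
    genome: GenomeAssembly,
    exclude: FeatureTrack,
    seed: int,
    max_attempts: int = 10_000,
) -> list[GenomicInterval]:
    """One random region per positive, matched in chromosome and length.

    Rejection-samples uniform starts until the candidate avoids ``exclude``,
    assembly gaps, and every positive.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    pos_track = FeatureTrack("positives", positives)
    out = []
    for i, pos in enumerate(positives):
        size = genome.sizes.get(pos.chrom)
        if size is None:
            raise ValueError(f"positive {i} on unknown chromosome {pos.chrom}")
        length = len(pos)
        if length > size:
            raise ValueError(f"positive {i} longer than chromosome {pos.chrom}")
        placed = None
        for _ in range(max_attempts):
            start = int(rng.integers(0, size - length + 1))
            cand = GenomicInterval(pos.chrom, start, start + length)
            if (
                not exclude.overlaps_any(cand)
                and not genome.gaps.overlaps_any(cand)
                and not pos_track.overlaps_any(cand)
            ):
                placed = cand
                break
        if placed is None:
            raise RuntimeError(
                f"could not place a matched random region for positive "
                f"{pos.name or i} ({pos.chrom}:{pos.start}-{pos.end}) "
                f"after {max_attempts} attempts"
            )
        out.append(placed)
    return out


def build_step1_set(
    records: Sequence[VistaRecord], genome: GenomeAssembly, seed: int
) -> LabeledSet:
    """Enhancer-vs-background set: all active records vs matched random regions."""
    actives = [rec for rec in records if rec.active]
    if not actives:
        raise ValueError("no active records to train on")
    # exclude all tested regions (active and inactive) from negative placement
    exclude = FeatureTrack("tested", [rec.interval for rec in records])
    randoms = sample_matched_random(
        [rec.interval for rec in actives], genome, exclude, seed
    )
    regions: dict[str, GenomicInterval] = {}
    positives, negatives = [], []
    for rec in actives:
        regions[rec.id] = rec.interval
        positives.append(rec.id)
    for i, iv in enumerate(randoms):
        rid = f"rnd_{i:05d}"
        regions[rid] = GenomicInterval(iv.chrom, iv.start, iv.end, name=rid)
        negatives.append(rid)
    return LabeledSet(positives, negatives, task="step1", regions=regions)


def build_step2_set(
    records: Sequence[VistaRecord],
    tissue: str,
    min_examples: int = 50,
    include_inactive: bool = True,
) -> LabeledSet:
    """Tissue-vs-rest set partitioning the tested regions.

    Positives are regions active in ``tissue`` (possibly among others);
    negatives are every other tested region.  Refuses tissues with too few
    positives for a stable classifier.
    """
    positives, negatives = [], []
    regions: dict[str, GenomicInterval] = {}
    for rec in records:
        if not include_inactive and not rec.active:
            continue
        regions[rec.id] = rec.interval
        if tissue in rec.tissues:
            positives.append(rec.id)
        else:
            negatives.append(rec.id)
    if len(positives) <= min_examples:
        raise ValueError(
            f"tissue {tissue!r} has only {len(positives)} positive examples "
            f"(> {min_examples} required)"
        )
    return LabeledSet(positives, negatives, task=tissue, regions=regions)


def build_brain_set(
    records: Sequence[VistaRecord],
    min_examples: int = 50,
    include_inactive: bool = True,
) -> LabeledSet:
    """Combined-brain set: positives active in forebrain, midbrain or hindbrain."""
    positives, negatives = [], []
    regions: dict[str, GenomicInterval] = {}
    for rec in records:
        if not include_inactive and not rec.active:
            continue
        regions[rec.id] = rec.interval
        if rec.tissues & set(BRAIN_SUBTISSUES):
            positives.append(rec.id)
        else:
            negatives.append(rec.id)
    if len(positives) <= min_examples:
        raise ValueError(
            f"combined brain set has only {len(positives)} positive examples "
            f"(> {min_examples} required)"
        )
    return LabeledSet(positives, negatives, task="brain", regions=regions)


def labeled_set_to_bed(labeled: LabeledSet, path: str | Path) -> None:
    """Serialize a labeled set as BED: task in name column, +/-1 in score."""
    intervals = []
    for rid, label in zip(labeled.ids, labeled.labels):
        iv = labeled.regions[rid]
        intervals.append(
            GenomicInterval(iv.chrom, iv.start, iv.end, name=labeled.task, score=float(label))
        )
    write_bed(FeatureTrack(labeled.task, intervals), path)
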