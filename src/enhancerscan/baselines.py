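"""Comparison baselines and the GWAS-SNP permutation enrichment test.

Baselines: a GC-content-only classifier (score = GC fraction), and
overlap-rule classifiers that call a region positive when it overlaps
peaks of given marks (any single mark, the union of mark groups, or their
intersection).  The enrichment test asks whether predicted enhancers
contain more GWAS SNPs than random length- and chromosome-matched,
gap-avoiding placements of the same regions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .features import gc_fraction
from .intervals import FeatureTrack, GenomeAssembly, GenomicInterval
from .trainsets import sample_matched_random

__all__ = [
    "PermutationResult",
    "gc_classifier_scores",
    "overlap_rule_classifier",
    "gwas_permutation_test",
    "read_snp_positions",
]

OVERLAP_RULES = ("any", "union_of_marks", "intersection_of_marks")


@dataclass
class PermutationResult:
    observed: int
    null_counts: np.ndarray
    p: float

    def __post_init__(self) -> None:
        n_perm = len(self.null_counts)
        if not (1.0 / (n_perm + 1) <= self.p <= 1.0):
            raise ValueError("p outside the achievable permutation range")


def gc_classifier_scores(
    regions: Sequence[GenomicInterval], genome: GenomeAssembly
) -> np.ndarray:
    """Score = GC fraction of each region; thresholding traces the ROC."""
    return np.array([gc_fraction(genome.fetch(region)) for region in regions])


def overlap_rule_classifier(
    regions: Sequence[GenomicInterval],
    track_groups: Sequence[Sequence[FeatureTrack]],
    rule: str,
) -> np.ndarray:
    """Binary predictions from peak-overlap rules.

    ``track_groups`` collects tracks per mark (e.g. one group per histone
    mark, several cell types each).  ``any``/``union_of_marks``: positive
    iff the region overlaps >=1 peak of any group; ``intersection_of_marks``:
    positive iff it overlaps >=1 peak of EVERY group.
    """
    if rule not in OVERLAP_RULES:
        raise ValueError(f"unknown rule {rule!r}; choose from {OVERLAP_RULES}")
    if not track_groups or any(len(group) == 0 for group in track_groups):
        raise ValueError("every track group must contain at least one track")
    preds = np.zeros(len(regions), dtype=int)
    for i, region in enumerate(regions):
        group_hits = [
            any(track.overlaps_any(region) for track in group)
            for group in track_groups
        ]
        preds[i] = int(all(group_hits) if rule == "intersection_of_marks" else any(group_hits))
    return preds


def _count_snps_in(regions: Sequence[GenomicInterval], snp_pos: dict[str, np.ndarray]) -> int:
    """Number of SNPs falling inside the union-insensitive region list.

    Counts each SNP once per containing region set membership; regions are
    assumed non-overlapping (predicted enhancer calls are merged).
    """
    total = 0
    for region in regions:
        pos = snp_pos.get(region.chrom)
        if pos is None:
            continue
        total += int(
            np.searchsorted(pos, region.end, side="left")
            - np.searchsorted(pos, region.start, side="left")
        )
    return total


def gwas_permutation_test(
    regions: FeatureTrack,
    snps: FeatureTrack,
    genome: GenomeAssembly,
    permutations: int = 1000,
    seed: int = 0,
) -> PermutationResult:
    """Permutation enrichment of SNPs inside predicted regions.

    The observed statistic is the number of SNPs contained in the regions.
    Each permutation re-places every region uniformly at random on its own
    chromosome with its own length, avoiding assembly gaps (randomized
    regions may overlap each other).  p uses the add-one convention
    p = (1 + #{null >= observed}) / (permutations + 1), so p is never 0.
    """
    if permutations < 1:
        raise ValueError("permutations must be >= 1")
    snp_pos: dict[str, np.ndarray] = {}
    for snp in snps:
        snp_pos.setdefault(snp.chrom, []).append(snp.start)  # type: ignore[arg-type]
    snp_pos = {c: np.sort(np.array(p)) for c, p in snp_pos.items()}

    observed = _count_snps_in(regions.intervals, snp_pos)
    no_exclusion = FeatureTrack("none")
    null_counts = np.empty(permutations, dtype=int)
    for i in range(permutations):
        placed = sample_matched_random(
            regions.intervals, genome, no_exclusion, seed=seed + i
        )
        null_counts[i] = _count_snps_in(placed, snp_pos)
    p = (1 + int(np.count_nonzero(null_counts >= observed))) / (permutations + 1)
    return PermutationResult(observed=observed, null_counts=null_counts, p=p)


def read_snp_positions(path: str, name: str = "snps") -> FeatureTrack:
    """Read SNPs from BED (1 bp intervals) or 2-column chrom/pos (1-based)."""
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 3 and fields[2].isdigit():
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            elif len(fields) == 2:
                chrom, pos = fields[0], int(fields[1])
                start, end = pos - 1, pos  # 1-based position -> 0-based interval
            else:
                raise ValueError(f"line {lineno}: expected BED or chrom<TAB>pos")
            intervals.append(GenomicInterval(chrom, start, end))
    return FeatureTrack(name, intervals)
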