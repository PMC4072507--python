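"""Per-region feature computation.

Each genomic region is summarised by three feature families that feed the
classifier, plus GC fraction for the content-only baseline:

* a k-mer spectrum (default k=4) of the region's DNA sequence,
* a binary vector of overlap with each functional-genomics peak track,
* the maximum score of any overlapping conservation element (0 if none).

k-mers are counted on the given strand only; windows containing a non-ACGT
character (assembly N runs, ambiguity codes) are skipped rather than
raising, so genome scans can cross gaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .intervals import FeatureTrack, GenomeAssembly, GenomicInterval

__all__ = [
    "SpectrumCounts",
    "FeatureBundle",
    "count_kmers",
    "gc_fraction",
    "binary_overlap_vector",
    "max_conservation",
    "build_feature_bundles",
    "bundles_to_matrices",
    "bundles_to_table",
]

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i


@dataclass(frozen=True)
class SpectrumCounts:
    """Occurrence counts of all 4^k k-mers, lexicographic over A<C<G<T."""

    k: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if len(self.counts) != 4**self.k:
            raise ValueError(f"counts must have length 4^{self.k}")


def _encode(seq: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def count_kmers(seq: str, k: int) -> SpectrumCounts:
    """Count all k-mer occurrences in ``seq`` (case-insensitive).

    Windows containing any non-ACGT character contribute nothing.  A
    sequence shorter than k yields all-zero counts.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n_kmers = 4**k
    if len(seq) < k:
        return SpectrumCounts(k, np.zeros(n_kmers, dtype=np.int64))
    codes = _encode(seq)
    valid = codes >= 0
    # rolling k-mer index: sum codes[i+j] * 4^(k-1-j)
    idx = np.zeros(len(codes) - k + 1, dtype=np.int64)
    ok = np.ones(len(codes) - k + 1, dtype=bool)
    for j in range(k):
        window = codes[j : j + len(idx)]
        idx = idx * 4 + np.where(window >= 0, window, 0)
        ok &= valid[j : j + len(idx)]
    counts = np.bincount(idx[ok], minlength=n_kmers).astype(np.int64)
    return SpectrumCounts(k, counts)


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T); non-ACGT characters excluded from the denominator."""
    codes = _encode(seq)
    n_valid = int(np.count_nonzero(codes >= 0))
    if n_valid == 0:
        raise ValueError("GC fraction undefined: sequence has no A/C/G/T bases")
    n_gc = int(np.count_nonzero((codes == 1) | (codes == 2)))
    return n_gc / n_valid


def binary_overlap_vector(
    region: GenomicInterval, tracks: Sequence[FeatureTrack]
) -> np.ndarray:
    """Presence/absence of overlap with each track, in the given track order."""
    return np.array(
        [1 if track.overlaps_any(region) else 0 for track in tracks], dtype=np.int8
    )


def max_conservation(region: GenomicInterval, elements: FeatureTrack) -> float:
    """Maximum score of any overlapping conservation element, 0 if none."""
    best = 0.0
    for element in elements.overlapping(region):
        if element.score is None:
            raise ValueError(
                f"conservation element {element.chrom}:{element.start}-{element.end} "
                "has no score"
            )
        best = max(best, float(element.score))
    return best


@dataclass
class FeatureBundle:
    """All features for one region, in classifier-ready form."""

    region_id: str
    overlap_bits: np.ndarray
    conservation: float
    spectrum: SpectrumCounts
    gc: float


def build_feature_bundles(
    regions: Sequence[GenomicInterval],
    genome: GenomeAssembly,
    tracks: Sequence[FeatureTrack],
    conservation_elements: FeatureTrack,
    k: int = 4,
    region_ids: Sequence[str] | None = None,
) -> list[FeatureBundle]:
    """One :class:`FeatureBundle` per region, preserving input order.

    Region ids default to ``name`` or ``chrom:start-end``.  A region outside
    its chromosome raises, naming the offending region.
    """
    if region_ids is not None and len(region_ids) != len(regions):
        raise ValueError("region_ids length must match regions")
    bundles = []
    for i, region in enumerate(regions):
        rid = (
            region_ids[i]
            if region_ids is not None
            else region.name or f"{region.chrom}:{region.start}-{region.end}"
        )
        try:
            seq = genome.fetch(region)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"region {rid}: {exc}") from exc
        codes = _encode(seq)
        has_acgt = bool(np.any(codes >= 0))
        bundles.append(
            FeatureBundle(
                region_id=rid,
                overlap_bits=binary_overlap_vector(region, tracks),
                conservation=max_conservation(region, conservation_elements),
                spectrum=count_kmers(seq, k),
                gc=gc_fraction(seq) if has_acgt else float("nan"),
            )
        )
    return bundles


def bundles_to_matrices(bundles: Sequence[FeatureBundle]) -> dict[str, np.ndarray]:
    """Stack bundles into per-family feature matrices (rows = regions).

    Keys: ``spectrum`` (n x 4^k), ``functional`` (n x n_tracks),
    ``conservation`` (n x 1), ``gc`` (n,).
    """
    if not bundles:
        raise ValueError("no bundles")
    return {
        "spectrum": np.stack([b.spectrum.counts for b in bundles]).astype(float),
        "functional": np.stack([b.overlap_bits for b in bundles]).astype(float),
        "conservation": np.array([[b.conservation] for b in bundles], dtype=float),
        "gc": np.array([b.gc for b in bundles], dtype=float),
    }


def bundles_to_table(
    bundles: Sequence[FeatureBundle], track_names: Sequence[str] | None = None
) -> pd.DataFrame:
    """Flat tab-separated-friendly table of all features for inspection."""
    if not bundles:
        return pd.DataFrame()
    k = bundles[0].spectrum.k
    kmer_names = _kmer_names(k)
    n_tracks = len(bundles[0].overlap_bits)
    if track_names is None:
        track_names = [f"track_{j}" for j in range(n_tracks)]
    rows = []
    for b in bundles:
        row: dict[str, object] = {"region_id": b.region_id}
        row.update(zip(track_names, b.overlap_bits.tolist()))
        row["conservation"] = b.conservation
        row["gc"] = b.gc
        row.update(zip(kmer_names, b.spectrum.counts.tolist()))
        rows.append(row)
    return pd.DataFrame(rows).set_index("region_id")


def _kmer_names(k: int) -> list[str]:
    names = [""]
    for _ in range(k):
        names = [p + base for p in names for base in "ACGT"]
    return names
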