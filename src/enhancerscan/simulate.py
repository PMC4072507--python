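"""Self-contained synthetic datasets for the whole prediction pipeline.

The generator emulates the statistical structure the classifier exploits,
at toy genome scale:

* a multi-chromosome assembly of i.i.d. bases at a background GC fraction,
* planted tissue-labeled enhancers, non-overlapping and well separated;
  heart enhancers get an elevated GC composition (0.49 vs 0.40 background,
  the contrast that makes heart enhancers the easiest tissue to call) and
  every tissue gets a few copies of a planted 6-mer motif,
* functional-genomics peak tracks affiliated with one tissue each: a peak
  covers a matching-tissue enhancer with high probability, an off-tissue
  enhancer with low probability, plus uniform background peaks,
* conservation elements covering most planted enhancers (high scores) and
  most tested-negative regions (the tested regions of the real training
  resource are strongly ascertained for conservation, active or not),
  plus sparse low-scoring background elements,
* a truth table of tested regions (active with tissue labels / inactive),
  and a scatter of GWAS-style SNPs.

Same seed, byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .intervals import (
    FeatureTrack,
    GenomeAssembly,
    GenomicInterval,
    VistaRecord,
    write_bed,
    write_chrom_sizes,
    write_fasta,
    write_vista_table,
)

__all__ = ["SimConfig", "SyntheticDataset", "generate_dataset", "truth_auc_ceiling"]

BASES = np.array(list("ACGT"))

DEFAULT_MOTIFS = {"heart": "CACGTG", "limb": "TGACAG", "brain": "CAGCTG"}


@dataclass
class SimConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_enhancers: int = 200
    n_negatives: int = 200  # tested regions without activity
    enhancer_length: int = 1500
    min_spacing: int = 5000  # between planted regions; avoids merge artifacts
    tissues: tuple[str, ...] = ("heart", "limb", "brain")
    tissue_proportions: tuple[float, ...] | None = None
    background_gc: float = 0.40
    heart_gc: float = 0.49
    motif_per_tissue: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    motif_copies: int = 2
    n_tracks: int = 12
    p_fg: float = 0.8  # matching-tissue track covers an enhancer
    p_offtissue: float = 0.2
    background_peak_rate: float = 30.0  # peaks per Mb
    peak_length: int = 400
    p_cons_enhancer: float = 0.95
    p_cons_inactive: float = 0.90
    cons_background_rate: float = 20.0  # elements per Mb
    cons_score_high: tuple[int, int] = (350, 650)
    cons_score_low: tuple[int, int] = (50, 300)
    n_snps: int = 300
    snp_in_enhancer_frac: float = 0.0  # 0 = null scatter

    def __post_init__(self) -> None:
        for name in ("background_gc", "heart_gc", "p_fg", "p_offtissue",
                     "p_cons_enhancer", "p_cons_inactive", "snp_in_enhancer_frac"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if min(self.chrom_length, self.enhancer_length, self.n_chroms) <= 0:
            raise ValueError("lengths and counts must be positive")
        if self.tissue_proportions is not None and len(self.tissue_proportions) != len(self.tissues):
            raise ValueError("tissue_proportions must match tissues")

    def tissue_gc(self, tissue: str) -> float:
        return self.heart_gc if tissue == "heart" else self.background_gc


@dataclass
class SyntheticDataset:
    config: SimConfig
    genome: GenomeAssembly
    tracks: list[FeatureTrack]
    conservation: FeatureTrack
    records: list[VistaRecord]
    truth: FeatureTrack  # planted enhancers, name = tissue
    snps: FeatureTrack

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write every component in its standard plain-text format."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tracks").mkdir(exist_ok=True)
        paths = {
            "genome": outdir / "genome.fa",
            "chrom_sizes": outdir / "genome.chrom.sizes",
            "conservation": outdir / "conservation.bed",
            "truth_table": outdir / "regions.tsv",
            "truth_bed": outdir / "truth_enhancers.bed",
            "snps": outdir / "snps.bed",
            "manifest": outdir / "manifest.json",
        }
        write_fasta(self.genome, paths["genome"])
        write_chrom_sizes(self.genome.sizes, paths["chrom_sizes"])
        write_bed(self.conservation, paths["conservation"])
        write_vista_table(self.records, paths["truth_table"])
        write_bed(self.truth, paths["truth_bed"])
        write_bed(self.snps, paths["snps"])
        for track in self.tracks:
            paths[f"track:{track.name}"] = p = outdir / "tracks" / f"{track.name}.bed"
            write_bed(track, p)
        manifest = dataclasses.asdict(self.config)
        manifest["tissues"] = list(manifest["tissues"])
        manifest["tissue_proportions"] = (
            list(self.config.tissue_proportions) if self.config.tissue_proportions else None
        )
        with open(paths["manifest"], "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return paths


def _place_regions(
    rng: np.random.Generator, config: SimConfig, n_regions: int
) -> list[tuple[str, int]]:
    """Non-overlapping placements >= min_spacing apart, spread over chroms.

    Uses the classic order-statistics construction: distribute counts over
    chromosomes in proportion to length, then convert sorted uniforms over
    the free space into spaced starts.
    """
    L, gap = config.enhancer_length, config.min_spacing
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    counts = rng.multinomial(n_regions, np.full(config.n_chroms, 1.0 / config.n_chroms))
    placements: list[tuple[str, int]] = []
    margin = 2000  # keep clear of chromosome ends
    for chrom, n_c in zip(chroms, counts):
        if n_c == 0:
            continue
        free = config.chrom_length - 2 * margin - n_c * L - (n_c - 1) * gap
        if free < 0:
            raise ValueError(
                f"cannot place {n_c} regions of {L} bp with {gap} bp spacing "
                f"on a {config.chrom_length} bp chromosome"
            )
        offsets = np.sort(rng.uniform(0, free, size=n_c))
        for i, off in enumerate(offsets):
            start = int(margin + off + i * (L + gap))
            placements.append((chrom, start))
    return placements


def _place_negative_slots(
    rng: np.random.Generator,
    config: SimConfig,
    enh_slots: list[tuple[str, int]],
    clearance: int = 1000,
    max_attempts: int = 100_000,
) -> list[tuple[str, int]]:
    """Place tested-negative regions avoiding enhancers (with clearance)
    and each other; no minimum spacing among negatives."""
    L = config.enhancer_length
    occupied: dict[str, list[tuple[int, int]]] = {
        f"chr{i + 1}": [] for i in range(config.n_chroms)
    }
    for chrom, start in enh_slots:
        occupied[chrom].append((start - clearance, start + L + clearance))
    chroms = list(occupied)
    out: list[tuple[str, int]] = []
    for _ in range(config.n_negatives):
        for attempt in range(max_attempts):
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            start = int(rng.integers(0, config.chrom_length - L + 1))
            if all(start >= e or start + L <= s for s, e in occupied[chrom]):
                occupied[chrom].append((start, start + L))
                out.append((chrom, start))
                break
        else:
            raise ValueError("could not place tested-negative regions; genome too full")
    return out


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate a complete synthetic dataset (deterministic given the seed)."""
    rng = np.random.default_rng(config.seed)
    L = config.enhancer_length
    total_needed = config.n_enhancers * (L + config.min_spacing)
    if total_needed > config.n_chroms * config.chrom_length:
        raise ValueError(
            f"{config.n_enhancers} enhancers need ~{total_needed} bp, "
            f"genome has {config.n_chroms * config.chrom_length}"
        )

    # --- region layout: enhancers get the spaced construction; tested-negative
    # regions only need to avoid overlap, placed by rejection sampling
    enh_slots = _place_regions(rng, config, config.n_enhancers)
    neg_slots = _place_negative_slots(rng, config, enh_slots)

    proportions = (
        np.asarray(config.tissue_proportions, dtype=float)
        if config.tissue_proportions is not None
        else np.full(len(config.tissues), 1.0 / len(config.tissues))
    )
    proportions = proportions / proportions.sum()
    enh_tissues = [
        config.tissues[i]
        for i in rng.choice(len(config.tissues), size=config.n_enhancers, p=proportions)
    ]

    # --- sequences: background, then overwrite planted enhancers
    seq_codes = {
        f"chr{i + 1}": _random_seq(rng, config.chrom_length, config.background_gc)
        for i in range(config.n_chroms)
    }
    motif_codes = {
        t: np.array([{"A": 0, "C": 1, "G": 2, "T": 3}[b] for b in m.upper()])
        for t, m in config.motif_per_tissue.items()
    }
    enhancers: list[GenomicInterval] = []
    for (chrom, start), tissue in zip(enh_slots, enh_tissues):
        body = _random_seq(rng, L, config.tissue_gc(tissue))
        motif = motif_codes.get(tissue)
        if motif is not None and config.motif_copies > 0:
            m = len(motif)
            n_slots = L // m
            slots = rng.choice(n_slots, size=min(config.motif_copies, n_slots), replace=False)
            for s in slots:
                body[s * m : s * m + m] = motif
        seq_codes[chrom][start : start + L] = body
        enhancers.append(GenomicInterval(chrom, start, start + L, name=tissue))
    negatives = [GenomicInterval(c, s, s + L, name="inactive") for c, s in neg_slots]

    genome = GenomeAssembly(
        sequences={c: "".join(BASES[codes]) for c, codes in seq_codes.items()}
    )

    # --- functional-genomics tracks
    per_tissue = max(1, config.n_tracks // len(config.tissues))
    track_specs = []
    for tissue in config.tissues:
        for j in range(per_tissue):
            track_specs.append((f"{tissue}_mark{j + 1}", tissue))
    for j in range(config.n_tracks - len(track_specs)):
        track_specs.append((f"unaffiliated_mark{j + 1}", None))

    tracks = []
    for name, affiliation in track_specs:
        peaks = []
        for enh in enhancers:
            p = config.p_fg if enh.name == affiliation else config.p_offtissue
            if rng.random() < p:
                pad_left = int(rng.integers(0, 251))
                pad_right = int(rng.integers(0, 251))
                peaks.append(
                    GenomicInterval(
                        enh.chrom,
                        max(0, enh.start - pad_left),
                        min(genome.sizes[enh.chrom], enh.end + pad_right),
                    )
                )
        for chrom, size in genome.sizes.items():
            n_bg = rng.poisson(config.background_peak_rate * size / 1e6)
            for start in rng.integers(0, max(1, size - config.peak_length), size=n_bg):
                peaks.append(GenomicInterval(chrom, int(start), int(start) + config.peak_length))
        tracks.append(FeatureTrack(name, peaks))

    # --- conservation elements
    cons = []
    lo, hi = config.cons_score_high
    for region, p_cov in [(e, config.p_cons_enhancer) for e in enhancers] + [
        (n, config.p_cons_inactive) for n in negatives
    ]:
        if rng.random() < p_cov:
            elen = int(rng.integers(L // 4, (3 * L) // 4))
            offset = int(rng.integers(0, L - elen))
            cons.append(
                GenomicInterval(
                    region.chrom,
                    region.start + offset,
                    region.start + offset + elen,
                    name="element",
                    score=float(rng.integers(lo, hi + 1)),
                )
            )
    lo_bg, hi_bg = config.cons_score_low
    for chrom, size in genome.sizes.items():
        n_bg = rng.poisson(config.cons_background_rate * size / 1e6)
        for start in rng.integers(0, size - 400, size=n_bg):
            elen = int(rng.integers(100, 401))
            cons.append(
                GenomicInterval(
                    chrom,
                    int(start),
                    min(size, int(start) + elen),
                    name="element",
                    score=float(rng.integers(lo_bg, hi_bg + 1)),
                )
            )
    conservation = FeatureTrack("conservation", cons)

    # --- truth table
    records = []
    for i, enh in enumerate(enhancers):
        records.append(
            VistaRecord(
                f"EH{i + 1:04d}",
                GenomicInterval(enh.chrom, enh.start, enh.end, name=f"EH{i + 1:04d}"),
                frozenset({enh.name}),
            )
        )
    for i, neg in enumerate(negatives):
        records.append(
            VistaRecord(
                f"NEG{i + 1:04d}",
                GenomicInterval(neg.chrom, neg.start, neg.end, name=f"NEG{i + 1:04d}"),
                frozenset(),
            )
        )

    # --- SNPs: a fraction planted inside enhancers, the rest uniform
    snp_ivs = []
    n_inside = int(round(config.n_snps * config.snp_in_enhancer_frac))
    if n_inside and enhancers:
        for idx in rng.integers(0, len(enhancers), size=n_inside):
            enh = enhancers[idx]
            pos = int(rng.integers(enh.start, enh.end))
            snp_ivs.append(GenomicInterval(enh.chrom, pos, pos + 1))
    chrom_names = list(genome.sizes)
    for _ in range(config.n_snps - n_inside):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        pos = int(rng.integers(0, genome.sizes[chrom]))
        snp_ivs.append(GenomicInterval(chrom, pos, pos + 1))
    snps = FeatureTrack("snps", snp_ivs)

    return SyntheticDataset(
        config=config,
        genome=genome,
        tracks=tracks,
        conservation=conservation,
        records=records,
        truth=FeatureTrack("truth", enhancers),
        snps=snps,
    )


def truth_auc_ceiling(config: SimConfig, n_mc: int = 20_000, seed: int = 0) -> float:
    """Monte-Carlo Bayes-optimal AUC of GC content alone (heart vs background).

    Per-region GC is Binomial(L, gc)/L under the i.i.d. composition model;
    the ceiling is P(gc_heart > gc_background) + 1/2 P(tie).
    """
    rng = np.random.default_rng(seed)
    L = config.enhancer_length
    pos = rng.binomial(L, config.heart_gc, size=n_mc)
    neg = rng.binomial(L, config.background_gc, size=n_mc)
    return float(np.mean((pos > neg) + 0.5 * (pos == neg)))
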