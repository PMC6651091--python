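"""Gene-feature partitioning of DMRs and intragenic position analysis.

Each DMR is assigned a single label from {promoter, gene_body, downstream,
unassociated}. Promoter and downstream windows are the 1500-bp flanks
upstream of the TSS and downstream of the TES, strand-aware; overlap is >= 1
shared bp. A DMR overlapping several windows of one gene takes the precedence
gene_body > promoter > downstream, so the three feature counts partition the
gene-associated total exactly. A DMR overlapping several genes is assigned to
the gene with the largest bp overlap against the gene's full footprint
(gene body plus both flanks); ties go to the lexicographically smallest
gene_id and are logged.

Intragenic DMRs additionally get an intron/exon placement (``spanning`` when
the DMR interval crosses any exon boundary) and a relative position: the
distance of the DMR midpoint from the TSS, measured in the direction of
transcription, divided by gene length, as a percentage clipped to [0, 100].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from intervaltree import IntervalTree

from .formats_io import GeneModel, GenomicInterval

logger = logging.getLogger(__name__)

FLANK = 1500

FEATURES = ("promoter", "gene_body", "downstream", "unassociated")


@dataclass(frozen=True)
class GeneFeatureAnnotation:
    gene_id: str | None
    feature: str  # promoter | gene_body | downstream | unassociated
    intragenic_placement: str = "n/a"  # intron | exon | spanning | n/a
    relative_position: float | None = None
    flank: int = FLANK

    def __post_init__(self) -> None:
        if (self.feature == "unassociated") != (self.gene_id is None):
            raise ValueError("feature=unassociated iff gene_id is None")
        if (self.relative_position is not None) != (self.feature == "gene_body"):
            raise ValueError("relative_position defined iff feature=gene_body")


def promoter_window(gene: GeneModel, flank: int = FLANK) -> GenomicInterval | None:
    """The 1500-bp window upstream of the TSS, strand-aware; None if it would
    fall entirely off the chromosome start."""
    iv = gene.interval
    if gene.strand == "+":
        start, end = iv.start - flank, iv.start
    else:
        start, end = iv.end, iv.end + flank
    start = max(start, 0)
    if start >= end:
        return None
    return GenomicInterval(iv.chrom, start, end, gene.strand)


def downstream_window(gene: GeneModel, flank: int = FLANK) -> GenomicInterval | None:
    """The 1500-bp window past the TES, strand-aware."""
    iv = gene.interval
    if gene.strand == "+":
        start, end = iv.end, iv.end + flank
    else:
        start, end = iv.start - flank, iv.start
    start = max(start, 0)
    if start >= end:
        return None
    return GenomicInterval(iv.chrom, start, end, gene.strand)


def relative_position(dmr: GenomicInterval, gene: GeneModel) -> float:
    """Relative intragenic position of the DMR midpoint, percent of gene length.

    0 at the TSS, 100 at the TES, measured along the direction of
    transcription; exactly invariant under translation of the whole gene and
    reflection to the opposite strand (the strand anchors are the interval's
    half-open endpoints).
    """
    length = gene.length
    if length <= 0:
        raise ValueError(f"gene {gene.gene_id}: zero-length model")
    mid = dmr.midpoint
    if gene.strand == "+":
        frac = (mid - gene.interval.start) / length
    else:
        frac = (gene.interval.end - mid) / length
    return float(min(100.0, max(0.0, 100.0 * frac)))


def intragenic_placement(dmr: GenomicInterval, gene: GeneModel) -> str:
    """intron / exon / spanning for a DMR assigned to the gene body."""
    for ex in gene.exons:
        if dmr.start >= ex.start and dmr.end <= ex.end:
            return "exon"
    # intron gaps between consecutive exons, plus terminal segments inside the
    # gene extent not covered by an exon
    gaps = []
    prev = gene.interval.start
    for ex in gene.exons:
        if ex.start > prev:
            gaps.append((prev, ex.start))
        prev = ex.end
    if gene.interval.end > prev:
        gaps.append((prev, gene.interval.end))
    for gap_start, gap_end in gaps:
        if dmr.start >= gap_start and dmr.end <= gap_end:
            return "intron"
    return "spanning"


class GeneContextIndex:
    """Interval index over gene footprints (gene extent plus both flanks)."""

    def __init__(self, genes: list[GeneModel], flank: int = FLANK) -> None:
        self.flank = flank
        self.genes = {g.gene_id: g for g in genes}
        if len(self.genes) != len(genes):
            raise ValueError("duplicate gene_ids")
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            iv = g.interval
            tree = self._trees.setdefault(iv.chrom, IntervalTree())
            tree.addi(max(0, iv.start - flank), iv.end + flank, g.gene_id)

    def candidates(self, query: GenomicInterval) -> list[GeneModel]:
        tree = self._trees.get(query.chrom)
        if tree is None:
            return []
        return [self.genes[hit.data] for hit in tree.overlap(query.start, query.end)]


def classify_feature(
    dmr: GenomicInterval,
    genes: list[GeneModel] | GeneContextIndex,
    flank: int = FLANK,
) -> GeneFeatureAnnotation:
    """Assign a single gene-feature label to one DMR (see module docstring)."""
    index = genes if isinstance(genes, GeneContextIndex) else GeneContextIndex(genes, flank)
    flank = index.flank
    best: GeneModel | None = None
    best_overlap = 0
    for gene in sorted(index.candidates(dmr), key=lambda g: g.gene_id):
        iv = gene.interval
        footprint = GenomicInterval(
            iv.chrom, max(0, iv.start - flank), iv.end + flank, iv.strand
        )
        ov = dmr.overlap_bp(footprint)
        if ov > best_overlap:
            best, best_overlap = gene, ov
        elif ov == best_overlap and ov > 0 and best is not None and gene.gene_id != best.gene_id:
            logger.info(
                "DMR %s:%d-%d ties between genes %s and %s; keeping %s",
                dmr.chrom, dmr.start, dmr.end, best.gene_id, gene.gene_id, best.gene_id,
            )
    if best is None:
        return GeneFeatureAnnotation(None, "unassociated")
    if dmr.overlap_bp(best.interval) > 0:
        return GeneFeatureAnnotation(
            best.gene_id,
            "gene_body",
            intragenic_placement(dmr, best),
            relative_position(dmr, best),
            flank,
        )
    prom = promoter_window(best, flank)
    if prom is not None and dmr.overlap_bp(prom) > 0:
        return GeneFeatureAnnotation(best.gene_id, "promoter", flank=flank)
    return GeneFeatureAnnotation(best.gene_id, "downstream", flank=flank)


def classify_features(
    dmrs: list[GenomicInterval], genes: list[GeneModel], flank: int = FLANK
) -> list[GeneFeatureAnnotation]:
    index = GeneContextIndex(genes, flank)
    return [classify_feature(d, index) for d in dmrs]


def dmg_set(annotations: list[GeneFeatureAnnotation]) -> set[str]:
    """Differentially methylated genes: genes hit by >= 1 DMR in any window."""
    return {a.gene_id for a in annotations if a.gene_id is not None}


# ---------------------------------------------------------------------------
# Printed-summary arithmetic
# ---------------------------------------------------------------------------

def round_half_up(x: float, ndigits: int = 0) -> float:
    """Round with ties away from zero at the printed granularity."""
    scale = 10**ndigits
    return math.floor(abs(x) * scale + 0.5) / scale * (1 if x >= 0 else -1)


@dataclass
class PartitionSummary:
    total_dmrs: int
    direction_counts: dict[str, int]
    direction_pct: dict[str, float]  # integer granularity
    zone_counts: dict[str, int]
    zone_pct: dict[str, float]  # one-decimal granularity
    feature_counts: dict[str, int]
    feature_pct: dict[str, float]  # integer granularity
    gene_associated: int
    gene_associated_pct: float
    feature_direction_counts: dict[str, dict[str, int]]
    feature_direction_pct: dict[str, dict[str, float]]


def summarize_partition(
    annotations: list[GeneFeatureAnnotation],
    zones: list,  # list[IslandZoneAnnotation]
    directions: list[str],
) -> PartitionSummary:
    """Counts and printed-granularity percentages for the zone trichotomy, the
    feature partition, and per-feature direction splits.

    Feature and direction shares are rounded half-up to whole percents, zone
    shares to one decimal — the granularities of the published figures.
    """
    n = len(directions)
    if len(annotations) != n or len(zones) != n:
        raise ValueError("annotations, zones and directions must align one per DMR")

    def pct(count: int, digits: int) -> float:
        return round_half_up(100.0 * count / n, digits) if n else 0.0

    direction_counts: dict[str, int] = {}
    for d in directions:
        direction_counts[d] = direction_counts.get(d, 0) + 1
    zone_counts = {"island": 0, "shore": 0, "open_sea": 0}
    for z in zones:
        zone_counts[z.zone] += 1
    feature_counts = {f: 0 for f in FEATURES}
    for a in annotations:
        feature_counts[a.feature] += 1
    gene_associated = n - feature_counts["unassociated"]

    feature_direction_counts: dict[str, dict[str, int]] = {
        f: {} for f in ("promoter", "gene_body", "downstream")
    }
    for a, d in zip(annotations, directions):
        if a.feature in feature_direction_counts:
            fd = feature_direction_counts[a.feature]
            fd[d] = fd.get(d, 0) + 1
    feature_direction_pct = {
        f: {
            d: round_half_up(100.0 * c / sum(fd.values()), 0)
            for d, c in fd.items()
        }
        if fd
        else {}
        for f, fd in feature_direction_counts.items()
    }

    return PartitionSummary(
        total_dmrs=n,
        direction_counts=direction_counts,
        direction_pct={d: pct(c, 0) for d, c in direction_counts.items()},
        zone_counts=zone_counts,
        zone_pct={z: pct(c, 1) for z, c in zone_counts.items()},
        feature_counts=feature_counts,
        feature_pct={f: pct(c, 0) for f, c in feature_counts.items()},
        gene_associated=gene_associated,
        gene_associated_pct=pct(gene_associated, 0),
        feature_direction_counts=feature_direction_counts,
        feature_direction_pct=feature_direction_pct,
    )
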