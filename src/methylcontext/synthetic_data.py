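"""Synthetic methylome generator with ground truth for every pipeline stage.

The generator emulates a three-group (MHF / PHF / CON) liver methylome study
profiled with two complementary assays: MeDIP (read depth proportional to
methylated CpG density) and MRE (reads at unmethylated methylation-sensitive
restriction sites). It produces:

* a genome of AT-rich, CpG-depleted background with planted GC- and CpG-rich
  islands (planted by composition, so the island caller is tested against
  emergent sequence, with the intended answer recorded as truth intervals);
* non-overlapping gene models with exon chains;
* per-bin methylation levels per group, with ``planted_dmr_count`` bins forced
  apart by ``dmr_effect`` in a known direction (the truth layer);
* per-sample negative-binomial MeDIP/MRE bin counts (Poisson at dispersion 0);
* a per-animal expression table in which a gene linked to an intragenic DMR
  receives a group effect whose sign follows the DMR's relative position
  (TSS-proximal methylation represses, TES-proximal methylation activates).

Everything is driven by ``SimulationConfig.seed``; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import gene_context
from .dmr_calling import BinMethylProfile, make_bins
from .formats_io import GeneModel, GenomicInterval

MRE_MOTIFS = ("CCGG", "CCGC", "GCGC", "ACGT", "CGCG")

_BASES = np.array(list("ACGT"))


class SimulationError(ValueError):
    """A configuration that cannot be realised (e.g. islands do not fit)."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic methylome.

    Defaults describe a compact two-chromosome genome with the statistical
    structure the pipeline assumes: AT-rich CpG-depleted background
    (GC 0.40, 80% of background CpG dinucleotides mutated away), GC 0.70
    islands, three diet groups with three animals each, mean bin coverage 30
    with mild overdispersion, and planted differential-methylation effects of
    0.6 on the methylation-fraction scale.
    """

    genome_length: int = 1_000_000
    n_chroms: int = 2
    island_count: int = 40
    island_length_range: tuple[int, int] = (300, 1500)
    background_gc: float = 0.40
    island_gc: float = 0.70
    cpg_depletion: float = 0.8
    gene_count: int = 60
    gene_length_range: tuple[int, int] = (2_000, 15_000)
    exons_per_gene_range: tuple[int, int] = (2, 8)
    n_samples_per_group: int = 3
    groups: tuple[str, ...] = ("MHF", "PHF", "CON")
    planted_dmr_count: int = 50
    dmr_effect: float = 0.6
    mean_coverage: float = 30.0
    dispersion: float = 0.05
    bin_size: int = 500
    expression_effect: float = 2.0
    expression_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.background_gc < self.island_gc <= 1):
            raise SimulationError("require 0 <= background_gc < island_gc <= 1")
        for name in ("island_length_range", "gene_length_range", "exons_per_gene_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo <= 0:
                raise SimulationError(f"{name}: require 0 < low <= high")
        if not (0 < self.dmr_effect <= 1):
            raise SimulationError("dmr_effect must be in (0, 1]")
        if self.n_samples_per_group < 1:
            raise SimulationError("n_samples_per_group must be >= 1")
        if self.dispersion < 0:
            raise SimulationError("dispersion must be >= 0")
        if self.mean_coverage <= 0:
            raise SimulationError("mean_coverage must be positive")
        if self.genome_length < self.n_chroms * self.bin_size:
            raise SimulationError("genome too short for the requested chromosomes")
        if self.planted_dmr_count > 0 and not {"MHF", "PHF"} <= set(self.groups):
            raise SimulationError("planted DMRs require both MHF and PHF groups")

    @property
    def chrom_lengths(self) -> dict[str, int]:
        base = self.genome_length // self.n_chroms
        lengths = {f"chr{i + 1}": base for i in range(self.n_chroms)}
        lengths[f"chr{self.n_chroms}"] += self.genome_length - base * self.n_chroms
        return lengths

    @property
    def samples(self) -> list[str]:
        return [f"{g}_{i + 1}" for g in self.groups for i in range(self.n_samples_per_group)]

    @property
    def group_of(self) -> dict[str, str]:
        return {s: s.rsplit("_", 1)[0] for s in self.samples}


@dataclass(frozen=True)
class MreSite:
    interval: GenomicInterval
    motif: str

    def __post_init__(self) -> None:
        if self.motif not in MRE_MOTIFS:
            raise ValueError(f"unknown MRE motif {self.motif!r}")


@dataclass
class SimulatedGenome:
    sequences: dict[str, str]
    islands: list[GenomicInterval]  # truth intervals
    genes: list[GeneModel]


@dataclass
class MethylationState:
    """Per-bin, per-group methylation levels plus the planted-DMR truth layer.

    ``truth`` holds one label per bin from {none, MHF_higher, PHF_higher};
    ``cpg_per_bin`` is carried along because MeDIP signal scales with it.
    """

    bins: list[GenomicInterval]
    partial: np.ndarray
    levels: dict[str, np.ndarray]
    truth: np.ndarray  # object dtype labels
    cpg_per_bin: np.ndarray

    def __post_init__(self) -> None:
        for g, lv in self.levels.items():
            if np.any((lv < 0) | (lv > 1)):
                raise ValueError(f"group {g}: methylation levels outside [0, 1]")


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def _deplete_cpg(codes: np.ndarray, rng: np.random.Generator, fraction: float) -> None:
    """Mutate the G of a fraction of CG dinucleotides to A or T, in place."""
    if fraction <= 0:
        return
    cg = np.flatnonzero((codes[:-1] == 1) & (codes[1:] == 2))
    hit = cg[rng.random(cg.size) < fraction]
    codes[hit + 1] = np.where(rng.random(hit.size) < 0.5, 0, 3)


def _place_nonoverlapping(
    rng: np.random.Generator,
    chrom_len: int,
    lengths: list[int],
    what: str,
    max_tries: int = 2000,
) -> list[tuple[int, int]]:
    placed: list[tuple[int, int]] = []
    for L in lengths:
        if L > chrom_len:
            raise SimulationError(f"{what} of length {L} exceeds chromosome length {chrom_len}")
        for _ in range(max_tries):
            start = int(rng.integers(0, chrom_len - L + 1))
            cand = (start, start + L)
            if all(cand[1] <= s or cand[0] >= e for s, e in placed):
                placed.append(cand)
                break
        else:
            raise SimulationError(
                f"could not place {len(lengths)} non-overlapping {what}s of total length "
                f"{sum(lengths)} on a {chrom_len} bp chromosome"
            )
    return sorted(placed)


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate the genome sequence with planted islands and gene models."""
    rng = np.random.default_rng([1, config.seed])
    chrom_lengths = config.chrom_lengths
    chroms = list(chrom_lengths)

    # split island/gene budgets across chromosomes proportionally to length
    island_chroms = rng.choice(chroms, size=config.island_count, replace=True)
    gene_chroms = rng.choice(chroms, size=config.gene_count, replace=True)

    sequences: dict[str, str] = {}
    islands: list[GenomicInterval] = []
    genes: list[GeneModel] = []
    for chrom in chroms:
        length = chrom_lengths[chrom]
        codes = _random_sequence(rng, length, config.background_gc)
        _deplete_cpg(codes, rng, config.cpg_depletion)

        n_isl = int(np.sum(island_chroms == chrom))
        isl_lens = [
            int(rng.integers(config.island_length_range[0], config.island_length_range[1] + 1))
            for _ in range(n_isl)
        ]
        for start, end in _place_nonoverlapping(rng, length, isl_lens, "island"):
            codes[start:end] = _random_sequence(rng, end - start, config.island_gc)
            islands.append(GenomicInterval(chrom, start, end))

        n_gen = int(np.sum(gene_chroms == chrom))
        gene_lens = [
            int(rng.integers(config.gene_length_range[0], config.gene_length_range[1] + 1))
            for _ in range(n_gen)
        ]
        for gi, (start, end) in enumerate(_place_nonoverlapping(rng, length, gene_lens, "gene")):
            strand = "+" if rng.random() < 0.5 else "-"
            gene_id = f"gene_{chrom}_{start}"
            interval = GenomicInterval(chrom, start, end, strand)
            genes.append(GeneModel(gene_id, interval, _random_exons(rng, interval, config)))

        sequences[chrom] = "".join(_BASES[codes])

    islands.sort(key=lambda iv: (iv.chrom, iv.start))
    genes.sort(key=lambda g: (g.interval.chrom, g.interval.start))
    return SimulatedGenome(sequences, islands, genes)


def _random_exons(
    rng: np.random.Generator, interval: GenomicInterval, config: SimulationConfig
) -> tuple[GenomicInterval, ...]:
    """An exon chain: k disjoint exons, first starting at the gene start and
    last ending at the gene end (so the extent is transcribed)."""
    lo, hi = config.exons_per_gene_range
    k = int(rng.integers(lo, hi + 1))
    length = interval.length
    k = max(1, min(k, length // 100))  # need room for >= 50 bp exons/introns
    # 2k-2 distinct interior cut points give 2k-1 non-empty alternating
    # exon/intron segments; first and last segments are exons, so the whole
    # extent is transcribed
    cuts = np.sort(rng.choice(np.arange(1, length), size=2 * k - 2, replace=False))
    edges = np.concatenate([[0], cuts, [length]])
    exons = [
        GenomicInterval(
            interval.chrom,
            interval.start + int(edges[i]),
            interval.start + int(edges[i + 1]),
            interval.strand,
        )
        for i in range(0, 2 * k - 1, 2)
    ]
    return tuple(exons)


# ---------------------------------------------------------------------------
# MRE recognition sites
# ---------------------------------------------------------------------------

def find_mre_sites(sequence: str, chrom: str = "chr") -> list[MreSite]:
    """All forward-strand occurrences of the five methylation-sensitive
    restriction-enzyme recognition sequences (CCGG, CCGC, GCGC, ACGT, CGCG),
    sorted by coordinate; overlapping occurrences are all reported."""
    seq = sequence.upper()
    sites: list[MreSite] = []
    for motif in MRE_MOTIFS:
        start = seq.find(motif)
        while start != -1:
            sites.append(MreSite(GenomicInterval(chrom, start, start + len(motif), "+"), motif))
            start = seq.find(motif, start + 1)
    sites.sort(key=lambda s: (s.interval.start, s.motif))
    return sites


def find_mre_sites_genome(sequences: dict[str, str]) -> list[MreSite]:
    out: list[MreSite] = []
    for chrom, seq in sequences.items():
        out.extend(find_mre_sites(seq, chrom))
    return out


# ---------------------------------------------------------------------------
# Methylation state and counts
# ---------------------------------------------------------------------------

def _per_bin_counts(
    bins: list[GenomicInterval], positions: dict[str, np.ndarray]
) -> np.ndarray:
    out = np.zeros(len(bins), dtype=np.int64)
    by_chrom: dict[str, list[int]] = {}
    for i, iv in enumerate(bins):
        by_chrom.setdefault(iv.chrom, []).append(i)
    for chrom, idx in by_chrom.items():
        pos = positions.get(chrom)
        if pos is None or pos.size == 0:
            continue
        starts = np.array([bins[i].start for i in idx])
        ends = np.array([bins[i].end for i in idx])
        out[np.asarray(idx)] = np.searchsorted(pos, ends) - np.searchsorted(pos, starts)
    return out


def cpg_positions(sequences: dict[str, str]) -> dict[str, np.ndarray]:
    out = {}
    for chrom, seq in sequences.items():
        arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
        out[chrom] = np.flatnonzero((arr[:-1] == ord("C")) & (arr[1:] == ord("G")))
    return out


def make_methylation_state(
    genome: SimulatedGenome,
    config: SimulationConfig,
    mre_sites: list[MreSite] | None = None,
) -> MethylationState:
    """Draw per-bin methylation levels and plant the DMR truth layer.

    Bins overlapping a truth island are lowly methylated (Beta(2, 6)), other
    bins highly (Beta(6, 2)); all groups share the base level. DMR bins are
    planted only where differential signal is observable (>= 3 CpGs, >= 1 MRE
    site, full-width bin) and forced to 0.5 +- dmr_effect/2 in MHF and PHF,
    with CON held at the 0.5 midpoint.
    """
    bins, partial = make_bins(config.chrom_lengths, config.bin_size)
    rng = np.random.default_rng([2, config.seed])

    cpg = _per_bin_counts(bins, cpg_positions(genome.sequences))
    if mre_sites is None:
        mre_sites = find_mre_sites_genome(genome.sequences)
    site_pos: dict[str, list[int]] = {}
    for s in mre_sites:
        site_pos.setdefault(s.interval.chrom, []).append(s.interval.start)
    sites = _per_bin_counts(
        bins, {c: np.sort(np.asarray(p)) for c, p in site_pos.items()}
    )

    island_flag = np.zeros(len(bins), dtype=bool)
    isl_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in genome.islands:
        isl_by_chrom.setdefault(iv.chrom, []).append(iv)
    for i, b in enumerate(bins):
        island_flag[i] = any(b.overlaps(iv) for iv in isl_by_chrom.get(b.chrom, []))

    base = np.where(
        island_flag, rng.beta(2, 6, size=len(bins)), rng.beta(6, 2, size=len(bins))
    )
    levels = {g: base.copy() for g in config.groups}
    truth = np.array(["none"] * len(bins), dtype=object)

    eligible = np.flatnonzero((cpg >= 3) & (sites >= 1) & ~partial)
    if eligible.size < config.planted_dmr_count:
        raise SimulationError(
            f"only {eligible.size} bins carry enough CpG/MRE signal for the "
            f"{config.planted_dmr_count} requested planted DMRs"
        )
    chosen = rng.choice(eligible, size=config.planted_dmr_count, replace=False)
    hi_level = 0.5 + config.dmr_effect / 2
    lo_level = 0.5 - config.dmr_effect / 2
    for b in chosen:
        if rng.random() < 0.5:
            hi_group, label = "MHF", "MHF_higher"
        else:
            hi_group, label = "PHF", "PHF_higher"
        lo_group = "PHF" if hi_group == "MHF" else "MHF"
        levels[hi_group][b] = hi_level
        levels[lo_group][b] = lo_level
        for g in config.groups:
            if g not in ("MHF", "PHF"):
                levels[g][b] = 0.5
        truth[b] = label
    return MethylationState(bins, partial, levels, truth, cpg)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean mu and variance mu + dispersion * mu^2;
    exactly Poisson when dispersion is 0."""
    mu = np.asarray(mu, dtype=float)
    if dispersion == 0:
        return rng.poisson(mu)
    size = 1.0 / dispersion
    out = np.zeros(mu.shape, dtype=np.int64)
    pos = mu > 0
    out[pos] = rng.negative_binomial(size, size / (size + mu[pos]))
    return out


def simulate_counts(
    state: MethylationState,
    sites: list[MreSite],
    config: SimulationConfig,
) -> BinMethylProfile:
    """Draw per-sample binned MeDIP and MRE counts from the methylation state.

    MeDIP bin means are ``mean_coverage * level * CpG_count / mean_CpG`` and
    MRE means ``mean_coverage * (1 - level) * site_count / mean_sites``, so a
    bin of average CpG/site content at full signal averages ``mean_coverage``
    reads. Counts are independent across samples, negative binomial with the
    configured dispersion.
    """
    bins = state.bins
    site_pos: dict[str, list[int]] = {}
    for s in sites:
        site_pos.setdefault(s.interval.chrom, []).append(s.interval.start)
    site_counts = _per_bin_counts(
        bins, {c: np.sort(np.asarray(p)) for c, p in site_pos.items()}
    )
    return _counts_from_arrays(state, site_counts, config)


def _counts_from_arrays(
    state: MethylationState, site_counts: np.ndarray, config: SimulationConfig
) -> BinMethylProfile:
    bins = state.bins
    if len(site_counts) != len(bins):
        raise ValueError("site counts do not match the bin list")
    rng = np.random.default_rng([3, config.seed])
    cpg_ref = max(float(state.cpg_per_bin.mean()), 1e-9)
    site_ref = max(float(site_counts.mean()), 1e-9)

    medip = {}
    mre = {}
    totals = {}
    for sample in config.samples:
        g = config.group_of[sample]
        level = state.levels[g]
        mu_medip = config.mean_coverage * level * state.cpg_per_bin / cpg_ref
        mu_mre = config.mean_coverage * (1 - level) * site_counts / site_ref
        medip[sample] = _nb_draw(rng, mu_medip, config.dispersion)
        mre[sample] = _nb_draw(rng, mu_mre, config.dispersion)
        totals[(sample, "medip")] = int(medip[sample].sum())
        totals[(sample, "mre")] = int(mre[sample].sum())
    return BinMethylProfile(
        bins=bins,
        medip_counts=pd.DataFrame(medip),
        mre_counts=pd.DataFrame(mre),
        totals=totals,
        group_of=dict(config.group_of),
        partial_bins=state.partial,
    )


# ---------------------------------------------------------------------------
# Bins-only datasets (no genome) for calibration studies
# ---------------------------------------------------------------------------

def simulate_bin_dataset(
    n_bins: int,
    config: SimulationConfig,
    planted: bool = True,
    cpg_mean: float = 8.0,
    site_mean: float = 3.0,
) -> tuple[MethylationState, BinMethylProfile]:
    """A bins-only dataset: per-bin CpG and MRE-site counts are drawn Poisson
    (means matching a CpG-depleted background with occasional dense bins)
    instead of being read off a simulated sequence. Used for large null and
    power studies where the sequence layer adds nothing.

    With ``planted=False`` no DMRs are planted: all groups share identical
    per-bin methylation levels (the null).
    """
    rng = np.random.default_rng([4, config.seed])
    bins, partial = make_bins({"chrSim": n_bins * config.bin_size}, config.bin_size)
    cpg = rng.poisson(cpg_mean, size=n_bins)
    sites = rng.poisson(site_mean, size=n_bins)
    base = rng.beta(6, 2, size=n_bins)
    levels = {g: base.copy() for g in config.groups}
    truth = np.array(["none"] * n_bins, dtype=object)
    if planted:
        eligible = np.flatnonzero((cpg >= 3) & (sites >= 1))
        if eligible.size < config.planted_dmr_count:
            raise SimulationError("not enough eligible bins for the planted DMRs")
        chosen = rng.choice(eligible, size=config.planted_dmr_count, replace=False)
        hi = 0.5 + config.dmr_effect / 2
        lo = 0.5 - config.dmr_effect / 2
        for b in chosen:
            if rng.random() < 0.5:
                levels["MHF"][b], levels["PHF"][b], truth[b] = hi, lo, "MHF_higher"
            else:
                levels["MHF"][b], levels["PHF"][b], truth[b] = lo, hi, "PHF_higher"
            for g in config.groups:
                if g not in ("MHF", "PHF"):
                    levels[g][b] = 0.5
    state = MethylationState(bins, partial, levels, truth, cpg)
    profile = _counts_from_arrays(state, sites, config)
    return state, profile


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def link_dmrs_to_genes(
    state: MethylationState, genes: list[GeneModel]
) -> pd.DataFrame:
    """Link each planted intragenic DMR to its gene with relative position.

    Returns a table (gene_id, direction, relative_position); a gene keeps its
    first linked DMR when several land in it.
    """
    index = gene_context.GeneContextIndex(genes)
    rows = []
    seen: set[str] = set()
    for i in np.flatnonzero(state.truth != "none"):
        ann = gene_context.classify_feature(state.bins[i], index)
        if ann.feature == "gene_body" and ann.gene_id not in seen:
            seen.add(ann.gene_id)
            rows.append(
                {
                    "gene_id": ann.gene_id,
                    "direction": str(state.truth[i]),
                    "relative_position": ann.relative_position,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "direction", "relative_position"])


def position_effect(relative_position: float) -> float:
    """Signed position-effect curve on [-1, 1]: methylation near the TSS
    represses the methylated group's expression, methylation near the TES
    activates it, crossing zero mid-gene."""
    return (relative_position - 50.0) / 50.0


def simulate_expression(
    genes: list[GeneModel],
    links: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Per-animal expression quantities (genes x animals, positive scale).

    log2 quantities are gene baseline + noise; a gene linked to an intragenic
    DMR adds ``expression_effect * position_effect(rel_pos)`` to the animals
    of the DMR's more-methylated group. With expression_effect 0 the groups
    are exchangeable (the null).
    """
    rng = np.random.default_rng([5, config.seed])
    animals = config.samples
    link_map = {
        r.gene_id: (r.direction, r.relative_position) for r in links.itertuples()
    }
    values = np.zeros((len(genes), len(animals)))
    for gi, gene in enumerate(genes):
        base = rng.normal(5.0, 1.0)
        log2 = base + rng.normal(0.0, config.expression_noise_sd, size=len(animals))
        link = link_map.get(gene.gene_id)
        if link is not None and config.expression_effect != 0:
            direction, rel_pos = link
            hi_group = direction.removesuffix("_higher")
            delta = config.expression_effect * position_effect(rel_pos)
            for ai, animal in enumerate(animals):
                if config.group_of[animal] == hi_group:
                    log2[ai] += delta
        values[gi] = np.power(2.0, log2)
    return pd.DataFrame(values, index=[g.gene_id for g in genes], columns=animals)


# ---------------------------------------------------------------------------
# Paper-shaped partition fixtures
# ---------------------------------------------------------------------------

def partition_fixture(
    total: int = 1744,
    direction_counts: tuple[int, int] = (754, 990),  # (MHF_higher, PHF_higher)
    zone_counts: tuple[int, int, int] = (227, 484, 1033),  # island, shore, open sea
    feature_counts: tuple[int, int, int] = (43, 557, 61),  # promoter, body, downstream
):
    """Construct a DMR record set with exactly the requested marginal counts.

    Returns ``(annotations, zones, directions)`` ready for
    :func:`methylcontext.gene_context.summarize_partition`. Used to exercise
    the summary arithmetic on study-sized record sets whose marginals are
    known inputs.
    """
    from .cpg_context import IslandZoneAnnotation

    n_mhf, n_phf = direction_counts
    if n_mhf + n_phf != total:
        raise ValueError("direction counts must sum to the total")
    if sum(zone_counts) != total:
        raise ValueError("zone counts must sum to the total")
    if sum(feature_counts) > total:
        raise ValueError("feature counts exceed the total")
    directions = ["MHF_higher"] * n_mhf + ["PHF_higher"] * n_phf

    zones = []
    for zone, count, dist in zip(
        ("island", "shore", "open_sea"), zone_counts, (0, 1000, 5000)
    ):
        zones.extend([IslandZoneAnnotation(zone, dist)] * count)

    annotations = []
    n_prom, n_body, n_down = feature_counts
    for i in range(n_prom):
        annotations.append(gene_context.GeneFeatureAnnotation(f"gene_p{i}", "promoter"))
    for i in range(n_body):
        annotations.append(
            gene_context.GeneFeatureAnnotation(
                f"gene_b{i}", "gene_body", "intron", 50.0
            )
        )
    for i in range(n_down):
        annotations.append(gene_context.GeneFeatureAnnotation(f"gene_d{i}", "downstream"))
    annotations.extend(
        [gene_context.GeneFeatureAnnotation(None, "unassociated")]
        * (total - n_prom - n_body - n_down)
    )
    return annotations, zones, directions
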