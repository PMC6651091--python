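"""CpG island calling and island/shore/open-sea zoning.

A CpG island is a sequence segment satisfying three criteria: length >= 200 bp,
GC content >= 50%, and an observed/expected CpG ratio >= 0.6, where
obs/exp = (#CpG * L) / (#C * #G). Shores are the 2000-bp flanks on either side
of an island; everything farther is open sea.

The caller slides a 200-bp window with step 1 across the sequence, takes the
union of all windows that satisfy every criterion, merges overlapping windows
into maximal segments, and then trims each merged segment symmetrically (one
base off each end per round) until the whole segment satisfies all three
criteria, discarding segments that shrink below the minimum length. The window
scan is computed with prefix sums so whole chromosomes are linear-time.

N bases are excluded from the GC and CpG tallies and from the effective
length used in the GC and obs/exp ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .formats_io import CoordinateError, GenomicInterval

SHORE_WIDTH = 2000


@dataclass(frozen=True)
class CpGIsland:
    interval: GenomicInterval
    gc_content: float
    obs_exp_ratio: float

    @property
    def length(self) -> int:
        return self.interval.length


@dataclass(frozen=True)
class IslandZoneAnnotation:
    """Zone of a query relative to the island set of its chromosome.

    ``nearest_island_distance`` is None when the chromosome carries no island.
    """

    zone: str  # island | shore | open_sea
    nearest_island_distance: int | None  # base-to-base distance, 0 if overlapping
    shore_width: int = SHORE_WIDTH


def cpg_obs_exp(window: str) -> float:
    """Observed/expected CpG ratio of a sequence window.

    Returns ``(#CpG * L) / (#C * #G)`` with N bases excluded from all tallies
    and from ``L``; 0.0 when the window contains no C or no G.
    """
    if len(window) < 1:
        raise ValueError("window must be non-empty")
    window = window.upper()
    n_c = window.count("C")
    n_g = window.count("G")
    if n_c == 0 or n_g == 0:
        return 0.0
    n_cpg = _count_cpg_excluding_n(window)
    eff_len = len(window) - window.count("N")
    return (n_cpg * eff_len) / (n_c * n_g)


def gc_content(window: str) -> float:
    """GC fraction with N bases excluded from numerator and denominator."""
    window = window.upper()
    eff_len = len(window) - window.count("N")
    if eff_len == 0:
        return 0.0
    return (window.count("C") + window.count("G")) / eff_len


def _count_cpg_excluding_n(window: str) -> int:
    return window.count("CG")


def _criteria_ok(
    start: int, end: int, min_gc: float, min_oe: float,
    c_cum: np.ndarray, g_cum: np.ndarray, cg_cum: np.ndarray, n_cum: np.ndarray,
) -> bool:
    n_c = int(c_cum[end] - c_cum[start])
    n_g = int(g_cum[end] - g_cum[start])
    n_n = int(n_cum[end] - n_cum[start])
    eff = (end - start) - n_n
    if eff == 0 or (n_c + n_g) / eff < min_gc:
        return False
    if n_c == 0 or n_g == 0:
        return False
    n_cg = int(cg_cum[end - 1] - cg_cum[start])
    return (n_cg * eff) / (n_c * n_g) >= min_oe


def _prefix_sums(seq: str) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_n = arr == ord("N")
    # cg_cum[i] = number of CG dinucleotides starting strictly before i
    is_cg = np.zeros(len(seq), dtype=bool)
    if len(seq) >= 2:
        is_cg[: len(seq) - 1] = is_c[:-1] & is_g[1:]
    zero = np.zeros(1, dtype=np.int64)
    return (
        np.concatenate([zero, np.cumsum(is_c)]),
        np.concatenate([zero, np.cumsum(is_g)]),
        np.concatenate([zero, np.cumsum(is_cg)]),
        np.concatenate([zero, np.cumsum(is_n)]),
    )


def call_islands(
    sequence: str,
    chrom: str = "chr",
    min_len: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
) -> list[CpGIsland]:
    """Call CpG islands on one chromosome sequence (forward strand).

    See the module docstring for the window/merge/trim procedure. Output is
    sorted and non-overlapping.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = sequence.upper()
    if len(seq) < min_len:
        return []
    c_cum, g_cum, cg_cum, n_cum = _prefix_sums(seq)
    sums = (c_cum, g_cum, cg_cum, n_cum)

    n_win = len(seq) - min_len + 1
    starts = np.arange(n_win)
    ends = starts + min_len
    n_c = c_cum[ends] - c_cum[starts]
    n_g = g_cum[ends] - g_cum[starts]
    n_n = n_cum[ends] - n_cum[starts]
    n_cg = cg_cum[ends - 1] - cg_cum[starts]
    eff = min_len - n_n
    with np.errstate(divide="ignore", invalid="ignore"):
        gc_ok = np.where(eff > 0, (n_c + n_g) / np.maximum(eff, 1) >= min_gc, False)
        denom = n_c * n_g
        oe_ok = np.where(denom > 0, (n_cg * np.maximum(eff, 1)) / np.maximum(denom, 1) >= min_oe, False)
    ok = gc_ok & oe_ok

    islands: list[CpGIsland] = []
    for seg_start, seg_end in _merge_qualifying_windows(ok, min_len):
        trimmed = _trim_segment(seg_start, seg_end, min_len, min_gc, min_oe, sums)
        if trimmed is not None:
            s, e = trimmed
            window = seq[s:e]
            islands.append(
                CpGIsland(
                    GenomicInterval(chrom, s, e),
                    gc_content=gc_content(window),
                    obs_exp_ratio=cpg_obs_exp(window),
                )
            )
    return islands


def _merge_qualifying_windows(ok: np.ndarray, win: int) -> list[tuple[int, int]]:
    """Union of qualifying fixed-width windows as merged (start, end) segments."""
    idx = np.flatnonzero(ok)
    if idx.size == 0:
        return []
    # windows [i, i+win) overlap or touch when consecutive starts differ <= win
    breaks = np.flatnonzero(np.diff(idx) > win)
    seg_first = np.concatenate([[0], breaks + 1])
    seg_last = np.concatenate([breaks, [idx.size - 1]])
    return [(int(idx[a]), int(idx[b]) + win) for a, b in zip(seg_first, seg_last)]


def _trim_segment(start, end, min_len, min_gc, min_oe, sums):
    while end - start >= min_len:
        if _criteria_ok(start, end, min_gc, min_oe, *sums):
            return start, end
        start += 1
        end -= 1
    return None


def zone_annotate(
    query: GenomicInterval,
    islands: list[CpGIsland] | list[GenomicInterval],
    shore_width: int = SHORE_WIDTH,
) -> IslandZoneAnnotation:
    """Zone a query interval against a chromosome-sorted island set.

    Precedence is island > shore > open sea: any shared bp with an island wins,
    then any shared bp with a 2000-bp flank. Distance is base-to-base to the
    nearest island on the query's chromosome (0 when overlapping).
    """
    ivs = [isl.interval if isinstance(isl, CpGIsland) else isl for isl in islands]
    same_chrom = [iv for iv in ivs if iv.chrom == query.chrom]
    if not same_chrom:
        return IslandZoneAnnotation("open_sea", None, shore_width)
    dist = min(query.distance_to(iv) for iv in same_chrom)
    if dist == 0:
        zone = "island"
    elif dist <= shore_width:
        zone = "shore"
    else:
        zone = "open_sea"
    return IslandZoneAnnotation(zone, dist, shore_width)


def zone_annotate_many(
    queries: list[GenomicInterval],
    islands: list[CpGIsland] | list[GenomicInterval],
    shore_width: int = SHORE_WIDTH,
    known_chroms: set[str] | None = None,
) -> list[IslandZoneAnnotation]:
    """Zone many queries; ``known_chroms`` (when given) validates query chroms."""
    ivs = sorted(
        (isl.interval if isinstance(isl, CpGIsland) else isl for isl in islands),
        key=lambda iv: (iv.chrom, iv.start),
    )
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in ivs:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out = []
    for q in queries:
        if known_chroms is not None and q.chrom not in known_chroms:
            raise CoordinateError(f"query chromosome {q.chrom!r} absent from genome")
        chrom_islands = by_chrom.get(q.chrom, [])
        if not chrom_islands:
            warnings.warn(f"no islands on {q.chrom}; query zoned open_sea", stacklevel=2)
        out.append(zone_annotate(q, chrom_islands, shore_width))
    return out
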