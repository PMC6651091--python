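"""On-disk formats and the shared genomic coordinate types.

All coordinates inside the package are 0-based half-open, BED style. GTF is
1-based inclusive on disk and converted on read/write. Every other module
consumes and produces the types defined here; no stage parses files itself.

Results tables are TSV with a header line, preceded by ``#``-comment lines
that record provenance (tool, config hash, seed) for reproducibility audits.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


class FormatError(ValueError):
    """A file violated its format contract (malformed row, bad characters...)."""


class CoordinateError(ValueError):
    """Interval coordinates violate the 0-based half-open contract."""


_IUPAC_DNA = set("ACGTNRYSWKMBDHV")


# ---------------------------------------------------------------------------
# Core types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval, optionally stranded.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise CoordinateError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise CoordinateError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance_to(self, other: "GenomicInterval") -> int:
        """Distance in bp between the nearest bases; 0 when the intervals overlap.

        An interval starting immediately after ``other`` ends is 1 bp away
        (its first base is the base after ``other``'s last base).
        """
        if self.chrom != other.chrom:
            raise CoordinateError("distance undefined across chromosomes")
        if self.overlaps(other):
            return 0
        if self.end <= other.start:
            return other.start - self.end + 1
        return self.start - other.end + 1


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: stranded extent plus an ordered exon chain.

    TSS/TES are single-base coordinates: on ``+`` the TSS is ``start`` and the
    TES is ``end - 1``; on ``-`` the TSS is ``end - 1`` and the TES ``start``.
    """

    gene_id: str
    interval: GenomicInterval
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise CoordinateError(f"gene {self.gene_id}: strand required")
        if not self.exons:
            raise FormatError(f"gene {self.gene_id}: no exons")
        prev_end = None
        for ex in self.exons:
            if ex.chrom != self.interval.chrom:
                raise CoordinateError(f"gene {self.gene_id}: exon off-chromosome")
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise CoordinateError(f"gene {self.gene_id}: exon outside gene extent")
            if prev_end is not None and ex.start < prev_end:
                raise CoordinateError(f"gene {self.gene_id}: exons overlap or unsorted")
            prev_end = ex.end

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        return self.interval.end - 1 if self.strand == "+" else self.interval.start


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an order-preserving ``{name: sequence}`` mapping.

    Sequences are uppercased on read (documented normalisation). Duplicate
    record names and non-IUPAC characters raise :class:`FormatError`.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise FormatError(f"{path}: duplicate FASTA record {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _IUPAC_DNA
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains non-IUPAC characters {sorted(bad)}"
            )
        out[rec.id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (0-based half-open) into intervals; extra columns ignored."""
    ivs = []
    for lineno, line in enumerate(_data_lines(path), start=1):
        fields = line.split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: BED row with fewer than 3 columns")
        chrom, start, end = fields[0], fields[1], fields[2]
        strand = fields[5] if len(fields) >= 6 and fields[5] in ("+", "-") else "."
        try:
            iv = GenomicInterval(chrom, int(start), int(end), strand)
        except (ValueError, CoordinateError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        ivs.append(iv)
    return ivs


def read_bed_table(path: str | Path) -> pd.DataFrame:
    """Read BED6 keeping name/score columns (used for truth and DMR BEDs)."""
    rows = []
    for lineno, line in enumerate(_data_lines(path), start=1):
        f = line.split("\t")
        if len(f) < 3:
            raise FormatError(f"{path}:{lineno}: BED row with fewer than 3 columns")
        rows.append(
            {
                "chrom": f[0],
                "start": int(f[1]),
                "end": int(f[2]),
                "name": f[3] if len(f) > 3 else ".",
                "score": float(f[4]) if len(f) > 4 and f[4] != "." else float("nan"),
                "strand": f[5] if len(f) > 5 else ".",
            }
        )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def write_bed(
    intervals: Iterable[GenomicInterval],
    path: str | Path,
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    intervals = list(intervals)
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else "."
            score = _format_score(scores[i]) if scores is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


def _format_score(x: float) -> str:
    return f"{int(x)}" if float(x).is_integer() else f"{x:g}"


def _data_lines(path: str | Path) -> Iterable[str]:
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield line


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str | Path) -> list[GeneModel]:
    """Read gene models from GTF (1-based inclusive on disk, converted on read).

    Exon features are grouped by ``gene_id``; a gene's extent is taken from its
    ``gene``/``transcript`` feature when present, otherwise from the exon span.
    Malformed rows raise, they are never skipped silently.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    extents: dict[str, GenomicInterval] = {}
    order: list[str] = []
    for lineno, line in enumerate(_data_lines(path), start=1):
        f = line.split("\t")
        if len(f) < 9:
            raise FormatError(f"{path}:{lineno}: GTF row with fewer than 9 columns")
        chrom, _source, feature, start1, end1, _score, strand, _frame, attrs = f[:9]
        try:
            start, end = int(start1) - 1, int(end1)
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
        if start >= end:
            raise FormatError(f"{path}:{lineno}: start >= end after 1->0-based conversion")
        attr_map = dict(_GTF_ATTR.findall(attrs))
        gene_id = attr_map.get("gene_id")
        if gene_id is None:
            raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
        if gene_id not in order:
            order.append(gene_id)
        iv = GenomicInterval(chrom, start, end, strand if strand in "+-" else ".")
        if feature == "exon":
            exons.setdefault(gene_id, []).append(iv)
        elif feature in ("gene", "transcript"):
            extents.setdefault(gene_id, iv)
    models = []
    for gid in order:
        ex = sorted(exons.get(gid, []), key=lambda e: e.start)
        if not ex:
            raise FormatError(f"{path}: gene {gid!r} has no exon features")
        extent = extents.get(gid)
        if extent is None:
            extent = GenomicInterval(ex[0].chrom, ex[0].start, ex[-1].end, ex[0].strand)
        models.append(GeneModel(gid, extent, tuple(ex)))
    return models


def write_gtf(genes: Iterable[GeneModel], path: str | Path, source: str = "methylcontext") -> None:
    with open(path, "w") as fh:
        for g in genes:
            attrs = f'gene_id "{g.gene_id}";'
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for ex in g.exons:
                fh.write(
                    f"{ex.chrom}\t{source}\texon\t{ex.start + 1}\t{ex.end}\t.\t{iv.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT: one set per line, ``name<TAB>description<TAB>member...``."""
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(_data_lines(path), start=1):
        f = line.split("\t")
        if len(f) < 3:
            raise FormatError(f"{path}:{lineno}: GMT row needs name, description, members")
        name = f[0]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate gene set {name!r}")
        sets[name] = {m for m in f[2:] if m}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


# ---------------------------------------------------------------------------
# Commented TSV plumbing
# ---------------------------------------------------------------------------

def write_tsv(
    df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    """Write a TSV with a ``#``-comment provenance block, then a header line."""
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read a TSV written by :func:`write_tsv`; returns (table, metadata)."""
    meta: dict[str, str] = {}
    buf = _io.StringIO()
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, value = body.split("=", 1)
                    meta[key.strip()] = value.strip()
            else:
                buf.write(line)
    buf.seek(0)
    return pd.read_csv(buf, sep="\t"), meta


def config_hash(config: Mapping[str, object]) -> str:
    """Stable short hash of a configuration mapping, for provenance comments."""
    payload = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha1(payload).hexdigest()[:12]


def read_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a YAML mapping")
    return cfg


# ---------------------------------------------------------------------------
# Count and expression matrices
# ---------------------------------------------------------------------------

def write_counts(profile, path: str | Path, meta: Mapping[str, object] | None = None) -> None:
    """Write a BinMethylProfile as TSV: chrom/start/end/partial, then one
    ``medip_<sample>`` and ``mre_<sample>`` column per sample; group labels
    and library totals go in the ``#`` comment block."""
    import numpy as np

    samples = profile.samples
    header_meta = dict(meta or {})
    header_meta["sample_groups"] = ",".join(f"{s}:{profile.group_of[s]}" for s in samples)
    header_meta["medip_totals"] = ",".join(
        f"{s}:{profile.totals[(s, 'medip')]}" for s in samples
    )
    header_meta["mre_totals"] = ",".join(
        f"{s}:{profile.totals[(s, 'mre')]}" for s in samples
    )
    partial = (
        profile.partial_bins
        if profile.partial_bins is not None
        else np.zeros(len(profile.bins), dtype=bool)
    )
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in profile.bins],
            "start": [iv.start for iv in profile.bins],
            "end": [iv.end for iv in profile.bins],
            "partial": partial.astype(int),
        }
    )
    for s in samples:
        df[f"medip_{s}"] = profile.medip_counts[s].to_numpy()
    for s in samples:
        df[f"mre_{s}"] = profile.mre_counts[s].to_numpy()
    write_tsv(df, path, header_meta)


def read_counts(path: str | Path):
    """Read a counts TSV written by :func:`write_counts` into a BinMethylProfile."""
    from .dmr_calling import BinMethylProfile

    df, meta = read_tsv(path)
    for key in ("sample_groups", "medip_totals", "mre_totals"):
        if key not in meta:
            raise FormatError(f"{path}: missing '# {key}=' metadata line")

    def parse_map(text: str) -> dict[str, str]:
        return dict(item.split(":", 1) for item in text.split(",") if item)

    group_of = parse_map(meta["sample_groups"])
    medip_totals = {k: int(v) for k, v in parse_map(meta["medip_totals"]).items()}
    mre_totals = {k: int(v) for k, v in parse_map(meta["mre_totals"]).items()}
    samples = [c[len("medip_"):] for c in df.columns if c.startswith("medip_")]
    if not samples:
        raise FormatError(f"{path}: no medip_<sample> columns")
    bins = [
        GenomicInterval(str(r.chrom), int(r.start), int(r.end)) for r in df.itertuples()
    ]
    import numpy as np

    totals = {}
    for s in samples:
        totals[(s, "medip")] = medip_totals[s]
        totals[(s, "mre")] = mre_totals[s]
    return BinMethylProfile(
        bins=bins,
        medip_counts=df[[f"medip_{s}" for s in samples]].rename(
            columns={f"medip_{s}": s for s in samples}
        ),
        mre_counts=df[[f"mre_{s}" for s in samples]].rename(
            columns={f"mre_{s}": s for s in samples}
        ),
        totals=totals,
        group_of={s: group_of[s] for s in samples},
        partial_bins=df["partial"].to_numpy(dtype=bool) if "partial" in df else None,
    )


def write_expression(
    values: pd.DataFrame,
    group_of: Mapping[str, str],
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    """Write a gene x animal expression matrix with group labels in comments."""
    header_meta = dict(meta or {})
    header_meta["animal_groups"] = ",".join(
        f"{a}:{group_of[a]}" for a in values.columns
    )
    df = values.reset_index().rename(columns={"index": "gene_id"})
    if df.columns[0] != "gene_id":
        df = df.rename(columns={df.columns[0]: "gene_id"})
    write_tsv(df, path, header_meta)


def read_expression(path: str | Path) -> tuple[pd.DataFrame, dict[str, str]]:
    """Read an expression TSV; returns (gene x animal values, animal->group)."""
    df, meta = read_tsv(path)
    if "animal_groups" not in meta:
        raise FormatError(f"{path}: missing '# animal_groups=' metadata line")
    group_of = dict(
        item.split(":", 1) for item in meta["animal_groups"].split(",") if item
    )
    values = df.set_index("gene_id")
    return values, group_of
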