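"""Reading mapped tags, binning them on a genome layout, and standard genomic I/O.

Coordinates are 0-based half-open (BED convention) throughout.  Bin ``i`` of a
chromosome covers ``[i*bin_size, (i+1)*bin_size)``; the global bin index space
is the concatenation of the per-chromosome bin ranges in layout order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

REGION_LABELS = ("DHE_LIB1", "DHE_LIB2", "CHE")


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosomes with lengths, tiled by fixed-width bins."""

    chromosomes: tuple[tuple[str, int], ...]
    bin_size: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        if not self.chromosomes:
            raise ValueError("layout needs at least one chromosome")
        seen = set()
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
            if name in seen:
                raise ValueError(f"duplicate chromosome {name!r}")
            seen.add(name)

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    def chrom_length(self, name: str) -> int:
        for cname, length in self.chromosomes:
            if cname == name:
                return length
        raise KeyError(name)

    def bins_per_chrom(self) -> dict[str, int]:
        bs = self.bin_size
        return {name: -(-length // bs) for name, length in self.chromosomes}

    def chrom_offsets(self) -> dict[str, int]:
        """Global index of the first bin of each chromosome."""
        offsets: dict[str, int] = {}
        acc = 0
        for name, nbins in self.bins_per_chrom().items():
            offsets[name] = acc
            acc += nbins
        return offsets

    @property
    def n_bins(self) -> int:
        return sum(self.bins_per_chrom().values())

    def bin_intervals(self) -> pd.DataFrame:
        """One row per global bin: chrom, start, end (end truncated at chrom end)."""
        frames = []
        for name, length in self.chromosomes:
            starts = np.arange(0, length, self.bin_size, dtype=np.int64)
            ends = np.minimum(starts + self.bin_size, length)
            frames.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        return pd.concat(frames, ignore_index=True)


@dataclass
class TagSet:
    """Mapped sequence tags: one record per (chrom, start, end, strand)."""

    df: pd.DataFrame  # columns: chrom, start, end, strand

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "strand"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"TagSet missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class BinnedLibrary:
    """Per-bin fragment counts over a :class:`GenomeLayout`."""

    layout: GenomeLayout
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or len(self.counts) != self.layout.n_bins:
            raise ValueError(
                f"counts length {len(self.counts)} != layout bins {self.layout.n_bins}"
            )
        if np.any(self.counts < 0):
            raise ValueError("bin counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def zero_bins(self) -> int:
        return int(np.count_nonzero(self.counts == 0))

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass
class GeneSet:
    """Gene TSS records; a gene id may occur on several rows (one per promoter)."""

    df: pd.DataFrame  # columns: gene_id, chrom, tss, strand

    def __post_init__(self) -> None:
        required = {"gene_id", "chrom", "tss", "strand"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"GeneSet missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def gene_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df["gene_id"]))


@dataclass
class RegionSet:
    """Labeled genomic intervals (DHE_LIB1 / DHE_LIB2 / CHE)."""

    df: pd.DataFrame  # columns: chrom, start, end, label

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "label"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"RegionSet missing columns: {sorted(missing)}")
        if len(self.df) and (self.df["start"] >= self.df["end"]).any():
            raise ValueError("regions require start < end")

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# readers / writers


def read_chrom_sizes(path: str | Path, bin_size: int) -> GenomeLayout:
    """Build a layout from a 2-column TSV of (chromosome name, length)."""
    chroms: list[tuple[str, int]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split()[:2]
            chroms.append((name, int(length)))
    return GenomeLayout(tuple(chroms), bin_size)


def read_tags(path: str | Path) -> TagSet:
    """Read tags from a BED file; strand (column 6) is required.

    Malformed records (too few fields, start >= end, bad strand) are dropped
    with a logged count; an empty file yields an empty TagSet.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    strands: list[str] = []
    n_bad = 0
    with open(path, newline=None) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                fields = line.split()
            if len(fields) < 6:
                raise ValueError(
                    f"{path}:{lineno}: BED6 with a strand column is required "
                    f"(got {len(fields)} fields); strand is needed to shift tags"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                n_bad += 1
                continue
            strand = fields[5]
            if strand not in ("+", "-") or start < 0 or start >= end:
                n_bad += 1
                logger.warning("%s:%d: rejected malformed BED record", path, lineno)
                continue
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
            strands.append(strand)
    if n_bad:
        logger.warning("%s: dropped %d malformed records", path, n_bad)
    df = pd.DataFrame(
        {
            "chrom": pd.Series(chroms, dtype=str),
            "start": pd.Series(starts, dtype=np.int64),
            "end": pd.Series(ends, dtype=np.int64),
            "strand": pd.Series(strands, dtype=str),
        }
    )
    return TagSet(df)


def read_tags_bam(path: str | Path) -> TagSet:
    """Convenience BAM reader: mapped primary alignments become tags."""
    import pysam  # optional extra

    chroms, starts, ends, strands = [], [], [], []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            chroms.append(rec.reference_name)
            starts.append(rec.reference_start)
            ends.append(rec.reference_end)
            strands.append("-" if rec.is_reverse else "+")
    df = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "strand": strands}
    )
    return TagSet(df)


def shift_to_centers(
    tags: TagSet, shift: int = 100, layout: GenomeLayout | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Shift each tag toward its fragment center.

    A sequenced tag is the 5' end of an immunoprecipitated fragment, so the
    fragment center lies ``shift`` bp downstream of the tag: ``start + shift``
    on the + strand, ``end - 1 - shift`` on the - strand.  Positions are
    clamped to the chromosome when a layout is given.

    Returns (chrom array, position array).
    """
    if shift < 0:
        raise ValueError("shift must be non-negative")
    df = tags.df
    plus = df["strand"].to_numpy() == "+"
    pos = np.where(
        plus,
        df["start"].to_numpy() + shift,
        df["end"].to_numpy() - 1 - shift,
    ).astype(np.int64)
    pos = np.maximum(pos, 0)
    chrom = df["chrom"].to_numpy()
    if layout is not None:
        lengths = dict(layout.chromosomes)
        limit = np.array([lengths.get(c, np.iinfo(np.int64).max) for c in chrom])
        pos = np.minimum(pos, limit - 1)
    return chrom, pos


def bin_positions(
    chroms: Sequence[str] | np.ndarray,
    positions: Sequence[int] | np.ndarray,
    layout: GenomeLayout,
    on_unknown_chrom: str = "drop",
) -> BinnedLibrary:
    """Count fragment-center positions per fixed-width bin.

    Positions on chromosomes absent from the layout are dropped with a logged
    count (``on_unknown_chrom="drop"``, the default) or raise
    (``on_unknown_chrom="error"``).
    """
    if on_unknown_chrom not in ("drop", "error"):
        raise ValueError("on_unknown_chrom must be 'drop' or 'error'")
    chroms = np.asarray(chroms)
    positions = np.asarray(positions, dtype=np.int64)
    counts = np.zeros(layout.n_bins, dtype=np.int64)
    offsets = layout.chrom_offsets()
    n_dropped = 0
    for name in pd.unique(chroms) if len(chroms) else []:
        sel = chroms == name
        if name not in offsets:
            if on_unknown_chrom == "error":
                raise ValueError(f"position on unknown chromosome {name!r}")
            n_dropped += int(sel.sum())
            continue
        pos = positions[sel]
        length = layout.chrom_length(name)
        if np.any((pos < 0) | (pos >= length)):
            raise ValueError(f"position outside chromosome {name!r}")
        idx = offsets[name] + pos // layout.bin_size
        counts += np.bincount(idx, minlength=layout.n_bins)
    if n_dropped:
        logger.warning("dropped %d positions on chromosomes not in layout", n_dropped)
    return BinnedLibrary(layout, counts)


def tags_to_library(
    tags: TagSet, layout: GenomeLayout, shift: int = 100, **kwargs
) -> BinnedLibrary:
    """read → shift → bin in one call."""
    chroms, pos = shift_to_centers(tags, shift=shift, layout=layout)
    return bin_positions(chroms, pos, layout, **kwargs)


def write_bedgraph(lib: BinnedLibrary, path: str | Path) -> None:
    """Write every bin (zeros included) as bedGraph, so read∘write is identity."""
    intervals = lib.layout.bin_intervals()
    values = lib.counts
    with open(path, "w") as fh:
        for chrom, start, end, v in zip(
            intervals["chrom"], intervals["start"], intervals["end"], values
        ):
            if float(v) == int(v):
                fh.write(f"{chrom}\t{start}\t{end}\t{int(v)}\n")
            else:
                fh.write(f"{chrom}\t{start}\t{end}\t{v:.6g}\n")


def read_bedgraph(path: str | Path, layout: GenomeLayout) -> BinnedLibrary:
    """Read a bedGraph whose intervals tile the layout at its bin size.

    Missing bins default to zero; an interval whose width is not the bin size
    (chromosome-end truncation aside) or is misaligned raises with the line.
    """
    counts = np.zeros(layout.n_bins, dtype=float)
    offsets = layout.chrom_offsets()
    bs = layout.bin_size
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, start, end, value = line.split("\t")[:4]
            start, end = int(start), int(end)
            if chrom not in offsets:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            length = layout.chrom_length(chrom)
            expected_end = min(start + bs, length)
            if start % bs != 0 or end != expected_end:
                raise ValueError(
                    f"{path}:{lineno}: interval [{start},{end}) does not tile "
                    f"the layout at bin size {bs}"
                )
            counts[offsets[chrom] + start // bs] = float(value)
    if np.allclose(counts, np.round(counts)):
        counts = counts.astype(np.int64)
    return BinnedLibrary(layout, counts)


def write_regions(regions: RegionSet, path: str | Path) -> None:
    """Write regions as BED with the label in the name field."""
    with open(path, "w") as fh:
        for row in regions.df.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{row.label}\n")


def read_regions(path: str | Path) -> RegionSet:
    """Generic labeled-BED reader (also accepts output of external callers)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            label = fields[3] if len(fields) > 3 else "region"
            rows.append((fields[0], int(fields[1]), int(fields[2]), label))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "label"])
    return RegionSet(df)


def read_genes(path: str | Path) -> GeneSet:
    """Read gene TSS records from BED6 (name = gene id; TSS from strand)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError("gene BED requires 6 columns (name and strand)")
            chrom, start, end, gene_id, _, strand = fields[:6]
            tss = int(start) if strand == "+" else int(end) - 1
            rows.append((gene_id, chrom, tss, strand))
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "tss", "strand"])
    return GeneSet(df)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a two-condition expression TSV: gene_id, expr_cond1, expr_cond2."""
    df = pd.read_csv(path, sep="\t")
    df.columns = ["gene_id", "expr_cond1", "expr_cond2"][: len(df.columns)]
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in expression table")
    return df.set_index("gene_id")
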