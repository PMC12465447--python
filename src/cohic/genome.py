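"""Genomic intervals, annotation parsing and binning.

All coordinates are 0-based half-open (BED convention). Gene tables that
arrive 1-based closed (GTF-style) are converted at parse time. Strand is
used only to derive the TSS; all distances are unstranded edge distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_MARKS = ("H3K27ac", "H3K4me3", "RAD21", "CTCF", "H3K9me3")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start + self.end)

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class Gene:
    """A gene with a strand-aware TSS and optional transcript intervals.

    The TSS is the 5' end: ``interval.start`` on the + strand and
    ``interval.end - 1`` on the - strand.
    """

    id: str
    interval: GenomicInterval
    biotype: str = "protein_coding"
    transcripts: tuple[GenomicInterval, ...] = ()

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    def promoter_upstream(self, upstream_bp: int = 500) -> GenomicInterval:
        """Strand-aware window extending ``upstream_bp`` upstream of the TSS."""
        if self.interval.strand == "-":
            start, end = self.tss + 1, self.tss + 1 + upstream_bp
        else:
            start, end = max(0, self.tss - upstream_bp), max(1, self.tss)
        return GenomicInterval(self.chrom, start, end)


class PeakSet:
    """Sorted ChIP-seq peak intervals for a single mark with per-peak signal."""

    def __init__(self, mark: str, peaks: Iterable[GenomicInterval], signal=None):
        peaks = list(peaks)
        if signal is None:
            signal = np.ones(len(peaks), dtype=float)
        signal = np.asarray(signal, dtype=float)
        if len(signal) != len(peaks):
            raise ValueError("signal length must match peak count")
        if np.any(signal < 0):
            raise ValueError("peak signal must be non-negative")
        order = sorted(range(len(peaks)), key=lambda i: (peaks[i].chrom, peaks[i].start, peaks[i].end))
        self.mark = mark
        self.peaks: list[GenomicInterval] = [peaks[i] for i in order]
        self.signal = signal[order]

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_chrom(self, chrom: str) -> list[GenomicInterval]:
        return [p for p in self.peaks if p.chrom == chrom]

    def filter(self, predicate: Callable[[GenomicInterval], bool]) -> "PeakSet":
        keep = [i for i, p in enumerate(self.peaks) if predicate(p)]
        return PeakSet(self.mark, [self.peaks[i] for i in keep], self.signal[keep])


class BinGrid:
    """Fixed-width genomic bins over a chromosome table.

    Bin ``i`` on a chromosome covers ``[i*bin_size, (i+1)*bin_size)``; the
    last bin is truncated at the chromosome end.
    """

    def __init__(self, bin_size: int, chrom_sizes: dict[str, int]):
        if bin_size <= 0:
            raise ValueError("bin_size must be positive")
        for name, length in chrom_sizes.items():
            if length <= 0:
                raise ValueError(f"non-positive length for chromosome {name}")
        self.bin_size = int(bin_size)
        self.chrom_sizes = dict(chrom_sizes)

    def n_bins(self, chrom: str) -> int:
        length = self.chrom_sizes[chrom]
        return int(np.ceil(length / self.bin_size))

    def bin_of(self, chrom: str, pos: int) -> int:
        if not 0 <= pos < self.chrom_sizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom} (length {self.chrom_sizes[chrom]})")
        return pos // self.bin_size

    def bin_interval(self, chrom: str, i: int) -> GenomicInterval:
        if not 0 <= i < self.n_bins(chrom):
            raise ValueError(f"bin {i} outside {chrom}")
        start = i * self.bin_size
        end = min((i + 1) * self.bin_size, self.chrom_sizes[chrom])
        return GenomicInterval(chrom, start, end)

    def bins_overlapping(self, interval: GenomicInterval) -> range:
        """Indices of every bin overlapping ``interval`` (half-open)."""
        first = interval.start // self.bin_size
        last = (interval.end - 1) // self.bin_size
        return range(first, min(last, self.n_bins(interval.chrom) - 1) + 1)


def peak_coverage_track(peaks: PeakSet, grid: BinGrid, chrom: str) -> np.ndarray:
    """Per-bin bp coverage of a PeakSet on one chromosome (orientation evidence)."""
    track = np.zeros(grid.n_bins(chrom))
    for p in peaks.by_chrom(chrom):
        for i in grid.bins_overlapping(p):
            b = grid.bin_interval(chrom, i)
            track[i] += min(p.end, b.end) - max(p.start, b.start)
    return track


def read_chrom_sizes(path) -> dict[str, int]:
    """Parse a two-column chrom.sizes file into an ordered name->length map."""
    sizes: dict[str, int] = {}
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'name length', got {line!r}")
        name, length = parts[0], int(parts[1])
        if name in sizes:
            raise ValueError(f"{path}:{lineno}: duplicate chromosome {name}")
        if length <= 0:
            raise ValueError(f"{path}:{lineno}: non-positive length for {name}")
        sizes[name] = length
    if not sizes:
        logger.warning("chrom.sizes file %s is empty", path)
    return sizes


def read_bed(path, mark: str = "H3K27ac", chrom_sizes: dict[str, int] | None = None) -> PeakSet:
    """Read a BED3+ file into a PeakSet; column 5, when present, is the signal.

    Records on chromosomes absent from ``chrom_sizes`` are skipped with a
    logged count rather than aborting.
    """
    peaks: list[GenomicInterval] = []
    signal: list[float] = []
    skipped = 0
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        chrom, start, end = parts[0], int(parts[1]), int(parts[2])
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end ({start} >= {end})")
        if chrom_sizes is not None and chrom not in chrom_sizes:
            skipped += 1
            continue
        strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
        peaks.append(GenomicInterval(chrom, start, end, strand))
        signal.append(float(parts[4]) if len(parts) > 4 else 1.0)
    if skipped:
        logger.warning("read_bed(%s): skipped %d records on unknown chromosomes", path, skipped)
    return PeakSet(mark, peaks, signal)


def read_gene_table(path) -> list[Gene]:
    """Read a tab-delimited gene table.

    Columns: gene_id, chrom, start, end, strand, biotype (0-based half-open,
    pre-converted at export time).
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"gene_id", "chrom", "start", "end", "strand", "biotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table {path} missing columns: {sorted(missing)}")
    genes = []
    for row in df.itertuples(index=False):
        genes.append(
            Gene(
                id=row.gene_id,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                biotype=row.biotype,
            )
        )
    return genes


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Edge distance in bp between two intervals on the same chromosome.

    Overlapping or abutting intervals have distance 0. Raises on different
    chromosomes (the distance is undefined there).
    """
    if a.chrom != b.chrom:
        raise ValueError(f"distance undefined across chromosomes ({a.chrom} vs {b.chrom})")
    if a.start < b.end and b.start < a.end:
        return 0
    return max(a.start - b.end, b.start - a.end, 0)


def nearest_feature(
    query: GenomicInterval,
    features: Sequence,
    predicate: Callable | None = None,
    interval_of: Callable = lambda f: f,
):
    """Nearest feature to ``query`` by edge distance, or (None, None).

    ``features`` may be intervals or carry intervals via ``interval_of``.
    Ties are broken by the smaller start coordinate. Only features on the
    query's chromosome are considered.
    """
    best = None
    best_dist = None
    for f in features:
        if predicate is not None and not predicate(f):
            continue
        iv = interval_of(f)
        if iv.chrom != query.chrom:
            continue
        d = interval_distance(query, iv)
        if best_dist is None or d < best_dist or (d == best_dist and iv.start < interval_of(best).start):
            best, best_dist = f, d
    return best, best_dist


def merge_peaks(a: PeakSet, b: PeakSet) -> PeakSet:
    """Union of two same-mark PeakSets with overlapping/abutting intervals coalesced.

    Merged peak signal is the sum of constituent signals.
    """
    if a.mark != b.mark:
        raise ValueError(f"cannot merge marks {a.mark} and {b.mark}")
    items = sorted(
        [(p.chrom, p.start, p.end, s) for p, s in zip(a.peaks, a.signal)]
        + [(p.chrom, p.start, p.end, s) for p, s in zip(b.peaks, b.signal)]
    )
    merged: list[tuple[str, int, int, float]] = []
    for chrom, start, end, s in items:
        if merged and merged[-1][0] == chrom and start <= merged[-1][2]:
            prev = merged[-1]
            merged[-1] = (chrom, prev[1], max(prev[2], end), prev[3] + s)
        else:
            merged.append((chrom, start, end, s))
    return PeakSet(
        a.mark,
        [GenomicInterval(c, s, e) for c, s, e, _ in merged],
        [sig for _, _, _, sig in merged],
    )
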