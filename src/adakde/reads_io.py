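"""Read input/output and read preprocessing.

Reads come from BAM/SAM files (via :mod:`pysam`) or from a minimal
3-column whitespace text format ``chrom  pos5  strand`` with 1-based
positions.  Preprocessing collapses duplicate reads, shifts the two strands
toward each other by half the fragment length, clamps to the chromosome
and sorts — producing the position array the density estimators consume.

Density tracks are written as bedGraph (piecewise-constant / dense) or
fixedStep WIG (dense), both plain text.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .density import ChromInfo, DensityTrack

__all__ = [
    "MappedRead",
    "PositionArray",
    "ChromInfo",
    "load_reads",
    "write_reads_text",
    "write_reads_bam",
    "preprocess",
    "write_bedgraph",
    "read_bedgraph",
    "write_wig_dense",
    "read_wig_dense",
]

_STRANDS = ("+", "-")


@dataclass(frozen=True)
class MappedRead:
    """One mapped single-end read: chromosome, 5'-most coordinate, strand."""

    chrom: str
    pos5: int
    strand: str

    def __post_init__(self) -> None:
        if self.pos5 < 1:
            raise ValueError(f"pos5 must be >= 1, got {self.pos5}")
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass(frozen=True)
class PositionArray:
    """Sorted 1-based read positions on one chromosome."""

    chrom: str
    positions: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        if pos.size < 1:
            raise ValueError("position array must contain at least one position")
        if np.any(np.diff(pos) < 0):
            raise ValueError("positions must be sorted ascending")
        if pos[0] < 1:
            raise ValueError("positions must be >= 1")
        object.__setattr__(self, "positions", pos)

    @property
    def n(self) -> int:
        return int(self.positions.size)


# ---------------------------------------------------------------------------
# read loading


def load_reads(source, fmt: str, chrom: str) -> list[MappedRead]:
    """Load the reads mapped to ``chrom`` from a BAM/SAM or bed-like file.

    For a minus-strand BAM alignment the 5' coordinate is the rightmost
    aligned base (1-based); for a plus-strand alignment it is the leftmost.
    """
    if fmt == "bam":
        reads = _load_bam(source, chrom)
    elif fmt == "bed-like":
        reads = _load_bedlike(source, chrom)
    else:
        raise ValueError(f"unknown read format {fmt!r}; expected 'bam' or 'bed-like'")
    if not reads:
        raise ValueError(f"no mapped reads found for chromosome {chrom!r} in {source}")
    return reads


def _load_bam(source, chrom: str) -> list[MappedRead]:
    import pysam

    reads = []
    with pysam.AlignmentFile(str(source), check_sq=False) as fh:
        if chrom not in fh.references:
            raise ValueError(
                f"chromosome {chrom!r} not present in {source} "
                f"(references: {', '.join(fh.references[:5])}...)"
            )
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if rec.reference_name != chrom:
                continue
            if rec.is_reverse:
                reads.append(MappedRead(chrom, rec.reference_end, "-"))
            else:
                reads.append(MappedRead(chrom, rec.reference_start + 1, "+"))
    return reads


def _load_bedlike(source, chrom: str) -> list[MappedRead]:
    reads = []
    seen_chroms = set()
    with open(source) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{source}:{line_no}: expected 'chrom pos strand'")
            seen_chroms.add(parts[0])
            if parts[0] != chrom:
                continue
            reads.append(MappedRead(parts[0], int(parts[1]), parts[2]))
    if not reads and chrom not in seen_chroms:
        raise ValueError(
            f"chromosome {chrom!r} not present in {source} "
            f"(found: {', '.join(sorted(seen_chroms)[:5])})"
        )
    return reads


def write_reads_text(reads: Iterable[MappedRead], path) -> None:
    """Write reads in the 3-column bed-like text format."""
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.pos5}\t{r.strand}\n")


def write_reads_bam(reads: Sequence[MappedRead], path, chrom_info: ChromInfo,
                    read_length: int = 36) -> None:
    """Write reads as unsorted BAM alignments of fixed ``read_length``.

    Used for round-trip testing of the BAM loader; minus-strand reads must
    satisfy ``pos5 >= read_length`` so the alignment fits the chromosome.
    """
    import pysam

    header = {"HD": {"VN": "1.6"},
              "SQ": [{"SN": chrom_info.name, "LN": int(chrom_info.length)}]}
    with pysam.AlignmentFile(str(path), "wb", header=header) as fh:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment()
            a.query_name = f"read{i}"
            a.query_sequence = "A" * read_length
            a.query_qualities = pysam.qualitystring_to_array("I" * read_length)
            a.cigartuples = [(0, read_length)]
            a.reference_id = 0
            a.mapping_quality = 60
            if r.strand == "-":
                a.flag = 16
                a.reference_start = r.pos5 - read_length  # 0-based start
            else:
                a.flag = 0
                a.reference_start = r.pos5 - 1
            fh.write(a)


# ---------------------------------------------------------------------------
# preprocessing


def half_fragment_shift(fragment_length: float) -> int:
    """round(L/2) with ties rounded up."""
    return int(math.floor(fragment_length / 2.0 + 0.5))


def preprocess(reads: Sequence[MappedRead], fragment_length: float,
               chrom_info: ChromInfo) -> PositionArray:
    """Dedup, shift strands toward each other, clamp and sort.

    Duplicates — identical (chrom, pos5, strand) — are collapsed before
    shifting, so a + and a - read landing on the same shifted coordinate
    remain distinct data points.  Shifted positions are clamped to
    ``[1, G]`` rather than dropped.
    """
    if fragment_length < 0:
        raise ValueError("fragment length must be >= 0")
    if not reads:
        raise ValueError("cannot preprocess an empty read list")
    chroms = {r.chrom for r in reads}
    if len(chroms) > 1:
        raise ValueError(f"reads span multiple chromosomes: {sorted(chroms)}")
    shift = half_fragment_shift(fragment_length)
    unique = {(r.pos5, r.strand) for r in reads}
    positions = np.array(
        [p + shift if s == "+" else p - shift for p, s in unique],
        dtype=np.int64,
    )
    positions = np.clip(positions, 1, chrom_info.length)
    positions.sort()
    return PositionArray(chrom=next(iter(chroms)), positions=positions)


# ---------------------------------------------------------------------------
# track output

_FMT = "%.12g"  # >= 10 significant digits round-trip


def _dense_runs(track: DensityTrack):
    """Yield (start, end, value) runs of equal value, 1-based inclusive."""
    if track.kind == "pconst":
        merged = []
        for s, e, v in track.pieces:
            if merged and merged[-1][2] == v and merged[-1][1] + 1 == int(s):
                merged[-1][1] = int(e)
            else:
                merged.append([int(s), int(e), float(v)])
        yield from ((s, e, v) for s, e, v in merged)
        return
    dense = track.to_dense()
    vals = dense.values
    if not len(vals):
        return
    change = np.flatnonzero(np.diff(vals) != 0)
    starts = np.concatenate([[0], change + 1])
    ends = np.concatenate([change, [len(vals) - 1]])
    for s, e in zip(starts, ends):
        yield dense.start + int(s), dense.start + int(e), float(vals[s])


def write_bedgraph(track: DensityTrack, path) -> None:
    """Write a bedGraph file (0-based half-open, zero runs omitted)."""
    if track.kind == "plin":
        raise ValueError("bedGraph requires a piecewise-constant or dense track")
    name = track.chrom_info.name
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{name} density"\n')
        for s, e, v in _dense_runs(track):
            if v == 0.0:
                continue
            fh.write(f"{name}\t{s - 1}\t{e}\t{_FMT % v}\n")


def read_bedgraph(path, chrom_info: ChromInfo) -> DensityTrack:
    """Parse a bedGraph file back into a piecewise-constant track."""
    pieces = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            chrom, s, e, v = line.split()[:4]
            if chrom != chrom_info.name:
                continue
            pieces.append((int(s) + 1, int(e), float(v)))
    arr = np.array(pieces, dtype=np.float64).reshape(-1, 3)
    return DensityTrack(chrom_info=chrom_info, kind="pconst", n_train=0,
                        start=int(arr[0, 0]) if len(arr) else 1, pieces=arr)


def write_wig_dense(track: DensityTrack, path) -> None:
    """Write the track's evaluated range as fixedStep step-1 WIG."""
    dense = track.to_dense()
    if dense.values is None or not len(dense.values):
        raise ValueError("cannot write an empty track range as WIG")
    name = track.chrom_info.name
    with open(path, "w") as fh:
        fh.write(f'track type=wiggle_0 name="{name} density"\n')
        fh.write(f"fixedStep chrom={name} start={dense.start} step=1\n")
        fh.writelines(_FMT % v + "\n" for v in dense.values)


def read_wig_dense(path, chrom_info: ChromInfo) -> DensityTrack:
    """Parse a single-block fixedStep WIG file back into a dense track."""
    start = None
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            if line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                start = int(fields["start"])
                continue
            values.append(float(line))
    if start is None or not values:
        raise ValueError(f"no fixedStep data found in {path}")
    return DensityTrack(chrom_info=chrom_info, kind="dense", n_train=0,
                        start=start, values=np.array(values))
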