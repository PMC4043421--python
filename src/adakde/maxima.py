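"""Strict local maxima of a density track and height summaries.

A position ``b`` is a strict local maximum when ``f(b) > f(b - 1)`` and
``f(b) > f(b + 1)``.  Plateaus therefore contribute no maxima, and the
endpoints of the evaluated range are excluded (no two-sided neighborhood).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .density import DensityTrack

__all__ = ["LocalMaximaSet", "strict_local_maxima", "height_histogram",
           "write_maxima_bed"]


@dataclass(frozen=True)
class LocalMaximaSet:
    """Positions (1-based, strictly increasing) and heights of the maxima."""

    positions: np.ndarray
    heights: np.ndarray

    @property
    def count(self) -> int:
        return int(self.positions.size)


def _dense_maxima(start: int, values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(values) < 3:
        return np.empty(0, np.int64), np.empty(0)
    mid = values[1:-1]
    hit = (mid > values[:-2]) & (mid > values[2:])
    idx = np.flatnonzero(hit) + 1
    return idx + start, values[idx]


def strict_local_maxima(track: DensityTrack) -> LocalMaximaSet:
    """All strict local maxima inside the track's evaluated range.

    Dense tracks are triple-scanned.  Piecewise representations are scanned
    analytically: a constant or linear stretch cannot hold an interior
    strict maximum, so only piece boundaries and breakpoints (and their
    immediate neighbors) are candidates.
    """
    if track.kind == "dense":
        pos, heights = _dense_maxima(track.start, track.values)
        return LocalMaximaSet(pos, heights)

    if track.kind == "pconst":
        cand = np.unique(np.concatenate([track.pieces[:, 0], track.pieces[:, 1]]))
    else:
        cand = np.unique(track.breakpoints[:, 0])
    cand = np.unique(np.concatenate([cand - 1, cand, cand + 1])).astype(np.int64)
    lo, hi = track._range()
    cand = cand[(cand > lo) & (cand < hi)]
    if not cand.size:
        return LocalMaximaSet(np.empty(0, np.int64), np.empty(0))
    f = track.value_at
    vb, vl, vr = f(cand), f(cand - 1), f(cand + 1)
    hit = (vb > vl) & (vb > vr)
    return LocalMaximaSet(cand[hit], vb[hit])


def height_histogram(maxima: LocalMaximaSet, bin_edges) -> np.ndarray:
    """Counts per bin; left-closed right-open except the last bin (closed)."""
    edges = np.asarray(bin_edges, dtype=np.float64)
    if edges.ndim != 1 or edges.size < 2:
        raise ValueError("need at least two bin edges")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly ascending")
    counts, _ = np.histogram(maxima.heights, bins=edges)
    return counts


def write_maxima_bed(maxima: LocalMaximaSet, chrom: str, bed_path,
                     tsv_path=None) -> None:
    """Export maxima as 1-bp BED intervals plus an exact-height TSV sidecar.

    The BED score column is the height scaled to 0-1000 relative to the
    tallest maximum, per BED convention; exact values go in the TSV.
    """
    top = maxima.heights.max() if maxima.count else 1.0
    with open(bed_path, "w") as fh:
        for p, h in zip(maxima.positions, maxima.heights):
            score = int(round(1000 * h / top)) if top > 0 else 0
            fh.write(f"{chrom}\t{p - 1}\t{p}\tmax\t{score}\t.\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("chrom\tposition\theight\n")
            for p, h in zip(maxima.positions, maxima.heights):
                fh.write(f"{chrom}\t{p}\t{float(h)!r}\n")
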