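"""Kernel density evaluation over integer genomic coordinates.

The estimate at an integer position x is the average of the translated
kernels, ``f(x) = (1/n) * sum_i K(x - x_i, h_i)``, optionally blended with
a uniform density over the chromosome, ``(1 - eps) * f(x) + eps / G``.

Three representations of the resulting track are supported:

* ``dense`` — per-base values over an explicit 1-based range (the union of
  kernel supports, clipped to the chromosome);
* ``pconst`` — piecewise-constant pieces ``(start, end, value)``, exact for
  the square kernel, built by an event sweep in time independent of G;
* ``plin`` — piecewise-linear breakpoints ``(position, value)``, exact for
  the triangle kernel; linear interpolation between breakpoints reproduces
  the dense values at every integer.

Kernels overhanging the chromosome are neither renormalized nor reflected;
their off-chromosome mass is simply dropped from the in-range sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .kernels import KernelSpec, build_kernel, discrete_normalizer

__all__ = [
    "ChromInfo",
    "MixtureParams",
    "DensityTrack",
    "fixed_kde",
    "adaptive_kde",
    "blend_uniform",
    "evaluate_at",
    "piecewise_constant_kde",
    "piecewise_linear_kde",
]

# pair-count cap per vectorized chunk in evaluate_at (memory bound)
_CHUNK_PAIRS = 4_000_000


@dataclass(frozen=True)
class ChromInfo:
    """Chromosome name and length G (1-based coordinates run 1..G)."""

    name: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("chromosome length must be >= 1")


@dataclass(frozen=True)
class MixtureParams:
    """Weight of the uniform component u(x) = 1/G on [1, G]."""

    epsilon: float
    G: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")
        if self.G < 1:
            raise ValueError("G must be >= 1")

    @property
    def uniform_value(self) -> float:
        return 1.0 / self.G


@dataclass
class DensityTrack:
    """A reconstructed density on one chromosome.

    Exactly one representation is populated, indicated by ``kind``:

    * ``dense``: ``start`` and ``values`` (``values[i]`` is the density at
      1-based position ``start + i``);
    * ``pconst``: ``pieces`` as an ``(n_pieces, 3)`` float array of
      ``(start, end, value)`` with 1-based inclusive bounds, sorted and
      non-overlapping;
    * ``plin``: ``breakpoints`` as an ``(n_bp, 2)`` float array of
      ``(position, value)`` with linear interpolation in between.

    Outside the stored range/pieces the density is ``baseline`` (0 before
    blending, ``eps / G`` after).
    """

    chrom_info: ChromInfo
    kind: str
    n_train: int
    epsilon: float = 0.0
    baseline: float = 0.0
    start: int = 0
    values: Optional[np.ndarray] = field(default=None, repr=False)
    pieces: Optional[np.ndarray] = field(default=None, repr=False)
    breakpoints: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def end(self) -> int:
        """Last 1-based position covered by the explicit representation."""
        if self.kind == "dense":
            return self.start + len(self.values) - 1
        if self.kind == "pconst":
            return int(self.pieces[-1, 1]) if len(self.pieces) else self.start
        return int(self.breakpoints[-1, 0]) if len(self.breakpoints) else self.start

    def value_at(self, positions) -> np.ndarray:
        """Density at integer positions (vectorized)."""
        q = np.asarray(positions, dtype=np.int64)
        scalar = q.ndim == 0
        q = np.atleast_1d(q)
        out = np.full(q.shape, self.baseline, dtype=np.float64)
        if self.kind == "dense":
            inside = (q >= self.start) & (q <= self.end)
            out[inside] = self.values[q[inside] - self.start]
        elif self.kind == "pconst":
            if len(self.pieces):
                starts = self.pieces[:, 0]
                idx = np.searchsorted(starts, q, side="right") - 1
                ok = idx >= 0
                idx_c = np.clip(idx, 0, len(starts) - 1)
                inside = ok & (q <= self.pieces[idx_c, 1])
                out[inside] = self.pieces[idx_c[inside], 2]
        else:  # plin
            if len(self.breakpoints):
                bx = self.breakpoints[:, 0]
                by = self.breakpoints[:, 1]
                inside = (q >= bx[0]) & (q <= bx[-1])
                out[inside] = np.interp(q[inside].astype(np.float64), bx, by)
        return out[0] if scalar else out

    def to_dense(self) -> "DensityTrack":
        """Materialize the track as per-base values over its covered range."""
        if self.kind == "dense":
            return self
        lo, hi = self._range()
        pos = np.arange(lo, hi + 1)
        return DensityTrack(
            chrom_info=self.chrom_info, kind="dense", n_train=self.n_train,
            epsilon=self.epsilon, baseline=self.baseline,
            start=lo, values=self.value_at(pos),
        )

    def _range(self) -> tuple[int, int]:
        if self.kind == "dense":
            return self.start, self.end
        if self.kind == "pconst":
            return int(self.pieces[0, 0]), int(self.pieces[-1, 1])
        return int(self.breakpoints[0, 0]), int(self.breakpoints[-1, 0])

    def total_mass(self) -> float:
        """Sum of the density over all integers in [1, G]."""
        lo, hi = self._range()
        lo, hi = max(lo, 1), min(hi, self.chrom_info.length)
        if self.kind == "dense":
            inrange = self.values[lo - self.start: hi - self.start + 1]
            explicit = float(inrange.sum())
        elif self.kind == "pconst":
            s = np.maximum(self.pieces[:, 0], 1)
            e = np.minimum(self.pieces[:, 1], self.chrom_info.length)
            w = np.maximum(e - s + 1, 0)
            explicit = float((w * self.pieces[:, 2]).sum())
        else:
            explicit = float(self.value_at(np.arange(lo, hi + 1)).sum())
        n_outside = self.chrom_info.length - (hi - lo + 1)
        return explicit + self.baseline * n_outside


# ---------------------------------------------------------------------------
# helpers


def _positions_array(X) -> np.ndarray:
    x = np.asarray(getattr(X, "positions", X), dtype=np.int64)
    if x.size == 0:
        raise ValueError("cannot build a density from an empty position array")
    if np.any(np.diff(x) < 0):
        raise ValueError("positions must be sorted ascending")
    return x


def _bandwidth_array(H, n: int) -> np.ndarray:
    h = np.asarray(H, dtype=np.float64)
    if h.ndim == 0:
        h = np.full(n, float(h))
    if h.size != n:
        raise ValueError(f"expected {n} bandwidths, got {h.size}")
    return h


def _iter_bandwidth_groups(x: np.ndarray, h: np.ndarray):
    """Yield (h_value, positions_subset) with positions kept sorted.

    KNN bandwidths are inter-point distances and therefore heavily repeated,
    so grouping lets one kernel table serve many points.
    """
    for hv in np.unique(h):
        yield float(hv), x[h == hv]


# ---------------------------------------------------------------------------
# dense evaluation


def _accumulate_dense(x: np.ndarray, h: np.ndarray, spec: KernelSpec,
                      chrom_info: ChromInfo) -> tuple[int, np.ndarray]:
    n = x.size
    radii = np.floor(spec.support_multiplier * h).astype(np.int64)
    lo = max(1, int((x - radii).min()))
    hi = min(chrom_info.length, int((x + radii).max()))
    values = np.zeros(hi - lo + 1, dtype=np.float64)
    for hv, pts in _iter_bandwidth_groups(x, h):
        kern = build_kernel(spec, hv)
        tbl = kern.weights / n
        r = kern.radius
        for xi in pts:
            a = int(xi) - r
            b = int(xi) + r
            ta, tb = 0, 2 * r + 1
            if a < lo:
                ta = lo - a
                a = lo
            if b > hi:
                tb -= b - hi
                b = hi
            if a > b:
                continue
            values[a - lo: b - lo + 1] += tbl[ta:tb]
    return lo, values


def adaptive_kde(X, H, spec: KernelSpec, chrom_info: ChromInfo) -> DensityTrack:
    """Dense sample-point estimate with per-point bandwidths ``H``."""
    x = _positions_array(X)
    h = _bandwidth_array(H, x.size)
    lo, values = _accumulate_dense(x, h, spec, chrom_info)
    return DensityTrack(chrom_info=chrom_info, kind="dense", n_train=x.size,
                        start=lo, values=values)


def fixed_kde(X, h: float, spec: KernelSpec, chrom_info: ChromInfo) -> DensityTrack:
    """Dense estimate with one constant bandwidth ``h`` for every point."""
    x = _positions_array(X)
    # bandwidth validity (finite, >= 0.5) is enforced by the kernel builder
    return adaptive_kde(x, np.full(x.size, float(h)), spec, chrom_info)


def blend_uniform(track: DensityTrack, params: MixtureParams) -> DensityTrack:
    """Mix the track with a uniform density: ``(1 - eps) f + eps / G``."""
    if params.G != track.chrom_info.length:
        raise ValueError("mixture G must match the track's chromosome length")
    eps = params.epsilon
    u = params.uniform_value
    scale = 1.0 - eps

    def mix(v):
        return scale * v + eps * u

    kwargs = dict(chrom_info=track.chrom_info, kind=track.kind,
                  n_train=track.n_train, epsilon=eps,
                  baseline=mix(track.baseline), start=track.start)
    if track.kind == "dense":
        kwargs["values"] = mix(track.values)
    elif track.kind == "pconst":
        pieces = track.pieces.copy()
        pieces[:, 2] = mix(pieces[:, 2])
        kwargs["pieces"] = pieces
    else:
        bps = track.breakpoints.copy()
        bps[:, 1] = mix(bps[:, 1])
        kwargs["breakpoints"] = bps
    return DensityTrack(**kwargs)


# ---------------------------------------------------------------------------
# direct query evaluation (no whole-chromosome track)


def evaluate_at(X, H, spec: KernelSpec, params: MixtureParams,
                queries) -> np.ndarray:
    """Blended density at query positions without materializing a track.

    Only the kernels whose support covers a query contribute to it; the
    covered queries of each kernel are located by binary search over the
    sorted query positions and the kernel weights are computed directly on
    the resulting (query, data point) pairs.  Equal to reading the
    corresponding dense track at the same positions.
    """
    x = _positions_array(X)
    h = _bandwidth_array(H, x.size)
    q = np.asarray(queries, dtype=np.int64)
    scalar = q.ndim == 0
    q = np.atleast_1d(q)
    if q.size and (q.min() < 1 or q.max() > params.G):
        raise ValueError("queries must lie within [1, G]")
    n = x.size
    order = np.argsort(q, kind="stable")
    qs = q[order]

    uh, inv = np.unique(h, return_inverse=True)
    radii = np.empty(uh.size, dtype=np.int64)
    norms = np.empty(uh.size, dtype=np.float64)
    for i, hv in enumerate(uh):
        radii[i], norms[i] = discrete_normalizer(spec, float(hv))
    r_pt = radii[inv]
    c_pt = norms[inv] / n
    # constant bandwidth: one shared weight table beats per-pair evaluation
    table = build_kernel(spec, float(uh[0])).weights / n if uh.size == 1 else None

    lo = np.searchsorted(qs, x - r_pt, side="left")
    hi = np.searchsorted(qs, x + r_pt, side="right")
    counts = hi - lo
    csum = np.cumsum(counts)
    out = np.zeros(qs.size, dtype=np.float64)
    pos = 0
    while pos < n:
        prev = csum[pos - 1] if pos else 0
        stop = int(np.searchsorted(csum, prev + _CHUNK_PAIRS, side="right"))
        stop = min(max(stop, pos + 1), n)
        c = counts[pos:stop]
        m = int(c.sum())
        if m:
            rep = np.repeat(np.arange(pos, stop), c)  # data-point index
            qidx = (np.arange(m)
                    - np.repeat(np.cumsum(c) - c, c)
                    + np.repeat(lo[pos:stop], c))
            offs = qs[qidx] - x[rep]
            if table is not None:
                w = table[offs + r_pt[0]]
            else:
                raw = np.ones(m) if spec.shape == "square" \
                    else _pairwise_weights(spec, offs, h[rep])
                w = raw * c_pt[rep]
            out += np.bincount(qidx, weights=w, minlength=qs.size)
        pos = stop
    eps = params.epsilon
    result = np.empty_like(out)
    result[order] = out
    result = (1.0 - eps) * result + eps * params.uniform_value
    return result[0] if scalar else result


def _pairwise_weights(spec: KernelSpec, offsets: np.ndarray,
                      h: np.ndarray) -> np.ndarray:
    """Unnormalized kernel values for pairs with per-pair bandwidths."""
    if spec.shape == "gaussian":
        o = offsets.astype(np.float64)
        return np.exp(-(o * o) / (2.0 * h * h))
    return 1.0 - np.abs(offsets).astype(np.float64) / (6.0 * h)


# ---------------------------------------------------------------------------
# exact sparse representations


def piecewise_constant_kde(X, H, spec: KernelSpec,
                           chrom_info: ChromInfo) -> DensityTrack:
    """Exact piecewise-constant square-kernel estimate via an event sweep.

    Each data point contributes one rise and one fall, so the result has at
    most ``2n + 1`` pieces; construction cost is independent of G.
    """
    if spec.shape != "square":
        raise ValueError("piecewise-constant representation requires the square kernel")
    x = _positions_array(X)
    h = _bandwidth_array(H, x.size)
    n = x.size
    radii = np.floor(3.0 * h).astype(np.int64)
    heights = 1.0 / (n * (2 * radii + 1))
    starts = x - radii
    ends = x + radii + 1  # first position after the kernel
    pos = np.concatenate([starts, ends])
    delta = np.concatenate([heights, -heights])
    order = np.argsort(pos, kind="stable")
    pos, delta = pos[order], delta[order]
    upos, first = np.unique(pos, return_index=True)
    agg = np.add.reduceat(delta, first)
    level = np.cumsum(agg)
    level[np.abs(level) < 1e-18] = 0.0  # float cancellation in zero gaps
    pieces = []
    for t in range(len(upos) - 1):
        s, e = int(upos[t]), int(upos[t + 1]) - 1
        s = max(s, 1)
        e = min(e, chrom_info.length)
        if s <= e:
            pieces.append((s, e, max(level[t], 0.0)))
    arr = np.array(pieces, dtype=np.float64).reshape(-1, 3)
    return DensityTrack(chrom_info=chrom_info, kind="pconst", n_train=n,
                        start=int(arr[0, 0]) if len(arr) else 1, pieces=arr)


def _prune_collinear(bx: np.ndarray, by: np.ndarray,
                     rtol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Drop interior breakpoints whose incoming and outgoing slopes agree.

    Removal uses immediate neighbors only, so a run of dropped points is a
    single linear segment and interpolation through the kept points is
    unchanged.
    """
    if len(bx) <= 2:
        return bx, by
    slopes = np.diff(by) / np.diff(bx)
    scale = np.maximum(np.abs(slopes[1:]), np.abs(slopes[:-1]))
    redundant = np.abs(slopes[1:] - slopes[:-1]) <= rtol * scale + 1e-300
    keep = np.ones(len(bx), dtype=bool)
    keep[1:-1] = ~redundant
    return bx[keep], by[keep]


def piecewise_linear_kde(X, H, spec: KernelSpec,
                         chrom_info: ChromInfo) -> DensityTrack:
    """Exact piecewise-linear triangle-kernel estimate.

    Built from slope-change events (support edges and apex of each kernel);
    linear interpolation between the returned breakpoints reproduces the
    dense evaluation at every integer.
    """
    if spec.shape != "triangle":
        raise ValueError("piecewise-linear representation requires the triangle kernel")
    x = _positions_array(X)
    h = _bandwidth_array(H, x.size)
    n = x.size
    ev_pos: list[np.ndarray] = []
    ev_chg: list[np.ndarray] = []
    for hv, pts in _iter_bandwidth_groups(x, h):
        kern = build_kernel(spec, hv)
        r = kern.radius
        w_edge = kern.weights[0] / n          # mass at offset -r
        s = (kern.weights[r] - kern.weights[0]) / (r * n)  # per-bp slope
        p = pts.astype(np.int64)
        ev_pos.extend([p - r, p - r + 1, p + 1, p + r + 1, p + r + 2])
        one = np.ones(p.size)
        ev_chg.extend([w_edge * one, (s - w_edge) * one, -2 * s * one,
                       (s - w_edge) * one, w_edge * one])
    pos = np.concatenate(ev_pos)
    chg = np.concatenate(ev_chg)
    nz = chg != 0.0
    pos, chg = pos[nz], chg[nz]
    order = np.argsort(pos, kind="stable")
    pos, chg = pos[order], chg[order]
    upos, first = np.unique(pos, return_index=True)
    slope_after = np.cumsum(np.add.reduceat(chg, first))

    # candidate breakpoints: every event position and the position just
    # before it (the function is linear on [p_t, p_{t+1} - 1])
    cand = np.unique(np.concatenate([upos, upos - 1]))
    # walk the event stream computing the value at each candidate; d(q),
    # the first difference of the track, changes only at event positions
    vals = np.empty(cand.size)
    val = 0.0
    cur = 0.0
    p0 = int(cand[0]) - 1
    ei = 0
    for ci, cp in enumerate(cand):
        cp = int(cp)
        while ei < upos.size and upos[ei] <= cp:
            e = int(upos[ei])
            val += cur * (e - 1 - p0)
            cur = slope_after[ei]
            val += cur
            p0 = e
            ei += 1
        val += cur * (cp - p0)
        p0 = cp
        vals[ci] = val
    vals[np.abs(vals) < 1e-18] = 0.0
    bx, by = _prune_collinear(cand.astype(np.float64), vals)
    # strip redundant zero breakpoints at the ends
    while len(bx) > 2 and by[0] == 0.0 and by[1] == 0.0:
        bx, by = bx[1:], by[1:]
    while len(bx) > 2 and by[-1] == 0.0 and by[-2] == 0.0:
        bx, by = bx[:-1], by[:-1]
    bps = np.column_stack([bx, by])
    return DensityTrack(chrom_info=chrom_info, kind="plin", n_train=n,
                        start=int(bx[0]), breakpoints=bps)
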