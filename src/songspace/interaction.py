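"""Temporal interaction statistics for pairs of song timelines.

Provides the vacant/overlapped/solo decomposition, the duty-cycle-preserving
gap-shuffle null, the solo-duration and asymmetric active-overlap
randomization tests, plug-in transfer entropy on binarized series with its
surrogate test, and session-level bootstraps.

All randomized machinery is vectorized: a batch of gap permutations is drawn
at once and the statistic is evaluated across the whole batch with numpy
broadcasting, which keeps 10,000-draw tests in the tens of milliseconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .timelines import BinarySeries, SongTimeline, binarize, n_bins

DEFAULT_N_RAND = 10_000
DEFAULT_N_BOOT = 10_000


@dataclass(frozen=True)
class PairDecomposition:
    """Partition of a window into vacant / overlapped / solo singing time."""

    duration: float
    vacant: float
    overlapped: float
    solo: float

    def __post_init__(self):
        if min(self.duration, self.vacant, self.overlapped, self.solo) < -1e-9:
            raise ValueError("decomposition components must be non-negative")
        if abs(self.vacant + self.overlapped + self.solo - self.duration) > 1e-6:
            raise ValueError("decomposition does not sum to the window duration")


@dataclass(frozen=True)
class RandTestResult:
    observed: float
    expected: float  # mean of the null distribution
    p_value: float
    n_rand: int
    seed: int | None = None


@dataclass(frozen=True)
class TEParams:
    """History lengths for transfer entropy; log base 2 (bits)."""

    k: int = 1
    l: int = 1

    def __post_init__(self):
        if self.k < 1 or self.l < 1:
            raise ValueError("history lengths k, l must be >= 1")


@dataclass(frozen=True)
class BootstrapResult:
    mean: float
    ci95: tuple[float, float]
    p_value: float
    n_boot: int
    seed: int | None = None


# ---------------------------------------------------------------------------
# interval kernels
# ---------------------------------------------------------------------------

def _check_windows(x: SongTimeline, y: SongTimeline):
    if x.window != y.window:
        raise ValueError("timelines have different windows")


def _pair_overlap(bx, ex, by, ey) -> float:
    """Total overlapped seconds between two sets of intervals (exact)."""
    if len(bx) == 0 or len(by) == 0:
        return 0.0
    o = np.minimum(ex[:, None], ey[None, :]) - np.maximum(bx[:, None], by[None, :])
    np.maximum(o, 0.0, out=o)
    return float(o.sum())


def decompose(x: SongTimeline, y: SongTimeline) -> PairDecomposition:
    """Exact vacant/overlapped/solo decomposition of the common window."""
    _check_windows(x, y)
    t0, t1 = x.window
    duration = t1 - t0
    dx, dy = x.total_singing, y.total_singing
    ov = _pair_overlap(x.begins, x.ends, y.begins, y.ends)
    solo = dx + dy - 2.0 * ov
    vacant = duration - dx - dy + ov
    return PairDecomposition(duration, vacant, ov, solo)


def _gap_durations(tl: SongTimeline) -> np.ndarray:
    """Nonsinging interval durations, including leading and trailing gaps."""
    t0, t1 = tl.window
    b, e = tl.begins, tl.ends
    if len(b) == 0:
        return np.array([t1 - t0])
    gaps = np.concatenate([[b[0] - t0], b[1:] - e[:-1], [t1 - e[-1]]])
    return np.maximum(gaps, 0.0)


def _starts_from_gaps(gaps: np.ndarray, durs: np.ndarray, t0: float) -> np.ndarray:
    """Song begin times from gap rows.  gaps: (n_draws, n_songs+1)."""
    cum_g = np.cumsum(gaps[:, :-1], axis=1)
    cum_d = np.concatenate([[0.0], np.cumsum(durs[:-1])]) if len(durs) else np.zeros(0)
    return t0 + cum_g + cum_d[None, :]


def shuffle_gaps(tl: SongTimeline, rng: np.random.Generator) -> SongTimeline:
    """Surrogate timeline: song durations and order preserved, nonsinging
    interval durations (incl. leading/trailing gaps) permuted uniformly."""
    durs = tl.ends - tl.begins
    gaps = rng.permutation(_gap_durations(tl))
    starts = _starts_from_gaps(gaps[None, :], durs, tl.window[0])[0]
    return SongTimeline(tl.individual_id,
                        tuple(zip(starts.tolist(), (starts + durs).tolist())),
                        tl.window)


def _batch_shuffled_starts(tl: SongTimeline, n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, n_songs) begin times of n independent gap shuffles."""
    gaps = _gap_durations(tl)
    G = np.tile(gaps, (n, 1))
    G = rng.permuted(G, axis=1)
    return _starts_from_gaps(G, tl.ends - tl.begins, tl.window[0])


def _coverage_pieces(sy: np.ndarray, ey: np.ndarray):
    """Piecewise-linear cumulative coverage of row-wise interval batches.

    Returns (bounds, val): per row, ``bounds`` interleaves begins and ends
    (sorted) and ``val[i]`` is the covered time accumulated up to
    ``bounds[i]``.  The coverage C(q) is then ``val[i] + (q - bounds[i])``
    inside a song piece and ``val[i]`` inside a gap piece.
    """
    n, k = sy.shape
    bounds = np.empty((n, 2 * k))
    bounds[:, 0::2] = sy
    bounds[:, 1::2] = ey
    dur = ey - sy
    cum = np.cumsum(dur, axis=1)
    val = np.empty((n, 2 * k))
    val[:, 0::2] = cum - dur
    val[:, 1::2] = cum
    return bounds, val


def _rowwise_searchsorted(a: np.ndarray, v: np.ndarray, side: str) -> np.ndarray:
    """searchsorted along axis 1 of a row-sorted (n, m) array for (n, q)
    queries, via per-row offsets and one flat searchsorted."""
    n, m = a.shape
    lo = min(float(a.min()), float(v.min()))
    hi = max(float(a.max()), float(v.max()))
    span = (hi - lo) + 1.0
    off = (np.arange(n) * span)[:, None]
    pos = np.searchsorted((a + off).ravel(), (v + off).ravel(), side=side)
    return pos.reshape(v.shape) - np.arange(n)[:, None] * m


def _coverage_at(bounds: np.ndarray, val: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Evaluate the cumulative coverage at query points, row-wise."""
    if bounds.shape[0] == 1 and q.shape[0] != 1:
        pos = np.searchsorted(bounds[0], q, side="right") - 1
    else:
        pos = _rowwise_searchsorted(bounds, q, side="right") - 1
    posc = np.clip(pos, 0, bounds.shape[1] - 1)
    base = np.take_along_axis(np.broadcast_to(val, (q.shape[0], val.shape[1])), posc, axis=1)
    bnd = np.take_along_axis(np.broadcast_to(bounds, (q.shape[0], bounds.shape[1])), posc, axis=1)
    in_song = (posc % 2 == 0)
    c = base + np.where(in_song, q - bnd, 0.0)
    return np.where(pos < 0, 0.0, c)


def _batch_overlap(sx, ex, sy, ey) -> np.ndarray:
    """Row-wise total overlap between (n, kx) and (n, ky) interval batches."""
    n = sx.shape[0]
    if sx.shape[1] == 0 or sy.shape[1] == 0:
        return np.zeros(n)
    bounds, val = _coverage_pieces(sy, ey)
    return (_coverage_at(bounds, val, ex) - _coverage_at(bounds, val, sx)).sum(axis=1)


# ---------------------------------------------------------------------------
# solo-duration randomization test
# ---------------------------------------------------------------------------

def solo_test(x: SongTimeline, y: SongTimeline,
              n_rand: int = DEFAULT_N_RAND, seed: int | None = None) -> RandTestResult:
    """Randomization test of the solo singing duration.

    Both timelines are gap-shuffled independently in each null draw; the
    p-value is the proportion of null solo durations strictly larger than
    the observed one.  Avoidance is flagged at p < .025 and active overlap
    at p > .975 (two-tailed reading).
    """
    _check_windows(x, y)
    rng = np.random.default_rng(seed)
    observed = decompose(x, y).solo
    dx, dy = x.total_singing, y.total_singing
    durx, dury = x.ends - x.begins, y.ends - y.begins
    sx = _batch_shuffled_starts(x, n_rand, rng)
    sy = _batch_shuffled_starts(y, n_rand, rng)
    ov = _batch_overlap(sx, sx + durx[None, :], sy, sy + dury[None, :])
    null_solo = dx + dy - 2.0 * ov
    p = float(np.mean(null_solo > observed))
    return RandTestResult(observed, float(null_solo.mean()), p, n_rand, seed)


# ---------------------------------------------------------------------------
# asymmetric active overlap
# ---------------------------------------------------------------------------

def _active_overlap(sx, ex, sy, ey, attribution: str) -> float:
    """Active-overlap seconds of X against fixed Y for one draw (1-D inputs)."""
    if len(sx) == 0 or len(sy) == 0:
        return 0.0
    # onset of x strictly inside a y song: b_y < b_x < e_y
    onset_in = ((sy[None, :] < sx[:, None]) & (sx[:, None] < ey[None, :])).any(axis=1)
    if not onset_in.any():
        return 0.0
    o = np.minimum(ex[:, None], ey[None, :]) - np.maximum(sx[:, None], sy[None, :])
    np.maximum(o, 0.0, out=o)
    if attribution == "union":
        per_song = o.sum(axis=1)
    elif attribution == "onset_song":
        inside = (sy[None, :] < sx[:, None]) & (sx[:, None] < ey[None, :])
        per_song = (o * inside).sum(axis=1)
    else:
        raise ValueError(f"unknown attribution {attribution!r}")
    return float(per_song[onset_in].sum())


def active_overlap_duration(target: SongTimeline, reference: SongTimeline,
                            attribution: str = "union") -> float:
    """Co-singing seconds attributed to the target: the sum, over target
    songs whose onset fell while the reference was already singing, of the
    co-singing time during those songs.

    ``attribution='union'`` counts all co-singing during such a song;
    ``'onset_song'`` counts only co-singing with the reference song that
    contained the onset.
    """
    _check_windows(target, reference)
    return _active_overlap(target.begins, target.ends,
                           reference.begins, reference.ends, attribution)


def asymmetric_overlap_test(target: SongTimeline, reference: SongTimeline,
                            n_rand: int = DEFAULT_N_RAND, seed: int | None = None,
                            attribution: str = "union") -> RandTestResult:
    """Randomization test of the target's active overlap with the reference.

    Only the target is gap-shuffled (the reference stays fixed); the p-value
    is the proportion of null active-overlap durations strictly smaller than
    the observed one.  The target significantly avoided overlap at p < .025
    and actively overlapped at p > .975.
    """
    _check_windows(target, reference)
    rng = np.random.default_rng(seed)
    observed = active_overlap_duration(target, reference, attribution)
    by, ey = reference.begins, reference.ends
    durx = target.ends - target.begins
    sx = _batch_shuffled_starts(target, n_rand, rng)
    null = np.empty(n_rand)
    if len(durx) == 0 or len(by) == 0:
        null[:] = 0.0
    elif attribution == "union":
        bx = sx
        ex = bx + durx[None, :]
        ybounds = np.ravel(np.column_stack([by, ey]))
        bounds, val = _coverage_pieces(by[None, :], ey[None, :])
        per_song = _coverage_at(bounds, val, ex) - _coverage_at(bounds, val, bx)
        # onset strictly inside a reference song: b_y < b_x < e_y
        pos = np.searchsorted(ybounds, bx, side="left")
        posc = np.minimum(pos, len(ybounds) - 1)
        inside = (pos % 2 == 1) & (ybounds[posc] != bx)
        null[:] = (per_song * inside).sum(axis=1)
    else:
        chunk = max(1, int(2_000_000 // max(1, len(durx) * len(by))))
        for i in range(0, n_rand, chunk):
            s = slice(i, min(i + chunk, n_rand))
            bx = sx[s]
            ex = bx + durx[None, :]
            in3 = (by[None, None, :] < bx[:, :, None]) & (bx[:, :, None] < ey[None, None, :])
            inside = in3.any(axis=2)
            o = np.minimum(ex[:, :, None], ey[None, None, :]) \
                - np.maximum(bx[:, :, None], by[None, None, :])
            np.maximum(o, 0.0, out=o)
            per_song = (o * in3).sum(axis=2)
            null[s] = (per_song * inside).sum(axis=1)
    p = float(np.mean(null < observed))
    return RandTestResult(observed, float(null.mean()), p, n_rand, seed)


# ---------------------------------------------------------------------------
# transfer entropy
# ---------------------------------------------------------------------------

def _history_codes(bits: np.ndarray, h: int) -> np.ndarray:
    """Integer codes of sliding h-step histories (code at index i encodes
    bits[i..i+h-1])."""
    if h == 1:
        return bits.astype(np.int64)
    w = sliding_window_view(bits, h)
    pw = (1 << np.arange(h - 1, -1, -1)).astype(np.int64)
    return w @ pw


def _te_codes(x: np.ndarray, y: np.ndarray, k: int, l: int) -> np.ndarray:
    """Joint outcome codes x_{t+1} | x_t^k | y_t^l over all valid t."""
    n = len(x)
    m = max(k, l)
    ts = np.arange(m - 1, n - 1)  # history ends at t, outcome at t+1
    xk = _history_codes(x, k)[ts - k + 1]
    yl = _history_codes(y, l)[ts - l + 1]
    x1 = x[ts + 1].astype(np.int64)
    return (x1 << (k + l)) | (xk << l) | yl


def _te_from_counts(counts: np.ndarray, k: int, l: int) -> np.ndarray:
    """Plug-in TE (bits) for each row of outcome counts (rows, 2^{k+l+1})."""
    c = counts.reshape(counts.shape[0], 2, 1 << k, 1 << l).astype(float)
    N = c.sum(axis=(1, 2, 3))
    c_xy = c.sum(axis=1)  # (rows, 2^k, 2^l): counts of (x^k, y^l)
    c_xx = c.sum(axis=3)  # (rows, 2, 2^k): counts of (x_{t+1}, x^k)
    c_x = c.sum(axis=(1, 3))  # (rows, 2^k)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = (c * c_x[:, None, :, None]) / (c_xy[:, None, :, :] * c_xx[:, :, :, None])
        term = np.where(c > 0, c * np.log2(ratio), 0.0)
    te = term.sum(axis=(1, 2, 3)) / N
    return np.maximum(te, 0.0)  # clamp -0.0 and rounding dust


def transfer_entropy(x: BinarySeries, y: BinarySeries,
                     params: TEParams = TEParams()) -> float:
    """Plug-in transfer entropy (bits) from source ``y`` to sink ``x``:
    expected log-ratio of the sink's transition probability with and without
    the source's past ``l`` states, given the sink's past ``k`` states.
    Zero-probability outcomes contribute 0."""
    if len(x.bits) != len(y.bits):
        raise ValueError("series lengths differ")
    if x.bin != y.bin:
        raise ValueError("series bin widths differ")
    k, l = params.k, params.l
    if len(x.bits) <= max(k, l) + 1:
        raise ValueError("series too short for the requested history lengths")
    codes = _te_codes(np.asarray(x.bits), np.asarray(y.bits), k, l)
    counts = np.bincount(codes, minlength=1 << (k + l + 1))[None, :]
    return float(_te_from_counts(counts, k, l)[0])


def te_test(sink: SongTimeline, source: SongTimeline,
            params: TEParams = TEParams(), bin: float = 0.5,
            n_rand: int = DEFAULT_N_RAND, seed: int | None = None) -> RandTestResult:
    """Surrogate test of the information flow source -> sink.

    The source's interval-level timeline is gap-shuffled (preserving bout
    structure) and re-binarized in each null draw; the p-value is the
    proportion of null TE values strictly larger than the observed one
    (one-tailed).
    """
    _check_windows(sink, source)
    rng = np.random.default_rng(seed)
    xb = binarize(sink, bin)
    observed = transfer_entropy(xb, binarize(source, bin), params)
    k, l = params.k, params.l
    nb = len(xb.bits)
    t0 = sink.window[0]
    durs = source.ends - source.begins
    starts = _batch_shuffled_starts(source, n_rand, rng)
    null = np.empty(n_rand)
    S = 1 << (k + l + 1)
    chunk = max(1, int(5_000_000 // max(1, nb)))
    x_arr = np.asarray(xb.bits)
    for i in range(0, n_rand, chunk):
        s = slice(i, min(i + chunk, n_rand))
        ybits = _batch_binarize(starts[s], starts[s] + durs[None, :], t0, nb, bin)
        rows = ybits.shape[0]
        codes = np.empty((rows, nb - max(k, l)), dtype=np.int64)
        for r in range(rows):
            codes[r] = _te_codes(x_arr, ybits[r], k, l)
        offset = (np.arange(rows, dtype=np.int64) * S)[:, None]
        flat = (codes + offset).ravel()
        counts = np.bincount(flat, minlength=rows * S).reshape(rows, S)
        null[s] = _te_from_counts(counts, k, l)
    p = float(np.mean(null > observed))
    return RandTestResult(observed, float(null.mean()), p, n_rand, seed)


def _batch_binarize(starts: np.ndarray, ends: np.ndarray, t0: float,
                    nb: int, binw: float) -> np.ndarray:
    """Midpoint-rule binarization of (n_draws, n_songs) interval batches."""
    n = starts.shape[0]
    if starts.shape[1] == 0:
        return np.zeros((n, nb), dtype=np.uint8)
    i0 = np.ceil((starts - t0) / binw - 0.5 - 1e-12).astype(np.int64)
    i1 = np.ceil((ends - t0) / binw - 0.5 - 1e-12).astype(np.int64)
    np.clip(i0, 0, nb, out=i0)
    np.clip(i1, 0, nb, out=i1)
    diff = np.zeros((n, nb + 1), dtype=np.int32)
    rows = np.repeat(np.arange(n), starts.shape[1])
    np.add.at(diff, (rows, i0.ravel()), 1)
    np.add.at(diff, (rows, i1.ravel()), -1)
    return (np.cumsum(diff[:, :-1], axis=1) > 0).astype(np.uint8)


# ---------------------------------------------------------------------------
# session-level bootstraps
# ---------------------------------------------------------------------------

_EFFECTS: dict[str, Callable] = {
    "expected_minus_observed": lambda v: float(v[1]) - float(v[0]),
    "te_minus_ternd": lambda v: float(v[0]) - float(v[1]),
    "obs_exp_ratio_diff": lambda v: float(v[0][0]) / float(v[0][1])
                                    - float(v[1][0]) / float(v[1][1]),
}


def bootstrap_effect(per_session_values: Sequence, effect: str,
                     n_boot: int = DEFAULT_N_BOOT, seed: int | None = None) -> BootstrapResult:
    """Session-resampling bootstrap of a mean effect.

    ``per_session_values`` holds one entry per session: an ``(observed,
    expected)`` pair for ``expected_minus_observed`` / ``te_minus_ternd``, or
    a pair of ``(observed, expected)`` pairs (one per individual) for
    ``obs_exp_ratio_diff``.  Sessions are resampled with replacement; the
    statistic is the mean per-session effect.  The two-sided sign-bootstrap
    p-value is ``2 * min(P*(stat <= 0), P*(stat >= 0))`` capped at 1.
    """
    if effect not in _EFFECTS:
        raise ValueError(f"unknown effect {effect!r}")
    vals = np.array([_EFFECTS[effect](v) for v in per_session_values], dtype=float)
    n = len(vals)
    if n < 2:
        raise ValueError("bootstrap needs at least 2 sessions")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    stats = vals[idx].mean(axis=1)
    lo, hi = np.percentile(stats, [2.5, 97.5])
    p = 2.0 * min(float(np.mean(stats <= 0.0)), float(np.mean(stats >= 0.0)))
    return BootstrapResult(float(vals.mean()), (float(lo), float(hi)),
                           min(p, 1.0), n_boot, seed)
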