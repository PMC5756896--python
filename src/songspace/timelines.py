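"""Per-individual song timelines: song-post assignment, binarization and
scoring against reference annotations.

A :class:`SongTimeline` is an ordered list of non-overlapping half-open
``[t_begin, t_end)`` intervals inside an analysis window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .io_formats import AnnotationSet, FormatError

_EPS = 1e-9


@dataclass(frozen=True)
class SongPost:
    """A fixed singing perch; localized sources within ``radius`` of the
    center are attributed to this individual."""

    individual_id: str
    center_xy: tuple[float, float]
    radius: float

    def __post_init__(self):
        if not self.radius > 0:
            raise ValueError(f"post {self.individual_id!r}: radius must be > 0")


@dataclass(frozen=True)
class SongTimeline:
    individual_id: str
    intervals: tuple[tuple[float, float], ...]
    window: tuple[float, float]

    def __post_init__(self):
        ivs = tuple((float(b), float(e)) for b, e in self.intervals)
        object.__setattr__(self, "intervals", ivs)
        object.__setattr__(self, "window", (float(self.window[0]), float(self.window[1])))
        t0, t1 = self.window
        prev_end = t0 - _EPS
        for b, e in ivs:
            if not b < e:
                raise ValueError(f"timeline {self.individual_id!r}: empty interval ({b}, {e})")
            if b < prev_end - _EPS:
                raise ValueError(f"timeline {self.individual_id!r}: intervals overlap or unsorted")
            if b < t0 - _EPS or e > t1 + _EPS:
                raise ValueError(f"timeline {self.individual_id!r}: interval outside window")
            prev_end = e

    @property
    def begins(self) -> np.ndarray:
        return np.array([b for b, _ in self.intervals], dtype=float)

    @property
    def ends(self) -> np.ndarray:
        return np.array([e for _, e in self.intervals], dtype=float)

    @property
    def total_singing(self) -> float:
        return float(sum(e - b for b, e in self.intervals))

    @property
    def duty_cycle(self) -> float:
        t0, t1 = self.window
        return self.total_singing / (t1 - t0) if t1 > t0 else 0.0

    def contains(self, t: float) -> bool:
        """True iff ``t`` lies inside a song interval (half-open)."""
        return any(b <= t < e for b, e in self.intervals)

    def clipped(self, window: tuple[float, float]) -> "SongTimeline":
        t0, t1 = window
        ivs = [(max(b, t0), min(e, t1)) for b, e in self.intervals if max(b, t0) < min(e, t1)]
        return SongTimeline(self.individual_id, tuple(ivs), (t0, t1))

    def complement_intervals(self) -> tuple[tuple[float, float], ...]:
        """Nonsinging intervals within the window (may include zero-length)."""
        t0, t1 = self.window
        out = []
        cur = t0
        for b, e in self.intervals:
            out.append((cur, b))
            cur = e
        out.append((cur, t1))
        return tuple(out)


@dataclass(frozen=True)
class BinarySeries:
    """0/1 singing indicator at fixed bin width starting at ``t0``."""

    bits: np.ndarray
    bin: float = 0.5
    t0: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "bits", np.asarray(self.bits, dtype=np.uint8))
        if self.bits.ndim != 1 or self.bits.size < 1:
            raise ValueError("bits must be a non-empty 1-D array")
        if not self.bin > 0:
            raise ValueError("bin width must be > 0")


@dataclass(frozen=True)
class EvaluationResult:
    """Duration-based confusion between a localized and a reference timeline."""

    tp: float
    fp: float
    tn: float
    fn: float

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total > 0 else 0.0

    @property
    def tpr(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d > 0 else 0.0

    @property
    def fpr(self) -> float:
        d = self.fp + self.tn
        return self.fp / d if d > 0 else 0.0


def timeline_from_annotations(annotations: AnnotationSet, individual: str,
                              window: tuple[float, float] | None = None) -> SongTimeline:
    """Build one individual's timeline from an annotation set."""
    win = window if window is not None else annotations.window
    ivs = annotations.intervals_for(individual)
    return SongTimeline(individual, tuple(sorted(ivs)), annotations.window).clipped(win)


# ---------------------------------------------------------------------------
# song-post assignment
# ---------------------------------------------------------------------------

def assign_to_posts(sources: Sequence, posts: Sequence[SongPost],
                    window: tuple[float, float]):
    """Assign localized sources to song posts and build per-individual
    timelines.

    A source belongs to the post whose center lies within that post's radius
    of the source (nearest center when several qualify).  When two sources
    assigned to the same individual overlap in time, the one that began
    earlier is kept and the other is dropped entirely.  Sources outside all
    post radii are returned separately.

    Returns ``(timelines, unassigned)`` where ``timelines`` maps
    individual_id to :class:`SongTimeline`.
    """
    centers = {p.individual_id: np.asarray(p.center_xy, dtype=float) for p in posts}
    if len(centers) != len(posts):
        raise ValueError("post individual_ids must be distinct")
    assigned: dict[str, list] = {p.individual_id: [] for p in posts}
    unassigned = []
    for s in sources:
        xy = np.asarray(s.xy, dtype=float)
        best = None
        best_d = math.inf
        for p in posts:
            d = float(np.hypot(*(xy - centers[p.individual_id])))
            if d <= p.radius and d < best_d:
                best, best_d = p.individual_id, d
        if best is None:
            unassigned.append(s)
        else:
            assigned[best].append(s)

    timelines: dict[str, SongTimeline] = {}
    t0, t1 = window
    for pid, srcs in assigned.items():
        srcs.sort(key=lambda s: (s.t_begin, s.t_end))
        kept: list[tuple[float, float]] = []
        for s in srcs:
            if kept and s.t_begin < kept[-1][1]:
                continue  # overlaps an earlier-beginning source: drop whole source
            kept.append((s.t_begin, s.t_end))
        clipped = [(max(b, t0), min(e, t1)) for b, e in kept if max(b, t0) < min(e, t1)]
        timelines[pid] = SongTimeline(pid, tuple(clipped), (t0, t1))
    return timelines, unassigned


# ---------------------------------------------------------------------------
# binarization (midpoint rule)
# ---------------------------------------------------------------------------

def n_bins(window: tuple[float, float], bin: float) -> int:
    return int(math.floor((window[1] - window[0]) / bin + 1e-9))


def binarize(timeline: SongTimeline, bin: float = 0.5) -> BinarySeries:
    """Binarize a timeline: bin i covers [t0+i*bin, t0+(i+1)*bin) and is 1
    iff some song interval contains the bin midpoint."""
    if not bin > 0:
        raise ValueError("bin width must be > 0")
    t0 = timeline.window[0]
    n = n_bins(timeline.window, bin)
    if n < 1:
        raise ValueError("window shorter than one bin")
    bits = np.zeros(n, dtype=np.uint8)
    for b, e in timeline.intervals:
        i0 = max(0, int(math.ceil((b - t0) / bin - 0.5 - 1e-12)))
        i1 = min(n, int(math.ceil((e - t0) / bin - 0.5 - 1e-12)))
        if i1 > i0:
            bits[i0:i1] = 1
    return BinarySeries(bits, bin=bin, t0=t0)


# ---------------------------------------------------------------------------
# evaluation against annotations
# ---------------------------------------------------------------------------

def evaluate(localized: SongTimeline, annotated: SongTimeline) -> EvaluationResult:
    """Exact duration-based confusion (TP/FP/TN/FN in seconds) between the
    localized and annotated singing sets over their common window."""
    if localized.window != annotated.window:
        raise ValueError("evaluate: timelines have different windows")
    t0, t1 = localized.window
    bounds = {t0, t1}
    for tl in (localized, annotated):
        for b, e in tl.intervals:
            bounds.add(b)
            bounds.add(e)
    pts = sorted(bounds)
    tp = fp = tn = fn = 0.0
    for a, b in zip(pts[:-1], pts[1:]):
        if b <= t0 or a >= t1:
            continue
        mid = 0.5 * (a + b)
        seg = b - a
        in_loc = localized.contains(mid)
        in_ann = annotated.contains(mid)
        if in_loc and in_ann:
            tp += seg
        elif in_loc:
            fp += seg
        elif in_ann:
            fn += seg
        else:
            tn += seg
    return EvaluationResult(tp, fp, tn, fn)
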