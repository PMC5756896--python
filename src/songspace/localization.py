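"""Triangulation of 2D song locations from per-array DOA events.

Each event is collapsed to one bearing (circular mean of its azimuth track);
candidate triples of events from three different arrays are gated in time
(begin/end spreads) and space (pairwise half-line intersection distances) and
accepted greedily, tightest spatial gate first, with one-to-one use of
events.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io_formats import ArrayGeometry, DOAEvent


@dataclass(frozen=True)
class LocalizationParams:
    """Gating and timing parameters of the triangulation.

    frame_dt        sampling step of azimuth tracks (s)
    max_spread      largest allowed pairwise distance between the three
                    ray intersections (m)
    begin_tol       largest allowed pairwise spread of event begin times (s);
                    generous because quiet introductory notes are often missed
    end_tol         largest allowed pairwise spread of event end times (s);
                    tight because song endings are loud and well localized
    end_correction  subtracted from the accepted source's end time (s) to
                    undo the silence-detection tail of the upstream detector
    """

    frame_dt: float = 0.2
    max_spread: float = 15.0
    begin_tol: float = 6.0
    end_tol: float = 1.0
    end_correction: float = 0.6

    def __post_init__(self):
        for name in ("frame_dt", "max_spread", "begin_tol", "end_tol", "end_correction"):
            if not getattr(self, name) > 0:
                raise ValueError(f"LocalizationParams.{name} must be > 0")


@dataclass(frozen=True)
class LocalizedSource:
    """A triangulated sound: centroid location, duration taken from the
    member event of the array nearest the centroid (end reduced by the
    end correction), and the gate statistics of the accepted triple."""

    xy: tuple[float, float]
    t_begin: float
    t_end: float
    member_events: tuple[tuple[str, str], ...]
    max_intersection_dist: float
    begin_spread: float
    end_spread: float

    def __post_init__(self):
        if not self.t_begin < self.t_end:
            raise ValueError("LocalizedSource: t_begin must be < t_end")

    @property
    def gate_stats(self) -> tuple[float, float, float]:
        return (self.max_intersection_dist, self.begin_spread, self.end_spread)


@dataclass(frozen=True)
class LocatedInterval:
    """A human-observed singing interval with its observed location."""

    individual_id: str
    t_begin: float
    t_end: float
    x: float
    y: float


def circular_mean_deg(azimuths_deg) -> float:
    """Direction of the mean unit vector, in degrees in [0, 360)."""
    az = np.deg2rad(np.asarray(azimuths_deg, dtype=float))
    if az.size == 0:
        raise ValueError("circular mean of empty set")
    s, c = np.sin(az).mean(), np.cos(az).mean()
    deg = float(np.rad2deg(np.arctan2(s, c)) % 360.0)
    return deg if deg < 360.0 else 0.0  # -1e-16 % 360 rounds to 360.0


def event_bearing(event: DOAEvent, t_window: tuple[float, float] | None = None) -> float:
    """Circular-mean bearing of an event's azimuth track, optionally
    restricted to frames inside ``t_window``."""
    az = event.azimuths
    if t_window is not None:
        t = event.times
        mask = (t >= t_window[0]) & (t <= t_window[1])
        if not mask.any():
            raise ValueError(f"event {event.event_id!r}: no track frames inside {t_window}")
        az = az[mask]
    return circular_mean_deg(az)


def intersect_rays(origin1, azimuth1_deg: float, origin2, azimuth2_deg: float,
                   parallel_tol: float = 1e-9):
    """Intersection of two half-lines, or None.

    Returns the unique point with a non-negative ray parameter on both
    half-lines; None when the rays are parallel within ``parallel_tol``
    radians or the lines cross behind either origin.
    """
    p = np.asarray(origin1, dtype=float)
    q = np.asarray(origin2, dtype=float)
    a1 = math.radians(azimuth1_deg)
    a2 = math.radians(azimuth2_deg)
    r = np.array([math.cos(a1), math.sin(a1)])
    s = np.array([math.cos(a2), math.sin(a2)])
    denom = r[0] * s[1] - r[1] * s[0]  # |sin(angle between)| for unit vectors
    if abs(denom) < parallel_tol:
        return None
    d = q - p
    t1 = (d[0] * s[1] - d[1] * s[0]) / denom
    t2 = (d[0] * r[1] - d[1] * r[0]) / denom
    if t1 < 0.0 or t2 < 0.0:
        return None
    return p + t1 * r


def triangulate(events_by_array: Mapping[str, Sequence[DOAEvent]],
                geometry: ArrayGeometry,
                params: LocalizationParams = LocalizationParams()) -> list[LocalizedSource]:
    """Triangulate sources from per-array DOA events.

    Candidate triples (one event from each of three arrays) must satisfy
    pairwise begin spreads <= begin_tol and end spreads <= end_tol; the three
    pairwise half-line intersections must all exist with max pairwise
    distance <= max_spread.  Accepted location is the centroid of the three
    intersections; duration comes from the member event of the array closest
    to the centroid, with the end correction subtracted.  Candidates are
    accepted greedily in ascending spatial-gate order and each event is used
    at most once.
    """
    if len(geometry.arrays) < 3:
        raise ValueError("triangulation requires at least 3 arrays")
    positions = geometry.positions()
    array_ids = sorted(a for a in geometry.array_ids if events_by_array.get(a))

    # per-array events sorted by begin time, with cached bearings
    ev_sorted: dict[str, list[DOAEvent]] = {}
    bearing: dict[tuple[str, str], float] = {}
    for a in array_ids:
        evs = sorted(events_by_array[a], key=lambda e: (e.t_begin, e.t_end, e.event_id))
        ev_sorted[a] = evs
        for e in evs:
            bearing[(a, e.event_id)] = event_bearing(e)

    candidates = []
    for trio in itertools.combinations(array_ids, 3):
        a1, a2, a3 = trio
        evs2 = ev_sorted[a2]
        evs3 = ev_sorted[a3]
        b2 = np.array([e.t_begin for e in evs2])
        b3 = np.array([e.t_begin for e in evs3])
        for e1 in ev_sorted[a1]:
            lo2 = int(np.searchsorted(b2, e1.t_begin - params.begin_tol, side="left"))
            hi2 = int(np.searchsorted(b2, e1.t_begin + params.begin_tol, side="right"))
            for e2 in evs2[lo2:hi2]:
                if abs(e1.t_end - e2.t_end) > params.end_tol:
                    continue
                lo = max(e1.t_begin, e2.t_begin) - params.begin_tol
                hi = min(e1.t_begin, e2.t_begin) + params.begin_tol
                lo3 = int(np.searchsorted(b3, lo, side="left"))
                hi3 = int(np.searchsorted(b3, hi, side="right"))
                for e3 in evs3[lo3:hi3]:
                    if (abs(e1.t_end - e3.t_end) > params.end_tol
                            or abs(e2.t_end - e3.t_end) > params.end_tol):
                        continue
                    cand = _gate_triple((a1, e1), (a2, e2), (a3, e3),
                                        positions, bearing, params)
                    if cand is not None:
                        candidates.append(cand)

    candidates.sort(key=lambda c: (c.max_intersection_dist, c.t_begin, c.member_events))
    used: set[tuple[str, str]] = set()
    accepted: list[LocalizedSource] = []
    for cand in candidates:
        if any(m in used for m in cand.member_events):
            continue
        used.update(cand.member_events)
        accepted.append(cand)
    accepted.sort(key=lambda s: (s.t_begin, s.t_end))
    return accepted


def _gate_triple(m1, m2, m3, positions, bearing, params):
    members = (m1, m2, m3)
    pts = []
    for (ai, ei), (aj, ej) in itertools.combinations(members, 2):
        pt = intersect_rays(positions[ai], bearing[(ai, ei.event_id)],
                            positions[aj], bearing[(aj, ej.event_id)])
        if pt is None:
            return None
        pts.append(pt)
    dmax = max(float(np.hypot(*(p - q)))
               for p, q in itertools.combinations(pts, 2))
    if dmax > params.max_spread:
        return None
    centroid = np.mean(pts, axis=0)
    nearest = min(members, key=lambda m: (float(np.hypot(*(centroid - positions[m[0]]))), m[0]))
    t_begin = nearest[1].t_begin
    t_end = nearest[1].t_end - params.end_correction
    if not t_begin < t_end:
        return None  # shorter than the end correction: cannot be a real song
    begins = [e.t_begin for _, e in members]
    ends = [e.t_end for _, e in members]
    return LocalizedSource(
        xy=(float(centroid[0]), float(centroid[1])),
        t_begin=t_begin,
        t_end=t_end,
        member_events=tuple((a, e.event_id) for a, e in members),
        max_intersection_dist=dmax,
        begin_spread=max(begins) - min(begins),
        end_spread=max(ends) - min(ends),
    )


# ---------------------------------------------------------------------------
# observed vs localized distances
# ---------------------------------------------------------------------------

def observed_localized_distances(observed: Sequence[LocatedInterval],
                                 sources: Sequence[LocalizedSource],
                                 tick: float = 1.0) -> dict[str, np.ndarray]:
    """Distances from each observed location to the nearest simultaneously
    active localized source, sampled every ``tick`` seconds inside each
    observed interval.  Ticks with no active source are skipped."""
    if not tick > 0:
        raise ValueError("tick must be > 0")
    src_b = np.array([s.t_begin for s in sources])
    src_e = np.array([s.t_end for s in sources])
    src_xy = np.array([s.xy for s in sources]).reshape(-1, 2)
    out: dict[str, list[float]] = {}
    for rec in observed:
        ticks = np.arange(rec.t_begin, rec.t_end, tick)
        obs = np.array([rec.x, rec.y])
        dists = out.setdefault(rec.individual_id, [])
        for t in ticks:
            active = (src_b <= t) & (t < src_e)
            if not active.any():
                continue
            d = np.hypot(*(src_xy[active] - obs).T)
            dists.append(float(d.min()))
    return {k: np.asarray(v) for k, v in out.items()}


def summarize_distances(distances: Mapping[str, np.ndarray],
                        cutoff: float = 30.0,
                        hist_bin: float = 2.0,
                        hist_max: float = 100.0) -> dict[str, dict]:
    """Per-individual mean +/- sd of distances below ``cutoff`` plus a
    histogram of all distances."""
    edges = np.arange(0.0, hist_max + hist_bin, hist_bin)
    summary = {}
    for ind, d in distances.items():
        near = d[d < cutoff]
        counts, _ = np.histogram(d, bins=edges)
        summary[ind] = {
            "n_ticks": int(d.size),
            "n_near": int(near.size),
            "mean": float(near.mean()) if near.size else float("nan"),
            "sd": float(near.std(ddof=1)) if near.size > 1 else float("nan"),
            "hist_counts": counts,
            "hist_edges": edges,
        }
    return summary
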