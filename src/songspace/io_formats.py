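"""Readers and writers for array geometry, DOA-event tables and annotations.

All on-disk artifacts are plain text.  Times are seconds from session start
(float, 0-based) and every interval is half-open ``[begin, end)``.  Azimuths
are stored in degrees; the internal convention is mathematical
(counterclockwise from +x / east).  Compass azimuths (clockwise from north)
are converted at the file boundary only.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

AZIMUTH_CONVENTIONS = ("math_ccw_from_east", "compass_cw_from_north")
GEOMETRY_FORMAT_VERSION = 1

DOA_COLUMNS = ("array_id", "event_id", "t", "azimuth", "t_begin", "t_end")
ANNOTATION_COLUMNS = ("individual", "t_begin", "t_end")


class FormatError(ValueError):
    """Raised on malformed input files or invalid domain values."""


# ---------------------------------------------------------------------------
# azimuth conventions
# ---------------------------------------------------------------------------

def to_math_azimuth(azimuth_deg, convention: str):
    """Convert an azimuth to the internal convention (ccw from east)."""
    az = np.asarray(azimuth_deg, dtype=float)
    if convention == "math_ccw_from_east":
        out = az % 360.0
    elif convention == "compass_cw_from_north":
        out = (90.0 - az) % 360.0
    else:
        raise FormatError(f"unknown azimuth convention: {convention!r}")
    return float(out) if out.ndim == 0 else out


def from_math_azimuth(azimuth_deg: float, convention: str) -> float:
    """Inverse of :func:`to_math_azimuth` (the mapping is an involution)."""
    return to_math_azimuth(azimuth_deg, convention)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArrayGeometry:
    """Planar positions of the microphone arrays plus the azimuth convention
    used by files associated with this geometry."""

    arrays: tuple[tuple[str, float, float], ...]
    azimuth_convention: str = "math_ccw_from_east"

    def __post_init__(self):
        object.__setattr__(self, "arrays", tuple((str(a), float(x), float(y)) for a, x, y in self.arrays))
        ids = [a for a, _, _ in self.arrays]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise FormatError(f"duplicate array_id(s): {dup}")
        if len(ids) < 2:
            raise FormatError("geometry needs at least 2 arrays (3 for triangulation)")
        for a, x, y in self.arrays:
            if not (math.isfinite(x) and math.isfinite(y)):
                raise FormatError(f"non-finite coordinate for array {a!r}")
        if self.azimuth_convention not in AZIMUTH_CONVENTIONS:
            raise FormatError(f"unknown azimuth convention: {self.azimuth_convention!r}")

    @property
    def array_ids(self) -> tuple[str, ...]:
        return tuple(a for a, _, _ in self.arrays)

    def positions(self) -> dict[str, np.ndarray]:
        return {a: np.array([x, y], dtype=float) for a, x, y in self.arrays}

    def to_internal_azimuth(self, azimuth_deg):
        """Convert an azimuth expressed in this geometry's declared
        convention to the internal math convention."""
        return to_math_azimuth(azimuth_deg, self.azimuth_convention)


@dataclass(eq=False)
class DOAEvent:
    """One localized directional sound at one array.

    ``track`` is an (n, 2) array of (t, azimuth_deg) frames, strictly
    increasing in t, inside [t_begin, t_end], azimuths in [0, 360) using the
    internal math convention.
    """

    array_id: str
    event_id: str
    t_begin: float
    t_end: float
    track: np.ndarray

    def __post_init__(self):
        self.track = np.asarray(self.track, dtype=float).reshape(-1, 2)
        self.t_begin = float(self.t_begin)
        self.t_end = float(self.t_end)
        if not self.t_begin < self.t_end:
            raise FormatError(
                f"event {self.event_id!r} on array {self.array_id!r}: t_begin >= t_end")
        if self.track.shape[0] == 0:
            raise FormatError(f"event {self.event_id!r}: empty azimuth track")
        t = self.track[:, 0]
        if np.any(np.diff(t) <= 0):
            raise FormatError(
                f"event {self.event_id!r} on array {self.array_id!r}: track times not strictly increasing")
        eps = 1e-9
        if t[0] < self.t_begin - eps or t[-1] > self.t_end + eps:
            raise FormatError(
                f"event {self.event_id!r}: track times outside [t_begin, t_end]")
        az = self.track[:, 1]
        if np.any(az < 0.0) or np.any(az >= 360.0):
            raise FormatError(f"event {self.event_id!r}: azimuths must lie in [0, 360)")

    @property
    def times(self) -> np.ndarray:
        return self.track[:, 0]

    @property
    def azimuths(self) -> np.ndarray:
        return self.track[:, 1]

    def __eq__(self, other):
        if not isinstance(other, DOAEvent):
            return NotImplemented
        return (self.array_id == other.array_id and self.event_id == other.event_id
                and self.t_begin == other.t_begin and self.t_end == other.t_end
                and np.array_equal(self.track, other.track))


@dataclass(frozen=True)
class AnnotationSet:
    """Per-individual annotated singing intervals within a window.

    Intervals are merged per individual at load time: abutting or overlapping
    records of the same individual become one interval (a bird does not
    overlap itself).
    """

    records: tuple[tuple[str, float, float], ...]
    window: tuple[float, float]

    def __post_init__(self):
        object.__setattr__(self, "records",
                           tuple((str(i), float(b), float(e)) for i, b, e in self.records))
        object.__setattr__(self, "window", (float(self.window[0]), float(self.window[1])))
        t0, t1 = self.window
        for i, b, e in self.records:
            if not b < e:
                raise FormatError(f"annotation for {i!r}: t_begin >= t_end")
            if b < t0 - 1e-9 or e > t1 + 1e-9:
                raise FormatError(f"annotation for {i!r} outside window {self.window}")

    @property
    def individuals(self) -> tuple[str, ...]:
        seen: list[str] = []
        for i, _, _ in self.records:
            if i not in seen:
                seen.append(i)
        return tuple(seen)

    def intervals_for(self, individual: str) -> list[tuple[float, float]]:
        return [(b, e) for i, b, e in self.records if i == individual]


# ---------------------------------------------------------------------------
# geometry files (YAML, versioned)
# ---------------------------------------------------------------------------

def read_geometry(path) -> ArrayGeometry:
    """Read an array-geometry config.

    Schema (YAML)::

        format: 1
        azimuth_convention: math_ccw_from_east | compass_cw_from_north
        arrays:
          - {id: m1, x: 0.0, y: 0.0}
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: not a mapping")
    if doc.get("format") != GEOMETRY_FORMAT_VERSION:
        raise FormatError(f"{path}: missing or unsupported 'format' (expected {GEOMETRY_FORMAT_VERSION})")
    raw = doc.get("arrays")
    if not raw:
        raise FormatError(f"{path}: no arrays listed")
    arrays = []
    for entry in raw:
        if "id" not in entry:
            raise FormatError(f"{path}: array entry without 'id'")
        if "x" not in entry or "y" not in entry or entry["x"] is None or entry["y"] is None:
            raise FormatError(f"{path}: array {entry.get('id')!r} is missing a coordinate")
        arrays.append((str(entry["id"]), float(entry["x"]), float(entry["y"])))
    convention = doc.get("azimuth_convention", "math_ccw_from_east")
    return ArrayGeometry(tuple(arrays), convention)


def geometry_to_dict(geometry: ArrayGeometry) -> dict:
    return {
        "format": GEOMETRY_FORMAT_VERSION,
        "azimuth_convention": geometry.azimuth_convention,
        "arrays": [{"id": a, "x": float(x), "y": float(y)} for a, x, y in geometry.arrays],
    }


def write_geometry(geometry: ArrayGeometry, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(geometry_to_dict(geometry), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# DOA event tables (CSV, one row per (event, frame))
# ---------------------------------------------------------------------------

def read_doa_events(path, convention: str = "math_ccw_from_east") -> list[DOAEvent]:
    """Read a DOA event table: columns ``array_id,event_id,t,azimuth,t_begin,t_end``.

    Rows belonging to the same (array_id, event_id) form one event; the track
    must already be in time order (non-monotone tracks are an error).
    """
    groups: dict[tuple[str, str], dict] = {}
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or tuple(h.strip() for h in header) != DOA_COLUMNS:
            raise FormatError(f"{path}: expected header {','.join(DOA_COLUMNS)}")
        for row in reader:
            if not row:
                continue
            array_id, event_id = row[0], row[1]
            t, az, tb, te = (float(v) for v in row[2:6])
            key = (array_id, event_id)
            g = groups.setdefault(key, {"t_begin": tb, "t_end": te, "frames": []})
            g["frames"].append((t, to_math_azimuth(az, convention)))
    events = []
    for (array_id, event_id), g in groups.items():
        track = np.array(g["frames"], dtype=float)
        if np.any(np.diff(track[:, 0]) <= 0):
            raise FormatError(f"{path}: non-monotone track times in event {event_id!r}")
        events.append(DOAEvent(array_id, event_id, g["t_begin"], g["t_end"], track))
    return events


def write_doa_events(events: Iterable[DOAEvent], path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DOA_COLUMNS)
        for ev in events:
            for t, az in ev.track:
                w.writerow([ev.array_id, ev.event_id, repr(float(t)), repr(float(az)),
                            repr(ev.t_begin), repr(ev.t_end)])


# ---------------------------------------------------------------------------
# annotations (interval table CSV or Praat TextGrid)
# ---------------------------------------------------------------------------

def _merge_intervals(intervals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    """Merge overlapping or abutting half-open intervals."""
    out: list[list[float]] = []
    for b, e in sorted(intervals):
        if out and b <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([b, e])
    return [(b, e) for b, e in out]


def _build_annotation_set(raw: list[tuple[str, float, float]],
                          window: tuple[float, float] | None) -> AnnotationSet:
    if window is None:
        if raw:
            window = (min(b for _, b, _ in raw), max(e for _, _, e in raw))
        else:
            window = (0.0, 0.0)
    by_ind: dict[str, list[tuple[float, float]]] = {}
    order: list[str] = []
    for i, b, e in raw:
        if i not in by_ind:
            by_ind[i] = []
            order.append(i)
        by_ind[i].append((b, e))
    records = []
    for i in order:
        for b, e in _merge_intervals(by_ind[i]):
            records.append((i, b, e))
    return AnnotationSet(tuple(records), window)


def read_annotations(path, dialect: str = "interval_table") -> AnnotationSet:
    """Read annotations from an interval table or a Praat TextGrid.

    ``interval_table``: CSV with header ``individual,t_begin,t_end``; an
    optional leading comment ``# window: t0 t1`` fixes the analysis window
    (otherwise min/max of the records is used).

    ``textgrid``: long-format Praat TextGrid; each interval tier is one
    individual, non-empty interval labels are songs.
    """
    if dialect == "interval_table":
        return _read_annotation_table(path)
    if dialect == "textgrid":
        return _read_textgrid(path)
    raise FormatError(f"unknown annotation dialect: {dialect!r}")


def _read_annotation_table(path) -> AnnotationSet:
    window = None
    raw: list[tuple[str, float, float]] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        lines = fh.read().splitlines()
    body = []
    for line in lines:
        if line.startswith("#"):
            m = re.match(r"#\s*window:\s*([-\d.eE+]+)\s+([-\d.eE+]+)", line)
            if m:
                window = (float(m.group(1)), float(m.group(2)))
        elif line.strip():
            body.append(line)
    if not body:
        return _build_annotation_set([], window)
    header = tuple(h.strip() for h in body[0].split(","))
    if header != ANNOTATION_COLUMNS:
        raise FormatError(f"{path}: expected header {','.join(ANNOTATION_COLUMNS)}")
    for rowno, line in enumerate(body[1:], start=1):
        fields = next(csv.reader([line]))
        ind, b, e = fields[0], float(fields[1]), float(fields[2])
        if not b < e:
            raise FormatError(f"{path}: row {rowno}: t_begin >= t_end")
        raw.append((ind, b, e))
    return _build_annotation_set(raw, window)


_TG_INTERVAL = re.compile(
    r'xmin\s*=\s*([-\d.eE+]+)\s*\n\s*xmax\s*=\s*([-\d.eE+]+)\s*\n\s*text\s*=\s*"([^"]*)"')


def _read_textgrid(path) -> AnnotationSet:
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    m0 = re.search(r"xmin\s*=\s*([-\d.eE+]+)", text)
    m1 = re.search(r"xmax\s*=\s*([-\d.eE+]+)", text)
    if not (m0 and m1):
        raise FormatError(f"{path}: not a TextGrid (missing global xmin/xmax)")
    window = (float(m0.group(1)), float(m1.group(1)))
    raw: list[tuple[str, float, float]] = []
    # split into tier blocks; the preamble before the first item is dropped
    blocks = re.split(r"item\s*\[\d+\]\s*:", text)[1:]
    for block in blocks:
        cls = re.search(r'class\s*=\s*"([^"]*)"', block)
        name = re.search(r'name\s*=\s*"([^"]*)"', block)
        if cls is None or cls.group(1) != "IntervalTier" or name is None:
            continue
        individual = name.group(1)
        # skip the tier's own xmin/xmax (first match pair without text) by
        # only taking xmin/xmax/text triples
        for b, e, label in _TG_INTERVAL.findall(block):
            if label.strip():
                bb, ee = float(b), float(e)
                if not bb < ee:
                    raise FormatError(f"{path}: degenerate interval in tier {individual!r}")
                raw.append((individual, bb, ee))
    return _build_annotation_set(raw, window)


def write_annotations(annotations: AnnotationSet, path) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# window: {annotations.window[0]!r} {annotations.window[1]!r}\n")
        w = csv.writer(fh)
        w.writerow(ANNOTATION_COLUMNS)
        for i, b, e in annotations.records:
            w.writerow([i, repr(b), repr(e)])
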