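"""Synthetic soundscapes: ground-truth song timelines with controllable
interaction structure, and the noisy per-array DOA events they would
produce.

Each bird is an alternating gap/song renewal process simulated on a fine
discrete grid.  Interactions modulate only the *onset* hazard of a waiting
bird (multiplied by ``suppression`` while any attended bird is singing);
ongoing songs are never truncated, so song-length distributions are
independent of the interaction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .io_formats import ArrayGeometry, DOAEvent, FormatError, read_geometry
from .timelines import SongTimeline

SIM_GRID = 0.05  # s; ten times finer than the 0.5 s analysis bin


@dataclass(frozen=True)
class BirdSpec:
    """One simulated bird: a song post, lognormal song durations, exponential
    (geometric on the grid) gaps, and uniform scatter of each song's true
    location within ``movement_radius`` of the post."""

    individual_id: str
    post_xy: tuple[float, float]
    song_log_mu: float = 1.2
    song_log_sigma: float = 0.3
    gap_mean: float = 6.0
    movement_radius: float = 0.0

    def __post_init__(self):
        if not self.song_log_sigma > 0:
            raise ValueError("song_log_sigma must be > 0")
        if not self.gap_mean > 0:
            raise ValueError("gap_mean must be > 0")
        if self.movement_radius < 0:
            raise ValueError("movement_radius must be >= 0")


@dataclass(frozen=True)
class InteractionSpec:
    """Directed onset-suppression coupling.

    ``targets`` lists directed (listener, singer) pairs: while any singer a
    listener attends to is singing, the listener's per-step onset probability
    is multiplied by ``suppression`` (0 = hard avoider, 1 = independent,
    >1 = overlapper).
    """

    mode: str = "independent"
    suppression: float = 1.0
    targets: tuple[tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.mode not in ("independent", "avoider", "overlapper"):
            raise ValueError(f"unknown interaction mode {self.mode!r}")
        if self.suppression < 0:
            raise ValueError("suppression must be >= 0")
        if self.mode == "independent" and self.suppression != 1.0:
            raise ValueError("independent mode requires suppression == 1")
        if self.mode == "avoider" and not self.suppression < 1.0:
            raise ValueError("avoider mode requires suppression < 1")
        if self.mode == "overlapper" and not self.suppression > 1.0:
            raise ValueError("overlapper mode requires suppression > 1")
        object.__setattr__(self, "targets", tuple((str(a), str(b)) for a, b in self.targets))


@dataclass(frozen=True)
class ObservationNoise:
    """Noise model applied per (song, array) when generating DOA events.

    ``begin_jitter_max`` is a uniform positive onset delay (missed quiet
    introductory notes); ``end_jitter_sd`` is small Gaussian end noise;
    ``miss_prob`` drops a (song, array) pair entirely; clutter events occur
    at a Poisson rate per array with uniform azimuths.
    """

    azimuth_sd: float = 0.0
    begin_jitter_max: float = 0.0
    end_jitter_sd: float = 0.0
    miss_prob: float = 0.0
    clutter_rate: float = 0.0  # events / minute / array
    clutter_dur: tuple[float, float] = (0.5, 3.0)

    def __post_init__(self):
        for name in ("azimuth_sd", "begin_jitter_max", "end_jitter_sd", "clutter_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError("miss_prob must be in [0, 1]")
        lo, hi = self.clutter_dur
        if lo < 0 or hi < lo:
            raise ValueError("clutter_dur must be a non-negative (lo, hi) range")


@dataclass(frozen=True)
class SimulatedScene:
    """Ground truth: per-individual timelines and per-song true locations
    (one (x, y) per song interval, in interval order)."""

    timelines: dict[str, SongTimeline]
    locations: dict[str, tuple[tuple[float, float], ...]]
    window: tuple[float, float]
    seed: int


def simulate_timelines(birds: Sequence[BirdSpec],
                       interaction: InteractionSpec,
                       window: tuple[float, float],
                       seed: int,
                       grid: float = SIM_GRID) -> SimulatedScene:
    """Simulate ground-truth timelines on a discrete grid.

    Onsets are drawn synchronously from the previous step's singing set, so
    the result does not depend on bird order.  Songs reaching the window end
    are clipped there.
    """
    rng = np.random.default_rng(seed)
    t0, t1 = float(window[0]), float(window[1])
    n_steps = max(0, int(round((t1 - t0) / grid)))
    ids = [b.individual_id for b in birds]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate bird ids")
    attends: dict[str, set[str]] = {i: set() for i in ids}
    for listener, singer in interaction.targets:
        if listener not in attends or singer not in attends:
            raise ValueError(f"interaction target ({listener}, {singer}) names unknown bird")
        attends[listener].add(singer)

    base_p = {b.individual_id: min(1.0, grid / b.gap_mean) for b in birds}
    remaining = {i: 0 for i in ids}
    cur_start: dict[str, float] = {}
    intervals: dict[str, list[tuple[float, float]]] = {i: [] for i in ids}
    singing_prev: set[str] = set()

    for step in range(n_steps):
        t = t0 + step * grid
        for b in birds:
            i = b.individual_id
            if remaining[i] > 0:
                continue
            p = base_p[i]
            if attends[i] & singing_prev:
                p = min(1.0, p * interaction.suppression)
            if p > 0 and rng.random() < p:
                dur = rng.lognormal(b.song_log_mu, b.song_log_sigma)
                steps = max(1, int(round(dur / grid)))
                remaining[i] = min(steps, n_steps - step)
                cur_start[i] = t
        singing_now: set[str] = set()
        for i in ids:
            if remaining[i] > 0:
                remaining[i] -= 1
                if remaining[i] == 0:
                    intervals[i].append((cur_start[i], t + grid))
                else:
                    singing_now.add(i)
        singing_prev = singing_now

    timelines = {i: SongTimeline(i, tuple(intervals[i]), (t0, t1)) for i in ids}
    locations: dict[str, tuple[tuple[float, float], ...]] = {}
    for b in birds:
        locs = []
        px, py = b.post_xy
        for _ in intervals[b.individual_id]:
            if b.movement_radius > 0:
                r = b.movement_radius * math.sqrt(rng.random())
                theta = rng.uniform(0.0, 2.0 * math.pi)
                locs.append((px + r * math.cos(theta), py + r * math.sin(theta)))
            else:
                locs.append((px, py))
        locations[b.individual_id] = tuple(locs)
    return SimulatedScene(timelines, locations, (t0, t1), int(seed))


def generate_doa_streams(scene: SimulatedScene,
                         geometry: ArrayGeometry,
                         noise: ObservationNoise,
                         seed: int,
                         frame_dt: float = 0.2,
                         end_tail: float = 0.6) -> list[DOAEvent]:
    """Emit the noisy per-array DOA events the scene would produce.

    For each (song, array) not missed: one event with a uniformly delayed
    begin, a Gaussian-jittered end plus ``end_tail`` (the silence-detection
    tail that localization later removes), and an azimuth track at
    ``frame_dt`` with i.i.d. Gaussian noise around the true array-to-song
    bearing.  Clutter events are Poisson per array with uniform azimuths.
    """
    if len(geometry.arrays) < 1:
        raise ValueError("need at least one array")
    rng = np.random.default_rng(seed)
    positions = geometry.positions()
    events: list[DOAEvent] = []
    for ind in scene.timelines:
        tl = scene.timelines[ind]
        locs = scene.locations[ind]
        for si, ((b, e), (sx, sy)) in enumerate(zip(tl.intervals, locs)):
            for array_id in geometry.array_ids:
                if noise.miss_prob > 0 and rng.random() < noise.miss_prob:
                    continue
                tb = b + (rng.uniform(0.0, noise.begin_jitter_max)
                          if noise.begin_jitter_max > 0 else 0.0)
                te = e + (rng.normal(0.0, noise.end_jitter_sd)
                          if noise.end_jitter_sd > 0 else 0.0) + end_tail
                if te <= tb + frame_dt:
                    te = tb + frame_dt
                ax, ay = positions[array_id]
                true_az = math.degrees(math.atan2(sy - ay, sx - ax)) % 360.0
                n_frames = int(math.floor((te - tb) / frame_dt + 1e-9)) + 1
                ts = tb + frame_dt * np.arange(n_frames)
                az = np.full(n_frames, true_az)
                if noise.azimuth_sd > 0:
                    az = az + rng.normal(0.0, noise.azimuth_sd, n_frames)
                track = np.column_stack([ts, az % 360.0])
                events.append(DOAEvent(array_id, f"{ind}_{si}", tb, te, track))
    # clutter, independent per array
    t0, t1 = scene.window
    span_min = (t1 - t0) / 60.0
    for array_id in geometry.array_ids:
        n_clutter = rng.poisson(noise.clutter_rate * span_min) if noise.clutter_rate > 0 else 0
        for ci in range(n_clutter):
            tb = rng.uniform(t0, t1)
            dur = rng.uniform(*noise.clutter_dur)
            te = tb + max(dur, frame_dt)
            az0 = rng.uniform(0.0, 360.0)
            n_frames = int(math.floor((te - tb) / frame_dt + 1e-9)) + 1
            ts = tb + frame_dt * np.arange(n_frames)
            az = np.full(n_frames, az0)
            if noise.azimuth_sd > 0:
                az = az + rng.normal(0.0, noise.azimuth_sd, n_frames)
            events.append(DOAEvent(array_id, f"clutter_{array_id}_{ci}", tb, te,
                                   np.column_stack([ts, az % 360.0])))
    return events


# ---------------------------------------------------------------------------
# scenario configs
# ---------------------------------------------------------------------------

def read_scenario(path):
    """Load a scenario config (YAML) describing birds, interaction, noise,
    geometry, window and seed.

    Schema::

        window: [0, 600]
        seed: 7
        birds:
          - {id: A, post: [30, 10], song_log_mu: 1.2, song_log_sigma: 0.3,
             gap_mean: 6.0, movement_radius: 2.0}
        interaction: {mode: avoider, suppression: 0.0, targets: [[B, A]]}
        noise: {azimuth_sd: 2.0, begin_jitter_max: 2.0, end_jitter_sd: 0.3,
                miss_prob: 0.05, clutter_rate: 0.5, clutter_dur: [0.5, 3.0]}
        geometry: {format: 1, arrays: [...]}   # or a path string
    """
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise FormatError(f"{path}: not a mapping")
    birds = []
    for b in doc.get("birds", []):
        birds.append(BirdSpec(
            individual_id=str(b["id"]),
            post_xy=tuple(float(v) for v in b["post"]),
            song_log_mu=float(b.get("song_log_mu", 1.2)),
            song_log_sigma=float(b.get("song_log_sigma", 0.3)),
            gap_mean=float(b.get("gap_mean", 6.0)),
            movement_radius=float(b.get("movement_radius", 0.0)),
        ))
    if not birds:
        raise FormatError(f"{path}: scenario lists no birds")
    inter = doc.get("interaction", {}) or {}
    interaction = InteractionSpec(
        mode=inter.get("mode", "independent"),
        suppression=float(inter.get("suppression", 1.0)),
        targets=tuple(tuple(p) for p in inter.get("targets", [])),
    )
    nz = doc.get("noise", {}) or {}
    noise = ObservationNoise(
        azimuth_sd=float(nz.get("azimuth_sd", 0.0)),
        begin_jitter_max=float(nz.get("begin_jitter_max", 0.0)),
        end_jitter_sd=float(nz.get("end_jitter_sd", 0.0)),
        miss_prob=float(nz.get("miss_prob", 0.0)),
        clutter_rate=float(nz.get("clutter_rate", 0.0)),
        clutter_dur=tuple(nz.get("clutter_dur", (0.5, 3.0))),
    )
    geo = doc.get("geometry")
    if isinstance(geo, str):
        geometry = read_geometry(geo)
    elif isinstance(geo, dict):
        arrays = tuple((str(a["id"]), float(a["x"]), float(a["y"])) for a in geo["arrays"])
        geometry = ArrayGeometry(arrays, geo.get("azimuth_convention", "math_ccw_from_east"))
    else:
        geometry = None
    window = tuple(float(v) for v in doc.get("window", (0.0, 600.0)))
    seed = int(doc.get("seed", 0))
    return birds, interaction, noise, geometry, window, seed
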