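"""Trajectory linking: radius-gated optimal assignment with one-frame memory.

Localizations in consecutive frames are linked when they lie within a
circular gate of ``link_radius`` pixels; among all gate-respecting
one-to-one assignments the one minimizing total squared displacement is
chosen (solved per frame with the Hungarian algorithm — greedy
nearest-neighbor linking is order-dependent and can differ from the
optimum on crossing tracks).  A track missing from one frame stays open
for ``memory`` further frames (default 1, covering a single blink or
missed detection) and may reconnect within the same radius measured from
its last seen position.  Tracks with fewer than ``min_steps`` links are
discarded before any diffusion analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

log = logging.getLogger(__name__)

_BIG = 1e15  # cost of a forbidden pairing; never chosen while dummies exist


@dataclass
class LinkParams:
    link_radius: float = 8.0   # px
    memory: int = 1            # frames a track may go undetected
    min_steps: int = 4         # a kept track has >= min_steps+1 localizations

    def __post_init__(self) -> None:
        if self.link_radius <= 0:
            raise ValueError("link_radius must be positive")
        if self.memory not in (0, 1):
            raise ValueError("memory must be 0 or 1")
        if self.min_steps < 1:
            raise ValueError("min_steps must be >= 1")


@dataclass
class Track:
    """One linked trajectory; arrays are aligned per localization.

    ``gap`` flags a localization that follows a 2-frame jump (the molecule
    was dark or missed for exactly one frame in between).
    """

    track_id: int
    frames: list[int] = field(default_factory=list)
    x_px: list[float] = field(default_factory=list)
    y_px: list[float] = field(default_factory=list)
    x_um: list[float] = field(default_factory=list)
    y_um: list[float] = field(default_factory=list)
    gap: list[bool] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def n_steps(self) -> int:
        return max(len(self.frames) - 1, 0)


@dataclass
class _Active:
    track: Track
    age: int = 0               # frames since last seen (0 = seen last frame)

    @property
    def last_xy(self) -> tuple[float, float]:
        return self.track.x_px[-1], self.track.y_px[-1]


def link_frame(active: list[_Active], locs: np.ndarray,
               params: LinkParams) -> tuple[list[int], list[int]]:
    """Assign this frame's localizations to open tracks.

    ``locs`` is (m, 2) pixel positions.  Returns (assignment, new) where
    ``assignment[i]`` is the localization index linked to ``active[i]`` or
    -1, and ``new`` lists unassigned localization indices.  Pairings are
    gated at ``link_radius`` (inclusive) and chosen to minimize total
    squared distance; within the gate, linking is always preferred to
    leaving both partners unassigned.
    """
    n, m = len(active), len(locs)
    if n == 0 or m == 0:
        return [-1] * n, list(range(m))
    last = np.array([a.last_xy for a in active])
    d2 = ((last[:, None, :] - locs[None, :, :]) ** 2).sum(axis=2)
    gate = d2 <= params.link_radius ** 2
    c0 = params.link_radius ** 2          # cost of leaving one side unassigned
    size = n + m
    cost = np.zeros((size, size))
    cost[:n, :m] = np.where(gate, d2, _BIG)
    cost[:n, m:] = _BIG
    cost[:n, m:][np.arange(n), np.arange(n)] = c0
    cost[n:, :m] = _BIG
    cost[n:, :m][np.arange(m), np.arange(m)] = c0
    rows, cols = linear_sum_assignment(cost)
    assignment = [-1] * n
    linked = set()
    for r, c in zip(rows, cols):
        if r < n and c < m and gate[r, c]:
            assignment[r] = int(c)
            linked.add(int(c))
    return assignment, [j for j in range(m) if j not in linked]


def build_tracks(localizations: pd.DataFrame,
                 params: LinkParams | None = None) -> list[Track]:
    """Link a localization table (frame, x_px, y_px[, x_um, y_um]) to tracks.

    Frames are processed in order; every frame index between the first and
    last localization is visited so open tracks age through empty frames.
    Track ids are assigned in creation order and are deterministic.
    """
    if params is None:
        params = LinkParams()
    df = localizations
    required = {"frame", "x_px", "y_px"}
    if not required.issubset(df.columns):
        raise ValueError(f"localization table needs columns {sorted(required)}")
    frames_col = df["frame"].to_numpy()
    if len(frames_col) and np.any(np.diff(frames_col) < 0):
        raise ValueError("localizations must be sorted by frame")
    tracks: list[Track] = []
    if len(df) == 0:
        return tracks
    has_um = {"x_um", "y_um"}.issubset(df.columns)
    by_frame = {int(f): g for f, g in df.groupby("frame", sort=True)}
    active: list[_Active] = []
    next_id = 0
    for f in range(int(frames_col.min()), int(frames_col.max()) + 1):
        g = by_frame.get(f)
        if g is None:
            xy = np.empty((0, 2))
        else:
            xy = g[["x_px", "y_px"]].to_numpy(dtype=float)
        assignment, new = link_frame(active, xy, params)
        survivors: list[_Active] = []
        for a, j in zip(active, assignment):
            if j >= 0:
                row = g.iloc[j]
                t = a.track
                t.frames.append(f)
                t.x_px.append(float(row["x_px"]))
                t.y_px.append(float(row["y_px"]))
                if has_um:
                    t.x_um.append(float(row["x_um"]))
                    t.y_um.append(float(row["y_um"]))
                t.gap.append(f - t.frames[-2] == 2)
                a.age = 0
                survivors.append(a)
            else:
                a.age += 1
                if a.age <= params.memory:
                    survivors.append(a)
        for j in new:
            row = g.iloc[j]
            t = Track(track_id=next_id)
            next_id += 1
            t.frames.append(f)
            t.x_px.append(float(row["x_px"]))
            t.y_px.append(float(row["y_px"]))
            if has_um:
                t.x_um.append(float(row["x_um"]))
                t.y_um.append(float(row["y_um"]))
            t.gap.append(False)
            tracks.append(t)
            survivors.append(_Active(track=t))
        active = survivors
    return tracks


def filter_tracks(tracks: list[Track],
                  params: LinkParams | None = None) -> list[Track]:
    """Drop tracks with fewer than ``min_steps`` links (default 4 steps,
    i.e. fewer than 5 localizations)."""
    if params is None:
        params = LinkParams()
    kept = [t for t in tracks if t.n_steps >= params.min_steps]
    log.info("filter_tracks: kept %d of %d (discarded %d short tracks)",
             len(kept), len(tracks), len(tracks) - len(kept))
    return kept


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for i in range(len(t)):
            rows.append({
                "track_id": t.track_id,
                "frame": t.frames[i],
                "x_px": t.x_px[i],
                "y_px": t.y_px[i],
                "x_um": t.x_um[i] if t.x_um else np.nan,
                "y_um": t.y_um[i] if t.y_um else np.nan,
                "gap_flag": int(t.gap[i]),
            })
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_px", "y_px",
                                       "x_um", "y_um", "gap_flag"])


def dataframe_to_tracks(df: pd.DataFrame) -> list[Track]:
    tracks = []
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("frame")
        t = Track(
            track_id=int(tid),
            frames=[int(v) for v in g["frame"]],
            x_px=list(map(float, g["x_px"])),
            y_px=list(map(float, g["y_px"])),
            x_um=list(map(float, g["x_um"])) if "x_um" in g else [],
            y_um=list(map(float, g["y_um"])) if "y_um" in g else [],
            gap=[bool(v) for v in g["gap_flag"]] if "gap_flag" in g
                else [False] * len(g),
        )
        tracks.append(t)
    return tracks
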