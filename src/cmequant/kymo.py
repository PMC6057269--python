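"""Kymographs through dynamic events and coated-pit lifetime measurement.

A polyline visiting all detected events (ordered by column, then row) is
rasterized and sampled with a small perpendicular averaging width to form
a position-by-time intensity matrix.  Event lifetimes are the lengths of
supra-threshold vertical runs; runs touching the first or last frame are
flagged censored, and summaries apply the field-standard minimum-lifetime
filter (events longer than 20 s by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import line as draw_line

from .exceptions import InputError, UndefinedResultError
from .spots import SpotSet, robust_sigma

__all__ = [
    "Kymograph",
    "LifetimeSummary",
    "build_kymograph",
    "measure_lifetimes",
    "summarize_lifetimes",
]


@dataclass
class Kymograph:
    """Space-time intensity matrix sampled along a path of events."""

    intensity: np.ndarray  # (path position, frame), >= 0
    path: np.ndarray  # (n, 2) int pixel coordinates (row, col)
    width_px: int
    frame_interval_s: float
    spot_path_indices: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    def __post_init__(self) -> None:
        if self.intensity.shape[0] != len(self.path):
            raise InputError("kymograph rows must match path length")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[1]


@dataclass
class LifetimeSummary:
    mean_s: float
    sd_s: float
    n: int
    censored_fraction: float


def build_kymograph(
    frames: np.ndarray,
    spots: SpotSet,
    width_px: int = 3,
    frame_interval_s: float = 1.0,
) -> Kymograph:
    """Trace a polyline connecting all spots (ordered by column, then row)
    and sample each path pixel as the mean over ``width_px`` pixels
    perpendicular to the local path direction."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise InputError("expected a (frames, height, width) stack")
    if len(spots) < 2:
        raise InputError("at least 2 spots are required to trace a path")
    order = np.lexsort((spots.coords[:, 0], spots.coords[:, 1]))
    ordered = spots.coords[order]

    path_pixels: list[tuple[int, int]] = []
    spot_indices = np.zeros(len(ordered), dtype=int)
    for i in range(len(ordered) - 1):
        rr, cc = draw_line(*ordered[i], *ordered[i + 1])
        seg = list(zip(rr.tolist(), cc.tolist()))
        if i > 0:
            seg = seg[1:]  # joint pixel already on the path
        else:
            spot_indices[0] = 0
        path_pixels.extend(seg)
        spot_indices[i + 1] = len(path_pixels) - 1
    path = np.asarray(path_pixels, dtype=int)

    # local direction from neighboring path pixels; perpendicular offsets
    h, w = frames.shape[1:]
    half = width_px // 2
    offsets = np.arange(-half, width_px - half)
    nxt = np.vstack([path[1:], path[-1:]])
    prv = np.vstack([path[:1], path[:-1]])
    direction = (nxt - prv).astype(float)
    norm = np.linalg.norm(direction, axis=1, keepdims=True)
    norm[norm == 0] = 1.0
    direction /= norm
    perp = np.column_stack([-direction[:, 1], direction[:, 0]])

    rows = np.rint(path[:, 0:1] + offsets[None, :] * perp[:, 0:1]).astype(int)
    cols = np.rint(path[:, 1:2] + offsets[None, :] * perp[:, 1:2]).astype(int)
    rows = np.clip(rows, 0, h - 1)
    cols = np.clip(cols, 0, w - 1)
    intensity = frames[:, rows, cols].mean(axis=2).T  # (path, frame)
    return Kymograph(intensity, path, width_px, frame_interval_s, spot_indices)


def _runs(above: np.ndarray, min_gap_frames: int) -> list[tuple[int, int]]:
    """Supra-threshold (start, end) runs; gaps shorter than
    ``min_gap_frames`` do not split an event."""
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 >= min_gap_frames:
            runs.append((int(start), int(prev)))
            start = i
        prev = i
    runs.append((int(start), int(prev)))
    return runs


def measure_lifetimes(
    kymo: Kymograph,
    k_sigma: float = 4.0,
    min_gap_frames: int = 3,
    min_lifetime_s: float = 20.0,
    positions: np.ndarray | None = None,
    merge_radius_px: int = 3,
) -> pd.DataFrame:
    """Extract event lifetimes from vertical supra-threshold runs.

    The threshold is the kymograph's background median plus ``k_sigma``
    robust sigmas.  With ``positions`` given (e.g. the path indices of the
    detected spots, ``kymo.spot_path_indices``), runs are measured only at
    those path positions.  Otherwise every position is scanned and runs
    that overlap in time within ``merge_radius_px`` path pixels are merged
    into a single event (the brightest run wins), since one
    diffraction-limited event spans several adjacent path rows.

    Returns a table with columns ``path_position, start_frame, end_frame,
    lifetime_s, censored, passes_filter``; may be empty.
    """
    mat = kymo.intensity
    threshold = np.median(mat) + k_sigma * robust_sigma(mat)
    n_frames = kymo.n_frames
    rows = np.arange(mat.shape[0]) if positions is None else np.asarray(positions, int)

    records = []
    for pos in rows:
        for start, end in _runs(mat[pos] > threshold, min_gap_frames):
            records.append(
                {
                    "path_position": int(pos),
                    "start_frame": start,
                    "end_frame": end,
                    "peak_intensity": float(mat[pos, start : end + 1].max()),
                }
            )
    if positions is None and records:
        # deduplicate events smeared over adjacent path rows
        records.sort(key=lambda r: r["peak_intensity"], reverse=True)
        accepted = []
        for rec in records:
            duplicate = any(
                abs(rec["path_position"] - a["path_position"]) <= merge_radius_px
                and rec["start_frame"] <= a["end_frame"]
                and rec["end_frame"] >= a["start_frame"]
                for a in accepted
            )
            if not duplicate:
                accepted.append(rec)
        records = accepted

    table = pd.DataFrame(
        records,
        columns=["path_position", "start_frame", "end_frame", "peak_intensity"],
    )
    table["lifetime_s"] = (
        table["end_frame"] - table["start_frame"] + 1
    ) * kymo.frame_interval_s
    table["censored"] = (table["start_frame"] == 0) | (
        table["end_frame"] == n_frames - 1
    )
    table["passes_filter"] = table["lifetime_s"] > min_lifetime_s
    return table.sort_values(["path_position", "start_frame"]).reset_index(drop=True)


def summarize_lifetimes(
    table: pd.DataFrame,
    min_lifetime_s: float = 20.0,
    include_censored: bool = False,
) -> LifetimeSummary:
    """Mean, SD and count of lifetimes longer than ``min_lifetime_s``.

    Censored events (runs touching the movie edge) are excluded by default
    and reported as a fraction of the post-filter events, mirroring the
    convention of flagging conditions where many events outlast the movie.

    Raises :class:`UndefinedResultError` on an empty post-filter set.
    """
    if len(table) == 0:
        raise UndefinedResultError("no events to summarize")
    passing = table[table["lifetime_s"] > min_lifetime_s]
    if len(passing) == 0:
        raise UndefinedResultError("no events pass the minimum-lifetime filter")
    censored_fraction = float(passing["censored"].mean())
    if not include_censored:
        passing = passing[~passing["censored"]]
    if len(passing) == 0:
        raise UndefinedResultError("all passing events are censored")
    values = passing["lifetime_s"].to_numpy()
    sd = float(values.std(ddof=1)) if len(values) > 1 else 0.0
    return LifetimeSummary(float(values.mean()), sd, int(len(values)), censored_fraction)
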