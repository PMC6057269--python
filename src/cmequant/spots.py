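"""Event detection and peak-aligned fluorescence-trace ensembles.

Dynamic endocytic events are found as the brightest spots of a temporal
standard-deviation projection; for each detected spot a background-
subtracted box trace is extracted per channel, traces are trimmed to a
window around the reference-channel maximum, and aligned ensembles
(mean +/- SD/SEM versus time, with time zero at the reference peak) are
built for comparison of recruitment timing across channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import peak_local_max

from .exceptions import InputError
from .synth import MovieStack

__all__ = [
    "SpotSet",
    "EventTrace",
    "AlignedEnsemble",
    "stddev_projection",
    "detect_events",
    "extract_trace",
    "extract_traces",
    "gate_traces",
    "align_and_average",
    "robust_sigma",
]


def robust_sigma(values: np.ndarray) -> float:
    """MAD-based robust standard deviation (1.4826 * MAD)."""
    values = np.asarray(values, dtype=float)
    med = np.median(values)
    return float(1.4826 * np.median(np.abs(values - med)))


@dataclass
class SpotSet:
    """Detected spot coordinates (row, col) with their projection scores.

    ``frame_index`` is None when the spots come from a temporal projection
    rather than a single frame.
    """

    coords: np.ndarray  # (n, 2) int, (row, col)
    scores: np.ndarray
    image_shape: tuple[int, int]
    frame_index: int | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=int).reshape(-1, 2)
        self.scores = np.asarray(self.scores, dtype=float).reshape(-1)
        h, w = self.image_shape
        if self.coords.size and (
            self.coords.min() < 0
            or self.coords[:, 0].max() >= h
            or self.coords[:, 1].max() >= w
        ):
            raise InputError("spot coordinates outside image bounds")

    def __len__(self) -> int:
        return len(self.coords)

    def mask(self) -> np.ndarray:
        """Binary single-pixel spot mask."""
        m = np.zeros(self.image_shape, dtype=bool)
        if len(self.coords):
            m[self.coords[:, 0], self.coords[:, 1]] = True
        return m


@dataclass
class EventTrace:
    """Per-channel fluorescence of one event, trimmed around the
    reference-channel maximum (``alignment_index`` within the series)."""

    event_id: int
    values: np.ndarray  # (n_channels, n_frames_window)
    channel_names: tuple[str, ...]
    reference_channel: int
    alignment_index: int
    frame_interval_s: float
    spot: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not (0 <= self.alignment_index < self.values.shape[1]):
            raise InputError("alignment_index outside trace")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    def channel(self, name_or_index: str | int) -> np.ndarray:
        if isinstance(name_or_index, str):
            name_or_index = self.channel_names.index(name_or_index)
        return self.values[name_or_index]


@dataclass
class AlignedEnsemble:
    """Stacked, peak-aligned traces of one channel with summary curves."""

    traces: np.ndarray  # (n_events, window_len)
    time_s: np.ndarray  # centered at 0 on the alignment index
    mean: np.ndarray
    sd: np.ndarray
    sem: np.ndarray

    @property
    def n_events(self) -> int:
        return self.traces.shape[0]


def stddev_projection(frames: np.ndarray, window_frames: int) -> np.ndarray:
    """Per-pixel temporal standard deviation over a window of frames
    centered on the middle of the movie."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise InputError("expected a (frames, height, width) stack")
    n = frames.shape[0]
    if not (1 <= window_frames <= n):
        raise InputError(f"window_frames {window_frames} exceeds movie length {n}")
    start = n // 2 - window_frames // 2
    start = min(max(start, 0), n - window_frames)
    return frames[start : start + window_frames].std(axis=0)


def detect_events(
    projection: np.ndarray,
    k_sigma: float = 4.0,
    min_separation_px: int = 5,
    max_spots: int | None = None,
) -> SpotSet:
    """Select the brightest local maxima of a projection image.

    The threshold is a robust background estimate: median + k_sigma times
    the MAD-derived sigma.  Maxima are kept greedily in descending score
    order subject to the minimum-separation constraint, capped at
    ``max_spots``.  An empty result is allowed.
    """
    projection = np.asarray(projection, dtype=float)
    if projection.size == 0:
        raise InputError("empty projection")
    threshold = np.median(projection) + k_sigma * robust_sigma(projection)
    # strictly greater than the robust background
    coords = peak_local_max(
        projection,
        min_distance=int(min_separation_px),
        threshold_abs=np.nextafter(threshold, np.inf),
        num_peaks=max_spots if max_spots is not None else np.inf,
        exclude_border=False,
    )
    scores = projection[coords[:, 0], coords[:, 1]] if len(coords) else np.zeros(0)
    order = np.argsort(scores)[::-1]
    return SpotSet(coords[order], scores[order], projection.shape)


def _box_bounds(spot: tuple[int, int], box_px: int, shape: tuple[int, int]):
    r, c = int(spot[0]), int(spot[1])
    rlo, clo = r - box_px // 2, c - box_px // 2
    rhi, chi = rlo + box_px, clo + box_px
    h, w = shape
    if rlo < 0 or clo < 0 or rhi > h or chi > w:
        raise InputError(f"box around spot {spot} extends outside the image")
    return rlo, rhi, clo, chi


def box_trace(
    frames: np.ndarray,
    spot: tuple[int, int],
    box_px: int = 8,
    annulus_px: int = 2,
) -> np.ndarray:
    """Background-subtracted mean intensity in a box around a spot, per
    frame.  Background is the median of an annulus ``annulus_px`` wide just
    outside the box (clipped at the image border)."""
    frames = np.asarray(frames, dtype=float)
    rlo, rhi, clo, chi = _box_bounds(spot, box_px, frames.shape[1:])
    box = frames[:, rlo:rhi, clo:chi].mean(axis=(1, 2))
    h, w = frames.shape[1:]
    arlo, aclo = max(rlo - annulus_px, 0), max(clo - annulus_px, 0)
    arhi, achi = min(rhi + annulus_px, h), min(chi + annulus_px, w)
    ring = np.ones((arhi - arlo, achi - aclo), dtype=bool)
    ring[rlo - arlo : rhi - arlo, clo - aclo : chi - aclo] = False
    annulus = frames[:, arlo:arhi, aclo:achi][:, ring]
    background = np.median(annulus, axis=1)
    return box - background


def extract_trace(
    stack: MovieStack,
    spot: tuple[int, int],
    half_window_frames: int = 50,
    box_px: int = 8,
    reference_channel: int = 0,
    event_id: int = 0,
) -> EventTrace:
    """Extract per-channel box traces for one spot, trimmed to
    ``half_window_frames`` on each side of the reference-channel maximum
    (earliest frame wins ties).

    Raises :class:`InputError` when the window does not fit in the movie;
    such events are excluded from ensembles.
    """
    names = tuple(c.name for c in stack.channels)
    full = np.stack(
        [box_trace(stack.channel(i), spot, box_px) for i in range(len(names))]
    )
    peak = int(np.argmax(full[reference_channel]))
    lo, hi = peak - half_window_frames, peak + half_window_frames + 1
    if lo < 0 or hi > full.shape[1]:
        raise InputError(
            f"window of +/-{half_window_frames} frames around reference peak "
            f"{peak} exceeds the movie (event {event_id})"
        )
    return EventTrace(
        event_id=event_id,
        values=full[:, lo:hi],
        channel_names=names,
        reference_channel=reference_channel,
        alignment_index=half_window_frames,
        frame_interval_s=stack.config.frame_interval_s,
        spot=(int(spot[0]), int(spot[1])),
    )


def extract_traces(
    stack: MovieStack,
    spots: SpotSet,
    half_window_frames: int = 50,
    box_px: int = 8,
    reference_channel: int = 0,
) -> tuple[list[EventTrace], list[int]]:
    """Extract traces for every spot; returns (kept traces, rejected spot
    indices) where rejections are windows truncated by the movie edge or
    boxes outside the image."""
    kept, rejected = [], []
    for i, spot in enumerate(spots.coords):
        try:
            kept.append(
                extract_trace(
                    stack, tuple(spot), half_window_frames, box_px,
                    reference_channel, event_id=i,
                )
            )
        except InputError:
            rejected.append(i)
    return kept, rejected


def gate_traces(
    traces: list[EventTrace],
    min_prominence_sigma: float = 3.0,
    edge_frames: int = 2,
) -> list[EventTrace]:
    """Automatic replacement for manual trace curation: keep traces whose
    reference-channel peak stands at least ``min_prominence_sigma`` noise
    SDs above baseline and whose peak is not pinned to the window edge
    (i.e. a rise precedes the fall)."""
    kept = []
    for tr in traces:
        ref = tr.channel(tr.reference_channel)
        noise = robust_sigma(np.diff(ref)) / np.sqrt(2.0)
        baseline = np.median(ref)
        peak = int(np.argmax(ref))
        prominent = ref[peak] - baseline >= min_prominence_sigma * max(noise, 1e-12)
        interior = edge_frames <= peak < len(ref) - edge_frames
        if prominent and interior:
            kept.append(tr)
    return kept


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    padded = np.pad(values, (window // 2, window - 1 - window // 2), mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def align_and_average(
    traces: list[EventTrace],
    smooth_window: int = 5,
    normalize: bool = False,
) -> dict[str, AlignedEnsemble]:
    """Stack traces on their shared alignment index and summarize.

    Optional centered moving-average smoothing and per-trace min-max
    normalization to [0, 1] are applied before averaging (constant traces
    are excluded from normalization with a warning).  Returns one
    :class:`AlignedEnsemble` per channel; the reference-channel mean curve
    attains its maximum at time zero by construction of the alignment.
    """
    if not traces:
        raise InputError("at least one trace is required")
    n_frames = {t.n_frames for t in traces}
    align = {t.alignment_index for t in traces}
    names = {t.channel_names for t in traces}
    if len(n_frames) != 1 or len(align) != 1 or len(names) != 1:
        raise InputError("traces have mixed window lengths, alignments or channels")
    channel_names = traces[0].channel_names
    alignment_index = traces[0].alignment_index
    dt = traces[0].frame_interval_s
    window_len = traces[0].n_frames
    time_s = (np.arange(window_len) - alignment_index) * dt

    ensembles: dict[str, AlignedEnsemble] = {}
    for ci, name in enumerate(channel_names):
        rows = []
        for tr in traces:
            v = tr.values[ci].astype(float)
            if smooth_window and smooth_window > 1:
                v = _moving_average(v, smooth_window)
            if normalize:
                lo, hi = v.min(), v.max()
                if hi - lo <= 0:
                    warnings.warn(
                        f"constant trace (event {tr.event_id}, channel {name}) "
                        "excluded from normalized ensemble",
                        stacklevel=2,
                    )
                    continue
                v = (v - lo) / (hi - lo)
            rows.append(v)
        if not rows:
            raise InputError(f"no usable traces for channel {name}")
        mat = np.vstack(rows)
        mean = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=0)
        sem = sd / np.sqrt(mat.shape[0])
        ensembles[name] = AlignedEnsemble(mat, time_s, mean, sd, sem)
    return ensembles
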