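"""Punctae colocalization by binary dilation and image subtraction.

Fluorescence maxima on both channels are reduced to binary single-pixel
spots; each reference spot is expanded to its 3x3 neighborhood and counts
as colocalized when at least one test spot falls inside the expanded
footprint.  The measure is directional: the fraction of reference punctae
with a partner need not equal the converse.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import InputError, UndefinedResultError
from .spots import SpotSet, detect_events

__all__ = ["ColocResult", "binarize_maxima", "coloc_fraction", "coloc_over_time"]


@dataclass
class ColocResult:
    """Colocalization counts for one frame (or projection)."""

    n_reference_spots: int
    n_colocalized: int
    fraction: float
    per_frame: list["ColocResult"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_colocalized > self.n_reference_spots:
            raise InputError("n_colocalized cannot exceed n_reference_spots")


def binarize_maxima(
    image: np.ndarray,
    k_sigma: float = 4.0,
    min_separation_px: int = 5,
) -> SpotSet:
    """Convert clear fluorescence maxima of a single frame into binary
    single-pixel spots (same detector contract as event detection)."""
    spots = detect_events(image, k_sigma=k_sigma, min_separation_px=min_separation_px)
    spots.frame_index = 0
    return spots


def coloc_fraction(
    reference: SpotSet,
    test: SpotSet,
    dilation_radius: int = 1,
) -> ColocResult:
    """Fraction of reference spots with >= 1 test spot inside their
    dilated footprint (Chebyshev radius ``dilation_radius``; the default 1
    is the 3x3-pixel expansion).  Multiple test spots in one footprint
    count once: the reference spot is the unit.

    Raises :class:`UndefinedResultError` when there are no reference spots.
    """
    if reference.image_shape != test.image_shape:
        raise InputError("spot sets must share image dimensions")
    n_ref = len(reference)
    if n_ref == 0:
        raise UndefinedResultError("colocalization undefined with zero reference spots")
    if len(test) == 0:
        return ColocResult(n_ref, 0, 0.0)
    test_coords = test.coords
    n_hit = 0
    for r, c in reference.coords:
        cheb = np.max(np.abs(test_coords - (r, c)), axis=1)
        if np.any(cheb <= dilation_radius):
            n_hit += 1
    return ColocResult(n_ref, n_hit, n_hit / n_ref)


def coloc_over_time(
    reference_frames: np.ndarray,
    test_frames: np.ndarray,
    k_sigma: float = 4.0,
    min_separation_px: int = 5,
    dilation_radius: int = 1,
) -> ColocResult:
    """Per-frame colocalization averaged over a time-lapse.

    A reference spot present in several frames is counted in each frame
    (no track-level linking).  Frames without reference spots are skipped.
    Returns an aggregate result whose ``fraction`` is the mean of the
    per-frame fractions and whose counts are summed over frames.
    """
    reference_frames = np.asarray(reference_frames, dtype=float)
    test_frames = np.asarray(test_frames, dtype=float)
    if reference_frames.shape != test_frames.shape:
        raise InputError("channel stacks must share dimensions")
    per_frame = []
    for i in range(reference_frames.shape[0]):
        ref = binarize_maxima(reference_frames[i], k_sigma, min_separation_px)
        ref.frame_index = i
        tst = binarize_maxima(test_frames[i], k_sigma, min_separation_px)
        tst.frame_index = i
        try:
            per_frame.append(coloc_fraction(ref, tst, dilation_radius))
        except UndefinedResultError:
            continue
    if not per_frame:
        raise UndefinedResultError("no frame contained reference spots")
    return ColocResult(
        n_reference_spots=sum(r.n_reference_spots for r in per_frame),
        n_colocalized=sum(r.n_colocalized for r in per_frame),
        fraction=float(np.mean([r.fraction for r in per_frame])),
        per_frame=per_frame,
    )
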