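"""Flow-cytometry uptake normalization and related population statistics.

Transferrin uptake is quantified as the median fluorescence of the uptake
measurement divided by the median fluorescence of the matched
surface-receptor measurement; replicate ratios are expressed relative to
the mean control ratio of their experiment so runs from different days can
be combined.  Also included: gating of high expressors for dominant-
negative experiments and the antibody-feeding uptake index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import InputError, UndefinedResultError
from .synth import CytometryPopulation

__all__ = [
    "UptakeSummary",
    "normalize_uptake",
    "relative_to_control",
    "gate_high_expressors",
    "feeding_index",
]


@dataclass
class UptakeSummary:
    """Per-replicate relative uptake values and per-condition summaries.

    ``per_replicate`` has columns ``condition, experiment, ratio,
    relative``; ``per_condition`` has ``condition, mean, sd, n``.  The
    control condition has mean relative value 1 in every experiment by
    construction.
    """

    per_replicate: pd.DataFrame
    per_condition: pd.DataFrame
    control_label: str
    excluded_experiments: list = field(default_factory=list)


def normalize_uptake(
    uptake: CytometryPopulation,
    surface: CytometryPopulation,
    min_cells: int = 5000,
) -> float:
    """Median uptake fluorescence divided by median surface-receptor
    fluorescence for one condition/replicate.  Populations smaller than
    ``min_cells`` warn (the measurement convention asks for at least 5,000
    cells) but are not rejected."""
    for pop, which in ((uptake, "uptake"), (surface, "surface")):
        if pop.n_cells < min_cells:
            warnings.warn(
                f"{which} population has {pop.n_cells} cells "
                f"(< {min_cells})",
                stacklevel=2,
            )
    surface_median = surface.median
    if surface_median == 0:
        raise UndefinedResultError("surface median is zero; ratio undefined")
    return uptake.median / surface_median


def relative_to_control(
    ratios: pd.DataFrame,
    control_label: str,
) -> UptakeSummary:
    """Express per-replicate normalized ratios relative to the mean control
    ratio of their experiment.

    ``ratios`` needs columns ``condition, experiment, ratio``.  Experiments
    without a control replicate are excluded and reported in the summary.
    """
    required = {"condition", "experiment", "ratio"}
    if not required.issubset(ratios.columns):
        raise InputError(f"ratios must have columns {sorted(required)}")
    excluded = []
    kept_rows = []
    for experiment, grp in ratios.groupby("experiment"):
        control = grp[grp["condition"] == control_label]["ratio"]
        if len(control) == 0:
            excluded.append(experiment)
            continue
        control_mean = control.mean()
        if control_mean == 0:
            raise UndefinedResultError(
                f"control mean ratio is zero in experiment {experiment}"
            )
        sub = grp.copy()
        sub["relative"] = sub["ratio"] / control_mean
        kept_rows.append(sub)
    if not kept_rows:
        raise UndefinedResultError("no experiment contains a control replicate")
    if excluded:
        warnings.warn(
            f"experiments without control excluded: {excluded}", stacklevel=2
        )
    per_replicate = pd.concat(kept_rows, ignore_index=True)
    per_condition = (
        per_replicate.groupby("condition")["relative"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else 0.0, n="size")
        .reset_index()
    )
    return UptakeSummary(per_replicate, per_condition, control_label, excluded)


def gate_high_expressors(
    signal: np.ndarray,
    background: float,
    fold: float = 100.0,
) -> np.ndarray:
    """Cells with signal at least ``fold`` times above a supplied scalar
    background (inclusive threshold).  Raises on an empty gate."""
    if not background > 0:
        raise InputError("background must be > 0")
    signal = np.asarray(signal, dtype=float)
    gated = signal[signal >= fold * background]
    if gated.size == 0:
        raise UndefinedResultError("gate is empty: no cell reaches the threshold")
    return gated


def feeding_index(
    total_signal: float,
    background_per_px: float,
    cell_area_px: float,
) -> float:
    """Antibody-feeding uptake index: background-subtracted internalized
    signal per unit cell area.  May be negative; reported as-is."""
    if not cell_area_px > 0:
        raise InputError("cell_area_px must be > 0")
    return (total_signal - background_per_px * cell_area_px) / cell_area_px
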