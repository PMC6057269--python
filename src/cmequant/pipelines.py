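"""End-to-end recovery experiments on synthetic data.

Each function plants a known population parameter with the generators,
runs the corresponding analysis pipeline exactly as it would run on real
data, and returns the recovered quantity.  These are the workflows used
by the example scripts and by the reproduction script; they are also the
package's own validation that every stage inverts its generator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import coloc, kinetics, kymo, popstats, spots, synth
from .kymo import LifetimeSummary

__all__ = [
    "lifetime_recovery_experiment",
    "coloc_recovery_experiment",
    "halfmax_recovery_experiment",
    "uptake_reduction_experiment",
    "surface_increase_experiment",
]


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass
class LifetimeRecovery:
    summary: LifetimeSummary
    planted_mean_s: float
    n_events_planted: int
    table: pd.DataFrame


def lifetime_recovery_experiment(
    lifetime_mean_s: float,
    lifetime_sd_s: float,
    n_events: int = 2016,
    movie_s: float = 120.0,
    frame_interval_s: float = 1.0,
    lifetime_bounds_s: tuple[float, float] = (20.0, 120.0),
    min_lifetime_s: float = 20.0,
    events_per_movie: int = 36,
    seed: int | np.random.Generator = 0,
) -> LifetimeRecovery:
    """Plant coated-pit events with truncated log-normal lifetimes, render
    movies, detect events on a standard-deviation projection, build
    kymographs and measure lifetimes with the minimum-lifetime filter.

    Detection uses a projection over the full movie so that no event is
    missed merely because it ran outside a short projection window (a short
    centered window would preferentially sample long-lived events and bias
    the recovered mean upward).
    """
    rng = _rng(seed)
    n_movies = int(np.ceil(n_events / events_per_movie))
    tables = []
    planted = []
    for m in range(n_movies):
        cfg = synth.ImagingConfig(
            n_frames=int(round(movie_s / frame_interval_s)),
            frame_interval_s=frame_interval_s,
            height_px=220,
            width_px=220,
            rng_seed=int(rng.integers(0, 2**31 - 1)),
        )
        events = synth.make_ccp_events(
            events_per_movie,
            cfg,
            lifetime_mean_s=lifetime_mean_s,
            lifetime_sd_s=lifetime_sd_s,
            lifetime_bounds_s=lifetime_bounds_s,
            margin_px=12,
            seed=rng,
        )
        movie = synth.render_movie(events, cfg, (synth.ChannelModel("ap2", True),))
        planted.extend(e.lifetime_s for e in events)
        projection = spots.stddev_projection(movie.channel(0), cfg.n_frames)
        detected = spots.detect_events(projection)
        if len(detected) < 2:
            continue
        kg = kymo.build_kymograph(
            movie.channel(0), detected, frame_interval_s=frame_interval_s
        )
        table = kymo.measure_lifetimes(
            kg, positions=kg.spot_path_indices, min_lifetime_s=min_lifetime_s
        )
        table["movie"] = m
        tables.append(table)
    all_events = pd.concat(tables, ignore_index=True)
    summary = kymo.summarize_lifetimes(all_events, min_lifetime_s=min_lifetime_s)
    return LifetimeRecovery(
        summary, float(np.mean(planted)), len(planted), all_events
    )


def coloc_recovery_experiment(
    planted_fraction: float = 0.8,
    n_frames: int = 10,
    n_reference: int = 196,
    frame_shape: tuple[int, int] = (400, 400),
    amplitude: float = 800.0,
    seed: int | np.random.Generator = 0,
) -> coloc.ColocResult:
    """Plant two-channel frames in which a known fraction of reference
    punctae has a partner within +/-1 px (the rest displaced >= 4 px),
    render them with noise, and measure colocalization per frame with the
    3x3-dilation rule, averaged over the time-lapse."""
    rng = _rng(seed)
    h, w = frame_shape
    yy, xx = np.mgrid[0:h, 0:w]
    sigma = 1.3
    ref_stack = np.empty((n_frames, h, w))
    test_stack = np.empty((n_frames, h, w))
    for t in range(n_frames):
        per_side = int(np.ceil(np.sqrt(n_reference)))
        rows = np.linspace(15, h - 16, per_side)
        cols = np.linspace(15, w - 16, per_side)
        grid = np.array([(r, c) for r in rows for c in cols])[:n_reference]
        grid = np.rint(grid + rng.uniform(-4, 4, size=grid.shape)).astype(int)
        coloc_mask = rng.random(n_reference) < planted_fraction
        partners = np.empty_like(grid)
        near = rng.integers(-1, 2, size=(n_reference, 2))
        far_axis = rng.integers(0, 2, n_reference)
        far_sign = rng.choice([-1, 1], n_reference)
        far_mag = rng.integers(4, 7, n_reference)
        far = np.zeros((n_reference, 2), dtype=int)
        far[np.arange(n_reference), far_axis] = far_sign * far_mag
        partners[coloc_mask] = grid[coloc_mask] + near[coloc_mask]
        partners[~coloc_mask] = grid[~coloc_mask] + far[~coloc_mask]
        ref_img = np.zeros((h, w))
        test_img = np.zeros((h, w))
        for (r, c), (pr, pc) in zip(grid, partners):
            ref_img += amplitude * np.exp(
                -((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2)
            )
            test_img += amplitude * np.exp(
                -((yy - pr) ** 2 + (xx - pc) ** 2) / (2 * sigma**2)
            )
        for img, stack in ((ref_img, ref_stack), (test_img, test_stack)):
            noisy = rng.poisson(img + 100.0).astype(float)
            noisy += rng.normal(0, 2.0, size=noisy.shape)
            stack[t] = np.maximum(noisy, 0)
    # "clear spots" binarization: on a frame of this many pixels a
    # 4-sigma threshold admits a handful of false maxima per frame
    # (~3e-5 * n_pixels); 5 sigma puts the cut above that regime while
    # the planted punctae sit far brighter still.
    return coloc.coloc_over_time(ref_stack, test_stack, k_sigma=5.0)


def halfmax_recovery_experiment(
    k_half_nM: float = 6.3,
    vmax: float = 1.0,
    concentrations_nM: np.ndarray | None = None,
    noise_cv: float = 0.05,
    n_replicates: int = 3,
    seed: int | np.random.Generator = 0,
) -> kinetics.ConcentrationResponse:
    """Generate slope-vs-concentration data from the one-site saturation
    model with multiplicative noise and refit it."""
    rng = _rng(seed)
    if concentrations_nM is None:
        concentrations_nM = np.geomspace(1.0, 100.0, 8)
    table = synth.simulate_slope_response(
        vmax, k_half_nM, concentrations_nM, noise_cv=noise_cv,
        seed=rng, n_replicates=n_replicates,
    )
    return kinetics.fit_halfmax_table(table, n_bootstrap=500, seed=rng)


def uptake_reduction_experiment(
    reduction_fraction: float = 0.43,
    n_replicates: int = 6,
    n_cells: int = 5000,
    cv: float = 0.5,
    control_median: float = 1000.0,
    seed: int | np.random.Generator = 0,
) -> float:
    """Plant a knockdown that scales the uptake median by
    ``1 - reduction_fraction`` at unchanged surface medians, run the
    normalization and control-relative pipeline, and return the recovered
    percent reduction."""
    rng = _rng(seed)
    rows = []
    kd_median = control_median * (1.0 - reduction_fraction)
    for exp in range(n_replicates):
        for condition, uptake_median in (("control", control_median), ("kd", kd_median)):
            up = synth.simulate_cytometry(
                uptake_median, cv, n_cells, seed=rng, condition=condition,
                replicate_id=exp, measurement="uptake",
            )
            surf = synth.simulate_cytometry(
                control_median, cv, n_cells, seed=rng, condition=condition,
                replicate_id=exp, measurement="surface",
            )
            rows.append(
                {
                    "condition": condition,
                    "experiment": exp,
                    "ratio": popstats.normalize_uptake(up, surf, min_cells=n_cells),
                }
            )
    summary = popstats.relative_to_control(pd.DataFrame(rows), "control")
    kd_mean = summary.per_condition.set_index("condition").loc["kd", "mean"]
    return float((1.0 - kd_mean) * 100.0)


def surface_increase_experiment(
    increase_fraction: float = 0.37,
    n_replicates: int = 5,
    n_cells: int = 5000,
    cv: float = 0.5,
    wild_type_median: float = 1000.0,
    seed: int | np.random.Generator = 0,
) -> float:
    """Plant a surface-receptor increase in the knockdown condition and
    recover it as the mean percent increase of per-replicate median
    ratios (knockdown over wild type)."""
    rng = _rng(seed)
    kd_median = wild_type_median * (1.0 + increase_fraction)
    ratios = []
    for exp in range(n_replicates):
        wt = synth.simulate_cytometry(
            wild_type_median, cv, n_cells, seed=rng, condition="wt",
            replicate_id=exp, measurement="surface",
        )
        kd = synth.simulate_cytometry(
            kd_median, cv, n_cells, seed=rng, condition="kd",
            replicate_id=exp, measurement="surface",
        )
        ratios.append(kd.median / wt.median)
    return float((np.mean(ratios) - 1.0) * 100.0)
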