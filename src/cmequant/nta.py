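"""Nanoparticle tracking analysis: Brownian sizing and curvature preference.

Each particle's diffusion coefficient is estimated from the slope of its
mean-squared displacement over the first few lags (free intercept, which
absorbs localization noise), converted to a hydrodynamic diameter via the
Stokes-Einstein relation, and histogrammed.  Comparing the size
distribution of the total (scatter-detected) population with the
protein-bound (fluorescence-detected) subpopulation yields a per-size-bin
enrichment, the membrane-curvature preference readout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import k as BOLTZMANN_J_PER_K

from .exceptions import InputError, ParameterError, UndefinedResultError
from .synth import ParticleTrackSet

__all__ = [
    "DiffusionEstimate",
    "SizeDistribution",
    "msd_curve",
    "diffusion_coefficient",
    "stokes_einstein_diameter",
    "size_particles",
    "curvature_preference",
]

DEFAULT_BINS_NM = np.arange(0.0, 1250.0, 50.0)  # covers 800 nm extruded liposomes


@dataclass
class DiffusionEstimate:
    """MSD-fit result for one track."""

    D_um2_s: float
    slope: float
    intercept: float
    non_diffusive: bool

    @property
    def valid(self) -> bool:
        return self.slope > 0 and not self.non_diffusive


@dataclass
class SizeDistribution:
    """Histogram of hydrodynamic diameters for one detection modality."""

    bin_edges_nm: np.ndarray
    counts: np.ndarray
    density: np.ndarray  # integrates to 1 over the binned range
    modality: str
    n_particles: int

    def __post_init__(self) -> None:
        if int(self.counts.sum()) != self.n_particles:
            raise InputError("counts must sum to n_particles")

    @property
    def bin_centers_nm(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_nm[:-1] + self.bin_edges_nm[1:])

    def median_nm(self, diameters: np.ndarray | None = None) -> float:
        if diameters is not None:
            return float(np.median(diameters))
        # histogram-based median
        cum = np.cumsum(self.counts)
        idx = int(np.searchsorted(cum, cum[-1] / 2.0))
        return float(self.bin_centers_nm[idx])


def msd_curve(track: np.ndarray, max_lag: int = 5) -> tuple[np.ndarray, np.ndarray]:
    """Time-averaged mean squared displacement at lags 1..max_lag.

    ``track`` is an (n, 3) array of (t_s, x_um, y_um) rows at a constant
    frame interval.  Returns (lag times in s, MSD in um^2)."""
    track = np.asarray(track, dtype=float)
    if track.ndim != 2 or track.shape[1] != 3:
        raise InputError("track must be an (n, 3) array of (t, x, y)")
    n = track.shape[0]
    if n < max_lag + 2:
        raise InputError(f"track length {n} too short for max_lag {max_lag}")
    dt = float(np.median(np.diff(track[:, 0])))
    xy = track[:, 1:3]
    lags = np.arange(1, max_lag + 1)
    msd = np.array(
        [np.mean(np.sum((xy[k:] - xy[:-k]) ** 2, axis=1)) for k in lags]
    )
    return lags * dt, msd


def diffusion_coefficient(
    track: np.ndarray,
    max_lag: int = 5,
    ballistic_ratio_threshold: float = 2.5,
) -> DiffusionEstimate:
    """Estimate D as slope/4 of the least-squares line through
    (lag time, MSD), intercept free.

    Tracks whose MSD grows super-linearly (MSD-per-unit-time ratio between
    the longest and shortest lag above ``ballistic_ratio_threshold``) are
    flagged non-diffusive (directed motion, e.g. flow); tracks with a
    non-positive fitted slope are invalid and excluded by callers.
    """
    tau, msd = msd_curve(track, max_lag)
    slope, intercept = np.polyfit(tau, msd, 1)
    rate_first = msd[0] / tau[0]
    rate_last = msd[-1] / tau[-1]
    non_diffusive = bool(
        rate_first > 0 and rate_last / rate_first > ballistic_ratio_threshold
    )
    return DiffusionEstimate(float(slope) / 4.0, float(slope), float(intercept), non_diffusive)


def stokes_einstein_diameter(
    D_um2_s: float,
    temperature_K: float,
    viscosity_Pa_s: float,
) -> float:
    """Hydrodynamic diameter d = kB*T / (3*pi*eta*D), in nm."""
    if not (temperature_K > 0 and viscosity_Pa_s > 0):
        raise ParameterError("temperature and viscosity must be > 0")
    if not D_um2_s > 0:
        raise ParameterError("diffusion coefficient must be > 0")
    D_m2_s = D_um2_s * 1e-12
    d_m = BOLTZMANN_J_PER_K * temperature_K / (3 * math.pi * viscosity_Pa_s * D_m2_s)
    return d_m * 1e9


def size_particles(trackset: ParticleTrackSet, max_lag: int = 5) -> pd.DataFrame:
    """Per-particle D and Stokes-Einstein diameter for a track set.

    Returns columns ``particle, D_um2_s, diameter_nm, excluded, reason``;
    particles with non-positive MSD slope or flagged directed motion are
    excluded (diameter NaN) and reported in the table.
    """
    rows = []
    for pid, track in zip(trackset.particle_ids, trackset.tracks):
        est = diffusion_coefficient(track, max_lag=max_lag)
        if est.non_diffusive:
            rows.append((pid, est.D_um2_s, np.nan, True, "non_diffusive"))
        elif est.D_um2_s <= 0:
            rows.append((pid, est.D_um2_s, np.nan, True, "negative_slope"))
        else:
            d = stokes_einstein_diameter(
                est.D_um2_s, trackset.temperature_K, trackset.viscosity_Pa_s
            )
            rows.append((pid, est.D_um2_s, d, False, ""))
    return pd.DataFrame(
        rows, columns=["particle", "D_um2_s", "diameter_nm", "excluded", "reason"]
    )


def _distribution(
    diameters: np.ndarray, bins: np.ndarray, modality: str
) -> SizeDistribution:
    counts, edges = np.histogram(diameters, bins=bins)
    widths = np.diff(edges)
    total = counts.sum()
    density = counts / (total * widths) if total > 0 else np.zeros_like(widths)
    return SizeDistribution(edges, counts, density, modality, int(total))


def curvature_preference(
    scatter: ParticleTrackSet,
    fluorescence: ParticleTrackSet,
    bins: np.ndarray = DEFAULT_BINS_NM,
    max_lag: int = 5,
) -> tuple[SizeDistribution, SizeDistribution, np.ndarray]:
    """Size both populations with the same estimator and binning and return
    (total distribution, bound distribution, per-bin enrichment).

    Enrichment is the bound/total normalized density ratio; bins with no
    total particles are NaN (undefined, flagged rather than zeroed).
    Raises :class:`UndefinedResultError` when the fluorescence set sizes no
    particles.
    """
    bins = np.asarray(bins, dtype=float)
    total_sizes = size_particles(scatter, max_lag=max_lag)
    bound_sizes = size_particles(fluorescence, max_lag=max_lag)
    total_d = total_sizes.loc[~total_sizes["excluded"], "diameter_nm"].to_numpy()
    bound_d = bound_sizes.loc[~bound_sizes["excluded"], "diameter_nm"].to_numpy()
    if bound_d.size == 0:
        raise UndefinedResultError(
            "no particles in the fluorescence (bound) set; enrichment undefined"
        )
    if total_d.size == 0:
        raise UndefinedResultError("no particles in the scatter (total) set")
    total_dist = _distribution(total_d, bins, "scatter")
    bound_dist = _distribution(bound_d, bins, "fluorescence")
    with np.errstate(divide="ignore", invalid="ignore"):
        enrichment = np.where(
            total_dist.density > 0, bound_dist.density / total_dist.density, np.nan
        )
    return total_dist, bound_dist, enrichment
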