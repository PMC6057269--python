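"""Synthetic data generators with embedded ground truth.

Every input the analysis modules consume can be generated here: two-channel
time-lapse movies of diffraction-limited endocytic events, flow-cytometry
per-cell fluorescence populations, pyrene-actin slope-vs-concentration data,
and 2-D Brownian particle tracks for nanoparticle tracking analysis (NTA).

The optical model is deliberately minimal: each event is a 2-D Gaussian spot
whose amplitude follows a saturating-exponential rise and an exponential
fall; a TIRF (evanescent-field) channel is additionally attenuated by
``exp(-z/d)`` where ``z`` is the axial displacement of the event and ``d``
the evanescent-field depth (~100 nm).  A widefield channel ignores ``z``.
Noise is the standard camera model: Poisson shot noise followed by additive
Gaussian read noise.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.constants import k as BOLTZMANN_J_PER_K

from .exceptions import ConfigurationError, InputError, ParameterError

__all__ = [
    "ImagingConfig",
    "ChannelModel",
    "EventSpec",
    "MovieStack",
    "CytometryPopulation",
    "ParticleTrackSet",
    "TIRF_WF_CHANNELS",
    "TWO_COLOR_TIRF",
    "render_movie",
    "sample_lifetimes",
    "simulate_cytometry",
    "simulate_slope_response",
    "simulate_brownian_tracks",
    "make_ccp_events",
    "make_retention_events",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition geometry, timing and camera model for a synthetic movie.

    Defaults correspond to the TIRF regime used for endocytic-event
    dynamics: 0.1 um pixels, 1 frame/s, and a ~100 nm evanescent field.
    ``photon_scale`` is the intensity per expected photon; setting it (and
    ``read_noise_sd``) to 0 disables the corresponding noise source, which
    is how noiseless ground-truth renders are produced.
    """

    pixel_size_um: float = 0.1
    frame_interval_s: float = 1.0
    n_frames: int = 120
    height_px: int = 128
    width_px: int = 128
    psf_sigma_px: float = 1.3
    evanescent_depth_nm: float = 100.0
    channel_gains: tuple[float, ...] = (1.0, 1.0)
    background_level: float = 100.0
    photon_scale: float = 1.0
    read_noise_sd: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "psf_sigma_px": self.psf_sigma_px,
            "evanescent_depth_nm": self.evanescent_depth_nm,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ConfigurationError(f"{name} must be > 0, got {value}")
        if self.n_frames < 1:
            raise ConfigurationError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.height_px < 1 or self.width_px < 1:
            raise ConfigurationError("image dimensions must be >= 1 px")
        if any(g <= 0 for g in self.channel_gains):
            raise ConfigurationError("channel gains must be > 0")
        if self.background_level < 0:
            raise ConfigurationError("background_level must be >= 0")
        if self.photon_scale < 0 or self.read_noise_sd < 0:
            raise ConfigurationError("noise parameters must be >= 0")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def without_noise(self) -> "ImagingConfig":
        return replace(self, photon_scale=0.0, read_noise_sd=0.0)


@dataclass(frozen=True)
class ChannelModel:
    """One acquisition channel.  ``z_sensitive`` marks an evanescent (TIRF)
    channel whose signal is attenuated by exp(-z/d); widefield channels are
    insensitive to axial displacement over the relevant range."""

    name: str
    z_sensitive: bool = False


TIRF_WF_CHANNELS = (ChannelModel("tirf", True), ChannelModel("wf", False))
TWO_COLOR_TIRF = (ChannelModel("ch0", True), ChannelModel("ch1", True))


@dataclass(frozen=True)
class EventSpec:
    """Ground truth for one endocytic event.

    ``x_px`` is the column and ``y_px`` the row of the event center
    (0-based, subpixel allowed).  The recruitment profile rises with time
    constant ``rise_tau_s``, plateaus, and falls exponentially with
    ``fall_tau_s`` starting ``3 * fall_tau_s`` before the end of the
    lifetime (or, if ``fall_start_s`` is given, at that many seconds after
    ``t_start_s``).  ``scission_time_s`` (absolute) starts a constant-speed
    axial ramp z(t) = z_speed * (t - scission); z is 0 before scission.
    """

    event_id: int
    x_px: float
    y_px: float
    t_start_s: float
    lifetime_s: float
    amplitudes: tuple[float, ...] = (600.0, 600.0)
    channel_offsets_s: tuple[float, ...] = (0.0, 0.0)
    rise_tau_s: float = 2.0
    fall_tau_s: float = 2.0
    fall_start_s: float | None = None
    scission_time_s: float | None = None
    z_speed_nm_per_s: float = 20.0
    z_offset_nm: float = 0.0
    retention_class: str = "membrane_retained"
    coloc_partner: bool = False

    def __post_init__(self) -> None:
        if not self.lifetime_s > 0:
            raise ParameterError(f"lifetime_s must be > 0, got {self.lifetime_s}")
        if self.scission_time_s is not None:
            lo, hi = self.t_start_s, self.t_start_s + self.lifetime_s
            if not (lo <= self.scission_time_s <= hi):
                raise ParameterError(
                    f"scission_time_s {self.scission_time_s} outside event "
                    f"interval [{lo}, {hi}]"
                )
        if self.z_speed_nm_per_s < 0:
            raise ParameterError("z_speed_nm_per_s must be >= 0")
        if self.z_offset_nm < 0:
            raise ParameterError("z_offset_nm must be >= 0")

    def z_nm(self, t_s: np.ndarray) -> np.ndarray:
        """Axial displacement (nm): a constant offset plus, after scission,
        a linear ramp.  Non-decreasing in time by construction."""
        t_s = np.asarray(t_s, dtype=float)
        z = np.full_like(t_s, float(self.z_offset_nm))
        if self.scission_time_s is not None:
            z = z + np.maximum(0.0, t_s - self.scission_time_s) * self.z_speed_nm_per_s
        return z

    def amplitude(self, t_s: np.ndarray, channel: int = 0) -> np.ndarray:
        """Recruitment amplitude (peak pixel intensity) at absolute times."""
        t_s = np.asarray(t_s, dtype=float)
        t_rel = t_s - self.t_start_s - self.channel_offsets_s[channel]
        amp = np.zeros_like(t_rel)
        inside = (t_rel >= 0) & (t_rel <= self.lifetime_s)
        if self.fall_start_s is not None:
            fall_start = self.fall_start_s
        else:
            fall_start = self.lifetime_s - 3.0 * self.fall_tau_s
        fall_start = min(max(fall_start, 0.0), self.lifetime_s)
        tr = t_rel[inside]
        rise = 1.0 - np.exp(-np.minimum(tr, fall_start) / self.rise_tau_s)
        fall = np.exp(-np.maximum(tr - fall_start, 0.0) / self.fall_tau_s)
        amp[inside] = self.amplitudes[channel] * rise * fall
        return amp


@dataclass
class MovieStack:
    """A rendered multi-channel time-lapse with its configuration and the
    ground-truth events embedded at render time."""

    intensities: np.ndarray  # (channel, frame, row, col), >= 0
    config: ImagingConfig
    channels: tuple[ChannelModel, ...]
    ground_truth: list[EventSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        expected = (
            len(self.channels),
            self.config.n_frames,
            self.config.height_px,
            self.config.width_px,
        )
        if self.intensities.shape != expected:
            raise ConfigurationError(
                f"intensity array shape {self.intensities.shape} does not match "
                f"config/channels {expected}"
            )
        if np.any(self.intensities < 0):
            raise ConfigurationError("intensities must be non-negative")

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Frames (T, H, W) of one channel, by name or index."""
        if isinstance(name_or_index, str):
            names = [c.name for c in self.channels]
            name_or_index = names.index(name_or_index)
        return self.intensities[name_or_index]


@dataclass
class CytometryPopulation:
    """Per-cell fluorescence draws for one condition/replicate/measurement."""

    condition: str
    replicate_id: int
    measurement: str  # "uptake" or "surface"
    per_cell_fluorescence: np.ndarray
    ground_truth_median: float

    def __post_init__(self) -> None:
        self.per_cell_fluorescence = np.asarray(self.per_cell_fluorescence, float)
        if self.per_cell_fluorescence.size < 1:
            raise ParameterError("a cytometry population needs at least one cell")
        if np.any(self.per_cell_fluorescence < 0):
            raise ParameterError("fluorescence values must be >= 0")

    @property
    def n_cells(self) -> int:
        return int(self.per_cell_fluorescence.size)

    @property
    def median(self) -> float:
        return float(np.median(self.per_cell_fluorescence))


@dataclass
class ParticleTrackSet:
    """Per-particle (t, x, y) tracks from one NTA detection modality.

    ``modality`` is "scatter" (all particles, detected by diffracted light)
    or "fluorescence" (the protein-bound subpopulation, detected by GFP
    emission).  Ground-truth hydrodynamic diameters are carried alongside.
    """

    tracks: list[np.ndarray]  # each (n, 3): t_s, x_um, y_um
    particle_ids: np.ndarray
    modality: str
    temperature_K: float
    viscosity_Pa_s: float
    frame_rate_hz: float = 25.0
    ground_truth_diameter_nm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not self.frame_rate_hz > 0:
            raise ParameterError("frame_rate_hz must be > 0")
        for tr in self.tracks:
            if np.any(np.diff(tr[:, 0]) <= 0):
                raise ParameterError("track times must be strictly increasing")

    @property
    def n_particles(self) -> int:
        return len(self.tracks)


# --------------------------------------------------------------------------
# movie rendering
# --------------------------------------------------------------------------

def render_movie(
    events: list[EventSpec],
    config: ImagingConfig,
    channels: tuple[ChannelModel, ...] = TWO_COLOR_TIRF,
    rng: np.random.Generator | None = None,
) -> MovieStack:
    """Render events into a multi-channel movie.

    Each event is drawn as a 2-D Gaussian of standard deviation
    ``config.psf_sigma_px`` whose peak amplitude follows the event's
    recruitment profile; on z-sensitive channels the amplitude is further
    multiplied by ``exp(-z(t)/d)`` with ``d = evanescent_depth_nm``.
    Poisson shot noise (if ``photon_scale > 0``) and Gaussian read noise
    (if ``read_noise_sd > 0``) are then applied.

    Raises
    ------
    InputError
        If any event center lies outside the image, listing the ids.
    """
    out_of_bounds = [
        e.event_id
        for e in events
        if not (0 <= e.y_px <= config.height_px - 1 and 0 <= e.x_px <= config.width_px - 1)
    ]
    if out_of_bounds:
        raise InputError(f"events outside image bounds: {out_of_bounds}")
    n_ch = len(channels)
    if len(config.channel_gains) < n_ch:
        raise ConfigurationError(
            f"config has {len(config.channel_gains)} gains for {n_ch} channels"
        )
    for e in events:
        if len(e.amplitudes) < n_ch or len(e.channel_offsets_s) < n_ch:
            raise ConfigurationError(
                f"event {e.event_id} does not specify all {n_ch} channels"
            )

    T, H, W = config.n_frames, config.height_px, config.width_px
    times = config.times_s
    stack = np.full((n_ch, T, H, W), float(config.background_level))
    radius = int(math.ceil(4 * config.psf_sigma_px))
    two_sigma_sq = 2.0 * config.psf_sigma_px**2

    for event in events:
        r0, c0 = event.y_px, event.x_px
        rlo = max(int(math.floor(r0)) - radius, 0)
        rhi = min(int(math.ceil(r0)) + radius, H - 1)
        clo = max(int(math.floor(c0)) - radius, 0)
        chi = min(int(math.ceil(c0)) + radius, W - 1)
        rows = np.arange(rlo, rhi + 1)
        cols = np.arange(clo, chi + 1)
        psf = np.exp(
            -((rows[:, None] - r0) ** 2 + (cols[None, :] - c0) ** 2) / two_sigma_sq
        )
        z = event.z_nm(times)
        attenuation = np.exp(-z / config.evanescent_depth_nm)
        for ci, channel in enumerate(channels):
            amp = event.amplitude(times, channel=ci) * config.channel_gains[ci]
            if channel.z_sensitive:
                amp = amp * attenuation
            active = np.nonzero(amp > 0)[0]
            if active.size == 0:
                continue
            stack[ci, active, rlo : rhi + 1, clo : chi + 1] += (
                amp[active, None, None] * psf[None, :, :]
            )

    if config.photon_scale > 0 or config.read_noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(config.rng_seed)
        if config.photon_scale > 0:
            stack = rng.poisson(stack / config.photon_scale) * config.photon_scale
        stack = stack.astype(float)
        if config.read_noise_sd > 0:
            stack = stack + rng.normal(0.0, config.read_noise_sd, size=stack.shape)
        stack = np.maximum(stack, 0.0)

    return MovieStack(stack, config, tuple(channels), list(events))


# --------------------------------------------------------------------------
# lifetime sampling (truncated log-normal with requested truncated moments)
# --------------------------------------------------------------------------

def _phi_mass(a: float, b: float) -> float:
    """P(a < Z < b) for standard normal Z, robust in both far tails."""
    if a + b > 0:  # both deep in the upper tail: difference of survival fns
        return float(special.ndtr(-a) - special.ndtr(-b))
    return float(special.ndtr(b) - special.ndtr(a))


def _truncated_lognormal_moments(
    mu: float, sigma: float, lower: float, upper: float
) -> tuple[float, float]:
    """Mean and SD of a log-normal(mu, sigma) truncated to [lower, upper]."""
    a = (math.log(lower) - mu) / sigma
    b = (math.log(upper) - mu) / sigma
    z = _phi_mass(a, b)
    if z <= 0:
        return math.nan, math.nan

    def raw_moment(k: int) -> float:
        mass = _phi_mass(a - k * sigma, b - k * sigma)
        if mass <= 0:
            return math.nan
        log_m = k * mu + 0.5 * k**2 * sigma**2 + math.log(mass) - math.log(z)
        if log_m > 700:
            return math.inf
        return math.exp(log_m)

    m1 = raw_moment(1)
    m2 = raw_moment(2)
    if not (math.isfinite(m1) and math.isfinite(m2)):
        return math.nan, math.nan
    var = max(m2 - m1**2, 0.0)
    return m1, math.sqrt(var)


def _mu_matching_mean(
    sigma: float, mean: float, lower: float, upper: float
) -> float | None:
    """mu such that the truncated log-normal has the requested mean.

    The truncated mean is increasing in mu with range (lower, upper), so a
    unique root exists for any sigma; the bracket is found on a coarse grid
    kept inside the numerically representable tail (|z-score| < ~34).
    """

    def f(mu: float) -> float:
        return _truncated_lognormal_moments(mu, sigma, lower, upper)[0] - mean

    span = min(34.0 * sigma, 600.0)
    mus = np.linspace(math.log(lower) - span, math.log(upper) + span, 400)
    vals = np.array([f(m) for m in mus])
    finite = np.isfinite(vals)
    for i in range(len(mus) - 1):
        if finite[i] and finite[i + 1] and vals[i] * vals[i + 1] < 0:
            return float(optimize.brentq(f, mus[i], mus[i + 1], xtol=1e-12))
    return None


_SOLVER_CACHE: dict[tuple[float, float, float, float, float], tuple[float, float]] = {}


def solve_truncated_lognormal(
    mean_s: float, sd_s: float, lower_s: float, upper_s: float,
    sd_tolerance: float = 0.10,
) -> tuple[float, float]:
    """Find (mu, sigma) of the underlying normal so that the log-normal
    truncated to [lower_s, upper_s] has the requested mean and SD.

    The mean is always matched exactly (1-D root in mu nested inside the
    sigma search).  Under heavy truncation the family's attainable SD at a
    given mean is bounded; when the requested SD lies outside that range
    the closest attainable SD is used — with a warning — as long as it is
    within ``sd_tolerance`` (relative).  Raises :class:`ParameterError`
    when the mean lies outside the interval or the SD misses by more.
    """
    if not (lower_s < mean_s < upper_s):
        raise ParameterError(
            f"requested mean {mean_s} outside truncation interval "
            f"({lower_s}, {upper_s})"
        )
    if not sd_s > 0:
        raise ParameterError("sd_s must be > 0 for the log-normal solver")
    cache_key = (mean_s, sd_s, lower_s, upper_s, sd_tolerance)
    if cache_key in _SOLVER_CACHE:
        return _SOLVER_CACHE[cache_key]

    sigmas = np.geomspace(0.02, 12.0, 60)
    mus, sds = [], []
    for sig in sigmas:
        mu = _mu_matching_mean(float(sig), mean_s, lower_s, upper_s)
        if mu is None:
            mus.append(math.nan)
            sds.append(math.nan)
            continue
        mus.append(mu)
        sds.append(_truncated_lognormal_moments(mu, float(sig), lower_s, upper_s)[1])
    sds = np.array(sds)
    finite = np.isfinite(sds)
    if not finite.any():
        raise ParameterError("truncated log-normal solver found no valid sigma")

    def sd_err(sig: float) -> float:
        mu = _mu_matching_mean(sig, mean_s, lower_s, upper_s)
        if mu is None:
            return math.nan
        return _truncated_lognormal_moments(mu, sig, lower_s, upper_s)[1] - sd_s

    # exact crossing if the target SD is attainable
    idx = np.nonzero(finite)[0]
    for i, j in zip(idx[:-1], idx[1:]):
        e1, e2 = sds[i] - sd_s, sds[j] - sd_s
        if e1 * e2 < 0:
            sig = float(optimize.brentq(sd_err, sigmas[i], sigmas[j], xtol=1e-10))
            mu = _mu_matching_mean(sig, mean_s, lower_s, upper_s)
            _SOLVER_CACHE[cache_key] = (mu, sig)
            return mu, sig

    # otherwise take the closest attainable SD at the exact mean
    best_i = idx[np.nanargmin(np.abs(sds[idx] - sd_s))]
    sig = float(sigmas[best_i])
    res = optimize.minimize_scalar(
        lambda s: abs(sd_err(s)) if math.isfinite(sd_err(s)) else 1e9,
        bracket=None,
        bounds=(max(sig / 2, 0.01), min(sig * 2, 12.0)),
        method="bounded",
    )
    if math.isfinite(res.fun) and res.fun < abs(sds[best_i] - sd_s):
        sig = float(res.x)
    mu = _mu_matching_mean(sig, mean_s, lower_s, upper_s)
    achieved = _truncated_lognormal_moments(mu, sig, lower_s, upper_s)[1]
    rel_miss = abs(achieved - sd_s) / sd_s
    if rel_miss > sd_tolerance:
        raise ParameterError(
            f"no truncated log-normal on [{lower_s}, {upper_s}] with mean "
            f"{mean_s} attains sd {sd_s} (closest: {achieved:.4g})"
        )
    if rel_miss > 1e-3:
        warnings.warn(
            f"requested sd {sd_s} unattainable at mean {mean_s} on "
            f"[{lower_s}, {upper_s}]; using closest attainable sd "
            f"{achieved:.4g} (mean matched exactly)",
            stacklevel=2,
        )
    _SOLVER_CACHE[cache_key] = (mu, sig)
    return mu, sig


def sample_lifetimes(
    mean_s: float,
    sd_s: float,
    lower_s: float,
    upper_s: float,
    n: int,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Draw ``n`` event lifetimes from a log-normal truncated to
    [lower_s, upper_s] whose *truncated* mean and SD equal the request.

    ``sd_s = 0`` degenerates to a point mass at ``mean_s``.
    """
    if not lower_s < upper_s:
        raise ParameterError("lower_s must be < upper_s")
    if n < 0:
        raise ParameterError("n must be >= 0")
    if n == 0:
        return np.zeros(0)
    if sd_s < 0:
        raise ParameterError("sd_s must be >= 0")
    if sd_s == 0:
        if not (lower_s <= mean_s <= upper_s):
            raise ParameterError("degenerate mean outside truncation interval")
        return np.full(n, float(mean_s))
    mu, sigma = solve_truncated_lognormal(mean_s, sd_s, lower_s, upper_s)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    a = (math.log(lower_s) - mu) / sigma
    b = (math.log(upper_s) - mu) / sigma
    log_values = stats.truncnorm.rvs(
        a, b, loc=mu, scale=sigma, size=n, random_state=rng
    )
    return np.clip(np.exp(log_values), lower_s, upper_s)


# --------------------------------------------------------------------------
# cytometry, kinetics, Brownian tracks
# --------------------------------------------------------------------------

def simulate_cytometry(
    median: float,
    cv: float,
    n_cells: int,
    seed: int | np.random.Generator = 0,
    condition: str = "",
    replicate_id: int = 0,
    measurement: str = "uptake",
) -> CytometryPopulation:
    """Log-normal per-cell fluorescence with the requested median and
    coefficient of variation (the log-normal median is its scale parameter,
    so the ground-truth median is exact)."""
    if not median > 0:
        raise ParameterError("median must be > 0")
    if cv < 0:
        raise ParameterError("cv must be >= 0")
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if cv == 0:
        values = np.full(n_cells, float(median))
    else:
        sigma = math.sqrt(math.log(1 + cv**2))
        values = median * np.exp(rng.normal(0.0, sigma, size=n_cells))
    return CytometryPopulation(condition, replicate_id, measurement, values, float(median))


def simulate_slope_response(
    vmax: float,
    k_half: float,
    concentrations: np.ndarray,
    noise_cv: float = 0.0,
    seed: int | np.random.Generator = 0,
    n_replicates: int = 1,
) -> pd.DataFrame:
    """Saturating (one-site) slope-vs-concentration data:
    slope(c) = vmax * c / (c + k_half), times mean-one multiplicative
    log-normal noise of the stated CV.  Returns columns
    ``concentration``, ``replicate``, ``slope``."""
    if not (vmax > 0 and k_half > 0):
        raise ParameterError("vmax and k_half must be > 0")
    concentrations = np.asarray(concentrations, dtype=float)
    if np.any(concentrations < 0):
        raise InputError("concentrations must be non-negative")
    if noise_cv < 0:
        raise ParameterError("noise_cv must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        clean = vmax * concentrations / (concentrations + k_half)
        if noise_cv > 0:
            sigma = math.sqrt(math.log(1 + noise_cv**2))
            factor = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=clean.shape))
        else:
            factor = 1.0
        for c, s in zip(concentrations, clean * factor):
            rows.append({"concentration": c, "replicate": rep, "slope": s})
    return pd.DataFrame(rows)


def diffusion_coefficient_um2_s(
    diameter_nm: float, temperature_K: float, viscosity_Pa_s: float
) -> float:
    """Stokes-Einstein diffusion coefficient D = kB*T / (3*pi*eta*d), in um^2/s."""
    if not (diameter_nm > 0 and temperature_K > 0 and viscosity_Pa_s > 0):
        raise ParameterError("diameter, temperature and viscosity must be > 0")
    d_m = diameter_nm * 1e-9
    d_m2_s = BOLTZMANN_J_PER_K * temperature_K / (3 * math.pi * viscosity_Pa_s * d_m)
    return d_m2_s * 1e12


def simulate_brownian_tracks(
    diameters_nm: np.ndarray,
    duration_s: float = 120.0,
    frame_rate_hz: float = 25.0,
    temperature_K: float = 298.0,
    viscosity_Pa_s: float = 8.9e-4,
    bound_fraction_by_size=None,
    seed: int | np.random.Generator = 0,
) -> tuple[ParticleTrackSet, ParticleTrackSet]:
    """Simulate 2-D Brownian tracks for a liposome population.

    Each particle diffuses with per-axis step variance ``2*D*dt`` where the
    Stokes-Einstein ``D`` follows from its ground-truth diameter.  The
    scatter set contains every particle; the fluorescence set keeps a
    Bernoulli subsample with per-particle probability
    ``bound_fraction_by_size(diameter_nm)`` (protein-bound particles).
    """
    diameters_nm = np.asarray(diameters_nm, dtype=float)
    if np.any(diameters_nm <= 0):
        raise ParameterError("diameters must be > 0")
    if not (temperature_K > 0 and viscosity_Pa_s > 0):
        raise ParameterError("temperature and viscosity must be > 0")
    if not frame_rate_hz > 0:
        raise ParameterError("frame_rate_hz must be > 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dt = 1.0 / frame_rate_hz
    n_steps = max(int(round(duration_s * frame_rate_hz)), 1)
    times = np.arange(n_steps + 1) * dt

    tracks: list[np.ndarray] = []
    for d in diameters_nm:
        D = diffusion_coefficient_um2_s(d, temperature_K, viscosity_Pa_s)
        step_sd = math.sqrt(2.0 * D * dt)
        steps = rng.normal(0.0, step_sd, size=(n_steps, 2))
        xy = np.vstack([np.zeros((1, 2)), np.cumsum(steps, axis=0)])
        tracks.append(np.column_stack([times, xy]))

    ids = np.arange(len(tracks))
    scatter = ParticleTrackSet(
        tracks, ids, "scatter", temperature_K, viscosity_Pa_s, frame_rate_hz,
        ground_truth_diameter_nm=diameters_nm.copy(),
    )
    if bound_fraction_by_size is None:
        bound_fraction_by_size = lambda d: 1.0  # noqa: E731
    probs = np.array([float(bound_fraction_by_size(d)) for d in diameters_nm])
    if np.any((probs < 0) | (probs > 1)):
        raise ParameterError("bound_fraction_by_size must map into [0, 1]")
    keep = rng.random(len(tracks)) < probs
    fluor = ParticleTrackSet(
        [t for t, k in zip(tracks, keep) if k],
        ids[keep],
        "fluorescence",
        temperature_K,
        viscosity_Pa_s,
        frame_rate_hz,
        ground_truth_diameter_nm=diameters_nm[keep].copy(),
    )
    return scatter, fluor


# --------------------------------------------------------------------------
# convenience event builders
# --------------------------------------------------------------------------

def _grid_positions(
    n: int, height: int, width: int, margin: int, rng: np.random.Generator,
    jitter_px: float = 3.0,
) -> np.ndarray:
    """Roughly regular (row, col) positions with jitter, all >= 2*jitter apart."""
    per_side = int(math.ceil(math.sqrt(n)))
    rows = np.linspace(margin, height - 1 - margin, per_side)
    cols = np.linspace(margin, width - 1 - margin, per_side)
    grid = np.array([(r, c) for r in rows for c in cols])[:n]
    grid = grid + rng.uniform(-jitter_px, jitter_px, size=grid.shape)
    return np.clip(grid, margin, [[height - 1 - margin, width - 1 - margin]])


def make_ccp_events(
    n_events: int,
    config: ImagingConfig,
    lifetime_mean_s: float = 32.7,
    lifetime_sd_s: float = 16.3,
    lifetime_bounds_s: tuple[float, float] = (20.0, 120.0),
    amplitude: float = 600.0,
    channel_offset_s: float = 0.0,
    rise_tau_s: float = 2.0,
    fall_tau_s: float = 2.0,
    margin_px: int = 10,
    edge_margin_s: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> list[EventSpec]:
    """Build a field of clathrin-coated-pit-like events on a jittered grid.

    Lifetimes are drawn from the truncated log-normal sampler; start times
    are uniform over the part of the movie that lets the event complete
    (events too long to fit start at the earliest allowed frame and are
    left to be flagged as censored by the downstream analysis).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = _grid_positions(n_events, config.height_px, config.width_px, margin_px, rng)
    lifetimes = sample_lifetimes(
        lifetime_mean_s, lifetime_sd_s, *lifetime_bounds_s, n=n_events, seed=rng
    )
    movie_len = config.n_frames * config.frame_interval_s
    events = []
    for i, ((r, c), life) in enumerate(zip(positions, lifetimes)):
        latest = movie_len - edge_margin_s - life
        t0 = rng.uniform(edge_margin_s, latest) if latest > edge_margin_s else edge_margin_s
        events.append(
            EventSpec(
                event_id=i,
                x_px=float(c),
                y_px=float(r),
                t_start_s=float(t0),
                lifetime_s=float(life),
                amplitudes=(amplitude, amplitude),
                channel_offsets_s=(0.0, channel_offset_s),
                rise_tau_s=rise_tau_s,
                fall_tau_s=fall_tau_s,
            )
        )
    return events


def make_retention_events(
    n_retained: int,
    n_internalized: int,
    config: ImagingConfig,
    lifetime_s: float = 60.0,
    amplitude: float = 600.0,
    wf_persistence_s: float = 25.0,
    z_speed_nm_per_s: float = 20.0,
    margin_px: int = 12,
    seed: int | np.random.Generator = 0,
) -> list[EventSpec]:
    """Events for the sequential widefield/TIRF retention paradigm.

    Internalized events undergo scission ``wf_persistence_s`` seconds before
    the recruitment profile starts to fall, so their TIRF signal (attenuated
    by the axial ramp) is lost while the widefield signal persists.
    Membrane-retained events never leave z = 0 and lose both channels
    together.  The default persistence (25 s) exceeds the time the default
    20 nm/s ramp needs to extinguish the TIRF signal completely, so the
    widefield channel is still near plateau at the TIRF loss frame.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = n_retained + n_internalized
    positions = _grid_positions(n, config.height_px, config.width_px, margin_px, rng)
    movie_len = config.n_frames * config.frame_interval_s
    fall_window = 3.0 * 2.0  # 3 * default fall tau
    events = []
    for i, (r, c) in enumerate(positions):
        internalized = i >= n_retained
        latest = movie_len - lifetime_s - 5.0
        t0 = rng.uniform(5.0, max(latest, 5.0 + 1e-6))
        fall_start = lifetime_s - fall_window
        scission = t0 + fall_start - wf_persistence_s if internalized else None
        events.append(
            EventSpec(
                event_id=i,
                x_px=float(c),
                y_px=float(r),
                t_start_s=float(t0),
                lifetime_s=float(lifetime_s),
                amplitudes=(amplitude, amplitude),
                channel_offsets_s=(0.0, 0.0),
                scission_time_s=scission,
                z_speed_nm_per_s=z_speed_nm_per_s,
                retention_class="internalized" if internalized else "membrane_retained",
            )
        )
    return events
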