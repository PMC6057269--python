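# Methods

`cmequant` re-creates, as tested code, the quantitative readouts used to
characterize actin regulation at clathrin-coated pits (CCPs): recruitment
dynamics from TIRF time-lapses, punctae colocalization, the sequential
widefield/TIRF membrane-retention paradigm, kymograph lifetime
measurement, flow-cytometry uptake normalization, pyrene-actin kinetics,
and nanoparticle-tracking sizing. Every analysis is paired with a
synthetic-data generator that embeds its ground truth, so each stage can
be validated as an inverse problem: plant a parameter, run the pipeline,
recover it.

## The optical model (`synth`)

An endocytic event is a diffraction-limited spot: a 2-D Gaussian of
standard deviation `psf_sigma_px` (default 1.3 px at 0.1 µm/px) whose peak
amplitude follows a recruitment profile

- rise: `A (1 − exp(−t/τ_rise))`, default `τ_rise` = 2 s,
- fall: exponential with `τ_fall` (default 2 s), starting `3 τ_fall`
  before the end of the event's lifetime (or at an explicit
  `fall_start_s`),
- zero outside `[t_start, t_start + lifetime]`.

The rise–plateau–fall family was chosen because measured recruitment
traces show exactly that shape without pinning a functional form; the
exponential pair is the simplest smooth realization.

Axial position `z(t)` is a constant offset plus, after scission, a linear
ramp at `z_speed_nm_per_s` (default 20 nm/s). TIRF (evanescent) channels
are attenuated by `exp(−z/d)` with `d = evanescent_depth_nm` (default
100 nm, the canonical evanescent-field depth); widefield channels ignore
`z`. Noise is the standard camera model: Poisson shot noise at
`photon_scale` intensity units per photon, then additive Gaussian read
noise; setting both scales to zero yields deterministic renders used by
the oracle tests. With noise off, the summed intensity above background
of an isolated spot equals `A · 2πσ²` to discretization accuracy — a
tested invariant.

The retention-event builder plants scission `wf_persistence_s` (default
25 s) before the recruitment fall begins. The default was chosen so that
the widefield channel is still near plateau when the TIRF signal has
fully disappeared: with a 20 nm/s ramp and a disappearance criterion of
background + 2σ, a spot of typical brightness needs ~17 s of ramp before
its TIRF trace is extinguished (the amplitude must fall ~30-fold through
`exp(−z/d)`), so a shorter persistence would make the paradigm's
signature — widefield decay delayed relative to TIRF — invisible even in
noiseless data.

## Lifetime distributions

Event lifetimes are drawn from a log-normal truncated to
`[lower_s, upper_s]` whose parameters are solved numerically so the
*truncated* mean matches the request exactly (1-D root in µ nested in a
search over σ; normal tail masses are computed with survival functions so
the solver is stable at extreme parameters). A caveat discovered while
building the solver: at a fixed truncated mean the family's attainable SD
is bounded. On [20, 120] s with mean 32.7 s the supremum is ≈ 15.8 s
(the σ → ∞ power-law limit), so a requested SD of 16.3 s cannot be met;
the sampler then matches the mean exactly, takes the closest attainable
SD, and warns. Requests whose SD misses by more than 10% raise a
parameterization error. The condition with mean 44.9 s / SD 21.7 s is
exactly solvable.

## Event detection and trace ensembles (`spots`)

Dynamic events are the brightest spots of a temporal standard-deviation
projection. "Brightest" is operationalized as local maxima above a
robust background threshold, median + k·1.4826·MAD with default k = 4,
kept greedily in descending score with a minimum separation of 5 px —
the selection itself is visual in common practice, so the rule is ours
and its recall/precision is characterized on planted events (≥ 90%
recall, ≤ 10% spurious at the default SNR; recall degrades monotonically
with added noise, a tested property).

Traces are background-subtracted box means (8×8 px box, background =
median of a 2-px annulus just outside the box), trimmed to ±50 frames
around the reference-channel maximum (earliest frame wins ties). Events
whose window exceeds the movie are excluded and reported. Manual trace
curation is replaced by an automatic gate — reference peak ≥ 3 noise SDs
above baseline, peak interior to the window — for reproducibility.
Ensembles stack traces on the shared alignment index; the reference-mean
maximum at time zero is a mathematical consequence of per-trace alignment
and is asserted. Optional smoothing is a centered moving average
(default 5 frames); min–max normalization maps each trace to [0, 1]
(constant traces are excluded with a warning). Note that smoothing an
asymmetric peak shifts its maximum; inter-channel peak *differences* are
unaffected, and that is the quantity reported.

## Colocalization (`coloc`)

Punctae in both channels are reduced to binary single-pixel spots by the
same detector. A reference spot is colocalized when ≥ 1 test spot lies
inside its 3×3-pixel dilated footprint (Chebyshev radius 1); multiple
partners count once, because the reference punctum is the unit of
analysis. The measure is directional by design. Time-resolved
colocalization is computed per frame and averaged, with no track
linking: a punctum present in n frames contributes n times.

## Membrane retention (`retention`)

"TIRF disappearance" is the first post-peak frame where the signal stays
below background + 2σ for ≥ 3 consecutive frames; both channels are
re-indexed so this frame is time zero, ±20 frames. Classification uses
the delay between the two channels' first half-maximum crossings after
their aligned peaks (WF minus TIRF): internalized if the delay exceeds 2
frames, else membrane-retained; events whose WF never reaches half decay
are flagged indeterminate. Half-maximum crossings make the call
invariant to any common gain, a tested invariant. On planted 50/50
populations at moderate noise the classifier is ≥ 90% accurate, and its
error rate decreases to zero with the noise.

## Kymographs and lifetimes (`kymo`)

The kymograph path is a polyline visiting all detected spots ordered by
column then row (a deterministic stand-in for the hand-drawn line), and
each path pixel is the mean over 3 px perpendicular to the local path
direction (noise suppression). Lifetimes are supra-threshold run lengths
per path position: threshold = kymograph median + 4 robust sigmas; gaps
shorter than 3 frames do not split an event; `lifetime = (end − start +
1) × frame_interval`. Runs touching the first or last frame are flagged
censored. When no positions are supplied, runs smeared over adjacent
path rows (one diffraction-limited event spans several) are merged, the
brightest row winning. Summaries apply the field's minimum-lifetime
filter (> 20 s, strict) and exclude censored events by default while
reporting their fraction — conditions where a third of events outlast the
movie are thereby visible rather than silently truncated. The frame
interval always comes from the imaging configuration; nothing is
hard-coded to 1 Hz or 0.5 Hz.

In the end-to-end lifetime experiments (`pipelines`), detection runs on a
projection over the *full* movie rather than a short centered window. A
short window would sample events with probability increasing in their
lifetime (length-biased sampling: a 20-frame centered window inflates a
32.7 s mean to ≈ 37.7 s), which is a selection artifact of the detection
protocol, not a property of the measurement; the full-movie projection
removes it.

## Cytometry statistics (`popstats`)

Per-cell fluorescence is modeled log-normal (non-negative, right-skewed,
the standard cytometry shape) with the requested median — exact, since
the log-normal median is its scale parameter — and CV. Uptake is
median(uptake)/median(surface); replicate ratios are divided by the mean
control ratio of their experiment, which makes the control mean exactly 1
per experiment and cancels day-to-day gain. Populations below the 5,000-
cell convention warn rather than fail. The high-expressor gate is
inclusive (≥ fold × background, default 100×) with the background a
supplied scalar, e.g. the median of an untransfected population. The
antibody-feeding index is background-subtracted signal per unit cell
area and may legitimately be negative.

## Kinetics (`kinetics`)

A reaction's polymerization rate is the maximum sliding-window
least-squares slope (default 11 points), which ignores the lag phase
without modeling it. The concentration–response is the one-site
saturation curve `slope = vmax·c/(c + k_half)` through the origin, fitted
by least squares with case-resampling bootstrap intervals (default 1000).
Fits are rejected as failures when slopes are constant (unidentifiable)
or the half-max lands more than 10× beyond the measured range.

## Nanoparticle tracking (`nta`)

Per-particle `D` is slope/4 of the least-squares line through
(lag·Δt, MSD) for lags 1–5, intercept free so static localization error
is absorbed rather than biasing the slope. Tracks whose MSD grows
super-linearly (last-to-first MSD-rate ratio > 2.5; pure flow gives 5 at
`max_lag` 5, pure diffusion 1) are flagged non-diffusive; non-positive
slopes exclude a particle, with the reason reported. Diameters follow
from Stokes–Einstein, `d = k_B T / (3πη D)`. Size distributions use
50-nm bins to 1200 nm by default (covering 800-nm extruded liposome
populations); enrichment is the bound/total normalized-density ratio with
empty-total bins NaN. Finite-track broadening of the size estimates is
characterized (per-class medians within 15% at 3000-step tracks) but not
deconvolved; detection-noise and track-length limits of real instruments
are vendor-specific and are left as user parameters.

## Problem sizes and reproducibility

All randomness flows from one seed per generator call (`numpy`
Generators; a passed Generator is used in place, so workflows can share
one stream). The reproduction script (`scripts/acceptance.py`) derives
independent child seeds from `--seed` via `SeedSequence`. The lifetime
experiments use ~2000 events per condition (56 movies of 36 events,
220×220 px, 120 frames) — enough that Monte Carlo error on the recovered
mean is ≈ 0.35 s; colocalization uses 10 frames of ~196 punctae;
cytometry uses 5,000 cells per population, 6 (uptake) or 5 (surface)
replicates; the dose-response uses 8 log-spaced concentrations × 3
replicates at 5% CV.

## What passing tests do and do not show

The generators emulate diffraction-limited spots on a uniform background
with Poisson + Gaussian noise, ideal exponential recruitment, instant
scission, and log-normal populations. They do not emulate cell-shape
background structure, clathrin plaques or focal-adhesion streaks,
photobleaching, stage drift, event merging/splitting, cytometry doublets
or spectral spillover, or NTA detection dropout. Recovery on these
synthetic inputs therefore demonstrates that the analysis code inverts
its stated model faithfully — not that the model captures every failure
mode of real microscopy data. Thresholds (k = 4 robust sigmas, 2σ
disappearance, 2-frame retention delay, >20 s lifetime filter) are the
package's operational defaults for rules that are applied visually at
the bench, and all of them are parameters.
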