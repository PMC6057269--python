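# cmequant

Quantitative analyses for clathrin-mediated endocytosis (CME) imaging and
biochemistry, with synthetic ground-truth data generators for every input.

During CME, adaptor and actin-regulatory proteins are recruited to
clathrin-coated pits (CCPs) with stereotyped timing, and their behavior is
quantified with a small set of standard readouts. This package implements
those readouts as a tested, reusable library for researchers who want the
measurements without hand-curated ImageJ workflows:

- **Recruitment dynamics** — events detected as the brightest spots of a
  temporal standard-deviation projection; per-event two-channel box traces
  aligned on the reference-channel peak and averaged (mean ± SD/SEM vs
  time, `t = 0` at the reference peak).
- **Colocalization** — punctae reduced to binary spots; a reference
  punctum colocalizes when a partner spot falls in its 3×3-dilated
  footprint; fractions per frame, averaged over time.
- **Membrane retention** — the sequential widefield/TIRF paradigm: because
  the evanescent field decays as `exp(−z/d)` with `d ≈ 100 nm`, a protein
  leaving on the budding vesicle loses TIRF signal before widefield;
  events are classified from the delay between the channels' half-decay
  times.
- **CCP lifetimes** — kymographs along a path through all detected events;
  lifetime = supra-threshold run length × frame interval, with censoring
  flags and the standard > 20 s filter.
- **Transferrin uptake** — cytometry normalization
  `median(uptake) / median(surface)`, expressed relative to the control
  mean per experiment; high-expressor gating; antibody-feeding index.
- **Actin kinetics** — pyrene-actin polymerization rates as maximal
  sliding-window slopes; one-site saturation fit
  `slope = v_max · c / (c + K_half)` with bootstrap CIs.
- **Nanoparticle tracking (NTA)** — per-particle diffusion from MSD
  slopes, Stokes–Einstein sizing `d = k_B T / (3πη D)`, and bound/total
  size-distribution enrichment as a membrane-curvature-preference readout.

The `synth` module generates every input the analyses consume — movies
with Gaussian-PSF events, Poisson + Gaussian camera noise and embedded
ground truth; log-normal cytometry populations; saturating dose-response
data; 2-D Brownian liposome tracks — so each pipeline is validated by
parameter recovery. See `docs/methods.md` for the models and their
assumptions.

## Worked example

`examples/04_ccp_lifetimes.py` plants CCP events whose lifetimes follow a
truncated log-normal with the control-condition mean of 32.7 s, renders
120 s movies at 1 Hz, and runs the full detection → kymograph →
run-length pipeline:

```
planted mean lifetime: 33.3 s (324 events)
recovered: 34.3 +/- 16.5 s (n = 291 events passing the >20 s filter, censored fraction 0.003)
-> the run-length measurement on kymograph rows inverts the generator's
   lifetime distribution to within a few percent.
```

The recovered mean tracks the planted sample mean to a few percent; the
censored fraction counts events still running at the movie edge (excluded
from the summary but reported, since long-lifetime conditions push many
events past the end of the movie). The other examples
(`examples/01…07`) each exercise one capability the same way and print
what the numbers mean.

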