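"""Sequential widefield/TIRF paradigm: does a protein leave with the vesicle?

The evanescent TIRF field is ~100 nm deep, so a protein departing on the
budding vesicle loses TIRF signal while keeping widefield signal for a
while; membrane-retained proteins lose both together.  This script plants
a half/half population, classifies every event from the delay between the
two channels' half-decay times, and scores the labels.
"""

import numpy as np

from cmequant import retention, spots, synth

cfg = synth.ImagingConfig(
    n_frames=120, frame_interval_s=2.0, height_px=320, width_px=320, rng_seed=3
)
events = synth.make_retention_events(50, 50, cfg, seed=4)
movie = synth.render_movie(events, cfg, synth.TIRF_WF_CHANNELS)

correct, delays = [], {"membrane_retained": [], "internalized": []}
for event in movie.ground_truth:
    spot = (int(round(event.y_px)), int(round(event.x_px)))
    tirf = spots.box_trace(movie.channel("tirf"), spot)
    wf = spots.box_trace(movie.channel("wf"), spot)
    background, noise = retention.estimate_trace_baseline(tirf)
    try:
        loss = retention.find_tirf_loss_frame(tirf, background, noise)
        wf_prof, tirf_prof = retention.aligned_decay_profiles(wf, tirf, loss)
    except Exception:
        continue  # no clean disappearance inside the movie
    result = retention.classify_retention(wf_prof, tirf_prof)
    if result.retention_class == retention.INDETERMINATE:
        continue
    correct.append(result.retention_class == event.retention_class)
    delays[event.retention_class].append(result.wf_delay_frames)

print(f"events classified: {len(correct)}, accuracy: {np.mean(correct):.2f}")
for label, d in delays.items():
    print(f"  {label}: mean WF delay {np.mean(d):+.1f} frames")
print("-> internalized events show a multi-frame widefield decay delay; "
      "membrane-retained events decay synchronously in both channels.")
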