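"""Peak-aligned recruitment ensembles from a two-channel TIRF movie.

Simulates endocytic events in which the second channel (think dynamin)
is recruited 4 s after the reference channel (think the F-BAR adaptor),
detects the events on a standard-deviation projection, extracts box
traces, and averages them aligned on the reference peak.
"""

import numpy as np

from cmequant import spots, synth

cfg = synth.ImagingConfig(n_frames=80, height_px=360, width_px=360, rng_seed=1)
events = synth.make_ccp_events(
    100, cfg,
    lifetime_mean_s=30.0, lifetime_sd_s=4.0, lifetime_bounds_s=(22.0, 45.0),
    channel_offset_s=4.0, margin_px=14, seed=2,
)
movie = synth.render_movie(events, cfg)

projection = spots.stddev_projection(movie.channel(0), cfg.n_frames)
detected = spots.detect_events(projection)
traces, rejected = spots.extract_traces(movie, detected, half_window_frames=25)
traces = spots.gate_traces(traces)
ensembles = spots.align_and_average(traces, smooth_window=5)

ref = ensembles["ch0"]
partner = ensembles["ch1"]
ref_peak = ref.time_s[np.argmax(ref.mean)]
partner_peak = partner.time_s[np.argmax(partner.mean)]
print(f"events detected: {len(detected)}, traces kept: {ref.n_events}")
print(f"reference-channel mean peaks at t = {ref_peak:+.0f} s")
print(f"partner-channel mean peaks at  t = {partner_peak:+.0f} s")
print(
    f"partner lag relative to reference: {partner_peak - ref_peak:+.0f} s "
    "(planted +4 s)"
)
print(
    "-> time zero is the reference peak; smoothing shifts both channels "
    "equally, so the inter-channel lag recovers the planted recruitment delay."
)
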