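"""Event detection, trace extraction and peak-aligned ensembles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmequant import spots, synth
from cmequant.exceptions import InputError

from conftest import make_event


class TestStddevProjection:
    def test_constant_movie_projects_to_zero(self):
        frames = np.full((20, 8, 8), 3.0)
        assert np.all(spots.stddev_projection(frames, 10) == 0)

    def test_alternating_pixel_has_sd_one(self):
        frames = np.full((20, 8, 8), 5.0)
        frames[::2, 3, 4] = 4.0
        frames[1::2, 3, 4] = 6.0
        proj = spots.stddev_projection(frames, 20)
        assert proj[3, 4] == pytest.approx(1.0)
        proj[3, 4] = 0.0
        assert np.all(proj == 0)

    def test_matches_elementwise_oracle(self, rng):
        frames = rng.normal(10, 2, size=(30, 6, 7))
        window = 12
        proj = spots.stddev_projection(frames, window)
        start = 30 // 2 - window // 2
        sub = frames[start : start + window]
        # brute-force per-pixel standard deviation
        for r in range(6):
            for c in range(7):
                vals = sub[:, r, c]
                m = sum(vals) / window
                var = sum((v - m) ** 2 for v in vals) / window
                assert proj[r, c] == pytest.approx(var**0.5)

    def test_window_longer_than_movie_rejected(self):
        with pytest.raises(InputError):
            spots.stddev_projection(np.zeros((5, 4, 4)), 6)


class TestDetectEvents:
    def test_flat_projection_yields_no_spots(self):
        assert len(spots.detect_events(np.zeros((32, 32)))) == 0

    def test_two_separated_gaussians_both_found(self):
        img = np.zeros((64, 64))
        yy, xx = np.mgrid[0:64, 0:64]
        for r, c in [(20, 20), (20, 40)]:
            img += 100 * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * 1.5**2))
        found = spots.detect_events(img, min_separation_px=5)
        coords = {tuple(p) for p in found.coords}
        assert coords == {(20, 20), (20, 40)}

    def test_planted_events_recovered_with_high_recall_low_spurious(self):
        cfg = synth.ImagingConfig(n_frames=60, height_px=256, width_px=256, rng_seed=5)
        events = synth.make_ccp_events(
            50, cfg, lifetime_mean_s=30.0, lifetime_sd_s=5.0,
            lifetime_bounds_s=(20.0, 55.0), seed=6,
        )
        movie = synth.render_movie(events, cfg)
        proj = spots.stddev_projection(movie.channel(0), 50)
        found = spots.detect_events(proj)
        truth = np.array([[e.y_px, e.x_px] for e in events])
        matched = sum(
            1
            for rc in found.coords
            if np.min(np.max(np.abs(truth - rc), axis=1)) <= 2
        )
        assert matched >= 0.9 * len(events)
        assert len(found) - matched <= 0.1 * len(found)

    def test_recall_non_increasing_with_noise(self):
        recalls = []
        for read_noise in (2.0, 40.0, 120.0):
            cfg = synth.ImagingConfig(
                n_frames=40, height_px=128, width_px=128,
                read_noise_sd=read_noise, rng_seed=2,
            )
            events = synth.make_ccp_events(
                9, cfg, lifetime_mean_s=25.0, lifetime_sd_s=3.0,
                lifetime_bounds_s=(15.0, 39.0), amplitude=80.0, seed=4,
            )
            movie = synth.render_movie(events, cfg)
            proj = spots.stddev_projection(movie.channel(0), 40)
            found = spots.detect_events(proj)
            truth = np.array([[e.y_px, e.x_px] for e in events])
            matched = {
                int(np.argmin(np.max(np.abs(truth - rc), axis=1)))
                for rc in found.coords
                if np.min(np.max(np.abs(truth - rc), axis=1)) <= 2
            }
            recalls.append(len(matched) / len(events))
        assert recalls[0] >= recalls[1] >= recalls[2]


class TestExtractTrace:
    def test_reference_argmax_at_planted_peak(self, noiseless_config):
        event = make_event(rise_tau_s=3.0, fall_tau_s=1.5, lifetime_s=20.0)
        movie = synth.render_movie([event], noiseless_config)
        trace = spots.extract_trace(movie, (24, 24), half_window_frames=10)
        # recruitment rises until the fall phase starts (3 * fall tau before end)
        peak_time = event.t_start_s + event.lifetime_s - 3 * event.fall_tau_s
        full = spots.box_trace(movie.channel(0), (24, 24))
        assert np.argmax(full) == pytest.approx(peak_time, abs=1)
        assert trace.alignment_index == 10

    def test_empty_background_trace_is_flat_zero(self, noiseless_config):
        movie = synth.render_movie([], noiseless_config)
        trace = spots.box_trace(movie.channel(0), (24, 24))
        assert np.allclose(trace, 0.0)

    def test_box_mean_matches_brute_force_oracle(self, rng):
        cfg = synth.ImagingConfig(
            n_frames=6, height_px=32, width_px=32, rng_seed=3
        )
        movie = synth.render_movie([make_event(x_px=16, y_px=16, t_start_s=0.0)], cfg)
        frames = movie.channel(0)
        spot, box = (16, 16), 8
        got = spots.box_trace(frames, spot, box_px=box)
        for t in range(6):
            vals = [
                frames[t, r, c]
                for r in range(spot[0] - box // 2, spot[0] - box // 2 + box)
                for c in range(spot[1] - box // 2, spot[1] - box // 2 + box)
            ]
            ring = []
            for r in range(spot[0] - box // 2 - 2, spot[0] - box // 2 + box + 2):
                for c in range(spot[1] - box // 2 - 2, spot[1] - box // 2 + box + 2):
                    if not (
                        spot[0] - box // 2 <= r < spot[0] - box // 2 + box
                        and spot[1] - box // 2 <= c < spot[1] - box // 2 + box
                    ):
                        ring.append(frames[t, r, c])
            expected = np.mean(vals) - np.median(ring)
            assert got[t] == pytest.approx(expected)

    def test_window_exceeding_movie_rejected_and_reported(self, noiseless_config):
        movie = synth.render_movie([make_event()], noiseless_config)
        with pytest.raises(InputError):
            spots.extract_trace(movie, (24, 24), half_window_frames=50)
        spotset = spots.SpotSet(np.array([[24, 24]]), np.array([1.0]), (48, 48))
        kept, rejected = spots.extract_traces(movie, spotset, half_window_frames=50)
        assert kept == [] and rejected == [0]


class TestAlignAndAverage:
    def _trace(self, values, event_id=0):
        values = np.asarray(values, dtype=float)
        return spots.EventTrace(
            event_id=event_id,
            values=values[None, :],
            channel_names=("ch0",),
            reference_channel=0,
            alignment_index=len(values) // 2,
            frame_interval_s=1.0,
        )

    def test_single_trace_mean_is_trace_sd_zero(self):
        tr = self._trace([0, 1, 3, 1, 0])
        ens = spots.align_and_average([tr], smooth_window=1)["ch0"]
        assert np.allclose(ens.mean, tr.values[0])
        assert np.all(ens.sd == 0)

    def test_identical_traces_have_zero_sd(self):
        tr1 = self._trace([0, 2, 5, 2, 0], 0)
        tr2 = self._trace([0, 2, 5, 2, 0], 1)
        ens = spots.align_and_average([tr1, tr2], smooth_window=1)["ch0"]
        assert np.all(ens.sd == 0)
        assert np.allclose(ens.mean, [0, 2, 5, 2, 0])

    def test_mixed_window_lengths_rejected(self):
        with pytest.raises(InputError):
            spots.align_and_average(
                [self._trace([0, 1, 0]), self._trace([0, 1, 2, 1, 0])]
            )

    def test_reference_mean_peaks_at_time_zero(self, rng):
        traces = []
        for i in range(30):
            v = rng.random(21)
            v[10] = 2.0  # alignment index is the argmax by construction
            traces.append(self._trace(v, i))
        ens = spots.align_and_average(traces, smooth_window=1)["ch0"]
        assert ens.time_s[np.argmax(ens.mean)] == 0.0

    def test_constant_trace_excluded_from_normalization_with_warning(self):
        flat = self._trace([1, 1, 1, 1, 1], 0)
        bumpy = self._trace([0, 1, 2, 1, 0], 1)
        with pytest.warns(UserWarning, match="constant trace"):
            ens = spots.align_and_average(
                [flat, bumpy], smooth_window=1, normalize=True
            )["ch0"]
        assert ens.n_events == 1

    def test_planted_interchannel_peak_offset_recovered(self):
        # second channel recruited 4 s after the reference channel
        cfg = synth.ImagingConfig(
            n_frames=80, height_px=360, width_px=360, rng_seed=11
        )
        events = synth.make_ccp_events(
            100, cfg, lifetime_mean_s=30.0, lifetime_sd_s=4.0,
            lifetime_bounds_s=(22.0, 45.0), channel_offset_s=4.0,
            margin_px=14, seed=12,
        )
        movie = synth.render_movie(events, cfg)
        spotset = spots.SpotSet(
            np.array([[round(e.y_px), round(e.x_px)] for e in events]),
            np.ones(len(events)),
            (cfg.height_px, cfg.width_px),
        )
        traces, _ = spots.extract_traces(movie, spotset, half_window_frames=25)
        assert len(traces) >= 50
        ens = spots.align_and_average(traces, smooth_window=5)
        lag = ens["ch1"].time_s[np.argmax(ens["ch1"].mean)]
        assert lag == pytest.approx(4.0, abs=1.0)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(
    st.lists(
        st.floats(min_value=-1e3, max_value=1e3, allow_nan=False),
        min_size=5,
        max_size=40,
    )
)
def test_minmax_normalization_maps_to_unit_interval(values):
    arr = np.asarray(values)
    if np.ptp(arr) == 0:
        return
    trace = spots.EventTrace(
        event_id=0,
        values=arr[None, :],
        channel_names=("ch0",),
        reference_channel=0,
        alignment_index=0,
        frame_interval_s=1.0,
    )
    ens = spots.align_and_average([trace], smooth_window=1, normalize=True)["ch0"]
    assert ens.traces.min() == pytest.approx(0.0)
    assert ens.traces.max() == pytest.approx(1.0)
    assert np.all((ens.traces >= -1e-12) & (ens.traces <= 1 + 1e-12))
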