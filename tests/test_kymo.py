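"""Kymograph construction and coated-pit lifetime measurement."""

import numpy as np
import pytest

from cmequant import kymo, spots, synth
from cmequant.exceptions import InputError, UndefinedResultError


def spotset_from_events(events, shape):
    coords = np.array([[round(e.y_px), round(e.x_px)] for e in events])
    return spots.SpotSet(coords, np.ones(len(coords)), shape)


class TestBuildKymograph:
    def test_static_spot_gives_uninterrupted_vertical_trace(self):
        cfg = synth.ImagingConfig(
            n_frames=100, height_px=64, width_px=64,
            photon_scale=0.0, read_noise_sd=0.0,
        )
        events = [
            synth.EventSpec(
                0, 20.0, 20.0, -1.0, 1000.0, amplitudes=(400.0, 400.0),
                rise_tau_s=0.1, fall_tau_s=0.1, fall_start_s=1000.0,
            ),
            synth.EventSpec(
                1, 44.0, 40.0, -1.0, 1000.0, amplitudes=(400.0, 400.0),
                rise_tau_s=0.1, fall_tau_s=0.1, fall_start_s=1000.0,
            ),
        ]
        movie = synth.render_movie(events, cfg)
        ss = spotset_from_events(events, (64, 64))
        kg = kymo.build_kymograph(movie.channel(0), ss, frame_interval_s=1.0)
        row = kg.intensity[kg.spot_path_indices[0]]
        assert np.all(row > cfg.background_level + 100)
        assert kg.intensity.shape[1] == 100

    def test_empty_movie_gives_uniform_background(self):
        frames = np.full((30, 48, 48), 7.0)
        ss = spots.SpotSet(np.array([[10, 10], [30, 35]]), np.ones(2), (48, 48))
        kg = kymo.build_kymograph(frames, ss)
        assert np.allclose(kg.intensity, 7.0)

    def test_fewer_than_two_spots_rejected(self):
        frames = np.zeros((10, 32, 32))
        ss = spots.SpotSet(np.array([[5, 5]]), np.ones(1), (32, 32))
        with pytest.raises(InputError):
            kymo.build_kymograph(frames, ss)

    def test_planted_event_occupies_expected_frames(self):
        cfg = synth.ImagingConfig(
            n_frames=60, height_px=64, width_px=64,
            photon_scale=0.0, read_noise_sd=0.0,
        )
        events = [
            synth.EventSpec(
                0, 15.0, 20.0, 10.0, 30.0, amplitudes=(500.0, 500.0),
                rise_tau_s=0.2, fall_tau_s=0.2,
            ),
            synth.EventSpec(
                1, 45.0, 40.0, 5.0, 20.0, amplitudes=(500.0, 500.0),
                rise_tau_s=0.2, fall_tau_s=0.2,
            ),
        ]
        movie = synth.render_movie(events, cfg)
        ss = spotset_from_events(events, (64, 64))
        kg = kymo.build_kymograph(movie.channel(0), ss, frame_interval_s=1.0)
        table = kymo.measure_lifetimes(kg, positions=kg.spot_path_indices)
        ev0 = table[table["path_position"] == kg.spot_path_indices[0]]
        assert len(ev0) == 1
        assert ev0["lifetime_s"].iloc[0] == pytest.approx(30.0, abs=1.0)

    def test_rows_match_independent_sampling_oracle(self, rng):
        # kymograph values vs a brute-force perpendicular-mean on 5 frames
        frames = rng.normal(50, 5, size=(20, 40, 40))
        ss = spots.SpotSet(np.array([[10, 5], [12, 30]]), np.ones(2), (40, 40))
        kg = kymo.build_kymograph(frames, ss, width_px=1)
        for t in rng.integers(0, 20, 5):
            for i, (r, c) in enumerate(kg.path):
                assert kg.intensity[i, t] == pytest.approx(frames[t, r, c])


class TestMeasureLifetimes:
    def _simple_kymo(self, runs, n_frames=100, dt=1.0, n_pos=40):
        mat = np.zeros((n_pos, n_frames))
        for pos, start, end in runs:
            mat[pos, start : end + 1] = 100.0
        path = np.column_stack([np.arange(n_pos), np.arange(n_pos)])
        return kymo.Kymograph(mat, path, 3, dt)

    def test_run_length_to_seconds_at_half_hertz(self):
        kg = self._simple_kymo([(5, 10, 39)], dt=2.0)
        table = kymo.measure_lifetimes(kg)
        assert table["lifetime_s"].iloc[0] == 60.0

    def test_short_event_fails_twenty_second_filter(self):
        # events must be LONGER than 20 s to be considered
        kg = self._simple_kymo([(5, 10, 17)], dt=1.0)
        table = kymo.measure_lifetimes(kg)
        assert table["lifetime_s"].iloc[0] == 8.0
        assert not table["passes_filter"].iloc[0]

    def test_exactly_twenty_seconds_fails_strict_filter(self):
        kg = self._simple_kymo([(5, 10, 29)], dt=1.0)
        table = kymo.measure_lifetimes(kg)
        assert table["lifetime_s"].iloc[0] == 20.0
        assert not table["passes_filter"].iloc[0]

    def test_censored_runs_flagged(self):
        kg = self._simple_kymo([(3, 0, 30), (8, 70, 99), (12, 40, 69)])
        table = kymo.measure_lifetimes(kg).sort_values("path_position")
        assert list(table["censored"]) == [True, True, False]

    def test_gap_shorter_than_min_gap_does_not_split(self):
        mat = np.zeros((10, 60))
        mat[4, 10:25] = 100.0
        mat[4, 26:40] = 100.0  # single-frame dropout at frame 25
        mat[4, 45:55] = 100.0  # 5-frame gap: separate event
        path = np.column_stack([np.arange(10), np.arange(10)])
        kg = kymo.Kymograph(mat, path, 3, 1.0)
        table = kymo.measure_lifetimes(kg, min_gap_frames=3)
        events = table[table["path_position"] == 4]
        assert len(events) == 2
        assert sorted(events["lifetime_s"]) == [10.0, 30.0]

    def test_planted_lifetimes_recovered_within_one_frame(self):
        # 500 planted events across movies, low noise
        recovered, planted = [], []
        for seed in range(14):
            cfg = synth.ImagingConfig(
                n_frames=120, height_px=220, width_px=220,
                read_noise_sd=1.0, rng_seed=100 + seed,
            )
            # sharp profile edges: the planted duration and the
            # supra-threshold duration coincide to within discretization
            events = synth.make_ccp_events(
                36, cfg, lifetime_mean_s=40.0, lifetime_sd_s=15.0,
                lifetime_bounds_s=(10.0, 100.0), margin_px=12,
                rise_tau_s=0.3, fall_tau_s=0.3, seed=200 + seed,
            )
            movie = synth.render_movie(events, cfg)
            ss = spotset_from_events(events, (220, 220))
            order = np.lexsort((ss.coords[:, 0], ss.coords[:, 1]))
            kg = kymo.build_kymograph(movie.channel(0), ss, frame_interval_s=1.0)
            table = kymo.measure_lifetimes(kg, positions=kg.spot_path_indices)
            for rank, ev_idx in enumerate(order):
                rows = table[table["path_position"] == kg.spot_path_indices[rank]]
                if len(rows) == 0:
                    continue
                # brief supra-threshold noise flickers fail the lifetime
                # filter downstream; the event is the brightest run
                best = rows.loc[rows["peak_intensity"].idxmax()]
                if best["censored"]:
                    continue
                recovered.append(best["lifetime_s"])
                planted.append(events[ev_idx].lifetime_s)
        recovered, planted = np.array(recovered), np.array(planted)
        assert len(recovered) >= 450
        within = np.abs(recovered - planted) <= 1.0
        assert within.mean() >= 0.95


class TestSummarizeLifetimes:
    def test_mean_and_sd_arithmetic(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "lifetime_s": [25.0, 35.0],
                "censored": [False, False],
                "passes_filter": [True, True],
            }
        )
        summary = kymo.summarize_lifetimes(table)
        assert summary.mean_s == 30.0
        assert summary.sd_s == pytest.approx(7.0710678)
        assert summary.n == 2

    def test_all_short_events_give_undefined_summary(self):
        import pandas as pd

        table = pd.DataFrame(
            {
                "lifetime_s": [8.0, 15.0, 20.0],
                "censored": [False] * 3,
                "passes_filter": [False] * 3,
            }
        )
        with pytest.raises(UndefinedResultError):
            kymo.summarize_lifetimes(table)

    def test_lifetimes_scale_linearly_with_frame_interval(self):
        mat = np.zeros((10, 60))
        mat[4, 10:40] = 100.0
        path = np.column_stack([np.arange(10), np.arange(10)])
        t1 = kymo.measure_lifetimes(kymo.Kymograph(mat, path, 3, 1.0))
        t2 = kymo.measure_lifetimes(kymo.Kymograph(mat, path, 3, 2.0))
        assert np.allclose(t2["lifetime_s"], 2.0 * t1["lifetime_s"])

    def test_censored_fraction_grows_with_planted_lifetime(self):
        fractions = []
        for mean_life in (25.0, 60.0):
            cfg = synth.ImagingConfig(
                n_frames=120, height_px=200, width_px=200, rng_seed=61
            )
            events = synth.make_ccp_events(
                25, cfg, lifetime_mean_s=mean_life, lifetime_sd_s=20.0,
                lifetime_bounds_s=(10.0, 200.0), edge_margin_s=-40.0, seed=62,
            )
            movie = synth.render_movie(events, cfg)
            ss = spotset_from_events(events, (200, 200))
            kg = kymo.build_kymograph(movie.channel(0), ss, frame_interval_s=1.0)
            table = kymo.measure_lifetimes(kg, positions=kg.spot_path_indices)
            fractions.append(table["censored"].mean())
        assert fractions[0] <= fractions[1]
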