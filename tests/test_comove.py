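"""Co-movement events: distances, run extraction, summaries, end-to-end recall."""

import numpy as np
import pandas as pd
import pytest

from chaperotrack import comove, pipeline
from chaperotrack.comove import ColocConfig, event_distance_stats, extract_events, \
    pair_distances, summarize_cells
from chaperotrack.simulate import DwellModel, SimConfig, simulate_movie


def track_df(points_by_track):
    rows = []
    for tid, pts in points_by_track.items():
        for f, (x, y) in enumerate(pts):
            rows.append((tid, f, x, y))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"])


def static_pair_distances(d, n_frames):
    """Distance table for one pair at constant separation d."""
    return pd.DataFrame({"track_a": 0, "track_b": 0,
                         "frame": np.arange(n_frames), "distance_um": d})


class TestPairDistances:
    def test_identical_tracks_zero(self):
        a = track_df({0: [(1.0, 2.0)] * 5})
        out = pair_distances(a, a.copy())
        assert np.allclose(out["distance_um"], 0.0)

    def test_three_four_five(self):
        a = track_df({0: [(0.0, 0.0)] * 4})
        b = track_df({0: [(0.3, 0.4)] * 4})
        out = pair_distances(a, b)
        assert np.allclose(out["distance_um"], 0.5)

    def test_matches_bruteforce_all_pairs(self):
        rng = np.random.default_rng(0)
        a = track_df({i: [tuple(rng.uniform(0, 5, 2)) for _ in range(8)]
                      for i in range(3)})
        b = track_df({i: [tuple(rng.uniform(0, 5, 2)) for _ in range(8)]
                      for i in range(2)})
        out = pair_distances(a, b)
        for row in out.itertuples():
            pa = a[(a.track_id == row.track_a) & (a.frame == row.frame)]
            pb = b[(b.track_id == row.track_b) & (b.frame == row.frame)]
            want = np.hypot(pa.x_um.iloc[0] - pb.x_um.iloc[0],
                            pa.y_um.iloc[0] - pb.y_um.iloc[0])
            assert row.distance_um == pytest.approx(want)
        assert len(out) == 3 * 2 * 8

    def test_missing_frames_absent(self):
        a = track_df({0: [(0, 0)] * 6})
        b = track_df({0: [(0, 0)] * 3})
        out = pair_distances(a, b)
        assert sorted(out["frame"]) == [0, 1, 2]


class TestExtractEvents:
    def test_twelve_frames_one_event(self):
        evs = extract_events(static_pair_distances(0.4, 12))
        assert len(evs) == 1
        assert evs[0].duration_s == pytest.approx(0.6)

    def test_nine_frames_below_minimum(self):
        """Runs shorter than 10 frames (500 ms) are discarded."""
        evs = extract_events(static_pair_distances(0.4, 9))
        assert evs == []

    def test_distance_exactly_at_threshold_breaks_run(self):
        """The colocalization rule is strict (< 0.5 µm)."""
        d = static_pair_distances(0.4, 12)
        d.loc[5, "distance_um"] = 0.5
        assert extract_events(d) == []

    def test_far_frame_splits_into_two_events(self):
        d = pd.concat([
            static_pair_distances(0.4, 12),
            pd.DataFrame({"track_a": [0], "track_b": [0], "frame": [12],
                          "distance_um": [0.8]}),
            static_pair_distances(0.4, 12).assign(frame=lambda x: x.frame + 13),
        ], ignore_index=True)
        evs = extract_events(d)
        assert len(evs) == 2
        assert all(ev.duration_s == pytest.approx(0.6) for ev in evs)

    def test_dropout_breaks_run(self):
        d = static_pair_distances(0.4, 25)
        d = d[d["frame"] != 12]
        evs = extract_events(d)
        assert len(evs) == 2

    def test_nearest_partner_rule(self):
        """A chaperone near two clients is paired with the nearer one only."""
        frames = np.arange(12)
        d = pd.concat([
            pd.DataFrame({"track_a": 0, "track_b": 0, "frame": frames,
                          "distance_um": 0.2}),
            pd.DataFrame({"track_a": 0, "track_b": 1, "frame": frames,
                          "distance_um": 0.4}),
        ], ignore_index=True)
        evs = extract_events(d)
        assert len(evs) == 1
        assert evs[0].client_track == 0

    def test_frame_conservation(self):
        """Event frames + discarded-run frames = all co-localized frames."""
        rng = np.random.default_rng(5)
        d = pd.DataFrame({
            "track_a": 0, "track_b": 0, "frame": np.arange(200),
            "distance_um": rng.uniform(0, 1, 200),
        })
        cfg = ColocConfig()
        evs = extract_events(d, cfg)
        coloc = (d["distance_um"] < cfg.max_distance).to_numpy()
        event_frames = sum(ev.n_frames for ev in evs)
        # recompute run-length decomposition independently
        runs, cur = [], 0
        for flag in coloc:
            if flag:
                cur += 1
            elif cur:
                runs.append(cur)
                cur = 0
        if cur:
            runs.append(cur)
        assert event_frames + sum(r for r in runs if r < cfg.min_frames) == coloc.sum()

    def test_threshold_monotonicity(self):
        """Wider radius or shorter minimum never yields fewer events."""
        rng = np.random.default_rng(6)
        d = pd.DataFrame({"track_a": 0, "track_b": 0, "frame": np.arange(400),
                          "distance_um": rng.uniform(0, 1.2, 400)})
        base = len(extract_events(d, ColocConfig()))
        wider = len(extract_events(d, ColocConfig(max_distance=0.8)))
        shorter = len(extract_events(d, ColocConfig(min_frames=5)))
        assert wider >= base
        assert shorter >= base

    def test_boundary_censoring_flag(self):
        d = static_pair_distances(0.4, 12)
        spans = {"a": {0: (0, 30)}, "b": {0: (0, 11)}}
        evs = extract_events(d, ColocConfig(), track_spans=spans)
        assert evs[0].boundary_censored
        evs2 = extract_events(d, ColocConfig(exclude_boundary_censored=True),
                              track_spans=spans)
        assert evs2 == []


class TestSummaries:
    def test_normalized_events(self):
        evs = extract_events(static_pair_distances(0.4, 12))
        by_cell = {i: evs * 3 for i in range(20)}   # 3 events in each of 20 cells
        _, norm = summarize_cells(by_cell, 20)
        assert norm == pytest.approx(3.0)
        _, norm0 = summarize_cells({0: []}, 4)
        assert norm0 == 0.0

    def test_normalized_equals_mean_when_all_cells_counted(self):
        ev = extract_events(static_pair_distances(0.4, 12))[0]
        by_cell = {0: [ev, ev], 1: [ev, ev, ev, ev]}
        summary, norm = summarize_cells(by_cell, 2)
        assert norm == pytest.approx(3.0)
        assert norm == pytest.approx(summary["n_events"].mean())

    def test_event_distance_stats(self):
        e1 = extract_events(static_pair_distances(0.1, 10))[0]
        e2 = extract_events(static_pair_distances(0.3, 10))[0]
        out = event_distance_stats([e1, e2])
        assert out["mean_distance_um"] == pytest.approx(0.2)
        single = event_distance_stats([extract_events(
            static_pair_distances(0.07, 10))[0]])
        assert single["mean_distance_um"] == pytest.approx(0.07)
        # oracle recomputation
        pooled = np.concatenate([e1.distances, e2.distances])
        assert out["mean_distance_um"] == pytest.approx(pooled.mean())
        with pytest.raises(ValueError):
            event_distance_stats([])


class TestEndToEnd:
    RECALL_CFG = dict(n_frames=500, n_chaperones=5, n_clients=5, k_on=100.0,
                      capture_radius=0.5, d_free=4.0, refractory_frames=25,
                      p_survive_frame=1.0, loc_sigma=0.02)

    def test_recall_and_duration_fidelity(self):
        """>=95% of fully visible true events >=0.75 s recovered within 2 frames."""
        tot_elig = tot_rec = tot_ok = 0
        for seed in range(5):
            cfg = SimConfig(**self.RECALL_CFG, seed=seed,
                            dwell_model=DwellModel(1.0))
            tracks, truth = simulate_movie(cfg)
            chap = tracks[tracks.channel == "chaperone"].drop(columns="channel")
            cli = tracks[tracks.channel == "client"].drop(columns="channel")
            evs = extract_events(pair_distances(chap, cli))
            rep = pipeline.recovery_report(truth, evs, min_frames=15)
            tot_elig += rep["n_true_eligible"]
            tot_rec += rep["recall"] * rep["n_true_eligible"]
            tot_ok += rep["recall_within_duration_tol"] * rep["n_true_eligible"]
        assert tot_elig >= 40
        assert tot_rec / tot_elig >= 0.95
        assert tot_ok / tot_elig >= 0.95

    def test_noise_free_completeness(self):
        """Without localization noise every eligible true event is recovered."""
        cfg = SimConfig(**{**self.RECALL_CFG, "loc_sigma": 0.0}, seed=9,
                        dwell_model=DwellModel(1.0))
        tracks, truth = simulate_movie(cfg)
        chap = tracks[tracks.channel == "chaperone"].drop(columns="channel")
        cli = tracks[tracks.channel == "client"].drop(columns="channel")
        evs = extract_events(pair_distances(chap, cli))
        rep = pipeline.recovery_report(truth, evs, min_frames=10)
        assert rep["n_true_eligible"] > 0
        assert rep["recall"] == 1.0

    def test_chance_colocalization_rate(self):
        """Non-interacting static particles: event count matches pi r^2 / A."""
        n_events = 0
        n_pairs = 0
        for seed in range(8):
            cfg = SimConfig(n_frames=20, n_chaperones=12, n_clients=12,
                            k_on=0.0, d_free=0.0, d_client=0.0, loc_sigma=0.0,
                            p_survive_frame=1.0, field_size=10.0, seed=100 + seed)
            tracks, _ = simulate_movie(cfg)
            chap = tracks[tracks.channel == "chaperone"].drop(columns="channel")
            cli = tracks[tracks.channel == "client"].drop(columns="channel")
            evs = extract_events(pair_distances(chap, cli),
                                 ColocConfig(nearest_partner_only=False))
            n_events += len(evs)
            n_pairs += 12 * 12
        expected = n_pairs * np.pi * 0.5**2 / 10.0**2
        assert expected / 2 <= n_events <= expected * 2
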