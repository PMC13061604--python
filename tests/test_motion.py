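"""MSD estimation, diffusion fitting, motion classes, rebinding cycles."""

import numpy as np
import pandas as pd
import pytest

from oracles import msd_double_loop
from chaperotrack.comove import ColocConfig, extract_events, pair_distances
from chaperotrack.motion import (
    MotionThresholds,
    classify_motion,
    find_rebind_cycles,
    fit_diffusion,
    msd,
    off_state_summary,
)
from chaperotrack.simulate import DwellModel, SimConfig, simulate_movie


def walk_df(xy):
    xy = np.asarray(xy, float)
    return pd.DataFrame({"track_id": 0, "frame": np.arange(len(xy)),
                         "x_um": xy[:, 0], "y_um": xy[:, 1]})


def brownian_xy(d, dt, n, seed):
    rng = np.random.default_rng(seed)
    steps = rng.normal(0, np.sqrt(2 * d * dt), (n, 2))
    return np.cumsum(steps, axis=0)


class TestMsd:
    def test_immobile_track_zero(self):
        curve = msd(walk_df(np.zeros((30, 2))), max_lag=5)
        assert np.allclose(curve, 0.0)

    def test_ballistic_identity(self):
        v = 0.2
        xy = np.stack([v * np.arange(40), np.zeros(40)], axis=1)
        curve = msd(walk_df(xy), max_lag=6)
        assert np.allclose(curve, (v * np.arange(1, 7)) ** 2)

    def test_equals_double_loop_oracle(self):
        xy = brownian_xy(0.5, 0.05, 48, seed=0)
        curve = msd(walk_df(xy), max_lag=10)
        assert np.allclose(curve, msd_double_loop(xy, 10))

    def test_short_track_rejected(self):
        with pytest.raises(ValueError):
            msd(walk_df(np.zeros((5, 2))), max_lag=10)

    def test_brownian_d_recovery_long_track(self):
        xy = brownian_xy(1.0, 0.05, 10_000, seed=1)
        curve = msd(walk_df(xy), max_lag=4)
        d, alpha = fit_diffusion(curve, 0.05, 4)
        assert d == pytest.approx(1.0, rel=0.10)


class TestFitDiffusion:
    def test_exact_linear_msd(self):
        dt = 0.05
        curve = 4 * 0.5 * np.arange(1, 7) * dt
        d, alpha = fit_diffusion(curve, dt, 4)
        assert d == pytest.approx(0.5, rel=1e-9)
        assert alpha == pytest.approx(1.0, abs=1e-9)

    def test_anomalous_exponent_from_loglog(self):
        dt = 0.05
        curve = 0.3 * (np.arange(1, 7) * dt) ** 0.5
        _, alpha = fit_diffusion(curve, dt, 4)
        assert alpha == pytest.approx(0.5, abs=1e-9)

    def test_noisy_brownian_with_localization_floor(self):
        """Localization noise adds an intercept; slope-based D stays within 15%."""
        loc = 0.02
        rng = np.random.default_rng(3)
        errs = []
        for seed in range(5):
            xy = brownian_xy(0.5, 0.05, 5000, seed=seed) + \
                rng.normal(0, loc, (5000, 2))
            curve = msd(walk_df(xy), max_lag=4)
            d, _ = fit_diffusion(curve, 0.05, 4)
            errs.append(abs(d - 0.5) / 0.5)
        assert np.median(errs) < 0.15

    def test_ensemble_median_centred_on_truth(self):
        ds = []
        for seed in range(100):
            xy = brownian_xy(0.8, 0.05, 200, seed=200 + seed)
            d, _ = fit_diffusion(msd(walk_df(xy), max_lag=4), 0.05, 4)
            ds.append(d)
        assert np.median(ds) == pytest.approx(0.8, rel=0.10)


class TestClassification:
    def test_immobile_is_stationary(self):
        curve = msd(walk_df(np.zeros((30, 2))), max_lag=4)
        d, alpha = fit_diffusion(curve, 0.05, 4)
        assert classify_motion(d, alpha) == "stationary"

    def test_brownian_is_diffusive(self):
        xy = brownian_xy(1.0, 0.05, 2000, seed=7)
        d, alpha = fit_diffusion(msd(walk_df(xy), max_lag=4), 0.05, 4)
        assert classify_motion(d, alpha) == "diffusive"

    def test_confined_walk_is_subdiffusive(self):
        """Reflected walk in a 0.2-µm box plateaus: alpha < 0.7 beyond corral time."""
        rng = np.random.default_rng(11)
        box = 0.2
        pos = np.full(2, box / 2)
        pts = []
        for _ in range(3000):
            pos = pos + rng.normal(0, np.sqrt(2 * 0.5 * 0.05), 2)
            pos = np.abs(pos) % (2 * box)
            pos = np.where(pos > box, 2 * box - pos, pos)
            pts.append(pos.copy())
        curve = msd(walk_df(np.array(pts)), max_lag=10)
        d, alpha = fit_diffusion(curve, 0.05, 10)
        assert alpha < 0.7
        assert classify_motion(d, alpha, MotionThresholds(n_fit_lags=10)) \
            in ("stationary", "sub-diffusive")

    def test_stationary_fraction_monotone_in_threshold(self):
        rng = np.random.default_rng(13)
        stats = []
        for seed in range(30):
            xy = brownian_xy(rng.uniform(0.001, 0.2), 0.05, 100, seed=500 + seed)
            stats.append(fit_diffusion(msd(walk_df(xy), max_lag=4), 0.05, 4))
        fracs = []
        for d_stat in (0.005, 0.02, 0.1):
            th = MotionThresholds(d_stationary=d_stat)
            fracs.append(np.mean([classify_motion(d, a, th) == "stationary"
                                  for d, a in stats]))
        assert fracs == sorted(fracs)


def synthetic_cycle_tracks():
    """Client at origin; chaperone: 12 on, 20 off (peaking 1.2 µm), 15 on."""
    frames = 12 + 20 + 15
    cli = pd.DataFrame({"track_id": 1, "frame": np.arange(frames),
                        "x_um": 0.0, "y_um": 0.0})
    x = np.concatenate([
        np.full(12, 0.01),
        0.55 + 0.65 * np.sin(np.linspace(0, np.pi, 20)),  # 0.55..1.2, all >= 0.5
        np.full(15, 0.01),
    ])
    chap = pd.DataFrame({"track_id": 0, "frame": np.arange(frames),
                         "x_um": x, "y_um": 0.0})
    return chap, cli


class TestRebinding:
    def test_constructed_cycle(self):
        chap, cli = synthetic_cycle_tracks()
        evs = extract_events(pair_distances(chap, cli))
        assert len(evs) == 2
        cycles, untrackable = find_rebind_cycles(evs, chap, cli)
        assert untrackable == 0
        assert len(cycles) == 1
        c = cycles[0]
        assert c.off_duration_s == pytest.approx(20 * 0.05)
        assert c.max_excursion_um == pytest.approx(1.2, abs=0.05)

    def test_single_event_no_cycle(self):
        chap, cli = synthetic_cycle_tracks()
        evs = extract_events(pair_distances(chap, cli))[:1]
        cycles, _ = find_rebind_cycles(evs, chap, cli)
        assert cycles == []

    def test_lost_chaperone_counted_untrackable(self):
        chap, cli = synthetic_cycle_tracks()
        chap = chap[(chap["frame"] < 15) | (chap["frame"] > 25)]
        evs = extract_events(pair_distances(chap, cli))
        assert len(evs) == 2
        cycles, untrackable = find_rebind_cycles(evs, chap, cli)
        assert cycles == []
        assert untrackable == 1

    def test_simulated_rebinding_against_truth_log(self):
        """Detected cycles correspond to true consecutive same-pair events."""
        n_cycles = n_false = 0
        for seed in range(4):
            cfg = SimConfig(n_frames=500, n_chaperones=4, n_clients=4,
                            k_on=100.0, capture_radius=0.5, d_free=4.0,
                            refractory_frames=25, p_survive_frame=1.0,
                            loc_sigma=0.02, seed=seed,
                            dwell_model=DwellModel(1.0))
            tracks, truth = simulate_movie(cfg)
            chap = tracks[tracks.channel == "chaperone"].drop(columns="channel")
            cli = tracks[tracks.channel == "client"].drop(columns="channel")
            evs = extract_events(pair_distances(chap, cli))
            cycles, _ = find_rebind_cycles(evs, chap, cli)
            # sub-threshold contacts (<10 frames) are non-specific by the
            # event definition, so cycles pair consecutive *eligible* events
            eligible = truth.events[
                truth.events.release_frame - truth.events.bind_frame + 1 >= 10]
            true_pairs = set()
            for (c_id, l_id), g in eligible.groupby(
                    ["chaperone_id", "client_id"]):
                g = g.sort_values("bind_frame")
                for a, b in zip(g.itertuples(), list(g.itertuples())[1:]):
                    true_pairs.add((c_id, l_id, a.release_frame, b.bind_frame))
            for cyc in cycles:
                ok = any(c == cyc.chaperone_track and l == cyc.client_track
                         and cyc.off_start >= rel and cyc.off_end <= bind
                         for c, l, rel, bind in true_pairs)
                n_cycles += 1
                n_false += not ok
        assert n_cycles >= 10
        assert n_false / n_cycles < 0.05


class TestOffStateSummary:
    def test_fraction_and_mean_excursion(self):
        chap, cli = synthetic_cycle_tracks()
        evs = extract_events(pair_distances(chap, cli))
        cycles, _ = find_rebind_cycles(evs, chap, cli)
        c = cycles[0]
        import copy
        c2 = copy.copy(c)
        c.max_excursion_um, c2.max_excursion_um = 0.5, 0.9
        c2.chaperone_track = 5
        out = off_state_summary([c, c2], n_trackable_off=10, n_all_trajectories=20)
        assert out["fraction_per_trackable_off"] == pytest.approx(0.2)
        assert out["fraction_per_all_trajectories"] == pytest.approx(0.1)
        assert out["mean_excursion_um"] == pytest.approx(0.7)

    def test_empty_cycles(self):
        out = off_state_summary([], n_trackable_off=5, n_all_trajectories=10)
        assert out["n_cycles"] == 0
        assert out["fraction_per_trackable_off"] == 0.0
        assert out["off_class_fractions"] == {}
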