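import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemotrax import (
    CalibrationMetadata,
    SimulationConfig,
    Spot,
    Track,
    compare_conditions,
    directionality_ratio,
    msd,
    plot_at_origin,
    regularize_track,
    simulate_tracks,
    summarize,
    track_speed,
)
from chemotrax.motility import MotilitySummary, track_msd

from conftest import straight_track, random_track


def summary_from_values(values, label=""):
    import pandas as pd

    df = pd.DataFrame(
        {
            "track_id": range(len(values)),
            "n_spots": 10,
            "duration_min": 20.0,
            "speed_um_per_min": values,
            "directionality": values,
        }
    )
    return MotilitySummary(per_track=df, msd=None, condition_label=label)


def loglog_slope(table):
    sel = table[(table.lag_min > 0) & (~table.low_confidence)]
    return np.polyfit(np.log(sel.lag_min), np.log(sel.msd_um2), 1)[0]


class TestRegularize:
    def test_gapless_track_unchanged(self, cal):
        tr = straight_track(n=5)
        assert regularize_track(tr, cal) is tr

    def test_simple_linear_interpolation(self, cal):
        tr = Track(0, [Spot(0, 0.0, 0.0, 5.0), Spot(2, 10.0, 4.0, 5.0)])
        reg = regularize_track(tr, cal)
        assert [s.frame for s in reg.spots] == [0, 1, 2]
        mid = reg.spots[1]
        assert (mid.x, mid.y) == (5.0, 2.0)
        assert mid.quality == 0.0  # interpolation flag
        assert reg.spots[0].quality == 5.0

    def test_random_gap_pattern_matches_closed_form(self, rng):
        frames = np.sort(rng.choice(np.arange(50), size=12, replace=False))
        xs = rng.uniform(0, 100, 12)
        ys = rng.uniform(0, 100, 12)
        tr = Track(0, [Spot(int(f), x, y) for f, x, y in zip(frames, xs, ys)])
        reg = regularize_track(tr)
        for s in reg.spots:
            i = np.searchsorted(frames, s.frame, side="right") - 1
            if frames[i] == s.frame:
                assert (s.x, s.y) == (xs[i], ys[i])
            else:
                w = (s.frame - frames[i]) / (frames[i + 1] - frames[i])
                assert s.x == pytest.approx(xs[i] + w * (xs[i + 1] - xs[i]))
                assert s.y == pytest.approx(ys[i] + w * (ys[i + 1] - ys[i]))


class TestSpeed:
    def test_ballistic_speed(self, cal):
        tr = straight_track(n=6, step=(10.0, 0.0))  # 10 um per 2 min frame
        assert track_speed(tr, cal) == pytest.approx(5.0)

    def test_stationary_track_has_zero_speed(self, cal):
        tr = Track(0, [Spot(0, 5.0, 5.0), Spot(1, 5.0, 5.0), Spot(2, 5.0, 5.0)])
        assert track_speed(tr, cal) == 0.0

    def test_matches_brute_force_summation(self, cal, rng):
        tr = random_track(rng, n=101)
        total = 0.0
        for a, b in zip(tr.spots, tr.spots[1:]):
            total += math.hypot(b.x - a.x, b.y - a.y)
        expect = total / (100 * cal.frame_interval)
        assert track_speed(tr, cal) == pytest.approx(expect, rel=1e-12)


class TestDirectionality:
    def test_straight_track_is_one(self):
        assert directionality_ratio(straight_track(n=10)) == pytest.approx(1.0)

    def test_out_and_back_is_zero(self):
        spots = [Spot(0, 0.0, 0.0), Spot(1, 30.0, 0.0), Spot(2, 0.0, 0.0)]
        assert directionality_ratio(Track(0, spots)) == pytest.approx(0.0)

    def test_right_angle_path(self):
        L = 13.0
        spots = [Spot(0, 0.0, 0.0), Spot(1, L, 0.0), Spot(2, L, L)]
        assert directionality_ratio(Track(0, spots)) == pytest.approx(1 / math.sqrt(2))

    def test_zero_path_is_undefined(self):
        tr = Track(0, [Spot(0, 1.0, 1.0), Spot(1, 1.0, 1.0)])
        assert math.isnan(directionality_ratio(tr))

    def test_bounded_in_unit_interval(self, rng):
        for i in range(50):
            d = directionality_ratio(random_track(rng, track_id=i))
            assert 0.0 <= d <= 1.0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        pts=st.lists(
            st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)),
            min_size=2, max_size=15,
        )
    )
    def test_ratio_in_unit_interval_for_any_path(self, pts):
        tr = Track(0, [Spot(i, x, y) for i, (x, y) in enumerate(pts)])
        d = directionality_ratio(tr)
        assert math.isnan(d) or 0.0 <= d <= 1.0 + 1e-12

    def test_deleting_interior_points_never_decreases_ratio(self, rng):
        # the provable core of why manually straightened tracks report
        # higher directionality: same endpoints, shorter measured path
        for i in range(100):
            tr = random_track(rng, track_id=i, n=30)
            d0 = directionality_ratio(tr)
            n_del = int(rng.integers(1, 20))
            keep_idx = sorted(
                {0, len(tr.spots) - 1}
                | set(rng.choice(np.arange(1, len(tr.spots) - 1),
                                 size=max(0, len(tr.spots) - 2 - n_del),
                                 replace=False).tolist())
            )
            sub = Track(i, [tr.spots[k] for k in keep_idx])
            assert directionality_ratio(sub) >= d0 - 1e-12


class TestMSD:
    def test_ballistic_msd_is_exact_quadratic(self, cal):
        v = 5.0  # um/min -> 10 um per frame
        tr = straight_track(n=21, step=(v * cal.frame_interval, 0.0))
        table = msd([tr], cal)
        for _, row in table[table.lag_min > 0].iterrows():
            expect = (v * row.lag_min) ** 2
            assert abs(row.msd_um2 - expect) / expect <= 1e-9

    def test_two_spot_track_single_lag(self, cal):
        tr = Track(0, [Spot(0, 0.0, 0.0), Spot(1, 3.0, 4.0)])
        table = msd([tr], cal)
        assert len(table) == 2  # lag 0 + one lag
        assert table.iloc[1].msd_um2 == pytest.approx(25.0)

    def test_lag_zero_and_track_count_monotone(self, cal, rng):
        tracks = [random_track(rng, i, n=int(rng.integers(5, 40))) for i in range(20)]
        table = msd(tracks, cal)
        assert table.iloc[0].msd_um2 == 0.0 and table.iloc[0].lag_min == 0.0
        n = table.n_tracks.to_numpy()
        assert (np.diff(n) <= 0).all()

    def test_overlapping_formula_matches_double_loop(self, cal, rng):
        tr = random_track(rng, n=40)
        fast = track_msd(tr, cal)
        pos = tr.positions
        for k in range(1, 40):
            acc = [
                (pos[t + k, 0] - pos[t, 0]) ** 2 + (pos[t + k, 1] - pos[t, 1]) ** 2
                for t in range(40 - k)
            ]
            assert fast[k - 1] == pytest.approx(np.mean(acc), rel=1e-12)

    def test_invariant_under_rigid_motion(self, cal, rng):
        tracks = [random_track(rng, i) for i in range(5)]
        theta, shift = 0.7, np.array([123.0, -45.0])
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = []
        for tr in tracks:
            pos = tr.positions @ R.T + shift
            moved.append(
                Track(tr.track_id, [
                    Spot(s.frame, float(p[0]), float(p[1])) for s, p in zip(tr.spots, pos)
                ])
            )
        a, b = msd(tracks, cal), msd(moved, cal)
        np.testing.assert_allclose(a.msd_um2, b.msd_um2, rtol=1e-9)
        for ta, tb in zip(tracks, moved):
            assert track_speed(ta, cal) == pytest.approx(track_speed(tb, cal))

    def test_ensemble_slopes_brownian_vs_ballistic(self, big_field_cal):
        common = dict(n_cells=200, image_size=(1024, 1024),
                      calibration=big_field_cal, n_frames=101, seed=3)
        brown = simulate_tracks(SimulationConfig(persistence_sd=20.0, **common))
        slope_b = loglog_slope(msd(brown.tracks, big_field_cal))
        assert 0.9 <= slope_b <= 1.1
        ball = simulate_tracks(
            SimulationConfig(bias_weight=1.0, speed_sd=0.0, persistence_sd=0.0, **common)
        )
        slope_l = loglog_slope(msd(ball.tracks, big_field_cal))
        assert 1.9 <= slope_l <= 2.1


class TestPlotAtOrigin:
    def test_series_limit_enforced(self, tmp_path):
        tracks = [straight_track(i, n=3) for i in range(257)]
        with pytest.raises(ValueError, match="subsample"):
            plot_at_origin(tracks, tmp_path / "p.png")
        out = plot_at_origin(tracks, tmp_path / "p.png", override_series_limit=True)
        assert out.exists()

    def test_alignment_is_translation_invariant(self, rng, tmp_path):
        tracks = [random_track(rng, i) for i in range(5)]
        shifted = [
            Track(t.track_id, [Spot(s.frame, s.x + 100.0, s.y - 50.0) for s in t.spots])
            for t in tracks
        ]
        for a, b in zip(tracks, shifted):
            np.testing.assert_allclose(
                a.positions - a.positions[0], b.positions - b.positions[0], atol=1e-9
            )
        assert plot_at_origin(tracks, tmp_path / "a.png").exists()


class TestCompareConditions:
    def test_identical_samples_not_significant(self, rng):
        vals = rng.uniform(0, 1, 12).tolist()
        r = compare_conditions(summary_from_values(vals), summary_from_values(vals))
        assert r.p_value > 0.99

    def test_fully_separated_exact_p(self, rng):
        a = summary_from_values(sorted(rng.uniform(0, 1, 10)))
        b = summary_from_values(sorted(rng.uniform(10, 11, 10)))
        r = compare_conditions(a, b)
        assert r.method == "exact"
        assert r.p_value == pytest.approx(2 / math.comb(20, 10), rel=1e-9)

    def test_u_statistic_matches_pairwise_count(self, rng):
        xa = rng.uniform(0, 1, 7)
        xb = rng.uniform(0, 1, 5)
        r = compare_conditions(summary_from_values(xa), summary_from_values(xb))
        u_brute = sum(1.0 for a in xa for b in xb if a > b) + 0.5 * sum(
            1.0 for a in xa for b in xb if a == b
        )
        assert r.u_statistic == pytest.approx(u_brute)

    def test_reports_mean_and_sem(self):
        a = summary_from_values([1.0, 2.0, 3.0])
        b = summary_from_values([4.0, 5.0, 6.0, 7.0])
        r = compare_conditions(a, b)
        assert r.mean_a == pytest.approx(2.0)
        assert r.sem_a == pytest.approx(np.std([1, 2, 3], ddof=1) / np.sqrt(3))
        assert (r.n_a, r.n_b) == (3, 4)

    def test_too_few_tracks_rejected(self):
        with pytest.raises(ValueError, match="3 tracks"):
            compare_conditions(summary_from_values([1, 2]), summary_from_values([1, 2, 3]))


class TestSummarize:
    def test_single_ballistic_track(self, cal):
        tr = straight_track(n=11, step=(10.0, 0.0))
        s = summarize([tr], cal, "demo")
        row = s.per_track.iloc[0]
        assert row.directionality == pytest.approx(1.0)
        assert row.speed_um_per_min == pytest.approx(5.0)
        assert s.condition_label == "demo"

    def test_large_population_row_count(self, big_field_cal):
        cfg = SimulationConfig(n_cells=120, image_size=(1024, 1024),
                               calibration=big_field_cal, seed=13)
        tracks = simulate_tracks(cfg).tracks
        s = summarize(tracks, big_field_cal)
        assert len(s.per_track) >= 100

    def test_biased_condition_has_higher_directionality(self, big_field_cal):
        common = dict(n_cells=100, image_size=(1024, 1024),
                      calibration=big_field_cal)
        s0 = summarize(
            simulate_tracks(SimulationConfig(bias_weight=0.0, seed=21, **common)).tracks,
            big_field_cal, "unbiased",
        )
        s1 = summarize(
            simulate_tracks(SimulationConfig(bias_weight=0.5, seed=22, **common)).tracks,
            big_field_cal, "biased",
        )
        assert s1.feature("directionality").mean() > s0.feature("directionality").mean()

    def test_writes_csv_summaries(self, cal, tmp_path, rng):
        tracks = [random_track(rng, i) for i in range(4)]
        summarize(tracks, cal, "cond", tmp_path)
        assert (tmp_path / "per_track_cond.csv").exists()
        assert (tmp_path / "msd_cond.csv").exists()
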