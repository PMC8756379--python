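"""C/N trajectory quantification: ratios, smoothing, pulses, AUC, classes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from erkscope.trajectories import (
    IntensityTimeSeries,
    Trajectory,
    TrajectoryError,
    TrajectoryFeatures,
    auc,
    classify,
    cn_at_time,
    compute_cn,
    compute_features,
    detect_pulses,
    peak_response,
    smooth,
    summarize_population,
)

from oracles import brute_force_pulses


def make_traj(cn, dt=1.0, smoothed=True, cell_id="c"):
    cn = np.asarray(cn, dtype=float)
    return Trajectory(cell_id, np.arange(len(cn)) * dt, cn, smoothed=smoothed)


# ---------------------------------------------------------------------------
# compute_cn
# ---------------------------------------------------------------------------

class TestComputeCN:
    @pytest.mark.parametrize(
        "cyto, nuc, bg, expected",
        [(200.0, 100.0, 0.0, 2.0), (300.0, 200.0, 100.0, 2.0)],
    )
    def test_background_subtracted_ratio(self, cyto, nuc, bg, expected):
        s = IntensityTimeSeries("c", [0.0, 1.0, 2.0], [nuc] * 3, [cyto] * 3, bg)
        traj = compute_cn(s)
        assert np.allclose(traj.cn, expected)

    def test_nonpositive_denominator_flags_frame(self):
        s = IntensityTimeSeries("c", [0.0, 1.0, 2.0],
                                [100.0, 100.0, 100.0],
                                [150.0, 150.0, 150.0],
                                np.array([0.0, 100.0, 0.0]))
        with pytest.warns(UserWarning, match="invalid frame"):
            traj = compute_cn(s)
        assert list(traj.excluded_frames) == [1]
        assert len(traj) == 2

    def test_all_invalid_raises_with_cell_name(self):
        s = IntensityTimeSeries("badcell", [0.0, 1.0], [50.0, 50.0],
                                [80.0, 80.0], 60.0)
        with pytest.raises(TrajectoryError, match="badcell"):
            compute_cn(s)

    def test_nonuniform_times_rejected(self):
        with pytest.raises(TrajectoryError, match="interval"):
            IntensityTimeSeries("c", [0.0, 1.0, 3.0], [1.0] * 3, [2.0] * 3)


# ---------------------------------------------------------------------------
# smooth
# ---------------------------------------------------------------------------

class TestSmooth:
    def test_three_point_mean_with_two_point_endpoints(self):
        traj = smooth(make_traj([1, 1, 4, 1, 1], smoothed=False))
        assert np.allclose(traj.cn, [1, 2, 2, 2, 1])
        assert traj.smoothed

    def test_constant_preserved(self):
        traj = smooth(make_traj([2.5] * 7, smoothed=False))
        assert np.allclose(traj.cn, 2.5)

    def test_linear_ramp_unchanged_interior(self):
        ramp = np.linspace(1.0, 2.0, 11)
        traj = smooth(make_traj(ramp, smoothed=False))
        assert np.allclose(traj.cn[1:-1], ramp[1:-1])

    def test_requires_three_frames(self):
        with pytest.raises(TrajectoryError, match=">=3"):
            smooth(make_traj([1.0, 2.0]))

    @given(st.lists(st.floats(min_value=0.1, max_value=10.0), min_size=3, max_size=40))
    def test_never_extends_range(self, values):
        traj = smooth(make_traj(values, smoothed=False))
        assert traj.cn.min() >= min(values) - 1e-12
        assert traj.cn.max() <= max(values) + 1e-12


# ---------------------------------------------------------------------------
# detect_pulses
# ---------------------------------------------------------------------------

class TestDetectPulses:
    def test_thirty_percent_peak_called(self):
        res = detect_pulses(make_traj([1.0, 1.0, 1.3, 1.0, 1.0]))
        assert list(res.pulse_indices) == [2]
        assert res.prominence[0] == pytest.approx(0.30)

    def test_nineteen_percent_peak_not_called(self):
        res = detect_pulses(make_traj([1.0, 1.0, 1.19, 1.0, 1.0]))
        assert res.n_pulses == 0

    def test_constant_has_no_pulses(self, flat_trajectory):
        assert detect_pulses(flat_trajectory).n_pulses == 0

    def test_threshold_must_be_positive(self, flat_trajectory):
        with pytest.raises(ValueError, match="positive"):
            detect_pulses(flat_trajectory, threshold=0.0)

    def test_larger_trough_mode_is_stricter(self):
        # peak 1.3 over troughs 1.0 (left) and 1.15 (right):
        # 30% over the smaller trough but only ~13% over the larger one
        cn = [1.0, 1.3, 1.15, 1.35, 1.1, 1.1]
        assert detect_pulses(make_traj(cn), mode="smaller").n_pulses >= 1
        res = detect_pulses(make_traj(cn), mode="larger")
        assert 1 not in list(res.pulse_indices)

    def test_plateau_first_frame_is_peak(self):
        res = detect_pulses(make_traj([1.0, 1.5, 1.5, 1.0, 1.0]))
        assert list(res.pulse_indices) == [1]

    @pytest.mark.parametrize("mode", ["smaller", "larger"])
    def test_matches_brute_force_oracle_on_short_grids(self, rng, mode):
        grid = np.array([1.0, 1.1, 1.2, 1.3, 1.5, 2.0])
        for _ in range(2000):
            n = rng.integers(3, 13)
            cn = grid[rng.integers(0, len(grid), size=n)]
            got = list(detect_pulses(make_traj(cn), mode=mode).pulse_indices)
            assert got == brute_force_pulses(cn, mode=mode)

    @given(
        st.lists(st.sampled_from([1.0, 1.1, 1.25, 1.6]), min_size=5, max_size=30),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_scale_invariance(self, values, k):
        t1 = detect_pulses(make_traj(values))
        t2 = detect_pulses(make_traj(np.asarray(values) * k))
        assert list(t1.pulse_indices) == list(t2.pulse_indices)

    def test_prominence_meets_threshold(self, rng):
        for _ in range(200):
            cn = 1.0 + rng.random(20)
            res = detect_pulses(make_traj(cn), threshold=0.15)
            assert (res.prominence >= 0.15 - 1e-12).all()
            assert (np.diff(res.pulse_indices) > 0).all()


# ---------------------------------------------------------------------------
# cn_at_time / auc / peak_response
# ---------------------------------------------------------------------------

class TestReadouts:
    def test_cn_at_time_constant(self, flat_trajectory):
        assert cn_at_time(flat_trajectory, 15.0) == pytest.approx(1.5)

    def test_cn_at_time_interior_window_is_21_frames_on_ramp(self):
        # 1-min frames: the +/-10 min window holds 21 frames, whose mean on
        # an affine signal equals the value at the window centre
        cn = 1.0 + 0.01 * np.arange(60)
        traj = make_traj(cn)
        assert cn_at_time(traj, 30.0) == pytest.approx(cn[30])

    def test_cn_at_time_clips_at_series_start(self):
        cn = 1.0 + 0.01 * np.arange(60)
        traj = make_traj(cn)
        assert cn_at_time(traj, 0.0) == pytest.approx(cn[:11].mean())

    def test_auc_four_frames_half_above_baseline(self):
        cn = np.array([1.0] * 5 + [1.5] * 4 + [1.0])
        traj = make_traj(cn)
        assert auc(traj, stim_time=4.0, window=(0.0, 4.0), baseline=1.0) \
            == pytest.approx(2.0)

    def test_auc_zero_at_baseline(self, flat_trajectory):
        assert auc(flat_trajectory, stim_time=5.0) == pytest.approx(0.0)

    def test_auc_empty_window_rejected(self, flat_trajectory):
        with pytest.raises(ValueError, match="window"):
            auc(flat_trajectory, stim_time=5.0, window=(10.0, 10.0))

    def test_auc_linearity_with_shared_baseline(self, rng):
        times = np.arange(50, dtype=float)
        x = 1.0 + rng.random(50)
        y = 1.0 + rng.random(50)
        a, b = 0.7, 1.3
        tx, ty = make_traj(x), make_traj(y)
        tz = Trajectory("z", times, a * x + b * y, smoothed=True)
        lhs = auc(tz, 10.0, (0.0, 30.0), baseline=a * 1.0 + b * 1.0)
        rhs = a * auc(tx, 10.0, (0.0, 30.0), baseline=1.0) \
            + b * auc(ty, 10.0, (0.0, 30.0), baseline=1.0)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_time_weighted_auc_scales_with_interval(self):
        cn = np.array([1.0] * 5 + [1.5] * 5)
        traj = make_traj(cn, dt=2.0)
        plain = auc(traj, 8.0, (0.0, 10.0), baseline=1.0)
        weighted = auc(traj, 8.0, (0.0, 10.0), baseline=1.0, time_weighted=True)
        assert weighted == pytest.approx(2.0 * plain)

    def test_peak_response_monotone_rise_gives_plateau(self):
        cn = np.concatenate([np.full(10, 1.0), np.linspace(1.0, 2.0, 10),
                             np.full(20, 2.0)])
        traj = make_traj(cn)
        assert peak_response(traj, stim_time=9.0) == pytest.approx(2.0)

    def test_peak_response_flat_returns_baseline(self, flat_trajectory):
        assert peak_response(flat_trajectory, stim_time=5.0) == pytest.approx(1.5)


# ---------------------------------------------------------------------------
# classify / summarize_population
# ---------------------------------------------------------------------------

def feats(cell_id, mean_cn, n_pulses, label=None):
    return TrajectoryFeatures(cell_id=cell_id, mean_cn=mean_cn,
                              n_pulses=n_pulses, class_label=label)


class TestClassification:
    def test_two_pulses_is_pulsing_regardless_of_mean(self):
        assert classify(feats("c", 0.1, 3)) == "pulsing"
        assert classify(feats("c", 99.0, 2), on_threshold=1.0) == "pulsing"

    def test_on_off_split_by_threshold(self):
        assert classify(feats("c", 1.4, 0), on_threshold=1.2) == "on"
        assert classify(feats("c", 1.1, 1), on_threshold=1.2) == "off"

    def test_missing_on_threshold_raises(self):
        with pytest.raises(ValueError, match="on_threshold"):
            classify(feats("c", 1.0, 1))

    def test_all_pulsing_population(self):
        s = summarize_population([feats(f"c{i}", 1.0, 2, "pulsing") for i in range(10)])
        assert s.class_fractions["all"] == {"on": 0.0, "pulsing": 1.0, "off": 0.0}

    def test_fold_change_between_conditions(self):
        s = summarize_population({
            "stiff": [feats("a", 2.0, 0, "on")],
            "soft": [feats("b", 1.0, 0, "off")],
        })
        assert s.fold_changes[("stiff", "soft")] == pytest.approx(2.0)

    def test_fractions_sum_to_one(self, rng):
        labels = ["on", "pulsing", "off"]
        pop = [feats(f"c{i}", rng.random() + 0.5,
                     2 if (lab := labels[rng.integers(3)]) == "pulsing" else 0, lab)
               for i in range(57)]
        s = summarize_population(pop)
        assert sum(s.class_fractions["all"].values()) == pytest.approx(1.0, abs=1e-9)

    def test_empty_population_rejected(self):
        with pytest.raises(ValueError):
            summarize_population([])


def test_compute_features_bundles_pulse_and_auc_readouts():
    cn = np.concatenate([np.full(30, 1.0), np.full(30, 1.6)])
    traj = make_traj(cn)
    f = compute_features(traj, stim_time=29.0, on_threshold=1.2,
                         cn_times=(50.0,))
    assert f.n_pulses == 0
    assert f.class_label in ("on", "off")
    assert f.auc_early is not None and f.auc_early > 0
    assert f.cn_at[50.0] == pytest.approx(1.6)
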