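"""Event detection, VF vectors, basic features and group statistics."""

import itertools

import numpy as np
import pytest

import gazefield as gf
from gazefield.gaze import compare_groups, detect_events, pearson_r


def _scripted_step(hold_ms=400, step_deg=5.0, step_ms=30):
    """Two holds separated by a smooth step traversed in ``step_ms`` ms."""
    t = np.arange(0, 2 * hold_ms + step_ms, 1.0)
    x = np.zeros(len(t))
    in_step = (t >= hold_ms) & (t < hold_ms + step_ms)
    phase = (t[in_step] - hold_ms) / step_ms
    x[in_step] = step_deg * 0.5 * (1 - np.cos(np.pi * phase))
    x[t >= hold_ms + step_ms] = step_deg
    return t, x, np.zeros(len(t))


class TestDetectEvents:
    def test_constant_position_is_one_fixation(self):
        t = np.arange(0, 1000, 1.0)
        fix, sac, gaps = detect_events(t, np.zeros(1000), np.zeros(1000))
        assert len(fix) == 1 and len(sac) == 0 and not gaps
        assert fix[0].duration == pytest.approx(1000.0)

    def test_five_degree_step_yields_two_fixations_one_saccade(self):
        t, x, y = _scripted_step()
        fix, sac, _ = detect_events(t, x, y)
        assert len(fix) == 2 and len(sac) == 1
        assert sac[0].amplitude == pytest.approx(5.0, abs=0.01)
        # hand-computed: velocity crosses 30 deg/s ~2 ms into the step
        assert sac[0].onset == pytest.approx(400, abs=4)
        assert sac[0].offset == pytest.approx(430, abs=4)

    def test_supra_threshold_velocity_and_acceleration_is_saccade(self):
        # 35 deg/s plateau reached with > 8000 deg/s^2 acceleration
        t = np.arange(0, 500, 1.0)
        v = np.where((t >= 200) & (t < 260), 35.0, 0.0)  # deg/s
        x = np.cumsum(v) / 1000.0
        fix, sac, _ = detect_events(t, x, np.zeros(len(t)))
        assert len(sac) == 1
        assert sac[0].peak_velocity > 30.0

    def test_all_nan_gaze_raises(self):
        t = np.arange(0, 100, 1.0)
        with pytest.raises(ValueError, match="NaN"):
            detect_events(t, np.full(100, np.nan), np.full(100, np.nan))

    def test_too_few_samples_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            fix, sac, gaps = detect_events(np.array([0.0]), np.array([0.0]),
                                           np.array([0.0]))
        assert fix == [] and sac == []

    def test_events_and_gaps_tile_the_trial_exactly(self):
        t, x, y = _scripted_step()
        x[500:540] = np.nan  # dropped samples
        fix, sac, gaps = detect_events(t, x, y)
        events = sorted(fix + sac, key=lambda e: e.onset)
        span = events[-1].offset - events[0].onset
        covered = sum(e.duration for e in events) + sum(b - a for a, b in gaps)
        assert covered == pytest.approx(span, abs=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_recovers_simulator_ground_truth(self, seed):
        """>= 95% of simulated events recovered with <= 1-sample boundaries."""
        track = gf.make_track(20.0, 0.5, seed=seed)
        fld = gf.make_field("normal", 0.0, noise_sd=0.0)
        trial = gf.simulate_trial(track, fld, gf.ObserverModel(),
                                  np.random.default_rng(seed))
        df = gf.emit_samples(trial)
        fix, sac, _ = detect_events(df["t_ms"].to_numpy(),
                                    df["x_deg"].to_numpy(),
                                    df["y_deg"].to_numpy())
        truth = sorted(trial.fixations + trial.saccades, key=lambda e: e.onset)
        hits = 0
        for ev in truth:
            pool = fix if isinstance(ev, gf.Fixation) else sac
            best = min(pool, key=lambda d: abs(d.onset - ev.onset))
            if (abs(best.onset - round(ev.onset)) <= 1.0 + 1e-9
                    and abs(best.offset - round(ev.offset)) <= 1.0 + 1e-9):
                hits += 1
        assert hits / len(truth) >= 0.95


class TestVFVectors:
    def test_leftward_step_is_negative_x(self):
        fixes = [gf.Fixation(0, 100, 10, 10), gf.Fixation(100, 200, 7, 10)]
        vec = gf.to_vf_vectors(fixes)
        assert vec.tolist() == [[-3.0, 0.0]]

    def test_downward_step_is_negative_y(self):
        fixes = [gf.Fixation(0, 100, 0, 0), gf.Fixation(100, 200, 0, -4)]
        assert gf.to_vf_vectors(fixes).tolist() == [[0.0, -4.0]]

    def test_identical_positions_give_zero_vector(self):
        fixes = [gf.Fixation(0, 100, 2, 3), gf.Fixation(100, 200, 2, 3)]
        assert gf.to_vf_vectors(fixes).tolist() == [[0.0, 0.0]]

    def test_fewer_than_two_fixations_empty(self):
        assert gf.to_vf_vectors([gf.Fixation(0, 100, 0, 0)]).shape == (0, 2)


class TestBasicFeatures:
    def test_median_of_known_durations(self):
        trial = gf.EventTrial("p", "c", fixations=[
            gf.Fixation(0, 200, 0, 0), gf.Fixation(200, 500, 0, 0),
            gf.Fixation(500, 900, 0, 0)])
        feats = gf.basic_features([trial])
        assert feats["fixation_duration_ms"] == pytest.approx(300.0)
        assert feats["n_fixations"] == 3

    def test_no_saccades_reports_undefined_not_zero(self):
        trial = gf.EventTrial("p", "c", fixations=[gf.Fixation(0, 100, 0, 0)])
        feats = gf.basic_features([trial])
        assert np.isnan(feats["saccade_amplitude_deg"])
        assert np.isnan(feats["saccade_peak_velocity_deg_s"])

    def test_matches_flat_recomputation_over_pooled_events(self, small_cohort):
        pid = small_cohort.participants("control")[0]
        trials = small_cohort.trials_of(pid)
        feats = gf.basic_features(trials)
        # independent flat oracle over the concatenated event list
        durs = [f.duration for t in trials for f in t.fixations]
        amps = [s.amplitude for t in trials for s in t.saccades]
        assert feats["fixation_duration_ms"] == pytest.approx(np.median(durs))
        assert feats["saccade_amplitude_deg"] == pytest.approx(np.median(amps))
        assert feats["n_fixations"] == len(durs)
        mean = gf.basic_features(trials, summary="mean")
        assert mean["saccade_amplitude_deg"] == pytest.approx(np.mean(amps))


def _exact_ranksum_p(a, b):
    """Exhaustive enumeration over all rank assignments (tie-free inputs)."""
    combined = np.concatenate([a, b])
    n1 = len(a)
    ranks = np.argsort(np.argsort(combined)) + 1.0
    observed = ranks[:n1].sum()
    total = 0
    extreme = 0
    mu = n1 * (len(combined) + 1) / 2.0
    for idx in itertools.combinations(range(len(combined)), n1):
        s = ranks[list(idx)].sum()
        total += 1
        if abs(s - mu) >= abs(observed - mu) - 1e-12:
            extreme += 1
    return extreme / total


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        res = compare_groups([1, 2, 3], [1, 2, 3], n_comparisons=1)
        assert res.p >= 0.99
        assert not res.significant

    @pytest.mark.parametrize("n_comp,alpha", [(4, 0.013), (3, 0.017), (1, 0.05)])
    def test_bonferroni_alpha_rounding(self, n_comp, alpha):
        res = compare_groups([1, 2, 3], [4, 5, 6], n_comparisons=n_comp)
        assert res.corrected_alpha == alpha

    @pytest.mark.parametrize("sizes", [(4, 4), (3, 5), (5, 6), (2, 6)])
    def test_matches_exhaustive_enumeration(self, sizes):
        rng = np.random.default_rng(sum(sizes))
        for _ in range(5):
            a = rng.normal(size=sizes[0])
            b = rng.normal(size=sizes[1])
            res = compare_groups(a, b)
            assert res.p == pytest.approx(_exact_ranksum_p(a, b), abs=1e-12)

    def test_all_tied_values_give_p_one(self):
        res = compare_groups([2.0, 2.0, 2.0], [2.0, 2.0], n_comparisons=1)
        assert res.p == 1.0 and res.z == 0.0

    def test_rejects_tiny_groups(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [2.0, 3.0])


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 50))
        expected = (np.mean((x - x.mean()) * (y - y.mean()))
                    / (x.std() * y.std()))
        assert pearson_r(x, y) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_is_undefined_with_warning(self):
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.isnan(pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]))
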