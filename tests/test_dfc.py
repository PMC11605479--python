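"""Scrubbing, sliding windows, state discovery, temporal metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import wmhtract as wt
from wmhtract.dfc import GAP, R_CLAMP, StateSequence, _runs, temporal_metrics
from wmhtract.exceptions import ConfigError, DataError, DegenerateError


def make_series(data, tr=2.5, fd=None, subject="S1"):
    return wt.SubjectSeries(subject=subject, data=np.asarray(data, float),
                            tr=tr, fd=fd)


class TestScrub:
    def test_zero_fd_flags_nothing(self):
        s = make_series(np.zeros((10, 3)), fd=np.zeros(10))
        out, report = wt.scrub(s)
        assert out.valid.all() and report["n_invalid"] == 0

    def test_limit_boundary_is_strict(self):
        s = make_series(np.zeros((3, 2)), fd=np.array([0.5, 1.0, 1.1]))
        out, report = wt.scrub(s)
        assert out.valid.tolist() == [True, True, False]
        assert report["n_invalid"] == 1

    def test_matches_per_frame_comparison_oracle(self, rng):
        fd = rng.uniform(0, 2, 50)
        s = make_series(rng.standard_normal((50, 4)), fd=fd)
        out, _ = wt.scrub(s)
        for i in range(50):
            assert out.valid[i] == (fd[i] <= 1.0)

    def test_high_motion_subject_flagged_for_exclusion(self):
        fd = np.full(10, 1.5)
        s = make_series(np.zeros((10, 2)), fd=fd)
        _, report = wt.scrub(s, max_invalid_frac=0.5)
        assert report["exclude"]

    def test_missing_fd_raises(self):
        s = make_series(np.zeros((10, 2)))
        with pytest.raises(DataError):
            wt.scrub(s)


class TestSlidingWindows:
    def test_window_count_arithmetic(self, rng):
        s = make_series(rng.standard_normal((180, 5)))
        stack = wt.sliding_windows(s, 50, 1)
        assert stack.n_windows == 131
        assert stack.vectors.shape == (131, 10)

    def test_identical_rois_give_clamped_fisher_z(self, rng):
        x = rng.standard_normal(60)
        s = make_series(np.column_stack([x, x]))
        stack = wt.sliding_windows(s, 30, 1)
        np.testing.assert_allclose(stack.vectors[:, 0], np.arctanh(R_CLAMP))

    def test_matches_explicit_correlation_oracle(self, rng):
        data = rng.standard_normal((60, 6))
        s = make_series(data)
        stack = wt.sliding_windows(s, 20, 1, fisher=False)
        iu = np.triu_indices(6, k=1)
        for t in range(stack.n_windows):
            r = np.corrcoef(data[t : t + 20], rowvar=False)[iu]
            np.testing.assert_allclose(stack.vectors[t], r, atol=1e-10)

    def test_window_longer_than_series_raises(self, rng):
        s = make_series(rng.standard_normal((30, 4)))
        with pytest.raises(ConfigError):
            wt.sliding_windows(s, 40)

    def test_scrubbed_frames_excluded_and_low_validity_flagged(self, rng):
        data = rng.standard_normal((40, 4))
        fd = np.zeros(40)
        fd[5:14] = 1.5  # 9 invalid frames
        s, _ = wt.scrub(make_series(data, fd=fd))
        stack = wt.sliding_windows(s, 20, 1)
        # window starting at 0 has 11/20 valid -> invalid at the 80% rule
        assert not stack.valid[0]
        assert stack.valid[-1]
        # correlations of a flagged window use only its valid frames
        sel = np.ones(40, bool); sel[5:14] = False
        frames = data[0:20][sel[0:20]]
        iu = np.triu_indices(4, k=1)
        expected = np.arctanh(np.clip(
            np.corrcoef(frames, rowvar=False)[iu], -R_CLAMP, R_CLAMP))
        np.testing.assert_allclose(stack.vectors[0], expected, atol=1e-10)


class TestFitStates:
    def test_identical_window_vectors_raise_degenerate(self):
        s = make_series(np.tile([1.0, 2.0, 3.0], (60, 1)) * 0 + 1.0)
        stack = wt.sliding_windows(s, 20)
        with pytest.raises(DegenerateError):
            wt.fit_states([stack], k_range=range(2, 4), seed=0)

    def test_fewer_windows_than_k_raises(self, rng):
        s = make_series(rng.standard_normal((21, 4)))
        stack = wt.sliding_windows(s, 20)  # 2 windows
        with pytest.raises(DataError):
            wt.fit_states([stack], k_range=range(2, 7), seed=0)

    def test_same_seed_reproduces_model(self, tiny_cfg, tiny_lesions):
        _, truth = tiny_lesions
        series, _ = wt.make_timeseries(tiny_cfg, truth.loads)
        stacks = [wt.sliding_windows(wt.scrub(s)[0], 30) for s in series[:6]]
        m1, q1 = wt.fit_states(stacks, k_range=range(2, 4), seed=3)
        m2, q2 = wt.fit_states(stacks, k_range=range(2, 4), seed=3)
        np.testing.assert_array_equal(m1.centroids, m2.centroids)
        for a, b in zip(q1, q2):
            np.testing.assert_array_equal(a.labels, b.labels)

    def test_three_separated_regimes_recovered(self):
        # three planted covariance regimes with slow switching: k-means at
        # the planted k recovers window labels near-perfectly on every
        # seed; the silhouette sweep prefers k = 3 on most seeds (its 2-vs-3
        # preference is marginal at this separation, see docs/methods.md)
        from sklearn.metrics import adjusted_rand_score

        chose_three = 0
        seeds = (4, 5, 6, 7)
        for seed in seeds:
            cfg = wt.SimulationConfig(
                seed=seed, n_patients=5, n_controls=3, grid_shape=(16, 16, 16),
                n_rois=50, n_volumes=300, planted_k=3, stay_prob=0.99,
            )
            atlas = wt.make_atlas(cfg)
            _, truth = wt.make_lesions(cfg, atlas)
            series, tst = wt.make_timeseries(cfg, truth.loads)
            stacks = [wt.sliding_windows(s) for s in series]
            model, _ = wt.fit_states(stacks, seed=seed)
            chose_three += model.chosen_k == 3
            _, seqs = wt.fit_states(stacks, k_range=[3], seed=seed)
            planted, est = [], []
            for s, q in zip(series, seqs):
                lab = wt.planted_window_labels(
                    tst.latent_sequences[s.subject], cfg.window_length
                )
                ok = (q.labels != GAP) & (lab > 0)
                planted.extend(lab[ok])
                est.extend(q.labels[ok])
            assert adjusted_rand_score(planted, est) >= 0.9, seed
        assert chose_three >= 3


class TestTemporalMetrics:
    @staticmethod
    def seq(labels, tr=2.5, step=1):
        return StateSequence(subject="S", labels=np.asarray(labels), tr=tr, step=step)

    def test_worked_example(self):
        m = temporal_metrics(self.seq([1, 1, 1, 2, 2, 1]), k=2)
        assert m["dwell_windows_1"] == pytest.approx(2.0)  # runs 3 and 1
        assert m["dwell_windows_2"] == pytest.approx(2.0)
        assert m["occupancy_1"] == pytest.approx(100 * 4 / 6)
        assert m["transitions"] == 2

    def test_constant_labels(self):
        m = temporal_metrics(self.seq([1] * 8), k=2)
        assert m["transitions"] == 0
        assert m["occupancy_1"] == pytest.approx(100.0)
        assert m["dwell_windows_1"] == pytest.approx(8.0)
        assert m["occupancy_2"] == 0.0
        assert np.isnan(m["dwell_windows_2"])

    def test_gap_breaks_runs_without_counting_transition(self):
        m = temporal_metrics(self.seq([1, 1, GAP, 2, 2]), k=2)
        assert m["transitions"] == 0
        assert m["dwell_windows_1"] == pytest.approx(2.0)
        assert m["dwell_windows_2"] == pytest.approx(2.0)
        assert m["occupancy_1"] == pytest.approx(50.0)

    def test_dwell_seconds_use_tr_and_step(self):
        m = temporal_metrics(self.seq([1, 1, 1, 1], tr=2.5, step=2), k=1)
        assert m["dwell_seconds_1"] == pytest.approx(4 * 2 * 2.5)

    def test_all_gaps_raises(self):
        with pytest.raises(DataError):
            temporal_metrics(self.seq([GAP, GAP]), k=2)

    def test_matches_independent_run_length_oracle(self, rng):
        # independent oracle: split on gaps, then itertools.groupby
        import itertools

        for _ in range(500):
            labels = rng.choice([GAP, 1, 2, 3], size=rng.integers(2, 40),
                                p=[0.15, 0.35, 0.35, 0.15])
            if (labels == GAP).all():
                continue
            m = temporal_metrics(self.seq(labels), k=3)
            segments = [
                list(g) for is_gap, g in itertools.groupby(labels, lambda x: x == GAP)
                if not is_gap
            ]
            runs = [
                (state, len(list(g)))
                for seg in segments
                for state, g in itertools.groupby(seg)
            ]
            n_valid = sum(length for _, length in runs)
            transitions = sum(
                len(list(itertools.groupby(seg))) - 1 for seg in segments
            )
            assert m["transitions"] == transitions
            for state in (1, 2, 3):
                lengths = [length for s, length in runs if s == state]
                occ = 100 * sum(lengths) / n_valid
                assert m[f"occupancy_{state}"] == pytest.approx(occ)
                if lengths:
                    assert m[f"dwell_windows_{state}"] == pytest.approx(
                        float(np.mean(lengths))
                    )
                else:
                    assert np.isnan(m[f"dwell_windows_{state}"])

    @given(
        st.lists(st.sampled_from([GAP, 1, 2]), min_size=1, max_size=60).filter(
            lambda ls: any(x != GAP for x in ls)
        )
    )
    def test_occupancy_sums_to_hundred_and_transition_bound(self, labels):
        m = temporal_metrics(self.seq(labels), k=2)
        total = m["occupancy_1"] + m["occupancy_2"]
        assert total == pytest.approx(100.0, abs=1e-9)
        n_valid = sum(1 for x in labels if x != GAP)
        assert 0 <= m["transitions"] <= max(n_valid - 1, 0)


class TestCompareTemporal:
    @staticmethod
    def metrics_frame(rows):
        return pd.DataFrame(rows)

    def test_identical_groups_give_unit_p(self, rng):
        rows = []
        for g, prefix in (("mTBI", "P"), ("HC", "C")):
            for i in range(10):
                rows.append({"subject": f"{prefix}{i}",
                             "occupancy_1": 50 + i, "occupancy_2": 50 - i,
                             "transitions": 5 + (i % 3)})
        metrics = self.metrics_frame(rows)
        cohort = pd.DataFrame({
            "subject": metrics["subject"],
            "group": ["mTBI"] * 10 + ["HC"] * 10,
        })
        out = wt.compare_temporal(metrics, cohort).set_index("metric")
        assert (out["p"] > 0.999).all()
        assert (out["p_fdr"] > 0.999).all()

    def test_planted_occupancy_difference_detected(self, rng):
        rows = []
        for i in range(15):
            rows.append({"subject": f"P{i}", "occupancy_2": 70 + rng.normal(0, 4),
                         "transitions": 5})
        for i in range(15):
            rows.append({"subject": f"C{i}", "occupancy_2": 50 + rng.normal(0, 4),
                         "transitions": 5})
        metrics = self.metrics_frame(rows)
        cohort = pd.DataFrame({"subject": metrics["subject"],
                               "group": ["mTBI"] * 15 + ["HC"] * 15})
        out = wt.compare_temporal(metrics, cohort).set_index("metric")
        assert out.loc["occupancy_2", "p_fdr"] < 0.05

    def test_single_subject_group_raises(self):
        metrics = self.metrics_frame(
            [{"subject": "P0", "occupancy_1": 60.0},
             {"subject": "C0", "occupancy_1": 50.0},
             {"subject": "C1", "occupancy_1": 55.0}]
        )
        cohort = pd.DataFrame({"subject": ["P0", "C0", "C1"],
                               "group": ["mTBI", "HC", "HC"]})
        with pytest.raises(DegenerateError):
            wt.compare_temporal(metrics, cohort)
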