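"""Generator correctness: determinism, planted structure, ground truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

import wmhtract as wt
from wmhtract.exceptions import ConfigError, SizingError
from wmhtract.registry import AFFECTED_TRACTS
from wmhtract.synth import CYTOKINES


def brute_force_load_ml(mask, atlas_map, voxel_volume):
    """Independent triple-loop oracle for the probability-weighted load."""
    s = 0.0
    nx, ny, nz = mask.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                if mask[i, j, k]:
                    s += atlas_map[i, j, k]
    return s * voxel_volume / 1000.0


class TestAtlas:
    def test_twenty_entries_with_probability_bounds(self):
        cfg = wt.SimulationConfig(seed=0, grid_shape=(32, 32, 32))
        atlas = wt.make_atlas(cfg)
        assert len(atlas) == 20
        assert set(atlas.names) == set(wt.TRACTS)
        for name in atlas.names:
            m = atlas.maps[name]
            assert m.min() >= 0 and m.max() <= 1
            assert m.sum() > 0

    def test_bit_identical_under_fixed_seed(self, tiny_cfg):
        a1, a2 = wt.make_atlas(tiny_cfg), wt.make_atlas(tiny_cfg)
        for name in a1.names:
            assert np.array_equal(a1.maps[name], a2.maps[name])

    def test_distinct_seeds_differ(self, tiny_cfg):
        import dataclasses

        other = dataclasses.replace(tiny_cfg, seed=tiny_cfg.seed + 1)
        a1, a2 = wt.make_atlas(tiny_cfg), wt.make_atlas(other)
        assert any(
            not np.array_equal(a1.maps[n], a2.maps[n]) for n in a1.names
        )

    def test_grid_too_small_raises_sizing_error(self):
        cfg = wt.SimulationConfig(seed=0, grid_shape=(8, 8, 8))
        with pytest.raises(SizingError):
            wt.make_atlas(cfg)


class TestLesions:
    def test_zero_intensity_gives_zero_loads(self, tiny_cfg, tiny_atlas):
        import dataclasses

        cfg = dataclasses.replace(
            tiny_cfg, lesion_intensity={"mTBI": 0.0, "HC": 0.0}
        )
        _, truth = wt.make_lesions(cfg, tiny_atlas)
        assert (truth.loads["wmh_ml"] == 0).all()
        assert (truth.loads["load_ratio_pct"] == 0).all()

    def test_planted_severe_patient_exceeds_every_control(self, tiny_lesions):
        _, truth = tiny_lesions
        ltr = truth.loads[truth.loads["tract"] == "LTR"].set_index("subject")
        severe = ltr.loc["P001", "wmh_ml"]
        controls = ltr[ltr.index.str.startswith("C")]["wmh_ml"]
        assert (severe > controls).all()

    def test_patient_mean_exceeds_control_mean_in_affected_tracts(self):
        cfg = wt.SimulationConfig(
            seed=11, n_patients=24, n_controls=20, grid_shape=(16, 16, 16)
        )
        atlas = wt.make_atlas(cfg)
        _, truth = wt.make_lesions(cfg, atlas)
        loads = truth.loads
        for tract in AFFECTED_TRACTS:
            t = loads[loads["tract"] == tract]
            pat = t["subject"].str.startswith("P")
            assert t[pat]["wmh_ml"].mean() > t[~pat]["wmh_ml"].mean(), tract

    def test_ground_truth_equals_bruteforce_voxel_loop(self, tiny_lesions, tiny_atlas):
        volumes, truth = tiny_lesions
        subject = "P002"
        mask = volumes[subject].values >= 0.8
        recorded = truth.loads[truth.loads["subject"] == subject].set_index("tract")
        for tract in ("LTR", "PCC", "LSLF"):
            oracle = brute_force_load_ml(
                mask, tiny_atlas.maps[tract], tiny_atlas.voxel_volume
            )
            got = recorded.loc[tract, "wmh_ml"]
            assert got == pytest.approx(oracle, rel=1e-9, abs=1e-12)


class TestTimeseries:
    def test_absorbing_chain_is_constant(self, tiny_cfg, tiny_lesions):
        import dataclasses

        _, truth = tiny_lesions
        cfg = dataclasses.replace(tiny_cfg, stay_prob=1 - 1e-12, occupancy_slope=0.0)
        _, tst = wt.make_timeseries(cfg, truth.loads)
        for seq in tst.latent_sequences.values():
            assert len(np.unique(seq)) == 1

    def test_state2_frames_have_stronger_interblock_correlation(self):
        cfg = wt.SimulationConfig(seed=0, n_rois=50)
        corrs = wt.state_correlations(cfg)
        rng = np.random.default_rng(0)
        sizes = [10] * 5
        edges = np.cumsum([0] + sizes)
        inter = ~np.asarray(
            [[any(edges[b] <= i < edges[b + 1] and edges[b] <= j < edges[b + 1]
                  for b in range(5)) for j in range(50)] for i in range(50)]
        )
        means = []
        for C in corrs:
            frames = rng.standard_normal((3000, 50)) @ np.linalg.cholesky(C).T
            r = np.corrcoef(frames, rowvar=False)
            means.append(np.abs(r[inter]).mean())
        assert means[1] > means[0]

    def test_requested_nonpd_covariance_raises_in_strict_mode(self):
        cfg = wt.SimulationConfig(seed=0, n_rois=50)
        with pytest.raises(ConfigError):
            wt.state_correlations(cfg, strict=True)

    def test_fd_fraction_zero_means_no_spikes(self, tiny_cfg, tiny_lesions):
        import dataclasses

        _, truth = tiny_lesions
        cfg = dataclasses.replace(tiny_cfg, fd_spike_frac=0.0)
        series, _ = wt.make_timeseries(cfg, truth.loads)
        for s in series:
            assert (s.fd <= 1.0).all()

    def test_fd_fraction_respected(self, tiny_cfg, tiny_lesions):
        import dataclasses

        _, truth = tiny_lesions
        cfg = dataclasses.replace(tiny_cfg, fd_spike_frac=0.1)
        series, _ = wt.make_timeseries(cfg, truth.loads)
        for s in series:
            assert (s.fd > 1.0).sum() == round(0.1 * cfg.n_volumes)

    def test_state2_occupancy_monotone_in_planted_load(self):
        # the planted link: state-2 persistence grows with LTR load, so
        # latent occupancy correlates positively across >= 30 subjects
        cfg = wt.SimulationConfig(
            seed=5, n_patients=24, n_controls=16, grid_shape=(16, 16, 16),
            n_volumes=360,
        )
        atlas = wt.make_atlas(cfg)
        _, truth = wt.make_lesions(cfg, atlas)
        _, tst = wt.make_timeseries(cfg, truth.loads)
        ltr = truth.loads.query("tract=='LTR'").set_index("subject")["wmh_ml"]
        subjects = list(tst.latent_sequences)
        occ = [float((tst.latent_sequences[s] == 2).mean()) for s in subjects]
        rho = spearmanr(ltr.reindex(subjects).to_numpy(), occ).statistic
        assert rho > 0

    def test_stay2_link_is_monotone_and_clipped(self):
        cfg = wt.SimulationConfig(seed=0)
        vals = [wt.stay2_probability(cfg, x) for x in (0.0, 0.5, 1.0, 5.0)]
        assert vals == sorted(vals)
        assert 0.5 < min(vals) and max(vals) <= 0.99


class TestCohortTable:
    def test_noise_free_slope_is_exact(self, tiny_atlas, tiny_cfg):
        import dataclasses

        cfg = dataclasses.replace(
            tiny_cfg,
            noise_sd={k: 0.0 for k in ("tmta", "dsc", "fds", "bds", "vf")},
            covariate_effect_scale=0.0,
        )
        _, truth = wt.make_lesions(cfg, tiny_atlas)
        table, ct = wt.make_cohort_table(cfg, truth.loads)
        df = table[table["group"] == "mTBI"].merge(
            truth.loads.query("tract=='LTR'")[["subject", "wmh_ml"]], on="subject"
        )
        res = wt.adjusted_association(df, "tmta", "wmh_ml")
        assert res.slope == pytest.approx(ct.slopes["tmta"], abs=1e-8)
        assert res.ci_high - res.ci_low == pytest.approx(0.0, abs=1e-8)

    def test_patients_slower_than_controls_on_processing_speed(self, tiny_cfg, tiny_lesions):
        _, truth = tiny_lesions
        table, _ = wt.make_cohort_table(tiny_cfg, truth.loads)
        g = table.groupby("group")["tmta"].mean()
        assert g["mTBI"] > g["HC"]

    def test_cytokine_columns_present_and_positive(self, tiny_cfg, tiny_lesions):
        _, truth = tiny_lesions
        table, _ = wt.make_cohort_table(tiny_cfg, truth.loads)
        for c in CYTOKINES:
            assert (table[c] > 0).all()


class TestProfilesGenerator:
    def test_planted_effect_and_bounds(self, tiny_cfg):
        labels = pd.Series(
            ["sWMH"] * 6 + ["mWMH"] * 6 + ["HC"] * 6,
            index=[f"S{i}" for i in range(18)],
        )
        profs, truth = wt.make_profiles(tiny_cfg, labels)
        node_cols = [c for c in profs.columns if c.startswith("node_")]
        assert len(node_cols) == 100
        vals = profs[node_cols].to_numpy()
        assert vals.min() >= 0 and vals.max() <= 1
        lo, hi = truth.profile_effect_nodes
        inside = [f"node_{j}" for j in range(lo, hi + 1)]
        sev = profs[profs["subgroup"] == "sWMH"][inside].to_numpy().mean()
        hc = profs[profs["subgroup"] == "HC"][inside].to_numpy().mean()
        assert sev - hc > 0.05


def test_simulate_cohort_is_deterministic(tiny_cfg):
    c1, c2 = wt.simulate_cohort(tiny_cfg), wt.simulate_cohort(tiny_cfg)
    pd.testing.assert_frame_equal(c1.truth.loads, c2.truth.loads)
    pd.testing.assert_frame_equal(c1.cohort, c2.cohort)
    for s1, s2 in zip(c1.series, c2.series):
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(s1.fd, s2.fd)
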