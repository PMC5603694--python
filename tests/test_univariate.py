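"""Univariate stages: masks, GLM/LSS estimation, group statistics, and
cluster-extent correction."""

import numpy as np
import pytest
from scipy import stats

from affectmvpc import synthetic, univariate
from affectmvpc.datasets import EventDesign, VolumeGeometry
from affectmvpc.univariate import TMap


class TestGroupGMMask:
    def test_identical_masks_pass_through(self, rng):
        m = rng.random(50) < 0.7
        group = univariate.build_group_gm_mask([m, m, m])
        np.testing.assert_array_equal(group.include, m)

    def test_half_fraction_is_inclusive_union_for_two_disjoint(self):
        a = np.array([True, False, True, False])
        b = np.array([False, True, False, False])
        group = univariate.build_group_gm_mask([a, b], include_fraction=0.5)
        np.testing.assert_array_equal(group.include, a | b)

    def test_group_vote_denoises_flips(self):
        # binomial tail: P(>=16 of 32 flips) at rate 0.1 is ~1e-10 per
        # voxel, so virtually every voxel matches the template
        geom = VolumeGeometry((10, 10, 10))
        template, masks = synthetic.generate_gm_masks(32, geom, flip_rate=0.1, seed=4)
        group = univariate.build_group_gm_mask(list(masks), 0.5)
        assert (group.include == template).mean() >= 0.99

    def test_leave_one_out_masks_exclude_held_out_subject(self):
        masks = [np.array([True, False]), np.array([False, True]), np.array([False, True])]
        loo = univariate.leave_one_out_gm_masks(masks, include_fraction=0.5)
        np.testing.assert_array_equal(loo[0], np.array([False, True]))

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError):
            univariate.build_group_gm_mask([np.ones(4, bool), np.ones(5, bool)])


class TestDilateMask:
    def test_interior_voxel_counts(self):
        geom = VolumeGeometry((5, 5, 5))
        mask = np.zeros(geom.n_voxels, bool)
        mask[geom.ravel(_point_volume(geom, (2, 2, 2))).argmax()] = True
        assert univariate.dilate_mask(mask, 1, geom).sum() == 7
        assert univariate.dilate_mask(mask, 2, geom).sum() == 25

    def test_brute_force_two_step_dilation(self):
        # oracle: two successive 6-neighbour expansions on a 5x5x5 grid
        geom = VolumeGeometry((5, 5, 5))
        mask = np.zeros(geom.grid_shape, bool)
        mask[2, 2, 2] = True
        expected = _brute_dilate(_brute_dilate(mask))
        got = univariate.dilate_mask(mask.reshape(-1), 2, geom)
        np.testing.assert_array_equal(got, expected.reshape(-1))

    def test_empty_mask_stays_empty(self):
        geom = VolumeGeometry((4, 4, 4))
        assert univariate.dilate_mask(np.zeros(64, bool), 1, geom).sum() == 0


def _point_volume(geom, idx):
    v = np.zeros(geom.grid_shape)
    v[idx] = 1.0
    return v


def _brute_dilate(vol):
    out = vol.copy()
    nx, ny, nz = vol.shape
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if vol[x, y, z]:
                    for dx, dy, dz in [(1,0,0),(-1,0,0),(0,1,0),(0,-1,0),(0,0,1),(0,0,-1)]:
                        i, j, k = x+dx, y+dy, z+dz
                        if 0 <= i < nx and 0 <= j < ny and 0 <= k < nz:
                            out[i, j, k] = True
    return out


class TestGLMAndLSS:
    def _sep_design(self, betas):
        n = len(betas)
        return EventDesign(
            onsets_s=np.arange(n) * 40.0 + 10.0,
            durations_s=np.full(n, 2.5),
            stim_ids=[f"s{i}" for i in range(n)],
            tr_s=2.0,
            n_volumes=int((10 + n * 40 + 20) / 2),
        )

    def test_lss_recovers_planted_betas_on_separated_trials(self):
        planted = np.array([1.0, 2.0, 3.0])
        d = self._sep_design(planted)
        ts = synthetic.generate_event_timeseries(d, planted)
        lss = univariate.fit_lss_betas(ts, d, drift_order=None)
        np.testing.assert_allclose(lss, planted, atol=1e-6)
        # oracle: with disjoint regressor supports LSS equals trial-wise
        # projection <r_i, y> / <r_i, r_i>
        for i in range(3):
            r_i = synthetic.hrf_convolved_regressor(
                d.onsets_s[[i]], d.durations_s[[i]], np.ones(1), d.frame_times
            )
            assert lss[i] == pytest.approx(float(r_i @ ts / (r_i @ r_i)), abs=1e-9)

    def test_lss_zero_betas_yield_zero(self):
        d = self._sep_design(np.zeros(3))
        ts = synthetic.generate_event_timeseries(d, np.zeros(3))
        np.testing.assert_allclose(univariate.fit_lss_betas(ts, d, drift_order=None), 0.0, atol=1e-10)

    def test_lss_class_means_match_condition_glm_contrast(self):
        betas = np.array([1.5, 0.5, 1.5, 0.5, 1.5, 0.5])
        d = self._sep_design(betas)
        cond = {f"s{i}": ("V_pos" if i % 2 == 0 else "V_neg") for i in range(6)}
        ts = synthetic.generate_event_timeseries(d, betas)
        _, contrast = univariate.fit_condition_glm(ts, d, cond, drift_order=None)
        lss = univariate.fit_lss_betas(ts, d, drift_order=None)
        lss_contrast = lss[::2].mean() - lss[1::2].mean()
        assert lss_contrast == pytest.approx(contrast, abs=1e-6)

    def test_condition_glm_with_drift_and_overlap(self):
        # jittered overlapping design, planted condition betas (1.5, 0.5)
        stim_ids = [f"s{i}" for i in range(10)]
        cond = {s: ("V_pos" if i % 2 == 0 else "V_neg") for i, s in enumerate(stim_ids)}
        d = synthetic.generate_event_design(stim_ids, seed=4)
        tb = np.array([1.5 if i % 2 == 0 else 0.5 for i in range(10)])
        drift = np.array([0.4, -0.3, 0.2])
        ts = synthetic.generate_event_timeseries(d, tb, drift_coefs=drift)
        betas, contrast = univariate.fit_condition_glm(ts, d, cond, drift_order=2)
        assert betas["V_pos"] == pytest.approx(1.5, abs=1e-8)
        assert contrast == pytest.approx(1.0, abs=1e-8)

    def test_equal_condition_betas_give_zero_contrast(self):
        stim_ids = [f"s{i}" for i in range(6)]
        cond = {s: ("A_high" if i < 3 else "A_low") for i, s in enumerate(stim_ids)}
        d = synthetic.generate_event_design(stim_ids, seed=9)
        ts = synthetic.generate_event_timeseries(d, np.full(6, 0.8))
        _, contrast = univariate.fit_condition_glm(ts, d, cond)
        assert contrast == pytest.approx(0.0, abs=1e-8)

    def test_all_zero_series_gives_zero_betas(self):
        stim_ids = [f"s{i}" for i in range(4)]
        cond = {s: ("V_pos" if i < 2 else "V_neg") for i, s in enumerate(stim_ids)}
        d = synthetic.generate_event_design(stim_ids, seed=2)
        betas, _ = univariate.fit_condition_glm(np.zeros(d.n_volumes), d, cond)
        assert betas["V_pos"] == pytest.approx(0.0, abs=1e-12)


class TestGroupTTest:
    def test_antisymmetric_pair_gives_zero(self):
        tmap = univariate.group_ttest_map(np.array([[1.0], [-1.0]]))
        assert tmap.t[0] == 0.0

    def test_zero_variance_flagged_not_infinite(self):
        tmap = univariate.group_ttest_map(np.full((32, 2), 0.7))
        assert tmap.degenerate.all()
        assert np.isfinite(tmap.t).all()

    def test_matches_closed_form_oracle(self, rng):
        x = rng.standard_normal((8, 20))
        tmap = univariate.group_ttest_map(x)
        n = 8
        expected = x.mean(0) / (x.std(0, ddof=1) / np.sqrt(n))
        np.testing.assert_allclose(tmap.t, expected, atol=1e-10)
        assert tmap.df == 7
        # and scipy agrees
        sp = stats.ttest_1samp(x, 0.0, axis=0).statistic
        np.testing.assert_allclose(tmap.t, sp, atol=1e-10)

    def test_hand_computed_example(self):
        vals = np.array([[0.2], [0.5], [0.1], [0.4]])
        t = univariate.group_ttest_map(vals).t[0]
        assert t == pytest.approx(0.3 / (np.std(vals, ddof=1) / 2.0), abs=1e-12)


class TestCriticalT:
    def test_reference_value_df31(self):
        assert univariate.critical_t(31, 0.001) == pytest.approx(3.63, abs=0.005)

    def test_cauchy_quartile(self):
        assert univariate.critical_t(1, 0.5) == pytest.approx(1.0, abs=1e-9)

    def test_normal_limit(self):
        assert univariate.critical_t(10**6, 0.05) == pytest.approx(1.96, abs=0.001)

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            univariate.critical_t(10, 0.0)


class TestMinClusterSize:
    def test_alpha_monotonicity(self, small_geometry):
        mask = np.ones(small_geometry.n_voxels, bool)
        k_loose = univariate.estimate_min_cluster_size(
            small_geometry, 0.0, mask, p_voxel=0.01, alpha=0.99, n_iter=200, seed=1
        )
        k_tight = univariate.estimate_min_cluster_size(
            small_geometry, 0.0, mask, p_voxel=0.01, alpha=0.05, n_iter=200, seed=1
        )
        assert k_loose <= k_tight

    def test_iid_noise_small_mask_needs_few_voxels(self, small_geometry):
        # with independent voxels at p=0.001 on 216 voxels, even the
        # maximum cluster rarely exceeds a couple of voxels
        mask = np.ones(small_geometry.n_voxels, bool)
        k = univariate.estimate_min_cluster_size(
            small_geometry, 0.0, mask, p_voxel=0.001, alpha=0.05, n_iter=2000, seed=3
        )
        assert k <= 3

    def test_k_min_nondecreasing_in_smoothness(self, small_geometry):
        mask = np.ones(small_geometry.n_voxels, bool)
        ks = [
            univariate.estimate_min_cluster_size(
                small_geometry, fwhm, mask, p_voxel=0.01, alpha=0.05, n_iter=300, seed=5
            )
            for fwhm in (0.0, 6.0, 12.0)
        ]
        assert ks[0] <= ks[1] <= ks[2]

    def test_empty_mask_rejected(self, small_geometry):
        with pytest.raises(ValueError):
            univariate.estimate_min_cluster_size(
                small_geometry, 6.0, np.zeros(small_geometry.n_voxels, bool), n_iter=100
            )


class TestExtractClusters:
    def _tmap_with_line(self, geom, n_voxels, value=5.0):
        t = np.zeros(geom.grid_shape)
        # a face-connected snake of n voxels
        coords = [(i % geom.grid_shape[0], i // geom.grid_shape[0], 0) for i in range(n_voxels)]
        for c in coords:
            t[c] = value
        return TMap(t=t.reshape(-1), df=31, degenerate=np.zeros(geom.n_voxels, bool))

    def test_fourteen_voxel_component_survives_k128(self):
        geom = VolumeGeometry((8, 8, 8))
        cs = univariate.extract_clusters(self._tmap_with_line(geom, 14), 3.63, 12.8, geom)
        assert len(cs) == 1 and cs.clusters[0].size == 14

    def test_twelve_voxel_component_removed_at_k128(self):
        geom = VolumeGeometry((8, 8, 8))
        cs = univariate.extract_clusters(self._tmap_with_line(geom, 12), 3.63, 12.8, geom)
        assert len(cs) == 0

    def test_adjacent_opposite_signs_form_separate_clusters(self):
        geom = VolumeGeometry((6, 6, 6))
        t = np.zeros(geom.grid_shape)
        t[1:3, 1, 1] = 5.0
        t[3:5, 1, 1] = -5.0
        cs = univariate.extract_clusters(
            TMap(t=t.reshape(-1), df=31, degenerate=np.zeros(geom.n_voxels, bool)),
            3.0,
            1.0,
            geom,
        )
        assert len(cs) == 2
        assert sorted(c.sign for c in cs.clusters) == [-1, 1]

    def test_partition_and_threshold_invariants(self, rng):
        geom = VolumeGeometry((7, 7, 7))
        t = rng.standard_normal(geom.n_voxels) * 3
        cs = univariate.extract_clusters(
            TMap(t=t, df=20, degenerate=np.zeros(geom.n_voxels, bool)), 4.0, 1.0, geom
        )
        labeled = cs.labels > 0
        assert np.all(np.abs(t[labeled]) >= 4.0)
        sizes = [c.size for c in cs.clusters]
        assert sizes == sorted(sizes, reverse=True)
        assert sum(sizes) == labeled.sum()

    def test_center_of_mass_in_mm(self):
        geom = VolumeGeometry((6, 6, 6), voxel_size_mm=(3.0, 3.0, 3.0))
        t = np.zeros(geom.grid_shape)
        t[2, 3, 4] = 6.0
        t[3, 3, 4] = 6.0
        cs = univariate.extract_clusters(
            TMap(t=t.reshape(-1), df=31, degenerate=np.zeros(geom.n_voxels, bool)), 3.0, 1.0, geom
        )
        assert cs.clusters[0].center_of_mass_mm == pytest.approx((7.5, 9.0, 12.0))


class TestBetaseriesValidation:
    def test_identical_maps_correlate_perfectly(self, rng):
        maps = rng.standard_normal((4, 30))
        sel = np.ones(30, bool)
        r, _ = univariate.validate_betaseries(maps, maps, sel)
        assert r == pytest.approx(1.0)
        r_neg, _ = univariate.validate_betaseries(maps, -maps, sel)
        assert r_neg == pytest.approx(-1.0)

    def test_estimators_agree_on_planted_signal(self, small_signal_dataset, stimulus_labels):
        from affectmvpc.pipeline import subject_contrast_maps

        data = small_signal_dataset
        contrasts = subject_contrast_maps(data, stimulus_labels, "valence")
        tmap = univariate.group_ttest_map(contrasts)
        loo = univariate.leave_one_out_gm_masks(data.gm_masks)
        sel = univariate.select_validation_voxels(tmap, 3.0, loo)
        if sel.sum() >= 3:
            # same planted contrast measured twice, with independent noise
            noisy = contrasts + np.random.default_rng(0).normal(0, 0.1, contrasts.shape)
            r, p = univariate.validate_betaseries(noisy, contrasts, sel)
            assert r > 0.9

    def test_empty_selection_rejected(self, rng):
        with pytest.raises(ValueError):
            univariate.validate_betaseries(
                rng.standard_normal((3, 10)), rng.standard_normal((3, 10)), np.zeros(10, bool)
            )
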