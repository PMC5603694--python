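"""Decoder interpretation: encoding patterns, affect-space projections,
probability warping, and the GP misclassification surface."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from affectmvpc import interpretation
from affectmvpc.interpretation import (
    decoder_to_encoder,
    correlate_maps,
    fit_misclassification_gp,
    hyperplane_affect_projection,
    joint_misclassification,
    predict_misclassification_surface,
    unwarp_probability,
    warp_probability,
)
from affectmvpc.mvpc import FoldResult


class TestDecoderToEncoder:
    def test_whitened_features_return_w_up_to_scale(self, rng):
        # huge sample of iid features: covariance is the identity
        X = rng.standard_normal((20000, 6))
        w = rng.standard_normal(6)
        a = decoder_to_encoder(X, w).a
        r = np.corrcoef(a, w)[0, 1]
        assert r > 0.999

    def test_two_voxel_toy_covariance(self, rng):
        # features with covariance [[2, 1], [1, 2]], w = (1, 0) -> a ∝ (2, 1)
        cov = np.array([[2.0, 1.0], [1.0, 2.0]])
        X = rng.multivariate_normal([0, 0], cov, size=200000)
        emap = decoder_to_encoder(X, np.array([1.0, 0.0]))
        assert emap.a[0] == pytest.approx(1.0, abs=1e-12)  # unit max abs
        assert emap.a[1] == pytest.approx(0.5, abs=0.02)

    def test_exact_on_sample_covariance(self, rng):
        X = rng.standard_normal((50, 8))
        w = rng.standard_normal(8)
        a_expected = np.cov(X, rowvar=False) @ w
        a_expected /= np.abs(a_expected).max()
        np.testing.assert_allclose(decoder_to_encoder(X, w).a, a_expected, atol=1e-10)

    def test_too_few_examples_rejected(self):
        with pytest.raises(ValueError):
            decoder_to_encoder(np.zeros((1, 3)), np.zeros(3))


class TestCorrelateMaps:
    def test_self_and_negated(self, rng):
        m = rng.standard_normal(40)
        assert correlate_maps(m, m)[0] == pytest.approx(1.0)
        assert correlate_maps(m, -m)[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        a, b = rng.standard_normal(30), rng.standard_normal(30)
        r, p = correlate_maps(a, b)
        ac, bc = a - a.mean(), b - b.mean()
        r_manual = (ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc))
        assert r == pytest.approx(r_manual, abs=1e-12)
        assert p == pytest.approx(stats.pearsonr(a, b).pvalue, abs=1e-12)

    def test_constant_map_rejected(self):
        with pytest.raises(ValueError):
            correlate_maps(np.ones(10), np.arange(10.0))


class TestWarp:
    def test_half_maps_to_zero(self):
        assert warp_probability(0.5) == pytest.approx(0.0, abs=1e-15)

    def test_round_trip_precision(self):
        p = 0.31
        assert unwarp_probability(warp_probability(p)) == pytest.approx(p, abs=1e-12)

    @given(st.floats(1e-6, 1 - 1e-6))
    def test_round_trip_property(self, p):
        assert unwarp_probability(warp_probability(p)) == pytest.approx(p, abs=1e-12)

    def test_boundary_clipping_keeps_finite(self):
        y0, y1 = warp_probability(0.0), warp_probability(1.0)
        assert np.isfinite(y0) and y0 < -6
        assert np.isfinite(y1) and y1 > 6

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            warp_probability(1.5)


def _fold(subject, stim_ids, true, pred):
    true = np.asarray(true)
    pred = np.asarray(pred)
    return FoldResult(
        subject_id=subject,
        rotation_index=0,
        test_stim_ids=tuple(stim_ids),
        true_labels=true,
        predicted_labels=pred,
        hyperplane_distances=pred.astype(float),
    )


class TestJointMisclassification:
    def _folds(self, error_rate_v, error_rate_a, stims=("a", "b"), n_subj=4):
        # each subject sees each stimulus once per dimension; a fraction
        # of subjects misclassify it
        folds_v, folds_a = [], []
        for s in range(n_subj):
            wrong_v = s < round(error_rate_v * n_subj)
            wrong_a = s < round(error_rate_a * n_subj)
            true = np.ones(len(stims))
            folds_v.append(_fold(f"sub{s}", stims, true, -true if wrong_v else true))
            folds_a.append(_fold(f"sub{s}", stims, true, -true if wrong_a else true))
        return tuple(folds_v), tuple(folds_a)

    @pytest.mark.parametrize(
        "pv, pa, expected",
        [(0.5, 0.5, 0.25), (0.0, 0.5, 0.0), (0.25, 0.25, 0.0625)],
    )
    def test_product_rule(self, pv, pa, expected):
        fv, fa = self._folds(pv, pa)
        table = joint_misclassification(fv, fa)
        np.testing.assert_allclose(table["p_joint"], expected, atol=1e-12)

    def test_error_rates_02_03_gives_006(self):
        fv, fa = self._folds(0.2, 0.3, n_subj=10)
        table = joint_misclassification(fv, fa)
        np.testing.assert_allclose(table["p_valence"], 0.2, atol=1e-12)
        np.testing.assert_allclose(table["p_arousal"], 0.3, atol=1e-12)
        np.testing.assert_allclose(table["p_joint"], 0.06, atol=1e-12)

    def test_correct_mode_complements(self):
        fv, fa = self._folds(0.2, 0.3, n_subj=10)
        table = joint_misclassification(fv, fa, mode="correct")
        np.testing.assert_allclose(table["p_joint"], 0.8 * 0.7, atol=1e-12)

    def test_mismatched_stimuli_rejected(self):
        fv, _ = self._folds(0.5, 0.5, stims=("a", "b"))
        _, fa = self._folds(0.5, 0.5, stims=("a", "c"))
        with pytest.raises(ValueError):
            joint_misclassification(fv, fa)


class TestAffectProjection:
    def _labels(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "stim_id": [f"s{i:02d}" for i in range(n)],
                "valence9": rng.uniform(1, 9, n),
                "arousal9": rng.uniform(2, 7.5, n),
            }
        )

    def _folds_from_distance(self, labels, dist_fn):
        folds = []
        for s in range(3):
            d = dist_fn(labels)
            folds.append(
                FoldResult(
                    subject_id=f"sub{s}",
                    rotation_index=0,
                    test_stim_ids=tuple(labels["stim_id"]),
                    true_labels=np.sign(d),
                    predicted_labels=np.sign(d),
                    hyperplane_distances=d,
                )
            )
        return tuple(folds)

    def test_valence_aligned_distances_recover_vertical_line(self):
        labels = self._labels()
        folds = self._folds_from_distance(labels, lambda t: (t["valence9"].to_numpy() - 5.0))
        proj = hyperplane_affect_projection(folds, labels, target="valence")
        angle = np.degrees(np.arccos(abs(proj.line_normal[0])))
        assert angle < 5.0

    def test_arousal_aligned_distances_recover_horizontal_line(self):
        labels = self._labels(seed=1)
        folds = self._folds_from_distance(labels, lambda t: (t["arousal9"].to_numpy() - 5.0))
        proj = hyperplane_affect_projection(folds, labels, target="arousal")
        angle = np.degrees(np.arccos(abs(proj.line_normal[1])))
        assert angle < 5.0

    def test_single_sign_distances_rejected(self):
        labels = self._labels(seed=2)
        folds = self._folds_from_distance(labels, lambda t: np.ones(len(t)))
        with pytest.raises(ValueError):
            hyperplane_affect_projection(folds, labels)

    def test_saturation_capped_at_one(self):
        labels = self._labels(seed=3)
        folds = self._folds_from_distance(labels, lambda t: (t["valence9"].to_numpy() - 5.0) * 3)
        proj = hyperplane_affect_projection(folds, labels)
        assert (proj.per_stimulus["saturation"] <= 1.0).all()


class TestMisclassificationGP:
    def test_constant_probability_gives_constant_surface(self, rng):
        coords = np.c_[rng.uniform(1, 9, 30), rng.uniform(2, 7.5, 30)]
        surf = predict_misclassification_surface(
            fit_misclassification_gp(coords, np.full(30, 0.3))
        )
        np.testing.assert_allclose(surf.p_surface, 0.3, atol=1e-3)

    def test_planted_bump_location_recovered(self, rng):
        # smooth bump centred at (7.2, 4.5) sampled at 45 points
        coords = np.c_[rng.uniform(1, 9, 45), rng.uniform(2, 7.5, 45)]
        p = 0.25 + 0.2 * np.exp(-((coords[:, 0] - 7.2) ** 2 + (coords[:, 1] - 4.5) ** 2) / 2)
        surf = predict_misclassification_surface(fit_misclassification_gp(coords, p))
        vmax, amax = surf.argmax
        assert abs(vmax - 7.2) <= 0.5
        assert abs(amax - 4.5) <= 0.5

    def test_grid_bounds_are_exact(self, rng):
        coords = np.c_[rng.uniform(1, 9, 10), rng.uniform(2, 7.5, 10)]
        surf = predict_misclassification_surface(
            fit_misclassification_gp(coords, rng.uniform(0.1, 0.4, 10))
        )
        assert surf.valence_grid[0] == 1.0 and surf.valence_grid[-1] == 9.0
        assert surf.arousal_grid[0] == 2.0 and surf.arousal_grid[-1] == 7.5
        assert ((surf.p_surface >= 0) & (surf.p_surface <= 1)).all()

    def test_duplicate_coordinates_jittered_not_fatal(self):
        coords = np.array([[2.0, 3.0]] * 3 + [[4.0, 5.0], [6.0, 3.5], [7.0, 6.0], [3.0, 2.5]])
        p = np.array([0.2, 0.3, 0.25, 0.4, 0.1, 0.3, 0.2])
        gp = fit_misclassification_gp(coords, p, seed=1)
        assert np.isfinite(gp.predict(np.array([[5.0, 5.0]]))).all()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_misclassification_gp(np.zeros((3, 2)), np.full(3, 0.2))

    def test_null_data_rarely_significant(self, rng):
        # per-stimulus t vs 0.25 on exchangeable per-subject products
        n_stim, n_subj = 40, 16
        sig = 0
        for i in range(n_stim):
            joint = rng.uniform(0, 0.5, n_subj)  # mean 0.25 by construction
            t = stats.ttest_1samp(joint, 0.25)
            sig += t.pvalue < 0.05
        assert sig / n_stim < 0.15
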