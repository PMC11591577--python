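"""PLS-DA / OPLS-DA, VIP scores, Q2 cross-validation, permutation, CV-ANOVA."""

import numpy as np
import pytest

from ftirchem.pls import (
    cv_anova, dummy_code, opls_predict_response, opls_vip, oplsda_fit,
    permutation_test, plsda_fit, plsda_predict, q2_crossval, stratified_folds,
    top_bands, vip_scores,
)


def _autoscale(X):
    return (X - X.mean(0)) / X.std(0, ddof=1)


def _random_model(rng, n=30, p=10, classes=2, n_comp=2):
    X = rng.normal(size=(n, p))
    y = np.array([f"C{i % classes}" for i in range(n)])
    return plsda_fit(_autoscale(X), y, n_comp)


class TestPlsdaFit:
    def test_perfectly_aligned_univariate_predictor(self):
        y = np.array(["A"] * 10 + ["B"] * 10)
        X = np.where(y == "A", -1.0, 1.0)[:, None]
        m = plsda_fit(X, y, 1)
        assert m.r2y == pytest.approx(1.0, abs=1e-10)

    def test_first_weight_matches_closed_form(self, rng):
        """Single-response first PLS weight is proportional to X^T y."""
        X = _autoscale(rng.normal(size=(24, 8)))
        y = np.array(["A"] * 12 + ["B"] * 12)
        yc = np.where(y == "A", -1.0, 1.0)
        m = oplsda_fit(X, y, n_orth=0)
        w_closed = X.T @ (yc - yc.mean())
        w_closed /= np.linalg.norm(w_closed)
        cos = abs(m.w_pred @ w_closed)
        assert cos >= 0.999

    def test_random_data_fits_within_bounds(self, rng):
        X = _autoscale(rng.normal(size=(30, 10)))
        y = np.array(["A", "B"] * 15)
        m = plsda_fit(X, y, 2)
        _, pred = plsda_predict(m, X)
        assert (pred == y).mean() >= 0.5
        assert 0 < m.r2y < 1

    def test_score_vectors_are_mutually_orthogonal(self, rng):
        m = _random_model(rng, n_comp=3)
        T = m.scores
        off = T.T @ T - np.diag(np.diag(T.T @ T))
        assert np.abs(off).max() < 1e-8

    def test_full_rank_pls_equals_ols(self, rng):
        X = _autoscale(rng.normal(size=(30, 5)))
        y = np.array(["A", "B"] * 15)
        Y, _ = dummy_code(y)
        Yc = Y - Y.mean(0)
        m = plsda_fit(X, y, 5)
        beta_ols = np.linalg.lstsq(X, Yc, rcond=None)[0]
        np.testing.assert_allclose(X @ m.coef, X @ beta_ols, atol=1e-8)

    def test_component_count_capped_by_rank(self, rng):
        with pytest.raises(ValueError):
            plsda_fit(rng.normal(size=(5, 3)), np.array(list("AABBB")), 5)

    def test_first_scores_agree_with_sklearn(self, rng):
        cross = pytest.importorskip("sklearn.cross_decomposition")
        X = _autoscale(rng.normal(size=(40, 12)))
        y = np.array(["A"] * 20 + ["B"] * 20)
        yc = np.where(y == "A", -1.0, 1.0)
        ours = oplsda_fit(X, y, n_orth=0).t_pred
        ref = cross.PLSRegression(n_components=1, scale=False).fit(X, yc)
        cos = abs(np.corrcoef(ours, ref.x_scores_[:, 0])[0, 1])
        assert cos >= 0.999


class TestVip:
    def test_equal_weights_give_unit_vip(self):
        y = np.array(["A"] * 8 + ["B"] * 8)
        base = np.where(y == "A", -1.0, 1.0)
        rng = np.random.default_rng(0)
        X = _autoscale(np.column_stack([base] * 4) + rng.normal(0, 1e-9, (16, 4)))
        m = plsda_fit(X, y, 1)
        np.testing.assert_allclose(vip_scores(m), 1.0, atol=1e-6)

    def test_mean_squared_vip_is_one(self, rng):
        for _ in range(20):
            m = _random_model(rng, n=25, p=8, n_comp=2)
            vip = vip_scores(m)
            assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-10)

    def test_dominant_variable_approaches_sqrt_p(self, rng):
        n = 300
        y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
        X = rng.normal(size=(n, 10)) * 1e-3
        X[:, 0] = np.where(y == "A", -1.0, 1.0)
        m = plsda_fit(_autoscale(X), y, 1)
        assert vip_scores(m)[0] == pytest.approx(np.sqrt(10), rel=0.05)

    def test_three_class_vip_recovers_planted_markers(self):
        """Top-10 VIP bands of a 3-class PLS-DA find every planted marker."""
        import ftirchem as fc
        from ftirchem.preprocess import PreprocessConfig, fit_scaler
        from ftirchem.synthetic import GroupEffect

        markers = (1335.5, 1304.0, 1449.5)
        hits = 0
        for seed in range(20):
            cfg = fc.default_cohort_config(seed=seed)
            cfg.sizes = {"ALS_T0": 19, "ALS_T6": 16, "ON": 7}
            cfg.effects = [
                GroupEffect(e.group, {k: 1.5 * v for k, v in e.deltas.items()})
                for e in cfg.effects if e.group in cfg.sizes
            ]
            s = fc.generate_cohort(cfg)
            pp = fc.preprocess(s, PreprocessConfig())
            X = fit_scaler(pp).transform(pp.absorbance)
            m = plsda_fit(X, pp.groups, 2)
            bands = top_bands(vip_scores(m), pp.grid.values, 10)
            hits += all(any(abs(b - mk) <= 4.0 for b in bands) for mk in markers)
        assert hits >= 18

    def test_top_bands_reports_distinct_bands(self):
        nus = np.arange(1500, 999, -0.5)
        vals = np.zeros(nus.size)
        for center, height in [(1335.5, 3.0), (1304.0, 2.5), (1449.5, 2.0)]:
            vals += height * np.exp(-((nus - center) ** 2) / 8.0)
        out = top_bands(vals, nus, n=3)
        assert out == [1335.5, 1304.0, 1449.5]
        # raw top-3 columns would all come from the strongest band
        raw = nus[np.argsort(vals)[::-1][:3]]
        assert np.all(np.abs(raw - 1335.5) <= 1.0)


class TestQ2:
    def test_deterministic_relation_predicts_well(self, rng):
        n = 200
        y = np.array(["A", "B"] * (n // 2))
        X = np.where(y == "A", -1.0, 1.0)[:, None] + rng.normal(0, 0.05, (n, 1))
        X = np.hstack([X, rng.normal(size=(n, 4))])
        assert q2_crossval(X, y, 1, folds=5, seed=0) >= 0.95

    def test_null_q2_is_negative_in_median(self):
        q2s = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(30, 20))
            y = np.array(["A", "B"] * 15)
            q2s.append(q2_crossval(X, y, 2, folds=5, seed=seed))
        assert np.median(q2s) <= 0

    def test_same_seed_same_folds_same_q2(self, rng):
        X = rng.normal(size=(30, 6))
        y = np.array(["A", "B"] * 15)
        assert q2_crossval(X, y, 2, seed=3) == q2_crossval(X, y, 2, seed=3)

    def test_folds_partition_samples(self):
        y = np.array(["A"] * 13 + ["B"] * 9)
        folds = stratified_folds(y, 5, seed=0)
        allidx = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(allidx, np.arange(22))


class TestOpls:
    def test_reduces_to_pls_without_orthogonal_structure(self, rng):
        y = np.array(["A"] * 15 + ["B"] * 15)
        X = _autoscale(np.where(y == "A", -1.0, 1.0)[:, None]
                       + rng.normal(0, 0.3, (30, 6)))
        m0 = oplsda_fit(X, y, n_orth=0)
        m1 = oplsda_fit(X, y, n_orth=1)
        cos = abs(np.corrcoef(m0.t_pred, m1.t_pred)[0, 1])
        assert cos >= 0.99

    def test_predictive_and_orthogonal_scores_uncorrelated(self, rng):
        X = _autoscale(rng.normal(size=(30, 12)))
        y = np.array(["A", "B"] * 15)
        m = oplsda_fit(X, y, n_orth=2)
        for a in range(m.t_orth.shape[1]):
            cov = np.cov(m.t_pred, m.t_orth[:, a])[0, 1]
            assert abs(cov) < 1e-8

    def test_orthogonal_filtering_rescues_q2(self):
        """Strong class-orthogonal variance hurts 1-comp PLS but not OPLS."""
        pls_q2, opls_q2 = [], []
        for seed in range(15):
            rng = np.random.default_rng(seed)
            n = 40
            y = np.array(["A", "B"] * (n // 2))
            signal = np.where(y == "A", -1.0, 1.0)
            conf = rng.normal(size=n) * 4.0       # class-orthogonal factor
            X = np.column_stack(
                [signal + 0.3 * rng.normal(size=n)]
                + [conf * w + 0.3 * rng.normal(size=n) for w in (1.0, 0.8, 0.6)]
                + [0.5 * signal + conf + 0.3 * rng.normal(size=n)]
            )
            pls_q2.append(q2_crossval(X, y, 1, seed=seed))
            opls_q2.append(q2_crossval(X, y, 1, seed=seed, n_orth=1))
        assert np.median(opls_q2) > np.median(pls_q2)

    def test_more_than_two_classes_redirected(self, rng):
        with pytest.raises(ValueError, match="two-class"):
            oplsda_fit(rng.normal(size=(9, 4)), np.array(list("AABBBCCCC")), 1)

    def test_x_variance_decomposition_is_complete(self, rng):
        X = _autoscale(rng.normal(size=(25, 8)))
        y = np.array(["A"] * 13 + ["B"] * 12)
        m = oplsda_fit(X, y, n_orth=1)
        ss_pred = float(np.outer(m.t_pred, m.p_pred).ravel() @ np.outer(m.t_pred, m.p_pred).ravel())
        ss_orth = sum(
            float((np.outer(m.t_orth[:, a], m.p_orth[:, a]) ** 2).sum())
            for a in range(m.t_orth.shape[1]))
        Xd = X.copy()
        for a in range(m.t_orth.shape[1]):
            t_o = Xd @ m.w_orth[:, a]
            Xd = Xd - np.outer(t_o, m.p_orth[:, a])
        resid = Xd - np.outer(m.t_pred, m.p_pred)
        total = float((X**2).sum())
        assert ss_pred + ss_orth + float((resid**2).sum()) == pytest.approx(total, rel=1e-8)


class TestPermutation:
    def test_strong_effect_reaches_minimum_p(self, rng):
        y = np.array(["A", "B"] * 15)
        X = np.where(y == "A", -1.0, 1.0)[:, None] + rng.normal(0, 0.1, (30, 1))
        X = np.hstack([X, rng.normal(size=(30, 3))])
        res = permutation_test(X, y, n_perm=49, seed=0, n_orth=1)
        assert res["p_q2"] == pytest.approx(1 / 50)

    def test_low_permutation_count_warns(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array(["A", "B"] * 6)
        with pytest.warns(UserWarning, match="permutations"):
            permutation_test(X, y, n_perm=9, seed=0, n_orth=1)


class TestCvAnova:
    def test_no_improvement_gives_f_zero_p_one(self):
        f, p = cv_anova(press=10.0, ss_tot=10.0, n=20, n_param=2)
        assert f == 0.0 and p == 1.0

    def test_perfect_prediction_limit(self):
        f, p = cv_anova(press=0.0, ss_tot=10.0, n=20, n_param=2)
        assert np.isinf(f) and p == 0.0

    def test_hand_computed_fixture(self):
        # n=10, 2 params: F = ((8-2)/2)/(2/7) = 10.5
        from scipy.stats import f as f_dist
        f, p = cv_anova(press=2.0, ss_tot=8.0, n=10, n_param=2)
        assert f == pytest.approx(10.5)
        assert p == pytest.approx(float(f_dist.sf(10.5, 2, 7)))
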