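"""SIMCA class models, membership tests, modelling/discriminant power."""

import numpy as np
import pytest

from ftirchem.simca import (
    choose_n_components, discriminant_power, modeling_power, object_distance,
    power_table, simca_classify, simca_fit, simca_report,
)


def _plane_data(rng, n=12, p=5, A=2, noise=0.0):
    L = rng.normal(size=(p, A))
    T = rng.normal(size=(n, A))
    X = T @ L.T + 3.0
    if noise:
        X = X + rng.normal(scale=noise, size=X.shape)
    return X


class TestSimcaFit:
    def test_exact_subspace_has_zero_residual_sd(self, rng):
        X = _plane_data(rng, A=2)
        m = simca_fit(X, 2)
        assert m.s0 == pytest.approx(0.0, abs=1e-10)

    def test_zero_components_collapse_to_pooled_sd(self, rng):
        X = rng.normal(size=(10, 4))
        m = simca_fit(X, 0)
        sd = X.std(axis=0, ddof=1)
        np.testing.assert_allclose(m.resid_sd, sd, rtol=1e-10)
        expected_s0 = np.sqrt((sd**2).sum() * 9 / (4 * 9))
        assert m.s0 == pytest.approx(expected_s0)

    def test_matches_independent_eigendecomposition_oracle(self):
        X = np.array([[1.0, 2.0, 0.5], [2.0, 3.9, 1.4], [3.0, 6.1, 2.6],
                      [4.0, 8.0, 3.4], [5.0, 10.0, 4.6]])
        m = simca_fit(X, 1)
        # oracle: eigenvector of the covariance matrix, explicit reconstruction
        Xc = X - X.mean(axis=0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc)
        v = evecs[:, -1]
        E = Xc - np.outer(Xc @ v, v)
        s0_oracle = np.sqrt((E**2).sum() / ((3 - 1) * (5 - 1 - 1)))
        assert m.s0 == pytest.approx(s0_oracle, rel=1e-10)

    def test_residual_dispersion_decreases_with_components(self, rng):
        X = rng.normal(size=(12, 6)) + _plane_data(rng, n=12, p=6, A=3)
        s0s = [simca_fit(X, A).s0 for A in range(4)]
        assert all(a > b for a, b in zip(s0s, s0s[1:]))

    def test_too_many_components_rejected(self, rng):
        with pytest.raises(ValueError):
            simca_fit(rng.normal(size=(4, 6)), 3)


class TestObjectDistance:
    def test_in_plane_object_has_zero_distance(self, rng):
        X = _plane_data(rng)
        m = simca_fit(X, 2)
        s, F = object_distance(m, X[0])
        assert s[0] == pytest.approx(0.0, abs=1e-10)

    def test_class_mean_has_zero_distance(self, rng):
        X = rng.normal(size=(10, 4))
        m = simca_fit(X, 1)
        s, F = object_distance(m, X.mean(axis=0))
        assert s[0] == pytest.approx(0.0, abs=1e-10)
        assert F[0] == pytest.approx(0.0, abs=1e-10)

    def test_hand_computed_residual(self):
        X = np.array([[1.0, 0.0, 0.0], [2.0, 0, 0], [3.0, 0, 0], [4.0, 0, 0]])
        X[:, 1] = [0.1, -0.1, 0.1, -0.1]   # off-plane wiggle
        m = simca_fit(X, 1)
        x = np.array([2.5, 0.3, 0.4])      # residual (0, ~0.3, 0.4) off the model line
        s, _ = object_distance(m, x)
        xc = x - m.mean
        e = xc - m.loadings @ (m.loadings.T @ xc)
        assert s[0] == pytest.approx(np.sqrt((e**2).sum() / 2), rel=1e-10)


class TestClassify:
    def test_object_in_class_subspace_accepted_and_forced_there(self, rng):
        XA = _plane_data(rng, n=15, noise=0.05)
        XB = _plane_data(rng, n=15, noise=0.05) + 30.0
        mA, mB = simca_fit(XA, 2), simca_fit(XB, 2)
        mA.label, mB.label = "A", "B"
        x = XA[3]
        acc, forced = simca_classify([mA, mB], x)
        assert acc[0, 0] and not acc[0, 1]
        assert forced[0] == "A"

    def test_extreme_object_rejected_by_all_but_still_forced(self, rng):
        XA = _plane_data(rng, n=15, noise=0.05)
        XB = _plane_data(rng, n=15, noise=0.05) + 30.0
        mA, mB = simca_fit(XA, 2), simca_fit(XB, 2)
        mA.label, mB.label = "A", "B"
        x = np.full(5, 1e4)
        acc, forced = simca_classify([mA, mB], x)
        assert not acc.any()
        assert forced[0] in ("A", "B")

    def test_identical_models_tie_to_first_label(self, rng):
        X = _plane_data(rng, n=15, noise=0.1)
        m1, m2 = simca_fit(X, 1), simca_fit(X, 1)
        m1.label, m2.label = "first", "second"
        _, forced = simca_classify([m1, m2], X[:3])
        assert (forced == "first").all()

    def test_open_acceptance_rate_matches_alpha(self, rng):
        """In-class acceptance of fresh model-generated objects ~ 1 - alpha."""
        rates = []
        for _ in range(100):
            p, A, n = 10, 2, 50
            L = rng.normal(size=(p, A))
            X = rng.normal(size=(n, A)) @ L.T + rng.normal(scale=0.3, size=(n, p))
            m = simca_fit(X, A)
            m.label = "A"
            Xnew = rng.normal(size=(100, A)) @ L.T + rng.normal(scale=0.3, size=(100, p))
            acc, _ = simca_classify([m], Xnew, alpha=0.05)
            rates.append(acc.mean())
        assert abs(np.mean(rates) - 0.95) < 0.05


class TestPower:
    def test_perfectly_reconstructed_variable_has_unit_mp(self, rng):
        X = _plane_data(rng, n=12, p=5, A=1)
        m = simca_fit(X, 1)
        mp = modeling_power(m, X)
        np.testing.assert_allclose(mp, 1.0, atol=1e-6)

    def test_zero_components_give_zero_mp(self, rng):
        X = rng.normal(size=(10, 4))
        mp = modeling_power(simca_fit(X, 0), X)
        np.testing.assert_allclose(mp, 0.0, atol=1e-12)

    def test_mp_bounded_and_high_on_structured_classes(self, rng):
        # every variable loads with norm 1.5 on the latent plane, so the
        # 2-component model captures nearly all of each variable's variance
        L = rng.normal(size=(10, 2))
        L *= 1.5 / np.linalg.norm(L, axis=1, keepdims=True)
        X = rng.normal(size=(20, 2)) @ L.T + rng.normal(scale=0.1, size=(20, 10))
        m = simca_fit(X, 2)
        mp = modeling_power(m, X)
        assert np.all((mp >= 0) & (mp <= 1))
        assert np.all(mp >= 0.85)

    def test_dp_near_one_under_the_null(self):
        vals = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            XA, XB = rng.normal(size=(20, 8)), rng.normal(size=(20, 8))
            dp = discriminant_power(simca_fit(XA, 1), simca_fit(XB, 1), XA, XB)
            vals.append(dp)
        vals = np.concatenate(vals)
        assert np.median(vals) == pytest.approx(1.0, abs=0.15)
        assert ((vals > 0.7) & (vals < 1.4)).mean() > 0.95

    def test_dp_flags_planted_class_shift(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            XA, XB = rng.normal(size=(19, 10)), rng.normal(size=(15, 10))
            XB[:, 0] += 3.0
            mA = simca_fit(XA, choose_n_components(XA))
            mB = simca_fit(XB, choose_n_components(XB))
            dp = discriminant_power(mA, mB, XA, XB)
            hits += (dp[0] > dp[1:]).all()
        assert hits >= 48

    def test_power_table_layout(self, rng):
        XA = _plane_data(rng, n=15, p=6, A=2, noise=0.1)
        XB = _plane_data(rng, n=15, p=6, A=2, noise=0.1) + 2.0
        mA, mB = simca_fit(XA, 2), simca_fit(XB, 2)
        mA.label, mB.label = "HC", "ALS_T0"
        nus = np.array([1234.0, 1475.0, 1310.5, 1033.5, 1400.5, 1355.0])
        tab = power_table({"HC": mA, "ALS_T0": mB}, {"HC": XA, "ALS_T0": XB}, nus)
        assert list(tab.columns) == ["Spectra Variable", "Discriminant Power",
                                     "Modeling Power HC", "Modeling Power ALS_T0"]
        dp = tab["Discriminant Power"].to_numpy()
        assert np.all(np.diff(dp) <= 0)


class TestReport:
    def test_report_columns_and_ranges(self, rng):
        XA = _plane_data(rng, n=14, p=6, A=2, noise=0.1)
        XB = _plane_data(rng, n=12, p=6, A=2, noise=0.1) + 10.0
        X = np.vstack([XA, XB])
        y = np.array(["A"] * 14 + ["B"] * 12)
        rep, models = simca_report(X, y, X[:4], y[:4], {"A": 2, "B": 2})
        frame = rep.to_frame()
        assert "Efficiency Forced Model (%)" in frame.columns
        vals = frame.iloc[:, 1:].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        assert np.all((finite >= 0) & (finite <= 100))
        # well-separated planes: forced assignment is perfect
        assert rep.rows["A"]["efficiency_forced"] == pytest.approx(100.0)
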