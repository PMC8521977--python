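"""The funnel network, baselines, and the cross-validation driver."""

import numpy as np
import pandas as pd
import pytest

import epivec as ev
from epivec.mlp import FunnelMLP
from epivec.models import _Standardizer, build_onehot_features


def hand_count_parameters(input_dim, widths):
    """Independent layer-by-layer count: affine weights and biases plus
    a scale and shift per batch-normalized hidden unit."""
    dims = [input_dim] + list(widths)
    affine = sum(dims[i] * dims[i + 1] + dims[i + 1] for i in range(len(widths)))
    affine += widths[-1] * 1 + 1
    batchnorm = 2 * sum(widths)
    return affine + batchnorm


class TestArchitecture:
    def test_parameter_count_matches_hand_count(self):
        widths = (256, 128, 64, 16, 4)
        expected = ((30 * 256 + 256) + (256 * 128 + 128) + (128 * 64 + 64)
                    + (64 * 16 + 16) + (16 * 4 + 4) + (4 * 1 + 1)
                    + 2 * (256 + 128 + 64 + 16 + 4))
        assert ev.count_parameters(30, widths) == expected
        assert hand_count_parameters(30, widths) == expected
        net = FunnelMLP(30, widths, seed=0)
        assert net.n_parameters() == expected

    def test_input_dim_respected(self):
        net = FunnelMLP(30, seed=0)
        out = net.predict(np.zeros((3, 30), dtype=np.float32))
        assert out.shape == (3,)
        with pytest.raises(ValueError):
            net.predict(np.zeros((3, 31)))

    def test_same_seed_same_initial_parameters(self):
        a, b = FunnelMLP(10, (8, 4), seed=5), FunnelMLP(10, (8, 4), seed=5)
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    def test_invalid_widths(self):
        with pytest.raises(ValueError):
            FunnelMLP(10, (8, 0), seed=0)


class TestTraining:
    def _linear_data(self, n=2000, d=10, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, d))
        y = X @ rng.standard_normal(d) * 0.3 + 1.0
        return X, y

    def test_noiseless_linear_target_learned(self):
        """The network drives training RMSE well below the target scale on
        a noiseless linear problem (threshold fixed from runs at 3 seeds)."""
        X, y = self._linear_data()
        net = FunnelMLP(10, (32, 16, 8), seed=1)
        log = net.fit(X, y, learning_rate=3e-3, max_epochs=200,
                      early_stop_patience=30, seed=1)
        assert min(log.train_rmse) < 0.05

    def test_fixed_seed_identical_loss_trace(self):
        X, y = self._linear_data(n=500)
        logs = []
        for _ in range(2):
            net = FunnelMLP(10, (16, 8), seed=3)
            logs.append(net.fit(X, y, max_epochs=5, seed=3))
        assert logs[0].train_rmse == logs[1].train_rmse
        assert logs[0].holdout_rmse == logs[1].holdout_rmse

    def test_constant_target_converges_to_constant(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((600, 6))
        y = np.full(600, 2.5)
        net = FunnelMLP(6, (16, 8), seed=0)
        net.fit(X, y, learning_rate=1e-2, max_epochs=150,
                early_stop_patience=30, seed=0)
        pred = net.predict(X)
        assert np.sqrt(np.mean((pred - 2.5) ** 2)) < 0.1

    def test_batch_vs_single_row_prediction(self):
        X, y = self._linear_data(n=300)
        net = FunnelMLP(10, (16, 8), seed=2)
        net.fit(X, y, max_epochs=3, seed=2)
        batch = net.predict(X[:5])
        singles = np.array([net.predict(X[i:i + 1])[0] for i in range(5)])
        np.testing.assert_allclose(batch, singles, atol=1e-6)

    def test_empty_or_nonfinite_rejected(self):
        net = FunnelMLP(4, (8,), seed=0)
        with pytest.raises(ValueError):
            net.fit(np.zeros((0, 4)), np.zeros(0))
        with pytest.raises(ValueError):
            net.fit(np.zeros((5, 4)), np.array([1, 2, np.nan, 4, 5]))


class TestGlobalBaseline:
    def _table(self):
        df = pd.DataFrame({
            "disease": ["a", "a", "b"],
            "country": ["x", "y", "x"],
            "age_group": [0, 0, 0],
            "incidence": [10.0, 1000.0, 50.0],
        })
        return ev.IncidenceTable(df, n_age=1)

    def test_mean_of_log_values(self):
        model = ev.fit_global_baseline(self._table())
        feats = build_onehot_features(self._table(), "d")
        pred = model.predict(feats)
        assert pred[0] == pytest.approx(2.0)  # mean of log10 {10, 1000}

    def test_unseen_disease_not_applicable(self):
        model = ev.fit_global_baseline(self._table())
        df = pd.DataFrame({"disease": ["zz"], "country": ["x"],
                           "age_group": [0], "incidence": [5.0]})
        feats = build_onehot_features(ev.IncidenceTable(df, n_age=1), "d")
        assert np.isnan(model.predict(feats)[0])

    def test_disease_age_grouping_distinguishes_cells(self):
        df = pd.DataFrame({
            "disease": ["a", "a"], "country": ["x", "x"],
            "age_group": [0, 1], "incidence": [10.0, 1000.0],
        })
        table = ev.IncidenceTable(df, n_age=2)
        model = ev.fit_global_baseline(table, grouping="disease-age")
        feats = build_onehot_features(table, "d")
        np.testing.assert_allclose(model.predict(feats), [1.0, 3.0])


class TestRidge:
    def test_small_alpha_recovers_coefficients(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((400, 6))
        beta = rng.standard_normal(6)
        y = X @ beta + 2.0
        keys = pd.DataFrame({"disease": ["d"] * 400, "country": ["c"] * 400,
                             "age_group": [0] * 400})
        from epivec.dataset import FeatureMatrix
        feats = FeatureMatrix(X=X, y=y, keys=keys, layout={"total_dim": 6})
        model = ev.fit_ridge(feats, alpha_grid=[1e-8])
        # independent oracle: ordinary least squares
        lstsq = np.linalg.lstsq(np.column_stack([X, np.ones(400)]), y, rcond=None)[0]
        got = model.predict(feats)
        want = X @ lstsq[:6] + lstsq[6]
        np.testing.assert_allclose(got, want, atol=1e-4)

    def test_huge_alpha_predicts_training_mean(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((200, 4))
        y = rng.standard_normal(200) + 3.0
        from epivec.dataset import FeatureMatrix
        keys = pd.DataFrame({"disease": ["d"] * 200, "country": ["c"] * 200,
                             "age_group": [0] * 200})
        feats = FeatureMatrix(X=X, y=y, keys=keys, layout={"total_dim": 4})
        model = ev.fit_ridge(feats, alpha_grid=[1e9])
        np.testing.assert_allclose(model.predict(feats), y.mean(), atol=0.05)

    def test_alpha_must_be_positive(self):
        from epivec.dataset import FeatureMatrix
        feats = FeatureMatrix(X=np.ones((3, 1)), y=np.ones(3),
                              keys=pd.DataFrame({"disease": list("abc"),
                                                 "country": list("abc"),
                                                 "age_group": [0, 0, 0]}))
        with pytest.raises(ValueError):
            ev.fit_ridge(feats, alpha_grid=[-1.0])


class TestOneHotFeatures:
    def test_dimensions_per_variant(self, small_table):
        table, _ = ev.filter_zero_incidence(small_table)
        d = build_onehot_features(table, "d")
        c = build_onehot_features(table, "c")
        dc = build_onehot_features(table, "dc")
        assert d.X.shape[1] == 6 + 20
        assert c.X.shape[1] == 4 + 20
        assert dc.X.shape[1] == 6 + 4 + 20

    def test_out_of_vocabulary_marked_not_applicable(self, small_table):
        table, _ = ev.filter_zero_incidence(small_table)
        vocab = {"disease": table.diseases[:3], "country": table.countries}
        feats = build_onehot_features(table, "d", vocab)
        unseen = ~table.df["disease"].isin(vocab["disease"])
        np.testing.assert_array_equal(feats.applicable, ~unseen.to_numpy())


class TestLeakageGuard:
    def test_standardizer_uses_training_rows_only(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((50, 3))
        s = _Standardizer(True).fit(X)
        np.testing.assert_allclose(s.transform(X).mean(axis=0), 0, atol=1e-12)
        # perturbing rows outside the fit set never changes the transform
        other = rng.standard_normal((50, 3)) * 100
        np.testing.assert_allclose(s.transform(X), (X - s.mean) / s.sd)
        s2 = _Standardizer(True).fit(X)
        np.testing.assert_array_equal(s.mean, s2.mean)
        assert not np.allclose(_Standardizer(True).fit(other).mean, s.mean)


class TestCrossValidate:
    def test_every_record_predicted_once_and_reports(self, small_table, providers):
        d, c = providers
        table, _ = ev.filter_zero_incidence(small_table)
        plan = ev.split_pairs(table, 3, seed=1)
        cfg = ev.RegressorConfig(seed=2, max_epochs=8, early_stop_patience=3)
        rep = ev.cross_validate(table, plan, "mlp", cfg, d, c)
        assert rep.n_scored == len(table)
        assert rep.n_not_applicable == 0
        assert 0 <= rep.concordance <= 1

    def test_global_under_disease_scheme_all_not_applicable(self, small_table):
        table, _ = ev.filter_zero_incidence(small_table)
        plan = ev.split_by_disease(table, 3, seed=1)
        rep = ev.cross_validate(table, plan, "global")
        assert rep.n_scored == 0
        assert rep.n_not_applicable == len(table)

    def test_onehot_country_under_country_scheme_all_not_applicable(self, small_table):
        table, _ = ev.filter_zero_incidence(small_table)
        plan = ev.split_by_country(table, 2, seed=1)
        cfg = ev.RegressorConfig(seed=2, max_epochs=3, early_stop_patience=2)
        rep = ev.cross_validate(table, plan, "onehot-c", cfg)
        assert rep.n_scored == 0

    def test_unknown_model_kind(self, small_table):
        table, _ = ev.filter_zero_incidence(small_table)
        plan = ev.split_pairs(table, 2, seed=0)
        with pytest.raises(ValueError, match="model kind"):
            ev.cross_validate(table, plan, "boost")
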