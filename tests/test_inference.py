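import numpy as np
import pandas as pd
import pytest

from behaviorome import inference as inf
from behaviorome.vocab import TARGET_SCORES


def _frame(values, name="S"):
    return pd.DataFrame({name: values})


class TestNormalization:
    def test_min_max_map(self):
        scaler = inf.normalize_scores(_frame([10.0, 20.0, 30.0]))
        out = scaler.transform(_frame([10.0, 20.0, 30.0]))
        assert out["S"].tolist() == [0.0, 0.5, 1.0]

    def test_test_values_clipped(self):
        scaler = inf.normalize_scores(_frame([10.0, 20.0, 30.0]))
        assert scaler.transform(_frame([45.0]))["S"].iloc[0] == 1.0
        assert scaler.transform(_frame([-5.0]))["S"].iloc[0] == 0.0

    def test_round_trip_identity(self):
        raw = _frame([3.0, 9.0, 4.5, 7.25])
        scaler = inf.normalize_scores(raw)
        back = scaler.inverse(scaler.transform(raw))
        assert np.allclose(back["S"], raw["S"], atol=1e-12)

    def test_constant_score_named_in_error(self):
        with pytest.raises(ValueError, match="S"):
            inf.normalize_scores(_frame([5.0, 5.0, 5.0]))


class TestVarianceFilter:
    def test_high_variance_retained_low_dropped(self):
        scores = pd.DataFrame({"hi": [0.0, 1.0, 0.0, 1.0], "lo": [0.5, 0.52, 0.5, 0.52]})
        assert inf.filter_targets_by_variance(scores, overrides=()) == ["hi"]

    def test_override_forces_retention(self):
        scores = pd.DataFrame({"DEX": [0.5, 0.51, 0.5, 0.51]})
        assert inf.filter_targets_by_variance(scores, overrides=()) == []
        assert inf.filter_targets_by_variance(scores, overrides=("DEX",)) == ["DEX"]

    def test_all_constant_gives_empty_set(self):
        scores = pd.DataFrame({"a": [0.3] * 4, "b": [0.9] * 4})
        assert inf.filter_targets_by_variance(scores, overrides=()) == []


@pytest.fixture(scope="module")
def tabular():
    """Small tabular cohort: 12 features, 7 targets + 4 supplementals."""
    rng = np.random.default_rng(3)
    n, p = 40, 12
    X = pd.DataFrame(
        rng.normal(size=(n, p)),
        columns=[f"home_f{i}" if i < 6 else f"watch_f{i}" for i in range(p)],
        index=[f"P{i:03d}" for i in range(n)],
    )
    signal = X["home_f0"].to_numpy()
    scores = {}
    for k, t in enumerate(TARGET_SCORES):
        scores[t] = np.clip(0.5 + 0.12 * signal + rng.normal(0, 0.03, n), 0, 1)
    for k in range(4):
        scores[f"sup_{k:02d}"] = np.clip(0.5 + 0.12 * signal + rng.normal(0, 0.03, n), 0, 1)
    return X, pd.DataFrame(scores, index=X.index)


class TestPredictors:
    def test_one_model_per_score(self, tabular):
        X, scores = tabular
        ind = inf.train_independent(X, scores, seed=0)
        assert set(ind) == set(scores.columns)
        assert all(p.stage == "independent" for p in ind.values())

    def test_noise_free_linear_scores_fit_closely(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(50, 8)), columns=[f"x{i}" for i in range(8)])
        y = pd.DataFrame({"Y": np.clip(0.5 + 0.1 * X["x0"] + 0.05 * X["x1"], 0, 1)})
        ind = inf.train_independent(X, y, seed=0)
        mae = np.abs(inf.predict_independent(ind, X)["Y"] - y["Y"]).mean()
        assert mae < 0.05

    def test_deterministic_given_seed(self, tabular):
        X, scores = tabular
        a = inf.predict_independent(inf.train_independent(X, scores, seed=5), X)
        b = inf.predict_independent(inf.train_independent(X, scores, seed=5), X)
        pd.testing.assert_frame_equal(a, b)

    def test_row_mismatch_rejected(self, tabular):
        X, scores = tabular
        with pytest.raises(ValueError, match="different numbers"):
            inf.train_independent(X.iloc[:-1], scores)

    def test_joint_feature_wiring(self, tabular):
        X, scores = tabular
        ind = inf.train_independent(X, scores, seed=0)
        joint = inf.train_joint(X, scores, independent=ind, seed=0)
        n_scores = scores.shape[1]
        for target, p in joint.items():
            # all columns of X plus every score except the target itself
            assert len(p.feature_names) == X.shape[1] + n_scores - 1
            assert target not in p.feature_names

    def test_joint_without_independent_rejected(self, tabular):
        X, scores = tabular
        with pytest.raises(ValueError, match="independent"):
            inf.train_joint(X, scores, independent=None)

    def test_two_stage_outputs_clipped(self, tabular):
        X, scores = tabular
        ind = inf.train_independent(X, scores, seed=0)
        joint = inf.train_joint(X, scores, independent=ind, seed=0)
        s1, s2 = inf.predict_two_stage(ind, joint, X)
        assert ((s1 >= 0) & (s1 <= 1)).all().all()
        assert ((s2 >= 0) & (s2 <= 1)).all().all()

    def test_joint_beats_independent_on_redundant_supplemental(self):
        """Target A equals supplemental S up to tiny noise; S is an easy
        function of one feature, so the stage-two predictor rides S's
        stage-one estimate to a lower test error."""
        rng = np.random.default_rng(0)
        n, p = 60, 12
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
        s = X["x0"].to_numpy()
        scores = pd.DataFrame(
            {
                "A": np.clip(0.5 + 0.12 * s + rng.normal(0, 0.01, n), 0, 1),
                "S": np.clip(0.5 + 0.12 * s, 0, 1),
            },
            index=X.index,
        )
        tr = np.arange(n) < 40
        ind = inf.train_independent(X[tr], scores[tr], seed=1)
        joint = inf.train_joint(X[tr], scores[tr], targets=("A",), independent=ind, seed=1)
        s1, s2 = inf.predict_two_stage(ind, joint, X[~tr])
        mae_ind = np.abs(s1["A"] - scores["A"][~tr]).mean()
        mae_joint = np.abs(s2["A"] - scores["A"][~tr]).mean()
        assert mae_joint < mae_ind


class TestPearson:
    def test_textbook_cases(self):
        assert inf.pearson_r([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert inf.pearson_r([1, 2, 3], [2, 1, 0]) == pytest.approx(-1.0)
        assert inf.pearson_r([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_input_returns_sentinel(self):
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(inf.pearson_r([1.0, 1.0, 1.0], [1, 2, 3]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            inf.pearson_r([1, 2, 3], [1, 2])


class TestLOSO:
    def test_table_shape_and_signal_recovery(self, tabular):
        X, scores = tabular
        demo = pd.DataFrame({"age": np.arange(len(X))}, index=X.index)
        res = inf.loso_evaluate(demo, X, scores, configs=("fusion",), seed=0)
        assert list(res.table.index) == [*TARGET_SCORES, "Average"]
        assert set(res.table.columns) == {"Fusion-I", "Fusion-J"}
        # a single shared linear signal with small noise is recoverable
        assert res.table.loc["Average", "Fusion-I"] > 0.5

    def test_modality_subsetting_excludes_other_features(self, tabular):
        X, scores = tabular
        from behaviorome.assemble import subset_features

        home = subset_features(X, "home")
        watch = subset_features(X, "watch")
        assert all(c.startswith("home_") for c in home.columns)
        assert all(c.startswith("watch_") for c in watch.columns)
        assert home.shape[1] + watch.shape[1] == X.shape[1]

    def test_no_leakage_of_held_out_scores(self, tabular):
        """Mutating a held-out subject's scores changes nothing about the
        predictions made for that subject."""
        X, scores = tabular
        demo = pd.DataFrame({"age": np.arange(len(X))}, index=X.index)
        target_subject = X.index[4]
        mutated = scores.copy()
        mutated.loc[target_subject] = 1.0 - mutated.loc[target_subject]
        a = inf.loso_evaluate(demo.iloc[:8], X.iloc[:8], scores.iloc[:8], configs=("fusion",),
                              stages=("independent",), seed=0)
        b = inf.loso_evaluate(demo.iloc[:8], X.iloc[:8], mutated.iloc[:8], configs=("fusion",),
                              stages=("independent",), seed=0)
        pa = a.predictions.query("subject == @target_subject")["pred"].to_numpy()
        pb = b.predictions.query("subject == @target_subject")["pred"].to_numpy()
        assert np.array_equal(pa, pb)

    def test_too_few_subjects_rejected(self, tabular):
        X, scores = tabular
        demo = pd.DataFrame({"age": [1, 2]}, index=X.index[:2])
        with pytest.raises(ValueError, match="3 subjects"):
            inf.loso_evaluate(demo, X.iloc[:2], scores.iloc[:2])
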