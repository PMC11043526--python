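import math

import numpy as np
import pandas as pd
import pytest

import enumstack as es


def softmax_frame(scores: np.ndarray, classes=("A", "B")):
    e = np.exp(scores - scores.max(axis=1, keepdims=True))
    return e / e.sum(axis=1, keepdims=True), classes


def linear_model(weights: dict[str, float]):
    """Two-class model whose class-A probability is a clipped linear score."""

    def fn(x: pd.DataFrame) -> pd.DataFrame:
        score = sum(w * x[f] for f, w in weights.items())
        p = np.clip(0.5 + 0.1 * score, 0.0, 1.0)
        return pd.DataFrame({"A": p, "B": 1 - p}, index=x.index)

    return fn


def make_table(values: dict[str, list[float]]):
    return pd.DataFrame(values)


class TestExactOracle:
    def test_single_feature_gets_full_credit(self):
        model = linear_model({"f1": 1.0})
        background = make_table({"f1": [0.0, 2.0]})
        sample = pd.Series({"f1": 3.0})
        phi = es.exact_shapley_oracle(model, background, sample, "A")
        expected = (0.5 + 0.1 * 3.0) - np.mean([0.5, 0.5 + 0.1 * 2.0])
        assert phi["f1"] == pytest.approx(expected, abs=1e-12)

    def test_additive_model_splits_into_marginal_deviations(self):
        model = linear_model({"f1": 1.0, "f2": 2.0})
        background = make_table({"f1": [0.0, 1.0], "f2": [0.0, -1.0]})
        sample = pd.Series({"f1": 2.0, "f2": 1.0})
        phi = es.exact_shapley_oracle(model, background, sample, "A")
        assert phi["f1"] == pytest.approx(0.1 * (2.0 - 0.5), abs=1e-12)
        assert phi["f2"] == pytest.approx(0.2 * (1.0 - (-0.5)), abs=1e-12)

    def test_dummy_feature_attributed_exactly_zero(self):
        model = linear_model({"f1": 1.0})  # ignores f2 entirely
        background = make_table({"f1": [0.0, 1.0], "f2": [5.0, -5.0]})
        sample = pd.Series({"f1": 1.0, "f2": 7.0})
        phi = es.exact_shapley_oracle(model, background, sample, "A")
        assert phi["f2"] == 0.0

    def test_too_many_features_rejected(self):
        cols = {f"f{i}": [0.0] for i in range(13)}
        with pytest.raises(ValueError, match="sampling"):
            es.exact_shapley_oracle(
                linear_model({"f0": 1.0}), make_table(cols), pd.Series({c: 0.0 for c in cols}), "A"
            )


class TestSampler:
    def test_single_feature_closed_form(self):
        model = linear_model({"f1": 1.0})
        background = make_table({"f1": [0.0, 2.0, 4.0]})
        samples = make_table({"f1": [3.0]})
        recs = es.shapley_sampling(model, background, samples, n_permutations=10, seed=0)
        rec = next(r for r in recs if r.class_name == "A")
        assert rec.shap_value == pytest.approx(0.1 * (3.0 - 2.0), abs=1e-12)
        assert rec.base_value == pytest.approx(0.5 + 0.1 * 2.0, abs=1e-12)

    def test_symmetric_features_get_equal_credit(self):
        model = linear_model({"f1": 1.0, "f2": 1.0})
        background = make_table({"f1": [0.0, 1.0], "f2": [0.0, 1.0]})
        samples = make_table({"f1": [2.0], "f2": [2.0]})
        recs = [
            r
            for r in es.shapley_sampling(model, background, samples, n_permutations=24, seed=0)
            if r.class_name == "A"
        ]
        values = {r.feature_name: r.shap_value for r in recs}
        assert values["f1"] == pytest.approx(values["f2"], abs=1e-12)

    @pytest.mark.parametrize("n_features", [3, 5])
    def test_full_permutation_budget_matches_exact_oracle(self, n_features):
        rng = np.random.default_rng(1)
        feats = [f"f{i}" for i in range(n_features)]
        weights = {f: w for f, w in zip(feats, rng.normal(size=n_features))}

        def model(x):  # mildly non-additive so the test is not trivial
            score = sum(w * x[f] for f, w in weights.items()) + 0.3 * x[feats[0]] * x[feats[1]]
            p = 1 / (1 + np.exp(-score))
            return pd.DataFrame({"A": p, "B": 1 - p}, index=x.index)

        background = pd.DataFrame(rng.normal(size=(6, n_features)), columns=feats)
        sample = pd.Series(rng.normal(size=n_features), index=feats)
        recs = es.shapley_sampling(
            model,
            background,
            sample.to_frame().T,
            n_permutations=math.factorial(n_features),
            seed=0,
        )
        oracle = es.exact_shapley_oracle(model, background, sample, "A")
        got = {r.feature_name: r.shap_value for r in recs if r.class_name == "A"}
        for f in feats:
            assert got[f] == pytest.approx(oracle[f], abs=1e-6)

    def test_local_accuracy(self):
        rng = np.random.default_rng(2)
        feats = ["f1", "f2", "f3"]
        model = linear_model({"f1": 0.5, "f2": -0.7, "f3": 0.2})
        background = pd.DataFrame(rng.normal(size=(5, 3)), columns=feats)
        samples = pd.DataFrame(rng.normal(size=(3, 3)), columns=feats)
        recs = es.shapley_sampling(model, background, samples, n_permutations=12, seed=0)
        outputs = model(samples)
        for (sid, cls), grp in pd.DataFrame(
            {
                "sid": [r.sample_id for r in recs],
                "cls": [r.class_name for r in recs],
                "phi": [r.shap_value for r in recs],
                "base": [r.base_value for r in recs],
            }
        ).groupby(["sid", "cls"]):
            reconstructed = grp["base"].iloc[0] + grp["phi"].sum()
            assert reconstructed == pytest.approx(outputs.loc[sid, cls], abs=1e-9)

    def test_estimation_error_shrinks_with_budget(self):
        rng = np.random.default_rng(3)
        feats = [f"f{i}" for i in range(4)]

        def model(x):
            score = x[feats[0]] * x[feats[1]] + np.sin(x[feats[2]]) - 0.5 * x[feats[3]]
            p = 1 / (1 + np.exp(-score))
            return pd.DataFrame({"A": p, "B": 1 - p}, index=x.index)

        background = pd.DataFrame(rng.normal(size=(5, 4)), columns=feats)
        sample = pd.Series(rng.normal(size=4), index=feats)
        oracle = es.exact_shapley_oracle(model, background, sample, "A")

        def mean_error(budget):
            errs = []
            for seed in range(4):
                recs = es.shapley_sampling(
                    model, background, sample.to_frame().T, n_permutations=budget, seed=seed
                )
                got = {r.feature_name: r.shap_value for r in recs if r.class_name == "A"}
                errs.append(max(abs(got[f] - oracle[f]) for f in feats))
            return np.mean(errs)

        e_small, e_mid, e_exact = mean_error(4), mean_error(12), mean_error(24)
        assert e_small >= e_mid >= e_exact
        assert e_exact < 1e-9  # 24 = 4! permutations: exact

    def test_constant_model_gives_zero_attributions(self):
        def model(x):
            return pd.DataFrame({"A": np.full(len(x), 0.4), "B": np.full(len(x), 0.6)}, index=x.index)

        background = make_table({"f1": [0.0, 1.0], "f2": [1.0, 2.0]})
        samples = make_table({"f1": [5.0], "f2": [5.0]})
        recs = es.shapley_sampling(model, background, samples, n_permutations=4, seed=0)
        assert all(abs(r.shap_value) < 1e-12 for r in recs)


class TestImportanceTable:
    def test_single_record_ranks_first_with_its_magnitude(self):
        rec = es.Attribution("s1", "A", "f1", -0.4, 1.0, 0.5)
        table = es.importance_table([rec])
        frame = table.per_class["A"]
        assert frame.iloc[0]["feature"] == "f1"
        assert frame.iloc[0]["mean_abs_shap"] == pytest.approx(0.4)

    def test_matches_group_by_mean_oracle(self):
        rng = np.random.default_rng(4)
        recs = [
            es.Attribution(f"s{i}", cls, feat, rng.normal(), rng.normal(), 0.3)
            for i in range(10)
            for cls in ("A", "B")
            for feat in ("f1", "f2", "f3")
        ]
        table = es.importance_table(recs)
        raw = pd.DataFrame(
            {
                "cls": [r.class_name for r in recs],
                "feat": [r.feature_name for r in recs],
                "abs_phi": [abs(r.shap_value) for r in recs],
            }
        )
        for cls in ("A", "B"):
            oracle = (
                raw[raw.cls == cls].groupby("feat")["abs_phi"].mean().sort_values(ascending=False)
            )
            got = table.per_class[cls].set_index("feature")["mean_abs_shap"]
            assert list(got.index) == list(oracle.index)
            assert np.allclose(got.to_numpy(), oracle.to_numpy())

    def test_dominant_feature_ranked_first(self):
        model = linear_model({"f1": 5.0, "f2": 0.1})
        rng = np.random.default_rng(5)
        background = pd.DataFrame(rng.normal(size=(8, 2)), columns=["f1", "f2"])
        samples = pd.DataFrame(rng.normal(size=(6, 2)), columns=["f1", "f2"])
        recs = es.shapley_sampling(model, background, samples, n_permutations=2, seed=0)
        table = es.importance_table(recs)
        assert table.per_class["A"].iloc[0]["feature"] == "f1"
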