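import numpy as np
import pandas as pd
import pytest

from mirsig._classifiers import make_classifier
from mirsig.platform_map import (
    PlatformMap,
    aggregate_mature_to_stemloop,
    compute_reference_stats,
    fit_platform_scale,
    moment_anchor,
    read_mature_map_tsv,
    read_platform_scale_tsv,
    read_reference_stats_tsv,
    rmse_objective,
    standardize_to_reference,
    write_mature_map_tsv,
    write_platform_scale_tsv,
    write_reference_stats_tsv,
    zscore_to_reference,
)
from mirsig.synthetic import SyntheticSpec, generate_labeled_expression


@pytest.fixture(scope="module")
def reference_setup():
    """Reference half + external half of one 20-feature, 4-class population,
    with a classifier trained on the standardized reference."""
    spec = SyntheticSpec(
        n_samples=700,
        n_classes=4,
        class_proportions=(0.4, 0.3, 0.2, 0.1),
        n_features=20,
        n_informative=20,
        effect_size=1.5,
        seed=11,
    )
    X, labels, _ = generate_labeled_expression(spec)
    codes = labels["class_code"].to_numpy()
    X_ref, y_ref = X.iloc[:300], codes[:300]
    X_ext, y_ext = X.iloc[300:], codes[300:]
    stats = compute_reference_stats(X_ref)
    clf = make_classifier("logistic_regression", 0)
    clf.fit(standardize_to_reference(X_ref, stats).to_numpy(), y_ref)
    return X_ext, y_ext, stats, clf


def external_zscores(X_ext, stats, a_true):
    """Fabricate platform z-scores against the *reference* statistics."""
    return ((X_ext / np.asarray(a_true)) - stats["mean"]) / stats["sd"]


class TestMatureAggregation:
    def test_mature_column_copied_to_stemloop_name(self):
        X = pd.DataFrame({"hsa-miR-10b": [5.0, 7.0]}, index=["s1", "s2"])
        mapping = pd.DataFrame({"mature": ["hsa-miR-10b"], "stemloop": ["hsa-mir-10b"]})
        out = aggregate_mature_to_stemloop(X, mapping)
        assert out["hsa-mir-10b"].tolist() == [5.0, 7.0]

    def test_one_mature_shared_by_two_stemloops(self):
        # one mature sequence produced by two loci gets copied to both
        X = pd.DataFrame({"hsa-miR-135a": [1.0, 2.0]}, index=["s1", "s2"])
        mapping = pd.DataFrame(
            {
                "mature": ["hsa-miR-135a", "hsa-miR-135a"],
                "stemloop": ["hsa-mir-135a-1", "hsa-mir-135a-2"],
            }
        )
        out = aggregate_mature_to_stemloop(X, mapping)
        assert (out["hsa-mir-135a-1"] == out["hsa-mir-135a-2"]).all()

    def test_unmapped_features_dropped_with_count(self):
        X = pd.DataFrame(
            {"hsa-miR-10b": [5.0], "hsa-miR-999": [1.0]}, index=["s1"]
        )
        mapping = pd.DataFrame({"mature": ["hsa-miR-10b"], "stemloop": ["hsa-mir-10b"]})
        out = aggregate_mature_to_stemloop(X, mapping)
        assert out.attrs["dropped_features"] == 1

    def test_empty_intersection_is_an_error(self):
        X = pd.DataFrame({"hsa-miR-1": [1.0]}, index=["s1"])
        mapping = pd.DataFrame({"mature": ["hsa-miR-2"], "stemloop": ["hsa-mir-2"]})
        with pytest.raises(ValueError, match="overlap"):
            aggregate_mature_to_stemloop(X, mapping)


class TestZscoreToReference:
    def _stats(self):
        return pd.DataFrame({"mean": [10.0], "sd": [2.0]}, index=pd.Index(["m"], name="feature"))

    def test_zero_zscore_maps_to_reference_mean(self):
        Z = pd.DataFrame({"m": [0.0]}, index=["s1"])
        out = zscore_to_reference(Z, self._stats(), pd.Series({"m": 1.0}))
        assert out.loc["s1", "m"] == 10.0

    def test_direct_arithmetic(self):
        Z = pd.DataFrame({"m": [1.0]}, index=["s1"])
        out = zscore_to_reference(Z, self._stats(), pd.Series({"m": 3.0}))
        assert out.loc["s1", "m"] == pytest.approx(36.0)

    def test_inverse_pair_with_re_zscoring(self):
        rng = np.random.default_rng(0)
        Z = pd.DataFrame({"m": rng.normal(size=8)}, index=[f"s{i}" for i in range(8)])
        stats = self._stats()
        X = zscore_to_reference(Z, stats, pd.Series({"m": 1.0}))
        back = (X - stats["mean"].to_numpy()) / stats["sd"].to_numpy()
        np.testing.assert_allclose(back.to_numpy(), Z.to_numpy())

    def test_linear_in_scale(self):
        rng = np.random.default_rng(1)
        Z = pd.DataFrame({"m": rng.normal(size=5)}, index=[f"s{i}" for i in range(5)])
        x1 = zscore_to_reference(Z, self._stats(), pd.Series({"m": 1.0}))
        x2 = zscore_to_reference(Z, self._stats(), pd.Series({"m": 2.0}))
        np.testing.assert_allclose(x2.to_numpy(), 2 * x1.to_numpy())

    def test_misaligned_features_are_an_error(self):
        Z = pd.DataFrame({"other": [0.0]}, index=["s1"])
        with pytest.raises(ValueError, match="aligned"):
            zscore_to_reference(Z, self._stats(), pd.Series({"other": 1.0}))


class TestRmseObjective:
    def test_zero_when_predictions_match(self, reference_setup):
        X_ext, y_ext, stats, clf = reference_setup
        Z = external_zscores(X_ext, stats, np.ones(20))
        pred = clf.predict(
            standardize_to_reference(
                zscore_to_reference(Z, stats, pd.Series(1.0, index=Z.columns)), stats
            ).to_numpy()
        )
        value = rmse_objective(np.ones(20), Z, pred, clf, stats)
        assert value == 0.0

    def test_code_arithmetic_on_stub_model(self):
        class StubModel:
            classes_ = np.array([1, 2, 4])

            def predict(self, X):
                return np.array([1, 2])

        stats = pd.DataFrame(
            {"mean": [0.0], "sd": [1.0]}, index=pd.Index(["m"], name="feature")
        )
        Z = pd.DataFrame({"m": [0.0, 0.0]}, index=["s1", "s2"])
        # predicted [1, 2] vs actual [1, 4]: sqrt((0^2 + 2^2) / 2)
        value = rmse_objective(np.ones(1), Z, [1, 4], StubModel(), stats)
        assert value == pytest.approx(np.sqrt(2.0))

    def test_sample_order_invariance(self, reference_setup):
        X_ext, y_ext, stats, clf = reference_setup
        Z = external_zscores(X_ext, stats, np.ones(20))
        perm = np.random.default_rng(0).permutation(len(Z))
        v1 = rmse_objective(np.ones(20), Z, y_ext, clf, stats)
        v2 = rmse_objective(np.ones(20), Z.iloc[perm], y_ext[perm], clf, stats)
        assert v1 == pytest.approx(v2)

    def test_unseen_class_code_is_an_error(self, reference_setup):
        X_ext, y_ext, stats, clf = reference_setup
        Z = external_zscores(X_ext, stats, np.ones(20))
        bad = y_ext.copy()
        bad[0] = 99
        with pytest.raises(ValueError, match="unseen"):
            rmse_objective(np.ones(20), Z, bad, clf, stats)


class TestFitPlatformScale:
    def test_monotone_acceptance_and_determinism(self, reference_setup):
        X_ext, y_ext, stats, clf = reference_setup
        rng = np.random.default_rng(7)
        a_true = rng.uniform(0.5, 2.0, size=20)
        Z = external_zscores(X_ext, stats, a_true)
        r1 = fit_platform_scale(Z, y_ext, clf, stats, budget=300, seed=5)
        r2 = fit_platform_scale(Z, y_ext, clf, stats, budget=300, seed=5)
        assert r1.objective_final <= r1.objective_init
        pd.testing.assert_series_equal(r1.scale, r2.scale)
        assert r1.n_evaluations <= 300 + 2

    def test_self_map_recovery_stays_near_unity(self, reference_setup):
        """External data drawn from the reference population (a_true = 1,
        no noise): the fitted scale improves the objective and its median
        error stays inside the loose identifiability tolerance."""
        X_ext, y_ext, stats, clf = reference_setup
        Z = external_zscores(X_ext, stats, np.ones(20))
        res = fit_platform_scale(Z, y_ext, clf, stats, budget=1000, seed=3)
        assert res.objective_final <= res.objective_init
        assert float(np.median(np.abs(res.scale.to_numpy() - 1.0))) <= 0.2

    def test_moment_anchor_tracks_true_scale(self, reference_setup):
        X_ext, y_ext, stats, clf = reference_setup
        rng = np.random.default_rng(7)
        a_true = rng.uniform(0.5, 2.0, size=20)
        Z = external_zscores(X_ext, stats, a_true)
        anchor = moment_anchor(Z, stats)
        rel = np.abs(anchor - a_true) / a_true
        assert float(np.median(rel)) <= 0.2

    def test_model_object_round_trip(self, reference_setup):
        X_ext, y_ext, stats, clf = reference_setup
        Z = external_zscores(X_ext, stats, np.ones(20))
        model = PlatformMap(Z, y_ext, clf, stats, platform="sim")
        res = model.fit(budget=100, seed=1)
        mapped = model.apply(res)
        assert mapped.shape == Z.shape
        assert "sim" in res.summary()


def test_tsv_round_trips(tmp_path):
    mapping = pd.DataFrame(
        {"mature": ["hsa-miR-10b"], "stemloop": ["hsa-mir-10b"]}
    )
    write_mature_map_tsv(mapping, tmp_path / "map.tsv")
    pd.testing.assert_frame_equal(read_mature_map_tsv(tmp_path / "map.tsv"), mapping)

    stats = pd.DataFrame(
        {"mean": [1.5, 2.0], "sd": [0.5, 1.0]},
        index=pd.Index(["m1", "m2"], name="feature"),
    )
    write_reference_stats_tsv(stats, tmp_path / "stats.tsv")
    pd.testing.assert_frame_equal(read_reference_stats_tsv(tmp_path / "stats.tsv"), stats)

    scale = pd.Series([1.25, 0.8], index=pd.Index(["m1", "m2"], name="feature"), name="a")
    write_platform_scale_tsv(scale, tmp_path / "scale.tsv")
    pd.testing.assert_series_equal(read_platform_scale_tsv(tmp_path / "scale.tsv"), scale)
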