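"""Stepwise discriminant selection, QDA, training configurations and
validation."""

import numpy as np
import pandas as pd
import pytest

from melanomorph.classify import (TrainingConfig, build_training_set,
                                  evaluate, fit_qda, predict_fossil,
                                  run_classification, stepwise_select)
from melanomorph.measurements import FEATURE_NAMES, compute_feature_table
from melanomorph.simulate import SlabConfig, simulate_slab
from melanomorph.taphonomy import ShrinkageScenario, apply_correction


@pytest.fixture(scope="module")
def slab_fossil(models):
    return simulate_slab(SlabConfig(n_locations=20, n_platelet=6, seed=77), models)


class TestTrainingConfigs:
    def test_invalid_ids(self):
        with pytest.raises(ValueError):
            TrainingConfig(0)
        with pytest.raises(ValueError):
            TrainingConfig(7)

    def test_scheme_properties(self):
        assert TrainingConfig(6).shrinkage_corrected
        assert not TrainingConfig(1).shrinkage_corrected
        assert TrainingConfig(4).non_platelet_only
        assert TrainingConfig(5).non_platelet_only
        assert not TrainingConfig(6).non_platelet_only

    def test_dataset1_merges_platelets_dataset2_separates(self, library, slab_fossil):
        t1 = build_training_set(library, slab_fossil, TrainingConfig(1))
        t2 = build_training_set(library, slab_fossil, TrainingConfig(2))
        assert t1.X.equals(t2.X)  # identical rows, labels differ only
        assert "hummingbird_platelet" not in set(t1.y)
        assert "hummingbird_platelet" in set(t2.y)
        differs = t1.y != t2.y
        assert set(t2.y[differs]) == {"hummingbird_platelet"}

    def test_dataset3_merges_nonhummingbird_platelets_into_rod_iridescence(
            self, library, slab_fossil):
        t3 = build_training_set(library, slab_fossil, TrainingConfig(3))
        assert "platelet_iridescence" not in set(t3.y)
        assert "hummingbird_platelet" in set(t3.y)

    def test_dataset5_separates_penguin(self, library, slab_fossil):
        t5 = build_training_set(library, slab_fossil, TrainingConfig(5),
                                non_platelet_fossil=slab_fossil)
        assert "penguin_brown_black" in set(t5.y)
        t1 = build_training_set(library, slab_fossil, TrainingConfig(1))
        assert "penguin_brown_black" not in set(t1.y)

    def test_dataset45_require_partition(self, library, slab_fossil):
        with pytest.raises(ValueError, match="non-platelet"):
            build_training_set(library, slab_fossil, TrainingConfig(4))

    def test_dataset6_scales_only_dimensional_features(self, library, slab_fossil):
        corrected = apply_correction(slab_fossil, ShrinkageScenario(0.20))
        t1 = build_training_set(library, slab_fossil, TrainingConfig(1))
        t6 = build_training_set(library, corrected, TrainingConfig(6))
        ratio = t6.fossil_X["length_mean"] / t1.fossil_X["length_mean"]
        assert np.allclose(ratio, 1.25, rtol=1e-12)
        for col in FEATURE_NAMES:
            if col in ("length_mean", "diameter_mean"):
                continue
            assert np.allclose(t6.fossil_X[col], t1.fossil_X[col], atol=1e-12)

    def test_small_class_error(self, library, slab_fossil):
        tiny = [s for s in library if s.colour_label != "grey"] + \
               [s for s in library if s.colour_label == "grey"][:2]
        with pytest.raises(ValueError, match="grey"):
            build_training_set(tiny, slab_fossil, TrainingConfig(1))


class TestStepwise:
    @staticmethod
    def _toy(seed, n=200, informative_shift=3.0):
        rng = np.random.default_rng(seed)
        X, y = [], []
        for k, label in enumerate(("a", "b")):
            block = rng.normal([informative_shift * k, 0.0], 1.0, (n, 2))
            X.append(block)
            y += [label] * n
        return (pd.DataFrame(np.vstack(X), columns=["informative", "noise"]),
                np.array(y))

    def test_noise_eliminated_informative_kept(self):
        kept = 0
        for rep in range(40):
            X, y = self._toy(1000 + rep)
            res = stepwise_select(X, y)
            kept += ("informative" in res.retained) and ("noise" not in res.retained)
        assert kept >= 36

    def test_alpha_one_retains_all(self):
        X, y = self._toy(3)
        res = stepwise_select(X, y, alpha=1.0)
        assert set(res.retained) == {"informative", "noise"}

    def test_collinear_duplicate_removed(self):
        X, y = self._toy(4)
        X["copy"] = X["informative"] * 2.0 + 1.0  # |r| = 1 with informative
        res = stepwise_select(X, y)
        assert "copy" in res.collinear_dropped or "informative" in res.collinear_dropped
        assert len({"copy", "informative"} & set(res.retained)) == 1

    def test_all_eliminated_raises_with_trace(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame(rng.normal(0, 1, (60, 2)), columns=["u", "v"])
        y = np.array(["a"] * 30 + ["b"] * 30)
        with pytest.raises(ValueError, match="eliminated"):
            stepwise_select(X, y, alpha=1e-12)


class TestQda:
    def test_closed_form_1d_boundary(self):
        # equal variance, equal priors: boundary at the midpoint of means
        m1, m2, s = 0.0, 4.0, 1.5
        rng = np.random.default_rng(6)
        X = np.r_[rng.normal(m1, s, 500), rng.normal(m2, s, 500)][:, None]
        y = np.array(["a"] * 500 + ["b"] * 500)
        # force exactly equal class covariance by using symmetric data
        Xs = np.r_[X[:500] - X[:500].mean() + m1, X[:500] - X[:500].mean() + m2]
        model = fit_qda(Xs, y)
        mid = (m1 + m2) / 2
        eps = 1e-6
        lo, _ = model.predict(np.array([[mid - eps]]))
        hi, _ = model.predict(np.array([[mid + eps]]))
        assert lo[0] == "a" and hi[0] == "b"
        # the discriminant scores cross at the midpoint to high precision
        scores = model.discriminant_scores(np.array([[mid]]))
        assert abs(scores[0, 0] - scores[0, 1]) < 1e-9

    def test_posterior_at_class_mean(self):
        rng = np.random.default_rng(7)
        X = np.vstack([rng.normal(0, 1, (100, 2)), rng.normal(10, 1, (100, 2))])
        y = np.array(["a"] * 100 + ["b"] * 100)
        model = fit_qda(X, y)
        _, post = model.predict(model.means[0][None, :])
        assert post[0, 0] > 0.99

    def test_duplication_sufficiency(self):
        rng = np.random.default_rng(8)
        X = rng.normal(0, 1, (60, 3))
        X[30:] += 4
        y = np.array(["a"] * 30 + ["b"] * 30)
        m1 = fit_qda(X, y)
        m2 = fit_qda(np.vstack([X, X]), np.r_[y, y])
        assert np.allclose(m1.means, m2.means)
        assert np.allclose(m1.covariances, m2.covariances)

    def test_posteriors_sum_to_one(self, library):
        feats = compute_feature_table(library)
        X = feats[list(FEATURE_NAMES)]
        y = feats["colour_label"].to_numpy()
        model = fit_qda(X, y)
        _, post = model.predict(X)
        assert np.allclose(post.sum(1), 1.0, atol=1e-12)

    def test_matches_sklearn_qda(self):
        from sklearn.discriminant_analysis import QuadraticDiscriminantAnalysis
        rng = np.random.default_rng(13)
        blocks, labels = [], []
        for k, (mu, sd) in enumerate((((0, 0, 0), 1.0), ((2, -1, 1), 1.5),
                                      ((-2, 2, 0), 0.7))):
            blocks.append(rng.normal(mu, sd, (100, 3)))
            labels += [f"c{k}"] * 100
        X = np.vstack(blocks)
        y = np.array(labels)
        ours, _ = fit_qda(X, y, priors="frequency").predict(X)
        theirs = QuadraticDiscriminantAnalysis().fit(X, y).predict(X)
        assert (ours == theirs).mean() > 0.99

    def test_equal_covariance_limit_reproduces_lda(self):
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
        rng = np.random.default_rng(9)
        X = np.vstack([rng.normal(0, 1, (150, 3)), rng.normal(1.5, 1, (150, 3))])
        y = np.array(["a"] * 150 + ["b"] * 150)
        pooled = np.cov((X - np.vstack([
            np.tile(X[y == c].mean(0), ((y == c).sum(), 1)) for c in ("a", "b")
        ])).T, ddof=0)
        model = fit_qda(X, y, priors="frequency")
        forced = fit_qda(X, y, priors="frequency")
        forced.covariances[:] = pooled + 1e-8 * np.eye(3)
        forced.__post_init__()
        lda = LinearDiscriminantAnalysis(solver="lsqr").fit(X, y)
        ours, _ = forced.predict(X)
        assert (ours == lda.predict(X)).mean() > 0.99

    def test_affine_invariance_of_predictions(self, library):
        feats = compute_feature_table(library)
        X = feats[list(FEATURE_NAMES)]
        y = feats["colour_label"].to_numpy()
        base, _ = fit_qda(X, y).predict(X)
        Xa = X * 3.7 + 11.0
        scaled, _ = fit_qda(Xa, y).predict(Xa)
        assert (base == scaled).all()


class TestEvaluate:
    def test_separable_library_perfect(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(np.vstack([rng.normal(0, 0.1, (30, 2)),
                                    rng.normal(10, 0.1, (30, 2))]),
                         columns=["u", "v"])
        y = np.array(["a"] * 30 + ["b"] * 30)
        rep = evaluate(X, y, ["u", "v"])
        assert rep.self_test_accuracy == 1.0
        assert rep.loo_accuracy == 1.0

    def test_chance_level_for_identical_distributions(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(0, 1, (120, 3)), columns=["u", "v", "w"])
        y = np.array(["a"] * 60 + ["b"] * 60)
        rep = evaluate(X, y, ["u", "v", "w"])
        half_width = 1.96 * np.sqrt(0.25 / 120)
        assert abs(rep.loo_accuracy - 0.5) < half_width + 0.05

    def test_self_test_optimism(self):
        # resubstitution accuracy >= LOO accuracy on average
        diffs = []
        for rep in range(25):
            rng = np.random.default_rng(12_000 + rep)
            X = pd.DataFrame(np.vstack([rng.normal(0, 1, (25, 2)),
                                        rng.normal(1.0, 1, (25, 2))]),
                             columns=["u", "v"])
            y = np.array(["a"] * 25 + ["b"] * 25)
            r = evaluate(X, y, ["u", "v"])
            diffs.append(r.self_test_accuracy - r.loo_accuracy)
        assert np.mean(diffs) >= 0.0


class TestFossilPrediction:
    def test_centroid_classified_to_own_class(self, library):
        feats = compute_feature_table(library)
        X = feats[list(FEATURE_NAMES)]
        y = feats["colour_label"].to_numpy()
        model = fit_qda(X, y)
        for i, cls in enumerate(model.classes):
            label, post = model.predict(model.means[i][None, :])
            assert label[0] == cls

    def test_missing_variable_error(self, library):
        feats = compute_feature_table(library)
        model = fit_qda(feats[list(FEATURE_NAMES)],
                        feats["colour_label"].to_numpy())
        with pytest.raises(ValueError, match="missing"):
            model.predict(feats[["length_mean"]])

    def test_synthetic_fossil_recovered(self, library, models, slab_fossil):
        # slab samples come from the black and platelet classes; QDA should
        # recover those labels at high per-sample accuracy
        t1 = build_training_set(library, slab_fossil, TrainingConfig(1))
        selection, model, report, pred = run_classification(t1)
        truth = {s.sample_id: ("platelet_iridescence" if s.stacking_evidence
                               else "black") for s in slab_fossil}
        acc = np.mean([pred.loc[sid, "predicted_colour"] == truth[sid]
                       for sid in pred.index])
        assert acc >= 0.9
        post_cols = [c for c in pred.columns if c.startswith("p_")]
        assert np.allclose(pred[post_cols].sum(1), 1.0, atol=1e-9)
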