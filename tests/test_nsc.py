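"""Nearest shrunken centroids: hand examples, oracle equivalence, LOOCV."""

import math

import numpy as np
import pandas as pd
import pytest

from ffpesig.nsc import NearestShrunkenCentroids, nsc_loocv, nsc_predict, nsc_train

from nsc_oracle import oracle_fit, oracle_predict, standardized_nearest_centroid_predict


def make_xy(X, y, genes=None, samples=None):
    X = np.asarray(X, dtype=float)
    genes = genes or [f"g{j}" for j in range(X.shape[0])]
    samples = samples or [f"S{i}" for i in range(X.shape[1])]
    return (
        pd.DataFrame(X, index=genes, columns=samples),
        pd.Series(list(y), index=samples),
    )


def random_instance(rng, n_genes=None, n_samples=None):
    n_genes = n_genes or int(rng.integers(2, 21))
    n_samples = n_samples or int(rng.integers(8, 31))
    X = rng.normal(0, 1, size=(n_genes, n_samples))
    y = ["A"] * (n_samples // 2) + ["B"] * (n_samples - n_samples // 2)
    informative = rng.choice(n_genes, size=max(1, n_genes // 3), replace=False)
    for j in informative:
        X[j, : n_samples // 2] += rng.normal(1.0, 0.3)
    return make_xy(X, y)


class TestTrain:
    def test_single_gene_hand_computation(self):
        """Classes {0,2} and {4,6}: pooled sd sqrt(2); d checked by hand."""
        Xdf, y = make_xy([[0.0, 2.0, 4.0, 6.0]], ["A", "A", "B", "B"])
        model = nsc_train(Xdf, y, delta=0.0)
        s = math.sqrt(2)
        assert model.pooled_within_sd.iloc[0] == pytest.approx(s)
        assert model.s0 == pytest.approx(s)
        assert model.overall_centroid.iloc[0] == pytest.approx(3.0)
        assert model.class_centroids.loc["g0", "A"] == pytest.approx(1.0)
        assert model.class_centroids.loc["g0", "B"] == pytest.approx(5.0)
        m = math.sqrt(1 / 2 - 1 / 4)
        assert model.m_k["A"] == pytest.approx(m)
        assert model.d.loc["g0", "A"] == pytest.approx((1 - 3) / (m * 2 * s))
        assert model.d.loc["g0", "B"] == pytest.approx((5 - 3) / (m * 2 * s))

    def test_zero_delta_keeps_centroids_exactly(self, rng):
        Xdf, y = random_instance(rng)
        model = nsc_train(Xdf, y, delta=0.0)
        pd.testing.assert_frame_equal(model.shrunken_centroids, model.class_centroids)
        pd.testing.assert_frame_equal(model.d_shrunk, model.d)

    def test_total_shrinkage_collapses_to_overall_centroid(self, rng):
        Xdf, y = random_instance(rng)
        dmax = float(nsc_train(Xdf, y, 0.0).d.abs().to_numpy().max())
        model = nsc_train(Xdf, y, delta=dmax + 1e-9)
        assert model.surviving_genes == []
        for k in model.classes:
            assert np.allclose(model.shrunken_centroids[k], model.overall_centroid)

    def test_class_with_one_sample_rejected(self):
        Xdf, y = make_xy([[0.0, 1.0, 2.0]], ["A", "B", "B"])
        with pytest.raises(ValueError):
            nsc_train(Xdf, y)

    def test_negative_delta_rejected(self, rng):
        Xdf, y = random_instance(rng)
        with pytest.raises(ValueError):
            nsc_train(Xdf, y, delta=-0.1)

    def test_surviving_genes_non_increasing_in_delta(self, rng):
        Xdf, y = random_instance(rng)
        dmax = float(nsc_train(Xdf, y, 0.0).d.abs().to_numpy().max())
        prev = None
        for delta in np.linspace(0, dmax, 8):
            genes = set(nsc_train(Xdf, y, float(delta)).surviving_genes)
            if prev is not None:
                assert genes <= prev
            prev = genes


class TestPredict:
    def test_hand_discriminant_example(self):
        """Centroids −1/+1, unit pooled scale, x = 0.9 → the +1 class."""
        Xdf, y = make_xy(
            [[-2.0, 0.0, 0.0, 2.0]], ["A", "A", "B", "B"]
        )
        model = nsc_train(Xdf, y, delta=0.0)
        # forces: centroids A=-1, B=+1; s_j = sqrt(((−2+1)²+(0+1)²+(0−1)²+(2−1)²)/2)=sqrt(2)
        label, scores = nsc_predict(model, pd.Series({"g0": 0.9}))
        assert label == "B"
        assert scores["B"] < scores["A"]

    def test_sample_at_centroid_predicts_its_class(self, rng):
        Xdf, y = random_instance(rng)
        model = nsc_train(Xdf, y, delta=0.0, priors={"A": 0.5, "B": 0.5})
        for k in model.classes:
            label, _ = nsc_predict(model, model.shrunken_centroids[k])
            assert label == k

    def test_total_shrinkage_with_skewed_priors_predicts_prior_class(self, rng):
        Xdf, y = random_instance(rng)
        dmax = float(nsc_train(Xdf, y, 0.0).d.abs().to_numpy().max())
        model = nsc_train(Xdf, y, delta=dmax + 1.0, priors={"A": 0.9, "B": 0.1})
        labels, _ = model.predict(Xdf)
        assert set(labels) == {"A"}

    def test_exact_tie_goes_to_first_class(self):
        Xdf, y = make_xy([[0.0, 2.0, 0.0, 2.0]], ["A", "A", "B", "B"])
        model = nsc_train(Xdf, y, delta=0.0, priors={"A": 0.5, "B": 0.5})
        # both centroids equal → all discriminants tie
        label, _ = nsc_predict(model, pd.Series({"g0": 5.0}))
        assert label == "A"

    def test_missing_gene_named(self, rng):
        Xdf, y = random_instance(rng)
        model = nsc_train(Xdf, y)
        with pytest.raises(ValueError, match="g0"):
            model.predict(Xdf.drop(index="g0"))


class TestOracleEquivalence:
    @pytest.mark.parametrize("m_variant", ["minus", "plus"])
    def test_matches_naive_loop_oracle(self, m_variant):
        """d, d', surviving genes and predictions agree with an independent
        naive-loop implementation on random instances across the grid."""
        rng = np.random.default_rng(2024)
        for _ in range(8):
            Xdf, y = random_instance(rng)
            X = Xdf.to_numpy()
            dmax = float(nsc_train(Xdf, y, 0.0, m_variant=m_variant).d.abs().to_numpy().max())
            for delta in np.linspace(0, dmax * 1.05, 5):
                model = nsc_train(Xdf, y, float(delta), m_variant=m_variant)
                ora = oracle_fit(X, list(y), float(delta), m_variant=m_variant)
                for ki, k in enumerate(model.classes):
                    assert np.allclose(model.d[k], ora["d"][k], atol=1e-10)
                    assert np.allclose(model.d_shrunk[k], ora["d_shrunk"][k], atol=1e-10)
                surv = [Xdf.index[j] for j in ora["surviving"]]
                assert model.surviving_genes == surv
                for i in range(0, X.shape[1], 7):
                    lab, _ = nsc_predict(model, Xdf.iloc[:, i])
                    lab_o, _ = oracle_predict(ora, X[:, i])
                    assert lab == lab_o

    def test_zero_delta_equals_standardized_nearest_centroid(self):
        rng = np.random.default_rng(99)
        Xdf, y = random_instance(rng)
        model = nsc_train(Xdf, y, delta=0.0)
        for i in range(Xdf.shape[1]):
            lab, _ = nsc_predict(model, Xdf.iloc[:, i])
            ref = standardized_nearest_centroid_predict(
                Xdf.to_numpy(), list(y), Xdf.iloc[:, i].to_numpy()
            )
            assert lab == ref


class TestLOOCV:
    def test_separable_classes_have_zero_error(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 0.2, size=(10, 20))
        X[:, :10] += 5.0  # effect ≫ noise
        Xdf, y = make_xy(X, ["A"] * 10 + ["B"] * 10)
        cv = nsc_loocv(Xdf, y, positive_class="A", grid_size=10)
        assert cv.errors[0] == 0.0
        assert cv.error_rate == 0.0

    def test_permuted_labels_give_chance_level_error(self):
        rng = np.random.default_rng(17)
        X = rng.normal(0, 1, size=(12, 40))
        labels = np.array(["A"] * 20 + ["B"] * 20)
        rng.shuffle(labels)
        Xdf, y = make_xy(X, labels)
        # balanced priors reflect the balanced design; fold-wise observed
        # proportions would otherwise bias heavily-shrunk folds toward the
        # class the held-out sample does not belong to
        cv = nsc_loocv(
            Xdf, y, priors={"A": 0.5, "B": 0.5}, positive_class="A", grid_size=15
        )
        assert 0.3 <= cv.error_rate <= 0.7

    def test_delta_tie_broken_to_largest(self):
        rng = np.random.default_rng(5)
        X = rng.normal(0, 0.2, size=(6, 16))
        X[:3, :8] += 4.0
        Xdf, y = make_xy(X, ["A"] * 8 + ["B"] * 8)
        cv = nsc_loocv(Xdf, y, positive_class="A", grid_size=12)
        best = cv.errors.min()
        tied = np.flatnonzero(cv.errors == best)
        assert cv.chosen_delta == pytest.approx(cv.delta_grid[tied.max()])

    def test_sensitivity_specificity_counts_consistent(self):
        rng = np.random.default_rng(31)
        X = rng.normal(0, 1, size=(8, 24))
        X[:4, :12] += 1.2
        Xdf, y = make_xy(X, ["MUT"] * 12 + ["WT"] * 12)
        cv = nsc_loocv(Xdf, y, positive_class="MUT")
        assert cv.sensitivity == pytest.approx(cv.n_true_positive / cv.n_positive)
        assert cv.specificity == pytest.approx(cv.n_true_negative / cv.n_negative)
        assert 0 <= cv.sensitivity <= 1 and 0 <= cv.specificity <= 1
        assert cv.error_rate == pytest.approx(cv.n_misclassified / cv.n_samples)
        quotient = f"{cv.sensitivity:.3f} = {cv.n_true_positive}/{cv.n_positive}"
        assert quotient in cv.summary()

    def test_class_too_small_for_loocv_rejected(self):
        Xdf, y = make_xy(np.random.default_rng(0).normal(size=(4, 6)),
                         ["A", "A", "B", "B", "B", "B"])
        with pytest.raises(ValueError, match="<2"):
            nsc_loocv(Xdf, y, positive_class="A")

    def test_informative_gene_recovery_across_seeds(self):
        """Where exactly genes G* carry the class effect, the chosen-delta
        surviving set overlaps G* with Jaccard >= 0.5 on average."""
        jaccards = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            n_genes, n = 16, 30
            X = rng.normal(0, 1, size=(n_genes, n))
            informative = set(rng.choice(n_genes, size=4, replace=False))
            for j in informative:
                X[j, : n // 2] += 2.0
            Xdf, y = make_xy(X, ["A"] * (n // 2) + ["B"] * (n - n // 2))
            cv = nsc_loocv(Xdf, y, positive_class="A", grid_size=20)
            chosen = {int(g[1:]) for g in cv.surviving_genes}
            jacc = len(chosen & informative) / len(chosen | informative)
            jaccards.append(jacc)
        assert float(np.mean(jaccards)) >= 0.5


class TestModelSurface:
    def test_model_class_mirrors_functions(self, rng):
        Xdf, y = random_instance(rng)
        mdl = NearestShrunkenCentroids(Xdf, y, positive_class="A")
        fit = mdl.fit(delta=0.3)
        ref = nsc_train(Xdf, y, delta=0.3)
        pd.testing.assert_frame_equal(fit.shrunken_centroids, ref.shrunken_centroids)

    def test_from_dataframe_constructor(self, rng):
        Xdf, y = random_instance(rng)
        df = Xdf.T.copy()
        df["label"] = y
        mdl = NearestShrunkenCentroids.from_dataframe(df, "label", positive_class="A")
        fit = mdl.fit(0.0)
        assert list(fit.overall_centroid.index) == list(Xdf.index)
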