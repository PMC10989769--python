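"""Classifier training/prediction, evaluation, proportions and chi-square."""

import numpy as np
import pytest
from scipy import stats as sps

import ramavit as rv
from ramavit.errors import RamavitError
from ramavit.preprocess import preprocess_ramanome
from ramavit.species_id import ClassifierConfig, ClassifierModel, EvalReport, evaluate


TINY_CFG = ClassifierConfig(input_length=128, base_channels=4, epochs=8, seed=0)


@pytest.fixture(scope="module")
def two_class_data(two_species_profiles):
    vit = {s: (1.0, 0.7) for s in "AB"}
    train = rv.simulate_ramanome(
        {"A": 60, "B": 60}, vit, t_h=3.0, seed=5, profiles=two_species_profiles
    )
    test = rv.simulate_ramanome(
        {"A": 30, "B": 30}, vit, t_h=3.0, seed=6, profiles=two_species_profiles
    )
    tr = rv.LabeledRamanome(preprocess_ramanome(train.ramanome), classes=["A", "B"])
    te = preprocess_ramanome(test.ramanome)
    te_labels = [s.meta.species_label for s in test.ramanome]
    return tr, te, te_labels


class TestCnn:
    def test_architecture_layer_count(self):
        assert TINY_CFG.n_conv_layers == 17
        assert TINY_CFG.n_weighted_layers == 18

    def test_separable_two_class_accuracy(self, two_class_data):
        tr, te, te_labels = two_class_data
        model = rv.train_cnn(tr, TINY_CFG)
        pred, proba = rv.predict(model, te)
        assert np.mean(np.array(pred) == np.array(te_labels)) >= 0.95
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-9)
        assert (proba >= 0).all()

    def test_permuted_labels_give_chance_accuracy(self, two_class_data):
        tr, te, te_labels = two_class_data
        rng = np.random.default_rng(9)
        shuffled = rv.Ramanome(
            [
                rv.Spectrum(
                    s.wavenumbers,
                    s.intensities,
                    rv.SpectrumMeta(
                        cell_id=s.meta.cell_id,
                        species_label=lab,
                    ),
                )
                for s, lab in zip(
                    tr.ramanome, rng.permutation([s.meta.species_label for s in tr.ramanome])
                )
            ]
        )
        model = rv.train_cnn(rv.LabeledRamanome(shuffled, classes=["A", "B"]), TINY_CFG)
        pred, _ = rv.predict(model, te)
        acc = np.mean(np.array(pred) == np.array(te_labels))
        assert abs(acc - 0.5) <= 0.15

    def test_deterministic_given_seed(self, two_class_data):
        tr, te, _ = two_class_data
        p1 = rv.predict(rv.train_cnn(tr, TINY_CFG), te)[1]
        p2 = rv.predict(rv.train_cnn(tr, TINY_CFG), te)[1]
        np.testing.assert_array_equal(p1, p2)

    def test_training_spectrum_recognised(self, two_class_data):
        tr, _, _ = two_class_data
        model = rv.train_cnn(tr, TINY_CFG)
        sub = rv.Ramanome(tr.ramanome.spectra[:5])
        pred, proba = rv.predict(model, sub)
        for s, p, pr in zip(sub, pred, proba):
            assert p == s.meta.species_label
            assert pr.max() > 0.5

    def test_class_with_single_spectrum_rejected(self, two_species_profiles):
        lab = rv.simulate_ramanome(
            {"A": 5, "B": 1}, {s: (1.0, 0.7) for s in "AB"}, seed=1,
            profiles=two_species_profiles,
        )
        with pytest.raises(RamavitError, match="fewer than 2"):
            rv.train_cnn(rv.LabeledRamanome(lab.ramanome), TINY_CFG)

    def test_empty_ramanome_empty_predictions(self, two_class_data):
        tr, _, _ = two_class_data
        model = rv.train_cnn(tr, TINY_CFG)
        pred, proba = rv.predict(model, rv.Ramanome([]))
        assert pred == [] and proba.shape == (0, 2)


class TestBaselines:
    @pytest.mark.parametrize("kind", ["rf", "svm"])
    def test_separable_task(self, two_class_data, kind):
        tr, te, te_labels = two_class_data
        model = rv.train_baselines(tr, kind, TINY_CFG)
        pred, _ = rv.predict(model, te)
        assert np.mean(np.array(pred) == np.array(te_labels)) >= 0.9

    def test_unknown_kind(self, two_class_data):
        with pytest.raises(RamavitError, match="unknown baseline"):
            rv.train_baselines(two_class_data[0], "mlp")

    def test_deterministic(self, two_class_data):
        tr, te, _ = two_class_data
        a = rv.predict(rv.train_baselines(tr, "rf", TINY_CFG), te)[1]
        b = rv.predict(rv.train_baselines(tr, "rf", TINY_CFG), te)[1]
        np.testing.assert_array_equal(a, b)


class _StubEstimator:
    """predict_proba stub with a fixed probability table."""

    def __init__(self, proba, classes):
        self._p = np.asarray(proba)
        self.classes_ = np.asarray(classes)

    def predict_proba(self, X):
        return np.tile(self._p, (X.shape[0], 1))


def _stub_model(proba, classes, grid):
    cfg = ClassifierConfig(n_classes=len(classes), standardize=False)
    return ClassifierModel(
        kind="rf", estimator=_StubEstimator(proba, classes), classes=list(classes),
        grid=grid, config=cfg,
    )


class TestPredictTieRule:
    def test_uniform_probabilities_pick_first_class(self, small_ramanome):
        grid = np.linspace(700, 1700, 32)
        model = _stub_model([0.5, 0.5], ["A", "B"], grid)
        pred, _ = rv.predict(model, small_ramanome)
        assert pred == ["A"] * len(small_ramanome)


class TestEvaluate:
    def _labelled(self, n_a, n_b):
        rng = np.random.default_rng(1)
        w = np.linspace(700, 1700, 64)
        spectra = []
        for i in range(n_a + n_b):
            lab = "A" if i < n_a else "B"
            spectra.append(
                rv.Spectrum(
                    w, rng.normal(size=64) + 1.5,
                    rv.SpectrumMeta(cell_id=f"c{i}", species_label=lab),
                )
            )
        return rv.LabeledRamanome(rv.Ramanome(spectra), classes=["A", "B"])


    def test_perfect_stub(self):
        data = self._labelled(20, 20)

        class PerfectModel:
            """Reads the truth off the metadata: accuracy 1 by design."""

            classes = ["A", "B"]

            def predict_proba(self, r):
                out = np.zeros((len(r), 2))
                for i, s in enumerate(r):
                    out[i, self.classes.index(s.meta.species_label)] = 1.0
                return out

        report = evaluate(lambda train: PerfectModel(), data, n_splits=3, seed=0)
        assert report.mean_acc == 1.0 and report.sd_acc == 0.0
        np.testing.assert_array_equal(report.confusion, np.eye(2))
        np.testing.assert_allclose(report.confusion.sum(axis=1), 1.0, atol=1e-9)

    def test_majority_stub_on_70_30(self):
        data = self._labelled(28, 12)
        grid = np.linspace(700, 1700, 32)

        def factory(train):
            return _stub_model([1.0, 0.0], ["A", "B"], grid)

        report = evaluate(factory, data, n_splits=3, seed=0)
        assert report.mean_acc == pytest.approx(0.7, abs=0.05)

    def test_reproducible(self):
        data = self._labelled(20, 20)
        grid = np.linspace(700, 1700, 32)

        def factory(train):
            return _stub_model([0.9, 0.1], ["A", "B"], grid)

        r1 = evaluate(factory, data, n_splits=3, seed=5)
        r2 = evaluate(factory, data, n_splits=3, seed=5)
        np.testing.assert_array_equal(r1.confusion, r2.confusion)
        assert r1.split_accs == r2.split_accs


class TestProportions:
    def test_single_class(self):
        est = rv.estimate_proportions(["A", "A", "A"])
        assert est.proportions == {"A": 1.0}

    def test_live_filter(self):
        est = rv.estimate_proportions(
            ["A", "B", "A", "B"], live_flags=[True, True, True, False]
        )
        assert est.proportions == {"A": 2 / 3, "B": 1 / 3}
        assert est.n_cells == 3 and est.live_only

    def test_all_dead_errors(self):
        with pytest.raises(RamavitError, match="no cells"):
            rv.estimate_proportions(["A", "B"], live_flags=[False, False])

    def test_proportions_sum_to_one(self):
        rng = np.random.default_rng(3)
        preds = list(rng.choice(list("ABCDE"), size=200))
        est = rv.estimate_proportions(preds, classes=list("ABCDE"))
        assert sum(est.proportions.values()) == pytest.approx(1.0, abs=1e-9)


class TestChiSquare:
    def test_threshold_value(self):
        assert rv.CHI2_DEFAULT_THRESHOLD == pytest.approx(11.070, abs=5e-4)
        assert rv.CHI2_DEFAULT_THRESHOLD == pytest.approx(
            float(sps.chi2.isf(0.05, 5)), abs=5e-4
        )

    def test_exact_proportional_counts(self):
        res = rv.chi_square_consistency({"A": 50, "B": 50}, {"A": 0.5, "B": 0.5})
        assert res.statistic == 0.0 and res.consistent

    def test_hand_computed_statistic(self):
        res = rv.chi_square_consistency({"A": 60, "B": 40}, {"A": 0.5, "B": 0.5})
        assert res.statistic == pytest.approx(4.0)

    def test_reported_experiment_value_is_consistent(self):
        res = rv.chi_square_consistency({"A": 60, "B": 40}, {"A": 0.5, "B": 0.5},
                                        threshold=11.070)
        assert res.consistent
        # the decision rule itself: 9.9214 <= 11.070
        assert rv.ChiSquareResult(9.9214, 11.070, 9.9214 <= 11.070).consistent

    def test_matches_scipy_on_random_instances(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            k = int(rng.integers(2, 6))
            p = rng.dirichlet(np.ones(k))
            obs = rng.multinomial(rng.integers(50, 400), p)
            keys = [f"c{i}" for i in range(k)]
            res = rv.chi_square_consistency(
                dict(zip(keys, obs)), dict(zip(keys, p))
            )
            expected = sps.chisquare(obs, f_exp=obs.sum() * p).statistic
            assert res.statistic == pytest.approx(float(expected), rel=1e-10)

    def test_df_mode_threshold(self):
        res = rv.chi_square_consistency(
            {"A": 50, "B": 30, "C": 10, "D": 5, "E": 5},
            {"A": 0.5, "B": 0.3, "C": 0.1, "D": 0.05, "E": 0.05},
            df_mode=True,
        )
        assert res.threshold == pytest.approx(float(sps.chi2.isf(0.05, 4)), abs=5e-4)

    def test_key_mismatch_and_zero_expected(self):
        with pytest.raises(RamavitError, match="keys"):
            rv.chi_square_consistency({"A": 1}, {"B": 1.0})
        with pytest.raises(RamavitError, match="zero expected"):
            rv.chi_square_consistency({"A": 5, "B": 5}, {"A": 1.0, "B": 0.0})
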