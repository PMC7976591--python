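"""Decision models: class weights, training contracts, determinism."""

from dataclasses import replace

import numpy as np
import pytest

from anemiadss.cohort import Medication
from anemiadss.features import apply_normalizer, build_features, fit_normalizer
from anemiadss.models import (
    ClassWeights,
    ModelConfig,
    equalize_recalls,
    inverse_ratio_weights,
    predict,
    train_model,
)
from anemiadss.simulate import GeneratorConfig, generate
from anemiadss.twostep import Threshold, classify_all, default_grid, roc_curve, select_threshold


class TestInverseRatioWeights:
    def test_training_cohort_counts(self):
        # the imbalance regime: 344 UP, 5151 STAY, 585 DOWN in 6080
        w = inverse_ratio_weights({"UP": 344, "STAY": 5151, "DOWN": 585})
        assert w.values == pytest.approx((5.891, 0.393, 3.464), abs=5e-4)

    def test_balanced_counts_unit_weights(self):
        w = inverse_ratio_weights({"UP": 10, "STAY": 10, "DOWN": 10})
        assert w.values == pytest.approx((1.0, 1.0, 1.0))

    def test_scale_invariance(self):
        a = inverse_ratio_weights({"UP": 7, "STAY": 80, "DOWN": 13})
        b = inverse_ratio_weights({"UP": 14, "STAY": 160, "DOWN": 26})
        assert a.values == pytest.approx(b.values)

    def test_zero_count_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            inverse_ratio_weights({"UP": 0, "STAY": 10, "DOWN": 5})


def test_probability_triple_must_normalize():
    from anemiadss.models import ProbabilityTriple
    ProbabilityTriple(p_up=0.2, p_stay=0.5, p_down=0.3)
    ProbabilityTriple(p_up=0.4, p_stay=0.6)  # binary iron output
    with pytest.raises(ValueError, match="sum to 1"):
        ProbabilityTriple(p_up=0.5, p_stay=0.2, p_down=0.1)


@pytest.fixture(scope="module")
def trained_esa(esa_training_data):
    cfg = ModelConfig(medication=Medication.ESA, seed=3, epochs=300, batch_size=128)
    w = inverse_ratio_weights(esa_training_data.class_counts())
    return cfg, train_model(cfg, esa_training_data, w)


class TestTraining:
    def test_probabilities_normalized(self, trained_esa, esa_training_data):
        _, model = trained_esa
        probs = predict(model, esa_training_data)
        assert probs.shape == (len(esa_training_data), 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert np.isfinite(probs).all()

    def test_deterministic_given_seed(self, esa_training_data):
        cfg = ModelConfig(medication=Medication.ESA, seed=9, epochs=10)
        w = inverse_ratio_weights(esa_training_data.class_counts())
        p1 = predict(train_model(cfg, esa_training_data, w), esa_training_data)
        p2 = predict(train_model(cfg, esa_training_data, w), esa_training_data)
        np.testing.assert_array_equal(p1, p2)

    def test_permuting_rows_permutes_outputs(self, trained_esa, esa_training_data):
        _, model = trained_esa
        perm = np.random.default_rng(0).permutation(len(esa_training_data))
        probs = predict(model, esa_training_data)
        probs_perm = predict(model, esa_training_data.subset(perm))
        np.testing.assert_allclose(probs[perm], probs_perm, atol=1e-6)

    def test_is_model_binary_head(self, small_clean_cohort):
        ds = build_features(small_clean_cohort, Medication.IS)
        dsn = apply_normalizer(fit_normalizer(ds), ds)
        cfg = ModelConfig(medication=Medication.IS, seed=1, epochs=30)
        model = train_model(cfg, dsn, ClassWeights.uniform(dsn.classes))
        probs = predict(model, dsn)
        assert probs.shape[1] == 2
        assert model.classes == ("UP", "STAY")

    def test_unnormalized_data_rejected(self, small_clean_cohort):
        ds = build_features(small_clean_cohort, Medication.ESA)
        cfg = ModelConfig(medication=Medication.ESA)
        with pytest.raises(ValueError, match="normalized"):
            train_model(cfg, ds, ClassWeights.uniform(ds.classes))

    def test_feature_mismatch_rejected(self, trained_esa, small_clean_cohort):
        _, model = trained_esa
        from anemiadss.features import FeatureConfig
        other = build_features(small_clean_cohort, Medication.ESA,
                               FeatureConfig(include_dose_history=False))
        other = apply_normalizer(fit_normalizer(other), other)
        with pytest.raises(ValueError, match="feature"):
            predict(model, other)

    def test_huge_l1_collapses_to_class_prior(self, esa_training_data):
        cfg = ModelConfig(medication=Medication.ESA, seed=4, epochs=400,
                          batch_size=128, l1_coeff=1.0)
        model = train_model(cfg, esa_training_data,
                            ClassWeights.uniform(esa_training_data.classes))
        probs = predict(model, esa_training_data)
        counts = esa_training_data.class_counts()
        prior = np.array([counts[c] for c in esa_training_data.classes], dtype=float)
        prior /= prior.sum()
        # input-independent and close to the class prior
        assert probs.std(axis=0).max() < 1e-6
        assert np.abs(probs - prior).max() < 0.05

    def test_learns_latent_rule_without_corruption(self, trained_esa, esa_training_data):
        """No label corruption: two-step with the selected threshold
        replicates the latent policy on the training set."""
        _, model = trained_esa
        probs = predict(model, esa_training_data)
        roc = roc_curve(probs, esa_training_data.y, esa_training_data.classes,
                        grid=default_grid())
        thr = select_threshold(roc)
        pred = classify_all(probs, thr, esa_training_data.classes)
        assert (pred == esa_training_data.y).mean() >= 0.95

    def test_save_load_round_trip(self, tmp_path, trained_esa, esa_training_data):
        _, model = trained_esa
        path = tmp_path / "model.json"
        model.save(path)
        from anemiadss.models import DecisionModel
        back = DecisionModel.load(path)
        np.testing.assert_allclose(predict(back, esa_training_data),
                                   predict(model, esa_training_data), atol=1e-6)


class TestEqualizeRecalls:
    def test_vacuous_tolerance_returns_init(self, esa_training_data):
        cfg = ModelConfig(medication=Medication.ESA, seed=5, epochs=10)
        init = inverse_ratio_weights(esa_training_data.class_counts())
        out = equalize_recalls(lambda w: train_model(cfg, esa_training_data, w),
                               esa_training_data, init, tol=1.0, max_rounds=4)
        assert out.values == init.values

    def test_reduces_spread_on_imbalanced_data(self, small_noisy_cohort):
        ds = build_features(small_noisy_cohort, Medication.ESA)
        dsn = apply_normalizer(fit_normalizer(ds), ds)
        cfg = ModelConfig(medication=Medication.ESA, seed=6, epochs=80,
                          batch_size=256)
        init = inverse_ratio_weights(dsn.class_counts())
        trainer = lambda w: train_model(cfg, dsn, w)

        def spread(weights):
            model = trainer(weights)
            pred = predict(model, dsn).argmax(axis=1)
            rec = [(pred[dsn.y == k] == k).mean() for k in range(3)]
            return max(rec) - min(rec)

        _, details = equalize_recalls(trainer, dsn, init, tol=0.02,
                                      max_rounds=4, return_details=True)
        assert details.spread <= spread(init) + 1e-9

    def test_increasing_up_weight_does_not_hurt_up_recall(self, esa_training_data):
        """Monotonicity over a 3-point weight ladder, fixed seed."""
        cfg = ModelConfig(medication=Medication.ESA, seed=7, epochs=60,
                          batch_size=256)
        recalls = []
        for up_w in (0.5, 2.0, 8.0):
            w = ClassWeights(("UP", "STAY", "DOWN"), (up_w, 1.0, 1.0), "adjusted")
            model = train_model(cfg, esa_training_data, w)
            pred = predict(model, esa_training_data).argmax(axis=1)
            mask = esa_training_data.y == 0
            recalls.append((pred[mask] == 0).mean())
        assert recalls[0] <= recalls[1] + 0.02
        assert recalls[1] <= recalls[2] + 0.02
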