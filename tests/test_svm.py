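"""SVM filter: tuning grid, training, prediction, LOPO evaluation."""

import numpy as np
import pytest

from plasmasieve import (
    CohortSpec,
    LabeledVariant,
    SvmConfig,
    hyperparameter_grid,
    lopo_evaluate,
    make_cohort,
    predict,
    train,
    train_final,
    tune_hyperparameters,
)
from plasmasieve.features import FeatureVector, N_FEATURES
from plasmasieve.variant_io import VariantKey


def _toy_rows(n=40, gap=6.0, seed=0, n_patients=4, n_signal=6):
    """Linearly separable rows: label = common sign of the signal features."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        label = i % 2 == 0
        values = rng.normal(0, 1.0, N_FEATURES)
        values[:n_signal] = (gap if label else -gap) + rng.normal(0, 0.5, n_signal)
        rows.append(LabeledVariant(
            patient_id=f"P{i % n_patients}",
            key=VariantKey("1", i + 1, "A", "C"),
            label=label,
            features=FeatureVector(values, np.zeros(N_FEATURES, dtype=bool)),
        ))
    return rows


class TestGridAndTuning:
    def test_grid_has_132_configurations(self):
        grid = hyperparameter_grid()
        assert len(grid) == 132
        assert sum(1 for g in grid if g.kernel == "linear") == 11
        assert sum(1 for g in grid if g.kernel == "rbf") == 121
        assert all(g.gamma is None for g in grid if g.kernel == "linear")

    def test_separable_fixture_reaches_perfect_inner_f1(self):
        rows = _toy_rows()
        config = tune_hyperparameters(rows, folds=4, seed=0)
        model = train(rows, config)
        pred, _ = predict(model, [r.features for r in rows])
        assert all(p == r.label for p, r in zip(pred, rows))

    def test_single_class_rejected(self):
        rows = [r for r in _toy_rows() if r.label]
        with pytest.raises(ValueError):
            tune_hyperparameters(rows)
        with pytest.raises(ValueError):
            train(rows, SvmConfig("linear", 1.0))


class TestTrainPredict:
    def test_deterministic_scores(self):
        rows = _toy_rows()
        config = SvmConfig("rbf", 5.0, 0.1)
        s1 = predict(train(rows, config), [r.features for r in rows])[1]
        s2 = predict(train(rows, config), [r.features for r in rows])[1]
        np.testing.assert_array_equal(s1, s2)

    def test_duplicated_rows_preserve_decision_signs(self, rng):
        rows = _toy_rows()
        probe = [FeatureVector(rng.normal(0, 3, N_FEATURES),
                               np.zeros(N_FEATURES, dtype=bool)) for _ in range(20)]
        config = SvmConfig("linear", 1.0)
        m1 = train(rows, config)
        m2 = train(rows + rows, config)
        p1, _ = predict(m1, probe)
        p2, _ = predict(m2, probe)
        np.testing.assert_array_equal(p1, p2)

    def test_threshold_extremes_and_monotonicity(self):
        rows = _toy_rows(n=200, n_patients=8)
        model = train(rows, SvmConfig("linear", 1.0))
        feats = [r.features for r in rows]
        truth = np.array([r.label for r in rows])
        assert predict(model, feats, threshold=np.inf)[0].sum() == 0
        assert predict(model, feats, threshold=-np.inf)[0].all()
        prev_recall, prev_kept = 1.1, None
        for thr in (-2.0, -0.5, 0.0, 0.5, 2.0):
            pred, _ = predict(model, feats, threshold=thr)
            tp = int((pred & truth).sum())
            recall = tp / truth.sum()
            assert recall <= prev_recall + 1e-12
            prev_recall = recall
            if prev_kept is not None:
                assert pred.sum() <= prev_kept
            prev_kept = pred.sum()

    def test_wrong_dimension_rejected(self):
        model = train(_toy_rows(), SvmConfig("linear", 1.0))
        with pytest.raises(ValueError, match="22"):
            predict(model, np.ones((3, 21)))


class TestSerialization:
    def test_roundtrip_scores_and_feature_order(self, tmp_path, rng):
        from plasmasieve import SvmModel

        rows = _toy_rows()
        model = train_final(rows, seed=0)
        path = tmp_path / "model.joblib"
        model.save(path)
        loaded = SvmModel.load(path)
        probe = [FeatureVector(rng.normal(size=N_FEATURES),
                               np.zeros(N_FEATURES, dtype=bool)) for _ in range(10)]
        np.testing.assert_array_equal(predict(model, probe)[1], predict(loaded, probe)[1])
        assert loaded.feature_names == model.feature_names
        assert len(loaded.feature_names) == 22
        assert loaded.training_fingerprint == model.training_fingerprint


class TestLopo:
    def test_three_patient_separable_cohort_is_perfect(self):
        rows = _toy_rows(n=30, n_patients=3)
        result = lopo_evaluate(rows, strategy="svm", seed=0)
        assert result.pooled.f1 == 1.0
        assert len(result.tuner_fingerprints) == 3

    def test_no_filter_strategy_identities(self, highsep_labeled):
        result = lopo_evaluate(highsep_labeled, strategy="none")
        assert result.pooled.recall == 1.0
        assert result.pooled.mcc == 0.0
        assert result.pooled.youden_j == 0.0

    def test_pooled_counts_equal_per_patient_sums(self, highsep_labeled):
        result = lopo_evaluate(highsep_labeled, strategy="rule", seed=0)
        assert result.pooled.tp == sum(m.tp for _, m in result.per_patient)
        assert result.pooled.fn == sum(m.fn for _, m in result.per_patient)

    def test_no_leakage_fingerprints(self, highsep_labeled):
        result = lopo_evaluate(highsep_labeled, strategy="none")
        for held_out, train_patients in result.tuner_fingerprints:
            assert held_out not in train_patients

    def test_label_only_rows_count_as_false_negatives(self):
        rows = _toy_rows(n=30, n_patients=3)
        extra = [LabeledVariant(patient_id="P0", key=VariantKey("1", 999, "A", "G"),
                                label=True)]
        base = lopo_evaluate(rows, strategy="none")
        with_extra = lopo_evaluate(rows + extra, strategy="none")
        assert with_extra.pooled.fn == base.pooled.fn + 1
        assert with_extra.pooled.recall < 1.0

    def test_fixed_strategy_evaluates_post_processing_only(self, highsep_cohort,
                                                           highsep_labeled):
        from plasmasieve import (
            CascadeConfig,
            ConsequenceAnnotation,
            lopo_evaluate,
            run_cascade,
        )

        annotations = {k: ConsequenceAnnotation(key=k, consequences=v)
                       for k, v in highsep_cohort.consequences.items()}
        config = CascadeConfig(cohort_sets=highsep_cohort.cohort_sets,
                               dbsnp=highsep_cohort.dbsnp)
        keep: set = set()
        for patient, calls in highsep_cohort.calls.items():
            kept, _ = run_cascade(calls, annotations, config)
            keep |= {(patient, c.key) for c in kept}
        result = lopo_evaluate(highsep_labeled, strategy="fixed",
                               keep_predicate=lambda r: (r.patient_id, r.key) in keep)
        baseline = lopo_evaluate(highsep_labeled, strategy="none")
        # annotation filters remove germline and artefact calls, so precision
        # improves over accepting everything; synonymous somatic calls cap recall
        assert result.pooled.precision > baseline.pooled.precision
        assert 0.0 < result.pooled.recall <= 1.0
        with pytest.raises(ValueError, match="keep_predicate"):
            lopo_evaluate(highsep_labeled, strategy="fixed")

    def test_needs_two_patients(self):
        rows = [r for r in _toy_rows() if r.patient_id == "P0"]
        with pytest.raises(ValueError):
            lopo_evaluate(rows)

    def test_f1_monotone_in_class_separation(self):
        # three-point check on the generative separation knob
        f1s = []
        for sep in (0.3, 2.0, 5.0):
            cohort = make_cohort(CohortSpec(
                n_patients=6, n_somatic=4, separation=sep,
                vaf_laws={"somatic": (3.0, 40.0)}, seed=5))
            res = lopo_evaluate(cohort.labeled_variants(), strategy="svm", seed=0)
            f1s.append(res.pooled.f1)
        assert f1s[0] <= f1s[1] <= f1s[2]
        assert f1s[2] > 0.9
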