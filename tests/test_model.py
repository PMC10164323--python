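"""Weights, idf, tf-idf, influence variants, scoring and prediction."""

from __future__ import annotations

import math

import numpy as np
import pytest

import owsum.model as owm
from oracle import oracle_model, oracle_predicted_set, oracle_scores
from conftest import random_instance
from owsum.chem import OccurrenceMatrix
from owsum.records import LabelMatrix

LN2 = math.log(2)


class TestWeightsIdfTfidf:
    def test_toy_weights_match_hand_counts(self, toy):
        G = owm.compute_weights(toy.occurrence, toy.labels)
        # classes (A, B) x features (f1, f2, f3)
        assert G[0, 0] == 1.0      # G(f1|A) = 2/2
        assert G[1, 0] == 0.0      # G(f1|B) = 0/2
        assert G[0, 1] == 0.5 and G[1, 1] == 0.5
        assert G[0, 2] == 0.0 and G[1, 2] == 1.0

    def test_toy_idf_values(self, toy):
        idf, trained = owm.compute_idf(toy.occurrence, toy.labels)
        assert trained.all()
        assert idf[1] == 0.0                      # f2 in both classes
        assert idf[0] == pytest.approx(LN2)       # f1 in 1 of 2 classes
        assert idf[2] == pytest.approx(LN2)

    def test_feature_in_every_class_has_zero_idf(self, rng=None):
        rng = np.random.default_rng(5)
        for _ in range(20):
            occ, labels = random_instance(rng)
            idf, trained = owm.compute_idf(occ, labels)
            counts = labels.values.T.astype(int) @ occ.values.astype(int)
            for j in range(len(occ.patterns)):
                if trained[j] and (counts[:, j] > 0).all():
                    assert idf[j] == 0.0

    def test_toy_tfidf_values(self, toy):
        tfidf = owm.compute_tfidf(toy.occurrence, toy.labels)
        assert tfidf[0, 0] == pytest.approx(LN2)   # (A, f1)
        assert tfidf[0, 1] == 0.0                  # (A, f2)
        assert tfidf[1, 2] == pytest.approx(LN2)   # (B, f3)

    def test_tf_equals_G_identity_on_random_instances(self):
        # the within-class term frequency coincides with the weight G, so
        # tfidf must equal G * idf elementwise on every instance
        rng = np.random.default_rng(11)
        for _ in range(100):
            occ, labels = random_instance(rng)
            G = owm.compute_weights(occ, labels)
            idf, _ = owm.compute_idf(occ, labels)
            tfidf = owm.compute_tfidf(occ, labels)
            np.testing.assert_array_equal(tfidf, G * idf[None, :])

    def test_empty_class_is_training_error(self, toy):
        labels = LabelMatrix(
            toy.labels.object_ids, ("A", "B", "ghost"),
            np.hstack([toy.labels.values,
                       np.zeros((4, 1), dtype=np.uint8)]),
        )
        with pytest.raises(owm.TrainingError, match="ghost"):
            owm.compute_weights(toy.occurrence, labels)


class TestFitVariants:
    def test_toy_tfidf_weighted_influence(self, toy):
        model = owm.fit(toy.occurrence, toy.labels, variant="tfidf_weighted")
        assert model.influence[0, 0] == pytest.approx(LN2)  # 1^2 * ln2
        assert model.influence[0, 1] == 0.0

    def test_toy_same_weighted_influence(self, toy):
        model = owm.fit(
            toy.occurrence, toy.labels, variant="same_weighted",
            feature_selection=False,
        )
        assert model.influence[0, 1] == 0.5   # a=1, G=0.5

    def test_zero_idf_features_have_zero_influence_under_tfidf(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            occ, labels = random_instance(rng)
            model = owm.fit(occ, labels, variant="tfidf_weighted",
                            feature_selection=False)
            zero_idf = model.idf == 0
            assert (model.influence[:, zero_idf] == 0).all()

    def test_division_variant_equals_plain_tfidf(self):
        # a = tfidf/G  =>  I = tfidf, with the G=0 singularity resolved to 0
        rng = np.random.default_rng(31)
        for _ in range(20):
            occ, labels = random_instance(rng)
            model = owm.fit(occ, labels, variant="tfidf_over_prfc")
            np.testing.assert_allclose(
                model.influence, model.tfidf, atol=1e-15
            )

    def test_unknown_variant_rejected(self, toy):
        with pytest.raises(ValueError, match="variant"):
            owm.fit(toy.occurrence, toy.labels, variant="bogus")

    def test_selection_mask_drops_exactly_zero_idf_features(self, toy):
        model = owm.fit(toy.occurrence, toy.labels, feature_selection=True)
        assert model.selected.tolist() == [True, False, True]
        model2 = owm.fit(toy.occurrence, toy.labels, feature_selection=False)
        assert model2.selected.all()


class TestScoringAndPrediction:
    def test_toy_score_uses_only_selected_present_features(self, toy):
        model = owm.fit(toy.occurrence, toy.labels, variant="tfidf_weighted")
        s, used = owm.score(np.array([1, 1, 0], dtype=np.uint8), model)
        assert s[0] == pytest.approx(LN2) and s[1] == 0.0
        assert used == 1   # f2 dropped by selection

    def test_empty_feature_vector_scores_zero_and_unpredictable(self, toy):
        model = owm.fit(toy.occurrence, toy.labels)
        s, used = owm.score(np.zeros(3, dtype=np.uint8), model)
        assert (s == 0).all() and used == 0
        res = owm.predict_from_scores("x", s, model.classes, used_features=0)
        assert res.status == "unpredictable" and not res.predicted

    def test_worked_two_class_score_example(self):
        # floral 1.67 beats medicinal 1.50 -> predict floral
        res = owm.predict_from_scores(
            "mol", {"floral": 1.67, "medicinal": 1.50}
        )
        assert res.predicted == frozenset({"floral"})
        assert res.status == "predicted"

    def test_all_equal_scores_over_full_class_set_is_unpredictable(self):
        res = owm.predict_from_scores(
            "mol", {c: 0.25 for c in "abcdef"}
        )
        assert res.status == "unpredictable" and not res.predicted

    def test_toy_tie_without_selection_is_unpredictable(self, toy):
        model = owm.fit(
            toy.occurrence, toy.labels, variant="same_weighted",
            feature_selection=False,
        )
        s, used = owm.score(np.array([0, 1, 0], dtype=np.uint8), model)
        assert s[0] == s[1] == 0.5
        res = owm.predict_from_scores("x", s, model.classes, used)
        assert res.status == "unpredictable"

    def test_proper_subset_tie_predicts_all_tied_classes(self):
        res = owm.predict_from_scores(
            "mol", {"a": 1.0, "b": 1.0, "c": 0.2}
        )
        assert res.predicted == frozenset({"a", "b"})

    def test_score_additivity(self, toy):
        # removing one feature lowers each class score by its influence
        model = owm.fit(toy.occurrence, toy.labels, feature_selection=False)
        full = np.array([1, 1, 1], dtype=np.uint8)
        s_full, _ = owm.score(full, model)
        for j in range(3):
            less = full.copy()
            less[j] = 0
            s_less, _ = owm.score(less, model)
            np.testing.assert_allclose(
                s_full - s_less, model.influence[:, j], atol=1e-12
            )


class TestInterpretation:
    def test_toy_ranking_for_class_A(self, toy):
        model = owm.fit(toy.occurrence, toy.labels, variant="tfidf_weighted",
                        feature_selection=False)
        ranked = owm.rank_features(model, "A")
        patterns = [p for p, _ in ranked]
        assert patterns[0] == toy.catalog.patterns[0]   # f1 tops the list
        assert ranked[0][1] == pytest.approx(LN2)
        assert ranked[1][1] == ranked[2][1] == 0.0

    def test_unique_class_feature_ranks_first(self, toy):
        model = owm.fit(toy.occurrence, toy.labels)
        assert owm.rank_features(model, "B")[0][0] == toy.catalog.patterns[2]

    def test_unknown_class_rejected(self, toy):
        model = owm.fit(toy.occurrence, toy.labels)
        with pytest.raises(KeyError):
            owm.rank_features(model, "no_such_class")

    def test_toy_influence_difference(self, toy):
        model = owm.fit(toy.occurrence, toy.labels, variant="tfidf_weighted",
                        feature_selection=False)
        diff = dict(owm.influence_difference(model, "A", "B"))
        f1, f2, f3 = toy.catalog.patterns
        assert diff[f1] == pytest.approx(LN2)
        assert diff[f2] == 0.0
        assert diff[f3] == pytest.approx(-LN2)

    def test_influence_difference_antisymmetry(self, toy):
        model = owm.fit(toy.occurrence, toy.labels)
        ab = dict(owm.influence_difference(model, "A", "B"))
        ba = dict(owm.influence_difference(model, "B", "A"))
        for p in ab:
            assert ab[p] == pytest.approx(-ba[p])

    def test_identical_classes_give_all_zeros(self, toy):
        model = owm.fit(toy.occurrence, toy.labels)
        assert all(
            v == 0.0 for _, v in owm.influence_difference(model, "A", "A")
        )


class TestModelInvariants:
    @pytest.mark.parametrize("variant", owm.VARIANTS)
    def test_brute_force_oracle_equivalence(self, variant):
        rng = np.random.default_rng(47)
        for _ in range(50):
            occ, labels = random_instance(rng)
            model = owm.fit(occ, labels, variant=variant,
                            feature_selection=True)
            orc = oracle_model(
                occ.values.tolist(), labels.values.tolist(),
                variant, True,
            )
            np.testing.assert_array_equal(model.G, np.array(orc["G"]))
            np.testing.assert_array_equal(model.idf, np.array(orc["idf"]))
            np.testing.assert_array_equal(
                model.influence, np.array(orc["influence"])
            )
            assert model.selected.tolist() == orc["selected"]
            for k in range(len(occ.object_ids)):
                s, used = owm.score(occ.values[k], model)
                s_orc, used_orc = oracle_scores(occ.values[k].tolist(), orc)
                assert used == used_orc
                np.testing.assert_allclose(s, s_orc, atol=1e-12)
                res = owm.predict(occ.subset([k]), model)[0]
                exp_set, exp_status = oracle_predicted_set(
                    s_orc, labels.classes, used_orc
                )
                assert res.predicted == exp_set
                assert res.status == exp_status

    def test_permutation_invariance_of_model_quantities(self):
        rng = np.random.default_rng(53)
        occ, labels = random_instance(rng)
        perm = rng.permutation(len(occ.object_ids)).tolist()
        m1 = owm.fit(occ, labels)
        m2 = owm.fit(occ.subset(perm), labels.subset(perm))
        np.testing.assert_array_equal(m1.G, m2.G)
        np.testing.assert_array_equal(m1.idf, m2.idf)
        np.testing.assert_array_equal(m1.influence, m2.influence)

    def test_log_base_invariance_of_predictions(self):
        # switching the idf log base rescales influences by a constant and
        # cannot change any argmax prediction
        rng = np.random.default_rng(59)
        for _ in range(30):
            occ, labels = random_instance(rng)
            m_e = owm.fit(occ, labels, variant="tfidf_weighted",
                          log_base=math.e)
            m_10 = owm.fit(occ, labels, variant="tfidf_weighted",
                           log_base=10.0)
            for pe, p10 in zip(owm.predict(occ, m_e), owm.predict(occ, m_10)):
                assert pe.predicted == p10.predicted
                assert pe.status == p10.status

    def test_selection_is_noop_under_tfidf_weighting(self):
        # idf = 0 features carry zero influence either way
        rng = np.random.default_rng(61)
        for _ in range(30):
            occ, labels = random_instance(rng)
            m_sel = owm.fit(occ, labels, variant="tfidf_weighted",
                            feature_selection=True)
            m_all = owm.fit(occ, labels, variant="tfidf_weighted",
                            feature_selection=False)
            for a, b in zip(owm.predict(occ, m_sel), owm.predict(occ, m_all)):
                assert a.predicted == b.predicted


class TestSerialization:
    def test_save_load_round_trip_preserves_predictions(self, toy, tmp_path):
        model = owm.fit(toy.occurrence, toy.labels, variant="tfidf_weighted")
        path = tmp_path / "model.tsv"
        owm.save_model(model, path)
        back = owm.load_model(path)
        assert back.classes == model.classes
        assert back.patterns == model.patterns
        np.testing.assert_allclose(back.influence, model.influence,
                                   rtol=1e-9)
        for a, b in zip(owm.predict(toy.occurrence, model),
                        owm.predict(toy.occurrence, back)):
            assert a.predicted == b.predicted and a.status == b.status
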