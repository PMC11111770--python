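import numpy as np
import pytest

from cytoscreen.classify import (
    SlideFeatureVector,
    default_bins,
    extract_features,
    feature_importances,
    feature_matrix,
    feature_names,
    predict_slide_grade,
    train_slide_classifier,
)
from cytoscreen.core import PatchGrade, RiskStratum, SlideGrade, SlideRecord
from cytoscreen.detection import DetectorProfile, PatchDetection, SlideDetectionSet
from cytoscreen.synthetic import CohortConfig, default_detector_profile, generate_cohort


def make_set(dets):
    return SlideDetectionSet(slide=SlideRecord("s", 4096, 4096), detections=dets)


def det(grade, conf, x=0.0):
    return PatchDetection(grade=grade, confidence=conf, box=(x, 0, x + 50, 50))


class TestExtractFeatures:
    def test_empty_set_all_zero(self):
        fv = extract_features(make_set([]))
        assert np.all(fv.values == 0.0)
        assert len(fv.values) == 6 * (3 + 10) + 6 + 1

    def test_single_lsil_detection_hand_computed(self):
        fv = extract_features(
            make_set([det("LSIL", 0.8)]), include_counts=False, include_glandular=False
        )
        s = fv.as_series()
        assert s["LSIL_max_conf"] == pytest.approx(0.8)
        assert s["LSIL_mean_conf"] == pytest.approx(0.8)
        assert s["LSIL_std_conf"] == pytest.approx(0.0)
        assert s["LSIL_bin_08"] == pytest.approx(1.0)  # [0.8, 0.9)
        lsil_bins = [f"LSIL_bin_{i:02d}" for i in range(10)]
        assert s[lsil_bins].sum() == pytest.approx(1.0)
        other = s.drop(labels=["LSIL_max_conf", "LSIL_mean_conf", "LSIL_std_conf"] + lsil_bins)
        assert np.all(other.values == 0.0)

    def test_two_hsil_detections_hand_computed(self):
        fv = extract_features(make_set([det("HSIL", 0.6), det("HSIL", 0.8, x=100)]))
        s = fv.as_series()
        assert s["HSIL_mean_conf"] == pytest.approx(0.7)
        assert s["HSIL_std_conf"] == pytest.approx(0.1)  # population SD
        assert s["HSIL_max_conf"] == pytest.approx(0.8)
        assert s["HSIL_bin_06"] == pytest.approx(0.5)
        assert s["HSIL_bin_08"] == pytest.approx(0.5)
        assert s["HSIL_count"] == pytest.approx(2.0)

    def test_confidence_one_lands_in_last_bin(self):
        fv = extract_features(make_set([det("SCC", 1.0)]))
        assert fv.as_series()["SCC_bin_09"] == pytest.approx(1.0)

    def test_permutation_invariance(self, rng):
        dets = [
            det(list(PatchGrade)[int(rng.integers(6))].value, float(rng.uniform(0, 1)), x=i * 60)
            for i in range(30)
        ]
        fv1 = extract_features(make_set(dets))
        shuffled = list(dets)
        rng.shuffle(shuffled)
        fv2 = extract_features(make_set(shuffled))
        assert np.allclose(fv1.values, fv2.values)

    def test_bin_proportions_sum_to_one_or_zero(self, small_cohort):
        slides, _ = small_cohort
        for ds in slides[:30]:
            fv = extract_features(ds)
            s = fv.as_series()
            for g in PatchGrade:
                key = g.value.replace("-", "_")
                total = s[[f"{key}_bin_{i:02d}" for i in range(10)]].sum()
                count = s[f"{key}_count"]
                assert total == pytest.approx(1.0 if count >= 1 else 0.0)
                assert s[f"{key}_max_conf"] >= s[f"{key}_mean_conf"] >= 0.0
                assert s[f"{key}_std_conf"] >= 0.0

    @pytest.mark.parametrize(
        "bins",
        [np.array([0.0]), np.array([0.0, 0.5, 0.4, 1.0]), np.array([0.1, 0.5, 1.0])],
    )
    def test_malformed_bins_rejected(self, bins):
        with pytest.raises(ValueError):
            extract_features(make_set([]), bins=bins)

    def test_feature_names_match_length(self):
        names = feature_names(default_bins(), include_counts=True, include_glandular=True)
        fv = extract_features(make_set([]))
        assert tuple(names) == fv.names


@pytest.fixture(scope="module")
def trained():
    slides, truths = generate_cohort(CohortConfig(n_slides=250, seed=5))
    feats = [extract_features(ds) for ds in slides]
    model = train_slide_classifier(feats, truths, n_trees=150)
    return model, feats, truths


class TestTrainSlideClassifier:
    def test_single_class_rejected(self, small_cohort):
        slides, _ = small_cohort
        feats = [extract_features(ds) for ds in slides[:10]]
        with pytest.raises(ValueError, match="2 distinct"):
            train_slide_classifier(feats, [SlideGrade.NILM] * 10)

    def test_determinism(self, trained):
        model, feats, truths = trained
        model2 = train_slide_classifier(feats, truths, n_trees=150)
        for fv in feats[:20]:
            assert predict_slide_grade(model, fv) == predict_slide_grade(model2, fv)

    def test_exposes_oob_accuracy(self, trained):
        model, _, _ = trained
        assert 0.0 <= model.oob_accuracy <= 1.0

    def test_permuted_labels_near_chance(self):
        """Shuffled labels give held-out accuracy near the majority rate."""
        slides, truths = generate_cohort(CohortConfig(n_slides=400, seed=31))
        feats = [extract_features(ds) for ds in slides]
        rng = np.random.default_rng(0)
        permuted = list(truths)
        rng.shuffle(permuted)
        model = train_slide_classifier(feats[:320], permuted[:320], n_trees=150)
        correct = sum(
            predict_slide_grade(model, fv).grade is t
            for fv, t in zip(feats[320:], permuted[320:])
        )
        acc = correct / 80
        majority = max(permuted[320:].count(g) for g in SlideGrade) / 80
        se = np.sqrt(majority * (1 - majority) / 80)
        assert acc <= majority + 3 * se

    def test_save_load_round_trip(self, trained, tmp_path):
        model, feats, _ = trained
        path = tmp_path / "model.joblib"
        model.save(path)
        from cytoscreen.classify import SlideClassifier

        restored = SlideClassifier.load(path)
        for fv in feats[:10]:
            assert predict_slide_grade(restored, fv) == predict_slide_grade(model, fv)


class TestPredictSlideGrade:
    def test_probabilities_sum_to_one(self, trained):
        model, feats, _ = trained
        for fv in feats[:50]:
            pred = predict_slide_grade(model, fv)
            assert sum(pred.probabilities.values()) == pytest.approx(1.0)
            assert all(p >= 0 for p in pred.probabilities.values())

    def test_abnormality_is_complement_of_nilm(self, trained):
        model, feats, _ = trained
        pred = predict_slide_grade(model, feats[0])
        assert pred.abnormality_score == pytest.approx(
            1.0 - pred.probabilities[SlideGrade.NILM]
        )

    def test_severity_tie_break(self, trained, monkeypatch):
        model, feats, _ = trained
        tie = np.zeros(len(model.classes))
        idx = {g: i for i, g in enumerate(model.classes)}
        tie[idx[SlideGrade.LSIL]] = 0.5
        tie[idx[SlideGrade.HSIL_PLUS]] = 0.5
        monkeypatch.setattr(
            model.estimator, "predict_proba", lambda X: tie.reshape(1, -1)
        )
        assert predict_slide_grade(model, feats[0]).grade is SlideGrade.HSIL_PLUS

    def test_feature_length_mismatch_rejected(self, trained):
        model, _, _ = trained
        bad = SlideFeatureVector(values=np.zeros(3), names=("a", "b", "c"))
        with pytest.raises(ValueError, match="layout"):
            predict_slide_grade(model, bad)

    def test_stratum_scores_respect_nesting(self, trained):
        model, feats, _ = trained
        for fv in feats[:50]:
            pred = predict_slide_grade(model, fv)
            hs = pred.stratum_score(RiskStratum.HSIL_PLUS)
            ls = pred.stratum_score(RiskStratum.LSIL_PLUS)
            asc = pred.stratum_score(RiskStratum.ASC_US_PLUS)
            assert hs <= ls + 1e-12 <= asc + 2e-12


class TestFeatureImportances:
    def test_top_k_rows(self, trained):
        model, _, _ = trained
        top = feature_importances(model, k=20)
        assert len(top) == 20
        values = [v for _, v in top]
        assert values == sorted(values, reverse=True)

    def test_k_beyond_feature_count_returns_all(self, trained):
        model, _, _ = trained
        top = feature_importances(model, k=10_000)
        assert len(top) == len(model.feature_names)

    def test_hsil_features_dominate_when_only_hsil_differs(self):
        """Cohort where grades differ only through HSIL-class rates."""
        zero = {g: 0.0 for g in PatchGrade}
        rates = {
            SlideGrade.NILM: dict(zero),
            SlideGrade.HSIL_PLUS: {**zero, PatchGrade.HSIL: 10.0},
        }
        profile = DetectorProfile(rates=rates, confusion=np.eye(6), fp_rate=0.2)
        prev = {g: 0.0 for g in SlideGrade}
        prev[SlideGrade.NILM] = 0.5
        prev[SlideGrade.HSIL_PLUS] = 0.5
        slides, truths = generate_cohort(
            CohortConfig(n_slides=200, seed=13, prevalences=prev, profile=profile)
        )
        feats = [extract_features(ds) for ds in slides]
        model = train_slide_classifier(feats, truths, n_trees=150)
        top5 = [name for name, _ in feature_importances(model, k=5)]
        assert sum(name.startswith("HSIL_") for name in top5) >= 3


class TestNoiseMonotonicity:
    def test_accuracy_nonincreasing_in_confusion_noise(self):
        """Held-out accuracy degrades as class-confusion noise rises."""
        accs = []
        for noise in (0.0, 0.45, 0.75):
            base = default_detector_profile()
            n = len(PatchGrade)
            confusion = np.full((n, n), noise / (n - 1))
            np.fill_diagonal(confusion, 1.0 - noise)
            profile = DetectorProfile(
                rates=base.rates,
                confusion=confusion,
                tp_conf=base.tp_conf,
                fp_conf=base.fp_conf,
                fp_rate=base.fp_rate,
            )
            slides, truths = generate_cohort(
                CohortConfig(n_slides=400, seed=101, profile=profile)
            )
            feats = [extract_features(ds) for ds in slides]
            model = train_slide_classifier(feats[:320], truths[:320], n_trees=150)
            correct = sum(
                predict_slide_grade(model, fv).grade is t
                for fv, t in zip(feats[320:], truths[320:])
            )
            accs.append(correct / 80)
        assert accs[0] + 1e-9 >= accs[1] >= accs[2] - 0.02  # small MC slack at the tail


class TestFeatureMatrix:
    def test_stable_headers(self, small_cohort):
        slides, _ = small_cohort
        feats = [extract_features(ds) for ds in slides[:5]]
        frame = feature_matrix(feats)
        assert list(frame.columns) == list(feats[0].names)
        assert frame.shape == (5, len(feats[0].names))

    def test_inconsistent_layout_rejected(self, small_cohort):
        slides, _ = small_cohort
        a = extract_features(slides[0])
        b = extract_features(slides[1], include_counts=False)
        with pytest.raises(ValueError):
            feature_matrix([a, b])
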