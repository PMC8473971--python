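import numpy as np
import pandas as pd
import pytest

from tepav.annotations import ABSENT, AMBIGUOUS, MISSING, PRESENT, CallMatrix
from tepav.classify import (
    ModelBundle,
    assemble_training_set,
    classify_panel,
    classify_table,
    confusion_rates,
    filter_high_ambiguity,
    filter_recalcitrant,
    label_from_probability,
    select_model,
    train,
)
from tepav.simulate import CoverageModel, SimConfig, simulate_features, simulate_truth_panel


def _labeled_frame(n_present, n_absent, seed=0, sep=30.0, noise=0.6):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_present + n_absent):
        present = i < n_present
        lam = sep if present else noise
        rows.append(
            {
                "te_id": f"te{i}",
                "sample_id": "s0",
                "start_cov": float(rng.poisson(lam)),
                "end_cov": float(rng.poisson(lam)),
                "order": ["LTR", "TIR", "Helitron"][i % 3],
                "label": PRESENT if present else ABSENT,
            }
        )
    return pd.DataFrame(rows)


class TestThresholds:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.70, PRESENT), (0.30, ABSENT), (0.50, AMBIGUOUS),
         (0.699999, AMBIGUOUS), (0.300001, AMBIGUOUS), (1.0, PRESENT), (0.0, ABSENT)],
    )
    def test_inclusive_boundaries(self, p, expected):
        assert label_from_probability(p) == expected

    def test_every_probability_gets_exactly_one_label(self):
        for p in np.linspace(0, 1, 101):
            assert label_from_probability(p) in (PRESENT, ABSENT, AMBIGUOUS)


class TestModelSelection:
    def _bundle(self):
        return ModelBundle(model_15x="m15", model_30x="m30")

    @pytest.mark.parametrize(
        "depth,expected", [(25.0, "30x"), (24.999, "15x"), (40.0, "30x"), (10.0, "15x")]
    )
    def test_switch_at_25x(self, depth, expected):
        assert select_model(self._bundle(), depth) == expected

    def test_nonpositive_depth_rejected(self):
        with pytest.raises(ValueError):
            select_model(self._bundle(), 0.0)

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ModelBundle(model_15x="a", model_30x="b", absent_max=0.8, present_min=0.7)


class TestAssembleTrainingSet:
    def _truth(self, frame):
        labels = frame.pivot(index="te_id", columns="sample_id", values="label")
        return CallMatrix(labels.fillna(MISSING))

    def test_balanced_sampling(self):
        frame = _labeled_frame(10, 10)
        truth = self._truth(frame)
        train_set, _ = assemble_training_set(
            truth, frame.drop(columns="label"), n_max=10, seed=1
        )
        assert len(train_set) == 10
        assert (train_set["label"] == PRESENT).sum() == 5

    def test_availability_cap_with_warning(self):
        frame = _labeled_frame(3, 100)
        truth = self._truth(frame)
        with pytest.warns(UserWarning, match="capped"):
            train_set, _ = assemble_training_set(
                truth, frame.drop(columns="label"), n_max=10, seed=1
            )
        assert (train_set["label"] == PRESENT).sum() == 3
        assert (train_set["label"] == ABSENT).sum() == 3

    def test_reproducible_under_seed(self):
        frame = _labeled_frame(50, 50)
        truth = self._truth(frame)
        feats = frame.drop(columns="label")
        a, _ = assemble_training_set(truth, feats, n_max=20, seed=7)
        b, _ = assemble_training_set(truth, feats, n_max=20, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_empty_class_rejected(self):
        frame = _labeled_frame(5, 0)
        truth = self._truth(frame)
        with pytest.raises(ValueError, match="balance"):
            assemble_training_set(truth, frame.drop(columns="label"), n_max=4)

    def test_holdout_group_becomes_test_set(self):
        frame = _labeled_frame(20, 20)
        frame["sample_id"] = ["s0", "s1"] * 20
        labels = frame.pivot(index="te_id", columns="sample_id", values="label").fillna(
            MISSING
        )
        truth = CallMatrix(labels)
        train_set, test_set = assemble_training_set(
            truth,
            frame.drop(columns="label"),
            n_max=100,
            groups={"s0": "gA", "s1": "gB"},
            holdout="gB",
            seed=0,
        )
        assert set(test_set["sample_id"]) == {"s1"}
        assert set(train_set["sample_id"]) == {"s0"}


class TestTrain:
    def test_separable_data_has_high_cv_accuracy(self):
        train_set = _labeled_frame(150, 150, sep=40.0, noise=0.2)
        _, report = train(train_set, folds=5, repeats=2, seed=0, n_estimators=60)
        assert report.cv_accuracy_mean >= 0.99

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(3)
        train_set = _labeled_frame(200, 200, seed=3)
        train_set["label"] = rng.permutation(train_set["label"].to_numpy())
        _, report = train(train_set, folds=5, repeats=3, seed=0, n_estimators=60)
        assert abs(report.cv_accuracy_mean - 0.5) <= max(3 * report.cv_accuracy_se, 0.08)

    def test_nonfinite_features_rejected(self):
        train_set = _labeled_frame(20, 20)
        train_set.loc[3, "start_cov"] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            train(train_set, folds=2, repeats=1, cv=False)

    def test_unseen_order_level_rejected_at_classification(self):
        train_set = _labeled_frame(30, 30)
        train_set["order"] = ["LTR", "TIR"] * 30
        model, _ = train(train_set, cv=False, n_estimators=20)
        probe = train_set.head(1).drop(columns="label").assign(order="Helitron")
        with pytest.raises(Exception, match="[Uu]nknown categor"):
            classify_table(model, probe)

    def test_coverage_importance_exceeds_order(self):
        train_set = _labeled_frame(300, 300)
        _, report = train(train_set, cv=False, n_estimators=100, seed=0)
        imp = report.importances
        assert imp["start_cov"] > imp["order"]
        assert imp["end_cov"] > imp["order"]


class TestDegradationMonotonicity:
    def test_accuracy_non_increasing_as_separation_shrinks(self):
        cfg = SimConfig(seed=21, n_samples=40, n_tes=150)
        panel = simulate_truth_panel(cfg)
        groups = {s: ("test" if i % 4 == 0 else "train") for i, s in enumerate(panel.sample_ids)}
        accs = []
        n_eval = None
        for absent_scale in (0.02, 0.45, 0.75):
            cm = CoverageModel(
                lambda_absent_scale=absent_scale, ambiguous_fraction=0.0
            )
            feats, covs = simulate_features(panel, depth=10.0, coverage_model=cm, seed=22)
            train_set, test_set = assemble_training_set(
                panel.truth_calls, feats, n_max=4000, groups=groups,
                holdout="test", seed=1,
            )
            model, _ = train(train_set, cv=False, n_estimators=60, seed=1)
            bundle = ModelBundle(model_15x=model, model_30x=model)
            calls = classify_panel(bundle, test_set.drop(columns="label"), covs)
            rates = confusion_rates(calls, panel.truth_calls)
            accs.append(rates["accuracy"])
            n_eval = rates["n"]
        se = np.sqrt(0.25 / n_eval)
        assert accs[1] <= accs[0] + se
        assert accs[2] <= accs[1] + se


class TestFilters:
    def _matrix(self, rows, samples):
        return CallMatrix(
            pd.DataFrame(rows, index=pd.Index([f"te{i}" for i in range(len(rows))],
                                              name="te_id"), columns=samples)
        )

    def test_recalcitrant_filter_keeps_only_cognate_present(self):
        m = self._matrix(
            [[PRESENT, ABSENT], [AMBIGUOUS, PRESENT], [ABSENT, PRESENT]],
            ["cognate", "other"],
        )
        retained, report = filter_recalcitrant(m, "cognate")
        assert retained == ["te0"]
        assert sorted(report["te_id"]) == ["te1", "te2"]

    def test_recalcitrant_missing_cognate_rejected(self):
        m = self._matrix([[PRESENT]], ["s1"])
        with pytest.raises(ValueError, match="cognate"):
            filter_recalcitrant(m, "nope")

    @pytest.mark.parametrize("n_ambiguous,kept", [(25, True), (26, False), (0, True)])
    def test_ambiguity_filter_is_strictly_greater_than(self, n_ambiguous, kept):
        row = [AMBIGUOUS] * n_ambiguous + [PRESENT] * (100 - n_ambiguous)
        m = self._matrix([row], [f"s{i}" for i in range(100)])
        assert (["te0"] == filter_high_ambiguity(m, 0.25)) is kept

    def test_ambiguity_denominator_excludes_missing(self):
        # 2 ambiguous of 4 non-missing = 50% -> removed despite 6 missing
        row = [AMBIGUOUS] * 2 + [PRESENT] * 2 + [MISSING] * 6
        m = self._matrix([row], [f"s{i}" for i in range(10)])
        assert filter_high_ambiguity(m, 0.25) == []


class TestConfusionRates:
    def _m(self, rows, samples=("s1", "s2")):
        return CallMatrix(
            pd.DataFrame(rows, index=pd.Index([f"te{i}" for i in range(len(rows))],
                                              name="te_id"), columns=list(samples))
        )

    def test_identical_calls_are_perfect(self):
        truth = self._m([[PRESENT, ABSENT], [ABSENT, PRESENT]])
        assert confusion_rates(truth, truth)["accuracy"] == 1.0

    def test_inverted_calls_are_zero(self):
        truth = self._m([[PRESENT, ABSENT], [ABSENT, PRESENT]])
        calls = self._m([[ABSENT, PRESENT], [PRESENT, ABSENT]])
        assert confusion_rates(calls, truth)["accuracy"] == 0.0

    def test_ambiguous_excluded_from_denominator(self):
        truth = self._m([[PRESENT, PRESENT], [ABSENT, ABSENT]])
        calls = self._m([[PRESENT, AMBIGUOUS], [ABSENT, PRESENT]])
        rates = confusion_rates(calls, truth)
        assert rates["n"] == 3
        assert rates["accuracy"] == pytest.approx(2 / 3)

    def test_no_overlap_rejected(self):
        a = self._m([[PRESENT, ABSENT]])
        b = CallMatrix(
            pd.DataFrame([[PRESENT]], index=pd.Index(["other"], name="te_id"),
                         columns=["sX"])
        )
        with pytest.raises(ValueError, match="no shared"):
            confusion_rates(a, b)


class TestBundleSerialization:
    def test_save_load_round_trip(self, tmp_path):
        train_set = _labeled_frame(30, 30)
        model, report = train(train_set, cv=False, n_estimators=10, seed=0)
        bundle = ModelBundle(
            model_15x=model, model_30x=model, training_report={"30x": report.to_dict()}
        )
        path = tmp_path / "bundle.joblib"
        bundle.save(path)
        loaded = ModelBundle.load(path)
        assert loaded.training_report["30x"]["importances"] == report.importances
        assert loaded.training_report["30x"]["n_train"] == report.n_train
        probe = train_set.drop(columns="label")
        orig = classify_table(bundle.model_30x, probe)["probability"]
        back = classify_table(loaded.model_30x, probe)["probability"]
        assert (orig == back).all()
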