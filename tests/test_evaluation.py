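import numpy as np
import pandas as pd
import pytest

from oracles import confusion_oracle
from sleepstage import reference
from sleepstage.evaluation import (
    agreement_rate,
    cohen_kappa,
    confusion,
    f1_score,
    kfold_cv,
    report,
    stratified_split,
)
from sleepstage.flags import DegenerateEpochWarning
from sleepstage.models import ModelSpec
from sleepstage.signal_io import STAGES


class TestStratifiedSplit:
    def test_benchmark_counts_give_1940_test_epochs(self):
        labels = reference.benchmark_labels()
        train, test = stratified_split(labels, test_frac=0.2, seed=0)
        assert test.size == 1940
        assert train.size == 9696 - 1940
        # per-class proportions preserved to within one epoch
        for stage, n in reference.CLASS_COUNTS.items():
            got = int(np.sum(labels[test] == stage))
            assert abs(got - 0.2 * n) <= 1.0

    def test_disjoint_exhaustive(self):
        labels = np.array(["W"] * 10 + ["N1"] * 10, dtype=object)
        train, test = stratified_split(labels, test_frac=0.3, seed=1)
        assert set(train) | set(test) == set(range(20))
        assert set(train) & set(test) == set()

    def test_zero_fraction(self):
        labels = np.array(["W"] * 5 + ["N1"] * 5, dtype=object)
        train, test = stratified_split(labels, test_frac=0.0, seed=0)
        assert test.size == 0 and train.size == 10

    def test_determinism(self):
        labels = reference.benchmark_labels()
        a = stratified_split(labels, seed=42)
        b = stratified_split(labels, seed=42)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_tiny_class_rejected(self):
        labels = np.array(["W"] * 10 + ["N1"], dtype=object)
        with pytest.raises(ValueError):
            stratified_split(labels, test_frac=0.2, seed=0)


class TestKFoldCV:
    def test_separable_data_perfect_folds(self, rng):
        x = pd.DataFrame({"f": np.r_[np.zeros(30), np.ones(30) * 10]})
        y = np.array(["W"] * 30 + ["N1"] * 30, dtype=object)
        accs = kfold_cv(ModelSpec("dt", seed=0), x, y, k=5, seed=0)
        assert accs.shape == (5,)
        assert np.all(accs == 1.0)

    def test_random_labels_near_chance(self, rng):
        n = 250
        x = pd.DataFrame(rng.standard_normal((n, 5)), columns=list("abcde"))
        y = rng.choice(list(STAGES), size=n)
        accs = kfold_cv(ModelSpec("dt", seed=0), x, y, k=5, seed=0)
        sd = np.sqrt(0.2 * 0.8 / n)
        assert abs(accs.mean() - 0.2) <= 3 * sd + 0.05

    def test_k_larger_than_smallest_class_rejected(self, rng):
        x = pd.DataFrame({"f": np.arange(10.0)})
        y = np.array(["W"] * 7 + ["N1"] * 3, dtype=object)
        with pytest.raises(ValueError):
            kfold_cv(ModelSpec("dt"), x, y, k=5, seed=0)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self, rng):
        y = rng.choice(list(STAGES), size=100)
        cm = confusion(y, y)
        assert np.trace(cm.to_numpy()) == 100
        assert cm.to_numpy().sum() == 100

    def test_single_pair(self):
        cm = confusion(["W"], ["N1"])
        assert cm.loc["W", "N1"] == 1
        assert cm.to_numpy().sum() == 1

    def test_matches_tally_oracle(self, rng):
        y_true = rng.choice(list(STAGES), size=500)
        y_pred = rng.choice(list(STAGES), size=500)
        cm = confusion(y_true, y_pred)
        assert np.array_equal(cm.to_numpy(), confusion_oracle(y_true, y_pred, STAGES))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion(["W", "W"], ["W"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            confusion(["W"], ["S4"])


class TestReport:
    def _published_cm(self):
        """Confusion matrix consistent with the published per-stage test and
        correct counts (off-diagonal errors placed arbitrarily: recall and
        pooled accuracy only depend on the row margins and the diagonal)."""
        t = reference.SVM_STAGE_TABLE
        cm = pd.DataFrame(0, index=list(STAGES), columns=list(STAGES))
        for stage in t.index:
            cm.loc[stage, stage] = t.loc[stage, "correct"]
            spill = [s for s in STAGES if s != stage][0]
            cm.loc[stage, spill] += t.loc[stage, "test"] - t.loc[stage, "correct"]
        return cm

    def test_published_recalls(self):
        rep = report(self._published_cm())
        assert round(rep.per_stage.loc["N3", "recall"], 4) == 0.9304
        assert round(rep.per_stage.loc["W", "recall"], 4) == 0.9326

    def test_published_overall_accuracy(self):
        rep = report(self._published_cm())
        assert round(100 * rep.accuracy, 2) == 81.86

    def test_f1_from_published_precision_recall(self):
        t = reference.SVM_STAGE_TABLE
        assert round(f1_score(t.loc["N3", "precision"], t.loc["N3", "recall"]), 4) == 0.9145
        assert round(f1_score(t.loc["N1", "precision"], t.loc["N1", "recall"]), 4) == 0.6827

    def test_f1_is_harmonic_mean_identity(self, rng):
        y_true = rng.choice(list(STAGES), size=400)
        y_pred = rng.choice(list(STAGES), size=400)
        rep = report(confusion(y_true, y_pred))
        for stage in STAGES:
            p, r = rep.per_stage.loc[stage, ["precision", "recall"]]
            assert rep.per_stage.loc[stage, "f1"] == pytest.approx(f1_score(p, r), abs=1e-12)

    def test_perfect_prediction_accuracy_one(self, rng):
        y = rng.choice(list(STAGES), size=50)
        assert report(confusion(y, y)).accuracy == 1.0

    def test_micro_metrics_equal_accuracy(self, rng):
        y_true = rng.choice(list(STAGES), size=300)
        y_pred = rng.choice(list(STAGES), size=300)
        cm = confusion(y_true, y_pred)
        tp = np.trace(cm.to_numpy())
        fp = cm.to_numpy().sum(axis=0).sum() - tp  # = total - trace
        fn = cm.to_numpy().sum(axis=1).sum() - tp
        micro_p = tp / (tp + fp)
        micro_r = tp / (tp + fn)
        assert micro_p == micro_r == report(cm).accuracy

    def test_never_predicted_stage_flagged(self):
        cm = confusion(["W", "W", "N1"], ["W", "W", "W"])
        with pytest.warns(DegenerateEpochWarning):
            rep = report(cm)
        assert rep.per_stage.loc["N1", "precision"] == 0.0


class TestAgreement:
    def test_identical(self):
        assert agreement_rate(["W", "N1"], ["W", "N1"]) == 1.0

    def test_disjoint(self):
        assert agreement_rate(["W", "N1"], ["N1", "W"]) == 0.0

    def test_one_in_hundred(self):
        a = ["W"] * 100
        b = ["W"] * 99 + ["N1"]
        assert agreement_rate(a, b) == pytest.approx(0.99)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            agreement_rate(["W"], ["W", "W"])


class TestCohenKappa:
    def test_perfect_diagonal(self):
        cm = pd.DataFrame(np.diag([10, 20, 30]))
        assert cohen_kappa(cm) == pytest.approx(1.0)

    def test_toy_two_class(self):
        # 80% agreement with 50/50 marginals -> kappa 0.6
        cm = pd.DataFrame([[40, 10], [10, 40]])
        assert cohen_kappa(cm) == pytest.approx(0.6)

    def test_independent_marginals_near_zero(self, rng):
        y_true = rng.choice(list(STAGES), size=20000)
        y_pred = rng.choice(list(STAGES), size=20000)
        assert cohen_kappa(confusion(y_true, y_pred)) == pytest.approx(0.0, abs=0.02)

    def test_degenerate_marginals_rejected(self):
        cm = pd.DataFrame([[5, 0], [0, 0]])
        with pytest.raises(ValueError):
            cohen_kappa(cm)
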