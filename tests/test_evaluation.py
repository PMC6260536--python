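"""Evaluation protocols: AAMI mapping, fold construction, metrics, CV."""

import numpy as np
import pytest

import ecgbeats as eb
from ecgbeats.evaluation import holdout_records, make_kfold_partition


class TestAAMIMapping:
    @pytest.mark.parametrize("symbol,expected", [
        ("L", "N"), ("!", "V"), ("/", "Q"), ("N", "N"), ("A", "S"),
        ("F", "F"), ("f", "Q"), ("x", "S"), ("E", "V"), ("j", "N"),
    ])
    def test_examples(self, symbol, expected):
        assert eb.map_to_aami(symbol) == expected

    def test_total_onto_exactly_five_classes(self):
        assert set(eb.AAMI_MAPPING) == set(eb.BEAT_SYMBOLS)
        assert set(eb.AAMI_MAPPING.values()) == set(eb.AAMI_CLASSES)
        assert len(eb.AAMI_CLASSES) == 5

    def test_unknown_symbol_rejected(self):
        with pytest.raises(KeyError):
            eb.map_to_aami("Z")

    def test_count_conservation(self, mixed_record):
        symbols = mixed_record.symbols
        mapped = [eb.map_to_aami(s) for s in symbols]
        assert len(mapped) == len(symbols)
        fine = {s: symbols.count(s) for s in set(symbols)}
        coarse = {c: mapped.count(c) for c in set(mapped)}
        assert sum(fine.values()) == sum(coarse.values())


class TestFolds:
    def test_floor_rule(self):
        folds = eb.make_folds(["N"] * 10, n_folds=3, seed=0)
        for f in folds:
            assert len(f.train_indices) == 7
            assert len(f.test_indices) == 3

    def test_special_fraction_for_sparse_class(self):
        labels = ["N"] * 10 + ["e"] * 2
        folds = eb.make_folds(labels, seed=1)
        for f in folds:
            e_train = sum(labels[i] == "e" for i in f.train_indices)
            e_test = sum(labels[i] == "e" for i in f.test_indices)
            assert (e_train, e_test) == (1, 1)

    def test_disjoint_and_exhaustive(self):
        labels = ["N"] * 40 + ["V"] * 25 + ["L"] * 9
        for f in eb.make_folds(labels, seed=2):
            train, test = set(f.train_indices), set(f.test_indices)
            assert not train & test
            assert train | test == set(range(len(labels)))

    def test_folds_resample_independently(self):
        labels = ["N"] * 200 + ["V"] * 200
        folds = eb.make_folds(labels, seed=3)
        tests = [set(f.test_indices) for f in folds]
        assert tests[0] != tests[1] and tests[1] != tests[2]

    def test_singleton_class_excluded_with_warning(self):
        labels = ["N"] * 10 + ["e"]
        with pytest.warns(UserWarning, match="excluded"):
            folds = eb.make_folds(labels, seed=0)
        for f in folds:
            assert 10 not in set(f.train_indices) | set(f.test_indices)

    def test_empty_labels_rejected(self):
        with pytest.raises(ValueError):
            eb.make_folds([])

    def test_kfold_partition_option(self):
        labels = ["N"] * 30 + ["V"] * 30
        folds = make_kfold_partition(labels, n_folds=3, seed=0)
        all_test = np.concatenate([f.test_indices for f in folds])
        assert sorted(all_test) == list(range(60))  # true partition


class TestConfusion:
    def test_diagonal_example(self):
        cm = eb.confusion(["N", "N", "V"], ["N", "N", "V"], ["N", "V"])
        assert np.array_equal(cm.counts, [[2, 0], [0, 1]])

    def test_conservation_and_permutation_invariance(self, rng):
        classes = ["N", "V", "L"]
        actual = rng.choice(classes, size=60)
        pred = rng.choice(classes, size=60)
        cm = eb.confusion(actual, pred, classes)
        assert cm.total == 60
        perm = rng.permutation(60)
        cm2 = eb.confusion(actual[perm], pred[perm], classes)
        assert np.array_equal(cm.counts, cm2.counts)

    def test_foreign_label_rejected(self):
        with pytest.raises(ValueError):
            eb.confusion(["N"], ["Z"], ["N", "V"])
        with pytest.raises(ValueError):
            eb.confusion(["N", "V"], ["N"], ["N", "V"])


def brute_force_metrics(counts):
    """Independent per-class recount straight from the definitions."""
    counts = np.asarray(counts)
    k = counts.shape[0]
    total = counts.sum()
    out = []
    for i in range(k):
        tp = sum(counts[a][p] for a in range(k) for p in range(k) if a == i and p == i)
        fn = sum(counts[a][p] for a in range(k) for p in range(k) if a == i and p != i)
        fp = sum(counts[a][p] for a in range(k) for p in range(k) if a != i and p == i)
        tn = sum(counts[a][p] for a in range(k) for p in range(k) if a != i and p != i)
        out.append({
            "se": 100 * tp / (tp + fn) if tp + fn else np.nan,
            "sp": 100 * tn / (tn + fp) if tn + fp else np.nan,
            "ppv": 100 * tp / (tp + fp) if tp + fp else np.nan,
            "acc": 100 * (tp + tn) / total,
        })
    return out


class TestPerClassMetrics:
    def test_worked_example(self):
        cm = eb.ConfusionMatrix(np.array([[2, 0], [1, 1]]), ["pos", "neg"])
        rep = eb.per_class_metrics(cm)
        assert rep.se[0] == pytest.approx(100.0)
        assert rep.ppv[0] == pytest.approx(100 * 2 / 3)
        assert rep.sp[0] == pytest.approx(50.0)
        assert rep.overall_accuracy == pytest.approx(75.0)

    def test_perfect_diagonal(self):
        cm = eb.ConfusionMatrix(np.diag([5, 3, 9]), ["N", "V", "L"])
        rep = eb.per_class_metrics(cm)
        for m in (rep.se, rep.sp, rep.ppv, rep.acc):
            assert np.allclose(m, 100.0)
        assert rep.overall_accuracy == 100.0

    def test_undefined_ratios_reported_as_nan_with_note(self):
        # class V never occurs and is never predicted
        cm = eb.ConfusionMatrix(np.array([[4, 0], [0, 0]]), ["N", "V"])
        rep = eb.per_class_metrics(cm)
        assert np.isnan(rep.se[1]) and np.isnan(rep.ppv[1])
        assert any("V" in n for n in rep.notes)
        avg = rep.averages()
        assert avg["Se"] == pytest.approx(100.0)  # NaNs excluded

    def test_matches_brute_force_recount(self, rng):
        for _ in range(100):
            k = int(rng.integers(2, 7))
            counts = rng.integers(0, 30, size=(k, k))
            if counts.sum() == 0:
                counts[0, 0] = 1
            cm = eb.ConfusionMatrix(counts, [str(i) for i in range(k)])
            rep = eb.per_class_metrics(cm)
            for i, ref in enumerate(brute_force_metrics(counts)):
                for name, arr in [("se", rep.se), ("sp", rep.sp),
                                  ("ppv", rep.ppv), ("acc", rep.acc)]:
                    if np.isnan(ref[name]):
                        assert np.isnan(arr[i])
                    else:
                        assert arr[i] == ref[name]

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            eb.per_class_metrics(eb.ConfusionMatrix(np.zeros((2, 2)), ["N", "V"]))


@pytest.fixture(scope="module")
def cv_results(mixed_dataset):
    net = eb.NetworkConfig(epochs=60, seed=5)
    class_cv = eb.cross_validate(mixed_dataset, "class_oriented", network=net, seed=9)
    aami_cv = eb.cross_validate(mixed_dataset, "subject_oriented", network=net, seed=9)
    return class_cv, aami_cv


class TestCrossValidate:
    def test_class_oriented_shape(self, cv_results):
        class_cv, _ = cv_results
        assert len(class_cv.class_list) == 18
        assert len(class_cv.folds) == 3
        frame = class_cv.average_frame()
        assert frame.shape == (18, 4)

    def test_subject_oriented_shape(self, cv_results, mixed_dataset):
        _, aami_cv = cv_results
        assert aami_cv.class_list == list(eb.AAMI_CLASSES)
        for fold in aami_cv.folds:
            n_train = len(fold.fold.train_indices)
            assert fold.cm.total + n_train == len(mixed_dataset)

    def test_overall_accuracy_consistent_with_stored_cm(self, cv_results):
        for cv in cv_results:
            for fold in cv.folds:
                C = fold.cm.counts
                assert fold.report.overall_accuracy == pytest.approx(
                    100.0 * np.trace(C) / C.sum()
                )
            assert cv.mean_overall_accuracy == pytest.approx(
                np.mean([f.report.overall_accuracy for f in cv.folds])
            )

    def test_unknown_scheme_rejected(self, mixed_dataset):
        with pytest.raises(ValueError):
            eb.cross_validate(mixed_dataset, scheme="bogus")


class TestLeakageGuard:
    def test_extractor_refuses_test_flagged_beats(self, mixed_dataset):
        flags = np.zeros(len(mixed_dataset), dtype=bool)
        flags[5] = True
        ext = eb.HybridFeatureExtractor()
        with pytest.raises(RuntimeError, match="leakage"):
            ext.fit(mixed_dataset, indices=np.array([2, 5, 7]), is_test=flags)


def test_holdout_records_keeps_records_intact():
    ids = np.array(["r1"] * 5 + ["r2"] * 4 + ["r3"] * 6)
    train, test = holdout_records(ids, ["r2"])
    assert set(ids[test]) == {"r2"}
    assert set(ids[train]) == {"r1", "r3"}
    assert len(train) + len(test) == 15
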