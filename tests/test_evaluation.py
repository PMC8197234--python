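"""Splitting, cross-validation plumbing, metric panels, summaries, t-SNE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from monoclass import evaluation as ev
from monoclass.synthetic_cells import CLASSES


def brute_force_metrics(truth, pred, classes):
    """Independent confusion-matrix oracle for the metric panel."""
    acc = sum(t == p for t, p in zip(truth, pred)) / len(truth)
    precs, recs, f1s = [], [], []
    for c in classes:
        tp = sum(1 for t, p in zip(truth, pred) if t == c and p == c)
        fp = sum(1 for t, p in zip(truth, pred) if t != c and p == c)
        fn = sum(1 for t, p in zip(truth, pred) if t == c and p != c)
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    return acc, np.mean(precs), np.mean(recs), np.mean(f1s)


class TestStratifiedSplit:
    def test_single_class_exact_fractions(self):
        tr, va, te = ev.stratified_split(["a"] * 100, ev.SplitSpec(rng_seed=0))
        assert (len(tr), len(va), len(te)) == (70, 10, 20)

    def test_partition_of_all_indices(self):
        labels = ["a"] * 37 + ["b"] * 23
        tr, va, te = ev.stratified_split(labels, ev.SplitSpec(rng_seed=1))
        combined = np.sort(np.concatenate([tr, va, te]))
        assert np.array_equal(combined, np.arange(60))

    @given(na=st.integers(5, 60), nb=st.integers(5, 60), seed=st.integers(0, 50))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_per_class_proportions_within_one_cell(self, na, nb, seed):
        labels = ["a"] * na + ["b"] * nb
        spec = ev.SplitSpec(rng_seed=seed)
        sets = ev.stratified_split(labels, spec)
        arr = np.asarray(labels)
        for s, frac in zip(sets, spec.fractions):
            for cls, n_cls in (("a", na), ("b", nb)):
                got = (arr[s] == cls).sum()
                assert abs(got - frac * n_cls) <= 1.0

    def test_class_with_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            ev.stratified_split(["a"] * 10 + ["b"] * 2, ev.SplitSpec())

    def test_grouped_split_keeps_patients_whole(self):
        rng = np.random.default_rng(2)
        patients = [f"p{i % 7}" for i in range(140)]
        labels = rng.choice(["a", "b"], 140).tolist()
        spec = ev.SplitSpec(group_by_patient=True, rng_seed=3)
        sets = ev.stratified_split(labels, spec, patient_ids=patients)
        seen = {}
        for s_idx, s in enumerate(sets):
            for i in s:
                pid = patients[i]
                assert seen.setdefault(pid, s_idx) == s_idx
        assert np.array_equal(np.sort(np.concatenate(sets)), np.arange(140))


class TestStratifiedKFold:
    def test_balanced_binary_even_folds(self):
        labels = ["a"] * 10 + ["b"] * 10
        folds = ev.stratified_kfold(labels, ev.FoldSpec(k=5, rng_seed=0))
        for f in folds:
            arr = np.asarray(labels)[f]
            assert (arr == "a").sum() == 2 and (arr == "b").sum() == 2

    def test_pigeonhole_counts(self):
        folds = ev.stratified_kfold(["a"] * 11, ev.FoldSpec(k=5, rng_seed=0))
        sizes = sorted(len(f) for f in folds)
        assert sizes == [2, 2, 2, 2, 3]

    def test_deterministic_given_seed(self):
        labels = (["a"] * 13 + ["b"] * 17)
        f1 = ev.stratified_kfold(labels, ev.FoldSpec(k=5, rng_seed=7))
        f2 = ev.stratified_kfold(labels, ev.FoldSpec(k=5, rng_seed=7))
        assert all(np.array_equal(x, y) for x, y in zip(f1, f2))

    @given(na=st.integers(6, 40), nb=st.integers(6, 40), seed=st.integers(0, 20))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_partition_and_stratification(self, na, nb, seed):
        labels = ["a"] * na + ["b"] * nb
        folds = ev.stratified_kfold(labels, ev.FoldSpec(k=5, rng_seed=seed))
        combined = np.sort(np.concatenate(folds))
        assert np.array_equal(combined, np.arange(na + nb))
        arr = np.asarray(labels)
        for cls in ("a", "b"):
            counts = [(arr[f] == cls).sum() for f in folds]
            assert max(counts) - min(counts) <= 1

    def test_small_class_rejected(self):
        with pytest.raises(ValueError, match="b"):
            ev.stratified_kfold(["a"] * 10 + ["b"] * 3, ev.FoldSpec(k=5))


class TestComputeMetrics:
    def test_perfect_predictions(self):
        p = ev.compute_metrics(["a", "b", "a"], ["a", "b", "a"])
        assert (p.accuracy, p.precision, p.recall, p.f1) == (1.0, 1.0, 1.0, 1.0)

    def test_hand_confusion_example(self):
        p = ev.compute_metrics(["a", "a", "b", "b"], ["a", "b", "a", "b"])
        assert p.accuracy == p.precision == p.recall == p.f1 == 0.5

    def test_degenerate_single_class_predictions(self):
        p = ev.compute_metrics(["a", "a", "b", "b"], ["a", "a", "a", "a"])
        assert p.accuracy == 0.5 and p.recall == 0.5
        assert p.precision == 0.25  # unpredicted class contributes 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(2, 40))
            truth = rng.choice(list(CLASSES), n).tolist()
            pred = rng.choice(list(CLASSES), n).tolist()
            panel = ev.compute_metrics(truth, pred, classes=CLASSES)
            acc, prec, rec, f1 = brute_force_metrics(truth, pred, CLASSES)
            assert panel.accuracy == pytest.approx(acc, abs=1e-12)
            assert panel.precision == pytest.approx(prec, abs=1e-12)
            assert panel.recall == pytest.approx(rec, abs=1e-12)
            assert panel.f1 == pytest.approx(f1, abs=1e-12)

    def test_label_outside_class_set_rejected(self):
        with pytest.raises(ValueError):
            ev.compute_metrics(["a"], ["z"], classes=("a", "b"))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ev.compute_metrics(["a"], ["a", "b"])


class TestSummarize:
    def test_five_fold_accuracy_row(self):
        s = ev.summarize([0.56, 0.57, 0.81, 0.77, 0.58])
        assert s.rounded() == (0.66, 0.12)

    def test_reviewer_accuracy_row(self):
        s = ev.summarize([0.86, 0.86, 0.72, 0.86, 0.76])
        assert s.rounded() == (0.81, 0.07)

    def test_constant_list_zero_std(self):
        assert ev.summarize([0.5, 0.5, 0.5]).rounded() == (0.5, 0.0)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            ev.summarize([0.5])

    def test_sample_not_population_sd(self):
        s = ev.summarize([0.0, 1.0])
        assert s.std == pytest.approx(np.sqrt(0.5))


@pytest.fixture(scope="module")
def clustered_features():
    rng = np.random.default_rng(5)
    centers = np.array([[0, 0, 0, 0], [20, 0, 0, 0], [0, 20, 0, 0]])
    feats = np.vstack([c + rng.normal(0, 0.5, (15, 4)) for c in centers])
    labels = np.repeat([0, 1, 2], 15)
    return feats, labels


class TestTsne:
    def test_deterministic_given_seed(self, clustered_features):
        feats, _ = clustered_features
        a = ev.tsne_embed(feats, rng_seed=0)
        b = ev.tsne_embed(feats, rng_seed=0)
        assert np.allclose(a, b)

    def test_duplicate_rows_land_close(self, clustered_features):
        feats, _ = clustered_features
        feats = np.vstack([feats, feats[0]])
        coords = ev.tsne_embed(feats, rng_seed=1)
        spread = np.ptp(coords, axis=0).max()
        assert np.linalg.norm(coords[0] - coords[-1]) < 0.05 * spread

    def test_separated_clusters_positive_silhouette(self, clustered_features):
        from sklearn.metrics import silhouette_score
        feats, labels = clustered_features
        coords = ev.tsne_embed(feats, rng_seed=2)
        assert silhouette_score(coords, labels) > 0

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            ev.tsne_embed(np.zeros((3, 4)), rng_seed=0)

    def test_embedding_plot_written(self, clustered_features, tmp_path):
        feats, labels = clustered_features
        coords = ev.tsne_embed(feats, rng_seed=3)
        out = tmp_path / "tsne.png"
        ev.plot_embedding(coords, labels, out)
        assert out.stat().st_size > 0
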