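"""Stratified splitting, 5-fold cross-validation, metric panels and t-SNE.

Metrics follow the four-number panel convention of this task — accuracy,
precision, recall, F1 — with precision/recall/F1 macro-averaged (equal
class weight; a class never predicted contributes precision 0).  Summary
rows are mean +/- sample standard deviation (n-1 denominator), rounded to
two decimals for reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from monoclass import classifier as clf
from monoclass.preprocess import PreprocessConfig, run_configuration
from monoclass.synthetic_cells import largest_remainder_counts


@dataclass(frozen=True)
class SplitSpec:
    """70/10/20 train/validation/test split, stratified by class.

    With ``group_by_patient`` every patient's cells land in one set
    (class stratification then becomes best-effort).
    """

    fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)
    group_by_patient: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (3,) or np.any(f <= 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError("fractions must be 3 positive values summing to 1")


@dataclass(frozen=True)
class FoldSpec:
    k: int = 5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass(frozen=True)
class MetricPanel:
    accuracy: float
    precision: float
    recall: float
    f1: float
    n_classes: int
    averaging: str = "macro"

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    std: float
    n: int

    def rounded(self) -> tuple[float, float]:
        """(mean, std) to 2 decimals — the table-report convention."""
        return round(self.mean, 2), round(self.std, 2)

    def __str__(self) -> str:
        m, s = self.rounded()
        return f"{m:.2f} ± {s:.2f}"


# ---------------------------------------------------------------------------
# splitting

def _encode(labels) -> tuple[np.ndarray, list]:
    uniq = sorted(set(labels), key=list(labels).index)
    return np.array([uniq.index(l) for l in labels]), uniq


def stratified_split(labels, spec: SplitSpec, patient_ids=None):
    """Partition indices into (train, validation, test) index arrays.

    Per class, indices are shuffled and apportioned to the three sets by
    largest remainder, so every set's class proportions match the requested
    fractions within one cell.  Patient-grouped mode instead deals whole
    patients to the set furthest below its target size.
    """
    labels = list(labels)
    n = len(labels)
    if spec.group_by_patient:
        if patient_ids is None:
            raise ValueError("group_by_patient requires patient_ids")
        return _grouped_split(labels, patient_ids, spec)

    rng = np.random.default_rng(spec.rng_seed)
    codes, uniq = _encode(labels)
    sets: list[list[int]] = [[], [], []]
    for c in range(len(uniq)):
        idx = np.flatnonzero(codes == c)
        if idx.size < 3:
            raise ValueError(f"class {uniq[c]!r} has fewer than 3 members")
        rng.shuffle(idx)
        counts = largest_remainder_counts(idx.size, np.asarray(spec.fractions))
        bounds = np.cumsum(counts)[:-1]
        for s, part in enumerate(np.split(idx, bounds)):
            sets[s].extend(part.tolist())
    return tuple(np.sort(np.array(s, dtype=int)) for s in sets)


def _grouped_split(labels, patient_ids, spec: SplitSpec):
    rng = np.random.default_rng(spec.rng_seed)
    patients = sorted(set(patient_ids))
    rng.shuffle(patients)
    n = len(labels)
    targets = np.asarray(spec.fractions) * n
    sizes = np.zeros(3)
    assignment: dict[str, int] = {}
    # largest-deficit-first greedy keeps set sizes near target fractions
    for pid in sorted(patients, key=lambda p: -list(patient_ids).count(p)):
        deficit = targets - sizes
        s = int(np.argmax(deficit))
        assignment[pid] = s
        sizes[s] += list(patient_ids).count(pid)
    sets: list[list[int]] = [[], [], []]
    for i, pid in enumerate(patient_ids):
        sets[assignment[pid]].append(i)
    return tuple(np.array(sorted(s), dtype=int) for s in sets)


def stratified_kfold(labels, spec: FoldSpec):
    """k disjoint, class-stratified test-fold index arrays (counts per class
    differ by at most 1 across folds)."""
    labels = list(labels)
    codes, uniq = _encode(labels)
    binc = np.bincount(codes)
    if binc.min() < spec.k:
        small = uniq[int(binc.argmin())]
        raise ValueError(f"class {small!r} has fewer members ({binc.min()}) than k={spec.k}")
    skf = StratifiedKFold(n_splits=spec.k, shuffle=True, random_state=spec.rng_seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), codes)]


def iter_folds(labels, spec: FoldSpec):
    """Yield (train_indices, test_indices) for each of the k folds."""
    folds = stratified_kfold(labels, spec)
    all_idx = np.arange(len(list(labels)))
    for test in folds:
        train = np.setdiff1d(all_idx, test)
        yield train, test


# ---------------------------------------------------------------------------
# metrics and summaries

def compute_metrics(true_labels, predicted_labels, classes=None) -> MetricPanel:
    """Accuracy plus macro precision/recall/F1 for one prediction set."""
    true_labels, predicted_labels = list(true_labels), list(predicted_labels)
    if len(true_labels) != len(predicted_labels):
        raise ValueError("label vectors differ in length")
    if classes is None:
        classes = sorted(set(true_labels) | set(predicted_labels))
    else:
        bad = (set(true_labels) | set(predicted_labels)) - set(classes)
        if bad:
            raise ValueError(f"labels outside class set: {sorted(bad)}")
    acc = accuracy_score(true_labels, predicted_labels)
    prec, rec, f1, _ = precision_recall_fscore_support(
        true_labels, predicted_labels, labels=list(classes),
        average="macro", zero_division=0,
    )
    return MetricPanel(accuracy=float(acc), precision=float(prec),
                       recall=float(rec), f1=float(f1), n_classes=len(classes))


def summarize(values) -> SummaryStats:
    """Mean +/- sample standard deviation (n-1) of a list of metric values."""
    values = np.asarray(list(values), dtype=float)
    if values.size < 2:
        raise ValueError("summarize needs at least 2 values")
    return SummaryStats(mean=float(values.mean()),
                        std=float(values.std(ddof=1)),
                        n=int(values.size))


# ---------------------------------------------------------------------------
# t-SNE embedding

def tsne_embed(features: np.ndarray, rng_seed: int = 0,
               perplexity: float | None = None) -> np.ndarray:
    """2-D t-SNE of feature rows; perplexity 30, lowered to (n-1)/3 for small n."""
    from sklearn.manifold import TSNE

    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if n < 5:
        raise ValueError("t-SNE needs at least 5 rows")
    if features.shape[1] == 0:
        raise ValueError("feature dimension is 0")
    if perplexity is None:
        perplexity = min(30.0, (n - 1) / 3.0)
    tsne = TSNE(n_components=2, random_state=rng_seed, perplexity=perplexity,
                init="pca")
    return tsne.fit_transform(features)


def plot_embedding(coords: np.ndarray, labels, path) -> None:
    """Scatter the 2-D embedding coloured by class and save to file."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    labels = np.asarray(list(labels))
    for lab in sorted(set(labels.tolist())):
        sel = labels == lab
        ax.scatter(coords[sel, 0], coords[sel, 1], s=12, label=lab, alpha=0.8)
    ax.legend()
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# cross-validation harness

@dataclass
class CrossValResult:
    panels: list[MetricPanel]
    summaries: dict[str, SummaryStats]
    scheme: str

    def table(self) -> dict:
        """Fold-by-fold rows plus the Mean +/- STD row, 2-dp rounded."""
        rows = {f"fold_{i + 1}": {k: round(v, 2) for k, v in p.as_dict().items()}
                for i, p in enumerate(self.panels)}
        rows["mean_std"] = {k: str(s) for k, s in self.summaries.items()}
        return rows


def run_cross_validation(records, config: PreprocessConfig,
                         spec: clf.TrainingSpec, folds: FoldSpec,
                         scheme: str = "3-class") -> CrossValResult:
    """Stratified k-fold CV of the class-weighted CNN under one configuration.

    For the 2-class scheme, promonocyte and blast are merged into a single
    precursor class *before* training.  Each fold trains on k-1 pieces and
    is scored on the held-out piece; summaries are mean +/- sample SD over
    folds for each metric.
    """
    labels = [r.true_label for r in records]
    if scheme == "2-class":
        labels = clf.merge_labels(labels)
    elif scheme != "3-class":
        raise ValueError(f"unknown scheme {scheme!r}")
    classes = tuple(sorted(set(labels), key=["monocyte", "promonocyte", "blast",
                                             "precursor"].index))
    patches = [run_configuration(r, config) for r in records]

    panels = []
    for i, (train_idx, test_idx) in enumerate(iter_folds(labels, folds)):
        fold_spec = clf.TrainingSpec(
            backbone=spec.backbone, learning_rate=spec.learning_rate,
            epochs=spec.epochs, batch_size=spec.batch_size,
            rng_seed=spec.rng_seed + i, init=spec.init,
            input_size=spec.input_size)
        model = clf.train([patches[j] for j in train_idx],
                          [labels[j] for j in train_idx],
                          fold_spec, classes=classes)
        probs = clf.predict(model, [patches[j] for j in test_idx])
        pred = [classes[j] for j in probs.argmax(axis=1)]
        panels.append(compute_metrics([labels[j] for j in test_idx], pred,
                                      classes=classes))
    summaries = {
        m: summarize([getattr(p, m) for p in panels])
        for m in ("accuracy", "precision", "recall", "f1")
    }
    return CrossValResult(panels=panels, summaries=summaries, scheme=scheme)
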