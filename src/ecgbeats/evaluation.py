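"""Evaluation protocols: class-oriented (18 labels) and AAMI 5-class.

The AAMI (ANSI/AAMI EC57) grouping collapses the 18 fine-grained beat
types into five superclasses:

===== ==========================================================
class members (fine-grained symbols)
===== ==========================================================
N     N (normal), L (LBBB), R (RBBB), e (atrial escape), j (nodal escape)
S     A (APC), a (aberrated APC), x (blocked APB), J (nodal premature), S
V     V (PVC), E (ventricular escape), ! (ventricular flutter wave)
F     F (fusion of ventricular and normal)
Q     Q (unclassifiable), f (fusion of paced and normal), / (paced), |
===== ==========================================================

"3-fold cross-validation" here means three independent stratified random
70/30 subsamplings (per class: floor(0.7 * count) training beats, minimum
1 train and 1 test), not a partition-based k-fold — a true k-fold is
available via :func:`make_kfold_partition` for comparison.  The atrial
escape class 'e' trains on 50% by default because of its very low beat
count.  Per-class metrics are one-vs-rest Se, Sp, PPV and Acc in percent;
ratios with a zero denominator are reported as NaN and excluded from
averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.model_selection import StratifiedKFold

from .io import BEAT_SYMBOLS

AAMI_CLASSES: tuple[str, ...] = ("N", "S", "V", "F", "Q")

#: fine-grained symbol -> AAMI superclass
AAMI_MAPPING: dict[str, str] = {
    "N": "N", "L": "N", "R": "N", "e": "N", "j": "N",
    "A": "S", "a": "S", "x": "S", "J": "S", "S": "S",
    "V": "V", "E": "V", "!": "V",
    "F": "F",
    "Q": "Q", "f": "Q", "/": "Q", "|": "Q",
}

DEFAULT_SPECIAL_FRACS: dict[str, float] = {"e": 0.5}


def map_to_aami(symbol: str, mapping: dict[str, str] | None = None) -> str:
    """Map one fine-grained beat symbol to its AAMI superclass."""
    mapping = AAMI_MAPPING if mapping is None else mapping
    try:
        return mapping[symbol]
    except KeyError:
        raise KeyError(f"symbol {symbol!r} has no AAMI mapping") from None


@dataclass(frozen=True)
class FoldSplit:
    """One stratified random train/test subsampling."""

    fold_id: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    seed: int


def make_folds(
    labels,
    n_folds: int = 3,
    train_frac: float = 0.70,
    special_fracs: dict[str, float] | None = None,
    seed: int = 0,
) -> list[FoldSplit]:
    """Three (by default) independent stratified 70/30 subsamplings.

    Per class the training count is ``floor(frac * count)`` clipped so
    that at least 1 beat lands on each side; classes with fewer than 2
    beats are excluded entirely (with a warning).  Fold seeds are spawned
    deterministically from the master seed.
    """
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label list")
    if special_fracs is None:
        special_fracs = dict(DEFAULT_SPECIAL_FRACS)
    classes, counts = np.unique(labels, return_counts=True)
    excluded = classes[counts < 2]
    if excluded.size:
        warnings.warn(
            f"classes with <2 beats excluded from folds: {list(excluded)}",
            UserWarning, stacklevel=2,
        )
    usable = set(classes[counts >= 2])
    child_seeds = np.random.SeedSequence(seed).spawn(n_folds)
    folds = []
    for f, css in enumerate(child_seeds):
        fold_seed = int(css.generate_state(1)[0] % (2**31))
        rng = np.random.default_rng(fold_seed)
        train, test = [], []
        for cls in sorted(usable):
            idx = np.flatnonzero(labels == cls)
            frac = special_fracs.get(str(cls), train_frac)
            n_train = int(np.floor(frac * len(idx)))
            n_train = min(max(n_train, 1), len(idx) - 1)
            perm = rng.permutation(idx)
            train.extend(perm[:n_train])
            test.extend(perm[n_train:])
        folds.append(
            FoldSplit(
                fold_id=f + 1,
                train_indices=np.sort(np.array(train, dtype=int)),
                test_indices=np.sort(np.array(test, dtype=int)),
                seed=fold_seed,
            )
        )
    return folds


def make_kfold_partition(labels, n_folds: int = 3, seed: int = 0) -> list[FoldSplit]:
    """Partition-based stratified k-fold (comparison option, not the default protocol)."""
    labels = np.asarray(labels)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [
        FoldSplit(fold_id=f + 1, train_indices=tr, test_indices=te, seed=seed)
        for f, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels))
    ]


@dataclass
class ConfusionMatrix:
    """Square count matrix; rows = actual class, columns = predicted."""

    counts: np.ndarray
    class_list: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.class_list)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be square and match class_list")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.class_list, columns=self.class_list)


def confusion(actual, predicted, class_list) -> ConfusionMatrix:
    """Count actual-vs-predicted labels over a fixed class list."""
    actual = np.asarray(actual)
    predicted = np.asarray(predicted)
    if len(actual) != len(predicted):
        raise ValueError("actual and predicted must have equal length")
    known = set(class_list)
    bad = {*actual, *predicted} - known
    if bad:
        raise ValueError(f"labels outside class_list: {sorted(bad)}")
    counts = _sk_confusion(actual, predicted, labels=list(class_list))
    return ConfusionMatrix(counts=counts, class_list=list(class_list))


@dataclass
class MetricsReport:
    """Per-class one-vs-rest metrics (percent) plus overall accuracy."""

    class_list: list[str]
    se: np.ndarray
    sp: np.ndarray
    ppv: np.ndarray
    acc: np.ndarray
    overall_accuracy: float
    notes: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"Se": self.se, "Sp": self.sp, "PPV": self.ppv, "Acc": self.acc},
            index=self.class_list,
        )

    def averages(self) -> dict[str, float]:
        """Mean of the defined (non-NaN) per-class values, plus overall accuracy."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = {
                "Se": float(np.nanmean(self.se)),
                "Sp": float(np.nanmean(self.sp)),
                "PPV": float(np.nanmean(self.ppv)),
                "Acc": float(np.nanmean(self.acc)),
            }
        out["overall_accuracy"] = self.overall_accuracy
        return out


def per_class_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """One-vs-rest Se/Sp/PPV/Acc per class, in percent.

    Se = TP/(TP+FN), Sp = TN/(TN+FP), PPV = TP/(TP+FP),
    Acc = (TP+TN)/total.  A zero denominator yields NaN with a note, and
    NaNs are excluded from the report averages.
    """
    C = cm.counts
    total = C.sum()
    if total == 0:
        raise ValueError("confusion matrix is all zeros")
    k = len(cm.class_list)
    se = np.full(k, np.nan)
    sp = np.full(k, np.nan)
    ppv = np.full(k, np.nan)
    acc = np.full(k, np.nan)
    notes = []
    for i, cls in enumerate(cm.class_list):
        tp = C[i, i]
        fn = C[i, :].sum() - tp
        fp = C[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn > 0:
            se[i] = 100.0 * tp / (tp + fn)
        else:
            notes.append(f"Se undefined for class {cls} (no actual beats)")
        if tn + fp > 0:
            sp[i] = 100.0 * tn / (tn + fp)
        else:
            notes.append(f"Sp undefined for class {cls}")
        if tp + fp > 0:
            ppv[i] = 100.0 * tp / (tp + fp)
        else:
            notes.append(f"PPV undefined for class {cls} (never predicted)")
        acc[i] = 100.0 * (tp + tn) / total
    overall = 100.0 * np.trace(C) / total
    return MetricsReport(list(cm.class_list), se, sp, ppv, acc, overall, notes)


@dataclass
class FoldResult:
    fold: FoldSplit
    cm: ConfusionMatrix
    report: MetricsReport


@dataclass
class CVResult:
    """Per-fold confusion matrices and metrics plus fold-averaged summary."""

    scheme: str
    class_list: list[str]
    folds: list[FoldResult]

    @property
    def mean_overall_accuracy(self) -> float:
        return float(np.mean([f.report.overall_accuracy for f in self.folds]))

    def average_frame(self) -> pd.DataFrame:
        """Per-class metrics averaged over folds (NaN-aware)."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            stacked = {
                m: np.nanmean(
                    np.vstack([getattr(f.report, m.lower()) for f in self.folds]), axis=0
                )
                for m in ("Se", "Sp", "PPV", "Acc")
            }
        return pd.DataFrame(stacked, index=self.class_list)


def cross_validate(
    dataset,
    scheme: str = "class_oriented",
    n_folds: int = 3,
    train_frac: float = 0.70,
    special_fracs: dict[str, float] | None = None,
    network=None,
    n_components: int = 6,
    seed: int = 0,
    normalizer: str = "n",
) -> CVResult:
    """Repeated stratified 70/30 evaluation of the full pipeline.

    Per fold: fit the two subband ICA models and the classifier's feature
    standardization on the training beats only, train the network, predict
    the held-out beats, and compute the confusion matrix and per-class
    metrics.  ``scheme`` selects the label set: ``"class_oriented"`` keeps
    the fine-grained symbols, ``"subject_oriented"`` relabels to the five
    AAMI superclasses before splitting.

    ``dataset`` is a :class:`ecgbeats.pipeline.BeatDataset`.
    """
    from .classifier import HeartbeatMLP, NetworkConfig
    from .pipeline import HybridFeatureExtractor

    if scheme not in ("class_oriented", "subject_oriented"):
        raise ValueError("scheme must be 'class_oriented' or 'subject_oriented'")
    symbols = np.asarray(dataset.symbols)
    if scheme == "subject_oriented":
        labels = np.array([map_to_aami(s) for s in symbols])
        class_list = [c for c in AAMI_CLASSES if c in set(labels)]
        fold_special = {}  # 'e' is already folded into AAMI class N
    else:
        labels = symbols
        class_list = sorted(set(labels))
        fold_special = special_fracs if special_fracs is not None else dict(DEFAULT_SPECIAL_FRACS)

    master = np.random.SeedSequence(seed)
    fold_seed, ica_seed, net_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(3)
    )
    folds = make_folds(labels, n_folds=n_folds, train_frac=train_frac,
                       special_fracs=fold_special, seed=fold_seed)
    network = network or NetworkConfig(seed=net_seed)

    results = []
    for fold in folds:
        tr, te = fold.train_indices, fold.test_indices
        is_test = np.zeros(len(labels), dtype=bool)
        is_test[te] = True
        extractor = HybridFeatureExtractor(
            n_components=n_components, random_state=ica_seed, normalizer=normalizer
        ).fit(dataset, indices=tr, is_test=is_test)
        X_train = extractor.transform(dataset, indices=tr)
        X_test = extractor.transform(dataset, indices=te)
        clf = HeartbeatMLP.from_config(network).fit(X_train, labels[tr])
        pred = clf.predict(X_test)
        cm = confusion(labels[te], pred, class_list)
        results.append(FoldResult(fold=fold, cm=cm, report=per_class_metrics(cm)))
    return CVResult(scheme=scheme, class_list=class_list, folds=results)


def holdout_records(record_ids, test_ids) -> tuple[np.ndarray, np.ndarray]:
    """Genuine subject/record holdout split (NOT the repeated-subsampling
    protocol above): returns (train_indices, test_indices) keeping every
    beat of a record on one side."""
    record_ids = np.asarray(record_ids)
    test_ids = set(test_ids)
    is_test = np.array([r in test_ids for r in record_ids])
    return np.flatnonzero(~is_test), np.flatnonzero(is_test)
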