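"""Cross-validated evaluation: stratified 5-fold CV, confusion-matrix metrics,
ROC/AUC, and the SVM / CNN-only / CNN+LSTM method comparison.

Splitting is by subject, so all of a subject's timepoints stay in one fold.
Headline numbers are pooled (micro) metrics — confusion counts summed over
the five test folds before applying

    accuracy  = (TP + TN) / (TP + TN + FN + FP) x 100%
    precision = TP / (TP + FP) x 100%
    recall    = TP / (TP + FN) x 100%

with per-fold mean +/- sd reported alongside. The positive class is the
more-diseased label (AD, or pMCI), so recall is sensitivity to disease.
Any GAN augmentation is fit strictly inside each training fold; synthetic
samples carry provenance tags and never reach a test fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .augment import GANConfig, generate_fc, train_gan
from .cohort import Cohort
from .connectome import TIMEPOINTS, FCMatrix, pearson_fc
from .model import (CNNConfig, LongitudinalSample, StackConfig, TrainConfig,
                    train_model)

TASKS = {"nc-ad": ("NC", "AD"), "smci-pmci": ("sMCI", "pMCI")}
METHODS = ("svm-linear", "cnn-only", "cnn-lstm")

__all__ = [
    "TASKS",
    "METHODS",
    "ConfusionCounts",
    "FoldAssignment",
    "MetricsReport",
    "kfold_split",
    "compute_metrics",
    "roc_auc",
    "cohort_samples",
    "run_comparison",
    "ComparisonResult",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(tp=int(np.sum((y_pred == 1) & (y_true == 1))),
                   tn=int(np.sum((y_pred == 0) & (y_true == 0))),
                   fp=int(np.sum((y_pred == 1) & (y_true == 0))),
                   fn=int(np.sum((y_pred == 0) & (y_true == 1))))


@dataclass
class FoldAssignment:
    """subject_id -> fold index in 0..k-1."""

    folds: dict[str, int]
    k: int

    def test_subjects(self, fold: int) -> list[str]:
        return [s for s, f in self.folds.items() if f == fold]

    def train_subjects(self, fold: int) -> list[str]:
        return [s for s, f in self.folds.items() if f != fold]


@dataclass
class MetricsReport:
    """Scalar metrics as fractions in [0, 1]; display via the *_pct properties.

    ``precision``/``recall`` are None when their denominator is zero.
    """

    accuracy: float
    precision: float | None
    recall: float | None
    auc: float | None = None
    roc_points: np.ndarray | None = None  # (n, 2) of (FPR, TPR)
    per_fold: pd.DataFrame | None = None

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.accuracy

    @property
    def precision_pct(self) -> float | None:
        return None if self.precision is None else 100.0 * self.precision

    @property
    def recall_pct(self) -> float | None:
        return None if self.recall is None else 100.0 * self.recall


def kfold_split(subjects: list[str], labels: list[int], k: int = 5,
                seed: int = 0) -> FoldAssignment:
    """Stratified subject-level partition, deterministic given seed."""
    labels = np.asarray(labels)
    if len(subjects) != len(labels):
        raise ValueError("subjects and labels length mismatch")
    for cls in np.unique(labels):
        if np.sum(labels == cls) < k:
            raise ValueError(f"class {cls} has fewer than k={k} subjects")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds: dict[str, int] = {}
    subjects = list(subjects)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(len(subjects)), labels)):
        for i in test_idx:
            folds[subjects[i]] = fold
    return FoldAssignment(folds=folds, k=k)


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    if c.total < 1:
        raise ValueError("empty confusion table")
    accuracy = (c.tp + c.tn) / c.total
    if c.tp + c.fp > 0:
        precision = c.tp / (c.tp + c.fp)
    else:
        warnings.warn("no positive predictions; precision undefined", stacklevel=2)
        precision = None
    if c.tp + c.fn > 0:
        recall = c.tp / (c.tp + c.fn)
    else:
        warnings.warn("no positive ground-truth samples; recall undefined", stacklevel=2)
        recall = None
    return MetricsReport(accuracy=accuracy, precision=precision, recall=recall)


def roc_auc(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points and trapezoid AUC from a threshold sweep over distinct scores.

    Equal scores are grouped at one threshold, so tied score blocks contribute
    diagonal ROC segments and the AUC equals the Mann-Whitney statistic with
    the usual 1/2 credit for ties.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for a ROC curve")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:
            j += 1
        tp += int(np.sum(y_sorted[i:j] == 1))
        fp += int(np.sum(y_sorted[i:j] == 0))
        points.append((fp / n_neg, tp / n_pos))
        i = j
    pts = np.array(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc


# ---------------------------------------------------------------------------
# comparison harness


def cohort_samples(cohort: Cohort, task: str) -> list[LongitudinalSample]:
    """FC sequences + binary labels for the two groups of one task."""
    if task not in TASKS:
        raise ValueError(f"unknown task {task!r}; expected one of {sorted(TASKS)}")
    neg_group, pos_group = TASKS[task]
    samples = []
    for _, row in cohort.subjects().iterrows():
        if row["group"] not in (neg_group, pos_group):
            continue
        sid = row["subject_id"]
        fcs = tuple(pearson_fc(cohort.series[(sid, tp)]) for tp in TIMEPOINTS)
        samples.append(LongitudinalSample(
            fc_sequence=fcs, label=int(row["group"] == pos_group),
            subject_id=sid))
    if not samples:
        raise ValueError(f"cohort contains no subjects for task {task!r}")
    return samples


_SCOPE_STEPS = {"BL": 1, "12m": 2, "24m": 3}


def _stratified_val_split(samples: list[LongitudinalSample], fraction: float,
                          rng: np.random.Generator):
    by_class: dict[int, list[LongitudinalSample]] = {0: [], 1: []}
    for s in samples:
        by_class[s.label].append(s)
    train, val = [], []
    for label, group in sorted(by_class.items()):
        idx = rng.permutation(len(group))
        n_val = max(1, int(round(fraction * len(group))))
        val += [group[i] for i in idx[:n_val]]
        train += [group[i] for i in idx[n_val:]]
    return train, val


def _augment_sequences(train_samples: list[LongitudinalSample], n_steps: int,
                       ratio: float, gan_config: GANConfig,
                       seed: int) -> list[LongitudinalSample]:
    """Per-(class, timepoint) GANs; synthetic sequences share one noise stream
    per class so the per-timepoint draws of one synthetic subject align."""
    real = [s for s in train_samples if s.provenance == "real"]
    out: list[LongitudinalSample] = []
    for label in (0, 1):
        class_samples = [s for s in real if s.label == label]
        n_new = int(round(ratio * len(class_samples)))
        if n_new == 0:
            continue
        per_tp: list[list[FCMatrix]] = []
        for step in range(3):
            fcs = [s.fc_sequence[step] for s in class_samples]
            cfg = GANConfig(**{**gan_config.__dict__,
                               "seed": gan_config.seed + 7 * label + step})
            state = train_gan(fcs, cfg, class_label=label)
            per_tp.append(generate_fc(state, n_new, seed=seed + label))
        for k in range(n_new):
            seq = tuple(
                FCMatrix(per_tp[step][k].values, subject_id=f"syn_{label}_{k:04d}",
                         timepoint=TIMEPOINTS[step], provenance="synthetic")
                for step in range(3))
            out.append(LongitudinalSample(fc_sequence=seq, label=label,
                                          subject_id=f"syn_{label}_{k:04d}",
                                          provenance="synthetic"))
    return out


def _svm_fold(train, test, n_steps):
    x_tr = np.stack([s.fc_sequence[n_steps - 1].upper_triangle() for s in train])
    y_tr = np.array([s.label for s in train])
    x_te = np.stack([s.fc_sequence[n_steps - 1].upper_triangle() for s in test])
    clf = SVC(kernel="linear", C=1.0)
    clf.fit(x_tr, y_tr)
    scores = clf.decision_function(x_te)
    preds = (scores > 0).astype(int)
    return preds, scores, None


def _nn_fold(train, test, n_steps, use_lstm, train_config, cnn_config,
             stack_config, val_fraction, fold_seed):
    rng = np.random.default_rng(fold_seed)
    tr, va = _stratified_val_split(train, val_fraction, rng)
    cfg = TrainConfig(epochs=train_config.epochs, batch_size=train_config.batch_size,
                      learning_rate=train_config.learning_rate, seed=fold_seed)
    result = train_model(tr, va, cfg, cnn_config=cnn_config,
                         stack_config=stack_config, use_lstm=use_lstm,
                         n_steps=n_steps)
    x_te = np.stack([s.feature_sequence()[:n_steps] for s in test])
    probs = result.model.predict_proba(x_te)
    preds = (probs > 0.5).astype(int)
    return preds, probs, result


@dataclass
class MethodScopeResult:
    method: str
    scope: str
    pooled: ConfusionCounts
    metrics: MetricsReport
    scores: np.ndarray
    labels: np.ndarray
    loss_curves: list[dict] = field(default_factory=list)


@dataclass
class ComparisonResult:
    table: pd.DataFrame
    details: dict[tuple[str, str], MethodScopeResult]
    fold_assignment: FoldAssignment
    task: str


def run_comparison(cohort: Cohort, task: str = "nc-ad",
                   methods: tuple[str, ...] = METHODS,
                   scope: str = "all", k: int = 5, seed: int = 0,
                   augment_ratio: float = 0.0,
                   train_config: TrainConfig | None = None,
                   cnn_config: CNNConfig | None = None,
                   stack_config: StackConfig | None = None,
                   gan_config: GANConfig | None = None,
                   val_fraction: float = 0.2) -> ComparisonResult:
    """Stratified 5-fold comparison of the requested methods.

    The single-timepoint methods (linear SVM, CNN-only) consume the scope's
    latest timepoint; CNN+LSTM consumes the sequence up to the scope
    timepoint (1-, 2- or 3-step unroll). ``scope="all"`` produces one row per
    timepoint per method.
    """
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; expected subset of {METHODS}")
    if scope not in (*_SCOPE_STEPS, "all"):
        raise ValueError(f"unknown scope {scope!r}")
    train_config = train_config or TrainConfig()
    gan_config = gan_config or GANConfig()
    samples = cohort_samples(cohort, task)
    by_id = {s.subject_id: s for s in samples}
    subjects = [s.subject_id for s in samples]
    labels = [s.label for s in samples]
    assignment = kfold_split(subjects, labels, k=k, seed=seed)
    scopes = list(_SCOPE_STEPS) if scope == "all" else [scope]
    details: dict[tuple[str, str], MethodScopeResult] = {}
    rows = []
    for sc in scopes:
        n_steps = _SCOPE_STEPS[sc]
        for method in methods:
            pooled = ConfusionCounts()
            all_scores, all_labels = [], []
            fold_rows, loss_curves = [], []
            for fold in range(k):
                train_ids = set(assignment.train_subjects(fold))
                test_ids = set(assignment.test_subjects(fold))
                assert not (train_ids & test_ids)
                train = [by_id[s] for s in subjects if s in train_ids]
                test = [by_id[s] for s in subjects if s in test_ids]
                assert all(s.provenance == "real" for s in test)
                if augment_ratio > 0:
                    train = train + _augment_sequences(
                        train, n_steps, augment_ratio, gan_config,
                        seed=seed * 1000 + fold)
                fold_seed = seed * 100 + fold
                if method == "svm-linear":
                    preds, scores, _ = _svm_fold(train, test, n_steps)
                elif method == "cnn-only":
                    preds, scores, res = _nn_fold(
                        train, test, n_steps, False, train_config, cnn_config,
                        stack_config, val_fraction, fold_seed)
                    loss_curves.append({"fold": fold, "train": res.train_loss,
                                        "val": res.val_loss})
                else:
                    preds, scores, res = _nn_fold(
                        train, test, n_steps, True, train_config, cnn_config,
                        stack_config, val_fraction, fold_seed)
                    loss_curves.append({"fold": fold, "train": res.train_loss,
                                        "val": res.val_loss})
                y_te = np.array([s.label for s in test])
                counts = ConfusionCounts.from_predictions(y_te, preds)
                pooled = pooled + counts
                all_scores.append(scores)
                all_labels.append(y_te)
                fm = compute_metrics(counts)
                fold_rows.append({"fold": fold, "accuracy": fm.accuracy,
                                  "precision": fm.precision, "recall": fm.recall})
            metrics = compute_metrics(pooled)
            scores = np.concatenate(all_scores)
            y_all = np.concatenate(all_labels)
            pts, auc = roc_auc(scores, y_all)
            metrics.auc = auc
            metrics.roc_points = pts
            metrics.per_fold = pd.DataFrame(fold_rows)
            details[(method, sc)] = MethodScopeResult(
                method=method, scope=sc, pooled=pooled, metrics=metrics,
                scores=scores, labels=y_all, loss_curves=loss_curves)
            fold_acc = metrics.per_fold["accuracy"]
            rows.append({
                "task": task, "method": method, "timepoint": sc,
                "accuracy_pct": round(metrics.accuracy_pct, 4),
                "precision_pct": (None if metrics.precision is None
                                  else round(metrics.precision_pct, 4)),
                "recall_pct": (None if metrics.recall is None
                               else round(metrics.recall_pct, 4)),
                "auc": round(auc, 6),
                "fold_accuracy_mean_pct": round(100 * fold_acc.mean(), 4),
                "fold_accuracy_sd_pct": round(100 * fold_acc.std(ddof=1), 4),
            })
    table = pd.DataFrame(rows)
    return ComparisonResult(table=table, details=details,
                            fold_assignment=assignment, task=task)
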