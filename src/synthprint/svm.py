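"""SVM training and repetition-averaged evaluation on feature tables.

The discriminator is a soft-margin SVM over the six-feature vectors, with
the three classic kernels:

* linear:      K(x, y) = x . y
* polynomial:  K(x, y) = (gamma x . y + r)^d
* RBF:         K(x, y) = exp(-gamma ||x - y||^2)

Labels are +1 for real fingerprints and -1 for synthetic ones. Because a
single random train/test split is noisy at small training proportions,
evaluation is averaged over many independent stratified splits; accuracy,
training/testing wall time and AUC are means over the repetitions.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn import metrics
from sklearn.svm import SVC

from .errors import InputError
from .features import FEATURE_NAMES

__all__ = [
    "LABEL_REAL",
    "LABEL_SYNTHETIC",
    "Dataset",
    "KernelSpec",
    "EvalResult",
    "SvmModel",
    "dataset_from_table",
    "split_dataset",
    "kernel_value",
    "train_svm",
    "evaluate",
    "repeat_evaluate",
    "roc_auc",
]

LABEL_REAL = 1
LABEL_SYNTHETIC = -1

_KERNEL_ORDER = ("linear", "poly", "rbf")
_KERNEL_ALIASES = {"linear": "linear", "poly": "poly", "polynomial": "poly", "rbf": "rbf"}


@dataclass
class Dataset:
    """Aligned feature matrix, +/-1 labels and per-row identifiers."""

    X: np.ndarray
    y: np.ndarray
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise InputError("feature matrix and labels are not aligned")
        if not self.ids:
            self.ids = [f"row_{i}" for i in range(len(self.y))]

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, idx: np.ndarray) -> "Dataset":
        return Dataset(self.X[idx], self.y[idx], [self.ids[i] for i in idx])


def dataset_from_table(table, label_map=None) -> Dataset:
    """Build a Dataset from an extract_table DataFrame (or a features CSV).

    ``label_map`` defaults to ``{"real": +1, "synthetic": -1}``.
    """
    import pandas as pd

    if isinstance(table, (str,)) or hasattr(table, "__fspath__"):
        table = pd.read_csv(table)
    label_map = label_map or {"real": LABEL_REAL, "synthetic": LABEL_SYNTHETIC}
    unknown = set(table["label"]) - set(label_map)
    if unknown:
        raise InputError(f"unknown labels in feature table: {sorted(unknown)}")
    X = table[list(FEATURE_NAMES)].to_numpy(dtype=np.float64)
    y = table["label"].map(label_map).to_numpy(dtype=int)
    return Dataset(X, y, [str(p) for p in table["path"]])


@dataclass
class KernelSpec:
    """Kernel choice and SVM hyperparameters.

    ``gamma`` defaults to 1/6 (one over the number of features), ``r`` (the
    polynomial offset, scikit-learn's ``coef0``) to 0 and the degree ``d``
    to 3, following LibSVM conventions; ``C`` is the soft-margin penalty.
    """

    kind: str = "rbf"
    C: float = 1.0
    gamma: float = 1.0 / len(FEATURE_NAMES)
    r: float = 0.0
    d: int = 3

    def __post_init__(self) -> None:
        if self.kind not in _KERNEL_ALIASES:
            raise InputError(f"unknown kernel: {self.kind!r}")
        self.kind = _KERNEL_ALIASES[self.kind]
        if self.C <= 0 or self.gamma <= 0 or self.d < 1:
            raise InputError("require C > 0, gamma > 0, integer degree >= 1")


@dataclass
class EvalResult:
    """Evaluation summary for one (kernel, proportion) configuration.

    For ``reps > 1`` the scalar fields are means over the repetitions and
    ``roc`` is computed from the decision values pooled across repetitions.
    ``roc``/``auc`` are None when the test set had a single class.
    """

    accuracy: float
    train_time: float
    test_time: float
    roc: np.ndarray | None
    auc: float | None
    reps: int
    proportion: float
    acc_per_rep: np.ndarray | None = None


def roc_auc(
    y: np.ndarray, scores: np.ndarray, pos_label: int = LABEL_REAL
) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC from continuous decision values.

    The ROC is swept over all thresholds of ``scores`` with ``pos_label`` as
    the positive class; it starts at (0, 0) and ends at (1, 1).
    """
    fpr, tpr, _ = metrics.roc_curve(y, scores, pos_label=pos_label)
    return np.column_stack([fpr, tpr]), float(metrics.auc(fpr, tpr))


def kernel_value(spec: KernelSpec, x: Sequence[float], y: Sequence[float]) -> float:
    """Evaluate the kernel function on a pair of feature vectors."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise InputError("kernel arguments must have equal length")
    if spec.kind == "linear":
        return float(x @ y)
    if spec.kind == "poly":
        return float((spec.gamma * (x @ y) + spec.r) ** spec.d)
    return float(np.exp(-spec.gamma * np.sum((x - y) ** 2)))


def split_dataset(ds: Dataset, proportion: float, seed: int) -> tuple[Dataset, Dataset]:
    """Stratified random train/test split.

    Per class, ``round(proportion * class_size)`` rows (round half up) go to
    the training set and the rest to testing; the assignment is a
    deterministic function of ``seed``.
    """
    if not 0.0 < proportion < 1.0:
        raise InputError(f"proportion must be in (0, 1), got {proportion}")
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for label in sorted(set(ds.y.tolist())):
        idx = np.flatnonzero(ds.y == label)
        n_train = int(np.floor(proportion * len(idx) + 0.5))
        if n_train < 1 or n_train >= len(idx):
            raise InputError(
                f"proportion {proportion} leaves class {label} empty in train or test"
            )
        perm = rng.permutation(idx)
        train_idx.extend(perm[:n_train].tolist())
        test_idx.extend(perm[n_train:].tolist())
    return ds.subset(np.array(sorted(train_idx))), ds.subset(np.array(sorted(test_idx)))


@dataclass
class SvmModel:
    """Fitted SVM plus the z-score scaling fitted on its training split."""

    svc: SVC
    mean: np.ndarray
    scale: np.ndarray
    spec: KernelSpec

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mean) / self.scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(self.transform(X))

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self.transform(X))


def train_svm(train: Dataset, spec: KernelSpec) -> tuple[SvmModel, float]:
    """Fit a scaled soft-margin SVM; returns the model and wall train time.

    Features are z-scored with the training split's mean and population
    standard deviation (an unscaled gray-variance feature, of order 10^3,
    would otherwise dominate RBF distances). Constant features get unit
    scale.
    """
    if len(set(train.y.tolist())) < 2:
        raise InputError("training set must contain both classes")
    mean = train.X.mean(axis=0)
    scale = train.X.std(axis=0)
    scale[scale == 0.0] = 1.0
    svc = SVC(
        kernel=spec.kind,
        C=spec.C,
        gamma=spec.gamma,
        coef0=spec.r,
        degree=spec.d,
        cache_size=64,
    )
    t0 = time.perf_counter()
    svc.fit((train.X - mean) / scale, train.y)
    train_time = time.perf_counter() - t0
    return SvmModel(svc=svc, mean=mean, scale=scale, spec=spec), train_time


def evaluate(model: SvmModel, test: Dataset, proportion: float = 0.5) -> EvalResult:
    """Accuracy, wall test time, ROC and trapezoidal AUC on one test set.

    The ROC is swept over the SVM's continuous decision values with the real
    class (+1) as positive. A single-class test set yields accuracy only.
    """
    if len(test) == 0:
        raise InputError("empty test set")
    t0 = time.perf_counter()
    pred = model.predict(test.X)
    test_time = time.perf_counter() - t0
    accuracy = float(np.mean(pred == test.y))
    roc = None
    auc = None
    if len(set(test.y.tolist())) == 2:
        roc, auc = roc_auc(test.y, model.decision_values(test.X))
    return EvalResult(
        accuracy=accuracy,
        train_time=0.0,
        test_time=test_time,
        roc=roc,
        auc=auc,
        reps=1,
        proportion=proportion,
    )


def repeat_evaluate(
    ds: Dataset,
    spec: KernelSpec,
    proportion: float,
    reps: int,
    seed: int,
) -> EvalResult:
    """Average accuracy/time/AUC over ``reps`` independent random splits.

    Split seeds are derived deterministically from the master seed, so two
    runs with the same arguments produce identical results (up to wall-clock
    times). The returned ROC pools decision values across repetitions.
    """
    if reps < 1:
        raise InputError("reps must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(reps) % (2**31)
    accs, train_times, test_times, aucs = [], [], [], []
    pooled_scores, pooled_labels = [], []
    for rep_seed in child_seeds:
        train, test = split_dataset(ds, proportion, int(rep_seed))
        model, t_train = train_svm(train, spec)
        res = evaluate(model, test, proportion)
        accs.append(res.accuracy)
        train_times.append(t_train)
        test_times.append(res.test_time)
        if res.auc is not None:
            aucs.append(res.auc)
            pooled_scores.append(model.decision_values(test.X))
            pooled_labels.append(test.y)
    roc = None
    if pooled_scores:
        roc, _ = roc_auc(np.concatenate(pooled_labels), np.concatenate(pooled_scores))
    return EvalResult(
        accuracy=float(np.mean(accs)),
        train_time=float(np.mean(train_times)),
        test_time=float(np.mean(test_times)),
        roc=roc,
        auc=float(np.mean(aucs)) if aucs else None,
        reps=reps,
        proportion=proportion,
        acc_per_rep=np.asarray(accs),
    )
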