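"""Hierarchical two-level linear SVM mapping (B%, Y%) to ordinal scores 1-5.

Field panels are dominated by healthy (score 1) plots, which makes a
flat 5-class model fragile.  The hierarchy first separates low {1,2},
medium {3} and high {4,5} susceptibility groups; a second-level binary
SVM then resolves 1-vs-2 within the low group and 4-vs-5 within the
high group.  Medium routes deterministically to score 3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.svm import LinearSVC

__all__ = [
    "GROUPS",
    "group_of",
    "split_train_test",
    "HierarchicalSVMClassifier",
    "ClassificationReport",
    "evaluate",
]

# Susceptibility groups: a partition of the five ordinal scores.
GROUPS: dict[str, tuple[int, ...]] = {"LOW": (1, 2), "MEDIUM": (3,), "HIGH": (4, 5)}
_GROUP_INDEX = {s: gi for gi, (_, members) in enumerate(sorted(GROUPS.items(),
                key=lambda kv: kv[1])) for s in members}
# sorted by members gives LOW=(1,2)->0, MEDIUM=(3,)->1, HIGH=(4,5)->2


def group_of(score: int) -> int:
    """Group index (0 low, 1 medium, 2 high) of an ordinal score."""
    return _GROUP_INDEX[int(score)]


def split_train_test(X, y, train_frac: float = 0.75, seed: int = 0):
    """Stratified random split, reproducible by seed.

    Classes with fewer than two members go entirely to the training
    side (with a warning); any class with >= 2 members contributes at
    least one row to each side.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must lie in (0, 1)")
    X = np.asarray(X)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    tr_idx, te_idx = [], []
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        n_c = idx.size
        if n_c < 2:
            warnings.warn(
                f"class {c} has {n_c} member(s); assigning all to training",
                stacklevel=2,
            )
            tr_idx.append(idx)
            continue
        n_tr = int(round(train_frac * n_c))
        n_tr = min(max(n_tr, 1), n_c - 1)
        tr_idx.append(idx[:n_tr])
        te_idx.append(idx[n_tr:])
    tr = np.sort(np.concatenate(tr_idx))
    te = np.sort(np.concatenate(te_idx)) if te_idx else np.array([], dtype=int)
    return (X[tr], y[tr]), (X[te], y[te])


class _Constant:
    """Degenerate one-class predictor used when a stage sees one label."""

    def __init__(self, value: int):
        self.value = int(value)

    def predict(self, X):
        return np.full(len(X), self.value, dtype=int)


class HierarchicalSVMClassifier:
    """Two-level linear SVM over (Y%, B%) features.

    Features are z-scored with training statistics before each margin
    fit.  ``C`` is the soft-margin constant shared by all stages.
    Stage-1 ties at a decision boundary resolve to the lowest group
    index (``argmax`` takes the first maximum; group classes are sorted
    ascending).
    """

    def __init__(self, C: float = 1.0):
        self.C = C
        self._fitted = False

    def _fit_stage(self, X, y, multiclass: bool = False):
        classes = np.unique(y)
        if classes.size == 1:
            return _Constant(classes[0])
        # joint multiclass margin: one linear score per class, argmax
        # decision; for binary stages this is the ordinary linear SVM
        # the joint solver needs a looser dual tolerance to declare
        # convergence; the decision surface is unaffected at this scale
        clf = LinearSVC(
            C=self.C,
            multi_class="crammer_singer" if multiclass else "ovr",
            max_iter=50_000,
            tol=1e-3 if multiclass else 1e-4,
        )
        clf.fit(X, y)
        return clf

    def fit(self, X, y) -> "HierarchicalSVMClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if not np.isin(y, [1, 2, 3, 4, 5]).all():
            raise ValueError("labels must be integers in 1..5")
        self._mean = X.mean(axis=0)
        self._std = X.std(axis=0)
        self._std[self._std == 0] = 1.0
        Z = (X - self._mean) / self._std
        groups = np.array([group_of(s) for s in y])
        if np.unique(groups).size == 1 and np.unique(y).size == 1:
            # single-score data degrades to a constant predictor
            self.stage1_ = _Constant(groups[0])
        else:
            self.stage1_ = self._fit_stage(Z, groups, multiclass=True)
        low = groups == 0
        high = groups == 2
        for name, sel, members in (("stage2_low_", low, GROUPS["LOW"]),
                                   ("stage2_high_", high, GROUPS["HIGH"])):
            if sel.any():
                present = np.unique(y[sel])
                if present.size < len(members):
                    warnings.warn(
                        f"{name[:-1]} sees only score(s) {present.tolist()}; "
                        "degrading to a constant predictor", stacklevel=2,
                    )
                setattr(self, name, self._fit_stage(Z[sel], y[sel]))
            else:
                warnings.warn(
                    f"no training rows for {name[:-1]}; using constant "
                    f"score {members[0]}", stacklevel=2,
                )
                setattr(self, name, _Constant(members[0]))
        self._fitted = True
        return self

    def predict(self, X) -> np.ndarray:
        if not self._fitted:
            raise ValueError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self._mean) / self._std
        groups = np.asarray(self.stage1_.predict(Z))
        out = np.empty(len(Z), dtype=int)
        out[groups == 1] = 3
        for gi, stage in ((0, self.stage2_low_), (2, self.stage2_high_)):
            sel = groups == gi
            if sel.any():
                out[sel] = stage.predict(Z[sel])
        return out

    def predict_group(self, X) -> np.ndarray:
        if not self._fitted:
            raise ValueError("classifier is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.asarray(self.stage1_.predict((X - self._mean) / self._std))


@dataclass
class ClassificationReport:
    """Metrics derived from the 5 x 5 confusion matrix (rows = truth)."""

    confusion: np.ndarray
    overall_accuracy: float
    per_class_accuracy: np.ndarray  # NaN for classes absent from the test set
    average_per_class_accuracy: float
    sensitivity: np.ndarray
    specificity: np.ndarray
    classes: tuple = (1, 2, 3, 4, 5)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "per_class_accuracy": self.per_class_accuracy,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            },
            index=pd.Index(self.classes, name="score"),
        )

    def summary(self) -> str:
        lines = [
            "Hierarchical classifier evaluation",
            f"  overall accuracy:            {self.overall_accuracy:.4f}",
            f"  average per-class accuracy:  {self.average_per_class_accuracy:.4f}",
            "",
            self.to_frame().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        absent = [c for c, a in zip(self.classes, self.per_class_accuracy)
                  if np.isnan(a)]
        if absent:
            lines.append(f"  classes absent from test set: {absent}")
        return "\n".join(lines)


def evaluate(y_true, y_pred) -> ClassificationReport:
    """Confusion-matrix metrics for ordinal predictions.

    Per-class accuracy is the diagonal over the row total (equal to
    one-vs-rest sensitivity); the average is taken over classes present
    in ``y_true``.  Specificity is TN / (TN + FP) one-vs-rest.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty test set")
    classes = (1, 2, 3, 4, 5)
    cm = confusion_matrix(y_true, y_pred, labels=list(classes))
    total = cm.sum()
    row = cm.sum(axis=1).astype(float)
    col = cm.sum(axis=0).astype(float)
    diag = np.diag(cm).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_class = np.where(row > 0, diag / row, np.nan)
        sens = np.where(row > 0, diag / row, np.nan)
        tn = total - row - col + diag
        spec = np.where((tn + col - diag) > 0, tn / (tn + col - diag), np.nan)
    return ClassificationReport(
        confusion=cm,
        overall_accuracy=float(diag.sum() / total),
        per_class_accuracy=per_class,
        average_per_class_accuracy=float(np.nanmean(per_class)),
        sensitivity=sens,
        specificity=spec,
    )
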