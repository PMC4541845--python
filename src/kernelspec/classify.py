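"""Variety classifiers: grid-searched RBF SVM (C-SVC) and PLS-DA.

The evaluation protocol mirrors standard chemometric practice for seed-lot
work: per class, 100 kernels train / 50 test drawn by a seeded stratified
split; SVM hyperparameters (C, gamma) are grid-searched over a geometric
2^-10..2^10 range by 5-fold cross-validated accuracy on the training set;
PLS-DA uses a fixed latent-variable count (default 11, capped at capacity)
and reports both its leave-one-out training accuracy and its test confusion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .band_selection import one_hot, plsda_classify, plsda_fit
from .features import FeatureTable, standardize

__all__ = [
    "SplitSpec",
    "GridSpec",
    "ClassifierResult",
    "split",
    "svm_train_eval",
    "plsda_train_eval",
    "run_comparison",
    "FEATURE_SETS",
]

# The six feature-set comparisons, as group lists over a master FeatureTable
# whose spectral_selected_* groups were added per selector.
FEATURE_SETS = {
    "full_bands": ["spectral_full"],
    "image_features": ["morphology", "texture"],
    "spa_bands": ["spectral_spa"],
    "plsda_bands": ["spectral_plsda"],
    "spa_fusion": ["spectral_spa", "morphology", "texture"],
    "plsda_fusion": ["spectral_plsda", "morphology", "texture"],
}


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test sizes per class and the split seed."""

    train_per_class: int = 100
    test_per_class: int = 50
    seed: int = 0


@dataclass
class GridSpec:
    """Geometric (C, gamma) grids and the CV fold count/seed for the search."""

    c_grid: np.ndarray = field(default_factory=lambda: 2.0 ** np.arange(-10, 11))
    gamma_grid: np.ndarray = field(default_factory=lambda: 2.0 ** np.arange(-10, 11))
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.c_grid = np.sort(np.asarray(self.c_grid, float))
        self.gamma_grid = np.sort(np.asarray(self.gamma_grid, float))
        if self.c_grid.size == 0 or self.gamma_grid.size == 0:
            raise ValueError("grids must be nonempty")
        if (self.c_grid <= 0).any() or (self.gamma_grid <= 0).any():
            raise ValueError("grids must be positive")

    @classmethod
    def coarse(cls, step: int = 4, folds: int = 5, seed: int = 0) -> "GridSpec":
        """Same 2^-10..2^10 range on a coarser exponent step."""
        g = 2.0 ** np.arange(-10, 11, step)
        return cls(c_grid=g, gamma_grid=g, folds=folds, seed=seed)


@dataclass
class ClassifierResult:
    """Confusion matrix and accuracies of one classifier on one feature set."""

    confusion: np.ndarray
    classes: np.ndarray
    per_class_accuracy: np.ndarray
    average_accuracy: float          # percent, trace/total * 100
    method: str
    params: dict = field(default_factory=dict)
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.astype(int).tolist(),
            "per_class_accuracy": [float(a) for a in self.per_class_accuracy],
            "average_accuracy": float(self.average_accuracy),
            "params": {k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                       for k, v in self.params.items()},
            "extras": {k: float(v) for k, v in self.extras.items()},
        }


def _result(y_true, y_pred, classes, method, params=None, extras=None) -> ClassifierResult:
    conf = confusion_matrix(y_true, y_pred, labels=classes)
    row = conf.sum(axis=1)
    per_class = np.where(row > 0, np.diag(conf) / np.maximum(row, 1), np.nan) * 100.0
    avg = float(np.trace(conf) / conf.sum() * 100.0)
    return ClassifierResult(conf, np.asarray(classes), per_class, avg, method,
                            params or {}, extras or {})


def split(table: FeatureTable, spec: SplitSpec = SplitSpec()) -> tuple[FeatureTable, FeatureTable]:
    """Seeded stratified split; z-scoring statistics come from train rows only.

    Raises ``ValueError`` when a class cannot supply train+test rows or when
    the test set would be empty.
    """
    if spec.test_per_class < 1:
        raise ValueError("test_per_class must be >= 1 (empty test set)")
    labels = table.labels
    classes = np.unique(labels)
    rng = np.random.default_rng(spec.seed)
    train_idx, test_idx = [], []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        need = spec.train_per_class + spec.test_per_class
        if len(idx) < need:
            raise ValueError(
                f"class {cls!r} has {len(idx)} kernels; {need} required for the split"
            )
        perm = rng.permutation(idx)
        train_idx.append(perm[: spec.train_per_class])
        test_idx.append(perm[spec.train_per_class: need])
    train_idx = np.sort(np.concatenate(train_idx))
    test_idx = np.sort(np.concatenate(test_idx))
    all_rows = np.concatenate([train_idx, test_idx])
    scaled = standardize(table.subset(all_rows), np.arange(len(train_idx)))
    n_tr = len(train_idx)
    return scaled.subset(np.arange(n_tr)), scaled.subset(np.arange(n_tr, len(all_rows)))


def svm_train_eval(train: FeatureTable, test: FeatureTable,
                   grid: GridSpec = None) -> ClassifierResult:
    """Grid-searched C-SVC with RBF kernel (one-vs-one multi-class).

    The (C, gamma) pair maximizing 5-fold CV accuracy on the training rows
    wins; ties resolve to the smallest C, then the smallest gamma.  The final
    model is refit on the full training set and scored on the test set.
    """
    grid = grid or GridSpec()
    Xtr, ytr = train.X, train.labels.astype(str)
    Xte, yte = test.X, test.labels.astype(str)
    cv = StratifiedKFold(n_splits=grid.folds, shuffle=True, random_state=grid.seed)
    folds = list(cv.split(Xtr, ytr))
    best = (-np.inf, None, None)
    for C in grid.c_grid:
        for gamma in grid.gamma_grid:
            correct = 0
            for tr, te in folds:
                clf = SVC(C=C, gamma=gamma, kernel="rbf", decision_function_shape="ovo")
                clf.fit(Xtr[tr], ytr[tr])
                correct += int((clf.predict(Xtr[te]) == ytr[te]).sum())
            score = correct / len(ytr)
            if score > best[0]:              # strict: first (smallest C, gamma) wins ties
                best = (score, C, gamma)
    _, C, gamma = best
    clf = SVC(C=C, gamma=gamma, kernel="rbf", decision_function_shape="ovo")
    clf.fit(Xtr, ytr)
    pred = clf.predict(Xte)
    classes = np.unique(np.concatenate([ytr, yte]))
    return _result(yte, pred, classes, "svm",
                   params={"C": C, "gamma": gamma},
                   extras={"cv_accuracy": best[0] * 100.0})


def plsda_train_eval(train: FeatureTable, test: FeatureTable,
                     n_components: int = 11) -> ClassifierResult:
    """PLS-DA classifier: argmax of predicted one-hot scores.

    Reports the test-set confusion as the headline result and the
    leave-one-out accuracy on the training set in ``extras['loo_accuracy']``.
    """
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    Xtr, ytr = train.X, train.labels.astype(str)
    Xte, yte = test.X, test.labels.astype(str)
    Ytr, classes = one_hot(ytr)
    cap = min(n_components, Xtr.shape[0] - 2, Xtr.shape[1])
    if cap < n_components:
        warnings.warn(f"n_components={n_components} capped at {cap}", stacklevel=2)

    loo_correct = 0
    for i in range(len(ytr)):
        keep = np.arange(len(ytr)) != i
        m = plsda_fit(Xtr[keep], Ytr[keep], cap, warn_on_cap=False)
        pred_i = classes[int(np.argmax((Xtr[i] - m.x_mean) @ m.coefficients + m.y_mean))]
        loo_correct += int(pred_i == ytr[i])

    model = plsda_fit(Xtr, Ytr, cap, warn_on_cap=False)
    pred = plsda_classify(model, Xte, classes=classes)
    all_classes = np.unique(np.concatenate([ytr, yte]))
    return _result(yte, pred, all_classes, "plsda",
                   params={"n_components": cap},
                   extras={"loo_accuracy": loo_correct / len(ytr) * 100.0})


def run_comparison(master: FeatureTable, split_spec: SplitSpec = SplitSpec(),
                   grid: GridSpec = None, n_components: int = 11,
                   feature_sets: dict | None = None,
                   methods=("svm", "plsda")) -> dict:
    """Evaluate both classifiers on the six feature sets over one shared split.

    ``master`` must carry the groups named by ``feature_sets`` (default: the
    module-level ``FEATURE_SETS`` mapping over groups ``spectral_full``,
    ``spectral_spa``, ``spectral_plsda``, ``morphology``, ``texture``).
    Returns ``{set_name: {method: ClassifierResult}}``.
    """
    feature_sets = feature_sets or FEATURE_SETS
    missing = [g for groups in feature_sets.values() for g in groups
               if g not in master.groups]
    if missing:
        raise ValueError(f"master table lacks groups {sorted(set(missing))}")
    results: dict[str, dict] = {}
    for set_name, groups in feature_sets.items():
        sub = master.select_groups(groups)
        train, test = split(sub, split_spec)   # same seed -> same rows per cell
        cell: dict[str, ClassifierResult] = {}
        if "svm" in methods:
            cell["svm"] = svm_train_eval(train, test, grid)
        if "plsda" in methods:
            cell["plsda"] = plsda_train_eval(train, test, n_components)
        results[set_name] = cell
    return results


def comparison_frame(results_by_side: dict[str, dict]) -> pd.DataFrame:
    """Tabulate ``{side: {set: {method: result}}}`` as accuracies in percent."""
    rows = []
    for side, sets in results_by_side.items():
        methods = {m for cell in sets.values() for m in cell}
        for method in ("svm", "plsda"):
            if method not in methods:
                continue
            row = {"side": side, "method": method}
            for set_name, cell in sets.items():
                if method in cell:
                    row[set_name] = round(cell[method].average_accuracy, 1)
            rows.append(row)
    return pd.DataFrame(rows)
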