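"""Informative-wavelength selection: successive projections algorithm (SPA)
and PLS-DA regression-coefficient ranking.

SPA is forward selection that fights collinearity directly: starting from a
given column k(0), each round projects every unselected column onto the
subspace orthogonal to the last selected column (the candidate columns are
mutated in place across rounds, so after n rounds every candidate is
orthogonal to all n selected columns) and picks the candidate with the
largest remaining norm.  The model size N is chosen by re-running the
selection for a grid of N (and candidate starts) and scoring each selected
set with the cross-validated RMSE of a PLS-DA model on one-hot class targets;
the smallest N on the RMSE plateau wins.

The comparator selector ranks wavelengths by the largest absolute PLS-DA
regression coefficient across classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cross_decomposition import PLSRegression
from sklearn.exceptions import ConvergenceWarning
from sklearn.model_selection import StratifiedKFold

from .segmentation import SpectrumMatrix

__all__ = [
    "SelectionResult",
    "PLSDAModel",
    "spa_select",
    "spa_choose_n",
    "plsda_fit",
    "plsda_predict",
    "plsda_choose_components",
    "plsda_coef_select",
    "one_hot",
]


def _as_matrix(X) -> np.ndarray:
    if isinstance(X, SpectrumMatrix):
        return X.values
    return np.asarray(X, float)


@dataclass
class SelectionResult:
    """Outcome of a wavelength-selection run.

    ``selected`` is in selection order for SPA and coefficient-rank order for
    the PLS-DA selector.  ``rmse_trace`` maps candidate model size N to the
    best cross-validated RMSE observed at that size.
    """

    selected: list[int]
    rmse_trace: dict[int, float] = field(default_factory=dict)
    method: str = "spa"
    start_band: int | None = None

    def to_dict(self, wavelengths: np.ndarray | None = None) -> dict:
        d = {
            "method": self.method,
            "start_band": self.start_band,
            "selected": [int(i) for i in self.selected],
            "rmse_trace": {str(k): float(v) for k, v in sorted(self.rmse_trace.items())},
        }
        if wavelengths is not None:
            d["wavelengths_nm"] = [float(wavelengths[i]) for i in self.selected]
        return d


# ---------------------------------------------------------------------------
# SPA
# ---------------------------------------------------------------------------

def spa_select(X, start: int, n_select: int, rtol: float = 1e-10) -> list[int]:
    """Successive projections selection of ``n_select`` columns from ``X``.

    Returns ``[start, k(1), ..., k(n_select-1)]``.  If every remaining
    projection is numerically zero (the selected columns span the candidates),
    selection stops early with a warning and a shorter list.
    """
    Xw = _as_matrix(X).copy()
    n_rows, n_cols = Xw.shape
    if not 0 <= start < n_cols:
        raise ValueError(f"start {start} out of range for {n_cols} columns")
    if n_select < 1 or n_select > n_cols:
        raise ValueError("need 1 <= n_select <= number of columns")
    norms0 = np.linalg.norm(Xw, axis=0)
    if np.any(norms0 == 0):
        raise ValueError("columns must not be all-zero")
    tol = rtol * norms0.max()

    selected = [start]
    candidates = np.ones(n_cols, dtype=bool)
    candidates[start] = False
    for _ in range(1, n_select):
        xk = Xw[:, selected[-1]]
        denom = xk @ xk
        if denom <= tol * tol:
            warnings.warn("SPA stopped early: last selected column has ~zero norm", stacklevel=2)
            break
        idx = np.nonzero(candidates)[0]
        coef = (xk @ Xw[:, idx]) / denom
        Xw[:, idx] -= np.outer(xk, coef)
        norms = np.linalg.norm(Xw[:, idx], axis=0)
        if norms.max() <= tol:
            warnings.warn(
                "SPA stopped early: remaining projections numerically zero", stacklevel=2
            )
            break
        k = idx[int(np.argmax(norms))]
        selected.append(int(k))
        candidates[k] = False
    return selected


def _rmsecv_plsda(X: np.ndarray, Y: np.ndarray, labels: np.ndarray,
                  n_components: int, folds: int = 5, seed: int = 0) -> float:
    """Cross-validated RMSE of a PLS-DA fit on one-hot targets."""
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    sq_err = 0.0
    count = 0
    for tr, te in cv.split(X, labels):
        model = plsda_fit(X[tr], Y[tr], n_components, warn_on_cap=False)
        pred = plsda_predict(model, X[te])
        sq_err += float(((pred - Y[te]) ** 2).sum())
        count += Y[te].size
    return np.sqrt(sq_err / count)


def spa_choose_n(X, labels, n_grid=None, starts=None, folds: int = 5,
                 seed: int = 0, rel_tol: float = 0.01,
                 max_eval_components: int = 10) -> SelectionResult:
    """Run SPA over a grid of model sizes N and candidate starts; keep the
    smallest N whose best RMSE sits on the plateau of the global minimum.

    Parameters
    ----------
    n_grid
        Candidate model sizes; default ``1..min(30, bands)``.
    starts
        Candidate first wavelengths k(0); default: every band.  Pass an int m
        to search only the m largest-norm columns — at study scale the full
        search multiplies cost without changing the chosen set.
    rel_tol
        Plateau rule: any (start, N) whose RMSE is within ``rel_tol`` relative
        of the global minimum is eligible; ties resolve to smaller N, then
        smaller start index.
    """
    Xm = _as_matrix(X)
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least two classes")
    n_cols = Xm.shape[1]
    if n_grid is None:
        n_grid = list(range(1, min(30, n_cols) + 1))
    n_grid = sorted(set(int(n) for n in n_grid))
    if not n_grid:
        raise ValueError("n_grid must be nonempty")
    if n_grid[-1] > n_cols:
        raise ValueError("n_grid exceeds band count")
    if starts is None:
        start_list = list(range(n_cols))
    elif np.isscalar(starts):
        norms = np.linalg.norm(Xm, axis=0)
        start_list = sorted(np.argsort(-norms, kind="stable")[: int(starts)].tolist())
    else:
        start_list = [int(s) for s in starts]

    Y, _ = one_hot(labels)
    n_max = n_grid[-1]
    records = []  # (rmse, N, start, bands)
    trace: dict[int, float] = {}
    for start in start_list:
        order = spa_select(Xm, start, n_max)   # greedy: prefixes give every N
        for N in n_grid:
            if N > len(order):
                continue
            bands = order[:N]
            ncomp = min(N, max_eval_components, Xm.shape[0] - 2)
            rmse = _rmsecv_plsda(Xm[:, bands], Y, labels, ncomp, folds=folds, seed=seed)
            records.append((rmse, N, start, bands))
            if N not in trace or rmse < trace[N]:
                trace[N] = rmse
    best_rmse = min(r[0] for r in records)
    eligible = [r for r in records if r[0] <= best_rmse * (1.0 + rel_tol)]
    eligible.sort(key=lambda r: (r[1], r[2]))  # smaller N, then smaller start
    _, N, start, bands = eligible[0]
    return SelectionResult(selected=list(bands), rmse_trace=trace,
                           method="spa", start_band=start)


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

def one_hot(labels) -> tuple[np.ndarray, np.ndarray]:
    """One-hot indicator matrix and the sorted class vector it encodes."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    Y = (labels[:, None] == classes[None, :]).astype(float)
    return Y, classes


@dataclass
class PLSDAModel:
    """PLS2 regression of one-hot class indicators on spectra.

    ``coefficients`` is bands x classes such that
    ``Y_hat = (X - x_mean) @ coefficients + y_mean``.
    """

    n_components: int
    coefficients: np.ndarray
    x_mean: np.ndarray
    y_mean: np.ndarray
    classes: np.ndarray | None = None


def plsda_fit(X, Y, n_components: int, warn_on_cap: bool = True) -> PLSDAModel:
    """Fit a PLS-DA model (PLS2 on one-hot targets, internally centered).

    ``n_components`` is capped at min(samples - 1, bands); a requested count
    above the cap is truncated (with a warning unless suppressed).
    """
    X = np.asarray(X, float)
    Y = np.asarray(Y)
    if Y.ndim == 1:                   # class labels, possibly strings
        Y, classes = one_hot(Y)
    else:
        Y = Y.astype(float)
        classes = None
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    cap = min(X.shape[0] - 1, X.shape[1])
    ncomp = min(n_components, cap)
    if ncomp < n_components and warn_on_cap:
        warnings.warn(
            f"n_components={n_components} exceeds data capacity; capped at {ncomp}",
            stacklevel=2,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.filterwarnings("ignore", message=".*y residual is constant.*")
        pls = PLSRegression(n_components=ncomp, scale=False)
        pls.fit(X, Y)
    # PLSRegression centers on the column means; recompute them here rather
    # than depending on the estimator's private attributes.
    return PLSDAModel(
        n_components=ncomp,
        coefficients=np.asarray(pls.coef_).T.copy(),   # (bands, classes)
        x_mean=X.mean(axis=0),
        y_mean=Y.mean(axis=0),
        classes=classes,
    )


def plsda_predict(model: PLSDAModel, X) -> np.ndarray:
    """Continuous one-hot scores Y_hat for ``X``."""
    X = np.asarray(X, float)
    return (X - model.x_mean) @ model.coefficients + model.y_mean


def plsda_classify(model: PLSDAModel, X, classes=None) -> np.ndarray:
    """Hard class assignment by argmax of the predicted indicator scores."""
    scores = plsda_predict(model, X)
    idx = np.argmax(scores, axis=1)
    cls = model.classes if classes is None else np.asarray(classes)
    if cls is None:
        return idx
    return cls[idx]


def _venetian_folds(labels: np.ndarray, folds: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Deterministic venetian-blind folds: class-sorted rows dealt round-robin."""
    order = np.argsort(np.asarray(labels, dtype=str), kind="stable")
    splits = []
    for f in range(folds):
        te = order[f::folds]
        tr = np.setdiff1d(order, te)
        splits.append((tr, te))
    return splits


def plsda_choose_components(X, Y, max_components: int, folds: int = 5) -> int:
    """Latent-variable count minimizing RMSECV (venetian-blind folds; ties to
    the smaller count)."""
    X = np.asarray(X, float)
    Y = np.asarray(Y)
    if Y.ndim == 1:                   # class labels, possibly strings
        labels = Y
        Y, _ = one_hot(Y)
    else:
        Y = Y.astype(float)
        labels = np.argmax(Y, axis=1)
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    cap = min(max_components, X.shape[0] - 1 - X.shape[0] // folds, X.shape[1])
    cap = max(cap, 1)
    splits = _venetian_folds(labels, folds)
    best_k, best_rmse = 1, np.inf
    for k in range(1, cap + 1):
        sq, cnt = 0.0, 0
        for tr, te in splits:
            model = plsda_fit(X[tr], Y[tr], k, warn_on_cap=False)
            pred = plsda_predict(model, X[te])
            sq += float(((pred - Y[te]) ** 2).sum())
            cnt += Y[te].size
        rmse = np.sqrt(sq / cnt)
        if rmse < best_rmse - 1e-12:
            best_k, best_rmse = k, rmse
    return best_k


def plsda_coef_select(model: PLSDAModel, n_bands: int) -> list[int]:
    """Top ``n_bands`` wavelengths by max-over-classes absolute regression
    coefficient, in descending rank (ties to the lower band index)."""
    score = np.abs(model.coefficients).max(axis=1)
    if not 1 <= n_bands <= len(score):
        raise ValueError("n_bands out of range")
    order = np.argsort(-score, kind="stable")
    return [int(i) for i in order[:n_bands]]
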