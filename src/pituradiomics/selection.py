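"""Sequential forward feature selection with a Gaussian-kernel SVM objective.

The classifier is a soft-margin SVM with the literal Gaussian kernel
G(xₙ, x) = exp(−‖xₙ − x‖²) — no kernel scale parameter, i.e. gamma = 1 on
per-fold standardized features — and box constraint C = 1. The selection
objective is the mean misclassification rate under stratified 10-fold
cross-validation, averaged over independently re-randomized repeats; a
feature is accepted only if it improves the objective by at least the
termination tolerance (default 1e-6).

The decision value f(x) = Σₙ wₙ yₙ G(xₙ, x) + b is exposed both through the
fitted model and through :func:`svm_score`, which evaluates the sum exactly
as written from the stored support vectors.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(Xv.shape[1])]
    yv = np.asarray(y).astype(int)
    if set(np.unique(yv)) - {0, 1}:
        # map arbitrary binary labels to {0,1}
        classes = np.unique(yv)
        if classes.size != 2:
            raise ValueError("y must contain exactly two classes")
        yv = (yv == classes[1]).astype(int)
    if np.unique(yv).size < 2:
        raise ValueError("y must contain both classes")
    return Xv, yv, names


def _standardize(train: np.ndarray, *others):
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return tuple((a - mu) / sd_safe for a in (train, *others)) + (mu, sd)


def cv_objective(X, y, feature_subset, folds: int = 10, repeats: int = 1,
                 seed: int = 0, C: float = 1.0, gamma: float = 1.0) -> float:
    """Mean cross-validated misclassification rate for one feature subset.

    Folds are stratified and shuffled; features are standardized using the
    training fold only. ``folds`` is clamped to the minority-class count so
    small cohorts remain usable. Deterministic given ``seed``.
    """
    Xv, yv, names = _as_xy(X, y)
    idx = [names.index(f) if isinstance(f, str) else int(f) for f in feature_subset]
    if not idx:
        raise ValueError("feature subset must be nonempty")
    Xs = Xv[:, idx]
    n_min = min(np.bincount(yv))
    if n_min < 2:
        raise ValueError("need at least 2 cases per class")
    k = min(folds, n_min)
    errs = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=(seed + 7919 * r) % 2**31)
        for tr, te in skf.split(Xs, yv):
            xtr, xte, _, _ = _standardize(Xs[tr], Xs[te])
            clf = SVC(kernel="rbf", gamma=gamma, C=C)
            clf.fit(xtr, yv[tr])
            errs.append(np.mean(clf.predict(xte) != yv[te]))
    return float(np.mean(errs))


@dataclass
class SelectionResult:
    """Outcome of greedy forward selection."""

    selected: list[str]
    objective_path: list[float]   # CV error after each accepted step
    baseline_objective: float     # majority-class error before any feature
    stopping_reason: str          # 'tolerance' | 'max_features' | 'exhausted'
    repeats: int
    seed: int


def sequential_select(X, y, tol: float = 1e-6, repeats: int = 1000,
                      max_features: int | None = None, folds: int = 10,
                      seed: int = 0, C: float = 1.0, gamma: float = 1.0) -> SelectionResult:
    """Greedy forward selection driven by the cross-validated SVM objective.

    Starting from an empty candidate set, every unselected feature is scored
    by :func:`cv_objective` on the current set plus that feature; the best
    is accepted if it improves the objective by at least ``tol``. The
    baseline objective of the empty set is the majority-class error rate.
    Candidates are evaluated in canonical (sorted-name) order and ties are
    broken toward the first, making the result invariant to column order.
    """
    Xdf = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
    Xdf.columns = [str(c) for c in Xdf.columns]
    _, yv, _ = _as_xy(Xdf, y)
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    order = sorted(Xdf.columns)
    selected: list[str] = []
    path: list[float] = []
    current = float(1.0 - np.bincount(yv).max() / yv.size)
    reason = "exhausted"
    step = 0
    while True:
        if max_features is not None and len(selected) >= max_features:
            reason = "max_features"
            break
        remaining = [f for f in order if f not in selected]
        if not remaining:
            reason = "exhausted"
            break
        scores = np.array([
            cv_objective(Xdf, yv, selected + [f], folds=folds, repeats=repeats,
                         seed=seed + 104729 * step, C=C, gamma=gamma)
            for f in remaining
        ])
        best = int(np.argmin(scores))  # ties -> first in canonical order
        if current - scores[best] < tol:
            reason = "tolerance"
            break
        selected.append(remaining[best])
        current = float(scores[best])
        path.append(current)
        step += 1
    return SelectionResult(selected, path, float(1.0 - np.bincount(yv).max() / yv.size),
                           reason, repeats, seed)


@dataclass
class SVMModel:
    """Gaussian-kernel SVM in the explicit support-vector form.

    ``weights`` are the non-negative dual coefficients wₙ, ``labels`` the
    support-vector labels yₙ ∈ {−1, +1}; the decision value is
    f(x) = Σₙ wₙ yₙ exp(−‖xₙ − x‖²) + b in the standardized feature space.
    """

    feature_names: list[str]
    support_vectors: np.ndarray   # (N, p), standardized space
    labels: np.ndarray            # (N,), ±1
    weights: np.ndarray           # (N,), in [0, C]
    bias: float
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    C: float = 1.0
    gamma: float = 1.0

    def standardize(self, X) -> np.ndarray:
        Xv = np.asarray(X, dtype=float)
        return (Xv - self.scaler_mean) / self.scaler_scale

    def to_json(self, path) -> None:
        obj = {
            "feature_names": self.feature_names,
            "support_vectors": self.support_vectors.tolist(),
            "labels": self.labels.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "C": self.C,
            "gamma": self.gamma,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SVMModel":
        with open(path) as fh:
            o = json.load(fh)
        return cls(o["feature_names"], np.array(o["support_vectors"]),
                   np.array(o["labels"]), np.array(o["weights"]), float(o["bias"]),
                   np.array(o["scaler_mean"]), np.array(o["scaler_scale"]),
                   float(o["C"]), float(o["gamma"]))


def train_svm(X, y, subset=None, C: float = 1.0, gamma: float = 1.0) -> SVMModel:
    """Fit the Gaussian-kernel SVM on standardized selected features."""
    Xv, yv, names = _as_xy(X, y)
    if subset is None:
        subset = names
    idx = [names.index(f) if isinstance(f, str) else int(f) for f in subset]
    sel_names = [names[i] for i in idx]
    Xs = Xv[:, idx]
    sd = Xs.std(axis=0)
    if np.any(sd == 0):
        bad = sel_names[int(np.argmin(sd))]
        raise ValueError(f"feature {bad!r} is constant; cannot standardize")
    mu = Xs.mean(axis=0)
    Z = (Xs - mu) / sd
    # tight SMO tolerance so the decision function is solver-order invariant
    clf = SVC(kernel="rbf", gamma=gamma, C=C, tol=1e-8)
    clf.fit(Z, yv)
    dual = clf.dual_coef_.ravel()  # = yₙ·αₙ
    return SVMModel(
        feature_names=sel_names,
        support_vectors=clf.support_vectors_.copy(),
        labels=np.sign(dual).astype(int),
        weights=np.abs(dual),
        bias=float(clf.intercept_[0]),
        scaler_mean=mu,
        scaler_scale=sd,
        C=C,
        gamma=gamma,
    )


def svm_score(model: SVMModel, x) -> np.ndarray | float:
    """Evaluate f(x) = Σₙ wₙ yₙ exp(−γ‖xₙ − x‖²) + b directly.

    ``x`` is in the original (unstandardized) feature space; pass a single
    vector or an (m, p) matrix. Non-finite inputs raise.
    """
    xv = np.asarray(x, dtype=float)
    single = xv.ndim == 1
    xv = np.atleast_2d(xv)
    if not np.all(np.isfinite(xv)):
        raise ValueError("svm_score requires finite input features")
    if xv.shape[1] != model.support_vectors.shape[1]:
        raise ValueError(f"expected {model.support_vectors.shape[1]} features, got {xv.shape[1]}")
    z = model.standardize(xv)
    d2 = ((z[:, None, :] - model.support_vectors[None, :, :]) ** 2).sum(axis=2)
    f = (np.exp(-model.gamma * d2) @ (model.weights * model.labels)) + model.bias
    return float(f[0]) if single else f
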