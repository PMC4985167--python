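"""Binary family-membership classifiers: Gaussian-kernel SVM, kNN and PNN.

All three backends share one contract: features are min-max scaled with
parameters learned on training data, ``train_*`` returns a
:class:`TrainedClassifier`, and ``predict`` yields a
:class:`PredictionResult` whose label is +1 (member) or -1 (non-member).

The SVM decision function is f(x) = sum_i alpha_i y_i K(x_i, x) + b with
the Gaussian kernel K(xi, xj) = exp(-||xj - xi||^2 / (2 sigma^2)); class
membership follows the sign of f, with f == 0 breaking to non-member.
The kNN rule is a Euclidean-distance majority vote. The PNN applies the
Bayes rule h_i c_i g_i(x) > h_j c_j g_j(x) with the Parzen density
g(x) = (1/n) sum_i exp(-sum_j ((x_j - x_ij)/sigma_j)^2)  -- note the
deliberately absent 1/2 factor and normalizing constant, which cancel in
the two-class decision when the smoothing is shared.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Any, Iterable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.svm import SVC

METHODS = ("svm", "knn", "pnn")

ARCHIVE_VERSION = 1


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature affine map learned on training data (min-max to [0, 1])."""

    min_: np.ndarray
    scale_: np.ndarray  # 1/(max-min); 0 for constant features


@dataclass
class TrainedClassifier:
    """A trained backend: method tag, hyperparameters and learned state."""

    method: str
    hyperparameters: dict[str, Any]
    learned_state: dict[str, Any]
    scaler: ScalerParams
    platt: tuple[float, float] | None = None
    config_digest: str | None = None
    family_id: str | None = None


@dataclass(frozen=True)
class PredictionResult:
    """One family-membership call for one query."""

    query_id: str
    family_id: str | None
    label: int  # +1 member, -1 non-member
    score: float
    probability: float | None = None


# ---------------------------------------------------------------------------
# scaling


def fit_scaler(X: np.ndarray) -> ScalerParams:
    """Learn a per-feature min-max transform; constant features map to 0."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("fit_scaler requires a non-empty 2-D matrix")
    mn = X.min(axis=0)
    rng = X.max(axis=0) - mn
    scale = np.where(rng > 0, 1.0 / np.where(rng > 0, rng, 1.0), 0.0)
    return ScalerParams(min_=mn, scale_=scale)


def apply_scaler(params: ScalerParams, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    return (X - params.min_) * params.scale_


def _check_labels(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y, dtype=int)
    if not set(np.unique(y)) <= {-1, 1}:
        raise ValueError("labels must be +/-1")
    if len(set(np.unique(y))) < 2:
        raise ValueError("both classes must be present in the training labels")
    return y


# ---------------------------------------------------------------------------
# SVM


def _gaussian_kernel(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    np.maximum(d2, 0.0, out=d2)
    return np.exp(-d2 / (2.0 * sigma**2))


def train_svm(
    X: np.ndarray,
    y: np.ndarray,
    cost: float = 1.0,
    class_weights: tuple[float, float] = (1.0, 1.0),
    sigma: float = 1.0,
    platt: bool = False,
    platt_folds: int = 3,
    seed: int = 0,
) -> TrainedClassifier:
    """Train a soft-margin Gaussian-kernel SVM with per-class costs.

    ``class_weights`` is (member weight, non-member weight); the effective
    misclassification cost per class is ``cost * weight``. With
    ``platt=True`` a posterior sigmoid is fitted to out-of-fold decision
    values (``platt_folds``-fold, stratified, seeded).
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    if cost <= 0 or sigma <= 0:
        raise ValueError("cost and sigma must be positive")
    w_pos, w_neg = class_weights
    if w_pos <= 0 or w_neg <= 0:
        raise ValueError("class weights must be positive")
    scaler = fit_scaler(X)
    Xs = apply_scaler(scaler, X)
    clf = _make_svc(cost, sigma, w_pos, w_neg)
    clf.fit(Xs, y)
    state = {
        "support_vectors": clf.support_vectors_.copy(),
        "dual_coef": clf.dual_coef_[0].copy(),
        "intercept": float(clf.intercept_[0]),
        "sigma": float(sigma),
        "n_features": X.shape[1],
    }
    model = TrainedClassifier(
        method="svm",
        hyperparameters={
            "cost": float(cost),
            "class_weights": (float(w_pos), float(w_neg)),
            "sigma": float(sigma),
        },
        learned_state=state,
        scaler=scaler,
    )
    if platt:
        f_oof = cross_validated_decision_values(
            X, y, cost=cost, class_weights=class_weights, sigma=sigma,
            n_folds=platt_folds, seed=seed,
        )
        model.platt = fit_platt(f_oof, y)
    return model


def _make_svc(cost: float, sigma: float, w_pos: float, w_neg: float) -> SVC:
    return SVC(
        C=cost,
        kernel="rbf",
        gamma=1.0 / (2.0 * sigma**2),
        class_weight={1: w_pos, -1: w_neg},
    )


def svm_decision_value(model: TrainedClassifier, X: np.ndarray) -> np.ndarray:
    """Decision values f(x) computed from the stored support representation."""
    st = model.learned_state
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != st["n_features"]:
        raise ValueError(
            f"dimension mismatch: model expects {st['n_features']} features, got {X.shape[1]}"
        )
    Xs = apply_scaler(model.scaler, X)
    K = _gaussian_kernel(Xs, st["support_vectors"], st["sigma"])
    return K @ st["dual_coef"] + st["intercept"]


def cross_validated_decision_values(
    X: np.ndarray,
    y: np.ndarray,
    cost: float,
    class_weights: tuple[float, float],
    sigma: float,
    n_folds: int = 3,
    seed: int = 0,
) -> np.ndarray:
    """Out-of-fold SVM decision values for Platt fitting (stratified k-fold)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_folds = min(n_folds, int(np.min(np.bincount((y > 0).astype(int)))))
    n_folds = max(n_folds, 2)
    out = np.empty(len(y))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    w_pos, w_neg = class_weights
    for tr, te in skf.split(X, y):
        scaler = fit_scaler(X[tr])
        clf = _make_svc(cost, sigma, w_pos, w_neg)
        clf.fit(apply_scaler(scaler, X[tr]), y[tr])
        out[te] = clf.decision_function(apply_scaler(scaler, X[te]))
    return out


def platt_probability(AB: tuple[float, float], f: np.ndarray | float) -> np.ndarray | float:
    """P(member | f) = 1 / (1 + exp(A f + B))."""
    A, B = AB
    z = A * np.asarray(f, dtype=float) + B
    # numerically stable sigmoid of -z
    return np.where(z >= 0, np.exp(-z) / (1.0 + np.exp(-z)), 1.0 / (1.0 + np.exp(z)))


def platt_objective(AB: Sequence[float], f: np.ndarray, t: np.ndarray) -> float:
    """Regularized cross-entropy of the sigmoid 1/(1+exp(A f + B)) vs targets t."""
    A, B = AB
    z = A * f + B
    # -[t log p + (1-t) log(1-p)] with p = sigmoid(-z), written stably
    nll = np.where(z >= 0, t * z + np.log1p(np.exp(-z)), (t - 1) * z + np.log1p(np.exp(z)))
    return float(np.sum(nll))


def _platt_targets(y: np.ndarray) -> np.ndarray:
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    t_pos = (n_pos + 1.0) / (n_pos + 2.0)
    t_neg = 1.0 / (n_neg + 2.0)
    return np.where(y == 1, t_pos, t_neg)


def fit_platt(decision_values: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Fit the posterior sigmoid parameters (A, B).

    Minimizes the regularized negative log-likelihood with the standard
    smoothed targets (n+1)/(n+2) and 1/(n+2). Degenerate input (all
    decision values identical) falls back to a constant prior-matching
    sigmoid (A = 0) with a warning.
    """
    f = np.asarray(decision_values, dtype=float)
    y = _check_labels(y)
    if np.allclose(f, f[0]):
        prior = float(np.mean(y == 1))
        prior = min(max(prior, 1e-6), 1 - 1e-6)
        warnings.warn(
            "identical decision values; falling back to prior-based constant probability"
        )
        return (0.0, float(np.log((1 - prior) / prior)))
    t = _platt_targets(y)
    res = minimize(
        platt_objective,
        x0=np.array([0.0, np.log((np.sum(y == -1) + 1.0) / (np.sum(y == 1) + 1.0))]),
        args=(f, t),
        method="BFGS",
    )
    A, B = res.x
    return (float(A), float(B))


def predict_svm(
    model: TrainedClassifier,
    X: np.ndarray,
    query_ids: Sequence[str] | None = None,
) -> list[PredictionResult]:
    """Classify queries by the sign of the decision value (0 -> non-member)."""
    f = svm_decision_value(model, X)
    probs = platt_probability(model.platt, f) if model.platt is not None else None
    out = []
    for i, fi in enumerate(f):
        qid = query_ids[i] if query_ids is not None else str(i)
        out.append(
            PredictionResult(
                query_id=qid,
                family_id=model.family_id,
                label=1 if fi > 0 else -1,
                score=float(fi),
                probability=None if probs is None else float(probs[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# kNN


def train_knn(X: np.ndarray, y: np.ndarray, k: int = 5) -> TrainedClassifier:
    """Store scaled training vectors for Euclidean majority-vote prediction."""
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(y):
        raise ValueError(f"k={k} exceeds number of training points {len(y)}")
    scaler = fit_scaler(X)
    return TrainedClassifier(
        method="knn",
        hyperparameters={"k": int(k)},
        learned_state={
            "X": apply_scaler(scaler, X),
            "y": y.copy(),
            "n_features": X.shape[1],
        },
        scaler=scaler,
    )


def predict_knn(
    model: TrainedClassifier,
    X: np.ndarray,
    query_ids: Sequence[str] | None = None,
) -> list[PredictionResult]:
    """Majority vote over the k nearest stored vectors; ties -> non-member.

    Score (and probability) is the fraction of member votes.
    """
    st = model.learned_state
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != st["n_features"]:
        raise ValueError(
            f"dimension mismatch: model expects {st['n_features']} features, got {X.shape[1]}"
        )
    k = model.hyperparameters["k"]
    Xs = apply_scaler(model.scaler, X)
    nn = NearestNeighbors(n_neighbors=k).fit(st["X"])
    _, idx = nn.kneighbors(Xs)
    out = []
    for i in range(len(Xs)):
        votes = st["y"][idx[i]]
        n_member = int(np.sum(votes == 1))
        frac = n_member / k
        qid = query_ids[i] if query_ids is not None else str(i)
        out.append(
            PredictionResult(
                query_id=qid,
                family_id=model.family_id,
                label=1 if n_member * 2 > k else -1,
                score=float(frac),
                probability=float(frac),
            )
        )
    return out


# ---------------------------------------------------------------------------
# PNN


def train_pnn(
    X: np.ndarray,
    y: np.ndarray,
    smoothing: float | np.ndarray = 0.1,
    priors: tuple[float, float] | None = None,
    costs: tuple[float, float] = (1.0, 1.0),
) -> TrainedClassifier:
    """Store scaled training vectors for Parzen-window density classification.

    ``smoothing`` is a shared sigma or a per-feature array sigma_j;
    ``priors`` defaults to training-class frequencies (member, non-member).
    """
    X = np.asarray(X, dtype=float)
    y = _check_labels(y)
    sm = np.asarray(smoothing, dtype=float)
    if np.any(sm <= 0):
        raise ValueError("smoothing must be positive")
    if sm.ndim not in (0, 1):
        raise ValueError("smoothing must be scalar or a per-feature array")
    if sm.ndim == 1 and sm.shape[0] != X.shape[1]:
        raise ValueError("per-feature smoothing length must equal feature count")
    if priors is None:
        priors = (float(np.mean(y == 1)), float(np.mean(y == -1)))
    if priors[0] <= 0 or priors[1] <= 0:
        raise ValueError("priors must be positive")
    if costs[0] <= 0 or costs[1] <= 0:
        raise ValueError("costs must be positive")
    scaler = fit_scaler(X)
    return TrainedClassifier(
        method="pnn",
        hyperparameters={
            "smoothing": sm.tolist() if sm.ndim else float(sm),
            "priors": (float(priors[0]), float(priors[1])),
            "costs": (float(costs[0]), float(costs[1])),
        },
        learned_state={
            "X": apply_scaler(scaler, X),
            "y": y.copy(),
            "n_features": X.shape[1],
        },
        scaler=scaler,
    )


def _pnn_log_density(model: TrainedClassifier, Xs: np.ndarray, cls: int) -> np.ndarray:
    """log g_cls(x) for scaled queries, computed stably via logsumexp."""
    st = model.learned_state
    sm = np.asarray(model.hyperparameters["smoothing"], dtype=float)
    Xc = st["X"][st["y"] == cls]
    scaled_q = Xs / sm
    scaled_t = Xc / sm
    d2 = (
        np.sum(scaled_q**2, axis=1)[:, None]
        + np.sum(scaled_t**2, axis=1)[None, :]
        - 2.0 * scaled_q @ scaled_t.T
    )
    np.maximum(d2, 0.0, out=d2)
    return logsumexp(-d2, axis=1) - np.log(len(Xc))


def pnn_density(model: TrainedClassifier, X: np.ndarray, cls: int) -> np.ndarray:
    """Parzen density g_cls(x) = (1/n) sum_i exp(-sum_j ((x_j-x_ij)/sigma_j)^2).

    Queries are given in the original (unscaled) feature space.
    """
    Xs = apply_scaler(model.scaler, np.atleast_2d(np.asarray(X, dtype=float)))
    return np.exp(_pnn_log_density(model, Xs, cls))


def predict_pnn(
    model: TrainedClassifier,
    X: np.ndarray,
    query_ids: Sequence[str] | None = None,
) -> list[PredictionResult]:
    """Bayes rule: member iff h1 c1 g1(x) > h2 c2 g2(x); ties -> non-member.

    Score (and probability) is the normalized posterior
    h1 c1 g1 / (h1 c1 g1 + h2 c2 g2), evaluated in log space.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    st = model.learned_state
    if X.shape[1] != st["n_features"]:
        raise ValueError(
            f"dimension mismatch: model expects {st['n_features']} features, got {X.shape[1]}"
        )
    Xs = apply_scaler(model.scaler, X)
    h1, h2 = model.hyperparameters["priors"]
    c1, c2 = model.hyperparameters["costs"]
    log_pos = np.log(h1 * c1) + _pnn_log_density(model, Xs, 1)
    log_neg = np.log(h2 * c2) + _pnn_log_density(model, Xs, -1)
    # posterior via stable softmax over the two log-terms
    m = np.maximum(log_pos, log_neg)
    post = np.exp(log_pos - m) / (np.exp(log_pos - m) + np.exp(log_neg - m))
    out = []
    for i in range(len(Xs)):
        qid = query_ids[i] if query_ids is not None else str(i)
        out.append(
            PredictionResult(
                query_id=qid,
                family_id=model.family_id,
                label=1 if log_pos[i] > log_neg[i] else -1,
                score=float(post[i]),
                probability=float(post[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# common train/predict dispatch


def train(method: str, X: np.ndarray, y: np.ndarray, **hyperparameters: Any) -> TrainedClassifier:
    if method == "svm":
        return train_svm(X, y, **hyperparameters)
    if method == "knn":
        return train_knn(X, y, **hyperparameters)
    if method == "pnn":
        return train_pnn(X, y, **hyperparameters)
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def predict(
    model: TrainedClassifier, X: np.ndarray, query_ids: Sequence[str] | None = None
) -> list[PredictionResult]:
    if model.method == "svm":
        return predict_svm(model, X, query_ids)
    if model.method == "knn":
        return predict_knn(model, X, query_ids)
    if model.method == "pnn":
        return predict_pnn(model, X, query_ids)
    raise ValueError(f"unknown method {model.method!r}")


# ---------------------------------------------------------------------------
# hyperparameter search


def expand_grid(grid: Mapping[str, Sequence[Any]]) -> list[dict[str, Any]]:
    """Expand a dict of value lists into grid points in deterministic order."""
    keys = list(grid)
    return [dict(zip(keys, combo)) for combo in product(*(grid[k] for k in keys))]


def default_grid(method: str, y: np.ndarray | None = None) -> list[dict[str, Any]]:
    """Small default hyperparameter grids per method.

    For the SVM the member-class weight candidates are 1 and the
    negative:positive count ratio of the training labels (when supplied).
    """
    if method == "svm":
        ratio = 1.0
        if y is not None:
            y = np.asarray(y)
            n_pos = max(int(np.sum(y == 1)), 1)
            ratio = float(np.sum(y == -1)) / n_pos
        weights = [(1.0, 1.0)]
        if ratio > 1.0:
            weights.append((ratio, 1.0))
        return expand_grid(
            {
                "cost": [1.0, 10.0, 100.0, 1000.0],
                "sigma": [0.5, 1.0, 2.0, 4.0],
                "class_weights": weights,
            }
        )
    if method == "knn":
        return expand_grid({"k": [1, 3, 5, 7, 9]})
    if method == "pnn":
        return expand_grid({"smoothing": [0.05, 0.1, 0.2, 0.4, 0.8]})
    raise ValueError(f"unknown method {method!r}")


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    pos = y_true == 1
    neg = ~pos
    se = np.mean(y_pred[pos] == 1) if pos.any() else 0.0
    sp = np.mean(y_pred[neg] == -1) if neg.any() else 0.0
    return (se + sp) / 2.0


def grid_search(
    method: str,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_tune: np.ndarray,
    y_tune: np.ndarray,
    grid: Sequence[Mapping[str, Any]],
) -> tuple[dict[str, Any], float]:
    """Exhaustive search maximizing balanced accuracy (SE+SP)/2 on the tune set.

    Ties break to the first grid point in supplied order. Returns
    (best hyperparameters, best criterion value).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("hyperparameter grid is empty")
    y_tune = np.asarray(y_tune, dtype=int)
    best: tuple[float, int] | None = None
    for gi, params in enumerate(grid):
        model = train(method, X_train, y_train, **params)
        preds = predict(model, X_tune)
        y_pred = np.array([p.label for p in preds])
        crit = _balanced_accuracy(y_tune, y_pred)
        if best is None or crit > best[0]:
            best = (crit, gi)
    assert best is not None
    return dict(grid[best[1]]), best[0]


# ---------------------------------------------------------------------------
# persistence (versioned JSON archive)


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, np.ndarray):
        return {"__ndarray__": obj.tolist()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, tuple):
        return list(obj)
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def _unjson(obj: Any) -> Any:
    if isinstance(obj, dict):
        if "__ndarray__" in obj:
            return np.asarray(obj["__ndarray__"], dtype=float)
        return {k: _unjson(v) for k, v in obj.items()}
    return obj


def save_model(model: TrainedClassifier, path: str | Path) -> None:
    """Serialize a model to a versioned JSON archive."""
    payload = {
        "format_version": ARCHIVE_VERSION,
        "method": model.method,
        "hyperparameters": _jsonable(model.hyperparameters),
        "learned_state": _jsonable(model.learned_state),
        "scaler": {
            "min": model.scaler.min_.tolist(),
            "scale": model.scaler.scale_.tolist(),
        },
        "platt": list(model.platt) if model.platt is not None else None,
        "config_digest": model.config_digest,
        "family_id": model.family_id,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> TrainedClassifier:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("format_version") != ARCHIVE_VERSION:
        raise ValueError(f"unsupported model archive version in {path}")
    state = _unjson(payload["learned_state"])
    if "y" in state:
        state["y"] = np.asarray(state["y"], dtype=int)
    if "n_features" in state:
        state["n_features"] = int(state["n_features"])
    if "intercept" in state:
        state["intercept"] = float(state["intercept"])
    hyper = _unjson(payload["hyperparameters"])
    for key in ("class_weights", "priors", "costs"):
        if key in hyper and isinstance(hyper[key], list):
            hyper[key] = tuple(hyper[key])
    return TrainedClassifier(
        method=payload["method"],
        hyperparameters=hyper,
        learned_state=state,
        scaler=ScalerParams(
            min_=np.asarray(payload["scaler"]["min"], dtype=float),
            scale_=np.asarray(payload["scaler"]["scale"], dtype=float),
        ),
        platt=tuple(payload["platt"]) if payload["platt"] is not None else None,
        config_digest=payload["config_digest"],
        family_id=payload["family_id"],
    )
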