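"""Regularized discriminant analysis (RDA) with stratified splitting and
cross-validated hyperparameter tuning.

The classifier is a Gaussian discriminant whose class covariances are
shrunk along two axes (Friedman-style):

    Sigma_k(lambda)        = (1 - lambda) * S_k + lambda * S_pooled
    Sigma_k(lambda, gamma) = (1 - gamma) * Sigma_k(lambda)
                             + gamma * (tr(Sigma_k(lambda)) / p) * I

lambda in [0, 1] blends per-class covariances (QDA) toward the pooled
covariance (LDA); gamma in [0, 1] shrinks toward a scaled identity
(nearest-mean behaviour at gamma = 1).  Classification uses the Gaussian
discriminant score

    d_k(x) = -1/2 log det Sigma_k - 1/2 (x - mu_k)' Sigma_k^{-1} (x - mu_k)
             + log pi_k

with ties broken to the lowest class index; posteriors are the softmax of
the scores.  Hyperparameters are chosen by stratified k-fold
cross-validation maximising mean balanced accuracy, with deterministic
tie-breaking toward more regularization (larger lambda, then larger gamma).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import linalg
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "RDAModel",
    "SplitPlan",
    "stratified_split",
    "fit_rda",
    "predict_rda",
    "tune_rda",
    "DEFAULT_GRID",
]

DEFAULT_GRID: tuple[tuple[float, float], ...] = tuple(
    (lam, gam) for lam in (0.0, 0.25, 0.5, 0.75, 1.0) for gam in (0.0, 0.1, 0.25, 0.5, 1.0)
)


@dataclass
class RDAModel:
    classes: list
    means: np.ndarray  # (K, p)
    class_covs: np.ndarray  # (K, p, p) raw sample covariances
    pooled_cov: np.ndarray  # (p, p)
    reg_covs: np.ndarray  # (K, p, p) regularized
    lam: float
    gamma: float
    priors: np.ndarray  # (K,)
    feature_names: list[str] | None = None
    # cached factorizations
    _chol: list = field(default_factory=list, repr=False)
    _logdet: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    @property
    def p(self) -> int:
        return self.means.shape[1]

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": [str(c) for c in self.classes],
                "means": self.means.tolist(),
                "reg_covs": self.reg_covs.tolist(),
                "pooled_cov": self.pooled_cov.tolist(),
                "lambda": self.lam,
                "gamma": self.gamma,
                "priors": self.priors.tolist(),
                "feature_names": self.feature_names,
            },
            indent=1,
        )


@dataclass
class SplitPlan:
    train_ids: list[int]
    test_ids: list[int]
    strata: dict[str, list[int]]
    fraction: float
    seed: int


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(
    strata_labels: Sequence[str],
    test_fraction: float = 0.2,
    seed: int = 0,
    min_stratum_for_test: int = 5,
    small_stratum: str = "warn",
) -> SplitPlan:
    """Stratified train/test split over integer row indices.

    Each stratum contributes ``round_half_up(n * test_fraction)`` test
    members (at least 1) when its size is at least ``min_stratum_for_test``;
    smaller strata go entirely to train with a warning (or raise when
    ``small_stratum='fatal'``), protecting tiny groups from losing their few
    members to the test set.
    """
    strata: dict[str, list[int]] = {}
    for i, s in enumerate(strata_labels):
        strata.setdefault(str(s), []).append(i)
    rng = np.random.default_rng(seed)
    train: list[int] = []
    test: list[int] = []
    for name in sorted(strata):
        idx = np.array(strata[name])
        n = len(idx)
        if n < min_stratum_for_test:
            if small_stratum == "fatal":
                raise ValueError(f"stratum {name!r} has only {n} member(s)")
            warnings.warn(
                f"stratum {name!r} has {n} member(s) (<{min_stratum_for_test}); "
                "all assigned to train",
                stacklevel=2,
            )
            train.extend(idx.tolist())
            continue
        n_test = max(1, _round_half_up(n * test_fraction))
        perm = rng.permutation(n)
        test.extend(idx[perm[:n_test]].tolist())
        train.extend(idx[perm[n_test:]].tolist())
    return SplitPlan(
        train_ids=sorted(train),
        test_ids=sorted(test),
        strata={k: list(v) for k, v in strata.items()},
        fraction=test_fraction,
        seed=seed,
    )


def _regularize(class_covs: np.ndarray, pooled: np.ndarray, lam: float, gamma: float) -> np.ndarray:
    covs = (1.0 - lam) * class_covs + lam * pooled[None, :, :]
    p = pooled.shape[0]
    traces = np.trace(covs, axis1=1, axis2=2)
    eye = np.eye(p)
    return (1.0 - gamma) * covs + gamma * (traces / p)[:, None, None] * eye


def fit_rda(
    X: np.ndarray,
    y: Sequence,
    lam: float,
    gamma: float,
    priors: np.ndarray | str = "empirical",
    feature_names: list[str] | None = None,
) -> RDAModel:
    """Fit the Gaussian discriminant with (lambda, gamma) shrinkage.

    Priors default to empirical class frequencies; pass "uniform" or an
    explicit vector.  Raises if any regularized covariance is singular,
    suggesting more shrinkage.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if not (0.0 <= lam <= 1.0 and 0.0 <= gamma <= 1.0):
        raise ValueError("lambda and gamma must lie in [0, 1]")
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("at least 2 classes required")
    n, p = X.shape
    K = len(classes)
    means = np.empty((K, p))
    class_covs = np.empty((K, p, p))
    counts = np.empty(K)
    pooled = np.zeros((p, p))
    for k, c in enumerate(classes):
        Xk = X[y == c]
        if len(Xk) < 2:
            raise ValueError(f"class {c!r} has fewer than 2 observations")
        counts[k] = len(Xk)
        means[k] = Xk.mean(axis=0)
        dev = Xk - means[k]
        class_covs[k] = dev.T @ dev / (len(Xk) - 1)
        pooled += dev.T @ dev
    pooled /= n - K
    if isinstance(priors, str):
        if priors == "empirical":
            pi = counts / n
        elif priors == "uniform":
            pi = np.full(K, 1.0 / K)
        else:
            raise ValueError(f"unknown priors {priors!r}")
    else:
        pi = np.asarray(priors, dtype=float)
        if np.any(pi <= 0):
            raise ValueError("priors must be positive")
        pi = pi / pi.sum()

    reg = _regularize(class_covs, pooled, lam, gamma)
    chols = []
    logdets = np.empty(K)
    for k in range(K):
        try:
            c_low = linalg.cho_factor(reg[k], lower=True)
        except linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"regularized covariance for class {classes[k]!r} is singular at "
                f"(lambda={lam}, gamma={gamma}); increase gamma or drop one "
                "shape feature"
            ) from exc
        chols.append(c_low)
        logdets[k] = 2.0 * np.sum(np.log(np.diag(c_low[0])))
    return RDAModel(
        classes=classes,
        means=means,
        class_covs=class_covs,
        pooled_cov=pooled,
        reg_covs=reg,
        lam=lam,
        gamma=gamma,
        priors=pi,
        feature_names=feature_names,
        _chol=chols,
        _logdet=logdets,
    )


def predict_rda(model: RDAModel, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Labels, posterior probabilities and discriminant scores for ``X``.

    Scores are the Gaussian log-discriminants (up to the shared -p/2 log 2pi
    constant); posteriors are their softmax and sum to 1 per specimen.
    Ties go to the lowest class index.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.p:
        raise ValueError(f"expected {model.p} features, got {X.shape[1]}")
    n = X.shape[0]
    K = model.n_classes
    scores = np.empty((n, K))
    for k in range(K):
        dev = X - model.means[k]
        sol = linalg.cho_solve(model._chol[k], dev.T)
        maha = np.sum(dev.T * sol, axis=0)
        scores[:, k] = -0.5 * model._logdet[k] - 0.5 * maha + np.log(model.priors[k])
    shifted = scores - scores.max(axis=1, keepdims=True)
    expd = np.exp(shifted)
    posterior = expd / expd.sum(axis=1, keepdims=True)
    labels = np.array([model.classes[k] for k in np.argmax(scores, axis=1)])
    return labels, posterior, scores


def tune_rda(
    X: np.ndarray,
    y: Sequence,
    grid: Sequence[tuple[float, float]] = DEFAULT_GRID,
    k: int = 10,
    seed: int = 0,
    priors: np.ndarray | str = "empirical",
) -> tuple[tuple[float, float], "pd.DataFrame"]:
    """Select (lambda, gamma) by stratified k-fold CV on balanced accuracy.

    ``k`` is reduced (with a warning) to the smallest class size when
    necessary.  Ties are broken toward more regularization: larger lambda,
    then larger gamma.  Returns the winning pair and the full CV table.
    """
    import pandas as pd

    from .pipeline import classification_metrics, confusion_matrix

    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    classes, counts = np.unique(y, return_counts=True)
    k_eff = min(k, int(counts.min()))
    if k_eff < k:
        warnings.warn(
            f"reducing CV folds from {k} to {k_eff} (smallest class size)",
            stacklevel=2,
        )
    if k_eff < 2:
        raise ValueError("smallest class too small for cross-validation")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=int(seed) % (2**31))
    folds = list(skf.split(X, y))
    rows = []
    for lam, gam in grid:
        bas = []
        for train_idx, val_idx in folds:
            try:
                model = fit_rda(X[train_idx], y[train_idx], lam, gam, priors=priors)
            except (np.linalg.LinAlgError, ValueError):
                bas.append(np.nan)
                continue
            pred, _, _ = predict_rda(model, X[val_idx])
            cm = confusion_matrix(y[val_idx], pred, labels=classes.tolist())
            _, ba, _ = classification_metrics(cm)
            bas.append(ba)
        rows.append(
            {
                "lambda": lam,
                "gamma": gam,
                "mean_balanced_accuracy": float(np.nanmean(bas)) if np.any(np.isfinite(bas)) else np.nan,
                "n_failed_folds": int(np.sum(~np.isfinite(bas))),
            }
        )
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["mean_balanced_accuracy"])
    if ok.empty:
        raise np.linalg.LinAlgError("every grid point failed; data too degenerate")
    best = ok.sort_values(
        ["mean_balanced_accuracy", "lambda", "gamma"], ascending=[False, False, False]
    ).iloc[0]
    return (float(best["lambda"]), float(best["gamma"])), table
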