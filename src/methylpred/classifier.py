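"""Kernel classifiers: a sparse Bayesian learner and an SVM alternative.

The sparse Bayesian classifier is a relevance-vector machine for binary
classification: a logistic-linear model over Gaussian kernel basis functions
(one per training point, plus a bias), with an independent zero-mean Gaussian
prior on each weight.  The per-weight prior precisions (alpha) are
re-estimated by type-II maximum likelihood; because the likelihood is
logistic, the weight posterior is approximated at each step by a Laplace
approximation found with Newton/IRLS.  Precisions that diverge past a pruning
threshold remove their basis function, which is what makes the solution
sparse: the surviving training points are the relevance vectors.

Features are standardised (train-set mean/variance) before the kernel, since
the four feature blocks live on wildly different scales and Gaussian kernels
are scale-sensitive.  The kernel width defaults to the median pairwise
distance of the (standardised) training data.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, log_expit
from sklearn.metrics.pairwise import euclidean_distances
from sklearn.svm import SVC

from .errors import ConfigurationError, DataError

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian kernel k(x, y) = exp(-||x - y||^2 / (2 width^2))."""

    kind: str = "gaussian"
    width: float | None = None  # None -> median pairwise-distance heuristic

    def __post_init__(self):
        if self.kind != "gaussian":
            raise ConfigurationError(f"unsupported kernel kind {self.kind!r}")
        if self.width is not None and self.width <= 0:
            raise ConfigurationError(f"kernel width must be positive, got {self.width}")


def median_width(X: np.ndarray, max_points: int = 1000, seed: int = 0) -> float:
    """Median pairwise Euclidean distance (subsampled beyond max_points)."""
    X = np.asarray(X, dtype=float)
    if len(X) > max_points:
        rng = np.random.default_rng(seed)
        X = X[rng.choice(len(X), max_points, replace=False)]
    d = euclidean_distances(X)
    vals = d[np.triu_indices_from(d, k=1)]
    med = float(np.median(vals))
    return med if med > 0 else 1.0


def gaussian_kernel(A: np.ndarray, B: np.ndarray, width: float) -> np.ndarray:
    d2 = euclidean_distances(A, B, squared=True)
    return np.exp(-d2 / (2.0 * width**2))


class _Standardizer:
    """Per-feature zero-mean unit-variance scaling fitted on training data.

    Constant features get scale 1 so they pass through (and contribute
    nothing to kernel distances after centering).
    """

    def fit(self, X: np.ndarray) -> "_Standardizer":
        self.mean_ = X.mean(axis=0)
        std = X.std(axis=0)
        self.scale_ = np.where(std > 0, std, 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2 or len(X) != len(y):
        raise DataError("features must be 2-D and aligned with labels")
    if not np.isfinite(X).all():
        raise DataError("features contain non-finite values")
    classes = np.unique(y)
    if len(classes) != 2:
        raise DataError(f"need exactly 2 classes, got {list(classes)}")
    return X, y, classes


class SparseBayesClassifier:
    """Relevance-vector classification with a Gaussian kernel.

    Parameters
    ----------
    kernel
        Kernel specification; width None triggers the median heuristic.
    max_iter
        Cap on hyperparameter re-estimation cycles (default 5000).
    tol
        Convergence threshold on the maximum relative change of the
        retained precisions.
    prune_threshold
        Basis functions whose precision exceeds this are removed.
    standardize
        Standardise features (train statistics) before the kernel.
    """

    def __init__(self, kernel: KernelSpec | None = None, max_iter: int = 5000,
                 tol: float = 1e-6, prune_threshold: float = 1e9,
                 standardize: bool = True, alpha_init: float = 1e-2,
                 bias_alpha: float = 1e-6, weight_floor: float = 1e-8,
                 seed: int | None = None):
        self.kernel = kernel or KernelSpec()
        self.max_iter = max_iter
        self.tol = tol
        self.prune_threshold = prune_threshold
        self.standardize = standardize
        self.alpha_init = alpha_init
        self.bias_alpha = bias_alpha
        self.weight_floor = weight_floor
        self.seed = seed

    # -- Laplace approximation -------------------------------------------
    @staticmethod
    def _penalised_ll(Phi, t, alpha, w):
        z = Phi @ w
        ll = np.sum(np.where(t == 1, log_expit(z), log_expit(-z)))
        return ll - 0.5 * np.sum(alpha * w**2)

    def _laplace_mode(self, Phi, t, alpha, w, max_newton=25, gtol=1e-5):
        """Newton/IRLS search for the posterior mode; returns (w, chol(H))."""
        obj = self._penalised_ll(Phi, t, alpha, w)
        for _ in range(max_newton):
            p = expit(Phi @ w)
            g = Phi.T @ (t - p) - alpha * w
            if np.max(np.abs(g)) < gtol:
                break
            b = np.clip(p * (1 - p), 1e-12, None)
            H = (Phi.T * b) @ Phi
            H[np.diag_indices_from(H)] += alpha
            cf = cho_factor(H, lower=True)
            dw = cho_solve(cf, g)
            if np.max(np.abs(dw)) < 1e-12 * (1.0 + np.max(np.abs(w))):
                break
            step, improved = 1.0, False
            for _ in range(12):
                w_new = w + step * dw
                obj_new = self._penalised_ll(Phi, t, alpha, w_new)
                if obj_new >= obj - 1e-10 * (1.0 + abs(obj)):
                    improved = True
                    break
                step /= 2.0
            if not improved:
                break  # already at the mode to numerical precision
            w, obj = w_new, obj_new
        # Hessian factor at the final iterate
        p = expit(Phi @ w)
        b = np.clip(p * (1 - p), 1e-12, None)
        H = (Phi.T * b) @ Phi
        H[np.diag_indices_from(H)] += alpha
        cf = cho_factor(H, lower=True)
        return w, cf

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y):
        X, y, classes = _check_Xy(X, y)
        self.classes_ = classes
        t = (y == classes[1]).astype(float)

        self.scaler_ = _Standardizer().fit(X) if self.standardize else None
        Xs = self.scaler_.transform(X) if self.scaler_ else X
        width = self.kernel.width or median_width(Xs, seed=self.seed or 0)
        self.width_ = float(width)
        self._train_X = Xs

        n = len(Xs)
        K = gaussian_kernel(Xs, Xs, self.width_)
        Phi_full = np.hstack([np.ones((n, 1)), K])  # column 0 = bias
        m = n + 1

        active = np.arange(m)
        alpha = np.full(m, self.alpha_init, dtype=float)
        alpha[0] = self.bias_alpha  # bias: fixed weak prior, never re-estimated
        w = np.zeros(m)
        self.converged_ = False
        self.n_iter_ = 0
        for it in range(self.max_iter):
            self.n_iter_ = it + 1
            Phi = Phi_full[:, active]
            # warm-started, so few Newton steps per cycle are actually taken
            w, cf = self._laplace_mode(Phi, t, alpha, w)
            Sigma_diag = np.diagonal(cho_solve(cf, np.eye(len(active)))).copy()
            gamma = np.clip(1.0 - alpha * Sigma_diag, 1e-12, 1.0)
            with np.errstate(divide="ignore"):
                alpha_new = np.where(w**2 > 0, gamma / np.maximum(w**2, 1e-300), np.inf)
            alpha_new[0] = self.bias_alpha
            # prune on diverged precision; also drop numerically dead bases —
            # noise-level weights, or data carrying no information about the
            # weight (gamma ~ 0) while the weight is already negligible —
            # whose precisions would otherwise diverge arbitrarily slowly
            dead = (np.abs(w) < self.weight_floor) | (
                (gamma <= 1e-5) & (np.abs(w) <= 1e-4)
            )
            keep = (alpha_new < self.prune_threshold) & ~dead
            keep[0] = True  # bias is never pruned
            rel = np.abs(alpha_new[keep] - alpha[keep]) / alpha[keep]
            pruned_any = not keep.all()
            active, alpha, w = active[keep], alpha_new[keep], w[keep]
            if not pruned_any and np.max(rel) < self.tol:
                self.converged_ = True
                break
        if not self.converged_:
            warnings.warn(
                f"sparse Bayes hyperparameters did not reach tol={self.tol} "
                f"within {self.max_iter} iterations",
                RuntimeWarning,
            )
        # final Laplace fit on the converged active set
        Phi = Phi_full[:, active]
        w, _ = self._laplace_mode(Phi, t, alpha, w)
        self.bias_ = float(w[0])
        rv_idx = active[1:] - 1  # training-row indices of kernel bases
        self.relevance_idx_ = rv_idx
        self.relevance_vectors_ = Xs[rv_idx]
        self.weights_ = w[1:]
        self.alpha_ = alpha
        return self

    # -- prediction -------------------------------------------------------
    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        self._check_width(X)
        Xs = self.scaler_.transform(X) if self.scaler_ else X
        K = gaussian_kernel(Xs, self.relevance_vectors_, self.width_)
        return K @ self.weights_ + self.bias_

    def predict_proba(self, X) -> np.ndarray:
        """Posterior probability of the positive class (logistic link)."""
        return expit(self.decision_function(X))

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        p = self.predict_proba(X)
        return np.where(p >= threshold, self.classes_[1], self.classes_[0])

    def _check_width(self, X):
        expected = self.relevance_vectors_.shape[1]
        if X.shape[1] != expected:
            raise DataError(
                f"feature width mismatch: model was trained on {expected} "
                f"features but input has {X.shape[1]}"
            )

    # -- serialization ----------------------------------------------------
    def save(self, path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "model": "sparse_bayes",
            "kernel": asdict(self.kernel),
            "width": self.width_,
            "max_iter": self.max_iter,
            "tol": self.tol,
            "prune_threshold": self.prune_threshold,
            "converged": self.converged_,
            "n_iter": self.n_iter_,
            "classes": np.asarray(self.classes_).tolist(),
            "scaler_mean": self.scaler_.mean_.tolist() if self.scaler_ else None,
            "scaler_scale": self.scaler_.scale_.tolist() if self.scaler_ else None,
            "bias": self.bias_,
            "weights": self.weights_.tolist(),
            "relevance_vectors": self.relevance_vectors_.tolist(),
            "alpha": self.alpha_.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "SparseBayesClassifier":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("model") != "sparse_bayes":
            raise DataError(f"{path} does not contain a sparse Bayes model")
        obj = cls(
            kernel=KernelSpec(**payload["kernel"]),
            max_iter=payload["max_iter"],
            tol=payload["tol"],
            prune_threshold=payload["prune_threshold"],
            standardize=payload["scaler_mean"] is not None,
        )
        obj.width_ = payload["width"]
        obj.converged_ = payload["converged"]
        obj.n_iter_ = payload["n_iter"]
        obj.classes_ = np.array(payload["classes"])
        if payload["scaler_mean"] is not None:
            obj.scaler_ = _Standardizer()
            obj.scaler_.mean_ = np.array(payload["scaler_mean"])
            obj.scaler_.scale_ = np.array(payload["scaler_scale"])
        else:
            obj.scaler_ = None
        obj.bias_ = payload["bias"]
        obj.weights_ = np.array(payload["weights"])
        obj.relevance_vectors_ = np.array(payload["relevance_vectors"])
        obj.alpha_ = np.array(payload["alpha"])
        return obj


def train_sparse_bayes(features, labels, kernel: KernelSpec | None = None,
                       max_iter: int = 5000, seed: int | None = None,
                       **kwargs) -> SparseBayesClassifier:
    """Convenience wrapper mirroring :class:`SparseBayesClassifier`."""
    model = SparseBayesClassifier(kernel=kernel, max_iter=max_iter, seed=seed, **kwargs)
    return model.fit(np.asarray(features, dtype=float), labels)


class SVMClassifier:
    """Soft-margin Gaussian-kernel SVM with the same predict contract.

    Delegates to scikit-learn's SVC; probability scores come from Platt
    calibration of the decision values.
    """

    def __init__(self, kernel: KernelSpec | None = None, cost: float = 1.0,
                 standardize: bool = True, seed: int | None = None):
        if cost <= 0:
            raise ConfigurationError(f"cost must be positive, got {cost}")
        self.kernel = kernel or KernelSpec()
        self.cost = cost
        self.standardize = standardize
        self.seed = seed

    def fit(self, X, y):
        X, y, classes = _check_Xy(X, y)
        self.classes_ = classes
        self.scaler_ = _Standardizer().fit(X) if self.standardize else None
        Xs = self.scaler_.transform(X) if self.scaler_ else X
        width = self.kernel.width or median_width(Xs, seed=self.seed or 0)
        self.width_ = float(width)
        self.n_features_ = X.shape[1]
        self.svc_ = SVC(
            C=self.cost,
            kernel="rbf",
            gamma=1.0 / (2.0 * self.width_**2),
            probability=True,
            random_state=self.seed,
        ).fit(Xs, y)
        return self

    def _prepare(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_:
            raise DataError(
                f"feature width mismatch: model was trained on "
                f"{self.n_features_} features but input has {X.shape[1]}"
            )
        return self.scaler_.transform(X) if self.scaler_ else X

    def predict_proba(self, X) -> np.ndarray:
        proba = self.svc_.predict_proba(self._prepare(X))
        pos_col = list(self.svc_.classes_).index(self.classes_[1])
        return proba[:, pos_col]

    def predict(self, X, threshold: float = 0.5) -> np.ndarray:
        p = self.predict_proba(X)
        return np.where(p >= threshold, self.classes_[1], self.classes_[0])


def train_svm(features, labels, kernel: KernelSpec | None = None,
              cost: float = 1.0, seed: int | None = None, **kwargs) -> SVMClassifier:
    model = SVMClassifier(kernel=kernel, cost=cost, seed=seed, **kwargs)
    return model.fit(np.asarray(features, dtype=float), labels)
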