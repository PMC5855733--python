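"""Importance-ranked incremental feature selection.

Features are scored by the absolute weight they receive in a single
linear-kernel soft-margin SVM fit on the standardised training table (one
score per feature, matching a one-shot weight-magnitude ranking; recursive
feature elimination is available as an optional mode).  Nested prefixes of
the ranking are then evaluated with an injectable cross-validation accuracy
function, and the prefix with the best accuracy is selected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .classifier import _Standardizer, _check_Xy
from .errors import DataError
from .pipeline import block_ledger


@dataclass
class SelectionResult:
    ranking: np.ndarray  # permutation of 0..d-1, most important first
    scores: np.ndarray  # importance score per original feature index
    dimensions: list[int]  # evaluated prefix sizes
    accuracies: list[float]  # CV accuracy per evaluated prefix
    chosen_dimension: int
    chosen_features: np.ndarray  # ranking[:chosen_dimension]
    block_composition: dict[str, int] = field(default_factory=dict)

    def write_report(self, path, feature_names=None) -> None:
        with open(path, "w") as fh:
            fh.write(f"# chosen_dimension = {self.chosen_dimension}\n")
            for blk, cnt in self.block_composition.items():
                fh.write(f"# block_{blk} = {cnt}\n")
            fh.write("rank\tfeature_index\tfeature_name\tscore\tselected\n")
            for rank, j in enumerate(self.ranking):
                name = feature_names[j] if feature_names is not None else str(j)
                sel = int(rank < self.chosen_dimension)
                fh.write(f"{rank}\t{j}\t{name}\t{self.scores[j]}\t{sel}\n")
            fh.write("dimension\taccuracy\n")
            for d, a in zip(self.dimensions, self.accuracies):
                fh.write(f"{d}\t{a}\n")


def importance_scores(features, labels, cost: float = 1.0,
                      seed: int | None = None) -> np.ndarray:
    """|w_j| of a linear soft-margin SVM on standardised features.

    Constant features are excluded from standardisation and scored 0.
    """
    X, y, _ = _check_Xy(np.asarray(features, dtype=float), labels)
    # (near-)constant columns carry no signal; excluding them also avoids
    # amplifying rounding noise through the unit-variance scaling
    constant = X.std(axis=0) <= 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
    Xs = _Standardizer().fit(X).transform(X)
    Xs[:, constant] = 0.0
    svc = SVC(kernel="linear", C=cost, random_state=seed).fit(Xs, y)
    w = np.abs(svc.coef_.ravel())
    w[constant] = 0.0
    return w


def importance_scores_rfe(features, labels, cost: float = 1.0, step: int = 10,
                          seed: int | None = None) -> np.ndarray:
    """Optional recursive-elimination variant: rank by elimination order."""
    from sklearn.feature_selection import RFE

    X, y, _ = _check_Xy(np.asarray(features, dtype=float), labels)
    Xs = _Standardizer().fit(X).transform(X)
    rfe = RFE(SVC(kernel="linear", C=cost, random_state=seed), step=step,
              n_features_to_select=1).fit(Xs, y)
    # lower ranking_ = more important; convert to a descending score
    return (rfe.ranking_.max() - rfe.ranking_ + 1).astype(float)


def kfold_svm_accuracy(n_splits: int = 5, cost: float = 1.0,
                       seed: int | None = 0):
    """Default evaluator factory: stratified k-fold Gaussian-SVM accuracy."""
    from .classifier import SVMClassifier

    def evaluator(X, y) -> float:
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        correct = 0
        for tr, te in skf.split(X, y):
            model = SVMClassifier(seed=seed).fit(X[tr], y[tr])
            correct += int(np.sum(model.predict(X[te]) == y[te]))
        return correct / len(y)

    return evaluator


def default_dimensions(d: int, dense_until: int = 200, stride: int = 10) -> list[int]:
    """Prefix sizes to evaluate: every size up to ``dense_until``, then strided."""
    dims = list(range(1, min(dense_until, d) + 1))
    dims += list(range(dense_until + stride, d + 1, stride))
    if dims[-1] != d:
        dims.append(d)
    return dims


def incremental_selection(features, labels, scores, evaluator,
                          dimensions=None) -> SelectionResult:
    """Evaluate nested prefixes of the importance ranking; keep the best.

    ``evaluator(X_subset, y) -> accuracy``; ties on the accuracy curve break
    toward the smaller dimension.  The report includes how many chosen
    features come from each extractor block.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if scores.shape[0] != X.shape[1]:
        raise DataError(
            f"got {scores.shape[0]} scores for {X.shape[1]} features"
        )
    ranking = np.argsort(-scores, kind="stable")
    if dimensions is None:
        dimensions = default_dimensions(X.shape[1])
    accuracies = [float(evaluator(X[:, ranking[:d]], y)) for d in dimensions]
    best = int(np.argmax(accuracies))
    chosen_dim = dimensions[best]
    chosen = ranking[:chosen_dim]
    composition: dict[str, int] = {}
    if X.shape[1] == sum(b.length for b in block_ledger()):
        for b in block_ledger():
            composition[b.name] = int(
                np.sum((chosen >= b.start) & (chosen < b.start + b.length))
            )
    return SelectionResult(
        ranking=ranking,
        scores=scores,
        dimensions=list(dimensions),
        accuracies=accuracies,
        chosen_dimension=chosen_dim,
        chosen_features=chosen,
        block_composition=composition,
    )
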