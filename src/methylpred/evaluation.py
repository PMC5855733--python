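"""Evaluation metrics and validation protocols.

Metrics: confusion counts plus ACC, MCC, SN (sensitivity), SP (specificity)
and the ROC curve with its AUC.  MCC returns 0 when its denominator
vanishes.  AUC uses the Mann-Whitney tie convention (tied scores count one
half), so it is stable under permutation of equal scores.

Protocols:

* target-jackknife cross-validation — leave-one-out restricted to real
  samples: every real sample is held out once and predicted by a model
  trained on all remaining rows (real and synthetic); synthetic rows only
  ever train.  Predictions are pooled into a single confusion matrix.
* chromosome-parity holdout — samples on chromosomes 1/3/5/7/9/11 train,
  samples on 2/4/6/8/10/12 test; anything else is excluded and reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .errors import DataError

TRAIN_CHROMS = frozenset({"1", "3", "5", "7", "9", "11"})
TEST_CHROMS = frozenset({"2", "4", "6", "8", "10", "12"})


@dataclass
class EvalReport:
    """Confusion counts, summary metrics and (optionally) the ROC curve."""

    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    mcc: float
    sn: float
    sp: float
    roc_points: list[tuple[float, float]] | None = None  # (FPR, TPR)
    auc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "ACC": self.acc, "MCC": self.mcc, "SN": self.sn, "SP": self.sp,
        }
        if self.auc is not None:
            d["AUC"] = self.auc
        return d

    def write_text(self, path) -> None:
        with open(path, "w") as fh:
            for k, v in self.to_dict().items():
                fh.write(f"{k}\t{v}\n")

    def write_roc(self, path) -> None:
        if self.roc_points is None:
            raise DataError("no ROC points to write")
        with open(path, "w") as fh:
            fh.write("FPR\tTPR\n")
            for fpr, tpr in self.roc_points:
                fh.write(f"{fpr}\t{tpr}\n")


def confusion_metrics(labels, predictions, positive=1) -> EvalReport:
    """ACC/MCC/SN/SP from binary labels and hard predictions.

    ACC = (TP+TN)/(TP+FP+TN+FN); SN = TP/(TP+FN); SP = TN/(TN+FP);
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), 0 when the
    denominator is 0.  SN (SP) is 0 when there are no positives (negatives).
    """
    y = np.asarray(labels)
    p = np.asarray(predictions)
    if len(y) == 0:
        raise DataError("cannot evaluate an empty prediction set")
    if len(y) != len(p):
        raise DataError(f"length mismatch: {len(y)} labels vs {len(p)} predictions")
    pos = y == positive
    pred_pos = p == positive
    tp = int(np.sum(pos & pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    acc = (tp + tn) / len(y)
    sn = tp / (tp + fn) if tp + fn else 0.0
    sp = tn / (tn + fp) if tn + fp else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom else 0.0
    return EvalReport(tp=tp, tn=tn, fp=fp, fn=fn, acc=acc, mcc=float(mcc),
                      sn=sn, sp=sp)


def roc_auc(labels, scores, positive=1):
    """ROC points (FPR, TPR) over all score thresholds, and the AUC.

    AUC equals the Mann-Whitney statistic: the probability that a random
    positive scores above a random negative, ties counting one half.
    """
    y = (np.asarray(labels) == positive).astype(int)
    s = np.asarray(scores, dtype=float)
    if y.min() == y.max():
        raise DataError("ROC requires both classes present")
    fpr, tpr, _ = roc_curve(y, s)
    auc = float(roc_auc_score(y, s))
    return list(zip(fpr.tolist(), tpr.tolist())), auc


def evaluate_predictions(labels, scores, threshold: float = 0.5,
                         positive=1) -> EvalReport:
    """Full report: threshold the scores for the confusion part, sweep for ROC."""
    report = confusion_metrics(
        labels, np.where(np.asarray(scores) >= threshold, positive, -999),
        positive=positive,
    )
    report.roc_points, report.auc = roc_auc(labels, scores, positive=positive)
    return report


def target_jackknife(features, labels, origins, trainer,
                     threshold: float = 0.5, positive=1,
                     progress: bool = False) -> EvalReport:
    """Leave-one-real-sample-out cross-validation.

    Parameters
    ----------
    features, labels, origins
        Aligned arrays/Series; origins entries are "real" or "synthetic".
    trainer
        Callable (X_train, y_train) -> fitted model with a
        ``predict_proba(X) -> positive-class score`` method.

    Every real sample is held out exactly once (n_real rounds); synthetic
    samples are never held out.  The pooled scores feed one confusion matrix
    and one ROC curve.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    o = np.asarray(origins)
    real_idx = np.flatnonzero(o == "real")
    if len(real_idx) == 0:
        raise DataError("target-jackknife needs at least one real sample")
    scores = np.empty(len(real_idx))
    for round_no, i in enumerate(real_idx):
        mask = np.ones(len(X), dtype=bool)
        mask[i] = False
        model = trainer(X[mask], y[mask])
        scores[round_no] = float(np.asarray(model.predict_proba(X[i : i + 1]))[0])
        if progress and (round_no + 1) % 50 == 0:
            print(f"  jackknife round {round_no + 1}/{len(real_idx)}", flush=True)
    report = evaluate_predictions(y[real_idx], scores, threshold=threshold,
                                  positive=positive)
    report.n_rounds = len(real_idx)
    return report


def _chrom_key(name: str) -> str:
    n = str(name)
    return n[3:] if n.lower().startswith("chr") else n


def chromosome_holdout_split(dataset):
    """Route odd-listed chromosomes to train, even-listed to test.

    ``dataset`` is a ``LabeledDataset`` whose records carry chromosome
    names.  Returns (train, test, excluded) where excluded lists records on
    chromosomes outside both lists (e.g. X, Y, MT).
    """
    from .dataset import LabeledDataset  # local import to avoid a cycle

    train, test, excluded = [], [], []
    for rec in dataset:
        if rec.chromosome is None:
            raise DataError(
                f"record {rec.identifier} has no chromosome; holdout "
                "validation needs genomic coordinates"
            )
        key = _chrom_key(rec.chromosome)
        if key in TRAIN_CHROMS:
            train.append(rec)
        elif key in TEST_CHROMS:
            test.append(rec)
        else:
            excluded.append(rec)
    return LabeledDataset(train), LabeledDataset(test), excluded
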