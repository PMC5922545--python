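"""Classifier comparison harness: F1, PR curves, AP/mAP, repeated runs.

Plant superpixels are a minority against background, so precision/recall
of the positive (plant) class — not accuracy — is the reporting currency.
AP uses the positive-rank-average estimator: the mean of precision taken
at each true positive's rank in the score ordering (a trapezoidal
alternative is available behind a flag).  Ties in scores are grouped at a
single threshold.  Repeated randomized runs (fresh folds each repeat)
yield distributions of F1 and AP per algorithm; mAP is the arithmetic
mean of AP over the repeats of a split.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from phenotray.training import assemble, kfold_splits, train


def confusion(pred: np.ndarray, truth: np.ndarray
              ) -> tuple[int, int, int, int]:
    """(TP, FP, FN, TN) counts with plant (1) as the positive class."""
    pred = np.asarray(pred).ravel()
    truth = np.asarray(truth).ravel()
    if pred.shape != truth.shape:
        raise ValueError("prediction/truth length mismatch")
    for arr in (pred, truth):
        if not np.all(np.isin(arr, [0, 1])):
            raise ValueError("labels must be binary (0/1)")
    tp = int(np.sum((pred == 1) & (truth == 1)))
    fp = int(np.sum((pred == 1) & (truth == 0)))
    fn = int(np.sum((pred == 0) & (truth == 1)))
    tn = int(np.sum((pred == 0) & (truth == 0)))
    return tp, fp, fn, tn


def prf1(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall, F1; any zero denominator yields 0 by convention."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be >= 0")
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def pr_curve(scores: np.ndarray, truth: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """(recall, precision) points from sweeping the threshold downward.

    One point per unique score value (ties grouped), predicted-positive =
    score >= threshold.  Recall is non-decreasing along the sweep.
    Requires at least one positive label.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth).ravel()
    if scores.shape != truth.shape:
        raise ValueError("score/truth length mismatch")
    n_pos = int(np.sum(truth == 1))
    if n_pos == 0:
        raise ValueError("PR curve undefined without positive labels")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    t = truth[order]
    tp_cum = np.cumsum(t == 1)
    n_pred = np.arange(1, len(s) + 1)
    # group ties: keep the last index of each run of equal scores
    last_of_tie = np.nonzero(np.r_[s[1:] != s[:-1], True])[0]
    recall = tp_cum[last_of_tie] / n_pos
    precision = tp_cum[last_of_tie] / n_pred[last_of_tie]
    return recall.astype(float), precision.astype(float)


def average_precision(scores: np.ndarray, truth: np.ndarray,
                      method: str = "rank") -> float:
    """AP of a ranking: positive-rank average (default) or trapezoidal.

    ``rank``: mean over true positives of precision at that positive's
    rank, with tied scores grouped (each positive in a tie group takes the
    group-end precision).  ``trapezoid``: area under the (recall,
    precision) curve by the trapezoidal rule from recall 0.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    truth = np.asarray(truth).ravel()
    recall, precision = pr_curve(scores, truth)  # validates inputs
    if method == "trapezoid":
        r = np.r_[0.0, recall]
        p = np.r_[precision[0], precision]
        return float(np.trapezoid(p, r))
    if method != "rank":
        raise ValueError("method must be 'rank' or 'trapezoid'")
    n_pos = int(np.sum(truth == 1))
    # positives in a tie group contribute the group's precision, weighted
    # by how many positives the group added
    d_tp = np.diff(np.r_[0.0, recall * n_pos])
    return float(np.sum(precision * d_tp) / n_pos)


def mean_ap(aps: list[float]) -> float:
    """Arithmetic mean of AP over repeated runs."""
    if len(aps) == 0:
        raise ValueError("need at least one AP value")
    return float(np.mean(aps))


@dataclass
class SplitScores:
    """Per-repeat metrics for one algorithm on one split."""

    f1: list[float] = field(default_factory=list)
    precision: list[float] = field(default_factory=list)
    recall: list[float] = field(default_factory=list)
    ap: list[float] = field(default_factory=list)

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.f1)) if self.f1 else float("nan")

    @property
    def map(self) -> float:
        return mean_ap(self.ap) if self.ap else float("nan")


@dataclass
class EvalReport:
    """Comparison results for one algorithm across repeated runs."""

    algorithm: str
    validation: SplitScores = field(default_factory=SplitScores)
    test: SplitScores = field(default_factory=SplitScores)
    pr_curves: dict = field(default_factory=dict)   # split -> (recall, prec)
    failures: list[str] = field(default_factory=list)
    seeds: list[int] = field(default_factory=list)
    # training wall-times are recorded for reference only, never asserted:
    # they are hardware-dependent and carry no scientific content here
    train_seconds: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        def _opt(x):  # empty splits serialize as null, not NaN
            return None if np.isnan(x) else x

        return {
            "algorithm": self.algorithm,
            "validation": {"f1": self.validation.f1,
                           "ap": self.validation.ap,
                           "mean_f1": _opt(self.validation.mean_f1),
                           "mAP": _opt(self.validation.map)},
            "test": {"f1": self.test.f1, "ap": self.test.ap,
                     "mean_f1": _opt(self.test.mean_f1),
                     "mAP": _opt(self.test.map)},
            "n_failures": len(self.failures),
            "seeds": self.seeds,
            "train_seconds": self.train_seconds,
        }


def _eval_split(model, X, y) -> tuple[float, float, float, float,
                                      np.ndarray, np.ndarray]:
    pred = model.predict(X)
    scores = model.predict_scores(X)
    tp, fp, fn, _ = confusion(pred, y)
    p, r, f1 = prf1(tp, fp, fn)
    ap = average_precision(scores, y)
    rec, prec = pr_curve(scores, y)
    return p, r, f1, ap, rec, prec


def compare_algorithms(train_pairs: list, test_pairs: list,
                       algorithms: tuple[str, ...] = ("rf", "svm", "mlp"),
                       k: int = 5, n_repeats: int = 10, seed: int = 0,
                       n_superpixels: int = 700,
                       hyperparams: dict | None = None
                       ) -> dict[str, EvalReport]:
    """Repeated cross-validated comparison with a distribution-shifted test.

    Each repeat reshuffles the image-grouped folds, trains every algorithm
    on the first fold's training side, and evaluates on that fold's
    validation images and on the held-out ``test_pairs`` (typically drawn
    from a shifted color distribution).  A failed run is recorded on the
    report and skipped, never fatal.  Micro-averaged (pooled-count) F1.
    """
    if not algorithms:
        raise ValueError("need at least one algorithm")
    hyperparams = hyperparams or {}
    data = assemble(train_pairs, n_target=n_superpixels)
    test = assemble(test_pairs, n_target=n_superpixels)
    reports = {a: EvalReport(algorithm=a) for a in algorithms}
    for rep in range(n_repeats):
        rep_seed = (seed + 104729 * rep) & 0x7FFFFFFF
        tr, va = kfold_splits(data, k=k, seed=rep_seed)[rep % k]
        for algo in algorithms:
            report = reports[algo]
            try:
                t0 = time.perf_counter()
                model = train(data, algorithm=algo,
                              hyperparams=hyperparams.get(algo),
                              seed=rep_seed, indices=tr)
                report.train_seconds.append(time.perf_counter() - t0)
                p, r, f1, ap, rec, prec = _eval_split(
                    model, data.X[va], data.y[va])
                report.validation.precision.append(p)
                report.validation.recall.append(r)
                report.validation.f1.append(f1)
                report.validation.ap.append(ap)
                report.pr_curves["validation"] = (rec, prec)
                p, r, f1, ap, rec, prec = _eval_split(model, test.X, test.y)
                report.test.precision.append(p)
                report.test.recall.append(r)
                report.test.f1.append(f1)
                report.test.ap.append(ap)
                report.pr_curves["test"] = (rec, prec)
                report.seeds.append(rep_seed)
            except Exception as err:  # record, continue with other runs
                report.failures.append(f"repeat {rep}: {err}")
    return reports
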