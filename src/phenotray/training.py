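"""Superpixel-level training data and plant/background classifiers.

Ground-truth binary masks are projected onto superpixels by majority vote
(a superpixel is plant iff more than half of its pixels are foreground;
an exact tie counts as background).  Features and labels pooled over many
pot images form a :class:`LabeledFeatureSet`; cross-validation folds are
grouped by source image so no image's superpixels leak across a split.

Three classifier families are supported through one sklearn-style
estimator, :class:`SuperpixelClassifier`:

rf
    random forest, 100 trees, entropy split criterion.
svm
    support vector machine, RBF kernel, library defaults.
mlp
    multi-layer perceptron, two hidden layers of 256 sigmoid units, Adam
    at learning rate 0.001; default epoch budget 200 (configurable).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from phenotray.colorfeat import SuperpixelMap, extract

ALGORITHMS = ("rf", "svm", "mlp")
# preference order for tie-breaking in model selection
_ALGO_RANK = {"rf": 0, "mlp": 1, "svm": 2}


def superpixel_labels(sp: SuperpixelMap, truth: np.ndarray) -> np.ndarray:
    """Project a binary ground-truth mask onto superpixels (majority rule).

    Returns an (N,) int array: 1 where strictly more than half of the
    superpixel's pixels are foreground, else 0 (ties -> background).
    """
    truth = np.asarray(truth)
    if truth.shape != sp.labels.shape:
        raise ValueError("mask shape does not match the superpixel map")
    uniq = np.unique(truth)
    if not np.all(np.isin(uniq, [0, 1])):
        raise ValueError("ground-truth mask must be binary (0/1)")
    flat = sp.labels.ravel()
    fg = np.bincount(flat, weights=truth.ravel().astype(float), minlength=sp.n)
    total = np.bincount(flat, minlength=sp.n).astype(float)
    return (fg * 2 > total).astype(int)


@dataclass
class LabeledFeatureSet:
    """Pooled superpixel features and labels with per-row provenance."""

    X: np.ndarray                 # (M, 3) mean-Lab rows
    y: np.ndarray                 # (M,) labels in {0, 1}
    image_ids: np.ndarray         # (M,) source image index per row
    sp_ids: np.ndarray            # (M,) superpixel id within its image

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if not (len(self.X) == len(self.y) == len(self.image_ids)
                == len(self.sp_ids)):
            raise ValueError("feature/label/provenance lengths differ")
        if self.X.ndim != 2 or self.X.shape[1] != 3:
            raise ValueError("X must be (M, 3)")
        if not np.all(np.isin(np.unique(self.y), [0, 1])):
            raise ValueError("labels must be binary")

    @property
    def n_images(self) -> int:
        return len(np.unique(self.image_ids))

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.X).tobytes())
        h.update(np.ascontiguousarray(self.y).tobytes())
        return h.hexdigest()[:16]


def assemble(pairs: list[tuple[np.ndarray, np.ndarray]],
             n_target: int = 700,
             compactness: float = 0.5) -> LabeledFeatureSet:
    """Extract and pool superpixel features/labels over (image, mask) pairs."""
    if len(pairs) == 0:
        raise ValueError("need at least one (image, mask) pair")
    X, y, img_ids, sp_ids = [], [], [], []
    for i, (img, mask) in enumerate(pairs):
        if np.asarray(mask).shape != np.asarray(img).shape[:2]:
            raise ValueError(f"image {i}: mask shape does not match image")
        sp = extract(img, n_target=n_target, compactness=compactness)
        labels = superpixel_labels(sp, (np.asarray(mask) > 0).astype(int))
        X.append(sp.features)
        y.append(labels)
        img_ids.append(np.full(sp.n, i))
        sp_ids.append(np.arange(sp.n))
    return LabeledFeatureSet(X=np.vstack(X), y=np.concatenate(y),
                             image_ids=np.concatenate(img_ids),
                             sp_ids=np.concatenate(sp_ids))


def kfold_splits(data: LabeledFeatureSet, k: int = 5,
                 seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Image-grouped k-fold splits: whole images validate exactly once.

    Returns k (train_idx, val_idx) row-index pairs.  Images are shuffled
    deterministically by ``seed`` and chunked into k folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    images = np.unique(data.image_ids)
    if k > len(images):
        raise ValueError(f"k={k} exceeds the number of images ({len(images)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(images)
    folds = np.array_split(perm, k)
    out = []
    for fold in folds:
        val = np.isin(data.image_ids, fold)
        out.append((np.nonzero(~val)[0], np.nonzero(val)[0]))
    return out


class SuperpixelClassifier(BaseEstimator, ClassifierMixin):
    """Binary plant/background classifier over mean-Lab superpixel features.

    A sklearn-compatible wrapper selecting one of three families by
    ``algorithm``; hyperparameters not listed here ride on the library
    defaults.  ``predict`` returns {0, 1}; ``predict_scores`` returns a
    continuous per-row score (probability of the plant class, or a
    decision-function value for SVM) for precision-recall analysis.

    Parameters
    ----------
    algorithm : {'rf', 'svm', 'mlp'}
    n_estimators : int
        RF tree count (default 100).
    criterion : str
        RF split criterion (default 'entropy').
    hidden_layer_sizes : tuple
        MLP architecture (default (256, 256)).
    epochs : int
        MLP iteration budget (default 200).
    learning_rate : float
        MLP Adam step size (default 0.001).
    random_state : int
    """

    def __init__(self, algorithm: str = "rf", n_estimators: int = 100,
                 criterion: str = "entropy",
                 hidden_layer_sizes: tuple = (256, 256), epochs: int = 200,
                 learning_rate: float = 0.001, random_state: int = 0):
        self.algorithm = algorithm
        self.n_estimators = n_estimators
        self.criterion = criterion
        self.hidden_layer_sizes = hidden_layer_sizes
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.random_state = random_state

    def _build(self):
        if self.algorithm == "rf":
            return RandomForestClassifier(
                n_estimators=self.n_estimators, criterion=self.criterion,
                random_state=self.random_state, n_jobs=1)
        if self.algorithm == "svm":
            return SVC(kernel="rbf", random_state=self.random_state)
        if self.algorithm == "mlp":
            return MLPClassifier(
                hidden_layer_sizes=self.hidden_layer_sizes,
                activation="logistic", solver="adam",
                learning_rate_init=self.learning_rate,
                max_iter=self.epochs, random_state=self.random_state)
        raise ValueError(f"unknown algorithm {self.algorithm!r}; "
                         f"choose from {ALGORITHMS}")

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (M, 3) mean-Lab features")
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training data contains a single class; both "
                             "plant and background examples are required")
        self.model_ = self._build()
        import warnings
        with warnings.catch_warnings():
            # the MLP's epoch budget is a deliberate cap, not a failure
            warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
            self.model_.fit(X, y)
        self.classes_ = self.model_.classes_
        self.n_features_in_ = X.shape[1]
        self.n_samples_ = len(y)
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (M, 3) mean-Lab features")
        return self.model_.predict(X).astype(int)

    def predict_scores(self, X) -> np.ndarray:
        """Continuous plant-class score per row (for PR curves)."""
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("X must be (M, 3) mean-Lab features")
        if hasattr(self.model_, "predict_proba"):
            pos = int(np.nonzero(self.model_.classes_ == 1)[0][0])
            return self.model_.predict_proba(X)[:, pos]
        return self.model_.decision_function(X)

    def save(self, path: str | Path, metadata: dict | None = None) -> Path:
        """Serialize to a joblib file plus a JSON sidecar of metadata."""
        path = Path(path)
        joblib.dump(self, path)
        side = {"format_version": 1, "algorithm": self.algorithm,
                "params": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in self.get_params().items()},
                "n_samples": getattr(self, "n_samples_", None)}
        side.update(metadata or {})
        path.with_suffix(path.suffix + ".json").write_text(
            json.dumps(side, indent=2))
        return path

    @staticmethod
    def load(path: str | Path) -> "SuperpixelClassifier":
        return joblib.load(path)


def train(data: LabeledFeatureSet, algorithm: str = "rf",
          hyperparams: dict | None = None, seed: int = 0,
          indices: np.ndarray | None = None) -> SuperpixelClassifier:
    """Fit a :class:`SuperpixelClassifier` on (a subset of) a feature set."""
    model = SuperpixelClassifier(algorithm=algorithm, random_state=seed,
                                 **(hyperparams or {}))
    if indices is None:
        return model.fit(data.X, data.y)
    return model.fit(data.X[indices], data.y[indices])


@dataclass
class CVCandidate:
    """One algorithm/hyperparameter combination with its per-fold scores."""

    algorithm: str
    hyperparams: dict = field(default_factory=dict)
    fold_f1: list[float] = field(default_factory=list)
    model: SuperpixelClassifier | None = None

    @property
    def mean_f1(self) -> float:
        if not self.fold_f1:
            raise ValueError("candidate has no fold results")
        return float(np.mean(self.fold_f1))


def select_model(candidates: list[CVCandidate]) -> CVCandidate:
    """Pick the candidate with the highest mean validation F1.

    Ties break toward fewer explicit hyperparameters, then by algorithm
    preference rf > mlp > svm.
    """
    if not candidates:
        raise ValueError("no candidates to select from")
    return min(candidates,
               key=lambda c: (-c.mean_f1, len(c.hyperparams),
                              _ALGO_RANK.get(c.algorithm, 99)))


def cross_validate(data: LabeledFeatureSet, algorithm: str, k: int = 5,
                   seed: int = 0,
                   hyperparams: dict | None = None) -> CVCandidate:
    """Image-grouped k-fold CV; returns the candidate with per-fold F1."""
    from phenotray.evaluation import confusion, prf1

    cand = CVCandidate(algorithm=algorithm, hyperparams=hyperparams or {})
    for fold, (tr, va) in enumerate(kfold_splits(data, k=k, seed=seed)):
        model = train(data, algorithm=algorithm, hyperparams=hyperparams,
                      seed=seed + fold, indices=tr)
        tp, fp, fn, _ = confusion(model.predict(data.X[va]), data.y[va])
        cand.fold_f1.append(prf1(tp, fp, fn)[2])
        cand.model = model  # last fold's model; refit on all data if needed
    return cand
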