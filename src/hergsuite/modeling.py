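"""Training, validation and evaluation of the three QSAR tasks.

Five learner families are exposed per task: random forest, k-nearest
neighbors, support vector machine and two gradient-boosting variants
(``gbt_light`` — histogram-based, ``gbt_extreme`` — classic stagewise
boosting).  Models are trained on binary fingerprint matrices, validated
with stratified 5-fold cross-validation, evaluated with the standard
confusion-matrix / regression metrics, and challenged with Y-randomization
(label scrambling) to rule out chance correlation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from scipy.stats import norm
from sklearn.ensemble import (
    GradientBoostingClassifier,
    GradientBoostingRegressor,
    HistGradientBoostingClassifier,
    HistGradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import Matern
from sklearn.metrics import (
    f1_score,
    matthews_corrcoef,
    mean_absolute_error,
    mean_squared_error,
    precision_score,
    r2_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor
from sklearn.svm import SVC, SVR

from .featurize import FingerprintMatrix, FingerprintSpec

ALGORITHMS = ("random_forest", "knn", "svm", "gbt_light", "gbt_extreme")
TASKS = ("binary", "multiclass", "regression")


@dataclass(frozen=True)
class ModelSpec:
    """Everything needed to reproduce one trained model."""

    task: str
    algorithm: str
    fingerprint: FingerprintSpec = field(default_factory=FingerprintSpec)
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 42

    def __post_init__(self):
        if self.task not in TASKS:
            raise ValueError(f"unknown task {self.task!r}")
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    def as_dict(self) -> dict:
        return {
            "task": self.task,
            "algorithm": self.algorithm,
            "fingerprint": self.fingerprint.as_dict(),
            "hyperparameters": dict(self.hyperparameters),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            task=d["task"],
            algorithm=d["algorithm"],
            fingerprint=FingerprintSpec(**d["fingerprint"]),
            hyperparameters=dict(d.get("hyperparameters", {})),
            seed=d.get("seed", 42),
        )


def _estimator(spec: ModelSpec):
    hp = dict(spec.hyperparameters)
    seed = spec.seed
    clf = spec.task in ("binary", "multiclass")
    if spec.algorithm == "random_forest":
        cls = RandomForestClassifier if clf else RandomForestRegressor
        hp.setdefault("n_estimators", 100)
        return cls(random_state=seed, **hp)
    if spec.algorithm == "knn":
        cls = KNeighborsClassifier if clf else KNeighborsRegressor
        hp.setdefault("n_neighbors", 5)
        return cls(**hp)
    if spec.algorithm == "svm":
        if clf:
            hp.setdefault("kernel", "rbf")
            return SVC(probability=True, random_state=seed, **hp)
        hp.setdefault("kernel", "rbf")
        return SVR(**hp)  # epsilon-SVR, the standard regression counterpart
    if spec.algorithm == "gbt_light":
        cls = HistGradientBoostingClassifier if clf else HistGradientBoostingRegressor
        hp.setdefault("max_iter", 100)
        return cls(random_state=seed, **hp)
    if spec.algorithm == "gbt_extreme":
        cls = GradientBoostingClassifier if clf else GradientBoostingRegressor
        hp.setdefault("n_estimators", 100)
        return cls(random_state=seed, **hp)
    raise ValueError(spec.algorithm)


# ---------------------------------------------------------------------------
# splitting


def stratified_split(y, test_fraction: float = 0.2, seed: int = 42,
                     task: str = "binary", n_bins: int = 5):
    """Stratified shuffle split into train/test index arrays.

    Classification stratifies on the labels; regression stratifies on
    quantile bins of the continuous target (``n_bins`` bins).  Deterministic
    for a fixed seed.
    """
    y = np.asarray(y)
    n = len(y)
    if task == "regression":
        if n < 10:
            raise ValueError("regression split needs at least 10 compounds")
        order = np.argsort(y, kind="stable")
        strata = np.empty(n, dtype=int)
        strata[order] = np.arange(n) * n_bins // n
    else:
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least two classes to stratify")
        if counts.min() < 2:
            raise ValueError("a class with a single member cannot be stratified")
        strata = y
    train_idx, test_idx = train_test_split(
        np.arange(n), test_size=test_fraction, random_state=seed, stratify=strata
    )
    return np.sort(train_idx), np.sort(test_idx)


# ---------------------------------------------------------------------------
# metrics


@dataclass
class MetricsReport:
    """Classification and/or regression metrics for one evaluation."""

    metrics: dict = field(default_factory=dict)
    stds: dict = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.metrics[key]

    def get(self, key, default=None):
        return self.metrics.get(key, default)

    def as_dict(self) -> dict:
        out = dict(self.metrics)
        for k, v in self.stds.items():
            out[f"{k}_sd"] = v
        return out


def _specificity(y_true, y_pred, positive=None) -> float:
    """Specificity TN / (TN + FP); macro one-vs-rest unless a positive
    class is given (binary)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    classes = [positive] if positive is not None else list(np.unique(y_true))
    vals = []
    for c in classes:
        tn = np.sum((y_true != c) & (y_pred != c))
        fp = np.sum((y_true != c) & (y_pred == c))
        vals.append(tn / (tn + fp) if tn + fp else 0.0)
    return float(np.mean(vals))


def evaluate_classification(y_true, y_pred, scores=None) -> MetricsReport:
    """Confusion-matrix metrics: BACC, precision, F1, MCC, Se, Sp (+AUC).

    Binary: the positive class is "blocker" when present, otherwise the
    last label in sorted order.  Multiclass metrics are macro-averaged
    one-vs-rest; BACC is the mean per-class recall.  AUC needs ``scores``
    (probability matrix or positive-class scores) and is omitted otherwise.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    classes = np.unique(np.concatenate([y_true, y_pred]))
    binary = len(classes) <= 2
    if binary:
        pos = "blocker" if "blocker" in classes else classes[-1]
        se = recall_score(y_true, y_pred, pos_label=pos, zero_division=0)
        precision = precision_score(y_true, y_pred, pos_label=pos, zero_division=0)
        f1 = f1_score(y_true, y_pred, pos_label=pos, zero_division=0)
        sp = _specificity(y_true, y_pred, positive=pos)
    else:
        se = recall_score(y_true, y_pred, average="macro", zero_division=0)
        precision = precision_score(y_true, y_pred, average="macro", zero_division=0)
        f1 = f1_score(y_true, y_pred, average="macro", zero_division=0)
        sp = _specificity(y_true, y_pred)
    # BACC as mean per-class recall == (Se + Sp) / 2 in the binary case
    recalls = [
        np.mean(y_pred[y_true == c] == c) for c in np.unique(y_true)
    ]
    bacc = float(np.mean(recalls))
    metrics = {
        "bacc": bacc,
        "precision": float(precision),
        "f1": float(f1),
        "mcc": float(matthews_corrcoef(y_true, y_pred)),
        "se": float(se),
        "sp": float(sp),
    }
    if scores is not None:
        scores = np.asarray(scores)
        try:
            if binary:
                if scores.ndim == 2:
                    # probability columns follow sorted class order (the
                    # sklearn classes_ convention)
                    pos_idx = int(np.searchsorted(np.unique(y_true), pos))
                    s = scores[:, pos_idx]
                else:
                    s = scores
                metrics["auc"] = float(roc_auc_score(y_true == pos, s))
            else:
                metrics["auc"] = float(
                    roc_auc_score(y_true, scores, multi_class="ovr", average="macro")
                )
        except ValueError:
            pass  # degenerate truth; AUC undefined
    return MetricsReport(metrics=metrics)


def evaluate_regression(y_true, y_pred) -> MetricsReport:
    """R^2, MSE, MAE and RMSE."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    if len(y_true) < 2:
        raise ValueError("need at least two points")
    if np.ptp(y_true) == 0:
        raise ValueError("constant truth: R^2 undefined")
    mse = float(mean_squared_error(y_true, y_pred))
    return MetricsReport(
        metrics={
            "r2": float(r2_score(y_true, y_pred)),
            "mse": mse,
            "mae": float(mean_absolute_error(y_true, y_pred)),
            "rmse": float(np.sqrt(mse)),
        }
    )


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainedModelBundle:
    """A fitted model plus everything needed to reuse it."""

    spec: ModelSpec
    model: object
    training_ids: list[str]
    classes: list | None = None
    ad_model: object = None
    metrics: dict = field(default_factory=dict)

    def predict(self, X) -> np.ndarray:
        return self.model.predict(np.asarray(X, dtype=float))

    def predict_scores(self, X) -> np.ndarray | None:
        X = np.asarray(X, dtype=float)
        if hasattr(self.model, "predict_proba"):
            return self.model.predict_proba(X)
        if hasattr(self.model, "decision_function"):
            return self.model.decision_function(X)
        return None

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "spec.json", "w") as fh:
            json.dump(
                {
                    "spec": self.spec.as_dict(),
                    "training_ids": self.training_ids,
                    "classes": self.classes,
                    "metrics": self.metrics,
                },
                fh,
                indent=2,
            )
        joblib.dump(self.model, directory / "model.joblib")
        if self.ad_model is not None:
            joblib.dump(self.ad_model, directory / "ad_model.joblib")

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModelBundle":
        directory = Path(directory)
        with open(directory / "spec.json") as fh:
            meta = json.load(fh)
        ad_path = directory / "ad_model.joblib"
        return cls(
            spec=ModelSpec.from_dict(meta["spec"]),
            model=joblib.load(directory / "model.joblib"),
            training_ids=meta["training_ids"],
            classes=meta.get("classes"),
            ad_model=joblib.load(ad_path) if ad_path.exists() else None,
            metrics=meta.get("metrics", {}),
        )


def train_model(spec: ModelSpec, X, y, ids=None) -> TrainedModelBundle:
    """Fit one learner on a fingerprint matrix.

    Deterministic given ``spec.seed``.  Degenerate targets (a single class,
    or zero variance for regression) raise instead of silently fitting a
    trivial model.
    """
    if isinstance(X, FingerprintMatrix):
        ids = ids if ids is not None else X.ids
        X = X.bits
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != len(y):
        raise ValueError("X row count must equal label count")
    if spec.task == "regression":
        if np.ptp(y.astype(float)) == 0:
            raise ValueError("degenerate regression target (zero variance)")
    elif len(np.unique(y)) < 2:
        raise ValueError("degenerate classification target (single class)")
    est = _estimator(spec).fit(X, y)
    return TrainedModelBundle(
        spec=spec,
        model=est,
        training_ids=list(ids) if ids is not None else [str(i) for i in range(len(y))],
        classes=list(est.classes_) if hasattr(est, "classes_") else None,
    )


def cross_validate(spec: ModelSpec, X, y, folds: int = 5,
                   seed: int | None = None) -> MetricsReport:
    """K-fold cross-validation; returns per-metric mean and SD.

    Folds are stratified for classification.  Every compound appears in
    exactly one validation fold.
    """
    if isinstance(X, FingerprintMatrix):
        X = X.bits
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if folds < 2:
        raise ValueError("need at least 2 folds")
    seed = spec.seed if seed is None else seed
    clf = spec.task in ("binary", "multiclass")
    if clf:
        if folds > np.unique(y, return_counts=True)[1].min():
            raise ValueError("more folds than members of the smallest class")
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split_iter = splitter.split(X, y)
    else:
        rng = np.random.RandomState(seed)
        perm = rng.permutation(len(y))
        split_iter = (
            (np.delete(perm, np.s_[i::folds]), perm[i::folds]) for i in range(folds)
        )
    per_fold: list[MetricsReport] = []
    for train_idx, valid_idx in split_iter:
        bundle = train_model(spec, X[train_idx], y[train_idx])
        pred = bundle.predict(X[valid_idx])
        if clf:
            per_fold.append(
                evaluate_classification(y[valid_idx], pred,
                                        bundle.predict_scores(X[valid_idx]))
            )
        else:
            per_fold.append(evaluate_regression(y[valid_idx], pred))
    keys = sorted(set().union(*(r.metrics for r in per_fold)))
    means, sds = {}, {}
    for k in keys:
        vals = [r.metrics[k] for r in per_fold if k in r.metrics]
        means[k] = float(np.mean(vals))
        sds[k] = float(np.std(vals))
    return MetricsReport(metrics=means, stds=sds)


def y_randomization(spec: ModelSpec, X_train, y_train, X_test, y_test,
                    rounds: int = 20, seed: int | None = None
                    ) -> list[MetricsReport]:
    """Label-scrambling control: retrain on permuted targets.

    Round ``r`` permutes the training labels with seed ``seed + r``,
    retrains, and evaluates on the untouched test split.  A real model must
    clearly outperform the distribution of scrambled scores.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    seed = spec.seed if seed is None else seed
    if isinstance(X_train, FingerprintMatrix):
        X_train = X_train.bits
    if isinstance(X_test, FingerprintMatrix):
        X_test = X_test.bits
    y_train = np.asarray(y_train)
    reports = []
    clf = spec.task in ("binary", "multiclass")
    for r in range(rounds):
        rng = np.random.RandomState(seed + r)
        y_perm = rng.permutation(y_train)
        bundle = train_model(spec, X_train, y_perm)
        pred = bundle.predict(X_test)
        if clf:
            reports.append(evaluate_classification(y_test, pred))
        else:
            reports.append(evaluate_regression(y_test, pred))
    return reports


# ---------------------------------------------------------------------------
# Bayesian hyperparameter tuning

#: editable default search spaces per algorithm; each entry is
#: (kind, low, high) with kind in {"int", "float", "log"} or ("cat", [...]).
DEFAULT_SEARCH_SPACES = {
    "random_forest": {
        "n_estimators": ("int", 50, 400),
        "max_depth": ("int", 3, 30),
        "min_samples_leaf": ("int", 1, 8),
    },
    "knn": {
        "n_neighbors": ("int", 1, 25),
        "weights": ("cat", ["uniform", "distance"]),
    },
    "svm": {
        "C": ("log", 1e-2, 1e3),
        "gamma": ("log", 1e-4, 1.0),
    },
    "gbt_light": {
        "max_iter": ("int", 50, 400),
        "learning_rate": ("log", 1e-2, 0.5),
        "max_leaf_nodes": ("int", 7, 63),
    },
    "gbt_extreme": {
        "n_estimators": ("int", 50, 300),
        "learning_rate": ("log", 1e-2, 0.5),
        "max_depth": ("int", 2, 8),
    },
}


def _sample_point(space: dict, rng: np.random.RandomState) -> dict:
    point = {}
    for name, dim in space.items():
        kind = dim[0]
        if kind == "int":
            point[name] = int(rng.randint(dim[1], dim[2] + 1))
        elif kind == "float":
            point[name] = float(rng.uniform(dim[1], dim[2]))
        elif kind == "log":
            point[name] = float(np.exp(rng.uniform(np.log(dim[1]), np.log(dim[2]))))
        elif kind == "cat":
            point[name] = dim[1][rng.randint(len(dim[1]))]
        else:
            raise ValueError(f"unknown dimension kind {kind!r}")
    return point


def _encode(point: dict, space: dict) -> list[float]:
    enc = []
    for name, dim in space.items():
        kind = dim[0]
        v = point[name]
        if kind == "int":
            enc.append((v - dim[1]) / max(dim[2] - dim[1], 1))
        elif kind == "float":
            enc.append((v - dim[1]) / (dim[2] - dim[1]))
        elif kind == "log":
            enc.append((np.log(v) - np.log(dim[1])) / (np.log(dim[2]) - np.log(dim[1])))
        else:
            enc.append(dim[1].index(v) / max(len(dim[1]) - 1, 1))
    return enc


@dataclass
class Trial:
    hyperparameters: dict
    score: float


def tune_hyperparameters(spec: ModelSpec, X, y, search_space: dict | None = None,
                         budget: int = 10, folds: int = 5,
                         seed: int | None = None,
                         n_initial: int = 5) -> tuple[ModelSpec, list[Trial]]:
    """Sequential model-based (Bayesian) hyperparameter search.

    The objective is the mean cross-validated score (BACC for
    classification, R^2 for regression).  The first ``n_initial`` trials are
    random; later candidates maximize expected improvement under a Gaussian
    process surrogate fitted to the encoded trial history.  Returns the best
    spec and the full trial log.
    """
    space = search_space if search_space is not None else DEFAULT_SEARCH_SPACES[spec.algorithm]
    if not space:
        raise ValueError("empty search space")
    seed = spec.seed if seed is None else seed
    rng = np.random.RandomState(seed)
    objective_key = "bacc" if spec.task in ("binary", "multiclass") else "r2"

    trials: list[Trial] = []

    def evaluate(point: dict) -> float:
        trial_spec = ModelSpec(
            task=spec.task, algorithm=spec.algorithm,
            fingerprint=spec.fingerprint, hyperparameters=point, seed=spec.seed,
        )
        report = cross_validate(trial_spec, X, y, folds=folds, seed=seed)
        return report.metrics[objective_key]

    for _ in range(min(n_initial, budget)):
        point = _sample_point(space, rng)
        trials.append(Trial(point, evaluate(point)))

    while len(trials) < budget:
        Xe = np.array([_encode(t.hyperparameters, space) for t in trials])
        ye = np.array([t.score for t in trials])
        gp = GaussianProcessRegressor(
            kernel=Matern(nu=2.5), alpha=1e-4, normalize_y=True,
            random_state=rng.randint(2**31 - 1),
        ).fit(Xe, ye)
        candidates = [_sample_point(space, rng) for _ in range(256)]
        Xc = np.array([_encode(c, space) for c in candidates])
        mu, sigma = gp.predict(Xc, return_std=True)
        best = ye.max()
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (mu - best) / sigma
            ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
            ei[sigma == 0] = 0.0
        point = candidates[int(np.argmax(ei))]
        trials.append(Trial(point, evaluate(point)))

    best_trial = max(trials, key=lambda t: t.score)
    best_spec = ModelSpec(
        task=spec.task, algorithm=spec.algorithm, fingerprint=spec.fingerprint,
        hyperparameters=best_trial.hyperparameters, seed=spec.seed,
    )
    return best_spec, trials
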