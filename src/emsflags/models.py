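"""The four base learners and their shared training protocol.

Architectures mirror the benchmarked set: a logistic GLM, a single-hidden-
layer feed-forward neural network, naive Bayes (Gaussian, with a tunable
kernel-density variant), and gradient-boosted trees. All are trained the
same way: repeated stratified k-fold cross-validation (default k=5 with 10
repeats) with random-search hyperparameter optimization selected on AUROC.
Fold assignments are fixed before the search so every candidate is compared
on identical folds, and the out-of-fold predictions of the winning
candidate (first repeat) are retained as stacking inputs.

Class imbalance is handled by stratified folds only — no resampling or
class weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import xgboost as xgb
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .matrix import FeatureMatrix
from .metrics import auroc

ARCHITECTURES = ("glm", "nnet", "naive_bayes", "xgb_tree")

#: L2 strength for the GLM: effectively maximum likelihood, but finite so
#: that perfectly separable flag counts still yield a stable fit.
GLM_RIDGE = 1e-8


@dataclass
class ModelSpec:
    """An architecture plus its random-search space.

    ``hyperparameter_space`` maps parameter name -> (low, high) range,
    ("log", low, high) for log-uniform, ("int", low, high) for integer
    uniform, or an explicit list of choices. ``None`` selects the declared
    per-architecture default space.
    """

    architecture: str
    hyperparameter_space: dict | None = None
    fixed_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(
                f"unknown architecture {self.architecture!r}; "
                f"expected one of {ARCHITECTURES}"
            )
        if self.hyperparameter_space is None:
            self.hyperparameter_space = dict(DEFAULT_SPACES[self.architecture])


@dataclass
class CvConfig:
    """Cross-validation and random-search settings."""

    k: int = 5
    repeats: int = 10
    search_n: int = 30
    metric: str = "auroc"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2 or self.repeats < 1 or self.search_n < 1:
            raise ValueError("require k >= 2, repeats >= 1, search_n >= 1")
        if self.metric != "auroc":
            raise ValueError("only AUROC selection is supported")


DEFAULT_SPACES = {
    "glm": {},
    "nnet": {"hidden": ("int", 1, 10), "decay": ("log", 1e-5, 1.0)},
    "naive_bayes": {
        "use_kernel": [False, True],
        "var_smoothing": ("log", 1e-9, 1e-3),
        "adjust": (0.5, 1.5),
    },
    "xgb_tree": {
        "n_estimators": ("int", 50, 300),
        "max_depth": ("int", 2, 8),
        "learning_rate": ("log", 1e-2, 0.5),
        "subsample": (0.5, 1.0),
        "colsample_bytree": (0.5, 1.0),
    },
}


def _sample_params(space: dict, rng) -> dict:
    params = {}
    for name, spec in space.items():
        if isinstance(spec, list):
            params[name] = spec[rng.integers(0, len(spec))]
        elif spec[0] == "int":
            params[name] = int(rng.integers(spec[1], spec[2] + 1))
        elif spec[0] == "log":
            params[name] = float(
                np.exp(rng.uniform(np.log(spec[1]), np.log(spec[2])))
            )
        else:
            params[name] = float(rng.uniform(spec[0], spec[1]))
    return params


def _complexity_key(architecture: str, params: dict):
    """Smaller-model tie-break key, per architecture."""
    if architecture == "nnet":
        return (params["hidden"], -params["decay"])
    if architecture == "naive_bayes":
        return (int(bool(params.get("use_kernel"))),)
    if architecture == "xgb_tree":
        return (params["n_estimators"] * params["max_depth"],)
    return (0,)


class KernelNaiveBayes:
    """Naive Bayes with per-feature Gaussian kernel density estimates.

    Silverman's rule sets the per-class, per-feature bandwidth, scaled by
    ``adjust`` and floored so constant features remain well-defined.
    """

    def __init__(self, adjust: float = 1.0, floor: float = 1e-3):
        self.adjust = adjust
        self.floor = floor

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._data = {}
        self._bandwidth = {}
        self._log_prior = {}
        for c in self.classes_:
            xc = X[y == c]
            self._data[c] = xc
            nc = xc.shape[0]
            sd = xc.std(axis=0, ddof=1) if nc > 1 else np.zeros(X.shape[1])
            h = self.adjust * 1.06 * sd * nc ** (-1 / 5)
            self._bandwidth[c] = np.maximum(h, self.floor)
            self._log_prior[c] = np.log(nc / X.shape[0])
        return self

    def _joint_log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((X.shape[0], len(self.classes_)))
        for j, c in enumerate(self.classes_):
            data = self._data[c]          # (nc, p)
            h = self._bandwidth[c]        # (p,)
            ll = np.full(X.shape[0], self._log_prior[c])
            for p in range(X.shape[1]):
                z = (X[:, p, None] - data[None, :, p]) / h[p]
                dens = np.exp(-0.5 * z * z).mean(axis=1) / (
                    h[p] * np.sqrt(2 * np.pi)
                )
                ll += np.log(np.maximum(dens, 1e-300))
            out[:, j] = ll
        return out

    def predict_proba(self, X):
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        prob = np.exp(jll)
        return prob / prob.sum(axis=1, keepdims=True)


class _NnetPipeline:
    """Standardize-then-MLP wrapper with a stable predict_proba surface."""

    def __init__(self, hidden: int, decay: float, seed: int, max_iter: int = 300):
        self.scaler = StandardScaler()
        self.mlp = MLPClassifier(
            hidden_layer_sizes=(int(hidden),),
            activation="logistic",
            solver="lbfgs",
            alpha=float(decay),
            max_iter=max_iter,
            random_state=int(seed) % (2**31 - 1),
        )

    def fit(self, X, y):
        Xs = self.scaler.fit_transform(X)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.mlp.fit(Xs, y)
        return self

    def predict_proba(self, X):
        return self.mlp.predict_proba(self.scaler.transform(X))


def _build_estimator(architecture: str, params: dict, seed: int):
    if architecture == "glm":
        ridge = params.get("ridge", GLM_RIDGE)
        return LogisticRegression(C=1.0 / ridge, solver="lbfgs", max_iter=2000)
    if architecture == "nnet":
        return _NnetPipeline(params["hidden"], params["decay"], seed=seed)
    if architecture == "naive_bayes":
        if params.get("use_kernel"):
            return KernelNaiveBayes(adjust=params.get("adjust", 1.0))
        return GaussianNB(var_smoothing=params.get("var_smoothing", 1e-9))
    if architecture == "xgb_tree":
        return xgb.XGBClassifier(
            n_estimators=int(params["n_estimators"]),
            max_depth=int(params["max_depth"]),
            learning_rate=float(params["learning_rate"]),
            subsample=float(params["subsample"]),
            colsample_bytree=float(params["colsample_bytree"]),
            random_state=int(seed) % (2**31 - 1),
            n_jobs=1,
            tree_method="hist",
            eval_metric="logloss",
            verbosity=0,
        )
    raise ValueError(architecture)


def _fit_predict(architecture, params, seed, X_train, y_train, X_val):
    est = _build_estimator(architecture, params, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X_train, y_train)
    proba = est.predict_proba(X_val)
    cls = list(getattr(est, "classes_", [0, 1]))
    return est, np.clip(proba[:, cls.index(1)], 0.0, 1.0)


@dataclass
class TrainedModel:
    """A fitted learner plus its CV trace and out-of-fold predictions."""

    spec: ModelSpec
    chosen_hyperparameters: dict
    fit_state: object = field(repr=False)
    cv_trace: list
    oof_predictions: np.ndarray = field(repr=False)
    record_ids: list = field(repr=False)
    column_names: list = field(repr=False)
    fold_scheme: np.ndarray = field(repr=False)
    cv: CvConfig = None
    mean_cv_auc: float = 0.0


def _fold_assignments(labels, cv: CvConfig):
    """Per-repeat fold-id arrays, fixed before the hyperparameter search."""
    rng = np.random.default_rng(cv.seed)
    schemes = []
    for _ in range(cv.repeats):
        skf = StratifiedKFold(
            n_splits=cv.k, shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        fold_id = np.empty(len(labels), dtype=int)
        for f, (_, val_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            fold_id[val_idx] = f
        schemes.append(fold_id)
    return schemes


def train_model(
    features: FeatureMatrix,
    labels,
    spec: ModelSpec,
    cv: CvConfig,
) -> TrainedModel:
    """Random-search CV training; winner refit on all rows.

    The winning candidate maximizes mean CV AUROC (ties go to the smaller
    model by a per-architecture complexity key, then the earlier draw) and
    is refit on the full training matrix. Deterministic for a fixed seed.
    """
    y = np.asarray(labels).astype(int)
    if len(y) != len(features.record_ids):
        raise ValueError("features and labels are misaligned")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if counts.min() < cv.k:
        raise ValueError(
            f"minority class has {counts.min()} rows; needs >= k={cv.k}"
        )
    X = features.values

    rng = np.random.default_rng(cv.seed + 1)
    if spec.hyperparameter_space:
        candidates = [
            _sample_params(spec.hyperparameter_space, rng)
            for _ in range(cv.search_n)
        ]
    else:
        candidates = [{}]
    for c in candidates:
        c.update(spec.fixed_params)

    schemes = _fold_assignments(y, cv)
    fit_seed = int(np.random.default_rng(cv.seed + 2).integers(0, 2**31 - 1))

    cv_trace = []
    oof_by_candidate = []
    for draw, params in enumerate(candidates):
        fold_aucs = []
        oof = np.full(len(y), np.nan)
        for r, fold_id in enumerate(schemes):
            for f in range(cv.k):
                val = fold_id == f
                _, proba = _fit_predict(
                    spec.architecture, params, fit_seed, X[~val], y[~val], X[val]
                )
                fold_aucs.append(auroc(proba, y[val]))
                if r == 0:
                    oof[val] = proba
        cv_trace.append(
            {
                "draw": draw,
                "params": dict(params),
                "mean_auc": float(np.mean(fold_aucs)),
                "sd_auc": float(np.std(fold_aucs, ddof=1)) if len(fold_aucs) > 1 else 0.0,
            }
        )
        oof_by_candidate.append(oof)

    order = sorted(
        range(len(candidates)),
        key=lambda i: (
            -cv_trace[i]["mean_auc"],
            _complexity_key(spec.architecture, candidates[i]),
            i,
        ),
    )
    best = order[0]
    est, _ = _fit_predict(
        spec.architecture, candidates[best], fit_seed, X, y, X[:1]
    )
    return TrainedModel(
        spec=spec,
        chosen_hyperparameters=dict(candidates[best]),
        fit_state=est,
        cv_trace=cv_trace,
        oof_predictions=oof_by_candidate[best],
        record_ids=list(features.record_ids),
        column_names=list(features.column_names),
        fold_scheme=schemes[0].copy(),
        cv=cv,
        mean_cv_auc=cv_trace[best]["mean_auc"],
    )


def predict_proba(model: TrainedModel, features: FeatureMatrix) -> np.ndarray:
    """Positive-class probabilities; columns are aligned by name."""
    missing = [c for c in model.column_names if c not in features.column_names]
    extra = [c for c in features.column_names if c not in model.column_names]
    if missing or extra:
        raise ValueError(
            f"feature columns do not match training columns "
            f"(missing={missing}, unexpected={extra})"
        )
    X = features.select(model.column_names).values
    proba = model.fit_state.predict_proba(X)
    cls = list(getattr(model.fit_state, "classes_", [0, 1]))
    return np.clip(proba[:, cls.index(1)], 0.0, 1.0)


# ---------------------------------------------------------------------------
# JSON serialization of fit states


def _fit_state_payload(model: TrainedModel) -> dict:
    est = model.fit_state
    arch = model.spec.architecture
    if arch == "glm":
        return {
            "coef": est.coef_.tolist(),
            "intercept": est.intercept_.tolist(),
            "classes": est.classes_.tolist(),
        }
    if arch == "nnet":
        return {
            "scaler_mean": est.scaler.mean_.tolist(),
            "scaler_scale": est.scaler.scale_.tolist(),
            "coefs": [w.tolist() for w in est.mlp.coefs_],
            "intercepts": [b.tolist() for b in est.mlp.intercepts_],
            "classes": est.mlp.classes_.tolist(),
        }
    if arch == "naive_bayes":
        if isinstance(est, KernelNaiveBayes):
            return {
                "kernel": True,
                "adjust": est.adjust,
                "floor": est.floor,
                "classes": [int(c) for c in est.classes_],
                "data": {str(int(c)): est._data[c].tolist() for c in est.classes_},
            }
        return {
            "kernel": False,
            "theta": est.theta_.tolist(),
            "var": est.var_.tolist(),
            "class_prior": est.class_prior_.tolist(),
            "classes": est.classes_.tolist(),
        }
    if arch == "xgb_tree":
        raw = est.get_booster().save_raw("json")
        return {"booster_json": bytes(raw).decode("utf-8")}
    raise ValueError(arch)


class _LinearPredictor:
    classes_ = np.array([0, 1])

    def __init__(self, coef, intercept):
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = np.asarray(intercept, dtype=float)

    def predict_proba(self, X):
        z = X @ self.coef.T + self.intercept
        p1 = 1.0 / (1.0 + np.exp(-z[:, 0]))
        return np.column_stack([1 - p1, p1])


class _NnetPredictor:
    classes_ = np.array([0, 1])

    def __init__(self, payload):
        self.mean = np.asarray(payload["scaler_mean"])
        self.scale = np.asarray(payload["scaler_scale"])
        self.coefs = [np.asarray(w) for w in payload["coefs"]]
        self.intercepts = [np.asarray(b) for b in payload["intercepts"]]

    def predict_proba(self, X):
        a = (np.asarray(X, dtype=float) - self.mean) / self.scale
        for w, b in zip(self.coefs, self.intercepts):
            a = a @ w + b
            a = 1.0 / (1.0 + np.exp(-a))  # logistic hidden and output units
        p1 = a[:, 0]
        return np.column_stack([1 - p1, p1])


class _GaussianNbPredictor:
    def __init__(self, payload):
        self.theta = np.asarray(payload["theta"])
        self.var = np.asarray(payload["var"])
        self.prior = np.asarray(payload["class_prior"])
        self.classes_ = np.asarray(payload["classes"])

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        jll = []
        for j in range(len(self.classes_)):
            ll = -0.5 * np.sum(
                np.log(2 * np.pi * self.var[j])
                + (X - self.theta[j]) ** 2 / self.var[j],
                axis=1,
            )
            jll.append(np.log(self.prior[j]) + ll)
        jll = np.column_stack(jll)
        jll -= jll.max(axis=1, keepdims=True)
        prob = np.exp(jll)
        return prob / prob.sum(axis=1, keepdims=True)


class _BoosterPredictor:
    classes_ = np.array([0, 1])

    def __init__(self, booster_json: str):
        self.booster = xgb.Booster()
        self.booster.load_model(bytearray(booster_json, "utf-8"))

    def predict_proba(self, X):
        p1 = self.booster.predict(xgb.DMatrix(np.asarray(X, dtype=float)))
        return np.column_stack([1 - p1, p1])


def _fit_state_from_payload(arch: str, payload: dict):
    if arch == "glm":
        return _LinearPredictor(payload["coef"], payload["intercept"])
    if arch == "nnet":
        return _NnetPredictor(payload)
    if arch == "naive_bayes":
        if payload["kernel"]:
            est = KernelNaiveBayes(adjust=payload["adjust"], floor=payload["floor"])
            X_parts, y_parts = [], []
            for c in payload["classes"]:
                data = np.asarray(payload["data"][str(c)], dtype=float)
                X_parts.append(data)
                y_parts.append(np.full(len(data), c))
            return est.fit(np.vstack(X_parts), np.concatenate(y_parts))
        return _GaussianNbPredictor(payload)
    if arch == "xgb_tree":
        return _BoosterPredictor(payload["booster_json"])
    raise ValueError(arch)


def model_payload(model: TrainedModel) -> dict:
    """JSON-ready payload for a trained model (parameters and fit state)."""
    return {
        "architecture": model.spec.architecture,
        "chosen_hyperparameters": model.chosen_hyperparameters,
        "cv": {
            "k": model.cv.k, "repeats": model.cv.repeats,
            "search_n": model.cv.search_n, "seed": model.cv.seed,
        } if model.cv else None,
        "cv_trace": model.cv_trace,
        "oof_predictions": model.oof_predictions.tolist(),
        "record_ids": model.record_ids,
        "column_names": model.column_names,
        "fold_scheme": model.fold_scheme.tolist(),
        "mean_cv_auc": model.mean_cv_auc,
        "fit_state": _fit_state_payload(model),
    }


def model_from_payload(payload: dict) -> TrainedModel:
    arch = payload["architecture"]
    cv = CvConfig(**payload["cv"]) if payload.get("cv") else None
    return TrainedModel(
        spec=ModelSpec(architecture=arch),
        chosen_hyperparameters=payload["chosen_hyperparameters"],
        fit_state=_fit_state_from_payload(arch, payload["fit_state"]),
        cv_trace=payload["cv_trace"],
        oof_predictions=np.asarray(payload["oof_predictions"], dtype=float),
        record_ids=payload["record_ids"],
        column_names=payload["column_names"],
        fold_scheme=np.asarray(payload["fold_scheme"], dtype=int),
        cv=cv,
        mean_cv_auc=payload["mean_cv_auc"],
    )


def save_model(model: TrainedModel, path) -> None:
    """Serialize a trained model to a JSON file."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_payload(model), fh, sort_keys=True)
        fh.write("\n")


def load_model(path) -> TrainedModel:
    with open(path, encoding="utf-8") as fh:
        return model_from_payload(json.load(fh))
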