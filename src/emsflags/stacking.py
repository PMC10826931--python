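"""Linear stacking of base learners on out-of-fold probabilities.

The combiner is an unpenalized logistic regression of the training labels
on each base model's out-of-fold predicted probabilities (intercept
included, coefficients unconstrained) — the linear stacking convention of
caret-style ensembling. Fitting on out-of-fold rather than in-sample
predictions keeps the combiner honest about each base model's
generalization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LogisticRegression

from .matrix import FeatureMatrix
from .models import model_from_payload, model_payload, predict_proba


@dataclass
class EnsembleModel:
    """Ordered base models plus a logistic combiner over their probabilities."""

    base_models: list
    intercept: float
    coefficients: np.ndarray = field(repr=False)
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.coefficients) != len(self.base_models):
            raise ValueError("one coefficient per base model required")


def fit_ensemble(base_models, labels, seed: int = 0) -> EnsembleModel:
    """Fit the logistic combiner on stacked out-of-fold probabilities.

    All base models must carry out-of-fold predictions over the same
    records with identical first-repeat fold assignments; anything else is
    an error (their predictions would not be comparable).
    """
    base_models = list(base_models)
    if len(base_models) < 1:
        raise ValueError("need at least one base model")
    ref = base_models[0]
    for m in base_models[1:]:
        if m.record_ids != ref.record_ids:
            raise ValueError("base models trained on different record sets")
        if not np.array_equal(m.fold_scheme, ref.fold_scheme):
            raise ValueError("base models trained with different fold schemes")
    y = np.asarray(labels).astype(int)
    if len(y) != len(ref.record_ids):
        raise ValueError("labels misaligned with base-model training records")
    Z = np.column_stack([m.oof_predictions for m in base_models])
    if np.any(np.isnan(Z)):
        raise ValueError("base models lack complete out-of-fold predictions")
    combiner = LogisticRegression(C=1e10, solver="lbfgs", max_iter=5000,
                                  tol=1e-10)
    combiner.fit(Z, y)
    cls = list(combiner.classes_)
    sign = 1.0 if cls.index(1) == 1 else -1.0
    return EnsembleModel(
        base_models=base_models,
        intercept=float(sign * combiner.intercept_[0]),
        coefficients=sign * combiner.coef_[0],
        training_meta={
            "seed": seed,
            "n_train": len(y),
            "fold_scheme_checksum": int(np.sum(ref.fold_scheme * np.arange(len(y)))),
        },
    )


def predict_ensemble(model: EnsembleModel, features: FeatureMatrix) -> np.ndarray:
    """logistic(intercept + sum coef * base probability), per record."""
    Z = np.column_stack(
        [predict_proba(m, features) for m in model.base_models]
    )
    z = model.intercept + Z @ model.coefficients
    return 1.0 / (1.0 + np.exp(-z))


def save_ensemble(model: EnsembleModel, path) -> None:
    """Serialize combiner plus embedded base-model states to one JSON file."""
    payload = {
        "intercept": model.intercept,
        "coefficients": model.coefficients.tolist(),
        "training_meta": model.training_meta,
        "base_models": [model_payload(m) for m in model.base_models],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True)
        fh.write("\n")


def load_ensemble(path) -> EnsembleModel:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return EnsembleModel(
        base_models=[model_from_payload(p) for p in payload["base_models"]],
        intercept=payload["intercept"],
        coefficients=np.asarray(payload["coefficients"]),
        training_meta=payload["training_meta"],
    )
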