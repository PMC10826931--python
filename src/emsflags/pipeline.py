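"""Orchestration: the featurizer x model benchmark grid, model-assisted
annotation batch selection, and the CI-based stopping rule.

``run_benchmark`` evaluates every requested (featurizer, architecture)
cell plus a per-featurizer stacked ensemble on a single shared stratified
train/test split, so feature methods are compared on identical held-out
records. Reports are plain JSON-able dicts and are byte-reproducible from
the configuration alone.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .flags import default_term_sets, featurize_flags
from .matrix import FeatureMatrix
from .metrics import (
    confusion_at_threshold,
    delong_ci,
    roc_points,
    variable_importance,
)
from .models import ARCHITECTURES, CvConfig, ModelSpec, predict_proba, train_model
from .records import Cohort, read_encounters, split_train_test, write_report
from .stacking import EnsembleModel, fit_ensemble, predict_ensemble
from .synth import GeneratorConfig, generate_cohort
from .textfeats import (
    ConceptLexicon,
    EmbeddingTable,
    demo_concept_resources,
    fit_tfidf,
    transform_tfidf,
    vectorize_narrative,
)

logger = logging.getLogger(__name__)

FEATURE_METHODS = ("flags", "tfidf", "concept")


@dataclass
class BenchmarkConfig:
    """Everything needed to reproduce one benchmark run."""

    generator: GeneratorConfig | None = None
    cohort_path: str | None = None
    methods: tuple = FEATURE_METHODS
    architectures: tuple = ARCHITECTURES
    include_ensemble: bool = True
    cv: CvConfig = field(default_factory=CvConfig)
    test_fraction: float = 0.2
    split_seed: int = 0
    threshold: float = 0.5
    tfidf_min_df: int = 1
    lexicon_path: str | None = None
    embeddings_path: str | None = None
    outdir: str | None = None

    def __post_init__(self) -> None:
        self.methods = tuple(self.methods)
        self.architectures = tuple(self.architectures)
        if not self.methods or not self.architectures:
            raise ValueError("need at least one method and one architecture")
        unknown = set(self.methods) - set(FEATURE_METHODS)
        if unknown:
            raise ValueError(f"unknown feature methods {sorted(unknown)}")
        unknown = set(self.architectures) - set(ARCHITECTURES)
        if unknown:
            raise ValueError(f"unknown architectures {sorted(unknown)}")
        if self.generator is None and self.cohort_path is None:
            self.generator = GeneratorConfig()

    @classmethod
    def from_dict(cls, payload: dict) -> "BenchmarkConfig":
        payload = dict(payload)
        if payload.get("generator") is not None and not isinstance(
            payload["generator"], GeneratorConfig
        ):
            gen = dict(payload["generator"])
            if "filler_vocab" in gen:
                gen["filler_vocab"] = tuple(gen["filler_vocab"])
            for key in ("age_range_positive", "age_range_negative"):
                if key in gen:
                    gen[key] = tuple(gen[key])
            payload["generator"] = GeneratorConfig(**gen)
        if payload.get("cv") is not None and not isinstance(
            payload["cv"], CvConfig
        ):
            payload["cv"] = CvConfig(**payload["cv"])
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _load_cohort(config: BenchmarkConfig):
    if config.cohort_path is not None:
        return read_encounters(config.cohort_path), None
    cohort, truth = generate_cohort(config.generator)
    return cohort, truth


def _concept_resources(config: BenchmarkConfig):
    if config.lexicon_path and config.embeddings_path:
        return (
            ConceptLexicon.from_tsv(config.lexicon_path),
            EmbeddingTable.from_tsv(config.embeddings_path),
        )
    return demo_concept_resources()


def _featurize(method, config, train, test):
    if method == "flags":
        return featurize_flags(train), featurize_flags(test)
    if method == "tfidf":
        model = fit_tfidf(train, min_df=config.tfidf_min_df)
        return transform_tfidf(model, train), transform_tfidf(model, test)
    if method == "concept":
        lexicon, embeddings = _concept_resources(config)
        return (
            vectorize_narrative(train, lexicon, embeddings),
            vectorize_narrative(test, lexicon, embeddings),
        )
    raise ValueError(method)


def _roc_to_dict(roc) -> dict:
    return {
        "auc": roc.auc,
        "variance": roc.variance,
        "ci_level": roc.ci_level,
        "ci": list(roc.ci),
        "n_pos": roc.n_pos,
        "n_neg": roc.n_neg,
    }


def run_benchmark(config: BenchmarkConfig) -> dict:
    """Run the full benchmark grid and return a JSON-able report dict.

    One stratified 80/20-style split is shared across all cells. The
    best-performing ensemble (or best cell when ensembles are disabled)
    additionally gets a threshold confusion table, and flag features get a
    per-predictor importance report.
    """
    cohort, _truth = _load_cohort(config)
    labels_all = cohort.labels()
    if np.isnan(labels_all).any():
        raise ValueError("benchmark cohort must be fully labeled")
    train, test = split_train_test(
        cohort, config.test_fraction, seed=config.split_seed,
        stratify_on_label=True,
    )
    y_train = train.labels().astype(int)
    y_test = test.labels().astype(int)

    cells = []
    scores_by_cell = {}
    importance = None
    for method in config.methods:
        try:
            f_train, f_test = _featurize(method, config, train, test)
        except Exception as exc:  # noqa: BLE001 - cell name added for context
            raise RuntimeError(f"featurization failed for {method!r}: {exc}") from exc
        if method == "flags" and importance is None:
            importance = variable_importance(f_train, y_train)
        base_models = []
        for arch in config.architectures:
            cell = f"{method}/{arch}"
            try:
                model = train_model(
                    f_train, y_train, ModelSpec(architecture=arch), config.cv
                )
                scores = predict_proba(model, f_test)
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"benchmark cell {cell} failed: {exc}") from exc
            roc = delong_ci(scores, y_test)
            logger.info("cell %s: AUROC %.4f CI (%.4f, %.4f)",
                        cell, roc.auc, *roc.ci)
            cells.append({"method": method, "model": arch, **_roc_to_dict(roc)})
            scores_by_cell[(method, arch)] = scores
            base_models.append(model)
        if config.include_ensemble:
            cell = f"{method}/ensemble"
            try:
                ensemble = fit_ensemble(base_models, y_train, seed=config.cv.seed)
                scores = predict_ensemble(ensemble, f_test)
            except Exception as exc:  # noqa: BLE001
                raise RuntimeError(f"benchmark cell {cell} failed: {exc}") from exc
            roc = delong_ci(scores, y_test)
            logger.info("cell %s: AUROC %.4f CI (%.4f, %.4f)",
                        cell, roc.auc, *roc.ci)
            ct = confusion_at_threshold(scores, y_test, config.threshold)
            cells.append(
                {
                    "method": method, "model": "ensemble", **_roc_to_dict(roc),
                    "confusion": {
                        "tn": ct.tn, "fp": ct.fp, "fn": ct.fn, "tp": ct.tp,
                        "threshold": ct.threshold,
                        "sensitivity": ct.sensitivity,
                        "specificity": ct.specificity,
                        "ppv": ct.ppv, "npv": ct.npv,
                        "accuracy": ct.accuracy,
                    },
                }
            )
            scores_by_cell[(method, "ensemble")] = scores

    if config.include_ensemble:
        candidates = [c for c in cells if c["model"] == "ensemble"]
    else:
        candidates = cells
    best = max(candidates, key=lambda c: (c["auc"], c["method"]))
    best_scores = scores_by_cell[(best["method"], best["model"])]
    confusion = confusion_at_threshold(best_scores, y_test, config.threshold)

    report = {
        "cells": cells,
        "best_cell": {"method": best["method"], "model": best["model"]},
        "confusion": {
            "tn": confusion.tn, "fp": confusion.fp,
            "fn": confusion.fn, "tp": confusion.tp,
            "threshold": confusion.threshold,
            "sensitivity": confusion.sensitivity,
            "specificity": confusion.specificity,
            "ppv": confusion.ppv, "npv": confusion.npv,
            "accuracy": confusion.accuracy,
        },
        "importance": importance.entries if importance is not None else None,
        "n_train": len(train),
        "n_test": len(test),
        "provenance": {
            "package": "emsflags",
            "version": __version__,
            "config": _config_to_dict(config),
        },
    }
    if config.outdir:
        _export(report, scores_by_cell, y_test, config.outdir)
    return report


def _config_to_dict(config: BenchmarkConfig) -> dict:
    payload = dataclasses.asdict(config)
    if payload.get("generator") is not None:
        payload["generator"]["filler_vocab"] = list(
            payload["generator"]["filler_vocab"]
        )
        for key in ("age_range_positive", "age_range_negative"):
            payload["generator"][key] = list(payload["generator"][key])
    payload["methods"] = list(config.methods)
    payload["architectures"] = list(config.architectures)
    return payload


def _export(report, scores_by_cell, y_test, outdir) -> None:
    import os

    os.makedirs(outdir, exist_ok=True)
    write_report(report, os.path.join(outdir, "benchmark_report.json"))
    for (method, model), scores in scores_by_cell.items():
        fpr, tpr, thr = roc_points(scores, y_test)
        path = os.path.join(outdir, f"roc_{method}_{model}.csv")
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["fpr", "tpr", "threshold"])
            for row in zip(fpr, tpr, thr):
                writer.writerow([repr(float(v)) for v in row])


# ---------------------------------------------------------------------------
# Model-assisted annotation


def select_annotation_batch(
    model,
    pool: Cohort,
    n_per_class: int,
    seed: int,
    featurizer=None,
    threshold: float = 0.5,
):
    """Sample a blinded annotation batch from a scored unlabeled pool.

    The model scores the pool (via ``featurizer``, flag features by
    default); ``n_per_class`` records are sampled uniformly from each
    predicted class at ``threshold``, the combined batch order is
    randomized, and predicted classes are withheld from the emitted
    records. Returns ``(batch, key)`` where ``key`` is the sealed
    record_id -> predicted-class map for later unblinding.
    """
    if featurizer is None:
        featurizer = lambda cohort: featurize_flags(cohort)  # noqa: E731
    features = featurizer(pool)
    if isinstance(model, EnsembleModel):
        scores = predict_ensemble(model, features)
    else:
        scores = predict_proba(model, features)
    pred_pos = [i for i, s in enumerate(scores) if s >= threshold]
    pred_neg = [i for i, s in enumerate(scores) if s < threshold]
    for name, idx in (("positives", pred_pos), ("negatives", pred_neg)):
        if len(idx) < n_per_class:
            raise ValueError(
                f"pool has only {len(idx)} predicted {name}; "
                f"{n_per_class} requested"
            )
    rng = np.random.default_rng(seed)
    take_pos = rng.choice(len(pred_pos), size=n_per_class, replace=False)
    take_neg = rng.choice(len(pred_neg), size=n_per_class, replace=False)
    chosen = [pred_pos[i] for i in take_pos] + [pred_neg[i] for i in take_neg]
    key = {
        pool[i].record_id: ("positive" if scores[i] >= threshold else "negative")
        for i in chosen
    }
    order = rng.permutation(len(chosen))
    records = [
        dataclasses.replace(pool[chosen[i]], label=None, phase=None)
        for i in order
    ]
    batch = Cohort(records, provenance=f"{pool.provenance} [annotation batch]")
    return batch, key


def stopping_rule(reports, lower_bound: float = 0.90):
    """Decide whether any benchmark cell's CI lower endpoint reaches the bound.

    Returns ``(stop, best_cell)``: ``stop`` is true iff some cell across
    the reports has a 95% CI lower endpoint >= ``lower_bound``, and
    ``best_cell`` is the qualifying cell with the highest lower endpoint
    (``None`` when no cell qualifies).
    """
    reports = list(reports)
    if not reports:
        raise ValueError("need at least one report")
    cells = [c for r in reports for c in r.get("cells", [])]
    if not cells:
        raise ValueError("no benchmark cells found in any report")
    qualifying = [c for c in cells if c["ci"][0] >= lower_bound]
    if not qualifying:
        return False, None
    best = max(qualifying, key=lambda c: (c["ci"][0], c["auc"]))
    return True, best
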