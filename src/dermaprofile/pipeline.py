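"""Leakage-free nested cross-validation orchestration.

Outer 5-fold loop; within each outer-training split, k-modes hyperparameters
are selected by subsample-projection stability, the model is refit on the
full training split, and surrogate cluster labels for the held-out fold come
from the training-derived prototypes only. A gradient-boosted classifier is
then trained on genetics + lifestyle inputs (phenotypes are excluded from
the classifier feature set) under three modality configurations, and
fold-aware attributions are computed on the held-out split. A final
full-data refit at the modal k serves descriptive profiling only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import KFold

from .attribution import (
    aggregate_attribution,
    gain_importance,
    permutation_importance,
    shap_contributions,
)
from .cohort import CohortTable
from .kmodes import ClusterModel, HyperParams, fit_kmodes, predict_labels
from .stability import StabilityConfig, StabilityResult, select_hyperparameters

#: modality ablation configurations; phenotypes never enter the classifier
FEATURE_CONFIGS = {
    "genetics": ("genetics",),
    "lifestyle": ("lifestyle",),
    "integrated": ("genetics", "lifestyle"),
}
METRIC_NAMES = ("accuracy", "macro_precision", "macro_recall", "macro_F1")


@dataclass(frozen=True)
class ClassifierConfig:
    """Gradient-boosted tree defaults (multiclass softmax objective)."""

    n_estimators: int = 300
    max_depth: int = 6
    learning_rate: float = 0.1

    def build(self, seed: int) -> xgb.XGBClassifier:
        return xgb.XGBClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            tree_method="hist",
            n_jobs=1,
            random_state=seed,
        )


@dataclass
class FoldRecord:
    fold_index: int
    selected_hp: HyperParams
    train_model: ClusterModel
    train_labels: np.ndarray
    test_labels: np.ndarray
    metrics: dict  # config name -> {metric -> value}
    attributions: dict  # method -> per-feature pd.Series (integrated config)
    selection_table: list[StabilityResult]

    def to_dict(self) -> dict:
        return {
            "fold_index": self.fold_index,
            "selected_hp": self.selected_hp.to_dict(),
            "train_model": self.train_model.to_dict(),
            "train_labels": self.train_labels.tolist(),
            "test_labels": self.test_labels.tolist(),
            "metrics": self.metrics,
            "attributions": {
                m: {k: float(v) for k, v in s.items()}
                for m, s in self.attributions.items()
            },
            "selection_table": [r.to_dict() for r in self.selection_table],
        }


@dataclass
class PipelineSummary:
    metrics: dict  # config -> metric -> {"mean": x, "std": y}
    modal_k: int
    per_fold_k: list[int]
    selection_tables: list[list[dict]]
    std_denominator: str = "population"

    def to_dict(self) -> dict:
        return {
            "metrics": self.metrics,
            "modal_k": self.modal_k,
            "per_fold_k": self.per_fold_k,
            "selection_tables": self.selection_tables,
            "std_denominator": self.std_denominator,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def make_outer_folds(
    n: int, n_folds: int = 5, seed: int = 0
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded shuffle split into near-equal disjoint test folds covering all rows."""
    if n < n_folds:
        raise ValueError(f"n={n} < n_folds={n_folds}")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(train, test) for train, test in kf.split(np.arange(n))]


def evaluate_multiclass(y_true, y_pred) -> dict[str, float]:
    """Accuracy plus macro precision/recall/F1 over classes present in either side.

    Per-class 0/0 ratios are defined as 0; the macro mean is unweighted.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        raise ValueError("empty input")
    labels = np.union1d(y_true, y_pred)
    precision, recall, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=labels, average="macro", zero_division=0
    )
    return {
        "accuracy": float(np.mean(y_true == y_pred)),
        "macro_precision": float(precision),
        "macro_recall": float(recall),
        "macro_F1": float(f1),
    }


def _macro_f1(y_true, y_pred) -> float:
    return evaluate_multiclass(y_true, y_pred)["macro_F1"]


def _child_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def fit_fold_clustering(
    cohort: CohortTable,
    train_idx: np.ndarray,
    grid: Sequence[HyperParams],
    stab_cfg: StabilityConfig,
) -> tuple[HyperParams, ClusterModel, list[StabilityResult]]:
    """Train-only selection + refit on the outer-training split.

    Clustering uses all three modalities. Held-out rows are never read, so
    the result is invariant to any modification of them.
    """
    cluster_cols = cohort.columns_for({"genetics", "lifestyle", "phenotype"})
    train_data = cohort.to_array(cluster_cols)[train_idx]
    hp, table = select_hyperparameters(train_data, grid, stab_cfg)
    model = fit_kmodes(
        train_data, hp, seed=_child_seed(stab_cfg.seed, 101),
        feature_names=cluster_cols,
    )
    return hp, model, table


def run_outer_fold(
    cohort: CohortTable,
    fold_index: int,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    grid: Sequence[HyperParams],
    stab_cfg: StabilityConfig,
    clf_cfg: ClassifierConfig,
    permutation_repeats: int = 10,
    compute_attributions: bool = True,
) -> FoldRecord:
    """One outer fold: selection, clustering, surrogate labels, ablation, attribution."""
    hp, model, table = fit_fold_clustering(cohort, train_idx, grid, stab_cfg)
    cluster_cols = cohort.columns_for({"genetics", "lifestyle", "phenotype"})
    data = cohort.to_array(cluster_cols)
    train_labels = predict_labels(model, data[train_idx])
    test_labels = predict_labels(model, data[test_idx])

    clf_frame = cohort.data[cohort.columns_for({"genetics", "lifestyle"})]
    metrics: dict[str, dict[str, float]] = {}
    attributions: dict[str, pd.Series] = {}
    for config, modalities in FEATURE_CONFIGS.items():
        cols = cohort.columns_for(set(modalities))
        X_train = clf_frame[cols].iloc[train_idx]
        X_test = clf_frame[cols].iloc[test_idx]
        clf = clf_cfg.build(seed=_child_seed(stab_cfg.seed, fold_index, 7))
        clf.fit(X_train, train_labels)
        y_pred = clf.predict(X_test)
        metrics[config] = evaluate_multiclass(test_labels, y_pred)
        if config == "integrated" and compute_attributions:
            gain = gain_importance(clf, cols)
            total = gain.sum()
            attributions["gain"] = gain / total if total > 0 else gain
            attributions["gain_raw"] = gain
            perm = permutation_importance(
                clf,
                X_test,
                test_labels,
                metric=_macro_f1,
                n_repeats=permutation_repeats,
                seed=_child_seed(stab_cfg.seed, fold_index, 11),
            )
            attributions["permutation"] = perm["mean_drop"]
            attributions["shap"], _ = shap_contributions(clf, X_test)
    return FoldRecord(
        fold_index=fold_index,
        selected_hp=hp,
        train_model=model,
        train_labels=train_labels,
        test_labels=test_labels,
        metrics=metrics,
        attributions=attributions,
        selection_table=table,
    )


def aggregate_folds(records: Sequence[FoldRecord]) -> PipelineSummary:
    """Mean and population-std of each metric per configuration; modal k."""
    records = list(records)
    if len(records) < 2:
        raise ValueError("need at least 2 fold records")
    metrics: dict[str, dict[str, dict[str, float]]] = {}
    for config in records[0].metrics:
        metrics[config] = {}
        for name in METRIC_NAMES:
            vals = np.array([r.metrics[config][name] for r in records])
            metrics[config][name] = {
                "mean": float(vals.mean()),
                "std": float(vals.std(ddof=0)),
            }
    ks = [r.selected_hp.n_clusters for r in records]
    uniq, counts = np.unique(ks, return_counts=True)
    modal_k = int(uniq[counts == counts.max()].min())  # ties -> smallest k
    return PipelineSummary(
        metrics=metrics,
        modal_k=modal_k,
        per_fold_k=[int(k) for k in ks],
        selection_tables=[[r.to_dict() for r in rec.selection_table] for rec in records],
    )


def run_nested_cv(
    cohort: CohortTable,
    grid: Sequence[HyperParams],
    stab_cfg: StabilityConfig,
    clf_cfg: ClassifierConfig | None = None,
    n_folds: int = 5,
    permutation_repeats: int = 10,
    compute_attributions: bool = True,
) -> tuple[list[FoldRecord], PipelineSummary, dict]:
    """Full nested protocol; returns fold records, summary, and attribution aggregate."""
    clf_cfg = clf_cfg or ClassifierConfig()
    folds = make_outer_folds(cohort.n_subjects, n_folds, seed=stab_cfg.seed)
    records = []
    for i, (train_idx, test_idx) in enumerate(folds):
        fold_cfg = StabilityConfig(
            repeats=stab_cfg.repeats,
            subsample_frac=stab_cfg.subsample_frac,
            alpha=stab_cfg.alpha,
            k_max=stab_cfg.k_max,
            seed=_child_seed(stab_cfg.seed, i),
            tie_tol=stab_cfg.tie_tol,
        )
        records.append(
            run_outer_fold(
                cohort, i, train_idx, test_idx, grid, fold_cfg, clf_cfg,
                permutation_repeats=permutation_repeats,
                compute_attributions=compute_attributions,
            )
        )
    summary = aggregate_folds(records)
    attribution_aggregate: dict = {}
    if compute_attributions:
        tables, consensus = aggregate_attribution(
            [
                {m: r.attributions[m] for m in ("gain", "permutation", "shap")}
                for r in records
            ]
        )
        attribution_aggregate = {"tables": tables, "consensus": consensus}
    return records, summary, attribution_aggregate


def final_descriptive_refit(
    cohort: CohortTable,
    k: int,
    init: str = "Cao",
    n_init: int = 10,
    max_iter: int = 300,
    seed: int = 0,
) -> dict:
    """Full-data refit at the modal k, for descriptive profiling only.

    Returns the model, per-cluster prevalence (count, fraction) and
    per-cluster modal profiles by modality, flagged ``descriptive_only``.
    """
    cols = cohort.columns_for({"genetics", "lifestyle", "phenotype"})
    data = cohort.to_array(cols)
    hp = HyperParams(n_clusters=k, init=init, n_init=n_init, max_iter=max_iter)
    model = fit_kmodes(data, hp, seed=seed, feature_names=cols)
    labels = predict_labels(model, data)
    counts = np.bincount(labels, minlength=k)
    prevalence = [
        {"cluster": int(c), "count": int(counts[c]), "fraction": float(counts[c] / len(labels))}
        for c in range(k)
    ]
    profiles = {}
    for c in range(k):
        mode_row = dict(zip(cols, model.modes[c].tolist()))
        profiles[str(c)] = {
            modality: {
                name: mode_row[name]
                for name in cohort.columns_for({modality})
            }
            for modality in ("genetics", "lifestyle", "phenotype")
        }
    return {
        "descriptive_only": True,
        "model": model,
        "labels": labels,
        "prevalence": prevalence,
        "modal_profiles": profiles,
    }
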