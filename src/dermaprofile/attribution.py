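"""Fold-aware feature attribution for the cluster-membership classifier.

Three complementary measures: model-internal total split gain, permutation
importance on held-out data (drop in macro-F1 after shuffling one column),
and SHAP-style additive contributions from the boosted trees' built-in
contribution scores. Per-fold tables are aggregated across outer folds as
mean +/- std with a cross-method consensus set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb

METHODS = ("gain", "permutation", "shap")


def _booster(model) -> xgb.Booster:
    if isinstance(model, xgb.Booster):
        return model
    try:
        return model.get_booster()
    except Exception as exc:  # includes sklearn NotFittedError
        raise ValueError("model is not a trained XGBoost classifier") from exc


def gain_importance(model, feature_names: Sequence[str]) -> pd.Series:
    """Total split gain per feature; features never split on score 0."""
    booster = _booster(model)
    raw = booster.get_score(importance_type="total_gain")
    names = list(feature_names)
    # boosters trained on unnamed arrays report f0..f{p-1}
    if booster.feature_names is not None:
        keymap = {name: name for name in names}
    else:
        keymap = {name: f"f{i}" for i, name in enumerate(names)}
    return pd.Series({name: float(raw.get(keymap[name], 0.0)) for name in names})


def permutation_importance(
    model,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    metric: Callable[[np.ndarray, np.ndarray], float],
    n_repeats: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Held-out permutation importance: baseline metric minus shuffled metric.

    Returns a frame indexed by feature with ``mean_drop`` and ``std`` over
    the seeded repeats. Only the probed column is shuffled.
    """
    if len(X_test) < 2:
        raise ValueError("permutation importance needs at least 2 test rows")
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    rng = np.random.default_rng(seed)
    y_test = np.asarray(y_test)
    baseline = metric(y_test, model.predict(X_test))
    rows = {}
    for col in X_test.columns:
        drops = np.empty(n_repeats)
        for r in range(n_repeats):
            shuffled = X_test.copy()
            shuffled[col] = rng.permutation(shuffled[col].to_numpy())
            drops[r] = baseline - metric(y_test, model.predict(shuffled))
        rows[col] = {"mean_drop": drops.mean(), "std": drops.std()}
    return pd.DataFrame.from_dict(rows, orient="index")


def shap_contributions(
    model, X_test: pd.DataFrame
) -> tuple[pd.Series, np.ndarray]:
    """Additive per-sample contributions from the boosted trees.

    Returns the per-feature mean of |contribution| over samples and classes,
    plus the raw contribution array (n, classes, p+1; last column is bias).
    Contributions plus bias reproduce the model's margin output per sample.
    """
    if len(X_test) == 0:
        raise ValueError("X_test is empty")
    booster = _booster(model)
    dm = xgb.DMatrix(X_test)
    contribs = booster.predict(dm, pred_contribs=True)
    if contribs.ndim == 2:  # binary case: (n, p+1)
        contribs = contribs[:, None, :]
    if contribs.shape[-1] != X_test.shape[1] + 1:
        raise ValueError("contribution shape does not match the feature set")
    mean_abs = np.abs(contribs[:, :, :-1]).mean(axis=(0, 1))
    return pd.Series(mean_abs, index=list(X_test.columns)), contribs


@dataclass
class AttributionTable:
    """Cross-fold aggregate: mean/std/rank per feature for one method."""

    method: str
    summary: pd.DataFrame  # index: feature; columns: mean, std, rank
    per_fold: pd.DataFrame  # index: feature; one column per fold

    def top(self, k: int = 10) -> pd.DataFrame:
        return self.summary.sort_values("rank").head(k)


def aggregate_attribution(
    per_fold_tables: Sequence[dict[str, pd.Series]], top_k: int = 10
) -> tuple[dict[str, AttributionTable], list[str]]:
    """Aggregate per-fold attribution values across outer folds.

    ``per_fold_tables`` holds one dict per fold mapping method name to a
    per-feature Series. Returns per-method tables (mean +/- std across
    folds, rank 1 = largest mean) and the cross-method consensus set:
    features in the top-``top_k`` of at least two methods.
    """
    if len(per_fold_tables) < 2:
        raise ValueError("need at least 2 folds to aggregate")
    methods = sorted({m for t in per_fold_tables for m in t})
    tables: dict[str, AttributionTable] = {}
    top_sets: list[set[str]] = []
    for method in methods:
        series = [t[method] for t in per_fold_tables if method in t]
        index = series[0].index
        for s in series[1:]:
            if set(s.index) != set(index):
                raise ValueError(f"inconsistent feature sets across folds ({method})")
        folds = pd.concat([s.reindex(index) for s in series], axis=1)
        folds.columns = [f"fold{i}" for i in range(len(series))]
        mean = folds.mean(axis=1)
        std = folds.std(axis=1, ddof=0)
        rank = mean.rank(ascending=False, method="first").astype(int)
        summary = pd.DataFrame({"mean": mean, "std": std, "rank": rank})
        tables[method] = AttributionTable(method, summary, folds)
        top_sets.append(set(summary.sort_values("rank").head(top_k).index))
    counts: dict[str, int] = {}
    for s in top_sets:
        for f in s:
            counts[f] = counts.get(f, 0) + 1
    consensus = sorted(f for f, c in counts.items() if c >= 2)
    return tables, consensus
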