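"""Train-only k-modes hyperparameter selection via subsample-projection stability.

For each candidate, R subsamples (80% of the training rows, without
replacement) are clustered and each solution is projected back onto the full
training set through its prototypes, giving R comparable labelings. Stability
is the mean pairwise Adjusted Rand Index over those labelings; candidates are
ranked by the k-penalized score

    Score(k) = mean_ARI - alpha * k / k_max

with mismatch cost as a secondary criterion among near-tied scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Sequence

import numpy as np

from .cohort import CohortTable
from .kmodes import ClusterModel, HyperParams, fit_kmodes, mean_mismatch_cost, predict_labels

#: the standard candidate grid: 3 * 2 * 3 * 3 = 54 candidates
GRID_N_CLUSTERS = (3, 4, 5)
GRID_INIT = ("Huang", "Cao")
GRID_N_INIT = (5, 10, 20)
GRID_MAX_ITER = (100, 300, 500)


def default_grid() -> list[HyperParams]:
    """The full 54-candidate selection grid."""
    return [
        HyperParams(n_clusters=k, init=init, n_init=n_init, max_iter=max_iter)
        for k, init, n_init, max_iter in product(
            GRID_N_CLUSTERS, GRID_INIT, GRID_N_INIT, GRID_MAX_ITER
        )
    ]


def compact_grid() -> list[HyperParams]:
    """A 6-candidate grid (k x init) for routine runs at moderate cohort sizes."""
    return [
        HyperParams(n_clusters=k, init=init, n_init=5, max_iter=100)
        for k, init in product(GRID_N_CLUSTERS, GRID_INIT)
    ]


@dataclass(frozen=True)
class StabilityConfig:
    repeats: int = 10
    subsample_frac: float = 0.80
    alpha: float = 0.01
    k_max: int = 5
    seed: int = 0
    tie_tol: float = 1e-6

    def __post_init__(self) -> None:
        if not (0 < self.subsample_frac <= 1):
            raise ValueError("subsample_frac must be in (0, 1]")
        if self.repeats < 2:
            raise ValueError("repeats must be >= 2")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")


@dataclass
class StabilityResult:
    hyperparams: HyperParams
    mean_ari: float
    mean_cost: float
    score: float
    n_pairs: int = 0

    def to_dict(self) -> dict:
        return {
            "hyperparams": self.hyperparams.to_dict(),
            "mean_ari": self.mean_ari,
            "mean_cost": self.mean_cost,
            "score": self.score,
            "n_pairs": self.n_pairs,
        }


def adjusted_rand_index(a: Sequence[int], b: Sequence[int]) -> float:
    """Hubert–Arabie Adjusted Rand Index between two labelings.

    If both labelings are single-cluster the chance-corrected denominator is
    zero and the partitions are identical; 1.0 is returned by convention.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("labelings must be equal-length 1-d arrays")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 items")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    contingency = np.zeros((ai.max() + 1, bi.max() + 1), dtype=np.int64)
    np.add.at(contingency, (ai, bi), 1)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_ij = comb2(contingency).sum()
    sum_a = comb2(contingency.sum(axis=1)).sum()
    sum_b = comb2(contingency.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb2(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


def penalized_score(mean_ari: float, k: int, alpha: float, k_max: int) -> float:
    """Selection score: mean ARI minus the mild cluster-count penalty."""
    if k > k_max:
        raise ValueError(f"k={k} exceeds k_max={k_max}")
    return mean_ari - alpha * k / k_max


def _child_seed(*keys: int) -> int:
    return int(np.random.SeedSequence(list(keys)).generate_state(1)[0] % (2**31))


def _as_array(train) -> np.ndarray:
    if isinstance(train, CohortTable):
        return train.to_array()
    return np.asarray(train, dtype=np.int64)


def stability_for_candidate(
    train,
    hp: HyperParams,
    cfg: StabilityConfig,
    candidate_index: int = 0,
) -> StabilityResult:
    """Subsample-projection stability of one candidate on the training set.

    Returns the mean pairwise ARI over the R projected labelings, the mean
    (over the R subsample models) mismatch cost on the full training set,
    and the penalized score.
    """
    data = _as_array(train)
    n = data.shape[0]
    size = int(np.floor(cfg.subsample_frac * n))
    if size < hp.n_clusters:
        raise ValueError(
            f"subsample size {size} is smaller than k={hp.n_clusters}"
        )
    labelings = []
    costs = []
    for rep in range(cfg.repeats):
        rep_seed = _child_seed(cfg.seed, candidate_index, rep)
        rng = np.random.default_rng(rep_seed)
        idx = rng.choice(n, size=size, replace=False)
        model = fit_kmodes(data[idx], hp, seed=rep_seed)
        labelings.append(predict_labels(model, data))
        costs.append(mean_mismatch_cost(model, data))
    aris = [
        adjusted_rand_index(la, lb) for la, lb in combinations(labelings, 2)
    ]
    mean_ari = float(np.mean(aris))
    return StabilityResult(
        hyperparams=hp,
        mean_ari=mean_ari,
        mean_cost=float(np.mean(costs)),
        score=penalized_score(mean_ari, hp.n_clusters, cfg.alpha, cfg.k_max),
        n_pairs=len(aris),
    )


def pick_winner(results: Sequence[StabilityResult], tie_tol: float) -> StabilityResult:
    """Max score; near-ties (within tie_tol) broken by lower cost, then order."""
    best_score = max(r.score for r in results)
    contenders = [r for r in results if best_score - r.score <= tie_tol]
    return min(contenders, key=lambda r: r.mean_cost)  # stable min -> grid order


def select_hyperparameters(
    train,
    grid: Sequence[HyperParams],
    cfg: StabilityConfig,
) -> tuple[HyperParams, list[StabilityResult]]:
    """Evaluate every candidate and return the winner plus the audit table.

    The winner maximizes the penalized score; candidates whose score is
    within ``cfg.tie_tol`` of the best are broken by lower mean mismatch
    cost, then by grid order.
    """
    grid = list(grid)
    if not grid:
        raise ValueError("candidate grid is empty")
    for hp in grid:
        if hp.n_clusters > cfg.k_max:
            raise ValueError(f"candidate k={hp.n_clusters} exceeds k_max={cfg.k_max}")
    results = [
        stability_for_candidate(train, hp, cfg, candidate_index=i)
        for i, hp in enumerate(grid)
    ]
    winner = pick_winner(results, cfg.tie_tol)
    return winner.hyperparams, results
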