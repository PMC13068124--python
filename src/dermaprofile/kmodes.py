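"""k-modes clustering for categorical data.

Lloyd-style alternation between nearest-mode assignment under matching
(Hamming) dissimilarity and per-column modal prototype updates, with Huang
(frequency-sampled, snapped to data) and Cao (density/dissimilarity-greedy,
deterministic) initialisations.

Tie-breaking is fixed for reproducibility: assignment ties go to the lowest
cluster index, mode-update ties to the smallest category code. Convergence
means the assignment vector is unchanged; empty clusters are repaired by
reseeding with the point farthest from its current mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

INIT_METHODS = ("Huang", "Cao")


@dataclass(frozen=True)
class HyperParams:
    n_clusters: int
    init: str = "Cao"
    n_init: int = 10
    max_iter: int = 100

    def __post_init__(self) -> None:
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.init not in INIT_METHODS:
            raise ValueError(f"init must be one of {INIT_METHODS}")
        if self.n_init < 1 or self.max_iter < 1:
            raise ValueError("n_init and max_iter must be >= 1")

    def to_dict(self) -> dict:
        return {
            "n_clusters": self.n_clusters,
            "init": self.init,
            "n_init": self.n_init,
            "max_iter": self.max_iter,
        }


@dataclass
class ClusterModel:
    """Fitted k-modes model: prototypes plus fit diagnostics."""

    modes: np.ndarray  # (k, p) integer category codes
    feature_names: tuple[str, ...]
    total_cost: int
    n_iter: int
    seed: int
    hyperparams: HyperParams
    cost_history: list[int] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return self.modes.shape[0]

    def to_dict(self) -> dict:
        return {
            "modes": self.modes.tolist(),
            "feature_names": list(self.feature_names),
            "total_cost": int(self.total_cost),
            "n_iter": int(self.n_iter),
            "seed": int(self.seed),
            "hyperparams": self.hyperparams.to_dict(),
            "cost_history": [int(c) for c in self.cost_history],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ClusterModel":
        return cls(
            modes=np.asarray(payload["modes"], dtype=np.int64),
            feature_names=tuple(payload["feature_names"]),
            total_cost=int(payload["total_cost"]),
            n_iter=int(payload["n_iter"]),
            seed=int(payload["seed"]),
            hyperparams=HyperParams(**payload["hyperparams"]),
            cost_history=[int(c) for c in payload.get("cost_history", [])],
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ClusterModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def matching_dissimilarity(x: Sequence[int], m: Sequence[int]) -> int:
    """Number of positions where two categorical vectors disagree."""
    x = np.asarray(x)
    m = np.asarray(m)
    if x.shape != m.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {m.shape}")
    return int(np.count_nonzero(x != m))


def _dissimilarity_matrix(data: np.ndarray, modes: np.ndarray) -> np.ndarray:
    """(n, k) mismatch counts between every row and every mode."""
    return (data[:, None, :] != modes[None, :, :]).sum(axis=2)


def _column_modes(data: np.ndarray) -> np.ndarray:
    """Per-column most frequent code, ties to the smallest code."""
    out = np.empty(data.shape[1], dtype=np.int64)
    for j in range(data.shape[1]):
        vals, counts = np.unique(data[:, j], return_counts=True)
        out[j] = vals[np.argmax(counts)]  # np.unique sorts, argmax takes first max
    return out


def _snap_to_data(proto: np.ndarray, data: np.ndarray, taken: list[np.ndarray]) -> np.ndarray:
    """Nearest data row to ``proto`` whose vector is distinct from ``taken``."""
    dists = (data != proto[None, :]).sum(axis=1)
    for idx in np.argsort(dists, kind="stable"):
        row = data[idx]
        if not any(np.array_equal(row, t) for t in taken):
            return row.copy()
    raise ValueError("fewer distinct rows than requested modes")


def init_modes(
    data: np.ndarray, k: int, method: str, rng: np.random.Generator
) -> np.ndarray:
    """Initial k x p mode matrix; all modes pairwise distinct as rows."""
    data = np.asarray(data, dtype=np.int64)
    n, p = data.shape
    if method not in INIT_METHODS:
        raise ValueError(f"init must be one of {INIT_METHODS}")
    if n < k:
        raise ValueError(f"need n >= k (n={n}, k={k})")
    if len(np.unique(data, axis=0)) < k:
        raise ValueError("fewer distinct rows than requested clusters")

    if k == 1:
        return _snap_to_data(_column_modes(data), data, [])[None, :]

    if method == "Huang":
        chosen: list[np.ndarray] = []
        for _ in range(k):
            proto = np.empty(p, dtype=np.int64)
            for j in range(p):
                vals, counts = np.unique(data[:, j], return_counts=True)
                proto[j] = rng.choice(vals, p=counts / counts.sum())
            chosen.append(_snap_to_data(proto, data, chosen))
        return np.vstack(chosen)

    # Cao: deterministic density / dissimilarity greedy selection
    dens = np.zeros(n)
    for j in range(p):
        vals, inverse, counts = np.unique(
            data[:, j], return_inverse=True, return_counts=True
        )
        dens += counts[inverse]
    dens /= n * p
    chosen = [data[int(np.argmax(dens))].copy()]
    while len(chosen) < k:
        scores = np.min(
            [dens * (data != m[None, :]).sum(axis=1) for m in chosen], axis=0
        )
        order = np.argsort(-scores, kind="stable")
        for idx in order:
            if not any(np.array_equal(data[idx], m) for m in chosen):
                chosen.append(data[idx].copy())
                break
    return np.vstack(chosen)


def _assign(data: np.ndarray, modes: np.ndarray) -> tuple[np.ndarray, int]:
    dist = _dissimilarity_matrix(data, modes)
    labels = dist.argmin(axis=1)  # argmin ties -> lowest cluster index
    return labels, int(dist[np.arange(len(data)), labels].sum())


def _single_run(
    data: np.ndarray, hp: HyperParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, int, int, list[int]]:
    k = hp.n_clusters
    modes = init_modes(data, k, hp.init, rng)
    labels, cost = _assign(data, modes)
    history = [cost]
    n_iter = 0
    for n_iter in range(1, hp.max_iter + 1):
        # (b) recompute each mode as the column-wise modal category of its members
        for c in range(k):
            members = data[labels == c]
            if len(members):
                modes[c] = _column_modes(members)
        # (a) reassign to nearest mode
        new_labels, cost = _assign(data, modes)
        # repair empty clusters with the farthest point from its current mode
        for c in range(k):
            if not np.any(new_labels == c):
                dist = _dissimilarity_matrix(data, modes)
                far = int(dist[np.arange(len(data)), new_labels].argmax())
                modes[c] = data[far]
                new_labels, cost = _assign(data, modes)
        history.append(cost)
        if np.array_equal(new_labels, labels):
            labels = new_labels
            break
        labels = new_labels
    return labels, modes, cost, n_iter, history


def fit_kmodes(
    data: np.ndarray,
    hp: HyperParams,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> ClusterModel:
    """Fit k-modes with restarts; returns the minimum-cost restart.

    Cao initialisation is deterministic, so a single run is performed
    regardless of ``n_init``. Restart ``r`` draws from
    ``default_rng(seed + r)`` so any restart is re-runnable in isolation.
    Restart ties on cost go to the lowest restart index.
    """
    data = np.asarray(data, dtype=np.int64)
    if data.ndim != 2:
        raise ValueError("data must be 2-dimensional")
    if data.shape[0] < hp.n_clusters:
        raise ValueError(f"n={data.shape[0]} < k={hp.n_clusters}")
    if feature_names is None:
        feature_names = tuple(f"f{j}" for j in range(data.shape[1]))
    feature_names = tuple(feature_names)
    if len(feature_names) != data.shape[1]:
        raise ValueError("feature_names length does not match data")

    n_runs = 1 if hp.init == "Cao" else hp.n_init
    best = None
    for r in range(n_runs):
        rng = np.random.default_rng(seed + r)
        labels, modes, cost, n_iter, history = _single_run(data, hp, rng)
        if best is None or cost < best[2]:
            best = (labels, modes, cost, n_iter, history)
    labels, modes, cost, n_iter, history = best
    return ClusterModel(
        modes=modes,
        feature_names=feature_names,
        total_cost=cost,
        n_iter=n_iter,
        seed=seed,
        hyperparams=hp,
        cost_history=history,
    )


def _check_features(model: ClusterModel, data: np.ndarray, feature_names) -> None:
    if data.ndim != 2 or data.shape[1] != model.modes.shape[1]:
        raise ValueError(
            f"feature mismatch: model has {model.modes.shape[1]} features, "
            f"data has {data.shape[1] if data.ndim == 2 else '?'}"
        )
    if feature_names is not None and tuple(feature_names) != model.feature_names:
        raise ValueError("feature names do not match the model")


def predict_labels(
    model: ClusterModel, data: np.ndarray, feature_names: Sequence[str] | None = None
) -> np.ndarray:
    """Assign each row to its nearest mode (ties to the lowest cluster index)."""
    data = np.asarray(data, dtype=np.int64)
    _check_features(model, data, feature_names)
    return _dissimilarity_matrix(data, model.modes).argmin(axis=1)


def mean_mismatch_cost(
    model: ClusterModel, data: np.ndarray, feature_names: Sequence[str] | None = None
) -> float:
    """Mean matching dissimilarity of each row to its assigned mode."""
    data = np.asarray(data, dtype=np.int64)
    _check_features(model, data, feature_names)
    if len(data) == 0:
        raise ValueError("cannot compute mean mismatch cost on an empty set")
    dist = _dissimilarity_matrix(data, model.modes)
    return float(dist.min(axis=1).mean())
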