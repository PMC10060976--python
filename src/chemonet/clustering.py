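"""Semi-supervised chemokine clustering.

Tumor samples are clustered on the z-scored chemokine panel with PAM
(partition around medoids) under the cosine distance; the fitted model
(medoids + per-gene scaling) is projected onto further cohorts with an
inverse-distance-weighted k-nearest-neighbor classifier.  Diagnostics
cover the within-cluster sum of squares curve, mean silhouette, the
fraction of explained variance and 10-fold cross-validated stability
(adjusted Rand index).

Determinism: BUILD and SWAP break cost ties by the lowest sample index,
so a fit is reproducible regardless of seed; the seed only enters fold
shuffling in cross-validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score
from sklearn.metrics.pairwise import cosine_distances
from sklearn.model_selection import KFold

from .core_data import ExpressionCohort, zscore_genes

__all__ = [
    "ClusterModel",
    "ClusterDiagnostics",
    "cosine_distance",
    "pam_fit",
    "choose_k",
    "explained_variance",
    "crossvalidate",
    "knn_project",
]


def cosine_distance(u, v) -> float:
    """1 - cos(u, v); in [0, 2]. Zero vectors are rejected."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ValueError("cosine distance undefined for zero vectors")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def _pam_exhaustive_pairs(D: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal 2-medoid subset by scanning all pairs (chunked, O(n^2) memory)."""
    n = D.shape[0]
    best_cost, best = np.inf, (0, 1)
    for i in range(n - 1):
        totals = np.minimum(D[:, i : i + 1], D[:, i + 1 :]).sum(axis=0)
        j = int(np.argmin(totals))
        if totals[j] < best_cost - 1e-12:
            best_cost = float(totals[j])
            best = (i, i + 1 + j)
    return np.array(best), best_cost


def _pam_on_distances(D: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, float]:
    """k-medoids on a precomputed distance matrix.

    Small instances are solved exactly (k=2 by a vectorized pair scan, tiny
    n by subset enumeration); larger ones use BUILD + SWAP to a local
    optimum.  Ties break on the lowest index, making the fit deterministic.

    Returns (medoid indices, assignment indices into medoid list, total cost).
    """
    n = D.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k == 2 and n <= 600:
        med, cost = _pam_exhaustive_pairs(D)
        assign = np.argmin(D[:, med], axis=1)
        return med, assign, cost
    from math import comb
    from itertools import combinations

    if comb(n, k) <= 20000:
        best_cost, best = np.inf, None
        for subset in combinations(range(n), k):
            c = D[:, subset].min(axis=1).sum()
            if c < best_cost - 1e-12:
                best_cost, best = float(c), subset
        med = np.array(best)
        assign = np.argmin(D[:, med], axis=1)
        return med, assign, best_cost
    # BUILD: greedy cost reduction
    medoids = [int(np.argmin(D.sum(axis=0)))]
    while len(medoids) < k:
        d_near = D[:, medoids].min(axis=1)
        gains = np.maximum(d_near[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    cost = D[:, medoids].min(axis=1).sum()
    # SWAP until local optimum
    while True:
        med = np.array(medoids)
        sub = D[:, med]
        order = np.argsort(sub, axis=1, kind="stable")
        d_near = sub[np.arange(n), order[:, 0]]
        nearest = order[:, 0]
        d_second = sub[np.arange(n), order[:, 1]] if k > 1 else np.full(n, np.inf)
        candidates = np.array([i for i in range(n) if i not in set(medoids)])
        if candidates.size == 0:
            break
        best = (cost, None, None)
        for mi, m in enumerate(medoids):
            d_rem = np.where(nearest == mi, d_second, d_near)
            totals = np.minimum(d_rem[:, None], D[:, candidates]).sum(axis=0)
            j = int(np.argmin(totals))
            if totals[j] < best[0] - 1e-12:
                best = (float(totals[j]), m, int(candidates[j]))
        if best[1] is None:
            break
        medoids = sorted(set(medoids) - {best[1]} | {best[2]})
        cost = D[:, medoids].min(axis=1).sum()
    med = np.array(medoids)
    assign = np.argmin(D[:, med], axis=1)
    return med, assign, float(D[np.arange(n), med[assign]].sum())


@dataclass
class ClusterModel:
    """Fitted chemokine-cluster definition, reusable for cross-cohort projection."""

    gene_panel: list[str]
    scaling: pd.DataFrame  # per-gene mean/sd in the training cohort
    medoid_ids: list[str]
    assignments: pd.Series  # training sample -> cluster name
    training_matrix: pd.DataFrame  # scaled genes × training samples
    k: int = 2
    distance: str = "cosine"
    total_cost: float = np.nan

    @property
    def cluster_names(self) -> list[str]:
        return sorted(self.assignments.unique())

    @property
    def medoids(self) -> pd.DataFrame:
        return self.training_matrix[self.medoid_ids]

    def to_json(self, path: str | Path) -> None:
        doc = {
            "gene_panel": self.gene_panel,
            "scaling": self.scaling.to_dict(orient="index"),
            "medoid_ids": self.medoid_ids,
            "assignments": self.assignments.to_dict(),
            "training_matrix": {
                "genes": list(self.training_matrix.index),
                "samples": list(self.training_matrix.columns),
                "values": self.training_matrix.to_numpy().tolist(),
            },
            "k": self.k,
            "distance": self.distance,
            "total_cost": self.total_cost,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "ClusterModel":
        doc = json.loads(Path(path).read_text())
        tm = doc["training_matrix"]
        return cls(
            gene_panel=doc["gene_panel"],
            scaling=pd.DataFrame.from_dict(doc["scaling"], orient="index"),
            medoid_ids=doc["medoid_ids"],
            assignments=pd.Series(doc["assignments"]),
            training_matrix=pd.DataFrame(tm["values"], index=tm["genes"], columns=tm["samples"]),
            k=doc["k"],
            distance=doc["distance"],
            total_cost=doc["total_cost"],
        )


@dataclass
class ClusterDiagnostics:
    wss: dict[int, float] = field(default_factory=dict)
    silhouette: dict[int, float] = field(default_factory=dict)
    explained_variance: float = np.nan
    cv_stability: float = np.nan

    @property
    def recommended_k(self) -> int:
        return max(self.silhouette, key=lambda k: (self.silhouette[k], -k))


def _name_clusters(scaled: pd.DataFrame, assign: np.ndarray, k: int) -> list[str]:
    """Cluster names ordered by mean panel expression: 'high'/'low' for k=2."""
    means = [scaled.to_numpy()[:, assign == c].mean() if (assign == c).any() else -np.inf for c in range(k)]
    rank = np.argsort(np.argsort([-m for m in means], kind="stable"), kind="stable")
    if k == 2:
        names = ["high", "low"]
    else:
        names = [f"c{i + 1}" for i in range(k)]
    return [names[rank[c]] for c in range(k)]


def pam_fit(scaled: pd.DataFrame, k: int = 2, seed: int | None = 0) -> ClusterModel:
    """Fit PAM with cosine distance on a z-scored panel matrix (genes × samples).

    The cluster with the greater mean panel expression is named "high"
    (k=2); medoids are actual training samples.
    """
    X = scaled.to_numpy(float).T  # samples × genes
    n = X.shape[0]
    if k >= n + 1:
        raise ValueError("k must be <= number of samples")
    if np.unique(X, axis=0).shape[0] < k:
        raise ValueError("fewer distinct samples than clusters")
    D = cosine_distances(X)
    med, assign, cost = _pam_on_distances(D, k)
    cluster_of = _name_clusters(scaled, assign, k)
    assignments = pd.Series([cluster_of[c] for c in assign], index=scaled.columns, name="cluster")
    return ClusterModel(
        gene_panel=list(scaled.index),
        scaling=pd.DataFrame(index=scaled.index),
        medoid_ids=[scaled.columns[i] for i in med],
        assignments=assignments,
        training_matrix=scaled.copy(),
        k=k,
        total_cost=cost,
    )


def fit_cluster_model(
    cohort: ExpressionCohort, gene_panel: Sequence[str], k: int = 2, seed: int | None = 0
) -> ClusterModel:
    """Z-score the panel within the cohort and fit PAM; stores scaling params."""
    scaled, params = zscore_genes(cohort, gene_panel)
    model = pam_fit(scaled, k=k, seed=seed)
    model.scaling = params
    model.gene_panel = list(gene_panel)
    return model


def _silhouette_mean(D: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette on a precomputed distance matrix; singleton clusters score 0."""
    n = D.shape[0]
    uniq = np.unique(labels)
    sil = np.zeros(n)
    for i in range(n):
        own = labels[i]
        same = (labels == own) & (np.arange(n) != i)
        if not same.any():
            continue  # singleton convention: 0
        a = D[i, same].mean()
        b = min(D[i, labels == c].mean() for c in uniq if c != own)
        sil[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return float(sil.mean())


def choose_k(scaled: pd.DataFrame, k_range: Sequence[int] = range(2, 7)) -> ClusterDiagnostics:
    """WSS and mean silhouette across k; recommended k = peak mean silhouette.

    The WSS "bend" is reported for inspection, not auto-decided.
    """
    X = scaled.to_numpy(float).T
    D = cosine_distances(X)
    diag = ClusterDiagnostics()
    for k in k_range:
        med, assign, _ = _pam_on_distances(D, k)
        d_to_med = D[np.arange(X.shape[0]), med[assign]]
        diag.wss[k] = float((d_to_med**2).sum())
        diag.silhouette[k] = _silhouette_mean(D, assign)
    return diag


def explained_variance(scaled: pd.DataFrame, assignments: pd.Series) -> float:
    """1 - WSS/TSS with Euclidean geometry on the scaled matrix.

    Cluster centroids are means in the scaled space; requires >= 2 clusters
    and non-identical samples.
    """
    X = scaled.to_numpy(float).T
    labels = assignments.loc[scaled.columns].to_numpy()
    if np.unique(labels).size < 2:
        raise ValueError("need >= 2 clusters")
    tss = ((X - X.mean(axis=0)) ** 2).sum()
    if tss == 0:
        raise ValueError("all samples identical: explained variance undefined")
    wss = 0.0
    for c in np.unique(labels):
        block = X[labels == c]
        wss += ((block - block.mean(axis=0)) ** 2).sum()
    return float(1.0 - wss / tss)


def crossvalidate(scaled: pd.DataFrame, k: int = 2, folds: int = 10, seed: int | None = 0) -> float:
    """Fold-wise refit stability: mean adjusted Rand index of held-out labels.

    Each fold refits PAM on the remaining samples, assigns the held-out
    samples to the nearest medoid, and compares against the full-data
    labels.
    """
    if folds < 2:
        raise ValueError("need >= 2 folds")
    X = scaled.to_numpy(float).T
    n = X.shape[0]
    full = pam_fit(scaled, k=k).assignments.to_numpy()
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    aris = []
    for train_idx, test_idx in kf.split(X):
        if train_idx.size < k:
            raise ValueError("fold smaller than number of clusters")
        sub = scaled.iloc[:, train_idx]
        model = pam_fit(sub, k=k)
        med_vec = model.medoids.to_numpy().T
        med_names = [model.assignments[m] for m in model.medoid_ids]
        D = cosine_distances(X[test_idx], med_vec)
        held = np.array([med_names[j] for j in D.argmin(axis=1)])
        aris.append(adjusted_rand_score(full[test_idx], held))
    return float(np.mean(aris))


def knn_project(
    model: ClusterModel,
    test_cohort: ExpressionCohort,
    k_neighbors: int = 15,
    use_training_scaling: bool = False,
) -> pd.Series:
    """Project cluster labels onto a test cohort by inverse-distance-weighted k-NN.

    The test panel is z-scored with the test cohort's own per-gene
    parameters by default (cross-platform transfer); training-cohort
    parameters are available behind ``use_training_scaling``.  A
    zero-distance neighbor's label is copied directly; weight ties resolve
    to the smallest-index neighbor within the tied clusters.
    """
    found, missing = test_cohort.find_genes(model.gene_panel)
    if missing:
        raise ValueError(f"test cohort lacks panel genes: {missing}")
    n_train = model.training_matrix.shape[1]
    if k_neighbors > n_train:
        raise ValueError(f"k_neighbors={k_neighbors} exceeds {n_train} training samples")
    if use_training_scaling:
        sub = test_cohort.values.loc[[found[g] for g in model.gene_panel]]
        sub.index = model.scaling.index
        scaled = sub.sub(model.scaling["mean"], axis=0).div(model.scaling["sd"], axis=0)
    else:
        scaled, _ = zscore_genes(test_cohort, model.gene_panel)
    Xt = scaled.to_numpy(float).T
    Xtr = model.training_matrix.to_numpy(float).T
    train_labels = model.assignments.to_numpy()
    D = cosine_distances(Xt, Xtr)
    out = []
    for i in range(Xt.shape[0]):
        d = D[i]
        zero = np.flatnonzero(d <= 1e-12)
        if zero.size:
            out.append(train_labels[zero[0]])
            continue
        nn = np.argsort(d, kind="stable")[:k_neighbors]
        weights: dict[str, float] = {}
        for j in nn:
            weights[train_labels[j]] = weights.get(train_labels[j], 0.0) + 1.0 / d[j]
        top = max(weights.values())
        tied = [c for c, w in weights.items() if np.isclose(w, top, rtol=0, atol=1e-12)]
        if len(tied) == 1:
            out.append(tied[0])
        else:
            for j in nn:  # smallest-index neighbor among tied clusters wins
                if train_labels[j] in tied:
                    out.append(train_labels[j])
                    break
    return pd.Series(out, index=scaled.columns, name="cluster")
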