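"""Expression subtype discovery by NMF consensus clustering.

The sample matrix V (p genes x n samples, shifted to be nonnegative) is
factorised as V ~ WH with W (p x k) the metagene matrix and H (k x n) the
per-sample metagene encodings, by multiplicative updates minimising the
generalised Kullback-Leibler divergence D(V || WH).  Each random restart
assigns every sample to its argmax metagene; co-clustering indicators
averaged over restarts form the consensus matrix, whose average-linkage
dendrogram yields both the final labels and the cophenetic correlation
used to select the rank k.  Cluster robustness is checked by
leave-one-out cross-validation with three classifiers (k-nearest
neighbors, signal-to-noise weighted voting, and a CART decision tree),
and clusters are characterised by Welch-t differential expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.spatial.distance import squareform
from scipy.stats import ttest_ind
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .io_formats import ExpressionMatrix
from .module_selection import fisher_enrichment

__all__ = [
    "NmfFactorization",
    "ConsensusResult",
    "DeResult",
    "nonnegativize",
    "nmf_factorize",
    "consensus_cluster",
    "select_rank",
    "loocv_error",
    "differential_expression",
    "cluster_enrichment",
]


@dataclass
class NmfFactorization:
    V: np.ndarray
    W: np.ndarray
    H: np.ndarray
    k: int
    objective: list[float] = field(default_factory=list)

    def reconstruction(self) -> np.ndarray:
        return self.W @ self.H


@dataclass
class ConsensusResult:
    k: int
    consensus: np.ndarray  # n x n, symmetric, unit diagonal
    cophenetic: float
    labels: np.ndarray  # 1..k per sample
    sample_ids: list[str]


@dataclass
class DeResult:
    gene_id: str
    t_statistic: float
    p_value: float
    higher_in: int  # cluster label with the larger mean


# ---------------------------------------------------------------------------


def nonnegativize(values: np.ndarray) -> tuple[np.ndarray, float]:
    """Shift the matrix by its global minimum if negative; returns (V, shift).

    A global shift preserves all pairwise sample Euclidean distances.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("matrix must be finite")
    mn = float(values.min()) if values.size else 0.0
    shift = -mn if mn < 0 else 0.0
    return values + shift, shift


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum() + WH.sum()
    return float(div)


def nmf_factorize(
    V: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> NmfFactorization:
    """KL-divergence NMF by multiplicative updates from a seeded random start.

    The update rules guarantee a non-increasing objective; iteration stops
    at ``max_iter`` or when the relative objective change over a check
    interval drops below ``tol``.
    """
    V = np.asarray(V, dtype=float)
    if np.any(V < 0):
        raise ValueError("V must be nonnegative")
    p, n = V.shape
    if not 1 <= k < min(p, n):
        raise ValueError(f"rank k={k} out of range for a {p}x{n} matrix")
    rng = np.random.default_rng(seed)
    eps = np.finfo(float).tiny
    W = rng.uniform(eps, 1.0, size=(p, k))
    H = rng.uniform(eps, 1.0, size=(k, n))

    trace: list[float] = []
    prev = np.inf
    for it in range(max_iter):
        WH = W @ H + eps
        H *= (W.T @ (V / WH)) / (W.sum(axis=0)[:, None] + eps)
        WH = W @ H + eps
        W *= ((V / WH) @ H.T) / (H.sum(axis=1)[None, :] + eps)
        if it % 10 == 0 or it == max_iter - 1:
            obj = _kl_divergence(V, W @ H + eps)
            trace.append(obj)
            if np.isfinite(prev) and prev - obj <= tol * max(abs(prev), 1.0):
                break
            prev = obj
    return NmfFactorization(V=V, W=W, H=H, k=k, objective=trace)


def _restart_labels(
    V: np.ndarray, k: int, seed: int, max_iter: int, tol: float
) -> np.ndarray:
    """Labels from one NMF restart; empty clusters trigger up to 3 re-draws."""
    for attempt in range(4):
        fac = nmf_factorize(V, k, seed=seed + 7919 * attempt, max_iter=max_iter, tol=tol)
        labels = np.argmax(fac.H, axis=0)
        if len(np.unique(labels)) == k:
            return labels
    warnings.warn(f"NMF restart (seed {seed}, k={k}) left an empty cluster", stacklevel=2)
    return labels


def consensus_cluster(
    V: np.ndarray,
    sample_ids: list[str],
    k_range: range | list[int] = range(2, 6),
    n_restarts: int = 30,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> list[ConsensusResult]:
    """NMF consensus clustering over a range of ranks.

    Per rank k: ``n_restarts`` seeded factorizations each assign samples to
    their argmax metagene; the consensus matrix is the mean co-clustering
    indicator.  Final labels cut the average-linkage dendrogram of
    (1 - consensus) at k clusters, and the cophenetic coefficient is the
    Pearson correlation between that dendrogram's cophenetic distances and
    the consensus distances.
    """
    if n_restarts < 10:
        raise ValueError("n_restarts must be >= 10")
    V = np.asarray(V, dtype=float)
    n = V.shape[1]
    if n != len(sample_ids):
        raise ValueError("sample_ids must match the number of columns of V")
    results = []
    for k in k_range:
        consensus = np.zeros((n, n))
        for r in range(n_restarts):
            child = (seed + 104729 * k + 13 * r) % 2**31
            labels = _restart_labels(V, k, child, max_iter, tol)
            conn = (labels[:, None] == labels[None, :]).astype(float)
            consensus += conn
        consensus /= n_restarts
        np.fill_diagonal(consensus, 1.0)
        dist = squareform(1.0 - consensus, checks=False)
        Z = average(dist)
        coph_dist = cophenet(Z)
        if np.ptp(dist) == 0 or np.ptp(coph_dist) == 0:
            rho = 1.0
        else:
            rho = float(np.corrcoef(dist, coph_dist)[0, 1])
        labels = fcluster(Z, t=k, criterion="maxclust")
        results.append(
            ConsensusResult(
                k=k,
                consensus=consensus,
                cophenetic=rho,
                labels=labels,
                sample_ids=list(sample_ids),
            )
        )
    return results


def select_rank(results: list[ConsensusResult]) -> ConsensusResult:
    """Rank with the highest cophenetic coefficient (smallest k on ties)."""
    if not results:
        raise ValueError("no consensus results")
    return max(results, key=lambda r: (r.cophenetic, -r.k))


# ---------------------------------------------------------------------------
# LOOCV


def _weighted_voting_predict(
    train_x: np.ndarray, train_y: np.ndarray, test_x: np.ndarray, classes: np.ndarray
) -> int:
    """Signal-to-noise weighted vote between two classes.

    Per gene g: weight w_g = (mu_1 - mu_2) / (s_1 + s_2), decision boundary
    b_g = (mu_1 + mu_2) / 2, vote w_g * (x_g - b_g); a positive sum elects
    the first class.  Ties go to the lowest class index.
    """
    c1, c2 = classes
    x1 = train_x[train_y == c1]
    x2 = train_x[train_y == c2]
    mu1, mu2 = x1.mean(axis=0), x2.mean(axis=0)
    s = x1.std(axis=0, ddof=1) + x2.std(axis=0, ddof=1)
    s = np.where(s == 0, np.finfo(float).eps, s)
    w = (mu1 - mu2) / s
    vote = float(np.sum(w * (test_x - (mu1 + mu2) / 2.0)))
    return int(c1 if vote >= 0 else c2)


def loocv_error(
    X: np.ndarray,
    labels: np.ndarray,
    classifier: str = "knn",
    n_neighbors: int = 3,
    max_depth: int = 3,
    min_samples_leaf: int = 3,
) -> float:
    """Leave-one-out misclassification rate of a cluster labelling.

    ``X`` is samples x features.  Classifiers: ``knn`` (Euclidean,
    majority of ``n_neighbors``), ``weighted_voting`` (two classes only),
    ``cart`` (Gini tree, bounded depth and leaf size).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    if X.shape[0] != n:
        raise ValueError("X rows must match labels")
    classes, counts = np.unique(labels, return_counts=True)
    if np.any(counts < 2):
        small = classes[counts < 2]
        raise ValueError(f"class {small[0]} has a single sample; LOOCV undefined")
    if classifier == "weighted_voting" and len(classes) != 2:
        raise ValueError("weighted_voting requires exactly 2 classes")

    errors = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        tr_x, tr_y, te_x = X[mask], labels[mask], X[i]
        if classifier == "knn":
            clf = KNeighborsClassifier(n_neighbors=min(n_neighbors, n - 1))
            clf.fit(tr_x, tr_y)
            pred = clf.predict(te_x[None, :])[0]
        elif classifier == "cart":
            clf = DecisionTreeClassifier(
                criterion="gini",
                max_depth=max_depth,
                min_samples_leaf=min_samples_leaf,
                random_state=0,
            )
            clf.fit(tr_x, tr_y)
            pred = clf.predict(te_x[None, :])[0]
        elif classifier == "weighted_voting":
            pred = _weighted_voting_predict(tr_x, tr_y, te_x, classes)
        else:
            raise ValueError(f"unknown classifier {classifier!r}")
        errors += int(pred != labels[i])
    return errors / n


# ---------------------------------------------------------------------------
# differential expression and enrichment


def differential_expression(
    expr: ExpressionMatrix, labels: dict[str, int], alpha: float = 0.001
) -> list[DeResult]:
    """Welch two-sample t-test per gene between two clusters; keep p < alpha."""
    classes = sorted(set(labels.values()))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    c1, c2 = classes
    cols1 = [j for j, s in enumerate(expr.sample_ids) if labels.get(s) == c1]
    cols2 = [j for j, s in enumerate(expr.sample_ids) if labels.get(s) == c2]
    x1 = expr.values[:, cols1]
    x2 = expr.values[:, cols2]
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = ttest_ind(x1, x2, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)
    out = []
    mean_diff = x1.mean(axis=1) - x2.mean(axis=1)
    for gi, gene in enumerate(expr.gene_ids):
        if p[gi] < alpha:
            out.append(
                DeResult(
                    gene_id=gene,
                    t_statistic=float(t[gi]),
                    p_value=float(p[gi]),
                    higher_in=c1 if mean_diff[gi] > 0 else c2,
                )
            )
    return sorted(out, key=lambda r: r.p_value)


def cluster_enrichment(
    de_results: list[DeResult],
    gene_sets,
    background: set[str],
    alpha: float = 0.05,
) -> dict[int, list[tuple[str, float]]]:
    """Per-cluster one-sided Fisher enrichment of up-regulated genes.

    Reports raw p < ``alpha`` without multiplicity correction.
    """
    by_cluster: dict[int, set[str]] = {}
    for r in de_results:
        by_cluster.setdefault(r.higher_in, set()).add(r.gene_id)
    out: dict[int, list[tuple[str, float]]] = {}
    for cluster, up in sorted(by_cluster.items()):
        up = up & background
        hits = []
        for name in sorted(gene_sets):
            _, _, _, _, p = fisher_enrichment(up, gene_sets[name].genes, background)
            if p < alpha:
                hits.append((name, p))
        out[cluster] = sorted(hits, key=lambda h: h[1])
    return out
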