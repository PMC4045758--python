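"""Condition-specific TRN inference: variance filter, MI, CLR, null screen.

The reverse-engineering step scores every sequence-prior TF->gene pair by
mutual information between the two expression profiles, estimated with a
plug-in histogram over equal-frequency bins,

    MI(X, Y) = sum_ij P(x_i, y_j) * log[ P(x_i, y_j) / (P(x_i) P(y_j)) ]

in nats.  Each edge's MI is then context-normalised CLR-style: for each
endpoint g, a z-score against the empirical MI distribution of all
candidate pairs incident to g (floored at 0), combined as
``clr = sqrt(z_tf^2 + z_target^2)``.

Prior edges are retained when their CLR score strictly exceeds the 95th
percentile (nearest-rank) of the CLR scores of randomly drawn non-prior
TF->gene pairs — by default a separate null sample of 1000 pairs per TF.
Retained edges grouped by TF form the regulatory modules of the network.

Equal-frequency binning makes the whole pipeline invariant under strictly
monotone transforms of the expression values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_formats import DirectedEdge, ExpressionMatrix

__all__ = [
    "JointHistogram",
    "ScoredEdge",
    "NullModel",
    "Trn",
    "filter_low_variance",
    "default_bins",
    "clr_from_mi",
    "discretize_equal_frequency",
    "mutual_information",
    "clr_scores",
    "sample_null_pairs",
    "retain_edges",
    "infer_trn",
]


def default_bins(n: int) -> int:
    """Bins per axis: floor(sqrt(n / 5)) clamped to [3, 10]."""
    return int(np.clip(int(np.sqrt(n / 5)), 3, 10))


def discretize_equal_frequency(x: np.ndarray, bins: int) -> np.ndarray:
    """Map values to ``bins`` equal-frequency codes.

    Bin edges are the empirical ``i*n/bins`` order statistics, so distinct
    values land ``n/bins`` per bin while tied values always share a bin
    (a constant vector occupies a single bin).
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    sorted_x = np.sort(x)
    edges = sorted_x[(np.arange(1, bins) * n) // bins]
    return np.searchsorted(edges, x, side="right")


@dataclass
class JointHistogram:
    """Joint bin counts of a discretised gene pair with marginals."""

    counts: np.ndarray  # (B, B), counts[i, j] = #{X in bin i, Y in bin j}

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be a square matrix")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def bins(self) -> int:
        return self.counts.shape[0]

    @classmethod
    def from_codes(cls, x_codes: np.ndarray, y_codes: np.ndarray, bins: int) -> "JointHistogram":
        if len(x_codes) != len(y_codes):
            raise ValueError("code vectors must have equal length")
        flat = np.bincount(
            np.asarray(x_codes, dtype=np.int64) * bins + np.asarray(y_codes, dtype=np.int64),
            minlength=bins * bins,
        )
        return cls(flat.reshape(bins, bins))

    def mutual_information(self) -> float:
        """Plug-in MI in nats; 0 for degenerate (single-bin) marginals."""
        n = self.counts.sum()
        if n == 0:
            return 0.0
        p = self.counts / n
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        mask = p > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = p * np.log(p / (px * py))
        return float(max(terms[mask].sum(), 0.0))


def mutual_information(x: np.ndarray, y: np.ndarray, bins: int | None = None) -> float:
    """MI (nats) between two samples under equal-frequency discretisation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if bins is None:
        bins = default_bins(len(x))
    xc = discretize_equal_frequency(x, bins)
    yc = discretize_equal_frequency(y, bins)
    return JointHistogram.from_codes(xc, yc, bins).mutual_information()


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScoredEdge:
    tf_id: str
    target_id: str
    mi: float
    clr: float
    is_prior: bool


@dataclass
class NullModel:
    """Per-TF (or global) null CLR distribution and its retention threshold."""

    tf_id: str
    null_clr: np.ndarray
    percentile: float = 95.0

    def __post_init__(self) -> None:
        self.null_clr = np.sort(np.asarray(self.null_clr, dtype=float))

    @property
    def threshold(self) -> float:
        """Nearest-rank percentile of the sorted null sample."""
        m = len(self.null_clr)
        if m == 0:
            return 0.0
        rank = int(np.ceil(self.percentile / 100.0 * m))
        return float(self.null_clr[max(rank, 1) - 1])


@dataclass
class Trn:
    """Retained network: scored prior edges grouped into per-TF modules."""

    edges: list[ScoredEdge]
    modules: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.modules:
            for e in self.edges:
                self.modules.setdefault(e.tf_id, set()).add(e.target_id)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for e in self.edges:
            out.add(e.tf_id)
            out.add(e.target_id)
        return out

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {(e.tf_id, e.target_id) for e in self.edges}


# ---------------------------------------------------------------------------


def filter_low_variance(expr: ExpressionMatrix, drop_fraction: float = 0.05) -> ExpressionMatrix:
    """Drop the ``drop_fraction`` of genes with smallest sample SD.

    Exactly ``floor(drop_fraction * n_genes)`` genes are removed; SD ties
    are broken by gene id (lexicographically earlier ids dropped first).
    """
    if not 0 <= drop_fraction < 1:
        raise ValueError("drop_fraction must be in [0, 1)")
    if expr.n_samples < 2:
        raise ValueError("need at least 2 samples to rank by SD")
    n_drop = int(np.floor(drop_fraction * expr.n_genes))
    if n_drop == 0:
        return expr
    sd = expr.values.std(axis=1, ddof=1)
    order = sorted(range(expr.n_genes), key=lambda i: (sd[i], expr.gene_ids[i]))
    dropped = set(order[:n_drop])
    keep = [g for i, g in enumerate(expr.gene_ids) if i not in dropped]
    return expr.subset_genes(keep)


def _pair_mis(
    expr: ExpressionMatrix, pairs: list[tuple[str, str]], bins: int | None = None
) -> np.ndarray:
    """MI for many pairs; genes are discretised once."""
    if bins is None:
        bins = default_bins(expr.n_samples)
    gidx = expr.gene_index()
    needed = sorted({g for p in pairs for g in p})
    codes = {g: discretize_equal_frequency(expr.values[gidx[g]], bins) for g in needed}
    b2 = bins * bins
    mis = np.empty(len(pairs))
    log = np.log
    for k, (a, b) in enumerate(pairs):
        flat = np.bincount(codes[a] * bins + codes[b], minlength=b2).astype(float)
        n = flat.sum()
        p = flat.reshape(bins, bins) / n
        px = p.sum(axis=1, keepdims=True)
        py = p.sum(axis=0, keepdims=True)
        mask = p > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = p * log(p / (px * py))
        mis[k] = max(terms[mask].sum(), 0.0)
    return mis


def clr_from_mi(pairs: list[tuple[str, str]], mis: np.ndarray) -> np.ndarray:
    """CLR score per pair from precomputed MI values.

    For each node g, the background mean and (population) SD are taken over
    the MI of all pairs incident to g; z_g = max(0, (MI - mu_g) / sd_g) and
    clr = sqrt(z_src^2 + z_dst^2).  A node with fewer than two incident
    pairs, or with zero MI spread, contributes z = 0 from its side.
    """
    mis = np.asarray(mis, dtype=float)
    nodes = sorted({g for p in pairs for g in p})
    nidx = {g: i for i, g in enumerate(nodes)}
    src = np.array([nidx[tf] for tf, _ in pairs])
    dst = np.array([nidx[tg] for _, tg in pairs])
    incident_idx = np.concatenate([src, dst])
    incident_mi = np.concatenate([mis, mis])

    counts = np.bincount(incident_idx, minlength=len(nodes)).astype(float)
    sums = np.bincount(incident_idx, weights=incident_mi, minlength=len(nodes))
    sqs = np.bincount(incident_idx, weights=incident_mi**2, minlength=len(nodes))
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sums / counts
        var = np.maximum(sqs / counts - mean**2, 0.0)
    sd = np.sqrt(var)

    n_sparse = int(np.sum(counts < 2))
    if n_sparse:
        warnings.warn(
            f"{n_sparse} nodes have < 2 incident candidate pairs; their CLR "
            "z-contribution is 0",
            stacklevel=2,
        )

    def zside(node_idx: np.ndarray) -> np.ndarray:
        ok = (counts[node_idx] >= 2) & (sd[node_idx] > 0)
        z = np.zeros(len(node_idx))
        z[ok] = (mis[ok] - mean[node_idx][ok]) / sd[node_idx][ok]
        return np.maximum(z, 0.0)

    z_src = zside(src)
    z_dst = zside(dst)
    return np.sqrt(z_src**2 + z_dst**2)


def clr_scores(
    expr: ExpressionMatrix,
    candidate_pairs: list[tuple[str, str, bool]],
    bins: int | None = None,
) -> list[ScoredEdge]:
    """Score candidate (tf, target, is_prior) pairs with MI and CLR.

    The CLR background for a node is the MI of all candidate pairs incident
    to it (prior and null together), see :func:`clr_from_mi`.
    """
    pairs = [(tf, tg) for tf, tg, _ in candidate_pairs]
    mis = _pair_mis(expr, pairs, bins=bins)
    clr = clr_from_mi(pairs, mis)
    return [
        ScoredEdge(tf, tg, float(mis[k]), float(clr[k]), prior)
        for k, (tf, tg, prior) in enumerate(candidate_pairs)
    ]


def sample_null_pairs(
    prior: list[DirectedEdge],
    genes: list[str],
    m: int = 1000,
    scope: str = "per_tf",
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Draw non-prior TF->gene pairs without replacement as the null sample.

    ``per_tf`` draws ``m`` pairs per TF (target not among that TF's prior
    targets); ``global`` draws ``m`` pairs over all TFs.  If fewer pairs are
    available than requested, all available pairs are returned with a
    warning.
    """
    if scope not in ("per_tf", "global"):
        raise ValueError("scope must be 'per_tf' or 'global'")
    rng = np.random.default_rng(seed)
    prior_targets: dict[str, set[str]] = {}
    for e in prior:
        prior_targets.setdefault(e.source, set()).add(e.target)
    tfs = sorted(prior_targets)
    gene_arr = list(genes)

    def tf_pool(tf: str) -> list[str]:
        excl = prior_targets[tf] | {tf}
        return [g for g in gene_arr if g not in excl]

    if scope == "per_tf":
        out: list[tuple[str, str]] = []
        for tf in tfs:
            pool = tf_pool(tf)
            if len(pool) < m:
                warnings.warn(
                    f"TF {tf}: only {len(pool)} non-prior genes available "
                    f"(requested {m})",
                    stacklevel=2,
                )
                chosen = range(len(pool))
            else:
                chosen = sorted(rng.choice(len(pool), size=m, replace=False).tolist())
            out.extend((tf, pool[i]) for i in chosen)
        return out

    all_pairs = [(tf, g) for tf in tfs for g in tf_pool(tf)]
    if len(all_pairs) < m:
        warnings.warn(
            f"only {len(all_pairs)} non-prior pairs available (requested {m})",
            stacklevel=2,
        )
        return all_pairs
    idx = sorted(rng.choice(len(all_pairs), size=m, replace=False).tolist())
    return [all_pairs[i] for i in idx]


def retain_edges(
    scored: list[ScoredEdge],
    null_models: dict[str, NullModel],
    percentile: float = 95.0,
) -> Trn:
    """Keep prior edges whose CLR strictly exceeds their TF's null threshold.

    ``null_models`` maps tf_id -> NullModel, with key ``"global"`` accepted
    as a fallback for every TF.  Modules with no surviving edge are dropped.
    """
    kept: list[ScoredEdge] = []
    for e in scored:
        if not e.is_prior:
            continue
        nm = null_models.get(e.tf_id) or null_models.get("global")
        if nm is None:
            raise KeyError(f"no null model for TF {e.tf_id}")
        nm.percentile = percentile
        if e.clr > nm.threshold:
            kept.append(e)
    return Trn(edges=kept)


def infer_trn(
    expr: ExpressionMatrix,
    prior: list[DirectedEdge],
    drop_fraction: float = 0.05,
    null_size: int = 1000,
    percentile: float = 95.0,
    null_scope: str = "per_tf",
    bins: int | None = None,
    seed: int = 0,
) -> tuple[Trn, list[ScoredEdge], dict[str, NullModel]]:
    """Run the full reverse-engineering screen.

    Returns the retained network, all scored candidate edges (prior and
    null), and the per-TF null models.  Prior edges whose endpoints are
    filtered out (low variance / absent) are silently dropped from the
    candidate set.
    """
    filtered = filter_low_variance(expr, drop_fraction)
    present = set(filtered.gene_ids)
    prior_kept = [e for e in prior if e.source in present and e.target in present]
    null_pairs = sample_null_pairs(
        prior_kept, filtered.gene_ids, m=null_size, scope=null_scope, seed=seed
    )
    candidates = [(e.source, e.target, True) for e in prior_kept]
    candidates += [(tf, g, False) for tf, g in null_pairs]
    scored = clr_scores(filtered, candidates, bins=bins)

    null_models: dict[str, NullModel] = {}
    if null_scope == "per_tf":
        by_tf: dict[str, list[float]] = {}
        for e in scored:
            if not e.is_prior:
                by_tf.setdefault(e.tf_id, []).append(e.clr)
        for tf, vals in by_tf.items():
            null_models[tf] = NullModel(tf, np.array(vals), percentile)
    else:
        vals = np.array([e.clr for e in scored if not e.is_prior])
        null_models["global"] = NullModel("global", vals, percentile)

    trn = retain_edges(scored, null_models, percentile)
    return trn, scored, null_models
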