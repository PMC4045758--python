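"""Planted-truth calibration and recovery studies.

These studies run the pipeline end-to-end on synthetic data from
:mod:`cnvtrn.synthetic_data` and measure how well the planted structure is
recovered: type-I calibration of the null screen, power on planted
regulons, CNV-region recovery, and clustering recovery.  They back both
the test suite and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import rand_score

from . import synthetic_data as sim
from .cnv_profiling import (
    call_recurrent_regions,
    classify_cnv_genes,
    gene_level_cn,
    segment_profiles,
    CnvCallSet,
    CnvRegion,
)
from .io_formats import GeneSet
from .module_selection import extract_modules, select_cnv_modules
from .subtype_clustering import (
    consensus_cluster,
    loocv_error,
    nonnegativize,
    select_rank,
)
from .trn_inference import infer_trn

__all__ = [
    "null_retention_study",
    "regulon_recovery_study",
    "cnv_recovery_study",
    "clustering_recovery_study",
]


# ---------------------------------------------------------------------------
# type-I calibration of the null screen


def null_retention_study(
    n_seeds: int = 50,
    n_genes: int = 1100,
    n_tfs: int = 20,
    targets_per_tf: int = 50,
    n_samples: int = 200,
    null_size: int = 1000,
    percentile: float = 95.0,
    seed: int = 0,
) -> np.ndarray:
    """Fraction of prior edges retained per seed when no regulation exists.

    With beta = 0 every prior pair is expression-independent, so the
    retained fraction estimates the screen's false-positive rate; with a
    strict 95th-percentile cut it should sit near 5%.
    """
    fractions = np.empty(n_seeds)
    for s in range(n_seeds):
        child = (seed + 15485863 * s) % 2**31
        ann = sim.simulate_annotation(n_genes, n_tfs, n_chroms=1, seed=child)
        prior = sim.simulate_prior(ann, targets_per_tf, seed=child)
        expr, _ = sim.simulate_expression(
            ann, prior, n_samples=n_samples, beta=0.0, noise_sd=1.0, k_true=1, seed=child
        )
        trn, _, _ = infer_trn(
            expr,
            prior,
            drop_fraction=0.0,
            null_size=null_size,
            percentile=percentile,
            seed=child,
        )
        fractions[s] = len(trn.edges) / len(prior)
    return fractions


# ---------------------------------------------------------------------------
# power and module recovery with a planted active regulon


@dataclass
class RegulonRecovery:
    edge_recall: float  # retained fraction of planted active edges
    module_selected: bool  # planted CNV-TF module survives selection
    module_type: str | None


def regulon_recovery_study(
    n_seeds: int = 100,
    n_genes: int = 1100,
    n_tfs: int = 8,
    targets_per_tf: int = 25,
    n_samples: int = 150,
    beta: float = 2.0,
    noise_sd: float = 0.1,
    null_size: int = 1000,
    seed: int = 0,
) -> list[RegulonRecovery]:
    """Recover planted active regulons and re-select the planted CNV module.

    One TF per seed is declared a CNV-TF, and a pathway gene set is built
    from half of its prior targets, so that the planted module must pass
    both enrichment screens of the selection step.
    """
    out: list[RegulonRecovery] = []
    for s in range(n_seeds):
        child = (seed + 32452843 * s) % 2**31
        ann = sim.simulate_annotation(n_genes, n_tfs, n_chroms=1, seed=child)
        prior = sim.simulate_prior(ann, targets_per_tf, seed=child)
        expr, truth = sim.simulate_expression(
            ann,
            prior,
            n_samples=n_samples,
            beta=beta,
            noise_sd=noise_sd,
            k_true=1,
            active_fraction=1.0,
            seed=child,
        )
        trn, _, _ = infer_trn(
            expr, prior, drop_fraction=0.0, null_size=null_size, seed=child
        )
        retained = trn.edge_pairs()
        recall = len(retained & truth.planted_edges) / len(truth.planted_edges)

        tfs = sorted({e.source for e in prior})
        planted_tf = tfs[0]
        planted_targets = sorted(e.target for e in prior if e.source == planted_tf)
        pathway_genes = frozenset(planted_targets[: max(len(planted_targets) // 2, 2)])
        gene_sets = {"PLANTED_PATHWAY": GeneSet("PLANTED_PATHWAY", "", pathway_genes)}
        cnv_call = CnvCallSet(
            cnv_genes={planted_tf},
            cnv_tfs={planted_tf},
            regions=[],
            table=None,  # type: ignore[arg-type]
        )
        modules = extract_modules(trn)
        network_genes = trn.genes
        expressed = set(expr.gene_ids)
        selected = (
            select_cnv_modules(modules, gene_sets, cnv_call, network_genes, expressed)
            if modules
            else []
        )
        hit = next((m for m in selected if m.tf_id == planted_tf), None)
        out.append(
            RegulonRecovery(
                edge_recall=recall,
                module_selected=hit is not None,
                module_type=hit.module_type if hit else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# CNV region recovery


@dataclass
class CnvRecovery:
    regions: list[CnvRegion]
    call_set: CnvCallSet
    direction_correct: bool
    boundary_error_genes: int  # max |boundary offset| in genes (large if missed)
    frequency_error: float
    planted_frequency: float


def cnv_recovery_study(
    n_genes: int = 40,
    n_tfs: int = 2,
    n_samples: int = 100,
    amplitude: float = 0.8,
    carrier_freq: float = 0.3,
    noise_sd: float = 0.1,
    region_genes: tuple[int, int] = (15, 25),
    marker_spacing: int = 4000,
    cbs_n_perm: int = 200,
    call_n_perm: int = 500,
    seed: int = 0,
) -> CnvRecovery:
    """Plant one amplified region, segment, call, and score the recovery.

    The planted region spans genes ``region_genes[0]..region_genes[1]-1``
    of a single chromosome.  Boundary error is measured in genes against
    the planted gene span; frequency error compares the called region
    frequency with the realised carrier fraction.
    """
    ann = sim.simulate_annotation(n_genes, n_tfs, n_chroms=1, seed=seed)
    lo, hi = region_genes
    start = int(ann.iloc[lo]["start"])
    end = int(ann.iloc[hi - 1]["end"])
    profiles, truth = sim.simulate_cnv(
        ann,
        [("chr1", start, end, "amp", amplitude)],
        n_samples=n_samples,
        carrier_freq=carrier_freq,
        marker_spacing=marker_spacing,
        noise_sd=noise_sd,
        seed=seed,
    )
    segments = segment_profiles(profiles, alpha=0.01, n_perm=cbs_n_perm, seed=seed)
    gene_cn = gene_level_cn(segments, ann)
    regions = call_recurrent_regions(
        gene_cn, ann, n_perm=call_n_perm, seed=seed
    )
    call_set = classify_cnv_genes(regions, ann)

    planted_genes = ann.iloc[lo:hi]["gene_id"].tolist()
    planted_freq = len(truth.planted_regions[0].carriers) / n_samples
    gene_pos = {g: i for i, g in enumerate(ann["gene_id"])}

    amp_regions = [r for r in regions if r.direction == "amp"]
    if not amp_regions:
        return CnvRecovery(regions, call_set, False, n_genes, 1.0, planted_freq)
    best = max(amp_regions, key=lambda r: len(set(r.gene_ids) & set(planted_genes)))
    first = gene_pos[best.gene_ids[0]]
    last = gene_pos[best.gene_ids[-1]]
    boundary_err = max(abs(first - lo), abs(last - (hi - 1)))
    freq_err = abs(best.frequency - planted_freq)
    return CnvRecovery(
        regions=regions,
        call_set=call_set,
        direction_correct=True,
        boundary_error_genes=int(boundary_err),
        frequency_error=float(freq_err),
        planted_frequency=planted_freq,
    )


# ---------------------------------------------------------------------------
# clustering recovery


@dataclass
class ClusteringRecovery:
    best_k: int
    cophenetics: dict[int, float]
    rand_index: float
    loocv_errors: dict[str, float]
    consensus_offblock_max: float  # largest between-cluster consensus entry


def clustering_recovery_study(
    n_genes: int = 200,
    n_tfs: int = 5,
    n_samples: int = 60,
    k_true: int = 2,
    cluster_shift: float = 3.0,
    n_restarts: int = 30,
    k_range: range = range(2, 6),
    max_iter: int = 300,
    seed: int = 0,
) -> ClusteringRecovery:
    """Plant separable sample clusters and recover them by NMF consensus."""
    ann = sim.simulate_annotation(n_genes, n_tfs, n_chroms=1, seed=seed)
    expr, truth = sim.simulate_expression(
        ann,
        prior=[],
        n_samples=n_samples,
        beta=0.0,
        noise_sd=1.0,
        k_true=k_true,
        cluster_shift=cluster_shift,
        active_fraction=0.0,
        seed=seed,
    )
    V, _ = nonnegativize(expr.values)
    results = consensus_cluster(
        V, expr.sample_ids, k_range=k_range, n_restarts=n_restarts,
        seed=seed, max_iter=max_iter,
    )
    best = select_rank(results)
    true_labels = np.array([truth.cluster_labels[s] for s in expr.sample_ids])
    ri = float(rand_score(true_labels, best.labels))

    same = true_labels[:, None] == true_labels[None, :]
    offblock = best.consensus[~same]
    offblock_max = float(offblock.max()) if offblock.size else 0.0

    errors = {
        clf: loocv_error(V.T, best.labels, classifier=clf)
        for clf in ("knn", "weighted_voting", "cart")
    }
    return ClusteringRecovery(
        best_k=best.k,
        cophenetics={r.k: r.cophenetic for r in results},
        rand_index=ri,
        loocv_errors=errors,
        consensus_offblock_max=offblock_max,
    )
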