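"""Paired synthetic expression / copy-number data with planted truth.

Every downstream stage of the pipeline has a recovery test against data
produced here: contiguous amplified or deleted genomic regions carried by
a random subset of samples, TF->target co-expression planted on a subset
of the sequence-prior edges, and separable sample clusters created by
mean shifts on an informative gene subset.

The expression model is linear-Gaussian: a TF's expression is standard
normal around its cluster mean, an active target is ``beta * tf + noise``,
and everything else is independent noise.  Under this model the Pearson
correlation of an active pair concentrates at ``beta / sqrt(beta^2 +
noise_sd^2)``, which makes planted effect sizes recoverable and gives a
mutual-information screen a monotone signal to detect.

A single global integer seed fans out to fixed per-stage child seeds, so
stages are reproducible independently of one another.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cnv_profiling import AMP, DEL, MarkerProfile
from .io_formats import ANNOTATION_COLUMNS, DirectedEdge, ExpressionMatrix, validate_annotation

__all__ = [
    "SimulationTruth",
    "PlantedRegion",
    "simulate_annotation",
    "simulate_prior",
    "simulate_cnv",
    "simulate_expression",
]

GENE_LENGTH = 10_000
GENE_GAP = 10_000
DEFAULT_MARKER_SPACING = 10_000

# fixed child-seed offsets per stage
_OFFSETS = {"annotation": 11, "prior": 23, "cnv": 37, "expression": 53}


def _child_seed(seed: int, stage: str) -> int:
    return (int(seed) + _OFFSETS[stage] * 1_000_003) % 2**31


@dataclass(frozen=True)
class PlantedRegion:
    chrom: str
    start: int
    end: int
    direction: str
    amplitude: float
    carriers: frozenset[str]


@dataclass
class SimulationTruth:
    """Ground truth planted by the generator."""

    seed: int
    planted_regions: list[PlantedRegion] = field(default_factory=list)
    planted_edges: set[tuple[str, str]] = field(default_factory=set)
    edge_beta: float = 0.0
    cluster_labels: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------


def simulate_annotation(
    n_genes: int, n_tfs: int, n_chroms: int = 1, seed: int = 0
) -> pd.DataFrame:
    """Place ``n_genes`` non-overlapping genes on ``n_chroms`` chromosomes.

    Genes are laid out in order with fixed length/gap; exactly ``n_tfs``
    are flagged as transcription factors (a seeded random subset).
    """
    if not 0 < n_tfs < n_genes:
        raise ValueError(f"need 0 < n_tfs < n_genes, got n_tfs={n_tfs}, n_genes={n_genes}")
    if n_chroms < 1:
        raise ValueError("n_chroms must be >= 1")
    rng = np.random.default_rng(_child_seed(seed, "annotation"))
    tf_rows = set(rng.choice(n_genes, size=n_tfs, replace=False).tolist())
    per_chrom = int(np.ceil(n_genes / n_chroms))
    rows = []
    for gi in range(n_genes):
        chrom = f"chr{gi // per_chrom + 1}"
        slot = gi % per_chrom
        start = slot * (GENE_LENGTH + GENE_GAP)
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "end": start + GENE_LENGTH,
                "gene_id": f"G{gi:05d}",
                "is_tf": gi in tf_rows,
            }
        )
    return validate_annotation(pd.DataFrame(rows, columns=ANNOTATION_COLUMNS))


def simulate_prior(
    annotation: pd.DataFrame, targets_per_tf: int, seed: int = 0
) -> list[DirectedEdge]:
    """Sample a sequence-style prior: each TF gets uniform random targets."""
    if targets_per_tf < 1:
        raise ValueError("targets_per_tf must be >= 1")
    genes = annotation["gene_id"].tolist()
    tfs = annotation.loc[annotation["is_tf"], "gene_id"].tolist()
    if targets_per_tf > len(genes) - 1:
        raise ValueError(
            f"targets_per_tf={targets_per_tf} exceeds available non-self genes "
            f"({len(genes) - 1})"
        )
    rng = np.random.default_rng(_child_seed(seed, "prior"))
    edges: list[DirectedEdge] = []
    for tf in tfs:
        pool = [g for g in genes if g != tf]
        targets = rng.choice(len(pool), size=targets_per_tf, replace=False)
        edges.extend(DirectedEdge(tf, pool[t], "prior") for t in sorted(targets))
    return edges


def simulate_cnv(
    annotation: pd.DataFrame,
    regions_spec: list[tuple[str, int, int, str, float]],
    n_samples: int,
    carrier_freq: float = 0.3,
    marker_spacing: int = DEFAULT_MARKER_SPACING,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> tuple[list[MarkerProfile], SimulationTruth]:
    """Simulate marker-level log-ratio profiles with planted CNV regions.

    ``regions_spec`` rows are ``(chrom, start, end, direction, amplitude)``
    with ``direction`` in {"amp", "del"} and ``|amplitude| > 0.3`` (the
    aberration-calling threshold — weaker plants would be undetectable by
    construction).  Each sample carries each region independently with
    probability ``carrier_freq``; carriers get a mean shift of +amplitude
    (amp) or -amplitude (del) at markers inside the region, and i.i.d.
    Gaussian noise is added everywhere.
    """
    validate_annotation(annotation)
    if not 0 < carrier_freq <= 1:
        raise ValueError("carrier_freq must be in (0, 1]")
    spec = []
    for chrom, start, end, direction, amplitude in regions_spec:
        if direction not in (AMP, DEL):
            raise ValueError(f"direction must be amp/del, got {direction}")
        if abs(amplitude) <= 0.3:
            raise ValueError(f"planted |amplitude| must exceed 0.3, got {amplitude}")
        spec.append((str(chrom), int(start), int(end), direction, abs(float(amplitude))))
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end, *_ in spec:
        for a, b in by_chrom.get(chrom, []):
            if max(a, start) < min(b, end):
                raise ValueError(f"overlapping planted regions on {chrom}")
        by_chrom.setdefault(chrom, []).append((start, end))

    rng = np.random.default_rng(_child_seed(seed, "cnv"))
    sample_ids = [f"S{si:04d}" for si in range(n_samples)]

    chrom_len = annotation.groupby("chrom")["end"].max().to_dict()
    marker_pos = {
        chrom: np.arange(marker_spacing // 2, int(length), marker_spacing, dtype=np.int64)
        for chrom, length in sorted(chrom_len.items())
    }

    planted: list[PlantedRegion] = []
    shift: dict[str, np.ndarray] = {
        chrom: np.zeros((n_samples, len(pos))) for chrom, pos in marker_pos.items()
    }
    for chrom, start, end, direction, amplitude in spec:
        carriers = np.flatnonzero(rng.random(n_samples) < carrier_freq)
        signed = amplitude if direction == AMP else -amplitude
        pos = marker_pos[chrom]
        inside = (pos >= start) & (pos < end)
        shift[chrom][np.ix_(carriers, inside)] += signed
        planted.append(
            PlantedRegion(
                chrom=chrom,
                start=start,
                end=end,
                direction=direction,
                amplitude=amplitude,
                carriers=frozenset(sample_ids[c] for c in carriers),
            )
        )

    profiles: list[MarkerProfile] = []
    for chrom, pos in marker_pos.items():
        noise = (
            rng.normal(0.0, noise_sd, size=(n_samples, len(pos)))
            if noise_sd > 0
            else np.zeros((n_samples, len(pos)))
        )
        signal = shift[chrom] + noise
        for si, sample in enumerate(sample_ids):
            profiles.append(MarkerProfile(sample, chrom, pos.copy(), signal[si]))
    profiles.sort(key=lambda p: (p.sample_id, p.chrom))
    truth = SimulationTruth(seed=seed, planted_regions=planted)
    return profiles, truth


def simulate_expression(
    annotation: pd.DataFrame,
    prior: list[DirectedEdge],
    n_samples: int,
    beta: float = 2.0,
    noise_sd: float = 0.1,
    k_true: int = 1,
    active_fraction: float = 1.0,
    cluster_shift: float = 3.0,
    informative_fraction: float = 0.8,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimulationTruth]:
    """Simulate expression with planted regulons and planted sample clusters.

    A seeded ``active_fraction`` of prior edges is planted as active;
    an active target equals ``beta * tf_expression + N(0, noise_sd)``.
    At most one active regulator is planted per target (ties resolved to
    the lexicographically first TF) and TF expression is never overwritten,
    so every planted edge carries the full, undiluted effect size.
    Samples are split into ``k_true`` balanced clusters; an informative
    subset of non-target genes has its mean shifted by ``cluster_shift`` in
    one cluster each, which makes the clusters separable.  All other genes
    are independent standard normal.  With unit per-gene noise the average
    silhouette of the true labels is about ``1 - sqrt(2p / (2p + s^2 m))``
    (p genes, m informative, shift s), so a majority of genes must be
    informative for clearly separated clusters; the default fraction 0.8
    gives silhouette ~0.5 at the default shift of 3.
    """
    validate_annotation(annotation)
    if not 0 <= active_fraction <= 1:
        raise ValueError("active_fraction must be in [0, 1]")
    if k_true > n_samples:
        raise ValueError(f"k_true={k_true} exceeds n_samples={n_samples}")
    if k_true < 1:
        raise ValueError("k_true must be >= 1")

    rng = np.random.default_rng(_child_seed(seed, "expression"))
    genes = annotation["gene_id"].tolist()
    gidx = {g: i for i, g in enumerate(genes)}
    sample_ids = [f"S{si:04d}" for si in range(n_samples)]

    labels = np.array([si % k_true + 1 for si in range(n_samples)])

    n_active = int(round(active_fraction * len(prior)))
    active_rows = set(rng.choice(len(prior), size=n_active, replace=False).tolist()) if n_active else set()
    drawn = {(prior[i].source, prior[i].target) for i in sorted(active_rows)}
    tf_set = set(annotation.loc[annotation["is_tf"], "gene_id"])
    active_regulator: dict[str, str] = {}
    for tf, tg in sorted(drawn):
        if tg in tf_set:  # TF expression stays exogenous N(cluster_mean, 1)
            continue
        active_regulator.setdefault(tg, tf)
    active_edges = {(tf, tg) for tg, tf in active_regulator.items()}

    values = rng.normal(0.0, 1.0, size=(len(genes), n_samples))

    # cluster-informative genes: non-TF genes that are not active targets
    if k_true > 1 and cluster_shift != 0.0:
        candidates = [g for g in genes if g not in tf_set and g not in active_regulator]
        n_info = max(k_true, int(round(informative_fraction * len(candidates))))
        info = rng.choice(len(candidates), size=min(n_info, len(candidates)), replace=False)
        for rank, ci in enumerate(sorted(info)):
            gene = candidates[ci]
            cluster = rank % k_true + 1
            values[gidx[gene], labels == cluster] += cluster_shift

    # overwrite active targets from their regulator
    for target, tf in sorted(active_regulator.items()):
        noise = rng.normal(0.0, noise_sd, size=n_samples) if noise_sd > 0 else 0.0
        values[gidx[target]] = beta * values[gidx[tf]] + noise

    expr = ExpressionMatrix(genes, sample_ids, values)
    truth = SimulationTruth(
        seed=seed,
        planted_edges=active_edges,
        edge_beta=beta,
        cluster_labels=dict(zip(sample_ids, labels.tolist())),
    )
    return expr, truth
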