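"""Copy-number profiling: segmentation and recurrent aberration calling.

Per-sample marker-level log-ratio profiles are segmented with a circular
binary-segmentation scheme (recursive change-point search with a
permutation test per split).  Segment means are collapsed to gene-level
copy-number values by length-weighted averaging, and recurrent amplified /
deleted regions are called with a G-score statistic against a
within-sample permutation null, Benjamini-Hochberg corrected.

This is deliberately simpler than marker-level peak callers: no peel-off,
no peak-boundary confidence intervals.  Downstream analysis only consumes
region membership, direction, frequency and q-value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .io_formats import Segment, validate_annotation

__all__ = [
    "MarkerProfile",
    "CnvRegion",
    "CnvCallSet",
    "segment_profile",
    "segment_profiles",
    "gene_level_cn",
    "call_recurrent_regions",
    "classify_cnv_genes",
]

AMP, DEL = "amp", "del"


@dataclass
class MarkerProfile:
    """Ordered marker positions and log2 copy-number ratios for one sample."""

    sample_id: str
    chrom: str
    positions: np.ndarray
    log_ratios: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.log_ratios = np.asarray(self.log_ratios, dtype=float)
        if self.positions.shape != self.log_ratios.shape:
            raise ValueError("positions and log_ratios must have equal length")
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError(
                f"marker positions not strictly increasing "
                f"(sample {self.sample_id}, chrom {self.chrom})"
            )
        if not np.all(np.isfinite(self.log_ratios)):
            raise ValueError(f"non-finite log ratio in sample {self.sample_id}")


@dataclass
class CnvRegion:
    """A recurrent amplified or deleted region spanning adjacent genes."""

    chrom: str
    start: int
    end: int
    direction: str
    q_value: float
    frequency: float
    gene_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.direction not in (AMP, DEL):
            raise ValueError(f"direction must be 'amp' or 'del', got {self.direction}")
        if not self.start < self.end:
            raise ValueError("region start must be < end")


@dataclass
class CnvCallSet:
    """Genes and TFs covered by significant recurrent CNV regions."""

    cnv_genes: set[str]
    cnv_tfs: set[str]
    regions: list[CnvRegion]
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.cnv_tfs <= self.cnv_genes:
            raise ValueError("cnv_tfs must be a subset of cnv_genes")


# ---------------------------------------------------------------------------
# segmentation


def _arc_tstats(prefix: np.ndarray, prefix_sq: np.ndarray, width: int) -> np.ndarray:
    """|t| of inside-vs-outside means for all arcs of a given width.

    ``prefix``/``prefix_sq`` are cumulative sums with a leading zero over one
    or more (rows of) value vectors of length m.  Returns |t| for every start
    position (vectorised over rows); arcs with zero pooled variance but a
    mean difference get t = inf.
    """
    m = prefix.shape[-1] - 1
    n_in = width
    n_out = m - width
    s_in = prefix[..., width:] - prefix[..., :-width]
    ss_in = prefix_sq[..., width:] - prefix_sq[..., :-width]
    total = prefix[..., -1:]
    total_sq = prefix_sq[..., -1:]
    s_out = total - s_in
    ss_out = total_sq - ss_in
    mean_in = s_in / n_in
    mean_out = s_out / n_out
    # pooled variance; dof = m - 2
    sse = (ss_in - n_in * mean_in**2) + (ss_out - n_out * mean_out**2)
    sse = np.maximum(sse, 0.0)
    denom_dof = max(m - 2, 1)
    se = np.sqrt(sse / denom_dof * (1.0 / n_in + 1.0 / n_out))
    diff = np.abs(mean_in - mean_out)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
    t = np.where(se == 0.0, np.where(diff > 0, np.inf, 0.0), t)
    return t


def _best_arc(values: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Maximal |t| circular arc (i, j] of ``values``; leftmost tie-break.

    Returns (t, i, j) with inside = values[i:j]; both sides have at least
    ``min_width`` markers.
    """
    m = len(values)
    prefix = np.concatenate([[0.0], np.cumsum(values)])
    prefix_sq = np.concatenate([[0.0], np.cumsum(values**2)])
    best_t, best_i, best_j = -1.0, -1, -1
    for width in range(min_width, m - min_width + 1):
        t = _arc_tstats(prefix, prefix_sq, width)
        i = int(np.argmax(t))
        if t[i] > best_t:
            best_t, best_i, best_j = float(t[i]), i, i + width
    return best_t, best_i, best_j


def _perm_pvalue(
    values: np.ndarray, observed_t: float, min_width: int, n_perm: int, rng: np.random.Generator
) -> float:
    """Permutation p-value of the maximal arc statistic."""
    m = len(values)
    perms = rng.permuted(np.tile(values, (n_perm, 1)), axis=1)
    prefix = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(perms, axis=1)], axis=1)
    prefix_sq = np.concatenate(
        [np.zeros((n_perm, 1)), np.cumsum(perms**2, axis=1)], axis=1
    )
    null_max = np.full(n_perm, -np.inf)
    for width in range(min_width, m - min_width + 1):
        t = _arc_tstats(prefix, prefix_sq, width)
        np.maximum(null_max, t.max(axis=1), out=null_max)
    exceed = int(np.sum(null_max >= observed_t))
    return (1 + exceed) / (1 + n_perm)


def _segment_recursive(
    values: np.ndarray,
    lo: int,
    hi: int,
    alpha: float,
    n_perm: int,
    min_width: int,
    rng: np.random.Generator,
    breakpoints: set[int],
) -> None:
    m = hi - lo
    if m < 2 * min_width:
        return
    v = values[lo:hi]
    if np.ptp(v) == 0.0:
        return
    t, i, j = _best_arc(v, min_width)
    if t <= 0.0:
        return
    p = _perm_pvalue(v, t, min_width, n_perm, rng)
    if p >= alpha:
        return
    cuts = sorted({lo + i, lo + j} - {lo, hi})
    if not cuts:
        return
    breakpoints.update(cuts)
    bounds = [lo, *cuts, hi]
    for a, b in zip(bounds, bounds[1:]):
        _segment_recursive(values, a, b, alpha, n_perm, min_width, rng, breakpoints)


def segment_profile(
    profile: MarkerProfile,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int = 0,
) -> list[Segment]:
    """Segment one marker profile by recursive circular binary splits.

    Each candidate split maximises the pooled-variance |t| between the
    markers inside an arc and those outside it; the split is accepted when
    its permutation p-value (``n_perm`` shuffles within the current segment)
    is below ``alpha``.  Segment boundaries are placed at midpoints between
    flanking markers so that segments tile the profiled interval.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    values = profile.log_ratios
    m = len(values)
    if m < 2 * min_width:
        warnings.warn(
            f"profile {profile.sample_id}/{profile.chrom} has {m} markers "
            f"(< {2 * min_width}); returning a single segment",
            stacklevel=2,
        )
        breakpoints: set[int] = set()
    else:
        rng = np.random.default_rng(seed)
        breakpoints = set()
        _segment_recursive(values, 0, m, alpha, n_perm, min_width, rng, breakpoints)

    pos = profile.positions
    if m > 1:
        spacing = int(round(np.median(np.diff(pos))))
    else:
        spacing = 1
    # boundary between marker k-1 and k
    def marker_bound(k: int) -> int:
        if k == 0:
            return max(int(pos[0]) - spacing // 2, 0)
        if k == m:
            return int(pos[-1]) + spacing // 2 + 1
        return int(pos[k - 1] + pos[k]) // 2

    idx_bounds = [0, *sorted(breakpoints), m]
    segments = []
    for a, b in zip(idx_bounds, idx_bounds[1:]):
        segments.append(
            Segment(
                sample_id=profile.sample_id,
                chrom=profile.chrom,
                start=marker_bound(a),
                end=marker_bound(b),
                num_markers=b - a,
                mean_log_ratio=float(np.mean(values[a:b])),
            )
        )
    return segments


def segment_profiles(
    profiles: list[MarkerProfile],
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int = 0,
) -> list[Segment]:
    """Segment many profiles; each gets a deterministic child seed."""
    out: list[Segment] = []
    for k, p in enumerate(profiles):
        out.extend(segment_profile(p, alpha, n_perm, min_width, seed=(seed + 1000003 * k) % 2**31))
    return out


# ---------------------------------------------------------------------------
# gene-level copy number


def gene_level_cn(segments: list[Segment], annotation: pd.DataFrame) -> pd.DataFrame:
    """Collapse segment means to a gene x sample copy-number matrix.

    A gene's value is the length-weighted mean of the segment means
    overlapping its interval; genes overlapping no segment of a sample are
    missing (NaN) for that sample.
    """
    validate_annotation(annotation)
    samples = sorted({s.sample_id for s in segments})
    sample_idx = {s: j for j, s in enumerate(samples)}
    genes = annotation["gene_id"].tolist()
    values = np.full((len(genes), len(samples)), np.nan)

    by_chrom: dict[str, dict[str, list[Segment]]] = {}
    for s in segments:
        by_chrom.setdefault(s.chrom, {}).setdefault(s.sample_id, []).append(s)

    seen_chroms = set(by_chrom)
    missing_chroms = set(annotation["chrom"]) - seen_chroms
    if missing_chroms:
        warnings.warn(
            f"annotation chromosomes absent from all profiles: {sorted(missing_chroms)}; "
            "their genes are missing",
            stacklevel=2,
        )

    for gi, row in enumerate(annotation.itertuples(index=False)):
        per_sample = by_chrom.get(row.chrom)
        if per_sample is None:
            continue
        for sample, segs in per_sample.items():
            wsum = 0.0
            vsum = 0.0
            for seg in segs:
                ov = min(row.end, seg.end) - max(row.start, seg.start)
                if ov > 0:
                    wsum += ov
                    vsum += ov * seg.mean_log_ratio
            if wsum > 0:
                values[gi, sample_idx[sample]] = vsum / wsum
    return pd.DataFrame(values, index=genes, columns=samples)


# ---------------------------------------------------------------------------
# recurrent region calling


def _g_scores(values: np.ndarray, amp_thr: float, del_thr: float) -> np.ndarray:
    """Per-gene (rows) amp and del G-scores, NaN-aware.  Shape (2, n_genes)."""
    amp = np.nansum(np.maximum(values - amp_thr, 0.0), axis=1)
    dele = np.nansum(np.maximum(del_thr - values, 0.0), axis=1)
    return np.vstack([amp, dele])


def call_recurrent_regions(
    gene_cn: pd.DataFrame,
    annotation: pd.DataFrame,
    amp_thr: float = 0.3,
    del_thr: float = -0.3,
    q_thr: float = 0.25,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[CnvRegion]:
    """Call recurrent amplified/deleted regions from gene-level copy number.

    Per gene and direction a G-score sums, over samples, the amplitude in
    excess of the directional threshold.  The null distribution comes from
    ``n_perm`` rounds in which every sample's gene values are independently
    permuted; null G-scores are pooled across genes (genes are exchangeable
    under this null).  Empirical p-values are BH-adjusted across
    genes x directions, and regions are maximal runs of genome-adjacent
    genes with q < ``q_thr`` in the same direction.

    Region frequency is the fraction of samples whose mean gene-level value
    across the region exceeds the directional threshold.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    validate_annotation(annotation)
    ann = annotation.set_index("gene_id").loc[gene_cn.index]
    values = gene_cn.to_numpy(dtype=float)

    all_missing = np.all(np.isnan(values), axis=1)
    if all_missing.any():
        warnings.warn(
            f"{int(all_missing.sum())} genes have no copy-number value in any "
            "sample and are excluded",
            stacklevel=2,
        )
    keep = ~all_missing
    values = values[keep]
    ann = ann[keep]
    gene_ids = list(gene_cn.index[keep])
    n_genes, n_samples = values.shape
    if n_genes == 0:
        return []

    obs = _g_scores(values, amp_thr, del_thr)

    rng = np.random.default_rng(seed)
    null_amp = np.empty(n_perm * n_genes)
    null_del = np.empty(n_perm * n_genes)
    for r in range(n_perm):
        perm = rng.permuted(values, axis=0)  # each sample column shuffled independently
        g = _g_scores(perm, amp_thr, del_thr)
        null_amp[r * n_genes : (r + 1) * n_genes] = g[0]
        null_del[r * n_genes : (r + 1) * n_genes] = g[1]
    null_amp.sort()
    null_del.sort()

    def empirical_p(obs_row: np.ndarray, null_sorted: np.ndarray) -> np.ndarray:
        # P(null >= obs), add-one corrected
        n_null = len(null_sorted)
        geq = n_null - np.searchsorted(null_sorted, obs_row, side="left")
        return (1.0 + geq) / (1.0 + n_null)

    p_amp = empirical_p(obs[0], null_amp)
    p_del = empirical_p(obs[1], null_del)
    _, q_all, _, _ = multipletests(np.concatenate([p_amp, p_del]), method="fdr_bh")
    q_amp, q_del = q_all[:n_genes], q_all[n_genes:]

    # significant direction per gene: smaller q wins; require G-score > 0
    sig_dir = np.full(n_genes, "", dtype=object)
    q_gene = np.ones(n_genes)
    for gi in range(n_genes):
        cands = []
        if q_amp[gi] < q_thr and obs[0, gi] > 0:
            cands.append((q_amp[gi], AMP))
        if q_del[gi] < q_thr and obs[1, gi] > 0:
            cands.append((q_del[gi], DEL))
        if cands:
            q_gene[gi], sig_dir[gi] = min(cands)

    # maximal runs of genome-adjacent significant genes with equal direction
    order = np.lexsort((ann["start"].to_numpy(), ann["chrom"].to_numpy()))
    regions: list[CnvRegion] = []
    run: list[int] = []

    def flush(run: list[int]) -> None:
        if not run:
            return
        members = [gene_ids[i] for i in run]
        direction = sig_dir[run[0]]
        sub = values[run]
        region_means = np.nanmean(sub, axis=0)
        with np.errstate(invalid="ignore"):
            if direction == AMP:
                passing = region_means > amp_thr
            else:
                passing = region_means < del_thr
        denom = int(np.sum(~np.isnan(region_means)))
        freq = float(np.sum(passing)) / denom if denom else 0.0
        regions.append(
            CnvRegion(
                chrom=str(ann.iloc[run[0]]["chrom"]),
                start=int(ann.iloc[run[0]]["start"]),
                end=int(max(ann.iloc[i]["end"] for i in run)),
                direction=str(direction),
                q_value=float(np.min(q_gene[run])),
                frequency=freq,
                gene_ids=members,
            )
        )

    prev_chrom = None
    for oi in order:
        if sig_dir[oi] == "":
            flush(run)
            run = []
            prev_chrom = None
            continue
        if run and (ann.iloc[oi]["chrom"] != prev_chrom or sig_dir[oi] != sig_dir[run[-1]]):
            flush(run)
            run = []
        run.append(oi)
        prev_chrom = ann.iloc[oi]["chrom"]
    flush(run)
    return sorted(regions, key=lambda r: (r.chrom, r.start))


def classify_cnv_genes(regions: list[CnvRegion], annotation: pd.DataFrame) -> CnvCallSet:
    """Union region members into CNV-gene and CNV-TF sets with a region table."""
    validate_annotation(annotation)
    is_tf = dict(zip(annotation["gene_id"], annotation["is_tf"]))
    cnv_genes: set[str] = set()
    for r in regions:
        cnv_genes |= set(r.gene_ids)
    cnv_tfs = {g for g in cnv_genes if is_tf.get(g, False)}
    rows = []
    for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
        tfs = sorted(g for g in r.gene_ids if is_tf.get(g, False))
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "q.value": r.q_value,
                "Amp/Del": "Amp" if r.direction == AMP else "Del",
                "Frequence": r.frequency,
                "n_genes": len(r.gene_ids),
                "TFs": ",".join(tfs),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "q.value", "Amp/Del", "Frequence", "n_genes", "TFs"],
    )
    return CnvCallSet(cnv_genes=cnv_genes, cnv_tfs=cnv_tfs, regions=list(regions), table=table)
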