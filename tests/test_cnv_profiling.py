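import numpy as np
import pandas as pd
import pytest

from cnvtrn.cnv_profiling import (
    MarkerProfile,
    CnvRegion,
    call_recurrent_regions,
    classify_cnv_genes,
    gene_level_cn,
    segment_profile,
)
from cnvtrn.io_formats import Segment, validate_annotation


def make_profile(values, sample="S1", chrom="chr1", spacing=1000):
    values = np.asarray(values, dtype=float)
    pos = np.arange(len(values)) * spacing + spacing // 2
    return MarkerProfile(sample, chrom, pos, values)


class TestSegmentation:
    def test_constant_profile_single_segment(self):
        segs = segment_profile(make_profile(np.zeros(100)), n_perm=100)
        assert len(segs) == 1
        assert segs[0].mean_log_ratio == 0.0
        assert segs[0].num_markers == 100

    def test_noiseless_step_exact_breakpoint(self):
        vals = np.concatenate([np.zeros(50), np.full(50, 0.8)])
        segs = segment_profile(make_profile(vals), alpha=0.05, n_perm=200, seed=1)
        assert len(segs) == 2
        assert [s.num_markers for s in segs] == [50, 50]
        assert segs[0].mean_log_ratio == pytest.approx(0.0)
        assert segs[1].mean_log_ratio == pytest.approx(0.8)

    def test_noiseless_plateau_three_segments(self):
        vals = np.concatenate([np.zeros(40), np.full(30, -0.7), np.zeros(40)])
        segs = segment_profile(make_profile(vals), alpha=0.05, n_perm=200, seed=2)
        assert [s.num_markers for s in segs] == [40, 30, 40]
        assert segs[1].mean_log_ratio == pytest.approx(-0.7)

    def test_noisy_step_breakpoint_within_two_markers(self):
        hits = 0
        n_runs = 20
        for s in range(n_runs):
            rng = np.random.default_rng(1000 + s)
            vals = np.concatenate([np.zeros(100), np.full(100, 0.8)])
            vals = vals + rng.normal(0, 0.1, size=200)
            segs = segment_profile(make_profile(vals), alpha=0.01, n_perm=200, seed=s)
            cuts = np.cumsum([seg.num_markers for seg in segs])[:-1]
            if len(cuts) and min(abs(c - 100) for c in cuts) <= 2:
                hits += 1
        assert hits >= int(0.9 * n_runs)

    def test_too_few_markers_warns_single_segment(self):
        with pytest.warns(UserWarning, match="single segment"):
            segs = segment_profile(make_profile([0.1, 0.2, 0.3]), min_width=2, n_perm=100)
        assert len(segs) == 1

    def test_segments_tile_profile(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0, 0.2, size=120)
        segs = segment_profile(make_profile(vals), n_perm=100, seed=3)
        assert sum(s.num_markers for s in segs) == 120
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start


class TestGeneLevelCn:
    def test_gene_inside_one_segment(self, tiny_annotation):
        segs = [Segment("S1", "chr1", 0, 60000, 60, 0.42)]
        with pytest.warns(UserWarning, match="absent"):
            cn = gene_level_cn(segs, tiny_annotation)
        assert cn.loc["G0", "S1"] == pytest.approx(0.42)
        assert np.isnan(cn.loc["G3", "S1"])  # chr2 unprofiled

    def test_gene_split_across_segments_weighted(self):
        ann = validate_annotation(
            pd.DataFrame(
                {"chrom": ["chr1"], "start": [0], "end": [1000],
                 "gene_id": ["G"], "is_tf": [False]}
            )
        )
        segs = [
            Segment("S1", "chr1", 0, 500, 5, 0.2),
            Segment("S1", "chr1", 500, 2000, 15, 0.6),
        ]
        cn = gene_level_cn(segs, ann)
        assert cn.loc["G", "S1"] == pytest.approx(0.4)

    def test_matches_per_basepair_oracle(self, rng):
        # random gene/segment layouts vs brute-force per-bp averaging
        for trial in range(10):
            bounds = np.sort(rng.choice(np.arange(1, 300), size=5, replace=False))
            bounds = [0, *bounds.tolist(), 300]
            means = rng.normal(0, 1, size=len(bounds) - 1)
            segs = [
                Segment("S1", "chr1", a, b, b - a, float(m))
                for a, b, m in zip(bounds, bounds[1:], means)
            ]
            per_bp = np.repeat(means, np.diff(bounds))
            starts = rng.integers(0, 280, size=4)
            genes = pd.DataFrame(
                {
                    "chrom": "chr1",
                    "start": starts,
                    "end": starts + rng.integers(1, 20, size=4),
                    "gene_id": [f"T{trial}G{i}" for i in range(4)],
                    "is_tf": False,
                }
            ).sort_values("start").reset_index(drop=True)
            genes = genes.drop_duplicates("start")
            cn = gene_level_cn(segs, validate_annotation(genes))
            for row in genes.itertuples(index=False):
                expected = per_bp[row.start : min(row.end, 300)].mean()
                assert cn.loc[row.gene_id, "S1"] == pytest.approx(expected, abs=1e-12)


def region_matrix(n_genes=40, n_samples=100, members=range(10, 15), carriers=range(30), value=0.6):
    values = np.zeros((n_genes, n_samples))
    for g in members:
        for s in carriers:
            values[g, s] = value
    genes = [f"G{i:03d}" for i in range(n_genes)]
    samples = [f"S{j:03d}" for j in range(n_samples)]
    return pd.DataFrame(values, index=genes, columns=samples)


def region_annotation(n_genes=40, tf_rows=()):
    return validate_annotation(
        pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(n_genes) * 1000,
                "end": np.arange(n_genes) * 1000 + 500,
                "gene_id": [f"G{i:03d}" for i in range(n_genes)],
                "is_tf": [i in set(tf_rows) for i in range(n_genes)],
            }
        )
    )


class TestRecurrentRegions:
    def test_recovers_planted_run_with_exact_frequency(self):
        gene_cn = region_matrix()
        ann = region_annotation()
        regions = call_recurrent_regions(gene_cn, ann, n_perm=200, seed=0)
        assert len(regions) == 1
        r = regions[0]
        assert r.direction == "amp"
        assert r.gene_ids == [f"G{i:03d}" for i in range(10, 15)]
        assert r.frequency == pytest.approx(0.30)
        assert r.q_value < 0.25

    def test_frequency_counts_threshold_passers_only(self):
        # 30 strong carriers plus one marginal sample just over the +0.3 cut
        gene_cn = region_matrix()
        gene_cn.iloc[10:15, 30] = 0.31
        ann = region_annotation()
        regions = call_recurrent_regions(gene_cn, ann, n_perm=200, seed=0)
        assert regions[0].frequency == pytest.approx(0.31)

    def test_deletion_direction(self):
        gene_cn = region_matrix(value=-0.7)
        regions = call_recurrent_regions(gene_cn, region_annotation(), n_perm=200, seed=0)
        assert len(regions) == 1
        assert regions[0].direction == "del"

    def test_null_matrix_rarely_yields_regions(self):
        hits = 0
        for s in range(10):
            rng = np.random.default_rng(500 + s)
            gene_cn = pd.DataFrame(
                rng.normal(0, 0.1, size=(30, 40)),
                index=[f"G{i:03d}" for i in range(30)],
                columns=[f"S{j}" for j in range(40)],
            )
            regions = call_recurrent_regions(gene_cn, region_annotation(30), n_perm=200, seed=s)
            hits += bool(regions)
        assert hits <= 1

    def test_all_missing_gene_excluded_with_warning(self):
        gene_cn = region_matrix()
        gene_cn.iloc[0, :] = np.nan
        with pytest.warns(UserWarning, match="excluded"):
            regions = call_recurrent_regions(gene_cn, region_annotation(), n_perm=200, seed=0)
        assert regions


class TestClassifyCnvGenes:
    def test_tf_and_gene_split(self):
        ann = region_annotation(5, tf_rows=[1])
        region = CnvRegion("chr1", 0, 2000, "amp", 0.01, 0.2,
                           gene_ids=["G000", "G001"])
        call = classify_cnv_genes([region], ann)
        assert call.cnv_genes == {"G000", "G001"}
        assert call.cnv_tfs == {"G001"}
        assert call.table.iloc[0]["Amp/Del"] == "Amp"
        assert call.table.iloc[0]["TFs"] == "G001"

    def test_disjoint_regions_union(self):
        ann = region_annotation(10)
        regions = [
            CnvRegion("chr1", 0, 1500, "amp", 0.01, 0.1, gene_ids=["G000", "G001"]),
            CnvRegion("chr1", 5000, 6500, "del", 0.02, 0.1, gene_ids=["G005", "G006"]),
        ]
        call = classify_cnv_genes(regions, ann)
        assert len(call.cnv_genes) == sum(len(r.gene_ids) for r in regions)
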