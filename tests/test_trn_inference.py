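import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from cnvtrn.io_formats import DirectedEdge, ExpressionMatrix
from cnvtrn.trn_inference import (
    JointHistogram,
    NullModel,
    ScoredEdge,
    clr_from_mi,
    clr_scores,
    default_bins,
    discretize_equal_frequency,
    filter_low_variance,
    infer_trn,
    mutual_information,
    retain_edges,
    sample_null_pairs,
)


def mi_double_sum_oracle(counts):
    """Direct double sum of the plug-in MI formula, in nats."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    total = 0.0
    for i in range(counts.shape[0]):
        for j in range(counts.shape[1]):
            pij = counts[i, j] / n
            if pij > 0:
                pi = counts[i, :].sum() / n
                pj = counts[:, j].sum() / n
                total += pij * math.log(pij / (pi * pj))
    return total


class TestVarianceFilter:
    def test_drop_count(self, rng):
        expr = ExpressionMatrix(
            [f"G{i}" for i in range(100)], [f"S{j}" for j in range(10)],
            rng.normal(size=(100, 10)),
        )
        assert filter_low_variance(expr, 0.05).n_genes == 95

    def test_constant_gene_always_dropped(self, rng):
        values = rng.normal(size=(20, 10))
        values[7] = 1.5
        expr = ExpressionMatrix([f"G{i}" for i in range(20)], [f"S{j}" for j in range(10)], values)
        out = filter_low_variance(expr, 0.05)
        assert "G7" not in out.gene_ids

    def test_matches_sort_oracle(self, rng):
        values = rng.normal(size=(50, 8))
        genes = [f"G{i:02d}" for i in range(50)]
        expr = ExpressionMatrix(genes, [f"S{j}" for j in range(8)], values)
        sd = values.std(axis=1, ddof=1)
        n_drop = 5
        expected_drop = set(sorted(range(50), key=lambda i: (sd[i], genes[i]))[:n_drop])
        out = filter_low_variance(expr, 0.1)
        assert set(out.gene_ids) == {g for i, g in enumerate(genes) if i not in expected_drop}

    def test_bad_fraction_rejected(self, small_expression):
        with pytest.raises(ValueError):
            filter_low_variance(small_expression, 1.0)


class TestMutualInformation:
    def test_exact_independence_is_zero(self):
        # joint exactly uniform over 3x3 bins
        counts = np.full((3, 3), 4.0)
        assert JointHistogram(counts).mutual_information() == pytest.approx(0.0, abs=1e-15)

    def test_identity_gives_log_b(self, rng):
        for B in (3, 5, 8):
            x = rng.normal(size=40 * B)
            assert mutual_information(x, x, bins=B) == pytest.approx(np.log(B), abs=1e-12)

    def test_matches_double_sum_oracle(self, rng):
        for _ in range(50):
            B = int(rng.integers(2, 7))
            counts = rng.integers(0, 20, size=(B, B)).astype(float)
            if counts.sum() == 0:
                continue
            mi = JointHistogram(counts).mutual_information()
            assert mi == pytest.approx(mi_double_sum_oracle(counts), abs=1e-12)

    def test_symmetric_and_nonnegative(self, rng):
        x, y = rng.normal(size=(2, 123))
        assert mutual_information(x, y) == pytest.approx(mutual_information(y, x))
        assert mutual_information(x, y) >= 0

    def test_constant_vector_zero(self):
        x = np.ones(60)
        y = np.arange(60.0)
        assert mutual_information(x, y) == 0.0

    def test_default_bins_clamped(self):
        assert default_bins(20) == 3
        assert default_bins(200) == 6
        assert default_bins(10_000) == 10

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        arrays(float, st.integers(15, 60),
               elements=st.floats(-50, 50, allow_nan=False)),
        arrays(float, st.integers(15, 60),
               elements=st.floats(-50, 50, allow_nan=False)),
    )
    def test_mi_properties_hold_on_arbitrary_vectors(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        mi = mutual_information(x, y, bins=3)
        assert 0.0 <= mi <= np.log(3) + 1e-12
        assert mi == pytest.approx(mutual_information(y, x, bins=3), abs=1e-12)

    def test_equal_frequency_codes_balanced(self, rng):
        x = rng.normal(size=120)
        codes = discretize_equal_frequency(x, 6)
        assert np.bincount(codes).tolist() == [20] * 6


class TestClr:
    def test_degenerate_distribution_gives_zero(self):
        pairs = [("TF", f"G{i}") for i in range(5)] + [(f"G{i}", f"H{i}") for i in range(5)]
        with pytest.warns(UserWarning):
            clr = clr_from_mi(pairs, np.full(10, 0.3))
        np.testing.assert_array_equal(clr, np.zeros(10))

    def test_matches_z_score_definition(self):
        # combined score recomputed pair-by-pair from the printed definition:
        # z floored at 0 per endpoint, clr = sqrt(z_src^2 + z_dst^2)
        tf_mis = [0.0, 2.0] * 10
        pairs = [("TF", f"N{i}") for i in range(20)]
        mis = list(tf_mis)
        pairs += [(f"N{i}", f"M{i}") for i in range(20)]
        mis += list(tf_mis)
        clr = clr_from_mi(pairs, np.array(mis))
        mis_arr = np.array(mis)

        def zside(node, k):
            inc = [i for i, p in enumerate(pairs) if node in p]
            sd = mis_arr[inc].std()
            if len(inc) < 2 or sd == 0:
                return 0.0
            return max(0.0, (mis_arr[k] - mis_arr[inc].mean()) / sd)

        for k, (a, b) in enumerate(pairs):
            assert clr[k] == pytest.approx(np.hypot(zside(a, k), zside(b, k)))

    def test_invariant_under_monotone_transform(self, rng):
        genes = [f"G{i}" for i in range(8)]
        samples = [f"S{j}" for j in range(60)]
        values = rng.normal(size=(8, 60))
        pairs = [(genes[i], genes[j], True) for i in range(4) for j in range(4, 8)]
        a = clr_scores(ExpressionMatrix(genes, samples, values), pairs)
        b = clr_scores(ExpressionMatrix(genes, samples, np.exp(values)), pairs)
        np.testing.assert_allclose([e.clr for e in a], [e.clr for e in b], atol=1e-12)


class TestNullPairs:
    def test_exhausted_tf_warns(self):
        prior = [DirectedEdge("TF1", "A"), DirectedEdge("TF1", "B")]
        with pytest.warns(UserWarning, match="TF1"):
            pairs = sample_null_pairs(prior, ["TF1", "A", "B"], m=10)
        assert pairs == []

    def test_deterministic_and_disjoint_from_prior(self, rng):
        genes = [f"G{i}" for i in range(50)]
        for trial in range(10):
            seed = int(rng.integers(0, 10_000))
            prior = [
                DirectedEdge("G0", g) for g in rng.choice(genes[1:], 10, replace=False)
            ]
            p1 = sample_null_pairs(prior, genes, m=20, seed=seed)
            p2 = sample_null_pairs(prior, genes, m=20, seed=seed)
            assert p1 == p2
            prior_set = {(e.source, e.target) for e in prior}
            assert not prior_set & set(p1)
            assert all(tf != g for tf, g in p1)

    def test_global_scope_size(self):
        prior = [DirectedEdge("TF1", "A"), DirectedEdge("TF2", "B")]
        pairs = sample_null_pairs(prior, ["TF1", "TF2", "A", "B", "C"], m=4, scope="global")
        assert len(pairs) == 4


class TestRetention:
    def test_boundary_is_strict(self):
        scored = [ScoredEdge("TF1", "A", 0.0, 0.0, True)]
        nm = {"TF1": NullModel("TF1", np.zeros(100))}
        trn = retain_edges(scored, nm)
        assert trn.edges == []

    def test_missing_null_model_named(self):
        scored = [ScoredEdge("TF9", "A", 0.1, 1.0, True)]
        with pytest.raises(KeyError, match="TF9"):
            retain_edges(scored, {})

    def test_nearest_rank_threshold(self):
        nm = NullModel("t", np.arange(1, 101, dtype=float), percentile=95.0)
        assert nm.threshold == 95.0  # ceil(0.95*100) = 95th order statistic

    def test_retention_monotone_in_clr(self):
        nm = {"TF1": NullModel("TF1", np.linspace(0, 1, 100))}
        low = retain_edges([ScoredEdge("TF1", "A", 0.5, 0.9, True)], nm)
        high = retain_edges([ScoredEdge("TF1", "A", 0.5, 2.0, True)], nm)
        assert low.edge_pairs() <= high.edge_pairs()

    def test_infer_trn_deterministic(self, rng):
        from cnvtrn import synthetic_data as sim

        ann = sim.simulate_annotation(60, 3, seed=1)
        prior = sim.simulate_prior(ann, 5, seed=1)
        expr, _ = sim.simulate_expression(ann, prior, 80, beta=1.5, seed=1)
        r1 = infer_trn(expr, prior, null_size=30, seed=42)
        r2 = infer_trn(expr, prior, null_size=30, seed=42)
        assert r1[0].edge_pairs() == r2[0].edge_pairs()
        assert [e.clr for e in r1[1]] == [e.clr for e in r2[1]]
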