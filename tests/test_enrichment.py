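import numpy as np
import pandas as pd
import pytest

from tigs.enrichment import (
    GsvaParams,
    gsva_scores,
    kernel_cdf_transform,
    mean_signature_score,
    random_control_scores,
    rank_walk_scores,
)
from tigs.io_formats import ExpressionMatrix, GeneSet

from .oracles import gsva_oracle, kernel_cdf_oracle, rank_walk_oracle


class TestKernelCdfTransform:
    def test_constant_gene_gives_half(self, toy_expr):
        t = kernel_cdf_transform(toy_expr)
        np.testing.assert_allclose(t[1], 0.5)  # G2 is constant

    def test_monotone_in_expression(self):
        m = ExpressionMatrix(["G"], ["S1", "S2"], np.array([[0.0, 10.0]]))
        t = kernel_cdf_transform(m)
        assert t[0, 1] > t[0, 0]

    def test_matches_brute_force_double_loop(self, toy_expr):
        np.testing.assert_allclose(
            kernel_cdf_transform(toy_expr),
            kernel_cdf_oracle(toy_expr.values),
            atol=1e-12,
        )

    def test_single_sample_rejected(self):
        m = ExpressionMatrix(["G"], ["S1"], np.array([[1.0]]))
        with pytest.raises(ValueError, match="2 samples"):
            kernel_cdf_transform(m)

    def test_values_are_probabilities(self, random_expr):
        t = kernel_cdf_transform(random_expr(seed=3))
        assert np.all((t > 0) & (t < 1))


class TestRankWalkScores:
    def test_identical_columns_identical_scores(self, five_gene_set, random_expr):
        m = random_expr(n_genes=15, n_samples=1, seed=1)
        twice = ExpressionMatrix(
            m.gene_ids, ["S0", "S1"], np.repeat(m.values, 2, axis=1)
        )
        sm = gsva_scores(twice, [GeneSet("s", ["G1", "G3", "G5"])])
        assert sm.values[0, 0] == sm.values[0, 1]

    def test_top_ranked_set_scores_positive(self):
        # set genes occupy exactly the top-m expression ranks in sample 0
        rng = np.random.default_rng(0)
        values = rng.normal(0, 1, size=(10, 3))
        values[:3, 0] += 100
        m = ExpressionMatrix([f"G{i}" for i in range(10)], ["A", "B", "C"], values)
        sm = gsva_scores(m, [GeneSet("top", ["G0", "G1", "G2"])])
        assert sm.values[0, 0] > 0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_step_by_step_oracle(self, seed, random_expr, five_gene_set):
        m = random_expr(n_genes=20, n_samples=6, seed=seed)
        t = kernel_cdf_transform(m)
        got = rank_walk_scores(t, m.gene_ids, m.sample_ids, [five_gene_set])
        want = rank_walk_oracle(t, m.gene_ids, five_gene_set.genes)
        np.testing.assert_allclose(got.values[0], want, atol=1e-10)

    def test_set_covering_universe_rejected(self, toy_expr):
        t = kernel_cdf_transform(toy_expr)
        with pytest.raises(ValueError, match="gene universe"):
            rank_walk_scores(
                t, toy_expr.gene_ids, toy_expr.sample_ids,
                [GeneSet("all", list(toy_expr.gene_ids))],
            )

    def test_sparse_set_skipped_with_warning(self, toy_expr):
        t = kernel_cdf_transform(toy_expr)
        with pytest.warns(UserWarning, match="skipped"):
            sm = rank_walk_scores(
                t, toy_expr.gene_ids, toy_expr.sample_ids,
                [GeneSet("lonely", ["G1", "ABSENT1", "ABSENT2"])],
            )
        assert sm.set_names == [] and sm.values.shape == (0, 3)


class TestEnrichmentInvariants:
    @pytest.mark.parametrize("seed", range(4))
    def test_scores_bounded_by_one(self, seed, random_expr):
        m = random_expr(n_genes=30, n_samples=8, seed=seed)
        sets = [GeneSet(f"s{k}", [f"G{i}" for i in range(k, k + 6)]) for k in range(4)]
        sm = gsva_scores(m, sets)
        assert np.all(np.abs(sm.values) <= 1.0)

    def test_sample_permutation_equivariance(self, random_expr, five_gene_set):
        m = random_expr(n_genes=20, n_samples=6, seed=9)
        perm = [3, 0, 5, 1, 4, 2]
        mp = ExpressionMatrix(
            m.gene_ids, [m.sample_ids[j] for j in perm], m.values[:, perm]
        )
        a = gsva_scores(m, [five_gene_set]).values[0]
        b = gsva_scores(mp, [five_gene_set]).values[0]
        np.testing.assert_allclose(a[perm], b, atol=1e-12)

    def test_translation_invariance(self, random_expr, five_gene_set):
        m = random_expr(n_genes=20, n_samples=6, seed=11)
        shifted = ExpressionMatrix(m.gene_ids, m.sample_ids, m.values + 17.3)
        a = gsva_scores(m, [five_gene_set]).values
        b = gsva_scores(shifted, [five_gene_set]).values
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestMeanSignatureScore:
    def test_arithmetic_mean(self):
        m = ExpressionMatrix(
            ["CD8A", "CD8B"], ["S1"], np.array([[4.0], [6.0]])
        )
        s = mean_signature_score(m, GeneSet("CD8", ["CD8A", "CD8B"]))
        assert s["S1"] == 5.0

    def test_singleton_equals_gene_row(self, random_expr):
        m = random_expr(seed=2)
        # PD-L1 biomarker convention: the single CD274 gene's expression
        m2 = ExpressionMatrix(["CD274"] + m.gene_ids[1:], m.sample_ids, m.values)
        s = mean_signature_score(m2, GeneSet("PDL1", ["CD274"]))
        np.testing.assert_array_equal(s.values, m2.values[0])

    def test_partial_set_warns_and_uses_present_genes(self):
        m = ExpressionMatrix(["CD8A"], ["S1", "S2"], np.array([[4.0, 8.0]]))
        with pytest.warns(UserWarning, match="absent"):
            s = mean_signature_score(m, GeneSet("CD8", ["CD8A", "CD8B"]))
        np.testing.assert_array_equal(s.values, [4.0, 8.0])

    def test_no_gene_present_is_error(self, toy_expr):
        with pytest.raises(ValueError, match="SIG"):
            mean_signature_score(toy_expr, GeneSet("SIG", ["NOPE"]))


class TestRandomControlScores:
    def test_seeded_reproducibility(self, random_expr):
        m = random_expr(n_genes=40, n_samples=5, seed=4)
        a = random_control_scores(m, n_genes=5, n_repeats=3, seed=42)
        b = random_control_scores(m, n_genes=5, n_repeats=3, seed=42)
        for x, y in zip(a, b):
            pd.testing.assert_series_equal(x, y)
            assert x.attrs["genes"] == y.attrs["genes"]

    def test_single_repeat(self, random_expr):
        out = random_control_scores(random_expr(seed=5), n_genes=4, n_repeats=1, seed=0)
        assert len(out) == 1

    def test_exclusion_is_respected_exhaustively(self, random_expr):
        m = random_expr(n_genes=40, n_samples=5, seed=6)
        excl = GeneSet("apm", [f"G{i}" for i in range(18)])
        out = random_control_scores(
            m, n_genes=10, n_repeats=20, seed=7, exclude=excl
        )
        for s in out:
            assert not set(s.attrs["genes"]) & set(excl.genes)

    def test_insufficient_eligible_genes(self, random_expr):
        m = random_expr(n_genes=10, n_samples=4, seed=8)
        with pytest.raises(ValueError, match="eligible genes"):
            random_control_scores(
                m, n_genes=5, n_repeats=1, seed=0,
                exclude=GeneSet("x", [f"G{i}" for i in range(6)]),
            )


def test_gsva_params_validation():
    with pytest.raises(ValueError, match="tau"):
        GsvaParams(tau=0)
    with pytest.raises(ValueError, match="bandwidth_factor"):
        GsvaParams(bandwidth_factor=-1)
    with pytest.raises(ValueError, match="kernel"):
        GsvaParams(kernel="poisson")


def test_zero_variance_gene_stays_scoreable(five_gene_set):
    values = np.vstack([np.full(6, 3.0), np.random.default_rng(1).normal(size=(19, 6))])
    m = ExpressionMatrix([f"G{i}" for i in range(20)], [f"S{j}" for j in range(6)], values)
    sm = gsva_scores(m, [five_gene_set])
    assert np.all(np.isfinite(sm.values))


def test_full_pipeline_matches_oracle(random_expr, five_gene_set):
    """kernel CDF + rank walk against the fully independent oracle."""
    m = random_expr(n_genes=20, n_samples=6, seed=123)
    got = gsva_scores(m, [five_gene_set]).values[0]
    want = gsva_oracle(m.values, m.gene_ids, five_gene_set.genes)
    np.testing.assert_allclose(got, want, atol=1e-10)
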