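import itertools

import numpy as np
import pandas as pd
import pytest

from circlinc import gsva
from circlinc.types import ExprMatrix, GeneSetCollection, ValidationError

from oracles import es_naive, kcdf_naive


def _expr(mat, genes=None):
    mat = np.asarray(mat, dtype=float)
    genes = genes or [f"G{i}" for i in range(mat.shape[0])]
    samples = [f"s{j}" for j in range(mat.shape[1])]
    return ExprMatrix(
        values=pd.DataFrame(mat, index=genes, columns=samples),
        group=pd.Series(["term"] * len(samples), index=samples),
    )


class TestKcdf:
    def test_two_equal_values_give_half(self):
        with pytest.warns(UserWarning, match="bandwidth floor"):
            z = gsva.kcdf_transform(_expr([[3.0, 3.0]]))
        np.testing.assert_allclose(z.to_numpy(), [[0.5, 0.5]], atol=1e-12)

    def test_widely_separated_pair(self):
        z = gsva.kcdf_transform(_expr([[0.0, 1000.0], [1.0, 2.0]]))
        np.testing.assert_allclose(z.to_numpy()[0], [0.25, 0.75], atol=1e-6)

    def test_strictly_increasing_in_own_value(self):
        base = np.array([[1.0, 2.0, 3.0, 4.0]])
        z0 = gsva.kcdf_transform(_expr(base)).to_numpy()[0, 2]
        bumped = base.copy()
        bumped[0, 2] += 0.25
        z1 = gsva.kcdf_transform(_expr(bumped)).to_numpy()[0, 2]
        assert z1 > z0

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(7, 5))
        z = gsva.kcdf_transform(_expr(x))
        np.testing.assert_allclose(z.to_numpy(), kcdf_naive(x), atol=1e-12)


class TestRankStatistic:
    def test_three_gene_scores(self):
        # z decreasing in gene order -> ranks (1,2,3) -> s = |1.5 - rank|
        z = pd.DataFrame([[0.9], [0.5], [0.1]], index=list("abc"), columns=["s"])
        s, order = gsva.rank_statistic(z)
        np.testing.assert_allclose(s["s"], [0.5, 0.5, 1.5])
        assert order[:, 0].tolist() == [0, 1, 2]

    def test_v_shape_symmetric_about_midrank(self):
        # |p/2 - rank| is V-shaped: extremes get the largest weights, the
        # mid-ranked gene the smallest; top and bottom differ by one rank unit
        z = pd.DataFrame([[0.9], [0.7], [0.3], [0.1]], columns=["s"])
        s, _ = gsva.rank_statistic(z)
        col = s["s"].to_numpy()
        assert col.argmin() in (1, 2)
        assert abs(col[0] - col[3]) == 1.0

    def test_gene_order_permutation_leaves_scores(self):
        rng = np.random.default_rng(1)
        z = pd.DataFrame(rng.uniform(size=(8, 3)),
                         index=[f"g{i}" for i in range(8)])
        s0, _ = gsva.rank_statistic(z)
        perm = rng.permutation(8)
        s1, _ = gsva.rank_statistic(z.iloc[perm])
        pd.testing.assert_frame_equal(s0.iloc[perm], s1)


class TestEnrichmentScore:
    def _setup3(self):
        z = pd.DataFrame([[0.9], [0.5], [0.1]], index=list("abc"), columns=["s"])
        s, order = gsva.rank_statistic(z)
        return s.to_numpy()[:, 0], order[:, 0]

    def test_singleton_top_set_scores_one(self):
        s, order = self._setup3()
        mask = np.array([True, False, False])
        assert gsva.enrichment_score(s, order, mask) == pytest.approx(1.0)

    def test_singleton_bottom_set_scores_minus_one(self):
        s, order = self._setup3()
        mask = np.array([False, False, True])
        assert gsva.enrichment_score(s, order, mask) == pytest.approx(-1.0)

    def test_degenerate_sets_rejected(self):
        s, order = self._setup3()
        with pytest.raises(ValidationError):
            gsva.enrichment_score(s, order, np.ones(3, dtype=bool))
        with pytest.raises(ValidationError):
            gsva.enrichment_score(s, order, np.zeros(3, dtype=bool))

    def test_six_gene_toy_matches_walk_oracle(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=(6, 4))
        expr = _expr(x)
        z = gsva.kcdf_transform(expr)
        s_frame, order = gsva.rank_statistic(z)
        for members in ({0, 2}, {1, 4, 5}):
            mask = np.array([i in members for i in range(6)])
            for j in range(4):
                es = gsva.enrichment_score(
                    s_frame.to_numpy()[:, j], order[:, j], mask
                )
                exp = es_naive(s_frame.to_numpy()[:, j], order[:, j].tolist(), members)
                assert es == pytest.approx(exp, abs=1e-12)

    def test_exhaustive_small_universe_oracle_equivalence(self):
        # all subsets of size <= 4 in universes of size <= 8
        rng = np.random.default_rng(23)
        for p in (5, 8):
            s = np.abs(p / 2.0 - np.arange(1, p + 1))
            order = rng.permutation(p)
            for k in (1, 2, 4):
                for members in itertools.combinations(range(p), k):
                    mask = np.zeros(p, dtype=bool)
                    mask[list(members)] = True
                    es = gsva.enrichment_score(s, order, mask)
                    exp = es_naive(s, order.tolist(), set(members))
                    assert es == pytest.approx(exp, abs=1e-12)


class TestGsvaMatrix:
    def test_bounded_on_random_data(self):
        rng = np.random.default_rng(0)
        for seed in range(20):
            x = np.random.default_rng(seed).normal(size=(40, 6))
            sets = GeneSetCollection(
                sets={
                    f"S{k}": ("", [f"G{i}" for i in rng.choice(40, 8, replace=False)])
                    for k in range(5)
                }
            )
            psm = gsva.gsva_matrix(_expr(x), sets)
            assert (np.abs(psm.scores.to_numpy()) <= 1.0 + 1e-12).all()

    def test_jointly_up_set_scores_higher_in_up_sample(self):
        # 10 genes; set genes coherently elevated in the last sample
        rng = np.random.default_rng(8)
        x = rng.normal(0.0, 0.3, size=(10, 6))
        x[:4, -1] += 3.0
        sets = GeneSetCollection(sets={"UP": ("", [f"G{i}" for i in range(4)])})
        psm = gsva.gsva_matrix(_expr(x), sets)
        row = psm.scores.loc["UP"]
        assert row.iloc[-1] == row.max()

    def test_size_filters_report_skipped(self):
        x = np.random.default_rng(3).normal(size=(10, 4))
        sets = GeneSetCollection(
            sets={"TINY": ("", ["G0"]), "OK": ("", ["G1", "G2", "G3"])}
        )
        psm = gsva.gsva_matrix(_expr(x), sets, min_size=2)
        assert "TINY" in psm.skipped_sets and list(psm.scores.index) == ["OK"]

    def test_all_sets_filtered_rejected(self):
        x = np.random.default_rng(3).normal(size=(10, 4))
        sets = GeneSetCollection(sets={"TINY": ("", ["G0"])})
        with pytest.raises(ValidationError):
            gsva.gsva_matrix(_expr(x), sets, min_size=2)

    def test_gene_and_sample_permutation_invariance(self):
        rng = np.random.default_rng(14)
        x = rng.normal(size=(12, 5))
        expr = _expr(x)
        sets = GeneSetCollection(
            sets={"A": ("", ["G1", "G3", "G7"]), "B": ("", ["G0", "G2", "G9", "G11"])}
        )
        base = gsva.gsva_matrix(expr, sets).scores
        gperm = rng.permutation(12)
        expr_g = ExprMatrix(values=expr.values.iloc[gperm], group=expr.group)
        pd.testing.assert_frame_equal(gsva.gsva_matrix(expr_g, sets).scores, base)
        sperm = ["s3", "s0", "s4", "s2", "s1"]
        expr_s = ExprMatrix(values=expr.values[sperm], group=expr.group[sperm])
        pd.testing.assert_frame_equal(
            gsva.gsva_matrix(expr_s, sets).scores, base[sperm]
        )
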