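import numpy as np
import pandas as pd
import pytest
from scipy import stats

from circlinc import correlate
from circlinc.types import ExprMatrix, RiskScore, ScorePanel, ValidationError

from oracles import pearson_naive


def _score(values, samples):
    panel = ScorePanel(ids=[], direction={}, constant={})
    return RiskScore(score=pd.Series(values, index=samples, dtype=float), panel=panel)


def _features(rows, samples, genes=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    genes = genes or [f"F{i}" for i in range(rows.shape[0])]
    return ExprMatrix(
        values=pd.DataFrame(rows, index=genes, columns=samples),
        group=pd.Series(["term"] * len(samples), index=samples),
    )


SAMPLES5 = ["a", "b", "c", "d", "e"]


class TestPearsonScreen:
    def test_perfect_linearity(self):
        x = np.array([1.0, 2, 3, 4, 5])
        tab, sig = correlate.pearson_screen(
            _score(x, SAMPLES5), _features(2 * x, SAMPLES5)
        )
        assert tab.loc["F0", "r"] == pytest.approx(1.0)
        assert tab.loc["F0", "ci_high"] == pytest.approx(1.0)
        assert "F0" in sig.index

    def test_hand_worked_r(self):
        s = _score([1, 2, 3, 4], list("wxyz"))
        tab, _ = correlate.pearson_screen(s, _features([1, 3, 2, 4], list("wxyz")))
        assert tab.loc["F0", "r"] == pytest.approx(0.8, abs=1e-12)

    def test_matches_brute_force_and_scipy(self):
        rng = np.random.default_rng(2)
        s = rng.normal(size=12)
        feats = rng.normal(size=(6, 12))
        samples = [f"s{j}" for j in range(12)]
        tab, _ = correlate.pearson_screen(_score(s, samples), _features(feats, samples))
        for i in range(6):
            r, p, ci = pearson_naive(feats[i], s)
            assert tab.iloc[i]["r"] == pytest.approx(r, abs=1e-12)
            assert tab.iloc[i]["p"] == pytest.approx(p, abs=1e-12)
            assert tab.iloc[i]["ci_low"] == pytest.approx(ci[0], abs=1e-12)
            assert tab.iloc[i]["ci_high"] == pytest.approx(ci[1], abs=1e-12)
            res = stats.pearsonr(feats[i], s)
            assert tab.iloc[i]["r"] == pytest.approx(res.statistic, abs=1e-12)
            assert tab.iloc[i]["p"] == pytest.approx(res.pvalue, abs=1e-9)

    def test_zero_variance_feature_flagged_not_dropped_silently(self):
        s = _score([1, 2, 3, 4, 5], SAMPLES5)
        feats = _features([[1, 1, 1, 1, 1], [1, 2, 1, 3, 2]], SAMPLES5)
        tab, _ = correlate.pearson_screen(s, feats)
        assert tab.attrs["excluded"] == ["F0"]
        assert list(tab.index) == ["F1"]

    def test_zero_variance_score_rejected(self):
        with pytest.raises(ValidationError):
            correlate.pearson_screen(
                _score([1, 1, 1, 1, 1], SAMPLES5),
                _features([1, 2, 3, 4, 5], SAMPLES5),
            )

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            correlate.pearson_screen(
                _score([1, 2, 3], list("abc")), _features([1, 2, 3], list("abc"))
            )

    def test_affine_score_invariance(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=10)
        feats = rng.normal(size=(4, 10))
        samples = [f"s{j}" for j in range(10)]
        t0, _ = correlate.pearson_screen(_score(s, samples), _features(feats, samples))
        t1, _ = correlate.pearson_screen(
            _score(3.5 * s + 2.0, samples), _features(feats, samples)
        )
        np.testing.assert_allclose(t0["r"], t1["r"], atol=1e-12)
        t2, _ = correlate.pearson_screen(
            _score(-2.0 * s, samples), _features(feats, samples)
        )
        np.testing.assert_allclose(t0["r"], -t2["r"], atol=1e-12)

    def test_fdr_family_is_screened_features_only(self):
        rng = np.random.default_rng(4)
        s = rng.normal(size=10)
        feats = rng.normal(size=(8, 10))
        samples = [f"s{j}" for j in range(10)]
        tab, _ = correlate.pearson_screen(_score(s, samples), _features(feats, samples))
        sub, _ = correlate.pearson_screen(
            _score(s, samples), _features(feats[:3], samples)
        )
        # q-values recomputed over the smaller family differ from slicing
        from circlinc.de import bh_fdr

        np.testing.assert_allclose(sub["fdr"], bh_fdr(sub["p"].to_numpy()), atol=1e-12)


class TestOverlap:
    def _sig(self, signs):
        return pd.DataFrame(
            {"r": [0.5 * s for s in signs.values()]}, index=list(signs)
        )

    def test_sign_concordant_intersection(self):
        a = self._sig({"a": -1, "b": -1, "c": +1})
        b = self._sig({"b": -1, "c": -1, "d": -1})
        out = correlate.overlap_cohorts(a, b)
        assert out.common_features == ["b"]
        assert out.sign == {"b": -1}

    def test_disjoint_sets_empty(self):
        out = correlate.overlap_cohorts(self._sig({"a": 1}), self._sig({"b": 1}))
        assert out.common_features == []

    def test_identical_sets_idempotent(self):
        a = self._sig({"x": -1, "y": 1})
        out = correlate.overlap_cohorts(a, a.copy())
        assert out.common_features == ["x", "y"]


class TestPCA:
    def _expr(self, mat):
        mat = np.asarray(mat, dtype=float)  # features x samples
        samples = [f"s{j}" for j in range(mat.shape[1])]
        return ExprMatrix(
            values=pd.DataFrame(mat, index=[f"F{i}" for i in range(mat.shape[0])],
                                columns=samples),
            group=pd.Series(["term"] * len(samples), index=samples),
        )

    def test_collinear_features_pc1_explains_all(self):
        base = np.array([1.0, 4, 2, 5, 3])
        scores, frac = correlate.pca_features(self._expr([base, 2 * base]))
        assert frac[0] == pytest.approx(1.0)

    def test_isotropic_gaussian_splits_variance(self):
        rng = np.random.default_rng(0)
        scores, frac = correlate.pca_features(self._expr(rng.normal(size=(2, 2000))))
        np.testing.assert_allclose(frac, [0.5, 0.5], atol=0.05)

    def test_matches_closed_form_eigendecomposition(self):
        x = np.array([[1.0, 2, 4, 3], [2.0, 1, 5, 4]])
        scores, frac = correlate.pca_features(self._expr(x))
        cov = np.cov(x)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        np.testing.assert_allclose(frac, evals / evals.sum(), atol=1e-12)
        # unit-norm score columns put coordinates in (-1, 1)
        np.testing.assert_allclose(
            np.linalg.norm(scores.to_numpy(), axis=0), [1.0, 1.0], atol=1e-12
        )

    def test_constant_feature_rejected(self):
        with pytest.raises(ValidationError):
            correlate.pca_features(self._expr([[1, 1, 1, 1], [1, 2, 3, 4]]))
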