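"""Pearson correlation screen against a risk score, and cross-cohort overlap.

The screen correlates one per-sample score with each candidate feature
(lincRNA expression or pathway scores), gates on two-sided p and a BH FDR
computed over the screened family only, and intersects significant features
across cohorts requiring the same correlation sign.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_fdr
from .types import ExprMatrix, OverlapResult, RiskScore, ValidationError


def pearson_screen(
    score: RiskScore,
    features: ExprMatrix,
    p_cut: float = 0.05,
    fdr_cut: float = 0.10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlate the score with every feature row; return (table, significant).

    The table has columns ``r, ci_low, ci_high, p, fdr``; the 95% CI is the
    Fisher-z interval, clamped to +-1 when |r| = 1. Zero-variance features are
    excluded from the tested family and listed in ``table.attrs["excluded"]``.
    """
    s = score.score.loc[features.sample_ids].to_numpy().astype(float)
    n = s.size
    if n < 4:
        raise ValidationError("correlation screen needs at least 4 samples")
    x = features.values.to_numpy().astype(float)

    if np.std(s) == 0:
        raise ValidationError("risk score has zero variance")
    sd_x = x.std(axis=1)
    ok = sd_x > 0
    excluded = list(features.gene_ids[~ok])

    xc = x[ok] - x[ok].mean(axis=1, keepdims=True)
    sc = s - s.mean()
    r = (xc @ sc) / (np.linalg.norm(xc, axis=1) * np.linalg.norm(sc))
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r**2)
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))

    zcrit = stats.norm.ppf(0.975)
    with np.errstate(divide="ignore"):
        z = np.arctanh(r)
    half = zcrit / np.sqrt(n - 3)
    ci_low = np.where(np.abs(r) >= 1.0, r, np.tanh(z - half))
    ci_high = np.where(np.abs(r) >= 1.0, r, np.tanh(z + half))

    table = pd.DataFrame(
        {"r": r, "ci_low": ci_low, "ci_high": ci_high, "p": p, "fdr": bh_fdr(p)},
        index=features.gene_ids[ok],
    )
    table.attrs["excluded"] = excluded
    significant = table[(table["p"] < p_cut) & (table["fdr"] < fdr_cut)].copy()
    return table, significant


def overlap_cohorts(
    a: pd.DataFrame, b: pd.DataFrame, names: tuple[str, str] = ("cohort1", "cohort2")
) -> OverlapResult:
    """Intersect significant features by ID requiring equal correlation sign."""
    common, sign = [], {}
    for g in a.index:
        if g in b.index and np.sign(a.loc[g, "r"]) == np.sign(b.loc[g, "r"]) != 0:
            common.append(g)
            sign[g] = int(np.sign(a.loc[g, "r"]))
    common = sorted(common)
    return OverlapResult(
        common_features=common,
        sign={g: sign[g] for g in common},
        per_cohort={names[0]: sorted(a.index), names[1]: sorted(b.index)},
    )


def pca_features(expr: ExprMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of samples over a small feature panel.

    Columns of the returned score frame are unit-norm principal-component
    coordinates (samples x components), which places them roughly in (-1, 1);
    the second return value is the explained-variance fraction per component.
    """
    x = expr.values.to_numpy().T.astype(float)  # samples x features
    if x.shape[1] < 2 or x.shape[0] < 3:
        raise ValidationError("PCA needs >= 2 features and >= 3 samples")
    if (x.std(axis=0) == 0).any():
        raise ValidationError("constant feature in PCA input")
    xc = x - x.mean(axis=0)
    u, sv, _ = np.linalg.svd(xc, full_matrices=False)
    frac = sv**2 / np.sum(sv**2)
    scores = pd.DataFrame(
        u,
        index=expr.sample_ids,
        columns=[f"PC{i + 1}" for i in range(u.shape[1])],
    )
    return scores, frac
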