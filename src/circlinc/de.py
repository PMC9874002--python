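"""Two-group differential expression with precision weights and a moderated t.

The model is the precision-weighted linear-model / empirical-Bayes approach
standard in bulk RNA-seq: counts are transformed to log2-CPM with a 0.5
offset, a mean-variance trend is fitted to per-gene residual standard
deviations by locally weighted scatterplot smoothing, observation-level
weights are the inverse fourth power of the predicted SD, and per-gene
variances are shrunk toward a scaled-F prior estimated by moment matching on
log-variances. The moderated t is the weighted group contrast divided by the
posterior standard error, referred to a t distribution with prior + residual
degrees of freedom.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

from .types import CASE_LABEL, CountMatrix, ExprMatrix, NormFactors, ValidationError


def _design_masks(group: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    case = (group == CASE_LABEL).to_numpy()
    ctrl = ~case
    if case.sum() < 2 or ctrl.sum() < 2:
        raise ValidationError("each group needs at least two samples")
    return case, ctrl


def voom_weights(
    counts: CountMatrix,
    factors: NormFactors,
    span: float = 0.5,
) -> tuple[ExprMatrix, pd.DataFrame]:
    """log2-CPM (0.5-offset) expression and mean-variance-trend precision weights.

    Returns the expression matrix ``log2((count + 0.5)/(eff_lib + 1) * 1e6)``
    and a gene x sample weight matrix equal to the predicted standard
    deviation (from the lowess trend of sqrt-SD on average log2-count) raised
    to the power -4. A degenerate trend (all residual SDs equal, e.g. zero)
    falls back to uniform weights.
    """
    case, ctrl = _design_masks(counts.group)
    eff = factors.effective_lib_size.loc[counts.sample_ids].to_numpy().astype(float)
    y = np.log2((counts.counts.to_numpy() + 0.5) / (eff + 1.0) * 1e6)

    fitted = np.empty_like(y)
    fitted[:, case] = y[:, case].mean(axis=1, keepdims=True)
    fitted[:, ctrl] = y[:, ctrl].mean(axis=1, keepdims=True)
    df_resid = y.shape[1] - 2
    sigma = np.sqrt(((y - fitted) ** 2).sum(axis=1) / df_resid)

    # mean log2 count per gene, on the count (not CPM) scale
    sx = y.mean(axis=1) + np.mean(np.log2(eff + 1.0)) - np.log2(1e6)
    sy = np.sqrt(sigma)

    expr = ExprMatrix(
        values=pd.DataFrame(y, index=counts.gene_ids, columns=counts.sample_ids),
        group=counts.group.copy(),
    )
    if np.ptp(sy) < 1e-12 or np.ptp(sx) < 1e-12:
        w = np.ones_like(y)
        return expr, pd.DataFrame(w, index=counts.gene_ids, columns=counts.sample_ids)

    trend = lowess(sy, sx, frac=span, it=3, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    # predicted count for every observation, mapped through the trend
    fitted_cpm = 2.0 ** fitted
    fitted_count = np.log2(1e-6 * fitted_cpm * (eff + 1.0))
    pred_sqrt_sd = np.interp(fitted_count, tx, ty)  # flat extrapolation at ends
    pred_sqrt_sd = np.maximum(pred_sqrt_sd, 1e-6)
    w = pred_sqrt_sd ** (-4.0)
    return expr, pd.DataFrame(w, index=counts.gene_ids, columns=counts.sample_ids)


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (y > 0)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-10:
            break
    return float(x)


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-matching fit of a scaled-F prior to observed gene variances.

    Matches mean and variance of log(s2) against the theoretical values for
    ``s2 ~ s2_prior * F(df, df_prior)`` using digamma/trigamma identities.
    Returns ``(s2_prior, df_prior)``; ``df_prior`` is infinite when the spread
    of log-variances is at or below the value implied by finite-df sampling
    alone.
    """
    ok = s2 > 0
    if not ok.any():
        return 1e-8, np.inf
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    if e.size < 2:
        return float(np.exp(emean)), np.inf
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        df_prior = 2.0 * _trigamma_inverse(evar)
        s2_prior = np.exp(
            emean + special.digamma(df_prior / 2.0) - np.log(df_prior / 2.0)
        )
    else:
        df_prior = np.inf
        s2_prior = np.exp(emean)
    return float(s2_prior), float(df_prior)


def moderated_t_test(
    expr: ExprMatrix,
    weights: pd.DataFrame | None = None,
    report_expr: ExprMatrix | None = None,
    prior: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Weighted two-group fit with empirical-Bayes variance moderation.

    Parameters
    ----------
    expr
        Matrix the linear model is fitted on (e.g. the voom-offset log2-CPM).
    weights
        Observation-level precision weights; ``None`` means unit weights.
    report_expr
        Matrix on which per-group means/SDs are reported (defaults to
        ``expr``); the screening convention reports group summaries on the
        log2(cpm+1) scale while testing on the offset scale.
    prior
        Optional fixed ``(s2_prior, df_prior)``; estimated from the data when
        omitted.

    Returns a DataFrame indexed by gene with columns ``mean_term, sd_term,
    mean_sptb, sd_sptb, effect, moderated_t, df_total, p, fdr, direction``.
    The effect is case minus control (sPTB - term), so negative t means
    downregulated in sPTB.
    """
    case, ctrl = _design_masks(expr.group)
    y = expr.values.to_numpy().astype(float)
    w = np.ones_like(y) if weights is None else weights.loc[
        expr.gene_ids, expr.sample_ids
    ].to_numpy().astype(float)
    if (w <= 0).any() or not np.isfinite(w).all():
        raise ValidationError("weights must be finite and positive")

    n = y.shape[1]
    df_resid = n - 2
    sw_case = w[:, case].sum(axis=1)
    sw_ctrl = w[:, ctrl].sum(axis=1)
    mu_case = (w[:, case] * y[:, case]).sum(axis=1) / sw_case
    mu_ctrl = (w[:, ctrl] * y[:, ctrl]).sum(axis=1) / sw_ctrl
    effect = mu_case - mu_ctrl
    v_unscaled = 1.0 / sw_case + 1.0 / sw_ctrl

    fitted = np.empty_like(y)
    fitted[:, case] = mu_case[:, None]
    fitted[:, ctrl] = mu_ctrl[:, None]
    s2 = (w * (y - fitted) ** 2).sum(axis=1) / df_resid

    s2_prior, df_prior = estimate_prior(s2, df_resid) if prior is None else prior
    if np.isinf(df_prior):
        s2_post = np.full_like(s2, s2_prior)
        df_total = np.inf
    else:
        s2_post = (df_prior * s2_prior + df_resid * s2) / (df_prior + df_resid)
        df_total = df_prior + df_resid
    t = effect / np.sqrt(s2_post * v_unscaled)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)

    rep = expr if report_expr is None else report_expr
    ry = rep.values.loc[expr.gene_ids, expr.sample_ids].to_numpy()
    out = pd.DataFrame(
        {
            "mean_term": ry[:, ctrl].mean(axis=1),
            "sd_term": ry[:, ctrl].std(axis=1, ddof=1),
            "mean_sptb": ry[:, case].mean(axis=1),
            "sd_sptb": ry[:, case].std(axis=1, ddof=1),
            "effect": effect,
            "moderated_t": t,
            "df_total": df_total,
            "p": p,
        },
        index=expr.gene_ids,
    )
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    out["direction"] = np.where(t < 0, "down", "up")
    out.attrs["s2_prior"] = s2_prior
    out.attrs["df_prior"] = df_prior
    return out


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any() or not np.isfinite(p).all():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def select_de(
    table: pd.DataFrame, p_cut: float = 0.05, fdr_cut: float = 0.25
) -> pd.DataFrame:
    """Rows with p < p_cut and fdr < fdr_cut; down/up counts in ``.attrs``."""
    sel = table[(table["p"] < p_cut) & (table["fdr"] < fdr_cut)].copy()
    sel.attrs["n_down"] = int((sel["direction"] == "down").sum())
    sel.attrs["n_up"] = int((sel["direction"] == "up").sum())
    return sel
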