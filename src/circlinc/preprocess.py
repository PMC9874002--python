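"""Count-matrix preprocessing: de-duplication, CPM filtering, TMM, log-CPM.

The normalization model is the standard between-sample scaling approach for
bulk RNA-seq: each sample j gets a trimmed-mean-of-M-values (TMM) factor f_j
such that the effective library size is ``lib_size_j * f_j``, and expression
is reported as ``log2(cpm + prior)`` against the effective library size.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import CountMatrix, ExprMatrix, NormFactors, ValidationError


def dedupe_transcripts(raw: CountMatrix) -> CountMatrix:
    """Collapse duplicated gene IDs, keeping the row with the highest total count.

    Ties are broken by first occurrence; row order is otherwise preserved.
    """
    counts = raw.counts
    if not counts.index.duplicated().any():
        return CountMatrix(counts=counts.copy(), group=raw.group.copy())
    totals = counts.sum(axis=1).to_numpy()
    keep = np.zeros(len(counts), dtype=bool)
    best: dict[str, int] = {}  # gene -> positional index of current best row
    for pos, (gene, tot) in enumerate(zip(counts.index, totals)):
        if gene not in best or tot > totals[best[gene]]:
            best[gene] = pos
    keep[list(best.values())] = True
    return CountMatrix(counts=counts.iloc[keep].copy(), group=raw.group.copy())


def filter_low_expression(
    counts: CountMatrix,
    cpm_threshold: float = 0.5,
    min_fraction: float = 0.70,
) -> CountMatrix:
    """Keep genes with cpm > ``cpm_threshold`` in at least ``min_fraction`` of samples.

    CPM uses the pre-filter library sizes; the sample-count threshold is
    ``ceil(min_fraction * n_samples)`` over all samples pooled (both groups).
    """
    lib = counts.lib_size.to_numpy().astype(float)
    if (lib <= 0).any():
        raise ValidationError("library size must be positive for all samples")
    cpm = counts.counts.to_numpy() / lib * 1e6
    n_needed = int(np.ceil(min_fraction * counts.counts.shape[1]))
    keep = (cpm > cpm_threshold).sum(axis=1) >= n_needed
    if not keep.any():
        warnings.warn("expression filter removed all genes", stacklevel=2)
    return CountMatrix(counts=counts.counts.loc[keep].copy(), group=counts.group.copy())


def _quantile_colwise(x: np.ndarray, p: float) -> np.ndarray:
    return np.quantile(x, p, axis=0)


def tmm_factors(
    counts: CountMatrix, trim_M: float = 0.30, trim_A: float = 0.05
) -> NormFactors:
    """Trimmed-mean-of-M-values scaling factors.

    Per sample against a reference sample (the one whose upper-quartile CPM is
    closest to the mean upper-quartile), gene-wise log-ratios M and abundances
    A are computed over genes expressed in both samples, doubly trimmed by the
    ``trim_M`` / ``trim_A`` quantiles, and combined by a precision-weighted
    mean with inverse asymptotic (binomial delta-method) variances as weights.
    Factors are rescaled to geometric mean 1.
    """
    mat = counts.counts.to_numpy().astype(float)
    lib = counts.lib_size.to_numpy().astype(float)
    if mat.shape[1] < 2:
        raise ValidationError("TMM needs at least two samples")
    if (lib <= 0).any():
        raise ValidationError("sample with zero library size")

    uq = _quantile_colwise(mat / lib * 1e6, 0.75)
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    log_factors = np.zeros(mat.shape[1])
    for j in range(mat.shape[1]):
        if j == ref:
            continue
        log_factors[j] = _tmm_pair(
            mat[:, j], mat[:, ref], lib[j], lib[ref], trim_M, trim_A
        )
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(
        factor=pd.Series(factors, index=counts.sample_ids),
        lib_size=counts.lib_size.astype(float),
    )


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_M: float,
    trim_A: float,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    obs, ref = obs[pos], ref[pos]
    if obs.size == 0:
        return 0.0
    p_obs = obs / n_obs
    p_ref = ref / n_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * (np.log2(p_obs) + np.log2(p_ref))
    # delta-method asymptotic variance of M under binomial sampling
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    if np.max(np.abs(M)) < 1e-6:
        return 0.0

    n = M.size
    lo_M = np.floor(n * trim_M) + 1
    hi_M = n + 1 - lo_M
    lo_A = np.floor(n * trim_A) + 1
    hi_A = n + 1 - lo_A
    rM = rankdata(M)
    rA = rankdata(A)
    keep = (rM >= lo_M) & (rM <= hi_M) & (rA >= lo_A) & (rA <= hi_A)
    if not keep.any():
        return 0.0
    w = 1.0 / v[keep]
    f = np.sum(w * M[keep]) / np.sum(w)
    return 0.0 if not np.isfinite(f) else f


def log_cpm(
    counts: CountMatrix, factors: NormFactors, prior: float = 1.0, base: float = 2.0
) -> ExprMatrix:
    """``log_base(cpm + prior)`` against TMM-effective library sizes."""
    eff = factors.effective_lib_size.loc[counts.sample_ids].to_numpy()
    cpm = counts.counts.to_numpy() / eff * 1e6
    vals = np.log(cpm + prior) / np.log(base)
    return ExprMatrix(
        values=pd.DataFrame(vals, index=counts.gene_ids, columns=counts.sample_ids),
        group=counts.group.copy(),
    )
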