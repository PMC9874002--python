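"""End-to-end two-cohort orchestration of the circadian-lincRNA screen.

Each cohort is processed fully independently (its own filter, TMM factors,
precision weights, DE panel, reflection constants) before any cross-cohort
overlap: dedupe -> CPM filter -> TMM -> log-CPM -> precision-weighted
moderated t -> DE selection (p<.05, FDR<.25) -> clock panel & DE lincRNAs ->
clock risk score -> Pearson screen of DE lincRNAs (p<.05, FDR<.10); the two
cohorts' significant lincRNAs are intersected with sign concordance to give
the "common circadian lincRNAs". Those feed a lincRNA-based risk score per
cohort, single-sample pathway scores, pathway-level DE and correlation
screens, and a final cross-cohort pathway overlap.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any

import pandas as pd

from . import correlate, de, gsva, preprocess, risk
from .types import (
    CLOCK_SYMBOLS,
    CountMatrix,
    ExprMatrix,
    GeneSetCollection,
    OverlapResult,
    RiskScore,
    ScorePanel,
)

log = logging.getLogger("circlinc")


@dataclass
class Thresholds:
    de_p: float = 0.05
    de_fdr: float = 0.25
    corr_p: float = 0.05
    corr_fdr: float = 0.10

    def __post_init__(self) -> None:
        for v in (self.de_p, self.de_fdr, self.corr_p, self.corr_fdr):
            if not 0.0 < v < 1.0:
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class CohortResult:
    """All per-cohort artifacts up to the circadian-lincRNA screen."""

    name: str
    counts_filtered: CountMatrix
    expr: ExprMatrix  # log2(cpm+1) on TMM-effective library sizes
    de_table: pd.DataFrame
    de_selected: pd.DataFrame
    clock_de: pd.DataFrame
    linc_de: pd.DataFrame
    clock_panel: ScorePanel | None
    clock_score: RiskScore | None
    linc_corr: pd.DataFrame | None
    linc_sig: pd.DataFrame | None
    status: str = "ok"
    n_genes_raw: int = 0
    n_lincRNAs_detected: int = 0


def _is_lincrna(gene: str, linc_ids: set[str] | None) -> bool:
    return gene in linc_ids if linc_ids is not None else gene.startswith("LINC")


def analyze_cohort(
    raw: CountMatrix,
    name: str = "cohort",
    clock_symbols: tuple[str, ...] = CLOCK_SYMBOLS,
    linc_ids: set[str] | None = None,
    thresholds: Thresholds | None = None,
    reflection_mode: str = "ceil_max",
    cpm_threshold: float = 0.5,
    min_fraction: float = 0.70,
) -> CohortResult:
    """One cohort through the clock-score correlation screen."""
    th = thresholds or Thresholds()
    n_raw = raw.counts.shape[0]
    cm = preprocess.dedupe_transcripts(raw)
    cm = preprocess.filter_low_expression(cm, cpm_threshold, min_fraction)
    log.info("%s: %d/%d genes pass the CPM filter", name, cm.counts.shape[0], n_raw)
    factors = preprocess.tmm_factors(cm)
    expr = preprocess.log_cpm(cm, factors)

    voom_expr, weights = de.voom_weights(cm, factors)
    table = de.moderated_t_test(voom_expr, weights, report_expr=expr)
    selected = de.select_de(table, th.de_p, th.de_fdr)
    log.info(
        "%s: %d DE transcripts (%d down, %d up)",
        name, len(selected), selected.attrs["n_down"], selected.attrs["n_up"],
    )

    clock_de = selected.loc[[g for g in selected.index if g in clock_symbols]]
    linc_mask = [g for g in selected.index if _is_lincrna(g, linc_ids)]
    linc_de = selected.loc[linc_mask]
    n_lincs = sum(_is_lincrna(g, linc_ids) for g in cm.gene_ids)

    res = CohortResult(
        name=name,
        counts_filtered=cm,
        expr=expr,
        de_table=table,
        de_selected=selected,
        clock_de=clock_de,
        linc_de=linc_de,
        clock_panel=None,
        clock_score=None,
        linc_corr=None,
        linc_sig=None,
        n_genes_raw=n_raw,
        n_lincRNAs_detected=n_lincs,
    )
    if clock_de.empty:
        res.status = "empty clock panel"
        log.warning("%s: no DE clock genes; stopping after the DE stage", name)
        return res
    if linc_de.empty:
        res.status = "no DE lincRNAs"
        log.warning("%s: no DE lincRNAs; stopping after the DE stage", name)
        return res

    res.clock_panel = risk.build_panel(clock_de, expr, reflection_mode)
    res.clock_score = risk.compute_risk_score(expr, res.clock_panel)
    linc_expr = ExprMatrix(values=expr.values.loc[linc_de.index], group=expr.group)
    res.linc_corr, res.linc_sig = correlate.pearson_screen(
        res.clock_score, linc_expr, th.corr_p, th.corr_fdr
    )
    log.info(
        "%s: %d/%d DE lincRNAs correlate with the clock score",
        name, len(res.linc_sig), len(linc_de),
    )
    return res


@dataclass
class StudyResult:
    """Everything the two-cohort study produced, plus a JSON-able report."""

    cohorts: dict[str, CohortResult]
    common_lincRNAs: OverlapResult | None = None
    linc_scores: dict[str, RiskScore] = field(default_factory=dict)
    pathway_scores: dict[str, Any] = field(default_factory=dict)
    pathway_de: dict[str, pd.DataFrame] = field(default_factory=dict)
    pathway_corr: dict[str, pd.DataFrame] = field(default_factory=dict)
    pathway_sig: dict[str, pd.DataFrame] = field(default_factory=dict)
    common_pathways: OverlapResult | None = None
    pca_scores: dict[str, pd.DataFrame] = field(default_factory=dict)
    report: dict[str, Any] = field(default_factory=dict)


def run_study(
    cohorts: dict[str, CountMatrix],
    gene_sets: GeneSetCollection | None = None,
    clock_symbols: tuple[str, ...] = CLOCK_SYMBOLS,
    linc_ids: set[str] | None = None,
    thresholds: Thresholds | None = None,
    reflection_mode: str = "ceil_max",
    seed: int | None = None,
    run_pathways: bool = True,
) -> StudyResult:
    """Run the full cross-cohort pipeline; degrades gracefully on empty stages."""
    th = thresholds or Thresholds()
    names = list(cohorts)
    if len(names) != 2:
        raise ValueError("the study design requires exactly two cohorts")
    results = {
        nm: analyze_cohort(
            cohorts[nm], nm, clock_symbols, linc_ids, th, reflection_mode
        )
        for nm in names
    }
    out = StudyResult(cohorts=results)

    a, b = (results[nm] for nm in names)
    if a.status == "ok" and b.status == "ok":
        out.common_lincRNAs = correlate.overlap_cohorts(
            a.linc_sig, b.linc_sig, (names[0], names[1])
        )
        log.info("common circadian lincRNAs: %s", out.common_lincRNAs.common_features)

    common = out.common_lincRNAs.common_features if out.common_lincRNAs else []
    if common and run_pathways and gene_sets is not None:
        for nm in names:
            res = results[nm]
            linc_panel = risk.build_panel(
                res.de_table.loc[common], res.expr, reflection_mode
            )
            out.linc_scores[nm] = risk.compute_risk_score(res.expr, linc_panel)
            psm = gsva.gsva_matrix(res.expr, gene_sets)
            out.pathway_scores[nm] = psm
            ptab = de.moderated_t_test(psm.as_expr())
            out.pathway_de[nm] = ptab
            psel = de.select_de(ptab, th.de_p, th.de_fdr)
            log.info("%s: %d DE pathways", nm, len(psel))
            sel_expr = ExprMatrix(
                values=psm.scores.loc[psel.index], group=psm.group
            )
            if len(psel) and out.linc_scores[nm] is not None:
                ctab, csig = correlate.pearson_screen(
                    out.linc_scores[nm], sel_expr, th.corr_p, th.corr_fdr
                )
            else:
                ctab = csig = pd.DataFrame(columns=["r", "ci_low", "ci_high", "p", "fdr"])
            out.pathway_corr[nm], out.pathway_sig[nm] = ctab, csig
        out.common_pathways = correlate.overlap_cohorts(
            out.pathway_sig[names[0]], out.pathway_sig[names[1]], (names[0], names[1])
        )
    if len(common) >= 2:
        for nm in names:
            panel_expr = ExprMatrix(
                values=results[nm].expr.values.loc[common], group=results[nm].expr.group
            )
            scores, frac = correlate.pca_features(panel_expr)
            scores.attrs["explained_variance_fraction"] = list(frac)
            out.pca_scores[nm] = scores

    out.report = build_report(out, names, th, seed)
    return out


def _overlap_dict(ov: OverlapResult | None) -> dict[str, Any] | None:
    if ov is None:
        return None
    return {
        "common": ov.common_features,
        "sign": {k: int(v) for k, v in ov.sign.items()},
        "n_down": sum(1 for v in ov.sign.values() if v < 0),
        "n_up": sum(1 for v in ov.sign.values() if v > 0),
        "per_cohort": ov.per_cohort,
    }


def build_report(
    res: StudyResult, names: list[str], th: Thresholds, seed: int | None
) -> dict[str, Any]:
    rep: dict[str, Any] = {"cohorts": {}, "seed": seed}
    for nm in names:
        c = res.cohorts[nm]
        rep["cohorts"][nm] = {
            "status": c.status,
            "n_genes_raw": c.n_genes_raw,
            "n_genes_filtered": int(c.counts_filtered.counts.shape[0]),
            "n_lincRNAs_detected": c.n_lincRNAs_detected,
            "n_de": len(c.de_selected),
            "n_de_down": c.de_selected.attrs.get("n_down", 0),
            "n_de_up": c.de_selected.attrs.get("n_up", 0),
            "de_clock_genes": {
                g: c.clock_de.loc[g, "direction"] for g in c.clock_de.index
            },
            "n_de_lincRNAs": len(c.linc_de),
            "n_correlated_lincRNAs": len(c.linc_sig) if c.linc_sig is not None else 0,
            "n_de_pathways": len(de.select_de(res.pathway_de[nm], th.de_p, th.de_fdr))
            if nm in res.pathway_de
            else None,
            "n_correlated_pathways": len(res.pathway_sig[nm])
            if nm in res.pathway_sig
            else None,
        }
    rep["common_circadian_lincRNAs"] = _overlap_dict(res.common_lincRNAs)
    rep["common_pathways"] = _overlap_dict(res.common_pathways)
    rep["thresholds"] = {
        "de_p": th.de_p, "de_fdr": th.de_fdr,
        "corr_p": th.corr_p, "corr_fdr": th.corr_fdr,
    }
    blob = json.dumps(rep, sort_keys=True, default=str).encode()
    rep["provenance"] = {"report_hash": hashlib.sha256(blob).hexdigest()}
    return rep


def report_to_markdown(rep: dict[str, Any]) -> str:
    lines = ["# Study report", ""]
    for nm, c in rep["cohorts"].items():
        lines += [
            f"## {nm}",
            f"- status: {c['status']}",
            f"- genes: {c['n_genes_raw']} raw, {c['n_genes_filtered']} after filter; "
            f"{c['n_lincRNAs_detected']} lincRNAs detected",
            f"- DE transcripts: {c['n_de']} ({c['n_de_down']} down, {c['n_de_up']} up)",
            f"- DE clock genes: {c['de_clock_genes']}",
            f"- DE lincRNAs: {c['n_de_lincRNAs']}; "
            f"score-correlated: {c['n_correlated_lincRNAs']}",
            "",
        ]
    ov = rep.get("common_circadian_lincRNAs")
    lines.append(
        "## Common circadian lincRNAs\n- "
        + (", ".join(ov["common"]) if ov and ov["common"] else "(none)")
    )
    pv = rep.get("common_pathways")
    if pv is not None:
        lines.append(
            f"\n## Common pathways\n- {len(pv['common'])} "
            f"({pv['n_down']} down, {pv['n_up']} up)"
        )
    return "\n".join(lines) + "\n"
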