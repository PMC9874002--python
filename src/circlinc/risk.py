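"""Unweighted composite risk score over a panel of selected transcripts.

Down-in-case ("protective") transcripts contribute ``c - x`` where ``c`` is
an integer reflection constant at least the transcript's observed maximum
expression across all samples of the cohort; up-in-case ("risk") transcripts
contribute ``x`` directly. The score is an unweighted sum, so affine details
of the constants shift every sample equally and leave correlations intact.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .types import ExprMatrix, RiskScore, ScorePanel, ValidationError


def build_panel(
    de: pd.DataFrame,
    expr: ExprMatrix,
    reflection_mode: str = "ceil_max",
) -> ScorePanel:
    """Derive panel directions and reflection constants from a DE subset.

    Direction is protective iff the fitted effect (case minus control) is
    negative. Protective constants are the ceiling of the observed maximum
    expression over all samples (``reflection_mode="ceil_max"``, the default)
    or the exact maximum (``"exact_max"``).
    """
    if reflection_mode not in ("ceil_max", "exact_max"):
        raise ValidationError(f"unknown reflection_mode {reflection_mode!r}")
    missing = [g for g in de.index if g not in expr.gene_ids]
    if missing:
        raise ValidationError(f"panel transcripts missing from expression: {missing}")
    direction: dict[str, str] = {}
    constant: dict[str, float] = {}
    for g in de.index:
        if de.loc[g, "effect"] < 0:
            direction[g] = "protective"
            mx = float(expr.values.loc[g].max())
            constant[g] = float(math.ceil(mx)) if reflection_mode == "ceil_max" else mx
        else:
            direction[g] = "risk"
    return ScorePanel(ids=list(de.index), direction=direction, constant=constant)


def compute_risk_score(expr: ExprMatrix, panel: ScorePanel) -> RiskScore:
    """score(j) = sum_risk x(g,j) + sum_protective (c_g - x(g,j))."""
    missing = [g for g in panel.ids if g not in expr.gene_ids]
    if missing:
        raise ValidationError(f"panel transcripts missing from expression: {missing}")
    total = pd.Series(0.0, index=expr.sample_ids)
    for g in panel.ids:
        x = expr.values.loc[g]
        if panel.direction[g] == "protective":
            c = panel.constant[g]
            if (x > c + 1e-12).any():
                warnings.warn(
                    f"expression of {g} exceeds its reflection constant {c}; "
                    "panel was built on a different population",
                    stacklevel=2,
                )
            total = total + (c - x)
        else:
            total = total + x
    return RiskScore(score=total, panel=panel)


def panel_to_records(panel: ScorePanel) -> list[dict]:
    """JSON-friendly panel description."""
    return [
        {
            "id": g,
            "direction": panel.direction[g],
            "constant": panel.constant.get(g),
        }
        for g in panel.ids
    ]
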