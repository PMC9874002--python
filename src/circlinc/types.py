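"""Core in-memory containers shared across the pipeline.

All matrices are pandas DataFrames with genes (or gene sets) on the rows and
samples on the columns; sample group labels live in a parallel Series indexed
by sample ID with values in ``{"sPTB", "term"}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GROUP_LABELS = ("sPTB", "term")
CASE_LABEL = "sPTB"
CONTROL_LABEL = "term"

#: Core molecular clock transcription-translation feedback loop genes screened
#: for differential expression (the clock panel is always restricted to these).
CLOCK_SYMBOLS = (
    "ARNTL", "ARNTL2", "CLOCK", "CRY1", "CRY2", "NPAS2", "NPAS3",
    "NR1D1", "NR1D2", "PER1", "PER2", "PER3", "RORA", "TIMELESS",
)


class InvalidSpecError(ValueError):
    """A simulation or pipeline specification violates its invariants."""


class ValidationError(ValueError):
    """An input file or in-memory object fails structural validation."""


def _check_group(group: pd.Series) -> pd.Series:
    bad = set(group.unique()) - set(GROUP_LABELS)
    if bad:
        raise ValidationError(
            f"unknown group labels {sorted(bad)!r}; expected {GROUP_LABELS}"
        )
    return group


@dataclass
class CountMatrix:
    """Integer gene x sample read counts plus per-sample group labels.

    ``counts`` rows are gene IDs (not necessarily unique before
    de-duplication), columns are unique sample IDs. ``lib_size`` is always the
    current column sum.
    """

    counts: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValidationError("duplicate sample IDs in count matrix")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("negative counts")
        if not set(self.counts.columns) <= set(self.group.index):
            raise ValidationError("sample metadata missing for some samples")
        self.group = _check_group(self.group.loc[self.counts.columns])

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def lib_size(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, CountMatrix)
            and self.counts.equals(other.counts)
            and self.group.equals(other.group)
        )


@dataclass
class NormFactors:
    """TMM scaling factors, anchored so their geometric mean is 1."""

    factor: pd.Series
    lib_size: pd.Series

    @property
    def effective_lib_size(self) -> pd.Series:
        return self.lib_size * self.factor


@dataclass
class ExprMatrix:
    """Normalized log-scale expression (gene x sample), e.g. log2(cpm+1)."""

    values: pd.DataFrame
    group: pd.Series

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("non-finite expression values")
        self.group = _check_group(self.group.loc[self.values.columns])

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns


@dataclass
class ScorePanel:
    """Transcript panel for the unweighted composite risk score.

    Down-in-case ("protective") transcripts are reflected about an integer
    constant >= their observed maximum expression; up-in-case ("risk")
    transcripts enter the sum directly.
    """

    ids: list[str]
    direction: dict[str, str]  # id -> "protective" | "risk"
    constant: dict[str, float]  # present only for protective ids

    def __post_init__(self) -> None:
        for g in self.ids:
            d = self.direction[g]
            if d not in ("protective", "risk"):
                raise ValidationError(f"bad direction {d!r} for {g}")
            if d == "protective" and g not in self.constant:
                raise ValidationError(f"protective transcript {g} lacks a constant")


@dataclass
class RiskScore:
    """Per-sample unweighted composite score over a ScorePanel."""

    score: pd.Series
    panel: ScorePanel


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT semantics): name -> (description, members)."""

    sets: dict[str, tuple[str, list[str]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} has no members")

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]


@dataclass
class PathwayScoreMatrix:
    """Gene-set x sample single-sample enrichment scores, bounded in [-1, 1]."""

    scores: pd.DataFrame
    group: pd.Series
    skipped_sets: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = self.scores.to_numpy()
        if not np.isfinite(arr).all() or (np.abs(arr) > 1 + 1e-12).any():
            raise ValidationError("pathway scores must be finite and within [-1, 1]")
        self.group = _check_group(self.group.loc[self.scores.columns])

    def as_expr(self) -> ExprMatrix:
        """View the score matrix as an ExprMatrix for downstream reuse."""
        return ExprMatrix(values=self.scores, group=self.group)


@dataclass
class OverlapResult:
    """Features significant in both cohorts with concordant correlation sign."""

    common_features: list[str]
    sign: dict[str, int]  # feature -> shared sign (+1 / -1)
    per_cohort: dict[str, list[str]]  # cohort name -> its significant features
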