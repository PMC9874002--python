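"""Two-cohort synthetic count studies with planted, recoverable structure.

The generative model mirrors what the analysis assumes about bulk placental
RNA-seq: negative-binomial counts around per-gene expected fractions of a
variable library size, heavy-tailed (log-normal) baseline abundances, a
case/control log2 fold-change on planted genes, and one shared Gaussian
latent factor on the log-mean scale that loads on the planted lincRNAs and
the down-regulated clock genes alike. Because the clock risk score reflects
down genes about a constant, that same-sign loading makes the planted
lincRNAs negatively correlated with the score, which is the structure the
screen is supposed to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import CLOCK_SYMBOLS, CountMatrix, GeneSetCollection, InvalidSpecError


@dataclass
class CohortSpec:
    """Shape and noise parameters of one simulated cohort.

    Library sizes are log-normal with mean ``lib_size_mean`` reads and
    coefficient of variation ``lib_size_cv``; ``nb_dispersion`` is the
    negative-binomial dispersion (variance = mu + dispersion * mu^2).
    ``baseline_meanlog``/``baseline_sdlog`` set the log-normal distribution
    of relative gene abundances; clock genes and lincRNAs are drawn with a
    narrower spread (and lincRNAs one natural-log unit lower) so the planted
    panel sits in the detectable mid-range, as the real panels do.
    """

    n_case: int = 16
    n_control: int = 16
    n_genes: int = 2000
    n_lincRNAs: int = 100
    clock_symbols: tuple[str, ...] = CLOCK_SYMBOLS
    lib_size_mean: float = 2e7
    lib_size_cv: float = 0.25
    nb_dispersion: float = 0.1
    baseline_meanlog: float = 3.0
    baseline_sdlog: float = 2.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_case < 2 or self.n_control < 2:
            raise InvalidSpecError("each group needs at least 2 samples")
        if self.n_genes < self.n_lincRNAs + len(self.clock_symbols):
            raise InvalidSpecError("n_genes too small for lincRNAs + clock panel")
        if self.nb_dispersion <= 0:
            raise InvalidSpecError("nb_dispersion must be > 0")
        if self.lib_size_mean <= 0 or self.lib_size_cv < 0:
            raise InvalidSpecError("library-size parameters must be positive")


@dataclass
class PlantedTruth:
    """Ground-truth labels planted into a synthetic cohort."""

    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> log2 FC
    planted_circadian_lincRNAs: set[str] = field(default_factory=set)
    clock_effect_directions: dict[str, str] = field(default_factory=dict)
    correlation_strength: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.correlation_strength <= 1.0:
            raise InvalidSpecError("correlation_strength must lie in [0, 1]")
        for g in self.planted_circadian_lincRNAs:
            if self.de_genes.get(g, 0.0) >= 0:
                raise InvalidSpecError(
                    f"planted lincRNA {g} must have negative log2 fold-change"
                )
        for g, d in self.clock_effect_directions.items():
            if d not in ("up", "down"):
                raise InvalidSpecError(f"clock direction for {g} must be up/down")


def default_truth(
    lfc: float = 1.0,
    correlation_strength: float = 0.7,
    n_background: int = 300,
) -> PlantedTruth:
    """Planted structure emulating the discovered pattern: five clock genes and
    five lincRNAs down in cases, tied together by one latent factor.

    ``n_background`` filler genes additionally carry case/control fold-changes
    (alternating sign, magnitudes cycling through 0.6-1.5 log2 units); the
    screened cohorts had on the order of 15% of transcripts differentially
    expressed, and the BH FDR gate only behaves realistically when the
    simulated transcriptome carries a comparable signal fraction.
    """
    clock_down = ("NPAS2", "NR1D1", "NR1D2", "PER3", "RORA")
    lincs = {f"LINC{i:05d}" for i in range(1, 6)}
    de = {g: -abs(lfc) for g in clock_down}
    de.update({g: -abs(lfc) for g in lincs})
    mags = (0.6, 0.8, 1.0, 1.25, 1.5)
    for i in range(n_background):
        de[f"GENE{i + 1:05d}"] = (1 if i % 2 else -1) * mags[i % len(mags)]
    return PlantedTruth(
        de_genes=de,
        planted_circadian_lincRNAs=lincs,
        clock_effect_directions={g: "down" for g in clock_down},
        correlation_strength=correlation_strength,
    )


def null_truth() -> PlantedTruth:
    return PlantedTruth()


def gene_universe(spec: CohortSpec) -> list[str]:
    """Deterministic gene universe: clock symbols, lincRNAs, filler genes."""
    n_fill = spec.n_genes - spec.n_lincRNAs - len(spec.clock_symbols)
    lincs = [f"LINC{i:05d}" for i in range(1, spec.n_lincRNAs + 1)]
    fill = [f"GENE{i:05d}" for i in range(1, n_fill + 1)]
    return list(spec.clock_symbols) + lincs + fill


def generate_cohort(
    spec: CohortSpec, truth: PlantedTruth
) -> tuple[CountMatrix, PlantedTruth]:
    """Draw one cohort's integer count matrix under the planted truth.

    Deterministic for a fixed (spec, truth): the same seed yields an
    identical matrix.
    """
    genes = gene_universe(spec)
    gene_set = set(genes)
    unknown = set(truth.de_genes) - gene_set
    if unknown:
        raise InvalidSpecError(f"planted genes outside the universe: {sorted(unknown)}")
    if not truth.planted_circadian_lincRNAs <= gene_set:
        raise InvalidSpecError("planted lincRNAs outside the universe")

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    n = spec.n_control + spec.n_case
    is_case = np.r_[np.zeros(spec.n_control, bool), np.ones(spec.n_case, bool)]
    sample_ids = [f"T{i + 1:02d}" for i in range(spec.n_control)] + [
        f"P{i + 1:02d}" for i in range(spec.n_case)
    ]
    group = pd.Series(np.where(is_case, "sPTB", "term"), index=sample_ids)

    # baseline relative abundances: heavy-tailed for filler genes, narrower
    # for the clock/lincRNA panel so it stays in the detectable mid-range
    w = np.empty(len(genes))
    is_clock = np.array([g in spec.clock_symbols for g in genes])
    is_linc = np.array([g.startswith("LINC") for g in genes])
    w[is_clock] = rng.lognormal(spec.baseline_meanlog, 1.0, is_clock.sum())
    w[is_linc] = rng.lognormal(spec.baseline_meanlog - 1.0, 1.0, is_linc.sum())
    rest = ~(is_clock | is_linc)
    w[rest] = rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, rest.sum())
    q = w / w.sum()

    if spec.lib_size_cv > 0:
        sig2 = np.log1p(spec.lib_size_cv**2)
        lib = rng.lognormal(np.log(spec.lib_size_mean) - sig2 / 2.0, np.sqrt(sig2), n)
    else:
        lib = np.full(n, spec.lib_size_mean)

    lfc = np.array([truth.de_genes.get(g, 0.0) for g in genes])
    loading = np.zeros(len(genes))
    carriers = set(truth.planted_circadian_lincRNAs) | {
        g for g, d in truth.clock_effect_directions.items() if d == "down"
    }
    loading[[i for i, g in enumerate(genes) if g in carriers]] = (
        truth.correlation_strength
    )
    # latent factor inducing score-lincRNA correlation; centered within each
    # group so it is orthogonal to the planted fold-changes (the group-mean
    # contrast stays exactly lfc, the factor only adds within-group co-variation)
    factor = rng.normal(0.0, 1.0, n)
    factor[is_case] -= factor[is_case].mean()
    factor[~is_case] -= factor[~is_case].mean()

    log2_shift = lfc[:, None] * is_case[None, :] + loading[:, None] * factor[None, :]
    mu = q[:, None] * lib[None, :] * 2.0**log2_shift
    r = 1.0 / spec.nb_dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids), group=group
    )
    return cm, truth


def factor_carriers(truth: PlantedTruth) -> set[str]:
    """Genes carrying the planted latent factor."""
    return set(truth.planted_circadian_lincRNAs) | {
        g for g, d in truth.clock_effect_directions.items() if d == "down"
    }


def generate_gene_sets(
    universe: list[str],
    truth: PlantedTruth,
    n_sets: int = 50,
    set_size_range: tuple[int, int] = (8, 15),
    n_enriched: int = 5,
    seed: int = 0,
    enriched_fraction: float = 0.7,
) -> GeneSetCollection:
    """Random gene sets, ``n_enriched`` of them seeded with latent-factor genes.

    Enriched sets draw ``enriched_fraction`` of their members (capped by the
    number of factor carriers) from the planted-factor genes so their pathway
    scores co-move with the lincRNA-based risk score; remaining sets are
    uniform draws from the universe.
    """
    if n_enriched > n_sets:
        raise InvalidSpecError("n_enriched cannot exceed n_sets")
    lo, hi = set_size_range
    if lo < 1 or hi < lo or hi > len(universe):
        raise InvalidSpecError("invalid set_size_range")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    carriers = sorted(factor_carriers(truth) & set(universe))
    others = [g for g in universe if g not in set(carriers)]

    sets: dict[str, tuple[str, list[str]]] = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        name = f"PATHWAY_{i + 1:03d}"
        if i < n_enriched:
            if not carriers:
                raise InvalidSpecError("no factor-carrying genes to enrich sets with")
            k = min(len(carriers), max(2, round(enriched_fraction * size)), size)
            core = list(rng.choice(carriers, size=k, replace=False))
            fill = list(rng.choice(others, size=size - k, replace=False))
            members = core + fill
            desc = "planted_enriched"
        else:
            members = list(rng.choice(universe, size=size, replace=False))
            desc = "random"
        sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


@dataclass
class StudyData:
    """A complete simulated two-cohort study plus its ground truth."""

    cohorts: dict[str, CountMatrix]
    truth: PlantedTruth
    gene_sets: GeneSetCollection


def simulate_study(
    seed: int = 0,
    truth: PlantedTruth | None = None,
    spec1: CohortSpec | None = None,
    spec2: CohortSpec | None = None,
    n_sets: int = 50,
    n_enriched: int = 5,
) -> StudyData:
    """Two independent cohorts sharing one planted truth, plus gene sets.

    Cohort shapes default to the two study designs the pipeline targets:
    10 term + 20 sPTB, and 16 + 16. All randomness derives from ``seed`` via
    spawned child streams, one per cohort and one for the gene sets.
    """
    ss = np.random.SeedSequence(seed)
    s1, s2, s3 = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    truth = default_truth() if truth is None else truth
    spec1 = spec1 or CohortSpec(n_case=20, n_control=10)
    spec2 = spec2 or CohortSpec(n_case=16, n_control=16)
    cm1, _ = generate_cohort(replace(spec1, seed=s1), truth)
    cm2, _ = generate_cohort(replace(spec2, seed=s2), truth)
    universe = gene_universe(spec1)
    if not factor_carriers(truth):
        n_enriched = 0
    sets = generate_gene_sets(
        universe, truth, n_sets=n_sets, n_enriched=n_enriched, seed=s3
    )
    return StudyData(cohorts={"cohort1": cm1, "cohort2": cm2}, truth=truth, gene_sets=sets)
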