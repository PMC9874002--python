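# Methods

`circlinc` implements a two-cohort screen for "circadian lincRNAs" in
placental bulk RNA-seq: long intergenic non-coding RNAs that are both
differentially expressed between spontaneous preterm (sPTB) and term
deliveries and correlated with the joint behaviour of the core molecular
clock genes, replicated across two independent cohorts. This note records
the statistical model at each stage, the synthetic data the package tests
itself against, and the design choices made where more than one reasonable
convention exists.

## Pipeline overview

Each cohort is processed fully independently — its own expression filter,
normalization factors, DE panel and score constants — before any
cross-cohort step:

1. de-duplicate transcript IDs (keep the row with the highest total count);
2. keep genes with CPM > 0.5 in ≥ 70% of samples (both groups pooled);
3. TMM scaling factors; expression as log2(cpm + 1) on effective library sizes;
4. precision-weighted moderated-t DE screen, gated at p < .05 and BH FDR < .25;
5. DE clock genes (within a fixed 14-symbol panel: ARNTL, ARNTL2, CLOCK,
   CRY1, CRY2, NPAS2, NPAS3, NR1D1, NR1D2, PER1, PER2, PER3, RORA, TIMELESS)
   form an unweighted composite risk score;
6. Pearson correlation of that score against the cohort's DE lincRNAs,
   gated at p < .05 and BH FDR < .10 over the screened family only;
7. significant lincRNAs are intersected across cohorts requiring the same
   correlation sign — the common circadian lincRNAs;
8. those lincRNAs form a second risk score; single-sample pathway scores
   are computed for a gene-set collection, screened for DE (p < .05,
   FDR < .25), correlated with the lincRNA score (p < .05, FDR < .10), and
   intersected across cohorts the same way;
9. a centered PCA of the common lincRNAs summarizes per-sample variation.

## Differential expression

Counts are transformed to `log2((count + 0.5) / (eff_lib + 1) * 1e6)`.
Per-gene residual SDs from the two-group fit are square-rooted and smoothed
against average log2-count by lowess (span 0.5, 3 robustness iterations);
each observation's fitted count is mapped through the trend and the weight
is the predicted SD to the power −4. A degenerate trend (all residual SDs
equal, e.g. an all-constant matrix) falls back to uniform weights so the fit
reduces to ordinary least squares.

The moderated t shrinks per-gene variances toward a scaled-F prior fitted by
moment matching on log-variances (digamma/trigamma identities; the trigamma
inverse by Newton iteration). When the spread of log-variances is at or
below what finite-df sampling alone implies, the prior df is infinite and
the statistic becomes normal-referenced. The group effect is coded
sPTB − term, so a negative t means down in sPTB. Group means/SDs are
reported on the log2(cpm+1) scale while the test runs on the offset scale;
both matrices are kept.

During development the whole stack was cross-checked against the reference
R toolchain on a 2,000-gene cohort: TMM factors agreed to 5e-15, precision
weights to ~3e-4 (different lowess implementations), moderated t to ~2e-4.
A 20×4 TMM fixture frozen from that reference (12 decimals) lives in the
test suite next to plain brute-force oracles for every statistic.

## Risk scores

The composite score is an unweighted sum over the selected panel. A
down-in-case ("protective") transcript contributes `c − x` with `c` the
ceiling of its observed maximum expression across all samples of that
cohort; an up-in-case transcript contributes `x` directly. Published panels
of this kind print integer constants, and the ceiling convention reproduces
them; an `exact_max` mode is available, and the two differ only by a
per-sample constant, so all downstream correlations are identical.
Constants are dataset-specific by construction. If a score is applied to a
population other than the one the panel was built on, expression may exceed
a constant; that is warned about but still scored, since the score stays
affine.

## Correlation screen

Pearson r by the product-moment formula; two-sided p from
`t = r sqrt(n−2)/sqrt(1−r²)`; 95% CI by Fisher z ± z₀.₉₇₅/√(n−3), clamped to
±1 when |r| = 1. BH q-values are computed over the screened family only —
the DE lincRNAs (or the DE pathways) entering that screen, not the whole
transcriptome — matching the pipeline's order of operations. Zero-variance
features are excluded from the family and reported, never silently dropped.
The cross-cohort overlap requires equal correlation sign; output order is
lexicographic for determinism.

## Single-sample pathway scores

The per-sample gene-set score is a kernel-CDF / rank / random-walk
statistic:

- activation: `z(g,j) = mean_k Φ((x(g,j) − x(g,k)) / h_g)` with a Gaussian
  kernel and bandwidth `h_g = SD_g / 4` (sample SD; floor 1e-8 for constant
  genes, which then score 0.5 everywhere and are flagged);
- per sample, genes are ranked by decreasing activation (stable ties) and
  weighted by the symmetric statistic `s = |p/2 − rank|`, which emphasizes
  genes at either extreme of the sample's profile;
- a walk down the ranked list adds `s^τ` (τ = 1) normalized by the set's
  total for member genes and subtracts `1/(p − m)` otherwise; the score is
  the maximum positive deviation plus the minimum negative deviation
  (max-diff form), bounded in [−1, 1].

Degenerate conventions: a set whose members all carry zero rank weight (a
singleton at exactly the middle rank, even p) uses uniform inside steps;
sets covering none or all of the universe are rejected; sets outside the
size window (default 2–500 after intersection with the expression universe)
are reported as skipped rather than scored. Pathway-level DE reuses the
moderated t with unit weights — scores are not counts, so no mean-variance
trend is fitted.

## Synthetic data

The generator emulates what the analysis assumes about the real cohorts:

- two independent cohorts shaped like the target studies (10 term + 20 sPTB;
  16 + 16), negative-binomial counts (`var = μ + φμ²`, φ = 0.1 by default)
  around per-gene fractions of a log-normal library size (mean 2e7 reads,
  CV 0.25);
- heavy-tailed log-normal baseline abundances (sdlog 2.2) for filler genes,
  so the CPM filter removes a realistic low tail; clock genes and lincRNAs
  are drawn with a narrower spread (sdlog 1.0; lincRNAs one natural-log unit
  lower), keeping the planted panel in the detectable mid-range where the
  real panels sit;
- planted effects: five clock genes and five lincRNAs at log2 FC = −1 in
  sPTB, plus ~300 background DE filler genes (alternating sign, magnitudes
  0.6–1.5). The background matters: the target studies report on the order
  of 15% of transcripts DE, and the BH gate at FDR < .25 only behaves the
  way it does there when the simulated transcriptome carries a comparable
  signal fraction;
- one standard-normal latent factor per cohort loads (coefficient =
  `correlation_strength`, default 0.7, log2 scale) on the planted lincRNAs
  and the down-regulated clock genes alike. Because the clock score reflects
  down genes about a constant, this same-sign loading makes the lincRNAs
  negatively correlated with the score. The factor is centered within each
  group so it is orthogonal to the planted fold-changes — it contributes
  pure within-group co-variation, and the truth labels mean exactly what
  they say;
- gene sets: uniform draws from the universe, except `n_enriched` sets that
  take ~70% of their members from the ten factor-carrying genes. Default
  set sizes are 8–15 so that "predominantly factor-carrying" is achievable
  against a 10-gene planted module in a 2,000-gene universe (a deliberately
  scaled-down transcriptome).

All randomness flows from one seed through spawned child streams (one per
cohort, one for gene sets), so a study is a pure function of its seed.

What the generator does **not** emulate: villous vs decidual sampling
heterogeneity, gestational-age or demographic covariates, batch structure,
gene-length or GC effects, correlated null genes, and the annotation
ambiguity of real lincRNA catalogues. Passing recovery tests therefore shows
the screen recovers its own planted structure under idealized independence
assumptions — not that the biological findings replicate.

## Calibration and recovery (what the analysis scripts measure)

- Null type-I rate: on 100 effect-free 16+16 cohorts (2,000 genes), the DE
  screen's p < .05 rate is ≈ 0.0487 against a 3-binomial-SD band of
  0.0485–0.0515 (195k tests). The slight conservativeness is a property of
  the precision-weighted moderated t on NB data, not of this
  implementation, which matches the reference toolchain to ~2e-4.
- Null cross-cohort overlap: over 50 paired null cohorts, the mean number of
  "common circadian lincRNAs" is 0.0 — the replication requirement is a
  strong false-positive guard.
- Recovery: over 50 paired 16+16 cohorts with the default planted truth,
  the screen returns exactly the five planted lincRNAs in ≈ 96% of studies,
  with every reported correlation negative (mean r ≈ −0.85); all five
  factor-seeded gene sets survive the pathway overlap in ≈ 92% of 25
  studies (≈ 98% per set).

Problem sizes (2,000 genes, 50 gene sets, 50–100 seeds) were chosen as the
smallest at which the filter, the FDR gates and the overlap all operate
non-trivially.

## Known limitations

- The voom-style transform is applied to TMM-scaled counts reconstructed
  from the filtered matrix; pipelines that log-transform before weighting
  would differ slightly.
- The log base for log(cpm+1) is 2 (configurable); printed tables from
  comparable studies are consistent with either base.
- De-duplication keeps the highest row total; "highest mean" or per-sample
  maxima are defensible alternatives and can change the kept row for
  unequal library sizes.
- The Pearson CI uses the large-sample Fisher approximation; at n ≤ 10 the
  interval is rough.
- Pathway scores are treated as approximately normal in the moderated t;
  they are bounded statistics, so extreme-tail p-values at the pathway
  level are approximate.
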