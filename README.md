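# circlinc

Cross-cohort discovery of clock-gene-correlated placental lincRNAs — and the
pathways that track them — from bulk RNA-seq read counts.

## The problem

Spontaneous preterm birth (sPTB) has been linked to deregulation of the
placental molecular clock. One way to look for non-coding players in that
process is a replication-first screen over two independent case/control
cohorts of placental RNA-seq: in each cohort, find the differentially
expressed (DE) core clock genes, combine them into one composite "risk
score" per sample, find the DE long intergenic non-coding RNAs (lincRNAs)
whose expression tracks that score, and keep only the lincRNAs that pass in
**both** cohorts with the same correlation sign. The same machinery then
runs at the pathway level on single-sample gene-set variation scores.

`circlinc` implements that screen as a tested library plus analysis
drivers, along with a synthetic two-cohort generator that plants the exact
structure the screen is supposed to recover — so every stage can be
validated end to end without any data download.

## The statistics inside

- **Normalization**: CPM filter (cpm > 0.5 in ≥ 70% of samples), trimmed
  mean of M-values (TMM) scaling factors, expression as log2(cpm + 1).
- **DE screen**: precision weights from a lowess mean-variance trend
  (weight = predicted SD⁻⁴ on log2-CPM with a 0.5 offset) and an
  empirical-Bayes moderated t: s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d), with the
  scaled-F prior (s₀², d₀) fitted by moment matching on log-variances.
  Gates: p < .05, Benjamini–Hochberg FDR < .25.
- **Risk score**: unweighted sum over the DE clock panel; a down-in-case
  transcript enters as (c − x) with c the integer ceiling of its observed
  maximum, an up-in-case transcript as x.
- **Correlation screen**: Pearson r, two-sided p, Fisher-z 95% CI, BH FDR
  over the screened family only. Gates: p < .05, FDR < .10. Cross-cohort
  overlap requires sign concordance.
- **Pathway scores**: Gaussian kernel-CDF per gene (bandwidth SD/4),
  symmetric rank statistic |p/2 − rank|, weighted Kolmogorov-style random
  walk, max-diff enrichment score bounded in [−1, 1].

See `docs/methods.md` for every convention and the generator's model.

## Worked example

```bash
python analysis/01_simulate_study.py
python analysis/02_run_screen.py
```

prints

```
cohort1: 2000 genes x 30 samples (20 sPTB / 10 term)
cohort2: 2000 genes x 32 samples (16 sPTB / 16 term)
planted lincRNAs: ['LINC00001', 'LINC00002', 'LINC00003', 'LINC00004', 'LINC00005']
...
common circadian lincRNAs: ['LINC00001', 'LINC00002', 'LINC00003', 'LINC00004', 'LINC00005']
planted set:               ['LINC00001', 'LINC00002', 'LINC00003', 'LINC00004', 'LINC00005']
planted structure recovered
common pathways: 6 (6 down, 0 up)
```

i.e. the two simulated cohorts (negative-binomial counts, five clock genes
and five lincRNAs planted down in sPTB, tied by one latent factor) go
through the full screen and the cross-cohort overlap returns exactly the
planted lincRNA set; the six common pathways include all five gene sets that
were seeded with factor-carrying genes. `analysis/03_null_calibration.py`
and `analysis/04_recovery_benchmark.py` quantify the same behaviour over
many seeds (type-I rate ≈ 5%, zero chance overlaps under the null, ≈ 96%
exact recovery). All tables land under `results/`.

The same pipeline runs from the shell on any pair of count matrices:

```bash
circlinc simulate --seed 0 --outdir study      # or bring your own TSVs
circlinc run config.yaml                       # counts + metadata + GMT per cohort
```

Equivalently in Python:

```python
import circlinc as cl
study = cl.simulate_study(seed=0)
result = cl.run_study(study.cohorts, study.gene_sets)
print(result.report["common_circadian_lincRNAs"]["common"])
```

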